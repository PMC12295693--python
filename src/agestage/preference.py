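"""Host-preference choice assays: oviposition and larval feeding.

An assay is a replicate × host-option count table — eggs deposited per
maize cultivar in a cage assay, or larvae settled per leaf-disk option at
the 24 h census.  The attachment (or selection) rate of option *i* within
a replicate is ``100 * count_i / sum(counts)``, so rates sum to 100 per
replicate and are invariant to the replicate's total.

Rates are compared with one-way ANOVA on arcsine-square-root transformed
proportions, followed by Duncan's multiple range test, mirroring the
standard analysis of such assays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import SchemaError
from .inference import AnovaResult, anova_oneway, arcsine_sqrt, duncan_mrt

__all__ = ["PreferenceAssay", "read_assay", "attachment_rates", "preference_anova"]


@dataclass(frozen=True)
class PreferenceAssay:
    """Replicate × option count table for one choice experiment."""

    options: tuple[str, ...]
    replicates: np.ndarray  # shape (n_replicates, n_options), non-negative ints
    assay_kind: str = "oviposition"  # or "feeding"
    label: str = ""

    def __post_init__(self):
        counts = np.asarray(self.replicates)
        object.__setattr__(self, "replicates", counts)
        if len(set(self.options)) != len(self.options):
            raise SchemaError("option labels must be unique")
        if counts.ndim != 2 or counts.shape[1] != len(self.options):
            raise SchemaError("replicates must be a (replicate, option) matrix")
        if counts.shape[0] < 1:
            raise SchemaError("need at least one replicate")
        if (counts < 0).any():
            raise SchemaError("counts must be non-negative")

    @property
    def n_replicates(self) -> int:
        return self.replicates.shape[0]


def read_assay(path, assay_kind: str = "oviposition", label: str = "") -> PreferenceAssay:
    """Read an assay from a ``replicate, option, count`` CSV."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as e:
        raise SchemaError(f"unreadable assay CSV: {e}") from e
    missing = {"replicate", "option", "count"} - set(df.columns)
    if missing:
        raise SchemaError(f"missing columns: {sorted(missing)}")
    table = df.pivot_table(index="replicate", columns="option", values="count", aggfunc="sum")
    if table.isna().any().any():
        raise SchemaError("every replicate must report every option")
    options = tuple(str(o) for o in table.columns)
    return PreferenceAssay(
        options=options, replicates=table.to_numpy(dtype=np.int64), assay_kind=assay_kind, label=label
    )


@dataclass(frozen=True)
class RateTable:
    options: tuple[str, ...]
    per_replicate: np.ndarray  # percent, shape (n_kept_replicates, n_options)
    mean: np.ndarray
    se: np.ndarray
    n_excluded: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"option": self.options, "mean_rate_pct": self.mean, "se": self.se}
        )


def attachment_rates(assay: PreferenceAssay) -> RateTable:
    """Per-replicate percentage rates per option, with mean ± SE over replicates.

    All-zero replicates carry no preference information and are excluded
    with a warning.
    """
    counts = assay.replicates.astype(float)
    totals = counts.sum(axis=1)
    keep = totals > 0
    n_excluded = int((~keep).sum())
    if n_excluded:
        warnings.warn(f"excluded {n_excluded} all-zero replicate(s)", stacklevel=2)
    if not keep.any():
        raise SchemaError("no replicate has a positive total count")
    rates = 100.0 * counts[keep] / totals[keep, None]
    nrep = rates.shape[0]
    se = rates.std(axis=0, ddof=1) / np.sqrt(nrep) if nrep > 1 else np.zeros(rates.shape[1])
    return RateTable(
        options=assay.options,
        per_replicate=rates,
        mean=rates.mean(axis=0),
        se=se,
        n_excluded=n_excluded,
    )


@dataclass(frozen=True)
class PreferenceComparison:
    group_labels: tuple[str, ...]
    anova: AnovaResult
    letters: tuple[str, ...]
    means: tuple[float, ...]  # raw-scale mean rates, percent


def preference_anova(
    rate_groups: dict[str, np.ndarray], alpha: float = 0.05
) -> PreferenceComparison:
    """ANOVA + Duncan letters over groups of replicate rates (percent).

    ``rate_groups`` maps a group label (e.g. a generation) to that
    group's replicate rates for one option.  The angular transform is
    applied to rates/100 before testing; reported means stay on the raw
    percentage scale.
    """
    labels = tuple(rate_groups)
    raw = [np.asarray(v, dtype=float) for v in rate_groups.values()]
    if any(v.size < 2 for v in raw):
        raise ValueError("each group needs at least two replicates")
    transformed = [arcsine_sqrt(v / 100.0) for v in raw]
    res = anova_oneway(transformed)
    letters = tuple(duncan_mrt(transformed, alpha=alpha))
    return PreferenceComparison(
        group_labels=labels,
        anova=res,
        letters=letters,
        means=tuple(float(v.mean()) for v in raw),
    )


def compare_assays_by_option(
    assays: dict[str, PreferenceAssay], alpha: float = 0.05
) -> dict[str, PreferenceComparison]:
    """Compare several assays (e.g. generations F1..F3) option by option.

    Returns one comparison per host option, each testing the option's
    rate across the given assays — the orientation of a per-cultivar
    column with letters down the generations.
    """
    first = next(iter(assays.values()))
    for a in assays.values():
        if a.options != first.options:
            raise SchemaError("assays must share the same option labels")
    tables = {k: attachment_rates(a) for k, a in assays.items()}
    out = {}
    for col, option in enumerate(first.options):
        groups = {k: t.per_replicate[:, col] for k, t in tables.items()}
        out[option] = preference_anova(groups, alpha=alpha)
    return out
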