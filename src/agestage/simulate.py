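"""Stochastic stage-structured cohort and assay generators.

The generator emulates the rearing protocol behind a two-sex life table:
a same-aged cohort followed daily through egg, six larval instars,
prepupa and pupa, with stage-specific survival, sex assigned at adult
emergence, and an adult fecundity schedule (pre-oviposition period,
number of oviposition days, per-female total eggs).

Distributional family: every integer quantity is ``min_days`` plus a
non-negative count offset drawn from

* a Poisson with the configured mean (``dispersion=None``, the default),
* a negative binomial with ``var = mu + mu**2 / dispersion`` (``dispersion > 0``), or
* exactly ``round(mean)`` (``dispersion=0``).

so location and spread are controlled independently, down to the
degenerate case (a stage lasting exactly its minimum).  Per-female total
fecundity is drawn the same way and split uniformly over the oviposition
days, so the mean/variance of totals is configurable while daily counts
remain integers.

The ``sweet``/``waxy``/``common``/``silage`` presets encode the
magnitudes of the published third-generation maize-cultivar cohorts
(stage durations and survival chains, sex ratios, fecundity, pupal
weights); they are calibration conveniences for testing the analysis
pipeline, not reconstructions of the unreleased raw records.

Closed-form expectations of the headline parameters are available via
:func:`expected_params` and serve as recovery oracles: by construction
``E[R0] = femaleFraction * prod(stage survivals) * (1 - zeroFraction) * E[total eggs]``.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np

from . import stages as st
from .cohort import Cohort, IndividualRecord
from .preference import PreferenceAssay

__all__ = [
    "StageSpec",
    "FecunditySpec",
    "WeightSpec",
    "CohortConfig",
    "AssayConfig",
    "generate_cohort",
    "generate_assay",
    "expected_params",
    "cohort_preset",
    "assay_preset",
    "COHORT_PRESETS",
    "ASSAY_PRESETS",
]


def _draw_counts(rng: np.random.Generator, mean: float, dispersion: float | None, size=None):
    """Non-negative integer draws with the family described in the module docstring."""
    if mean < 0:
        raise ValueError("mean must be non-negative")
    if dispersion is None:
        return rng.poisson(mean, size=size)
    if dispersion == 0:
        val = int(round(mean))
        return val if size is None else np.full(size, val, dtype=np.int64)
    if dispersion < 0:
        raise ValueError("dispersion must be None, 0 or positive")
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


@dataclass(frozen=True)
class StageSpec:
    """One pre-adult stage: duration = min_days + offset; survival per stage."""

    min_days: int
    mean_offset: float
    survival: float
    dispersion: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.survival <= 1.0):
            raise ValueError("survival must be in [0, 1]")
        if self.min_days < 1:
            raise ValueError("stages last at least one day")

    @property
    def mean_duration(self) -> float:
        return self.min_days + self.mean_offset


@dataclass(frozen=True)
class FecunditySpec:
    """Adult female schedule: APOP, oviposition days, totals, post-reproductive life."""

    apop_min: int = 3
    apop_mean_offset: float = 0.5
    ovi_min: int = 3
    ovi_mean_offset: float = 0.7
    total_eggs_mean: float = 500.0
    total_eggs_dispersion: float | None = 4.0
    zero_fraction: float = 0.2  # females that never lay
    post_min: int = 1
    post_mean_offset: float = 0.3

    def __post_init__(self):
        if not (0.0 <= self.zero_fraction < 1.0):
            raise ValueError("zero_fraction must be in [0, 1)")
        if self.ovi_min < 1:
            raise ValueError("reproductive females lay on at least one day")


@dataclass(frozen=True)
class WeightSpec:
    """Pupal weight (mg), normal by latent sex, measured on every pupa."""

    female_mean: float = 150.0
    female_sd: float = 15.0
    male_mean: float = 155.0
    male_sd: float = 20.0


@dataclass(frozen=True)
class CohortConfig:
    n: int = 100
    stages: tuple[StageSpec, ...] = ()  # one per pre-adult stage, egg..pupa
    female_fraction: float = 0.5
    fecundity: FecunditySpec = field(default_factory=FecunditySpec)
    male_longevity_min: int = 5
    male_longevity_mean_offset: float = 3.0
    weights: WeightSpec | None = field(default_factory=WeightSpec)
    seed: int = 0
    label: str = "synthetic"

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if len(self.stages) != len(st.PRE_ADULT_STAGES):
            raise ValueError(f"need {len(st.PRE_ADULT_STAGES)} stage specs (egg..pupa)")
        if not (0.0 <= self.female_fraction <= 1.0):
            raise ValueError("female_fraction must be in [0, 1]")


@dataclass(frozen=True)
class AssayConfig:
    """Multinomial choice-assay generator settings."""

    options: tuple[str, ...] = ("sweet", "waxy", "common", "silage")
    weights: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    total_mean: float = 1000.0
    total_dispersion: float | None = None
    replicates: int = 3
    assay_kind: str = "oviposition"
    seed: int = 0
    label: str = "synthetic"

    def __post_init__(self):
        if len(self.weights) != len(self.options):
            raise ValueError("weights and options must align")
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any() or not math.isclose(float(w.sum()), 1.0, rel_tol=1e-9):
            raise ValueError("weights must be a probability simplex")
        if self.replicates < 1 or self.total_mean <= 0:
            raise ValueError("need >= 1 replicate and a positive total")


# ---------------------------------------------------------------------------


def _simulate_individual(rng: np.random.Generator, cfg: CohortConfig, ident: str) -> IndividualRecord:
    entries: dict[str, int] = {}
    day = 0
    death = None
    reached_pupa = False
    fec = cfg.fecundity
    for label, spec in zip(st.PRE_ADULT_STAGES, cfg.stages):
        entries[label] = day
        dur = max(1, spec.min_days + int(_draw_counts(rng, spec.mean_offset, spec.dispersion)))
        if rng.random() >= spec.survival:  # dies within this stage
            death = day + int(rng.integers(1, dur + 1))
            break
        day += dur
        if label == st.PUPA:
            reached_pupa = True

    weight = None
    eggs: dict[int, int] = {}
    if st.PUPA in entries and cfg.weights is not None:
        latent_female = rng.random() < cfg.female_fraction
        spec = cfg.weights
        mu, sd = (spec.female_mean, spec.female_sd) if latent_female else (spec.male_mean, spec.male_sd)
        weight = float(max(1.0, rng.normal(mu, sd)))
    elif st.PUPA in entries:
        latent_female = rng.random() < cfg.female_fraction
    if reached_pupa:
        adult_entry = day
        if latent_female:
            entries[st.FEMALE_ADULT] = adult_entry
            apop = fec.apop_min + int(_draw_counts(rng, fec.apop_mean_offset, None))
            od = fec.ovi_min + int(_draw_counts(rng, fec.ovi_mean_offset, None))
            post = fec.post_min + int(_draw_counts(rng, fec.post_mean_offset, None))
            death = adult_entry + apop + od + post
            if rng.random() >= fec.zero_fraction:
                total = int(_draw_counts(rng, fec.total_eggs_mean, fec.total_eggs_dispersion))
                split = rng.multinomial(total, np.full(od, 1.0 / od))
                eggs = {adult_entry + apop + t: int(k) for t, k in enumerate(split) if k > 0}
        else:
            entries[st.MALE_ADULT] = adult_entry
            lon = cfg.male_longevity_min + int(_draw_counts(rng, cfg.male_longevity_mean_offset, None))
            death = adult_entry + lon
    return IndividualRecord(
        id=ident,
        stage_entry_day=entries,
        death_day=int(death),
        daily_eggs=eggs,
        pupal_weight_mg=weight,
    )


def generate_cohort(cfg: CohortConfig, seed: int | None = None) -> Cohort:
    """Draw a cohort; identical config + seed gives an identical cohort.

    Individuals are independent.  Death within a stage strikes with
    probability ``1 - survival`` and falls uniformly inside the stage's
    drawn duration; sex is assigned at adult emergence (latent at
    pupation so pupal weight can depend on sex).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    width = len(str(cfg.n))
    individuals = tuple(
        _simulate_individual(rng, cfg, f"{cfg.label}-{i:0{width}d}") for i in range(cfg.n)
    )
    return Cohort(individuals, label=cfg.label)


def expected_params(cfg: CohortConfig) -> dict[str, float]:
    """Closed-form expectations implied by a config (recovery oracles).

    Keys: ``R0``, ``sa_pct`` (pre-adult survival), ``F``, ``Fr``,
    ``mean_duration_<stage>``, ``preadult_days`` and
    ``female_fraction``.
    """
    surv = float(np.prod([s.survival for s in cfg.stages]))
    fec = cfg.fecundity
    Fr = fec.total_eggs_mean
    F = (1.0 - fec.zero_fraction) * Fr
    out = {
        "R0": surv * cfg.female_fraction * F,
        "sa_pct": 100.0 * surv,
        "F": F,
        "Fr": Fr,
        "female_fraction": cfg.female_fraction,
        "preadult_days": float(sum(s.mean_duration for s in cfg.stages)),
    }
    for label, spec in zip(st.PRE_ADULT_STAGES, cfg.stages):
        out[f"mean_duration_{label}"] = spec.mean_duration
    return out


def generate_assay(cfg: AssayConfig, seed: int | None = None) -> PreferenceAssay:
    """Draw a choice assay: per replicate a multinomial over the options."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    rows = []
    for _ in range(cfg.replicates):
        total = int(_draw_counts(rng, cfg.total_mean, cfg.total_dispersion))
        rows.append(rng.multinomial(total, np.asarray(cfg.weights, dtype=float)))
    return PreferenceAssay(
        options=cfg.options,
        replicates=np.array(rows, dtype=np.int64),
        assay_kind=cfg.assay_kind,
        label=cfg.label,
    )


# ---------------------------------------------------------------------------
# presets — third-generation maize-cultivar cohort magnitudes


def _stage_specs(durations, survivals) -> tuple[StageSpec, ...]:
    specs = []
    for mean, surv in zip(durations, survivals):
        lo = max(1, int(math.floor(mean)))
        specs.append(StageSpec(min_days=lo, mean_offset=round(mean - lo, 6), survival=surv))
    return tuple(specs)


def _preset(
    label, durations, counts, n, n_female, n_male, F, Fr, apop, ovi, female_longevity,
    male_longevity, wf, wm,
) -> CohortConfig:
    # counts: completers of egg..pupa; successive ratios give per-stage survival
    chain = [n] + list(counts)
    survivals = [b / a for a, b in zip(chain, chain[1:])]
    post = max(0.0, female_longevity - apop - ovi)
    return CohortConfig(
        n=n,
        stages=_stage_specs(durations, survivals),
        female_fraction=n_female / (n_female + n_male),
        fecundity=FecunditySpec(
            apop_min=int(apop),
            apop_mean_offset=round(apop - int(apop), 6),
            ovi_min=int(ovi),
            ovi_mean_offset=round(ovi - int(ovi), 6),
            total_eggs_mean=Fr,
            total_eggs_dispersion=4.0,
            zero_fraction=round(1.0 - F / Fr, 6),
            post_min=int(post),
            post_mean_offset=round(post - int(post), 6),
        ),
        male_longevity_min=max(1, int(male_longevity) - 3),
        male_longevity_mean_offset=round(male_longevity - max(1, int(male_longevity) - 3), 6),
        weights=WeightSpec(female_mean=wf[0], female_sd=wf[1], male_mean=wm[0], male_sd=wm[1]),
        label=label,
    )


#: cultivar presets (stage-duration means, completer counts, sex split,
#: fecundity and pupal weight) at the published third-generation magnitudes
COHORT_PRESETS: dict[str, CohortConfig] = {
    "sweet": _preset(
        "sweet",
        durations=(3.0, 2.9, 2.1, 2.2, 2.5, 2.5, 3.1, 1.2, 8.7),
        counts=(99, 96, 92, 91, 90, 88, 87, 84, 72),
        n=100, n_female=39, n_male=33,
        F=458.0, Fr=596.0, apop=3.5, ovi=3.7,
        female_longevity=8.5, male_longevity=8.4,
        wf=(152.6, 14.0), wm=(159.8, 22.0),
    ),
    "waxy": _preset(
        "waxy",
        durations=(3.0, 2.8, 2.0, 2.2, 2.5, 2.2, 3.0, 1.5, 8.8),
        counts=(99, 97, 95, 90, 89, 89, 84, 76, 65),
        n=100, n_female=34, n_male=31,
        F=382.0, Fr=481.0, apop=3.7, ovi=3.3,
        female_longevity=7.8, male_longevity=7.6,
        wf=(143.1, 22.0), wm=(152.6, 27.0),
    ),
    "common": _preset(
        "common",
        durations=(3.0, 2.9, 2.3, 2.3, 2.7, 2.4, 2.8, 1.4, 9.5),
        counts=(100, 98, 93, 91, 91, 91, 84, 80, 68),
        n=100, n_female=33, n_male=35,
        F=425.0, Fr=520.0, apop=3.4, ovi=3.3,
        female_longevity=8.2, male_longevity=8.1,
        wf=(142.7, 22.0), wm=(155.8, 24.0),
    ),
    "silage": _preset(
        "silage",
        durations=(3.0, 2.6, 2.2, 2.0, 2.1, 2.3, 3.0, 1.4, 9.0),
        counts=(100, 94, 93, 90, 86, 86, 83, 78, 64),
        n=100, n_female=34, n_male=30,
        F=371.0, Fr=504.0, apop=3.8, ovi=3.5,
        female_longevity=7.8, male_longevity=7.2,
        wf=(132.7, 19.0), wm=(141.8, 21.0),
    ),
}

#: oviposition-assay presets: option weights at published first/third
#: generation magnitudes for the population reared on sweet maize
ASSAY_PRESETS: dict[str, AssayConfig] = {
    "sweet-F1": AssayConfig(weights=(0.265, 0.249, 0.236, 0.25), replicates=3, label="sweet-F1"),
    "sweet-F3": AssayConfig(weights=(0.313, 0.229, 0.215, 0.243), replicates=3, label="sweet-F3"),
    "uniform": AssayConfig(weights=(0.25, 0.25, 0.25, 0.25), replicates=3, label="uniform"),
}


def cohort_preset(name: str, **overrides) -> CohortConfig:
    """A named cultivar preset, optionally with field overrides (e.g. seed)."""
    cfg = COHORT_PRESETS[name]
    if not overrides:
        return cfg
    d = asdict_config(cfg)
    d.update(overrides)
    return cohort_config_from_dict(d)


def assay_preset(name: str, **overrides) -> AssayConfig:
    cfg = ASSAY_PRESETS[name]
    if not overrides:
        return cfg
    d = asdict(cfg)
    d.update(overrides)
    return AssayConfig(**d)


def asdict_config(cfg: CohortConfig) -> dict:
    """Config as plain nested dict (for YAML/JSON provenance echo)."""
    d = asdict(cfg)
    return d


def cohort_config_from_dict(d: dict) -> CohortConfig:
    """Inverse of :func:`asdict_config` (accepts YAML/JSON-loaded dicts)."""
    d = dict(d)
    d["stages"] = tuple(StageSpec(**s) for s in d.get("stages", ()))
    if d.get("fecundity") is not None and not isinstance(d["fecundity"], FecunditySpec):
        d["fecundity"] = FecunditySpec(**d["fecundity"])
    if d.get("weights") is not None and not isinstance(d["weights"], WeightSpec):
        d["weights"] = WeightSpec(**d["weights"])
    return CohortConfig(**d)
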