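"""Individual life-history records and cohorts, with CSV round-trip.

A cohort is the unit of analysis: one insect per record, followed daily
from oviposition (age 0) to death.  Records store stage-entry days, the
death (or censoring) day, daily egg counts for females, and an optional
pupal weight.  Sex is implied by which adult stage, if any, was entered;
individuals dying before adult emergence are ``undetermined``.

The on-disk format is a long CSV with columns ``id, event, day, value``:

==================  ===========================  =======================
event               day                          value
==================  ===========================  =======================
``stage_entry``     integer age at entry         stage label
``death``           first day no longer alive    (empty)
``censored``        day observation stopped      (empty)
``eggs``            age-day of the egg count     non-negative integer
``pupal_weight_mg`` (empty)                      weight in mg
==================  ===========================  =======================

``stage_entry:<label>`` with an empty value is accepted on read as an
alias.  Rows are written sorted by id then day, so write→read is an exact
round trip and row order never affects the parsed cohort.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import pandas as pd

from . import stages as st
from .errors import SchemaError

__all__ = [
    "IndividualRecord",
    "Cohort",
    "Finding",
    "read_cohort",
    "write_cohort",
    "validate_cohort",
]


@dataclass(frozen=True)
class IndividualRecord:
    """Complete life history of one insect.

    Parameters
    ----------
    id : str
        Unique identifier within the cohort.
    stage_entry_day : dict
        Stage label -> integer age (days) at entry.  Age 0 is the day the
        egg is laid, so every record has ``{"egg": 0, ...}``.
    death_day : int or None
        First age-day on which the individual is no longer alive
        (an individual with ``death_day == d`` was alive on days
        ``0..d-1``).  ``None`` for censored individuals.
    censored_day : int or None
        Day observation stopped, for censored individuals.
    daily_eggs : dict
        Age-day -> egg count laid that day (females only).
    pupal_weight_mg : float or None
        Pupal weight measured once, in mg.
    """

    id: str
    stage_entry_day: dict[str, int]
    death_day: int | None = None
    censored_day: int | None = None
    daily_eggs: dict[int, int] = field(default_factory=dict)
    pupal_weight_mg: float | None = None

    @property
    def sex(self) -> str:
        if st.FEMALE_ADULT in self.stage_entry_day:
            return "female"
        if st.MALE_ADULT in self.stage_entry_day:
            return "male"
        return "undetermined"

    @property
    def censored(self) -> bool:
        return self.death_day is None

    @property
    def end_day(self) -> int:
        """Last day + 1 of observed life (death day or censoring day)."""
        d = self.death_day if self.death_day is not None else self.censored_day
        if d is None:
            raise SchemaError(f"record {self.id!r}: neither death nor censor day")
        return d

    def stage_on(self, day: int) -> str | None:
        """Stage occupied on age-day ``day``, or None if not alive then."""
        if day < 0 or day >= self.end_day:
            return None
        current = None
        for label in st.STAGES:
            entry = self.stage_entry_day.get(label)
            if entry is not None and entry <= day:
                current = label
        return current

    def total_eggs(self) -> int:
        return sum(self.daily_eggs.values())


@dataclass(frozen=True)
class Cohort:
    """A same-aged group of individually reared insects (daily census)."""

    individuals: tuple[IndividualRecord, ...]
    label: str = ""

    #: census interval in days; the whole framework assumes daily censusing
    census_interval: int = 1

    def __post_init__(self):
        object.__setattr__(self, "individuals", tuple(self.individuals))

    @property
    def n(self) -> int:
        return len(self.individuals)

    @property
    def max_day(self) -> int:
        return max(ind.end_day for ind in self.individuals)

    def females(self) -> tuple[IndividualRecord, ...]:
        return tuple(i for i in self.individuals if i.sex == "female")

    def males(self) -> tuple[IndividualRecord, ...]:
        return tuple(i for i in self.individuals if i.sex == "male")

    def total_eggs(self) -> int:
        return sum(i.total_eggs() for i in self.individuals)


@dataclass(frozen=True)
class Finding:
    """One validation finding: which record broke which rule."""

    id: str
    rule: str
    detail: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.id}] {self.rule}: {self.detail}" if self.detail else f"[{self.id}] {self.rule}"


def _validate_record(ind: IndividualRecord) -> list[Finding]:
    out: list[Finding] = []
    entries = ind.stage_entry_day
    if st.EGG not in entries or entries.get(st.EGG) != 0:
        out.append(Finding(ind.id, "egg-at-zero", "record must enter 'egg' at age 0"))
    if st.FEMALE_ADULT in entries and st.MALE_ADULT in entries:
        out.append(Finding(ind.id, "both-adult-stages", "female_adult and male_adult both present"))
    # contiguity + strict ordering along the stage chain
    prev_label, prev_day = None, None
    seen = [s for s in st.STAGES if s in entries]
    for label in seen:
        day = entries[label]
        if prev_label is not None:
            if day <= prev_day:
                out.append(
                    Finding(ind.id, "stage-order", f"entry({label})={day} <= entry({prev_label})={prev_day}")
                )
            expected = st.next_stages(prev_label)
            if label not in expected:
                out.append(Finding(ind.id, "stage-skipped", f"{prev_label} -> {label}"))
        prev_label, prev_day = label, day
    if ind.death_day is None and ind.censored_day is None:
        out.append(Finding(ind.id, "no-endpoint", "neither death_day nor censored_day"))
    elif ind.death_day is not None and ind.censored_day is not None:
        out.append(Finding(ind.id, "dead-and-censored"))
    elif prev_day is not None and ind.end_day <= prev_day:
        out.append(
            Finding(ind.id, "death-before-entry", f"end day {ind.end_day} <= last stage entry {prev_day}")
        )
    has_endpoint = ind.death_day is not None or ind.censored_day is not None
    if ind.daily_eggs:
        if ind.sex != "female":
            out.append(Finding(ind.id, "eggs-on-nonfemale", f"sex={ind.sex}"))
        elif has_endpoint:
            lo = entries[st.FEMALE_ADULT]
            hi = ind.end_day
            bad = [d for d in ind.daily_eggs if not (lo <= d < hi)]
            if bad:
                out.append(Finding(ind.id, "eggs-outside-adult-life", f"days {sorted(bad)}"))
        if any(v < 0 for v in ind.daily_eggs.values()):
            out.append(Finding(ind.id, "negative-eggs"))
    return out


def validate_cohort(cohort: Cohort) -> list[Finding]:
    """Check every type invariant; empty list iff the cohort is well formed."""
    findings: list[Finding] = []
    if cohort.n == 0:
        return [Finding("", "empty-cohort", "cohort has no individuals")]
    ids = [i.id for i in cohort.individuals]
    dup = {x for x in ids if ids.count(x) > 1}
    for d in sorted(dup):
        findings.append(Finding(d, "duplicate-id"))
    for ind in cohort.individuals:
        findings.extend(_validate_record(ind))
    return findings


def _require_valid(cohort: Cohort) -> Cohort:
    findings = validate_cohort(cohort)
    if findings:
        raise SchemaError("; ".join(str(f) for f in findings[:10]))
    return cohort


# ---------------------------------------------------------------------------
# CSV round trip


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort to the long CSV schema (rows sorted by id, then day)."""
    rows: list[tuple[str, str, object, object]] = []
    for ind in cohort.individuals:
        for label, day in ind.stage_entry_day.items():
            rows.append((ind.id, "stage_entry", day, label))
        if ind.death_day is not None:
            rows.append((ind.id, "death", ind.death_day, ""))
        if ind.censored_day is not None:
            rows.append((ind.id, "censored", ind.censored_day, ""))
        for day in sorted(ind.daily_eggs):
            rows.append((ind.id, "eggs", day, ind.daily_eggs[day]))
        if ind.pupal_weight_mg is not None:
            rows.append((ind.id, "pupal_weight_mg", "", repr(float(ind.pupal_weight_mg))))
    df = pd.DataFrame(rows, columns=["id", "event", "day", "value"])
    df["_day"] = pd.to_numeric(df["day"], errors="coerce").fillna(-1)
    df = df.sort_values(["id", "_day", "event", "value"], kind="mergesort").drop(columns="_day")
    df.to_csv(path, index=False)


def _int_day(row, what: str) -> int:
    day = row["day"]
    try:
        f = float(day)
        i = int(f)
        if i != f:
            raise ValueError
        return i
    except (TypeError, ValueError):
        raise SchemaError(f"record {row['id']!r}: non-integer day {day!r} for {what}") from None


def read_cohort(path, label: str = "") -> Cohort:
    """Read and validate a cohort from the long CSV schema.

    Raises :class:`SchemaError` naming the offending row on malformed input.
    """
    try:
        df = pd.read_csv(path, dtype={"id": str, "event": str, "value": str}, keep_default_na=False)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as e:
        raise SchemaError(f"unreadable cohort CSV: {e}") from e
    missing = {"id", "event", "day", "value"} - set(df.columns)
    if missing:
        raise SchemaError(f"missing columns: {sorted(missing)}")
    if len(df) == 0:
        raise SchemaError("empty cohort file")

    individuals = []
    for ind_id, grp in df.groupby("id", sort=True):
        entries: dict[str, int] = {}
        eggs: dict[int, int] = {}
        death = censor = None
        weight = None
        for _, row in grp.iterrows():
            event = row["event"]
            if event.startswith("stage_entry"):
                lab = event.split(":", 1)[1] if ":" in event else row["value"]
                if lab not in st.STAGE_INDEX:
                    raise SchemaError(f"record {ind_id!r}: unknown stage {lab!r}")
                if lab in entries:
                    raise SchemaError(f"record {ind_id!r}: duplicate stage entry {lab!r}")
                entries[lab] = _int_day(row, f"stage_entry {lab}")
            elif event == "death":
                if death is not None:
                    raise SchemaError(f"record {ind_id!r}: duplicate death row")
                death = _int_day(row, "death")
            elif event == "censored":
                censor = _int_day(row, "censored")
            elif event == "eggs":
                day = _int_day(row, "eggs")
                try:
                    count = int(row["value"])
                except ValueError:
                    raise SchemaError(f"record {ind_id!r}: non-integer egg count {row['value']!r}") from None
                eggs[day] = eggs.get(day, 0) + count
            elif event == "pupal_weight_mg":
                weight = float(row["value"])
            else:
                raise SchemaError(f"record {ind_id!r}: unknown event {event!r}")
        individuals.append(
            IndividualRecord(
                id=str(ind_id),
                stage_entry_day={s: entries[s] for s in st.STAGES if s in entries},
                death_day=death,
                censored_day=censor,
                daily_eggs=eggs,
                pupal_weight_mg=weight,
            )
        )
    return _require_valid(Cohort(tuple(individuals), label=label))


def cohort_to_csv_text(cohort: Cohort) -> str:
    """Render the canonical CSV as a string (used for provenance/digests)."""
    buf = io.StringIO()
    write_cohort(cohort, buf)
    return buf.getvalue()


def relabel(cohort: Cohort, label: str) -> Cohort:
    return replace(cohort, label=label)
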