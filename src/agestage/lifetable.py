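"""Age-stage, two-sex life-table grids and cohort summary statistics.

The central object is the age-stage survival grid ``s_xj``: the probability
that a newborn is alive and in stage *j* at age *x* (days).  Because both
sexes and the variable developmental rate among individuals are kept, stage
overlap in age is represented exactly — no adult-only or female-only
approximation is made.  From the same daily census come the fecundity
surfaces ``f_xj`` (eggs per living female per day), ``m_x`` (population
age-specific fecundity) and the net maternity ``l_x m_x`` whose sum is the
net reproductive rate.

All grid entries are census counts divided by the cohort size N, so every
entry is a multiple of 1/N and ``N * sum(l_x m_x)`` equals the raw total
egg count exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stages as st
from .cohort import Cohort, IndividualRecord, validate_cohort
from .errors import DataError, SchemaError

__all__ = [
    "LifeTableGrid",
    "FecundityGrid",
    "StageStat",
    "CohortSummary",
    "compute_sxj",
    "compute_fecundity",
    "summarize_cohort",
    "pupation_rate",
    "emergence_rate",
    "larval_survival_rate",
    "immature_survival_rate",
]


@dataclass(frozen=True)
class LifeTableGrid:
    """Age × stage survival surface with its marginals and transition counts.

    Attributes
    ----------
    sxj : ndarray, shape (A+1, 11)
        Fraction of the cohort alive in stage j at age x; rows span ages
        0..A where A is the last death/censor day (the final row is zero).
    lx : ndarray, shape (A+1,)
        Age-specific survival, the row sums of ``sxj``.
    counts : ndarray of int
        ``sxj * N`` — the raw daily census.
    transitions : ndarray of int, shape (A, 11, 11)
        ``transitions[x, j, y]`` is the number of individuals alive in
        stage j at age x and in stage y at age x+1; row deficits are
        deaths.  Drives the life-expectancy and reproductive-value
        recursions.
    n : int
        Cohort size N.
    """

    sxj: np.ndarray
    lx: np.ndarray
    counts: np.ndarray
    transitions: np.ndarray
    n: int

    @property
    def n_ages(self) -> int:
        return self.sxj.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Tidy long form: one row per (age, stage) with s_xj and l_x."""
        ages, cols = np.nonzero(np.ones_like(self.sxj))
        return pd.DataFrame(
            {
                "age": ages,
                "stage": [st.STAGES[c] for c in cols],
                "sxj": self.sxj[ages, cols],
                "lx": self.lx[ages],
            }
        )


@dataclass(frozen=True)
class FecundityGrid:
    """Age × stage fecundity surface and derived maternity schedule."""

    fxj: np.ndarray  # eggs per living individual of stage j at age x
    mx: np.ndarray  # population age-specific fecundity
    net_maternity: np.ndarray  # l_x * m_x
    n: int
    total_eggs: int

    def to_frame(self) -> pd.DataFrame:
        age = np.arange(len(self.mx))
        return pd.DataFrame(
            {
                "age": age,
                "fxj_female_adult": self.fxj[:, st.FEMALE_ADULT_COL],
                "mx": self.mx,
                "lxmx": self.net_maternity,
            }
        )


@dataclass(frozen=True)
class StageStat:
    """mean ± SE with the number of completers it averages over."""

    n: int
    mean: float
    se: float


@dataclass(frozen=True)
class CohortSummary:
    """Per-cohort development, survival and reproduction statistics."""

    label: str
    n: int
    stage_durations: dict[str, StageStat]
    total_larval: StageStat | None
    total_immature: StageStat | None
    larval_survival_pct: float
    pupation_rate_pct: float
    emergence_rate_pct: float
    immature_survival_pct: float
    n_female: int
    n_male: int
    apop: StageStat | None
    tpop: StageStat | None
    oviposition_days: StageStat | None
    fecundity_F: float | None  # eggs per female adult (all females)
    fecundity_Fr: float | None  # eggs per reproductive female
    adult_longevity: dict[str, StageStat]
    total_longevity: dict[str, StageStat]
    mean_longevity: StageStat
    pupal_weight: dict[str, StageStat]
    reason: str = ""  # why reproduction fields are None, if they are

    def to_frame(self) -> pd.DataFrame:
        rows = []

        def add(name, stat):
            if stat is None:
                return
            if isinstance(stat, StageStat):
                rows.append((name, stat.mean, stat.se, stat.n))
            else:
                rows.append((name, stat, math.nan, math.nan))

        for lab, s in self.stage_durations.items():
            add(f"duration_{lab}_d", s)
        add("total_larval_duration_d", self.total_larval)
        add("total_immature_duration_d", self.total_immature)
        add("larval_survival_pct", self.larval_survival_pct)
        add("pupation_rate_pct", self.pupation_rate_pct)
        add("emergence_rate_pct", self.emergence_rate_pct)
        add("immature_survival_pct", self.immature_survival_pct)
        add("n_female", self.n_female)
        add("n_male", self.n_male)
        add("APOP_d", self.apop)
        add("TPOP_d", self.tpop)
        add("oviposition_days_d", self.oviposition_days)
        add("F_eggs_per_female", self.fecundity_F)
        add("Fr_eggs_per_reproductive_female", self.fecundity_Fr)
        for sex, s in self.adult_longevity.items():
            add(f"adult_longevity_{sex}_d", s)
        for sex, s in self.total_longevity.items():
            add(f"total_longevity_{sex}_d", s)
        add("mean_longevity_d", self.mean_longevity)
        for sex, s in self.pupal_weight.items():
            add(f"pupal_weight_{sex}_mg", s)
        return pd.DataFrame(rows, columns=["statistic", "value", "se", "n"])


# ---------------------------------------------------------------------------
# grids


def _stage_col_per_day(ind: IndividualRecord, n_ages: int) -> np.ndarray:
    """0-based stage column per age-day; -1 where not alive."""
    cols = np.full(n_ages, -1, dtype=np.int64)
    entries = sorted(
        ((day, st.STAGE_INDEX[lab] - 1) for lab, day in ind.stage_entry_day.items()),
    )
    end = ind.end_day
    for (day, col), nxt in zip(entries, entries[1:] + [(end, -1)]):
        hi = min(nxt[0], end)
        if day < hi:
            cols[day:hi] = col
    return cols


def compute_sxj(cohort: Cohort) -> LifeTableGrid:
    """Daily age-stage census of the cohort, as fractions of N.

    Raises
    ------
    SchemaError
        If the cohort is empty or invalid.
    """
    findings = validate_cohort(cohort)
    if findings:
        raise SchemaError("; ".join(str(f) for f in findings[:10]))
    n_ages = cohort.max_day + 1
    counts = np.zeros((n_ages, st.N_STAGES), dtype=np.int64)
    trans = np.zeros((n_ages - 1, st.N_STAGES, st.N_STAGES), dtype=np.int64)
    for ind in cohort.individuals:
        cols = _stage_col_per_day(ind, n_ages)
        alive = cols >= 0
        counts[alive, cols[alive]] += 1
        both = alive[:-1] & alive[1:]
        x = np.nonzero(both)[0]
        trans[x, cols[x], cols[x + 1]] += 1
    sxj = counts / cohort.n
    lx = sxj.sum(axis=1)
    return LifeTableGrid(sxj=sxj, lx=lx, counts=counts, transitions=trans, n=cohort.n)


def compute_fecundity(cohort: Cohort, grid: LifeTableGrid) -> FecundityGrid:
    """Fecundity surfaces from the daily egg census.

    ``f_xj`` is nonzero only in the female-adult column: eggs laid on day x
    divided by the number of females alive on day x.  ``m_x`` is the
    pooled-cohort fecundity ``sum_j s_xj f_xj / sum_j s_xj``.
    """
    n_ages = grid.n_ages
    eggs_per_day = np.zeros(n_ages, dtype=np.int64)
    for ind in cohort.individuals:
        for day, k in ind.daily_eggs.items():
            if day >= n_ages:
                raise DataError(f"egg record on day {day} beyond the grid ({n_ages} ages)")
            eggs_per_day[day] += k
    females_alive = grid.counts[:, st.FEMALE_ADULT_COL]
    bad = (eggs_per_day > 0) & (females_alive == 0)
    if bad.any():
        raise DataError(f"eggs recorded on days with no living females: {np.nonzero(bad)[0].tolist()}")
    fxj = np.zeros_like(grid.sxj)
    with np.errstate(invalid="ignore"):
        fxj[:, st.FEMALE_ADULT_COL] = np.where(
            females_alive > 0, eggs_per_day / np.maximum(females_alive, 1), 0.0
        )
    net_maternity = eggs_per_day / grid.n
    mx = np.where(grid.lx > 0, net_maternity / np.maximum(grid.lx, 1e-300), 0.0)
    return FecundityGrid(
        fxj=fxj,
        mx=mx,
        net_maternity=net_maternity,
        n=grid.n,
        total_eggs=int(eggs_per_day.sum()),
    )


# ---------------------------------------------------------------------------
# summary statistics


def _stat(values) -> StageStat | None:
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        return None
    se = float(v.std(ddof=1) / math.sqrt(v.size)) if v.size > 1 else 0.0
    return StageStat(n=int(v.size), mean=float(v.mean()), se=se)


def _completed(ind: IndividualRecord, label: str) -> bool:
    """True if the individual finished stage ``label`` (entered a successor)."""
    if label not in ind.stage_entry_day:
        return False
    return any(nxt in ind.stage_entry_day for nxt in st.next_stages(label))


def _duration(ind: IndividualRecord, label: str) -> int:
    entry = ind.stage_entry_day[label]
    nxt = min(ind.stage_entry_day[s] for s in st.next_stages(label) if s in ind.stage_entry_day)
    return nxt - entry


def pupation_rate(pupated: int, larval_completers: int) -> float:
    """Percent of larval completers (finished the sixth instar) that reached the pupal stage."""
    return 100.0 * pupated / larval_completers if larval_completers else math.nan


def emergence_rate(emerged: int, pupated: int) -> float:
    """Percent of pupae from which an adult eclosed."""
    return 100.0 * emerged / pupated if pupated else math.nan


def larval_survival_rate(larval_completers: int, entered_instar1: int) -> float:
    """Percent of hatched larvae that completed the sixth instar."""
    return 100.0 * larval_completers / entered_instar1 if entered_instar1 else math.nan


def immature_survival_rate(n_adults: int, n: int) -> float:
    """Pre-adult survival s_a: percent of the cohort reaching adulthood."""
    return 100.0 * n_adults / n if n else math.nan


def summarize_cohort(cohort: Cohort) -> CohortSummary:
    """Development, survival and reproduction summary of one cohort.

    Stage durations are averaged over completers only; censored
    individuals never count as completers of stages they did not finish.
    Rates use count-based denominators: larval survival is sixth-instar
    completers over first-instar entrants, pupation is pupae over larval
    completers, emergence is adults over pupae, and s_a is adults over N.
    """
    findings = validate_cohort(cohort)
    if findings:
        raise SchemaError("; ".join(str(f) for f in findings[:10]))
    inds = cohort.individuals

    durations: dict[str, StageStat] = {}
    for label in st.PRE_ADULT_STAGES:
        stat = _stat(_duration(i, label) for i in inds if _completed(i, label))
        if stat is not None:
            durations[label] = stat

    larval = [i for i in inds if _completed(i, st.INSTARS[-1])]
    total_larval = _stat(
        i.stage_entry_day[st.PREPUPA] - i.stage_entry_day[st.INSTARS[0]] for i in larval
    )
    adults = [i for i in inds if i.sex != "undetermined"]
    total_immature = _stat(
        min(i.stage_entry_day.get(st.FEMALE_ADULT, 10**9), i.stage_entry_day.get(st.MALE_ADULT, 10**9))
        for i in adults
    )

    entered_i1 = sum(1 for i in inds if st.INSTARS[0] in i.stage_entry_day)
    pupated = sum(1 for i in inds if st.PUPA in i.stage_entry_day)
    females, males = cohort.females(), cohort.males()

    # reproduction
    reason = ""
    apop = tpop = ovi = None
    F = Fr = None
    if not adults:
        reason = "no adults emerged; reproduction statistics undefined"
    elif not females:
        reason = "no female adults; reproduction statistics undefined"
    else:
        layers = [f for f in females if f.total_eggs() > 0]
        if layers:
            apop = _stat(min(f.daily_eggs) - f.stage_entry_day[st.FEMALE_ADULT] for f in layers)
            tpop = _stat(min(f.daily_eggs) for f in layers)
            ovi = _stat(sum(1 for v in f.daily_eggs.values() if v > 0) for f in layers)
            total = sum(f.total_eggs() for f in females)
            F = total / len(females)
            Fr = total / len(layers)
        else:
            reason = "no female laid eggs; oviposition statistics undefined"
            F = 0.0

    adult_longevity = {}
    total_longevity = {}
    for sex, group, col in (("female", females, st.FEMALE_ADULT), ("male", males, st.MALE_ADULT)):
        done = [i for i in group if not i.censored]
        s = _stat(i.death_day - i.stage_entry_day[col] for i in done)
        if s is not None:
            adult_longevity[sex] = s
        s = _stat(i.death_day for i in done)
        if s is not None:
            total_longevity[sex] = s
    mean_longevity = _stat(i.death_day for i in inds if not i.censored)
    if mean_longevity is None:
        raise DataError("all individuals censored; longevity undefined")

    weights: dict[str, StageStat] = {}
    for sex, group in (("female", females), ("male", males), ("all", inds)):
        s = _stat(i.pupal_weight_mg for i in group if i.pupal_weight_mg is not None)
        if s is not None:
            weights[sex] = s

    return CohortSummary(
        label=cohort.label,
        n=cohort.n,
        stage_durations=durations,
        total_larval=total_larval,
        total_immature=total_immature,
        larval_survival_pct=larval_survival_rate(len(larval), entered_i1),
        pupation_rate_pct=pupation_rate(pupated, len(larval)),
        emergence_rate_pct=emergence_rate(len(adults), pupated),
        immature_survival_pct=immature_survival_rate(len(adults), cohort.n),
        n_female=len(females),
        n_male=len(males),
        apop=apop,
        tpop=tpop,
        oviposition_days=ovi,
        fecundity_F=F,
        fecundity_Fr=Fr,
        adult_longevity=adult_longevity,
        total_longevity=total_longevity,
        mean_longevity=mean_longevity,
        pupal_weight=weights,
        reason=reason,
    )
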