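"""Shared fixtures: hand-built toy cohorts and a session-scoped synthetic cohort."""

from __future__ import annotations

import pytest

from agestage import Cohort, IndividualRecord, cohort_preset, generate_cohort


def make_ind(
    ident: str,
    entries: dict[str, int],
    death: int | None,
    eggs: dict[int, int] | None = None,
    weight: float | None = None,
    censored: int | None = None,
) -> IndividualRecord:
    return IndividualRecord(
        id=ident,
        stage_entry_day=entries,
        death_day=death,
        censored_day=censored,
        daily_eggs=eggs or {},
        pupal_weight_mg=weight,
    )


def quick_female(ident="f1", adult_day=28, death=36, eggs=None, weight=150.0):
    """A female with a plausible full pre-adult path entering adulthood at ``adult_day``."""
    entries = {
        "egg": 0, "instar1": 3, "instar2": 6, "instar3": 8, "instar4": 10,
        "instar5": 13, "instar6": 15, "prepupa": 18, "pupa": 19,
        "female_adult": adult_day,
    }
    return make_ind(ident, entries, death, eggs=eggs, weight=weight)


def quick_male(ident="m1", adult_day=28, death=36, weight=155.0):
    entries = {
        "egg": 0, "instar1": 3, "instar2": 6, "instar3": 8, "instar4": 10,
        "instar5": 13, "instar6": 15, "prepupa": 18, "pupa": 19,
        "male_adult": adult_day,
    }
    return make_ind(ident, entries, death, weight=weight)


@pytest.fixture(scope="session")
def sweet_cohort() -> Cohort:
    return generate_cohort(cohort_preset("sweet", seed=11))


@pytest.fixture(scope="session")
def silage_cohort() -> Cohort:
    return generate_cohort(cohort_preset("silage", seed=12))


@pytest.fixture()
def toy4() -> Cohort:
    """Four individuals: laying female, male, larval death, egg death."""
    female = quick_female("a-f", adult_day=28, death=36, eggs={31: 10, 32: 20, 34: 5})
    male = quick_male("b-m", adult_day=29, death=38)
    larval_death = make_ind("c-l", {"egg": 0, "instar1": 3, "instar2": 6}, death=8, weight=None)
    egg_death = make_ind("d-e", {"egg": 0}, death=2)
    return Cohort((female, male, larval_death, egg_death), label="toy4")


def census_oracle(cohort: Cohort):
    """Independent brute-force daily census: dict (day, stage_label) -> count.

    Walks every individual day by day using only the record's entry map,
    re-deriving the stage each day from scratch.
    """
    from agestage.stages import STAGES

    tally: dict[tuple[int, str], int] = {}
    for ind in cohort.individuals:
        end = ind.death_day if ind.death_day is not None else ind.censored_day
        for day in range(0, end):
            best = None
            for label in STAGES:
                if label in ind.stage_entry_day and ind.stage_entry_day[label] <= day:
                    best = label
            if best is not None:
                tally[(day, best)] = tally.get((day, best), 0) + 1
    return tally
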