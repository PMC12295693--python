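"""Fixed developmental stage vocabulary for *Spodoptera frugiperda* cohorts.

The life cycle is egg, six larval instars, prepupa, pupa, and a sex-split
adult stage.  Stages carry 1-based indices; the female adult is stage 10 and
the male adult stage 11.  The pre-adult path 1..9 is linear: an individual
may die in any stage but never skips one, and stages 10/11 are mutually
exclusive terminal stages entered from the pupa.
"""

from __future__ import annotations

EGG = "egg"
INSTARS = tuple(f"instar{i}" for i in range(1, 7))
PREPUPA = "prepupa"
PUPA = "pupa"
FEMALE_ADULT = "female_adult"
MALE_ADULT = "male_adult"

#: Ordered stage labels; position + 1 is the stage index.
STAGES: tuple[str, ...] = (EGG, *INSTARS, PREPUPA, PUPA, FEMALE_ADULT, MALE_ADULT)

#: Stage label -> 1-based index (female_adult == 10, male_adult == 11).
STAGE_INDEX: dict[str, int] = {s: i + 1 for i, s in enumerate(STAGES)}

#: Pre-adult stages, in developmental order (indices 1..9).
PRE_ADULT_STAGES: tuple[str, ...] = STAGES[:9]

N_STAGES = len(STAGES)

FEMALE_ADULT_COL = STAGE_INDEX[FEMALE_ADULT] - 1  # 0-based column in grids
MALE_ADULT_COL = STAGE_INDEX[MALE_ADULT] - 1
PUPA_COL = STAGE_INDEX[PUPA] - 1


def next_stages(label: str) -> tuple[str, ...]:
    """Possible successor stages of ``label`` (empty for adult stages)."""
    idx = STAGE_INDEX[label]
    if label == PUPA:
        return (FEMALE_ADULT, MALE_ADULT)
    if idx >= STAGE_INDEX[PUPA]:
        return ()
    return (STAGES[idx],)  # idx is 1-based, so STAGES[idx] is the next label
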