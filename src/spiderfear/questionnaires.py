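"""Questionnaire, behavioral-approach-test, and interview scoring.

Implements the standard scoring rules of the instruments used in spider-fear
research:

* **SPQ** (Spider Questionnaire): 31 true/false items, nine reverse-scored,
  total 0-31.
* **SNAQ** (Snake Questionnaire): 30 true/false items, nine reverse-scored,
  total 0-30.
* **DS-R** (Disgust Scale - Revised): 25 disgust-elicitor items on a 0-4
  scale (items 1, 6, 10 reverse-scored) plus two catch questions (items 12
  and 16) excluded from the total; total 0-100.
* **BAT** (behavioral approach test): number of completed approach steps
  toward a live tarantula, 0-7 (7 = touched the animal with a finger).
* structured clinical interview: six yes/no questions; >= 5 fearful answers
  classify the respondent as phobic.

The identity of the nine reverse-keyed SPQ/SNAQ items and the DS-R
item-to-subscale map are not published; both are configuration inputs on
`ScoringKey` with documented defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np


@dataclass(frozen=True)
class ScoringKey:
    """Scoring rules for one instrument."""

    n_items: int
    reversed_items: frozenset = frozenset()
    catch_items: frozenset = frozenset()
    item_scale: str = "binary"  # "binary" | "likert0to4"
    catch_key: Mapping[int, int] = field(default_factory=dict)
    subscales: Mapping[str, tuple] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.reversed_items <= set(range(1, self.n_items + 1)):
            raise ValueError("reversed_items must be 1-based indices within the item range")
        if self.catch_items & self.reversed_items:
            raise ValueError("catch items must be disjoint from reverse-scored items")
        if self.item_scale not in ("binary", "likert0to4"):
            raise ValueError(f"unknown item_scale {self.item_scale!r}")


@dataclass(frozen=True)
class ScoreResult:
    total: int
    valid: bool = True
    subscale_totals: Mapping[str, int] | None = None


# default keys; reversed-item identities are a documented convention, not
# published item numbers
SPQ_KEY = ScoringKey(n_items=31, reversed_items=frozenset(range(1, 10)))
SNAQ_KEY = ScoringKey(n_items=30, reversed_items=frozenset(range(1, 10)))
DSR_KEY = ScoringKey(
    n_items=27,
    reversed_items=frozenset({1, 6, 10}),
    catch_items=frozenset({12, 16}),
    item_scale="likert0to4",
    catch_key={12: 0, 16: 4},
    # synthetic default assignment of the 25 elicitors to the three factors;
    # the instrument's real map is not printed in the sources we score against
    subscales={
        "core": tuple(i for i in (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 13) if i not in (12, 16)),
        "animal_reminder": (14, 15, 17, 18, 19, 20, 21, 22),
        "contamination": (23, 24, 25, 26, 27),
    },
)


def score_binary_questionnaire(responses: Sequence, key: ScoringKey = SPQ_KEY) -> ScoreResult:
    """Total = sum over items of (response XOR reverse-keyed).

    ``responses`` are the raw true/false answers in questionnaire order; a
    fearful answer on a regular item and a non-fearful answer on a
    reverse-keyed item each contribute one point.
    """
    responses = np.asarray(responses, dtype=bool)
    if responses.shape != (key.n_items,):
        raise ValueError(f"expected {key.n_items} responses, got {responses.shape}")
    rev = np.zeros(key.n_items, dtype=bool)
    for i in key.reversed_items:
        rev[i - 1] = True
    return ScoreResult(total=int(np.sum(responses ^ rev)))


def score_dsr(responses: Sequence[int], key: ScoringKey = DSR_KEY) -> ScoreResult:
    """DS-R total over the 25 elicitor items; catch items checked, not summed.

    Reverse items contribute ``4 - x``.  ``valid`` is False when any catch
    response differs from the keyed attention value; the total is still
    reported so the caller can apply the drop rule.
    """
    responses = np.asarray(responses, dtype=int)
    if responses.shape != (key.n_items,):
        raise ValueError(f"expected {key.n_items} responses, got {responses.shape}")
    if responses.min() < 0 or responses.max() > 4:
        raise ValueError("DS-R responses must lie in 0..4")

    def item_value(pos: int) -> int:
        x = int(responses[pos - 1])
        return 4 - x if pos in key.reversed_items else x

    scored_positions = [i for i in range(1, key.n_items + 1) if i not in key.catch_items]
    total = sum(item_value(i) for i in scored_positions)
    valid = all(int(responses[pos - 1]) == keyed for pos, keyed in key.catch_key.items())
    subscales = None
    if key.subscales:
        subscales = {
            name: sum(item_value(i) for i in items if i not in key.catch_items)
            for name, items in key.subscales.items()
        }
    return ScoreResult(total=int(total), valid=valid, subscale_totals=subscales)


def score_bat(steps_completed: Sequence[bool]) -> int:
    """BAT score = number of completed approach steps (0-7).

    The steps are ordered (walk closer x3, uncover and look, open the
    terrarium, touch with a pencil, touch with a finger) and must form a
    prefix: completing a later step without all earlier ones is invalid.
    Score 0 (no step attempted) is permitted.
    """
    steps = np.asarray(steps_completed, dtype=bool)
    if steps.size > 7:
        raise ValueError("at most 7 BAT steps")
    n_done = int(np.sum(steps))
    if not np.all(steps[:n_done]):
        raise ValueError("BAT steps must form a prefix (a later step requires all earlier ones)")
    return n_done


def classify_interview(answers: Sequence[bool]) -> str:
    """'phobic' iff at least five of the six answers imply high spider fear."""
    answers = np.asarray(answers, dtype=bool)
    if answers.shape != (6,):
        raise ValueError("interview has exactly 6 questions")
    return "phobic" if int(answers.sum()) >= 5 else "not_phobic"


def score_cohort(cohort_frame) -> "pd.DataFrame":  # noqa: F821
    """Append SPQ/SNAQ/DS-R totals and interview classification to a cohort table."""
    import pandas as pd

    df = cohort_frame.copy()
    spq_cols = [f"spq_{i:02d}" for i in range(1, 32)]
    snaq_cols = [f"snaq_{i:02d}" for i in range(1, 31)]
    dsr_cols = [f"dsr_{i:02d}" for i in range(1, 28)]
    int_cols = [f"interview_{i}" for i in range(1, 7)]
    df["spq"] = [score_binary_questionnaire(r, SPQ_KEY).total for r in df[spq_cols].to_numpy()]
    df["snaq"] = [score_binary_questionnaire(r, SNAQ_KEY).total for r in df[snaq_cols].to_numpy()]
    dsr = [score_dsr(r, DSR_KEY) for r in df[dsr_cols].to_numpy()]
    df["dsr"] = [r.total for r in dsr]
    df["dsr_valid"] = [r.valid for r in dsr]
    df["interview_class"] = [classify_interview(r) for r in df[int_cols].to_numpy()]
    return pd.DataFrame(df)
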