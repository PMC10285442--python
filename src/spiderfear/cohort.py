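"""Seeded synthetic cohort with planted phobic/control structure.

The generative model is an extreme-groups latent-trait model.  Each subject
carries three standardized latent traits -- spider fear, snake fear, disgust
propensity -- drawn from a trivariate normal whose spider component is
shifted between groups.  Every observed measure is a noisy monotone readout
of the relevant trait:

* binary questionnaire items (SPQ, SNAQ) follow a logistic item-response
  model with per-item difficulty; reverse-keyed items are stored in the
  raw (un-recoded) direction so the scoring module must undo them;
* DS-R elicitor items are a discretized linear readout of the disgust trait;
* the behavioral approach test (BAT) thresholds ``spider_trait + noise``
  against seven ordered cut-points, so high-fear subjects complete few steps;
* the six structured-interview questions are steep logistic readouts of the
  spider trait, calibrated so phobics almost always answer >= 5 in the
  fearful direction and controls essentially never do;
* 1-7 Likert fear ratings of six picture categories load on the spider trait
  (spider categories), the snake trait (snake/lizard), or neither
  (leaves/beetles).

All draws derive from ``EffectConfig.seed``; a fixed config reproduces the
cohort bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import EffectConfig, RATING_CATEGORIES

# --- item-response calibration (fixed; see docs/methods.md) -----------------
SPQ_N_ITEMS = 31
SNAQ_N_ITEMS = 30
DSR_N_ITEMS = 27
SPQ_REVERSED = frozenset(range(1, 10))  # 1-based; only the count (nine) is published
SNAQ_REVERSED = frozenset(range(1, 10))
DSR_REVERSED = frozenset({1, 6, 10})
DSR_CATCH = frozenset({12, 16})
DSR_CATCH_KEY = {12: 0, 16: 4}

_SPQ_SLOPE = 1.7
_SPQ_DIFF = np.linspace(0.9, 3.1, SPQ_N_ITEMS)
_SNAQ_SLOPE = 1.7
_SNAQ_DIFF = np.linspace(1.4, 3.8, SNAQ_N_ITEMS)
_DSR_LOAD = 0.6
_DSR_NOISE = 0.8
_DSR_BASE = np.linspace(0.7, 2.5, DSR_N_ITEMS - len(DSR_CATCH))
_BAT_CUTPOINTS = np.array([1.9, 2.7, 3.3, 3.8, 4.2, 4.6, 5.0])
_BAT_NOISE = 0.8
_INTERVIEW_SLOPE = 10.0
_INTERVIEW_DIFF = 1.5
_SNAQ_MAX_SCORE = 17  # study inclusion rule: no respondent above 17


@dataclass(eq=False)
class Subject:
    """One simulated respondent with raw (unscored) responses."""

    id: str
    group: str  # "phobic" | "control"
    age: float
    spider_trait: float
    snake_trait: float
    disgust_trait: float
    spq_items: np.ndarray = field(default=None)  # 31 bools, raw direction
    snaq_items: np.ndarray = field(default=None)  # 30 bools
    dsr_items: np.ndarray = field(default=None)  # 27 ints 0-4 (incl. 2 catch)
    bat_steps: int = 0
    interview_answers: np.ndarray = field(default=None)  # 6 bools
    ratings: dict = field(default_factory=dict)  # category -> (n_pictures,) ints 1-7

    def validate(self) -> None:
        assert len(self.spq_items) == SPQ_N_ITEMS
        assert len(self.snaq_items) == SNAQ_N_ITEMS
        assert len(self.dsr_items) == DSR_N_ITEMS
        assert 0 <= self.bat_steps <= 7
        assert len(self.interview_answers) == 6
        for cat, vals in self.ratings.items():
            if not np.all((vals >= 1) & (vals <= 7)):
                raise ValueError(f"ratings out of 1-7 range for {cat}")


def _binary_items(trait: float, slope: float, difficulty: np.ndarray,
                  reversed_items: frozenset, rng: np.random.Generator) -> np.ndarray:
    """Raw true/false responses whose *scored* direction is logistic in the trait."""
    p_scored = expit(slope * (trait - difficulty))
    scored = rng.random(len(difficulty)) < p_scored
    raw = scored.copy()
    for i in reversed_items:  # raw response is flipped for reverse-keyed items
        raw[i - 1] = ~scored[i - 1]
    return raw


def _binary_score(raw: np.ndarray, reversed_items: frozenset) -> int:
    s = 0
    for i, r in enumerate(raw, start=1):
        s += int(bool(r) != (i in reversed_items))
    return s


def _dsr_items(disgust_trait: float, rng: np.random.Generator) -> np.ndarray:
    items = np.zeros(DSR_N_ITEMS, dtype=int)
    elicitor_pos = [i for i in range(1, DSR_N_ITEMS + 1) if i not in DSR_CATCH]
    latent = _DSR_BASE + _DSR_LOAD * disgust_trait + rng.normal(0.0, _DSR_NOISE, len(elicitor_pos))
    scored = np.clip(np.rint(latent), 0, 4).astype(int)
    for pos, s in zip(elicitor_pos, scored):
        items[pos - 1] = (4 - s) if pos in DSR_REVERSED else s
    for pos, keyed in DSR_CATCH_KEY.items():
        items[pos - 1] = keyed
    return items


def _bat_steps(spider_trait: float, rng: np.random.Generator) -> int:
    # completed steps = number of cut-points still above the (noisy) fear level
    level = spider_trait + rng.normal(0.0, _BAT_NOISE)
    return int(np.sum(level < _BAT_CUTPOINTS))


def _interview(spider_trait: float, rng: np.random.Generator,
               group: str | None = None) -> np.ndarray:
    """Six monotone-logistic yes/no answers, selection-consistent with the group.

    Group membership in the emulated study was *defined* by the interview
    (phobics answered >= 5 in the fearful direction; controls scored 0 on all
    six), so draws inconsistent with the subject's recruited group are
    redrawn -- the analogue of the recruitment truncation.
    """
    p = expit(_INTERVIEW_SLOPE * (spider_trait - _INTERVIEW_DIFF))
    for _ in range(200):
        ans = rng.random(6) < p
        if group == "phobic" and ans.sum() < 5:
            continue
        if group == "control" and ans.sum() > 0:
            continue
        return ans
    # rejection exhausted (deep-tail trait): condition on the recruitment rule
    return np.full(6, group == "phobic")


def generate_ratings(subject: Subject, config: EffectConfig,
                     rng: np.random.Generator | None = None) -> dict:
    """Per-picture 1-7 fear ratings for the six stimulus categories.

    rating = round(clip(mu_c + w_c*spider + w'_c*snake + eps, 1, 7)) with 40
    unique pictures per category by default.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    out = {}
    for cat in RATING_CATEGORIES:
        if cat not in config.rating_mu:
            raise KeyError(f"unknown category {cat!r}")
        mu = (config.rating_mu[cat]
              + config.rating_weights.get(cat, 0.0) * subject.spider_trait
              + config.snake_rating_weights.get(cat, 0.0) * subject.snake_trait)
        eps = rng.normal(0.0, config.rating_noise_sd, config.pictures_per_category)
        out[cat] = np.clip(np.rint(mu + eps), 1, 7).astype(int)
    return out


def generate_cohort(config: EffectConfig) -> list[Subject]:
    """Generate the full seeded cohort (phobics first, then controls)."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    rho_s, rho_d = config.snake_trait_corr, config.disgust_trait_corr
    rho_sd = rho_s * rho_d
    cov = np.array([[1.0, rho_s, rho_d], [rho_s, 1.0, rho_sd], [rho_d, rho_sd, 1.0]])
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(3))

    mean_p, mean_c = config.trait_means
    subjects: list[Subject] = []
    groups = [("phobic", mean_p, config.n_phobic), ("control", mean_c, config.n_control)]
    idx = 0
    for group, mu, n in groups:
        for _ in range(n):
            idx += 1
            # recruitment truncation: redraw until the spider trait is
            # consistent with the group's screening rule
            for _attempt in range(1000):
                z = chol @ rng.standard_normal(3)
                spider = mu + config.trait_sd * z[0]
                if config.trait_truncation is None:
                    break
                lo, hi = config.trait_truncation
                if group == "phobic" and spider >= lo:
                    break
                if group == "control" and spider <= hi:
                    break
            snake = rho_s * mu + config.trait_sd * z[1]
            disgust = rho_d * mu + config.trait_sd * z[2]
            snake = min(snake, config.snake_trait_cap)
            subj = Subject(
                id=f"S{idx:03d}",
                group=group,
                age=float(rng.uniform(*config.age_range)),
                spider_trait=float(spider),
                snake_trait=float(snake),
                disgust_trait=float(disgust),
            )
            subj.spq_items = _binary_items(spider, _SPQ_SLOPE, _SPQ_DIFF, SPQ_REVERSED, rng)
            # SNAQ respects the study's inclusion cutoff: resample rare >17 draws
            for _attempt in range(100):
                snaq = _binary_items(snake, _SNAQ_SLOPE, _SNAQ_DIFF, SNAQ_REVERSED, rng)
                if _binary_score(snaq, SNAQ_REVERSED) <= _SNAQ_MAX_SCORE:
                    break
            subj.snaq_items = snaq
            subj.dsr_items = _dsr_items(disgust, rng)
            subj.bat_steps = _bat_steps(spider, rng)
            subj.interview_answers = _interview(spider, rng, group=group)
            subj.ratings = generate_ratings(subj, config, rng)
            subj.validate()
            subjects.append(subj)
    return subjects


def cohort_to_frame(subjects: Iterable[Subject]) -> pd.DataFrame:
    """Wide table: one row per subject, raw item responses in wide columns."""
    rows = []
    for s in subjects:
        row = {
            "subject_id": s.id,
            "group": s.group,
            "age": s.age,
            "spider_trait": s.spider_trait,
            "snake_trait": s.snake_trait,
            "disgust_trait": s.disgust_trait,
            "bat_steps": s.bat_steps,
        }
        row.update({f"spq_{i:02d}": int(v) for i, v in enumerate(s.spq_items, 1)})
        row.update({f"snaq_{i:02d}": int(v) for i, v in enumerate(s.snaq_items, 1)})
        row.update({f"dsr_{i:02d}": int(v) for i, v in enumerate(s.dsr_items, 1)})
        row.update({f"interview_{i}": int(v) for i, v in enumerate(s.interview_answers, 1)})
        rows.append(row)
    return pd.DataFrame(rows)


def ratings_to_frame(subjects: Iterable[Subject]) -> pd.DataFrame:
    """Long table: (subject, category, picture, rating)."""
    rows = []
    for s in subjects:
        for cat, vals in s.ratings.items():
            for j, r in enumerate(vals, 1):
                rows.append({"subject_id": s.id, "category": cat, "picture": j, "rating": int(r)})
    return pd.DataFrame(rows)
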