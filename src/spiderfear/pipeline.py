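"""End-to-end synthetic study: simulate, score, scan, analyze.

`run_study` chains all stages the way the analysis was designed: generate
the cohort, score the instruments, simulate both fMRI sessions and compute
each subject's Spider Fear Index, then run the multivariate analyses --
RDA of fear ratings on (group, SFI, SPQ, SNAQ, DS-R, BAT, age) with
sequential permutation tests, AIC reduction of the linear model for SFI,
discriminant classification into phobic/control, and Spearman correlations
among SFI, SPQ, BAT and the spider fear scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import generate_cohort, cohort_to_frame
from .config import BrainSpec, EffectConfig, RATING_CATEGORIES
from .correlation import spearman
from .discriminant import ConfusionMatrix, GroupDiscriminant
from .model_selection import SelectionResult, lm_aic_select
from .ordination import RDA, RDAResult, rda_sequential_test
from .questionnaires import score_cohort
from .sfi import SFIPipelineResult, sfi_pipeline

#: variables entering the RDA / LM / DFA, in the order terms are tested
RDA_TERMS = ("group", "sfi", "spq", "snaq", "dsr", "bat", "age")
DFA_FEATURES = ("fs_tarantula", "fs_snake", "fs_daddy_long_legs", "snaq")


@dataclass
class StudyResult:
    scores: pd.DataFrame  # one row per analyzed subject
    sfi: SFIPipelineResult
    rda: RDAResult
    rda_tests: pd.DataFrame
    selection: SelectionResult
    confusion: ConfusionMatrix
    variable_F: pd.DataFrame
    correlations: dict = field(default_factory=dict)


def subject_table(cohort, sfi_result: SFIPipelineResult | None = None) -> pd.DataFrame:
    """Scored per-subject table: questionnaires, BAT, category fear scores, SFI."""
    df = score_cohort(cohort_to_frame(cohort))
    df = df.rename(columns={"bat_steps": "bat"})
    fs = {
        f"fs_{cat}": [float(np.mean(s.ratings[cat])) for s in cohort]
        for cat in RATING_CATEGORIES
    }
    df = pd.concat([df, pd.DataFrame(fs, index=df.index)], axis=1)
    if sfi_result is not None:
        df = df.merge(sfi_result.table[["subject_id", "sfi"]], on="subject_id", how="inner")
    return df


def ratings_matrix(cohort, per_picture: bool = True) -> pd.DataFrame:
    """RDA response matrix: respondents x per-picture ratings (or category means)."""
    if per_picture:
        cols = {}
        for cat in RATING_CATEGORIES:
            n_pic = len(cohort[0].ratings[cat])
            for j in range(n_pic):
                cols[f"{cat}_{j + 1:02d}"] = [int(s.ratings[cat][j]) for s in cohort]
        return pd.DataFrame(cols, index=[s.id for s in cohort])
    return pd.DataFrame(
        {cat: [float(np.mean(s.ratings[cat])) for s in cohort] for cat in RATING_CATEGORIES},
        index=[s.id for s in cohort],
    )


def run_study(config: EffectConfig | None = None, spec: BrainSpec | None = None,
              seed: int = 0, n_perm: int = 1999, per_picture_ratings: bool = True,
              exclude_ids: tuple[str, ...] = (),
              selection_strategy: str = "backward") -> StudyResult:
    """Run the complete synthetic study and all downstream analyses."""
    if config is None:
        config = EffectConfig(seed=seed)
    if spec is None:
        spec = BrainSpec()
    cohort = generate_cohort(config)
    sfi_res = sfi_pipeline(cohort, spec, config, seed=seed, exclude_ids=exclude_ids)
    analyzed = [s for s in cohort if s.id not in set(exclude_ids)]
    df = subject_table(analyzed, sfi_res)
    df["group_num"] = (df["group"] == "phobic").astype(float)

    # RDA of fear ratings on the explanatory battery
    Y = ratings_matrix(analyzed, per_picture=per_picture_ratings)
    X = df[["group_num", "sfi", "spq", "snaq", "dsr", "bat", "age"]].rename(
        columns={"group_num": "group"})
    X = X.set_axis(list(RDA_TERMS), axis=1)
    rda_model = RDA().fit(X, Y)
    tests = rda_sequential_test(Y, X, term_order=list(RDA_TERMS), n_perm=n_perm, seed=seed)

    # LM of SFI on the subjective measures, reduced by AIC
    candidates = df[["bat", "spq", "snaq", "dsr",
                     "fs_tarantula", "fs_daddy_long_legs", "fs_leaves", "fs_beetle",
                     "fs_lizard", "fs_snake", "group_num", "age"]].rename(
        columns={"group_num": "group"})
    selection = lm_aic_select(df["sfi"], candidates, strategy=selection_strategy)

    # DFA on the strongest discriminators
    dfa = GroupDiscriminant().fit(df[list(DFA_FEATURES)], df["group"].to_numpy())
    confusion = dfa.confusion()

    fs_spider = df["fs_tarantula"].to_numpy()
    corr = {
        "sfi_spq": spearman(df["sfi"], df["spq"]),
        "sfi_bat": spearman(df["sfi"], df["bat"]),
        "sfi_fs": spearman(df["sfi"], fs_spider),
        "spq_bat": spearman(df["spq"], df["bat"]),
        "spq_fs": spearman(df["spq"], fs_spider),
        "bat_fs": spearman(df["bat"], fs_spider),
    }
    return StudyResult(scores=df, sfi=sfi_res, rda=rda_model.result(tests),
                       rda_tests=tests, selection=selection, confusion=confusion,
                       variable_F=dfa.variable_F_, correlations=corr)
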