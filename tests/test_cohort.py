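"""Cohort generator: determinism, calibration, monotone dose-response."""

import numpy as np
import pandas as pd
import pytest

from spiderfear import EffectConfig, cohort_to_frame, generate_cohort, generate_ratings
from spiderfear.cohort import SNAQ_REVERSED, _binary_score
from spiderfear.questionnaires import score_cohort


def _scored(config):
    return score_cohort(cohort_to_frame(generate_cohort(config)))


def zero_effect_config(n=200, seed=0):
    zeros = {c: 0.0 for c in ("tarantula", "daddy_long_legs", "beetle", "leaves", "snake", "lizard")}
    return EffectConfig(
        n_phobic=n, n_control=n, trait_means=(0.0, 0.0), activation_gain=0.0,
        rating_weights=zeros, snake_rating_weights=zeros, trait_truncation=None,
        seed=seed,
    )


class TestGenerateCohort:
    def test_determinism_bitwise(self, default_config):
        a = generate_cohort(default_config)
        b = generate_cohort(default_config)
        assert cohort_to_frame(a).equals(cohort_to_frame(b))
        for sa, sb in zip(a, b):
            for cat in sa.ratings:
                assert np.array_equal(sa.ratings[cat], sb.ratings[cat])

    def test_null_effect_no_group_difference(self):
        df = _scored(zero_effect_config(n=300, seed=3))
        means = df.groupby("group")["spq"].mean()
        # Monte-Carlo error of a mean-difference of ~binomial scores at n=300
        assert abs(means["phobic"] - means["control"]) < 1.0

    def test_default_group_ordering_and_calibration(self, default_config):
        df = _scored(default_config)
        m = df.groupby("group")[["spq", "bat_steps"]].mean()
        assert m.loc["phobic", "spq"] > m.loc["control", "spq"]
        assert m.loc["phobic", "bat_steps"] < m.loc["control", "bat_steps"]
        assert 18 <= m.loc["phobic", "spq"] <= 26
        assert 0 <= m.loc["control", "spq"] <= 5

    def test_item_vector_lengths_and_bounds(self, default_cohort):
        for s in default_cohort:
            assert len(s.spq_items) == 31
            assert len(s.snaq_items) == 30
            assert len(s.dsr_items) == 27
            assert len(s.interview_answers) == 6
            assert 0 <= s.bat_steps <= 7
            for vals in s.ratings.values():
                assert vals.min() >= 1 and vals.max() <= 7
                assert len(vals) == 40

    def test_snaq_inclusion_cutoff(self, default_cohort):
        scores = [_binary_score(s.snaq_items, SNAQ_REVERSED) for s in default_cohort]
        assert max(scores) <= 17

    def test_interview_matches_recruitment(self, default_cohort):
        for s in default_cohort:
            n_true = int(np.sum(s.interview_answers))
            if s.group == "phobic":
                assert n_true >= 5
            else:
                assert n_true == 0

    def test_monotone_dose_response(self):
        """Larger trait separation -> larger group gaps in every spider-linked observable."""
        spq_gaps, bat_gaps, fs_gaps = [], [], []
        for sep in (0.0, 1.5, 3.0):
            cfg = EffectConfig(n_phobic=150, n_control=150, trait_means=(sep, 0.0),
                               trait_truncation=None, seed=11)
            cohort = generate_cohort(cfg)
            df = score_cohort(cohort_to_frame(cohort))
            m = df.groupby("group")[["spq", "bat_steps"]].mean()
            spq_gaps.append(m.loc["phobic", "spq"] - m.loc["control", "spq"])
            bat_gaps.append(m.loc["control", "bat_steps"] - m.loc["phobic", "bat_steps"])
            fs = pd.Series(
                [np.mean(s.ratings["tarantula"]) for s in cohort],
                index=[s.group for s in cohort],
            )
            fs_gaps.append(fs.loc["phobic"].mean() - fs.loc["control"].mean())
        for gaps in (spq_gaps, bat_gaps, fs_gaps):
            assert gaps[0] < gaps[1] < gaps[2]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            EffectConfig(n_phobic=1, seed=0)
        with pytest.raises(ValueError):
            EffectConfig(snake_trait_corr=1.5, seed=0)
        with pytest.raises(ValueError):
            EffectConfig(trait_sd=0.0, seed=0)
        with pytest.raises(ValueError):
            EffectConfig(seed=None)

    def test_config_json_roundtrip(self, default_config):
        again = EffectConfig.from_json(default_config.to_json())
        assert again == default_config


class TestGenerateRatings:
    def test_floor_and_ceiling(self, default_cohort):
        subj = default_cohort[0]
        ones = {c: 0.0 for c in ("tarantula", "daddy_long_legs", "beetle", "leaves", "snake", "lizard")}
        floor_cfg = EffectConfig(rating_mu={c: 1.0 for c in ones}, rating_weights=ones,
                                 snake_rating_weights=ones, rating_noise_sd=0.0, seed=0)
        r = generate_ratings(subj, floor_cfg)
        assert all(np.all(v == 1) for v in r.values())
        ceil_cfg = EffectConfig(rating_mu={c: 9.0 for c in ones}, rating_weights=ones,
                                snake_rating_weights=ones, rating_noise_sd=0.0, seed=0)
        r = generate_ratings(subj, ceil_cfg)
        assert all(np.all(v == 7) for v in r.values())

    def test_phobic_tarantula_above_control(self, default_cohort):
        fs = {g: np.mean([np.mean(s.ratings["tarantula"]) for s in default_cohort if s.group == g])
              for g in ("phobic", "control")}
        assert fs["phobic"] > fs["control"]

    def test_unknown_category_raises(self, default_cohort):
        cfg = EffectConfig(rating_mu={"tarantula": 1.0}, seed=0)
        with pytest.raises(KeyError):
            generate_ratings(default_cohort[0], cfg)
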