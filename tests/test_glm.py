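"""Voxelwise OLS, contrast t-maps, group one-sample t-test."""

import numpy as np
import pytest
from scipy import stats

from spiderfear import BrainSpec, EffectConfig, fit_glm, simulate_bold
from spiderfear.bold import VolumeSeries, planted_betas
from spiderfear.cohort import Subject
from spiderfear.design import DesignMatrix, build_design_matrix, build_session
from spiderfear.glm import VoxelGLM, contrast_tmap, group_onesample_tmap


@pytest.fixture(scope="module")
def session():
    return build_session("spider", 4, seed=1)


@pytest.fixture(scope="module")
def design(session):
    return build_design_matrix(session)


def _series(data, tr=1.5):
    return VolumeSeries(data=data, tr_s=tr, subject_id="x")


class TestFitGLM:
    def test_noiseless_recovery_of_planted_betas(self, small_spec, session, design):
        spec = BrainSpec(grid_dims=small_spec.grid_dims, true_roi=small_spec.true_roi,
                         noise_sd=0.0, baseline_amplitude=0.2)
        cfg = EffectConfig(activation_gain=0.6, seed=0)
        subj = Subject(id="s", group="phobic", age=30, spider_trait=2.0,
                       snake_trait=0.0, disgust_trait=0.0)
        series = simulate_bold(subj, session, spec, cfg, seed=0, design=design)
        fit = fit_glm(series, design)
        planted = planted_betas(subj, design, spec, cfg)
        assert np.allclose(fit.betas, planted, atol=1e-8)
        assert np.allclose(fit.sigma2, 0.0, atol=1e-12)

    def test_y_equal_to_regressor_exact_fit(self, design):
        n_vol = design.n_volumes
        y = np.tile(design.column("tarantula"), (8, 1)).reshape(2, 2, 2, n_vol)
        fit = fit_glm(_series(y), design)
        j = design.regressor_names.index("tarantula")
        expected = np.zeros(design.n_regressors)
        expected[j] = 1.0
        assert np.allclose(fit.betas, expected, atol=1e-10)
        assert np.allclose(fit.sigma2, 0.0, atol=1e-12)

    def test_pure_noise_betas_within_sampling_bounds(self, design):
        rng = np.random.default_rng(7)
        y = rng.normal(0, 1, size=(1, 1, 1, design.n_volumes))
        glm = VoxelGLM().fit(design, _series(y))
        for name in ("tarantula", "daddy_long_legs", "beetle", "leaves"):
            c = np.zeros(design.n_regressors)
            c[design.regressor_names.index(name)] = 1.0
            t = glm.contrast(c).tvalues.ravel()[0]
            assert abs(t) < 4.0

    def test_matches_generic_lstsq_solver(self, design, rng):
        y = rng.normal(size=(3, 3, 3, design.n_volumes))
        fit = fit_glm(_series(y), design)
        oracle, *_ = np.linalg.lstsq(design.matrix, y.reshape(-1, design.n_volumes).T, rcond=None)
        assert np.allclose(fit.betas, oracle.T, atol=1e-9)

    def test_dimension_mismatch_raises(self, design):
        with pytest.raises(ValueError):
            fit_glm(_series(np.zeros((2, 2, 2, 10))), design)

    def test_rank_deficient_design_raises(self, design):
        m = np.column_stack([design.matrix, design.matrix[:, 0]])
        with pytest.raises(ValueError):
            DesignMatrix(matrix=m, regressor_names=design.regressor_names + ("dup",))


class TestContrastTmap:
    def test_antisymmetry(self, design, rng):
        y = rng.normal(size=(2, 2, 2, design.n_volumes))
        fit = fit_glm(_series(y), design)
        c = design.contrast_vector("tarantula", "beetle")
        t_pos = contrast_tmap(fit, c).tvalues
        t_neg = contrast_tmap(fit, -c).tvalues
        assert np.allclose(t_pos, -t_neg)

    def test_all_zero_contrast_raises(self, design, rng):
        y = rng.normal(size=(1, 1, 1, design.n_volumes))
        fit = fit_glm(_series(y), design)
        with pytest.raises(ValueError):
            contrast_tmap(fit, np.zeros(design.n_regressors))

    def test_textbook_two_regressor_oracle(self):
        """Hand-coded OLS t formula on a tiny fixed problem, matched to 1e-10."""
        X = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0], [1.0, 3.0], [1.0, 4.0]])
        y = np.array([1.1, 1.9, 3.2, 3.8, 5.1])
        dm = DesignMatrix(matrix=X, regressor_names=("intercept", "slope"))
        series = _series(y.reshape(1, 1, 1, 5))
        fit = fit_glm(series, dm)
        c = np.array([0.0, 1.0])
        t = contrast_tmap(fit, c).tvalues.ravel()[0]
        # independent brute-force computation
        beta = np.linalg.inv(X.T @ X) @ X.T @ y
        rss = float(np.sum((y - X @ beta) ** 2))
        s2 = rss / (5 - 2)
        t_oracle = beta[1] / np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        assert np.isclose(t, t_oracle, atol=1e-10)

    def test_planted_effect_raises_roi_t(self, small_spec, session, design):
        cfg = EffectConfig(activation_gain=0.8, seed=0)
        subj = Subject(id="s", group="phobic", age=30, spider_trait=3.0,
                       snake_trait=0.0, disgust_trait=0.0)
        series = simulate_bold(subj, session, small_spec, cfg, seed=3, design=design)
        fit = fit_glm(series, design)
        tmap = contrast_tmap(fit, design.contrast_vector("tarantula", "beetle"))
        roi = small_spec.roi_mask_array()
        assert tmap.tvalues[roi].mean() > tmap.tvalues[~roi].mean() + 2.0


class TestGroupOneSample:
    def test_matches_hand_formula(self, rng):
        maps = [rng.normal(size=(4, 4, 4)) for _ in range(12)]
        gm = group_onesample_tmap(maps)
        stack = np.stack(maps)
        expected = stack.mean(0) / (stack.std(0, ddof=1) / np.sqrt(12))
        assert np.allclose(gm.tvalues, expected)
        assert gm.df == 11
        # cross-check against scipy's one-sample t at one voxel
        t_sp = stats.ttest_1samp(stack[:, 0, 0, 0], 0.0).statistic
        assert np.isclose(gm.tvalues[0, 0, 0], t_sp)

    def test_sign_flip_negates(self, rng):
        maps = [rng.normal(size=(3, 3, 3)) for _ in range(5)]
        a = group_onesample_tmap(maps).tvalues
        b = group_onesample_tmap([-m for m in maps]).tvalues
        assert np.allclose(a, -b)

    def test_identical_maps_flagged_infinite(self):
        m = np.ones((2, 2, 2))
        gm = group_onesample_tmap([m, m, m])
        assert np.all(np.isinf(gm.tvalues))
        assert np.all(gm.tvalues > 0)

    def test_fewer_than_two_raises(self):
        with pytest.raises(ValueError):
            group_onesample_tmap([np.zeros((2, 2, 2))])


def test_null_type_one_error_calibrated(design):
    """Under pure noise, ~5% of voxels exceed the two-sided 5% critical value."""
    rng = np.random.default_rng(99)
    y = rng.normal(size=(12, 12, 12, design.n_volumes))
    fit = fit_glm(_series(y), design)
    tmap = contrast_tmap(fit, design.contrast_vector("tarantula", "beetle"))
    crit = stats.t.ppf(0.975, df=fit.df)
    frac = np.mean(np.abs(tmap.tvalues) > crit)
    n = tmap.tvalues.size
    ci = 3 * np.sqrt(0.05 * 0.95 / n)
    assert abs(frac - 0.05) < ci + 0.01
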