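"""ROI definition and Spider Fear Index computation."""

import numpy as np
import pytest

from spiderfear import BrainSpec, EffectConfig, compute_sfi, define_roi, generate_cohort
from spiderfear.glm import StatMap
from spiderfear.sfi import EmptyROIError, ROIMask, sfi_pipeline


def _tmap(values, df=30):
    return StatMap(tvalues=np.asarray(values, dtype=float), df=df)


class TestDefineROI:
    def test_single_voxel_no_correction_factor(self):
        from scipy import stats
        df = 20
        t_sig = stats.t.ppf(0.96, df)  # one-sided p ~ 0.04 < 0.05
        roi = define_roi(_tmap(np.array([[[t_sig]]]), df=df), alpha=0.05)
        assert roi.n_voxels == 1
        t_ns = stats.t.ppf(0.94, df)  # p ~ 0.06
        roi = define_roi(_tmap(np.array([[[t_ns]]]), df=df), alpha=0.05)
        assert roi.n_voxels == 0

    def test_infinite_sentinels_excluded_from_candidacy(self):
        t = np.zeros((2, 2, 2))
        t[0, 0, 0] = np.inf
        t[1, 1, 1] = 8.0
        roi = define_roi(_tmap(t, df=25), alpha=0.05)
        assert not roi.mask[0, 0, 0]
        assert roi.mask[1, 1, 1]

    def test_planted_effect_recovers_true_roi(self, small_spec):
        """Strong planted gain: ROI covers most true voxels, few false positives."""
        from spiderfear.bold import simulate_bold
        from spiderfear.design import build_design_matrix, build_session
        from spiderfear.glm import VoxelGLM, group_onesample_tmap

        session = build_session("fear", 8, seed=0)
        design = build_design_matrix(session)
        cfg = EffectConfig(activation_gain=1.0, seed=0)
        cohort = generate_cohort(EffectConfig(n_phobic=12, n_control=2, seed=4))
        phobics = [s for s in cohort if s.group == "phobic"]
        c = design.contrast_vector("tarantula", "beetle")
        maps = []
        for i, subj in enumerate(phobics):
            series = simulate_bold(subj, session, small_spec, cfg, seed=100 + i, design=design)
            maps.append(VoxelGLM().fit(design, series).contrast_estimates(c))
        gm = group_onesample_tmap(maps)
        roi = define_roi(gm, alpha=0.05)
        truth = small_spec.roi_mask_array()
        assert (roi.mask & truth).sum() >= 0.75 * truth.sum()
        assert (roi.mask & ~truth).sum() <= 2

    def test_max_t_permutation_agrees_on_strong_effect(self, rng):
        maps = [rng.normal(0, 1, (5, 5, 5)) for _ in range(14)]
        for m in maps:
            m[2, 2, 2] += 4.0  # strong common effect at one voxel
        from spiderfear.glm import group_onesample_tmap

        gm = group_onesample_tmap(maps)
        roi_b = define_roi(gm, alpha=0.05, method="bonferroni")
        roi_p = define_roi(gm, alpha=0.05, method="max_t_permutation",
                           subject_maps=maps, n_perm=499, seed=0)
        assert roi_b.mask[2, 2, 2] and roi_p.mask[2, 2, 2]
        assert roi_p.mask.sum() <= roi_b.mask.sum() + 2

    def test_unknown_method_raises(self):
        with pytest.raises(ValueError):
            define_roi(_tmap(np.ones((2, 2, 2))), method="fdr")


class TestComputeSFI:
    def test_mean_of_constant_is_constant(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[0, 0, 0] = mask[1, 1, 1] = True
        roi = ROIMask(mask=mask, alpha=0.05, method="bonferroni")
        t = np.full((3, 3, 3), 2.5)
        assert compute_sfi(_tmap(t), roi).sfi == 2.5

    def test_two_voxel_arithmetic_mean(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[0, 0, 0] = mask[2, 2, 2] = True
        roi = ROIMask(mask=mask, alpha=0.05, method="bonferroni")
        t = np.zeros((3, 3, 3))
        t[0, 0, 0], t[2, 2, 2] = 1.0, 3.0
        assert compute_sfi(_tmap(t), roi).sfi == 2.0

    def test_empty_roi_raises(self):
        roi = ROIMask(mask=np.zeros((2, 2, 2), dtype=bool), alpha=0.05, method="bonferroni")
        with pytest.raises(EmptyROIError):
            compute_sfi(_tmap(np.ones((2, 2, 2))), roi)

    def test_grid_mismatch_raises(self):
        roi = ROIMask(mask=np.ones((2, 2, 2), dtype=bool), alpha=0.05, method="bonferroni")
        with pytest.raises(ValueError):
            compute_sfi(_tmap(np.ones((3, 3, 3))), roi)

    def test_invariant_to_voxel_relabeling(self, rng):
        mask = rng.random((4, 4, 4)) < 0.3
        mask[0, 0, 0] = True
        t = rng.normal(size=(4, 4, 4))
        roi = ROIMask(mask=mask, alpha=0.05, method="bonferroni")
        sfi = compute_sfi(_tmap(t), roi).sfi
        perm = rng.permutation(64)
        t2 = t.ravel()[perm].reshape(4, 4, 4)
        m2 = mask.ravel()[perm].reshape(4, 4, 4)
        roi2 = ROIMask(mask=m2, alpha=0.05, method="bonferroni")
        assert np.isclose(compute_sfi(_tmap(t2), roi2).sfi, sfi)


@pytest.fixture(scope="module")
def small_run(small_spec):
    cfg = EffectConfig(n_phobic=8, n_control=8, seed=2)
    cohort = generate_cohort(cfg)
    return cohort, sfi_pipeline(cohort, small_spec, cfg, seed=2, blocks_per_condition=4)


class TestPipeline:
    def test_phobic_sfi_above_control(self, small_run):
        _, res = small_run
        m = res.table.groupby("group")["sfi"].mean()
        assert m["phobic"] > m["control"]

    def test_determinism(self, small_spec, small_run):
        cohort, res = small_run
        cfg = EffectConfig(n_phobic=8, n_control=8, seed=2)
        again = sfi_pipeline(cohort, small_spec, cfg, seed=2, blocks_per_condition=4)
        assert res.table.equals(again.table)
        assert np.array_equal(res.roi.mask, again.roi.mask)

    def test_zero_gain_raises_empty_roi(self, small_spec):
        cfg = EffectConfig(n_phobic=6, n_control=2, activation_gain=0.0, seed=3)
        cohort = generate_cohort(cfg)
        with pytest.raises(EmptyROIError):
            sfi_pipeline(cohort, small_spec, cfg, seed=3, blocks_per_condition=4)

    def test_exclusion_hook(self, small_spec, small_run):
        cohort, _ = small_run
        cfg = EffectConfig(n_phobic=8, n_control=8, seed=2)
        res = sfi_pipeline(cohort, small_spec, cfg, seed=2, blocks_per_condition=4,
                           exclude_ids=(cohort[0].id,))
        assert cohort[0].id not in set(res.table.subject_id)
        assert len(res.table) == 15

    def test_roi_independent_session_null_sfi_centered(self, small_spec):
        """ROI from the fear session; a null spider session gives SFI ~ 0."""
        cfg = EffectConfig(n_phobic=10, n_control=2, seed=6)
        cohort = generate_cohort(cfg)
        cfg_null = EffectConfig(n_phobic=10, n_control=2, seed=6, activation_gain=0.5)
        res = sfi_pipeline(cohort, small_spec, cfg_null, seed=6, blocks_per_condition=4)
        # now recompute SFI from pure-noise t-maps restricted to that ROI
        rng = np.random.default_rng(0)
        sfis = []
        for _ in range(200):
            t = rng.standard_t(df=300, size=small_spec.grid_dims)
            sfis.append(compute_sfi(_tmap(t, df=300), res.roi).sfi)
        se = np.std(sfis) / np.sqrt(len(sfis))
        assert abs(np.mean(sfis)) < 4 * se + 0.05
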