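"""Smoothing, voxelwise statistics, TFCE, permutation FWE, ROI tests."""

import numpy as np
import pytest
from scipy import stats

import stategrain as sg
from stategrain.inference import (
    FWHM_TO_SIGMA,
    PermutationScheme,
    TFCEParams,
    _tfce_max_batch,
    paired_t_map,
    pairwise_target_tests,
    permutation_fwe,
    repeated_anova_map,
    smooth_map,
    tfce_enhance,
)

from _tfce_oracle import tfce_bruteforce


class TestSmoothing:
    def test_sigma_conversion(self):
        # 6 mm FWHM at 2 mm voxels: sigma = 6 / (2 sqrt(2 ln 2)) / 2
        assert 6.0 * FWHM_TO_SIGMA / 2.0 == pytest.approx(1.274, abs=1e-3)

    def test_constant_volume_unchanged(self):
        vol = np.full((8, 8, 8), 3.3)
        np.testing.assert_allclose(smooth_map(vol, 6.0, 2.0), vol, atol=1e-12)

    def test_zero_fwhm_is_identity(self, rng):
        vol = rng.normal(size=(6, 6, 6))
        np.testing.assert_array_equal(smooth_map(vol, 0.0, 2.0), vol)

    def test_global_mean_preserved(self, rng):
        vol = rng.normal(size=(10, 10, 10))
        sm = smooth_map(vol, 6.0, 2.0)
        assert sm.mean() == pytest.approx(vol.mean(), abs=1e-10)

    def test_impulse_spreads_with_requested_sigma(self):
        vol = np.zeros((21, 21, 21))
        vol[10, 10, 10] = 1.0
        sm = smooth_map(vol, 6.0, 2.0)
        x = np.arange(21) - 10.0
        marginal = sm.sum(axis=(1, 2))
        sigma_emp = np.sqrt((marginal * x**2).sum() / marginal.sum())
        assert sigma_emp == pytest.approx(6.0 * FWHM_TO_SIGMA / 2.0, rel=0.02)

    def test_nan_voxels_stay_nan_and_do_not_leak(self):
        vol = np.ones((8, 8, 8))
        vol[2, 2, 2] = np.nan
        sm = smooth_map(vol, 4.0, 2.0)
        assert np.isnan(sm[2, 2, 2])
        valid = np.isfinite(sm)
        np.testing.assert_allclose(sm[valid], 1.0, atol=1e-12)


class TestStatMaps:
    def test_paired_t_matches_hand_arithmetic(self):
        a = np.array([1.1, 1.3, 1.2, 1.2]).reshape(4, 1, 1, 1)
        b = np.array([1.0, 1.0, 1.0, 1.0]).reshape(4, 1, 1, 1)
        # diffs (0.1, 0.3, 0.2, 0.2): mean 0.2, sd sqrt(0.02/3)
        sm = paired_t_map(a, b)
        expected = 0.2 / (np.sqrt(0.02 / 3.0) / 2.0)
        assert sm.values[0, 0, 0] == pytest.approx(expected, abs=1e-12)
        assert sm.df == 3.0

    def test_identical_stacks_give_zero_or_nan(self, rng):
        a = rng.normal(size=(5, 4, 4, 4))
        sm = paired_t_map(a, a.copy())
        assert np.isnan(sm.values).all()  # zero-variance everywhere

    def test_two_level_anova_is_squared_paired_t(self, rng):
        a = rng.normal(size=(6, 5, 5, 5))
        b = rng.normal(size=(6, 5, 5, 5))
        t = paired_t_map(a, b).values
        f = repeated_anova_map({"x": a, "y": b}).values
        np.testing.assert_allclose(f, t**2, atol=1e-8)

    def test_three_level_anova_matches_hand_partition(self):
        # subjects × conditions table [[1,2,3],[2,4,6],[3,3,3]]:
        # SS_cond = 6, SS_subj = 6, SS_err = 4, F = (6/2)/(4/4) = 3
        data = np.array(
            [[[1.0], [2.0], [3.0]], [[2.0], [4.0], [3.0]], [[3.0], [6.0], [3.0]]]
        )  # (k=3 conditions, n=3 subjects, 1 voxel)
        data = data.reshape(3, 3, 1, 1, 1)
        sm = repeated_anova_map(data)
        assert sm.values[0, 0, 0] == pytest.approx(3.0, abs=1e-12)
        assert sm.df == (2.0, 4.0)

    def test_equal_means_give_small_f(self, rng):
        base = rng.normal(size=(8, 6, 6, 6))
        noise = {t: base + 0.01 * rng.normal(size=base.shape) for t in "abc"}
        sm = repeated_anova_map(noise)
        assert np.nanmedian(sm.values) < 5.0


class TestTfce:
    def test_zero_map_enhances_to_zero(self):
        out = tfce_enhance(np.zeros((6, 6, 6)))
        np.testing.assert_array_equal(out, 0.0)

    def test_isolated_voxel_integrates_to_cubed_height(self):
        vol = np.zeros((9, 9, 9))
        h = 2.0
        vol[4, 4, 4] = h
        out = tfce_enhance(vol, TFCEParams(E=0.5, H=2.0))
        # analytic: ∫0..h 1^0.5 t² dt = h³/3, up to dh discretization
        assert out[4, 4, 4] == pytest.approx(h**3 / 3.0, rel=0.02)
        assert (out[vol == 0] == 0).all()

    def test_two_voxel_plateau_scales_with_sqrt_extent(self):
        vol = np.zeros((9, 9, 9))
        h = 1.5
        vol[4, 4, 4] = vol[4, 4, 5] = h
        out = tfce_enhance(vol, TFCEParams(E=0.5, H=2.0))
        expected = np.sqrt(2.0) * h**3 / 3.0
        assert out[4, 4, 4] == pytest.approx(expected, rel=0.02)
        assert out[4, 4, 5] == pytest.approx(expected, rel=0.02)

    def test_negative_values_enhanced_separately(self):
        vol = np.zeros((7, 7, 7))
        vol[1, 1, 1] = 2.0
        vol[5, 5, 5] = -2.0
        out = tfce_enhance(vol, TFCEParams(E=0.5, H=2.0))
        assert out[1, 1, 1] > 0
        assert out[5, 5, 5] == pytest.approx(-out[1, 1, 1], abs=1e-12)

    def test_matches_bruteforce_on_random_maps(self, rng):
        # explicit dh not aligned with any map's peak, so both paths see
        # the same threshold set without floating-point edge effects
        params = TFCEParams(E=0.5, H=2.0, dh=0.0731, connectivity=26)
        for _ in range(5):
            vol = rng.normal(size=(8, 8, 8))
            vol[vol < 0.3] = 0.0
            expected = tfce_bruteforce(vol, 0.5, 2.0, 0.0731, 26)
            got = tfce_enhance(vol, params)
            np.testing.assert_allclose(got, expected, atol=1e-8)

    def test_monotone_in_input(self, rng):
        params = TFCEParams(E=0.5, H=2.0, dh=0.05)
        vol = np.abs(rng.normal(size=(6, 6, 6)))
        base = tfce_enhance(vol, params)
        bumped = vol.copy()
        i = tuple(rng.integers(0, 6, size=3))
        bumped[i] += 0.5
        out = tfce_enhance(bumped, params)
        assert (out >= base - 1e-12).all()

    def test_batch_maxima_equal_per_map_enhancement(self, rng):
        params = TFCEParams()
        stack = rng.normal(size=(7, 8, 8, 8))
        mask = np.ones((8, 8, 8), dtype=bool)
        batch = _tfce_max_batch(stack, params, mask)
        for i in range(len(stack)):
            per_map = tfce_enhance(np.clip(stack[i], 0, None), params, mask).max()
            assert batch[i] == pytest.approx(per_map, rel=1e-10, abs=1e-12)


class TestPermutationFwe:
    def test_exhaustive_sign_flips_and_minimum_p(self, rng):
        a = rng.normal(size=(10, 5, 5, 5))
        b = rng.normal(size=(10, 5, 5, 5))
        cp = permutation_fwe(
            (a, b), scheme=PermutationScheme(n_perms=5000, seed=0)
        )
        assert cp.exhaustive
        assert cp.n_perms_used == 1024  # all 2^10 sign flips
        valid = np.isfinite(cp.p)
        assert np.nanmin(cp.p[valid]) >= 1.0 / 1024
        assert np.nanmax(cp.p[valid]) <= 1.0

    def test_p_monotone_in_enhanced_statistic(self, rng):
        a = rng.normal(size=(8, 6, 6, 6)) + 0.4
        b = rng.normal(size=(8, 6, 6, 6))
        cp = permutation_fwe((a, b), scheme=PermutationScheme(n_perms=200, seed=1))
        enh = cp.enhanced.ravel()
        p = cp.p.ravel()
        pos = enh > 0
        order = np.argsort(enh[pos])
        assert (np.diff(p[pos][order]) <= 1e-12).all()

    def test_strong_planted_effect_detected(self):
        cfg = sg.SimulationConfig(
            n_subjects=10, grid_shape=(10, 10, 10), targets=("self", "far"),
            n_states=8, dispersion_by_target={"self": 1.2, "far": 0.1},
            baseline_dispersion=0.3, noise_sd=0.1, seed=30,
        )
        mask = np.ones(cfg.grid_shape, dtype=bool)
        region = cfg.region_mask()
        maps = {"self": [], "far": []}
        for s in range(cfg.n_subjects):
            ps = sg.simulate_subject_betas(cfg, s)
            d = sg.searchlight_distinctiveness(ps, mask, radius=2, min_voxels=10)
            for t in maps:
                maps[t].append(smooth_map(d[t].values, 4.0, 2.0))
        cp = permutation_fwe(
            (np.array(maps["self"]), np.array(maps["far"])),
            scheme=PermutationScheme(n_perms=500, seed=31),
        )
        assert np.nanmin(cp.p[region]) < 0.05

    def test_anova_contrast_exhaustive_for_tiny_design(self, rng):
        data = {t: rng.normal(size=(3, 4, 4, 4)) for t in ("x", "y")}
        cp = permutation_fwe(
            data, contrast="anova",
            scheme=PermutationScheme(n_perms=100, seed=2, kind="target-relabel"),
        )
        assert cp.exhaustive
        assert cp.n_perms_used == 8  # (2!)^3 relabelings
        assert np.nanmin(cp.p) >= 1.0 / 8

    def test_rerun_with_same_seed_is_deterministic(self, rng):
        a = rng.normal(size=(8, 5, 5, 5))
        b = rng.normal(size=(8, 5, 5, 5))
        p1 = permutation_fwe((a, b), scheme=PermutationScheme(300, seed=9)).p
        p2 = permutation_fwe((a, b), scheme=PermutationScheme(300, seed=9)).p
        np.testing.assert_array_equal(p1, p2)


class TestPairwiseTargetTests:
    def test_hand_computed_cohens_d(self):
        a = np.array([1.1, 1.2, 1.3, 1.2])
        b = np.array([1.0, 1.0, 1.0, 1.0])
        # diffs (0.1, 0.2, 0.3, 0.2): mean 0.2, sd sqrt(0.02/3)
        res = pairwise_target_tests({"self": a, "far": b})[0]
        sd = np.sqrt(0.02 / 3.0)
        assert res.cohen_d == pytest.approx(0.2 / sd, abs=1e-12)
        assert res.t == pytest.approx(0.2 / (sd / 2.0), abs=1e-12)
        assert res.mean_diff == pytest.approx(0.2)
        assert res.delta_r == pytest.approx(-0.2)
        expected_p = 2 * stats.t.sf(res.t, df=3)
        assert res.p == pytest.approx(expected_p, abs=1e-12)

    def test_identical_scalars_give_null_result(self):
        a = np.array([0.5, 0.6, 0.7])
        res = pairwise_target_tests({"self": a, "far": a.copy()})[0]
        assert res.t == 0.0 and res.p == 1.0

    def test_bonferroni_multiplies_and_caps(self):
        rng = np.random.default_rng(5)
        scalars = {t: rng.normal(size=6) for t in ("self", "close", "far")}
        out = pairwise_target_tests(scalars, bonferroni_m=3)
        for r in out:
            assert r.p_adjusted == pytest.approx(min(1.0, 3 * r.p), abs=1e-12)

    def test_constant_nonzero_difference_rejected(self):
        a = np.array([1.0, 1.0, 1.0])
        b = np.array([0.5, 0.5, 0.5])
        with pytest.raises(ValueError, match="zero-variance"):
            pairwise_target_tests({"self": a, "far": b})
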