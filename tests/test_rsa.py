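"""Correlation-distance RDMs, the distinctiveness statistic, searchlights."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import stategrain as sg
from stategrain.rsa import (
    RDM,
    average_target_dissimilarity,
    compute_rdm,
    correct_block_structure,
    roi_distinctiveness,
    searchlight_centers,
    searchlight_distinctiveness,
    sphere_offsets,
)


def _hand_pearson(x, y):
    """Brute-force Pearson r from the covariance formula."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / (vx * vy) ** 0.5


class TestComputeRdm:
    def test_identical_patterns_have_zero_distance(self):
        v = np.array([1.0, 2.0, 5.0, 3.0])
        rdm = compute_rdm({("a", "s1"): v, ("a", "s2"): v.copy()})
        assert rdm.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_negated_pattern_has_distance_two(self):
        v = np.array([1.0, -2.0, 0.5, 3.0])
        rdm = compute_rdm({("a", "s1"): v, ("a", "s2"): -v})
        assert rdm.matrix[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_matches_hand_computed_correlations(self):
        vecs = {
            ("a", "s1"): np.array([1.0, 2.0, 4.0, 3.0]),
            ("a", "s2"): np.array([0.0, 1.0, 1.0, 5.0]),
            ("a", "s3"): np.array([2.0, -1.0, 0.0, 1.0]),
        }
        rdm = compute_rdm(vecs)
        keys = list(vecs)
        for i, j in combinations(range(3), 2):
            expected = 1.0 - _hand_pearson(vecs[keys[i]], vecs[keys[j]])
            assert rdm.matrix[i, j] == pytest.approx(expected, abs=1e-12)

    def test_constant_pattern_dropped_and_recorded(self):
        vecs = {
            ("a", "s1"): np.array([1.0, 2.0, 3.0]),
            ("a", "s2"): np.array([5.0, 5.0, 5.0]),
            ("a", "s3"): np.array([3.0, 1.0, 2.0]),
        }
        rdm = compute_rdm(vecs)
        assert rdm.dropped == [("a", "s2")]
        assert rdm.n_conditions == 2

    def test_all_constant_raises(self):
        vecs = {("a", "s1"): np.ones(4), ("a", "s2"): np.full(4, 2.0)}
        with pytest.raises(ValueError, match="non-constant"):
            compute_rdm(vecs)

    def test_short_patterns_rejected(self):
        with pytest.raises(ValueError, match="length"):
            compute_rdm({("a", "1"): np.array([1.0, 2.0]),
                         ("a", "2"): np.array([2.0, 1.0])})

    def test_rdm_invariants_on_random_patterns(self, rng):
        vecs = {("t", f"s{i}"): rng.normal(size=40) for i in range(8)}
        rdm = compute_rdm(vecs)
        m = rdm.matrix
        np.testing.assert_allclose(m, m.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(m), 0.0, atol=1e-12)
        assert m.min() >= 0.0 and m.max() <= 2.0


class TestAverageTargetDissimilarity:
    def _rdm_for(self, values, n_states=30):
        conds = [("self", f"s{i}") for i in range(n_states)] + [("far", "f0"), ("far", "f1")]
        n = len(conds)
        m = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        m[iu] = values
        m = m + m.T
        return RDM(conditions=conds, matrix=m)

    def test_mean_over_all_within_target_pairs(self, rng):
        n = 32
        vals = rng.uniform(0.1, 1.9, size=n * (n - 1) // 2)
        rdm = self._rdm_for(vals)
        idx = [i for i, (t, _) in enumerate(rdm.conditions) if t == "self"]
        pairs = list(combinations(idx, 2))
        assert len(pairs) == 435  # C(30, 2)
        expected = sum(rdm.matrix[i, j] for i, j in pairs) / len(pairs)
        got = average_target_dissimilarity(rdm, "self")
        assert got == pytest.approx(expected, abs=1e-12)

    def test_constant_entries_give_that_constant(self):
        conds = [("a", "1"), ("a", "2"), ("a", "3")]
        m = np.full((3, 3), 0.7)
        np.fill_diagonal(m, 0.0)
        assert average_target_dissimilarity(RDM(conds, m), "a") == pytest.approx(0.7)

    def test_cross_target_entries_never_contribute(self, rng):
        vals = rng.uniform(0.1, 1.9, size=32 * 31 // 2)
        rdm = self._rdm_for(vals)
        base = average_target_dissimilarity(rdm, "self")
        m = rdm.matrix.copy()
        sf = [i for i, (t, _) in enumerate(rdm.conditions) if t == "far"]
        ss = [i for i, (t, _) in enumerate(rdm.conditions) if t == "self"]
        for i in ss:
            for j in sf:
                m[i, j] = m[j, i] = 1.23
        perturbed = RDM(rdm.conditions, m)
        assert average_target_dissimilarity(perturbed, "self") == base

    def test_single_state_rejected(self):
        conds = [("a", "1"), ("b", "1"), ("b", "2")]
        m = np.zeros((3, 3))
        with pytest.raises(ValueError, match="fewer than 2"):
            average_target_dissimilarity(RDM(conds, m), "a")


class TestSearchlightGeometry:
    def test_radius_four_sphere_has_257_voxels(self):
        # brute-force enumeration oracle over the bounding cube
        count = sum(
            1
            for x in range(-4, 5)
            for y in range(-4, 5)
            for z in range(-4, 5)
            if x * x + y * y + z * z <= 16
        )
        assert count == 257
        assert len(sphere_offsets(4)) == count

    def test_interior_center_gets_full_sphere(self):
        mask = np.ones((11, 11, 11), dtype=bool)
        centers, _ = searchlight_centers(mask, radius=4)
        by_center = dict((c, len(nbr)) for c, nbr in centers)
        assert by_center[(5, 5, 5)] == 257

    def test_radius_zero_is_center_only(self):
        mask = np.ones((4, 4, 4), dtype=bool)
        centers, _ = searchlight_centers(mask, radius=0, min_voxels=1)
        for c, nbr in centers:
            assert nbr.shape == (1, 3)
            assert tuple(nbr[0]) == c

    def test_corner_neighborhood_smaller_than_interior(self):
        mask = np.ones((9, 9, 9), dtype=bool)
        centers, _ = searchlight_centers(mask, radius=2, min_voxels=1)
        sizes = dict((c, len(nbr)) for c, nbr in centers)
        assert sizes[(0, 0, 0)] < sizes[(4, 4, 4)]

    def test_small_neighborhoods_skipped(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[:2, :2, :2] = True  # 8 voxels only
        centers, skipped = searchlight_centers(mask, radius=2, min_voxels=30)
        assert centers == []
        assert len(skipped) == 8

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            searchlight_centers(np.zeros((3, 3, 3), dtype=bool), radius=1)


class TestSearchlightDistinctiveness:
    def test_matches_per_center_rdm_loop(self, small_patterns):
        """The vectorized engine equals explicit per-center RDM averaging."""
        mask = np.ones(small_patterns.grid_shape, dtype=bool)
        maps = searchlight_distinctiveness(
            small_patterns, mask, radius=2, min_voxels=10
        )
        centers, _ = searchlight_centers(mask, radius=2, min_voxels=10)
        rng = np.random.default_rng(0)
        for c, nbr in [centers[i] for i in rng.choice(len(centers), 25, replace=False)]:
            vox_mask = np.zeros(mask.shape, dtype=bool)
            vox_mask[nbr[:, 0], nbr[:, 1], nbr[:, 2]] = True
            rdm = compute_rdm(small_patterns, voxel_index=vox_mask)
            for t in ("self", "far"):
                expected = average_target_dissimilarity(rdm, t)
                assert maps[t].values[c] == pytest.approx(expected, abs=1e-10)

    def test_planted_effect_direction(self):
        cfg = sg.SimulationConfig(
            n_subjects=6, grid_shape=(10, 10, 10), targets=("self", "far"),
            n_states=8, dispersion_by_target={"self": 1.0, "far": 0.2},
            baseline_dispersion=0.3, noise_sd=0.2, seed=21,
        )
        mask = np.ones(cfg.grid_shape, dtype=bool)
        region = cfg.region_mask()
        diffs = []
        for s in range(cfg.n_subjects):
            ps = sg.simulate_subject_betas(cfg, s)
            maps = searchlight_distinctiveness(ps, mask, radius=2, min_voxels=10)
            diffs.append(maps["self"].values - maps["far"].values)
        group = np.nanmean(diffs, axis=0)
        assert np.nanmean(group[region]) > 0
        assert np.nanmean(group[region]) > np.nanmean(group[~region])

    def test_null_difference_centered_on_zero(self):
        cfg = sg.SimulationConfig(
            n_subjects=8, grid_shape=(8, 8, 8), targets=("self", "far"),
            n_states=8, dispersion_by_target={"self": 0.5, "far": 0.5},
            baseline_dispersion=0.5, noise_sd=0.3, seed=4,
        )
        mask = np.ones(cfg.grid_shape, dtype=bool)
        diffs = []
        for s in range(cfg.n_subjects):
            ps = sg.simulate_subject_betas(cfg, s)
            maps = searchlight_distinctiveness(ps, mask, radius=2, min_voxels=10)
            diffs.append(maps["self"].values - maps["far"].values)
        group = np.nanmean(diffs, axis=0)
        assert abs(np.nanmean(group)) < 0.02

    def test_two_condition_neighborhood_equals_pairwise_distance(self, rng):
        data = rng.normal(size=(4, 5, 5, 5))
        ps = sg.PatternSet(
            subject=0,
            conditions=[("a", "1"), ("a", "2"), ("b", "1"), ("b", "2")],
            data=data,
        )
        mask = np.ones((5, 5, 5), dtype=bool)
        maps = searchlight_distinctiveness(ps, mask, radius=1.5, min_voxels=5)
        rdm_full = compute_rdm(ps, voxel_index=None if False else mask)
        # at the central voxel, the "a" value is the single (a1, a2) distance
        vox = np.zeros(mask.shape, dtype=bool)
        nbr = sphere_offsets(1.5) + 2
        vox[nbr[:, 0], nbr[:, 1], nbr[:, 2]] = True
        local = compute_rdm(ps, voxel_index=vox)
        assert maps["a"].values[2, 2, 2] == pytest.approx(
            local.matrix[0, 1], abs=1e-10
        )

    def test_gain_and_offset_invariance(self, small_patterns):
        """Pearson distance ignores a common affine rescaling of patterns."""
        mask = np.ones(small_patterns.grid_shape, dtype=bool)
        base = searchlight_distinctiveness(small_patterns, mask, radius=2,
                                           min_voxels=10)
        scaled = sg.PatternSet(
            subject=0, conditions=small_patterns.conditions,
            data=3.7 * small_patterns.data + 11.0,
            affine=small_patterns.affine,
        )
        other = searchlight_distinctiveness(scaled, mask, radius=2, min_voxels=10)
        for t in base:
            np.testing.assert_allclose(
                base[t].values, other[t].values, atol=1e-8
            )

    def test_interior_value_invariant_to_mask_padding(self, small_patterns):
        full = np.ones(small_patterns.grid_shape, dtype=bool)
        inner = np.zeros_like(full)
        inner[1:-1, 1:-1, 1:-1] = True
        a = searchlight_distinctiveness(small_patterns, full, radius=1.5,
                                        min_voxels=5)
        b = searchlight_distinctiveness(small_patterns, inner, radius=1.5,
                                        min_voxels=5)
        # deep-interior voxel: neighborhood identical under either mask
        center = (4, 4, 4)
        for t in a:
            assert a[t].values[center] == pytest.approx(
                b[t].values[center], abs=1e-12
            )


class TestRoiDistinctiveness:
    def test_planted_ordering_reproduced(self):
        cfg = sg.SimulationConfig(
            n_subjects=1, grid_shape=(8, 8, 8),
            targets=("self", "close", "far"), n_states=10,
            dispersion_by_target={"self": 1.0, "close": 0.6, "far": 0.2},
            noise_sd=0.1, seed=13,
        )
        ps = sg.simulate_subject_betas(cfg, 0)
        vals = roi_distinctiveness(ps, cfg.region_mask())
        assert vals["self"] > vals["close"] > vals["far"]

    def test_tiny_roi_rejected(self, small_patterns):
        roi = np.zeros(small_patterns.grid_shape, dtype=bool)
        roi[0, 0, 0] = True
        with pytest.raises(ValueError, match="at least 3"):
            roi_distinctiveness(small_patterns, roi)

    def test_identical_patterns_give_zero(self):
        base = np.random.default_rng(3).normal(size=(4, 4, 4))
        data = np.stack([base, base, base + 1.0, base * 2.0])
        ps = sg.PatternSet(
            subject=0,
            conditions=[("a", "1"), ("a", "2"), ("b", "1"), ("b", "2")],
            data=data,
        )
        vals = roi_distinctiveness(ps, np.ones((4, 4, 4), dtype=bool))
        assert vals["a"] == pytest.approx(0.0, abs=1e-12)


class TestBlockCorrection:
    def _frames(self, s, g, labels=("c1", "c2", "c3")):
        return (
            pd.DataFrame(s, index=labels, columns=labels),
            pd.DataFrame(g, index=labels, columns=labels),
        )

    def test_identity_induced_centers_offdiagonals(self):
        s = np.array([[1.0, 0.4, 0.2], [0.4, 1.0, 0.6], [0.2, 0.6, 1.0]])
        sim, ind = self._frames(s, np.eye(3))
        out = correct_block_structure(sim, ind).to_numpy()
        offd = np.array([0.4, 0.2, 0.6])
        expected = offd - offd.mean()
        iu = np.triu_indices(3, k=1)
        np.testing.assert_allclose(out[iu], expected, atol=1e-12)
        np.testing.assert_allclose(np.diag(out), np.diag(s))

    def test_proportional_similarity_fully_removed(self):
        g = np.array([[1.0, 0.5, 0.1], [0.5, 1.0, 0.3], [0.1, 0.3, 1.0]])
        s = 0.8 * g
        np.fill_diagonal(s, 1.0)
        sim, ind = self._frames(s, g)
        out = correct_block_structure(sim, ind).to_numpy()
        iu = np.triu_indices(3, k=1)
        np.testing.assert_allclose(out[iu], 0.0, atol=1e-12)

    def test_matches_hand_regression_residuals(self):
        # y = (0.9, 0.1, 0.5) on x = (0.6, 0.0, 0.3): perfect line
        # y = 0.1 + (4/3) x, so residuals are exactly zero
        s = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.5], [0.1, 0.5, 1.0]])
        g = np.array([[1.0, 0.6, 0.0], [0.6, 1.0, 0.3], [0.0, 0.3, 1.0]])
        sim, ind = self._frames(s, g)
        out = correct_block_structure(sim, ind).to_numpy()
        iu = np.triu_indices(3, k=1)
        np.testing.assert_allclose(out[iu], 0.0, atol=1e-12)

    def test_label_mismatch_rejected(self):
        s = np.eye(3)
        sim, _ = self._frames(s, s)
        _, ind = self._frames(s, s, labels=("x", "y", "z"))
        with pytest.raises(ValueError, match="share labels"):
            correct_block_structure(sim, ind)
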