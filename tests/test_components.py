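"""Component-analysis contracts: thresholding, dominance, correlations."""

import numpy as np
import pytest

from voxlica.components import (
    cross_correlate,
    dominance_labels,
    matched_recovery_score,
    region_summary,
    select_components_of_interest,
    threshold_map,
)
from voxlica.types import AnnotationVolume, VoxelMask


class TestThresholdMap:
    def test_against_sort_based_oracle(self):
        """1..1000: count survivors by sorting instead of percentiles."""
        v = np.arange(1.0, 1001.0)
        tm = threshold_map(v)
        srt = np.sort(v)
        low_cut = np.percentile(v, 1)
        high_cut = np.percentile(v, 99)
        assert tm.negative_voxels.size == int((srt < low_cut).sum())
        assert tm.positive_voxels.size == int((srt > high_cut).sum())
        # the selected values are exactly the extreme order statistics
        np.testing.assert_array_equal(
            np.sort(v[tm.positive_voxels]), srt[-tm.positive_voxels.size:])

    def test_constant_map_selects_nothing(self):
        with pytest.warns(UserWarning, match="constant map"):
            tm = threshold_map(np.full(500, 2.0))
        assert tm.n_selected == 0

    def test_symmetric_map_has_balanced_tails(self):
        rng = np.random.default_rng(0)
        half = rng.standard_normal(500)
        v = np.concatenate([half, -half])
        tm = threshold_map(v)
        assert tm.negative_voxels.size == tm.positive_voxels.size

    def test_small_map_warns(self):
        with pytest.warns(UserWarning, match="voxels"):
            threshold_map(np.arange(50.0))

    def test_two_percent_mass_on_continuous_maps(self):
        rng = np.random.default_rng(42)
        for n in (1000, 5000, 63113):
            v = rng.standard_normal(n)
            tm = threshold_map(v)
            assert abs(tm.n_selected - 0.02 * n) <= 2


class TestSelectComponents:
    def test_floor_zero_returns_all(self, ref_decomp):
        assert select_components_of_interest(ref_decomp, floor=0.0) == list(
            range(ref_decomp.L))

    def test_unique_component_excluded(self, ref_decomp, ref_truth):
        pairs, _, _ = matched_recovery_score(ref_decomp.H, ref_truth.H_true)
        unique_est = [e for e, t in pairs if t == 4][0]
        selected = select_components_of_interest(ref_decomp)
        assert unique_est not in selected

    def test_shared_components_included(self, ref_decomp, ref_truth):
        pairs, _, _ = matched_recovery_score(ref_decomp.H, ref_truth.H_true)
        shared_est = [e for e, t in pairs if t != 4]
        selected = select_components_of_interest(ref_decomp)
        assert set(shared_est) <= set(selected)


class TestDominance:
    def test_zero_weight_modality_gives_full_dominance(self, ref_decomp,
                                                       ref_truth):
        pairs, _, _ = matched_recovery_score(ref_decomp.H, ref_truth.H_true)
        unique_est = [e for e, t in pairs if t == 4][0]
        tm = threshold_map(ref_decomp.H[unique_est], component_id=unique_est)
        dom = dominance_labels(ref_decomp, unique_est, tm)
        assert set(dom.labels) == {"gene_dominated"}

    def test_equal_energy_is_shared(self, ref_decomp):
        import dataclasses
        dec = dataclasses.replace(
            ref_decomp, X=[ref_decomp.X[0], ref_decomp.X[0]],
            W=[ref_decomp.W[0], ref_decomp.W[0]])
        tm = threshold_map(dec.H[0], component_id=0)
        dom = dominance_labels(dec, 0, tm)
        assert set(dom.labels) == {"shared"}

    def test_ten_to_one_weight_ratio_labels_heavy_modality(self, ref_decomp):
        import dataclasses
        W_heavy = [w.copy() for w in ref_decomp.W]
        W_heavy[1][0] = 10.0 * W_heavy[0][0] * (
            np.linalg.norm(ref_decomp.X[0][:, 0])
            / np.linalg.norm(ref_decomp.X[1][:, 0]))
        dec = dataclasses.replace(ref_decomp, W=W_heavy)
        tm = threshold_map(dec.H[0], component_id=0)
        dom = dominance_labels(dec, 0, tm)
        heavy_label = f"{dec.modality_names[1]}_dominated"
        frac = np.mean(dom.labels == heavy_label)
        assert frac >= 0.95

    def test_joint_rescaling_invariance(self, ref_decomp):
        import dataclasses
        dec = dataclasses.replace(
            ref_decomp, W=[w * 7.5 for w in ref_decomp.W])
        tm = threshold_map(ref_decomp.H[0], component_id=0)
        a = dominance_labels(ref_decomp, 0, tm)
        b = dominance_labels(dec, 0, tm)
        np.testing.assert_array_equal(a.labels, b.labels)


class TestCrossCorrelate:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal((1, 300))
        tab = cross_correlate(v, v)
        assert tab.rho[0, 0] == pytest.approx(1.0)
        assert tab.p[0, 0] < 1e-100

    def test_negation_gives_minus_one(self):
        v = np.arange(50.0)[None]
        tab = cross_correlate(v, -v)
        assert tab.rho[0, 0] == pytest.approx(-1.0)

    def test_hand_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 3.0, 5.0])
        xc, yc = x - x.mean(), y - y.mean()
        expected = np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))
        tab = cross_correlate(x[None], y[None])
        assert tab.rho[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_p_matches_scipy_pearsonr(self):
        from scipy.stats import pearsonr
        rng = np.random.default_rng(5)
        x = rng.standard_normal((2, 40))
        y = rng.standard_normal((3, 40))
        tab = cross_correlate(x, y)
        for i in range(2):
            for j in range(3):
                r, p = pearsonr(x[i], y[j])
                assert tab.rho[i, j] == pytest.approx(r, abs=1e-12)
                assert tab.p[i, j] == pytest.approx(p, rel=1e-9)

    def test_zero_variance_reported_missing(self):
        tab = cross_correlate(np.ones((1, 10)), np.arange(10.0)[None])
        assert np.isnan(tab.rho[0, 0])
        assert not tab.significant[0, 0]

    def test_symmetry_up_to_transposition(self):
        rng = np.random.default_rng(2)
        a, b = rng.standard_normal((2, 30)), rng.standard_normal((4, 30))
        t1 = cross_correlate(a, b)
        t2 = cross_correlate(b, a)
        np.testing.assert_allclose(t1.rho, t2.rho.T, atol=1e-14)


class TestRegionSummary:
    def _setup(self):
        grid = np.ones((2, 3, 1), dtype=bool)
        mask = VoxelMask(grid)
        region_id = np.array([[[1], [1], [2]], [[2], [2], [3]]])
        annot = AnnotationVolume(region_id,
                                 {1: "A", 2: "B", 3: "C"})
        return mask, annot

    def test_entire_region_selected(self):
        mask, annot = self._setup()
        from voxlica.components import ThresholdedMap
        tm = ThresholdedMap(0, 0.0, 0.0, np.array([0, 1]), np.array([], int))
        df = region_summary(tm, annot, mask)
        row = df[df.region_name == "A"].iloc[0]
        assert row.n_selected_voxels == 2
        assert row.pct_of_region_volume == pytest.approx(100.0)

    def test_empty_selection(self):
        mask, annot = self._setup()
        from voxlica.components import ThresholdedMap
        tm = ThresholdedMap(0, 0.0, 0.0, np.array([], int), np.array([], int))
        assert len(region_summary(tm, annot, mask)) == 0

    def test_manual_tally(self):
        mask, annot = self._setup()
        from voxlica.components import ThresholdedMap
        # voxel order (row-major): (0,0),(0,1),(0,2),(1,0),(1,1),(1,2)
        tm = ThresholdedMap(0, 0.0, 0.0, np.array([2]), np.array([3, 5]))
        df = region_summary(tm, annot, mask).set_index("region_name")
        assert df.loc["B", "n_selected_voxels"] == 2   # voxels 2 and 3
        assert df.loc["B", "region_voxels"] == 3
        assert df.loc["C", "n_selected_voxels"] == 1


def test_integer_coded_volume_exports(ref_decomp, ref_mask):
    from voxlica.components import dominance_to_volume, thresholded_to_volume

    tm = threshold_map(ref_decomp.H[0], component_id=0)
    vol = thresholded_to_volume(tm, ref_mask)
    assert vol.shape == ref_mask.grid.shape
    assert int((vol == 1).sum()) == tm.positive_voxels.size
    assert int((vol == -1).sum()) == tm.negative_voxels.size
    assert not vol[~ref_mask.grid].any()

    dom = dominance_labels(ref_decomp, 0, tm)
    dvol = dominance_to_volume(dom, ref_mask)
    assert int((dvol > 0).sum()) == dom.voxel_indices.size


class TestMatchedRecovery:
    def test_true_vs_true(self, ref_truth):
        _, rhos, mean = matched_recovery_score(ref_truth.H_true,
                                               ref_truth.H_true)
        assert mean == pytest.approx(1.0, abs=1e-12)

    def test_permutation_and_sign_invariance(self, ref_truth):
        perm = [3, 0, 4, 1, 2]
        flipped = ref_truth.H_true[perm] * np.array([[-1], [1], [-1], [1], [1]])
        pairs, rhos, mean = matched_recovery_score(flipped, ref_truth.H_true)
        assert mean == pytest.approx(1.0, abs=1e-12)
        assert sorted(t for _, t in pairs) == [0, 1, 2, 3, 4]

    def test_independent_noise_scores_low(self):
        rng = np.random.default_rng(9)
        a = rng.standard_normal((5, 1000))
        b = rng.standard_normal((5, 1000))
        _, _, mean = matched_recovery_score(a, b)
        assert mean < 0.15

    def test_rectangular_matching(self, ref_truth):
        _, rhos, _ = matched_recovery_score(ref_truth.H_true[:3],
                                            ref_truth.H_true)
        assert rhos.size == 3
        np.testing.assert_allclose(rhos, 1.0, atol=1e-12)
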