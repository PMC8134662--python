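"""Brunner-Munzel voxel mapping, FDR correction, thresholding, ROI lookup."""

import numpy as np
import pytest
from scipy import stats

from strokenest.lsm import (
    UntestableVoxelError,
    bm_map,
    bm_test,
    fdr_adjust,
    lsm_rois,
    run_lsm,
    threshold_to_weights,
)

import oracles


class TestBmTest:
    def test_identical_samples_give_zero_statistic(self):
        res = bm_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_matches_hand_oracle(self):
        x, y = [1, 2, 4, 5, 8], [3, 6, 7, 9, 10]
        res = bm_test(x, y)
        W, df, p = oracles.brunner_munzel(x, y)
        assert res.statistic == pytest.approx(W, abs=1e-12)
        assert res.df == pytest.approx(df, abs=1e-12)
        assert res.pvalue == pytest.approx(p, abs=1e-12)

    def test_matches_scipy_reference(self, rng):
        for _ in range(50):
            n1, n2 = rng.integers(2, 30, size=2)
            x = rng.integers(0, 10, n1).astype(float)
            y = rng.integers(0, 10, n2).astype(float)
            res = bm_test(x, y)
            if res.degenerate:
                continue
            ref = stats.brunnermunzel(x, y)
            assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert res.pvalue == pytest.approx(ref.pvalue, abs=1e-10)

    def test_group_swap_negates_statistic_preserves_p(self, rng):
        x = rng.normal(size=9)
        y = rng.normal(size=14)
        a, b = bm_test(x, y), bm_test(y, x)
        assert a.statistic == pytest.approx(-b.statistic, abs=1e-12)
        assert a.pvalue == pytest.approx(b.pvalue, abs=1e-12)

    def test_complete_separation_flagged_degenerate(self):
        res = bm_test([1, 2, 3], [10, 11, 12])
        assert res.degenerate
        assert res.pvalue == 1.0

    def test_small_group_untestable(self):
        with pytest.raises(UntestableVoxelError):
            bm_test([1.0], [2.0, 3.0, 4.0])


class TestFdrAdjust:
    def test_single_p_identity(self):
        assert fdr_adjust([0.05]) == pytest.approx([0.05])

    def test_stepup_known_case(self):
        q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert fdr_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])

    def test_order_preserving_and_dominates_p(self, rng):
        p = rng.random(60)
        q = fdr_adjust(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestBmMap:
    def test_per_voxel_equals_scalar_test(self, cohort200):
        """Vectorized map agrees with bm_test run voxel by voxel."""
        masks = cohort200.lesions[:60]
        scores = cohort200.clinical["nihss_48h"].to_numpy(float)[:60]
        sm = bm_map(masks, scores)
        tested = np.argwhere(sm.tested_mask)
        rng = np.random.default_rng(0)
        for idx in rng.choice(len(tested), size=min(40, len(tested)), replace=False):
            v = tuple(tested[idx])
            grp = masks[(slice(None), *v)]
            res = bm_test(scores[grp], scores[~grp])
            if res.degenerate:
                assert sm.degenerate_mask[v]
                continue
            assert sm.statistic[v] == pytest.approx(res.statistic, abs=1e-10)
            assert sm.p[v] == pytest.approx(res.pvalue, abs=1e-10)

    def test_identical_lesions_give_identical_stats(self):
        shape = (8, 8, 8)
        lesion = np.zeros(shape, bool)
        lesion[2:5, 2:5, 2:5] = True
        masks = np.stack([lesion] * 6 + [np.roll(lesion, 3, axis=0)] * 6)
        scores = np.arange(12.0)
        sm = bm_map(masks, scores, coverage_threshold=0.10)
        vals = sm.statistic[lesion & sm.tested_mask & ~np.roll(lesion, 3, axis=0)]
        assert len(np.unique(np.round(vals, 12))) == 1

    def test_low_coverage_voxel_excluded(self):
        shape = (8, 8, 8)
        masks = np.zeros((20, *shape), bool)
        masks[:, 2, 2, 2] = True        # lesioned in all: intact group empty
        masks[0, 5, 5, 5] = True        # 1/20 = 5% < 10%
        masks[:10, 3, 3, 3] = True      # 50%: testable
        sm = bm_map(masks, np.arange(20.0))
        assert not sm.tested_mask[5, 5, 5]
        assert not sm.tested_mask[2, 2, 2]  # intact group < 2
        assert sm.tested_mask[3, 3, 3]

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            bm_map(np.zeros((3, 4, 4, 4), bool), [1.0, 2.0, 3.0])

    def test_label_swap_invariance(self, cohort200):
        """Swapping lesioned/intact at every voxel leaves p and q unchanged."""
        masks = cohort200.lesions[:40]
        scores = cohort200.clinical["nihss_48h"].to_numpy(float)[:40]
        sm = bm_map(masks, scores)
        sm_swapped = bm_map(~masks, scores, coverage_threshold=1e-9)
        both = sm.tested_mask & sm_swapped.tested_mask
        assert np.allclose(sm.p[both], sm_swapped.p[both], atol=1e-10)
        assert np.allclose(
            sm.statistic[both], -sm_swapped.statistic[both], atol=1e-10
        )


class TestThresholdAndRois:
    def test_no_survivor_means_empty_weights_and_rois(self, small_atlas):
        shape = small_atlas.shape
        from strokenest.lsm import VoxelStatMap

        sm = VoxelStatMap(
            tested_mask=np.ones(shape, bool),
            statistic=np.full(shape, 1.0),
            p=np.full(shape, 0.5),
            q=np.full(shape, 0.5),
            degenerate_mask=np.zeros(shape, bool),
        )
        w = threshold_to_weights(sm, alpha=0.05)
        assert (w == 0).all()
        assert lsm_rois(w, small_atlas) == []

    def test_single_survivor_gets_absolute_weight(self, small_atlas):
        shape = small_atlas.shape
        from strokenest.lsm import VoxelStatMap

        stat = np.zeros(shape)
        q = np.ones(shape)
        rid = small_atlas.region_ids[0]
        voxel = tuple(np.argwhere(small_atlas.labels == rid)[0])
        stat[voxel] = -3.2
        q[voxel] = 0.01
        sm = VoxelStatMap(np.ones(shape, bool), stat, np.ones(shape), q,
                          np.zeros(shape, bool))
        w = threshold_to_weights(sm)
        assert w[voxel] == pytest.approx(3.2)
        assert (w != 0).sum() == 1
        assert lsm_rois(w, small_atlas) == [rid]

    def test_alpha_one_keeps_all_nondegenerate(self, cohort200):
        masks = cohort200.lesions[:40]
        scores = cohort200.clinical["nihss_48h"].to_numpy(float)[:40]
        sm = bm_map(masks, scores)
        w = threshold_to_weights(sm, alpha=1.0)
        keep = sm.tested_mask & ~sm.degenerate_mask
        assert ((w != 0) == (keep & (sm.statistic != 0))).all()

    def test_cluster_straddling_two_regions(self, small_atlas):
        shape = small_atlas.shape
        gm = [r for r in small_atlas.region_ids if small_atlas.tissue_of(r) == "GM"]
        w = np.zeros(shape)
        for rid in gm[:2]:
            w[tuple(np.argwhere(small_atlas.labels == rid)[0])] = 2.0
        assert lsm_rois(w, small_atlas) == sorted(gm[:2])


def test_run_lsm_outputs_consistent(cohort200, tmp_path):
    from strokenest.lsm import save_lsm_outputs

    masks = cohort200.lesions[:80]
    scores = cohort200.clinical["nihss_48h"].to_numpy(float)[:80]
    sm, weights, rois = run_lsm(masks, scores, cohort200.atlas)
    nz_regions = {
        int(r) for r in np.unique(cohort200.atlas.labels[weights != 0]) if r
    }
    assert set(rois) == nz_regions
    assert ((sm.q >= sm.p - 1e-15) | ~sm.tested_mask).all()
    save_lsm_outputs(tmp_path, sm, weights, rois)
    assert (tmp_path / "rois.json").exists()
    assert (tmp_path / "weights.nii.gz").exists()
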