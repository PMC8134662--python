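"""Toy atlas construction and synthetic cohort generation."""

import numpy as np
import pandas as pd
import pytest

from strokenest.atlas import AtlasSizingError, make_toy_atlas
from strokenest.simulate import (
    SimulationConfig,
    SimulationConfigError,
    cohort_checksum,
    default_atlas,
    default_config_for_atlas,
    sample_lesion,
    simulate_cohort,
    simulate_outcomes,
)


class TestToyAtlas:
    def test_regions_disjoint_and_tabled(self):
        atlas = make_toy_atlas((32, 32, 32), 6, 2, seed=1)
        assert len(atlas.regions) == 8
        atlas.validate()  # disjointness + table consistency + WM contiguity
        # labels partition: every voxel has at most one region by construction
        assert set(np.unique(atlas.labels)) == set(atlas.region_ids) | {0}

    def test_deterministic_for_seed(self):
        a = make_toy_atlas((32, 32, 32), 6, 2, seed=1)
        b = make_toy_atlas((32, 32, 32), 6, 2, seed=1)
        assert np.array_equal(a.labels, b.labels)
        pd.testing.assert_frame_equal(a.regions, b.regions)

    def test_impossible_packing_raises_sizing_error(self):
        with pytest.raises(AtlasSizingError):
            make_toy_atlas((16, 16, 16), 500, 1, seed=1, max_tries=300)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            make_toy_atlas((8, 8, 8), 3, 1, seed=0)
        with pytest.raises(ValueError):
            make_toy_atlas((16, 16, 16), 3, 0, seed=0)

    def test_wm_tracts_contiguous_along_axis(self, small_atlas):
        wm = small_atlas.regions[small_atlas.regions["tissue"] == "WM"]
        for _, row in wm.iterrows():
            mask = small_atlas.labels == row["region_id"]
            ax = "xyz".index(row["axis"])
            other = tuple(i for i in range(3) if i != ax)
            counts = mask.sum(axis=other)
            occ = np.nonzero(counts)[0]
            assert (counts[occ[0]: occ[-1] + 1] > 0).all()

    def test_roundtrip_on_disk(self, small_atlas, tmp_path):
        small_atlas.save(tmp_path / "atlas")
        loaded = type(small_atlas).load(tmp_path / "atlas")
        assert np.array_equal(loaded.labels, small_atlas.labels)
        loaded.validate()


class TestSampleLesion:
    def test_degenerate_point_territory_forces_center(self, small_atlas):
        cfg = SimulationConfig(
            n_patients=10,
            territory_center=(8.0, 8.0, 8.0),
            territory_radius=0.0,
            lesion_size_range=(20, 20),
        )
        rng = np.random.default_rng(0)
        for _ in range(5):
            mask = sample_lesion(small_atlas, cfg, rng)
            assert mask[8, 8, 8]  # centre voxel always lesioned

    def test_exact_size_before_clipping(self, small_atlas):
        cfg = SimulationConfig(
            n_patients=10,
            territory_center=(8.0, 8.0, 8.0),
            territory_radius=2.0,
            territory_prob=1.0,
            lesion_size_range=(30, 30),
        )
        rng = np.random.default_rng(1)
        # deep-interior territory: clipping removes nothing
        for _ in range(10):
            assert sample_lesion(small_atlas, cfg, rng).sum() == 30

    def test_lesions_inside_brain(self, small_atlas):
        cfg = SimulationConfig(n_patients=10, territory_center=(8, 8, 8),
                               territory_radius=4.0)
        rng = np.random.default_rng(2)
        brain = small_atlas.brain_mask
        for _ in range(10):
            mask = sample_lesion(small_atlas, cfg, rng)
            assert mask.any() and not (mask & ~brain).any()

    def test_territory_enrichment_vs_mirror(self):
        """Monte-Carlo: mean overlap with the territory beats its x-mirror."""
        atlas = default_atlas(seed=3)
        cfg = default_config_for_atlas(atlas, n_patients=10, seed=3)
        rng = np.random.default_rng(3)
        center = np.asarray(cfg.territory_center)
        shape = atlas.shape
        grids = np.indices(shape).astype(float)

        def ball(c):
            return ((grids[0] - c[0]) ** 2 + (grids[1] - c[1]) ** 2
                    + (grids[2] - c[2]) ** 2) <= cfg.territory_radius**2

        territory = ball(center)
        mirror_c = center.copy()
        mirror_c[0] = (shape[0] - 1) - center[0]
        mirror = ball(mirror_c)
        t_ov, m_ov = [], []
        for _ in range(300):
            mask = sample_lesion(atlas, cfg, rng)
            t_ov.append((mask & territory).sum())
            m_ov.append((mask & mirror).sum())
        assert np.mean(t_ov) > 2 * np.mean(m_ov)


class TestSimulateOutcomes:
    def _identity_config(self, **kw):
        defaults = dict(
            n_patients=10,
            baseline_intercept=0.0,
            baseline_coef=1.0,
            outcome_intercept=0.0,
            outcome_coefs={"nihss_48h": 1.0},
            noise_sd_48=0.0,
            noise_sd_30=0.0,
        )
        defaults.update(kw)
        return SimulationConfig(**defaults)

    def test_identity_chain(self):
        cfg = self._identity_config()
        rng = np.random.default_rng(0)
        out = simulate_outcomes({}, {"nihss_baseline": 15}, cfg, rng)
        assert out == (15, 15, 15)

    def test_eloquent_overlap_adds_linearly(self):
        cfg = self._identity_config(eloquent_effects={3: 10.0})
        rng = np.random.default_rng(0)
        out = simulate_outcomes(
            {"overlaps": {3: 0.5}}, {"nihss_baseline": 15}, cfg, rng
        )
        assert out[1] == 20  # baseline + 10*0.5

    def test_tract_integrity_loss_adds(self):
        cfg = self._identity_config(tract_effects={2: 8.0})
        rng = np.random.default_rng(0)
        out = simulate_outcomes(
            {"integrities": {2: 0.25}}, {"nihss_baseline": 10}, cfg, rng
        )
        assert out[1] == 16  # 10 + 8*(1-0.25)

    def test_clipping_floor_and_ceiling(self):
        cfg = self._identity_config(baseline_intercept=-20.0)
        rng = np.random.default_rng(0)
        assert simulate_outcomes({}, {"nihss_baseline": 4}, cfg, rng)[1] == 0
        cfg2 = self._identity_config(baseline_intercept=50.0)
        assert simulate_outcomes({}, {"nihss_baseline": 4}, cfg2, rng)[1] == 42

    def test_invalid_overlap_rejected(self):
        cfg = self._identity_config(eloquent_effects={1: 1.0})
        with pytest.raises(ValueError):
            simulate_outcomes(
                {"overlaps": {1: 1.5}}, {"nihss_baseline": 5}, cfg,
                np.random.default_rng(0),
            )


class TestSimulateCohort:
    def test_unknown_eloquent_region_rejected(self, small_atlas):
        cfg = SimulationConfig(n_patients=10, eloquent_effects={999: 5.0})
        with pytest.raises(SimulationConfigError):
            simulate_cohort(cfg, small_atlas)

    def test_deterministic_checksum(self, small_atlas):
        cfg = default_config_for_atlas(small_atlas, n_patients=12, seed=7)
        a = simulate_cohort(cfg, small_atlas)
        b = simulate_cohort(cfg, small_atlas)
        assert cohort_checksum(a) == cohort_checksum(b)

    def test_patient_substreams_stable_under_cohort_growth(self, small_atlas):
        cfg10 = default_config_for_atlas(small_atlas, n_patients=10, seed=5)
        cfg15 = default_config_for_atlas(small_atlas, n_patients=15, seed=5)
        a = simulate_cohort(cfg10, small_atlas)
        b = simulate_cohort(cfg15, small_atlas)
        pd.testing.assert_frame_equal(a.clinical, b.clinical.iloc[:10])
        assert np.array_equal(a.lesions, b.lesions[:10])

    def test_nihss_in_valid_range(self, cohort200):
        for col in ("nihss_baseline", "nihss_48h", "nihss_30d"):
            v = cohort200.clinical[col]
            assert v.between(0, 42).all()
            assert (v == v.astype(int)).all()

    def test_ground_truth_lists_effect_regions(self, cohort200):
        gt = cohort200.ground_truth
        cfg = cohort200.config
        expected = sorted(
            {r for r, b in cfg.eloquent_effects.items() if b > 0}
            | {t for t, g in cfg.tract_effects.items() if g > 0}
        )
        assert gt["eloquent_regions"] == expected

    def test_beta_recovery_by_least_squares_at_zero_noise(self, small_atlas):
        """With noise off, OLS on the true overlaps recovers each beta ±0.5."""
        gm = [r for r in small_atlas.region_ids
              if small_atlas.tissue_of(r) == "GM"]
        betas = {gm[0]: 9.0, gm[1]: 6.0}
        cfg = SimulationConfig(
            n_patients=200, seed=11,
            eloquent_effects=betas, tract_effects={},
            baseline_coef=1.0, noise_sd_48=0.0, noise_sd_30=0.0,
            territory_center=(8.0, 8.0, 8.0), territory_radius=5.0,
            lesion_size_range=(50, 800),
        )
        cohort = simulate_cohort(cfg, small_atlas)
        from strokenest.features import overlap_fraction

        resp = (cohort.clinical["nihss_48h"]
                - cfg.baseline_coef * cohort.clinical["nihss_baseline"]).to_numpy(float)
        design = np.column_stack([
            [overlap_fraction(m, small_atlas.labels == r) for m in cohort.lesions]
            for r in betas
        ] + [np.ones(len(resp))])
        est, *_ = np.linalg.lstsq(design, resp, rcond=None)
        for est_b, true_b in zip(est[:2], betas.values()):
            assert abs(est_b - true_b) < 0.5  # rounding/clipping tolerance

    def test_on_disk_roundtrip_and_byte_determinism(self, small_atlas, tmp_path):
        cfg = default_config_for_atlas(small_atlas, n_patients=10, seed=3)
        cohort = simulate_cohort(cfg, small_atlas)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        cohort.save(d1)
        simulate_cohort(cfg, small_atlas).save(d2)
        files1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        files2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
        assert files1 == files2
        for rel in files1:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes(), rel
        loaded = type(cohort).load(d1)
        pd.testing.assert_frame_equal(loaded.clinical, cohort.clinical)
        assert np.array_equal(loaded.lesions, cohort.lesions)
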