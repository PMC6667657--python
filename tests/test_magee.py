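"""Seed geometry, seed maps, paired contrasts, GEE and MAGEE."""

import numpy as np
import pytest
from scipy import stats

from tinnet import magee as mg
from tinnet import synth
from tinnet.containers import ScoreTable, StatMap

AFF2 = np.diag([2.0, 2.0, 2.0, 1.0])


def _scores(n=10, sessions=("pre", "post", "followup"), seed=0):
    rng = np.random.default_rng(seed)
    return ScoreTable.from_wide(
        {f"sub{i:02d}": {s: float(rng.normal(45, 15)) for s in sessions}
         for i in range(n)})


class TestSeedGeometry:
    def test_8mm_sphere_on_2mm_grid_has_257_voxels(self):
        spec = mg.SeedSpec("probe", spheres=[((16, 16, 16), 8.0)])
        mask = mg.build_seed(spec, (17, 17, 17), AFF2)
        assert mask.sum() == 257

    def test_tiny_radius_single_voxel(self):
        spec = mg.SeedSpec("pt", spheres=[((16, 16, 16), 0.9)])
        mask = mg.build_seed(spec, (17, 17, 17), AFF2)
        assert mask.sum() == 1

    def test_two_sphere_union_single_mask(self):
        # default-mode seeds: medial prefrontal + posterior cingulate
        aff = AFF2.copy()
        aff[:3, 3] = [-40, -70, -30]
        spec = mg.SeedSpec("DMN", spheres=[((8, 59, 19), 8.0),
                                           ((-2, -50, 25), 8.0)])
        mask = mg.build_seed(spec, (41, 65, 35), aff)
        single = [mg.build_seed(mg.SeedSpec("a", spheres=[s]),
                                (41, 65, 35), aff) for s in spec.spheres]
        np.testing.assert_array_equal(mask, single[0] | single[1])
        assert mask.sum() == single[0].sum() + single[1].sum()  # disjoint

    def test_centre_outside_grid_rejected(self):
        spec = mg.SeedSpec("bad", spheres=[((200, 0, 0), 8.0)])
        with pytest.raises(ValueError, match="outside"):
            mg.build_seed(spec, (17, 17, 17), AFF2)


class TestSeedToVoxelMap:
    def test_planted_correlation_recovered(self):
        rng = np.random.default_rng(0)
        n_t = 300
        vol = rng.standard_normal((8, 8, 8, n_t))
        seed_mask = np.zeros((8, 8, 8), bool)
        seed_mask[0, 0, 0] = True
        s = vol[0, 0, 0]
        rho = 0.6
        vol[4, 4, 4] = rho * (s - s.mean()) / s.std() + \
            np.sqrt(1 - rho ** 2) * rng.standard_normal(n_t)
        out = mg.seed_to_voxel_map(vol, seed_mask, AFF2)
        assert out.values[4, 4, 4] == pytest.approx(np.arctanh(0.6),
                                                    abs=3 / np.sqrt(n_t - 3))

    def test_null_voxels_have_small_z(self):
        rng = np.random.default_rng(1)
        vol = rng.standard_normal((8, 8, 8, 300))
        seed_mask = np.zeros((8, 8, 8), bool)
        seed_mask[0, 0, 0] = True
        out = mg.seed_to_voxel_map(vol, seed_mask, AFF2)
        z = out.values[~seed_mask]
        assert np.mean(np.abs(z) < 0.2) >= 0.99

    def test_identical_voxel_hits_clip_bound(self):
        rng = np.random.default_rng(2)
        vol = rng.standard_normal((8, 8, 8, 50))
        seed_mask = np.zeros((8, 8, 8), bool)
        seed_mask[2, 2, 2] = True
        out = mg.seed_to_voxel_map(vol, seed_mask, AFF2)
        assert out.values[2, 2, 2] == pytest.approx(np.arctanh(1 - 1e-7))

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        vol = rng.standard_normal((8, 8, 8, 60))
        seed_mask = np.zeros((8, 8, 8), bool)
        seed_mask[1, 1, 1] = True
        a = mg.seed_to_voxel_map(vol, seed_mask, AFF2).values
        b = mg.seed_to_voxel_map(vol * 3.5 + 10, seed_mask, AFF2).values
        np.testing.assert_allclose(a, b, atol=1e-10)


class TestExtractClusters:
    def _wald_map(self, blobs):
        vals = np.zeros((16, 16, 16))
        for (sl, height) in blobs:
            vals[sl] = height
        return StatMap(vals, AFF2, stat_kind="wald")

    def test_extent_filter_keeps_large_blob_only(self):
        high = stats.chi2.isf(1e-6, df=1)
        blob_a = (slice(0, 5), slice(0, 5), slice(0, 5))      # 125 voxels
        blob_b = (slice(10, 14), slice(10, 13), slice(10, 14))  # 48 voxels
        m = self._wald_map([(blob_a, high), (blob_b, high)])
        out = mg.extract_clusters(m, height_p=1e-5, min_extent=100)
        assert len(out) == 1
        assert out.iloc[0]["size"] == 125

    def test_empty_supra_threshold_set(self):
        m = self._wald_map([])
        out = mg.extract_clusters(m, height_p=1e-5, min_extent=10)
        assert out.empty

    def test_connectivity_semantics_edge_touching_blobs(self):
        """Two blobs touching only across an edge (face diagonal) are
        separate under 6-connectivity, merged under 18."""
        vals = np.zeros((8, 8, 8))
        vals[2, 2, 2] = vals[3, 3, 2] = 50.0
        m = StatMap(vals, AFF2, stat_kind="wald")
        out6 = mg.extract_clusters(m, 1e-5, 0, connectivity=6)
        out18 = mg.extract_clusters(m, 1e-5, 0, connectivity=18)
        assert len(out6) == 2 and len(out18) == 1

    def test_peak_coordinates_round_trip_affine(self):
        vals = np.zeros((10, 10, 10))
        vals[3, 7, 5] = 99.0
        aff = np.array([[2, 0, 0, -10], [0, 2, 0, -20],
                        [0, 0, 2, -5], [0, 0, 0, 1.0]])
        m = StatMap(vals, aff, stat_kind="wald")
        out = mg.extract_clusters(m, 1e-5, 0)
        mm = out.iloc[0][["peak_x_mm", "peak_y_mm", "peak_z_mm"]].to_numpy()
        back = m.mm_to_ijk(mm.astype(float))[0]
        np.testing.assert_allclose(back, [3, 7, 5], atol=1e-10)


class TestPairedContrast:
    def _null_maps(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        return ([StatMap(rng.standard_normal((12, 12, 12)), AFF2, "z")
                 for _ in range(n)],
                [StatMap(rng.standard_normal((12, 12, 12)), AFF2, "z")
                 for _ in range(n)])

    def test_identical_maps_no_clusters(self):
        a, _ = self._null_maps()
        res = mg.paired_contrast(a, [StatMap(m.values.copy(), AFF2, "z")
                                     for m in a], height_p=0.01,
                                 min_extent=0)
        assert res.clusters.empty

    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(4)
        region = (slice(3, 9), slice(3, 9), slice(3, 8))  # 180 voxels
        a, b = [], []
        for _ in range(10):
            base = rng.standard_normal((12, 12, 12))
            eff = base.copy()
            eff[region] += 2.0
            a.append(StatMap(base, AFF2, "z"))
            b.append(StatMap(eff + 0.1 * rng.standard_normal((12, 12, 12)),
                             AFF2, "z"))
        res = mg.paired_contrast(a, b, height_p=1e-3, min_extent=20,
                                 seed=0)
        assert len(res.clusters) >= 1
        big = res.clusters.iloc[0]
        assert big["size"] >= 0.8 * 180
        assert big.p_perm <= 0.05

    def test_exact_enumeration_used_for_ten_subjects(self):
        a, b = self._null_maps()
        res = mg.paired_contrast(a, b, height_p=0.001, min_extent=0)
        assert res.exact and len(res.null_max_mass) == 1024


class TestGEE:
    def test_single_observation_per_subject_equals_ols(self):
        rng = np.random.default_rng(0)
        x = rng.normal(50, 10, 40)
        y = 1 + 0.3 * x + rng.standard_normal(40)
        res = mg.gee_fit(y, x, np.arange(40))
        beta_ols = np.polyfit(x, y, 1)
        assert res.beta[1] == pytest.approx(beta_ols[0], abs=1e-10)
        assert res.beta[0] == pytest.approx(beta_ols[1], abs=1e-10)

    def test_matches_statsmodels_exchangeable_gee(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        n_sub = 25
        ids = np.repeat(np.arange(n_sub), 3)
        x = rng.normal(50, 15, n_sub * 3)
        y = 2 + 0.5 * x + np.repeat(rng.normal(0, 2, n_sub), 3) + \
            rng.standard_normal(n_sub * 3)
        ours = mg.gee_fit(y, x, ids)
        ref = sm.GEE(y, sm.add_constant(x), groups=ids,
                     cov_struct=sm.cov_struct.Exchangeable()).fit()
        np.testing.assert_allclose(ours.beta, ref.params, rtol=1e-6)
        np.testing.assert_allclose(ours.slope_se, ref.bse[1], rtol=1e-4)

    def test_slope_recovery_with_subject_intercepts(self):
        rng = np.random.default_rng(2)
        n_sub = 50
        ids = np.repeat(np.arange(n_sub), 3)
        x = rng.normal(0, 1, n_sub * 3)
        y = 2 + 0.5 * x + np.repeat(rng.normal(0, 1, n_sub), 3) + \
            0.5 * rng.standard_normal(n_sub * 3)
        res = mg.gee_fit(y, x, ids)
        assert res.slope == pytest.approx(0.5, abs=0.1)

    def test_unbalanced_sessions_handled(self):
        rng = np.random.default_rng(3)
        ids = np.array([0, 0, 0, 1, 1, 2, 2, 2, 3, 4, 4])
        x = rng.normal(0, 1, len(ids))
        y = 0.7 * x + rng.standard_normal(len(ids))
        res = mg.gee_fit(y, x, ids)
        assert np.isfinite(res.slope) and np.isfinite(res.slope_se)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            mg.gee_fit(np.arange(6.0), np.ones(6), [0, 0, 1, 1, 2, 2])

    def test_null_wald_tracks_chi2_quantiles(self):
        """QQ slope of null Wald statistics against chi2(1) is ~1."""
        rng = np.random.default_rng(4)
        n_sub = 50
        ids = np.repeat(np.arange(n_sub), 3)
        x = rng.normal(50, 15, n_sub * 3)
        Y = (np.repeat(rng.normal(0, 1, (n_sub, 200)), 3, axis=0)
             + rng.standard_normal((n_sub * 3, 200)))
        beta, cov, _, _ = mg._gee_batch(Y, x, ids)
        w = beta[1] ** 2 / cov[:, 1, 1]
        qs = np.linspace(0.1, 0.9, 9)
        emp = np.quantile(w, qs)
        ref = stats.chi2.ppf(qs, df=1)
        slope = np.polyfit(ref, emp, 1)[0]
        assert 0.8 < slope < 1.25


class TestAdaptiveSmoothing:
    def test_constant_beta_map_is_fixed_point(self):
        beta = np.full((10, 10, 10), 0.7)
        var = np.full((10, 10, 10), 0.2)
        b2, v2 = mg.adaptive_smooth(beta, var)
        np.testing.assert_allclose(b2, beta, atol=1e-6)
        np.testing.assert_allclose(v2, var, atol=1e-6)

    def test_spike_magnitude_strictly_decreases(self):
        """A spike a few robust SDs above a noisy null field shrinks on
        every pass (a spike far beyond the similarity bandwidth would
        instead be preserved - that is the point of adaptivity)."""
        rng = np.random.default_rng(0)
        beta = 0.2 * rng.standard_normal((12, 12, 12))
        beta[6, 6, 6] = 0.6
        var = np.full_like(beta, 0.1)
        prev = 0.6
        for r in (1.0, 2.0, 3.0):
            beta, var = mg.adaptive_smooth(beta, var, radii=(r,))
            assert beta[6, 6, 6] < prev
            prev = beta[6, 6, 6]


class TestMAGEE:
    def test_zero_iterations_equals_voxelwise_gee(self):
        scores = _scores(n=8)
        ds = synth.gen_voxel_dataset((8, 8, 8), scores, effect_beta=0.0,
                                     seed=5, n_time=40)
        zmaps = {k: mg.seed_to_voxel_map(v, ds.seed_mask, ds.affine)
                 for k, v in ds.data.items()}
        res = mg.MAGEE(zmaps, scores, n_iter=0).fit()
        np.testing.assert_array_equal(res.beta_map.values, res.raw_beta)
        # spot-check one voxel against the scalar GEE path
        keys = sorted(zmaps)
        y = np.array([zmaps[k].values[5, 5, 5] for k in keys])
        x = np.array([scores.get(*k) for k in keys])
        ids = np.array([k[0] for k in keys])
        single = mg.gee_fit(y, x, ids)
        assert res.raw_beta[5, 5, 5] == pytest.approx(single.slope,
                                                      rel=1e-8)

    def test_planted_region_carries_peak_wald(self):
        scores = _scores(n=10, seed=3)
        ds = synth.gen_voxel_dataset((12, 12, 12), scores,
                                     effect_beta=-0.015, seed=6,
                                     n_time=80)
        zmaps = {k: mg.seed_to_voxel_map(v, ds.seed_mask, ds.affine)
                 for k, v in ds.data.items()}
        res = mg.MAGEE(zmaps, scores, n_iter=5).fit()
        peak = np.unravel_index(res.wald_map.values.argmax(),
                                res.wald_map.values.shape)
        assert ds.target_mask[peak]

    def test_subject_without_scores_dropped(self):
        scores = _scores(n=6)
        ds = synth.gen_voxel_dataset((8, 8, 8), scores, effect_beta=0.0,
                                     seed=7, n_time=40)
        zmaps = {k: mg.seed_to_voxel_map(v, ds.seed_mask, ds.affine)
                 for k, v in ds.data.items()}
        extra = StatMap(np.zeros((8, 8, 8)), ds.affine, "z")
        zmaps[("sub99", "pre")] = extra
        res = mg.MAGEE(zmaps, scores).fit()
        assert res.dropped_subjects == ["sub99"]


class TestSeedSerialization:
    def test_json_round_trip_preserves_mask(self, tmp_path):
        spec = mg.SeedSpec("DMN", spheres=[((8, 59, 19), 8.0),
                                           ((-2, -50, 25), 8.0)])
        p = tmp_path / "seed.json"
        spec.to_json(p)
        spec2 = mg.SeedSpec.from_json(p)
        aff = AFF2.copy()
        aff[:3, 3] = [-40, -70, -30]
        m1 = mg.build_seed(spec, (41, 65, 35), aff)
        m2 = mg.build_seed(spec2, (41, 65, 35), aff)
        np.testing.assert_array_equal(m1, m2)
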