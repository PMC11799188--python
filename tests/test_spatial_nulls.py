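import numpy as np
import pytest

import tcgrad as t


class TestPairwiseDistances:
    def test_three_four_five_triangle(self):
        coords = np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0], [3.0, 4.0, 0.0]])
        d = t.pairwise_distances(coords)
        assert d[0, 1] == pytest.approx(3.0)
        assert d[1, 2] == pytest.approx(4.0)
        assert d[0, 2] == pytest.approx(5.0)
        assert (d == d.T).all()
        assert (np.diag(d) == 0).all()

    def test_translation_invariance(self, rng):
        c = rng.random((20, 3))
        assert np.allclose(t.pairwise_distances(c), t.pairwise_distances(c + 5.0), atol=1e-12)


class TestEmpiricalVariogram:
    def test_matches_loop_oracle(self, rng):
        coords = rng.random((30, 3)) * 10
        x = rng.standard_normal(30)
        d = t.pairwise_distances(coords)
        v = t.empirical_variogram(x, d, n_bins=6, cutoff_pct=100.0)
        # from-scratch oracle over upper-triangle pairs
        edges = np.linspace(0.0, d[np.triu_indices(30, 1)].max(), 7)
        sums = np.zeros(6)
        counts = np.zeros(6)
        for i in range(30):
            for j in range(i + 1, 30):
                b = min(int(np.searchsorted(edges[1:-1], d[i, j], side="right")), 5)
                sums[b] += 0.5 * (x[i] - x[j]) ** 2
                counts[b] += 1
        for b in range(6):
            if counts[b] > 0:
                assert v.gamma[b] == pytest.approx(sums[b] / counts[b], rel=1e-9)
            else:
                assert np.isnan(v.gamma[b])
        assert (v.pair_counts == counts).all()

    def test_two_point_semivariance(self):
        """gamma for one pair with values 0 and 2 is (0-2)^2 / 2 = 2."""
        coords = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        v = t.empirical_variogram(np.array([0.0, 2.0]), t.pairwise_distances(coords),
                                  n_bins=1, cutoff_pct=100.0)
        assert v.gamma[0] == pytest.approx(2.0)

    def test_constant_map_gamma_zero(self, rng):
        coords = rng.random((15, 3))
        v = t.empirical_variogram(np.full(15, 3.3), t.pairwise_distances(coords))
        assert np.nanmax(v.gamma) == 0.0

    def test_absent_values_excluded(self, small_geom):
        x = np.asarray(small_geom.u1, dtype=float).copy()
        x[:3] = np.nan
        d = t.pairwise_distances(small_geom.seeds)
        v = t.empirical_variogram(x, d)
        ref = t.empirical_variogram(x[3:], d[3:, 3:])
        assert np.allclose(v.gamma, ref.gamma, equal_nan=True)


class TestSurrogates:
    def test_resample_preserves_value_multiset(self, small_geom, rng):
        d = t.pairwise_distances(small_geom.seeds)
        x = small_geom.u1
        ens = t.variogram_surrogates(x, d, n_surr=5, rng=11, resample=True)
        for s in ens.maps:
            assert np.array_equal(np.sort(s), np.sort(x))

    def test_seeded_reproducibility(self, small_geom):
        d = t.pairwise_distances(small_geom.seeds)
        a = t.variogram_surrogates(small_geom.u1, d, n_surr=4, rng=7)
        b = t.variogram_surrogates(small_geom.u1, d, n_surr=4, rng=7)
        assert (a.maps == b.maps).all()
        assert (a.selected_k == b.selected_k).all()

    def test_different_seeds_differ(self, small_geom):
        d = t.pairwise_distances(small_geom.seeds)
        a = t.variogram_surrogates(small_geom.u1, d, n_surr=2, rng=1)
        b = t.variogram_surrogates(small_geom.u1, d, n_surr=2, rng=2)
        assert not (a.maps == b.maps).all()

    def test_surrogates_break_topography(self, small_geom):
        """A surrogate should not be the original map (nor a trivial copy)."""
        d = t.pairwise_distances(small_geom.seeds)
        ens = t.variogram_surrogates(small_geom.u1, d, n_surr=5, rng=3)
        for s in ens.maps:
            assert abs(np.corrcoef(s, small_geom.u1)[0, 1]) < 0.95

    def test_variogram_fidelity_on_smooth_map(self, small_geom, small_cfg):
        """Surrogate variograms track the empirical one on an SA map."""
        from tcgrad.synthetic_data import sa_noise
        d = t.pairwise_distances(small_geom.seeds)
        # 2 mm smoothing: short-range SA, well inside the small cloud's
        # extent, so the stationary surrogate model is well specified
        x = sa_noise(small_geom, np.random.default_rng(0), 2.0)
        gen = t.SurrogateGenerator(d)
        ens = gen(x, n_surr=20, rng=0)
        ge = gen.ws.gamma(x)
        devs = []
        for s in ens.maps:
            gs = gen.ws.gamma(s)
            ok = np.isfinite(ge) & np.isfinite(gs) & (ge > 0)
            devs.append(np.mean(np.abs(gs[ok] - ge[ok]) / ge[ok]))
        assert np.mean(devs) < 0.5

    def test_incomplete_map_rejected(self, small_geom):
        d = t.pairwise_distances(small_geom.seeds)
        x = small_geom.u1.copy()
        x[0] = np.nan
        with pytest.raises(ValueError, match="present"):
            t.variogram_surrogates(x, d, n_surr=1, rng=0)

    def test_bandwidth_grid_validated(self, small_geom):
        d = t.pairwise_distances(small_geom.seeds)
        with pytest.raises(ValueError):
            t.SurrogateGenerator(d, knn_grid=(0, 5))
        with pytest.raises(ValueError):
            t.SurrogateGenerator(d, knn_grid=(5, d.shape[0]))


class TestSaCorrectedCorrelation:
    def test_identical_maps_give_r_one_minimal_p(self, small_geom):
        d = t.pairwise_distances(small_geom.seeds)
        res = t.sa_corrected_correlation(small_geom.u1, small_geom.u1, d, n_surr=100, rng=0)
        assert res.r_obs == pytest.approx(1.0)
        # no surrogate correlates with the map as well as the map itself
        assert res.p_sa == pytest.approx(1 / 101)

    def test_p_value_bounds_and_count(self, small_geom):
        d = t.pairwise_distances(small_geom.seeds)
        res = t.sa_corrected_correlation(small_geom.u1, small_geom.u2, d, n_surr=50, rng=1)
        assert 1 / 51 <= res.p_sa <= 1.0
        assert res.null_distribution.size == 50
        # add-one convention: p is exactly (1 + #extreme) / (1 + N)
        n_extreme = int(np.sum(np.abs(res.null_distribution) >= abs(res.r_obs)))
        assert res.p_sa == pytest.approx((1 + n_extreme) / 51)

    def test_r_obs_matches_plain_pearson(self, small_geom):
        d = t.pairwise_distances(small_geom.seeds)
        res = t.sa_corrected_correlation(small_geom.u1, small_geom.u2, d, n_surr=10, rng=0)
        assert res.r_obs == pytest.approx(np.corrcoef(small_geom.u1, small_geom.u2)[0, 1], abs=1e-12)

    def test_pairwise_complete_subsetting(self, small_geom):
        d = t.pairwise_distances(small_geom.seeds)
        x = small_geom.u1.copy()
        x[:4] = np.nan
        res = t.sa_corrected_correlation(x, small_geom.u2, d, n_surr=10, rng=0)
        ref = np.corrcoef(small_geom.u1[4:], small_geom.u2[4:])[0, 1]
        assert res.r_obs == pytest.approx(ref, abs=1e-12)

    def test_too_few_complete_pairs_rejected(self):
        coords = np.random.default_rng(0).random((12, 3))
        d = t.pairwise_distances(coords)
        x = np.full(12, np.nan)
        x[:5] = 1.0
        with pytest.raises(ValueError, match="10"):
            t.sa_corrected_correlation(x, np.arange(12.0), d, n_surr=5, rng=0)

    def test_generator_reuse_matches_fresh(self, small_geom):
        d = t.pairwise_distances(small_geom.seeds)
        gen = t.SurrogateGenerator(d)
        a = t.sa_corrected_correlation(small_geom.u1, small_geom.u2, d, n_surr=20, rng=5)
        b = t.sa_corrected_correlation(small_geom.u1, small_geom.u2, d, n_surr=20, rng=5,
                                       generator=gen)
        assert (a.null_distribution == b.null_distribution).all()
        assert a.p_sa == b.p_sa
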