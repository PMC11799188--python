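import numpy as np
import pytest

import tcgrad as t
from tcgrad.synthetic_data import sa_noise, sc_rates


class TestGeometry:
    def test_seeded_reproducibility(self, small_cfg):
        a = t.make_geometry(small_cfg)
        b = t.make_geometry(small_cfg)
        assert (a.u1 == b.u1).all() and (a.u2 == b.u2).all()
        assert (a.seeds.coords == b.seeds.coords).all()
        assert (a.parcel_anchors == b.parcel_anchors).all()

    def test_axes_standardized(self, small_geom):
        for u in (small_geom.u1, small_geom.u2):
            assert abs(u.mean()) < 1e-9
            assert abs(u.var() - 1.0) < 1e-9

    def test_axes_nearly_orthogonal(self, small_geom):
        # Gram-Schmidt makes the sample correlation exactly zero
        assert abs(np.corrcoef(small_geom.u1, small_geom.u2)[0, 1]) <= 0.1

    def test_requested_seed_count(self, small_geom, small_cfg):
        assert small_geom.seeds.n_seeds == small_cfg.n_seeds

    def test_too_few_seeds_rejected(self):
        with pytest.raises(ValueError):
            t.make_geometry(t.SynthConfig(n_seeds=4, n_parcels=4))

    def test_communities_cover_all_parcels(self, small_geom):
        assert len(small_geom.community) == small_geom.parcel_anchors.shape[0]


class TestStreamlineCounts:
    def test_deterministic_seed_at_anchor(self, small_cfg):
        geom = t.make_geometry(small_cfg)
        # move one anchor exactly onto seed 0's latent position
        anchors = geom.parcel_anchors.copy()
        anchors[0] = [geom.u1[0], geom.u2[0]]
        geom2 = t.LatentGeometry(
            seeds=geom.seeds, u1=geom.u1, u2=geom.u2, parcel_anchors=anchors,
            community=geom.community, voxel_indices=geom.voxel_indices,
            volume_shape=geom.volume_shape, affine=geom.affine,
        )
        m = t.simulate_sc_counts(geom2, small_cfg, deterministic=True)
        assert m.values[0, 0] == pytest.approx(small_cfg.intensity_scale, abs=1e-9)

    def test_distant_anchor_rate_vanishes(self, small_geom, small_cfg):
        d = small_geom.latent_distances()
        lam = sc_rates(small_geom, small_cfg)
        far = d > 5 * small_cfg.kernel_width
        assert lam[far].max() < 1e-3 * small_cfg.intensity_scale

    def test_poisson_mean_matches_rate(self, small_geom, small_cfg):
        """Monte-Carlo: per-cell mean over 2000 replicates within 3 SE of the rate."""
        lam = sc_rates(small_geom, small_cfg)
        rng = np.random.default_rng(99)
        cells = [(int(i), int(j)) for i, j in zip(
            rng.integers(0, lam.shape[0], 10), rng.integers(0, lam.shape[1], 10))]
        n_rep = 2000
        sums = np.zeros(len(cells))
        for _ in range(n_rep):
            draw = rng.poisson([lam[c] for c in cells])
            sums += draw
        for k, c in enumerate(cells):
            mean = sums[k] / n_rep
            se = np.sqrt(lam[c] / n_rep)
            assert abs(mean - lam[c]) <= 3 * se + 1e-9

    def test_counts_are_integral_nonnegative(self, small_geom, small_cfg):
        m = t.simulate_sc_counts(small_geom, small_cfg)
        assert m.values.min() >= 0
        assert np.array_equal(m.values, np.round(m.values))


class TestScalarMaps:
    def test_noiseless_qt1_is_perfectly_anticorrelated_with_u1(self, small_geom, small_cfg):
        import dataclasses
        cfg0 = dataclasses.replace(small_cfg, noise_sd=0.0)
        m = t.simulate_qt1(small_geom, cfg0)
        r = np.corrcoef(m.values, small_geom.u1)[0, 1]
        assert r == pytest.approx(np.sign(cfg0.coupling_qt1), abs=1e-9)

    def test_coupling_magnitude_invariance_and_sign_flip(self, small_geom, small_cfg):
        """noise_sd is a ratio, so corr(map, u1) is invariant to |coupling|
        and flips sign with the coupling sign."""
        import dataclasses
        rs = {}
        for c in (-60.0, -0.6, 0.6):
            cfg = dataclasses.replace(small_cfg, coupling_qt1=c)
            m = t.simulate_qt1(small_geom, cfg, rng=np.random.default_rng(5))
            rs[c] = np.corrcoef(m.values, small_geom.u1)[0, 1]
        assert rs[-60.0] == pytest.approx(rs[-0.6], abs=1e-9)
        # the shared noise field also correlates with u1, so the flip is in
        # sign only, not in exact magnitude
        assert rs[-60.0] < -0.5 and rs[0.6] > 0.5

    def test_noiseless_corematrix_tracks_u2_not_u1(self, small_geom, small_cfg):
        import dataclasses
        cfg0 = dataclasses.replace(small_cfg, noise_sd=0.0)
        m = t.simulate_corematrix(small_geom, cfg0)
        assert abs(np.corrcoef(m.values, small_geom.u2)[0, 1]) == pytest.approx(1.0, abs=1e-9)
        assert abs(np.corrcoef(m.values, small_geom.u1)[0, 1]) <= 0.1

    def test_fixed_seed_reproducibility(self, small_geom, small_cfg):
        a = t.simulate_qt1(small_geom, small_cfg)
        b = t.simulate_qt1(small_geom, small_cfg)
        assert (a.values == b.values).all()


class TestTimeseries:
    def test_single_dominant_parcel_reproduces_its_series(self, small_cfg):
        import dataclasses
        # tiny kernel width: each seed loads almost entirely on its nearest anchor
        cfg = dataclasses.replace(small_cfg, kernel_width=0.02, n_timepoints=200)
        geom = t.make_geometry(cfg)
        vts, pts = t.simulate_timeseries(geom, cfg, noise_sd=0.0)
        w = sc_rates(geom, cfg)
        i = int(np.argmax(w.max(axis=1) / np.maximum(w.sum(axis=1), 1e-300)))
        j = int(np.argmax(w[i]))
        r = np.corrcoef(vts[i], pts[j])[0, 1]
        assert r > 0.999

    def test_equal_weights_give_symmetric_correlations(self, small_cfg):
        import dataclasses
        # huge kernel width: all weights equal -> symmetric voxel-parcel correlation
        cfg = dataclasses.replace(small_cfg, kernel_width=1e6, n_timepoints=5000)
        geom = t.make_geometry(cfg)
        vts, pts = t.simulate_timeseries(geom, cfg, noise_sd=0.1)
        fc = t.fc_matrix(vts, pts)
        row = fc.values[0]
        assert row.std() < 0.05
        assert row.mean() > 0

    def test_fixed_seed_reproducibility(self, small_geom, small_cfg):
        a = t.simulate_timeseries(small_geom, small_cfg)
        b = t.simulate_timeseries(small_geom, small_cfg)
        assert (a[0] == b[0]).all() and (a[1] == b[1]).all()

    def test_too_few_timepoints_rejected(self, small_geom, small_cfg):
        import dataclasses
        cfg = dataclasses.replace(small_cfg, n_timepoints=10)
        with pytest.raises(ValueError):
            t.simulate_timeseries(small_geom, cfg)


class TestSubjectStack:
    def test_unit_loadings_no_noise_give_perfect_covariance(self, small_geom, small_cfg):
        n, p = small_geom.seeds.n_seeds, small_cfg.n_parcels
        stack = t.simulate_subject_qt1_stack(
            small_geom, small_cfg, noise_sd=0.0, beta=np.ones(n), gamma=np.ones(p))
        r = t.structural_covariance(stack)
        assert np.allclose(r.values, 1.0)

    def test_zero_loading_voxel_has_null_covariance_row(self, small_geom, small_cfg):
        import dataclasses
        cfg = dataclasses.replace(small_cfg, n_subjects=200)
        n, p = small_geom.seeds.n_seeds, cfg.n_parcels
        beta = np.ones(n)
        beta[0] = 0.0
        stack = t.simulate_subject_qt1_stack(
            small_geom, cfg, noise_sd=0.3, beta=beta, gamma=np.ones(p))
        r = t.structural_covariance(stack)
        assert np.abs(r.values[0]).mean() < 0.2
        assert np.abs(r.values[1:]).mean() > 0.8

    def test_too_few_subjects_rejected(self, small_geom, small_cfg):
        import dataclasses
        cfg = dataclasses.replace(small_cfg, n_subjects=2)
        with pytest.raises(ValueError):
            t.simulate_subject_qt1_stack(small_geom, cfg)

    def test_fixed_seed_reproducibility(self, small_geom, small_cfg):
        a = t.simulate_subject_qt1_stack(small_geom, small_cfg)
        b = t.simulate_subject_qt1_stack(small_geom, small_cfg)
        assert (a.voxel_values == b.voxel_values).all()


class TestSpatialAutocorrelation:
    def test_noise_variogram_increases_within_smoothing_range(self, small_geom):
        """SA noise semivariance grows with distance up to the smoothing range."""
        d = t.pairwise_distances(small_geom.seeds)
        rng = np.random.default_rng(3)
        ok = 0
        for _ in range(20):
            x = sa_noise(small_geom, rng, 3.0)
            v = t.empirical_variogram(x, d, n_bins=8)
            g = v.gamma[~np.isnan(v.gamma)]
            within = v.bin_centers[~np.isnan(v.gamma)] <= 6.0
            diffs = np.diff(g[within[: len(g)]])
            ok += (diffs >= -0.02).all()
        assert ok >= 18  # allow rare sampling blips
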