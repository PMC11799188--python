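# Methods note

This note documents the computational model implemented in `tcgrad`: the
gradient pipeline, the synthetic generator, the surrogate-based
statistics, the numerical conventions, and what the package deliberately
does not model. Every number quoted here is computed by the test suite
(`tests/`) or the driver script (`scripts/acceptance.py`); the note makes
no empirical claims beyond those.

## 1. Gradient pipeline

**Input.** A seed-by-parcel connectivity matrix: thalamic seed voxels as
rows, ipsilateral cortical parcels as columns. Three modalities share the
pipeline:

- *Structural* (`sc_counts`): non-negative streamline counts. Columns are
  divided by their maximum (`normalize_columns_max`) so that no parcel
  dominates by size or distance; all-zero columns are left untouched with
  a warning.
- *Functional* (`fc_r` → `fc_z`): Pearson correlation of seed and parcel
  time series, Fisher r-to-z transformed (arctanh, with |r| clamped to
  1 − 1e-7 so collinear series stay finite).
- *Covariance* (`scov_r`): across-subject Pearson correlation of qT1
  between each seed voxel and each cortical parcel; requires ≥ 3 subjects.

**Thresholding.** Each row is thresholded at a percentile of its own
values (defaults: 75th for structural, 90th for functional), computed
with linear interpolation (`numpy.percentile` default); entries strictly
below the threshold are zeroed, ties are kept. A `global` scope using one
matrix-wide threshold is available. Row-wise thresholding is the default
because seeds differ widely in total streamline count.

**Affinity.** The normalized-angle kernel between row profiles:
`a_ij = 1 − arccos(cos_sim(x_i, x_j)) / π`, which maps identical profiles
to 1, orthogonal ones to 0.5 and antiparallel ones to 0 (asserted exactly
in the tests). Zero-norm rows are an error (or 0.5 under a permissive
flag). The kernel depends only on profile direction, so it is invariant
to per-seed scaling.

**Embedding.** Diffusion map embedding with α = 0.5 (Fokker–Planck
normalization): the affinity is degree-normalized as
`W'_ij = W_ij / (d_i^α d_j^α)`, converted to the Markov operator
`P = D'⁻¹ W'`, and eigendecomposed via the symmetric conjugate
`D'^{1/2} P D'^{-1/2}` (so only a symmetric eigensolver is needed). The
trivial stationary eigenpair is dropped; eigenvectors are divided by the
trivial eigenvector (which restores the Markov eigenvectors from the
symmetric ones) and scaled by `λ/(1−λ)` — the diffusion-time-0
convention; at `t > 0` the scale is `λ^t`. Ten components are retained by
default. A disconnected affinity graph is an error reporting component
sizes. The implementation is pinned to a dense brute-force
eigendecomposition of the nonsymmetric operator, per-component |r| ≥
0.999 over 20 random affinities.

**Explained variance** of component k is `λ_k / Σ_j λ_j` over the
*retained* spectrum — a relative share of the kept components, not of the
full operator trace. This is the convention under which two leading
components summing to ≈ 45% of ten retained components are comparable
across runs.

**Sign.** Eigenvector signs are arbitrary; `align_sign` orients each
component either against a reference map (non-negative correlation) or so
its largest-magnitude entry is positive. `match_components` greedily
assigns target axes to distinct components by maximal |correlation|.

**Downstream.** `project_gradient` correlates a thalamic gradient with
every parcel column (pairwise-complete, ≥ 3 observations), yielding a
cortical map in [−1, 1]; `decode_by_communities` averages it within the
seven canonical resting-state networks; `decode_by_nuclei` takes medians
(with quartiles) within THOMAS-style nucleus labels. Orderings are
ascending by the statistic with lexical tie-breaks.

## 2. Synthetic generator

The generator emulates the *inputs* of a TC gradient study, not MRI
physics. All generators are pure functions of a `SynthConfig` and an RNG
seed; child seeds are derived at fixed offsets (+1 qT1, +2 core–matrix,
+3 time series, +4 subject stack).

**Geometry.** Seed voxels sit on an isotropic grid (default
`voxel_size = 2.0` mm) clipped to an ellipsoid with 2 : 1.3 : 1 semi-axes
(longest along x), sized to hold `n_seeds` (default 600, vs ~1000 in a
real hemispheric mask); the default cloud spans ≈ 28 × 16 × 12 mm,
thalamus-like proportions. Seeds are ordered by ascending linear voxel
index in C order (last axis fastest) — an affine-independent convention
recorded in every file the package writes.

**Planted axes.** `u1` is the standardized x-axis projection plus a small
(0.1-weighted) smooth perturbation — a dominant medial-to-lateral-like
axis. `u2` is a smooth random field Gram-Schmidt-orthogonalized against
`u1`; both are standardized, and their sample correlation is exactly
zero. Smooth fields are white noise convolved with a Gaussian distance
kernel; the axes use `axis_smoothing_mm = 12` (broad, so the axes are
large-scale), while map noise uses `sa_smoothing_mm = 3` (short-range).
The two scales are separate parameters because they play different roles:
the axes must be smooth enough to be recoverable, the noise rough enough
that the stationary surrogate model is well specified at the default
cloud size.

**Connectivity.** Each of the `n_parcels` (default 100) cortical parcels
gets an anchor on a jittered grid tiling the central 98% of (u1, u2)
space; communities are assigned by angular sector. Expected streamline
counts follow a Gaussian kernel of latent distance,
`λ_ij = intensity_scale · exp(−d²/(2 · kernel_width²))` (defaults 500 and
0.8 latent units), and observed counts are Poisson draws (a
`deterministic` flag returns the rates exactly, enabling closed-form
tests). Seeds therefore project most strongly to parcels anchored near
them in latent space, which is what makes (u1, u2) recoverable as
gradients.

**Scalar maps.** `qT1 = 1500 ms + coupling_qt1 · u1 + noise` with
`coupling_qt1 = −60 ms` (qT1 decreases along the myelin axis, as in
quantitative T1 of gray matter); the core–matrix proxy is planted on `u2`
with unit coupling. `noise_sd` (default 0.8) is a *noise-to-signal
ratio*: the standardized SA noise field is scaled by
`noise_sd · |coupling|`, so one knob is meaningful for a map in
milliseconds and a dimensionless one alike.

**Time series.** Parcel signals are independent unit-variance AR(1)
series (φ = 0.3, mild temporal autocorrelation); each voxel mixes them
with weights proportional to its streamline rates plus white noise, so
functional connectivity inherits the planted axes. Default 700
timepoints, ≥ 50 required.

**Subject stacks.** Each of `n_subjects` (default 50) subjects carries
shared standard-normal factors; voxel and parcel qT1 load on them through
the rank-6 SVD of the streamline-rate matrix (scaled by 0.5), plus
independent noise. Across-subject correlation then reconstructs the
connectivity pattern — structurally connected pairs covary by
construction. Passing explicit per-voxel/per-parcel loadings selects the
single-factor special case `value = mean + loading · factor + noise`.

**Nuclei.** K-means on seed coordinates partitions the cloud into 11
spatially compact "nuclei" carrying THOMAS-style labels (AV, VA, VLa,
VLP, VPL, Pul, MGN, CM, MD, Hb, MTT) — a stand-in for an atlas, with no
claim to anatomical correspondence.

## 3. Spatial-autocorrelation-corrected statistics

Correlating two smooth brain maps and reading a parametric p-value
overstates significance, because spatial autocorrelation (SA) slashes the
effective sample size. `tcgrad` uses variogram-matched surrogates: per
draw, the map is permuted, smoothed over each seed's k nearest neighbors
with an exponential distance-decaying kernel, and least-squares fitted
(scale + nugget) so the smoothed map's variogram matches the empirical
one; the bandwidth k with minimal misfit is kept from a grid of
{0.1, …, 0.5} × n, and the surrogate values are rank-mapped back onto the
original value multiset (exactly preserved, asserted in the tests).
Variograms use 25 equal-width bins up to the 70th percentile of pairwise
distances; empty bins are flagged, never silently dropped.

`sa_corrected_correlation(x, y, …)` surrogates the *first* argument (by
convention the derived quantity, e.g. a gradient; features are fixed
references) and reports the two-sided add-one p-value
`p_SA = (1 + #{|r_null| ≥ |r_obs|}) / (1 + n_surr)`, bounded below by
`1/(n_surr+1)`. Each surrogate consumes an independent RNG substream
spawned from one seed, so ensembles are reproducible and
order-independent.

**Calibration.** Under the null (independent 3 mm-smoothed maps on a
400-seed cloud), the empirical type-I rate at α = 0.05 over 200 seeded
repetitions falls within [0.02, 0.10] (acceptance test 6; the driver
script prints the exact rate per seed).

## 4. Numerical conventions

- Percentiles: linear interpolation throughout (thresholds, quartiles).
- Correlations are clipped to [−1, 1] after computation; zero-variance
  series yield NaN with a warning rather than an exception, and exactly
  constant series are detected via peak-to-peak, not via the
  floating-point residue of mean-centering.
- Missing values are explicit NaN; correlation-type operations use
  pairwise-complete observations with minimum-count guards (3 for
  correlations, 10 for the SA test).
- TSV round-trips are bit-exact: floats are written as Python `repr` and
  parsed with round-trip precision.
- All RNG is `numpy.random.Generator`-based with explicit seeds;
  derived seeds stay below 2³¹.

## 5. Limitations

- **Stationarity of the surrogate model.** Variogram-matched surrogates
  assume a stationary covariance. When a map's smoothing range is a large
  fraction of the domain extent, the map is effectively a trend, the
  stationary model is misspecified, and the test becomes anticonservative.
  This is why map noise defaults to 3 mm smoothing on a ~28 mm cloud and
  why the calibration test runs in that regime; users correlating
  trend-like maps should expect inflated false-positive rates.
- **Near-degenerate leading eigenvalues.** The two planted axes are
  symmetric by construction, so the leading eigenvalues are close
  (≈ 23% vs ≈ 22% explained variance at the default seed) and on some
  seeds the two gradients rotate within their shared subspace; component
  matching against reference axes is then essential, and feature
  statistics vary with seed accordingly.
- **What is not modeled.** No MRI physics, no tractography biases
  (distance confounds, gyral bias), no subject registration error, no
  head motion, no hemodynamic response, no cortical geometry (parcels are
  points in latent space), no contralateral connectivity, and no claim
  that synthetic nuclei or communities match anatomy. The generator is a
  test harness for the mathematics of the pipeline, not a forward model
  of the brain.
- **Scale.** Defaults run on one CPU in seconds to minutes; the package
  does not target cluster-scale tractography inputs, although the I/O
  layer reads arbitrary NIfTI masks and TSV matrices.
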