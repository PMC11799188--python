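"""Synthetic thalamus-like data with planted two-axis latent structure.

The generator emulates the inputs of a thalamocortical gradient study
without any MRI: an ellipsoidal cloud of seed voxels, two latent
organizational axes (``u1``, the medial-to-lateral axis, tied to the
ellipsoid's longest anatomical direction; ``u2``, a smooth field
orthogonal to it), cortical parcels anchored in latent space, and — on
top of these — streamline-count matrices, scalar microstructure maps,
BOLD-like time series and multi-subject qT1 stacks, each carrying
spatially autocorrelated (SA) noise.

Streamline counts follow a Poisson model around a Gaussian latent-distance
kernel: seeds project most strongly to parcels anchored near them in
(u1, u2) space.  Every generator is a pure function of its config and
seed, and a ``deterministic`` flag replaces sampling with expectations to
enable exact tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .io_core import COMMUNITIES, ConnectivityMatrix, ParcelSpace, ScalarSeedMap, SeedSpace, SubjectStack

#: THOMAS-style thalamic nucleus labels used for synthetic decoding
NUCLEUS_LABELS = ("AV", "VA", "VLa", "VLP", "VPL", "Pul", "MGN", "CM", "MD", "Hb", "MTT")

#: AR(1) coefficient of parcel time series: mild temporal autocorrelation,
#: far from the unit root
AR1_COEF = 0.3

QT1_BASELINE_MS = 1500.0


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic study.

    Defaults mirror a desk-scale version of the study conditions: ~600
    seed voxels per hemisphere (the real masks hold ~1000), 2 mm isotropic
    voxels (so the seed cloud spans a thalamus-like ~28 x 16 x 12 mm),
    100 ipsilateral cortical parcels, 50 subjects and ~700 resting-state
    timepoints.

    ``noise_sd`` is a noise-to-signal ratio: scalar-map SA noise is scaled
    to ``noise_sd * |coupling|`` so the same knob is meaningful for qT1
    (ms) and the dimensionless core-matrix proxy alike.
    """

    n_seeds: int = 600
    n_parcels: int = 100
    voxel_size: float = 2.0
    intensity_scale: float = 500.0
    kernel_width: float = 0.8
    noise_sd: float = 0.8
    sa_smoothing_mm: float = 3.0
    axis_smoothing_mm: float = 12.0
    n_subjects: int = 50
    n_timepoints: int = 700
    coupling_qt1: float = -60.0
    coupling_cm: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_seeds < 2 or self.n_parcels < 2:
            raise ValueError("counts must be >= 2")
        if self.kernel_width <= 0:
            raise ValueError("kernel_width must be positive")
        if self.intensity_scale <= 0:
            raise ValueError("intensity_scale must be positive")


@dataclass(frozen=True)
class LatentGeometry:
    """Seed cloud plus planted axes and parcel anchors.

    ``u1`` and ``u2`` are standardized (mean 0, variance 1) per-seed latent
    coordinates with |corr(u1, u2)| <= 0.1; ``parcel_anchors`` are (p, 2)
    positions tiling (u1, u2) space; ``community`` labels parcels by the
    seven canonical networks.
    """

    seeds: SeedSpace
    u1: np.ndarray
    u2: np.ndarray
    parcel_anchors: np.ndarray
    community: tuple
    voxel_indices: np.ndarray  # (n, 3) integer voxel coordinates
    volume_shape: tuple
    affine: np.ndarray

    @property
    def parcels(self) -> ParcelSpace:
        return ParcelSpace(
            parcel_ids=tuple(f"parcel{j:03d}" for j in range(self.parcel_anchors.shape[0])),
            community=self.community,
        )

    def latent_distances(self) -> np.ndarray:
        """(n_seeds, n_parcels) distances from seeds to anchors in (u1,u2)."""
        seed_pos = np.column_stack([self.u1, self.u2])
        return cdist(seed_pos, self.parcel_anchors)


def _smooth_field(coords: np.ndarray, white: np.ndarray, smoothing_mm: float) -> np.ndarray:
    """Smooth white noise over seeds with a Gaussian distance kernel.

    Returns a standardized (mean 0, sd 1) spatially autocorrelated field.
    """
    d = cdist(coords, coords)
    w = np.exp(-(d**2) / (2.0 * smoothing_mm**2))
    w /= w.sum(axis=1, keepdims=True)
    f = w @ white
    sd = f.std()
    if sd == 0:
        return np.zeros_like(f)
    return (f - f.mean()) / sd


def sa_noise(geom: LatentGeometry, rng: np.random.Generator, smoothing_mm: float | None = None) -> np.ndarray:
    """A fresh standardized SA noise field over the seed cloud."""
    if smoothing_mm is None:
        smoothing_mm = 3.0
    white = rng.standard_normal(geom.seeds.n_seeds)
    return _smooth_field(geom.seeds.coords, white, smoothing_mm)


def make_geometry(cfg: SynthConfig) -> LatentGeometry:
    """Build the seed cloud, latent axes, parcel anchors and communities.

    Seeds sit on a voxel grid clipped to an ellipsoid with 2:1.3:1 semi-axes
    (the longest along x, the "medial-to-lateral" direction).  ``u1`` is
    the standardized x projection plus a small smooth perturbation; ``u2``
    is a smooth random field Gram-Schmidt-orthogonalized against u1, so
    their sample correlation is exactly zero.  Parcel anchors tile the
    rectangle spanned by the central 98% of (u1, u2); communities are
    assigned by angular sector around the anchor-cloud center.
    """
    if cfg.n_seeds < 8:
        raise ValueError("need at least 8 seeds for a meaningful geometry")
    rng = np.random.default_rng(cfg.rng_seed)

    # ellipsoid sized so the voxel grid holds >= n_seeds voxels
    ratios = np.array([2.0, 1.3, 1.0])
    a = (cfg.n_seeds / (4.0 / 3.0 * np.pi * ratios.prod())) ** (1.0 / 3.0) + 1.0
    while True:
        semi = ratios * a
        half = np.ceil(semi).astype(int)
        grid = np.stack(
            np.meshgrid(*[np.arange(-h, h + 1) for h in half], indexing="ij"), axis=-1
        ).reshape(-1, 3)
        r = np.sqrt(((grid / semi) ** 2).sum(axis=1))
        if np.sum(r <= 1.0) >= cfg.n_seeds:
            break
        a *= 1.2  # grow the ellipsoid until enough grid voxels fit (tiny n only)
    inside = np.argsort(r, kind="stable")[: cfg.n_seeds]
    vox = grid[np.sort(inside)]  # deterministic order before index shift

    shape = tuple(2 * half + 1)
    vox_idx = vox + half  # non-negative voxel indices
    affine = np.diag([cfg.voxel_size] * 3 + [1.0])
    affine[:3, 3] = -half * cfg.voxel_size  # grid center back at (0,0,0) mm
    lin = np.ravel_multi_index(tuple(vox_idx.T), shape)
    order = np.argsort(lin)
    vox_idx = vox_idx[order]
    lin = lin[order]
    coords = vox_idx * cfg.voxel_size + affine[:3, 3]
    seeds = SeedSpace(seed_ids=lin, coords=coords, hemisphere="L", voxel_size=cfg.voxel_size)

    # u1: standardized longest-axis projection + small smooth perturbation
    x = coords[:, 0]
    base = (x - x.mean()) / x.std()
    pert = _smooth_field(coords, rng.standard_normal(cfg.n_seeds), cfg.axis_smoothing_mm)
    u1 = base + 0.1 * pert
    u1 = (u1 - u1.mean()) / u1.std()

    # u2: smooth field orthogonalized against u1 (Gram-Schmidt), standardized
    raw = _smooth_field(coords, rng.standard_normal(cfg.n_seeds), cfg.axis_smoothing_mm)
    raw = raw - raw.mean()
    u2 = raw - (raw @ u1) / (u1 @ u1) * u1
    if u2.std() < 1e-12:
        raise RuntimeError("degenerate u2 field; change rng_seed")
    u2 = (u2 - u2.mean()) / u2.std()

    # parcel anchors tile the central (u1, u2) rectangle on a jittered grid
    lo = [np.quantile(u, 0.01) for u in (u1, u2)]
    hi = [np.quantile(u, 0.99) for u in (u1, u2)]
    g = int(np.ceil(np.sqrt(cfg.n_parcels)))
    g1, g2 = np.meshgrid(np.linspace(lo[0], hi[0], g), np.linspace(lo[1], hi[1], g), indexing="ij")
    anchors = np.column_stack([g1.ravel(), g2.ravel()])[: cfg.n_parcels]
    anchors = anchors + rng.uniform(-0.05, 0.05, size=anchors.shape)

    # communities by angular sector around the anchor centroid
    centered = anchors - anchors.mean(axis=0)
    theta = np.arctan2(centered[:, 1], centered[:, 0])
    bins = np.linspace(-np.pi, np.pi, len(COMMUNITIES) + 1)
    sector = np.clip(np.digitize(theta, bins) - 1, 0, len(COMMUNITIES) - 1)
    community = tuple(COMMUNITIES[s] for s in sector)

    return LatentGeometry(
        seeds=seeds, u1=u1, u2=u2, parcel_anchors=anchors, community=community,
        voxel_indices=vox_idx, volume_shape=shape, affine=affine,
    )


def sc_rates(geom: LatentGeometry, cfg: SynthConfig) -> np.ndarray:
    """Expected streamline counts: Gaussian kernel of latent distance."""
    d = geom.latent_distances()
    return cfg.intensity_scale * np.exp(-(d**2) / (2.0 * cfg.kernel_width**2))


def simulate_sc_counts(
    geom: LatentGeometry, cfg: SynthConfig, deterministic: bool = False,
    rng: np.random.Generator | None = None,
) -> ConnectivityMatrix:
    """Streamline-count matrix: Poisson draws around the latent-distance rates.

    In deterministic mode the matrix equals the rates exactly (non-negative
    real); otherwise it is non-negative integer Poisson counts.
    """
    lam = sc_rates(geom, cfg)
    if deterministic:
        values = lam
    else:
        if rng is None:
            rng = np.random.default_rng(cfg.rng_seed)
        values = rng.poisson(lam).astype(float)
    return ConnectivityMatrix(values=values, modality="sc_counts", seeds=geom.seeds,
                              parcels=geom.parcels, hemisphere=geom.seeds.hemisphere)


def _scalar_map(geom, cfg, rng, axis: np.ndarray, baseline: float, coupling: float,
                name: str, units: str) -> ScalarSeedMap:
    noise = sa_noise(geom, rng, cfg.sa_smoothing_mm) if cfg.noise_sd > 0 else 0.0
    values = baseline + coupling * axis + cfg.noise_sd * abs(coupling) * noise
    return ScalarSeedMap(values=values, name=name, units=units)


def simulate_qt1(geom: LatentGeometry, cfg: SynthConfig,
                 rng: np.random.Generator | None = None) -> ScalarSeedMap:
    """Group qT1 proxy: baseline + coupling_qt1 * u1 + SA noise.

    With the default negative coupling, qT1 decreases along u1 — the
    myelin-content axis runs opposite to qT1, as in quantitative T1
    imaging of gray matter.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed + 1)
    return _scalar_map(geom, cfg, rng, geom.u1, QT1_BASELINE_MS, cfg.coupling_qt1, "qt1", "ms")


def simulate_corematrix(geom: LatentGeometry, cfg: SynthConfig,
                        rng: np.random.Generator | None = None) -> ScalarSeedMap:
    """Core-matrix cell-type proxy planted on u2 (dimensionless)."""
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed + 2)
    return _scalar_map(geom, cfg, rng, geom.u2, 0.0, cfg.coupling_cm, "corematrix", "")


def simulate_timeseries(
    geom: LatentGeometry, cfg: SynthConfig, rng: np.random.Generator | None = None,
    noise_sd: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """BOLD-like series: (voxel_ts (n_seeds, T), parcel_ts (n_parcels, T)).

    Parcel signals are independent unit-variance AR(1) series; each voxel
    mixes them with weights proportional to its streamline rates, plus
    white observation noise, so voxel-parcel correlation inherits the
    planted axes.
    """
    if cfg.n_timepoints < 50:
        raise ValueError("need at least 50 timepoints")
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed + 3)
    if noise_sd is None:
        noise_sd = 0.5
    T = cfg.n_timepoints
    innov_sd = np.sqrt(1.0 - AR1_COEF**2)  # stationary unit variance
    eps = rng.standard_normal((cfg.n_parcels, T)) * innov_sd
    parcel_ts = np.empty((cfg.n_parcels, T))
    parcel_ts[:, 0] = rng.standard_normal(cfg.n_parcels)
    for t in range(1, T):
        parcel_ts[:, t] = AR1_COEF * parcel_ts[:, t - 1] + eps[:, t]
    w = sc_rates(geom, cfg)
    s = w.sum(axis=1, keepdims=True)
    # a seed whose rates all underflow mixes parcels uniformly
    w = np.where(s > 0, w / np.where(s > 0, s, 1.0), 1.0 / cfg.n_parcels)
    voxel_ts = w @ parcel_ts + noise_sd * rng.standard_normal((geom.seeds.n_seeds, T))
    return voxel_ts, parcel_ts


def simulate_subject_qt1_stack(
    geom: LatentGeometry, cfg: SynthConfig, rng: np.random.Generator | None = None,
    noise_sd: float = 0.5, beta: np.ndarray | None = None, gamma: np.ndarray | None = None,
    n_factors: int = 6, factor_scale: float = 0.5,
) -> SubjectStack:
    """Multi-subject qT1 stack whose covariance tracks connectivity.

    Each subject carries shared standard-normal factors; voxel i reads
    ``mu_i + sum_k B_ik f_sk + noise`` and parcel j reads
    ``nu_j + sum_k G_jk f_sk + noise``.  By default the factor loadings B
    and G come from the rank-``n_factors`` SVD of the streamline-rate
    matrix (scaled by ``factor_scale``), so the across-subject
    voxel-parcel covariance reconstructs the connectivity pattern and
    structurally connected pairs covary by construction.

    Passing explicit per-voxel ``beta`` and per-parcel ``gamma`` loadings
    selects the single-factor special case
    ``voxel = mu_i + beta_i * f_s + noise``.

    ``noise_sd`` here is absolute (same units as the factor loadings).
    """
    if cfg.n_subjects < 3:
        raise ValueError("structural covariance needs at least 3 subjects")
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed + 4)
    mu = QT1_BASELINE_MS + cfg.coupling_qt1 * geom.u1
    nu = QT1_BASELINE_MS + np.zeros(cfg.n_parcels)
    if beta is not None or gamma is not None:
        if beta is None or gamma is None:
            raise ValueError("give both beta and gamma or neither")
        B = np.asarray(beta, dtype=float)[:, None]
        G = np.asarray(gamma, dtype=float)[:, None]
    else:
        lam = sc_rates(geom, cfg)
        lam_n = lam / lam.std()
        K = min(n_factors, min(lam.shape) - 1)
        U, S, Vt = np.linalg.svd(lam_n, full_matrices=False)
        B = U[:, :K] * np.sqrt(S[:K]) * factor_scale
        G = Vt[:K].T * np.sqrt(S[:K]) * factor_scale
    F = rng.standard_normal((cfg.n_subjects, B.shape[1]))
    vox = mu[None, :] + F @ B.T + noise_sd * rng.standard_normal((cfg.n_subjects, geom.seeds.n_seeds))
    par = nu[None, :] + F @ G.T + noise_sd * rng.standard_normal((cfg.n_subjects, cfg.n_parcels))
    return SubjectStack(voxel_values=vox, parcel_values=par)


def assign_nuclei(geom: LatentGeometry, n_nuclei: int = 11, rng_seed: int = 0) -> np.ndarray:
    """Partition seeds into contiguous synthetic "nuclei" by k-means on coords.

    Returns one THOMAS-style label per seed.  The partition is a stand-in
    for an atlas segmentation: spatially compact, deterministic for a
    given seed, with no claim to anatomical correspondence.
    """
    from scipy.cluster.vq import kmeans2

    if n_nuclei > len(NUCLEUS_LABELS):
        raise ValueError(f"at most {len(NUCLEUS_LABELS)} nucleus labels available")
    rng = np.random.default_rng(rng_seed)
    coords = geom.seeds.coords
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # kmeans2 warns on empty clusters
        _, labels = kmeans2(coords, n_nuclei, minit="++", seed=rng, iter=50)
    return np.array([NUCLEUS_LABELS[k] for k in labels])
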