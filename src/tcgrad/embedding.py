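"""Normalized-angle affinity and diffusion-map embedding.

The embedding follows the anisotropic-diffusion construction: given a
symmetric non-negative affinity W with degrees d, form
``W' = W / (d_i^alpha d_j^alpha)``, row-normalize to a Markov operator
``P = D'^{-1} W'``, and take the leading non-trivial eigenvectors of P.
``alpha = 0.5`` (Fokker-Planck scaling) discounts sampling density while
preserving large-scale geometry.  Eigenpairs are obtained from the
symmetric conjugate ``D'^{1/2} P D'^{-1/2}`` for numerical stability and
back-transformed.

The diffusion-time-0 convention scales eigenvector k by
``lambda_k / (1 - lambda_k)``; loadings are unitless and sign-arbitrary,
so :func:`align_sign` fixes signs deterministically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.sparse.csgraph import connected_components

from .io_core import ScalarSeedMap, logger


@dataclass(frozen=True)
class AffinityMatrix:
    """Symmetric non-negative seed-by-seed similarity in [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("affinity must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("affinity must be symmetric within 1e-10")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("affinity values must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class GradientSet:
    """Low-dimensional gradient loadings with their eigenvalue spectrum.

    ``loadings`` is (n_seeds, k); ``explained_variance`` holds each
    retained eigenvalue as a fraction of the retained eigenvalue sum.
    """

    loadings: np.ndarray
    eigenvalues: np.ndarray
    explained_variance: np.ndarray
    alpha: float
    diffusion_time: float = 0.0

    def __post_init__(self) -> None:
        lam = np.asarray(self.eigenvalues, dtype=float)
        if np.any(np.diff(lam) > 1e-12):
            raise ValueError("eigenvalues must be non-increasing")
        if np.any(lam <= 0) or np.any(lam > 1 + 1e-9):
            raise ValueError("retained eigenvalues must lie in (0, 1]")

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def component(self, k: int) -> ScalarSeedMap:
        """Gradient k (0-based) as a per-seed scalar map."""
        return ScalarSeedMap(values=self.loadings[:, k], name=f"G{k + 1}")


def normalized_angle_affinity(profiles: np.ndarray, permissive: bool = False) -> AffinityMatrix:
    """Normalized-angle similarity of row profiles.

    ``a_ij = 1 - arccos(cos_sim(row_i, row_j)) / pi`` maps cosine
    similarity into [0, 1]: identical directions give 1, orthogonal 0.5,
    antiparallel 0.

    Zero-norm rows have no direction; by default they raise (naming the
    offending seeds).  Under ``permissive=True`` their similarities are
    set to the uninformative value 0.5 (1 on the diagonal).
    """
    p = np.asarray(profiles, dtype=float)
    if p.ndim != 2:
        raise ValueError("profiles must be 2-D")
    if not np.all(np.isfinite(p)):
        raise ValueError("profiles contain non-finite values")
    norms = np.linalg.norm(p, axis=1)
    zero = norms == 0
    if zero.any():
        if not permissive:
            raise ValueError(
                f"zero-norm connectivity profile(s) at seed row(s) {np.where(zero)[0].tolist()}"
            )
        logger.warning("affinity: %d zero-norm row(s) assigned similarity 0.5", int(zero.sum()))
    unit = p / np.where(zero, 1.0, norms)[:, None]
    cos = np.clip(unit @ unit.T, -1.0, 1.0)
    a = 1.0 - np.arccos(cos) / np.pi
    if zero.any():
        a[zero, :] = 0.5
        a[:, zero] = 0.5
    np.fill_diagonal(a, 1.0)
    a = (a + a.T) / 2.0  # symmetrize away float round-off
    return AffinityMatrix(values=a)


def diffusion_map_embed(
    W: AffinityMatrix | np.ndarray,
    alpha: float = 0.5,
    n_components: int = 10,
    diffusion_time: float = 0.0,
) -> GradientSet:
    """Diffusion-map embedding of an affinity matrix.

    Returns the ``n_components`` leading non-trivial eigenvectors of the
    alpha-normalized Markov operator, scaled by ``lambda/(1-lambda)``
    (``diffusion_time=0``) or ``lambda^t`` (t > 0), with explained
    variance over the retained spectrum.

    Raises if the affinity graph is disconnected (thresholding that
    severs the graph must be fixed upstream, not silently patched) or if
    fewer than ``n_components + 1`` eigenpairs exist.
    """
    if isinstance(W, AffinityMatrix):
        Wv = W.values
    else:
        Wv = np.asarray(W, dtype=float)
        Wv = AffinityMatrix(values=Wv).values  # validate
    n = Wv.shape[0]
    if n < n_components + 1:
        raise ValueError(f"need at least {n_components + 1} nodes for {n_components} components")

    n_comp, labels = connected_components((Wv > 0).astype(np.int8), directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise ValueError(f"affinity graph is disconnected; component sizes {sizes.tolist()}")

    d = Wv.sum(axis=1)
    with np.errstate(divide="ignore"):
        inv_da = d ** (-alpha) if alpha > 0 else np.ones(n)
    Wp = Wv * np.outer(inv_da, inv_da)
    dp = Wp.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(dp)
    # symmetric conjugate of P = D'^-1 W'
    S = Wp * np.outer(inv_sqrt, inv_sqrt)
    S = (S + S.T) / 2.0
    evals, evecs = scipy.linalg.eigh(S, subset_by_index=(n - n_components - 1, n - 1))
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]

    # back-transform: eigenvectors of P, then normalize by the trivial one
    psi = evecs * inv_sqrt[:, None]
    psi = psi / psi[:, [0]]  # trivial eigenvector becomes the constant 1
    lam = evals[1:]
    psi = psi[:, 1:]
    if np.any(lam <= 0):
        raise ValueError("non-positive retained eigenvalue; graph may be near-bipartite")
    lam = np.minimum(lam, 1.0)  # guard round-off above 1
    if diffusion_time == 0:
        scale = lam / (1.0 - lam)
    else:
        scale = lam**diffusion_time
    loadings = psi * scale
    return GradientSet(
        loadings=loadings,
        eigenvalues=lam,
        explained_variance=explained_variance(lam),
        alpha=alpha,
        diffusion_time=diffusion_time,
    )


def explained_variance(eigenvalues: np.ndarray) -> np.ndarray:
    """Each eigenvalue as a fraction of the retained eigenvalue sum."""
    lam = np.asarray(eigenvalues, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("eigenvalues must be positive")
    if np.any(np.diff(lam) > 1e-12):
        raise ValueError("eigenvalues must be descending")
    return lam / lam.sum()


def align_sign(g: GradientSet, reference: ScalarSeedMap | np.ndarray | None = None) -> GradientSet:
    """Fix the arbitrary eigenvector signs deterministically.

    With a reference map, each component is flipped so its correlation
    with the reference is non-negative; without one, so its
    largest-magnitude entry is positive.  Idempotent.
    """
    L = g.loadings.copy()
    ref = None
    if reference is not None:
        ref = reference.values if isinstance(reference, ScalarSeedMap) else np.asarray(reference, dtype=float)
        if ref.size != L.shape[0]:
            raise ValueError("reference length must match loadings")
        ref = ref - np.nanmean(ref)
    for k in range(L.shape[1]):
        col = L[:, k]
        if np.allclose(col.std(), 0):
            warnings.warn(f"component {k} has zero variance; sign left unchanged", stacklevel=2)
            continue
        if ref is not None:
            mask = np.isfinite(ref)
            s = np.dot(col[mask] - col[mask].mean(), ref[mask])
        else:
            s = col[np.argmax(np.abs(col))]
        if s < 0:
            L[:, k] = -col
    return GradientSet(
        loadings=L, eigenvalues=g.eigenvalues, explained_variance=g.explained_variance,
        alpha=g.alpha, diffusion_time=g.diffusion_time,
    )
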