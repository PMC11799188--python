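"""Functional connectivity, group qT1 and structural covariance builders.

All three produce seed-by-parcel matrices comparable to the structural
connectome: FC correlates voxel and parcel time series within a scan,
structural covariance correlates qT1 across subjects, and the group qT1
map is the voxel-wise across-subject mean.
"""

from __future__ import annotations

import warnings

import numpy as np

from .io_core import ConnectivityMatrix, ScalarSeedMap, SubjectStack, logger

#: clamp applied to |r| before arctanh so collinear series stay finite
FISHER_CLAMP = 1.0 - 1e-7


def _cross_correlation(X: np.ndarray, Y: np.ndarray, axis_name: str) -> np.ndarray:
    """Pearson r between every row of X and every row of Y (shared columns).

    Rows with zero variance yield NaN entries and a warning rather than an
    exception: a flat series carries no correlation information.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[1] != Y.shape[1]:
        raise ValueError("X and Y must share the observation axis")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        return _cross_correlation_pairwise(X, Y)
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    xs = np.sqrt((Xc**2).sum(axis=1))
    ys = np.sqrt((Yc**2).sum(axis=1))
    # ptp catches exactly-constant rows whose centered norm is only
    # floating-point residue rather than exactly zero
    bad_x = (xs == 0) | (np.ptp(X, axis=1) == 0)
    bad_y = (ys == 0) | (np.ptp(Y, axis=1) == 0)
    if bad_x.any() or bad_y.any():
        warnings.warn(
            f"zero-variance {axis_name}: {int(bad_x.sum())} row(s), {int(bad_y.sum())} column(s); "
            "entries set to NaN", stacklevel=3,
        )
        logger.warning("zero-variance %s series: rows=%d cols=%d",
                       axis_name, int(bad_x.sum()), int(bad_y.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ Yc.T) / np.outer(xs, ys)
    r = np.clip(r, -1.0, 1.0)
    r[bad_x, :] = np.nan
    r[:, bad_y] = np.nan
    return r


def _cross_correlation_pairwise(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pairwise-complete fallback when inputs carry missing observations."""
    n_missing = int(np.sum(~np.isfinite(X)) + np.sum(~np.isfinite(Y)))
    logger.warning("correlation over pairwise-complete observations (%d missing values)", n_missing)
    r = np.full((X.shape[0], Y.shape[0]), np.nan)
    fx = np.isfinite(X)
    fy = np.isfinite(Y)
    for i in range(X.shape[0]):
        for j in range(Y.shape[0]):
            ok = fx[i] & fy[j]
            if ok.sum() < 3:
                continue
            if np.ptp(X[i, ok]) == 0 or np.ptp(Y[j, ok]) == 0:
                continue
            xi = X[i, ok] - X[i, ok].mean()
            yj = Y[j, ok] - Y[j, ok].mean()
            den = np.sqrt((xi**2).sum() * (yj**2).sum())
            if den > 0:
                r[i, j] = np.clip((xi @ yj) / den, -1.0, 1.0)
    return r


def fc_matrix(voxel_ts: np.ndarray, parcel_ts: np.ndarray) -> ConnectivityMatrix:
    """Thalamocortical functional connectivity: Pearson r of time series.

    ``voxel_ts`` is (n_seeds, T) and ``parcel_ts`` is (n_parcels, T) from
    the same (intrahemispheric) scan; T must be at least 3.
    """
    if voxel_ts.shape[1] < 3:
        raise ValueError("need at least 3 timepoints for a correlation")
    r = _cross_correlation(voxel_ts, parcel_ts, "time series")
    return ConnectivityMatrix(values=r, modality="fc_r")


def fisher_z(m: ConnectivityMatrix) -> ConnectivityMatrix:
    """Fisher r-to-z transform (arctanh), applied element-wise.

    |r| is clamped to ``1 - 1e-7`` first so exactly collinear series map
    to a large finite z instead of infinity.
    """
    if m.modality != "fc_r":
        raise ValueError(f"fisher_z expects fc_r, got {m.modality}")
    r = np.clip(m.values, -FISHER_CLAMP, FISHER_CLAMP)
    return m.with_values(np.arctanh(r), modality="fc_z")


def group_qt1(stack: SubjectStack) -> ScalarSeedMap:
    """Voxel-wise qT1 mean across subjects, skipping absent entries."""
    if stack.n_subjects < 1:
        raise ValueError("empty stack")
    vals = stack.voxel_values
    counts = np.isfinite(vals).sum(axis=0)
    if np.any(counts < stack.n_subjects):
        logger.info("group_qt1: per-voxel subject counts range %d-%d",
                    int(counts.min()), int(counts.max()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN voxels -> NaN
        mean = np.nanmean(vals, axis=0)
    return ScalarSeedMap(values=mean, name="qt1", units="ms")


def structural_covariance(stack: SubjectStack) -> ConnectivityMatrix:
    """Thalamocortical structural covariance: across-subject Pearson r.

    Entry (i, j) correlates voxel i's qT1 with parcel j's qT1 over
    subjects.  With fewer than 3 subjects any two points give |r| = 1, so
    that is rejected as degenerate.
    """
    if stack.n_subjects < 3:
        raise ValueError("correlation across subjects degenerate with < 3 subjects")
    r = _cross_correlation(stack.voxel_values.T, stack.parcel_values.T, "across-subject")
    return ConnectivityMatrix(values=r, modality="scov_r")
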