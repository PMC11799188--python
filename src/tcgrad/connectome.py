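"""Assembly of group-level thalamocortical connectivity matrices.

The structural pipeline order is: average subject count matrices,
normalize each column by its maximum, threshold at a percentile, then
(downstream) build the affinity and embed.  Thresholding defaults to
per-row: each seed keeps its strongest connections, so no seed's profile
is wiped out by globally dominant parcels.
"""

from __future__ import annotations

import warnings

import numpy as np

from .io_core import ConnectivityMatrix, logger


def group_average(matrices: list[ConnectivityMatrix]) -> ConnectivityMatrix:
    """Element-wise mean of same-shape, same-modality subject matrices."""
    if not matrices:
        raise ValueError("no matrices to average")
    first = matrices[0]
    for m in matrices[1:]:
        if m.shape != first.shape:
            raise ValueError(f"shape mismatch: {m.shape} vs {first.shape}")
        if m.modality != first.modality:
            raise ValueError(f"modality mismatch: {m.modality} vs {first.modality}")
    stack = np.stack([m.values for m in matrices])
    return first.with_values(stack.mean(axis=0))


def normalize_columns_max(m: ConnectivityMatrix) -> ConnectivityMatrix:
    """Divide every column by its maximum (streamline-count normalization).

    Columns whose maximum is positive end with maximum exactly 1; all-zero
    columns are left untouched (with a warning) rather than divided.
    """
    v = m.values
    if np.nanmin(v) < 0:
        raise ValueError("column-max normalization expects non-negative input")
    colmax = np.nanmax(v, axis=0)
    zero = colmax <= 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero column(s) left unnormalized", stacklevel=2)
        logger.warning("normalize_columns_max: %d all-zero column(s)", int(zero.sum()))
    safe = np.where(zero, 1.0, colmax)
    return m.with_values(v / safe, modality="sc_norm")


def threshold_percentile(
    m: ConnectivityMatrix, pct: float, scope: str = "row"
) -> ConnectivityMatrix:
    """Zero entries strictly below the pct-th percentile.

    The percentile (linear interpolation between order statistics) is
    computed per row under ``scope="row"`` — each seed keeps roughly its
    top ``(100-pct)%`` of connections — or over the whole matrix under
    ``scope="global"``.  Entries equal to the threshold are retained.
    """
    if not (0 <= pct < 100):
        raise ValueError("pct must lie in [0, 100)")
    v = m.values
    if scope == "row":
        thr = np.percentile(v, pct, axis=1, keepdims=True)
    elif scope == "global":
        thr = np.percentile(v, pct)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return m.with_values(np.where(v < thr, 0.0, v))
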