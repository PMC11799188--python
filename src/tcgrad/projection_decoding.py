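"""Cortical projection of thalamic gradients and atlas-based decoding.

A thalamic gradient is mapped onto the cortex by correlating it with each
column (parcel) of a thalamocortical matrix: a parcel whose connectivity
profile follows the gradient scores high.  The resulting cortical map is
decoded by averaging within functional communities; thalamic maps are
decoded by nucleus medians.  Orderings are deterministic, with lexical
tie-breaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import ConnectivityMatrix, ParcelSpace, ScalarSeedMap, logger


@dataclass(frozen=True)
class CorticalMap:
    """One Pearson r per cortical parcel, tagged by its source."""

    values: np.ndarray
    parcel_ids: tuple
    source: tuple = ("G1", "sc_norm")

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.size != len(self.parcel_ids):
            raise ValueError("one value per parcel required")
        finite = v[np.isfinite(v)]
        if finite.size and (finite.min() < -1 - 1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError("cortical map values must lie in [-1, 1]")


@dataclass(frozen=True)
class GroupSummary:
    """Per-group statistic with the ascending group ordering.

    ``order`` lists group labels sorted ascending by the statistic, ties
    broken lexically.  ``extras`` carries quartiles for raincloud-style
    export when the statistic is a median.
    """

    labels: tuple
    statistic: dict
    values: dict
    order: tuple
    stat_name: str
    extras: dict | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rank, lab in enumerate(self.order):
            row = {"label": lab, "rank": rank, self.stat_name: self.statistic[lab],
                   "n": len(self.values[lab])}
            if self.extras is not None:
                row.update(self.extras[lab])
            rows.append(row)
        return pd.DataFrame(rows)


def _pearson_vs_columns(g: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Pearson r of g against every column of M, pairwise-complete."""
    out = np.full(M.shape[1], np.nan)
    for j in range(M.shape[1]):
        col = M[:, j]
        ok = np.isfinite(g) & np.isfinite(col)
        if ok.sum() < 3:
            continue
        gc = g[ok] - g[ok].mean()
        cc = col[ok] - col[ok].mean()
        den = np.sqrt((gc**2).sum() * (cc**2).sum())
        if den == 0:
            continue
        out[j] = np.clip(gc @ cc / den, -1.0, 1.0)
    return out


def project_gradient(g: ScalarSeedMap | np.ndarray, m: ConnectivityMatrix,
                     gradient_id: str = "G1") -> CorticalMap:
    """Correlate a thalamic gradient with each parcel's connectivity column.

    Zero-variance columns yield absent entries with a warning; a
    zero-variance gradient is an error (it can correlate with nothing).
    """
    gv = g.values if isinstance(g, ScalarSeedMap) else np.asarray(g, dtype=float)
    if gv.size != m.shape[0]:
        raise ValueError("gradient length must equal the matrix row count")
    finite = gv[np.isfinite(gv)]
    if finite.size < 3 or finite.std() == 0:
        raise ValueError("gradient has zero variance")
    vals = _pearson_vs_columns(gv, m.values)
    n_absent = int(np.sum(~np.isfinite(vals)))
    if n_absent:
        warnings.warn(f"{n_absent} zero-variance column(s) produced absent entries", stacklevel=2)
        logger.warning("project_gradient: %d absent parcel value(s)", n_absent)
    parcel_ids = m.parcels.parcel_ids if m.parcels is not None else tuple(
        f"p{j}" for j in range(m.shape[1])
    )
    return CorticalMap(values=vals, parcel_ids=parcel_ids, source=(gradient_id, m.modality))


def _group_summary(values: np.ndarray, labels: np.ndarray, stat: str) -> GroupSummary:
    uniq = sorted(set(labels.tolist()))
    statistic, per_group, extras = {}, {}, {}
    excluded = []
    for lab in uniq:
        v = values[labels == lab]
        v = v[np.isfinite(v)]
        per_group[lab] = v.tolist()
        if v.size == 0:
            excluded.append(lab)
            continue
        if stat == "mean":
            statistic[lab] = float(v.mean())
        else:
            statistic[lab] = float(np.median(v))
            q1, q3 = np.percentile(v, [25, 75])  # linear interpolation
            extras[lab] = {"q1": float(q1), "q3": float(q3)}
    if excluded:
        warnings.warn(f"group(s) with all values absent excluded: {excluded}", stacklevel=3)
    order = tuple(sorted(statistic, key=lambda lab: (statistic[lab], lab)))
    return GroupSummary(
        labels=tuple(uniq), statistic=statistic, values=per_group, order=order,
        stat_name=stat, extras=extras if stat == "median" else None,
    )


def decode_by_communities(c: CorticalMap, parcels: ParcelSpace) -> GroupSummary:
    """Community means of a cortical map, ordered ascending by mean."""
    if parcels.community is None:
        raise ValueError("ParcelSpace carries no community labels")
    if parcels.n_parcels != c.values.size:
        raise ValueError("parcel count mismatch")
    return _group_summary(c.values, np.asarray(parcels.community), "mean")


def decode_by_nuclei(g: ScalarSeedMap | np.ndarray, nucleus_labels) -> GroupSummary:
    """Nucleus medians (plus quartiles) of a thalamic map, ordered by median.

    Seeds with no label (None/NaN/empty) are excluded with a logged count.
    """
    gv = g.values if isinstance(g, ScalarSeedMap) else np.asarray(g, dtype=float)
    labels = np.asarray(nucleus_labels, dtype=object)
    if labels.size != gv.size:
        raise ValueError("one nucleus label per seed required")
    labeled = np.array([lab is not None and lab == lab and lab != "" for lab in labels])
    if not labeled.all():
        logger.warning("decode_by_nuclei: %d unlabeled seed(s) excluded", int((~labeled).sum()))
    return _group_summary(gv[labeled], labels[labeled].astype(str), "median")


def gradient_space_table(
    g1: ScalarSeedMap | np.ndarray,
    g2: ScalarSeedMap | np.ndarray,
    overlays: dict | None = None,
    seed_ids=None,
) -> pd.DataFrame:
    """Per-seed table of the (G1, G2) plane with overlay columns.

    One row per seed (none dropped), in seed order, for external 2-D
    scatter plotting color-coded by qT1, cell type, nuclei, etc.
    """
    v1 = g1.values if isinstance(g1, ScalarSeedMap) else np.asarray(g1, dtype=float)
    v2 = g2.values if isinstance(g2, ScalarSeedMap) else np.asarray(g2, dtype=float)
    if v1.size != v2.size:
        raise ValueError("g1 and g2 must have equal length")
    if seed_ids is None:
        seed_ids = np.arange(v1.size)
    data = {"seed_id": np.asarray(seed_ids), "g1": v1, "g2": v2}
    if overlays:
        for name, ov in overlays.items():
            ovv = ov.values if isinstance(ov, ScalarSeedMap) else np.asarray(ov)
            if ovv.size != v1.size:
                raise ValueError(f"overlay {name!r} length mismatch")
            data[name] = ovv
    return pd.DataFrame(data)


def map_consistency(individual_maps, group_map: ScalarSeedMap | np.ndarray) -> list:
    """Pearson r of each individual map against the group map.

    Individuals with zero variance yield NaN with a warning.
    """
    gv = group_map.values if isinstance(group_map, ScalarSeedMap) else np.asarray(group_map, dtype=float)
    out = []
    for i, ind in enumerate(individual_maps):
        iv = ind.values if isinstance(ind, ScalarSeedMap) else np.asarray(ind, dtype=float)
        if iv.size != gv.size:
            raise ValueError("all maps must share length")
        ok = np.isfinite(iv) & np.isfinite(gv)
        ic = iv[ok] - iv[ok].mean()
        gc = gv[ok] - gv[ok].mean()
        den = np.sqrt((ic**2).sum() * (gc**2).sum())
        if den == 0:
            warnings.warn(f"individual map {i} has zero variance", stacklevel=2)
            out.append(float("nan"))
        else:
            out.append(float(np.clip(ic @ gc / den, -1.0, 1.0)))
    return out
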