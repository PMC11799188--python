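"""Deterministic I/O for thalamocortical gradient pipelines.

All on-disk exchange uses two formats: NIfTI-1 volumes for masks and
voxel-wise scalar maps, and plain TSV for matrices, time series and label
tables.  Every matrix TSV carries one leading metadata comment line
(``# modality=... hemisphere=...``) so files are self-describing and
diffable.

Seed ordering convention
------------------------
Thalamic seed voxels are ordered by ascending linear index over the volume
*as stored*, with the last array axis varying fastest (C-order
``np.ravel_multi_index``).  The convention is affine-independent and makes
seed order a pure function of the mask array; it is recorded in the
metadata of every file this module writes.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger("tcgrad")

#: canonical resting-state community names used for cortical decoding
COMMUNITIES = ("Visual", "Somatomotor", "DAN", "VAN", "Limbic", "FPN", "DMN")

#: modality tags a ConnectivityMatrix may carry
MODALITIES = ("sc_counts", "sc_norm", "fc_r", "fc_z", "scov_r")

SEED_ORDER_CONVENTION = "ascending-linear-index-C-order"


def configure_logging(level: str = "INFO") -> None:
    """Attach a stderr handler to the package logger (idempotent)."""
    if not logger.handlers:
        h = logging.StreamHandler()
        h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(h)
    logger.setLevel(getattr(logging, level.upper()))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SeedSpace:
    """The ordered set of thalamic seed voxels for one hemisphere.

    Attributes
    ----------
    seed_ids : (n,) int array
        Strictly increasing identifiers; by convention the linear voxel
        index in the source mask volume.
    coords : (n, 3) float array
        Voxel-center coordinates in physical mm (affine-transformed).
    hemisphere : str
        ``"L"`` or ``"R"``.
    voxel_size : float
        Isotropic voxel edge length in mm (informational).
    """

    seed_ids: np.ndarray
    coords: np.ndarray
    hemisphere: str = "L"
    voxel_size: float = 1.0

    def __post_init__(self) -> None:
        ids = np.asarray(self.seed_ids, dtype=int)
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "seed_ids", ids)
        object.__setattr__(self, "coords", coords)
        if ids.ndim != 1 or coords.shape != (ids.size, 3):
            raise ValueError("seed_ids must be (n,), coords must be (n, 3)")
        if ids.size < 2:
            raise ValueError("a SeedSpace needs at least 2 seeds")
        if np.any(np.diff(ids) <= 0):
            raise ValueError("seed_ids must be strictly increasing")
        if np.unique(coords, axis=0).shape[0] != coords.shape[0]:
            raise ValueError("seed coordinates must be unique")
        if self.hemisphere not in ("L", "R"):
            raise ValueError("hemisphere must be 'L' or 'R'")

    @property
    def n_seeds(self) -> int:
        return int(self.seed_ids.size)


@dataclass(frozen=True)
class ParcelSpace:
    """The ordered set of cortical target parcels.

    ``community`` optionally maps every parcel to one of the seven
    canonical resting-state networks.
    """

    parcel_ids: tuple
    community: tuple | None = None

    def __post_init__(self) -> None:
        ids = tuple(self.parcel_ids)
        object.__setattr__(self, "parcel_ids", ids)
        if len(set(ids)) != len(ids):
            raise ValueError("parcel_ids must be unique")
        if self.community is not None:
            comm = tuple(self.community)
            object.__setattr__(self, "community", comm)
            if len(comm) != len(ids):
                raise ValueError("community labels must cover all parcels")
            unknown = set(comm) - set(COMMUNITIES)
            if unknown:
                raise ValueError(f"unknown community labels: {sorted(unknown)}")

    @property
    def n_parcels(self) -> int:
        return len(self.parcel_ids)


@dataclass(frozen=True)
class ConnectivityMatrix:
    """A seed-by-parcel connectivity matrix tagged by modality.

    Modalities: raw streamline counts (``sc_counts``), column-max
    normalized counts (``sc_norm``), functional correlation (``fc_r``) and
    its Fisher z transform (``fc_z``), and across-subject structural
    covariance correlation (``scov_r``).
    """

    values: np.ndarray
    modality: str
    seeds: SeedSpace | None = None
    parcels: ParcelSpace | None = None
    hemisphere: str = "L"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise ValueError("values must be 2-D (seeds x parcels)")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.modality == "sc_counts" and np.nanmin(v) < 0:
            raise ValueError("streamline counts must be non-negative")
        if self.modality in ("fc_r", "scov_r"):
            finite = v[np.isfinite(v)]
            if finite.size and (finite.min() < -1 - 1e-12 or finite.max() > 1 + 1e-12):
                raise ValueError(f"{self.modality} values must lie in [-1, 1]")
        if self.seeds is not None and self.seeds.n_seeds != v.shape[0]:
            raise ValueError("row count does not match SeedSpace")
        if self.parcels is not None and self.parcels.n_parcels != v.shape[1]:
            raise ValueError("column count does not match ParcelSpace")

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def with_values(self, values: np.ndarray, modality: str | None = None) -> "ConnectivityMatrix":
        return ConnectivityMatrix(
            values=values,
            modality=modality or self.modality,
            seeds=self.seeds,
            parcels=self.parcels,
            hemisphere=self.hemisphere,
        )


@dataclass(frozen=True)
class ScalarSeedMap:
    """One scalar value per seed voxel (qT1 in ms, a gradient, ...).

    Missing values are explicit NaN, never silently zero.
    """

    values: np.ndarray
    name: str = "map"
    units: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1:
            raise ValueError("a ScalarSeedMap is 1-D")

    @property
    def n_seeds(self) -> int:
        return int(self.values.size)

    @property
    def n_missing(self) -> int:
        return int(np.sum(~np.isfinite(self.values)))


@dataclass(frozen=True)
class SubjectStack:
    """Per-subject paired thalamic-voxel and cortical-parcel values.

    Rows are subjects; used to compute thalamocortical structural
    covariance (across-subject correlation of qT1).
    """

    voxel_values: np.ndarray
    parcel_values: np.ndarray

    def __post_init__(self) -> None:
        vv = np.asarray(self.voxel_values, dtype=float)
        pv = np.asarray(self.parcel_values, dtype=float)
        object.__setattr__(self, "voxel_values", vv)
        object.__setattr__(self, "parcel_values", pv)
        if vv.ndim != 2 or pv.ndim != 2 or vv.shape[0] != pv.shape[0]:
            raise ValueError("voxel and parcel stacks must share the subject axis")
        for name, arr in (("voxel", vv), ("parcel", pv)):
            if np.any(np.all(~np.isfinite(arr), axis=1)):
                raise ValueError(f"a subject is entirely absent in the {name} stack")

    @property
    def n_subjects(self) -> int:
        return int(self.voxel_values.shape[0])


@dataclass
class PipelineConfig:
    """Analysis parameters.

    Defaults follow the study conventions: SC matrices thresholded at the
    75th percentile, FC at the 90th, diffusion-map anisotropy alpha = 0.5,
    ten retained components and 1000 surrogate maps for spatial nulls.
    """

    threshold_percentile_sc: float = 75.0
    threshold_percentile_fc: float = 90.0
    alpha: float = 0.5
    n_components: int = 10
    n_surrogates: int = 1000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for pct in (self.threshold_percentile_sc, self.threshold_percentile_fc):
            if not (0 <= pct < 100):
                raise ValueError("percentiles must lie in [0, 100)")
        if not (0 <= self.alpha <= 1):
            raise ValueError("alpha must lie in [0, 1]")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
            fh.write("\n")


# ---------------------------------------------------------------------------
# NIfTI readers / writers
# ---------------------------------------------------------------------------


def read_seed_space(mask_volume: str | Path, hemisphere: str = "L") -> SeedSpace:
    """Build a SeedSpace from a binary NIfTI mask.

    One seed per nonzero voxel.  Coordinates are voxel centers mapped to
    physical mm through the affine; ordering follows the package's linear
    index convention (see module docstring).

    Raises
    ------
    ValueError
        If the volume is not 3-D, not binary, or empty.
    """
    img = nib.load(str(mask_volume))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"mask must be 3-D, got shape {data.shape}")
    vals = np.unique(data[np.isfinite(data)])
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"mask must be binary (0/1); found values {vals[:10]}")
    idx = np.argwhere(data > 0)
    if idx.shape[0] == 0:
        raise ValueError("mask is empty")
    lin = np.ravel_multi_index(tuple(idx.T), data.shape)  # C order, last axis fastest
    order = np.argsort(lin)
    idx = idx[order]
    lin = lin[order]
    coords = nib.affines.apply_affine(img.affine, idx)
    vsize = float(np.mean(np.abs(nib.affines.voxel_sizes(img.affine))))
    return SeedSpace(seed_ids=lin, coords=coords, hemisphere=hemisphere, voxel_size=vsize)


def write_mask(path: str | Path, shape: tuple, seed_voxels: np.ndarray, affine: np.ndarray) -> None:
    """Write a binary mask NIfTI from (n, 3) voxel indices."""
    data = np.zeros(shape, dtype=np.uint8)
    data[tuple(np.asarray(seed_voxels, dtype=int).T)] = 1
    nib.save(nib.Nifti1Image(data, affine), str(path))


def write_scalar_volume(
    path: str | Path,
    seeds: SeedSpace,
    values: np.ndarray,
    shape: tuple,
    affine: np.ndarray,
    background: float = np.nan,
) -> None:
    """Paint per-seed values back into a volume at the seeds' linear indices."""
    data = np.full(shape, background, dtype=np.float32)
    data.flat[seeds.seed_ids] = values
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_scalar_map(
    source: str | Path,
    seeds: SeedSpace,
    name: str = "map",
    units: str = "",
) -> ScalarSeedMap:
    """Read a per-seed scalar map from a NIfTI volume or a two-column TSV.

    For a volume, values are sampled at the seeds' linear indices (the
    volume must share the mask's grid).  For a TSV (columns ``seed_id``,
    ``value``), rows are aligned to the SeedSpace order; seeds without a
    row become explicit NaN with a warning.
    """
    source = Path(source)
    if source.suffix in (".nii", ".gz") or str(source).endswith(".nii.gz"):
        img = nib.load(str(source))
        data = np.asarray(img.dataobj, dtype=float)
        if seeds.seed_ids.max() >= data.size:
            raise ValueError("seed index outside volume extent")
        values = data.flat[seeds.seed_ids].astype(float)
    else:
        df = pd.read_csv(source, sep="\t", comment="#", float_precision="round_trip")
        if "seed_id" not in df.columns or df.shape[1] < 2:
            raise ValueError("scalar map TSV needs 'seed_id' plus one value column")
        value_col = [c for c in df.columns if c != "seed_id"][0]
        lookup = dict(zip(df["seed_id"].astype(int), df[value_col].astype(float)))
        values = np.array([lookup.get(int(s), np.nan) for s in seeds.seed_ids])
    n_missing = int(np.sum(~np.isfinite(values)))
    if n_missing:
        warnings.warn(f"scalar map {name!r}: {n_missing} seed(s) have no value", stacklevel=2)
        logger.warning("scalar map %r: %d seed(s) missing", name, n_missing)
    return ScalarSeedMap(values=values, name=name, units=units)


def write_scalar_map(path: str | Path, seeds: SeedSpace, m: ScalarSeedMap) -> None:
    with open(path, "w") as fh:
        fh.write(f"# name={m.name} units={m.units} seed_order={SEED_ORDER_CONVENTION}\n")
        fh.write(f"seed_id\t{m.name}\n")
        for sid, v in zip(seeds.seed_ids, m.values):
            fh.write(f"{sid}\t{float(v)!r}\n")


# ---------------------------------------------------------------------------
# TSV matrix I/O
# ---------------------------------------------------------------------------


def _parse_metadata_line(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for token in first[1:].split():
            if "=" in token:
                k, v = token.split("=", 1)
                meta[k] = v
    return meta


def read_matrix(
    path: str | Path,
    seeds: SeedSpace | None = None,
    parcels: ParcelSpace | None = None,
    expected_shape: tuple | None = None,
) -> ConnectivityMatrix:
    """Read a seed x parcel matrix TSV.

    Layout: one ``#`` metadata line, a header row of parcel ids, and a
    first column of seed ids.  Rows are re-sorted into SeedSpace order
    (ascending seed id) regardless of on-disk row order.
    """
    path = Path(path)
    meta = _parse_metadata_line(path)
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip", index_col=0)
    if df.index.name != "seed_id":
        raise ValueError("matrix TSV must have a 'seed_id' header column")
    df = df.sort_index()
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    if expected_shape is not None and values.shape != tuple(expected_shape):
        raise ValueError(f"shape {values.shape} != expected {tuple(expected_shape)}")
    if seeds is not None:
        if not np.array_equal(df.index.to_numpy(dtype=int), seeds.seed_ids):
            raise ValueError("seed ids in file do not match SeedSpace")
    if parcels is None:
        parcels = ParcelSpace(parcel_ids=tuple(df.columns))
    modality = meta.get("modality", "sc_counts")
    hemi = meta.get("hemisphere", "L")
    return ConnectivityMatrix(values=values, modality=modality, seeds=seeds, parcels=parcels, hemisphere=hemi)


def write_matrix(path: str | Path, m: ConnectivityMatrix, seed_ids: Sequence[int] | None = None) -> None:
    """Write a ConnectivityMatrix TSV with its metadata comment line."""
    if seed_ids is None:
        if m.seeds is None:
            raise ValueError("need seed_ids or an attached SeedSpace")
        seed_ids = m.seeds.seed_ids
    parcel_ids = m.parcels.parcel_ids if m.parcels is not None else [f"p{j}" for j in range(m.shape[1])]
    df = pd.DataFrame(m.values, index=pd.Index(seed_ids, name="seed_id"), columns=list(parcel_ids))
    with open(path, "w") as fh:
        fh.write(
            f"# modality={m.modality} hemisphere={m.hemisphere} "
            f"seed_order={SEED_ORDER_CONVENTION}\n"
        )
        df.to_csv(fh, sep="\t", lineterminator="\n")


def read_timeseries(path: str | Path) -> tuple[np.ndarray, list]:
    """Read a (series x timepoints) TSV; returns (array, row ids)."""
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip", index_col=0)
    return df.to_numpy(dtype=float), list(df.index)


def write_timeseries(path: str | Path, ts: np.ndarray, ids: Sequence, kind: str) -> None:
    df = pd.DataFrame(np.asarray(ts, dtype=float), index=pd.Index(list(ids), name=f"{kind}_id"))
    df.columns = [f"t{t}" for t in range(df.shape[1])]
    with open(path, "w") as fh:
        fh.write(f"# kind={kind}_timeseries\n")
        df.to_csv(fh, sep="\t", lineterminator="\n")


def read_subject_stack(voxel_path: str | Path, parcel_path: str | Path) -> SubjectStack:
    """Read subject x voxel and subject x parcel TSV stacks."""
    vv = pd.read_csv(voxel_path, sep="\t", comment="#", float_precision="round_trip", index_col=0).to_numpy(dtype=float)
    pv = pd.read_csv(parcel_path, sep="\t", comment="#", float_precision="round_trip", index_col=0).to_numpy(dtype=float)
    return SubjectStack(voxel_values=vv, parcel_values=pv)


def write_subject_stack(voxel_path: str | Path, parcel_path: str | Path, stack: SubjectStack,
                        seed_ids: Sequence[int], parcel_ids: Sequence) -> None:
    subj = pd.Index([f"sub{s:03d}" for s in range(stack.n_subjects)], name="subject")
    pd.DataFrame(stack.voxel_values, index=subj, columns=list(seed_ids)).to_csv(voxel_path, sep="\t")
    pd.DataFrame(stack.parcel_values, index=subj, columns=list(parcel_ids)).to_csv(parcel_path, sep="\t")


def read_label_table(path: str | Path, key: str, value: str) -> dict:
    """Read a two-column label TSV (e.g. seed_id -> nucleus) into a dict."""
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    return dict(zip(df[key], df[value]))


def write_label_table(path: str | Path, mapping: dict, key: str, value: str) -> None:
    pd.DataFrame({key: list(mapping.keys()), value: list(mapping.values())}).to_csv(
        path, sep="\t", index=False
    )
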