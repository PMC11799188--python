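"""End-to-end conveniences chaining the pipeline stages.

These wrappers fix the canonical stage order — normalize, threshold,
normalized-angle affinity, diffusion-map embed — for the structural and
functional branches, and provide the component-to-axis matching used to
evaluate planted-axis recovery on synthetic data.
"""

from __future__ import annotations

import numpy as np

from .connectome import normalize_columns_max, threshold_percentile
from .embedding import GradientSet, diffusion_map_embed, normalized_angle_affinity
from .io_core import ConnectivityMatrix, PipelineConfig
from .modality_maps import fc_matrix, fisher_z


def embed_matrix(
    m: ConnectivityMatrix,
    threshold_pct: float,
    alpha: float = 0.5,
    n_components: int = 10,
    threshold_scope: str = "row",
) -> GradientSet:
    """Threshold a seed-by-parcel matrix, build the affinity, and embed."""
    thr = threshold_percentile(m, threshold_pct, scope=threshold_scope)
    aff = normalized_angle_affinity(thr.values)
    return diffusion_map_embed(aff, alpha=alpha, n_components=n_components)


def structural_gradients(counts: ConnectivityMatrix, cfg: PipelineConfig | None = None) -> GradientSet:
    """Streamline counts -> column-max normalize -> threshold -> embed."""
    cfg = cfg or PipelineConfig()
    norm = normalize_columns_max(counts)
    return embed_matrix(norm, cfg.threshold_percentile_sc, cfg.alpha, cfg.n_components)


def functional_gradients(voxel_ts: np.ndarray, parcel_ts: np.ndarray,
                         cfg: PipelineConfig | None = None) -> GradientSet:
    """Time series -> Pearson FC -> Fisher z -> threshold -> embed."""
    cfg = cfg or PipelineConfig()
    z = fisher_z(fc_matrix(voxel_ts, parcel_ts))
    return embed_matrix(z, cfg.threshold_percentile_fc, cfg.alpha, cfg.n_components)


def match_components(g: GradientSet, targets: dict) -> dict:
    """Match gradient components to target axes by maximal |correlation|.

    ``targets`` maps axis names to per-seed arrays.  Axes are matched
    greedily in order of their best achievable |r|, without reusing a
    component.  Returns ``{axis: (component_index, r)}`` with signed r.
    """
    L = g.loadings
    names = list(targets)
    corr = np.zeros((len(names), L.shape[1]))
    for a, name in enumerate(names):
        t = np.asarray(targets[name], dtype=float)
        tc = t - t.mean()
        for k in range(L.shape[1]):
            c = L[:, k] - L[:, k].mean()
            den = np.sqrt((tc**2).sum() * (c**2).sum())
            corr[a, k] = tc @ c / den if den > 0 else 0.0
    result = {}
    used = set()
    for _ in names:
        masked = np.abs(corr.copy())
        for a, name in enumerate(names):
            if name in result:
                masked[a, :] = -1
        for k in used:
            masked[:, k] = -1
        a, k = np.unravel_index(np.argmax(masked), masked.shape)
        result[names[a]] = (int(k), float(corr[a, k]))
        used.add(int(k))
    return result
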