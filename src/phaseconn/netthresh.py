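"""Cluster Span Threshold (CST) binarization of weighted networks.

CST chooses a network density without a free parameter: sweeping a
density grid, it retains the top-d fraction of edges by weight and
classifies each retained edge as a *cluster* edge (member of at least
one triangle in the retained graph) or a *span* edge (tree-like).  The
selected density is the grid point whose cluster-edge proportion is
nearest 1/2, balancing clustered against spanning structure.  The
resulting boolean mask is applied to edge statistics so only
informative connections enter cluster formation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class BinaryMask:
    """Symmetric boolean edge mask with its selected density."""

    mask: np.ndarray  # channels x channels bool, symmetric, false diagonal
    density: float
    cluster_proportion: float
    degenerate: bool = False  # no density produced any triangle

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.mask, k=1).sum())


def _cluster_edge_proportion(adj: np.ndarray) -> float:
    """Fraction of retained edges participating in >= 1 triangle."""
    retained = int(np.triu(adj, k=1).sum())
    if retained == 0:
        return 0.0
    paths = adj.astype(np.int32) @ adj.astype(np.int32)
    cluster = adj & (paths > 0)
    return float(np.triu(cluster, k=1).sum()) / retained


def cst_select_threshold(
    weights: np.ndarray,
    densities: np.ndarray | None = None,
    tie_break: str | None = "lexicographic",
) -> BinaryMask:
    """Select the CST density for a symmetric non-negative weight matrix.

    For each candidate density (default grid 1%..100% in 1% steps) the
    top-d fraction of edges is retained and the cluster-edge proportion
    computed; the density whose proportion is nearest 0.5 wins (ties go
    to the lower density).  Equal weights are ordered by lexicographic
    pair order when ``tie_break`` is "lexicographic"; with
    ``tie_break=None`` a fully tied matrix is rejected.
    """
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    if w.ndim != 2 or w.shape[1] != n:
        raise ValueError("weights must be a square matrix")
    if n < 4:
        raise ValueError("CST needs >= 4 nodes")
    if not np.allclose(w, w.T, atol=1e-12):
        raise ValueError("weights must be symmetric")
    iu, ju = np.triu_indices(n, k=1)
    vals = w[iu, ju]
    if np.any(vals < 0):
        raise ValueError("edge weights must be non-negative")
    if not np.any(vals > 0):
        raise ValueError("all edge weights are zero; nothing to threshold")
    if np.all(vals == vals[0]) and tie_break is None:
        raise ValueError(
            "all edge weights are equal; enable a deterministic tie-break "
            "to rank them"
        )
    if tie_break == "lexicographic":
        order = np.lexsort((ju, iu, -vals))
    elif tie_break is None:
        order = np.argsort(-vals, kind="stable")
    else:
        raise ValueError(f"unknown tie_break {tie_break!r}")
    # zero-weight pairs carry no connectivity and are never retained
    n_nonzero = int((vals > 0).sum())
    order = order[:n_nonzero]
    m = len(vals)
    if densities is None:
        densities = np.arange(1, 101) / 100.0

    best = None  # (distance, density, k, proportion)
    max_prop = 0.0
    adj = np.zeros((n, n), dtype=bool)
    added = 0
    for d in np.sort(densities):
        k = min(int(np.floor(d * m + 0.5)), n_nonzero)
        if k == 0:
            continue
        while added < k:
            e = order[added]
            adj[iu[e], ju[e]] = adj[ju[e], iu[e]] = True
            added += 1
        prop = _cluster_edge_proportion(adj)
        max_prop = max(max_prop, prop)
        dist = abs(prop - 0.5)
        if best is None or dist < best[0] - 1e-12:
            best = (dist, float(d), k, prop)
    assert best is not None
    _, density, k_sel, prop = best

    mask = np.zeros((n, n), dtype=bool)
    for e in order[:k_sel]:
        mask[iu[e], ju[e]] = mask[ju[e], iu[e]] = True
    return BinaryMask(mask, density, prop, degenerate=(max_prop == 0.0))


def masks_per_band(group_mean_wpli: np.ndarray, **kw) -> list[BinaryMask]:
    """CST mask per band from a channels x channels x bands mean-WPLI array."""
    return [cst_select_threshold(group_mean_wpli[:, :, b], **kw)
            for b in range(group_mean_wpli.shape[2])]


def stack_masks(masks: list[BinaryMask]) -> np.ndarray:
    return np.stack([m.mask for m in masks], axis=2)


def apply_cst_mask(stat: np.ndarray, masks: np.ndarray | list[BinaryMask]) -> np.ndarray:
    """Null out (NaN) statistics outside the mask; masked-in values unchanged."""
    if isinstance(masks, list):
        masks = stack_masks(masks)
    if masks.shape != stat.shape:
        raise ValueError(
            f"mask shape {masks.shape} does not match statistics shape {stat.shape}"
        )
    out = np.where(masks, stat, np.nan)
    return out


def mask_to_frame(mask: BinaryMask, ch_names, band: str) -> pd.DataFrame:
    """Edge-list export of a mask."""
    iu, ju = np.triu_indices(mask.mask.shape[0], k=1)
    keep = mask.mask[iu, ju]
    return pd.DataFrame({
        "band": [band] * int(keep.sum()),
        "ch_i": [ch_names[i] for i in iu[keep]],
        "ch_j": [ch_names[j] for j in ju[keep]],
    })


def mask_to_matrix(mask: BinaryMask, ch_names) -> pd.DataFrame:
    """Square 0/1 matrix export with channel labels."""
    return pd.DataFrame(mask.mask.astype(int), index=list(ch_names),
                        columns=list(ch_names))
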