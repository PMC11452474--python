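"""Edge-wise repeated-measures statistics with cluster-based permutation
correction.

Per electrode pair and band, condition effects are tested with a one-way
repeated-measures ANOVA (subject as blocking factor) or a paired t-test
for pairwise contrasts.  Family-wise error over the thousands of edges
is controlled non-parametrically: supra-threshold edges (parametric
critical value at the cluster-forming alpha) are grouped into clusters
— two edges are adjacent iff they share an electrode — and the observed
cluster masses are referred to the permutation distribution of the
maximum cluster mass, obtained by permuting condition labels within
subject.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass
class Cluster:
    edges: list[tuple[int, int, int]]  # (chan_i, chan_j, band_index)
    mass: float
    p: float
    tail: str = "pos"  # "pos"/"neg" for t; "pos" for F


@dataclass
class EdgeStatResult:
    """Edge-wise test statistics with optional clusters and mask."""

    stat: np.ndarray  # channels x channels x bands (NaN outside mask)
    df: tuple
    kind: str  # "F" or "t"
    ch_names: tuple[str, ...]
    band_names: tuple[str, ...]
    mask: np.ndarray | None = None
    clusters: list[Cluster] = field(default_factory=list)
    p_uncorrected: np.ndarray | None = None
    degenerate: np.ndarray | None = None
    threshold: float | None = None
    n_perm: int | None = None
    exhaustive: bool = False

    def significant_clusters(self, alpha: float = 0.005) -> list[Cluster]:
        return [c for c in self.clusters if c.p < alpha]

    def to_frame(self) -> pd.DataFrame:
        """Edge table: band, ch_i, ch_j, stat, p_corrected, cluster_id."""
        cluster_of: dict[tuple[int, int, int], tuple[int, float]] = {}
        for cid, c in enumerate(self.clusters, start=1):
            for e in c.edges:
                cluster_of[e] = (cid, c.p)
        n = len(self.ch_names)
        iu, ju = np.triu_indices(n, k=1)
        rows = []
        for b, band in enumerate(self.band_names):
            for i, j in zip(iu, ju):
                s = self.stat[i, j, b]
                if np.isnan(s):
                    continue
                cid, p = cluster_of.get((i, j, b), (None, np.nan))
                rows.append({"band": band, "ch_i": self.ch_names[i],
                             "ch_j": self.ch_names[j], "stat": s,
                             "p_corrected": p, "cluster_id": cid})
        return pd.DataFrame(rows,
                            columns=["band", "ch_i", "ch_j", "stat",
                                     "p_corrected", "cluster_id"])


@dataclass
class PermutationScheme:
    """Permutation design for the cluster test.

    ``cluster_forming_alpha`` sets the parametric critical value that
    admits an edge into a cluster; ``cluster_alpha`` is the significance
    level for the corrected cluster p-value.
    """

    n_perm: int = 1000
    seed: int = 0
    cluster_alpha: float = 0.005
    cluster_forming_alpha: float = 0.005

    def __post_init__(self) -> None:
        if self.n_perm < 100:
            raise ValueError("need >= 100 permutations")
        for a in (self.cluster_alpha, self.cluster_forming_alpha):
            if not (0 < a < 0.5):
                raise ValueError("alphas must lie in (0, 0.5)")


# ---------------------------------------------------------------------------
# core statistics (vectorized over trailing axes)

def rm_anova_f(data: np.ndarray) -> tuple[np.ndarray, tuple[int, int], np.ndarray]:
    """One-way repeated-measures F over axis 1, subjects on axis 0.

    F = MS_condition / MS_(condition x subject residual) with
    df = (k-1, (k-1)(n-1)).  Zero residual variance with a nonzero
    condition effect yields +inf and a degeneracy flag; a completely
    constant cell set yields F = 0.
    """
    n, k = data.shape[:2]
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 conditions")
    gm = data.mean(axis=(0, 1))
    cm = data.mean(axis=0)          # condition means
    sm = data.mean(axis=1)          # subject means
    ss_cond = n * ((cm - gm) ** 2).sum(axis=0)
    ss_subj = k * ((sm - gm) ** 2).sum(axis=0)
    ss_tot = ((data - gm) ** 2).sum(axis=(0, 1))
    ss_err = np.maximum(ss_tot - ss_cond - ss_subj, 0.0)
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    degenerate = ms_err <= 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ms_cond / ms_err
    f = np.where(degenerate, np.where(ms_cond > 0, np.inf, 0.0), f)
    return f, (df1, df2), degenerate


def paired_t(diff: np.ndarray) -> tuple[np.ndarray, int, np.ndarray]:
    """Paired t over axis 0 of per-subject differences."""
    n = diff.shape[0]
    if n < 2:
        raise ValueError("need >= 2 subjects")
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    degenerate = sd <= 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / math.sqrt(n))
        sentinel = np.where(mean != 0, np.sign(mean) * np.inf, 0.0)
    t = np.where(degenerate, sentinel, t)
    return t, n - 1, degenerate


def _check_complete(data: np.ndarray, subjects, conditions) -> None:
    bad = np.argwhere(np.isnan(data).reshape(data.shape[0], data.shape[1], -1).any(axis=2))
    if bad.size:
        s, c = bad[0]
        sid = subjects[s] if subjects is not None else f"#{s}"
        cond = conditions[c] if conditions is not None else f"#{c}"
        raise ValueError(f"missing cell: subject {sid}, condition {cond}")


def rm_anova_edges(data: np.ndarray, ch_names, band_names,
                   subjects=None, conditions=None) -> EdgeStatResult:
    """RM-ANOVA per edge and band.

    ``data`` is subjects x conditions x channels x channels x bands of
    band-averaged WPLI.
    """
    _check_complete(data, subjects, conditions)
    f, df, degen = rm_anova_f(data)
    p = sps.f.sf(f, *df)
    idx = np.arange(f.shape[0])
    f[idx, idx, :] = 0.0
    return EdgeStatResult(f, df, "F", tuple(ch_names), tuple(band_names),
                          p_uncorrected=p, degenerate=degen)


def paired_t_edges(data: np.ndarray, cond_a: int, cond_b: int, ch_names,
                   band_names, subjects=None, conditions=None) -> EdgeStatResult:
    """Paired t per edge and band for condition ``cond_b`` minus ``cond_a``."""
    _check_complete(data, subjects, conditions)
    t, df, degen = paired_t(data[:, cond_b] - data[:, cond_a])
    p = 2 * sps.t.sf(np.abs(t), df)
    idx = np.arange(t.shape[0])
    t[idx, idx, :] = 0.0
    return EdgeStatResult(t, (df,), "t", tuple(ch_names), tuple(band_names),
                          p_uncorrected=p, degenerate=degen)


# ---------------------------------------------------------------------------
# cluster formation: edges adjacent iff they share an electrode, i.e. the
# clusters are the connected components of the graph drawn by the
# supra-threshold edges (per band).

def _edge_components(edges_ij: np.ndarray, n_nodes: int) -> np.ndarray:
    """Component label per edge via union-find over electrodes."""
    parent = np.arange(n_nodes)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges_ij:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
    return np.array([find(i) for i, _ in edges_ij])


def _clusters_from_map(values: np.ndarray, supra: np.ndarray,
                       n_ch: int) -> list[tuple[list[tuple[int, int, int]], float]]:
    """Group supra-threshold edges (upper-tri, per band) into clusters."""
    out = []
    for b in range(values.shape[2]):
        iu, ju = np.nonzero(np.triu(supra[:, :, b], k=1))
        if iu.size == 0:
            continue
        edges = np.column_stack([iu, ju])
        labels = _edge_components(edges, n_ch)
        for lab in np.unique(labels):
            sel = labels == lab
            mass = float(values[iu[sel], ju[sel], b].sum())
            out.append(([(int(i), int(j), b) for i, j in edges[sel]], mass))
    return out


def _max_mass(values: np.ndarray, supra: np.ndarray, n_ch: int) -> float:
    clusters = _clusters_from_map(values, supra, n_ch)
    return max((m for _, m in clusters), default=0.0)


# ---------------------------------------------------------------------------
# permutation engines

def _f_label_perms(n_sub: int, k: int, n_perm: int,
                   rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    """Within-subject condition-label permutations (n_perm x n_sub x k)."""
    n_distinct = math.factorial(k) ** n_sub if n_sub * math.log(math.factorial(k)) < 40 else None
    if n_distinct is not None and n_distinct <= n_perm:
        logger.warning(
            "requested %d permutations but only %d distinct label assignments "
            "exist; enumerating exhaustively", n_perm, n_distinct)
        perms = np.array(list(itertools.product(
            list(itertools.permutations(range(k))), repeat=n_sub)))
        return perms, True
    base = np.tile(np.arange(k), (n_perm, n_sub, 1))
    return rng.permuted(base, axis=2), False


def _t_sign_perms(n_sub: int, n_perm: int,
                  rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    """Within-subject condition-pair swaps, coded as +/-1 (n_perm x n_sub)."""
    if n_sub < 31 and 2 ** n_sub <= n_perm:
        logger.warning(
            "requested %d permutations but only %d distinct sign flips exist; "
            "enumerating exhaustively", n_perm, 2 ** n_sub)
        signs = np.array(list(itertools.product((1, -1), repeat=n_sub)))
        return signs, True
    return rng.choice((1, -1), size=(n_perm, n_sub)), False


def permutation_cluster_test(
    data: np.ndarray,
    observed: EdgeStatResult,
    scheme: PermutationScheme,
    mask: np.ndarray | None = None,
    contrast: tuple[int, int] | None = None,
) -> EdgeStatResult:
    """Cluster-based permutation correction of an edge statistic map.

    ``data`` is subjects x conditions x channels x channels x bands.
    For an F map the null is built by permuting condition labels within
    subject; for a t map (``contrast`` = (a, b)) by swapping the two
    conditions per subject (sign flips of the differences).  The same
    mask and parametric cluster-forming threshold are applied to every
    permutation; corrected p = (1 + #{perm max >= observed mass}) /
    (1 + n_perm), which can never be exactly zero.
    """
    n_sub, n_cond = data.shape[:2]
    n_ch = data.shape[2]
    n_band = data.shape[4]
    rng = np.random.default_rng(scheme.seed)

    if mask is None:
        mask = ~np.isnan(observed.stat)
    stat_masked = np.where(mask, observed.stat, np.nan)

    # flatten to masked upper-tri edges for fast permutation recomputation
    iu, ju = np.triu_indices(n_ch, k=1)
    edge_band = [(i, j, b) for b in range(n_band)
                 for i, j in zip(iu, ju) if mask[i, j, b]]
    if edge_band:
        ei = np.array([e[0] for e in edge_band])
        ej = np.array([e[1] for e in edge_band])
        eb = np.array([e[2] for e in edge_band])
        flat = data[:, :, ei, ej, eb]  # n_sub x n_cond x E
    else:
        flat = np.empty((n_sub, n_cond, 0))

    def rebuild(vals: np.ndarray) -> np.ndarray:
        full = np.full((n_ch, n_ch, n_band), np.nan)
        full[ei, ej, eb] = vals
        full[ej, ei, eb] = vals
        return full

    if observed.kind == "F":
        df1, df2 = observed.df
        crit = sps.f.isf(scheme.cluster_forming_alpha, df1, df2)
        obs_clusters = [
            (e, m, "pos") for e, m in _clusters_from_map(
                stat_masked, np.nan_to_num(stat_masked, nan=-np.inf) > crit, n_ch)
        ]
        perms, exhaustive = _f_label_perms(n_sub, n_cond, scheme.n_perm, rng)
        null_max = np.zeros(len(perms))
        sub_idx = np.arange(n_sub)[:, None]
        for pi, labels in enumerate(perms):
            shuffled = flat[sub_idx, labels, :]
            f, _, _ = rm_anova_f(shuffled)
            supra = f > crit
            if supra.any():
                null_max[pi] = _max_mass(rebuild(f), rebuild(supra) > 0, n_ch)
        nulls = {"pos": null_max}
    elif observed.kind == "t":
        if contrast is None:
            raise ValueError("a t-map permutation test needs the contrast (a, b)")
        a, b = contrast
        df = observed.df[0]
        crit = sps.t.isf(scheme.cluster_forming_alpha, df)
        s = np.nan_to_num(stat_masked, nan=0.0)
        obs_clusters = [(e, m, "pos") for e, m in
                        _clusters_from_map(stat_masked, s > crit, n_ch)]
        obs_clusters += [(e, -m, "neg") for e, m in
                         _clusters_from_map(stat_masked, s < -crit, n_ch)]
        diff = flat[:, b, :] - flat[:, a, :]
        signs, exhaustive = _t_sign_perms(n_sub, scheme.n_perm, rng)
        null_pos = np.zeros(len(signs))
        null_neg = np.zeros(len(signs))
        for pi, sgn in enumerate(signs):
            t, _, _ = paired_t(sgn[:, None] * diff)
            if (np.abs(t) > crit).any():
                tm = rebuild(t)
                null_pos[pi] = _max_mass(tm, rebuild(t > crit) > 0, n_ch)
                null_neg[pi] = _max_mass(-tm, rebuild(t < -crit) > 0, n_ch)
        nulls = {"pos": null_pos, "neg": null_neg}
    else:
        raise ValueError(f"unknown statistic kind {observed.kind!r}")

    n_eff = len(next(iter(nulls.values())))
    clusters = []
    for edges, mass, tail in obs_clusters:
        null = nulls[tail]
        signed_mass = mass if tail == "pos" else -mass
        p = (1.0 + float((null >= abs(mass)).sum())) / (1.0 + n_eff)
        clusters.append(Cluster(edges=edges, mass=signed_mass, p=p, tail=tail))
    clusters.sort(key=lambda c: c.p)
    return EdgeStatResult(
        stat=stat_masked, df=observed.df, kind=observed.kind,
        ch_names=observed.ch_names, band_names=observed.band_names,
        mask=mask, clusters=clusters, p_uncorrected=observed.p_uncorrected,
        degenerate=observed.degenerate, threshold=float(crit),
        n_perm=n_eff, exhaustive=exhaustive,
    )
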