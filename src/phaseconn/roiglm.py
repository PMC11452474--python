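"""ROI-pooled connectivity statistics with FDR correction and the
behavior-connectivity GLM.

Connectivity is pooled by averaging WPLI over all electrode pairs
spanning two named regions of interest, tested per band and ROI pair
with the repeated-measures ANOVA, and corrected with Benjamini-Hochberg
FDR across the full family (8 bands x 12 ROI pairings = 96 tests by
default).  The link to behavioral familiarization is a no-intercept
normal GLM (identity link): per-subject connectivity change between two
repetitions regressed on the corresponding behavior-score change;
regression through the origin gives slope = sum(xy)/sum(x^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .clusterstats import rm_anova_f

DEFAULT_ROIS: dict[str, tuple[str, ...]] = {
    "right_frontal": ("F2", "F4", "F6", "FC2", "FC4", "FC6"),
    "left_frontal": ("F1", "F3", "F5", "FC1", "FC3", "FC5"),
    "right_parietal": ("CP2", "CP4", "P4", "P6", "CP6"),
    "left_parietal": ("CP1", "CP3", "P3", "P5", "CP5"),
    "right_temporal": ("FT10", "FT8", "T8", "TP8", "P8"),
    "left_temporal": ("FT9", "FT7", "T7", "TP7", "P7"),
}

CONTRASTS: dict[str, tuple[str, str]] = {
    "3v1": ("rep3", "rep1"),
    "2v1": ("rep2", "rep1"),
    "3v2": ("rep3", "rep2"),
}


@dataclass(frozen=True)
class ROISet:
    """Named, disjoint electrode groups and their analyzed pairings."""

    rois: tuple[tuple[str, tuple[str, ...]], ...] = tuple(DEFAULT_ROIS.items())

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for name, members in self.rois:
            overlap = seen & set(members)
            if overlap:
                raise ValueError(f"ROI {name!r} overlaps another ROI: {sorted(overlap)}")
            seen |= set(members)

    def members(self, name: str) -> tuple[str, ...]:
        return dict(self.rois)[name]

    def pairings(self) -> list[tuple[str, str]]:
        """All bilateral frontal-parietal, frontal-temporal and
        temporal-parietal combinations present in the set (12 under the
        defaults)."""
        names = [n for n, _ in self.rois]
        by_lobe = {
            lobe: [n for n in names if n.endswith(lobe)]
            for lobe in ("frontal", "parietal", "temporal")
        }
        pairs = []
        for la, lb in (("frontal", "parietal"), ("frontal", "temporal"),
                       ("temporal", "parietal")):
            pairs += [(a, b) for a in by_lobe[la] for b in by_lobe[lb]]
        return pairs


def pool_roi_connectivity(
    data: np.ndarray,
    ch_names,
    band_names,
    subjects,
    conditions,
    rois: ROISet = ROISet(),
) -> pd.DataFrame:
    """Pool WPLI over all cross-ROI electrode pairs.

    ``data`` is subjects x conditions x channels x channels x bands.
    The pooled value for an ROI pair is the mean over the Cartesian
    product of the two electrode groups (self-pairs excluded), e.g.
    6 x 5 = 30 pairs for right_frontal x right_parietal.
    """
    ch_index = {c: i for i, c in enumerate(ch_names)}
    rows = []
    for roi_a, roi_b in rois.pairings():
        for roi in (roi_a, roi_b):
            missing = [c for c in rois.members(roi) if c not in ch_index]
            if missing:
                raise ValueError(
                    f"electrode {missing[0]!r} of ROI {roi!r} is not in the "
                    "connectivity matrix")
        ia = [ch_index[c] for c in rois.members(roi_a)]
        ib = [ch_index[c] for c in rois.members(roi_b)]
        pairs = [(i, j) for i in ia for j in ib if i != j]
        pi = np.array([p[0] for p in pairs])
        pj = np.array([p[1] for p in pairs])
        pooled = data[:, :, pi, pj, :].mean(axis=2)  # sub x cond x band
        for si, s in enumerate(subjects):
            for ci, c in enumerate(conditions):
                for bi, b in enumerate(band_names):
                    rows.append({
                        "subject_id": s, "condition": c,
                        "roi_pair": f"{roi_a}~{roi_b}", "band": b,
                        "value": pooled[si, ci, bi],
                    })
    return pd.DataFrame(rows)


def bh_fdr(p: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, adjusted p-values)."""
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, p_adj


def roi_rm_anova_fdr(pooled: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """RM-ANOVA per band x ROI pair with BH-FDR over the whole family."""
    conditions = sorted(pooled["condition"].unique())
    subjects = sorted(pooled["subject_id"].unique())
    wide = pooled.pivot_table(index=["band", "roi_pair"],
                              columns=["subject_id", "condition"],
                              values="value")
    rows = []
    for (band, pair), row in wide.iterrows():
        table = np.array([[row[(s, c)] for c in conditions] for s in subjects])
        f, (df1, df2), degen = rm_anova_f(table)
        from scipy.stats import f as fdist
        rows.append({"band": band, "roi_pair": pair, "F": float(f),
                     "df1": df1, "df2": df2,
                     "p_raw": float(fdist.sf(f, df1, df2)),
                     "degenerate": bool(degen)})
    out = pd.DataFrame(rows)
    reject, p_adj = bh_fdr(out["p_raw"].to_numpy(), alpha)
    out["p_fdr"] = p_adj
    out["significant"] = reject
    return out


def glm_origin_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """No-intercept normal GLM (identity link): y = slope * x.

    Returns (slope, two-sided p, degenerate).  slope = sum(xy)/sum(x^2);
    the p-value is the t-test on the slope with n-1 residual df.
    Degenerate when x is all zero (no slope estimable) or the fit is
    exact (zero residual variance).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.allclose(x, 0.0):
        return np.nan, np.nan, True
    fit = sm.OLS(y, x[:, None]).fit()
    slope = float(fit.params[0])
    if fit.ssr <= 1e-12 * max(1.0, float(np.sum(y ** 2))):
        return slope, np.nan, True
    return slope, float(fit.pvalues[0]), False


def glm_behavior_link(
    pooled: pd.DataFrame,
    behavior: pd.DataFrame,
    bands: tuple[str, ...] = ("theta", "alpha"),
    alpha: float = 0.05,
    rois: ROISet = ROISet(),
) -> pd.DataFrame:
    """Regress connectivity change on behavior change, per band, ROI pair
    and repetition contrast; BH-FDR within each contrast's family
    (2 bands x 12 pairs = 24 analyses by default)."""
    subjects = sorted(pooled["subject_id"].unique())
    beh = behavior.pivot_table(index="subject_id", columns="condition",
                               values="mean_score")
    conn = pooled.pivot_table(index=["band", "roi_pair", "subject_id"],
                              columns="condition", values="value")
    rows = []
    for contrast, (cb, ca) in CONTRASTS.items():
        x = (beh[cb] - beh[ca]).reindex(subjects).to_numpy()
        for band in bands:
            for roi_a, roi_b in rois.pairings():
                pair = f"{roi_a}~{roi_b}"
                sub = conn.loc[(band, pair)]
                y = (sub[cb] - sub[ca]).reindex(subjects).to_numpy()
                slope, p, degen = glm_origin_fit(x, y)
                rows.append({"band": band, "roi_pair": pair,
                             "contrast": contrast, "slope": slope,
                             "p_raw": p, "degenerate": degen})
    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    out["significant"] = False
    for contrast in out["contrast"].unique():
        sel = (out["contrast"] == contrast) & out["p_raw"].notna()
        if sel.any():
            reject, p_adj = bh_fdr(out.loc[sel, "p_raw"].to_numpy(), alpha)
            out.loc[sel, "p_fdr"] = p_adj
            out.loc[sel, "significant"] = reject
    return out
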