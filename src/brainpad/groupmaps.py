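"""Region-wise group-difference t-maps, BH-FDR, and map/weight relations.

Two routes to the same cortical difference map: a pooled-variance two-sample
t-test on harmonized features (the ComBat path), and per-region OLS with
group, age, sex and site covariates (the regression-diagnosis path).  The
sign convention is patients minus controls throughout, so thinning in the
patient group appears as negative t.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TMap",
    "roi_ttest_map",
    "bh_fdr",
    "regression_tmap",
    "correlate_weights_tmap",
    "top_feature_overlap",
    "partial_corr",
]


@dataclass(frozen=True)
class TMap:
    """Region-indexed t-statistics with BH-adjusted significance.

    ``excluded`` marks regions where the t-statistic is undefined (zero
    pooled variance); those regions carry NaN t/p/q, are left out of the FDR
    correction, and are never significant.
    """

    region_ids: list[str]
    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    significant: np.ndarray
    excluded: np.ndarray
    q_threshold: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": self.region_ids,
                "t": self.t,
                "p": self.p,
                "q": self.q,
                "significant": self.significant.astype(int),
            }
        )


def bh_fdr(p_values, q_threshold: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns (adjusted p, rejected mask) with rejection at adjusted p below
    ``q_threshold``; adjusted p_(i) = min_{j >= i} (m * p_(j) / j), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    _, q, _, _ = multipletests(p, alpha=q_threshold, method="fdr_bh")
    return q, q < q_threshold


def _finalize_tmap(region_ids, t, p, q_threshold) -> TMap:
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    excluded = ~np.isfinite(t)
    if excluded.any():
        warnings.warn(
            f"{int(excluded.sum())} region(s) with undefined t excluded from FDR",
            RuntimeWarning,
        )
    q = np.full_like(p, np.nan)
    significant = np.zeros(len(t), dtype=bool)
    valid = ~excluded
    if valid.any():
        q[valid], significant[valid] = bh_fdr(p[valid], q_threshold)
    return TMap(list(region_ids), t, np.where(excluded, np.nan, p), q,
                significant, excluded, q_threshold)


def roi_ttest_map(
    features: pd.DataFrame, groups, q_threshold: float = 0.05, welch: bool = False
) -> TMap:
    """Per-region two-sample t-test (patients minus controls) with BH-FDR.

    ``features`` is a subject x region table (ideally harmonized); ``groups``
    aligns with its rows and contains the labels HC and MDD.
    """
    groups = np.asarray(groups)
    a = features.loc[groups == "MDD"].to_numpy(dtype=float)
    b = features.loc[groups == "HC"].to_numpy(dtype=float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("both groups need at least 2 subjects")
    # constant within both groups: pooled variance is exactly zero
    degenerate = (np.ptp(a, axis=0) == 0) & (np.ptp(b, axis=0) == 0)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=not welch)
    t = np.where(degenerate, np.nan, t)
    p = np.where(degenerate, np.nan, p)
    return _finalize_tmap(features.columns, t, p, q_threshold)


def regression_tmap(
    features: pd.DataFrame,
    groups,
    covariates: pd.DataFrame,
    q_threshold: float = 0.05,
) -> TMap:
    """Per-region OLS t-map for the group effect, controlling age, sex, site.

    The design is [intercept, group(MDD=1), age, sex, site dummies (first
    site as reference)]; the reported t is the group coefficient's
    t-statistic, FDR-corrected across regions.
    """
    groups = np.asarray(groups)
    n = len(features)
    cols = ["intercept", "group"]
    design = [np.ones(n), (groups == "MDD").astype(float)]
    for name in ("age", "sex"):
        if name in covariates:
            design.append(covariates[name].to_numpy(dtype=float))
            cols.append(name)
    if "site" in covariates:
        site = covariates["site"].to_numpy()
        levels = np.unique(site)
        for lev in levels[1:]:
            design.append((site == lev).astype(float))
            cols.append(f"site[{lev}]")
    X = np.column_stack(design)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns QR pivoting would drop
        from scipy.linalg import qr as scipy_qr

        _, _, piv = scipy_qr(X, pivoting=True, mode="economic")
        bad = sorted(cols[j] for j in piv[rank:])
        raise ValueError(f"rank-deficient design; collinear column(s): {bad}")

    Y = features.to_numpy(dtype=float)
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y
    resid = Y - X @ beta
    dof = n - X.shape[1]
    if dof < 1:
        raise ValueError("not enough subjects for the regression design")
    s2 = (resid**2).sum(axis=0) / dof
    g = cols.index("group")
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(XtX_inv[g, g] * s2)
        t = np.where(se > 0, beta[g] / se, np.nan)
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return _finalize_tmap(features.columns, t, p, q_threshold)


def correlate_weights_tmap(weights, tmap: TMap) -> tuple[float, float]:
    """Pearson correlation across regions between model weights and the t-map."""
    if isinstance(weights, pd.Series):
        weights = weights.reindex(tmap.region_ids).to_numpy(dtype=float)
        if np.isnan(weights).any():
            raise ValueError("weights missing for some t-map regions")
    weights = np.asarray(weights, dtype=float)
    valid = ~tmap.excluded
    if weights.shape[0] != len(tmap.region_ids):
        raise ValueError(
            f"length mismatch: {weights.shape[0]} weights vs "
            f"{len(tmap.region_ids)} regions"
        )
    res = stats.pearsonr(weights[valid], tmap.t[valid])
    return float(res.statistic), float(res.pvalue)


def top_feature_overlap(
    ranking_scores: pd.Series, significant_mask, k: int = 60
) -> tuple[int, list[str]]:
    """Overlap between the top-k regions by |score| and the significant set.

    Ties in |score| are broken by lexicographic region id.  Returns the
    overlap count and the sorted list of overlapping region ids.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k > len(ranking_scores):
        raise ValueError(f"k={k} exceeds number of regions {len(ranking_scores)}")
    order = sorted(
        ranking_scores.index, key=lambda r: (-abs(ranking_scores[r]), str(r))
    )
    top = set(order[:k])
    mask = pd.Series(np.asarray(significant_mask, dtype=bool),
                     index=ranking_scores.index)
    sig = set(mask.index[mask])
    hits = sorted(top & sig)
    return len(hits), hits


def partial_corr(x, y, covariates=None) -> tuple[float, float]:
    """Pearson correlation of x and y after residualizing both on covariates.

    With k covariates the p-value uses a t distribution with n - k - 2
    degrees of freedom; with no covariates this reduces to the plain Pearson
    correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if covariates is None:
        C = np.empty((n, 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    k = C.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 observations (n={n}, k={k})")
    D = np.column_stack([np.ones(n), C])
    rx = x - D @ np.linalg.lstsq(D, x, rcond=None)[0]
    ry = y - D @ np.linalg.lstsq(D, y, rcond=None)[0]
    # a variable fully explained by the covariates has nothing left to
    # correlate: report zero association rather than roundoff noise
    if (np.linalg.norm(rx) <= 1e-10 * max(1.0, np.linalg.norm(x - x.mean()))
            or np.linalg.norm(ry) <= 1e-10 * max(1.0, np.linalg.norm(y - y.mean()))):
        return 0.0, 1.0
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    r = float(np.clip((rx @ ry) / denom, -1.0, 1.0))
    dof = n - k - 2
    t = r * np.sqrt(dof / max(1.0 - r**2, 1e-300))
    p = float(2.0 * stats.t.sf(abs(t), dof))
    return r, p
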