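"""PLS1 regression of regional gene expression on a cortical difference map.

The regions x genes expression matrix is the predictor block and the
region-wise group-difference t-map the response.  Components are extracted by
NIPALS with deflation of X only; the variance explained in the response is
the incremental R-squared of y on the cumulative component scores.  Component
significance uses spatial-autocorrelation-preserving surrogates of the
response map, and gene contributions are ranked by the bootstrap-corrected
weight (weight divided by its bootstrap standard error across region
resamples).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .geometry import ParcellationGeometry
from .mapstats import make_surrogates

__all__ = [
    "PLS1Regression",
    "PLSResult",
    "fit_pls1",
    "pls_spatial_permutation",
    "bootstrap_gene_weights",
    "rank_risk_genes",
]


class PLS1Regression(BaseEstimator):
    """NIPALS partial least squares with a single response vector.

    Both the predictor columns and the response are z-scored across regions
    before fitting (``scale=False`` skips the predictor scaling).  Each
    component's sign is fixed so that its scores correlate non-negatively
    with the response.

    Fitted attributes: ``x_weights_`` (genes x k), ``x_scores_``
    (regions x k, mutually orthogonal), ``x_loadings_``, ``y_loadings_`` (k,)
    and ``varexp_y_`` (incremental R-squared of y per component).
    """

    def __init__(self, n_components: int = 1, scale: bool = True):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, y) -> "PLS1Regression":
        X_arr = np.asarray(X, dtype=float)
        y_arr = np.asarray(y, dtype=float)
        n, m = X_arr.shape
        if y_arr.shape != (n,):
            raise ValueError("y must be a vector aligned to the rows of X")
        if np.ptp(y_arr) == 0:
            raise ValueError("response map is constant")
        if self.n_components > min(n - 1, m):
            raise ValueError(
                f"n_components={self.n_components} exceeds min(n_regions - 1, n_genes)"
            )

        Xc = X_arr - X_arr.mean(axis=0)
        if self.scale:
            sd = X_arr.std(axis=0)
            Xc = Xc / np.where(sd == 0, 1.0, sd)
        yc = (y_arr - y_arr.mean()) / y_arr.std()
        self._y_std_ = yc.copy()

        k = self.n_components
        W = np.empty((m, k))
        T = np.empty((n, k))
        P = np.empty((m, k))
        q = np.empty(k)
        for c in range(k):
            w = Xc.T @ yc
            nw = np.linalg.norm(w)
            if nw == 0:
                raise ValueError("X carries no covariance with y at component "
                                 f"{c + 1}")
            w /= nw
            t = Xc @ w
            if t @ yc < 0:  # sign convention: scores align with the response
                w, t = -w, -t
            tt = t @ t
            p = Xc.T @ t / tt
            W[:, c], T[:, c], P[:, c] = w, t, p
            q[c] = yc @ t / tt
            Xc = Xc - np.outer(t, p)

        # incremental R^2 of the standardized response on cumulative scores
        varexp = np.empty(k)
        prev = 0.0
        for c in range(1, k + 1):
            beta, *_ = np.linalg.lstsq(T[:, :c], yc, rcond=None)
            resid = yc - T[:, :c] @ beta
            r2 = 1.0 - (resid @ resid) / (yc @ yc)
            varexp[c - 1] = r2 - prev
            prev = r2

        self.x_weights_ = W
        self.x_scores_ = T
        self.x_loadings_ = P
        self.y_loadings_ = q
        self.varexp_y_ = varexp
        return self


@dataclass
class PLSResult:
    """PLS fit with optional permutation/bootstrap annotations."""

    gene_ids: list[str]
    region_ids: list[str]
    x_weights: np.ndarray
    scores: np.ndarray
    y_loadings: np.ndarray
    varexp_y: np.ndarray
    p_component: np.ndarray | None = None
    gene_z: np.ndarray | None = None
    ranking: list[str] | None = None


def _align(X: pd.DataFrame, y) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    if isinstance(y, pd.Series):
        if list(y.index) != list(X.index):
            raise ValueError("expression regions and response regions are misaligned")
        y_arr = y.to_numpy(dtype=float)
    else:
        y_arr = np.asarray(y, dtype=float)
        if y_arr.shape[0] != len(X):
            raise ValueError("response length does not match expression regions")
    return X.to_numpy(dtype=float), y_arr, list(X.columns), list(X.index)


def fit_pls1(X: pd.DataFrame, y, n_components: int = 1, scale: bool = True) -> PLSResult:
    """Fit PLS1 of expression (regions x genes) on a response map."""
    X_arr, y_arr, gene_ids, region_ids = _align(X, y)
    est = PLS1Regression(n_components=n_components, scale=scale).fit(X_arr, y_arr)
    return PLSResult(gene_ids, region_ids, est.x_weights_, est.x_scores_,
                     est.y_loadings_, est.varexp_y_)


def pls_spatial_permutation(
    X: pd.DataFrame,
    y,
    geometry: ParcellationGeometry,
    n_perm: int = 10000,
    seed: int = 0,
    n_components: int = 1,
    scale: bool = True,
) -> np.ndarray:
    """Spatially-corrected permutation p per component.

    Surrogate responses preserving the t-map's value distribution and spatial
    autocorrelation are generated, PLS is refit on each, and
    p_k = (1 + #{varexp_surr_k >= varexp_obs_k}) / (n_perm + 1).
    """
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19")
    X_arr, y_arr, *_ = _align(X, y)
    obs = PLS1Regression(n_components, scale=scale).fit(X_arr, y_arr).varexp_y_
    surr = make_surrogates(y_arr, geometry, n_perm, seed=seed)
    exceed = np.zeros(n_components)
    for b in range(n_perm):
        ve = PLS1Regression(n_components, scale=scale).fit(X_arr, surr[b]).varexp_y_
        exceed += ve >= obs
    return (1.0 + exceed) / (n_perm + 1.0)


def bootstrap_gene_weights(
    X: pd.DataFrame, y, n_boot: int = 1000, seed: int = 0, scale: bool = True
) -> pd.DataFrame:
    """Bootstrap-corrected component-1 gene weights and descending ranking.

    Regions (the observational units) are resampled with replacement; each
    replicate's weight vector is sign-aligned to the original fit and the
    corrected weight is gene_z = weight / bootstrap SD.  Returns a DataFrame
    (gene_id, weight, bootstrap_se, gene_z, rank) sorted by gene_z
    descending.
    """
    if n_boot < 50:
        raise ValueError("n_boot must be >= 50 for stable standard errors")
    X_arr, y_arr, gene_ids, _ = _align(X, y)
    n = X_arr.shape[0]
    w0 = PLS1Regression(1, scale=scale).fit(X_arr, y_arr).x_weights_[:, 0]

    rng = np.random.default_rng(seed)
    W = np.empty((n_boot, len(gene_ids)))
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, size=n)
        if np.ptp(y_arr[idx]) == 0:
            continue  # degenerate resample: redraw
        try:
            wb = PLS1Regression(1, scale=scale).fit(X_arr[idx], y_arr[idx]).x_weights_[:, 0]
        except ValueError:
            continue
        if wb @ w0 < 0:
            wb = -wb
        W[b] = wb
        b += 1
    se = W.std(axis=0, ddof=1)
    gene_z = w0 / np.maximum(se, 1e-300)

    out = pd.DataFrame(
        {"gene_id": gene_ids, "weight": w0, "bootstrap_se": se, "gene_z": gene_z}
    ).sort_values("gene_z", ascending=False, kind="stable").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def rank_risk_genes(
    gene_table: pd.DataFrame, risk_gene_list
) -> tuple[pd.DataFrame, list[str]]:
    """Restrict the ranked gene table to a designated risk-gene list.

    Order is preserved; risk genes absent from the table are returned
    separately rather than raising, unless none of the risk genes are known.
    """
    risk = list(dict.fromkeys(risk_gene_list))
    known = set(gene_table["gene_id"])
    unknown = [g for g in risk if g not in known]
    present = [g for g in risk if g in known]
    if not present:
        raise ValueError("no risk gene is present in the ranked gene table")
    sub = gene_table[gene_table["gene_id"].isin(present)].reset_index(drop=True)
    return sub, unknown
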