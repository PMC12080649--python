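"""Brain-age prediction with linear SVR and brain-PAD group inference.

A linear support-vector regression is trained on morphometry features of
healthy controls to predict chronological age.  Applied to held-out subjects,
the brain-predicted age deviation (brain-PAD = predicted minus chronological
age, in years) is compared between patients and controls with a pooled-
variance two-sample t-test, with Cohen's d and a permutation null obtained by
retraining the model under shuffled training labels.  Permutation feature
importance re-prioritizes regions by their contribution to test-set accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.svm import LinearSVR

__all__ = [
    "BrainAgeSVR",
    "PADResult",
    "GroupDiff",
    "PermutationTestResult",
    "split_cohort",
    "train_brainage",
    "predict_and_pad",
    "compare_groups",
    "permutation_null_pad",
    "permutation_feature_importance",
]


class BrainAgeSVR(RegressorMixin, BaseEstimator):
    """L2-regularized epsilon-insensitive linear regression of age on features.

    Features are z-scored with training-set statistics only; zero-variance
    training features are dropped (and recorded in ``dropped_features_``)
    rather than producing infinite scales.

    Parameters
    ----------
    C : float
        Inverse regularization strength.
    epsilon : float
        Width of the insensitive tube, in years.
    tol, max_iter : solver controls (deterministic given fixed inputs).
    """

    def __init__(self, C: float = 1.0, epsilon: float = 0.1, tol: float = 1e-4,
                 max_iter: int = 100000):
        self.C = C
        self.epsilon = epsilon
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y) -> "BrainAgeSVR":
        X_arr, names = _matrix(X)
        y = np.asarray(y, dtype=float)
        if X_arr.shape[0] < 2:
            raise ValueError("need at least 2 training subjects")
        if y.shape[0] != X_arr.shape[0]:
            raise ValueError("ages length does not match feature rows")
        if np.ptp(y) == 0:
            raise ValueError("training ages are constant; age regression is degenerate")

        mean = X_arr.mean(axis=0)
        scale = X_arr.std(axis=0)
        keep = scale > 0
        self.dropped_features_ = (
            [names[j] for j in np.flatnonzero(~keep)] if names is not None
            else np.flatnonzero(~keep).tolist()
        )
        self.feature_names_in_ = names
        self.mean_, self.scale_, self.keep_ = mean, np.where(keep, scale, 1.0), keep

        Z = (X_arr[:, keep] - mean[keep]) / scale[keep]
        svr = LinearSVR(
            C=self.C, epsilon=self.epsilon, tol=self.tol, max_iter=self.max_iter,
            loss="epsilon_insensitive", dual=True, random_state=0,
        )
        svr.fit(Z, y)
        coef = np.zeros(X_arr.shape[1])
        coef[keep] = svr.coef_
        self.coef_ = coef  # per original feature, in z-scored units
        self.intercept_ = float(svr.intercept_[0] if np.ndim(svr.intercept_) else svr.intercept_)
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "coef_"):
            raise ValueError("BrainAgeSVR is not fitted")
        X_arr, names = _matrix(X)
        if names is not None and self.feature_names_in_ is not None:
            if names != self.feature_names_in_:
                missing = sorted(set(self.feature_names_in_) - set(names))
                extra = sorted(set(names) - set(self.feature_names_in_))
                raise ValueError(
                    f"feature columns do not match training layout; "
                    f"missing={missing[:5]}, extra={extra[:5]}"
                )
        if X_arr.shape[1] != self.coef_.shape[0]:
            raise ValueError(
                f"expected {self.coef_.shape[0]} features, got {X_arr.shape[1]}"
            )
        Z = (X_arr - self.mean_) / self.scale_
        return Z @ self.coef_ + self.intercept_


def _matrix(X) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    return np.asarray(X, dtype=float), None


@dataclass(frozen=True)
class PADResult:
    """Predictions and brain-PAD for one set of subjects."""

    predicted_age: np.ndarray
    brain_pad: np.ndarray
    pearson_r: float
    mae_years: float


@dataclass(frozen=True)
class GroupDiff:
    """Two-sample comparison of brain-PAD (patients minus controls)."""

    t_statistic: float
    p_value: float
    cohens_d: float
    d_ci_low: float
    d_ci_high: float
    mean_difference_years: float


@dataclass(frozen=True)
class PermutationTestResult:
    """Observed group difference, permutation null values, and p-value."""

    observed: float
    null: np.ndarray
    p_value: float


def split_cohort(cohort: pd.DataFrame, train_fraction_hc: float, seed: int = 0
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Split: a random fraction of HCs trains the model; everyone else tests.

    Returns (train_ids, test_ids) as subject_id arrays in cohort order; the
    training set contains ``round(train_fraction_hc * n_HC)`` healthy
    controls sampled without replacement, and the test set the remaining HCs
    plus all patients.
    """
    if not 0 < train_fraction_hc < 1:
        raise ValueError("train_fraction_hc must be in (0, 1)")
    hc_ids = cohort.loc[cohort["group"] == "HC", "subject_id"].to_numpy()
    if hc_ids.size < 2:
        raise ValueError("cohort must contain at least 2 healthy controls")
    n_train = int(round(train_fraction_hc * hc_ids.size))
    if n_train == 0 or n_train == hc_ids.size:
        raise ValueError(
            f"train_fraction_hc={train_fraction_hc} yields an empty train or test set"
        )
    rng = np.random.default_rng(seed)
    train = set(rng.choice(hc_ids, size=n_train, replace=False).tolist())
    all_ids = cohort["subject_id"].to_numpy()
    in_train = np.array([s in train for s in all_ids])
    return all_ids[in_train], all_ids[~in_train]


def train_brainage(features_train, ages_train, C: float = 1.0, epsilon: float = 0.1,
                   **params) -> BrainAgeSVR:
    """Train the linear SVR age model. See :class:`BrainAgeSVR`."""
    return BrainAgeSVR(C=C, epsilon=epsilon, **params).fit(features_train, ages_train)


def predict_and_pad(model: BrainAgeSVR, features, ages) -> PADResult:
    """Predict ages and compute brain-PAD, Pearson r and MAE."""
    ages = np.asarray(ages, dtype=float)
    pred = model.predict(features)
    pad = pred - ages
    if np.ptp(ages) == 0 or np.ptp(pred) == 0:
        r = np.nan
    else:
        r = float(stats.pearsonr(ages, pred).statistic)
    return PADResult(pred, pad, r, float(np.mean(np.abs(pad))))


def compare_groups(brain_pad, groups) -> GroupDiff:
    """Pooled-variance two-sample t-test of brain-PAD, patients minus controls.

    Cohen's d uses the pooled SD; its 95% CI uses the normal approximation
    SE(d) = sqrt((n1+n2)/(n1*n2) + d^2 / (2*(n1+n2))).
    """
    pad = np.asarray(brain_pad, dtype=float)
    groups = np.asarray(groups)
    if not np.all(np.isfinite(pad)):
        raise ValueError("brain_pad contains non-finite values")
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {list(labels)}")
    # patients minus controls when the standard labels are used; otherwise
    # second label minus first in sorted order
    if set(labels) == {"HC", "MDD"}:
        a, b = pad[groups == "MDD"], pad[groups == "HC"]
    else:
        a, b = pad[groups == labels[1]], pad[groups == labels[0]]
    n1, n2 = len(a), len(b)
    if min(n1, n2) < 2:
        raise ValueError("each group needs at least 2 subjects")
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance; t-test undefined")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    diff = float(a.mean() - b.mean())
    d = diff / np.sqrt(sp2)
    se_d = np.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2.0 * (n1 + n2)))
    z = stats.norm.ppf(0.975)
    return GroupDiff(float(t), float(p), float(d), float(d - z * se_d),
                     float(d + z * se_d), diff)


def permutation_null_pad(
    features: pd.DataFrame,
    ages: pd.Series,
    groups: pd.Series,
    split: tuple[np.ndarray, np.ndarray],
    n_perm: int = 10000,
    seed: int = 0,
    shuffle: str = "train_ages",
    C: float = 1.0,
    epsilon: float = 0.1,
) -> PermutationTestResult:
    """Permutation null for the test-set brain-PAD group difference.

    ``shuffle='train_ages'`` (default): each permutation shuffles the
    training-set age labels, retrains the model, and records the test-set
    brain-PAD difference (patients minus controls).  ``shuffle='test_groups'``
    keeps the fitted model and permutes the test-set diagnosis labels instead.
    p = (1 + #{|null| >= |observed|}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if shuffle not in ("train_ages", "test_groups"):
        raise ValueError(f"unknown shuffle mode {shuffle!r}")
    train_ids, test_ids = split
    Xtr = features.loc[train_ids]
    Xte = features.loc[test_ids]
    ytr = ages.loc[train_ids].to_numpy(dtype=float)
    yte = ages.loc[test_ids].to_numpy(dtype=float)
    gte = groups.loc[test_ids].to_numpy()

    model = BrainAgeSVR(C=C, epsilon=epsilon).fit(Xtr, ytr)
    pad = model.predict(Xte) - yte
    is_pat = gte == "MDD" if "MDD" in gte else gte == np.unique(gte)[1]
    observed = float(pad[is_pat].mean() - pad[~is_pat].mean())

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    if shuffle == "train_ages":
        Xtr_arr = Xtr  # DataFrame reuse keeps column checks
        for b in range(n_perm):
            y_perm = rng.permutation(ytr)
            m = BrainAgeSVR(C=C, epsilon=epsilon).fit(Xtr_arr, y_perm)
            pad_b = m.predict(Xte) - yte
            null[b] = pad_b[is_pat].mean() - pad_b[~is_pat].mean()
    else:
        for b in range(n_perm):
            perm = rng.permutation(is_pat)
            null[b] = pad[perm].mean() - pad[~perm].mean()
    p = (1.0 + np.sum(np.abs(null) >= abs(observed))) / (n_perm + 1.0)
    return PermutationTestResult(observed, null, float(p))


def permutation_feature_importance(
    model: BrainAgeSVR, features_test, ages_test, n_rep: int = 10, seed: int = 0
) -> np.ndarray:
    """Importance of feature j = mean increase in test MAE when column j is
    shuffled (years); 0 for features the model ignores."""
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    X, _ = _matrix(features_test)
    y = np.asarray(ages_test, dtype=float)
    if X.shape[0] == 0:
        raise ValueError("empty test set")
    base_pred = model.predict(features_test)
    base_mae = np.mean(np.abs(base_pred - y))
    rng = np.random.default_rng(seed)
    importance = np.zeros(X.shape[1])
    # linear model: permuting column j shifts predictions by coef_j * dz_j only
    for j in range(X.shape[1]):
        zj = (X[:, j] - model.mean_[j]) / model.scale_[j]
        acc = 0.0
        for _ in range(n_rep):
            pred = base_pred + (rng.permutation(zj) - zj) * model.coef_[j]
            acc += np.mean(np.abs(pred - y))
        importance[j] = acc / n_rep - base_mae
    return importance
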