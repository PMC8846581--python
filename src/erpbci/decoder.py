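"""Shrinkage-regularized LDA for target/non-target ERP classification.

The decoder is a binary linear discriminant on interval-mean ERP
features.  The pooled within-class covariance is regularized toward a
scaled identity,

    Sigma(gamma) = (1 - gamma) * Sigma_hat + gamma * nu * I,

with nu the mean of Sigma_hat's diagonal (the average empirical
eigenvalue) and gamma chosen analytically (Ledoit-Wolf) unless given.
The weight vector solves Sigma(gamma) w = mu_target - mu_nontarget and
the bias places the boundary midway between the projected class means
(equal priors; ranking metrics such as AUC are unaffected by priors).

Session-to-session transfer initializes the model from the concatenated
features of earlier sessions; within a session the class means and the
global covariance track non-stationarity through exponential supervised
updates with rates eta1 (means) and eta2 (covariance).  Performance is
assessed by chronological k-fold cross-validation to avoid temporal
leakage, scored as area under the ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.covariance import ledoit_wolf_shrinkage
from sklearn.metrics import roc_auc_score

from .preprocessing import FeatureMatrix

__all__ = [
    "LDAClassifier",
    "AdaptationConfig",
    "CVResult",
    "fit_slda",
    "ledoit_wolf_gamma",
    "decision_values",
    "adapt",
    "transfer_init",
    "auc",
    "chronological_cv_auc",
]


@dataclass
class LDAClassifier:
    """State of the adapting shrinkage-LDA decoder.

    ``sigma`` stores the unshrunk pooled covariance estimate; ``w`` and
    ``b`` are recomputed from (mu_target, mu_nontarget, sigma, gamma)
    whenever the statistics change.
    """

    w: np.ndarray
    b: float
    mu_target: np.ndarray
    mu_nontarget: np.ndarray
    sigma: np.ndarray
    gamma: float

    def __post_init__(self) -> None:
        d = self.w.shape[0]
        if not (
            self.mu_target.shape == (d,)
            and self.mu_nontarget.shape == (d,)
            and self.sigma.shape == (d, d)
        ):
            raise ValueError("inconsistent classifier dimensions")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")

    def copy(self) -> "LDAClassifier":
        return LDAClassifier(
            w=self.w.copy(),
            b=float(self.b),
            mu_target=self.mu_target.copy(),
            mu_nontarget=self.mu_nontarget.copy(),
            sigma=self.sigma.copy(),
            gamma=float(self.gamma),
        )


@dataclass(frozen=True)
class AdaptationConfig:
    """Supervised adaptation rates: eta1 for class means, eta2 for the
    global covariance.  Defaults follow the values tuned on healthy
    control data (0.005 / 0.001)."""

    eta1: float = 0.005
    eta2: float = 0.001

    def __post_init__(self) -> None:
        if not (0.0 <= self.eta1 <= 1.0 and 0.0 <= self.eta2 <= 1.0):
            raise ValueError("adaptation rates must be in [0, 1]")


@dataclass(frozen=True)
class CVResult:
    """Chronological cross-validation outcome."""

    auc: float
    per_fold_auc: tuple[float, ...]
    fold_bounds: tuple[tuple[int, int], ...]
    pooled_auc: float


def _as_xy(features: FeatureMatrix | np.ndarray, labels=None):
    if isinstance(features, FeatureMatrix):
        return np.asarray(features.values, dtype=float), np.asarray(features.labels)
    return np.asarray(features, dtype=float), np.asarray(labels)


def ledoit_wolf_gamma(X: np.ndarray) -> float:
    """Analytic shrinkage intensity for rows already centered (e.g. per
    class), clipped to [0, 1]."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to estimate shrinkage")
    return float(np.clip(ledoit_wolf_shrinkage(X, assume_centered=True), 0.0, 1.0))


def _solve_weights(
    mu_t: np.ndarray, mu_n: np.ndarray, sigma: np.ndarray, gamma: float
) -> tuple[np.ndarray, float]:
    d = sigma.shape[0]
    nu = float(np.trace(sigma)) / d
    sigma_shrunk = (1.0 - gamma) * sigma + gamma * nu * np.eye(d)
    delta = mu_t - mu_n
    try:
        w = np.linalg.solve(sigma_shrunk, delta)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"shrunk covariance singular at gamma={gamma}; increase shrinkage"
        ) from err
    b = -float(w @ (mu_t + mu_n)) / 2.0
    return w, b


def fit_slda(
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray | None = None,
    gamma: float | str = "auto",
) -> LDAClassifier:
    """Fit the shrinkage LDA.

    ``gamma="auto"`` estimates the shrinkage intensity analytically from
    the class-centered training rows; a float in [0, 1] fixes it.  The
    covariance is the maximum-likelihood pooled estimate (divisor n,
    matching the analytic-shrinkage derivation).
    """
    X, y = _as_xy(features, labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.tolist()}")
    pos, neg = max(classes), min(classes)
    n_pos, n_neg = int((y == pos).sum()), int((y == neg).sum())
    if min(n_pos, n_neg) < 2:
        raise ValueError("need >= 2 samples per class")

    mu_t = X[y == pos].mean(axis=0)
    mu_n = X[y == neg].mean(axis=0)
    centered = X.copy()
    centered[y == pos] -= mu_t
    centered[y == neg] -= mu_n
    sigma = centered.T @ centered / X.shape[0]

    if gamma == "auto":
        gamma_val = ledoit_wolf_gamma(centered)
    else:
        gamma_val = float(gamma)
        if not 0.0 <= gamma_val <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
    w, b = _solve_weights(mu_t, mu_n, sigma, gamma_val)
    return LDAClassifier(
        w=w, b=b, mu_target=mu_t, mu_nontarget=mu_n, sigma=sigma, gamma=gamma_val
    )


def decision_values(
    clf: LDAClassifier, features: FeatureMatrix | np.ndarray
) -> np.ndarray:
    """Signed distances to the decision hyperplane, w.x + b; larger means
    more target-like."""
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != clf.w.shape[0]:
        raise ValueError(
            f"feature dimension {X.shape[1]} != classifier dimension {clf.w.shape[0]}"
        )
    return X @ clf.w + clf.b


def adapt(
    clf: LDAClassifier,
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray | None = None,
    cfg: AdaptationConfig = AdaptationConfig(),
) -> LDAClassifier:
    """Supervised exponential update over one run of labelled epochs.

    Per epoch x of class c: mu_c <- (1 - eta1) mu_c + eta1 x, then
    sigma <- (1 - eta2) sigma + eta2 (x - mu_bar)(x - mu_bar)^T with
    mu_bar the current pooled (equal-prior) mean.  The weight vector and
    bias are recomputed once after the batch; returns a new classifier.
    """
    X, y = _as_xy(features, labels)
    bad = set(np.unique(y)) - {0, 1}
    if bad:
        raise ValueError(f"unknown label values {sorted(bad)}; expected 0/1")
    new = clf.copy()
    for x, c in zip(X, y):
        if c == 1:
            new.mu_target = (1.0 - cfg.eta1) * new.mu_target + cfg.eta1 * x
        else:
            new.mu_nontarget = (1.0 - cfg.eta1) * new.mu_nontarget + cfg.eta1 * x
        mu_bar = 0.5 * (new.mu_target + new.mu_nontarget)
        dev = x - mu_bar
        new.sigma = (1.0 - cfg.eta2) * new.sigma + cfg.eta2 * np.outer(dev, dev)
    new.w, new.b = _solve_weights(
        new.mu_target, new.mu_nontarget, new.sigma, new.gamma
    )
    return new


def transfer_init(prior_sessions: list[FeatureMatrix]) -> LDAClassifier:
    """Pre-train on the chronological concatenation of earlier sessions'
    features (transfer initialization for the first online run)."""
    if not prior_sessions:
        raise ValueError("transfer_init requires at least one prior session")
    X = np.concatenate([np.asarray(s.values, dtype=float) for s in prior_sessions])
    y = np.concatenate([np.asarray(s.labels) for s in prior_sessions])
    return fit_slda(X, y)


def auc(outputs: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve of the classifier outputs.

    Equals the Mann-Whitney statistic: the fraction of (target,
    non-target) pairs ranked correctly, ties counting one half.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size != 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(outputs, dtype=float)))


def chronological_cv_auc(
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray | None = None,
    k: int = 5,
    gamma: float | str = "auto",
) -> CVResult:
    """k-fold chronological cross-validation of the shrinkage LDA.

    Rows are split into k contiguous chronological blocks; each block is
    scored by a model fitted on the remaining blocks.  The headline value
    is the mean of per-fold AUCs; the pooled AUC over all held-out
    outputs is reported alongside.
    """
    X, y = _as_xy(features, labels)
    n = X.shape[0]
    if k < 2 or k > n:
        raise ValueError("k must be in [2, n]")
    bounds = []
    edges = np.linspace(0, n, k + 1).astype(int)
    per_fold = []
    all_out = np.empty(n)
    for f in range(k):
        lo, hi = int(edges[f]), int(edges[f + 1])
        test_idx = np.arange(lo, hi)
        train_idx = np.concatenate([np.arange(0, lo), np.arange(hi, n)])
        if np.unique(y[test_idx]).size < 2:
            raise ValueError(f"fold {f} ({lo}:{hi}) does not contain both classes")
        clf = fit_slda(X[train_idx], y[train_idx], gamma=gamma)
        out = decision_values(clf, X[test_idx])
        all_out[test_idx] = out
        per_fold.append(auc(out, y[test_idx]))
        bounds.append((lo, hi))
    return CVResult(
        auc=float(np.mean(per_fold)),
        per_fold_auc=tuple(per_fold),
        fold_bounds=tuple(bounds),
        pooled_auc=auc(all_out, y),
    )
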