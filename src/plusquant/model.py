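"""Continuous Plus-severity regression.

Feature weighting/selection uses neighbourhood component analysis (NCA)
for regression: per-feature weights w are fitted by minimizing the
leave-one-out soft-neighbour prediction loss

    f(w) = sum_i sum_{j != i} p_ij |y_i - y_j| + lambda * sum_r w_r^2,
    p_ij = exp(-d_w(x_i, x_j)) / sum_{k != i} exp(-d_w(x_i, x_k)),
    d_w(x_i, x_j) = sum_r w_r^2 |x_ir - x_jr|,

so features that help predict the target through their neighbourhood
structure receive large weights.  The k top-weighted features feed an
ordinary-least-squares linear model whose output is the continuous 1-5
severity index; accuracy is evaluated by k-fold cross-validated MSE/MAE
against the experts' average score.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class NCAWeights:
    w: np.ndarray
    lambda_reg: float
    objective_trace: list
    seed: int = 0


@dataclass
class SeverityModel:
    intercept: float
    coefficients: np.ndarray  # on standardized features
    selected_features: list
    feature_means: np.ndarray
    feature_sds: np.ndarray
    training_n: int

    def save(self, path) -> None:
        blob = {
            "intercept": self.intercept,
            "coefficients": list(map(float, self.coefficients)),
            "selected_features": list(self.selected_features),
            "feature_means": list(map(float, self.feature_means)),
            "feature_sds": list(map(float, self.feature_sds)),
            "training_n": self.training_n,
        }
        Path(path).write_text(json.dumps(blob, indent=2))

    @classmethod
    def load(cls, path) -> "SeverityModel":
        blob = json.loads(Path(path).read_text())
        return cls(
            intercept=blob["intercept"],
            coefficients=np.asarray(blob["coefficients"]),
            selected_features=blob["selected_features"],
            feature_means=np.asarray(blob["feature_means"]),
            feature_sds=np.asarray(blob["feature_sds"]),
            training_n=blob["training_n"],
        )


@dataclass
class CVReport:
    mse_mean: float
    mse_sd: float
    mae_mean: float
    mae_sd: float
    fold_assignments: np.ndarray
    seed: int


def _standardize(X: np.ndarray) -> tuple:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    if (sd == 0).any():
        raise ValueError("constant feature column; cannot standardize")
    return (X - mu) / sd, mu, sd


def _nca_objective_grad(w: np.ndarray, absdiff: np.ndarray, ydiff: np.ndarray,
                        lam: float) -> tuple:
    """Objective and gradient of the NCA regression loss.

    absdiff: (n, n, p) |x_ir - x_jr|; ydiff: (n, n) |y_i - y_j|.
    """
    n = absdiff.shape[0]
    d = absdiff @ (w**2)  # (n, n) weighted L1 distances
    np.fill_diagonal(d, np.inf)
    logits = -d
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    loss_i = (p * ydiff).sum(axis=1)  # (n,)
    obj = float(loss_i.sum() + lam * (w**2).sum())
    # d obj / d d_ij = -p_ij (l_ij - loss_i)
    g_d = -p * (ydiff - loss_i[:, None])
    grad = 2.0 * w * np.einsum("ij,ijr->r", g_d, absdiff) + 2.0 * lam * w
    return obj, grad


def nca_regression_weights(
    X: np.ndarray,
    y: np.ndarray,
    lambda_reg: float | None = None,
    seed: int = 0,
    iters: int = 500,
    lr: float = 0.1,
) -> NCAWeights:
    """Fit per-feature NCA-for-regression weights by gradient descent.

    Features are standardized internally; weights start at 1 and descend
    the leave-one-out objective with a step-halving line search, so the
    recorded objective trace is non-increasing.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < 10:
        raise ValueError("need at least 10 samples for NCA")
    lam = 1.0 / n if lambda_reg is None else lambda_reg
    Xs, _, _ = _standardize(X)
    absdiff = np.abs(Xs[:, None, :] - Xs[None, :, :])
    ydiff = np.abs(y[:, None] - y[None, :])
    w = np.ones(p)
    obj, grad = _nca_objective_grad(w, absdiff, ydiff, lam)
    trace = [obj]
    step = lr
    for _ in range(iters):
        for _halve in range(30):
            w_new = w - step * grad
            obj_new, grad_new = _nca_objective_grad(w_new, absdiff, ydiff, lam)
            if np.isfinite(obj_new) and obj_new <= obj:
                break
            step *= 0.5
        else:
            break  # no descent direction at machine precision
        w, obj, grad = w_new, obj_new, grad_new
        trace.append(obj)
        step *= 1.2
        if len(trace) > 2 and trace[-2] - trace[-1] < 1e-10 * max(1.0, abs(trace[-1])):
            break
    return NCAWeights(w=np.abs(w), lambda_reg=lam, objective_trace=trace, seed=seed)


def select_features(weights: NCAWeights, k: int) -> list:
    """Indices of the k largest weights; ties broken by feature order."""
    w = np.asarray(weights.w, dtype=float)
    if k > len(w):
        raise ValueError("k exceeds number of features")
    order = np.argsort(-w, kind="stable")
    return sorted(order[:k].tolist())


def fit_linear(X_sel: np.ndarray, y: np.ndarray, feature_names: list | None = None) -> SeverityModel:
    """OLS on standardized selected features, intercept included."""
    X_sel = np.asarray(X_sel, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X_sel.shape
    if n <= k + 1:
        raise ValueError("need more samples than features + 1")
    Xs, mu, sd = _standardize(X_sel)
    A = np.column_stack([np.ones(n), Xs])
    cond = np.linalg.cond(A)
    if cond > 1e10:
        raise ValueError(f"design matrix is rank-deficient or near-collinear (cond={cond:.2e})")
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    names = feature_names or [f"x{i}" for i in range(k)]
    return SeverityModel(
        intercept=float(coef[0]),
        coefficients=coef[1:],
        selected_features=list(names),
        feature_means=mu,
        feature_sds=sd,
        training_n=n,
    )


def predict_severity(model: SeverityModel, x: np.ndarray) -> tuple:
    """Predict the continuous severity index for one feature vector.

    Returns ``(raw, clamped)`` where clamped is raw limited to [1, 5],
    the range of the grading scale.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != len(model.coefficients):
        raise ValueError("feature vector length mismatch")
    if not np.all(np.isfinite(x)):
        raise ValueError("missing (non-finite) feature value")
    xs = (x - model.feature_means) / model.feature_sds
    raw = float(model.intercept + xs @ model.coefficients)
    return raw, float(np.clip(raw, 1.0, 5.0))


def kfold_cv(X: np.ndarray, y: np.ndarray, k: int = 5, seed: int = 0) -> CVReport:
    """k-fold cross-validated MSE/MAE of the linear severity model."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if not 2 <= k <= n:
        raise ValueError("need n >= k >= 2")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    folds[order] = np.arange(n) % k
    mses, maes = [], []
    for f in range(k):
        test = folds == f
        if test.sum() < 2:
            raise ValueError(f"fold {f} has fewer than 2 samples")
        model = fit_linear(X[~test], y[~test])
        preds = np.array([predict_severity(model, xi)[0] for xi in X[test]])
        resid = preds - y[test]
        mses.append(float(np.mean(resid**2)))
        maes.append(float(np.mean(np.abs(resid))))
    return CVReport(
        mse_mean=float(np.mean(mses)),
        mse_sd=float(np.std(mses, ddof=1)),
        mae_mean=float(np.mean(maes)),
        mae_sd=float(np.std(maes, ddof=1)),
        fold_assignments=folds,
        seed=seed,
    )


def significance_stars(p: float) -> str:
    """Conventional significance annotation: * <0.05, ** <0.01, *** <0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def group_ttests(features: np.ndarray, grades: np.ndarray,
                 feature_names: list | None = None) -> pd.DataFrame:
    """Welch t-tests between every pair of severity levels, per feature.

    Returns a tidy DataFrame (level_a, level_b, feature, p_value, stars).
    Level pairs where either group has < 2 samples are skipped and
    flagged with NaN p-values.  P-values are raw (no multiple-testing
    correction).
    """
    X = np.asarray(features, dtype=float)
    g = np.asarray(grades, dtype=int)
    names = feature_names or [f"x{i}" for i in range(X.shape[1])]
    levels = sorted(set(g.tolist()))
    rows = []
    for la, lb in itertools.combinations(levels, 2):
        a, b = X[g == la], X[g == lb]
        for j, name in enumerate(names):
            if len(a) < 2 or len(b) < 2:
                rows.append({"level_a": la, "level_b": lb, "feature": name,
                             "p_value": np.nan, "stars": "skipped"})
                continue
            if np.array_equal(a[:, j], b[:, j]) or (np.ptp(a[:, j]) == 0 and np.ptp(b[:, j]) == 0
                                                    and a[0, j] == b[0, j]):
                p = 1.0
            else:
                p = float(stats.ttest_ind(a[:, j], b[:, j], equal_var=False).pvalue)
            rows.append({"level_a": la, "level_b": lb, "feature": name,
                         "p_value": p, "stars": significance_stars(p)})
    return pd.DataFrame(rows)
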