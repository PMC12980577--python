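"""Elastic-net logistic fatigue classifier with stratified nested CV.

Workflow (MS patients only, complete cases):

1. ``nested_cv_fit`` — stratified 5-fold nested cross-validation, repeated
   (default 50 times) with fresh splits. In each outer split a 5-fold inner
   CV searches alpha in 0.1..1.0 (1.0 = lasso) crossed with ~100 log-spaced
   lambdas (from the data-driven lambda_max down four decades); the pair with
   the lowest inner-CV binomial deviance is refit on the outer-train fold and
   evaluated on the held-out fold. Held-out predictions are pooled per repeat
   to compute ROC-AUC, PR-AUC, accuracy, sensitivity, specificity, balanced
   accuracy and the Brier score; aggregates are means with percentile 95%
   intervals over repeats. Selection frequency of a predictor is the fraction
   of outer refits giving it a nonzero coefficient.
2. ``stability_refit`` — a descriptive ridge-logistic refit on predictors with
   mean selection frequency > 0.50, with odds ratios, stratified-bootstrap
   95% CIs, and McFadden / Cox-Snell / Nagelkerke pseudo-R^2.

Continuous predictors are z-scored strictly inside each training fold; binary
columns (e.g. sex) pass through unscaled. The solver is a glmnet-style
IRLS + coordinate-descent path, compiled with numba; sklearn supplies the
splitters and metrics only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "nested_cv_fit", "stability_refit", "classification_metrics",
    "enet_logistic_path", "build_feature_matrix", "ModelReport", "RefitReport",
]

logger = logging.getLogger(__name__)

METRIC_NAMES = ("roc_auc", "pr_auc", "accuracy", "sensitivity", "specificity",
                "balanced_accuracy", "brier")


# ---------------------------------------------------------------------------
# Elastic-net logistic path solver (glmnet-style IRLS + coordinate descent)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _enet_path_impl(X, y, alpha, lambdas, max_outer, max_inner, tol):
    n, p = X.shape
    n_lam = len(lambdas)
    coefs = np.zeros((n_lam, p))
    intercepts = np.zeros(n_lam)
    beta = np.zeros(p)
    ybar = y.mean()
    if ybar <= 0.0 or ybar >= 1.0:
        # single-class data: intercept-only at +-inf; clamp
        b0 = 25.0 if ybar >= 1.0 else -25.0
        for li in range(n_lam):
            intercepts[li] = b0
        return intercepts, coefs
    b0 = np.log(ybar / (1.0 - ybar))
    eta = np.empty(n)
    for li in range(n_lam):
        lam = lambdas[li]
        l1 = lam * alpha
        l2 = lam * (1.0 - alpha)
        for _ in range(max_outer):
            # IRLS working response
            for i in range(n):
                e = b0
                for j in range(p):
                    e += X[i, j] * beta[j]
                eta[i] = e
            w = np.empty(n)
            z = np.empty(n)
            for i in range(n):
                pr = 1.0 / (1.0 + np.exp(-eta[i]))
                wi = pr * (1.0 - pr)
                if wi < 1e-5:
                    wi = 1e-5
                w[i] = wi
                z[i] = eta[i] + (y[i] - pr) / wi
            wsum = w.sum()
            # residual r = z - b0 - X beta
            r = np.empty(n)
            for i in range(n):
                r[i] = z[i] - eta[i]
            max_delta_outer = 0.0
            for _ in range(max_inner):
                max_delta = 0.0
                for j in range(p):
                    num = 0.0
                    den = 0.0
                    for i in range(n):
                        num += w[i] * X[i, j] * (r[i] + X[i, j] * beta[j])
                        den += w[i] * X[i, j] * X[i, j]
                    num /= n
                    den = den / n + l2
                    if num > l1:
                        new_b = (num - l1) / den
                    elif num < -l1:
                        new_b = (num + l1) / den
                    else:
                        new_b = 0.0
                    d = new_b - beta[j]
                    if d != 0.0:
                        for i in range(n):
                            r[i] -= X[i, j] * d
                        beta[j] = new_b
                        if abs(d) > max_delta:
                            max_delta = abs(d)
                # intercept update
                num0 = 0.0
                for i in range(n):
                    num0 += w[i] * r[i]
                d0 = num0 / wsum
                if d0 != 0.0:
                    b0 += d0
                    for i in range(n):
                        r[i] -= d0
                if abs(d0) > max_delta:
                    max_delta = abs(d0)
                if max_delta < tol:
                    break
                if max_delta > max_delta_outer:
                    max_delta_outer = max_delta
            if max_delta_outer < 10.0 * tol:
                break
        intercepts[li] = b0
        coefs[li] = beta
    return intercepts, coefs


def enet_logistic_path(X: np.ndarray, y: np.ndarray, alpha: float,
                       lambdas: np.ndarray, max_outer: int = 30,
                       max_inner: int = 100, tol: float = 1e-7):
    """Coefficient path over a descending lambda grid (warm-started).

    Returns (intercepts, coefs) with coefs of shape (n_lambda, n_features).
    ``alpha`` is the elastic-net mixing parameter (1 = lasso, 0 = ridge); the
    penalty is lambda * (alpha*||b||_1 + (1-alpha)/2*||b||_2^2) on the mean
    log-loss scale.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    lambdas = np.ascontiguousarray(lambdas, dtype=np.float64)
    return _enet_path_impl(X, y, float(alpha), lambdas, max_outer, max_inner, tol)


def _lambda_grid(X: np.ndarray, y: np.ndarray, alpha: float,
                 n_lambda: int = 100, decades: float = 4.0) -> np.ndarray:
    """Log-spaced grid from the data-driven lambda_max down ``decades``."""
    n = len(y)
    lam_max = np.abs(X.T @ (y - y.mean())).max() / (n * max(alpha, 1e-3))
    lam_max = max(lam_max, 1e-6)
    return np.logspace(np.log10(lam_max), np.log10(lam_max) - decades, n_lambda)


def _predict(intercept: float, beta: np.ndarray, X: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(intercept + X @ beta)))


# ---------------------------------------------------------------------------
# Fold-wise standardization
# ---------------------------------------------------------------------------

def _binary_mask(X: np.ndarray) -> np.ndarray:
    return np.array([len(np.unique(X[:, j])) <= 2 for j in range(X.shape[1])])


def _fold_scale(X_tr: np.ndarray, X_te: np.ndarray, binary: np.ndarray):
    """Z-score continuous columns using training statistics only."""
    mu = X_tr.mean(axis=0)
    sd = X_tr.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    mu = np.where(binary, 0.0, mu)
    sd = np.where(binary, 1.0, sd)
    return (X_tr - mu) / sd, (X_te - mu) / sd


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def classification_metrics(y: np.ndarray, prob: np.ndarray,
                           threshold: float = 0.5) -> dict[str, float]:
    """Pooled-prediction metrics; threshold 0.5 for the hard-label metrics."""
    y = np.asarray(y, dtype=int)
    prob = np.asarray(prob, dtype=float)
    pred = (prob >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    return {
        "roc_auc": float(roc_auc_score(y, prob)) if len(np.unique(y)) > 1 else np.nan,
        "pr_auc": float(average_precision_score(y, prob)) if len(np.unique(y)) > 1 else np.nan,
        "accuracy": float((tp + tn) / len(y)),
        "sensitivity": float(sens),
        "specificity": float(spec),
        "balanced_accuracy": float(np.nanmean([sens, spec])),
        "brier": float(np.mean((prob - y) ** 2)),
    }


# ---------------------------------------------------------------------------
# Nested cross-validation
# ---------------------------------------------------------------------------

@dataclass
class ModelReport:
    per_repeat: pd.DataFrame                  # one row per repeat, metric columns
    aggregate: dict                           # metric -> (mean, lo95, hi95)
    selection_frequency: pd.Series            # MSF per predictor
    feature_names: list[str]
    n_repeats: int
    seed: int
    refit: "RefitReport | None" = None


@dataclass
class RefitReport:
    predictors: list[str]
    beta: np.ndarray
    odds_ratio: np.ndarray
    or_ci: np.ndarray                          # (p, 2) stratified-bootstrap 95% CI
    intercept: float
    pseudo_r2: dict                            # mcfadden / cox_snell / nagelkerke
    ridge_lambda: float
    n: int
    seed: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "predictor": self.predictors, "beta": self.beta,
            "odds_ratio": self.odds_ratio,
            "or_ci_low": self.or_ci[:, 0], "or_ci_high": self.or_ci[:, 1],
        })


def build_feature_matrix(frame: pd.DataFrame, predictors: list[str],
                         outcome: str = "fatigued") -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Complete-case numeric matrix from a cohort feature table.

    ``sex`` is encoded 1 = female, 0 = male. Rows with any missing predictor
    or outcome are dropped (complete-case rule).
    """
    df = frame.copy()
    if "sex" in predictors and df["sex"].dtype == object:
        df["sex"] = (df["sex"] == "F").astype(float)
    sub = df[predictors + [outcome]].astype(float)
    sub = sub.dropna()
    X = sub[predictors].to_numpy()
    y = sub[outcome].to_numpy().astype(int)
    return X, y, list(predictors)


def _stratified_split(y, n_splits, seed, max_bumps=10):
    """Stratified K-fold; bumps the seed if a fold degenerates to one class."""
    for bump in range(max_bumps):
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                              random_state=(seed + bump) % (2 ** 31))
        folds = list(skf.split(np.zeros(len(y)), y))
        ok = all(len(np.unique(y[tr])) == 2 for tr, _ in folds)
        if ok:
            if bump:
                logger.info("degenerate stratified split; seed bumped by %d", bump)
            return folds
    raise ValueError("cannot build stratified folds with both classes present")


def nested_cv_fit(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str] | None = None,
    n_outer: int = 5,
    n_inner: int = 5,
    alphas: np.ndarray | None = None,
    n_lambda: int = 100,
    n_repeats: int = 50,
    seed: int = 0,
    threshold: float = 0.5,
) -> ModelReport:
    """Repeated stratified nested CV for the elastic-net logistic model."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(X.shape[1])]
    if alphas is None:
        alphas = np.round(np.arange(0.1, 1.01, 0.1), 2)
    binary = _binary_mask(X)
    rows = []
    n_sel = np.zeros(X.shape[1])
    n_outer_fits = 0
    for rep in range(n_repeats):
        rep_seed = (seed * 1009 + rep * 7727) % (2 ** 31)
        outer_folds = _stratified_split(y, n_outer, rep_seed)
        pooled_prob = np.empty(len(y))
        for of, (tr, te) in enumerate(outer_folds):
            X_tr_raw, X_te_raw = X[tr], X[te]
            y_tr, _ = y[tr], y[te]
            X_tr, X_te = _fold_scale(X_tr_raw, X_te_raw, binary)
            # inner grid search: deviance accumulated over inner folds
            grids = {a: _lambda_grid(X_tr, y_tr, a, n_lambda) for a in alphas}
            dev = np.zeros((len(alphas), n_lambda))
            inner_folds = _stratified_split(y_tr, n_inner, rep_seed + 13 * of + 1)
            for itr, ite in inner_folds:
                Xi_tr, Xi_te = _fold_scale(X_tr_raw[itr], X_tr_raw[ite], binary)
                yi_tr, yi_te = y_tr[itr], y_tr[ite]
                for ai, a in enumerate(alphas):
                    b0s, betas = enet_logistic_path(Xi_tr, yi_tr, a, grids[a])
                    eta = np.clip(b0s[:, None] + betas @ Xi_te.T, -35.0, 35.0)
                    probs = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
                    dev[ai] += -2.0 * (yi_te * np.log(probs) + (1 - yi_te) * np.log(1 - probs)).sum(axis=1)
            ai, li = np.unravel_index(np.argmin(dev), dev.shape)
            best_a, best_grid = alphas[ai], grids[alphas[ai]]
            b0s, betas = enet_logistic_path(X_tr, y_tr, best_a, best_grid[:li + 1])
            b0, beta = b0s[li], betas[li]
            pooled_prob[te] = _predict(b0, beta, X_te)
            n_sel += (beta != 0).astype(float)
            n_outer_fits += 1
        rows.append(classification_metrics(y, pooled_prob, threshold))
    per_repeat = pd.DataFrame(rows)
    aggregate = {
        m: (float(per_repeat[m].mean()),
            float(np.percentile(per_repeat[m], 2.5)),
            float(np.percentile(per_repeat[m], 97.5)))
        for m in METRIC_NAMES
    }
    msf = pd.Series(n_sel / n_outer_fits, index=feature_names, name="msf")
    return ModelReport(per_repeat=per_repeat, aggregate=aggregate,
                       selection_frequency=msf, feature_names=list(feature_names),
                       n_repeats=n_repeats, seed=seed)


# ---------------------------------------------------------------------------
# Descriptive ridge refit
# ---------------------------------------------------------------------------

def _log_likelihood(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _ridge_fit(X: np.ndarray, y: np.ndarray, lam: float):
    b0s, betas = enet_logistic_path(X, y, 0.0, np.array([lam]))
    return b0s[0], betas[0]


def stability_refit(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    retained: list[str],
    ridge_lambda: float = 0.01,
    n_boot: int = 1000,
    seed: int = 0,
) -> RefitReport:
    """Descriptive ridge-logistic refit on the stability-selected predictors.

    Odds ratios exp(beta) with 95% stratified (within-class) bootstrap
    percentile CIs, plus pseudo-R^2 (McFadden, Cox-Snell, Nagelkerke) from the
    unpenalized log-likelihoods of the fitted vs intercept-only model. If the
    fit shows signs of separation (runaway coefficients), the penalty is
    raised one decade at a time (logged).
    """
    if not retained:
        raise ValueError("retained predictor list is empty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    cols = [feature_names.index(r) for r in retained]
    Xr = X[:, cols]
    binary = _binary_mask(Xr)
    Xs, _ = _fold_scale(Xr, Xr, binary)
    lam = ridge_lambda
    for _ in range(6):
        b0, beta = _ridge_fit(Xs, y, lam)
        if np.abs(beta).max() < 25.0:
            break
        logger.info("possible separation at ridge lambda=%g; raising a decade", lam)
        lam *= 10.0
    n = len(y)
    p_hat = _predict(b0, beta, Xs)
    ll = _log_likelihood(y, p_hat)
    p0 = y.mean()
    ll0 = _log_likelihood(y, np.full(n, p0))
    mcfadden = 1.0 - ll / ll0 if ll0 != 0 else 0.0
    cox_snell = 1.0 - np.exp(2.0 * (ll0 - ll) / n)
    nagelkerke = cox_snell / (1.0 - np.exp(2.0 * ll0 / n))
    rng = np.random.default_rng(seed)
    idx0, idx1 = np.flatnonzero(y == 0), np.flatnonzero(y == 1)
    boots = np.empty((n_boot, len(retained)))
    for b in range(n_boot):
        sel = np.concatenate([rng.choice(idx0, len(idx0), replace=True),
                              rng.choice(idx1, len(idx1), replace=True)])
        Xb, _ = _fold_scale(Xr[sel], Xr[sel], binary)
        _, bb = _ridge_fit(Xb, y[sel], lam)
        boots[b] = bb
    ci = np.exp(np.percentile(boots, [2.5, 97.5], axis=0).T)
    return RefitReport(
        predictors=list(retained), beta=beta, odds_ratio=np.exp(beta),
        or_ci=ci, intercept=float(b0),
        pseudo_r2={"mcfadden": float(mcfadden), "cox_snell": float(cox_snell),
                   "nagelkerke": float(nagelkerke)},
        ridge_lambda=lam, n=n, seed=seed,
    )
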