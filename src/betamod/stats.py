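"""Nonparametric group statistics, bootstrap correlations, and mediation.

A small self-contained statistics layer mirroring the analysis plan of the
study this package implements:

* Kruskal-Wallis with tie correction (scipy), followed by Dunn's post-hoc
  z tests with the tie-corrected pooled variance and Bonferroni correction
  over all pairs (implemented here: no maintained implementation is
  pre-installed).
* Spearman correlations with seeded percentile bootstrap CIs (1000 paired
  resamples).
* Simple mediation (x -> m -> y) by the product of OLS coefficients, with
  bias-corrected (BC) percentile bootstrap CIs and two-sided bootstrap p.
* The fatigue regression: OLS of FSS on z-scored beta modulation depth and
  MADRS, reporting standardized betas, t, and the model F.
* Pearson chi-square (no continuity correction) for sex distribution.

Bonferroni over the three primary EEG measures (ERD, ERS, depth) is exposed
as :func:`bonferroni_primary` (familywise alpha / 3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "KWResult", "DunnResult", "SpearmanResult", "MediationResult", "RegressionResult",
    "kruskal_wallis", "dunn_posthoc", "spearman_boot", "mediate",
    "fss_regression", "chi_square_sex", "bonferroni_primary",
]


@dataclass
class KWResult:
    h: float
    p: float
    group_sizes: tuple[int, ...]


@dataclass
class DunnResult:
    pairs: list[tuple[int, int]]
    z: np.ndarray
    p_raw: np.ndarray
    p_bonferroni: np.ndarray


@dataclass
class SpearmanResult:
    rho: float
    p: float
    ci: tuple[float, float]
    n: int
    n_boot: int
    seed: int


@dataclass
class MediationResult:
    """Direct (c'), indirect (a*b) and total (c) effects with BC bootstrap CIs."""

    de: float
    ie: float
    te: float
    de_ci: tuple[float, float]
    ie_ci: tuple[float, float]
    te_ci: tuple[float, float]
    de_p: float
    ie_p: float
    te_p: float
    n: int
    seed: int


@dataclass
class RegressionResult:
    beta: dict[str, float]     # standardized coefficients
    t: dict[str, float]
    p: dict[str, float]
    f: float
    f_p: float
    df: tuple[int, int]
    r2: float


def _clean_groups(groups) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float) for g in groups]
    out = [g[np.isfinite(g)] for g in out]
    if any(len(g) == 0 for g in out):
        raise ValueError("every group must be non-empty")
    return out


def kruskal_wallis(*groups) -> KWResult:
    """Rank-based H test (tie-corrected), p from chi-square with k-1 df."""
    gs = _clean_groups(groups)
    if sum(len(g) for g in gs) < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(gs)
    if np.all(pooled == pooled[0]):
        return KWResult(0.0, 1.0, tuple(len(g) for g in gs))
    h, p = sps.kruskal(*gs)
    return KWResult(float(h), float(p), tuple(len(g) for g in gs))


def dunn_posthoc(*groups, alpha: float = 0.05) -> DunnResult:
    """Dunn's pairwise rank tests after Kruskal-Wallis.

    z_ij = (meanrank_i - meanrank_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j))
    with the tie term T = sum(t^3 - t) / (12 (N - 1)); two-tailed p values,
    Bonferroni over all k(k-1)/2 pairs (capped at 1).
    """
    gs = _clean_groups(groups)
    k = len(gs)
    if k < 2:
        return DunnResult([], np.array([]), np.array([]), np.array([]))
    pooled = np.concatenate(gs)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    sizes = [len(g) for g in gs]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(k)]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    pairs, zs, ps = [], [], []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            pairs.append((i, j))
            zs.append(z)
            ps.append(2.0 * sps.norm.sf(abs(z)))
    p_raw = np.array(ps)
    m = len(pairs)
    return DunnResult(pairs, np.array(zs), p_raw, np.minimum(1.0, p_raw * m))


def spearman_boot(x, y, n_boot: int = 1000, seed: int = 0) -> SpearmanResult:
    """Spearman rho with a seeded percentile bootstrap CI over paired resamples.

    Pairwise-complete: pairs with a missing member are dropped first.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: Spearman correlation undefined")
    res = sps.spearmanr(x, y)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boots = np.empty(n_boot)
    for b in range(n_boot):
        xb, yb = x[idx[b]], y[idx[b]]
        if np.ptp(xb) == 0 or np.ptp(yb) == 0:
            boots[b] = np.nan
            continue
        boots[b] = sps.spearmanr(xb, yb).statistic
    boots = boots[np.isfinite(boots)]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return SpearmanResult(float(res.statistic), float(res.pvalue),
                          (float(lo), float(hi)), n, n_boot, seed)


def _ols(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Coefficients of y ~ 1 + x (columns); intercept first."""
    design = np.column_stack([np.ones(len(y)), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return coef


def _bc_ci(boots: np.ndarray, estimate: float, level: float = 0.95) -> tuple[float, float]:
    """Bias-corrected percentile bootstrap CI (BC, not BCa)."""
    boots = boots[np.isfinite(boots)]
    prop = np.mean(boots < estimate)
    prop = min(max(prop, 1.0 / (len(boots) + 1)), 1 - 1.0 / (len(boots) + 1))
    z0 = sps.norm.ppf(prop)
    za = sps.norm.ppf((1 - level) / 2)
    lo = sps.norm.cdf(2 * z0 + za)
    hi = sps.norm.cdf(2 * z0 - za)
    return tuple(np.percentile(boots, [100 * lo, 100 * hi]))


def _boot_p(boots: np.ndarray) -> float:
    """Two-sided bootstrap sign proportion p-value."""
    boots = boots[np.isfinite(boots)]
    p_neg = np.mean(boots < 0)
    p_pos = np.mean(boots > 0)
    return float(min(1.0, 2.0 * min(p_neg, p_pos)))


def mediate(x, m, y, n_boot: int = 1000, seed: int = 0) -> MediationResult:
    """Product-of-coefficients mediation with BC percentile bootstrap CIs.

    IE = a*b from m ~ x and y ~ x + m (both OLS); DE = c' (coefficient of x in
    y ~ x + m); TE = c from y ~ x. On the point estimates TE = DE + IE exactly
    (listwise-complete data). x may be a binary group dummy.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(m) & np.isfinite(y)
    x, m, y = x[keep], m[keep], y[keep]
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 complete triples")
    r_xm = np.corrcoef(x, m)[0, 1]
    if abs(r_xm) > 0.999:
        raise ValueError("x and m are collinear; mediation effects unidentified")

    def effects(xi, mi, yi):
        a = _ols(xi[:, None], mi)[1]
        cp_b = _ols(np.column_stack([xi, mi]), yi)[1:]
        c = _ols(xi[:, None], yi)[1]
        return cp_b[0], a * cp_b[1], c  # DE, IE, TE

    de, ie, te = effects(x, m, y)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boots = np.empty((n_boot, 3))
    for b in range(n_boot):
        sel = idx[b]
        if np.ptp(x[sel]) == 0:
            boots[b] = np.nan
            continue
        boots[b] = effects(x[sel], m[sel], y[sel])
    return MediationResult(
        de=float(de), ie=float(ie), te=float(te),
        de_ci=_bc_ci(boots[:, 0], de), ie_ci=_bc_ci(boots[:, 1], ie),
        te_ci=_bc_ci(boots[:, 2], te),
        de_p=_boot_p(boots[:, 0]), ie_p=_boot_p(boots[:, 1]), te_p=_boot_p(boots[:, 2]),
        n=n, seed=seed,
    )


def fss_regression(fss, beta_depth, madrs) -> RegressionResult:
    """OLS of FSS on z-scored beta modulation depth and MADRS.

    Standardized betas (z-scored outcome and predictors), per-coefficient t
    and p, and the model F with (2, n-3) df.
    """
    fss = np.asarray(fss, dtype=float)
    cols = {"beta_depth": np.asarray(beta_depth, dtype=float),
            "MADRS": np.asarray(madrs, dtype=float)}
    keep = np.isfinite(fss)
    for v in cols.values():
        keep &= np.isfinite(v)
    fss = fss[keep]
    n = len(fss)
    if n <= 3:
        raise ValueError("need more than 3 complete cases")

    def z(v):
        return (v - v.mean()) / v.std(ddof=1)

    yz = z(fss)
    xz = np.column_stack([z(cols[k][keep]) for k in cols])
    design = np.column_stack([np.ones(n), xz])
    coef, *_ = np.linalg.lstsq(design, yz, rcond=None)
    resid = yz - design @ coef
    df_resid = n - 3
    sse = resid @ resid
    sst = yz @ yz  # z-scored outcome: mean 0
    r2 = 1.0 - sse / sst
    if df_resid <= 0 or sse <= 1e-12 * sst:
        f_stat, f_p = np.inf, 0.0
        mse = 0.0
    else:
        mse = sse / df_resid
        f_stat = ((sst - sse) / 2) / mse
        f_p = float(sps.f.sf(f_stat, 2, df_resid))
    cov = mse * np.linalg.inv(design.T @ design) if mse > 0 else np.zeros((3, 3))
    se = np.sqrt(np.diag(cov))
    names = list(cols)
    beta = {nm: float(coef[i + 1]) for i, nm in enumerate(names)}
    tvals = {nm: float(coef[i + 1] / se[i + 1]) if se[i + 1] > 0 else np.inf
             for i, nm in enumerate(names)}
    pvals = {nm: float(2 * sps.t.sf(abs(tvals[nm]), df_resid)) if np.isfinite(tvals[nm]) else 0.0
             for nm in names}
    return RegressionResult(beta=beta, t=tvals, p=pvals, f=float(f_stat),
                            f_p=f_p, df=(2, df_resid), r2=float(r2))


def chi_square_sex(counts) -> tuple[float, float]:
    """Pearson chi-square on a group x sex contingency table (no continuity
    correction). Zero-margin rows/columns are rejected."""
    table = np.asarray(counts, dtype=float)
    if (table < 0).any() or not np.allclose(table, np.round(table)):
        raise ValueError("contingency table must hold non-negative integers")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero-margin row or column in contingency table")
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue)


def bonferroni_primary(p_values: dict[str, float], n_tests: int = 3) -> dict[str, float]:
    """Bonferroni over the three primary EEG measures (ERD, ERS, depth)."""
    return {k: min(1.0, v * n_tests) for k, v in p_values.items()}
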