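"""Statistics layer: KW/Dunn oracles, bootstrap correlation, mediation, regression."""

import numpy as np
import pytest
from scipy import stats as sps

from betamod.stats import (
    bonferroni_primary,
    chi_square_sex,
    dunn_posthoc,
    fss_regression,
    kruskal_wallis,
    mediate,
    spearman_boot,
)


def _kw_oracle(*groups):
    """Hand-ranked Kruskal-Wallis H with tie correction."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    bounds = np.cumsum([0] + [len(g) for g in groups])
    h = 12.0 / (n * (n + 1)) * sum(
        ranks[bounds[i]:bounds[i + 1]].sum() ** 2 / len(g)
        for i, g in enumerate(groups)
    ) - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1 - np.sum(counts ** 3 - counts) / (n ** 3 - n)
    return h / tie


class TestKruskalWallis:
    def test_small_case_against_hand_formula(self):
        groups = ([1, 2], [3, 4], [5, 6])
        res = kruskal_wallis(*groups)
        assert res.h == pytest.approx(4.571, abs=1e-3)
        assert res.h == pytest.approx(_kw_oracle(*map(np.array, groups)), abs=1e-10)

    def test_identical_groups_h_zero(self):
        res = kruskal_wallis([2.0, 2.0], [2.0, 2.0], [2.0, 2.0])
        assert res.h == 0.0 and res.p == 1.0

    def test_tied_data_matches_oracle(self, rng):
        groups = [rng.integers(0, 4, 8).astype(float) for _ in range(3)]
        res = kruskal_wallis(*groups)
        assert res.h == pytest.approx(_kw_oracle(*groups), abs=1e-10)

    def test_p_agrees_with_permutation_null(self, rng):
        # exact-null oracle: permutation distribution of H at n=4 per group
        groups = [rng.standard_normal(4) for _ in range(3)]
        res = kruskal_wallis(*groups)
        pooled = np.concatenate(groups)
        n_perm = 100_000
        perms = rng.permuted(np.tile(pooled, (n_perm, 1)), axis=1)
        h_null = np.empty(n_perm)
        for i in range(n_perm):
            h_null[i] = _kw_oracle(perms[i, :4], perms[i, 4:8], perms[i, 8:])
        p_perm = np.mean(h_null >= res.h - 1e-12)
        # chi-square approximation vs exact permutation: MC + approximation error
        assert res.p == pytest.approx(p_perm, abs=0.05)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1.0, 2.0], [])


class TestDunn:
    def _dunn_oracle(self, groups):
        # independently coded textbook formula, including the tie term
        pooled = np.concatenate(groups)
        n = len(pooled)
        ranks = sps.rankdata(pooled)
        bounds = np.cumsum([0] + [len(g) for g in groups])
        mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(groups))]
        _, counts = np.unique(pooled, return_counts=True)
        ties = np.sum(counts ** 3 - counts) / (12 * (n - 1))
        out = {}
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                se = np.sqrt((n * (n + 1) / 12 - ties) * (1 / len(groups[i]) + 1 / len(groups[j])))
                out[(i, j)] = (mean_ranks[i] - mean_ranks[j]) / se
        return out

    def test_identical_groups_all_null(self):
        res = dunn_posthoc([1.0, 1.0, 1.0], [1.0, 1.0], [1.0, 1.0, 1.0])
        assert np.allclose(res.z, 0.0)
        assert np.allclose(res.p_bonferroni, 1.0)

    def test_antisymmetry_under_group_swap(self, rng):
        a, b, c = (rng.standard_normal(6) for _ in range(3))
        r1 = dunn_posthoc(a, b, c)
        r2 = dunn_posthoc(b, a, c)
        # pair (0,1) flips sign; p unchanged
        assert r1.z[0] == pytest.approx(-r2.z[0], abs=1e-12)
        assert np.allclose(np.sort(r1.p_raw), np.sort(r2.p_raw), atol=1e-12)

    def test_matches_formula_oracle_with_ties(self, rng):
        groups = [rng.integers(0, 5, 7).astype(float) for _ in range(3)]
        res = dunn_posthoc(*groups)
        oracle = self._dunn_oracle(groups)
        for (i, j), z in zip(res.pairs, res.z):
            assert z == pytest.approx(oracle[(i, j)], abs=1e-10)
        assert np.allclose(res.p_bonferroni, np.minimum(1.0, res.p_raw * 3))


class TestSpearmanBoot:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        res = spearman_boot(x, x, seed=0)
        assert res.rho == pytest.approx(1.0)
        assert res.ci == (pytest.approx(1.0), pytest.approx(1.0))
        res_neg = spearman_boot(x, -x, seed=0)
        assert res_neg.rho == pytest.approx(-1.0)

    def test_seed_determinism_and_ci_bounds(self, rng):
        x = rng.standard_normal(30)
        y = 0.5 * x + rng.standard_normal(30)
        r1 = spearman_boot(x, y, seed=42)
        r2 = spearman_boot(x, y, seed=42)
        assert r1.ci == r2.ci
        assert -1.0 <= r1.ci[0] <= r1.rho <= r1.ci[1] <= 1.0

    def test_pairwise_complete_deletion(self, rng):
        x = rng.standard_normal(20)
        y = x.copy()
        x[3] = np.nan
        res = spearman_boot(x, y, seed=0)
        assert res.n == 19 and res.rho == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError):
            spearman_boot(np.ones(10), np.arange(10.0))


class TestMediation:
    def test_te_equals_de_plus_ie(self, rng):
        n = 50
        x = rng.standard_normal(n)
        m = 0.5 * x + rng.standard_normal(n)
        y = 0.3 * x + 0.4 * m + rng.standard_normal(n)
        res = mediate(x, m, y, n_boot=200, seed=0)
        assert res.te == pytest.approx(res.de + res.ie, abs=1e-10)

    def test_known_truth_recovery(self):
        # a = b = 0.5, noise SD 1 -> IE = 0.25; average over replicates
        rng = np.random.default_rng(99)
        ies = []
        for _ in range(20):
            n = 60
            x = rng.standard_normal(n)
            m = 0.5 * x + rng.standard_normal(n)
            y = 0.5 * m + rng.standard_normal(n)
            ies.append(mediate(x, m, y, n_boot=200, seed=1).ie)
        assert np.mean(ies) == pytest.approx(0.25, abs=0.08)

    def test_null_ie_ci_coverage(self):
        # b = 0 in truth -> IE CI should cover 0 ~95% of the time
        rng = np.random.default_rng(7)
        cover = 0
        n_rep = 200
        for _ in range(n_rep):
            n = 40
            x = rng.standard_normal(n)
            m = 0.6 * x + rng.standard_normal(n)
            y = 0.5 * x + rng.standard_normal(n)  # y independent of m given x
            res = mediate(x, m, y, n_boot=300, seed=3)
            if res.ie_ci[0] <= 0.0 <= res.ie_ci[1]:
                cover += 1
        assert cover / n_rep == pytest.approx(0.95, abs=0.05)

    def test_binary_group_dummy_x(self, rng):
        x = np.repeat([0.0, 1.0], 20)
        m = 1.0 * x + rng.standard_normal(40)
        y = 2.0 * x + 0.5 * m + rng.standard_normal(40)
        res = mediate(x, m, y, n_boot=200, seed=0)
        assert res.te == pytest.approx(res.de + res.ie, abs=1e-10)
        assert res.ie > 0

    def test_collinear_rejected(self):
        x = np.arange(20.0)
        with pytest.raises(ValueError):
            mediate(x, 2 * x, np.random.default_rng(0).standard_normal(20))


class TestFSSRegression:
    def test_orthogonal_predictors_give_marginal_correlations(self, rng):
        n = 400
        b = rng.standard_normal(n)
        b -= b.mean()
        m = rng.standard_normal(n)
        m -= m.mean()
        # orthogonalize the centered predictors exactly (zero correlation)
        m = m - (m @ b) / (b @ b) * b
        f = 0.4 * b - 0.3 * m + rng.standard_normal(n)
        res = fss_regression(f, b, m)
        rb = np.corrcoef(f, b)[0, 1]
        rm = np.corrcoef(f, m)[0, 1]
        assert res.beta["beta_depth"] == pytest.approx(rb, abs=1e-10)
        assert res.beta["MADRS"] == pytest.approx(rm, abs=1e-10)

    def test_exact_linear_combination_flagged(self, rng):
        n = 30
        b = rng.standard_normal(n)
        m = rng.standard_normal(n)
        f = 1.0 * b - 2.0 * m
        res = fss_regression(f, b, m)
        assert res.r2 == pytest.approx(1.0, abs=1e-9)
        assert np.isinf(res.f)

    def test_statsmodels_cross_check(self, rng):
        import statsmodels.api as sm
        n = 35
        b = rng.standard_normal(n)
        m = 0.3 * b + rng.standard_normal(n)
        f = -0.4 * b + 0.5 * m + rng.standard_normal(n)
        res = fss_regression(f, b, m)
        z = lambda v: (v - v.mean()) / v.std(ddof=1)
        sm_fit = sm.OLS(z(f), sm.add_constant(np.column_stack([z(b), z(m)]))).fit()
        assert res.beta["beta_depth"] == pytest.approx(sm_fit.params[1], abs=1e-10)
        assert res.t["MADRS"] == pytest.approx(sm_fit.tvalues[2], abs=1e-8)
        assert res.f == pytest.approx(sm_fit.fvalue, rel=1e-8)
        assert res.df == (2, n - 3)

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError):
            fss_regression([1.0, 2, 3], [1.0, 2, 3], [3.0, 2, 1])


class TestChiSquare:
    def test_equal_proportions_zero(self):
        stat, p = chi_square_sex([[10, 10], [5, 5], [20, 20]])
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_matches_hand_computed_pearson(self):
        table = np.array([[13, 6], [11, 11], [11, 7]], dtype=float)
        stat, _ = chi_square_sex(table)
        exp = np.outer(table.sum(1), table.sum(0)) / table.sum()
        assert stat == pytest.approx(((table - exp) ** 2 / exp).sum(), abs=1e-10)

    def test_statistic_grows_with_n(self):
        s1, _ = chi_square_sex([[8, 2], [4, 6]])
        s2, _ = chi_square_sex([[80, 20], [40, 60]])
        assert s2 == pytest.approx(10 * s1, rel=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_sex([[0, 0], [3, 4]])


def test_kw_dunn_chain_type_i_error_at_nominal_level():
    # familywise error of the gated chain (Dunn only after KW rejects) on
    # null data stays at or below alpha, within Monte-Carlo tolerance
    rng = np.random.default_rng(314)
    n_rep = 1000
    kw_rej = 0
    chain_rej = 0
    for _ in range(n_rep):
        groups = [rng.standard_normal(n) for n in (16, 19, 17)]
        kw = kruskal_wallis(*groups)
        if kw.p < 0.05:
            kw_rej += 1
            dunn = dunn_posthoc(*groups)
            if (dunn.p_bonferroni < 0.05).any():
                chain_rej += 1
    assert kw_rej / n_rep <= 0.05 + 0.02
    assert chain_rej / n_rep <= 0.05 + 0.02


def test_bonferroni_primary_three_measures():
    ps = {"erd": 0.02, "ers": 0.5, "depth": 0.004}
    corr = bonferroni_primary(ps)
    assert corr["erd"] == pytest.approx(0.06)
    assert corr["ers"] == 1.0
    assert corr["depth"] == pytest.approx(0.012)
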