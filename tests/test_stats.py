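import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenoconv.stats import (
    StatsError,
    bh_flags,
    choose_test,
    chi_squared,
    compare_phenotype_distributions,
    crude_or,
    dichotomize_outcome,
    fisher_exact,
    logistic_mle,
    prevalence_test,
    rank_tests,
)

cells = st.integers(min_value=0, max_value=40)
tables_2x2 = st.tuples(cells, cells, cells, cells).map(
    lambda t: [[t[0], t[1]], [t[2], t[3]]]
)


def fisher_oracle(table):
    """Independent two-sided Fisher by exact-Fraction enumeration."""
    (a, b), (c, d) = table
    n, r1, r2, c1 = a + b + c + d, a + b, c + d, a + c
    if n == 0:
        return 1.0
    denom = math.comb(n, c1)
    probs = {
        k: Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)
        for k in range(max(0, c1 - r2), min(r1, c1) + 1)
    }
    obs = probs[a]
    return float(sum(v for v in probs.values() if v <= obs))


class TestDichotomize:
    def test_collapse(self):
        assert dichotomize_outcome("low") == 0
        assert dichotomize_outcome("moderate") == 1
        assert dichotomize_outcome("high") == 1
        with pytest.raises(StatsError):
            dichotomize_outcome("extreme")

    def test_category_counts_collapse_to_published_2x2(self):
        """Moderate+high vs low on the polypharmacy category counts
        (yes: 14/22/27, no: 23/12/6) gives [[49,14],[18,23]]."""
        yes, no = (14, 22, 27), (23, 12, 6)
        table = [[yes[1] + yes[2], yes[0]], [no[1] + no[2], no[0]]]
        assert table == [[49, 14], [18, 23]]


class TestCrudeOR:
    def test_polypharmacy_or(self):
        res = crude_or([[49, 14], [18, 23]])
        assert round(res.odds_ratio, 2) == 4.47
        assert round(res.ci_low, 2) == 1.90
        assert round(res.ci_high, 2) == 10.53
        assert not res.correction_applied

    def test_diagnosis_or(self):
        res = crude_or([[28, 8], [39, 29]])
        assert round(res.odds_ratio, 2) == 2.60
        assert round(res.ci_low, 2) == 1.04
        assert round(res.ci_high, 2) == 6.54

    @pytest.mark.parametrize("k", [1, 5, 20])
    def test_balanced_table_is_null(self, k):
        res = crude_or([[k, k], [k, k]])
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.ci_low * res.ci_high == pytest.approx(1.0)  # symmetric on log scale

    def test_agrees_with_direct_log_scale_formula(self):
        a, b, c, d = 3, 1, 1, 7
        res = crude_or([[a, b], [c, d]])
        log_or = math.log(a) - math.log(b) - math.log(c) + math.log(d)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert res.odds_ratio == pytest.approx(math.exp(log_or))
        assert res.ci_low == pytest.approx(math.exp(log_or - 1.96 * se))
        assert res.ci_high == pytest.approx(math.exp(log_or + 1.96 * se))

    def test_zero_cell_gets_haldane_anscombe(self):
        res = crude_or([[5, 0], [3, 4]])
        assert res.correction_applied
        ref = crude_or([[5.5, 0.5], [3.5, 4.5]])  # no zero: no further correction
        assert res.odds_ratio == pytest.approx(ref.odds_ratio)

    def test_zero_margin_undefined(self):
        res = crude_or([[0, 0], [3, 4]])
        assert not res.defined and math.isnan(res.odds_ratio)

    @given(tables_2x2)
    @settings(max_examples=200, derandomize=True)
    def test_invariance_and_ci_p_consistency(self, table):
        res = crude_or(table)
        if not res.defined:
            return
        # simultaneous row and column swap leaves the OR unchanged
        (a, b), (c, d) = table
        swapped = crude_or([[d, c], [b, a]])
        assert swapped.odds_ratio == pytest.approx(res.odds_ratio)
        # transposition too (ad/bc is symmetric)
        assert crude_or([[a, c], [b, d]]).odds_ratio == pytest.approx(res.odds_ratio)
        # Wald CI excludes 1 iff Wald p < 0.05
        excludes_one = res.ci_low > 1 or res.ci_high < 1
        assert excludes_one == (res.p_value < 0.05)


class TestFisherExact:
    def test_nausea_table(self):
        assert fisher_exact([[1, 10], [3, 1]]) == pytest.approx(0.033, abs=5e-4)

    @pytest.mark.parametrize("n, m", [(3, 4), (0, 5), (7, 0)])
    def test_constant_column_is_uninformative(self, n, m):
        assert fisher_exact([[0, n], [0, m]]) == 1.0

    @given(tables_2x2)
    @settings(max_examples=300, derandomize=True)
    def test_matches_enumeration_oracle(self, table):
        assert fisher_exact(table) == pytest.approx(fisher_oracle(table), abs=1e-12)

    @given(tables_2x2)
    @settings(max_examples=100, derandomize=True)
    def test_matches_scipy_reference(self, table):
        from scipy.stats import fisher_exact as scipy_fisher

        assert fisher_exact(table) == pytest.approx(
            scipy_fisher(table).pvalue, abs=1e-7
        )


class TestChiSquared:
    def test_um_proportion_comparison_significant(self):
        # 10/117 UMs in the cohort vs 33/820 in the reference population
        res = chi_squared([[10, 107], [33, 787]])
        assert res.p_value < 0.05

    def test_perfect_independence(self):
        res = chi_squared([[10, 20], [20, 40]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(StatsError):
            chi_squared([[0, 0], [3, 4]])

    @given(st.tuples(*(st.integers(1, 30),) * 4))
    @settings(max_examples=100, derandomize=True)
    def test_equals_squared_two_proportion_z(self, t):
        """On a 2x2 table the Pearson statistic equals the squared pooled
        two-proportion z statistic (algebraic identity)."""
        a, b, c, d = t
        res = chi_squared([[a, b], [c, d]])
        n1, n2 = a + b, c + d
        p1, p2, p = a / n1, c / n2, (a + c) / (n1 + n2)
        if p in (0.0, 1.0):
            return
        z = (p1 - p2) / math.sqrt(p * (1 - p) * (1 / n1 + 1 / n2))
        assert res.statistic == pytest.approx(z**2, rel=1e-9)

    def test_small_count_rule(self):
        assert choose_test([[1, 10], [3, 1]]) == "fisher_exact"
        assert choose_test([[20, 30], [25, 35]]) == "chi_squared"
        p, used = prevalence_test([[1, 10], [3, 1]])
        assert used == "fisher_exact" and p == pytest.approx(0.033, abs=5e-4)


class TestRankTests:
    def test_identical_groups(self):
        res = rank_tests([[1, 2, 3, 4], [1, 2, 3, 4]])
        assert res.test_used == "mann_whitney"
        assert res.p_value == pytest.approx(1.0)

    def test_three_groups_use_kruskal_wallis(self):
        res = rank_tests([[1, 2], [3, 4], [5, 6]])
        assert res.test_used == "kruskal_wallis"

    def test_empty_group_rejected(self):
        with pytest.raises(StatsError):
            rank_tests([[1, 2], []])

    def test_close_to_exact_permutation_enumeration(self):
        """Asymptotic Mann-Whitney p within 0.01 of the exact permutation
        distribution of the U statistic on a small fixture."""
        rng = np.random.default_rng(7)
        g1, g2 = rng.normal(0, 1, 6), rng.normal(0.8, 1, 6)
        approx = rank_tests([list(g1), list(g2)]).p_value
        pooled = np.concatenate([g1, g2])
        n1 = len(g1)
        u_obs = sum(x > y for x in g1 for y in g2) + 0.5 * sum(x == y for x in g1 for y in g2)
        center = n1 * len(g2) / 2
        count = total = 0
        for idx in itertools.combinations(range(len(pooled)), n1):
            a = pooled[list(idx)]
            b = np.delete(pooled, list(idx))
            u = sum(x > y for x in a for y in b)
            count += abs(u - center) >= abs(u_obs - center) - 1e-12
            total += 1
        assert approx == pytest.approx(count / total, abs=0.01)


class TestLogisticMLE:
    def test_single_binary_covariate_reproduces_crude_or(self):
        a, b, c, d = 49, 14, 18, 23
        y = np.array([1] * a + [0] * b + [1] * c + [0] * d)
        x = np.array([1.0] * (a + b) + [0.0] * (c + d))
        fit = logistic_mle(y, pd.DataFrame({"x": x}))
        row = fit.results().iloc[0]
        ref = crude_or([[a, b], [c, d]])
        assert row["odds_ratio"] == pytest.approx(ref.odds_ratio, abs=1e-6)
        assert row["ci_low"] == pytest.approx(ref.ci_low, abs=1e-6)
        assert row["ci_high"] == pytest.approx(ref.ci_high, abs=1e-6)
        assert not fit.separation

    def test_matches_statsmodels_reference(self):
        rng = np.random.default_rng(42)
        x1 = rng.normal(size=200)
        x2 = (rng.random(200) < 0.4).astype(float)
        p = 1 / (1 + np.exp(-(-0.3 + 0.7 * x1 - 0.5 * x2)))
        y = (rng.random(200) < p).astype(float)
        X = pd.DataFrame({"x1": x1, "x2": x2})
        fit = logistic_mle(y, X)
        import statsmodels.api as sm

        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert fit.coef == pytest.approx(ref.params.to_numpy(), abs=1e-6)
        assert fit.se == pytest.approx(ref.bse.to_numpy(), rel=1e-4)

    def test_quasi_separation_flagged(self):
        # 15 patients; the 3-patient exposure class has outcome 1 throughout
        y = np.array([1] * 3 + [1] * 5 + [0] * 7, dtype=float)
        x = np.array([1] * 3 + [0] * 12, dtype=float)
        fit = logistic_mle(y, pd.DataFrame({"x": x}))
        assert fit.separation

    def test_degenerate_outcome_rejected(self):
        with pytest.raises(StatsError, match="degenerate"):
            logistic_mle(np.ones(10), pd.DataFrame({"x": np.arange(10.0)}))

    def test_rank_deficient_design_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(StatsError, match="rank"):
            logistic_mle(
                np.array([0, 1] * 5), pd.DataFrame({"x": x, "x2": 2 * x})
            )


class TestPhenotypeDistributions:
    def test_um_excess_detected(self):
        cohort = {"NM": 45, "IM": 30, "PM": 5, "UM": 10}
        ref = {"NM": 400, "IM": 300, "PM": 40, "UM": 33}
        # scale cohort to the published margins for the UM row
        cohort = {**cohort, "UM": 10, "NM": 117 - 10 - 30 - 5}
        ref = {**ref, "UM": 33, "NM": 820 - 33 - 300 - 40}
        out = compare_phenotype_distributions(cohort, ref).set_index("category")
        assert out.loc["UM", "p_value"] < 0.05

    def test_identical_distributions_all_null(self):
        counts = {"NM": 50, "IM": 30, "PM": 10, "UM": 10}
        out = compare_phenotype_distributions(counts, counts)
        assert np.allclose(out["p_value"], 1.0)

    def test_category_mismatch_rejected(self):
        with pytest.raises(StatsError):
            compare_phenotype_distributions({"NM": 1}, {"IM": 1})


def test_bh_flags_do_not_alter_p_values():
    p = [0.001, 0.01, 0.04, 0.2, 0.9]
    flags = bh_flags(p)
    assert flags.dtype == bool and len(flags) == 5
    assert flags[0] and not flags[-1]
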