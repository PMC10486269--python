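"""Association statistics for the phenoconversion analysis.

The statistical layer mirrors standard epidemiological practice on small
clinical cohorts: crude odds ratios with 95% Wald confidence intervals on
the dichotomized side-effect burden (moderate+high vs low), a two-sided
point-probability Fisher exact test for sparse prevalence tables, Pearson
chi-squared for larger ones (the rule: Fisher whenever any expected cell is
below 5), Mann-Whitney / Kruskal-Wallis for score comparisons, and a
logistic maximum-likelihood fit (IRLS) for covariate-adjusted odds ratios
with explicit separation detection.  Raw p-values are reported by default;
Benjamini-Hochberg flags are available as an option and never change the
defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

Z_95 = 1.96  # fixed Wald quantile; reproduces printed 95% CI bounds


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class AssociationResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    test_used: str
    correction_applied: bool = False
    defined: bool = True  # False when a zero margin makes the OR undefined


def dichotomize_outcome(category: str) -> int:
    """Collapse the three-level UKU category to binary: low=0, moderate/high=1."""
    if category == "low":
        return 0
    if category in ("moderate", "high"):
        return 1
    raise StatsError(f"unknown category {category!r}")


def _as_2x2(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise StatsError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise StatsError("negative cell count")
    return t


def crude_or(table, z: float = Z_95) -> AssociationResult:
    """Crude odds ratio with Wald CI for a 2x2 table [[a, b], [c, d]].

    OR = ad/bc.  If any cell is zero the Haldane-Anscombe correction (+0.5
    on every cell) is applied and flagged.  A zero row or column margin
    leaves the OR undefined (``defined=False``).  The p-value is the Wald
    z-test on log OR.
    """
    t = _as_2x2(table)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return AssociationResult(
            odds_ratio=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
            p_value=float("nan"), test_used="wald_or", correction_applied=False,
            defined=False,
        )
    corrected = bool((t == 0).any())
    if corrected:
        t = t + 0.5
    a, b = t[0]
    c, d = t[1]
    log_or = math.log(a * d) - math.log(b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    p = 2 * sps.norm.sf(abs(log_or) / se)
    return AssociationResult(
        odds_ratio=math.exp(log_or),
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        p_value=float(p),
        test_used="wald_or",
        correction_applied=corrected,
    )


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table, margins fixed.

    Uses the point-probability method: sum the hypergeometric probabilities
    of every table (with the observed margins) whose probability does not
    exceed the observed table's.  Computed in exact integer arithmetic, so
    probability ties are resolved exactly rather than to floating tolerance.
    """
    t = np.asarray(table)
    _as_2x2(t)
    t = t.astype(int)
    r1, r2 = int(t[0].sum()), int(t[1].sum())
    c1 = int(t[:, 0].sum())
    n = r1 + r2
    if n == 0:
        return 1.0
    # numerator of P(k) with common denominator C(n, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    obs = math.comb(r1, int(t[0, 0])) * math.comb(r2, int(t[1, 0]))
    num = sum(
        w
        for k in range(lo, hi + 1)
        if (w := math.comb(r1, k) * math.comb(r2, c1 - k)) <= obs
    )
    return num / math.comb(n, c1)


class ChiSquaredResult(NamedTuple):
    statistic: float
    dof: int
    p_value: float


def chi_squared(table) -> ChiSquaredResult:
    """Pearson chi-squared test of independence, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise StatsError("contingency table must be 2-dimensional")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise StatsError("chi-squared undefined for a zero margin")
    stat, p, dof, _ = sps.chi2_contingency(t, correction=False)
    return ChiSquaredResult(statistic=float(stat), dof=int(dof), p_value=float(p))


def expected_counts(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    return np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()


def choose_test(table) -> str:
    """Small-count rule: Fisher if any expected cell < 5, else chi-squared."""
    return "fisher_exact" if (expected_counts(table) < 5).any() else "chi_squared"


def prevalence_test(table, rule: str = "auto") -> tuple[float, str]:
    """p-value for a 2xk prevalence table under the small-count rule.

    ``rule`` may be "auto" (expected-cell rule), "fisher_exact" or
    "chi_squared".
    """
    t = np.asarray(table, dtype=float)
    if rule == "auto":
        rule = choose_test(t)
    if rule == "fisher_exact":
        if t.shape != (2, 2):
            raise StatsError("Fisher exact implemented for 2x2 tables only")
        return fisher_exact(t), "fisher_exact"
    if rule == "chi_squared":
        return chi_squared(t).p_value, "chi_squared"
    raise StatsError(f"unknown test rule {rule!r}")


class RankTestResult(NamedTuple):
    p_value: float
    test_used: str


def rank_tests(groups: Sequence[Sequence[float]]) -> RankTestResult:
    """Nonparametric comparison of score distributions across groups.

    Two groups: Mann-Whitney U (normal approximation, tie-corrected); more
    than two: Kruskal-Wallis.  Empty groups are an error.
    """
    if len(groups) < 2:
        raise StatsError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise StatsError("empty group")
    if len(groups) == 2:
        res = sps.mannwhitneyu(groups[0], groups[1], alternative="two-sided", method="asymptotic")
        return RankTestResult(p_value=float(res.pvalue), test_used="mann_whitney")
    res = sps.kruskal(*groups)
    return RankTestResult(p_value=float(res.pvalue), test_used="kruskal_wallis")


@dataclass(frozen=True)
class LogisticFit:
    """Adjusted logistic-regression results, one row per covariate."""

    names: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    converged: bool
    separation: bool
    n_iter: int

    def results(self, z: float = Z_95) -> pd.DataFrame:
        """Per-covariate OR, Wald CI and p (intercept excluded)."""

        def _exp(x: float) -> float:  # diverged fits can overflow exp
            try:
                return math.exp(x)
            except OverflowError:
                return float("inf")

        rows = []
        for i, name in enumerate(self.names):
            if name == "const":
                continue
            b, s = float(self.coef[i]), float(self.se[i])
            p = 2 * sps.norm.sf(abs(b) / s) if s > 0 else float("nan")
            rows.append(
                {
                    "covariate": name,
                    "odds_ratio": _exp(b),
                    "ci_low": _exp(b - z * s),
                    "ci_high": _exp(b + z * s),
                    "p_value": float(p),
                    "test_used": "wald_logistic",
                    "separation_flag": self.separation,
                }
            )
        return pd.DataFrame(rows)


def logistic_mle(
    outcome: Sequence[int],
    covariates: pd.DataFrame,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> LogisticFit:
    """Binary logistic regression by iteratively reweighted least squares.

    An intercept is added automatically.  Wald standard errors come from
    the observed information at the MLE.  Quasi-separation (a diverging
    coefficient, here |beta| > 15, or failure to converge with exploding
    coefficients) sets ``separation=True``; on very small strata this
    mirrors the practice of refusing to report a logistic OR at all.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise StatsError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise StatsError("outcome is degenerate (all 0 or all 1)")
    X = np.column_stack([np.ones(len(y)), np.asarray(covariates, dtype=float)])
    names = ("const",) + tuple(covariates.columns)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise StatsError("design matrix is rank-deficient")
    beta = np.zeros(X.shape[1])
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        # information matrix X' W X; guard against numerically dead weights
        XtWX = X.T @ (X * w[:, None])
        try:
            delta = np.linalg.solve(XtWX, X.T @ (y - mu))
        except np.linalg.LinAlgError:
            break
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            converged = True
            break
    separation = bool(np.max(np.abs(beta)) > 15 or not converged)
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    cov = np.linalg.pinv(X.T @ (X * w[:, None]))
    se = np.sqrt(np.diag(cov))
    return LogisticFit(
        names=names, coef=beta, se=se, converged=converged,
        separation=separation, n_iter=n_iter,
    )


def compare_phenotype_distributions(
    cohort_counts: Mapping[str, int],
    reference_counts: Mapping[str, int],
    rule: str = "auto",
) -> pd.DataFrame:
    """Per-category comparison of two phenotype distributions.

    For each category a 2x2 table (category vs rest x population) is tested
    with the small-count rule.  Both populations must share the category
    set.  Returns one row per category with proportions and p-value.
    """
    if set(cohort_counts) != set(reference_counts):
        raise StatsError("category sets differ between populations")
    n_cohort = sum(cohort_counts.values())
    n_ref = sum(reference_counts.values())
    rows = []
    for cat in cohort_counts:
        a, c = cohort_counts[cat], reference_counts[cat]
        table = [[a, n_cohort - a], [c, n_ref - c]]
        p, used = prevalence_test(table, rule=rule)
        rows.append(
            {
                "category": cat,
                "cohort_n": a,
                "cohort_prop": a / n_cohort if n_cohort else float("nan"),
                "reference_n": c,
                "reference_prop": c / n_ref if n_ref else float("nan"),
                "p_value": p,
                "test_used": used,
            }
        )
    return pd.DataFrame(rows)


def bh_flags(p_values: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Optional Benjamini-Hochberg rejection flags (does not alter p-values)."""
    from statsmodels.stats.multitest import multipletests

    reject, _, _, _ = multipletests(p_values, alpha=alpha, method="fdr_bh")
    return reject
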