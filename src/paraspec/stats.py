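"""Enrichment and association statistics: 2x2 contingency tests with odds
ratios, Bonferroni/BH multiple-testing control, rank comparisons of tau,
and multivariate linear models of tau on expression and duplication status.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .containers import ValidationError


@dataclass
class ContingencyResult:
    """One enrichment test of a gene subset against a binary property.

    The 2x2 table rows are (in tested subset, rest of universe), columns
    are (property true, property false). The odds ratio is the sample
    cross-product ratio a*d / (b*c), reported as inf when b*c == 0.
    """

    tested_group: str
    reference_group: str
    table: np.ndarray
    pct_tested: float
    statistic: float
    p_value: float
    test_used: str
    odds_ratio: float
    bonferroni_threshold: float

    @property
    def significant(self) -> bool:
        return self.p_value < self.bonferroni_threshold


def odds_ratio_2x2(table: np.ndarray) -> float:
    a, b = float(table[0, 0]), float(table[0, 1])
    c, d = float(table[1, 0]), float(table[1, 1])
    if b * c == 0:
        return np.inf
    return (a * d) / (b * c)


def contingency_from_counts(
    n_tested: int, n_tested_prop: int, n_other: int, n_other_prop: int
) -> np.ndarray:
    """Build the 2x2 table [[a, b], [c, d]] from group sizes and property counts."""
    table = np.array(
        [
            [n_tested_prop, n_tested - n_tested_prop],
            [n_other_prop, n_other - n_other_prop],
        ],
        dtype=np.int64,
    )
    if (table < 0).any():
        raise ValidationError(f"negative cell in contingency table: {table.tolist()}")
    return table


def contingency_test(
    table: np.ndarray,
    tested_group: str = "tested",
    reference_group: str = "reference",
    n_tests_for_bonferroni: int = 1,
) -> ContingencyResult:
    """Chi-squared (no continuity correction) or, when any expected cell
    count is below 5, two-sided Fisher's exact test on a 2x2 table."""
    table = np.asarray(table, dtype=np.int64)
    if table.shape != (2, 2):
        raise ValidationError("contingency table must be 2x2")
    row = table.sum(axis=1)
    if row[0] == 0 or row[1] == 0:
        raise ValidationError("empty tested group or empty complement")
    expected = np.outer(row, table.sum(axis=0)) / table.sum()
    if (expected < 5).any():
        stat, p = sps.fisher_exact(table, alternative="two-sided")
        test_used = "fisher"
    else:
        stat, p, _, _ = sps.chi2_contingency(table, correction=False)
        test_used = "chi_squared"
    return ContingencyResult(
        tested_group=tested_group,
        reference_group=reference_group,
        table=table,
        pct_tested=100.0 * table[0, 0] / row[0],
        statistic=float(stat),
        p_value=float(p),
        test_used=test_used,
        odds_ratio=odds_ratio_2x2(table),
        bonferroni_threshold=bonferroni_threshold(0.05, n_tests_for_bonferroni),
    )


def enrichment_test(
    universe: pd.Index,
    tested: pd.Index,
    prop: pd.Series,
    tested_group: str = "tested",
    reference_group: str = "reference",
    n_tests_for_bonferroni: int = 1,
    exclude: pd.Index | None = None,
) -> ContingencyResult:
    """Enrichment of a boolean property in ``tested`` relative to the rest of
    ``universe``.

    ``exclude`` removes an explicit gene set from the universe before the
    table is built (e.g. homogeneous-family members outside their family's
    main module, which are dropped from all family-related tests).
    """
    universe = pd.Index(universe).unique()
    if exclude is not None:
        universe = universe.difference(pd.Index(exclude))
    tested = pd.Index(tested).unique().intersection(universe)
    if len(tested) == 0 or len(tested) == len(universe):
        raise ValidationError("tested group empty or equal to the universe")
    p = prop.reindex(universe)
    if p.isna().any():
        raise ValidationError("property undefined for part of the universe")
    p = p.astype(bool)
    in_tested = universe.isin(tested)
    table = contingency_from_counts(
        int(in_tested.sum()),
        int(p[in_tested].sum()),
        int((~in_tested).sum()),
        int(p[~in_tested].sum()),
    )
    return contingency_test(
        table,
        tested_group=tested_group,
        reference_group=reference_group,
        n_tests_for_bonferroni=n_tests_for_bonferroni,
    )


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance cutoff alpha / n_tests."""
    if n_tests < 1:
        raise ValidationError("n_tests must be >= 1")
    return alpha / n_tests


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def rank_compare_tau(group_a, group_b) -> dict:
    """Two-sided Mann-Whitney U (normal approximation, tie-corrected)
    comparing two tau samples; reports both medians."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be nonempty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return {
        "statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
    }


def tau_linear_model(tau: pd.Series, predictors: pd.DataFrame) -> pd.DataFrame:
    """OLS of tau on a design of expression level and class indicators.

    ``predictors`` holds the non-constant terms; an intercept is added.
    Supports designs such as max expression + paralog status over all
    genes, + duplication type within paralogs, or + age category within
    SSDs. Raises on a collinear design, naming the offending terms.
    """
    X = predictors.copy().astype(float)
    X.insert(0, "intercept", 1.0)
    y = tau.reindex(X.index).astype(float)
    if y.isna().any():
        keep = y.notna()
        X, y = X[keep], y[keep]
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        from .preprocess import _collinear_columns

        raise ValidationError(
            f"collinear model terms: {_collinear_columns(X)}"
        )
    fit = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
    return pd.DataFrame(
        {
            "term": X.columns,
            "estimate": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p_value": fit.pvalues,
        }
    ).reset_index(drop=True)
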