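"""Tau scoring, the pooled permutation null, FDR calls and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paraspec.regions import REGIONS_7
from paraspec.specificity import (
    PermutationNull,
    assign_region,
    bin_by_expression,
    call_specific,
    compute_tau,
    empirical_pvalues,
    permutation_null,
    tau_by_phyletic_age,
)


def brute_force_tau(means):
    """Independent literal evaluation of the specificity index."""
    x = [max(v, 0.0) for v in means]
    mx = max(x)
    if mx <= 0:
        return float("nan")
    return sum(1.0 - v / mx for v in x) / (len(x) - 1)


class TestComputeTau:
    @pytest.mark.parametrize(
        "means,expected",
        [
            ([1, 0, 0, 0, 0, 0, 0], 1.0),
            ([3, 3, 3, 3, 3, 3, 3], 0.0),
            ([2, 1, 1, 1, 1, 1, 1], 0.5),
            ([-1, 2, 0, 0, 0, 0, 0], 1.0),  # negative clipped to 0
        ],
    )
    def test_known_values(self, means, expected):
        assert compute_tau(np.array(means, dtype=float)) == pytest.approx(expected)

    def test_all_zero_vector_is_undefined(self):
        assert np.isnan(compute_tau(np.zeros(7)))

    def test_matrix_form_matches_vector_form(self):
        rng = np.random.default_rng(0)
        M = rng.uniform(-1, 5, size=(40, 7))
        taus = compute_tau(M)
        for i in range(40):
            assert taus[i] == pytest.approx(compute_tau(M[i]))

    @settings(deadline=None, max_examples=200)
    @given(
        st.lists(st.floats(min_value=0, max_value=100), min_size=2, max_size=9).filter(
            lambda v: max(v) > 0
        )
    )
    def test_bounds_and_oracle(self, means):
        tau = compute_tau(np.array(means))
        assert 0.0 <= tau <= 1.0 + 1e-12
        assert tau == pytest.approx(brute_force_tau(means), abs=1e-12)

    @settings(deadline=None, max_examples=100)
    @given(
        st.lists(st.floats(min_value=0.01, max_value=50), min_size=3, max_size=7),
        st.floats(min_value=0.01, max_value=100),
    )
    def test_scale_invariance(self, means, c):
        arr = np.array(means)
        if arr.max() <= 0:
            return
        assert compute_tau(arr * c) == pytest.approx(compute_tau(arr), abs=1e-9)

    def test_monotone_in_the_maximum(self):
        base = np.array([2.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        taus = [compute_tau(np.array([m, 1, 1, 1, 1, 1, 1.0])) for m in (2, 4, 8, 16)]
        assert all(b > a for a, b in zip(taus, taus[1:]))


class TestPermutationNull:
    def test_reproducible_with_seed(self, adjusted, fixture_data):
        _, samples, _, _ = fixture_data
        a = permutation_null(adjusted, samples, n_permutations=1, seed=9)
        b = permutation_null(adjusted, samples, n_permutations=1, seed=9)
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_planted_genes_exceed_extreme_null_quantile(self, tau_scored, fixture_data):
        _, _, _, truth = fixture_data
        results, null = tau_scored
        planted = truth.genes.loc[results.index, "is_region_specific"]
        q999 = np.quantile(null.pooled, 0.999)
        frac_above = (results.loc[planted, "tau"] > q999).mean()
        assert frac_above > 0.5  # strongly planted signal clears the null tail

    def test_null_matches_observed_under_no_structure(self):
        # expression with no region association: observed and permuted tau
        # distributions agree (small KS distance)
        from paraspec.containers import ExpressionMatrix
        from paraspec.preprocess import region_means
        from paraspec.regions import REGIONS_13
        from scipy.stats import ks_2samp

        rng = np.random.default_rng(4)
        n_per = 8
        samples = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(13 * n_per)],
                "region_13": np.repeat(REGIONS_13, n_per),
                "platform": "P",
                "age": 50.0,
                "sex": "f",
                "genetic_pc1": 0.0,
                "genetic_pc2": 0.0,
                "genetic_pc3": 0.0,
            }
        ).set_index("sample_id")
        vals = rng.lognormal(1.0, 0.3, size=(300, 13 * n_per))
        m = ExpressionMatrix(
            values=pd.DataFrame(vals, index=[f"g{i}" for i in range(300)],
                                columns=samples.index),
            transform_state="adjusted",
        )
        tau_obs = compute_tau(region_means(m, samples, "r7"))
        null = permutation_null(m, samples, n_permutations=30, seed=4)
        ks = ks_2samp(tau_obs, null.pooled).statistic
        assert ks < 0.1


class TestCallSpecific:
    def test_boundary_pvalues(self):
        null = PermutationNull(n_permutations=1, scores=np.linspace(0, 0.5, 100)[None, :])
        p = empirical_pvalues(np.array([0.9, 0.0]), null)
        assert p[0] == pytest.approx(1 / 101)  # above every pooled score
        assert p[1] == pytest.approx((99 + 1) / 101)  # only 0.0 itself not higher

    def test_specific_set_equals_tau_threshold_set(self, tau_scored):
        results, null = tau_scored
        called = results["is_region_specific"].astype(bool)
        assert called.any()
        thr = null.tau_threshold
        expected = results["tau"] >= thr
        pd.testing.assert_series_equal(called, expected & results["tau"].notna(),
                                       check_names=False)

    def test_flag_matches_q_value_rule(self, tau_scored):
        results, _ = tau_scored
        ok = results["q_value"].notna()
        assert (
            results.loc[ok, "is_region_specific"]
            == (results.loc[ok, "q_value"] < 0.01)
        ).all()

    def test_assigned_region_present_iff_specific(self, tau_scored):
        results, _ = tau_scored
        assert results.loc[results["is_region_specific"], "assigned_region"].notna().all()
        assert results.loc[~results["is_region_specific"], "assigned_region"].isna().all()

    def test_assigned_region_attains_max_region_mean(self, tau_scored, r7_means):
        results, _ = tau_scored
        spec = results[results["is_region_specific"]]
        clipped = r7_means.clip(lower=0)
        for g, row in spec.iterrows():
            assert clipped.loc[g, row["assigned_region"]] == pytest.approx(
                row["max_region_mean"]
            )

    def test_no_specific_genes_reports_inf_threshold(self):
        null = PermutationNull(n_permutations=1, scores=np.full((1, 50), 0.99))
        tau = pd.Series(np.full(5, 0.1), index=[f"g{i}" for i in range(5)])
        r7 = pd.DataFrame(
            np.ones((5, 7)), index=tau.index, columns=list(REGIONS_7)
        )
        results, thr = call_specific(tau, null, r7, fdr_alpha=0.01)
        assert np.isinf(thr)
        assert not results["is_region_specific"].any()


class TestAssignRegion:
    def test_argmax(self):
        row = pd.Series([5, 1, 1, 1, 1, 1, 1.0], index=list(REGIONS_7))
        assert assign_region(row) == REGIONS_7[0]

    def test_exact_tie_goes_lexicographically_first(self):
        row = pd.Series([1.0] * 7, index=list(REGIONS_7))
        assert assign_region(row) == "amygdala-hippocampus"

    def test_matches_planted_target_for_recovered_genes(self, tau_scored, fixture_data):
        _, _, _, truth = fixture_data
        results, _ = tau_scored
        planted = truth.genes.loc[results.index]
        hit = results["is_region_specific"] & planted["is_region_specific"]
        agree = (
            results.loc[hit, "assigned_region"] == planted.loc[hit, "target_region"]
        ).mean()
        assert agree >= 0.95


class TestSummaries:
    def test_expression_bins(self):
        results = pd.DataFrame(
            {
                # log2(RPKM+1) of max region mean: 0.5 RPKM -> 0.58; 127 -> 7.0
                "max_region_mean": [np.log2(1.5), np.log2(128.0), 3.2],
                "is_region_specific": [True, False, True],
            },
            index=["a", "b", "c"],
        )
        classes = pd.Series(["x", "x", "y"], index=["a", "b", "c"])
        out = bin_by_expression(results, classes)
        assert out.loc[out["gene_class"] == "x", "bin"].tolist() == ["[0,1)", "[7,inf)"]
        assert out.loc[out["gene_class"] == "y", "bin"].tolist() == ["[3,4)"]
        row = out[(out["bin"] == "[0,1)") & (out["gene_class"] == "x")].iloc[0]
        assert row["n_genes"] == 1 and row["pct_specific"] == 100.0

    def test_phyletic_age_summary_and_exclusions(self, tau_scored, fixture_data):
        _, _, annotation, truth = fixture_data
        results, _ = tau_scored
        out = tau_by_phyletic_age(results, annotation)
        assert {"phyletic_age", "n", "tau_median"} <= set(out.columns)
        # genes without a phyletic age (singletons, unannotated) are excluded
        n_with_age = annotation.loc[results.index, "phyletic_age"].notna().sum()
        assert out["n"].sum() <= n_with_age

    def test_young_ages_more_specific_than_old(self, tau_scored, fixture_data):
        # ySSDs (ages < 0.25) are planted more region-specific than oSSDs
        _, _, annotation, _ = fixture_data
        results, _ = tau_scored
        age = annotation.loc[results.index, "phyletic_age"]
        young = results.loc[age[age < 0.25].index, "tau"].median()
        old = results.loc[age[age > 0.45].index, "tau"].median()
        assert young > old
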