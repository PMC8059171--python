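"""TOM network construction, module detection, family homogeneity."""

import numpy as np
import pandas as pd
import pytest

from paraspec.containers import ExpressionMatrix, ValidationError
from paraspec.coexpression import (
    NetworkParams,
    adjacency_matrix,
    classify_families,
    homogeneity_permutation_test,
    infer_modules,
    tom_similarity,
)


def brute_force_tom(A):
    """Literal elementwise evaluation of the topological overlap formula."""
    n = A.shape[0]
    k = A.sum(axis=0)
    T = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(A[i, u] * A[u, j] for u in range(n) if u != i and u != j)
            T[i, j] = (l_ij + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return T


def expr_from_array(X, prefix="g"):
    return ExpressionMatrix(
        values=pd.DataFrame(
            X,
            index=[f"{prefix}{i}" for i in range(X.shape[0])],
            columns=[f"s{j}" for j in range(X.shape[1])],
        ),
        transform_state="adjusted",
    )


class TestTom:
    @pytest.mark.parametrize("n_genes", [3, 7, 10])
    def test_matches_brute_force(self, n_genes):
        rng = np.random.default_rng(n_genes)
        X = rng.normal(size=(n_genes, 25))
        A = adjacency_matrix(X, beta=6)
        np.testing.assert_allclose(tom_similarity(A), brute_force_tom(A), atol=1e-12)

    def test_three_gene_hand_set_correlations(self):
        # construct data whose correlation structure is exactly known:
        # g0 = g1 (cor 1), g2 independent in expectation
        X = np.array(
            [[1.0, 2, 3, 4, 5, 6], [1.0, 2, 3, 4, 5, 6], [1.0, -1, 1, -1, 1, -1]]
        )
        A = adjacency_matrix(X, beta=6)
        T = tom_similarity(A)
        np.testing.assert_allclose(T, brute_force_tom(A), atol=1e-12)
        assert T[0, 1] > 0.99  # near-maximal overlap for the identical pair

    def test_symmetry_range_and_unit_diagonal(self):
        rng = np.random.default_rng(2)
        A = adjacency_matrix(rng.normal(size=(8, 30)), beta=6)
        T = tom_similarity(A)
        np.testing.assert_allclose(T, T.T)
        assert np.diag(T) == pytest.approx(1.0)
        assert (T >= 0).all() and (T <= 1 + 1e-12).all()


def two_block_data(n_per_block=6, n_samples=40, noise=1e-3, seed=0):
    rng = np.random.default_rng(seed)
    latents = rng.normal(size=(2, n_samples))
    X = np.vstack(
        [latents[b] + noise * rng.normal(size=(n_per_block, n_samples)) for b in (0, 1)]
    )
    return X


class TestInferModules:
    def test_two_planted_blocks_recovered_exactly(self):
        X = two_block_data()
        modules = infer_modules(expr_from_array(X), NetworkParams(soft_power=6))
        labels = modules.to_numpy()
        assert set(labels) == {1, 2}
        assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1
        assert labels[0] != labels[6]

    def test_uncorrelated_genes_stay_unassigned(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 60))
        modules = infer_modules(expr_from_array(X), NetworkParams(soft_power=6))
        assert (modules == 0).all()

    def test_gene_order_invariance_up_to_relabeling(self):
        X = two_block_data(n_per_block=5, seed=3)
        m1 = infer_modules(expr_from_array(X), NetworkParams(soft_power=6))
        perm = np.random.default_rng(0).permutation(X.shape[0])
        m2 = infer_modules(expr_from_array(X[perm]), NetworkParams(soft_power=6))
        # same partition: co-membership matrices agree after inverse permutation
        a = m1.to_numpy()
        b = m2.to_numpy()[np.argsort(perm)]
        co_a = (a[:, None] == a[None, :]) & (a[:, None] != 0)
        co_b = (b[:, None] == b[None, :]) & (b[:, None] != 0)
        np.testing.assert_array_equal(co_a, co_b)

    def test_constant_gene_is_an_error(self):
        X = two_block_data()
        X[3] = 1.0
        with pytest.raises(ValidationError, match="constant"):
            infer_modules(expr_from_array(X), NetworkParams(soft_power=6))


def make_annotation(families):
    """families: {family_id: (member_ids, n_total)} -> annotation frame."""
    rows = []
    for fam, (members, n_total) in families.items():
        for g in members:
            rows.append(
                {
                    "gene_id": g,
                    "status": "paralog",
                    "dup_category": "SSD",
                    "ssd_age": "ySSD",
                    "family_id": fam,
                    "family_total_size": n_total,
                    "phyletic_age": 0.1,
                    "chrom": "chr1",
                    "start": 1000,
                }
            )
    return pd.DataFrame(rows).set_index("gene_id")


class TestClassifyFamilies:
    def test_full_family_in_one_module_is_homogeneous(self):
        ann = make_annotation({"f": (["a", "b"], 2)})
        modules = pd.Series({"a": 7, "b": 7})
        fams, excluded = classify_families(modules, ann)
        assert fams.loc["f", "status"] == "homogeneous"
        assert fams.loc["f", "fraction"] == 1.0
        assert len(excluded) == 0

    def test_exact_sixty_percent_is_heterogeneous(self):
        # 3 of 5 members co-modular: 0.60 is NOT strictly above 0.60
        ann = make_annotation({"f": ([f"g{i}" for i in range(5)], 5)})
        modules = pd.Series({"g0": 4, "g1": 4, "g2": 4, "g3": 9, "g4": 2})
        fams, _ = classify_families(modules, ann)
        assert fams.loc["f", "fraction"] == pytest.approx(0.6)
        assert fams.loc["f", "status"] == "heterogeneous"

    def test_unexpressed_member_counts_in_denominator(self):
        # family of 3 with only 2 expressed, both in module 4: 2/3 > 0.60
        ann = make_annotation({"f": (["a", "b"], 3)})
        modules = pd.Series({"a": 4, "b": 4})
        fams, _ = classify_families(modules, ann)
        assert fams.loc["f", "status"] == "homogeneous"
        assert fams.loc["f", "n_total"] == 3 and fams.loc["f", "n_expressed"] == 2

    def test_modal_tie_is_heterogeneous(self):
        ann = make_annotation({"f": (["a", "b", "c", "d"], 4)})
        modules = pd.Series({"a": 1, "b": 1, "c": 2, "d": 2})
        fams, _ = classify_families(modules, ann)
        assert fams.loc["f", "status"] == "heterogeneous"

    def test_grey_labels_never_form_a_main_module(self):
        ann = make_annotation({"f": (["a", "b", "c"], 3)})
        modules = pd.Series({"a": 0, "b": 0, "c": 0})
        fams, _ = classify_families(modules, ann)
        assert fams.loc["f", "status"] == "heterogeneous"

    def test_excluded_set_is_outside_main_module(self):
        ann = make_annotation({"f": (["a", "b", "c", "d"], 4)})
        modules = pd.Series({"a": 5, "b": 5, "c": 5, "d": 8})
        fams, excluded = classify_families(modules, ann)
        assert fams.loc["f", "status"] == "homogeneous"
        assert list(excluded) == ["d"]

    def test_every_family_with_expressed_members_is_classified(
        self, fixture_data, adjusted
    ):
        _, _, ann, _ = fixture_data
        paralogs = ann.index[ann["status"] == "paralog"].intersection(adjusted.gene_ids)
        modules = infer_modules(
            adjusted.with_values(adjusted.values.loc[paralogs], "adjusted"),
            NetworkParams(),
        )
        fams, _ = classify_families(modules, ann)
        has_fam = ann["family_id"].notna()
        n_with_expressed = sum(
            len(members.index.intersection(modules.index)) > 0
            for _, members in ann[has_fam].groupby("family_id")
        )
        assert len(fams) == n_with_expressed
        assert set(fams["status"]) <= {"homogeneous", "heterogeneous"}


class TestHomogeneityPermutation:
    def test_extreme_observation_bounds_p(self):
        # many perfectly co-modular families: observed count beats every null
        families = {f"f{i}": ([f"a{i}", f"b{i}"], 2) for i in range(30)}
        ann = make_annotation(families)
        modules = pd.Series(
            {g: i + 1 for i, fam in enumerate(families.values()) for g in fam[0]}
        )
        out = homogeneity_permutation_test(modules, ann, n_permutations=1000, seed=0)
        assert out["observed_count"] == 30
        assert (out["null_counts"] < 30).all()
        assert out["empirical_p"] <= 1 / 1001

    def test_single_permutation_support(self):
        ann = make_annotation({"f": (["a", "b"], 2)})
        modules = pd.Series({"a": 1, "b": 1})
        out = homogeneity_permutation_test(modules, ann, n_permutations=1, seed=0)
        assert out["empirical_p"] in (0.5, 1.0)

    def test_random_labels_give_unremarkable_p(self):
        rng = np.random.default_rng(8)
        families = {f"f{i}": ([f"a{i}", f"b{i}"], 2) for i in range(40)}
        ann = make_annotation(families)
        genes = [g for fam in families.values() for g in fam[0]]
        ps = []
        for rep in range(5):
            labels = rng.integers(1, 15, size=len(genes))
            modules = pd.Series(labels, index=genes)
            out = homogeneity_permutation_test(modules, ann, n_permutations=100, seed=rep)
            ps.append(out["empirical_p"])
        assert 0.05 < np.median(ps) <= 1.0
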