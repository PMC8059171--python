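"""Family region-specificity, reciprocal pair filtering, genomic distances."""

import numpy as np
import pandas as pd
import pytest

from paraspec.families_pairs import (
    build_pairs,
    classify_distance,
    classify_family_specificity,
    pair_shared_specificity,
)


def results_frame(spec_map):
    """gene -> assigned region (None = not specific) into a tau result frame."""
    rows = {
        g: {
            "is_region_specific": region is not None,
            "assigned_region": region if region else pd.NA,
        }
        for g, region in spec_map.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def annotation_frame(families):
    rows = []
    for fam, members in families.items():
        for g in members:
            rows.append(
                {"gene_id": g, "status": "paralog", "dup_category": "SSD",
                 "ssd_age": "ySSD", "family_id": fam, "family_total_size": len(members),
                 "phyletic_age": 0.1, "chrom": "chr1", "start": 0}
            )
    return pd.DataFrame(rows).set_index("gene_id")


class TestFamilySpecificity:
    def test_both_members_same_region_is_specific(self):
        ann = annotation_frame({"f": ["a", "b"]})
        res = results_frame({"a": "cerebellum", "b": "cerebellum"})
        out = classify_family_specificity(res, ann)
        assert out.loc["f", "status"] == "region_specific"
        assert out.loc["f", "major_region"] == "cerebellum"

    def test_half_specific_is_not_a_strict_majority(self):
        ann = annotation_frame({"f": ["a", "b", "c", "d"]})
        res = results_frame({"a": "cortex", "b": "cortex", "c": None, "d": None})
        out = classify_family_specificity(res, ann)
        assert out.loc["f", "status"] == "not_region_specific"  # 2 > 0.5*4 fails

    def test_modal_region_tie_disqualifies(self):
        ann = annotation_frame({"f": ["a", "b", "c"]})
        res = results_frame({"a": "cortex", "b": "cerebellum", "c": "hypothalamus"})
        out = classify_family_specificity(res, ann)
        assert out.loc["f", "status"] == "not_region_specific"

    def test_member_order_invariance(self):
        ann = annotation_frame({"f": ["a", "b", "c"]})
        res = results_frame({"a": "cortex", "b": "cortex", "c": None})
        out1 = classify_family_specificity(res, ann)
        out2 = classify_family_specificity(res.iloc[::-1], ann)
        pd.testing.assert_frame_equal(out1, out2)

    def test_major_members_are_specific_in_gene_results(self, tau_scored, fixture_data):
        # cross-module consistency: a region-specific family's major-region
        # members must be drawn from the gene-level specific set
        _, _, ann, _ = fixture_data
        results, _ = tau_scored
        fams = classify_family_specificity(results, ann)
        spec_fams = fams[fams["status"] == "region_specific"]
        for fam_id, row in spec_fams.iterrows():
            members = ann.index[ann["family_id"] == fam_id].intersection(results.index)
            in_major = results.loc[members, "assigned_region"] == row["major_region"]
            assert results.loc[members[in_major], "is_region_specific"].all()


class TestBuildPairs:
    def test_reciprocal_pair_kept_once(self):
        ann = annotation_frame({"f": ["a", "b"]})
        rows = pd.DataFrame(
            [("a", "b", "ySSD"), ("b", "a", "ySSD")],
            columns=["gene_a", "gene_b", "dup_category"],
        )
        out = build_pairs(ann, rows)
        assert len(out) == 1
        assert out.loc[0, ["gene_a", "gene_b"]].tolist() == ["a", "b"]
        assert bool(out.loc[0, "reciprocal"])

    def test_single_orientation_excluded(self):
        ann = annotation_frame({"f": ["a", "b"]})
        rows = pd.DataFrame([("a", "b", "ySSD")], columns=["gene_a", "gene_b", "dup_category"])
        assert len(build_pairs(ann, rows)) == 0

    def test_conflicting_categories_dropped(self):
        ann = annotation_frame({"f": ["a", "b"]})
        rows = pd.DataFrame(
            [("a", "b", "ySSD"), ("b", "a", "WGD")],
            columns=["gene_a", "gene_b", "dup_category"],
        )
        assert len(build_pairs(ann, rows)) == 0


class TestDistance:
    @pytest.mark.parametrize(
        "coord_a,coord_b,expected",
        [
            (("chr1", 1_000_000), ("chr1", 1_500_000), "tandem"),
            (("chr1", 0), ("chr2", 0), "inter_chromosomal"),
            (("chr1", 0), ("chr1", 5_000_000), "intra_chromosomal"),
        ],
    )
    def test_distance_classes(self, coord_a, coord_b, expected):
        ann = annotation_frame({"f": ["a", "b"]})
        ann.loc["a", ["chrom", "start"]] = coord_a
        ann.loc["b", ["chrom", "start"]] = coord_b
        pairs = pd.DataFrame(
            [("a", "b", "ySSD", True)],
            columns=["gene_a", "gene_b", "dup_category", "reciprocal"],
        )
        out = classify_distance(pairs, ann)
        assert out.loc[0, "distance_class"] == expected

    def test_partition_is_exhaustive_on_fixture(self, fixture_data):
        _, _, ann, truth = fixture_data
        pairs = build_pairs(ann, truth.pair_rows)
        out = classify_distance(pairs, ann)
        assert set(out["distance_class"]) <= {
            "tandem", "intra_chromosomal", "inter_chromosomal"
        }
        assert out["distance_class"].notna().all()

    def test_simulated_distances_match_ground_truth(self, fixture_data):
        _, _, ann, truth = fixture_data
        pairs = classify_distance(build_pairs(ann, truth.pair_rows), ann)
        merged = pairs.merge(truth.pairs, on=["gene_a", "gene_b"], suffixes=("", "_true"))
        assert (merged["distance_class"] == merged["distance_class_true"]).all()


class TestPairSharedSpecificity:
    def test_counting_rules(self):
        pairs = pd.DataFrame(
            [
                ("a", "b", "ySSD", True),  # both specific, same region
                ("c", "d", "ySSD", True),  # both specific, different regions
                ("e", "f", "ySSD", True),  # one non-specific -> excluded
            ],
            columns=["gene_a", "gene_b", "dup_category", "reciprocal"],
        )
        res = results_frame(
            {"a": "cortex", "b": "cortex", "c": "cortex", "d": "cerebellum",
             "e": "cortex", "f": None}
        )
        out = pair_shared_specificity(pairs, res)
        row = out.loc["ySSD"]
        assert row["n_pairs"] == 3
        assert row["n_both_specific"] == 2
        assert row["n_same_region"] == 1
        assert row["pct_same_region"] == pytest.approx(50.0)

    def test_planted_yssd_pairs_share_regions_more_than_wgd(
        self, tau_scored, fixture_data
    ):
        _, _, ann, truth = fixture_data
        results, _ = tau_scored
        pairs = build_pairs(ann, truth.pair_rows)
        out = pair_shared_specificity(pairs, results)
        assert out.loc["ySSD", "pct_same_region"] > out.loc["WGD", "pct_same_region"]
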