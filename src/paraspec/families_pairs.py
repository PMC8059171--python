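"""Family-level region-specificity and paralog-pair genomic-distance
analyses.

A family is *region-specific* when strictly more than half of its
EXPRESSED members are declared region-specific to the same region (the
modal region among its specific members; a modal tie disqualifies the
family). The majority fraction is configurable.

Duplicate pairs are retained only when listed reciprocally (a->b and b->a)
with the same duplication category in both orientations. Pair genomic
distance uses gene start coordinates: different chromosomes ->
inter-chromosomal; same chromosome and |delta start| < 1 Mb -> tandem;
otherwise intra-chromosomal.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import ValidationError

log = logging.getLogger(__name__)


def classify_family_specificity(
    results: pd.DataFrame,
    annotation: pd.DataFrame,
    majority_fraction: float = 0.5,
) -> pd.DataFrame:
    """Per-family region-specificity from per-gene specificity calls.

    ``results`` is the per-gene tau result table (is_region_specific,
    assigned_region). Only families with >= 1 expressed member appear.
    """
    has_family = annotation["family_id"].notna() & (annotation["family_id"].astype(str) != "")
    rows = []
    for family_id, members in annotation.loc[has_family].groupby("family_id"):
        expressed = members.index.intersection(results.index)
        if len(expressed) == 0:
            continue
        res = results.loc[expressed]
        spec = res[res["is_region_specific"].astype(bool)]
        n_specific = len(spec)
        major_region, n_in_major = pd.NA, 0
        if n_specific:
            counts = spec["assigned_region"].value_counts()
            top = counts.max()
            modal = counts.index[counts == top]
            if len(modal) == 1:
                major_region, n_in_major = modal[0], int(top)
        status = (
            "region_specific"
            if n_in_major > majority_fraction * len(expressed)
            else "not_region_specific"
        )
        rows.append(
            {
                "family_id": family_id,
                "n_expressed": len(expressed),
                "n_specific": n_specific,
                "major_region": major_region,
                "n_in_major": n_in_major,
                "status": status,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["family_id", "n_expressed", "n_specific", "major_region", "n_in_major", "status"],
    )
    return out.set_index("family_id")


def build_pairs(annotation: pd.DataFrame, pair_rows: pd.DataFrame) -> pd.DataFrame:
    """Reciprocal duplicate pairs from raw (gene_a, gene_b, category) rows.

    A pair is kept iff both orientations are present with the same
    category; orientation conflicts are dropped and logged. Output is
    deduplicated with gene_a < gene_b lexicographically.
    """
    seen: dict[tuple[str, str], set[str]] = {}
    for row in pair_rows.itertuples(index=False):
        a, b, cat = str(row.gene_a), str(row.gene_b), str(row.dup_category)
        if a == b:
            continue
        seen.setdefault((a, b), set()).add(cat)
    records = []
    for (a, b), cats in seen.items():
        if a > b:
            continue  # handled from the canonical orientation
        back = seen.get((b, a))
        if back is None:
            continue  # not reciprocal
        if len(cats) > 1 or len(back) > 1 or cats != back:
            log.info("pair (%s, %s) dropped: conflicting categories %s vs %s", a, b, cats, back)
            continue
        records.append({"gene_a": a, "gene_b": b, "dup_category": next(iter(cats)),
                        "reciprocal": True})
    out = pd.DataFrame(records, columns=["gene_a", "gene_b", "dup_category", "reciprocal"])
    return out.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)


def classify_distance(
    pairs: pd.DataFrame, annotation: pd.DataFrame, tandem_bp: int = 1_000_000
) -> pd.DataFrame:
    """Add a distance_class column: tandem | intra_chromosomal |
    inter_chromosomal, or 'unknown' when coordinates are missing."""
    out = pairs.copy()
    classes = []
    for row in out.itertuples(index=False):
        cls = "unknown"
        if row.gene_a in annotation.index and row.gene_b in annotation.index:
            ca, cb = annotation.loc[row.gene_a, "chrom"], annotation.loc[row.gene_b, "chrom"]
            sa, sb = annotation.loc[row.gene_a, "start"], annotation.loc[row.gene_b, "start"]
            if pd.notna(ca) and pd.notna(cb) and pd.notna(sa) and pd.notna(sb):
                if ca != cb:
                    cls = "inter_chromosomal"
                elif abs(int(sa) - int(sb)) < tandem_bp:
                    cls = "tandem"
                else:
                    cls = "intra_chromosomal"
        classes.append(cls)
    out["distance_class"] = classes
    n_unknown = classes.count("unknown")
    if n_unknown:
        log.info("classify_distance: %d pairs without coordinates excluded", n_unknown)
    return out


def pair_shared_specificity(pairs: pd.DataFrame, results: pd.DataFrame) -> pd.DataFrame:
    """Per duplication category: among pairs with both members declared
    region-specific, the fraction assigned to the same region.

    Counts are reported alongside the fraction so small denominators stay
    visible.
    """
    rows = []
    for cat, sub in pairs.groupby("dup_category"):
        n_pairs = len(sub)
        both = same = 0
        for row in sub.itertuples(index=False):
            if row.gene_a not in results.index or row.gene_b not in results.index:
                continue
            ra, rb = results.loc[row.gene_a], results.loc[row.gene_b]
            if bool(ra["is_region_specific"]) and bool(rb["is_region_specific"]):
                both += 1
                if ra["assigned_region"] == rb["assigned_region"]:
                    same += 1
        rows.append(
            {
                "dup_category": cat,
                "n_pairs": n_pairs,
                "n_both_specific": both,
                "n_same_region": same,
                "pct_same_region": 100.0 * same / both if both else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("dup_category")
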