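"""In-memory containers for the pipeline: expression matrix, sample table,
gene annotation, plus their validation rules.

The expression matrix is a thin wrapper around a genes x samples pandas
DataFrame carrying a ``transform_state`` tag so that each pipeline stage can
assert it receives values on the scale it expects:

* ``raw_rpkm``  — non-negative RPKM abundances as distributed;
* ``log2p1``    — log2(RPKM + 1);
* ``adjusted``  — covariate-adjusted log2 values (residuals + fitted
  intercept; may be negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regions import REGIONS_13

TRANSFORM_STATES = ("raw_rpkm", "log2p1", "adjusted")

DUP_CATEGORIES = ("WGD", "SSD", "WGD_SSD", "unannotated", "none")
SSD_AGES = ("ySSD", "wSSD", "oSSD", "not_applicable")

#: gene classes used throughout (annotation-level view of dup_category x ssd_age)
GENE_CLASSES = ("singleton", "WGD", "ySSD", "wSSD", "oSSD", "WGD_SSD", "unannotated")


class ValidationError(ValueError):
    """Input data violates a container invariant."""


@dataclass
class ExpressionMatrix:
    """Gene x sample abundance matrix with a transform-state tag."""

    values: pd.DataFrame  # index = gene ids, columns = sample ids
    transform_state: str = "raw_rpkm"

    def __post_init__(self) -> None:
        if self.transform_state not in TRANSFORM_STATES:
            raise ValidationError(
                f"unknown transform_state {self.transform_state!r}; "
                f"expected one of {TRANSFORM_STATES}"
            )
        dup_genes = self.values.index[self.values.index.duplicated()].unique()
        if len(dup_genes):
            raise ValidationError(f"duplicate gene ids: {sorted(dup_genes)}")
        dup_samples = self.values.columns[self.values.columns.duplicated()].unique()
        if len(dup_samples):
            raise ValidationError(f"duplicate sample ids: {sorted(dup_samples)}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite value at gene {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}"
            )
        if self.transform_state == "raw_rpkm" and (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative RPKM at gene {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: pd.DataFrame, transform_state: str) -> "ExpressionMatrix":
        return ExpressionMatrix(values=values, transform_state=transform_state)


COVARIATE_COLUMNS = ("platform", "age", "sex", "genetic_pc1", "genetic_pc2", "genetic_pc3")
SAMPLE_COLUMNS = ("sample_id", "region_13", "region_7") + COVARIATE_COLUMNS


def validate_sample_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample attribute table (region labels + covariates).

    Requires unique sample ids, region_13 drawn from the 13 territory names,
    region_7 consistent with the fixed merge map, and complete covariates.
    Returns the table indexed by sample_id.
    """
    from .regions import merge_region

    df = samples.copy()
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique()
        raise ValidationError(f"duplicate sample ids: {sorted(dups)}")
    missing = [c for c in SAMPLE_COLUMNS[1:] if c not in df.columns and c != "region_7"]
    if missing:
        raise ValidationError(f"sample table missing columns: {missing}")
    bad = sorted(set(df["region_13"]) - set(REGIONS_13))
    if bad:
        raise ValidationError(f"unknown region_13 labels: {bad}")
    expected_r7 = df["region_13"].map(merge_region)
    if "region_7" not in df.columns:
        df["region_7"] = expected_r7
    elif not (df["region_7"] == expected_r7).all():
        off = df.index[df["region_7"] != expected_r7][:5].tolist()
        raise ValidationError(f"region_7 inconsistent with the merge map for samples {off}")
    cov = df[list(COVARIATE_COLUMNS)]
    if cov.isna().any().any():
        cols = cov.columns[cov.isna().any()].tolist()
        raise ValidationError(f"missing covariate values in columns {cols}")
    return df


ANNOTATION_COLUMNS = (
    "gene_id",
    "status",
    "dup_category",
    "ssd_age",
    "family_id",
    "family_total_size",
    "phyletic_age",
    "chrom",
    "start",
)


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Validate a gene annotation table against the duplication-category rules.

    Enforced invariants:

    * status in {paralog, singleton}; dup_category / ssd_age drawn from their
      controlled vocabularies;
    * an SSD age class implies dup_category == SSD;
    * singletons carry no duplication category and no family;
    * family_total_size >= number of annotated members carrying the family id
      (the total size counts members absent from the expression matrix).
    """
    df = annotation.copy()
    if "gene_id" in df.columns:
        df = df.set_index("gene_id")
    if df.index.duplicated().any():
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValidationError(f"duplicate gene ids in annotation: {dups}")

    bad = sorted(set(df["status"]) - {"paralog", "singleton"})
    if bad:
        raise ValidationError(f"unknown status values: {bad}")
    bad = sorted(set(df["dup_category"]) - set(DUP_CATEGORIES))
    if bad:
        raise ValidationError(f"unknown dup_category values: {bad}")
    bad = sorted(set(df["ssd_age"]) - set(SSD_AGES))
    if bad:
        raise ValidationError(f"unknown ssd_age values: {bad}")

    aged = df["ssd_age"] != "not_applicable"
    off = df.index[aged & (df["dup_category"] != "SSD")].tolist()
    if off:
        raise ValidationError(f"ssd_age set on non-SSD genes: {off[:5]}")

    singles = df["status"] == "singleton"
    off = df.index[singles & (df["dup_category"] != "none")].tolist()
    if off:
        raise ValidationError(f"singletons with a duplication category: {off[:5]}")
    has_family = df["family_id"].notna() & (df["family_id"].astype(str) != "")
    off = df.index[singles & has_family].tolist()
    if off:
        raise ValidationError(f"singletons carrying a family_id: {off[:5]}")
    off = df.index[(df["status"] == "paralog") & (df["dup_category"] == "none")].tolist()
    if off:
        raise ValidationError(f"paralogs with dup_category 'none': {off[:5]}")

    fam = df.loc[has_family]
    n_members = fam.groupby("family_id").size()
    totals = fam.groupby("family_id")["family_total_size"].first()
    too_small = n_members.index[totals.reindex(n_members.index) < n_members].tolist()
    if too_small:
        raise ValidationError(
            f"family_total_size smaller than annotated member count for families {too_small[:5]}"
        )
    return df


def gene_class(annotation: pd.DataFrame) -> pd.Series:
    """Collapse (status, dup_category, ssd_age) into the seven gene classes.

    singleton | WGD | ySSD | wSSD | oSSD | WGD_SSD | unannotated
    """
    cls = pd.Series("unannotated", index=annotation.index, name="gene_class")
    cls[annotation["status"] == "singleton"] = "singleton"
    cls[annotation["dup_category"] == "WGD"] = "WGD"
    cls[annotation["dup_category"] == "WGD_SSD"] = "WGD_SSD"
    ssd = annotation["dup_category"] == "SSD"
    for age in ("ySSD", "wSSD", "oSSD"):
        cls[ssd & (annotation["ssd_age"] == age)] = age
    return cls


@dataclass
class RunConfig:
    """Run-level configuration shared by all pipeline stages."""

    n_permutations: int = 1000
    fdr_alpha: float = 0.01
    low_expr_rpkm: float = 0.1
    lfc_threshold: float = 0.5  # kept for provenance; DE itself is external
    homogeneity_fraction: float = 0.60  # strict inequality
    family_specific_fraction: float = 0.50  # strict majority of expressed members
    tandem_bp: int = 1_000_000
    rng_seed: int = 0
    # module detection
    soft_power: int | str = "auto"
    min_module_size: int = 2
    cut_height: float = 0.99
    deep_split: int = 4
    pooled_null: bool = True

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if not 0 < self.fdr_alpha < 1:
            raise ValidationError("fdr_alpha must lie in (0, 1)")
        if self.low_expr_rpkm < 0:
            raise ValidationError("low_expr_rpkm must be non-negative")
        if not 0 < self.homogeneity_fraction < 1:
            raise ValidationError("homogeneity_fraction must lie in (0, 1)")
        if self.tandem_bp <= 0:
            raise ValidationError("tandem_bp must be positive")
        if not 0 < self.cut_height <= 1:
            raise ValidationError("cut_height must lie in (0, 1]")
        if not 0 <= self.deep_split <= 4:
            raise ValidationError("deep_split must lie in 0..4")
        if self.min_module_size < 1:
            raise ValidationError("min_module_size must be >= 1")
        if self.soft_power != "auto" and int(self.soft_power) < 1:
            raise ValidationError("soft_power must be 'auto' or a positive integer")

    def config_hash(self) -> str:
        import hashlib
        import json

        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
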