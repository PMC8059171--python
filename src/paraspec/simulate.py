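"""Synthetic GTEx-like CNS expression data with planted ground truth.

The generator emulates the statistical structure the analysis assumes so
that every downstream classifier can be scored against known truth:

* 13 CNS territories (collapsible to 7 merged regions) with a fixed number
  of samples each;
* per-gene log-normal abundances on the RPKM scale: log2 expression =
  class-dependent baseline + planted region effect + family latent profile
  + covariate terms + Gaussian noise, mapped back through
  RPKM = 2^x - 1 floored at 0;
* seven gene classes (singleton, WGD, ySSD, wSSD, oSSD, WGD_SSD,
  unannotated-paralog) with class-specific baselines (ySSDs weaker) and
  class-specific planted region-specificity rates;
* paralog families assembled within class, ~47% of size 2 with a decaying
  tail; a configurable fraction of families is *homogeneous* — all members
  share one latent region profile (plus small member-specific deviations),
  which is what the co-expression stage is meant to recover;
* region effects are planted at the 7-region (merged) level so that the
  13 -> 7 merge never splits a planted signal;
* covariate/batch structure (platform, sex, age, three genotype PCs) with
  per-gene coefficients, removable by the adjustment stage;
* genomic coordinates with class-dependent tandem placement of size-2
  families (< 1 Mb apart on one chromosome), denser for young SSDs.

Default class counts and region-specificity rates mirror the annotated
16,427-gene universe the analysis was designed around; smaller problem
sizes are configured explicitly wherever speed matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GENE_CLASSES, ExpressionMatrix, ValidationError, validate_annotation, validate_sample_table
from .regions import REGION_MERGE_MAP, REGIONS_7, REGIONS_13

#: annotated-universe class sizes (genes retained after expression filtering)
DEFAULT_N_GENES = {
    "singleton": 6092,
    "WGD": 5114,
    "ySSD": 1192,
    "wSSD": 1260,
    "oSSD": 1267,
    "WGD_SSD": 966,
    "unannotated": 536,
}

#: observed per-class region-specificity rates used as planting defaults
DEFAULT_FRAC_SPECIFIC = {
    "singleton": 0.139,
    "WGD": 0.157,
    "ySSD": 0.286,
    "wSSD": 0.240,
    "oSSD": 0.156,
    "WGD_SSD": 0.192,
    "unannotated": 0.192,
}

#: probability that a size-2 family of the class is placed in tandem (< 1 Mb)
DEFAULT_TANDEM_FRACTION = {
    "singleton": 0.0,
    "WGD": 0.05,
    "ySSD": 0.5,
    "wSSD": 0.25,
    "oSSD": 0.1,
    "WGD_SSD": 0.1,
    "unannotated": 0.1,
}

#: probability that planted-specific members of one family share a target region
DEFAULT_SHARED_TARGET = {
    "singleton": 0.0,
    "WGD": 0.31,
    "ySSD": 0.59,
    "wSSD": 0.50,
    "oSSD": 0.50,
    "WGD_SSD": 0.40,
    "unannotated": 0.40,
}

#: class shifts of the baseline log2 abundance (young SSDs weaker)
DEFAULT_BASELINE_SHIFT = {
    "singleton": 0.0,
    "WGD": 0.2,
    "ySSD": -1.0,
    "wSSD": -0.3,
    "oSSD": 0.0,
    "WGD_SSD": 0.0,
    "unannotated": -0.2,
}

#: phyletic-age sampling windows per class (None -> no age recorded)
PHYLETIC_AGE_RANGES = {
    "singleton": None,
    "WGD": (0.25, 0.45),
    "ySSD": (0.05, 0.25),
    "wSSD": (0.25, 0.45),
    "oSSD": (0.45, 0.80),
    "WGD_SSD": (0.20, 0.60),
    "unannotated": None,
}


@dataclass
class SimulationSpec:
    samples_per_region: int = 97
    n_genes: dict = field(default_factory=lambda: dict(DEFAULT_N_GENES))
    frac_region_specific: dict = field(default_factory=lambda: dict(DEFAULT_FRAC_SPECIFIC))
    specificity_effect: float = 4.0  # multiplicative fold elevation on RPKM scale
    baseline_mean_log2: float = 3.0
    dispersion: float = 1.5  # sd of per-gene baseline log2 abundance
    noise_sd: float = 0.5  # per-sample residual sd on log2 scale
    class_baseline_shift: dict = field(default_factory=lambda: dict(DEFAULT_BASELINE_SHIFT))
    prob_family_size_2: float = 0.47
    family_tail_geom_p: float = 0.55  # size = 3 + Geom(p) - 1 beyond size 2
    frac_homogeneous_families: float = 0.03
    frac_region_specific_families: float = 0.23  # among homogeneous families
    family_profile_sd: float = 1.0  # sd of the shared latent region profile
    member_profile_jitter_sd: float = 0.1
    unexpressed_member_prob: float = 0.2  # chance a family counts one absent member
    shared_target_fraction: dict = field(default_factory=lambda: dict(DEFAULT_SHARED_TARGET))
    covariate_effects: dict = field(
        default_factory=lambda: {"platform": 0.3, "sex": 0.1, "age": 0.005, "pc": 0.1}
    )
    tandem_fraction: dict = field(default_factory=lambda: dict(DEFAULT_TANDEM_FRACTION))
    tandem_bp: int = 1_000_000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.samples_per_region < 1:
            raise ValidationError("samples_per_region must be >= 1")
        unknown = set(self.n_genes) - set(GENE_CLASSES)
        if unknown:
            raise ValidationError(f"unknown gene classes: {sorted(unknown)}")
        if any(n < 0 for n in self.n_genes.values()) or sum(self.n_genes.values()) < 2:
            raise ValidationError("gene counts must be non-negative and total >= 2")
        for name, d in (
            ("frac_region_specific", self.frac_region_specific),
            ("tandem_fraction", self.tandem_fraction),
            ("shared_target_fraction", self.shared_target_fraction),
        ):
            if any(not 0 <= v <= 1 for v in d.values()):
                raise ValidationError(f"{name} probabilities must lie in [0, 1]")
        for name, v in (
            ("prob_family_size_2", self.prob_family_size_2),
            ("frac_homogeneous_families", self.frac_homogeneous_families),
            ("frac_region_specific_families", self.frac_region_specific_families),
        ):
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.specificity_effect < 1:
            raise ValidationError("specificity_effect must be >= 1 (1 = no elevation)")


@dataclass
class GroundTruth:
    """Planted truth for every downstream classifier."""

    genes: pd.DataFrame  # gene_id -> is_region_specific, target_region
    families: pd.DataFrame  # family_id -> is_homogeneous, is_region_specific, major_region
    pairs: pd.DataFrame  # gene_a, gene_b, dup_category, distance_class
    pair_rows: pd.DataFrame  # raw reciprocal (gene_a, gene_b, category) rows


CHROMOSOMES = tuple(f"chr{i}" for i in range(1, 23))
CHROM_LENGTH = 240_000_000


def _draw_family_sizes(rng: np.random.Generator, n_genes: int, spec: SimulationSpec) -> list[int]:
    sizes: list[int] = []
    remaining = n_genes
    while remaining >= 2:
        if rng.random() < spec.prob_family_size_2:
            size = 2
        else:
            size = 2 + int(rng.geometric(spec.family_tail_geom_p))
        size = min(size, remaining)
        if remaining - size == 1:  # never strand a lone member
            size += 1
        sizes.append(size)
        remaining -= size
    return sizes


def simulate(spec: SimulationSpec) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (expression raw_rpkm, sample table, annotation, ground truth)."""
    rng = np.random.default_rng(spec.rng_seed)

    # ---- samples and covariates -------------------------------------------
    n_samples = spec.samples_per_region * 13
    sample_ids = [f"S{i:05d}" for i in range(n_samples)]
    region_13 = np.repeat(REGIONS_13, spec.samples_per_region)
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "region_13": region_13,
            "region_7": [REGION_MERGE_MAP[r] for r in region_13],
            "platform": rng.choice(["HiSeqA", "HiSeqB"], size=n_samples),
            "age": rng.uniform(20.0, 70.0, size=n_samples).round(1),
            "sex": rng.choice(["female", "male"], size=n_samples),
            "genetic_pc1": rng.normal(0.0, 1.0, size=n_samples),
            "genetic_pc2": rng.normal(0.0, 1.0, size=n_samples),
            "genetic_pc3": rng.normal(0.0, 1.0, size=n_samples),
        }
    )
    samples = validate_sample_table(samples)
    r7_codes = np.array([REGIONS_7.index(r) for r in samples["region_7"]])

    # ---- genes, classes, families -----------------------------------------
    classes = [c for c in GENE_CLASSES for _ in range(spec.n_genes.get(c, 0))]
    n_genes = len(classes)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    gene_class = pd.Series(classes, index=pd.Index(gene_ids, name="gene_id"), name="gene_class")

    family_id = pd.Series(pd.NA, index=gene_class.index, dtype="object")
    family_rows = []
    fam_counter = 0
    for cls in GENE_CLASSES:
        if cls == "singleton":
            continue
        members_all = gene_class.index[gene_class == cls].to_numpy()
        rng.shuffle(members_all)
        offset = 0
        for size in _draw_family_sizes(rng, len(members_all), spec):
            fam = f"F{fam_counter:05d}"
            fam_counter += 1
            members = members_all[offset : offset + size]
            offset += size
            family_id[members] = fam
            extra = int(rng.random() < spec.unexpressed_member_prob)
            family_rows.append(
                {"family_id": fam, "gene_class": cls, "members": members,
                 "n_total": size + extra}
            )

    # ---- planted specificity and family homogeneity -----------------------
    is_specific = np.zeros(n_genes, dtype=bool)
    target_region = np.full(n_genes, -1)
    cls_arr = gene_class.to_numpy()
    for cls in GENE_CLASSES:
        mask = cls_arr == cls
        frac = spec.frac_region_specific.get(cls, 0.0)
        planted = rng.random(mask.sum()) < frac
        if spec.specificity_effect <= 1.0:
            planted[:] = False  # no elevation -> nothing is truly specific
        is_specific[mask] = planted
        target_region[mask] = rng.integers(0, 7, size=mask.sum())
    target_region[~is_specific] = -1

    gene_pos = {g: i for i, g in enumerate(gene_class.index)}
    fam_truth_rows = []
    region_profiles = np.zeros((n_genes, 7))
    for fam in family_rows:
        members_idx = np.array([gene_pos[g] for g in fam["members"]])
        homogeneous = rng.random() < spec.frac_homogeneous_families
        shared_profile = rng.normal(0.0, spec.family_profile_sd, size=7)
        fam_specific = homogeneous and (rng.random() < spec.frac_region_specific_families)
        fam_target = int(rng.integers(0, 7))
        shared_frac = spec.shared_target_fraction.get(fam["gene_class"], 0.0)
        member_shares_target = rng.random(len(members_idx)) < shared_frac
        if homogeneous:
            # a homogeneous family is coherent: one shared latent profile and
            # one shared specificity status, overriding per-gene planting
            region_profiles[members_idx] = shared_profile + rng.normal(
                0.0, spec.member_profile_jitter_sd, size=(len(members_idx), 7)
            )
            planted = bool(fam_specific and spec.specificity_effect > 1.0)
            is_specific[members_idx] = planted
            target_region[members_idx] = fam_target if planted else -1
        else:
            # planted-specific members of one family share the family target
            # with class-dependent probability (young SSD pairs most often)
            for share, gi in zip(member_shares_target, members_idx):
                if is_specific[gi] and share:
                    target_region[gi] = fam_target
        fam_truth_rows.append(
            {
                "family_id": fam["family_id"],
                "is_homogeneous": homogeneous,
                "is_region_specific": bool(fam_specific and spec.specificity_effect > 1.0),
                "major_region": REGIONS_7[fam_target] if fam_specific else pd.NA,
            }
        )

    # ---- genomic coordinates ----------------------------------------------
    chrom = pd.Series(rng.choice(CHROMOSOMES, size=n_genes), index=gene_class.index)
    start = pd.Series(
        rng.integers(1, CHROM_LENGTH, size=n_genes), index=gene_class.index, dtype="int64"
    )
    for fam in family_rows:
        if len(fam["members"]) != 2:
            continue
        if rng.random() < spec.tandem_fraction.get(fam["gene_class"], 0.0):
            a, b = fam["members"]
            chrom[b] = chrom[a]
            offset = int(rng.integers(1_000, max(2_000, spec.tandem_bp - 100_000)))
            start[b] = min(start[a] + offset, CHROM_LENGTH - 1)

    # ---- annotation table --------------------------------------------------
    dup_category = pd.Series("none", index=gene_class.index, dtype="object")
    ssd_age = pd.Series("not_applicable", index=gene_class.index, dtype="object")
    status = pd.Series("paralog", index=gene_class.index, dtype="object")
    status[gene_class == "singleton"] = "singleton"
    dup_category[gene_class == "WGD"] = "WGD"
    dup_category[gene_class == "WGD_SSD"] = "WGD_SSD"
    dup_category[gene_class == "unannotated"] = "unannotated"
    for age in ("ySSD", "wSSD", "oSSD"):
        dup_category[gene_class == age] = "SSD"
        ssd_age[gene_class == age] = age
    phyletic_age = pd.Series(np.nan, index=gene_class.index, dtype=float)
    for cls, rng_window in PHYLETIC_AGE_RANGES.items():
        if rng_window is None:
            continue
        mask = gene_class == cls
        phyletic_age[mask] = np.round(
            rng.uniform(rng_window[0], rng_window[1], size=int(mask.sum())), 2
        )
    n_total_by_fam = {f["family_id"]: f["n_total"] for f in family_rows}
    annotation = pd.DataFrame(
        {
            "status": status,
            "dup_category": dup_category,
            "ssd_age": ssd_age,
            "family_id": family_id,
            "family_total_size": family_id.map(n_total_by_fam).astype("Int64"),
            "phyletic_age": phyletic_age,
            "chrom": chrom,
            "start": start,
        }
    )
    annotation = validate_annotation(annotation.reset_index().rename(columns={"index": "gene_id"}))

    # ---- expression assembly (log2 scale) ---------------------------------
    baseline = rng.normal(spec.baseline_mean_log2, spec.dispersion, size=n_genes)
    baseline += np.array([spec.class_baseline_shift.get(c, 0.0) for c in cls_arr])

    region_effect = region_profiles.copy()  # gene x 7
    log2_fold = np.log2(spec.specificity_effect)
    rows = np.flatnonzero(is_specific)
    region_effect[rows, target_region[rows]] += log2_fold

    design = np.column_stack(
        [
            (samples["platform"] == "HiSeqB").to_numpy(float),
            (samples["sex"] == "male").to_numpy(float),
            samples["age"].to_numpy(float) - 45.0,
            samples["genetic_pc1"].to_numpy(float),
            samples["genetic_pc2"].to_numpy(float),
            samples["genetic_pc3"].to_numpy(float),
        ]
    )  # samples x 6
    eff = spec.covariate_effects
    coef_sd = np.array(
        [eff.get("platform", 0.0), eff.get("sex", 0.0), eff.get("age", 0.0),
         eff.get("pc", 0.0), eff.get("pc", 0.0), eff.get("pc", 0.0)]
    )
    coefs = rng.normal(0.0, 1.0, size=(n_genes, 6)) * coef_sd

    # x is log2 RPKM: noise is multiplicative on the RPKM scale, so the
    # log2(RPKM + 1) analysis transform naturally compresses the variance
    # of weakly expressed genes, as it does for real abundance data
    log2_expr = (
        baseline[:, None]
        + region_effect[:, r7_codes]
        + coefs @ design.T
        + rng.normal(0.0, spec.noise_sd, size=(n_genes, n_samples))
    )
    rpkm = np.exp2(log2_expr)
    expr = ExpressionMatrix(
        values=pd.DataFrame(rpkm, index=gene_class.index, columns=samples.index),
        transform_state="raw_rpkm",
    )

    # ---- ground truth and pair list ---------------------------------------
    genes_truth = pd.DataFrame(
        {
            "gene_class": cls_arr,
            "is_region_specific": is_specific,
            "target_region": [
                REGIONS_7[t] if t >= 0 else pd.NA for t in target_region
            ],
        },
        index=gene_class.index,
    )
    families_truth = pd.DataFrame(fam_truth_rows).set_index("family_id")

    pair_records, raw_rows = [], []
    for fam in family_rows:
        members = sorted(fam["members"])
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                raw_rows.append({"gene_a": a, "gene_b": b, "dup_category": fam["gene_class"]})
                raw_rows.append({"gene_a": b, "gene_b": a, "dup_category": fam["gene_class"]})
                if chrom[a] != chrom[b]:
                    dist_class = "inter_chromosomal"
                elif abs(int(start[a]) - int(start[b])) < spec.tandem_bp:
                    dist_class = "tandem"
                else:
                    dist_class = "intra_chromosomal"
                pair_records.append(
                    {"gene_a": a, "gene_b": b, "dup_category": fam["gene_class"],
                     "distance_class": dist_class}
                )
    truth = GroundTruth(
        genes=genes_truth,
        families=families_truth,
        pairs=pd.DataFrame(pair_records),
        pair_rows=pd.DataFrame(raw_rows),
    )
    return expr, samples, annotation, truth


def fixture_small(seed: int = 1) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Fixed ~600-gene, 13 x 10-sample dataset used across the test suite.

    Contains all seven gene classes, a few hundred families with a planted
    30% homogeneous fraction, and tandem-enriched size-2 ySSD families.
    """
    spec = SimulationSpec(
        samples_per_region=10,
        n_genes={
            "singleton": 160,
            "WGD": 140,
            "ySSD": 120,
            "wSSD": 60,
            "oSSD": 60,
            "WGD_SSD": 40,
            "unannotated": 20,
        },
        frac_homogeneous_families=0.30,
        frac_region_specific_families=0.30,
        prob_family_size_2=0.60,
        tandem_fraction={**DEFAULT_TANDEM_FRACTION, "ySSD": 0.9},
        noise_sd=0.4,
        rng_seed=seed,
    )
    return simulate(spec)
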