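"""Expression preprocessing: gene filtering, log transform, covariate
adjustment, and per-region mean profiles at the 13- and 7-region levels.

The processing order mirrors how the abundance values are prepared before
any specificity or co-expression analysis:

1. drop genes with null variance across all samples, then genes whose mean
   RPKM is below ``low_expr_rpkm`` in every one of the 13 territories;
2. log-transform, v -> log2(v + 1);
3. per gene, regress the log values on the technical and biological
   covariates (sequencing platform, age, sex, three genotype PCs) and keep
   residuals + fitted intercept, so mean differences between genes survive
   adjustment while covariate structure is removed. Adjusted values may be
   negative; downstream clipping is the specificity module's concern.

7-region means are unweighted averages of the constituent 13-region means
(NOT pooled sample means), so unequal territory sample sizes do not skew
the merged profile.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import COVARIATE_COLUMNS, ExpressionMatrix, ValidationError
from .regions import REGION_MERGE_MAP, REGIONS_7, REGIONS_13

log = logging.getLogger(__name__)


def filter_genes(
    m: ExpressionMatrix, samples: pd.DataFrame, low_expr_rpkm: float = 0.1
) -> ExpressionMatrix:
    """Remove null-variance genes, then genes weakly expressed in every region.

    A gene is retained iff its variance across all samples is > 0 AND its
    mean RPKM reaches ``low_expr_rpkm`` in at least one of the 13 regions.
    """
    if m.transform_state != "raw_rpkm":
        raise ValidationError(f"filter_genes expects raw_rpkm, got {m.transform_state}")
    vals = m.values
    var_ok = vals.var(axis=1, ddof=0) > 0
    n_const = int((~var_ok).sum())

    r13 = samples.loc[vals.columns, "region_13"]
    region_means = vals.T.groupby(r13).mean().T  # genes x regions
    expr_ok = (region_means >= low_expr_rpkm).any(axis=1)
    n_weak = int((var_ok & ~expr_ok).sum())

    keep = var_ok & expr_ok
    log.info(
        "filter_genes: removed %d null-variance and %d weakly expressed genes; kept %d",
        n_const, n_weak, int(keep.sum()),
    )
    if not keep.any():
        raise ValidationError("no genes pass filters")
    return m.with_values(vals.loc[keep], "raw_rpkm")


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise v -> log2(v + 1)."""
    if m.transform_state != "raw_rpkm":
        raise ValidationError(f"log_transform expects raw_rpkm, got {m.transform_state}")
    if (m.values.to_numpy() < 0).any():
        raise ValidationError("negative abundances cannot be log-transformed")
    return m.with_values(np.log2(m.values + 1.0), "log2p1")


def build_design(samples: pd.DataFrame) -> pd.DataFrame:
    """Covariate design matrix: intercept + treatment-coded categoricals
    (most frequent level as reference) + numeric covariates."""
    cols = {"intercept": np.ones(len(samples))}
    for cat in ("platform", "sex"):
        levels = samples[cat].value_counts()  # most frequent first
        for level in levels.index[1:]:
            cols[f"{cat}[{level}]"] = (samples[cat] == level).astype(float).to_numpy()
    for num in ("age", "genetic_pc1", "genetic_pc2", "genetic_pc3"):
        v = samples[num].astype(float).to_numpy()
        if v.std() > 0:  # constant covariates carry nothing to adjust for
            cols[num] = v
    return pd.DataFrame(cols, index=samples.index)


def adjust_covariates(m: ExpressionMatrix, samples: pd.DataFrame) -> ExpressionMatrix:
    """Per-gene OLS on the covariates; returns residuals + fitted intercept.

    The fitted intercept is kept so that between-gene mean differences are
    preserved; only variance attributable to the covariates is removed.
    Raises on a rank-deficient design, naming the collinear columns.
    """
    if m.transform_state != "log2p1":
        raise ValidationError(f"adjust_covariates expects log2p1, got {m.transform_state}")
    cov = samples.loc[m.sample_ids, list(COVARIATE_COLUMNS)]
    if cov.isna().any().any():
        raise ValidationError("covariates contain missing values")
    X = build_design(samples.loc[m.sample_ids])
    Xv = X.to_numpy()
    rank = np.linalg.matrix_rank(Xv)
    if rank < Xv.shape[1]:
        collinear = _collinear_columns(X)
        raise ValidationError(f"rank-deficient covariate design; collinear columns: {collinear}")
    Y = m.values.to_numpy()  # genes x samples
    beta, *_ = np.linalg.lstsq(Xv, Y.T, rcond=None)  # p x genes
    fitted = Xv @ beta  # samples x genes
    resid = Y.T - fitted
    adjusted = (resid + beta[0]).T  # add back the fitted intercept per gene
    out = pd.DataFrame(adjusted, index=m.gene_ids, columns=m.sample_ids)
    return m.with_values(out, "adjusted")


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    """Greedy scan: columns whose addition does not raise the design rank."""
    bad, kept = [], np.empty((len(X), 0))
    for name in X.columns:
        cand = np.column_stack([kept, X[name].to_numpy()])
        if np.linalg.matrix_rank(cand) == kept.shape[1]:
            bad.append(name)
        else:
            kept = cand
    return bad


def region_means(
    m: ExpressionMatrix, samples: pd.DataFrame, level: str = "r7"
) -> pd.DataFrame:
    """Per-gene mean expression by region.

    * ``r13`` — mean over each territory's samples;
    * ``r7``  — unweighted average of the constituent r13 means.
    """
    labels = samples.loc[m.sample_ids, "region_13"]
    present = [r for r in REGIONS_13 if (labels == r).any()]
    missing = [r for r in REGIONS_13 if r not in present]
    if missing:
        raise ValidationError(f"regions without samples: {missing}")
    means13 = m.values.T.groupby(labels).mean().T[list(REGIONS_13)]
    if level == "r13":
        return means13
    if level != "r7":
        raise ValueError(f"unknown level {level!r}")
    groups: dict[str, list[str]] = {r7: [] for r7 in REGIONS_7}
    for r13, r7 in REGION_MERGE_MAP.items():
        groups[r7].append(r13)
    out = {r7: means13[members].mean(axis=1) for r7, members in groups.items()}
    return pd.DataFrame(out)[list(REGIONS_7)]
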