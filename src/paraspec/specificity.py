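"""Tau region-specificity scoring with a permutation-calibrated threshold.

The tau index summarises how narrowly a gene is expressed across the n = 7
merged CNS regions:

    tau = sum_i (1 - x_i / max_j x_j) / (n - 1)

where x_i is the gene's mean expression in region i. tau is 0 for a
perfectly uniform profile and 1 for expression confined to a single region.
Covariate adjustment can push region means slightly negative; means are
clipped at 0 before scoring so the max-normalisation semantics (and the
[0, 1] range) are preserved. A gene whose clipped means are all zero has no
defined tau and is excluded from specificity calls.

There is no universal tau cutoff for a single-organ analysis, so the
threshold is calibrated empirically: region labels are permuted across
samples (at the 13-territory level, then merged, so the null respects the
unequal territory sizes feeding each merged mean), tau is recomputed for
every gene in every permutation, and all permuted scores are pooled into
one empirical null. Each gene's p-value is the proportion of pooled null
scores exceeding its observed tau; Benjamini-Hochberg correction across
genes then declares region-specific genes at q < fdr_alpha. The smallest
tau among the declared genes is the induced tau threshold — because the
null is shared, p-values are monotone in tau and the specific set is
exactly {tau >= threshold}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, ValidationError
from .preprocess import region_means
from .regions import REGION_MERGE_MAP, REGIONS_7, REGIONS_13

log = logging.getLogger(__name__)


def compute_tau(means: np.ndarray | pd.DataFrame) -> np.ndarray | float:
    """Tau specificity index of one mean vector or a genes x regions matrix.

    Negative means are clipped to 0 first. Returns NaN for rows whose
    clipped means are all zero (tau undefined).
    """
    arr = np.asarray(means, dtype=float)
    one_d = arr.ndim == 1
    if one_d:
        arr = arr[None, :]
    if arr.shape[1] < 2:
        raise ValidationError("tau needs at least 2 regions")
    arr = np.clip(arr, 0.0, None)
    mx = arr.max(axis=1)
    n = arr.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = (1.0 - arr / mx[:, None]).sum(axis=1) / (n - 1)
    tau[mx <= 0.0] = np.nan
    return float(tau[0]) if one_d else tau


@dataclass
class PermutationNull:
    """Pooled empirical null of tau under shuffled region labels."""

    n_permutations: int
    scores: np.ndarray  # n_permutations x n_genes, NaN where tau undefined
    tau_threshold: float = field(default=np.inf)

    @property
    def pooled(self) -> np.ndarray:
        """All finite permuted scores, sorted ascending."""
        flat = self.scores.ravel()
        return np.sort(flat[np.isfinite(flat)])


def _region_weight_matrices(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(samples x 13 averaging matrix for given label codes, 13 x 7 merge)."""
    counts = np.bincount(labels, minlength=13).astype(float)
    if (counts == 0).any():
        empty = [REGIONS_13[i] for i in np.flatnonzero(counts == 0)]
        raise ValidationError(f"regions without samples: {empty}")
    W = np.zeros((len(labels), 13))
    W[np.arange(len(labels)), labels] = 1.0 / counts[labels]
    M = np.zeros((13, 7))
    for i13, r13 in enumerate(REGIONS_13):
        i7 = REGIONS_7.index(REGION_MERGE_MAP[r13])
        M[i13, i7] = 1.0
    M /= M.sum(axis=0, keepdims=True)
    return W, M


def permutation_null(
    m: ExpressionMatrix,
    samples: pd.DataFrame,
    n_permutations: int = 1000,
    seed: int = 0,
) -> PermutationNull:
    """Recompute tau for every gene under uniformly shuffled region labels.

    Labels are shuffled at the 13-territory level; the fixed merge map is
    then applied before taking the 7-region means, exactly as for the
    observed scores.
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    X = m.values.to_numpy()
    labels = np.array(
        [REGIONS_13.index(r) for r in samples.loc[m.sample_ids, "region_13"]]
    )
    W, M = _region_weight_matrices(labels)
    n_samples = len(labels)
    scores = np.empty((n_permutations, X.shape[0]))
    for p in range(n_permutations):
        perm = rng.permutation(n_samples)
        means7 = X[:, perm] @ (W @ M)
        scores[p] = compute_tau(means7)
    return PermutationNull(n_permutations=n_permutations, scores=scores)


def empirical_pvalues(
    tau: np.ndarray, null: PermutationNull, pooled: bool = True, plus_one: bool = True
) -> np.ndarray:
    """p = proportion of null tau scores strictly greater than the observed tau.

    ``pooled`` compares against the null pooled over all genes (finer
    resolution: N = n_permutations x n_genes); otherwise each gene is
    compared against its own permuted scores. ``plus_one`` applies the
    (c + 1)/(N + 1) correction so no p-value is exactly zero.
    """
    tau = np.asarray(tau, dtype=float)
    p = np.full(tau.shape, np.nan)
    ok = np.isfinite(tau)
    add = 1 if plus_one else 0
    if pooled:
        ref = null.pooled
        n_ref = len(ref)
        greater = n_ref - np.searchsorted(ref, tau[ok], side="right")
        p[ok] = (greater + add) / (n_ref + add)
    else:
        for i in np.flatnonzero(ok):
            col = null.scores[:, i]
            col = col[np.isfinite(col)]
            p[i] = ((col > tau[i]).sum() + add) / (len(col) + add)
    return p


def call_specific(
    tau: pd.Series,
    null: PermutationNull,
    r7_means: pd.DataFrame,
    fdr_alpha: float = 0.01,
    pooled: bool = True,
    plus_one: bool = True,
) -> tuple[pd.DataFrame, float]:
    """Declare region-specific genes at BH q < fdr_alpha and assign regions.

    Returns the per-gene result table and the induced tau threshold (the
    smallest tau among declared genes; +inf with a warning when no gene is
    declared). Genes with undefined tau are flagged and never declared.
    """
    genes = tau.index
    pvals = empirical_pvalues(tau.to_numpy(), null, pooled=pooled, plus_one=plus_one)
    q = np.full(len(genes), np.nan)
    ok = np.isfinite(pvals)
    if ok.any():
        _, q_ok, _, _ = multipletests(pvals[ok], method="fdr_bh")
        q[ok] = q_ok
    specific = np.where(ok, q < fdr_alpha, False)

    assigned = pd.Series(pd.NA, index=genes, dtype="object")
    if specific.any():
        assigned[specific] = [
            assign_region(r7_means.loc[g]) for g in genes[specific]
        ]
        tau_threshold = float(tau.to_numpy()[specific].min())
    else:
        tau_threshold = np.inf
        log.warning("no genes declared region-specific; tau threshold reported as +inf")
    null.tau_threshold = tau_threshold

    clipped = r7_means.clip(lower=0.0)
    results = pd.DataFrame(
        {
            "tau": tau,
            "max_region_mean": clipped.max(axis=1),
            "empirical_p": pvals,
            "q_value": q,
            "is_region_specific": specific,
            "assigned_region": assigned,
        },
        index=genes,
    )
    results.index.name = "gene_id"
    return results, tau_threshold


def assign_region(r7_means_row: pd.Series) -> str:
    """Region with the highest mean; exact ties go to the lexicographically
    first region name with a logged warning."""
    vals = r7_means_row[list(REGIONS_7)].to_numpy(dtype=float)
    top = np.flatnonzero(vals == vals.max())
    if len(top) > 1:
        log.warning(
            "tie for assigned region (%s); keeping %s",
            [REGIONS_7[i] for i in top], REGIONS_7[top[0]],
        )
    return REGIONS_7[top[0]]


def score_specificity(
    m: ExpressionMatrix,
    samples: pd.DataFrame,
    n_permutations: int = 1000,
    fdr_alpha: float = 0.01,
    seed: int = 0,
    pooled: bool = True,
) -> tuple[pd.DataFrame, PermutationNull]:
    """Convenience wrapper: region means -> tau -> permutation null -> calls."""
    r7 = region_means(m, samples, level="r7")
    tau = pd.Series(compute_tau(r7), index=r7.index, name="tau")
    n_undef = int(tau.isna().sum())
    if n_undef:
        log.info("tau undefined (all-zero clipped means) for %d genes", n_undef)
    null = permutation_null(m, samples, n_permutations=n_permutations, seed=seed)
    results, _ = call_specific(tau, null, r7, fdr_alpha=fdr_alpha, pooled=pooled)
    return results, null


#: right edge (log2 scale) of the open-ended top expression bin: log2(128)
LAST_BIN_EDGE = 7.0


def bin_by_expression(
    results: pd.DataFrame, classes: pd.Series
) -> pd.DataFrame:
    """Per expression-bin, per gene-class counts and percent region-specific.

    Bins are 1-unit intervals of log2(RPKM + 1) of each gene's maximal
    region mean: [0,1), [1,2), ... with a final open bin [7, inf) grouping
    everything expressed at >= 127 RPKM (log2(128) = 7).
    """
    idx = results.index.intersection(classes.index)
    x = results.loc[idx, "max_region_mean"].to_numpy(dtype=float)
    bins = np.minimum(np.floor(np.clip(x, 0.0, None)), LAST_BIN_EDGE).astype(int)
    labels = [f"[{b},{b + 1})" for b in range(int(LAST_BIN_EDGE))] + [
        f"[{int(LAST_BIN_EDGE)},inf)"
    ]
    df = pd.DataFrame(
        {
            "bin": [labels[b] for b in bins],
            "gene_class": classes.loc[idx].to_numpy(),
            "specific": results.loc[idx, "is_region_specific"].to_numpy(),
        }
    )
    out = (
        df.groupby(["bin", "gene_class"], sort=False)
        .agg(n_genes=("specific", "size"), n_specific=("specific", "sum"))
        .reset_index()
    )
    out["pct_specific"] = 100.0 * out["n_specific"] / out["n_genes"]
    order = {lab: i for i, lab in enumerate(labels)}
    return out.sort_values(["bin", "gene_class"], key=lambda s: s.map(order).fillna(s)).reset_index(
        drop=True
    )


def tau_by_phyletic_age(results: pd.DataFrame, annotation: pd.DataFrame) -> pd.DataFrame:
    """Quartile summaries of tau for genes grouped by distinct phyletic age."""
    idx = results.index.intersection(annotation.index)
    age = annotation.loc[idx, "phyletic_age"]
    has_age = age.notna()
    if (~has_age).any():
        log.info("tau_by_phyletic_age: %d genes without phyletic age excluded",
                 int((~has_age).sum()))
    df = pd.DataFrame({"age": age[has_age], "tau": results.loc[idx, "tau"][has_age]})
    df = df[df["tau"].notna()]
    out = (
        df.groupby("age")["tau"]
        .agg(
            n="size",
            tau_q25=lambda s: s.quantile(0.25),
            tau_median="median",
            tau_q75=lambda s: s.quantile(0.75),
        )
        .reset_index()
        .rename(columns={"age": "phyletic_age"})
        .sort_values("phyletic_age")
        .reset_index(drop=True)
    )
    return out
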