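"""Weighted co-expression modules of paralogs and gene-family homogeneity.

Module detection follows the weighted-correlation-network recipe: Pearson
correlation across all CNS samples -> soft-thresholded adjacency
a_ij = |cor|^beta (unsigned by default; a signed variant keeps only
positive correlation) -> topological overlap similarity

    t_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),

-> average-linkage hierarchical clustering of the dissimilarity 1 - t ->
a static cut at ``cut_height`` with recursive, quantile-based refinement
of loose clusters (our deterministic stand-in for dynamic tree cutting,
tuned towards many small, tightly co-expressed modules, since about half
of the annotated gene families contain only two genes). Clusters smaller
than ``min_module_size`` are relegated to label 0 (the classical "grey"
unassigned group). Labels are canonicalised by descending module size so
they are invariant to gene input order.

A family is *homogeneous* when strictly more than ``homogeneity_fraction``
(default 60%) of its TOTAL membership — counting members absent from the
expression matrix — falls into one non-grey module; otherwise it is
heterogeneous. Significance of the observed homogeneous-family count is
assessed by permuting module labels across paralogs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import ExpressionMatrix, ValidationError

log = logging.getLogger(__name__)



@dataclass
class NetworkParams:
    signed: bool = False
    soft_power: int | str = "auto"
    min_module_size: int = 2
    deep_split: int = 4
    cut_height: float = 0.99
    scale_free_r2_target: float = 0.8

    def __post_init__(self) -> None:
        if not 0 < self.cut_height <= 1:
            raise ValidationError("cut_height must lie in (0, 1]")
        if not 0 <= self.deep_split <= 4:
            raise ValidationError("deep_split must lie in 0..4")
        if self.min_module_size < 1:
            raise ValidationError("min_module_size must be >= 1")


def adjacency_matrix(X: np.ndarray, beta: int, signed: bool = False) -> np.ndarray:
    """Soft-thresholded co-expression adjacency with zero diagonal."""
    const = X.std(axis=1) == 0
    if const.any():
        raise ValidationError(
            f"constant gene rows (no defined correlation) at indices {np.flatnonzero(const)[:5].tolist()}"
        )
    cor = np.corrcoef(X)
    if signed:
        sim = (1.0 + cor) / 2.0
    else:
        sim = np.abs(cor)
    A = np.clip(sim, 0.0, 1.0) ** beta
    np.fill_diagonal(A, 0.0)
    return A


def tom_similarity(A: np.ndarray) -> np.ndarray:
    """Topological overlap similarity of an adjacency matrix (diag treated as 1)."""
    k = A.sum(axis=0)
    L = A @ A  # with zero diagonal this is sum over u != i, j
    kmin = np.minimum.outer(k, k)
    T = (L + A) / (kmin + 1.0 - A)
    np.fill_diagonal(T, 1.0)
    return T


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log degree-distribution regression.

    Positive when the fit is good AND the slope is negative (the scale-free
    signature); near 0 or negative otherwise.
    """
    k = k[k > 0]
    if len(k) < n_bins:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins).astype(float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    ok = counts > 0
    if ok.sum() < 3:
        return 0.0
    x, y = np.log10(centers[ok]), np.log10(counts[ok] / counts.sum())
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 0.0
    return float(-np.sign(slope) * r2)


def pick_soft_power(
    X: np.ndarray, signed: bool = False, target_r2: float = 0.8, fallback: int = 6
) -> int:
    """Smallest beta in 1..20 whose network is approximately scale-free."""
    for beta in range(1, 21):
        A = adjacency_matrix(X, beta, signed=signed)
        if scale_free_fit(A.sum(axis=0)) >= target_r2:
            return beta
    return fallback


def _split_params(params: NetworkParams) -> tuple[float, float]:
    """Map deep_split onto (tightness height, minimum split gap).

    A subtree whose top merge exceeds the tightness height is always split
    (the static part of the cut); below it, a subtree is split only when
    its top merge is separated from both children by at least the minimum
    gap — a deep valley in the dendrogram. Larger deep_split lowers the
    tightness height and shrinks the required gap, producing more and
    smaller modules.
    """
    h_tight = params.cut_height - 0.0125 * (1 + params.deep_split)
    min_gap = 0.25 * (1.0 - params.deep_split / 5.0)
    return h_tight, min_gap


def cut_modules(dist: np.ndarray, params: NetworkParams) -> np.ndarray:
    """Top-down cut of the average-linkage tree.

    Starting from the static cut at ``cut_height``, each subtree is split
    recursively while it is too loose (top merge above the tightness
    height) or while its top merge stands out from its children by the
    minimum gap — but never when a resulting child would fall below
    ``min_module_size``. Accepted subtrees become modules; genes shed into
    undersized fragments get label 0.
    """
    from scipy.cluster.hierarchy import to_tree

    n = dist.shape[0]
    if n < 2:
        return np.zeros(n, dtype=int)
    Z = linkage(squareform(dist, checks=False), method="average")
    h_tight, min_gap = _split_params(params)
    force_height = min(params.cut_height, h_tight)

    root = to_tree(Z)
    labels = np.zeros(n, dtype=int)
    next_label = 0
    stack = [root]
    while stack:
        node = stack.pop()
        if node.is_leaf():
            continue  # singleton fragment -> stays 0
        left, right = node.get_left(), node.get_right()
        size_l, size_r = left.get_count(), right.get_count()
        both_viable = (
            size_l >= params.min_module_size and size_r >= params.min_module_size
        )
        gap = node.dist - max(left.dist, right.dist)
        must_split = node.dist > force_height
        wants_split = both_viable and gap >= min_gap
        if must_split or wants_split:
            stack.extend((left, right))
        else:
            members = node.pre_order(lambda leaf: leaf.id)
            if len(members) >= params.min_module_size:
                next_label += 1
                labels[members] = next_label
    return _canonical_labels(labels)


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel modules 1..K by descending size (ties by first occurrence)."""
    out = np.zeros_like(labels)
    nonzero = [lab for lab in np.unique(labels) if lab != 0]
    order = sorted(
        nonzero,
        key=lambda lab: (-int((labels == lab).sum()), int(np.flatnonzero(labels == lab)[0])),
    )
    for new, lab in enumerate(order, start=1):
        out[labels == lab] = new
    return out


def infer_modules(
    m: ExpressionMatrix, params: NetworkParams | None = None, seed: int = 0
) -> pd.Series:
    """Co-expression module labels for every gene of the (paralog-restricted)
    matrix; label 0 marks unassigned genes. Deterministic; ``seed`` is
    accepted for interface symmetry but the procedure has no randomness."""
    params = params or NetworkParams()
    X = m.values.to_numpy()
    if X.shape[0] < 2 or X.shape[1] < 3:
        raise ValidationError("module inference needs >= 2 genes and >= 3 samples")
    beta = (
        pick_soft_power(X, signed=params.signed, target_r2=params.scale_free_r2_target)
        if params.soft_power == "auto"
        else int(params.soft_power)
    )
    A = adjacency_matrix(X, beta, signed=params.signed)
    T = tom_similarity(A)
    dist = 1.0 - T
    np.fill_diagonal(dist, 0.0)
    # guard against tiny asymmetries from floating point
    dist = np.maximum((dist + dist.T) / 2.0, 0.0)
    labels = cut_modules(dist, params)
    log.info(
        "infer_modules: beta=%d, %d modules, %d unassigned of %d genes",
        beta, len(set(labels) - {0}), int((labels == 0).sum()), len(labels),
    )
    return pd.Series(labels, index=m.gene_ids, name="module")


def classify_families(
    modules: pd.Series,
    annotation: pd.DataFrame,
    homogeneity_fraction: float = 0.60,
) -> tuple[pd.DataFrame, pd.Index]:
    """Homogeneous/heterogeneous status for every family with expressed members.

    The denominator is the family's TOTAL size (expressed or not); the
    numerator is the largest number of members sharing one non-grey module
    (modal ties -> heterogeneous). Also returns the members of homogeneous
    families that are NOT in the family's main module — the genes removed
    from all downstream homogeneous-family tests.
    """
    has_family = annotation["family_id"].notna() & (annotation["family_id"].astype(str) != "")
    fam_ann = annotation.loc[has_family]
    rows = []
    excluded: list[str] = []
    for family_id, members in fam_ann.groupby("family_id"):
        expressed = members.index.intersection(modules.index)
        if len(expressed) == 0:
            log.info("family %s has no expressed members; skipped", family_id)
            continue
        n_total = int(members["family_total_size"].iloc[0])
        labels = modules.loc[expressed]
        nonzero = labels[labels != 0]
        if len(nonzero):
            counts = nonzero.value_counts()
            top = counts.max()
            modal = counts.index[counts == top]
            tied = len(modal) > 1
            main_module = int(modal[0]) if not tied else 0
            n_in_main = int(top) if not tied else 0
        else:
            tied, main_module, n_in_main = False, 0, 0
        fraction = n_in_main / n_total
        homogeneous = (not tied) and n_in_main > 0 and fraction > homogeneity_fraction
        rows.append(
            {
                "family_id": family_id,
                "n_total": n_total,
                "n_expressed": len(expressed),
                "main_module": main_module if homogeneous else (main_module or 0),
                "n_in_main": n_in_main,
                "fraction": fraction,
                "status": "homogeneous" if homogeneous else "heterogeneous",
            }
        )
        if homogeneous:
            excluded.extend(expressed[(labels != main_module).to_numpy()])
    out = pd.DataFrame(rows).set_index("family_id") if rows else pd.DataFrame(
        columns=["n_total", "n_expressed", "main_module", "n_in_main", "fraction", "status"]
    )
    return out, pd.Index(excluded, name="gene_id")


def _count_homogeneous(
    perm_labels: np.ndarray,
    family_slices: list[tuple[np.ndarray, int]],
    homogeneity_fraction: float,
) -> int:
    count = 0
    for idx, n_total in family_slices:
        labs = perm_labels[idx]
        labs = labs[labs != 0]
        if labs.size == 0:
            continue
        binc = np.bincount(labs)
        top = binc.max()
        if (binc == top).sum() > 1:  # modal tie -> heterogeneous
            continue
        if top / n_total > homogeneity_fraction:
            count += 1
    return count


def homogeneity_permutation_test(
    modules: pd.Series,
    annotation: pd.DataFrame,
    n_permutations: int = 1000,
    seed: int = 0,
    homogeneity_fraction: float = 0.60,
) -> dict:
    """Permutation significance of the observed homogeneous-family count.

    Module labels are shuffled uniformly across paralogs (preserving the
    label multiset) and families reclassified for each permutation;
    empirical_p = (#{null >= observed} + 1) / (n_permutations + 1).
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    has_family = annotation["family_id"].notna() & (annotation["family_id"].astype(str) != "")
    fam_ann = annotation.loc[has_family]
    gene_pos = {g: i for i, g in enumerate(modules.index)}
    family_slices = []
    for family_id, members in fam_ann.groupby("family_id"):
        idx = np.array([gene_pos[g] for g in members.index if g in gene_pos], dtype=int)
        if len(idx):
            family_slices.append((idx, int(members["family_total_size"].iloc[0])))
    labels = modules.to_numpy().astype(int)
    observed = _count_homogeneous(labels, family_slices, homogeneity_fraction)
    null_counts = np.empty(n_permutations, dtype=int)
    for p in range(n_permutations):
        null_counts[p] = _count_homogeneous(
            rng.permutation(labels), family_slices, homogeneity_fraction
        )
    empirical_p = (int((null_counts >= observed).sum()) + 1) / (n_permutations + 1)
    return {
        "observed_count": observed,
        "null_counts": null_counts,
        "empirical_p": empirical_p,
    }
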