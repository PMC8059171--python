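"""End-to-end orchestration: preprocess -> tau/specificity -> enrichments ->
co-expression modules -> family classification -> pair analyses.

Every stage failure is re-raised with the stage name; outputs are TSV
tables carrying a provenance header (version, seed, config hash) and are
byte-identical across reruns with the same seed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import io as pio
from .containers import ExpressionMatrix, RunConfig, gene_class
from .coexpression import (
    NetworkParams,
    classify_families,
    homogeneity_permutation_test,
    infer_modules,
)
from .families_pairs import (
    build_pairs,
    classify_distance,
    classify_family_specificity,
    pair_shared_specificity,
)
from .preprocess import adjust_covariates, filter_genes, log_transform, region_means
from .specificity import score_specificity
from .stats import enrichment_test

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


#: the seven standard (reference, tested, property) enrichment triples
STANDARD_ENRICHMENTS = (
    ("protein_coding", "paralog", None),
    ("paralog", "WGD", None),
    ("paralog", "SSD", None),
    ("paralog", "ySSD", None),
    ("SSD", "ySSD", None),
    ("SSD", "oSSD", None),
    ("WGD+wSSD", "wSSD", None),
)


def _class_index(annotation: pd.DataFrame, group: str) -> pd.Index:
    cls = gene_class(annotation)
    if group == "protein_coding":
        return annotation.index
    if group == "paralog":
        return annotation.index[annotation["status"] == "paralog"]
    if group == "SSD":
        return annotation.index[annotation["dup_category"] == "SSD"]
    if group == "WGD+wSSD":
        return annotation.index[(cls == "WGD") | (cls == "wSSD")]
    return annotation.index[cls == group]


def specificity_enrichment_table(
    results: pd.DataFrame,
    annotation: pd.DataFrame,
    triples=STANDARD_ENRICHMENTS,
) -> pd.DataFrame:
    """Enrichment of region-specific genes across duplication categories,
    one row per (reference, tested) pair, Bonferroni-corrected for the
    number of triples tested."""
    prop = results["is_region_specific"].astype(bool)
    rows = []
    for reference, tested, _ in triples:
        universe = _class_index(annotation, reference).intersection(results.index)
        tested_idx = _class_index(annotation, tested).intersection(universe)
        r = enrichment_test(
            universe,
            tested_idx,
            prop,
            tested_group=tested,
            reference_group=reference,
            n_tests_for_bonferroni=len(triples),
        )
        rows.append(
            {
                "reference_group": reference,
                "tested_group": tested,
                "n_tested": int(r.table[0].sum()),
                "pct_specific": r.pct_tested,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "odds_ratio": r.odds_ratio,
                "test_used": r.test_used,
                "bonferroni_threshold": r.bonferroni_threshold,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    config: RunConfig,
    expression: ExpressionMatrix,
    samples: pd.DataFrame,
    annotation: pd.DataFrame,
    pair_rows: pd.DataFrame | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run every stage on in-memory inputs; optionally write result tables.

    Returns a dict with all intermediate and final artifacts. Genes absent
    from the annotation are dropped with a logged count (the analysis is
    restricted to the annotated gene universe).
    """

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    n_unannotated = len(expression.gene_ids.difference(annotation.index))
    if n_unannotated:
        log.info("dropping %d genes absent from the annotation", n_unannotated)
        expression = expression.with_values(
            expression.values.loc[expression.gene_ids.intersection(annotation.index)],
            expression.transform_state,
        )

    filtered = stage("filter", filter_genes, expression, samples, config.low_expr_rpkm)
    logged = stage("log_transform", log_transform, filtered)
    adjusted = stage("adjust_covariates", adjust_covariates, logged, samples)
    r7 = stage("region_means", region_means, adjusted, samples, "r7")

    results, null = stage(
        "specificity",
        score_specificity,
        adjusted,
        samples,
        n_permutations=config.n_permutations,
        fdr_alpha=config.fdr_alpha,
        seed=config.rng_seed,
        pooled=config.pooled_null,
    )
    enrich = stage("enrichment", specificity_enrichment_table, results, annotation)

    paralogs = annotation.index[annotation["status"] == "paralog"].intersection(
        adjusted.gene_ids
    )
    paralog_expr = adjusted.with_values(adjusted.values.loc[paralogs], "adjusted")
    params = NetworkParams(
        soft_power=config.soft_power,
        min_module_size=config.min_module_size,
        deep_split=config.deep_split,
        cut_height=config.cut_height,
    )
    modules = stage("modules", infer_modules, paralog_expr, params, config.rng_seed)
    families, excluded = stage(
        "classify_families", classify_families, modules, annotation, config.homogeneity_fraction
    )
    homog_test = stage(
        "homogeneity_test",
        homogeneity_permutation_test,
        modules,
        annotation,
        n_permutations=config.n_permutations,
        seed=config.rng_seed,
        homogeneity_fraction=config.homogeneity_fraction,
    )
    family_spec = stage(
        "family_specificity",
        classify_family_specificity,
        results,
        annotation,
        config.family_specific_fraction,
    )

    pairs = None
    if pair_rows is not None and len(pair_rows):
        pairs = stage("pairs", build_pairs, annotation, pair_rows)
        pairs = stage("pair_distance", classify_distance, pairs, annotation, config.tandem_bp)
        pair_spec = stage("pair_specificity", pair_shared_specificity, pairs, results)
    else:
        pair_spec = pd.DataFrame()

    artifacts = {
        "adjusted": adjusted,
        "r7_means": r7,
        "tau_results": results,
        "null": null,
        "tau_threshold": null.tau_threshold,
        "enrichment": enrich,
        "modules": modules,
        "families": families,
        "excluded_genes": excluded,
        "homogeneity_test": homog_test,
        "family_specificity": family_spec,
        "pairs": pairs,
        "pair_specificity": pair_spec,
    }
    if outdir is not None:
        _write_outputs(artifacts, config, Path(outdir))
    return artifacts


def _write_outputs(artifacts: dict, config: RunConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    adj = artifacts["adjusted"].values.copy()
    adj.index.name = "gene_id"
    pio.write_table(adj, outdir / "adjusted_matrix.tsv", config, index=True)
    pio.write_table(
        artifacts["tau_results"].reset_index(), outdir / "tau_results.tsv", config
    )
    pio.write_table(artifacts["enrichment"], outdir / "enrichment.tsv", config)
    mod = artifacts["modules"].rename("module").reset_index().rename(columns={"index": "gene_id"})
    pio.write_table(mod, outdir / "modules.tsv", config)
    pio.write_table(
        artifacts["families"].reset_index(), outdir / "family_homogeneity.tsv", config
    )
    pio.write_table(
        artifacts["family_specificity"].reset_index(), outdir / "family_specificity.tsv", config
    )
    if artifacts["pairs"] is not None:
        pio.write_table(artifacts["pairs"], outdir / "pair_distance.tsv", config)
        pio.write_table(
            artifacts["pair_specificity"].reset_index(), outdir / "pair_specificity.tsv", config
        )
    log.info("pipeline outputs written to %s", outdir)


def run_pipeline_from_paths(
    config: RunConfig,
    expression: str | Path,
    samples: str | Path,
    annotation: str | Path,
    pairs: str | Path | None = None,
    outdir: str | Path = "results",
) -> dict:
    """File-path front end of :func:`run_pipeline`."""
    expr = pio.read_expression(expression)
    samp = pio.read_samples(samples)
    ann = pio.read_annotation(annotation)
    pair_rows = pio.read_table(pairs) if pairs else None
    return run_pipeline(config, expr, samp, ann, pair_rows=pair_rows, outdir=outdir)
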