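"""Readers/writers for the tabular formats the pipeline consumes and emits.

Expression matrices are accepted either as GCT 1.2 (the dialect GTEx v6
shipped: a ``#1.2`` version line, an ``n_genes<TAB>n_samples`` line, then a
header row ``Name, Description, <samples...>``) or as plain TSV with gene
ids in the first column. Other GCT versions are rejected outright.

All result tables are written as TSV with a ``#``-prefixed provenance
header (package version, seed, config hash) and floats at 6 significant
digits, so that reruns under the same seed are byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import (
    ANNOTATION_COLUMNS,
    ExpressionMatrix,
    RunConfig,
    ValidationError,
    validate_annotation,
    validate_sample_table,
)

log = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


class FormatError(ValueError):
    """A file does not follow its declared dialect."""


def read_expression(path: str | Path, format: str = "auto") -> ExpressionMatrix:
    """Read a raw-RPKM expression matrix from a GCT 1.2 or TSV file."""
    path = Path(path)
    if format == "auto":
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format == "gct":
        df = _read_gct(path)
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        df.index = df.index.astype(str)
    else:
        raise ValueError(f"unknown expression format {format!r}")
    _check_numeric(df, path)
    return ExpressionMatrix(values=df.astype(float), transform_state="raw_rpkm")


def _read_gct(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().rstrip("\n")
        if version != "#1.2":
            raise FormatError(
                f"{path}: unsupported GCT version line {version!r}; only '#1.2' is supported"
            )
        dims = fh.readline().rstrip("\n").split("\t")
        try:
            n_genes, n_samples = int(dims[0]), int(dims[1])
        except (IndexError, ValueError):
            bad_line = "\t".join(dims)
            raise FormatError(
                f"{path}: malformed GCT dimension line {bad_line!r}"
            ) from None
        df = pd.read_csv(fh, sep="\t")
    if df.columns[0] != "Name" or df.columns[1] != "Description":
        raise FormatError(
            f"{path}: GCT header must start with 'Name\\tDescription', got "
            f"{list(df.columns[:2])!r}"
        )
    df = df.set_index("Name").drop(columns="Description")
    df.index = df.index.astype(str)
    if df.shape != (n_genes, n_samples):
        raise FormatError(
            f"{path}: declared {n_genes} genes x {n_samples} samples but found "
            f"{df.shape[0]} x {df.shape[1]}"
        )
    return df


def _check_numeric(df: pd.DataFrame, path: Path) -> None:
    non_numeric = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise FormatError(f"{path}: non-numeric expression columns {non_numeric[:5]}")


def write_expression(m: ExpressionMatrix, path: str | Path, format: str = "auto") -> None:
    """Write an expression matrix as GCT 1.2 or TSV (gene ids first column)."""
    path = Path(path)
    if format == "auto":
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{m.shape[0]}\t{m.shape[1]}\n")
            out = m.values.copy()
            out.insert(0, "Description", m.gene_ids)
            out.index.name = "Name"
            out.to_csv(fh, sep="\t", float_format=FLOAT_FORMAT)
    elif format == "tsv":
        out = m.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)
    else:
        raise ValueError(f"unknown expression format {format!r}")


def read_samples(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample attribute table (TSV)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    return validate_sample_table(df)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read and validate a gene annotation table (TSV).

    Logs a per-class load summary (counts of the seven duplication classes).
    """
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        dtype={"gene_id": str, "family_id": str, "chrom": str},
    )
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: annotation table missing columns {missing}")
    ann = validate_annotation(df)
    from .containers import gene_class

    counts = gene_class(ann).value_counts().to_dict()
    log.info("annotation loaded: %d genes; class counts %s", len(ann), counts)
    return ann


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    out = samples.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    out = annotation.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def provenance_header(config: RunConfig) -> str:
    return (
        f"# paraspec {__version__} | seed={config.rng_seed} | "
        f"config={config.config_hash()}\n"
    )


def write_table(df: pd.DataFrame, path: str | Path, config: RunConfig | None = None,
                index: bool = False) -> None:
    """Write a result table as TSV with the provenance header."""
    with open(path, "w") as fh:
        if config is not None:
            fh.write(provenance_header(config))
        df.to_csv(fh, sep="\t", float_format=FLOAT_FORMAT, index=index)


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a result table written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
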