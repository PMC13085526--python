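"""Readers and writers for the flat-file dialects used across the pipeline.

All numeric output is formatted with 9 significant digits so that repeated
runs of the same seeded analysis produce byte-identical files (the pipeline
manifest hashes outputs to certify reproducibility).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, MatrixError, SAMPLE_COLUMNS

FLOAT_FORMAT = "%.9g"


def format_float(x: float) -> str:
    return FLOAT_FORMAT % x


# -- expression matrices ----------------------------------------------------

def write_expression_matrix(m: ExpressionMatrix, values_path, samples_path) -> None:
    """Write values TSV (first column ``gene_id``) and sample-metadata TSV."""
    df = m.values.copy()
    df.insert(0, "gene_id", df.index)
    df.to_csv(values_path, sep="\t", index=False, float_format=FLOAT_FORMAT)
    meta = m.samples[SAMPLE_COLUMNS]
    meta.to_csv(samples_path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_expression_matrix(values_path, samples_path, scale="linear") -> ExpressionMatrix:
    values = _read_strict_tsv(values_path)
    if values.columns[0] != "gene_id":
        raise MatrixError(f"{values_path}: first column must be 'gene_id'")
    values = values.set_index("gene_id").rename_axis(None)
    values = values.astype(float)
    samples = pd.read_csv(samples_path, sep="\t", dtype={"plant_pool_id": str})
    missing = set(SAMPLE_COLUMNS) - set(samples.columns)
    if missing:
        raise MatrixError(f"{samples_path}: missing columns {sorted(missing)}")
    samples = samples.set_index("sample_id", drop=False).rename_axis(None)
    samples = samples.loc[list(values.columns)]
    return ExpressionMatrix(values=values, samples=samples, scale=scale)


def _read_strict_tsv(path) -> pd.DataFrame:
    """Read a TSV rejecting ragged rows with the offending line number."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        width = len(header)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            if len(line.rstrip("\n").split("\t")) != width:
                raise MatrixError(
                    f"{path}: line {lineno} has a different number of "
                    f"fields than the header ({width})"
                )
    return pd.read_csv(path, sep="\t")


# -- gene sets --------------------------------------------------------------

def read_gene_list(path) -> set[str]:
    """One gene id per line; blank lines and ``#`` comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def write_gene_list(genes, path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")


def read_gmt(path) -> dict[str, set[str]]:
    """GMT: set name, description, then member genes, tab-separated."""
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise MatrixError(f"{path}: line {lineno}: GMT rows need >= 3 fields")
        name, genes = fields[0], fields[2:]
        if len(genes) != len(set(genes)):
            warnings.warn(f"GMT set {name!r}: duplicate gene ids deduplicated")
        sets[name] = set(genes)
    return sets


def write_gmt(sets: dict[str, set[str]], path, description="na") -> None:
    lines = [
        "\t".join([name, description] + sorted(genes))
        for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# -- homolog maps and term annotations --------------------------------------

def read_homolog_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"source_gene", "target_gene", "score"}
    if not need <= set(df.columns):
        raise MatrixError(f"{path}: homolog map needs columns {sorted(need)}")
    if not np.isfinite(df["score"]).all():
        raise MatrixError(f"{path}: non-finite homolog scores")
    return df


def write_homolog_map(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_annotation(path) -> dict[str, set[str]]:
    """Flat term annotation TSV: ``term_id, gene_id`` (optional term_name)."""
    df = pd.read_csv(path, sep="\t")
    if not {"term_id", "gene_id"} <= set(df.columns):
        raise MatrixError(f"{path}: annotation needs term_id and gene_id columns")
    ann: dict[str, set[str]] = {}
    for term, sub in df.groupby("term_id"):
        ann[str(term)] = set(sub["gene_id"])
    return ann
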