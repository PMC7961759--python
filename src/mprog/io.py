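"""Readers and writers for the pipeline's standard formats: GCT 1.2
expression matrices, GMT gene-set collections, TSV matrices, and CSV
annotation tables."""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

from .preprocess import ExpressionMatrix

__all__ = [
    "read_gct",
    "write_gct",
    "read_gmt",
    "write_gmt",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_annotations",
]

FLOAT_FMT = "%.10g"


def read_gct(path, unit: str = "TPM") -> ExpressionMatrix:
    """Read a GCT 1.2 file (#1.2 header, dims line, NAME/Description
    columns)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if header != "#1.2":
            raise ValueError(f"{path}: line 1: expected '#1.2', got {header!r}")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise ValueError(f"{path}: line 2: malformed dimensions line")
        n_genes, n_samples = int(dims[0]), int(dims[1])
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df = df.drop(columns=["Description"], errors="ignore")
    if df.shape != (n_genes, n_samples):
        raise ValueError(
            f"{path}: line 2: dimensions {n_genes}x{n_samples} do not match "
            f"data {df.shape[0]}x{df.shape[1]}")
    return ExpressionMatrix.from_frame(df, unit=unit)


def write_gct(m: ExpressionMatrix, path) -> None:
    path = Path(path)
    df = m.to_frame()
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{m.n_genes}\t{m.n_samples}\n")
        out = df.copy()
        out.insert(0, "Description", "na")
        out.index.name = "NAME"
        out.to_csv(fh, sep="\t", float_format=FLOAT_FMT)


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file: one tab-separated line per set, name, description,
    then members.  Duplicate members are dropped with a warning."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected name, description and "
                    "at least one member")
            name, members = parts[0], parts[2:]
            members = [g for g in members if g]
            deduped = list(dict.fromkeys(members))
            if len(deduped) < len(members):
                warnings.warn(
                    f"{path}: line {lineno}: duplicate members in {name!r} "
                    "removed")
            sets[name] = deduped
    return sets


def write_gmt(sets: dict[str, list[str]], path,
              descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_matrix_tsv(path, unit: str | None = None):
    df = pd.read_csv(path, sep="\t", index_col=0)
    if unit is None:
        return df
    return ExpressionMatrix.from_frame(df, unit=unit)


def write_matrix_tsv(m, path) -> None:
    frame = m.to_frame() if hasattr(m, "to_frame") else m
    frame.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_annotations(path, index_col: str = "sample_id") -> pd.DataFrame:
    df = pd.read_csv(path)
    if index_col not in df.columns:
        raise ValueError(f"{path}: missing {index_col!r} column")
    return df.set_index(index_col)
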