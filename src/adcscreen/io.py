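"""Readers and writers for expression matrices and annotation tables.

Expression matrices travel as TSV (gene rows, sample columns, first column
``gene_id``) or GCT 1.2 (version line ``#1.2``, a dimensions line, then a
matrix with ``NAME``/``Description`` columns). Sample and gene annotation
tables are plain TSV with the index in the first column. Writers round-trip
bit-identically with the readers at the stated precision.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import pandas as pd

__all__ = [
    "ParseError",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_expression_gct",
    "write_expression_gct",
    "read_table_tsv",
    "write_table_tsv",
    "load_fixture_table",
]

FLOAT_FORMAT = "%.6g"


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


def _check_unique(values, kind: str, path) -> None:
    seen = set()
    for v in values:
        if v in seen:
            raise ParseError(f"{path}: duplicate {kind} id {v!r}")
        seen.add(v)


def read_expression_tsv(path) -> pd.DataFrame:
    """Read a genes × samples TSV matrix (first column = gene ids)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ParseError(f"{path}:1: expected gene id column plus samples")
        samples = header[1:]
        _check_unique(samples, "sample", path)
        genes, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ParseError(f"{path}:{lineno}: expected {len(header)} "
                                 f"fields, got {len(parts)}")
            genes.append(parts[0])
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    _check_unique(genes, "gene", path)
    return pd.DataFrame(rows, index=genes, columns=samples, dtype=float)


def write_expression_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id",
                  float_format=FLOAT_FORMAT)


def read_expression_gct(path) -> pd.DataFrame:
    """Read a GCT 1.2 matrix; validates the version and dimension lines."""
    path = Path(path)
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ParseError(f"{path}:1: expected GCT version line '#1.2', "
                             f"got {version!r}")
        dims = fh.readline().split()
        if len(dims) != 2:
            raise ParseError(f"{path}:2: expected '<n_genes> <n_samples>'")
        try:
            n_genes, n_samples = int(dims[0]), int(dims[1])
        except ValueError:
            raise ParseError(f"{path}:2: non-integer dimensions") from None
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2 or header[0].upper() != "NAME":
            raise ParseError(f"{path}:3: expected NAME/Description header")
        samples = header[2:]
        if len(samples) != n_samples:
            raise ParseError(f"{path}:3: header lists {len(samples)} samples, "
                             f"dimension line says {n_samples}")
        _check_unique(samples, "sample", path)
        genes, rows = [], []
        for lineno, line in enumerate(fh, start=4):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ParseError(f"{path}:{lineno}: expected {len(header)} "
                                 f"fields, got {len(parts)}")
            genes.append(parts[0])
            try:
                rows.append([float(v) for v in parts[2:]])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    if len(genes) != n_genes:
        raise ParseError(f"{path}: {len(genes)} gene rows, dimension line "
                         f"says {n_genes}")
    _check_unique(genes, "gene", path)
    return pd.DataFrame(rows, index=genes, columns=samples, dtype=float)


def write_expression_gct(matrix: pd.DataFrame, path, descriptions=None) -> None:
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{matrix.shape[0]}\t{matrix.shape[1]}\n")
        fh.write("NAME\tDescription\t" + "\t".join(map(str, matrix.columns)) + "\n")
        desc = descriptions if descriptions is not None else {}
        for gene, row in matrix.iterrows():
            vals = "\t".join(FLOAT_FORMAT % v for v in row.to_numpy())
            fh.write(f"{gene}\t{desc.get(gene, 'na')}\t{vals}\n")


def read_table_tsv(path, index_col: int = 0) -> pd.DataFrame:
    """Read an annotation table (sample or gene metadata) from TSV."""
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_table_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def load_fixture_table(name: str) -> pd.DataFrame:
    """Load a packaged target-table fixture (``table1`` or ``table2``).

    ``table1`` holds the 50 cell-membrane targets, ``table2`` the 50
    extracellular targets, each with a marker-group column and per-subtype
    and per-normal-tissue mean log2 expression.
    """
    ref = importlib.resources.files("adcscreen") / "data" / f"{name}.tsv"
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t", index_col=0)
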