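"""Readers and writers for expression tables and screening outputs.

Two input formats are supported: plain delimited tables (first column =
gene/probe identifier, remaining columns = per-sample expression) and the
GEO series-matrix text format, whose probe x sample table sits between
``!series_matrix_table_begin`` / ``!series_matrix_table_end`` markers.
Probe-to-gene-symbol conversion is deliberately not performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .core import CandidateRanking
from .matrix import ExpressionMatrix

__all__ = [
    "TableSpec",
    "read_expression_table",
    "read_series_matrix",
    "write_expression_table",
    "write_ranking",
    "read_ranking",
]

SERIES_TABLE_BEGIN = "!series_matrix_table_begin"
SERIES_TABLE_END = "!series_matrix_table_end"


@dataclass
class TableSpec:
    """How to parse a delimited expression table.

    ``delimiter=None`` auto-detects between tab and comma.  ``duplicates``
    is ``"error"`` (strict, default) or ``"first"`` (keep first occurrence
    -- GEO probe tables can contain duplicates).
    """

    delimiter: str | None = None
    gene_id_column: int = 0
    header: bool = True
    duplicates: str = "error"


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_expression_table(
    path: str | Path, spec: TableSpec | None = None
) -> ExpressionMatrix:
    """Read a delimited gene x sample expression table.

    The gene-identifier column (default: the first) becomes the index;
    every remaining column must be numeric (scientific notation accepted).
    """
    spec = spec or TableSpec()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such expression table: {path}")
    sep = spec.delimiter or _sniff_delimiter(path)
    df = pd.read_csv(
        path, sep=sep, header=0 if spec.header else None, dtype=str,
        comment="#", skip_blank_lines=True,
    )
    if df.shape[1] < 3:
        raise ValueError(
            f"{path}: found {df.shape[1]} columns; need a gene-id column "
            "plus at least 2 sample columns"
        )
    gene_col = df.columns[spec.gene_id_column]
    df = df.set_index(gene_col)
    df.index = df.index.astype(str).str.strip().str.strip('"')

    if df.index.duplicated().any():
        if spec.duplicates == "first":
            df = df[~df.index.duplicated(keep="first")]
        else:
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"{path}: duplicate gene id {dup!r} (strict mode)")

    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().to_numpy().any():
        r, c = next(zip(*numeric.isna().to_numpy().nonzero()))
        raise ValueError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at gene "
            f"{df.index[r]!r}, sample column {df.columns[c]!r}"
        )
    if numeric.empty:
        raise ValueError(f"{path}: empty expression table")
    return ExpressionMatrix.from_dataframe(numeric)


def read_series_matrix(path: str | Path) -> ExpressionMatrix:
    """Read the expression table of a GEO series-matrix file.

    Everything outside the ``!series_matrix_table_begin`` /
    ``!series_matrix_table_end`` block (series/sample metadata lines) is
    ignored.  Probe identifiers become gene ids; sample accessions become
    sample ids; surrounding quotes are stripped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such series-matrix file: {path}")
    lines: list[str] = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if stripped.lower().startswith(SERIES_TABLE_BEGIN):
                in_table = True
                continue
            if stripped.lower().startswith(SERIES_TABLE_END):
                in_table = False
                break
            if in_table and stripped:
                lines.append(stripped)
    if not lines:
        raise ValueError(
            f"{path}: no {SERIES_TABLE_BEGIN} table block found; "
            "is this a series-matrix file?"
        )
    rows = [[cell.strip().strip('"') for cell in ln.split("\t")] for ln in lines]
    header, body = rows[0], rows[1:]
    if not body:
        raise ValueError(f"{path}: series-matrix table block is empty")
    df = pd.DataFrame(body, columns=header).set_index(header[0])
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().to_numpy().any():
        bad = numeric.index[numeric.isna().any(axis=1)][0]
        raise ValueError(f"{path}: non-numeric expression value at probe {bad!r}")
    return ExpressionMatrix.from_dataframe(numeric)


def write_expression_table(
    expr: ExpressionMatrix, path: str | Path, delimiter: str = "\t"
) -> None:
    """Write a matrix in the delimited format :func:`read_expression_table` reads."""
    expr.to_dataframe().to_csv(path, sep=delimiter)


def write_ranking(ranking: CandidateRanking, path: str | Path) -> None:
    """Write a candidate ranking as a two-column table with provenance header.

    Header comment lines record the sample pairs screened, k, and the
    score kind; data rows are ``gene_id<TAB>score`` ascending by score.
    An empty intersection yields a header-only file.
    """
    with open(path, "w") as fh:
        pair_str = ";".join(f"{a}|{b}" for a, b in ranking.pairs)
        fh.write(f"# pairs={pair_str}\n")
        fh.write(f"# k={ranking.k} score={ranking.score_kind}\n")
        fh.write("gene_id\tscore\n")
        for gene, score in ranking.entries:
            fh.write(f"{gene}\t{score:.10g}\n")


def read_ranking(path: str | Path) -> CandidateRanking:
    """Read a ranking written by :func:`write_ranking`."""
    pairs: list[tuple[str, str]] = []
    k = 0
    score_kind = "sigma2"
    entries: list[tuple[str, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# pairs="):
                spec = line[len("# pairs="):]
                pairs = [
                    tuple(p.split("|", 1)) for p in spec.split(";") if p  # type: ignore[misc]
                ]
            elif line.startswith("# k="):
                fields = dict(f.split("=", 1) for f in line[2:].split())
                k = int(fields.get("k", 0))
                score_kind = fields.get("score", score_kind)
            elif line and not line.startswith("#") and not line.startswith("gene_id\t"):
                gene, score = line.split("\t")
                entries.append((gene, float(score)))
    return CandidateRanking(entries, k, pairs, score_kind)
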