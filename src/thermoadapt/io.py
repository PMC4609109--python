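"""File I/O: expression TSV, sample sheets, GMT gene sets, GEO Series Matrix.

All on-disk formats are plain text.  Expression matrices are tab-separated
with a gene-id first column and one column per array; comment lines starting
with ``#`` are skipped on read (the CLI writes provenance headers that way).
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import TextIO

import numpy as np
import pandas as pd

from .core import validate_matrix, validate_meta


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


def _open(path, mode="r"):
    if hasattr(path, "read") or hasattr(path, "write"):
        return path, False
    return open(path, mode), True


def read_matrix(path) -> pd.DataFrame:
    """Read a genes x samples expression TSV.

    First column holds gene ids, the header row holds sample ids, the body is
    numeric.  Duplicate ids, ragged rows and non-numeric cells raise
    :class:`ParseError` naming the offending line.
    """
    handle, close = _open(path)
    try:
        header: list[str] | None = None
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields[1:]
                if not header:
                    raise ParseError(f"line {lineno}: header has no sample columns")
                continue
            if len(fields) != len(header) + 1:
                raise ParseError(
                    f"line {lineno}: expected {len(header) + 1} fields, got {len(fields)}"
                )
            gene_ids.append(fields[0])
            try:
                rows.append([float(v) for v in fields[1:]])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-numeric cell ({exc})") from None
        if header is None or not rows:
            raise ParseError("empty expression matrix file")
    finally:
        if close:
            handle.close()
    matrix = pd.DataFrame(rows, index=pd.Index(gene_ids, name="gene_id"), columns=header)
    try:
        validate_matrix(matrix)
    except ValueError as exc:
        raise ParseError(str(exc)) from None
    return matrix


def write_matrix(matrix: pd.DataFrame, path, header_lines: list[str] | None = None) -> None:
    """Write a genes x samples expression TSV (full float precision)."""
    handle, close = _open(path, "w")
    try:
        for line in header_lines or []:
            handle.write(f"# {line}\n")
        handle.write("gene_id\t" + "\t".join(map(str, matrix.columns)) + "\n")
        for gene, row in zip(matrix.index, matrix.to_numpy()):
            handle.write(str(gene) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")
    finally:
        if close:
            handle.close()


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a sample sheet TSV (sample_id, strain, condition, replicate, ...)."""
    meta = pd.read_csv(path, sep="\t", comment="#", dtype={"strain": str, "sample_id": str})
    meta["replicate"] = meta["replicate"].astype(int)
    if "growth_rate" in meta.columns:
        meta["growth_rate"] = pd.to_numeric(meta["growth_rate"], errors="coerce")
    return validate_meta(meta)


def write_sample_sheet(meta: pd.DataFrame, path, header_lines: list[str] | None = None) -> None:
    handle, close = _open(path, "w")
    try:
        for line in header_lines or []:
            handle.write(f"# {line}\n")
        meta.to_csv(handle, sep="\t", index=False)
    finally:
        if close:
            handle.close()


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>genes...``."""
    handle, close = _open(path)
    sets: dict[str, list[str]] = {}
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"line {lineno}: GMT line needs name, description, >=1 gene")
            name = fields[0]
            if name in sets:
                raise ParseError(f"line {lineno}: duplicate set name {name!r}")
            sets[name] = fields[2:]
    finally:
        if close:
            handle.close()
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "thermoadapt") -> None:
    handle, close = _open(path, "w")
    try:
        for name, members in sets.items():
            handle.write("\t".join([name, description, *members]) + "\n")
    finally:
        if close:
            handle.close()


def read_geo_series_matrix(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the expression table of a GEO Series Matrix text file.

    Parses the block between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end`` and captures ``!Sample_title`` /
    ``!Sample_geo_accession`` metadata lines.  Returns ``(matrix, titles)``
    where ``titles`` is a partial sample sheet (``sample_id``, ``title``)
    for manual strain/condition mapping.  Values are passed through
    untransformed; interpretation of the log base is left to the caller.
    """
    handle, close = _open(path)
    titles: list[str] = []
    accessions: list[str] = []
    table_lines: list[str] = []
    in_table = False
    saw_table = False
    try:
        for line in handle:
            line = line.rstrip("\n")
            if line.lower().startswith("!series_matrix_table_begin"):
                in_table = True
                saw_table = True
                continue
            if line.lower().startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                if line:
                    table_lines.append(line)
                continue
            if line.startswith("!Sample_title"):
                titles = [f.strip('"') for f in line.split("\t")[1:]]
            elif line.startswith("!Sample_geo_accession"):
                accessions = [f.strip('"') for f in line.split("\t")[1:]]
    finally:
        if close:
            handle.close()
    if not saw_table or len(table_lines) < 2:
        raise ParseError("no series-matrix table section found")
    buf = _io.StringIO("\n".join(table_lines))
    table = pd.read_csv(buf, sep="\t")
    table.columns = [str(c).strip('"') for c in table.columns]
    table.iloc[:, 0] = table.iloc[:, 0].astype(str).str.strip('"')
    matrix = table.set_index(table.columns[0])
    matrix.index.name = "gene_id"
    matrix = matrix.astype(float)
    sample_ids = list(matrix.columns)
    if titles and accessions and len(titles) == len(accessions):
        title_by_acc = dict(zip(accessions, titles))
        mapped = [title_by_acc.get(s, "") for s in sample_ids]
    elif titles and len(titles) == len(sample_ids):
        mapped = titles
    else:
        mapped = [""] * len(sample_ids)
    partial = pd.DataFrame({"sample_id": sample_ids, "title": mapped})
    return matrix, partial


def write_series(values: pd.Series, path, value_name: str = "value",
                 header_lines: list[str] | None = None) -> None:
    """Write a per-gene vector (e.g. a delta profile) as a two-column TSV."""
    handle, close = _open(path, "w")
    try:
        for line in header_lines or []:
            handle.write(f"# {line}\n")
        handle.write(f"gene_id\t{value_name}\n")
        for gene, v in values.items():
            handle.write(f"{gene}\t{float(v)!r}\n")
    finally:
        if close:
            handle.close()
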