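"""Readers and writers for the track formats the pipeline consumes.

All genomic coordinates are 0-based half-open internally, whatever the
on-disk dialect.  Methylation is always the fraction of methylated reads
in ``[0, 1]``.

Formats
-------
* CGI track: BED4+4, tab-separated, no header —
  ``chrom  start  end  name  length  cpgNum  gcFraction  obsExp``
* per-CpG methylation: bedGraph-like TSV, no header —
  ``chrom  pos  pos+2  methylated_reads  coverage``
* gene models: BED12 (thickStart/thickEnd delimit the coding span)
* expression: TSV with header ``gene_id  expr1  expr2``
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import (CALL_COLUMNS, GENE_COLUMNS, ISLAND_COLUMNS,
                    ParseError, ValidationError)

log = logging.getLogger("irdm")


def _read_lines(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def _sorted_genomic(df: pd.DataFrame, poscol: str, path) -> pd.DataFrame:
    keys = df[["chrom", poscol]]
    if not keys.equals(keys.sort_values(["chrom", poscol],
                                        ignore_index=True)):
        log.warning("%s is not coordinate-sorted; sorting on load", path)
        df = df.sort_values(["chrom", poscol], ignore_index=True)
    return df


def read_cgi_track(path) -> pd.DataFrame:
    """Read a BED4+4 CpG-island track into an island table."""
    rows = []
    for lineno, parts in _read_lines(path):
        if len(parts) != 8:
            raise ParseError(f"{path}:{lineno}: expected 8 fields, "
                             f"got {len(parts)}")
        try:
            rows.append((parts[0], int(parts[1]), int(parts[2]), parts[3],
                         int(parts[4]), int(parts[5]),
                         float(parts[6]), float(parts[7])))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
    df = pd.DataFrame(rows, columns=ISLAND_COLUMNS)
    validate_islands(df)
    return _sorted_genomic(df, "start", path)


def validate_islands(df: pd.DataFrame) -> None:
    if len(df) == 0:
        return
    if (df["end"] <= df["start"]).any():
        raise ValidationError("island with end <= start")
    if ((df["end"] - df["start"]) != df["length"]).any():
        raise ValidationError("island length != end - start")
    if (df["cpg_count"] < 1).any():
        raise ValidationError("island with cpg_count < 1")
    if df["island_id"].duplicated().any():
        raise ValidationError("duplicate island ids")


def write_cgi_track(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=ISLAND_COLUMNS)


def read_methylation(path, cell_line=None, replica_id=None) -> pd.DataFrame:
    """Read per-CpG read evidence for one replica of one cell line.

    Returns a frame with columns ``chrom, pos, coverage, methylated_reads``
    (plus ``cell_line``/``replica_id`` when given), sorted by position.
    """
    rows = []
    for lineno, parts in _read_lines(path):
        if len(parts) != 5:
            raise ParseError(f"{path}:{lineno}: expected 5 fields, "
                             f"got {len(parts)}")
        try:
            chrom, pos = parts[0], int(parts[1])
            meth, cov = int(parts[3]), int(parts[4])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        if cov < 0 or meth < 0 or meth > cov:
            raise ValidationError(
                f"{path}:{lineno}: methylated reads {meth} outside "
                f"[0, coverage={cov}]")
        rows.append((chrom, pos, cov, meth))
    df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    df = _sorted_genomic(df, "pos", path)
    if cell_line is not None:
        df["cell_line"] = cell_line
    if replica_id is not None:
        df["replica_id"] = replica_id
    return df


def write_methylation(df: pd.DataFrame, path) -> None:
    out = pd.DataFrame({
        "chrom": df["chrom"], "start": df["pos"], "end": df["pos"] + 2,
        "methylated_reads": df["methylated_reads"],
        "coverage": df["coverage"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def read_gene_models(path) -> pd.DataFrame:
    """Read BED12 gene models.

    The coding span is thickStart..thickEnd; the translational start is
    thickStart on the + strand and thickEnd on the - strand (the larger
    genomic edge of the coding span).  Exon intervals come from the block
    fields.  Returns columns ``gene_id, chrom, strand, tx_start, tx_end,
    cds_start, exon_starts, exon_ends`` with exon coordinates as tuples.
    """
    rows = []
    for lineno, parts in _read_lines(path):
        if len(parts) != 12:
            raise ParseError(f"{path}:{lineno}: expected 12 BED12 fields, "
                             f"got {len(parts)}")
        try:
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name, strand = parts[3], parts[5]
            thick_start, thick_end = int(parts[6]), int(parts[7])
            sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        if strand not in "+-":
            raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
        exon_starts = tuple(start + o for o in offsets)
        exon_ends = tuple(s + sz for s, sz in zip(exon_starts, sizes))
        cds_start = thick_start if strand == "+" else thick_end
        rows.append((name, chrom, strand, start, end, cds_start,
                     exon_starts, exon_ends))
    df = pd.DataFrame(rows, columns=GENE_COLUMNS)
    validate_genes(df)
    return _sorted_genomic(df, "tx_start", path)


def validate_genes(df: pd.DataFrame) -> None:
    for rec in df.itertuples():
        if not rec.tx_start <= rec.cds_start <= rec.tx_end:
            raise ValidationError(
                f"gene {rec.gene_id}: cds_start outside transcript")
        starts, ends = rec.exon_starts, rec.exon_ends
        if len(starts) == 0:
            raise ValidationError(f"gene {rec.gene_id}: no exons")
        prev_end = rec.tx_start - 1
        for s, e in zip(starts, ends):
            if s >= e or s < rec.tx_start or e > rec.tx_end or s <= prev_end - 1:
                raise ValidationError(
                    f"gene {rec.gene_id}: bad exon [{s},{e})")
            if s < prev_end:
                raise ValidationError(
                    f"gene {rec.gene_id}: overlapping/unsorted exons")
            prev_end = e


def write_gene_models(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for rec in df.itertuples():
            sizes = ",".join(str(e - s) for s, e
                             in zip(rec.exon_starts, rec.exon_ends))
            offsets = ",".join(str(s - rec.tx_start)
                               for s in rec.exon_starts)
            if rec.strand == "+":
                thick_start, thick_end = rec.cds_start, rec.tx_end
            else:
                thick_start, thick_end = rec.tx_start, rec.cds_start
            fh.write("\t".join(map(str, (
                rec.chrom, rec.tx_start, rec.tx_end, rec.gene_id, 0,
                rec.strand, thick_start, thick_end, "0",
                len(rec.exon_starts), sizes, offsets))) + "\n")


def read_expression(path) -> pd.DataFrame:
    """Read a two-replica expression table (TSV with header)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "expr1", "expr2"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: missing columns "
                         f"{sorted(required - set(df.columns))}")
    if (df[["expr1", "expr2"]].to_numpy(float) < 0).any():
        raise ValidationError(f"{path}: negative expression value")
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False,
              columns=["gene_id", "expr1", "expr2"])


def write_matrix(matrix, path) -> None:
    out = matrix.levels.copy()
    out.insert(0, "island_id", out.index)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_matrix(path):
    from .types import MethylationMatrix
    df = pd.read_csv(path, sep="\t").set_index("island_id")
    support = pd.DataFrame(np.where(df.notna(), 1, np.nan),
                           index=df.index, columns=df.columns)
    return MethylationMatrix(levels=df, n_cpgs=support)
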