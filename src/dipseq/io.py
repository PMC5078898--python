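"""Readers and writers for the plain-text formats the pipeline touches.

Tags travel as BED3/BED6 (one record per tag, the record start is the tag
position), gene models as BED12 or refFlat-style TSV, scored region sets as
BED-plus-columns TSV, count matrices as TSV with a header, genomes as
two-column TSV. All coordinates on disk follow the BED 0-based half-open
convention, matching the in-memory contract.
"""

from __future__ import annotations

import collections
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import GeneModel, Genome, GenomicInterval, TagSet


class ParseError(ValueError):
    """Raised for malformed records; message names the file and line."""


# ---------------------------------------------------------------- genomes


def read_genome(path: str | Path) -> Genome:
    lengths: dict[str, int] = {}
    for lineno, line in enumerate(_lines(path), start=1):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns (chrom, length)")
        try:
            lengths[fields[0]] = int(fields[1])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-integer length {fields[1]!r}") from None
    return Genome(lengths)


def write_genome(genome: Genome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.chrom_lengths.items():
            fh.write(f"{name}\t{length}\n")


# ------------------------------------------------------------------- tags


def read_tags(
    path: str | Path,
    genome: Genome,
    assay: str,
    condition: str,
    sample_id: str | None = None,
    collapse_duplicates: bool = False,
) -> TagSet:
    """Load a BED3/BED6 tag file into a :class:`TagSet`.

    Each record contributes one tag at its start coordinate; strand is taken
    from column 6 when present, else '+'. Duplicate coordinates are kept by
    default (``collapse_duplicates`` collapses them).
    """
    positions: dict[str, list[int]] = collections.defaultdict(list)
    strands: dict[str, list[str]] = collections.defaultdict(list)
    for lineno, line in enumerate(_lines(path), start=1):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: BED requires >= 3 columns")
        chrom = fields[0]
        if chrom not in genome:
            raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        try:
            start = int(fields[1])
            end = int(fields[2])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
        if start < 0 or start >= end:
            raise ParseError(f"{path}:{lineno}: invalid BED interval {start}-{end}")
        if start >= genome.length_of(chrom):
            raise ValueError(
                f"{path}:{lineno}: start {start} beyond end of {chrom!r} "
                f"({genome.length_of(chrom)} bp)"
            )
        strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "+"
        positions[chrom].append(start)
        strands[chrom].append(strand)
    tags = TagSet(
        sample_id or Path(path).stem,
        assay,
        condition,
        genome,
        {c: np.asarray(p, dtype=np.int64) for c, p in positions.items()},
        {c: np.asarray(s) for c, s in strands.items()},
    )
    return tags.collapse_duplicates() if collapse_duplicates else tags


def write_tags(tags: TagSet, path: str | Path) -> None:
    """Write a TagSet as BED6; each tag becomes a 1 bp record."""
    with open(path, "w") as fh:
        for chrom, pos, strand in tags.iter_tags():
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t.\t0\t{strand}\n")


# ------------------------------------------------------------ gene models


def read_gene_models(path: str | Path, fmt: str | None = None) -> list[GeneModel]:
    """Parse gene models from BED12 or refFlat-style TSV.

    The format is sniffed from the first data line when ``fmt`` is None:
    refFlat lines carry the strand in column 4, BED12 in column 6.
    """
    lines = list(enumerate(_lines(path), start=1))
    if not lines:
        return []
    if fmt is None:
        first = lines[0][1].split("\t")
        if len(first) >= 11 and first[3] in ("+", "-"):
            fmt = "refflat"
        elif len(first) >= 12 and first[5] in ("+", "-"):
            fmt = "bed12"
        else:
            raise ParseError(f"{path}: cannot determine gene-model format")
    parse = _parse_refflat_line if fmt == "refflat" else _parse_bed12_line
    return [parse(path, lineno, line) for lineno, line in lines]


def _parse_bed12_line(path, lineno: int, line: str) -> GeneModel:
    f = line.split("\t")
    if len(f) < 12:
        raise ParseError(f"{path}:{lineno}: BED12 requires 12 columns")
    chrom, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
    n_blocks = int(f[9])
    sizes = [int(x) for x in f[10].rstrip(",").split(",")]
    offsets = [int(x) for x in f[11].rstrip(",").split(",")]
    if len(sizes) != n_blocks or len(offsets) != n_blocks:
        raise ParseError(f"{path}:{lineno}: blockCount inconsistent with block lists")
    exons = []
    for size, off in zip(sizes, offsets):
        ex_start = start + off
        ex_end = ex_start + size
        if ex_end > end:
            raise ParseError(f"{path}:{lineno}: exon block extends past gene end")
        exons.append(GenomicInterval(chrom, ex_start, ex_end))
    try:
        return GeneModel(name, chrom, strand, start, end, tuple(exons))
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: {exc}") from None


def _parse_refflat_line(path, lineno: int, line: str) -> GeneModel:
    f = line.split("\t")
    if len(f) < 11:
        raise ParseError(f"{path}:{lineno}: refFlat requires 11 columns")
    name, chrom, strand = f[1], f[2], f[3]
    start, end = int(f[4]), int(f[5])
    n_exons = int(f[8])
    ex_starts = [int(x) for x in f[9].rstrip(",").split(",")]
    ex_ends = [int(x) for x in f[10].rstrip(",").split(",")]
    if len(ex_starts) != n_exons or len(ex_ends) != n_exons:
        raise ParseError(f"{path}:{lineno}: exonCount inconsistent with exon lists")
    exons = tuple(GenomicInterval(chrom, s, e) for s, e in zip(ex_starts, ex_ends))
    try:
        return GeneModel(name, chrom, strand, start, end, exons)
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: {exc}") from None


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as BED12 (round-trips through read_gene_models)."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            exons = g.exons or (g.span,)
            sizes = ",".join(str(e.length) for e in exons) + ","
            offsets = ",".join(str(e.start - g.start) for e in exons) + ","
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t{len(exons)}\t{sizes}\t{offsets}\n"
            )


# ---------------------------------------------------------------- regions


def write_regions(regions: pd.DataFrame, path: str | Path) -> None:
    """Write a scored-region table as BED-plus TSV with a header line.

    ``regions`` must carry chrom/start/end; any further columns (count, p,
    q, direction ...) are preserved. Rows are written sorted by
    (chrom, start, end); overlapping regions are permitted and preserved.
    """
    required = {"chrom", "start", "end"}
    if not required.issubset(regions.columns):
        raise ValueError(f"region table must contain columns {sorted(required)}")
    out = regions.sort_values(["chrom", "start", "end"], kind="stable")
    out.to_csv(path, sep="\t", index=False)


def read_regions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if len(df) == 0:
        return df
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def intervals_to_frame(intervals: Iterable[GenomicInterval]) -> pd.DataFrame:
    rows = [(iv.chrom, iv.start, iv.end) for iv in intervals]
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def frame_to_intervals(df: pd.DataFrame) -> list[GenomicInterval]:
    return [
        GenomicInterval(r.chrom, int(r.start), int(r.end))
        for r in df.itertuples(index=False)
    ]


# ----------------------------------------------------------------- counts


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    """Write a genes x samples count table; the index column is gene_id."""
    counts.to_csv(path, sep="\t", index=True, index_label="gene_id")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def _lines(path: str | Path):
    """Yield non-empty, non-comment lines with trailing newline stripped."""
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line and not line.startswith(("#", "track", "browser")):
                yield line
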