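"""Core genomic containers shared by every pipeline stage.

Coordinates are 0-based half-open throughout (the BED convention): an
interval ``[start, end)`` covers ``end - start`` base pairs and a tag is a
single base-pair point, the 5' start of a uniquely mapped sequencing read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

ASSAYS = ("5mC", "5hmC", "RNA")


class Genome:
    """An ordered set of named chromosomes with lengths in base pairs."""

    def __init__(self, chrom_lengths: Mapping[str, int]):
        if len(chrom_lengths) == 0:
            raise ValueError("genome must contain at least one chromosome")
        names = list(chrom_lengths)
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in chrom_lengths.items():
            if int(length) <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        self._lengths = {str(n): int(l) for n, l in chrom_lengths.items()}

    @property
    def chrom_names(self) -> list[str]:
        return list(self._lengths)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self._lengths)

    def length_of(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    @property
    def total_length(self) -> int:
        return sum(self._lengths.values())

    def __eq__(self, other) -> bool:
        return isinstance(other, Genome) and self._lengths == other._lengths

    def __repr__(self) -> str:
        return f"Genome({len(self._lengths)} chromosomes, {self.total_length} bp)"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval ``[start, end)`` on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def to_one_based_closed(self) -> tuple[str, int, int]:
        """Convert to the 1-based fully-closed convention (e.g. GFF)."""
        return (self.chrom, self.start + 1, self.end)

    @classmethod
    def from_one_based_closed(cls, chrom: str, start1: int, end1: int) -> "GenomicInterval":
        return cls(chrom, start1 - 1, end1)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals; overlapping or book-ended runs collapse to one.

    Output is sorted by (chrom, start). Book-ended means ``a.end == b.start``.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlap or book-end
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


class TagSet:
    """Uniquely mapped tag coordinates for one sequencing library.

    Positions are stored per chromosome as sorted int64 arrays; strand is
    retained for the record but ignored by window and gene counting (the
    library preparations here are unstranded).
    """

    def __init__(
        self,
        sample_id: str,
        assay: str,
        condition: str,
        genome: Genome,
        positions: Mapping[str, np.ndarray],
        strands: Mapping[str, np.ndarray] | None = None,
    ):
        if assay not in ASSAYS:
            raise ValueError(f"assay must be one of {ASSAYS}, got {assay!r}")
        self.sample_id = str(sample_id)
        self.assay = assay
        self.condition = str(condition)
        self.genome = genome
        self._positions: dict[str, np.ndarray] = {}
        self._strands: dict[str, np.ndarray] = {}
        for chrom, pos in positions.items():
            if chrom not in genome:
                raise ValueError(f"tags on unknown chromosome {chrom!r}")
            pos = np.asarray(pos, dtype=np.int64)
            length = genome.length_of(chrom)
            if pos.size and (pos.min() < 0 or pos.max() >= length):
                bad = pos[(pos < 0) | (pos >= length)][0]
                raise ValueError(
                    f"tag position {bad} outside chromosome {chrom!r} [0, {length})"
                )
            strand = (
                np.asarray(strands[chrom])
                if strands is not None and chrom in strands
                else np.full(pos.size, "+", dtype="<U1")
            )
            if strand.size != pos.size:
                raise ValueError(f"strand array length mismatch on {chrom!r}")
            order = np.argsort(pos, kind="stable")
            self._positions[chrom] = pos[order]
            self._strands[chrom] = strand[order]

    @property
    def library_size(self) -> int:
        return int(sum(p.size for p in self._positions.values()))

    @property
    def chroms(self) -> list[str]:
        return [c for c in self.genome.chrom_names if c in self._positions]

    def positions_on(self, chrom: str) -> np.ndarray:
        """Sorted tag positions on one chromosome (empty array if none)."""
        return self._positions.get(chrom, np.empty(0, dtype=np.int64))

    def strands_on(self, chrom: str) -> np.ndarray:
        return self._strands.get(chrom, np.empty(0, dtype="<U1"))

    def iter_tags(self) -> Iterator[tuple[str, int, str]]:
        for chrom in self.chroms:
            for pos, strand in zip(self._positions[chrom], self._strands[chrom]):
                yield chrom, int(pos), str(strand)

    def count_in(self, interval: GenomicInterval) -> int:
        pos = self.positions_on(interval.chrom)
        return int(
            np.searchsorted(pos, interval.end, side="left")
            - np.searchsorted(pos, interval.start, side="left")
        )

    def count_intervals(self, intervals: Iterable[GenomicInterval]) -> np.ndarray:
        """Vectorized :meth:`count_in` over a list of intervals."""
        ivs = list(intervals)
        out = np.zeros(len(ivs), dtype=np.int64)
        for i, iv in enumerate(ivs):
            out[i] = self.count_in(iv)
        return out

    def collapse_duplicates(self) -> "TagSet":
        """Return a copy with identical (chrom, position) tags collapsed to one."""
        new_pos = {}
        new_strand = {}
        for chrom in self.chroms:
            pos = self._positions[chrom]
            keep = np.ones(pos.size, dtype=bool)
            keep[1:] = pos[1:] != pos[:-1]
            new_pos[chrom] = pos[keep]
            new_strand[chrom] = self._strands[chrom][keep]
        return TagSet(self.sample_id, self.assay, self.condition, self.genome,
                      new_pos, new_strand)

    def __repr__(self) -> str:
        return (
            f"TagSet({self.sample_id!r}, assay={self.assay}, "
            f"condition={self.condition!r}, n={self.library_size})"
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene span with strand-aware TSS and an exon structure.

    ``tss`` is the span start on the + strand and ``end - 1`` on the −
    strand; ``mappable_length`` is the summed exon length used downstream as
    the selection-bias weight for length-aware enrichment testing.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[GenomicInterval, ...] = field(default=())

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid gene span [{self.start}, {self.end})")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        for e in exons:
            if e.chrom != self.chrom or e.start < self.start or e.end > self.end:
                raise ValueError(f"exon {e} outside gene span of {self.gene_id}")
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping exons in {self.gene_id}")
        object.__setattr__(self, "exons", exons)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def mappable_length(self) -> int:
        if not self.exons:
            return self.length
        return sum(e.length for e in self.exons)
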