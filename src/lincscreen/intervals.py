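"""Coordinate conventions and interval arithmetic.

All coordinates are 0-based half-open (BED convention). Two intervals
overlap iff they share a chromosome and their half-open spans intersect;
strand is ignored unless an operation states otherwise. The transcription
start site (TSS) of a minus-strand transcript is ``end - 1``, the last
0-based transcribed base, so that symmetric promoter windows treat both
strands identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Iterator, Sequence

from intervaltree import IntervalTree

STRAND_PLUS = "+"
STRAND_MINUS = "-"
STRAND_NONE = "."
VALID_STRANDS = frozenset((STRAND_PLUS, STRAND_MINUS, STRAND_NONE))

BIOTYPE_LNCRNA = "lncRNA"
BIOTYPE_CODING = "protein_coding"
VALID_BIOTYPES = frozenset((BIOTYPE_LNCRNA, BIOTYPE_CODING))


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open span ``[start, end)`` on a named chromosome.

    Empty intervals (``start >= end``) are rejected; positions are
    non-negative base pairs.
    """

    chrom: str
    start: int
    end: int
    strand: str = STRAND_NONE

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval requires a chromosome name")
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:[{self.start},{self.end}): "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return overlaps(self, other)

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Width of the intersection in bp (0 when disjoint)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:[{self.start},{self.end}){self.strand}"


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff ``a`` and ``b`` share a chromosome and their spans intersect.

    Half-open semantics: adjacent intervals ([0,10) vs [10,20)) do not
    overlap. Strand is ignored.
    """
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


@dataclass(frozen=True)
class Transcript:
    """A stranded, possibly multi-exon annotation record.

    ``exons`` are sorted, non-overlapping, lie within ``interval`` and
    span it exactly (first exon starts at ``interval.start``, last ends at
    ``interval.end``). ``locus_id`` groups isoforms of one locus.
    """

    transcript_id: str
    locus_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...] = field(default=())
    biotype: str = BIOTYPE_LNCRNA

    def __post_init__(self) -> None:
        if self.interval.strand == STRAND_NONE:
            raise ValueError(
                f"transcript {self.transcript_id}: strand must be + or -"
            )
        if self.biotype not in VALID_BIOTYPES:
            raise ValueError(
                f"transcript {self.transcript_id}: unknown biotype {self.biotype!r}"
            )
        exons = self.exons if self.exons else (
            GenomicInterval(self.interval.chrom, self.interval.start,
                            self.interval.end, self.interval.strand),
        )
        object.__setattr__(self, "exons", tuple(exons))
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.interval.chrom:
                raise ValueError(
                    f"transcript {self.transcript_id}: exon on {ex.chrom} "
                    f"outside {self.interval.chrom}"
                )
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(
                    f"transcript {self.transcript_id}: exons unsorted or overlapping"
                )
            prev_end = ex.end
        if (self.exons[0].start != self.interval.start
                or self.exons[-1].end != self.interval.end):
            raise ValueError(
                f"transcript {self.transcript_id}: exon span does not match "
                "transcript interval"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    def tss(self) -> tuple[str, int]:
        return tss_of(self)


def tss_of(t: Transcript) -> tuple[str, int]:
    """Chromosome and 0-based position of the transcription start site.

    Plus strand: ``interval.start``. Minus strand: ``interval.end - 1``
    (the last 0-based transcribed base).
    """
    if t.strand == STRAND_PLUS:
        return t.chrom, t.interval.start
    if t.strand == STRAND_MINUS:
        return t.chrom, t.interval.end - 1
    raise ValueError(f"transcript {t.transcript_id}: TSS undefined without strand")


class IntervalIndex:
    """Indexed overlap queries over (interval, payload) pairs.

    Query results are exactly the pairs whose interval overlaps the query
    interval, i.e. set-equal to the brute-force pairwise definition.
    Built on one interval tree per chromosome.
    """

    def __init__(self, items: Iterable[tuple[GenomicInterval, Any]] = ()) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._n = 0
        for i, (iv, payload) in enumerate(items):
            if not isinstance(iv, GenomicInterval):
                raise TypeError(f"item {i}: expected GenomicInterval, got {iv!r}")
            tree = self._trees.setdefault(iv.chrom, IntervalTree())
            tree.addi(iv.start, iv.end, (iv, payload))
            self._n += 1

    def __len__(self) -> int:
        return self._n

    def query(self, q: GenomicInterval) -> list[tuple[GenomicInterval, Any]]:
        """All (interval, payload) pairs overlapping ``q``, sorted by span."""
        tree = self._trees.get(q.chrom)
        if tree is None:
            return []
        hits = [node.data for node in tree.overlap(q.start, q.end)]
        hits.sort(key=lambda pair: (pair[0].start, pair[0].end, str(pair[1])))
        return hits

    def any_overlap(self, q: GenomicInterval) -> bool:
        tree = self._trees.get(q.chrom)
        return bool(tree is not None and tree.overlaps(q.start, q.end))

    def chromosomes(self) -> set[str]:
        return set(self._trees)


def build_index(items: Sequence[tuple[GenomicInterval, Any]]) -> IntervalIndex:
    """Build an :class:`IntervalIndex`; rejects invalid records by position."""
    return IntervalIndex(items)


def merge_intervals(ivs: Iterable[GenomicInterval]) -> Iterator[tuple[str, int, int]]:
    """Yield the union of intervals as (chrom, start, end) runs, merged per
    chromosome and sorted by (chrom, start)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in ivs:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for chrom in sorted(by_chrom):
        spans = sorted(by_chrom[chrom])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                yield chrom, cur_s, cur_e
                cur_s, cur_e = s, e
        yield chrom, cur_s, cur_e
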