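"""Readers and writers for BED, GTF and bedGraph.

Coordinates are converted to the internal 0-based half-open convention at
the boundary: BED and bedGraph are stored as-is, GTF (1-based inclusive) is
shifted on read and unshifted on write. All readers accept plain or
gzip-compressed files (by ``.gz`` suffix). Round trips are exact on
coordinates, identifiers, strands and values.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence, TextIO

from gffutils.feature import feature_from_line

from .coverage import CoverageTrack
from .intervals import (
    BIOTYPE_LNCRNA,
    GenomicInterval,
    STRAND_NONE,
    Transcript,
)


class FileFormatError(ValueError):
    """A malformed record, reported with its file and line number."""


def _open_text(path: str | Path, mode: str = "rt") -> TextIO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _numbered_lines(path: str | Path) -> Iterator[tuple[int, str]]:
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def _fail(path: str | Path, lineno: int, msg: str) -> None:
    raise FileFormatError(f"{path}:{lineno}: {msg}")


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | Path, biotype: str = BIOTYPE_LNCRNA) -> list[Transcript]:
    """Read transcripts from BED6 or BED12.

    BED6 lines become single-exon transcripts; BED12 exons are expanded
    from blockStarts/blockSizes. The name column is the transcript_id and,
    lacking any other grouping, also the locus_id. Strand '.' is an error:
    a transcript's TSS is undefined without orientation.
    """
    out: list[Transcript] = []
    for lineno, line in _numbered_lines(path):
        f = line.split("\t")
        if len(f) < 6:
            _fail(path, lineno, f"expected >= 6 tab-separated fields, got {len(f)}")
        chrom, name, strand = f[0], f[3], f[5]
        try:
            start, end = int(f[1]), int(f[2])
        except ValueError:
            _fail(path, lineno, f"non-integer coordinates {f[1]!r}, {f[2]!r}")
        if start >= end:
            _fail(path, lineno, f"start {start} >= end {end}")
        if strand == STRAND_NONE:
            _fail(path, lineno, f"transcript {name!r} has strand '.'")
        try:
            if len(f) >= 12:
                nblocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
                if not (len(sizes) == len(offsets) == nblocks):
                    _fail(path, lineno, "blockCount does not match block lists")
                exons = tuple(
                    GenomicInterval(chrom, start + off, start + off + size, strand)
                    for off, size in zip(offsets, sizes)
                )
            else:
                exons = (GenomicInterval(chrom, start, end, strand),)
            out.append(
                Transcript(
                    transcript_id=name,
                    locus_id=name,
                    interval=GenomicInterval(chrom, start, end, strand),
                    exons=exons,
                    biotype=biotype,
                )
            )
        except ValueError as err:
            _fail(path, lineno, str(err))
    return out


def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read plain intervals (e.g. peak calls) from BED3+; strand optional."""
    out: list[GenomicInterval] = []
    for lineno, line in _numbered_lines(path):
        f = line.split("\t")
        if len(f) < 3:
            _fail(path, lineno, f"expected >= 3 tab-separated fields, got {len(f)}")
        strand = f[5] if len(f) >= 6 and f[5] in "+-" else STRAND_NONE
        try:
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
        except ValueError as err:
            _fail(path, lineno, str(err))
    return out


def write_bed(transcripts: Sequence[Transcript], path: str | Path) -> None:
    """Write transcripts as BED12; read_bed(write_bed(x)) reproduces
    coordinates, ids, strands and exon structure exactly."""
    with _open_text(path, "wt") as fh:
        for t in transcripts:
            iv = t.interval
            sizes = ",".join(str(ex.length) for ex in t.exons)
            offsets = ",".join(str(ex.start - iv.start) for ex in t.exons)
            fh.write(
                "\t".join(
                    (
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        t.transcript_id,
                        "0",
                        iv.strand,
                        str(iv.start),
                        str(iv.end),
                        "0",
                        str(len(t.exons)),
                        sizes,
                        offsets,
                    )
                )
                + "\n"
            )


def write_bed_intervals(ivs: Sequence[GenomicInterval], path: str | Path,
                        names: Sequence[str] | None = None) -> None:
    with _open_text(path, "wt") as fh:
        for i, iv in enumerate(ivs):
            name = names[i] if names is not None else f"region_{i + 1}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# GTF

def read_gtf(path: str | Path, biotype: str = BIOTYPE_LNCRNA) -> list[Transcript]:
    """Read transcripts from GTF exon features.

    GTF 1-based inclusive coordinates become 0-based half-open
    ``(start - 1, end)``. Exons are grouped by ``transcript_id``; the
    transcript interval is the exon span. Mixed strands within one
    transcript or an exon lacking transcript_id are errors.
    """
    exons_by_tx: dict[str, list[GenomicInterval]] = {}
    locus_by_tx: dict[str, str] = {}
    order: list[str] = []
    for lineno, line in _numbered_lines(path):
        feature = feature_from_line(line, dialect=None)
        if feature.featuretype != "exon":
            continue
        attrs = feature.attributes
        if "transcript_id" not in attrs or not attrs["transcript_id"]:
            _fail(path, lineno, "exon feature without transcript_id")
        tid = attrs["transcript_id"][0]
        gid = attrs["gene_id"][0] if attrs.get("gene_id") else tid
        if feature.strand not in "+-":
            _fail(path, lineno, f"exon of {tid!r} lacks a +/- strand")
        try:
            iv = GenomicInterval(
                feature.seqid, feature.start - 1, feature.end, feature.strand
            )
        except ValueError as err:
            _fail(path, lineno, str(err))
        if tid in exons_by_tx:
            prev = exons_by_tx[tid][0]
            if prev.strand != iv.strand:
                _fail(path, lineno, f"transcript {tid!r} mixes strands")
            if prev.chrom != iv.chrom:
                _fail(path, lineno, f"transcript {tid!r} spans chromosomes")
        else:
            order.append(tid)
            locus_by_tx[tid] = gid
        exons_by_tx.setdefault(tid, []).append(iv)

    out: list[Transcript] = []
    for tid in order:
        exons = sorted(exons_by_tx[tid], key=lambda e: e.start)
        span = GenomicInterval(
            exons[0].chrom, exons[0].start, exons[-1].end, exons[0].strand
        )
        out.append(
            Transcript(
                transcript_id=tid,
                locus_id=locus_by_tx[tid],
                interval=span,
                exons=tuple(exons),
                biotype=biotype,
            )
        )
    return out


def write_gtf(transcripts: Sequence[Transcript], path: str | Path,
              source: str = "lincscreen") -> None:
    """Write exon features in GTF 2.2 (1-based inclusive coordinates)."""
    with _open_text(path, "wt") as fh:
        for t in transcripts:
            for ex in t.exons:
                attrs = (
                    f'gene_id "{t.locus_id}"; transcript_id "{t.transcript_id}";'
                )
                fh.write(
                    "\t".join(
                        (
                            ex.chrom,
                            source,
                            "exon",
                            str(ex.start + 1),
                            str(ex.end),
                            ".",
                            ex.strand,
                            ".",
                            attrs,
                        )
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# bedGraph

def read_bedgraph(path: str | Path) -> CoverageTrack:
    """Read a 4-column bedGraph (0-based half-open) into a CoverageTrack.

    Overlapping runs and negative values are rejected; the total signal is
    computed on load.
    """
    runs: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, line in _numbered_lines(path):
        f = line.split("\t")
        if len(f) < 4:
            _fail(path, lineno, f"expected 4 tab-separated fields, got {len(f)}")
        try:
            start, end, value = int(f[1]), int(f[2]), float(f[3])
        except ValueError:
            _fail(path, lineno, f"non-numeric fields {f[1:4]!r}")
        if value < 0:
            _fail(path, lineno, f"negative coverage value {value}")
        runs.setdefault(f[0], []).append((start, end, value))
    try:
        return CoverageTrack.from_runs(runs)
    except ValueError as err:
        raise FileFormatError(f"{path}: {err}") from err


def _format_value(v: float) -> str:
    """Decimal text preserving at least 6 significant digits; integers are
    written without a decimal point."""
    if v == int(v):
        return str(int(v))
    return repr(v)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for chrom in sorted(track.chromosomes()):
            for start, end, value in track.runs(chrom):
                fh.write(f"{chrom}\t{start}\t{end}\t{_format_value(value)}\n")


# ---------------------------------------------------------------------------
# FASTA (transcript sequences for the coding filter)

def read_fasta(path: str | Path) -> dict[str, str]:
    """Sequences keyed by record id; ids must match transcript_id values."""
    from Bio import SeqIO

    with _open_text(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


def load_transcripts(path: str | Path, biotype: str) -> list[Transcript]:
    """Dispatch on extension: .bed -> read_bed, .gtf/.gff -> read_gtf."""
    name = Path(path).name
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith(".bed"):
        return read_bed(path, biotype=biotype)
    if name.endswith((".gtf", ".gff")):
        return read_gtf(path, biotype=biotype)
    raise ValueError(f"cannot infer annotation format from {path!r} "
                     "(expected .bed or .gtf)")
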