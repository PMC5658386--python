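"""Partition a lncRNA catalogue into intergenic vs gene-overlapping.

A lncRNA is intergenic iff its full transcript span overlaps no
protein-coding gene span (strand-agnostic; an antisense lncRNA inside a
gene is not intergenic). Span-level overlap is the default — "intergenic"
conventionally excludes intronic lncRNAs — with an exon-level mode behind
a flag for catalogues where intronic transcripts should survive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

from .intervals import GenomicInterval, IntervalIndex, Transcript


@dataclass(frozen=True)
class IntergenicPartition:
    """Exhaustive, exclusive split of the input catalogue.

    ``overlapping`` carries, per transcript, the ids of the genes it hits
    (always >= 1); ``intergenic`` transcripts hit none.
    """

    intergenic: tuple[Transcript, ...]
    overlapping: tuple[tuple[Transcript, tuple[str, ...]], ...]

    @property
    def intergenic_ids(self) -> set[str]:
        return {t.transcript_id for t in self.intergenic}

    @property
    def overlapping_ids(self) -> set[str]:
        return {t.transcript_id for t, _ in self.overlapping}

    def write_tsv(self, path: str | Path) -> None:
        """transcript_id, status, comma-joined gene ids ('.' if none)."""
        with open(path, "w") as fh:
            fh.write("transcript_id\tstatus\tgene_ids\n")
            rows = [(t, "intergenic", ()) for t in self.intergenic]
            rows += [(t, "overlapping", gids) for t, gids in self.overlapping]
            for t, status, gids in rows:
                fh.write(
                    f"{t.transcript_id}\t{status}\t{','.join(gids) or '.'}\n"
                )


def _expanded(iv: GenomicInterval, margin: int) -> GenomicInterval:
    if margin == 0:
        return iv
    return GenomicInterval(iv.chrom, max(0, iv.start - margin), iv.end + margin,
                           iv.strand)


def classify_intergenic(
    lncs: list[Transcript],
    genes: list[Transcript],
    margin: int = 0,
    exon_level: bool = False,
) -> IntergenicPartition:
    """Split ``lncs`` by overlap with protein-coding gene annotations.

    Parameters
    ----------
    margin:
        Flanking buffer in bp added to each gene span before testing;
        0 (default) tests bare overlap only.
    exon_level:
        When True, test lncRNA exons against gene exons instead of span
        vs span, so intronic lncRNAs count as intergenic.

    Output order within each class follows input order. An empty gene list
    is degenerate but legal: a warning is issued and every transcript is
    classified intergenic.
    """
    if not genes:
        warnings.warn(
            "empty gene list: every lncRNA will be classified intergenic",
            stacklevel=2,
        )
    items: list[tuple[GenomicInterval, str]] = []
    for g in genes:
        if exon_level:
            items.extend((_expanded(ex, margin), g.locus_id) for ex in g.exons)
        else:
            items.append((_expanded(g.interval, margin), g.locus_id))
    index = IntervalIndex(items)

    intergenic: list[Transcript] = []
    overlapping: list[tuple[Transcript, tuple[str, ...]]] = []
    for t in lncs:
        probes = t.exons if exon_level else (t.interval,)
        gene_ids: dict[str, None] = {}  # insertion-ordered unique ids
        for probe in probes:
            for _, gid in index.query(probe):
                gene_ids[gid] = None
        if gene_ids:
            overlapping.append((t, tuple(gene_ids)))
        else:
            intergenic.append(t)
    return IntergenicPartition(tuple(intergenic), tuple(overlapping))
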