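"""Synthetic epigenome generator with planted ground truth.

Generates, from a single seed, a toy genome carrying protein-coding genes
and lncRNAs of known intergenic/overlapping status, two-condition
("pre"/"post" differentiation) coverage tracks for two histone marks with
promoter enrichment planted at a chosen subset of intergenic lncRNAs, and
TF peak calls at a subset of those — plus a truth manifest, so the entire
screen can be validated end to end with no external data.

Noise model: coverage is drawn per fixed-width bin as a count draw with
variance equal to the mean (Poisson) around a flat base rate; planted
promoters multiply the post-condition mean by ``enrich_fold`` over
``enrich_span`` bp centred on the TSS, in both marks jointly. An optional
negative-binomial overdispersion factor is available for heavier-tailed
noise. Distractor TF peaks are placed far from every promoter window so
the TF filter is exercised non-trivially.

Intergenic lncRNA TSSs are spaced at least ``2w + enrich_span`` apart so
that one promoter's planted signal cannot leak into another's window —
the simulation keeps planted and unplanted promoters statistically
independent.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .coverage import CoverageTrack
from .intervals import (
    BIOTYPE_CODING,
    BIOTYPE_LNCRNA,
    GenomicInterval,
    Transcript,
    overlaps,
    tss_of,
)
from .io import write_bed, write_bed_intervals, write_gtf, write_bedgraph
from .promoter import DEFAULT_WINDOW_HALF_WIDTH
from .screen import DEFAULT_MARKS

STATUS_INTERGENIC = "intergenic"
STATUS_OVERLAPPING = "overlapping"

_MAX_PLACEMENT_TRIES = 2000


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic screen.

    Defaults describe a 2 Mb single-chromosome genome at mean depth 30
    per bp with 8-fold promoter enrichment over 2 kb — deep and strong
    enough that the thresholded ratio call is essentially noise-free —
    and a 50-lncRNA catalogue of which 30 are intergenic, 10 carry
    planted enrichment in both marks and 4 of those carry a TF peak.
    """

    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 2_000_000}
    )
    n_genes: int = 10
    n_lnc: int = 50
    frac_intergenic: float = 0.6
    n_planted_marks: int = 10
    n_planted_tf: int = 4
    base_rate: float = 30.0
    enrich_fold: float = 8.0
    enrich_span: int = 2_000
    bin_size: int = 50
    marks: tuple[str, ...] = DEFAULT_MARKS
    gene_length_range: tuple[int, int] = (5_000, 50_000)
    lnc_length_range: tuple[int, int] = (1_000, 5_000)
    window_half_width: int = DEFAULT_WINDOW_HALF_WIDTH
    tf_peak_width: int = 400
    n_distractor_peaks: int = 10
    overdispersion: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        n_intergenic = self.n_intergenic
        if not (0 <= self.n_planted_tf <= self.n_planted_marks <= n_intergenic):
            raise ValueError(
                f"need n_planted_tf <= n_planted_marks <= n_intergenic, got "
                f"{self.n_planted_tf} / {self.n_planted_marks} / {n_intergenic}"
            )
        if self.enrich_fold < 1:
            raise ValueError("enrich_fold must be >= 1")
        if self.base_rate <= 0 or self.bin_size <= 0 or self.enrich_span <= 0:
            raise ValueError("base_rate, bin_size and enrich_span must be positive")
        if self.n_lnc > 0 and self.n_intergenic == 0 and self.frac_intergenic > 0:
            raise ValueError("frac_intergenic too small for n_lnc")

    @property
    def n_intergenic(self) -> int:
        return int(round(self.frac_intergenic * self.n_lnc))

    @property
    def min_tss_spacing(self) -> int:
        # keeps any planted enrichment out of every other promoter window
        return 2 * self.window_half_width + self.enrich_span


@dataclass(frozen=True)
class TruthRecord:
    status: str
    planted_marks: bool
    planted_tf: bool


@dataclass(frozen=True)
class TruthManifest:
    """Per-transcript ground truth, consistent with the SimConfig counts."""

    records: Mapping[str, TruthRecord]

    def _ids(self, pred) -> set[str]:
        return {tid for tid, r in self.records.items() if pred(r)}

    @property
    def intergenic_ids(self) -> set[str]:
        return self._ids(lambda r: r.status == STATUS_INTERGENIC)

    @property
    def overlapping_ids(self) -> set[str]:
        return self._ids(lambda r: r.status == STATUS_OVERLAPPING)

    @property
    def planted_mark_ids(self) -> set[str]:
        return self._ids(lambda r: r.planted_marks)

    @property
    def planted_tf_ids(self) -> set[str]:
        return self._ids(lambda r: r.planted_tf)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("transcript_id\tstatus\tplanted_marks\tplanted_tf\n")
            for tid, r in self.records.items():
                fh.write(
                    f"{tid}\t{r.status}\t{int(r.planted_marks)}\t{int(r.planted_tf)}\n"
                )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "TruthManifest":
        records: dict[str, TruthRecord] = {}
        with open(path) as fh:
            header = fh.readline()
            assert header.startswith("transcript_id")
            for line in fh:
                tid, status, pm, pt = line.rstrip("\n").split("\t")
                records[tid] = TruthRecord(status, bool(int(pm)), bool(int(pt)))
        return cls(records)


@dataclass(frozen=True)
class Fixture:
    """Everything one simulated screen needs, plus its ground truth."""

    cfg: SimConfig
    genes: tuple[Transcript, ...]
    lncs: tuple[Transcript, ...]
    manifest: TruthManifest
    tracks: Mapping[tuple[str, str], CoverageTrack]
    tf_peaks: tuple[GenomicInterval, ...]


def _pick_chrom(cfg: SimConfig, rng: np.random.Generator) -> tuple[str, int]:
    names = sorted(cfg.chrom_lengths)
    lengths = np.array([cfg.chrom_lengths[c] for c in names], dtype=float)
    idx = int(rng.choice(len(names), p=lengths / lengths.sum()))
    return names[idx], int(lengths[idx])


def _make_exons(
    iv: GenomicInterval, rng: np.random.Generator
) -> tuple[GenomicInterval, ...]:
    """Single exon, or two exons split by an intron when there is room."""
    if iv.length >= 2_000 and rng.random() < 0.5:
        intron_len = int(rng.integers(200, min(1_000, iv.length - 1_000)))
        e1_end = int(rng.integers(iv.start + 200, iv.end - intron_len - 200))
        return (
            GenomicInterval(iv.chrom, iv.start, e1_end, iv.strand),
            GenomicInterval(iv.chrom, e1_end + intron_len, iv.end, iv.strand),
        )
    return (GenomicInterval(iv.chrom, iv.start, iv.end, iv.strand),)


def _place_span(
    cfg: SimConfig,
    rng: np.random.Generator,
    length_range: tuple[int, int],
    accept,
) -> GenomicInterval:
    for _ in range(_MAX_PLACEMENT_TRIES):
        chrom, chrom_len = _pick_chrom(cfg, rng)
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        if length >= chrom_len:
            continue
        start = int(rng.integers(0, chrom_len - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        iv = GenomicInterval(chrom, start, start + length, strand)
        if accept(iv):
            return iv
    raise RuntimeError(
        "could not place a feature without forbidden overlaps after "
        f"{_MAX_PLACEMENT_TRIES} tries; use a larger genome or fewer features"
    )


def generate_annotation(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[list[Transcript], list[Transcript], TruthManifest]:
    """Place genes and lncRNAs and draw the planted subsets.

    Genes are uniform, mutually non-overlapping, 5-50 kb. Intergenic
    lncRNAs sit clear of all gene spans with TSSs spaced by at least
    ``cfg.min_tss_spacing``; "overlapping" lncRNAs intersect a gene by at
    least 100 bp. Deterministic given the generator state.
    """
    genes: list[Transcript] = []
    gene_spans: list[GenomicInterval] = []
    for i in range(cfg.n_genes):
        iv = _place_span(
            cfg, rng, cfg.gene_length_range,
            lambda iv: not any(overlaps(iv, g) for g in gene_spans),
        )
        gene_spans.append(iv)
        genes.append(
            Transcript(
                transcript_id=f"gene_{i + 1:03d}",
                locus_id=f"gene_{i + 1:03d}",
                interval=iv,
                exons=_make_exons(iv, rng),
                biotype=BIOTYPE_CODING,
            )
        )

    statuses = [STATUS_INTERGENIC] * cfg.n_intergenic
    statuses += [STATUS_OVERLAPPING] * (cfg.n_lnc - cfg.n_intergenic)
    rng.shuffle(statuses)

    lncs: list[Transcript] = []
    placed_tss: list[tuple[str, int]] = []

    def tss_clear(iv: GenomicInterval) -> bool:
        chrom = iv.chrom
        t = iv.start if iv.strand == "+" else iv.end - 1
        return all(
            c != chrom or abs(t - p) >= cfg.min_tss_spacing
            for c, p in placed_tss
        )

    for i, status in enumerate(statuses):
        if status == STATUS_INTERGENIC:
            iv = _place_span(
                cfg, rng, cfg.lnc_length_range,
                lambda iv: (
                    not any(overlaps(iv, g) for g in gene_spans)
                    and tss_clear(iv)
                ),
            )
        else:
            if not gene_spans:
                raise ValueError("overlapping lncRNAs require at least one gene")
            iv = _place_span(
                cfg, rng, cfg.lnc_length_range,
                lambda iv: (
                    any(iv.overlap_bp(g) >= 100 for g in gene_spans)
                    and tss_clear(iv)
                ),
            )
        placed_tss.append(
            (iv.chrom, iv.start if iv.strand == "+" else iv.end - 1)
        )
        lncs.append(
            Transcript(
                transcript_id=f"linc_{i + 1:03d}",
                locus_id=f"locus_{i + 1:03d}",
                interval=iv,
                exons=_make_exons(iv, rng),
                biotype=BIOTYPE_LNCRNA,
            )
        )

    intergenic_ids = sorted(
        t.transcript_id
        for t, s in zip(lncs, statuses)
        if s == STATUS_INTERGENIC
    )
    planted_marks = set(
        rng.choice(intergenic_ids, size=cfg.n_planted_marks, replace=False)
    ) if cfg.n_planted_marks else set()
    planted_tf = set(
        rng.choice(sorted(planted_marks), size=cfg.n_planted_tf, replace=False)
    ) if cfg.n_planted_tf else set()

    records = {
        t.transcript_id: TruthRecord(
            status=s,
            planted_marks=t.transcript_id in planted_marks,
            planted_tf=t.transcript_id in planted_tf,
        )
        for t, s in zip(lncs, statuses)
    }
    return genes, lncs, TruthManifest(records)


def _bin_overlap_fractions(
    n_bins: int, bin_size: int, start: int, end: int
) -> tuple[int, int, np.ndarray]:
    """Per-bin fraction of each bin covered by [start, end)."""
    lo = max(0, start // bin_size)
    hi = min(n_bins, -(-end // bin_size))
    idx = np.arange(lo, hi)
    bin_starts = idx * bin_size
    ov = np.minimum(bin_starts + bin_size, end) - np.maximum(bin_starts, start)
    return lo, hi, np.clip(ov, 0, bin_size) / bin_size


def generate_tracks(
    cfg: SimConfig,
    lncs: list[Transcript],
    manifest: TruthManifest,
    rng: np.random.Generator,
) -> tuple[dict[tuple[str, str], CoverageTrack], list[GenomicInterval]]:
    """Draw per-bin count noise around the (optionally enriched) mean and
    place TF peaks.

    Post-condition means at planted promoters are multiplied by
    ``enrich_fold`` over ``enrich_span`` bp centred on the TSS, jointly in
    both marks; pre-condition means are flat. TF peaks are
    ``tf_peak_width`` bp centred on planted-TF TSSs, plus distractor
    peaks placed clear of every promoter window.
    """
    planted = manifest.planted_mark_ids
    chrom_names = sorted(cfg.chrom_lengths)

    base_means: dict[str, np.ndarray] = {}
    post_means: dict[str, np.ndarray] = {}
    for chrom in chrom_names:
        n_bins = -(-cfg.chrom_lengths[chrom] // cfg.bin_size)
        base_means[chrom] = np.full(n_bins, cfg.base_rate, dtype=float)
        post_means[chrom] = base_means[chrom].copy()
    for t in lncs:
        if t.transcript_id not in planted:
            continue
        chrom, tss = tss_of(t)
        half = cfg.enrich_span // 2
        start = max(0, tss - half)
        end = min(cfg.chrom_lengths[chrom], tss + half)
        n_bins = post_means[chrom].size
        lo, hi, frac = _bin_overlap_fractions(n_bins, cfg.bin_size, start, end)
        post_means[chrom][lo:hi] += cfg.base_rate * (cfg.enrich_fold - 1) * frac

    def draw(mean: np.ndarray) -> np.ndarray:
        if cfg.overdispersion:
            d = cfg.overdispersion
            return rng.negative_binomial(mean / d, 1.0 / (1.0 + d)).astype(float)
        return rng.poisson(mean).astype(float)

    tracks: dict[tuple[str, str], CoverageTrack] = {}
    for mark in cfg.marks:
        for cond, means in (("pre", base_means), ("post", post_means)):
            runs = {}
            for chrom in chrom_names:
                chrom_len = cfg.chrom_lengths[chrom]
                values = draw(means[chrom])
                starts = np.arange(values.size, dtype=np.int64) * cfg.bin_size
                ends = np.minimum(starts + cfg.bin_size, chrom_len)
                runs[chrom] = (starts, ends, values)
            tracks[(mark, cond)] = CoverageTrack(runs)

    tf_peaks: list[GenomicInterval] = []
    half_peak = cfg.tf_peak_width // 2
    for t in lncs:
        if t.transcript_id in manifest.planted_tf_ids:
            chrom, tss = tss_of(t)
            start = max(0, tss - half_peak)
            tf_peaks.append(
                GenomicInterval(chrom, start, start + cfg.tf_peak_width)
            )
    all_tss = [tss_of(t) for t in lncs]
    clearance = cfg.window_half_width + cfg.tf_peak_width
    for _ in range(cfg.n_distractor_peaks):
        for _try in range(_MAX_PLACEMENT_TRIES):
            chrom, chrom_len = _pick_chrom(cfg, rng)
            center = int(rng.integers(half_peak, chrom_len - half_peak))
            if all(
                c != chrom or abs(center - p) >= clearance for c, p in all_tss
            ):
                tf_peaks.append(
                    GenomicInterval(
                        chrom, center - half_peak, center - half_peak + cfg.tf_peak_width
                    )
                )
                break
        else:
            raise RuntimeError(
                "could not place a distractor TF peak clear of all promoter "
                "windows; use a larger genome"
            )
    return tracks, tf_peaks


def simulate(cfg: SimConfig = SimConfig()) -> Fixture:
    """Generate a complete fixture from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    genes, lncs, manifest = generate_annotation(cfg, rng)
    tracks, tf_peaks = generate_tracks(cfg, lncs, manifest, rng)
    return Fixture(
        cfg=cfg,
        genes=tuple(genes),
        lncs=tuple(lncs),
        manifest=manifest,
        tracks=tracks,
        tf_peaks=tuple(tf_peaks),
    )


def write_fixture(fix: Fixture, outdir: str | Path) -> dict[str, Path]:
    """Write the fixture in standard formats; re-reading through the io
    module reproduces the in-memory objects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["genes"] = outdir / "genes.gtf"
    write_gtf(list(fix.genes), paths["genes"])
    paths["lncs"] = outdir / "lncs.bed"
    write_bed(list(fix.lncs), paths["lncs"])
    for (mark, cond), track in fix.tracks.items():
        key = f"track:{mark}:{cond}"
        paths[key] = outdir / f"{mark}_{cond}.bedGraph"
        write_bedgraph(track, paths[key])
    paths["tf_peaks"] = outdir / "tf_peaks.bed"
    write_bed_intervals(
        list(fix.tf_peaks), paths["tf_peaks"],
        names=[f"peak_{i + 1}" for i in range(len(fix.tf_peaks))],
    )
    paths["truth"] = outdir / "truth.tsv"
    fix.manifest.write_tsv(paths["truth"])
    paths["simconfig"] = outdir / "simconfig.json"
    cfg_dict = dataclasses.asdict(fix.cfg)
    cfg_dict["chrom_lengths"] = dict(cfg_dict["chrom_lengths"])
    with open(paths["simconfig"], "w") as fh:
        json.dump(cfg_dict, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
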