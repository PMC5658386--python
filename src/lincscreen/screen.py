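"""The four-stage lincRNA screen cascade.

Stages, mirroring the narrative order of the original genome-wide screen
(catalogue -> intergenic -> promoter marks increased -> TF-bound):

1. intergenic filtering against protein-coding gene spans;
2. (optional) ORF-length coding filter, when sequences are supplied;
3. per-mark differential promoter calls; a survivor must be "increased"
   in all configured marks (conjunction) by default;
4. transcription-factor filter: >= ``tf_min_overlap`` bp of the promoter
   window covered by TF peaks. Peak presence, not TF signal density, is
   the implemented rule: the TF track enters the screen as binding sites.

Alongside the survivor cascade the screen reports a Venn accounting of
the per-mark increased sets and the TF-bound set, and ranks the final
candidates by their post-differentiation density in a key mark
(H3K4me3 by default) with a deterministic lexicographic tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import AbstractSet, Mapping, Sequence

from .coverage import CoverageTrack
from .intergenic import IntergenicPartition, classify_intergenic
from .intervals import GenomicInterval, IntervalIndex, Transcript
from .orf import OrfReport, coding_flag, longest_orf
from .promoter import (
    CONDITION_POST,
    CONDITION_PRE,
    CONDITIONS,
    DEFAULT_FOLD_THRESHOLD,
    DEFAULT_PSEUDOCOUNT,
    DEFAULT_WINDOW_HALF_WIDTH,
    DifferentialCall,
    PromoterWindow,
    differential_call,
    promoter_window,
    window_density,
)

DEFAULT_MARKS = ("H3K4me3", "H3K27ac")
TF_LABEL = "TF"

STAGE_INPUT = "input"
STAGE_INTERGENIC = "intergenic"
STAGE_NONCODING = "noncoding"
STAGE_MARKS = "marks_increased"
STAGE_TF = "tf_bound"


@dataclass(frozen=True)
class ScreenConfig:
    """All screen parameters; the screen itself is deterministic.

    w: promoter half-width in bp (+/- w around the TSS).
    tau: fold threshold on the pseudocounted post/pre density ratio.
    eps: pseudocount added to both densities.
    marks: histone marks that must each have a pre and a post track.
    require_all_marks: survivors must be increased in every mark
        (True, default) or in at least one (False).
    tf_min_overlap: minimum bp of promoter window covered by TF peaks.
    coding_max_orf_aa: ORF cutoff for the optional coding filter;
        None disables the stage even when sequences are supplied.
    key_mark: ranking mark for candidates (defaults to the first mark).
    collapse_loci: keep only the best-ranked transcript per locus_id.
    intergenic_margin / intergenic_exon_level: forwarded to the
        intergenic filter.
    """

    w: int = DEFAULT_WINDOW_HALF_WIDTH
    tau: float = DEFAULT_FOLD_THRESHOLD
    eps: float = DEFAULT_PSEUDOCOUNT
    marks: tuple[str, ...] = DEFAULT_MARKS
    require_all_marks: bool = True
    tf_min_overlap: int = 1
    coding_max_orf_aa: int | None = None
    key_mark: str | None = None
    collapse_loci: bool = False
    intergenic_margin: int = 0
    intergenic_exon_level: bool = False

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ValueError("w must be positive")
        if self.tau <= 1:
            raise ValueError("tau must exceed 1")
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if not self.marks:
            raise ValueError("at least one mark is required")
        if self.tf_min_overlap < 1:
            raise ValueError("tf_min_overlap must be >= 1 bp")
        if self.key_mark is not None and self.key_mark not in self.marks:
            raise ValueError(f"key_mark {self.key_mark!r} not in marks {self.marks}")

    @property
    def ranking_mark(self) -> str:
        return self.key_mark if self.key_mark is not None else self.marks[0]


@dataclass(frozen=True)
class Candidate:
    transcript_id: str
    locus_id: str
    post_densities: Mapping[str, float]  # mark -> post-condition density
    tf_overlap_bp: int


@dataclass(frozen=True)
class ScreenResult:
    """The cascade's full audit trail.

    ``stage_counts`` is ordered and non-increasing; ``venn`` maps each
    non-empty subset of {mark..., TF} to its disjoint region count;
    ``candidates`` are the ranked final survivors.
    """

    stage_counts: tuple[tuple[str, int], ...]
    survivors: Mapping[str, tuple[str, ...]]
    partition: IntergenicPartition
    calls: tuple[DifferentialCall, ...]
    densities: Mapping[tuple[str, str, str], float]  # (tid, mark, cond)
    tf_overlap: Mapping[str, int]
    venn: Mapping[tuple[str, ...], int]
    candidates: tuple[Candidate, ...]
    orf_reports: tuple[OrfReport, ...] = field(default=())

    @property
    def candidate_ids(self) -> tuple[str, ...]:
        return tuple(c.transcript_id for c in self.candidates)


def venn_counts(
    sets: Mapping[str, AbstractSet[str]]
) -> dict[tuple[str, ...], int]:
    """Disjoint region counts for 2 or 3 labelled sets.

    Every non-empty label subset gets a key (labels in input order);
    each element is counted exactly once, in the region of all labels
    containing it, so region counts sum to |union|.
    """
    labels = list(sets)
    if not 2 <= len(labels) <= 3:
        raise ValueError(f"venn accounting needs 2 or 3 sets, got {len(labels)}")
    regions: dict[tuple[str, ...], int] = {}
    for size in range(1, len(labels) + 1):
        for combo in combinations(labels, size):
            regions[combo] = 0
    universe = set().union(*sets.values())
    for element in universe:
        membership = tuple(lb for lb in labels if element in sets[lb])
        regions[membership] += 1
    return regions


def tf_overlap_bp(win: PromoterWindow, peaks: IntervalIndex) -> int:
    """bp of the window covered by the union of overlapping TF peaks.

    Overlapping peaks are merged before summing, so stacked peak calls do
    not double-count coverage.
    """
    iv = win.interval
    hits = peaks.query(iv)
    if not hits:
        return 0
    clipped = sorted(
        (max(p.start, iv.start), min(p.end, iv.end)) for p, _ in hits
    )
    covered = 0
    cur_s, cur_e = clipped[0]
    for s, e in clipped[1:]:
        if s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
    covered += cur_e - cur_s
    return covered


def rank_candidates(
    survivors: Sequence[str],
    densities: Mapping[tuple[str, str, str], float],
    key_mark: str,
    condition: str = CONDITION_POST,
) -> list[str]:
    """Transcript ids by descending (key_mark, condition) density; ties
    break lexicographically on transcript_id."""
    missing = [t for t in survivors if (t, key_mark, condition) not in densities]
    if missing:
        raise KeyError(
            f"no ({key_mark}, {condition}) density for {missing[:5]}"
        )
    return sorted(
        survivors, key=lambda t: (-densities[(t, key_mark, condition)], t)
    )


def _validate_inputs(
    lncs: Sequence[Transcript],
    tracks: Mapping[tuple[str, str], CoverageTrack],
    cfg: ScreenConfig,
) -> None:
    for mark in cfg.marks:
        for cond in CONDITIONS:
            if (mark, cond) not in tracks:
                raise ValueError(f"missing coverage track for ({mark}, {cond})")
    lnc_chroms = {t.chrom for t in lncs}
    for (mark, cond), track in tracks.items():
        if lnc_chroms and not (lnc_chroms & track.chromosomes()):
            raise ValueError(
                f"chromosome names of ({mark}, {cond}) track "
                f"({sorted(track.chromosomes())[:3]}...) share nothing with "
                f"the lncRNA annotation ({sorted(lnc_chroms)[:3]}...); "
                "check naming conventions"
            )


def run_screen(
    lncs: Sequence[Transcript],
    genes: Sequence[Transcript],
    tracks: Mapping[tuple[str, str], CoverageTrack],
    tf_peaks: Sequence[GenomicInterval],
    cfg: ScreenConfig = ScreenConfig(),
    chrom_lengths: Mapping[str, int] | None = None,
    sequences: Mapping[str, str] | None = None,
) -> ScreenResult:
    """Run the full cascade and return its audit trail.

    ``chrom_lengths`` defaults to the largest run end per chromosome over
    all coverage tracks. ``sequences`` (transcript_id -> sequence)
    activates the ORF coding filter when ``cfg.coding_max_orf_aa`` is set.
    """
    _validate_inputs(lncs, tracks, cfg)
    if chrom_lengths is None:
        chrom_lengths = {}
        for track in tracks.values():
            for chrom in track.chromosomes():
                chrom_lengths[chrom] = max(
                    chrom_lengths.get(chrom, 0), track.chrom_length(chrom)
                )

    stage_counts: list[tuple[str, int]] = [(STAGE_INPUT, len(lncs))]
    survivors: dict[str, tuple[str, ...]] = {
        STAGE_INPUT: tuple(t.transcript_id for t in lncs)
    }

    # stage: intergenic
    partition = classify_intergenic(
        list(lncs), list(genes),
        margin=cfg.intergenic_margin, exon_level=cfg.intergenic_exon_level,
    )
    pool: list[Transcript] = list(partition.intergenic)
    stage_counts.append((STAGE_INTERGENIC, len(pool)))
    survivors[STAGE_INTERGENIC] = tuple(t.transcript_id for t in pool)

    # optional stage: coding filter
    orf_reports: list[OrfReport] = []
    if sequences is not None and cfg.coding_max_orf_aa is not None:
        kept = []
        for t in pool:
            if t.transcript_id not in sequences:
                raise KeyError(
                    f"no sequence provided for transcript {t.transcript_id}"
                )
            report = longest_orf(sequences[t.transcript_id], t.transcript_id)
            orf_reports.append(report)
            if not coding_flag(report, cfg.coding_max_orf_aa):
                kept.append(t)
        pool = kept
        stage_counts.append((STAGE_NONCODING, len(pool)))
        survivors[STAGE_NONCODING] = tuple(t.transcript_id for t in pool)

    # stage: differential promoter marks
    windows: dict[str, PromoterWindow] = {}
    densities: dict[tuple[str, str, str], float] = {}
    calls: list[DifferentialCall] = []
    increased_by_mark: dict[str, set[str]] = {m: set() for m in cfg.marks}
    def _density(track: CoverageTrack, win: PromoterWindow) -> float:
        # a signal-free track is a degenerate but legal screen input: every
        # window density is 0, so every ratio is 1 and nothing is called
        if track.total_signal == 0:
            return 0.0
        return window_density(track, win)

    for t in pool:
        win = promoter_window(t, cfg.w, chrom_lengths[t.chrom])
        windows[t.transcript_id] = win
        for mark in cfg.marks:
            d_pre = _density(tracks[(mark, CONDITION_PRE)], win)
            d_post = _density(tracks[(mark, CONDITION_POST)], win)
            densities[(t.transcript_id, mark, CONDITION_PRE)] = d_pre
            densities[(t.transcript_id, mark, CONDITION_POST)] = d_post
            call = differential_call(
                t.transcript_id, mark, d_pre, d_post, cfg.tau, cfg.eps
            )
            calls.append(call)
            if call.increased:
                increased_by_mark[mark].add(t.transcript_id)

    if cfg.require_all_marks:
        marks_ok = set.intersection(*increased_by_mark.values())
    else:
        marks_ok = set.union(*increased_by_mark.values())
    mark_survivors = [t for t in pool if t.transcript_id in marks_ok]
    stage_counts.append((STAGE_MARKS, len(mark_survivors)))
    survivors[STAGE_MARKS] = tuple(t.transcript_id for t in mark_survivors)

    # stage: TF peak overlap with the promoter window
    peak_index = IntervalIndex((p, i) for i, p in enumerate(tf_peaks))
    tf_bp: dict[str, int] = {
        t.transcript_id: tf_overlap_bp(windows[t.transcript_id], peak_index)
        for t in pool
    }
    tf_set = {tid for tid, bp in tf_bp.items() if bp >= cfg.tf_min_overlap}
    final = [t for t in mark_survivors if t.transcript_id in tf_set]
    stage_counts.append((STAGE_TF, len(final)))
    survivors[STAGE_TF] = tuple(t.transcript_id for t in final)

    counts = [n for _, n in stage_counts]
    assert counts == sorted(counts, reverse=True), (
        f"cascade counts must be non-increasing, got {stage_counts}"
    )

    venn_sets: dict[str, set[str]] = dict(increased_by_mark)
    venn_sets[TF_LABEL] = tf_set
    venn = venn_counts(venn_sets)

    ranked = rank_candidates(
        [t.transcript_id for t in final], densities, cfg.ranking_mark
    )
    by_id = {t.transcript_id: t for t in final}
    candidates = [
        Candidate(
            transcript_id=tid,
            locus_id=by_id[tid].locus_id,
            post_densities={
                m: densities[(tid, m, CONDITION_POST)] for m in cfg.marks
            },
            tf_overlap_bp=tf_bp[tid],
        )
        for tid in ranked
    ]
    if cfg.collapse_loci:
        seen: set[str] = set()
        collapsed = []
        for c in candidates:
            if c.locus_id not in seen:
                seen.add(c.locus_id)
                collapsed.append(c)
        candidates = collapsed

    return ScreenResult(
        stage_counts=tuple(stage_counts),
        survivors=survivors,
        partition=partition,
        calls=tuple(calls),
        densities=densities,
        tf_overlap=tf_bp,
        venn=venn,
        candidates=tuple(candidates),
        orf_reports=tuple(orf_reports),
    )
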