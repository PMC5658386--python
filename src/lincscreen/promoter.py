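"""Promoter windows, depth-normalised window densities, differential calls.

The promoter of a transcript is the +/- w bp window around its TSS
(w = 2,500 bp by default), clamped to chromosome bounds. The signal
density over a window is the bp-mean coverage scaled per million units of
genome-wide track signal — an RPM-like quantity, so windows are comparable
between tracks of different sequencing depth and multiplying a whole track
by a constant changes no density. A promoter is called "increased upon
differentiation" for a mark when the pseudocounted post/pre density ratio
reaches the fold threshold:

    ratio = (d_post + eps) / (d_pre + eps) >= tau

There is no replicate structure here, hence no statistical test; the call
is a thresholded ratio and tau, eps are explicit screen parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .coverage import CoverageTrack
from .intervals import GenomicInterval, Transcript, tss_of

CONDITION_PRE = "pre"
CONDITION_POST = "post"
CONDITIONS = (CONDITION_PRE, CONDITION_POST)

DEFAULT_WINDOW_HALF_WIDTH = 2500
DEFAULT_FOLD_THRESHOLD = 2.0
DEFAULT_PSEUDOCOUNT = 0.25


@dataclass(frozen=True)
class PromoterWindow:
    """Unstranded span [TSS - w, TSS + w) clamped to [0, chrom length)."""

    transcript_id: str
    interval: GenomicInterval


@dataclass(frozen=True)
class DensityRecord:
    transcript_id: str
    mark: str
    condition: str
    density: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.density) and self.density >= 0):
            raise ValueError(
                f"{self.transcript_id}/{self.mark}/{self.condition}: "
                f"density must be finite and >= 0, got {self.density}"
            )


@dataclass(frozen=True)
class DifferentialCall:
    transcript_id: str
    mark: str
    d_pre: float
    d_post: float
    ratio: float
    increased: bool


def promoter_window(t: Transcript, w: int, chrom_len: int) -> PromoterWindow:
    """The +/- w bp window around the TSS, clamped to the chromosome.

    Length is 2w except near chromosome edges; the window is never empty.
    A TSS at or beyond ``chrom_len`` indicates an annotation/genome
    mismatch and is an error.
    """
    if w <= 0:
        raise ValueError(f"window half-width must be positive, got {w}")
    chrom, tss = tss_of(t)
    if tss >= chrom_len:
        raise ValueError(
            f"transcript {t.transcript_id}: TSS {tss} beyond {chrom} "
            f"length {chrom_len} (annotation/genome mismatch?)"
        )
    start = max(0, tss - w)
    end = min(chrom_len, tss + w)
    return PromoterWindow(t.transcript_id, GenomicInterval(chrom, start, end))


def window_density(track: CoverageTrack, win: PromoterWindow) -> float:
    """bp-mean coverage in the window per million units of total signal.

        density = (window signal / window length) * 1e6 / total_signal

    Partial run overlaps are pro-rated by overlapping bp. A track with no
    signal at all cannot be normalised and is rejected.
    """
    total = track.total_signal
    if total <= 0:
        raise ValueError("cannot normalise against a track with zero total signal")
    iv = win.interval
    mean_cov = track.window_sum(iv.chrom, iv.start, iv.end) / iv.length
    return mean_cov * (1e6 / total)


def differential_call(
    transcript_id: str,
    mark: str,
    d_pre: float,
    d_post: float,
    tau: float = DEFAULT_FOLD_THRESHOLD,
    eps: float = DEFAULT_PSEUDOCOUNT,
) -> DifferentialCall:
    """Threshold the pseudocounted post/pre ratio at fold ``tau``.

    ``eps > 0`` stabilises empty windows: with both densities 0 the ratio
    is exactly 1 and the call is negative for any ``tau > 1``.
    """
    if tau <= 1:
        raise ValueError(f"fold threshold tau must exceed 1, got {tau}")
    if eps <= 0:
        raise ValueError(f"pseudocount eps must be positive, got {eps}")
    ratio = (d_post + eps) / (d_pre + eps)
    return DifferentialCall(
        transcript_id=transcript_id,
        mark=mark,
        d_pre=d_pre,
        d_post=d_post,
        ratio=ratio,
        increased=ratio >= tau,
    )
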