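"""Shared fixtures: hand-built annotations and one simulated screen."""

from __future__ import annotations

import numpy as np
import pytest

from lincscreen import (
    CoverageTrack,
    GenomicInterval,
    SimConfig,
    Transcript,
    simulate,
)


def make_tx(
    tid: str,
    chrom: str = "chr1",
    start: int = 1000,
    end: int = 5000,
    strand: str = "+",
    biotype: str = "lncRNA",
    locus: str | None = None,
    exons: tuple[tuple[int, int], ...] | None = None,
) -> Transcript:
    ex = (
        tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons)
        if exons
        else ()
    )
    return Transcript(
        transcript_id=tid,
        locus_id=locus or tid,
        interval=GenomicInterval(chrom, start, end, strand),
        exons=ex,
        biotype=biotype,
    )


def random_intervals(
    rng: np.random.Generator, n: int, chroms=("chr1", "chr2"), max_pos=10_000
) -> list[GenomicInterval]:
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, max_pos - 1))
        end = int(rng.integers(start + 1, min(start + 500, max_pos) + 1))
        out.append(GenomicInterval(chrom, start, end))
    return out


def uniform_track(chrom="chr1", length=10_000, value=2.0) -> CoverageTrack:
    return CoverageTrack.from_runs({chrom: [(0, length, value)]})


@pytest.fixture(scope="session")
def default_fixture():
    """One default-condition simulated screen (2 Mb, depth 30, fold 8)."""
    return simulate(SimConfig(seed=0))


@pytest.fixture(scope="session")
def small_sim_config():
    """A reduced genome for fast CLI round trips."""
    return SimConfig(
        chrom_lengths={"chr1": 600_000},
        n_genes=3,
        n_lnc=12,
        frac_intergenic=0.5,
        n_planted_marks=4,
        n_planted_tf=2,
        n_distractor_peaks=3,
        seed=7,
    )
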