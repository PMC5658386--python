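"""Piecewise-constant coverage tracks.

A :class:`CoverageTrack` stores, per chromosome, sorted non-overlapping
runs of constant per-base signal; positions outside any run have value 0
(standard bedGraph semantics). The genome-wide bp-weighted total is cached
and used to depth-normalise window densities.
"""

from __future__ import annotations

from typing import Iterator, Mapping, Sequence

import numpy as np


class CoverageTrack:
    """Per-chromosome runs of (start, end, value >= 0) with a cached total.

    ``total_signal`` is the bp-weighted sum ``sum(value * (end - start))``
    over all runs of all chromosomes.
    """

    def __init__(self, runs: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        total = 0.0
        for chrom, (starts, ends, values) in runs.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            if not (starts.shape == ends.shape == values.shape):
                raise ValueError(f"{chrom}: run arrays have mismatched lengths")
            if starts.size:
                if np.any(starts < 0) or np.any(ends <= starts):
                    raise ValueError(f"{chrom}: runs must satisfy 0 <= start < end")
                if np.any(values < 0):
                    raise ValueError(f"{chrom}: negative coverage value")
                if np.any(starts[1:] < ends[:-1]):
                    bad = int(np.argmax(starts[1:] < ends[:-1]))
                    raise ValueError(
                        f"{chrom}: overlapping runs near positions "
                        f"{int(starts[bad])}-{int(ends[bad])} and "
                        f"{int(starts[bad + 1])}-{int(ends[bad + 1])}"
                    )
                total += float(np.sum(values * (ends - starts)))
            self._runs[chrom] = (starts, ends, values)
        self._total = total

    @classmethod
    def from_runs(
        cls, runs: Mapping[str, Sequence[tuple[int, int, float]]]
    ) -> "CoverageTrack":
        """Build from per-chromosome (start, end, value) triples; runs are
        sorted here, overlap is rejected."""
        arrays = {}
        for chrom, triples in runs.items():
            triples = sorted(triples)
            if triples:
                s, e, v = map(np.asarray, zip(*triples))
            else:
                s = e = np.empty(0, dtype=np.int64)
                v = np.empty(0, dtype=np.float64)
            arrays[chrom] = (s, e, v)
        return cls(arrays)

    @property
    def total_signal(self) -> float:
        return self._total

    def chromosomes(self) -> set[str]:
        return set(self._runs)

    def chrom_length(self, chrom: str) -> int:
        """End of the last run on ``chrom`` (0 if the chromosome is absent)."""
        runs = self._runs.get(chrom)
        if runs is None or runs[1].size == 0:
            return 0
        return int(runs[1][-1])

    def runs(self, chrom: str) -> Iterator[tuple[int, int, float]]:
        starts, ends, values = self._runs.get(
            chrom, (np.empty(0, np.int64),) * 2 + (np.empty(0, np.float64),)
        )
        for s, e, v in zip(starts, ends, values):
            yield int(s), int(e), float(v)

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        """Total signal over ``[start, end)``; partial run overlaps are
        pro-rated by the number of overlapping bp."""
        if start < 0 or end <= start:
            raise ValueError(f"invalid window [{start},{end})")
        entry = self._runs.get(chrom)
        if entry is None:
            return 0.0
        starts, ends, values = entry
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if lo >= hi:
            return 0.0
        ov = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        return float(np.sum(values[lo:hi] * ov))

    def scaled(self, factor: float) -> "CoverageTrack":
        """A new track with every run value multiplied by ``factor > 0``."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return CoverageTrack(
            {c: (s, e, v * factor) for c, (s, e, v) in self._runs.items()}
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoverageTrack):
            return NotImplemented
        if set(self._runs) != set(other._runs):
            return False
        for chrom, (s, e, v) in self._runs.items():
            os, oe, ov = other._runs[chrom]
            if not (
                np.array_equal(s, os)
                and np.array_equal(e, oe)
                and np.array_equal(v, ov)
            ):
                return False
        return True
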