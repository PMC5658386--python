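"""ORF-length surrogate for coding-potential assessment.

Dedicated coding-potential classifiers score codon usage, conservation and
more; this module deliberately implements only the transparent core
criterion — the longest sense-strand open reading frame — as an optional,
clearly documented cascade stage. The 100 aa default cutoff is the
classical lncRNA ORF convention.

Search rules: the three forward frames of the annotated sense strand are
scanned for ATG...{TAA, TAG, TGA}; ORF length is counted in amino acids
excluding the stop; ORFs that never reach an in-sequence stop are not
counted; a codon containing N can be neither start, stop nor coding and
breaks any ORF running through it; U is read as T.
"""

from __future__ import annotations

from dataclasses import dataclass

START_CODON = "ATG"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_VALID = frozenset("ACGTN")

DEFAULT_MAX_ORF_AA = 100


@dataclass(frozen=True)
class OrfReport:
    transcript_id: str
    longest_orf_aa: int
    frame: int  # 0/1/2; lowest frame index on ties


def longest_orf(seq: str, transcript_id: str = "") -> OrfReport:
    """Longest ATG-to-stop ORF over the three forward frames.

    Returns length in aa (stop excluded) and the frame carrying it; ties
    across frames resolve to the lowest frame index. Empty or start-less
    sequences report 0 aa in frame 0.
    """
    s = seq.upper().replace("U", "T")
    bad = set(s) - _VALID
    if bad:
        raise ValueError(
            f"transcript {transcript_id or '<seq>'}: invalid characters "
            f"{sorted(bad)} (alphabet is A/C/G/T/U/N)"
        )
    best_aa, best_frame = 0, 0
    for frame in range(3):
        earliest_start: int | None = None  # codon index of earliest open ATG
        for ci in range((len(s) - frame) // 3):
            codon = s[frame + 3 * ci : frame + 3 * ci + 3]
            if "N" in codon:
                earliest_start = None  # untranslatable codon breaks open ORFs
            elif codon in STOP_CODONS:
                if earliest_start is not None:
                    aa = ci - earliest_start
                    if aa > best_aa:
                        best_aa, best_frame = aa, frame
                    earliest_start = None
            elif codon == START_CODON and earliest_start is None:
                earliest_start = ci
    return OrfReport(transcript_id, best_aa, best_frame)


def coding_flag(report: OrfReport, max_orf_aa: int | None = DEFAULT_MAX_ORF_AA) -> bool:
    """True iff the longest ORF reaches ``max_orf_aa`` (inclusive boundary).

    ``max_orf_aa=None`` disables the filter: everything passes as
    non-coding.
    """
    if max_orf_aa is None:
        return False
    return report.longest_orf_aa >= max_orf_aa


def write_orf_tsv(reports: list[OrfReport], path, max_orf_aa: int | None) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tlongest_orf_aa\tframe\tcoding_flag\n")
        for r in reports:
            fh.write(
                f"{r.transcript_id}\t{r.longest_orf_aa}\t{r.frame}\t"
                f"{coding_flag(r, max_orf_aa)}\n"
            )
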