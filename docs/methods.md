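# Methods

## The screening procedure

`lincscreen` implements a genome-wide cascade for finding long intergenic
non-coding RNAs (lincRNAs) whose promoters gain activating chromatin marks
between two cellular states — the design used to pull
differentiation-regulated lincRNAs out of a large lncRNA catalogue in
adipocyte biology, where the two states are pre- and post-adipogenic
differentiation and the final filter is binding of the master adipogenic
transcription factor PPARγ.

Given a lncRNA catalogue, a protein-coding annotation, per-mark/per-state
coverage tracks and TF peak calls, the cascade is:

1. **Intergenic filter.** A lncRNA survives iff its transcript span
   overlaps no protein-coding gene span (strand-agnostic, half-open
   coordinates). Span-level overlap is the default because "intergenic"
   conventionally excludes intronic and antisense transcripts; an
   exon-level mode (`exon_level=True`) and a flanking margin are exposed
   for catalogues where those conventions differ.
2. **Coding filter (optional).** When transcript sequences are supplied, a
   transcript with a sense-strand ORF of ≥ `coding_max_orf_aa` amino acids
   (default 100 aa, the classical lncRNA convention) is removed. This is a
   deliberately transparent surrogate for full coding-potential
   classifiers, which score codon usage and conservation as well.
3. **Differential promoter marking.** For each surviving transcript the
   promoter window `[TSS − w, TSS + w)` (default w = 2,500 bp) is scored
   in each histone mark (default H3K4me3 and H3K27ac) and each condition:

       density = (mean per-bp coverage in window) × 10⁶ / total track signal

   an RPM-like normalisation that cancels sequencing depth. The mark is
   "increased" when `(d_post + ε)/(d_pre + ε) ≥ τ` (defaults τ = 2,
   ε = 0.25). A transcript survives when all configured marks increase
   (conjunction; `require_all_marks=False` relaxes to disjunction). With
   no replicate structure in the inputs, the call is a thresholded ratio,
   not a significance test.
4. **TF filter.** A survivor must have ≥ `tf_min_overlap` bp (default
   1 bp) of its promoter window covered by the union of TF peaks — peak
   presence, not TF signal density, because peak calls are the natural
   currency of published TF ChIP-seq. Overlapping peaks are merged before
   counting so stacked calls never double-count.

Candidates are ranked by descending post-state density of a key mark
(H3K4me3 by default), with a lexicographic transcript-id tie-break so the
output is deterministic. Alongside the cascade the screen reports a Venn
accounting: each transcript in the union of {mark₁ increased, mark₂
increased, TF-bound} is counted in exactly one region, so region counts
sum to the union size.

## Coordinate conventions and numerical choices

* All coordinates are 0-based half-open internally (BED convention); GTF
  is converted at the file boundary. Adjacent intervals do not overlap.
* Minus-strand TSS is `end − 1`, the last 0-based transcribed base, so
  ± w windows treat both strands symmetrically.
* Windows are clamped at chromosome edges rather than discarded; the
  density denominator uses the clamped length.
* The window `[TSS − w, TSS + w)` has even length, so reflecting all
  coordinates (`x → L − x`, strands swapped) shifts it by exactly 1 bp.
  Densities are therefore mirror-symmetric only to ~1/(2w) relative
  (≈ 2×10⁻⁴ at the default w); classifications and candidate sets are
  unaffected at realistic depths, and the test suite asserts symmetry at
  a 10⁻³ relative tolerance.
* Depth rescaling: multiplying a track by a constant cancels exactly in
  the density formula; for power-of-two factors this is bit-exact in
  floating point (exponent shift only), which the tests exploit.
* A coverage track with zero total signal cannot be normalised;
  `window_density` rejects it. The cascade treats such a degenerate track
  as an all-zero density source (every ratio is 1, nothing is called) so
  that screens over empty tracks complete with an honest empty result.
* Chromosome names are matched as exact strings. Inputs whose name sets
  share nothing with the lncRNA annotation fail loudly rather than
  producing silent empty joins.
* ORF search scans the three forward frames of the sense strand for
  ATG…{TAA, TAG, TGA}; length is counted in amino acids excluding the
  stop, ORFs with no in-sequence stop are not counted, codons containing
  N break any ORF through them, U is read as T, and frame ties resolve to
  the lowest frame index.

## The synthetic epigenome

`lincscreen simulate` generates the study conditions the screen is
validated under. Defaults: one 2 Mb chromosome; 10 protein-coding genes
(5–50 kb, mutually non-overlapping); 50 lncRNAs (1–5 kb) of which 60% are
placed clear of all gene spans and 40% intersect a gene by ≥ 100 bp;
10 intergenic lncRNAs carry planted promoter enrichment in both marks and
4 of those carry a 400 bp TF peak at the TSS, plus 10 distractor peaks
placed clear of every promoter window.

Coverage is drawn per 50 bp bin as a Poisson count around a flat base
rate of 30 per bp (variance = mean; an optional negative-binomial
overdispersion factor is available). In the post state the mean over
2 kb centred on a planted TSS is multiplied by `enrich_fold` (default 8),
jointly in both marks. At these settings the full-window post/pre ratio
at a planted promoter is ≈ 3.7 (the 2 kb enrichment is diluted over the
5 kb window and the post total signal is ~7% higher), many standard errors
above τ = 2, while unplanted ratios concentrate at 1 with ≈ 3% sampling
error — so recall, precision and the null call rate are essentially
deterministic at desk scale. Intergenic TSSs are spaced ≥ 2w +
enrich_span apart so one promoter's planted signal cannot leak into
another's window; this is what makes exact planted-set recovery a fair
expectation rather than a statistical accident.

What the simulation does **not** model: mappability and GC bias,
fragment-level read placement, replicate structure, input/IgG background,
peak-shape heterogeneity, or catalogue redundancy (one transcript per
locus). Passing tests therefore demonstrate the correctness of the
pipeline's logic and calibration under its stated noise model, not
robustness to every artefact of real ChIP-seq.

## Problem sizes used in validation

The test suite and the acceptance summary run the simulator at its
default 2 Mb / depth-30 scale: 10 replicates for planted recovery, 10 for
null calibration, with seeds derived from a single base seed. The whole
suite completes in seconds; the screen itself is O(runs + transcripts ×
log peaks) and handles genome-scale inputs without special treatment.

## Known limitations

* The thresholded ratio has no error model; with replicated tracks a
  count-based test would be preferable.
* The TF stage tests peak presence only; an increased-TF-signal mode is
  future work.
* Literal survivor counts from any particular published screen depend on
  the exact catalogue and annotation freeze and are not reproducible from
  this package's synthetic inputs; the validation is property-based
  (planted-truth recovery, calibration, invariances) by design.
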