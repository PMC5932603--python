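# Methods

## Coordinate and sequence conventions

All analysis happens in transcript space: 0-based, half-open intervals on
the sense strand of the mature spliced transcript. GFF3 (1-based inclusive)
and VCF (1-based) are converted at the I/O boundary; BED and bedGraph
outputs are 0-based half-open. Minus-strand genes are reverse-complemented
at load and variant alleles complemented during projection, so all
downstream logic is strand-free. The genetic code defaults to NCBI table 1;
other tables (e.g. vertebrate mitochondrial, where smORFs also occur) can be
selected but are not used by the test conditions. Codons containing N
translate to `X` and yield an `unknown` variant effect.

## altORF model

An alternative ORF is any ATG-initiated reading frame on the transcript,
extended to the first in-frame stop (stop codon included in the footprint),
distinct from the annotated CDS. Choices where conventions genuinely vary:

- **Minimum length** `min_aa = 30` amino acids, stop excluded — the cut-off
  used by large altProt catalogues. It is a parameter, not a claim about
  biology; raising it only removes ORFs (tested monotonicity).
- **One ORF per (frame, stop)**: the 5′-most start wins, matching the
  longest-isoform convention; `report_all_starts=True` preserves every start.
- **`require_stop=True`** by default: an ORF must terminate within the
  transcript. Open-ended ORFs at transcript ends can be enabled.
- **In-frame CDS overlaps are not altORFs** (frame offset 0 against the CDS:
  truncations/extensions share the canonical product's frame). Same-frame
  ORFs that do not overlap the CDS *are* altORFs.
- ORFs shorter than 100 codons are tagged smORFs (annotation only).
- Footprints include the stop codon, so stop-loss variants count as hits.

Classification is purely positional: `uORF` entirely 5′ of the CDS, `dORF`
entirely 3′, `overlap_nested` inside it, `overlap_partial` crossing one
boundary, `lncRNA_orf` on CDS-free transcripts.

## Variant effects and the silent-but-altering flag

Each SNV is classified per ORF from its ref/alt codon pair: synonymous,
stop_retained, missense, nonsense (sense→stop), stop_loss (stop→sense), or
start_loss (any change to codon 0 that is not itself a stop gain; in the
standard code no single substitution turns ATG into a stop, so start_loss
covers all codon-0 changes). `stop_retained` counts as silent in the
canonical frame — no amino acid changes. A variant is *silent-but-altering*
when its canonical-frame effect is silent and at least one overlapping
altORF effect is missense/nonsense/start_loss/stop_loss. Only SNVs are
modelled; indels (true frameshifts) are out of scope. Recurrent variants
carry an `occurrence_count` and all fractions are occurrence-weighted; a
`--unique` flag collapses recurrence.

A useful structural fact, enforced by the test suite: the standard code has
no second-position redundancy, so a canonical wobble-position (codon
position 3) synonymous SNV that falls inside an out-of-frame nested altORF
always lands on that altORF's codon position 1 or 2 — exactly where it can
change the alternative protein.

## Chance model for enrichment

The question "are altORF hits among synonymous SNVs more frequent than
expected by chance?" needs an explicit null. Ours conditions on gene
composition and per-transcript mutation counts: the *synonymous space* of a
transcript is every (position, alt) pair whose substitution is synonymous or
stop-retained in the canonical frame; the null redraws, per transcript, the
observed number of SNV occurrences uniformly **with replacement** (mutational
recurrence is real) from that space, and recomputes the pooled hit fraction.
The p-value is one-sided and +1-corrected, `p = (1 + #{perm ≥ obs})/(B + 1)`,
so p ∈ (0, 1]; the analytic expectation `expected_frac` is the
occurrence-weighted mean altORF coverage of the spaces and equals the null
mean of the statistic. `p_perm` refers to the positional ("fell within")
fraction, whose null expectation is exactly that coverage; an analogous
`p_perm_altering` is reported for the altering fraction. Defaults:
`n_perm = 1000`, seeded and fully deterministic. Gene-level flags and
altProt length medians are reported descriptively and are not permuted.

A note on calibration: permutation p-values are discrete. When the observed
statistic can tie with permuted values on a coarse grid (few variants), the
+1-corrected p is conservative and its distribution visibly sub-uniform;
with ≈2,000 draws the grid is fine enough that uniformity holds to
Kolmogorov–Smirnov precision, which is the condition the calibration test
uses.

## Conservation periodicity

Coding sequence under purifying selection conserves codon positions 1–2
more strongly than the wobble position. For each frame *f* the track is
split by codon position (base *i* belongs to position `((i − f) mod 3) + 1`)
and the statistic `δ_f = mean(pos-1 ∪ pos-2) − mean(pos-3)` is computed **on
raw scores**; significance comes from shuffling score order (`n_perm = 999`
default, one-sided, +1-corrected) and frames are called at
`p ≤ α/3` (Bonferroni over the three frames), which supports multi-frame
calls for dual-coding regions. Haar-wavelet denoising — symmetric padding,
universal soft threshold `λ = σ̂·√(2 ln n)` with σ̂ from the MAD of the
finest-scale details — is attached for reporting only: thresholding would
distort the permutation null unpredictably, so it never feeds the statistic.
With `threshold_rule="none"` the transform is an identity to 1e-9 relative
error. Tracks must be gap-free; gaps are rejected at load unless linear
interpolation is explicitly requested.

## Synthetic data

The generator emulates the study's inputs — an altProt catalogue and
tissue-specific synonymous tumour variants — with complete ground truth.

- **Transcripts.** 25 mRNA genes plus 5 lncRNAs by default, lengths uniform
  on 900–3,000 nt at GC 0.5, two exons each (exercising splice projection on
  every fixture; strands alternate), CDS occupying ~50% of the mRNA length.
  Each mRNA gets one planted uORF, dORF, and nested overlapping altORF
  (partial overlaps available, off by default); each lncRNA one ORF. Planted
  altProt lengths are log-normal with median 45 aa — the reported median
  length of catalogued altProts — truncated to [30, 300] aa.
- **Constructive planting.** Start codon written, body codons sampled
  avoiding in-frame stops (and, for CDS-overlapping ORFs, avoiding induced
  canonical-frame stops; canonical start/stop codons are frozen), terminal
  stop written. Incidental ORFs ≥ `min_aa` arising in the background are then
  destroyed by mutating their start codons, so `predict_altorfs` on an
  emitted transcript returns exactly the planted set and the truth table is
  complete by construction. Planted altORFs may overlap the CDS but not each
  other — that keeps the constraint network single-pass solvable.
- **Variants.** Drawn from the synonymous space, so every emitted SNV is
  canonical-synonymous by construction; pairs inside altORF footprints get
  sampling weight `enrichment_factor`. Factor 1 is the exact null; the
  default 2 emulates the observed excess of altORF hits (the effect size is
  not documented anywhere authoritative; 2 is the factor the power analysis
  uses). Only CDS-overlapping altORFs (nested/partial) can be hit — a
  synonymous variant lies inside the CDS by definition — so uORF/dORF
  columns in the per-gene table count alterations only via partial overlaps.
- **Tracks.** Gaussian noise (sd 0.5 default) plus `depth` (1.0 default)
  added at codon positions 1–2 of every planted/canonical footprint,
  superposed additively for overlapping ORFs.

What the synthetic conditions do **not** show: real tumour mutational
signatures and tissue stratification, transcript-expression weighting,
phylogenetically realistic conservation scores (real phyloP noise is neither
Gaussian nor i.i.d., and its neutral model is itself fit under a uni-coding
assumption), non-ATG initiation, and indels. Passing tests demonstrate
correctness of the computations and calibration of the statistics under the
stated conditions, not effect sizes in real data — headline percentages from
catalogue-dependent analyses (which OpenProt release, which TCGA extract)
are intentionally not targets.

## Numerical and degenerate-input choices

Permutation and simulation randomness uses NumPy `Generator` seeded
explicitly everywhere; identical seeds give byte-identical outputs
(verified end-to-end, including written bundles). Empty variant sets,
CDS-free transcripts in CDS-requiring operations, too-short tracks
(< 30 nt for periodicity, < 2 for the wavelet), out-of-range positions, and
ref-allele mismatches raise informative errors; annotation violations at
load (CDS length not a multiple of 3, missing ATG or stop) reject the
record, log a diagnostic, and let the run continue. Infeasible generator
configurations (an altORF that cannot fit its host region) fail before
sampling.

## Problem sizes used by the tests

The acceptance-style checks run at sizes chosen to make their statistical
assertions sharp while staying desk-scale: 1,000 random transcripts for
ORF-oracle equivalence, 50 exhaustive-SNV fixtures for effect-oracle
equivalence, 500 replicates × 2,000 draws for null calibration, 200 runs for
each power/false-positive rate, 300-codon tracks for periodicity. The
acceptance script mirrors the default study conditions above.
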