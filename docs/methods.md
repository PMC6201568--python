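# Methods

## Scope and model

The package infers a bacterial repressor's direct regulon from three kinds
of evidence: experimentally mapped binding sites (DNase I footprints plus
curated site tables), promoter sequence, and a two-condition RNA-seq
comparison (wild type vs. regulator deletion). The operative motif model
is deliberately simple and matches how such sites are described in the
bacterial literature: an ungapped set of equal-length sites, a
position-frequency matrix (PFM), a degenerate IUPAC consensus, and
mismatch counting — not a probabilistic PWM with log-odds scores. All
known PhaR sites are 12-mers with no indels, so a gapped or
information-theoretic model would add parameters without adding evidence.

## Consensus derivation

`build_pfm` tallies base counts per column; `derive_iupac_consensus` maps
each column to the minimal IUPAC code covering every base whose frequency
is ≥ `min_frequency`. If no base reaches the threshold the code covers all
observed bases, so the consensus never excludes an observed site entirely.

* `min_frequency` default **0.25**: with eight input sites, a base must
  occur at least twice to enter a column's code. This is the threshold
  that reproduces the published code from the printed sites: the derived
  TGCRBYGCASMA agrees at 11/12 positions and is a strict subset at the
  12th (B ⊂ N). The original nine-sequence alignment included one site
  never printed, which evidently contributed the fourth base at that
  position; we do not guess it.
* At `min_frequency ≤ 1/n_sites` every input base enters its column, so
  every input site matches the derived consensus exactly (soundness
  property, tested).

## Scanning

`scan_sequence` tests every L-window of a promoter region on both strands
(the published analysis does not state strandedness; a repressor site can
act in either orientation, so both-strand scanning is the default) and
reports all windows within `max_mismatch` of the consensus, overlaps
included, with no greedy masking.

* `max_mismatch` default **1**: all 70 published candidate sites lie
  within one mismatch of TGCRNYGCASMA (exhaustively tested), so 1 is the
  smallest budget consistent with the published tables.
* The ambiguity base N in genomic sequence matches nothing, including the
  N code: an unknown base is never evidence for a site.
* The scanner is vectorized (per-position boolean lookup, summed over the
  12 consensus columns) and is tested for exact agreement with a naive
  every-window/every-strand oracle.
* `consensus_match_probability` gives the Poisson-binomial probability
  that a uniform-random window matches within the budget
  (9.92 × 10⁻⁵ for TGCRNYGCASMA at ≤ 1 mismatch); it is the analytic
  false-positive expectation used in the benchmarks.

## Promoter windows

Windows are anchored on the mapped transcription start site (TSS) and
span **−200 … +20 bp** by default. The published analysis does not state
its window; −200/+20 comfortably contains the mapped sites, which flank or
overlap the −35 element. Genes without a mapped TSS are anchored on the
start codon (logged); windows are clipped at contig ends and flagged.
External files use 1-based inclusive coordinates (GFF convention);
internal arithmetic is 0-based half-open, converted only in readers and
writers.

## Expression screen

RPKM = reads / (gene length in kb × library size in millions). Fold change
is the symmetric max(r, 1/r) with r = RPKM_mut/RPKM_wt, with direction
recorded separately; "more than x-fold" is strict, so a gene exactly at
the threshold is left unchanged. Reported values are rounded half-up to
2 decimals (matching the published tables; one published gene prints 2.00
from an unrounded 2.0021); unrounded values drive all decisions.

* Pseudocount ε default **0.01 RPKM**, added to both conditions only when
  one of them is zero. The published tables contain no zeros; the choice
  only matters for synthetic and user data.
* No dispersion estimation or hypothesis testing: the study design is one
  library per strain, so the fold change itself is the screening
  statistic. An optional `min_rpkm` floor exists but defaults off.
* RPKM's library-size normalization carries the usual composition bias:
  if a large fraction of the transcriptome changes in one direction,
  fold changes compress toward unity in that condition. This is visible
  in the synthetic benchmark (40% of genes planted) and negligible at
  genome scale, where a few dozen genes change out of ~8,300.

## Regulon inference

`infer_regulon` intersects genes with ≥ 1 promoter hit and a
beyond-threshold fold change: up-in-mutant → repressed, down-in-mutant →
activated, bound but sub-threshold → a separate bound-no-DE table (the
regulator's weak binding to its own promoter is the motivating case).
One site is reported per gene — fewest mismatches, then leftmost, then +
strand — because the published tables print a single site per gene; the
full hit list is retained in the hits table. Tables sort by genomic
position, falling back to locus-tag number when coordinates are unknown
(as in the packaged fixture). The result is invariant to input ordering.

`run_pipeline` chains promoters → consensus → scan → DE → regulon from a
config, writes every stage's table with a provenance header (parameters,
input MD5s, seed) and is byte-deterministic in its tables for fixed inputs
(the run report additionally carries wall-clock stage timings).

## Binding assays

**Footprints.** Both channels are smoothed with a centered moving average
(`smooth_window` 3) and normalized to unit mean; the per-position ratio
bound/control is thresholded and maximal sub-threshold runs become
protected regions. Normalization is two-pass: candidate protected
positions found in the first pass are excluded from the normalizing means,
so deep protection cannot bias the baseline. Runs separated by ≤
`merge_gap` (2 bp) merge before the `min_len` (8 bp) filter. Defaults
(`ratio_threshold` 0.5) are chosen so a 12-bp site of moderate depth is
robustly called; the original study reported footprints as figure
hatching, so these are package defaults, all configurable. Calls are
invariant to coordinate translation and to common positive rescaling of
both channels. Smoothing blurs boundaries by ≤ 1 position at this window;
the recovery benchmark scores boundaries at ±2 bp.

**Binding curves.** Fraction bound = complex/(free + complex) per lane;
the model is the single-site hyperbola f([P]) = [P]/([P] + K_d), fitted by
bounded scalar least squares on (0, 10 × max concentration]. No Hill
coefficient is fitted by default: the data show no cooperativity evidence,
and at an 8-point titration a second shape parameter is poorly
constrained. A fit pinned at the search bound or a curve with no signal is
returned as non-converged rather than raising.

## Synthetic data

Generators are pure functions of (parameters, seed) with no global RNG
state, and every planted feature is recorded in a serializable truth
object, so downstream stages are scored against recorded truth only.

* **Genome**: genes alternate strands on one contig (fixed gene length
  900 bp, intergenic 600 bp — enough that neighboring promoter windows
  never overlap); TSSs sit 60 bp upstream of each start codon; background
  bases are i.i.d. with configurable GC (default 0.5 for analytic
  tractability of the false-positive expectation; a `gc` parameter allows
  matching the ~64% GC of the real genome). A chosen fraction of genes
  (default 0.4) receives one site — a uniform draw from the consensus
  expansion, or a PFM sample — at a uniform offset in its promoter
  window, on a random strand.
* **Counts**: negative binomial with size (shape) parameter `dispersion`
  (default 10, variance μ + μ²/size; `inf` gives the Poisson limit),
  baseline mean 500 per gene in both libraries. Planted repressed genes
  get mutant mean × 8, activated genes ÷ 8 by default. The baseline is
  flat across genes: gene-to-gene abundance variation would not affect the
  within-gene ratios the screen uses, so it is omitted.
* **Footprints**: control = 1 + truncated Gaussian noise (σ 0.05); bound =
  control × depth (0.3) inside the planted window, plus independent noise.
* **Binding curves**: the hyperbola at the 8-point, 0–110 nM titration
  series with Gaussian noise clipped to [0, 1].

What these simulations do *not* emulate: operon structure (correlated
counts and shared promoters), GC-content and repeat structure of a real
genome, sequencing-depth variation between libraries beyond a scalar
factor, and footprint heteroscedasticity along a capillary trace. Passing
the recovery benchmarks therefore demonstrates correctness of the
implementation under the stated noise models, not performance on real
sequencing data.

## Numerical and degenerate-input choices

* Mismatch counting is integer-exact; ties between equally good hits
  resolve deterministically (offset, then strand).
* Fold-change reporting uses decimal half-up rounding to avoid binary
  float round-to-even surprises at printed precision.
* Zero RPKM in both conditions with ε = 0 is an error, not a silent 1.0.
* Regions shorter than the consensus scan to an empty hit list with a
  warning; an all-zero footprint control channel is an error; a degenerate
  all-zero binding curve yields a non-converged estimate.
* The K_d recovery benchmark at noise σ = 0.05 shows a small downward
  median bias (~0.6% at K_d 25 nM): clipping noisy fractions to [0, 1]
  slightly raises low-concentration points. This is inherent to bounded
  fraction data, documented rather than corrected.

## Known limitations

* The consensus procedure is a deterministic stand-in for the original
  gapped-alignment motif search; it reproduces the published code from the
  printed sites but cannot recover contributions of unprinted inputs.
* Candidate tables are per-gene: hits are not propagated across operons,
  so co-transcribed downstream genes are not credited to an upstream site.
* The screen has no replication-aware error model; with one library per
  condition, low-expression genes are fold-change-noisy and the strict
  threshold is the only guard.
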