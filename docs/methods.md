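# Methods

## Scope and model

`promarch` implements the promoter-level analysis layer for a two-condition
(control vs. factor-knockdown) multi-omic experiment: strand-resolved
nascent transcription (NET-seq), nucleosome occupancy (MNase-seq),
accessibility (ATAC-seq) and expression (RNA-seq). Alignment, peak calling
and enrichment analyses are out of scope; inputs are aligned tags/fragments
and a count matrix, and the factor-bound status of each gene is an input
label.

### Coordinates and windows

All internal coordinates are 0-based half-open (BED-native); GTF input is
converted at the boundary. TSS and TES are stored as boundary coordinates
(for a minus-strand gene the TSS is the rightmost coordinate; the first
transcribed base is `tss − 1`). A strand-oriented window `[a, b)` in
transcript coordinates maps to `[tss+a, tss+b)` on plus-strand genes and to
the mirrored `[tss−b, tss−a)` on minus-strand genes, making all region
lengths strand-independent. The analysis windows are:

| window | definition | length |
|---|---|---|
| proximal promoter | −30 / +250 around the TSS | 280 bp |
| gene body | TSS+300 to TES−200 | gene length − 500 |
| antisense window | 1,000 bp upstream of the TSS, opposite strand | 1,000 bp |
| isolation margin | 2.5 kb upstream of the TSS | — |
| upstream occupancy | −450 / −30 (covers the −1/−2 nucleosomes) | 420 bp |

Genes shorter than 500 bp are unusable for the travelling ratio and are
flagged, not dropped silently. The isolation filter removes a gene when its
upstream margin intersects another gene's annotated span; an optional mode
additionally extends the other genes' spans by their own upstream margin,
which discards bidirectional pairs sharing a promoter (whether such pairs
should be removed is genuinely open; the default keeps them, the flag
removes them).

Metaprofiles anchor on the first transcribed base; offset `o` reads base
`pos + o` on plus anchors and `pos − o` on minus anchors, so the flip is an
involution and sense/antisense swap tracks rather than coordinates.

### Normalization and smoothing

Tracks are normalized to 1× depth (RPGC): values are scaled by
`effective_genome_size / total_signal_bp`, so the genome-wide mean per-bp
signal is 1. The effective genome size is the total non-N genome length
(synthetic genomes carry no blacklist; a blacklist-subtraction hook exists
but curating one is out of scope). Normalization is a one-way state machine:
re-normalizing a normalized track is an error. Smoothing with window *w*
uses a centered moving average over `2·(w//2)+1` bins (21 bins for the
default *w*=20), shrunk at chromosome edges; a centered window was chosen
over an uncentered 20-bin one because it is symmetric around each base, at
the cost of a one-bin difference from the nominal window. Interior signal
sums are conserved exactly.

### Statistics

* Welch's two-sample t with Welch–Satterthwaite degrees of freedom; when
  both samples are constant and equal the statistic is defined as t=0, p=1;
  constant and unequal is an error.
* Benjamini–Hochberg step-up adjustment (Bonferroni selectable).
* TMM normalization factors follow the trimmed-mean-of-M-values recipe:
  pairwise against a reference sample (by default the one whose CPM upper
  quartile is closest to the mean), log-ratios doubly trimmed (30% on M,
  5% on A), inverse-asymptotic-variance weighted, factors rescaled to
  geometric mean 1. The implementation is cross-checked against
  edgeR::calcNormFactors in the test suite.
* The DE caller filters genes at CPM > 1 in at least half the samples,
  TMM-normalizes, tests each gene with Welch's t on log2(CPM + 0.5) and
  adjusts with BH. This deliberately avoids moderated-variance modelling:
  the package's claims are about recovery on synthetic data with ≥2
  replicates, not about reproducing any particular moderated-model gene
  list. logFC is the difference of condition means of log2-CPM
  (pseudocount 0.5, recorded in the table metadata).
* Slope comparison: `z = (β₁ − β₂)/√(s²₁ + s²₂)` with a two-sided normal
  p-value; both standard errors zero with unequal slopes is reported as a
  degenerate infinite z with p = 0 and a flag.
* Antisense and occupancy fold changes use a pseudocount of 0.1 signal
  units per kb (10⁻⁴ per bp) to keep log ratios finite at empty windows.

### High-occupancy row filter

TSS rows dominated by a short high-occupancy unit (snoRNA-like) are removed
by a deterministic rule: a row is dropped iff some 100-bp sliding window
contains ≥ 80% of the row's total signal. This replaces clustering-based
triage with a seed-free, testable criterion; an optional k-means mode
(fixed seed, configurable k and rounds) drops clusters whose centroid
violates the same rule. A side effect of the deterministic rule is that
very weakly transcribed genes whose only signal is the pause peak can be
removed as spike-like; this is intended (such rows carry no usable
gene-body information).

## Synthetic data generator

The generator emulates the study conditions, not raw reads: no sequencing
errors, no alignment, no mappability structure. Genes are laid on one
chromosome with ≥ 2.6 kb intergenic gaps, so the 2.5-kb isolation filter is
a no-op unless violations are deliberately planted; promoters are GC-rich
(0.60) on a 0.42-GC background. Six gene classes —
{up, down, unchanged} × {bound, unbound} — default to 200 genes each.

Per-assay models and defaults (all tunable through `TruthConfig`):

* **NET-seq**: Poisson gene-body rate 0.1 tags/bp at the reference
  expression level, coupled to a gene-level expression factor through a
  power law (exponent 1.2 for bound, 0.9 for unbound genes, lognormal
  residual σ=0.3) so the log-log slope comparison has a planted direction;
  a Gaussian pause peak at TSS+40 (σ=15 bp, ~100 tags); antisense Poisson
  rate 0.02 tags/bp in the 1-kb upstream window (~20 tags/window),
  multiplied by `antisense_gain` (default 2) at bound-up genes in the
  knockdown; splicing intermediates planted exactly at exon/intron
  3′-terminal bases at 5% of the sense tag count; PCR duplicates as copies
  of primary tags (rate 0.1) with shared UMIs, while every primary tag gets
  a unique UMI — so duplicate removal and intermediate removal are exactly
  invertible, and clean tags are nudged one base off terminal bases to keep
  the inversion exact.
* **MNase**: fragments drawn around phased dyads (+1 at TSS+120, then every
  180 bp; −1/−2 at −180/−360) with Gaussian fuzz σ=20 bp, lengths
  N(147, 10) clipped to 120–190 bp, ~30 fragments per dyad, plus short
  TF-sized fragments at the promoter; the upstream dyad weight is
  multiplied by `1 − upstream_nucleosome_loss` (default loss 0.4) at
  bound-up genes in the knockdown.
* **ATAC**: short NFR fragments (N(60,15) clipped < 100 bp) over
  −100/+50 around the TSS, weight ×1.5 at bound-up genes in the knockdown,
  plus mononucleosome-spanning fragments at the +1 dyad.
* **RNA-seq**: negative-binomial counts (dispersion 0.05), lognormal
  baseline means (median 150, σ=1), planted logFC ±2 for up/down classes,
  4 replicates per condition, lognormal library-size factors (σ=0.1).

Because the generator plants effects only where the study's qualitative
findings put them (bound-up genes), passing tests demonstrate that the
pipeline recovers direction and significance of such effects at realistic
depths — not that it reproduces any real dataset's magnitudes, nor that it
is robust to mappability artifacts, copy-number variation or
isoform complexity, which the generator does not model.

## Orchestration and reproducibility

A single seed fans out to fixed per-stage streams (genome, NET-seq, MNase,
ATAC, counts), so stages can be regenerated in isolation; all derived seeds
stay below 2³¹. The pipeline writes per-gene TSVs, class contrasts, slope
comparisons, metaprofiles and a `manifest.json` echoing every parameter,
seed and filter count; identical config and seed give byte-identical
bundles (the output directory itself is excluded from the manifest).

Default problem sizes (200 genes/class for single runs; 20 replicates for
the planted-effect study and 50 for null calibration, the latter at 100
genes/class) were chosen so a complete validation runs on a laptop-class
single core in minutes while keeping ≥ 19/20 detection power and tight
binomial bands on null calibration.

## Known limitations

* The DE caller's Welch-on-log2-CPM is anticonservative-to-conservative at
  2 replicates; recovery guarantees are stated for ≥ 4 replicates.
* NFR selection is a plain fragment-length threshold (≤ 100 bp), not a
  trained classifier; it is exact on the generator and approximate on real
  ATAC data.
* "RT-bias" removal is UMI-aware positional deduplication only; no
  sequence-composition heuristics.
* The splicing-intermediate filter uses one collapsed exon/intron model per
  gene; overlapping isoforms with different terminal bases are not
  enumerated.
* bigWig is not written; tracks round-trip through bedGraph (values kept to
  six decimals).
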