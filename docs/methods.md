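# Methods

## Background and model

At actively transcribed mammalian promoters, high-coverage PolII ChIP-seq
shows a stereotyped bimodal occupancy: an *initiation* peak centered a few
bp upstream of the transcription start site (TSS) and a *pausing* peak
roughly 110 bp downstream of it, just upstream of the +1 nucleosome. This
package models each gene's promoter-proximal profile as a sum of two
Gaussians,

    f(x) = A · [ exp(−(x−μu)² / 2σu²) + (1/r) · exp(−(x−μu−d)² / 2σd²) ],

with x in bp relative to the annotated TSS, oriented 5′→3′ of the gene:

| parameter | meaning                                   | bounds     | grid step |
|-----------|-------------------------------------------|------------|-----------|
| μu        | initiation-peak center (model TSS shift)  | [−200,200] | 2 bp      |
| d         | inter-peak distance                       | [40, 250]  | 2 bp      |
| σu, σd    | peak widths (sd)                          | [6, 150]   | 2 bp      |
| r         | upstream max / downstream max             | [0.05, 20] | ×1.05     |
| A         | amplitude (tags/bp)                       | ≥ 0        | closed form |

Peak occupancies follow from the Gaussian areas, p_u = Aσu√(2π) and
p_d = (A/r)σd√(2π). Two indices summarize promoter state:

* **promoter-escape index** ρ = (p_u − p_d) / max(p_u, p_d) ∈ [−1, 1],
  positive when the initiation peak holds more signal;
* **pause-release index** π = gene-body tag density / downstream-peak
  tag density, where the downstream-peak density is p_d/(4σd) (the mean
  over ±2σd around the pausing peak) and the body density is the mean
  tags/bp over [TSS+300, min(PAS, TSS+3000)] in gene orientation. These
  two windows are not dictated by the biology and are exposed as
  configuration; changing them rescales π but preserves its ordering.

## Tag processing

Tags are stranded 5′ read positions (0-based, half-open coordinates).
Because fragments are sequenced from either end, the plus- and
minus-strand pileups flank the fragment population; the lag maximizing
the raw-count cross-correlation between the strands (scanned over
0–500 bp) estimates the mean fragment length, and shifting each strand
by half of it centers tags on fragment midpoints. In the synthetic data
the minus tag is recorded at the half-open fragment end, so the
estimated lag equals the fragment length (~148 bp, per-strand shift 74);
for tracks whose minus tags sit at the leftmost alignment coordinate the
`read_len` argument of `apply_shifts` restores the 5′ position first.
Pileups are anchored at the annotated TSS and flipped for minus-strand
genes so positive coordinates are always downstream.

An optional PCR-artifact filter zeroes isolated tag towers: a position
with more than 10 tags is kept only if some other position within ±50 bp
carries strictly more than two-thirds of its count. Duplicates are
retained by default and the filter is opt-in, since deep promoter signal
legitimately saturates single positions. For paired-end data, the
histogram of fragment centers (fragments of 150–170 bp, inclusive;
even-length midpoints round down) is an independent route to the same
midpoint density and agrees with the shifted single-end pileup.

## Fitting procedure

The shape parameters are estimated by cyclic coordinate ascent. Each
move re-optimizes one coordinate by an exhaustive 1-D grid search
maximizing the fit quality, defined as the zero-lag Pearson correlation
between the rendered model and the data over the fit window (default
[−300, +400] bp). A cycle applies, in order: a whole-profile
translation (μu), an upstream-peak slide holding the downstream center
μu+d fixed, then d, σu, σd and r. The slide move exists because the
dominant peak pins μu+d, creating a ridge in (μu, d) that defeats
strictly per-parameter updates. The current value is always included in
the candidate grid, so the quality trace is non-decreasing; iteration
stops when a cycle improves the quality by less than `tol` (default
1e-4) or after `max_iter` (default 100) cycles. Amplitude is recovered
afterwards by least squares of the data on the unit-amplitude shape.

Initialization places μu at the profile maximum within ±100 bp, with
consensus d = 110, σu = 40, σd = 20, r = 1. Because the maximum is the
*pausing* peak for downstream-dominant genes (r < 1), a second start at
μu − 110 is also run and the better-quality fit is kept.

Both the data and every candidate model are smoothed with the same
5-bp-σ Gaussian kernel before the correlation. Smoothing only the data
would inflate fitted widths by convolution (σ → √(σ²+25)); smoothing
both sides stabilizes 1-bp Poisson noise while keeping noise-free
recovery exact and the quality of a perfect render at 1. The kernel is
a flag (`smooth_sigma=0` disables it).

Profiles with fewer than 20 tags in the window, or zero variance, are
reported as unfittable (null row in cohort tables) rather than dropped.
A single-Gaussian profile is fitted without error: the second component
degenerates (r at a bound or σd absorbed) with quality still near 1.

**Identifiability limit.** For blended shapes — small d with a wide
upstream peak overlapping a dominant downstream peak — distinct
parameter sets render curves whose Pearson correlation with the data
exceeds 0.999. No correlation-driven search can separate such sets, so
individual parameter estimates in this regime carry errors of up to a
few tens of bp even on noise-free input, while the fitted curve itself
matches the data (quality ≥ 0.99 across the generator's parameter
ranges). Cohort-level summaries (the inter-peak mode, ρ sign fractions,
shift concordance) are robust to this tail; per-gene parameters of
low-separation promoters should be interpreted with care.

## TSS refinement from RNA-seq

First-exon RNA-seq coverage is roughly rectangular, so the TSS is
re-estimated by correlating the coverage with the indicator of
[s, first splice junction) while the left edge s scans ±200 bp around
the annotated TSS in 1-bp steps (ties broken toward zero). The
correlation window is [TSS−300, junction), capped at 3 kb for long
first exons. A best edge further than 120 bp from the annotation is
rejected as unacceptable. Because coverage rises gradually (probit
onset), the correlation-optimal edge sits at the half-rise point; no
deconvolution of the onset is attempted.

Concordance between the RNA edge shifts and the PolII model shifts (μu)
is summarized by R² and the mean offset (rna − polII). The initiation
peak sits ~15 bp upstream of the consensus TSS while RNA coverage starts
~15 bp downstream of it, so the two models disagree by a systematic
~30 bp even when both are exact. `refined_tss` exposes an optional fixed
correction (e.g. +15 bp) to move from the initiation peak to the
consensus TSS; the default applies none, reporting the raw model shift.

## Promoter catalog

A promoter is *isolated* when no other TSS or PAS lies within ±1 kb of
its TSS (the gene's own PAS counts against it — relevant only for genes
shorter than 1 kb — its own TSS does not); *bidirectional* when an
opposite-strand TSS lies < 1 kb upstream, with a nested 170–200 bp
sub-class at the mode of the opposite-TSS distance distribution.
Averaged profiles of non-isolated genes carry an upstream shoulder near
−200 bp from the oppositely directed transcription, so model analyses
(fits, concordance) are restricted to isolated promoters.

Expression strata use microarray-unit thresholds: low < 6.0,
moderate 6.0–8.0 (inclusive), high > 8.0. Sequence features over
TSS ± 1 kb: CpG dinucleotide count (CpG-rich ⇔ > 50), GC fraction over
non-N bases, and a TATA-box score — the maximum log₂-odds of a
canonical TATAWAWR position-weight matrix against a uniform background,
with "strong TATA" ⇔ score > −5 and a top-2% selection helper. The PWM
is a documented canonical consensus matrix, not a fit to any particular
collection; the score scale and thresholds are interface constants.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
per gene: fragment midpoints from the two-Gaussian mixture (component
areas rσu:σd) centered 15 bp upstream of the *true* TSS, plus a uniform
background over the gene region that doubles as the elongation signal;
fragment lengths Normal(148, 15²) (min 30); each fragment emits both a
plus-strand start tag and a minus-strand end tag. Per-gene parameters:
d ~ Normal(110, 20²) truncated to [60, 180]; σd ~ Normal(20, 5²)
truncated below 5; σu = 2σd·LogNormal(0, 0.2²); log r ~
Normal(−0.525, 0.25²), calibrated so 70% of genes have ρ > 0 (the
induced ρ mode sits near +0.1). Expression is Normal(7.5, 1.2²)
microarray units and scales depth as 2^(expr−7.5), spanning roughly two
orders of magnitude. Annotated TSSs deviate from true TSSs by
Normal(0, 40²) truncated at ±200 bp. Genes sit on one synthetic contig
with ≥3 kb gaps; a configurable fraction form head-to-head pairs with
opposite-TSS distances Normal(200, 30²) truncated to [120, 950] bp.
RNA-seq coverage rises as a probit step (σ = 40 bp) centered 15 bp
downstream of the true TSS, stays flat to the first splice junction
(first-exon length LogNormal, 250–2500 bp) and falls sharply; counts
are Poisson. Isolated single-position PCR towers can be injected for
filter testing; they are placed ≥100 bp from any comparable tower so the
filter provably removes them.

The generator does **not** emulate: sequence-level reads (no FASTQ, no
mappability or GC bias), multi-contig genomes, alternative TSSs or
splice isoforms, strand-specific RNA-seq, or chromatin marks. Passing
tests therefore demonstrate correctness of the quantification pipeline
under the assumed signal model, not robustness to mapping artifacts or
annotation complexity found in real data. The gene-body tag rate
relative to promoter peaks is not constrained by any printed value and
is a free knob (`background_rate`, default 0.02 fragments/bp); the
absolute scale of π inherits this choice directly.

## Problem sizes and reproducibility

Analysis drivers default to a 150-gene cohort (~4×10⁵ fragments); the
acceptance script uses 500 isolated genes at ~2000 fragments/promoter
for the inter-peak consensus and 300 paired PolII+RNA genes for the
shift-offset recovery — sizes at which the cohort-level summaries are
stable while a full run stays in the minutes range on one core. All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical seeds reproduce cohorts
bit-exactly.
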