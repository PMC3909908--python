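# Methods

## The detection problem

Chromothripsis-like patterns (CTLP) are chromosome-local clusters of many
copy-number status changes — the array-level signature of localized genome
shattering. Given a segmented log2-ratio profile, the task is to decide, per
chromosome, whether its status changes are clustered far beyond what a
homogeneous background of copy-number aberrations (CNAs) would produce, and
where the clustered region lies.

## Preprocessing of segmented profiles

Segments are reduced to ordered runs of copy-number status
(gain / neutral / loss) with breakpoints between runs. Three rules are
applied, in order:

1. **Size filter.** Segments shorter than `min_segment_bp` (default 10 kb,
   about the practical resolution of the densest SNP platforms) are removed.
   The freed gap is annexed by the left neighbour; a gap at the left end of
   the covered span goes to the right neighbour. Any convention within a few
   Mb is immaterial at the 5 Mb positional accuracy of the scan.
2. **Status calling.** A segment is a gain iff its mean log2 ratio is at or
   above `gain_log2` (default +0.15), a loss iff at or below `loss_log2`
   (default −0.15), otherwise neutral. Boundaries are inclusive, matching
   common calling practice. Thresholds are array-specific in principle and
   configurable globally or per sample.
3. **Transition suppression.** Where adjacent segments differ in mean log2
   by less than `merge_distance` (default `gain_log2 + |loss_log2|`), the
   right segment inherits the left segment's status and no breakpoint is
   emitted. This damps segmentation "striation" artifacts — trains of small
   segments produced by local probe correlation or background noise.
   Suppression operates on the transition, not by re-estimating segment
   means, and propagates left to right.

Equal-status neighbours are then coalesced into runs, and breakpoints are
placed at run boundaries (the start of the right-hand run). `n_G` — the
genome-wide status-change count — sums breakpoints over the included
chromosomes (autosomes 1–22 for hg18 by default; sex chromosomes can be
included by flag, since array cohorts are inconsistent about them).

Emitted run means are length-weighted over the member segments whose
*called* status equals the run status. This makes re-calling the emitted
runs reproduce their statuses exactly. Full idempotence of the pipeline
(re-feeding emitted runs returns identical runs) additionally requires that
adjacent run means stay at least `merge_distance` apart; this holds for the
well-separated state palettes the detector targets (and that the synthetic
generator produces) but can fail for profiles whose within-run means
straddle a calling threshold. We consider this a documented limitation
rather than a defect: transition suppression is an artifact filter, and
applying it twice to borderline data legitimately merges borderline runs.

## The scan statistic

Let *G* be the genome represented linearly (sum of included chromosome
lengths) and *W* a fixed window size. Sliding *W* along each chromosome in
5 Mb steps defines a collection of candidate zones; windows never span
chromosomes. With `n_W` the breakpoints inside a window, `n_G` the total,
and `mu_W = (W/G) * n_G` the Poisson expectation under homogeneity, the
window's score is

```
log10 λ = n_W·log10(n_W/μ_W) + (n_G−n_W)·log10((n_G−n_W)/(n_G−μ_W))
```

if `n_W/μ_W > (n_G−n_W)/(n_G−μ_W)`, else 0. The score is the (base-10 log)
likelihood ratio of a piecewise-constant Poisson intensity elevated inside
the window versus a uniform intensity, and is 0 whenever the window is not
in excess. Conventions: `0·log 0 = 0` when `n_W = n_G`; windows with
`μ_W ≥ n_G` (a window covering the whole genome) score 0.

Window sizes default to the deduplicated, Mb-rounded chromosome lengths of
the assembly, clipped to ≥ 30 Mb (for hg18: 24 sizes, 47–247 Mb). The series
is fully overridable; studies on toy assemblies with equal chromosome
lengths should pass an explicit series, since the default degenerates to a
single whole-chromosome window there. Per chromosome, the window maximizing
the score is the CTLP candidate; ties are broken toward the smaller window,
then the leftmost start (an arbitrary but deterministic choice).

**Calling.** A chromosome is CTLP iff its best window has `n_W ≥ 20` and
`log10 λ ≥ 8`. These joint thresholds are the canonical operating point
calibrated on published chromothripsis cases (31 positive vs 475 negative
chromosomes); the `cohort` module's ROC sweep can re-derive an operating
point (max Youden J over the joint threshold grid) on any labelled set. The
reported region is the best window trimmed to its outermost internal
breakpoints, giving ±5 Mb positional accuracy (the step length).

**Classification.** A called region is chromosome-level if it spans ≥ 80%
of its chromosome; else arm-level if it lies within one arm and covers
≥ 90% of that arm; else localized. Telomere involvement means ≥ 1 bp
overlap with a terminal 5 Mb window. Genome fractions (CTLP length / G and
gain+loss length / G) use the included-chromosome set.

## Telomere-enrichment test

Each chromosome is treated as a circle; per iteration the terminal junction
is rotated to a uniform position while CTLP regions stay fixed, and the
statistic is the number of CTLP chromosomes overlapping a (rotated)
terminal window. The observed value uses the actual terminals (junction at
0). The p-value is the add-one permutation estimator
`(1 + #{null ≥ obs}) / (1 + n_sims)` with floor `1/(n_sims+1)` — at the
default 10,000 iterations the smallest reportable p is just under 10⁻⁴.

Rotation is one of several readings of "randomize the terminal locations,
keeping lengths"; it is the only one we found that preserves chromosome
length exactly, so it is the implemented null.

Calibration: under a null in which regions are themselves uniform on the
circularized chromosomes, the p-values are approximately uniform. Because
the statistic is a discrete count, exact uniformity requires the tie mass
per cohort to be small; the calibration study therefore uses cohorts of
100–250 calls with heterogeneous region lengths and chromosomes (cohorts of
this scale are realistic — large array surveys yield > 10³ CTLP
chromosomes). Small homogeneous cohorts give conservative (super-uniform)
p-values purely through tie granularity.

## Platform-resolution study

From a full-resolution probe table with a known detectable event, probes
are subsampled uniformly to a target count, re-segmented, preprocessed and
re-scanned; sensitivity is the fraction of runs recovering the truth
chromosome. Segmentation on this pathway is greedy binary segmentation
minimizing residual sum of squares with a per-changepoint penalty
(default `2·σ̂²·ln n`, σ̂ from the median absolute first difference — robust
to the piecewise-constant signal). Boundaries are placed at probe midpoints.
Greedy binary segmentation recovers noiseless step signals exactly and
matches an exhaustive dynamic-programming changepoint oracle on
well-separated signals; it was chosen over optimal DP for near-linear
runtime at 10⁶ probes.

## Synthetic data

The generator emulates the structure the detector assumes:

- **Background:** `n_cna` non-overlapping CNA segments (default sizes
  1–20 Mb, gain +0.4 / loss −0.5 on log2 scale) placed uniformly with a
  50 kb separation from each other and from chromosome ends, so each CNA
  contributes exactly two status changes; the rest of the genome is neutral.
- **CTLP events:** a region is shattered into `n_fragments ≥ 2` intervals
  by uniform stick-breaking over a 10 kb floor (so every fragment survives
  the size filter), with states alternating (no equal neighbours) from a
  palette — gain/neutral by default, mirroring the restricted copy-state
  picture of strict chromothripsis; wider palettes emulate looser CTLP.
- **Probes:** per chromosome, a Poisson number of probes at the requested
  density (SNP6-like ≈ 588 probes/Mb) with uniform positions and Gaussian
  log2 noise (default SD 0.15; 0.2 in the resolution study).

Not modelled: tumor purity and clonal mixtures, allele-specific states,
GC/wave artifacts, probe-specific variance, and inter-array threshold
heterogeneity. Passing recovery tests therefore demonstrates correctness of
the statistical machinery on idealized profiles, not performance on raw
clinical arrays.

## Study designs and problem sizes

Simulation studies run on a six-chromosome synthetic assembly
(6 × 130 Mb = 780 Mb, centromeres at 60–65 Mb) with an explicit window
series {30, 50, 90, 130 Mb}; this keeps hundreds of full pipeline runs
cheap while preserving the geometry that matters (many chromosomes, window
series spanning the chromosome length). Scaling quantities (μ_W, genome
fractions) are relative to *G*, so conclusions transfer qualitatively, not
numerically, to hg18-scale genomes.

- **Scan-vs-oracle equivalence:** 100 random single-chromosome genomes
  (40–200 Mb, ≤ 50 breakpoints, clustered or uniform), exhaustive window
  enumeration as the oracle.
- **Parameter recovery:** 100 genomes with one injected 28-fragment event
  (default ~30 Mb region) at SNP6-like density, noise SD 0.15; sensitivity
  ≥ 95% and refined-region Jaccard ≥ 0.5 in ≥ 90% of cases. 100 null
  genomes (10 background CNAs) bound the false-call rate at ≤ 1%.
- **Platform resolution:** one 30-fragment event in 8 Mb rendered at
  1300 probes/Mb (~10⁶ probes), subsampled to 10k/50k/250k/1M probes,
  20 replicates each; sensitivity must be non-decreasing within binomial
  error, rising from ~0 at 10k to ~1 at full resolution.
- **Telomere calibration:** 200 cohorts × 400 rotations; KS uniformity at
  α = 0.01.

## Numerical choices and degenerate inputs

- Scores are computed in log space throughout; the scalar entry point
  rejects `μ_W ∉ (0, n_G)` while the scanner treats such windows as score 0.
- Chromosomes shorter than every window size are absent from scan results;
  breakpoint-free genomes score 0 everywhere.
- Telomere windows on chromosomes shorter than twice the window are
  truncated to a non-overlapping partition.
- A region qualifying as both chromosome-level and arm-level is classified
  chromosome-level (precedence chromosome > arm > localized).
- Frequencies are reported to one decimal in percent; confidence intervals
  are Wilson by default (Clopper–Pearson available) — the CI method behind
  published frequency tables of this kind is typically unstated, and point
  estimates are the stable quantity.
- Fisher, KS and chi-square tests delegate to scipy; Fisher is
  cross-checked against full hypergeometric enumeration in the test suite.
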