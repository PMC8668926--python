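# Methods

This note documents the statistical models, conventions and numerical
choices behind `pitx1tools`, and what the synthetic-data tests do and do
not demonstrate about real data.

## Expression classing

Per-cell normalization is the standard counts-per-ten-thousand log
transform, `x = ln(1 + count / total × scale)` with `scale = 10,000`
(exposed as a flag).  Classification is a step function of `x` with two
boundaries, `t_low = 0.3` and `t_high = 1.45`, each boundary belonging to
the **lower** class (`x = 0.3` is non/low, `x = 1.45` is intermediate).
The literature around these thresholds is not perfectly consistent about
strict versus non-strict inequalities; we adopt the ≤ convention of the
figure-level class definitions and apply it uniformly.

Thresholds are frozen inputs by default.  Re-deriving them from data is an
explicit opt-in: estimate two Gaussian-kernel densities (one per condition
or per axis), and take the smallest crossing of the two curves inside a
search window.  Kernel density uses a direct kernel sum on an even grid of
512 points spanning `[min − 3bw, max + 3bw]`; the automatic bandwidth is
Silverman's rule of thumb, `0.9 · min(sd, IQR/1.34) · n^(−1/5)`.  Crossings
are sign changes of the interpolated difference curve, located by linear
interpolation between bracketing grid points; all crossings in the window
are reported and the smallest is returned (a deterministic rule — named
thresholds are single points).  Identical curves (difference exactly zero)
raise a "no intersection" error rather than returning an arbitrary point.

QC keeps cells with ≥ 200 detected genes and mitochondrial fraction within
[1%, 15%]; the removal bounds are exclusive (a cell at exactly 200 genes,
1% or 15% is kept), matching the "less than" / "higher than" phrasing of
the underlying filters.  High mitochondrial content marks dying cells; very
low content marks contaminating blood cells.

Fold changes of the non/low fraction are computed on unrounded fractions;
groups with a zero reference fraction are flagged undefined rather than
reported as numbers.

## Differential proportion analysis

Observed statistic per cluster: difference of within-condition proportions
(a log-ratio variant is available behind a flag).  The null distribution is
built under the pooled composition: each iteration re-partitions the pooled
label multiset into the two condition sizes — a label permutation, drawn
efficiently as a multivariate hypergeometric over cluster counts — and
then redraws an expected fraction `p_mix` of each condition's labels
i.i.d. from the pooled empirical distribution.  `p_mix = 0` is the exact
permutation null, `p_mix = 1` the multinomial bootstrap null; any mixture
reproduces the sampling variance of the observed statistic under the null,
so the test's type-I error matches its nominal level (verified at
α = 0.05 over 200 null replicates in the acceptance suite).

A design note: a scheme that perturbs each condition's *own observed*
labels (retaining 1 − p of them) centres the null at `(1 − p) ×` the
observed statistic, so the null tracks the observation and the test
essentially never rejects.  The pooled re-partition used here is the
calibrated member of the "mixing" family and is what the package commits
to; the construction is fully documented precisely because descriptions of
such tests in the literature are often too terse to pin down.

P-values are two-sided add-one empirical estimates,
`(1 + #{|null| ≥ |obs|}) / (n_perm + 1)`, hence never exactly zero.
Defaults are `n_perm = 100,000` and `p_mix = 0.1`; the test suite uses
`n_perm = 2,000` for runtime.  Null draws are consumed in
sorted-condition-label order, so swapping the two populations negates all
statistics and reproduces bit-identical p-values under the same seed.
Pairwise comparisons across k conditions derive the seed of the i-th pair
(combinations order) as `seed + i`.  Raw p-values are reported without
multiple-testing correction; the conventional display rule highlights
p < 0.01.

## Capture-HiC post-processing

Coordinates: external files and presets are 1-based inclusive; internal
bin indices are 0-based half-open, with exact converters (the region start
always falls in bin 0).  Binning increments `M[i, j]` and `M[j, i]` per
off-diagonal pair and the diagonal once per within-bin pair, so the upper
triangle sums to the pair count.

Knight–Ruiz balancing is the inner–outer Newton iteration with
conjugate-gradient inner solves of the original algorithm.  Bins that are
masked or have a zero marginal are removed before balancing and re-inserted
as masked zero rows.  The bias is scaled so every unmasked row sum of the
balanced matrix equals the mean raw row sum of the balanced bins (total
mass is preserved; only the uniform-row-sum property matters downstream).
Default tolerance 1e-8 on the residual 2-norm, 500 outer iterations;
non-convergence raises instead of returning a partial result.  The test
suite cross-checks against an independent alternating-scaling (Sinkhorn)
fixed-point oracle, `b ← sqrt(b / (A b))`, run to 1e-12.

"Scaling two maps together across their subdiagonals" is implemented as
per-offset mean matching: for each diagonal offset the two maps' means over
unmasked entries are moved to their common average.  The convention is
symmetric in the two maps, idempotent on identical maps, and removes the
distance-decay imbalance that would otherwise dominate a subtraction map.
Offsets where either mean is zero are left unscaled and reported.  The
subtraction `a − b` is signed and requires jointly scaled inputs (an
explicit override exists).  Display exports clip unmasked entries above
the 99th percentile (linear-interpolation quantile of unmasked entries).

Virtual 4C: a pair qualifies iff exactly one mate lies in the viewpoint.
The outside mate is counted in a raw bin (default 1,000 bp) and the profile
value of each smoothing interval (default 5,000 bp, which must be a
multiple of the raw bin) is the mean of the raw bins it covers.  Real
pipelines count per restriction fragment; a fixed raw bin stands in for the
fragment map so synthetic data can exercise the same two-scale
count-then-average structure, and fragment-based counting can be slotted
in later.  Values are raw counts by default, with an optional per-million
normalization; whether to normalize before smoothing is genuinely
underdetermined in the source material, so raw counts are the default.
bedGraph output converts exactly to 0-based half-open coordinates.

## Synthetic data

The cell generator draws, per (condition, cluster), a latent class from
configured simplex weights, then a normalized expression value from the
class component:

* non/low: point mass at 0 with probability 0.8, else uniform on
  (0, 0.3] — a zero-inflated left mode;
* intermediate: truncated normal, loc 0.85, scale 0.35, support
  (0.3, 1.45];
* high: truncated normal, loc 2.2, scale 0.55, support (1.45, 6].

No distributional form for the "on" components is established empirically;
truncated normals inside the class intervals are a convention chosen so
that latent classes are identified with classification intervals and
recovery tests have exact targets.  The raw UMI count is reconstructed as
`round((e^x − 1) × total / scale)` and then clamped into the count range
whose normalized value lies in the latent class's interval.  The clamp
matters: UMI counts quantize the normalized scale (at a 10⁴-total library
the value 0.3 sits between counts 0 and 1), and plain rounding would
silently re-label ~9% of low-intermediate draws as non/low.  Library sizes
are log-normal (median 10⁴, σ = 0.35) floored at 3,500 total UMIs — the
floor emulates droplet cell-calling and guarantees every class interval
contains an achievable count.  QC covariates are log-normal detected-gene
counts (median 2,500) and Beta(2, 38) mitochondrial fractions, so a
realistic few percent of cells fail each QC rule independently of class.

The default study design has four conditions (wildtype hindlimb and
forelimb, enhancer-deletion hindlimb, knockout hindlimb) and nine
mesenchymal clusters (proximal PPP/TP/ICT/PC, distal DP/DPP/EDC/LDC, mixed
Ms), ~5,000 cells per condition.  Class weights are set so condition-level
aggregates echo the published fractions (wildtype hindlimb 21/40/39%;
deletion ≈ 35% non/low; ICT ≈ 3.5×, PPP ≈ 2×, proximal ≈ 2.1×, distal
≈ 1.5× non/low increases), and cluster sizes shift progenitors up and
differentiated clusters down in the mutants, giving the composition test a
true positive.  The forelimb and knockout conditions are silent
(0.98/0.02/0).

The contact generator samples mate distances from a truncated power law
(default exponent −1, minimum distance 1 kb), places the left mate
uniformly given the distance, and enforces loop enrichments by rejection
sampling against the maximum enrichment weight — the output distribution
is exactly decay × enrichment, and enrichment 1 reduces to pure decay.
The default two-condition design is a 300 kb region at 5 kb bins with one
10 kb-anchor loop (enrichment 5) present in the active condition only, at
10⁵ pairs per condition.  This desk-scale geometry keeps Poisson noise on
near-diagonal offsets below the loop signal at the anchor offset, so the
subtraction pipeline has an unambiguous expected argmax.

What the synthetic tests do **not** show: the generators have no
transcriptome beyond the target gene, no doublets or ambient RNA, no
batch or replicate structure, no restriction-fragment geometry, and no
capture-efficiency variation along the region.  Passing tests demonstrate
that the implementations compute their definitions correctly and recover
planted structure at realistic sizes — not that the thresholds or
permutation settings are optimal for any particular real dataset.

## Bulk statistics

RPKM is `count × 10⁹ / (length × total)`.  The expression floor removes a
gene only when it is at or below the threshold (inclusive) in **every**
sample of the subset; one sample above the floor rescues it.  Z-scores use
the sample (n − 1) standard deviation by default (`ddof` exposed);
zero-variance genes are flagged and returned as NaN rows rather than
divided.  Log2 fold changes average replicate RPKM per group and apply a
small pseudocount (default 0.01, flag) purely to guard zero means.

## Problem sizes and determinism

Test and acceptance runs use: ~20,000 synthetic cells across four
conditions; 10⁵ values per condition for threshold recovery; 200 null
replicates × 2,000 permutations for test calibration (100,000 permutations
for the headline comparisons); 50 random matrices up to 50 × 50 for
balancing checks; and 10⁵ contact pairs per condition for the subtraction
and virtual-4C checks — sizes at which every targeted effect is separated
from its sampling noise by a comfortable margin.  All randomness flows
through `numpy.random.Generator` seeded from explicit integers; identical
seeds give byte-identical generator output and bit-identical test
statistics.
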