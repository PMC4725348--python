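# Methods

## Chip and library model

A chip is a 66 × 66 grid of micro-wells at 300 μm pitch (≈ 2 cm per side).
Each well (TopoUnit) is tiled over a 290 × 290 μm area with one repeating
*feature*: a square bounding box of side FeatSize ∈ {10, 20, 28} μm
containing 1–5 primitives (circles, equilateral triangles, rectangles), all
extruded to a constant 10 μm height. A library of `n_designs` (default
2,176) is placed in duplicate, leaving 66² − 2·2,176 = 4 flat-control wells.
Features tile edge-to-edge on a FeatSize grid (no stated inter-feature gap
exists; 290/FeatSize is truncated to whole features).

Random designs are sampled per design as: FeatSize uniform over the three
sizes; primitive count uniform on {1,…,5}; primitive kind uniform over the
three kinds; size parameters uniform on [1 μm, FeatSize] (a rectangle's two
draws are ordered so length ≥ width); rotation uniform on [0°, 360°); and
the center uniform over the exact admissible region where the rotated shape
fits the bounding square. Sampling the center directly on the constraint
set gives the same conditional law as naive rejection without spurious
failures; size/rotation draws whose admissible region is empty are re-drawn
against a retry budget (1,000 per design). Distinctness is enforced by a
SHA-256 hash of the rasterized mask, which also makes the fingerprint
invariant to primitive ordering.

Masks are rasterized at 0.2 μm/pixel (10 μm feature → 50 × 50) by
pixel-center point-in-primitive tests with no anti-aliasing: fine enough to
resolve 1 μm primitives, cheap enough that a full library renders in
seconds.

## Descriptors

- **FCP** = mean of the binary mask ∈ [0, 1].
- **pattern area** = FeatSize² · FCP (μm²), the absolute covered area —
  exact by construction, which the tests assert row-wise.
- **WN*q*** = fraction of the feature mask's spectral energy near radial
  spatial frequency *q*. The 2-D DFT power spectrum is computed on the
  unshifted periodic grid; the DC term and radial frequencies above Nyquist
  (1/(2·resolution) = 2.5 cycles/μm) are excluded; a band centered at *q*
  cycles/μm with default width 0.05 cycles/μm collects power over
  (q − 0.025, q + 0.025], normalized by total included power. Band units are
  therefore dimensionless fractions; default bands are WN0.2 and WN1.
  Bands partitioning the radial axis sum to 1 exactly. A constant mask has
  no non-DC power and reports 0 (0/0 guard). Wave numbers are computed on
  the single feature, not the tiled unit.
- Primitive statistics: counts per kind, total analytic primitive area
  (sum, ignoring overlap), and mean size parameter per kind (0 when a kind
  is absent).

**Decorrelation.** Before modeling, numeric columns are filtered greedily
in table order: a column is retained iff its squared Pearson correlation
with every already-retained column is ≤ 0.75. Table order puts the primary
descriptors (FeatSize, FCP, pattern area) before derived primitive
statistics, so when two columns are near-collinear — e.g. pattern area vs
total primitive area, r² ≈ 0.87 on the default library — the primary
descriptor survives. Alternatives keyed to raw variance would instead keep
whichever column happens to have the larger numeric scale, which is
unit-dependent and retains the derived statistic; the sequential rule is
deterministic and scale-free. Constant columns are dropped up front with a
warning.

## Synthetic screen generator

The generator reproduces the statistical structure the analysis assumes; it
does not render images.

**Planted response.** Each design's hit probability is
p = σ(β₀ + βₚₐ·z(pattern area) + β_wn·z(WN0.2) + β_fcp·z(FCP)), z-scored
over the library. Defaults β₀ = −10.6, βₚₐ = −14, β_wn = +1.5,
β_fcp = +0.75 make the response *near-threshold* in pattern area: on the
default library the half-maximum sits at ≈ 60 μm² and designs well
below/above saturate to hit/non-hit, so "hit" behaves as a class with the
conditional rates below rather than a continuum. The steepness is what
makes the planted structure recoverable end-to-end: with a shallow linear
response the Top/Bottom extremes become pure FeatSize classes (pattern area
and WN0.2 are both strongly FeatSize-dependent) and the tree's root split
lands on FeatSize instead of the true driver. The coefficient ordering
|βₚₐ| ≫ β_wn > β_fcp encodes "small pattern area first, then high wave
number, then high density".

**Counts and geometry.** 4 h cells are a homogeneous Poisson scatter at
100 cells/mm² (9 expected per 0.09 mm² well), independent of descriptors.
(The stated screen density and the stated ~12 cells per unit are mutually
inconsistent — 100 × 0.09 = 9 — so density is taken as primary.) 24 h
counts are Poisson with mean 12 · 3ᵖ per well, i.e. a maximum three-fold
effect for saturated hits and flat-control behavior (fold 1) for non-hits.
24 h cells are placed by a Neyman–Scott process: cluster count
1 + Poisson(max(N/μ_size − 1, 0)) with mean cluster size μ_size = 2 + 2p
(hits form more and larger clusters), centers uniform in the well,
offspring N(0, 10 μm), clipped to the well.

**Classes and intensities.** Per 24 h cell: Oct4⁺ with probability
q = p·0.85 + (1 − p)·0.35; EdU⁺ with probability 0.70 given Oct4⁺ and 0.02
given Oct4⁻ — so ~30% of Oct4⁺ cells are EdU⁻ and essentially all EdU⁺
cells are Oct4⁺. 4 h cells use a fixed Oct4⁺ rate of 0.7. Intensities are
class-conditional log-normals per channel (Oct4: meanlog 6.68 vs 4.79,
sdlog 0.35; EdU: 6.91/0.30 vs 4.38/0.45; DAPI class-free 6.21/0.30) plus
additive N(40, 8) background clamped at 0. The separations are calibrated
so that automated gating agrees with the generating labels at ≥ 95% (the
suite measures ≈ 98–99%). Outliers: each channel independently multiplied
by Uniform(5, 10) at rate 0.5%. Wells are flagged unreadable independently
at rate 18/1018. Every draw descends from one seed (chips via
`SeedSequence.spawn`), so identical seeds give byte-identical tables.

Truth columns (`truth_*`) are carried separately and never read by analysis
code; a test scrambles them and asserts the outputs are unchanged.

**What the generator does not emulate:** spatial intensity gradients and
illumination artifacts, cell segmentation errors, edge effects between
wells, density-dependent (crowding) growth, ROCK-inhibitor or apoptosis
kinetics, 4-day colony formation, and any real geometry→biology coupling
beyond the planted logistic form. Passing tests therefore demonstrate that
the *analysis* recovers a known structure of this statistical shape — not
that the planted biology is correct.

## Quantification

Per chip and channel, in a single pass each: subtract the 5th-percentile
baseline and clamp at 0; remove cells with |intensity − mean| > 2.5 SD
(sample SD; zero SD removes nothing; on standard-normal data this removes
2(1 − Φ(2.5)) ≈ 1.24%). Gates are two-component Gaussian EM fits on
log1p intensity (deterministic quantile initialization, σ floor 0.05,
threshold at the equal-posterior point between the component means); a
degenerate fit (component separation < 1 pooled SD or weight < 2%) falls
back to the 95% intensity quantile with a warning. Gating replaces the
manual per-screen thresholds a human operator would set, making runs
reproducible. Clusters are single-linkage connected components at 25 μm
(≈ two nuclear diameters), computed with a KD-tree and checked against a
brute-force union-find oracle. Per-well summaries (counts, % positive with
post-filter denominators, median Oct4 intensity, cluster statistics) are
pooled per design as the mean over readable wells (normally 6 = 3 chips ×
2 duplicates); designs with no readable wells are emitted with NaN metrics.

## Ranking, comparisons, models

Designs are ranked by pooled 24 h Oct4⁺ count (stable descending sort, ties
by design id); the first/last k = 100 are TOP/BOTTOM. Group comparisons
use group medians, ratio-of-median fold-changes and two-sided Wilcoxon
rank-sum tests without multiplicity correction (each panel is reported with
its own stars); groups under 3 observations get NaN p-values.

The tree is CART: exhaustive Gini split search over midpoints of sorted
unique values (ties to the lowest feature index then lowest threshold),
grown under min_split = 20, min_leaf = 7, a complexity gate of 0.01 of root
impurity and max depth 30; pruned by cost-complexity on misclassification
risk via weakest-link alphas, 10-fold stratified CV at geometric-mean
alphas, and 1-SE selection (smallest tree within one SE of the minimum CV
risk). Against permuted-label noise this prunes at least as aggressively
as rpart at matched settings (38/50 vs 25/50 collapses to ≤ 1 split in the
suite's simulation). Tree predictions depend only on the ordering of each
column, so they are invariant under strictly monotone per-column
transforms.

The logistic model is maximum likelihood via IRLS with step halving (the
log-likelihood path is non-decreasing by construction), internal
standardization (per-SD coefficients), Wald standard errors from the final
Fisher information, and explicit non-convergence and separation warnings.
Evaluation uses a stratified 75/25 split, accuracy at a 0.5 cutoff, a
threshold-swept ROC and trapezoid AUC (equal to the normalized
Mann–Whitney U, which the tests verify by direct pair counting).
Unscreened designs are ranked by the linear decision score (monotone in
probability, immune to saturation ties) and the 30 highest/lowest are
returned as predicted hits/non-hits.

Effect sizes of called hits are estimated on independent confirmation
screens of the same chip: re-ranking winners on their own screen inflates
the apparent fold (winner's curse); a fresh replicate recovers the planted
three-fold effect within its sampling error.

## Problem sizes and numerical notes

The test suite runs the full default configuration: 2,176 designs,
3 chips, ≈ 4 × 10⁵ cells per screen; the end-to-end recovery checks use
one default screen plus 3 confirmation screens and 20 re-screened
replicates for root-split stability (the dominant descriptor is recovered
20/20). Descriptor spectra are validated against a direct-summation
O(N⁴) DFT oracle to 10⁻⁹ relative error on masks up to 64²; the logistic
fit is validated against statsmodels to 10⁻⁶ relative error; AUC against
scikit-learn. The band edges use half-open intervals (lo, hi] with a 10⁻¹²
guard so that partitions are exact; mask boundary tests are inclusive;
EM uses a σ floor of 0.05 to prevent component collapse on clamped zeros.

## Known limitations

- Descriptor set covers only mask geometry and spectra (no texture
  statistics such as GLCM or fractal dimension).
- The decorrelation result depends on the documented column priority; a
  different priority changes which member of a collinear pair survives.
- The planted response uses library-level z-scores, so ResponseModel
  coefficients are calibrated to the default library's descriptor scale;
  markedly different libraries shift the effective pattern-area threshold.
- With the default near-threshold response the Top/Bottom extremes are
  cleanly separable, so hold-out accuracy and AUC saturate at 1.0; real
  screens sit well below this.
- Flat controls are only 4 wells per chip, so flat-referenced fold-changes
  carry ~10% sampling noise per screen.
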