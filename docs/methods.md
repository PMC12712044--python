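# Methods

`myotex` implements a complete 2D myocardial texture-analysis workflow —
MaZda-style feature extraction on ring-shaped regions of interest,
directional reduction to a fixed 50-feature catalog, two robustness
screens, and normality-gated group statistics — driven entirely by a
parametric short-axis phantom generator so that every stage runs without
imaging data. This note records the models, the numerical conventions, the
defaults that matter, and what the synthetic studies do and do not
demonstrate.

## Gray-level normalization

Texture statistics are computed on quantized gray levels, never on raw
intensities. For a masked ROI with raw mean μ and SD σ, intensity `v` maps
to

    level = 1 + floor( (clip(v, μ−3σ, μ+3σ) − (μ−3σ)) / (6σ) · (Ng−1) + 0.5 )

with half-up rounding and saturation at the window ends. The window is
re-estimated per ROI, which makes the entire 50-feature vector exactly
invariant to positive affine rescaling of the input image (a property the
test suite asserts on the full vector). A zero-variance ROI maps every
pixel to the mid-scale level `round((Ng+1)/2)` and sets a degenerate flag
instead of erroring, so constant phantoms pass through the screens with
defined behavior.

`Ng = 64` by default. The gray-level depth of the original desktop tools
is not standardized; 6 bits is their common default and keeps the
co-occurrence sum-average statistics in the familiar 2..2Ng range
(clustering near 64–65 for mid-scale textures). It is configurable
everywhere.

Coordinates are `(row, col)`, 0-based; polar angles are counter-clockwise
from the +col axis with the row axis pointing down. Septal and lateral
sector ROIs default to 120° windows centered at 180° and 0°.

## Feature catalog

Fifty features in six families:

| family | n | notes |
|---|---|---|
| histogram | 9 | moments of the level distribution (population denominators, excess kurtosis) and nearest-rank percentiles 1/10/50/90/99 |
| absolute gradient | 5 | central differences `/2`, only where the full 4-neighbourhood is in-mask |
| run-length matrix | 5 | Galloway statistics, averaged over directions 0/45/90/135° |
| co-occurrence matrix | 22 | 11 Haralick statistics × pixel offsets d = 2 and d = 5, averaged over the four directions per offset |
| autoregressive model | 5 | causal four-neighbour least-squares fit: θ1..θ4 and residual RMS |
| Haar wavelet | 4 | one-level orthonormal subband energies over in-mask 2×2 blocks |

Direction-dependent features are reduced by *feature-level* averaging (the
statistic is computed per direction, then the four values are averaged),
because the in-plane rotation of a short-axis acquisition carries no
anatomical meaning; feature-level averaging makes the averaged values
exactly invariant under 90° image rotation, which the suite asserts.

Numerical conventions, fixed once:

* all entropies use natural logarithms with 0·log 0 ≡ 0;
* co-occurrence tables are symmetric (both pair orderings accumulated) and
  normalized over in-mask pairs only;
* `SumVarnc` is the variance of the `p_{x+y}` distribution about
  `SumAverg` (the common desktop-tool convention), not the classical
  variant that centers on the sum entropy;
* runs are maximal equal-level segments along lattice lines, broken
  wherever the line leaves the mask;
* the AR fit mean-centres levels and uses pixels whose four causal
  neighbours are in-mask (≥ 20 required); rank-deficient normal equations
  fall back to the pseudo-inverse with a flag;
* the wavelet transform fills out-of-mask bounding-box pixels with the
  masked mean, edge-pads odd dimensions, and averages squared coefficients
  only over 2×2 blocks that lie fully inside the mask;
* undefined values (degenerate ROI, no co-occurrence pairs, too few AR
  pixels) propagate as NaN and are never silently replaced by zero — the
  screens must see missingness.

## Robustness screens

**ROI-size screen.** Each feature is rank-correlated (Spearman, average
ranks on ties) against ROI pixel count across a cohort whose ROIs differ
only in size; features with |r| ≥ 0.80 (the conventional "strong
correlation" boundary) are excluded. Exclusion is monotone in the
threshold. Constant or partially undefined features cannot be assessed and
are retained with a warning.

**Repeatability screen.** Duplicate readings are summarised by the
root-mean-square coefficient of variation: per subject,
`cov_i = (|x_i1 − x_i2|/√2) / mean_i`, pooled as `100·sqrt(mean(cov²))`.
This is the standard test–retest form built on the duplicate-measurement
within-subject SD; it is scale-free and symmetric in the two readings.
Cohort stability is the relative standard deviation `100·SD/|mean|`
(sample SD). A feature passes when intra-observer RMS CoV ≤ 10%,
inter-observer RMS CoV ≤ 10%, and RSD ≤ 30%. The stricter 20% RSD bound
that a completed screen typically reports is available as a configuration
preset; 30% is the stated criterion and the default. ED and ES are
screened independently. RSD is evaluated on observer 1's first reading.

## Group statistics

Comparisons are gated on Shapiro–Wilk normality at α = 0.05 (computed on
within-subject differences for paired designs): paired t vs Wilcoxon
signed-rank, independent t vs Mann–Whitney U, one-way ANOVA vs
Kruskal–Wallis. Significance is two-tailed at α = 0.05. For four-group
contrasts, pairwise post-hoc p-values are Bonferroni-adjusted and capped
at exactly 1.0 — the signature of capped Bonferroni columns in published
comparison tables. The classical equal-variance t/ANOVA forms are the
default (a Welch switch exists). The normality α and the post-hoc method
are declared choices; neither is standardized in the clinical literature
this workflow models. No multiplicity control is applied across features,
matching the workflow being reproduced. Absolute correlations are binned
as low (< 0.5), intermediate ([0.5, 0.8)), strong (≥ 0.8).

The suite calibrates every branch on simulated nulls: the type-I error at
α = 0.05 must lie in [0.035, 0.065] over 1000 replicates per branch.

## Phantom generator

A phantom is an annular "myocardial wall" on a 128×128 raster (default
inner/outer radii 30/46 px), a bright blood pool inside, and a dark noisy
background outside. The wall texture is the sum of

1. a stationary causal AR field with the same four-neighbour model the
   feature engine fits — `L(x,y) = θ1·L(x−1,y) + θ2·L(x−1,y−1) +
   θ3·L(x,y−1) + θ4·L(x+1,y−1) + e` — synthesized by raster scan (row
   recursion run as a linear filter; 32-px burn-in trimmed, field
   standardized to unit SD), and
2. focal Gaussian-profile inclusions ("bumps": trabeculae / vessel-like
   structures), with fixed density per wall pixel (0.010), width
   σ = 1.8 px, and N(0, 2.5) amplitudes in field-SD units.

Default AR coefficients are θ = (0.66, −0.33, 0.66, 0) — a smooth,
near-unit-root field whose pair correlation is still ≈ 0.99 at offset 2
but has decayed appreciably by offset 5.

The two-component design is deliberate, and it is what reproduces the
published ROI-size mechanism. Run-length non-uniformity statistics are
*extensive* — a larger ROI holds more runs, so `Average_RLNonUni` and
`Average_GLevNonU` track ROI area almost perfectly regardless of texture.
Among co-occurrence statistics, only the long-distance Shannon entropy is
size-dependent, and for a sampling reason: level pairs at offset 5 spread
over many more table cells than pairs at offset 2 (the bumps are wide
enough that offset-2 pairs straddling them stay close in level while
offset-5 pairs do not), so the S5 joint entropy is systematically
under-sampled at realistic ROI sizes and rises with ROI area. The
concentrated co-occurrence core contributed by the smooth background keeps
the angular second moment and the short-distance statistics saturated,
hence size-stable. A pure Gaussian AR wall cannot produce this separation
— all entropy-like statistics then co-trend with area — which is why the
inclusions are part of the default texture, not an option.

The wall texture is rendered in a band extending 4 px beyond the nominal
contours (`wall_pad`). Real myocardium has no intensity step exactly at a
drawn contour, and observer re-draws must disagree within wall-like
tissue; without the pad, a dilated mask swallows background pixels five
SDs away, which wrecks the μ±3σ window discontinuously and makes observer
variability wildly non-monotone in the perturbation radius.

**Cohorts.**

* *Size cohort* (3 × 10 subjects): ring areas scaled by 0.6 / 1.0 / 1.5
  (radii by the square root), per-subject area jitter ±10%, identical
  texture parameters throughout — any feature-vs-area correlation is a
  ROI-size effect by construction.
* *Repeatability cohort* (30 subjects, ED and ES): the image is fixed per
  subject; each reading re-draws the masks under an observer model
  (uniform boundary dilation/erosion bounded by a perturbation radius,
  default 0.5 px, plus sector-angle jitter, default SD 5°). Readings are
  keyed (observer, reading): (1,1) reference, (1,2) intra-observer repeat,
  (2,1) second observer. A zero observer model reproduces the reference
  masks exactly, so all RMS CoV values are exactly 0 — the anchor of the
  screen's property tests. No quantitative observer-variability level is
  published for this workflow; the default magnitude was chosen to
  exercise the screen (most features pass at 0.5 px, failures appear by
  3 px), not to reproduce any particular pass count.
* *Population* (600 subjects by default; the committed pipeline
  configuration runs 120 to keep a full run on a laptop in ~1 minute):
  four equal age bands × sex (60% female), an ED and an ES phantom per
  subject. Effect sizes are synthetic stand-ins declared in
  `PopulationEffects` (systole thickens the wall ×1.35, shifts the AR
  coefficients and gain; males carry ×1.12 ring radius; texture gain and
  correlation drift across age bands). The ring-size analog of LV mass is
  truncated at ±1 SD of its sex mean so size effects cannot masquerade as
  texture effects.

All generators are deterministic under a master seed; per-subject streams
are spawned from it, so cohorts are reproducible element-by-element and
re-running a pipeline stage rewrites byte-identical CSVs.

## What the synthetic studies show — and what they do not

Passing screens on phantoms demonstrates that the *statistics and the
machinery* behave as specified: extensive features are excluded by the
size screen with the published mechanism, repeatability indexes are exact
at zero perturbation and monotone in observer noise, and the test branches
hold their nominal size. The phantoms do not emulate acquisition physics
(no bSSFP banding, coil bias, papillary muscles, or motion), so pass/fail
counts for the repeatability screen and the specific significant-feature
counts in population comparisons are properties of the synthetic effect
sizes, not predictions for real cohorts. Published texture values from
clinical tables depend on a non-public MRI cohort and are out of scope.

## Problem sizes used by the tests

The acceptance checks run the size screen at the full 3 × 10 design. The
repeatability monotonicity check uses 8 subjects at ED over perturbation
radii 0.5 / 1.5 / 3.0 px; statistics calibration uses 1000 replicates of
n = 25 per group per branch; AR recovery uses a 30-px-thick ring
(radii 40/70 on a 160² raster), where all four coefficients are recovered
within ±0.05 and the innovation SD within 10%. These sizes were chosen so
the whole suite completes in well under a minute of compute per module
while keeping every statistical margin comfortable.

## Known limitations

* The AR neighbourhood is first-order causal; it cannot generate
  quasi-periodic textures, and near-unit-root coefficient sets amplify
  realization-to-realization variance (few independent patches per ROI).
* The observer model perturbs contour radii and sector angles only; it
  has no local boundary wiggles, so mask perturbations are smoother than
  human re-draws.
* The exact membership of the size-screen exclusion set is stochastic at
  the margins: across master seeds, the three expected features are the
  excluded set in roughly three quarters of cohorts, and the retained
  count stays within ±2 of 47 in all cohorts observed; `S5-Average_AngScMom`
  is the feature most likely to join the exclusion set, for the same
  sampling reason that excludes the S5 entropy.
* Percentile features use nearest-rank on quantized levels, so they move
  in integer steps; their repeatability statistics are correspondingly
  discrete.
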