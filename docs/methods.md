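# Methods

## Scope and model

`nichescape` implements the analysis chain for asking how much of the
spatial turnover in community composition (β-diversity) across a forested
landscape is attributable to environmental niches, how much to stochastic
dispersal, and how much to their spatially autocorrelated overlap. The
chain couples four model components: a spectral-species estimator of
Bray-Curtis dissimilarity, Mantel statistics for spatial autocorrelation,
generalised dissimilarity models (GDM) for deviance partitioning, and a
spatially explicit neutral coalescent whose dispersal and speciation
parameters are inferred by matching distance I-splines.

## Spectral species estimation

Pixels pass three quality filters: finite spectra, NDVI ≥ 0.8 (bands
nearest 660 and 800 nm; the exact band positions are configurable because
sensor band grids differ), and illumination zenith ≤ 50°. Surviving spectra
are brightness-normalised by their Euclidean norm — the standard way to
remove albedo/illumination magnitude while keeping spectral shape — and
resampled: bands below 420 nm, above 2400 nm and inside the water-vapour
windows (1350–1480, 1780–2032 nm) are dropped; remaining bands are averaged
in non-overlapping groups of three (below 1000 nm) or two (above), trailing
incomplete groups over whatever bands remain.

Clustering uses mini-batch k-means (full-batch optional at desk scale) with
a fixed seed; assignment is nearest centroid with ties to the lowest
cluster id. The cluster count is a configuration choice: an elbow
diagnostic (`select_k`) reports mean within-cluster sum of squares per
candidate k and flags the largest second difference of log WSS as a
suggestion only, because the right k is data-dependent. Cluster abundances
are counted in square cells (default edge 100 m = 1 ha) and cells with less
than 25% valid-pixel coverage are excluded. Abundances enter Bray-Curtis as
raw pixel counts, not per-cell proportions: the dissimilarity formula is
defined on counts, and with near-complete coverage the two choices differ
negligibly; with variable coverage, counts preserve the information that a
sparsely covered cell contributed fewer observations.

## Mantel statistics

The Mantel statistic is the Pearson correlation of the upper triangles of
two dissimilarity matrices; p-values come from jointly permuting rows and
columns of one matrix, using the add-one estimator
p = (1 + #{|Mr*| ≥ |Mr|}) / (n_perm + 1), which is never zero and unbiased
under the null. An exhaustive mode enumerates all n! relabelings for small
fixtures.

The correlogram cuts pairwise geographic distances into equal-width classes
covering [0, max distance]; the class count follows Sturges' rule
⌈1 + log₂(m)⌉ on the number m of pairs, which truncates the far classes
where few pairs remain. Per class, the statistic correlates the
dissimilarity matrix with the binary class-membership matrix, sign-flipped
so that a positive value means "sites this far apart are more similar than
expected by chance" (positive spatial autocorrelation). Confidence
intervals are percentile 2.5/97.5 over bootstrap replicates that resample
sites with replacement; pairs formed by a site and its own duplicate have
zero distance and no information, and are excluded from replicate
statistics.

## Generalised dissimilarity modelling

GDM regresses observed dissimilarity d ∈ [0, 1) on monotone transforms of
predictor differences under the negative-exponential link
d̂ = 1 − exp(−η), η = a0 + Σ_k |f_k(x_jk) − f_k(x_ik)|, with geographic
distance entering as a single I-spline term of the pair distance. Each f_k
is a non-negative combination of I-splines — integrals of M-splines built
from B-spline antiderivatives, 0 at the lowest knot, 1 at the highest —
with knots at the 0/50/100th percentiles of the predictor (order 3 by
default; both are configurable). Monotonicity and non-negativity are what
make the fitted splines readable: their slope is the rate of compositional
turnover per unit predictor and their maximum is the total turnover
attributed to that predictor (the coefficient sum).

Fitting minimises the binomial-type deviance
Σ 2[d ln(d/d̂) + (1−d) ln((1−d)/(1−d̂))] by iteratively reweighted least
squares with a non-negativity constraint (scipy's NNLS on the weighted
working response), intercept included in the constraint. Numerical
choices: observed d is truncated to [1e-9, 1−1e-9] so the objective stays
finite at the 0/1 boundary; the linear predictor is capped at η = 15
(d̂ within 3·10⁻⁷ of 1) because saturated pairs otherwise produce divergent
working responses; a step is halved toward the previous iterate when the
deviance worsens, and the fit stops when no descent remains, when the
largest coefficient change drops below 1e-8, or after 200 iterations
(non-convergence is signalled). The intercept-only null deviance uses the
closed-form optimum d̂ = mean(d). Percent deviance explained is
100 (1 − dev_model/dev_null), clamped to [0, 100] for reporting (the raw
value is kept on the model).

The partition fits distance-only, environment-only and full models:
unique D = full − explained(E), unique E = full − explained(D),
shared D×E = explained(D) + explained(E) − full. A negative component
(possible with finite samples) is clamped to zero and the remaining
components rescaled so the three still sum to the full-model explained
deviance — matching the convention of reporting 0% rather than small
negative overlaps. The full model's distance spline is the "D only without
D×E" target (spatial turnover not attributable to spatially structured
environment); the distance-only model's spline is the "D + D×E" target
(the observed spatial pattern). Categorical forest type enters as
orthogonal (Helmert) contrast columns; permutation importance shuffles one
predictor's site values at a time (consistently across all pairs), refits,
and reports the mean loss in explained deviance over 50 permutations by
default. Refitting (rather than re-evaluating fixed coefficients) is the
conservative choice: it credits a predictor only with explanatory power the
remaining predictors cannot absorb.

## Neutral coalescent simulation

The simulator traces sampled individuals backwards in time. Each event
picks an active lineage uniformly at random; with probability ν (per-birth
speciation) it speciates and its descendant samples receive a fresh species
(ids in speciation-event order); otherwise it moves to a parent cell drawn
through its dispersal kernel and a uniform parent index within that cell's
density, coalescing with any active lineage already occupying that
(cell, index). Uniform event picking is the discrete-time equivalent of the
continuous-time process up to a time rescaling, which the equilibrium
census does not depend on. When a single active lineage remains it
speciates immediately: its eventual speciation is certain and assigns one
species to all its descendants, so the shortcut is exact and avoids an
O(1/ν) tail of uninformative events.

The dispersal kernel is a 2D Student-t-type family with radial density
f(r) ∝ r (1 + r²/(τσ²))^(−(τ+2)/2): σ sets the scale (conceptually the
mean dispersal distance), τ the tail fatness, and τ → ∞ recovers the
Rayleigh/Gaussian kernel of scale σ — which is what makes the kernel
testable against closed forms. Radii are drawn by inverse CDF,
r = σ√(τ((1−U)^(−2/τ) − 1)), angles uniformly. The kernel family is an
explicit, swappable strategy object. The landscape boundary is closed:
out-of-bounds proposals are redrawn rather than wrapped, because a forest
reserve is a bounded arena, with a rejection cap guarding against
starvation.

The forest-type-aware variant keeps within-type dynamics neutral but
accepts a cross-type parent proposal only with probability m (the mixing
penalty); rejected proposals redraw the dispersal. The boundary cases
consume no random draw, so m=1 is bit-identical to the naive code path on
a shared seed, and m=0 makes cross-type ancestry impossible — with point
speciation that forces Bray-Curtis between types to exactly 1. Each forest
type may carry its own kernel. A spatially implicit "global" mode draws the
parent uniformly among all individuals; in that limit the expected sample
richness has the Ewens sampling formula closed form
E[S] = Σ_{i=0}^{J−1} θ/(θ+i), θ = ν(J−1)/(1−ν), which serves as the
simulator's analytic oracle.

## Parameter inference

The inference loop simulates one census per (σ, τ, ν) grid entry (each run
seeded from the master seed and grid index, so results are independent of
execution order), computes its Bray-Curtis matrix, fits a distance-only GDM
and evaluates the distance I-spline on a shared grid of 100 equally spaced
distances from 0 to the maximum pairwise distance. Candidates are scored
against an empirical target spline by RMSE over that grid (maximum absolute
difference is available); ties break toward smaller ν, then σ, then τ.
Pointwise comparison captures both readings of a spline — slope (turnover
rate with distance) and maximum (total turnover). The consistency report
asks whether one candidate lies within 1.25× of the per-target best score
for *all* targets simultaneously; a consistent candidate indicates
dispersal acting independently of the niche structure that distinguishes
the targets, an inconsistent family indicates per-type parameterisation is
required.

## Synthetic data: what it emulates and what it does not

The generator produces (a) a categorical forest-type mosaic and terrain
covariates as Gaussian random fields with exponential covariance
(spectral/FFT synthesis on a doubled grid; the `autocorr_range` parameter
is the practical range at which the variogram reaches ~95% of its sill);
(b) pixel-level communities where each species has a forest-type affinity
and an elevational optimum — assignment probabilities
∝ exp(niche_strength × suitability) — and occurs in dispersal-shaped
patches via a Thomas-process approximation (uniform parent points; a pixel
copies its nearest parent's species with probability
aggregation/(1+aggregation)); and (c) a reflectance cube drawn from smooth
vegetation-like per-species mean spectra plus Gaussian noise, with an
`invalid_fraction` of pixels planted to fail the quality filters (half flat
low-NDVI spectra, half zenith > 50°). Setting niche_strength = 0 and
aggregation = 0 yields i.i.d. uniform species assignment, the null that
downstream stages are calibrated against.

What the generator does *not* emulate: radiative transfer, sensor PSF/BRDF,
atmospheric effects beyond the planted invalid pixels, within-crown
spectral variation, hydrology, or temporally changing landscapes. Passing
tests on synthetic data therefore demonstrate the correctness and
calibration of the estimators under known generating processes — not that
any particular real landscape satisfies those processes' assumptions.

## Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| cell size | 100 | m | 1-ha analysis cells |
| NDVI threshold | 0.8 | — | below this, low forest cover |
| zenith cut | 50 | degrees | BRDF correction unreliable beyond |
| min. cell coverage | 25 | % | sparse cells give unstable counts |
| knots per predictor | 3 (0/50/100th pct) | — | standard GDM default |
| I-spline order | 3 | — | smooth monotone transforms |
| Mantel permutations | 999 | — | p resolution ~0.001 |
| bootstrap replicates | 500 | — | stable percentile CIs |
| importance permutations | 50 | — | stable mean loss |
| mixing penalty m | 1 | — | no penalty = fully neutral |
| density | 1 | individuals/cell | desk scale; configurable raster |

## Problem sizes used in tests and the acceptance script

Simulation experiments run at desk scale, chosen so each check has clear
statistical resolution: the Ewens check uses J = 400 individuals, ν = 0.05
and 200 replicates; null calibrations use 20 seeds; closed-loop parameter
recovery uses a 60×60-cell arena with 5 individuals in every third cell
(400 sites, 2000 samples), a 3×3 candidate grid containing the truth and 20
trials, with success meaning the truth is selected or the winner's score is
within one Monte-Carlo standard error (estimated from three replicate runs
at the truth) of the truth's; the naive-vs-aware dichotomy uses a
three-stripe 60×60 landscape with per-type σ of 1/4/16 cells and targets
averaged over two replicate censuses to suppress Monte-Carlo noise.

## Known limitations

- The coalescent event loop is pure Python; it is comfortable at desk scale
  (10³–10⁴ samples) but not at the scale of full landscapes with millions
  of individuals.
- GDM percent deviance depends mildly on the d-truncation constant when
  many pairs are fully dissimilar (d = 1); comparisons between models
  fitted with the same constant are unaffected.
- The correlogram's bootstrap CI treats sites as exchangeable; under strong
  spatial autocorrelation resampling sites is conservative at short
  distances.
- Orthogonal contrasts are exactly orthogonal across sites only for
  balanced type frequencies; for unbalanced landscapes they remain a valid
  coding, just not orthogonal in the sample.
- The mixing penalty is a per-proposal acceptance probability; other
  penalisations (e.g. distance-dependent) would need a different rule but
  slot into the same strategy interface.
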