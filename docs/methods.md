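# Methods

This note documents the models, conventions and numerical choices behind the
package, what the synthetic-data generator does and does not emulate, and the
known limitations.

## Landmark models and measurements

A tooth-score cross-section is a 7-landmark 2D configuration: LM1/LM7 the
shoulders, LM4 the deepest point, LM2/LM3 and LM5/LM6 computational wall
landmarks.  Wall landmarks are placed at **equal arc-length thirds** along
the digitised wall polyline (LM1→LM4 and LM4→LM7).  Arc length was chosen
over, say, equal x-spacing because it matches what curve-tracing digitisers
produce and is invariant to the coordinate frame.  LM5 sits nearer the base
and LM6 nearer the shoulder, mirroring the LM2/LM3 order, so that WIM pairs
the shoulder-adjacent computed points (LM2–LM6) and WIB the base-adjacent
ones (LM3–LM5); with straight walls this gives exactly WIM = (2/3)·WIS and
WIB = (1/3)·WIS, a property the tests assert.

Validation accepts mirrored digitisations: the constraint is that LM4 and
all wall landmarks lie on one side of the shoulder chord, not on a fixed
sign of the cross product.  All seven measurements are similarity-covariant:
rigid motions and reflections leave them unchanged, scaling by s multiplies
the six lengths by s and leaves OA fixed.

Tooth pits are 30-landmark 3D configurations: LM1/LM2 length endpoints
(LM1 the one farther from the width axis), LM3/LM4 width endpoints, LM5 the
deepest point, then a 5x5 patch in row-major order.  The package only
consumes such configurations; placing the patch on a mesh is a digitisation
step outside its scope.

File I/O: a permissive morphologika dialect (case-insensitive `[block]`
headers, whitespace-delimited numbers, optional label block, unknown blocks
skipped with a logged warning) plus TPS reading with `SCALE=` applied.
Coordinates are millimetres; angles are degrees at every interface and
radians internally.

## Circular statistics

Opening angles are directional data.  Descriptives: mean direction and
mean resultant length R̄ from the resultant vector; circular variance
v = 1 − R̄; standardised skew s = b₂/(1−R̄)^{3/2} and kurtosis
k = (a₂ − R̄⁴)/(1−R̄)² from the second trigonometric moment (a₂, b₂) about
the mean direction.  The circular median minimises mean circular distance;
for ties/even n the midpoint of the minimising directions is used, broken
toward the mean direction.

The Rayleigh test reports R̄ as its statistic with the standard large-sample
series p-value.  The reflective-symmetry test uses the second sine moment
about the **median** direction, b₂ = mean sin 2(θ−θ̃).  Rather than an
asymptotic variance (which, for median centring, is substantially smaller
than the naive moment variance because the median re-estimates location),
the null distribution is generated by randomly reflecting the deviations
about the median and re-centring each replicate on its own median; the
reflection draw is derandomised from the data, so the test is deterministic.
Under a Von Mises null its empirical size at 0.05 is ≈ 0.05–0.07.

Two-sample tests (all randomised, p = (exceedances + 1)/(reps + 1), default
reps 9999, seeded):

* **Y_g** — Watson's large-sample common-mean statistic
  2(Σwᵢ − |Σwᵢe^{iμ̂ᵢ}|) with wᵢ the inverse estimated variance of each
  group's mean direction (circular dispersion / nᵢ); calibrated by
  bootstrap after recentring both groups to a common mean.
* **P_g** — Fisher's common-median statistic from the counts above/below
  the pooled median's diameter; calibrated by label permutation with the
  pooled median held fixed.
* **W_g** — the Mardia–Watson–Wheeler uniform-scores statistic; label
  permutation.  Uniform scores make it exactly invariant to a common
  rotation of both samples, as are the other two statistics.

## Robust univariate layer

Each linear measurement is gated by Shapiro–Wilk at p < 0.003 — three
standard deviations, the same evidence threshold used everywhere else —
choosing mean/SD vs median/√BWMV descriptives and Welch vs Yuen equivalence
tests.  The biweight midvariance uses tuning constant 9 on MAD-standardised
deviations; under normality √BWMV/SD ≈ 1 (tested: mean ratio within
[0.9, 1.1] at n = 200).

Equivalence (TOST): the null is |Δ| ≥ ε·scale.  ε defaults to 0.2 Cohen's-d
units — a "small effect" boundary — and is always reported alongside the
result; the scale is the pooled SD (Welch) or the pooled winsorised SD
(Yuen, trim 0.2).  p is the larger one-sided p-value.  Multivariate
equivalence runs TOST per principal component of the pooled, centred data,
retaining components up to 95% of variance, and aggregates as the PC-wise
**maximum p** (the weakest equivalence claim carries) with summed |d|; the
aggregation is a package convention, recorded in every output.

## Evidence calibration

Every p-value is mapped to: BFB = 1/(−e·p·ln p) (bounded at 1 for
p > 1/e); posterior odds = BFB × prior odds (default prior probability of a
real effect 0.5, i.e. odds 1); FPR = 1/(1 + posterior odds); and the
continuous calibrated null probability p(H0) with branch point p* = 0.3681:
x/(1+x) below, 1/(1+x) above, x = −e·p·ln p.  p(H0) is strictly increasing,
equals 0.5 exactly at p = 1/e, and coincides with FPR at prior 0.5 on the
evidence branch.  Because x ≤ 1 everywhere, the unsaturated kernel 1/x is
≥ 1 on both branches; above 1/e it reads as the odds bound favouring the
null.  Since permutation p-values are bounded below by 1/(reps+1) and the
calibration needs the open interval, p is clipped to (1e-300, 1−1e-16)
before calibrating.

## Geometric morphometrics

GPA: translate to common centroid, optionally scale to unit centroid size
(shape space; form space skips the scaling), then iterate optimal rotations
onto the evolving mean until the mean-shape change falls below 1e-8
(max 100 iterations).  Reflections are never allowed — marks have a
consistent handedness from the digitisation protocol.  Aligned
configurations are kept exactly unit-size in shape space; an orthogonal
tangent projection at the mean provides the flat coordinates used by PCA
and regression.

Allometry: Goodall-type F for the covariate (default log centroid size) on
the tangent coordinates, group main effects partialled out when groups are
given, the covariate-by-group interaction tested separately; p-values by
residual randomisation (RRPP, default 999 permutations, seeded).  Residual
diagnostics report Shapiro W/p, |skew| and |kurtosis| of the residual
Procrustes distances.  A caveat the test suite makes explicit: centroid
size is itself a function of shape (aspect and relative depth change it at
fixed physical size), so even a perfectly isometric generator shows a small
genuine shape–CS association; null-calibration checks therefore use a
covariate constructed independent of shape (the generator exposes its true
size for exactly this purpose).

TPS: the standard 2D thin-plate interpolant with kernel r²log r², exact at
the landmarks, bending energy trace(WᵀKW) (zero for any affine target),
mapped over a margin-expanded lattice.  t-SNE: 3 components, perplexity
⌈√n⌉, 500 iterations, random init under the given seed (Barnes–Hut).  The
mixed-metric PCA first maps OA → cos θ + sin θ so the angle lives on a
linear scale, then decomposes the covariance of raw columns by default
(standardisation is a switch; the variance split between components depends
on it, but single-factor structure recovery does not).

## Bayesian two-group model

Independent Student-t likelihoods per group with weakly informative,
data-scaled priors: mu ~ Normal(pooled mean, 10·pooled SD), sigma ~
Half-Normal(10·pooled SD), nu ~ 1 + Exponential(mean 29).  Sampling uses an
affine-invariant ensemble (32 walkers, differential-evolution moves);
"chains" are truly independent ensembles with separate starting balls, so
split R-hat across chains is a meaningful convergence check (flagged, not
fatal, above 1.01).  Scales and nu−1 are sampled on the log scale.

Cohen's δ standardises the location difference by the **model-implied SD**
sigma·sqrt(nu/(nu−2)) (nu floored at 2.2), not the raw t-scale: with heavy
tails the t-scale underestimates the SD by up to ~10%, which would bias δ
upward relative to its usual SD-unit definition.  PS is the posterior-
predictive probability that a draw from group 1 exceeds one from group 2,
estimated with one predictive pair per retained posterior draw.  The
"step size 0.9" of the reference configuration is interpreted as a target
acceptance probability; it is recorded in the diagnostics and inert for the
ensemble moves.

## Synthetic data: what it emulates, and what not

The generator reproduces, per population (two captive parks, two wild
packs): Von Mises opening angles with the published central directions
(158.67 / 147.09 / 132.51 / 132.19 degrees) and concentrations back-solved
from the published circular variances (0.02 / 0.02 / 0.03 / 0.01);
lognormal WIS and D marginals with central = median transcribed from the
published per-population tables (captive depths 0.05 / 0.07 mm, wild
0.09 / 0.12 mm) and sigma matched so the lognormal SD equals the published
robust scale; and a Gaussian copula coupling (D, WIS) at Kendall tau 0.59.
Lognormal marginals were chosen because the published distributions are
non-negative and strongly right-skewed.

Each (WIS, D, OA) triple must admit a triangle: OA cannot exceed
2·atan(WIS/2D).  Infeasible draws redraw **OA only** (rejection, then grid
inversion of the truncated Von Mises), preserving the (WIS, D) marginals
exactly; the redraw count is logged.  The truncation pulls realised OA
medians a few degrees below the nominal central directions (e.g. pooled
captive ≈ 140 vs 151 nominal) — the captive/wild contrast that drives every
group-level conclusion is preserved, but per-group OA centrals should be
read as emulation, not transcription.  The base lands at depth D with the
lateral offset solved so the interior angle equals OA exactly, the
left/right sign random; walls are straight.

Pits are elliptic-paraboloid depressions with the 5-fixed + 5x5-patch
scheme.  Relative depth and aspect are drawn independently of absolute
size, so the slope-free generator is exactly isometric; a nonzero
`allometry_slope` displaces shape along a fixed "deepening" mode
(translation-free per axis, so superimposition cannot absorb it)
proportionally to log centroid size.  Pit size parameters (length median
2.5 mm, depth median 0.35 mm) are realistic for wolf cusps but are package
choices — no per-population pit measurement table is published — and the
default pit populations deliberately carry **no** group effect, mirroring
the finding that pit morphology is not conditioned by captivity.

What passing tests on this generator do *not* show: real cross-sections
have curved, irregular walls (the generator's are straight, so the
WIM/WIB width ratios are exact rather than approximate); real digitisation
error is spatially correlated; and real populations differ in more than
the three emulated marginals.  Conclusions about the *methods* transfer;
conclusions about wolves require the real data.

## Problem sizes and numerical conventions

Randomisation defaults: 9999 resamples for circular tests, 999 permutations
for allometry, add-one p-value estimators throughout so p is never 0.
Calibration-of-tests checks run 500 null replicates at 199 resamples with
n = 30 per group (circular) and n = 20 specimens (allometry); Bayesian
recovery uses 20 seeded fits at n = 150 with 4 chains x (500 tune + 500
draws).  These sizes give binomial/Monte-Carlo error comfortably inside the
asserted bands while keeping the default suite quick.  GPA tolerance 1e-8,
max 100 iterations; PCA via SVD of centred data; degenerate inputs
(constant samples, zero-size configurations, collinear TPS references)
raise informative errors rather than propagating NaNs.

## Known limitations and surfaced inconsistencies

* The published 95% HDI values paired with the Bayesian differences in the
  motivating study (differences of 0.08 and 0.048 mm with intervals
  [0.015, 0.017] and [0.019, 0.020]) are internally inconsistent —
  an interval that excludes its own point estimate; the package reports
  proper HDIs and makes no attempt to reproduce those numbers.
* One published calibration pair (p = 4.0e-8 → p(H0) = 5.0e-7) disagrees
  with the closed form that reproduces all other pairs (which gives
  ≈ 1.9e-6); it is treated as a typesetting error and excluded.
* The "stress" covariate (individuals per enclosure area) is supported as a
  configurable per-group scalar through the allometry interface; its
  construction from husbandry metadata is inherently ad hoc and the package
  takes no position on the right operationalisation.
* Axial (pi-periodic) angular data and Von Mises mixtures are out of scope;
  so are semilandmark sliding and 3D surface warping.
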