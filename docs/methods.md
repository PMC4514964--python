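# Methods

## The scientific setting

Interfollicular epidermis is a stratified epithelium in which basal
keratinocytes proliferate, detach, and migrate superficially while
terminally differentiating over roughly two weeks. Depth within the
tissue therefore proxies differentiation stage, and depth-resolved
immunofluorescence of phospho-Raf-1, phospho-MEK-1/2, phospho-ERK-1/2 and
calmodulin turns a single tissue section into an extended pseudo-time
course of ERK-MAPK signaling. `epiderk` implements the three
computational layers of that analysis — spatial conditioning of sampled
intensities, permutation tests of spatially conditioned association, and
a steady-state ODE model of the cascade driven by calcium signaling —
plus a synthetic-data generator that stands in for the original image
data, which were never deposited.

## Spatial conditioning

Each sampled region carries a tissue-layer index i ∈ {0, 1, 2} (basal,
spinous/granular, transitional) and minimum distances d₁, d₂ to the deep
and superficial boundaries of its layer. The layer-normalized distance
u = i + d₁/(d₁+d₂) ∈ [0, 3] absorbs local variation in layer thickness
(rête ridges, inter-patient differences). Because the layers contain
roughly 1 : 4 : 2 cells, u is mapped piecewise-linearly onto a model
depth d ∈ [0, 7] with slopes (1, 4, 2), and binned into 7 coarse
(one depth unit each) or 28 fine (quarter-unit) spatial partitions.

Partition bins are left-closed/right-open in model depth, [k−1, k), with
the superficial limit d = 7 assigned to the last bin. This convention
makes the layer boundaries land at the documented partition edges
(u = 1 → fine partition 5, u = 2 → fine partition 21) and keeps the
coarse and fine schemes exactly nested (coarse = ⌈fine/4⌉).

Intensities are z-scored within each patient × target × compartment group
(each immunolabeling experiment has an arbitrary gain), smoothed with a
loess fit applied separately within each tissue layer, and aggregated to
per-partition means. Empty partitions are flagged (count 0, value NaN)
and excluded pairwise downstream — never imputed.

The loess smoother is a locally weighted polynomial regression: for each
evaluation point the nearest ⌈span·n⌉ samples receive tricube weights and
a local quadratic is fitted by weighted least squares. Local quadratic
(rather than linear) reproduces curvature near layer edges; the span
default 0.25 is configurable since no canonical value exists for these
data. The smoother is evaluated only within each layer's observed u
range, so it never extrapolates.

## Association statistics

The null hypothesis is that the strength of association between two
targets' spatial profiles does not depend on spatial conditioning. For a
pair of 28-partition profiles we compute the Pearson correlation and a
plug-in mutual-information estimate (equal-width 8 × 8 histogram over
each variable's observed range, base-2 logarithm, 0·log 0 ≡ 0), then
scramble one profile along the spatial axis (random sampling without
replacement; permuting one member is distributionally equivalent to
permuting both and halves the cost). The default 100,000 permutations
(tests use 1,000) give two-sided 99 % thresholds for Pearson (0.5/99.5
percentiles) and a one-sided 99 % threshold for MI, plus p-values with
the (b+1)/(n+1) correction so a finite resample never reports p = 0.
The plug-in MI estimator is biased upward at these sample sizes, but the
null is built with the same estimator, so the bias cancels in the test.
No multiple-testing correction is applied across pairs; flags are
per-pair at p ≤ 0.01.

## The cascade model

State variables are fractional activations (activity relative to an
arbitrary maximum) of cytoplasmic phospho-Raf-1, cytoplasmic/nuclear
phospho-MEK-1/2 and cytoplasmic/nuclear phospho-ERK-1/2. Interactions
use the normalized Hill function f(x) = B·xⁿ/(Kⁿ+xⁿ) with B and K fixed
in closed form by f(0) = 0, f(EC₅₀) = ½, f(1) = 1:
Kⁿ = EC₅₀ⁿ/(1 − 2·EC₅₀ⁿ), B = Kⁿ + 1. The construction degenerates at
2·EC₅₀ⁿ = 1 (where the constraints force f = xⁿ); that parameter point is
rejected. Inhibition is the negative of activation; dephosphorylation is
inhibition times the output's own activation. The Raf-1 equation clamps
its net drive at zero (max(·, 0)) so that CaM and ERKc inhibition can
cancel the Ca²⁺ activation but never act as phosphatases.

Inputs are parameterized by baseline b and amplitude a of fractional
activation (b, a ∈ [0, 1], b + a ≤ 1): tissue Ca²⁺ rises linearly to its
peak at d = 5 and declines over the transitional layer; plasma-membrane
CaM rises over the basal layer to a peak at d = 1, decays as e^(1−d) over
the spinous/granular layers, and sits at baseline beyond d = 5 (the small
jump at d = 5 is part of the published profile and is implemented as
printed, not smoothed). Shuttling between compartments is first order,
with the cytoplasm-to-nucleus volume ratio r(d) (linear, 2 deep → 5
superficial) multiplying cytoplasm→nucleus fluxes in the nuclear
equations and dividing nucleus→cytoplasm fluxes in the cytoplasmic ones,
conserving material between compartments of different size.

Defaults: n = 1.4, EC₅₀ = 0.5, τ = 1, w = 1, X_max = 1 per species;
shuttling s_MEKcn = 0.05, s_MEKnc = 0.5, s_ERKcn = s_ERKnc = 0.01
(reflecting measured transport-coefficient ratios); input parameters
b_Ca = 0.754, a_Ca = 0.092, b_CaM = 0.363, a_CaM = 0.485 (the
least-squares fit to phospho-ERK data). Reaction weights are validated
to [0, 1], the convention of the normalized-Hill (logic-ODE) formalism.

### Numerical solution

The model starts from the fully unphosphorylated state (all zeros); the
initial condition is not biologically constrained, and the multi-start
convergence property (below) justifies the choice a posteriori.
`solve_steady_state` integrates one depth with an adaptive 2(3)-order
Runge-Kutta pair over 50 time units with maximum step 0.1.
`spatial_profile` integrates all grid depths simultaneously with a
fixed-step RK4 (dt = 0.1), exiting early once max|dX/dt| < 1e−10 — past
that point the trajectory no longer moves at any accuracy of interest.
Convergence is always asserted, not assumed: each returned state carries
its residual max|dX/dt|, flagged non-converged at ≥ 1e−6. Inside the
fit objective, where thousands of steady-state evaluations are needed, a
short coarse integration (dt = 0.25, 15 time units) seeds a batched
Newton polish on rhs = 0 (finite-difference Jacobians), with fallback to
full integration. The three routes — adaptive pair, fixed-step RK4, and
algebraic root — agree within 1e−5 componentwise in the test suite.

Steady states lie in [0, X_max] componentwise for the default and
near-default parameters. The bound is not automatic for arbitrary rates:
the nuclear species have no Hill-bounded production term, so e.g.
MEKn* = r·s_cn·MEKc/(1 + s_nc) can exceed X_max when volume-scaled import
outruns export. The randomized-sweep sampler used for robustness tests
therefore enforces r_superficial·s_cn ≤ s_nc (comfortably satisfied at
the default rates), under which the bound holds provably. The sampler
also caps the Hill exponent at n ≤ 2.2: combining much steeper Hill
kinetics with strong ERKc ⊣ Rafc negative feedback carries the cascade
across a Hopf bifurcation into sustained oscillation — a well-known
behavior of feedback-bearing MAPK cascades — where no steady state
exists and the quasi-steady-state interpretation breaks down. Slowly
damped parameter sets near that boundary need more than 50 time units to
converge, so the sweeps integrate with a horizon of up to 2000 time
units and early exit; the default 50-unit/0.1-step setting remains the
solver default for the standard configuration.

### The knockout experiment

`knockout_cam` zeroes the CaM→Raf-1 inhibition weight, leaving all else
unchanged. Without the calmodulin brake the cascade sees the full Ca²⁺
drive, so steady-state ERK activation weakly increases at every depth and
the spatial profile follows the calcium input more linearly.

## Input fitting

Only the four input parameters are estimated; all cascade constants stay
at defaults. Data are cytoplasmic and nuclear phospho-ERK profiles on
the 7 coarse partitions, taken at partition-center depths d = k − 0.5
(the alignment between partition-aggregated data and the model grid is a
package choice; the half-cell grid brackets these centers). Each data
profile is standardized internally, and for each candidate parameter
vector each species' model output is affine-scaled onto its data by
ordinary least squares before residuals are formed — immunofluorescence
z-scores carry no absolute units, so only profile shape constrains the
inputs, and the objective is invariant to affine transformations of the
data. The outer optimizer is bounded nonlinear least squares on
(b_Ca, ã_Ca, b_CaM, ã_CaM) ∈ [0, 1]⁴ with a = (1−b)·ã enforcing
b + a ≤ 1, multi-started (default 16) from seeded random interior points.

Two robustness devices handle the objective's geometry. When CaM
inhibition exceeds the Ca²⁺ drive at every depth the model output is
identically zero and the objective is exactly flat; starts there are
deterministically shifted toward the responsive region (stronger Ca²⁺,
weaker CaM) before optimizing. And each start receives one refinement
pass — re-optimization from a drive-increasing shove of its solution —
which rescues starts trapped in weak-response local minima. With
noise-free data, essentially every random start then reaches the global
minimum (SSE ≈ 0) at the generating parameters.

### Identifiability

The four parameters are exactly identifiable from noise-free profiles
(recovery to ~1e−9). Under measurement noise they are not all well
conditioned: the objective has a flat valley along compensating
(b_CaM, a_CaM) combinations — the noise-free SSE of the best fit with
b_CaM displaced by ±0.1 from its true value stays below the expected
residual floor of noise with SD 0.05 per standardized point. Under such
noise the global optimum itself wanders along this valley, so CaM
parameter estimates scatter by roughly ±0.2–0.3 while the fitted curves
remain visually indistinguishable. This is a property of the model/data
combination (7 + 7 points, shape-only fitting), not of the optimizer;
users should treat fitted CaM parameters from noisy profiles as one
member of an equivalence class and report the fitted curves alongside.

## Synthetic data

The generator emulates the study design: 3 patients; panel of
phospho-Raf-1, phospho-MEK-1/2, phospho-ERK-1/2 in cytoplasm and nucleus
plus plasma-membrane calmodulin; per-patient intensity offsets
(SD 0.2 z-units) and homoscedastic Gaussian measurement noise (default
SD 0.1 z-units; a heteroscedastic option scales SD by up to 1.5× toward
the surface). Sample positions are uniform on u ∈ [0, 3); boundary
distances are back-computed from u and a nominal 30-unit layer thickness
so the conditioning round trip is exact. Per-target sample counts were
not reported for the original study; the default 300 per patient and
target gives dense coverage of all 28 fine partitions. Trends are either
catalog shapes (linear rise to a per-target peak depth, then a partial
drop — qualitatively matching the measured rise over the
spinous/granular layers and transitional decline, with CaM peaking at
d = 1 instead) or forward model solutions. `scramble=True` permutes
intensities within each patient/target/compartment series using a
dedicated RNG stream, so positions and marginals are byte-identical to
the unscrambled table — the calibration null for the permutation test.

For model-forward profile generation, `standardize=True` maps each
species' steady-state curve to mean 0, SD 1 before applying gain, offset
and noise — emulating the per-experiment z-scoring of the real data, so
that noise SD is expressed relative to each profile's own spatial
variation (the nuclear phospho-ERK curve spans a far smaller absolute
range than the cytoplasmic one).

What the generator does not emulate: intercellular heterogeneity beyond
additive noise (e.g. the rare phospho-MEK-bright basal cells), spatially
correlated noise within an image, segmentation error in the boundary
distances, and any target-specific nonlinearity of the fluorescence
scale. Passing tests on synthetic data therefore demonstrate that the
pipeline recovers the structure it assumes, not that real images satisfy
those assumptions.

## Problem sizes

Default test-suite and acceptance-script scales: permutation tests use
1,000 permutations (analysis default 100,000); calibration uses 500
replicate scrambled generations and power 200 structured pairs;
steady-state robustness sweeps use 50–100 random parameter sets × 5
depths; noisy recovery uses 20 replicates (tests) / 10 (script) with 3
starts each. These sizes give Monte-Carlo standard errors comfortably
inside the asserted tolerances.
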