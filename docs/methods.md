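# Methods

This note records the models, the choices made where the design was
open, and what the synthetic world does and does not establish.

## Landing-success model

Per-attempt success is Bernoulli with a logit link. Fixed effects:
centred wind speed (m s⁻¹, per-minute reading near the cliff), centred
turbulence intensity (dimensionless), ledge class (3 levels), species
(2), height band (4), plus wind×ledge and turbulence×ledge
interactions. Centring the continuous covariates removes their
collinearity with the interaction columns; the centring means are
stored on the fit so predictions accept raw values. The random
intercept is indexed by the combined (day, colony) label: weather and
topography make all attempts at one colony on one day alike, and the
shared intercept absorbs that dependence.

Reference levels are `large` ledge, `guillemot`, and the top height
band `h4`, so reported contrasts are "long-narrow ledge vs large",
"razorbill vs guillemot", "lowest band vs top", matching how the
fitted model is usually tabulated.

### Estimation

The marginal likelihood factorises over groups; each group contributes
a one-dimensional integral over its random intercept. We evaluate it
with adaptive Gauss–Hermite quadrature: per group, Newton iterations
find the posterior mode of `b` (the objective is strictly concave, so
a clipped Newton step converges in a handful of iterations to
|gradient| < 1e-10), the local curvature sets the quadrature scale,
and Q nodes (default 7; Q = 1 is the Laplace approximation) are
combined through log-sum-exp. The outer optimisation is L-BFGS-B over
(β, σ) with σ bounded below by 0, started from a statsmodels GLM fit
and σ = 0.5, followed by a damped Newton polish on the
finite-difference gradient and Hessian. The polish matters for
reproducibility: it pins the optimum so tightly that refitting after
adding a constant to the wind column changes coefficients by < 1e-8,
as the invariance of the centred design demands. σ < 1e-8 falls back
to the exact degenerate case (plain logistic likelihood), so the
boundary is handled without special pleading.

Standard errors are Wald, from the inverse numerical Hessian; AIC is
`2k − 2·logLik` with the random-intercept variance counted as one
parameter. Against `lme4::glmer` (bobyqa, Laplace) on a synthetic
table the estimates, SEs, σ and log-likelihood agree to ~2e-4; the
cross-check is kept as a test.

Convergence failure and separation (any |β| > 10, or saturated fitted
probabilities in the starting GLM) are flagged on the fit object, not
raised, so pipelines can report them.

### Analysis of deviance

The per-term table is sequential (Type I) in the order the model lists
its terms: each term's deviance drop is measured between the fits with
and without it, all retaining the random intercept; the null model is
intercept + random intercept. The reported F-analogue is
drop/df and "deviance explained" is the drop as a percentage of the
null deviance. This is the unique definition under which a published
per-term F/deviance table is internally consistent (every row's
F×df/null-deviance reproduces its printed percentage), which is why it
was adopted.

### R² and residuals

Nakagawa marginal R² is `var(Xβ) / (var(Xβ) + σ² + π²/3)`; conditional
R² adds σ² to the numerator. π²/3 is the latent logistic residual
variance. The residual check is a basic simulated-residual analogue:
simulate replicate responses from the fitted model (fresh random
intercepts each time), convert each binary observation to a randomised
PIT residual, and KS-test against uniformity. It detects gross
misspecification, not subtle autocorrelation.

## Attempt model

For a fixed profile the fitted logit is affine in raw wind,
`η(W) = ln a − bW`, giving `p(W) = a/(a + e^{bW})` with `b` the negated
total wind slope (main effect plus the profile ledge's interaction) and
`ln a` the linear predictor at W = 0. The collapse is algebraic, so it
agrees with `predict_success` to machine precision — tested at 1e-12.
The turbulence covariate is frozen at the profile's TI value (default:
its centring mean); turbulence otherwise enters the attempt model only
through the fluctuation SD `u = TI·U`.

Instantaneous cliff wind per attempt is LogNormal with
`s² = ln(1 + u²/U²)`, `m = ln U − s²/2` (exact moment match; `u = 0`
degenerates to a point mass). Attempts are independent draws — no
within-bout wind autocorrelation is modelled, so attempt-number tails
in strongly autocorrelated weather will be underestimated; that is a
stated non-goal.

`P = E[p(W)]` is integrated on the standardised log scale,
`∫ p(e^{m+st}) φ(t) dt` over t ∈ [−10, 10], with scipy's adaptive
quadrature at absolute tolerance 1e-10. The integrand is smooth and
bounded by φ, and the truncation error is below the Normal tail mass
beyond 10 SD (~1e-23). The Monte-Carlo oracle (`mean_landing_prob_mc`)
exists solely to cross-check this integral and is held to 3 SEs at 10⁶
draws in the acceptance suite.

The attempt count is geometric: `P(S = n) = (1−P)^{n−1} P`,
`E[S] = 1/P`, `P(S ≤ n) = 1 − (1−P)^n`. At-sea curves use
`U = ratio × sea wind` with the ratio a mean-of-ratios over wind
directions (matching per-direction normalisation of the flow
solutions); the curve tables default to 20 attempts, the order of
magnitude a guillemot may need near the seasonal wind maximum.

## Energetics

`cost = power × duration / 1000` kJ. Flight power and prey energy are
literature-derived inputs, not outputs of this analysis, so they are
config values; the defaults (power 4900/34 ≈ 144.1 W, loop 34 s, prey
29.4 kJ) are chosen to reproduce the published worked example exactly
(4.9 kJ per loop; one sandeel ≈ 6 loops). Only the products are
constrained by observation; the power value itself is back-derived.

## Wind-field post-processing

`u = √((2/3)k/ρ)` with ρ = 1 kg m⁻³ by default (the density is then a
no-op, as in the flow modelling); `I = u/U`, flagged (NaN/raised) at
U = 0 rather than returned infinite. Height adjustment uses the
logarithmic profile with separate roughness defaults over land (0.1 m,
the flow model's value) and sea (0.001 m, configurable — the sea value
is not fixed by the source analysis).

## Orientation

Mean direction and mean resultant length R̄ from the unit-vector mean;
Rayleigh `Z = nR̄²` with the standard `1/(4n)`–`1/(288n²)` corrected
p-value, validated against a simulated uniform null (agreement well
within 0.01 for n ∈ {5, 11, 50}; the test uses 10⁵ resamples so the
Monte-Carlo error ~0.0015 does not swamp the comparison). Published
circular test statistics sometimes print R̄ where Z is meant — at
n = 11, "0.314" only reconciles with p = 0.346 as R̄ — so both values
are always reported.

## Synthetic world

The generator inverts the success model: draw design structure, draw
winds, compute the true linear predictor, add the group intercept,
flip the coin. Defaults state the observed world:

- 26 days × 5 colonies; one global seed split into independent
  substreams (structure / winds / turbulence / intercepts / outcomes)
  via `SeedSequence.spawn`, so same seed ⇒ byte-identical tables.
- Colony mean wind 3.5 m s⁻¹ (the upper end of observed colony
  medians); day-level means LogNormal with CV 0.45 so that day-to-day
  weather, not just minute noise, drives wind variation; per-minute
  fluctuation LogNormal at TI 0.2 (typical near-cliff turbulence).
- True coefficients: the published point estimates. The intercept
  (never printed) is 1.5 — baseline success ≈ 0.82 at mean wind for a
  guillemot on a large ledge — and the two unprinted height offsets
  are −0.30/−0.15, interpolating toward the printed lowest-band −0.58.
- Ledge shares pooled ≈ 47% long-narrow / 31% large / 22% small,
  razorbill share 0.288, with per-species ledge profiles making
  razorbills choose small ledges ~5× as often as guillemots.
- Random-intercept SD 0.5 logits.
- Attempt volumes per (day, colony) are uniform — the real per-colony
  effort is unpublished, so a flat allocation was chosen once.
- Loop durations: LogNormal, median 34 s, log-SD 0.28, clipped to the
  observed [11, 58] s.

What a green test establishes: the estimator recovers the generating
parameters without bias and with calibrated intervals *when the model
is true*. The generator does not emulate observer error, within-day
wind autocorrelation, repeated attempts by the same individual, or
colony-specific wind exposure, so green tests say nothing about
robustness to those.

## Numerical notes and limitations

- Quadrature default Q = 7 nodes; Laplace (Q = 1) differs from Q = 7
  by ~0.2 in log-likelihood at n = 3000 and is what the lme4
  comparison uses.
- The geometric quantile is `⌈ln(1−q)/ln(1−P)⌉`, exact for the
  discrete law.
- Wind grids from the generator are statistical textures (smoothed
  noise with TI anti-correlated with U), not flow solutions; the
  sea-to-cliff ratio is only ever computed from user-supplied paired
  samples.
- Absolute landing-probability curves depend on the intercept and
  centring means, which are data-dependent; they are reproducible only
  by refitting the underlying observation table, not from published
  coefficients alone.
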