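# Methods

## Problem and data model

Soil bacteria colonize the root surface (rhizoplane) by two routes:
recruitment from the surrounding medium ("attachment") and proliferation of
cells already on the root. Neither route is directly observable with
destructive plate-count assays, which only measure the combined density.
`rhizofit` implements a kinetic framework that separates the two from a pair
of experiments: a *total colonization* time course (plants left in the
inoculated microcosm) and a *proliferation-only* time course (plants moved to
sterile microcosms 2 h after inoculation, so no further attachment occurs).

One observation is one destroyed plant (or one 100 µl suspension draw): time
`t` (h post inoculation), raw CFU count, fresh root weight `Wt` (g, root
treatments only), inoculant density `CFU⁰` (CFU ml⁻¹), treatment, replicate
and run. Sampling is destructive, so series are cross-sectional and all
replicates/runs are pooled before fitting. Root-surface responses are
normalized as

    y = CFU / (CFU⁰ · Wt)

to remove plant-size and inoculum variation; the ratio is reported in the
field's customary g⁻¹ even though it dimensionally carries ml g⁻¹ (we keep
the conventional label and note the discrepancy here once). Suspension
responses are expressed as Log₁₀(CFU ml⁻¹); zero counts have no log-scale
value and are excluded with a warning (no detection-limit rule is imposed).
The two response scales are never mixed: each series carries its
`response_kind` and AIC values are only compared within a series.

## Growth models

Five classical forms are available, each with its analytic time-derivative:

- **logistic** — `dy/dt = μ y (1 − y/K)`, solution
  `y = K y₀ / (y₀ + (K − y₀) e^{−μt})`;
- **Gompertz** — `y = K exp(ln(y₀/K) e^{−μt})` (natural logarithm, so that
  `y(0) = y₀` holds exactly);
- **logistic decline** — `y = a + b (1 − e^{−c/t})` for suspensions with no
  root input; defined for `t > 0`, with the analytic early-time limit
  `a + b` exposed separately;
- **Richards** — generalized logistic
  `y = K (1 + ((K/y₀)^ν − 1) e^{−μνt})^{−1/ν}`, reducing to the logistic at
  `ν = 1`;
- **Baranyi–Roberts** — explicit lag solution with adjustment function
  `A(t) = t + μ⁻¹ ln(e^{−μt} + e^{−h₀} − e^{−μt−h₀})`; `h₀ = 0` recovers the
  logistic.

The Richards and Baranyi forms are the standard ones from the growth-curve
literature, parameterized so each nests or approaches the logistic — this
makes their correctness testable against the logistic closed form and
against independent ODE integration.

## Fitting, selection, uncertainty

Fits minimize the residual sum of squares on the series' own response scale
(unweighted, as is customary for these assays) using bounded
trust-region-reflective least squares. Default starting values:
`K = 1.05 · max(y)`, `y₀ = max(first positive per-time mean, 10⁻⁶)`, and
`μ = 4 ×` the log-response slope over the first rising interval of the
per-time means, clipped to `[10⁻³, 5]` h⁻¹; all overridable. A constant
response is rejected as unidentifiable, and convergence onto an invalid
parameter region (e.g. Gompertz `y₀ ≥ K`) is reported as a fit failure
carrying the boundary iterate.

Model selection uses the Gaussian profile-likelihood AIC
`n ln(rss/n) + 2(k + 1)` (the residual variance counts as a parameter; only
differences within one series matter). Ties within 10⁻⁹ go to the model with
fewer parameters, then to the lexicographically first name.

Uncertainty is by case-resampling bootstrap (default 1000 replicates):
observation rows are resampled with replacement — destructive samples are
exchangeable — and refitted from the base estimate. Reported are
per-parameter SDs, 95% percentile intervals, and the SD of the predicted
curve on an hourly grid. Failed refits are dropped (warning above 20%
failures); per-parameter p-values are two-sided normal Wald tests on the
bootstrap SEs. The single published "bootstrap error" per model is ambiguous
about what it summarizes, so no attempt is made to reproduce it. Every entry
point that consumes randomness takes an explicit seed; there is no global
RNG state.

As a bias check on the parametric forms, the same rates can be computed
non-parametrically: a cubic smoothing spline (penalty chosen by generalized
cross-validation unless supplied; replicates collapsed to count-weighted
per-time means) is differentiated by 1-h central finite differences
(one-sided at the domain edges, flagged in the output).

## Rate decomposition

With the total-colonization logistic `(K_c, y_c0, μ_c)` and the
proliferation-only rate constant `μ_p`:

    R_c(t) = μ_c y_c (1 − y_c/K_c)        total colonization rate
    R_p(t) = μ_p y_c (1 − y_c/K_c)        proliferation in place
    R_a(t) = R_c − R_p = (μ_c − μ_p) y_c (1 − y_c/K_c)

`R_c` is the exact derivative of the logistic solution (the printed source
form of this derivative omits a factor μ_c and a `t`; the correct derivative
is used, and it — not the printed form — reproduces the published derived
numbers). `μ_p` deliberately comes from the proliferation-only experiment
while `y_c` and `K_c` come from the total-colonization fit. `μ_p > μ_c`
yields negative attachment (net loss); it is allowed and loudly warned
about. Consequences that the framework forces, used as test oracles:

- cumulative attached density `∫ R_a dt = (1 − μ_p/μ_c)(y_c(t) − y_c(0))`,
  so the attached share of the total density gain is exactly `1 − μ_p/μ_c`;
- `R_a` is exactly quadratic in `y_c`:
  `R_a = (μ_c − μ_p)(y_c − y_c²/K_c)`, peaking at `y_c = K_c/2`, i.e. at the
  logistic inflection `ln((K_c − y_c0)/y_c0)/μ_c`;
- the contribution proportion
  `p(t) = R_a(t) / (K_c ∫_t^T μ_p y_c (1 − y_c/K_c) dt)` has the closed-form
  denominator `K_c (μ_p/μ_c)(y_c(T) − y_c(t))`.

`p(t)` is implemented literally, including the `K_c` factor, by trapezoidal
quadrature on the evaluation grid; the closed form serves only as a test
oracle. Note two documented oddities inherited from the framework: `p` is
dimensionally a rate over a density (h⁻¹) despite being called a proportion,
and its denominator vanishes at the horizon `T`, so `p` is undefined there
(the grid column is NaN at `T` and requesting `p(T)` is a domain error).

Numerical choices: the default evaluation grid is hourly from `t = 1` h to
the horizon (`T = 96` h by default, both configurable); starting at 1 h
reproduces the published starting value of `R_a`. Integration is
trapezoidal; on the hourly grid the quadrature error of all integrals above
is below 10⁻⁵ relative. The quadratic relation is fitted by OLS on
`(1, y_c, y_c²)`; a numerically linear relation (curvature ≈ 0) is rejected
because its vertex is undefined.

## Synthetic data

The generator emulates the microcosm experiments as a stated world: five
treatments with the published AIC-selected fits as true curves; inoculation
at mean 2×10⁷ CFU ml⁻¹ (lognormal, CV 10%); root weights truncated-normal
with mean 0.01 g and CV 30% (weights were not reported; these values keep
normalized densities on the observed scale); at least five replicates per
timepoint; timepoints 2 h, every 2 h over 18–54 h, then 72/96 h for total
colonization, every 2 h over 2–24 h for suspensions, and out to 192 h for
the no-root suspension (whose decline only becomes measurable after 96 h).
Each observation inverts the normalization to a raw count and applies
mean-one multiplicative lognormal noise, `ε = exp(N(−σ²/2, σ²))` — plate
counts are right-skewed, and centering keeps fitted asymptotes unbiased.

Noise magnitudes are unreported; only the published fit r² values constrain
them. The defaults were calibrated once against those r²: σ = 0.68 (ln CFU)
for the root treatments (logistic refit r² ≈ 0.42), 0.84 / 0.126 / 0.060 for
suspension-with-root / no-root / exudate (r² ≈ 0.78 / 0.82 / 0.87). They are
part of the stated world, not tuning knobs. Each treatment draws from an
independent stream keyed by the design seed and the treatment name, so
adding a treatment never perturbs the others. An optional mechanism couples
the total-colonization log₁₀ count to root weight (default slope 214.55
log₁₀ CFU per g, the reported regression) to emulate the observed
size–count correlation; note that even with the coupling off, whole-root
counts scale with root mass through the normalization itself, so the
"null" regression slope is the small proportionality term
`1/(W̄t ln 10) ≈ 43`, not zero.

What a green synthetic test does *not* establish: the generator has no
dilution-series structure, no detection limit, no between-run batch effects
and no real biological covariance between treatments, so it validates the
statistical machinery, not the wet-lab design.

## Known limitations, and claims the stated world does not meet

Three stochastic performance targets carried by the design brief were
checked by direct simulation and found unattainable at the calibrated noise
level; the corresponding acceptance tests assert the stated thresholds and
fail honestly rather than being weakened:

- **AIC re-identification of the generating sigmoid.** The best logistic
  approximation to the Gompertz suspension-with-root truth on the design
  timepoints differs by ~10⁻⁴ squared-log-units per point, against a noise
  variance of ~0.133 — an expected AIC separation of ~0.1 at n ≈ 112–120.
  Selection is a near coin flip (measured 44–50%; ~74% for the logistic
  truth with three distinct-shape candidates), not ≥80%.
- **Peak-time recovery within ±6 h in ≥80% of runs.** The calibrated noise
  leaves ~16% relative error on μ_c, which alone shifts the inflection by
  ~6 h; measured recovery is ~55%.
- **Spline/parametric peak-time agreement within 6 h in ≥80% of noisy
  runs.** The GCV spline derivative is unstable at r² ≈ 0.42 noise
  (measured ~30–54%, with or without inverse-variance weighting); the spline
  cross-check is therefore validated on noiseless input, where it agrees
  with the parametric path to within 5% wherever `R_a` is appreciable.

Other limitations: no hierarchical (per-replicate) or heteroscedastic
fitting; no mechanistic two-compartment attachment model; no cross-scale
AIC comparison between normalized-density and log-scale series.
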