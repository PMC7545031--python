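# rhizofit

Kinetics of root-surface (rhizoplane) colonization from destructive CFU
assays: growth-curve fitting, AIC model selection, bootstrap uncertainty,
and decomposition of the total colonization rate into **bacterial
attachment** versus **on-root proliferation**.

## The problem

When a bacterial suspension meets a plant root, the density of bacteria on
the root surface grows by two routes: recruitment of cells from the medium
(attachment) and division of cells already on the root (proliferation).
Plate-count assays destroy the plant and only measure the combined density,
so the attachment rate cannot be observed directly. It can, however, be
*derived* from two experiments — a total-colonization time course, and a
proliferation-only time course in which plants are transferred to sterile
microcosms 2 h after inoculation so that attachment stops.

With the total-colonization density following a logistic curve
y_c(t) with parameters (K_c, y_c0, μ_c), and μ_p the rate constant of the
proliferation-only fit, the rates decompose as

    R_c(t) = μ_c · y_c (1 − y_c/K_c)          total colonization rate
    R_p(t) = μ_p · y_c (1 − y_c/K_c)          proliferation in place
    R_a(t) = R_c − R_p                        attachment (recruitment)

Integrating R_a gives the cumulative density recruited from the medium, and

    p(t) = R_a(t) / ( K_c ∫_t^T μ_p y_c (1 − y_c/K_c) dt )

weighs attachment at time t against all future proliferation up to the
experiment horizon T (96 h by default). For logistic inputs R_a is an exact
quadratic in y_c, peaking at y_c = K_c/2.

The package also fits the surrounding machinery a practitioner needs: the
classical logistic, Gompertz, Baranyi, Richards and logistic-decline growth
models with analytic derivatives; normalization of raw counts by inoculant
density and root weight (y = CFU/(CFU⁰·Wt)); pooled nonlinear least-squares
fits with Gaussian AIC selection; case-resampling bootstrap SEs, percentile
intervals and prediction bands; cubic-smoothing-spline rate estimates as a
non-parametric cross-check; and a synthetic microcosm generator that
emulates the full experimental design for end-to-end testing. See
`docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Reproduce the attachment-rate decomposition from published parameter
estimates for *Pseudomonas fluorescens* SBW25 on lettuce roots (shipped in
`rhizofit.reference`):

```python
import rhizofit as rf

decomp = rf.AttachmentDecomposition(
    rf.reference.TOTAL_COLONIZATION,      # K_c=8.855974, y_c0=0.007333, mu_c=0.184677
    rf.reference.PROLIFERATION.mu,        # mu_p=0.09949397
)
print(decomp.rates().summary())
```

```
Attachment decomposition
==========================================================
colonization: K_c=8.85597, y_c0=0.007333, mu_c=0.184677 h^-1
proliferation rate constant mu_p=0.099494 h^-1
grid: 1..96 h (96 points), horizon 96 h
----------------------------------------------------------
peak attachment rate : 0.1883 g^-1 h^-1 at t = 38 h
attachment at t=1 h : 0.0007505 g^-1 h^-1
attachment at t=96 h : 1.818e-05 g^-1 h^-1
cumulative attached density : 4.081 g^-1
attached fraction of density gain : 0.4613 (closed form 1 - mu_p/mu_c = 0.4613)
==========================================================
```

Reading: attachment is negligible in the first hours, peaks at 0.188 g⁻¹ h⁻¹
38 h post inoculation (when the root is half colonized, y_c ≈ 4.26 g⁻¹) and
collapses as the surface saturates; 46% of the final density was recruited
from the medium rather than grown in place.

Fitting and selection work statsmodels-style on data:

```python
df, truth = rf.generate_dataset(rf.default_design(seed=1))
series = rf.build_series(df, "total")
best, comparison = rf.select_model(series)     # AIC over 5 candidate models
best.bootstrap(reps=1000, seed=1)
print(best.summary())
```

The same pipeline is scriptable from the shell:

```sh
rhizofit simulate --out run/ --seed 1
rhizofit fit      --input run/dataset.csv --out run/ --reps 1000 --seed 1
rhizofit decompose --input run/dataset.csv --out run/
```

## Acceptance script

`scripts/acceptance.py` recomputes, from the published parameter estimates
alone, the derived quantities of the original analysis: the hourly
attachment-rate curve (its peak value, peak hour, values at 1 h and 96 h,
and the colonization density at the peak) and the no-root suspension levels
at 2 h and 192 h from the logistic-decline model.

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
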