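# Methods

This note documents the models, parameter conventions, numerical choices,
and known limitations of `mixrisk`.

## Pipeline model

The analysis treats risk as a composition of conditionally independent
stages per simulated individual *i* in region *r* and chemical *j*:

    C_ext[i,j]  ~ TruncNormal(μ_rj, σ_rj; ≥0)          external conc., µg/m³
    D[i,j]      = C_ext[i,j] · IR[i] · t · 10⁻³        internal dose, mg/kg/day
    C[i,j]      = D[i,j] · Css[i,j]                    in-vitro equivalent, µM
    E[i]        = mixture(C[i,·]; hill params)          % assay activity

The inhalation rate IR is carried per kilogram body weight (m³/kg/day),
so body weight never appears explicitly — it is absorbed into the rate.
`t` (days) defaults to 1: the steady-state plasma assumption behind Css
is taken to be reached within a day, so longer integration would
double-count. The µg→mg factor 10⁻³ is exposed as `dose_scaling` for
other unit systems.

## Hill concentration-response model

Each chemical × assay curve is the log-logistic (hill) function in log10
concentration used across high-throughput screening:

    f(c) = tp / (1 + 10^((log10AC50 − log10 c)·slope))

* `tp` — top, maximal response (% activity), box-constrained to
  (0, 1.5 × max observed response];
* `log10AC50` — log10 of the half-maximal concentration (µM), constrained
  to the observed log-concentration range ± 3 decades;
* `slope` — hill coefficient, fixed at 1 in the 2-parameter variant
  (the form under which GCA has a closed-form solution), free in
  [0.3, 8] in the 3-parameter variant.

Responses are assumed pre-normalized to a zero baseline (standard
"% activity" convention), so no intercept is fitted. Fitting is maximum
likelihood under i.i.d. Gaussian residuals with free `log_sigma` — a
deliberately simple, swappable error model. Initialization: `tp₀` = max
response, `log10AC50₀` = median log10 concentration, `slope₀` = 1,
`log_sigma₀` = log sd of responses. Optimization is L-BFGS-B with an
analytic gradient, followed by damped Newton steps (using a
finite-difference Hessian of the analytic gradient) to drive the gradient
norm below the convergence threshold when the optimum is interior.

A fit is `converged` only if the optimizer succeeded, the gradient norm
is < 1e−6, the observed information matrix is positive definite, and no
parameter sits on a box bound. Standard errors are square roots of the
inverse-information diagonal. Flat curves (zero response range) and
curves with no positive response are flagged degenerate rather than
raising; noiseless data are likewise flagged (the Gaussian scale MLE
degenerates at zero residual) while still returning exact point
estimates. Non-converged chemicals are excluded from the roster.

AIC = 2k − 2·loglik with k counting `log_sigma` (3 or 4 free
parameters).

## Mixture models

**GCA.** The joint effect E solves `Σⱼ Cⱼ / fⱼ⁻¹(E) = 1`. For slope-1
curves the inverse is `fⱼ⁻¹(E) = AC50ⱼ · E/(tpⱼ − E)`, extended
algebraically past the top with a sign change — this is what lets GCA
accommodate partial agonists, whose presence pulls the mixture effect
toward their own (lower) top. The closed form

    E = Σⱼ(Cⱼ·tpⱼ/AC50ⱼ) / (1 + Σⱼ(Cⱼ/AC50ⱼ))

is the default evaluation path; the numeric route brackets the same
root monotonically on E ∈ (0, max tpⱼ) and is cross-checked against the
closed form in the test suite (agreement < 1e−8 over random mixtures).
With non-unit slopes the inverse `AC50·(E/(tp−E))^(1/slope)` has no real
extension above `tp`, so the search interval is capped at the smallest
top among non-unit-slope chemicals; if no root exists there the interval
bound is returned with a warning flag.

**IA.** Survival-fraction multiplication normalized to a reference
maximum: `E = e_ref·(1 − Πⱼ(1 − fⱼ(Cⱼ)/e_ref))` with
`e_ref = maxⱼ tpⱼ` over the assay's covered chemicals. This choice makes
IA well defined and bounded for heterogeneous tops; the input data do not
determine it, so it is exposed as a parameter.

**Hazard quotient.** The default convention scales the whole mixture at
fixed ratio: find s* with `response(s*·C) = (hq_percent/100)·e_ref` and
report `HQ = 1/s*`. HQ is therefore homogeneous of degree 1 in C, and
HQ > 1 means the mixture already exceeds the reference response level.
The root is found on log10 s ∈ [−12, 12] by Brent's method (absolute
tolerance 1e−10, ≤ 200 iterations); the slope-1 GCA case uses the exact
algebraic solution `s* = T/(A − T·B)` with `A = ΣC·tp/AC50`,
`B = ΣC/AC50`, `T` the target. If the model's asymptote never reaches
the target the HQ is 0 with a warning; if the root lies below the
bracket the bracket bound is returned. The classical hazard-index
convention `Σⱼ Cⱼ/ECpⱼ` (each chemical against its own p% effect
concentration) is available as `convention="hazard_index"` but is not
the default, because it ignores mixture interaction under GCA.

## Population simulation

All sampling flows through per-(region, component) RNG substreams
derived from one master seed (`SeedSequence` spawn keys: CRC-32 of the
region id × a fixed component index). Consequences: region order never
affects results, and re-running a single component (as the sensitivity
analysis does) reproduces exactly its draws from the full run.

* **Age** — bracket chosen multinomially by proportion, then an integer
  age uniform within the bracket. Open-ended top brackets are sampled
  uniformly on [85, 99]; 99 is the global age cap.
* **Obesity** — one prevalence draw per region from
  Normal(prev_mean, prev_sd) truncated to [0, 1] (propagating the survey
  confidence interval), then an independent Bernoulli per individual.
* **Inhalation rate** — Normal(bracket mean, bracket sd) truncated at 0,
  by the individual's age bracket.
* **Exposure** — per chemical, Normal(mean, sd) truncated at 0. The
  input tables supply only mean/sd semantics; the truncated normal is
  this package's distributional choice.
* **Css** — uniform bootstrap resampling with replacement from the
  pre-simulated sample vector of the individual's
  (chemical, age group, weight class) stratum. Default age groups:
  0–17, 18–44, 45–64, 65+ (configurable on `CssTable`). The Css unit is
  read as µM per unit daily dose rate (mg/kg/day).

Truncated normals are drawn by inverse-CDF transform of a single uniform
per value, which keeps draws exact, reproducible, and well defined at
sd = 0 (degenerate at the mean).

## Spatial summaries

Single-assay maps use per-region empirical percentiles of the metric
over individuals. Multi-assay risk is the nested "p total quantile of
the q assay-level quantiles": q-th percentile over individuals within
each assay, then p-th percentile across assays. Assay-level quantiles
are taken over individuals *within* each region. All percentiles use
linear interpolation between order statistics (NumPy's default
estimator). Defaults: assay quantiles (10, 50, 90), total quantiles
(5, 10) — conservative lower-tail summaries for hazard quotients.

Assays with partial chemical coverage are evaluated on their covered
subset of the global roster; the roster itself is global (exposure ∩
converged fits ∩ Css), not per-assay.

## Sensitivity analysis

One-at-a-time Monte Carlo: the chosen component re-samples from its
distribution while the others are pinned to central values — age: the
exact median of the region's discrete age distribution; obesity: all
"Normal"; external concentration: the exposure mean; Css: the stratum
median; fit parameters: the MLE. When fit parameters vary, (tp,
log10AC50, slope) are drawn per replicate from independent normals
centred at the MLE with the fitted standard errors, truncated to
validity (tp > 0, slope in the fitting box); covariances are not used.
Inhalation rate is deterministic given age (bracket mean), so its
variability enters only through the age component. Pinning every
component reproduces a bitwise-constant baseline — guaranteed by
evaluating the closed forms with elementwise reductions rather than
BLAS matrix products, whose row blocking can differ by 1 ulp.

## Synthetic studies

The generator emulates the *shape* of the real inputs: a rectangular
grid of unit-degree regions; log-normal exposure means (median ≈ 2
µg/m³) with sd fixed at 30 % of the mean; true hill tops uniform on
[50, 120] % activity and log10 AC50 on [−1, 1] with slope 1 (optionally
[0.8, 3]); 3 replicate responses at 10 log-spaced concentrations
(10⁻²–10² µM) with additive Gaussian noise; log-normal Css strata
(geometric means 1–10, σ_log = 0.3, 50 samples per stratum) with the
Obese stratum multiplied by 1.2 — an arbitrary, documented effect size
that makes weight-class contrasts visible, not a physiological claim;
seven age brackets with Dirichlet-jittered proportions; obesity
prevalence 0.25–0.40 (sd 0.03); inhalation rates monotone decreasing in
age. One assay always omits one chemical (when counts allow) so partial
assay coverage is exercised.

It does **not** emulate spatial autocorrelation of real exposure
surfaces, non-hill curve shapes, demographic covariance, or real
toxicokinetic between-chemical correlation — so passing tests show the
machinery is correct, not that any real region's risk is reproduced.

Test and validation problem sizes (500 fitted curves at 5 % noise for
recovery; a 5-region × 4-chemical × 2-assay study with 200 individuals
per region for the end-to-end runs; 1,000 random mixtures for the
mixture-model cross-checks) were chosen as the smallest scales at which
the Monte Carlo assertions are stable across seeds.

## Determinism and outputs

One master seed drives everything; written artifacts (CSV tables with
sorted keys and fixed column order, GeoJSON with sorted keys, manifests
without timestamps, PNG figures with fixed metadata) are byte-identical
across reruns. In-memory provenance keeps wall-clock timestamps; they
are deliberately excluded from files.

## Known limitations

* No physiologic toxicokinetic simulation: Css arrives as a sample
  table from an upstream model.
* No sex stratification; individual variability enters through age,
  weight class, inhalation rate, exposure, and Css only.
* The Gaussian residual model for curve fitting is not robust to heavy
  outliers (a Student-t alternative would slot into the same MLE
  machinery).
* GCA with non-unit slopes is only defined up to the smallest top among
  those chemicals; mixtures pushed beyond it return a flagged bound.
* Hit-call filtering and cytotoxicity correction are upstream concerns:
  the concentration-response table is taken at face value.
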