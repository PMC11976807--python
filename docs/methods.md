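# Methods

## Setting and data model

The package analyses microdialysis sampling of unbound drug during and after
hyperthermic intraperitoneal chemotherapy (HIPEC). The experimental unit is a
catheter placed in one tissue compartment of one animal; nine compartments
are distinguished (two liver sites, superficial and profound rectum,
superficial and profound stomach, three peritoneal sites — the dual-depth
organs are modelled as separate compartments, each with its own kinetic
parameters). A catheter yields twelve interval-averaged dialysate samples:
eight 30-min intervals over 0–240 min and four 60-min intervals over
240–480 min, with time zero at perfusion start. The 30-min tissue
equilibration before perfusion is not modelled; no data are collected in it.

All times are minutes, doses mg, concentrations µg/mL. The dosing protocol
(`protocol` module) prescribes dose per m² of body surface area,
`SA = 0.0970·W^0.633` m² for a pig of weight W kg, split 50/25/25% at
0/30/60 min over a 90-min perfusion.

## Recovery calibration

A catheter recovers only a fraction (relative recovery, RR) of the true
extracellular concentration. RR is calibrated per catheter by
retrodialysis-by-drug, `RR = 100·(1 − C_dialysate/C_perfusate)`; when the
usual two calibration samples (C1, C2) exist the mean of the two RRs is
used — the field reports both samples but no combination rule, and the mean
is the natural symmetric choice. RR values outside (0, 100] are physically
impossible and mark the probe as malfunctioning; such catheters are excluded
entirely, mirroring the exclusion of displaced catheters in practice.
Dialysate values below the assay quantification limit (LLOQ, 0.030 µg/mL)
are retained with a censoring flag; the default downstream handling excludes
them from the fit (conservative), with LLOQ/2 imputation available.

## Kinetic model

Tissue concentration follows zero-order input with first-order elimination
from a drug-free start:

    C(t) = (k_in/k_e)(1 − e^(−k_e t))      t ≤ t_in
    C(t) = C(t_in) e^(−k_e (t − t_in))     t > t_in

Only the tissue is observed, so the reservoir's initial content, transfer
rate and bolus schedule are not separately identifiable; they collapse into
(k_in, t_in, k_e), which is what we estimate.
`map_central_parameterization` documents the correspondence: total central
input divided by the transfer rate gives the input duration, and an
event-driven walk detects the (non-default) case where the reservoir runs
dry between boluses, yielding disjoint input windows. By default the three
boluses are assumed to keep the reservoir non-empty until a single depletion
time — consistent with the observed unimodal curves and with peak times
(~100–125 min) that exceed the 90-min perfusion. For the same reason the
drain at 90 min is not a hard cutoff on t_in: drug already in transit
through the interstitium keeps supplying the sampled depth.

Predictions for samples are interval averages of C(t), computed from the
analytic antiderivative (microdialysis physically integrates over the
collection window); midpoint point-prediction is a config option. Derived
parameters are model-based: T_max = t_in, C_max = C(t_in),
T_1/2 = ln2/k_e, and AUC_0–last the analytic integral to 480 min — the
fitted-curve versions, not observed-data trapezoids, since the fitted model
smooths measurement noise.

## Mixed-effects estimation

Per tissue compartment, log-observations get log interval-average
predictions with additive Gaussian error (i.e. log-normal proportional
error — concentrations span more than an order of magnitude). Animal-level
random effects act on log k_in and log k_e; t_in is a tissue-level constant:
with at most eight animals a third variance component is not supportable,
and peak-time variation is narrow. Duplicate catheters of one animal share
that animal's random effects.

Estimation maximizes the Laplace-approximate marginal likelihood. Two
structural facts make this fast and stable:

* the k_in random effect shifts the log-prediction additively, so its
  conditional mode is a ridge-regression closed form; the per-animal inner
  problem is a 1-D search over the k_e effect (Newton with a bounded-Brent
  fallback);
* optimization proceeds in stages — pooled fixed-effects least squares to
  pin the structural parameters, a Nelder–Mead pass over the three variance
  components only, then a full L-BFGS-B polish with bounds. The staging
  avoids a known ridge where an offset in a fixed effect hides inside an
  inflated random-effect variance.

Log-SDs are bounded in [log 1e-6, log 10] so the zero-noise limit stays
finite; an estimate at the lower bound means "no detectable variability".
The fixed-effect covariance comes from the numeric Hessian of the negative
marginal log-likelihood (variance components held at their estimates), with
eigenvalues clipped positive so near-flat directions produce wide rather
than zero uncertainties. CIs for derived parameters are Wald on the log
scale via the delta method, back-transformed (hence always positive). The
fit is deterministic given data and options; the result is invariant to row
order of the input table.

With a single animal (or `random_effects=False`) the model drops random
effects and fits plain nonlinear least squares on the log scale.

## Tissue comparisons and limits of agreement

Between-tissue contrasts operate on per-catheter derived parameters,
log-transformed: a linear mixed model `log(param) ~ tissue + (1|animal)`
(statsmodels MixedLM, REML) gives ratios of estimated medians with Wald CIs
and two-sided p-values. P-values are reported unadjusted with a 5%
threshold; a multiplicity correction is deliberately not applied by default
(the analysis reports all pairwise contrasts for transparency), and callers
can adjust externally.

Reproducibility of duplicate catheters uses `log(param) ~ 1 + (1|animal)`
within an organ: with residual log-SD σ, 95% of same-animal catheter ratios
fall within a factor `LOA = exp(1.96·√2·σ)` (the √2 because a ratio
compounds two independent catheter errors). The one-way random-intercept
REML is implemented directly (profiled scalar criterion via
Sherman–Morrison) because the parametric-bootstrap CI (default 1000
replicates, seeded) and Monte-Carlo validation need millisecond refits; it
is cross-checked against statsmodels MixedLM in the test suite. The
pipeline's `AnalysisConfig` uses 200 bootstrap replicates per LOA cell so a
full run over four organs and three parameters stays interactive; the
library default remains 1000.

## Synthetic experiment generator

The generator emulates the study design end-to-end: per animal and
compartment, parameters are drawn log-normally around compartment medians;
per catheter, an RR is drawn from a truncated normal matching the reported
per-compartment means and SDs; interval-average tissue concentrations are
converted to dialysate scale (×RR/100), multiplied by log-normal noise,
censored below LLOQ, and whole catheters are removed by independent
Bernoulli failure.

Defaults are the study conditions: 8 animals; 9 catheters per animal;
compartment medians set from the reported values (Cmax 0.45–3.11 µg/mL,
Tmax 100.6–124.4 min, T1/2 15.9–41.0 min) inverted through the closed form
(t_in = Tmax, k_e = ln2/T1/2, k_in from the peak equation); catheter failure
probability 19/62; LLOQ 0.030 µg/mL. Where no value is reported the defaults
are declared synthetic choices: between-animal log-SDs 0.4 (k_in) and 0.15
(k_e); residual log-SD 0.20, matching the assay's ~20% intermediate
precision; calibration perfusate 5 µg/mL; animal weights uniform on
58–62 kg. By default the calibration records encode each catheter's true RR
exactly (two identical C1/C2 samples), so recovery correction inverts the
corruption identically — `miscalibrated_rr_sd` injects calibration error for
robustness studies. `n_planned_catheters` subsamples the planned series
(e.g. 62 of 72) to reproduce alternative catheter accounting.

What the generator does **not** emulate: spatial diffusion between depths
(depth differences are just different compartment parameters), temperature
heterogeneity, drift in recovery over the 8-h experiment, correlated
catheter failures, or assay error structure beyond log-normality. Passing
recovery tests therefore demonstrate estimator correctness under the model's
own assumptions, not robustness to these real-data features.

## Numerical choices and edge cases

* Closed-form kinetics use `expm1` throughout; they match an adaptive ODE
  integrator and quadrature to ≤1e-6 relative error over randomized draws.
* If the sampling window ends before t_in, T_max is clamped to the window end
  with a warning (peak not observed).
* Starting values: t_in from the time of the largest observation, k_e from
  the post-peak log-linear slope (fallback ln2/30 min when fewer than two
  post-peak points), k_in by inverting the peak equation, all clamped
  positive.
* Degenerate comparison inputs (all values identical) return the exact null
  result; a singular mixed model falls back to an OLS contrast with a
  warning. Exact duplicate agreement short-circuits the LOA REML to σ = 0.
* Problem sizes in the validation suite (numbers of Monte-Carlo replicates,
  tissues fitted, bootstrap draws) are chosen as the smallest that make the
  asserted tolerances statistically meaningful.

## Known limitations

* No systemic/plasma compartment or recirculation: profound-depth
  concentrations are attributed entirely to local penetration.
* The Laplace approximation with ≤8 animals gives first-order-accurate
  variance components; random-effect SDs are reported without CIs.
* Censored observations are excluded rather than integrated over (no
  likelihood contribution below LLOQ); with heavy censoring late in the
  washout this can bias k_e slightly upward.
* Wald CIs on back-transformed scales are asymptotic; with n = 4–8 animals
  they are approximate.
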