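# Methods

## Model and assumptions

The package models a parent pollutant *S* degraded by a microbial culture
with total first-order rate constant `k_tot` (d⁻¹), a fixed fraction `f` of
the degraded flux appearing as one tracked intermediate *P* that itself
decays first-order with `k₂` (d⁻¹):

    dS/dt = −k_tot·S
    dP/dt = f·k_tot·S − k₂·P

Assumptions: rate constants are time-invariant (no growth-linked/Monod
dynamics, no biphasic DFOP behaviour), the branching fraction is constant
over the experiment, there is a single tracked intermediate (no cascade
accounting), and cultures start with no intermediate (`P0 = 0` by default).
Time is in days throughout, concentrations in mg/L.

The closed form is `S(t) = S0·e^{−k_tot t}` and the Bateman daughter
solution for *P*; when `|k₂ − k_tot| ≤ 1e−8` d⁻¹ the analytic equal-rate
limit `P = (P0 + f·k_tot·S0·t)·e^{−k_tot t}` is used instead. The 1e−8
threshold sits below double-precision cancellation noise for the exponent
ranges encountered (rates ≲ 2 d⁻¹, horizons ≲ tens of days); continuity at
the switch is property-tested. An adaptive RK45 integration of the same
right-hand sides (rtol 1e−10, atol 1e−12) is kept as an internal oracle and
must agree with the closed form to 1e−8 mg/L. Trajectory values in
(−1e−12, 0) are clipped to 0 as float noise; anything more negative raises,
to distinguish noise from bugs.

Derived quantities: half-life ln2/k, formation rate `k_a = f·k_tot`
(exact, never re-estimated separately), and the intermediate peak time
`ln(k₂/k_tot)/(k₂ − k_tot)` (limit `1/k_tot`), which depends only on the
two rate constants — `f` and `S0` scale the curve without moving its
argmax.

## Global fit

Both series are fitted jointly by unweighted least squares on the raw mg/L
scale; with starting concentrations near 60 mg/L (parent) and peaks near
10–25 mg/L (intermediate) the two series are of comparable magnitude, so
unweighted pooling is the default and per-series inverse-variance weighting
(weights from a first unweighted pass) is optional. Parameters are
optimized on transformed scales — log for `k_tot`, `k₂`, `S0`; logit for
`f` — which enforces positivity and `0 < f < 1` without hard bounds.
The optimizer is scipy's trust-region-reflective nonlinear least squares
with finite-difference gradients, ftol = xtol = gtol = 1e−12, so noiseless
synthetic data are recovered to better than 1e−6 relative error (tested).

Initialization is cheap and data-driven: `k_tot` from a log-linear
regression of the parent series, `f = 0.5`, `k₂ = k_tot`, `S0` = the
earliest parent observation. `S0` is estimated by default — the nominal
spiked mass need not equal the dissolved measurable concentration — with a
`fix_S0` option for the nominal-value convention. Replicates enter as
independent observations by default (no hierarchical structure); a
`use_replicate_means` option fits per-time means instead.

Below-LOD observations are censored values, not zeros: the default policy
excludes them from the objective, and an LOD/2 substitution policy is
provided. A fully censored series or fewer than 3 distinct usable time
points per series (4 observations total) is a fitting error, as is
optimizer non-convergence (the error message carries the optimizer status).

Goodness of fit: R² = 1 − SSR/SST pooled over both series, with SST using
each series' own mean, so a flat per-series-mean predictor scores exactly
0; per-series R² values are reported alongside because a single pooled
number can hide an imbalanced fit. Per-series residual standard deviations
use `sqrt(SSR_s/(n_s − 2))`, charging each series roughly two of the four
shared parameters.

## Parametric bootstrap

Uncertainty is by parametric bootstrap: each resample draws observations as
model prediction + per-series Gaussian noise with the fitted sigma, clipped
at 0 (additive-Gaussian is the least-structured observation model for
concentration residuals and matches the generator, keeping simulation and
inference internally consistent; clipping rather than rejection implements
the "no negative concentrations" constraint and is negligible at the
noise/signal ratios here). Each resample is refitted from the point
estimate with the original fit options; non-converged refits are dropped
and counted rather than redrawn, keeping the resample count interpretable,
and more than 20 % failures is an error. Intervals are empirical 5–95 %
percentiles with linear interpolation. A single integer seed drives the
whole resampling stream, and because observations are canonically sorted,
the draws table is bit-identical across runs and across input-row
permutations.

Robustness of the branching fraction is summarised by its 5–95 % interval,
the fraction of draws with `f > 0.5` (probability the tracked intermediate
carries the dominant share of the flux), and its coefficient of variation
(ddof = 1).

## Stoichiometry

Molar yield = 100·(P_formed/MW_int)/(S_degraded/MW_parent), with formula
weights shipped in an editable registry (pyrene 202.25, 2,2′-diphenic acid
242.23 g/mol, plus the other compounds of the pathway). The time-course
version compares each sampling time against t = 0 replicate means and flags
times with non-positive parent depletion as undefined rather than dividing
by zero. The mass-flow invariant `P ≤ f·(S0 − S)` caps the model yield at
`100·f·MW_int/MW_parent`.

## Relative expression (2^−ΔΔCt)

Livak convention, in this order: technical replicates are averaged to one
Ct per (gene, condition, biological replicate); ΔCt subtracts the reference
gene (default 16S rRNA) within the stratum; ΔΔCt subtracts the gene's mean
control-condition ΔCt (default control: glucose-grown cultures); the fold
change 2^−ΔΔCt is computed per biological replicate and reported as the
arithmetic mean with SD. The reference gene is exactly 1.0 in every
condition by construction, and fold changes are invariant to any constant
Ct offset applied to a whole stratum (both tested). Induction calls are
descriptive threshold flags (default > 2-fold); significance testing and
primer-efficiency (Pfaffl) correction are out of scope.

## Synthetic-data generator

The generator emulates the study design: parent spiked at 60 mg/L,
triplicate sampling on days {0, 1, 3, 5, 7, 9, 11, 13, 15}, closed-form
trajectories at the fitted study parameters (`k_tot = 0.142`, `f = 0.4437`
so `k_a = 0.063`, `k₂ = 0.150`, all d⁻¹) plus additive Gaussian noise
clipped at zero, and LOD flagging. Defaults chosen once: σ_parent =
2.0 mg/L (~3 % of the starting concentration, typical UPLC replicate
scatter and the level used in the recovery checks), σ_intermediate =
1.0 mg/L (scaled to the smaller intermediate signal), LOD = 0.02 mg/L for
both channels (the one reported instrument LOD for the UPLC method, stated
for 1-hydroxy-2-naphthoic acid). A lognormal noise option exists for
robustness experiments. Ct tables are generated with the reference gene at
a fixed baseline and targets shifted by −log2(fold) in the treatment
condition, 0.2-cycle noise by default.

What the generator does **not** emulate: heteroscedastic or
concentration-proportional measurement error, abiotic losses
(volatilisation, sorption to glass), lag phases or growth-coupled rate
changes, replicate-level batch effects, and qPCR efficiency differences
between primers. Passing recovery tests therefore demonstrates correctness
of the estimators under the stated observation model, not robustness to
every artefact of real chromatography or qPCR data.

## Problem sizes in the heavy checks

The suite's calibration check runs 200 outer replicates with 200 bootstrap
resamples each (5–95 % interval coverage of the true `k_tot` must fall in
[0.80, 0.97]); noisy-recovery checks use 50 seeds at σ = 2 mg/L and 1 mg/L.
These sizes give stable pass/fail behaviour at a few minutes of runtime;
production analyses should keep the 500-resample default.

## Known limitations

* Censored observations are dropped or crudely imputed (LOD/2); no
  censored-likelihood (Tobit-style) objective.
* No model selection against alternative kinetics (Michaelis–Menten, DFOP,
  Monod-linked); the branched first-order form is assumed.
* Replicates are treated as independent; no mixed-effects hierarchy.
* The intermediate mass balance covers one metabolite; flux through
  undetected routes is absorbed into `1 − f`.
* Percentile intervals are not bias-corrected (no BCa).
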