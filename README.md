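# pahkin

Parent–metabolite first-order degradation kinetics for pollutant
biodegradation studies, built around the shake-flask design used to
characterise bacterial pyrene degradation proceeding through 2,2′-diphenic
acid (DIPA) as the central intermediate.

It is aimed at environmental microbiologists and biodegradation modellers
who have replicate concentration time courses of a parent compound and one
tracked intermediate and want rate constants, branching fractions, and
honest uncertainty for them — plus the molar-yield and RT-qPCR (2^−ΔΔCt)
calculations that usually accompany such a study.

## The model

Parent concentration *S* (mg L⁻¹) and intermediate concentration *P*
(mg L⁻¹) follow a branched first-order scheme:

```
dS/dt = −k_tot · S
dP/dt = f · k_tot · S − k₂ · P          k_a = f · k_tot
```

* `k_tot` (d⁻¹) — total parent degradation rate constant; half-life
  DT50 = ln 2 / k_tot.
* `f` (–) — branching fraction: the share of degraded parent flux that
  appears as the tracked intermediate; `k_a = f·k_tot` is the effective
  formation rate constant.
* `k₂` (d⁻¹) — intermediate degradation rate constant.

The intermediate solution is the classical Bateman expression
`P(t) = P₀e^{−k₂t} + f·k_tot·S₀/(k₂−k_tot)·(e^{−k_tot t} − e^{−k₂ t})`,
with the analytic limit used when `k₂ ≈ k_tot`. Both series are **globally
fitted** by nonlinear least squares (rates on log scale, `f` on logit
scale), and parameter uncertainty comes from a **parametric bootstrap**
(default 500 resamplings, 5–95 % percentile intervals). Below-LOD
observations are censored, not zeros, and are excluded from the objective
by default.

Alongside the kinetics the package provides:

* **stoichiometry** — molar-yield accounting between compounds of different
  molecular weight (pyrene 202.25, DIPA 242.23 g mol⁻¹);
* **expression** — Livak 2^−ΔΔCt relative expression from tidy Ct tables,
  with the 16S reference gene normalised to exactly 1.0;
* **simulate** — a seeded generator producing time-course and Ct datasets
  with the study's design (triplicates, days 0–15, additive noise, LOD
  flags), so every stage is testable without any download.

## Worked example

```python
import pahkin as pk

data = pk.simulate_timecourse(pk.STUDY_PARAMS, pk.DesignSpec(seed=42))
fit  = pk.fit_branched_model(data)
boot = pk.parametric_bootstrap(fit, data, n=500, seed=1)
```

Running `python examples/simulate_and_fit.py` prints:

```
n observations fitted : 54
k_tot  = 0.140 /d   (truth 0.142)
f      = 0.467       (truth 0.4437)
k2     = 0.155 /d   (truth 0.15)
k_a    = 0.065 /d   (= f * k_tot)
S0     = 59.4 mg/L  (truth 60.0)
R^2    = 0.991 (pooled over both series)
half-life = 4.96 d
```

i.e. from one noisy triplicate time course the global fit recovers the
generating rate constants to a few percent; `k_a = f·k_tot` holds exactly
by construction, and the pyrene half-life follows as ln 2 / k_tot. The
other scripts in `examples/` walk through bootstrap intervals and
branching-fraction robustness, molar yields (the 23.0 mg/L DIPA vs
47.3 mg/L degraded pyrene snapshot gives 40.6 %), 2^−ΔΔCt expression, and
the full pipeline report.

A thin CLI mirrors the library: `pahkin simulate | fit | bootstrap |
yield | ddct | run` (see `pahkin --help`).

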