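"""Parametric-bootstrap percentile intervals for the branched-model fit.

Resamples synthetic datasets from the fitted model plus per-series Gaussian
noise, refits each, and reports 5-95% percentile intervals plus robustness
summaries of the branching fraction f.
"""

import pahkin as pk

data = pk.simulate_timecourse(pk.STUDY_PARAMS, pk.DesignSpec(seed=42))
fit = pk.fit_branched_model(data)
boot = pk.parametric_bootstrap(fit, data, n=500, seed=1)
rob = pk.branching_robustness(boot)

print(f"resamples: {boot.n_resamples} ({boot.n_failed} failed refits dropped)")
for name in ("k_tot", "f", "k2", "k_a"):
    lo, hi = boot.intervals[name]
    point = boot.point_estimate[name]
    print(f"{name:6s} = {point:.4f}  [5%, 95%] = [{lo:.4f}, {hi:.4f}]")
print()
print(f"f interval      : [{rob['f_interval'][0]:.3f}, {rob['f_interval'][1]:.3f}]")
print(f"P(f > 0.5)      : {rob['dominance_fraction']:.3f}  (chance the intermediate route dominates)")
print(f"CV of f         : {rob['cv']:.3f}")
print()
print("Narrow intervals that bracket the point estimate indicate the fit is")
print("well constrained by the time-course design and noise level.")
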