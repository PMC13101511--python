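"""Molar-yield accounting: how much degraded pyrene shows up as DIPA.

Mass concentrations are converted to moles (pyrene 202.25 g/mol, DIPA
242.23 g/mol) so parent loss and intermediate accumulation are comparable.
"""

import pahkin as pk

# snapshot accounting: 23.0 mg/L DIPA present when 47.3 mg/L pyrene is gone
y = pk.molar_yield_percent(23.0, pk.DIPHENIC_ACID, 47.3, pk.PYRENE)
print(f"day-7 snapshot molar yield: {y:.1f}%")
print("-> about 40% of the degraded pyrene molecules are present as DIPA.")
print()

# the same accounting over a full (noiseless) model time course
data = pk.simulate_timecourse(
    pk.STUDY_PARAMS,
    pk.DesignSpec(noise_sigma_parent=0, noise_sigma_intermediate=0, lod_parent=0, lod_intermediate=0),
)
table = pk.timecourse_molar_yield(data)
print(table[["time_d", "parent_degraded", "intermediate_formed", "molar_yield_percent"]].to_string(index=False))
print()
print("The yield is capped at 100*f*MW_DIPA/MW_pyrene; undefined at t=0 where")
print("no parent has yet been degraded (NaN row).")
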