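"""Measure a fluorescence light curve on a synthetic community.

Runs the 12-step actinic ladder (0-1200 umol photons m^-2 s^-1) on a
mid-season cyanobacteria-dominated sample with the GOR protocol.  The
first-five-step means characterise the dark-to-dim regime; ETR_max is the
highest per-PSII electron transport rate reached, and P_max the asymptote
of the Webb light-response fit.
"""

from mstaf import (SuccessionScenario, SyntheticSample, default_protocols,
                   run_flc, simulate_succession)

states = simulate_succession(SuccessionScenario(seed=11))
sample = SyntheticSample(state=states[12])  # mid-season date
gor = default_protocols()["GOR"]

res = run_flc(sample, gor, seed=1)
print(f"community: {sample.state.abundance}")
print(f"F_o (mean, first 5 steps)      = {res.F_o_mean5:.2f} a.u.")
print(f"F_v/F_m (mean, first 5 steps)  = {res.FvFm_mean5:.3f}")
print(f"sigma_PII (mean, first 5)      = {res.sigma_mean5:.3f} nm^2")
print(f"alpha_PII (mean, first 5)      = {res.alpha_mean5:.4f}")
print(f"ETR_max = {res.ETR_max:.1f} electrons PSII^-1 s^-1")
print(f"P_max   = {res.P_max:.1f} electrons PSII^-1 s^-1 (Webb asymptote)")
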