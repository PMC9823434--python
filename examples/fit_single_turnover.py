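"""Fit a single-turnover induction curve.

Simulates one noisy ST trace under the green-orange-red (GOR) pulse and
inverts it.  The fitted F_o/F_m bracket the fluorescence rise, sigma_PII is
the PSII absorption cross-section driving the rise rate, and the
saturation status says whether the pulse closed essentially all PSII
(required for a trustworthy F_m).
"""

from mstaf import default_protocols, fit_st_trace, simulate_st_trace

gor = default_protocols()["GOR"]
trace = simulate_st_trace(F_o=100.0, F_m=300.0, sigma_PII=4.0, protocol=gor,
                          noise_sd=2.0, seed=1)
fit = fit_st_trace(trace, gor)

print(f"true parameters: F_o=100, F_m=300, sigma_PII=4.0 nm^2")
print(f"fitted:          F_o={fit.F_o:.2f}, F_m={fit.F_m:.2f}, "
      f"sigma_PII={fit.sigma_PII:.3f} nm^2")
print(f"F_v/F_m = {fit.Fv_over_Fm:.3f}   (max PSII photochemical efficiency)")
print(f"alpha_PII = {fit.alpha_PII:.4f} photons PSII^-1 us^-1 "
      f"-> saturation: {fit.saturation_status}")
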