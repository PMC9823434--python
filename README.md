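# mstaf

Multispectral single-turnover active fluorometry for mixed phytoplankton
communities.

Freshwater reservoirs prone to cyanobacterial blooms are monitored with
active fluorometers that flash a sample with a saturating single-turnover
(ST) pulse and read the chlorophyll fluorescence rise. `mstaf` implements
the full analysis chain for a seven-waveband instrument (LEDs at 416, 452,
473, 495, 534, 594 and 622 nm; emission through 685 and 730 nm bandpass
filters), for scientists who want to fit, simulate and stress-test these
measurements in Python:

* **ST induction fitting** — the rise from F_o (all PSII reaction centres
  open) to F_m (all closed) follows
  `F(t) = F_o + (F_m − F_o)·C(t)(1−ρ)/(1−ρC(t))` with
  `dC/dt = α(1−C)/(1−ρC)`, `α = σ_PII · E_ST` (photon flux units) and
  connectivity ρ; nonlinear least squares recovers F_o, F_m, σ_PII (and
  optionally ρ), with a saturation QC on α and end-of-pulse closure.
* **Fluorescence light curves (FLCs)** — 12 actinic steps from 0 to
  1200 µmol photons m⁻² s⁻¹; per-step electron transport
  `J_PII = σ_PII′ · E · 0.602214`, first-five-step means of F_o, F_v/F_m,
  α_PII, σ_PII, ETR as max J_PII, and P_max from a Webb exponential
  light-response fit.
* **Excitation spectra** — F_v and σ_PII across the seven wavebands under
  algae- or cyanobacteria-optimised dose schedules, with automatic mode
  selection from the blue vs orange F_o response.
* **The 730/685 discriminator** — cyanobacteria keep most chlorophyll *a*
  in photosystem I (emitting near 730 nm, non-variable), so
  F_o(GOR, 730/685) rises with their relative abundance; OLS with a slope
  t-test and adjusted R² quantifies the relationship.
* **Synthetic data** — a two-group seasonal-succession generator (spring
  algal pulse, logistic cyanobacterial rise, lognormal date noise,
  Poisson Sedgewick-Rafter counting error) that produces raw ST traces at
  both emission bands for every excitation protocol.

## Worked example

```python
from mstaf import default_protocols, fit_st_trace, simulate_st_trace

gor = default_protocols()["GOR"]          # 534+594+622 nm, 20,990 µmol
trace = simulate_st_trace(F_o=100.0, F_m=300.0, sigma_PII=4.0,
                          protocol=gor, noise_sd=2.0, seed=1)
fit = fit_st_trace(trace, gor)
print(fit.F_o, fit.F_m, fit.sigma_PII, fit.saturation_status)
```

prints (`examples/fit_single_turnover.py`):

```
fitted:          F_o=100.62, F_m=299.86, sigma_PII=3.983 nm^2
F_v/F_m = 0.664   (max PSII photochemical efficiency)
alpha_PII = 0.0504 photons PSII^-1 us^-1 -> saturation: optimal
```

i.e. at 1% noise the fit recovers the generating parameters to well under
a percent, and α_PII ≈ 0.05 sits inside the optimal saturation band
[0.042, 0.064] — the pulse closed essentially all PSII, so F_m is measured
rather than extrapolated.

The `examples/` directory holds one short script per capability
(induction fitting, light curves, excitation spectra, the emission-ratio
discriminator, the full seasonal pipeline); each prints the numbers it
computes and a line on what they mean. A thin CLI mirrors the library:
`mstaf simulate | fit-st | run-flc | spectra | ratios | regress |
pipeline`.

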