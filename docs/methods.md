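# Methods

## Single-turnover kinetics

A single-turnover (ST) pulse is a 100–200 µs saturating flash intense
enough to close every PSII reaction centre about once. With `C(t)` the
closed-centre fraction, the package models the pulse as

    dC/dt = α (1 − C) / (1 − ρ C),     C(0) = 0
    F(t)  = F_o + (F_m − F_o) · C (1 − ρ) / (1 − ρ C)

where `α = σ_PII · φ(E_ST)` is the photon arrival rate per PSII (µs⁻¹),
`σ_PII` the functional absorption cross-section (nm² PSII⁻¹), `E_ST` the
summed LED intensity of the pulse and `ρ ∈ [0, 1)` the excitonic
connectivity between PSII units. For `ρ = 0` the closed form
`C = 1 − exp(−αt)` is used; for `ρ > 0` the separable ODE gives the
implicit relation `ρC − (1−ρ)ln(1−C) = αt`, inverted by a safeguarded
Newton iteration (the left side is strictly increasing, so the inversion
is globally convergent from the `ρ = 0` start). Assumptions: no reopening
(QA⁻ reoxidation) within the pulse, no baseline drift, no
non-photochemical quenching kinetics inside the 100–200 µs window.

The photon-unit bridge is `φ(E) = E · 6.02214076×10⁻⁷` photons nm⁻² µs⁻¹
per µmol photons m⁻² s⁻¹ (Avogadro constant, m²→nm², s→µs). This is the
only dimensionally consistent way to make `σ_PII` (nm²) times a dose in
µmol photons m⁻² s⁻¹ yield `α_PII` in photons PSII⁻¹ µs⁻¹; instruments
summarise the same relationship with scaled constants, and no equivalence
with any vendor's internal formula is claimed. A useful anchor: under the
GOR pulse (20,990 µmol) the optimal α band [0.042, 0.064] corresponds to
σ_PII ∈ [3.32, 5.06] nm².

## Fitting and quality control

`fit_st_trace` estimates `(F_o, F_v, σ_PII[, ρ])` by bounded nonlinear
least squares (`F_m = F_o + F_v` enforces `F_m ≥ F_o`; box bounds
`F_o, F_v ≥ 0`, `σ ∈ [0, 50]` nm², `ρ ∈ [0, 0.95]`). No lower bound ties
F_m to the observed maximum — that would bias F_m upward under noise.
Initialisation is deterministic and derivative-free: F_o from the first
three samples, F_m from the last three, α from a through-origin fit of
`−log(1 − normalised F)` against time. The trace is normalised to unit
magnitude before optimisation, which makes the fit exactly scale
equivariant. Traces whose apparent F_v is below 0.1% of the trace
magnitude are rejected as flat (no induction rise to invert). ρ is fitted
only on request and defaults to 0; the field protocols analysed here do
not report connectivity.

Saturation QC: a fit is **unsaturated** when `α < 0.02` *or* the expected
end-of-trace closure `1 − exp(−α·t_end)` is below 0.98 (the closure at the
α = 0.02 boundary of a 200 µs pulse, so the two rules coincide on
full-length pulses and the closure rule extends the diagnosis to truncated
records); **optimal** when `α ∈ [0.042, 0.064]`; otherwise **suboptimal**.
Both thresholds are config-overridable (`SaturationThresholds`). The test
suite freezes the empirical behaviour that the flag fires before the
median F_m error at 1% noise reaches 5%.

## Protocols

The registry encodes the five named LED combinations (B = 452+452 at
100 µs; GOR = 534+594+622; GORB; GOB; GO, all at 200 µs) with per-LED
maxima G = 10,500, O = 2,896, R = 7,594 and the two blue LEDs auto-ranging
in 14,108–16,819 / 14,068–16,719 µmol photons m⁻² s⁻¹. Per-LED values are
primary; printed range strings are treated as documentation (their sums
reconcile exactly for GOR, the B upper bound and the GORB upper bound,
which are the values asserted in tests). The 416, 473 and 495 nm channels
have no published maxima and default to the stronger blue LED's maximum,
overridable by constructing a custom LED bank. Blue auto-adjustment is
modelled as a user-set intensity inside the printed window; no feedback
controller is implemented. The actinic source is a scalar intensity per
step; LED spectral bandwidth is not modelled.

## Fluorescence light curves

Twelve actinic steps, 0→1200 µmol photons m⁻² s⁻¹, each treated as at
steady state (acclimation time is not modelled). Per step,
`J_PII = σ_PII′ · E · 0.602214` electrons PSII⁻¹ s⁻¹ (one electron per
photon used for PSII photochemistry). F_o, F_v/F_m, α_PII and σ_PII
decline along the ladder, so each is averaged over the five lowest steps
(including dark, in acquisition order); ETR is the maximum J_PII; P_max
and the initial slope come from a Webb exponential fit
`J(E) = P_max(1 − exp(−α_LC E / P_max))`. P_max is reported on the J_PII
scale (electrons PSII⁻¹ s⁻¹), the only unit in which a light-response
asymptote is well defined here. Data that never saturate drive P_max into
its upper box bound (50× max J); the fit is then flagged and only α_LC is
meaningful.

## Excitation spectra

Each waveband is probed with a single-LED ST pulse. Dose schedules: the
algae-optimised schedule anchors on the 452 nm maximum (≈16.8 mmol) with
weaker LEDs capped at their own maxima; the cyanobacteria-optimised
schedule delivers the 594 nm maximum (2,896 µmol) at every waveband. The
instrument's true scaling law is unpublished; these package defaults aim
for equal photon dose under the anchor constraint and are fully
config-exposed (`DoseSchedule`). Mode selection uses the blue share
`F_o(452)/(F_o(452)+F_o(594)) ≥ 0.5 → algae`, scale-invariant by
construction. Reported F_v and σ_PII are not dose-corrected; the
orange/blue F_v contrast is therefore a function of both pigments and
schedule, which is exactly the instrument's behaviour the package mirrors.

## Emission ratio and statistics

`F_o(730/685)` uses dark-adapted F_o through the 730 and 685 nm filters;
under GOR excitation it increases strictly with the cyanobacterial share
of biomass in the generator (PSI chlorophyll *a* allocation). Regression
is simple OLS in closed form with a two-sided slope t-test and
`adj R² = 1 − (1 − R²)(n − 1)/(n − 2)`; no multiple-testing correction is
applied (per-regression p-values are reported, matching field practice),
p-values below 1e−15 print as "< 1e−15". Abundances enter regressions
untransformed.

## Synthetic generator

The generator emulates a temperate-reservoir season: 23 sampling dates,
algae dominant on the first date (spring diatom pulse, Gaussian bump at
the season start plus a smaller autumn rise), cyanobacteria rising
logistically to summer dominance, multiplicative lognormal date-to-date
noise (sd 0.3 on the log scale — enough volatility to look like real
count series without claiming fidelity). Microscopy counts are Poisson
over the counted volume (100 × 1 µL units; estimates are counts × 10),
unbiased with variance 10 × density.

Group optics are synthetic package constants; the physics fixes only signs
and orderings (algal σ spectrum peaks at 416–452 nm, cyanobacterial at
594–622 nm; cyanobacterial 730 nm allocation 0.45 ≫ algal 0.12). The
absolute values are chosen once so that at the default LED intensities a
cyanobacteria-dominated community gives α_PII(GO) ≈ 0.016 (< 0.02, an
unsaturated green-orange pulse) and α_PII(GOR) ≈ 0.03, while an
algae-dominated community puts α_PII(B) in the optimal band — the
saturation regime structure the analysis is designed to diagnose.
Community F_o/F_m mix linearly in abundance (so B + GOR = GORB holds
exactly); a mixture's two-exponential induction curve is collapsed to a
single effective cross-section (the F_v-weighted mean of group
excitation-weighted σ) before trace synthesis, keeping simulated traces
exactly identifiable by the three-parameter fit. Light adaptation uses a
single quenching factor `q(E) = E50/(E50 + E)` (default E50 = 300 µmol)
applied to σ′ and F_v′. Trace noise is additive Gaussian with sd a
fraction (default 1%) of the sample's F_v.

What passing tests therefore show: the estimators and QC logic are correct
on data satisfying the model assumptions, with realistic dynamic ranges
and noise. What they do not show: robustness to baseline drift,
within-pulse quenching, state transitions, pigment packaging, multi-group
taxonomic structure, or real instrument gain behaviour — none of which the
generator produces.

Randomness: one seed per scenario; substreams are derived via seed
sequences keyed on (date, protocol id, emission band), so adding a
protocol to a run never perturbs existing draws.

## Problem sizes and numerics

Default traces carry ~1 sample per µs (100 or 200 points). The recovery
experiments use 100 traces at 1% noise with physiological draws
(F_v/F_m ∈ [0.25, 0.6], σ ∈ [2.5, 5.5] nm²); statistical calibration uses
1,000 null regressions at n = 23 and 200 seasonal realisations — sizes at
which every check is stable and the whole suite runs in seconds.
Optimiser tolerances are 1e−14 (xtol/ftol); the ρ-inversion Newton stops
at 1e−14; closed-form vs ODE agreement is verified to 1e−8 relative.

## Known limitations

* Connectivity fitting is available but lightly exercised; ρ and σ are
  partially confounded on short, noisy pulses.
* The Webb form is the only light-response model; no photoinhibition
  term, so declining high-light tails pull P_max down rather than being
  modelled.
* Excitation spectra report raw (not dose-normalised) F_v, so
  cross-mode comparisons must divide by dose (the tests do exactly this).
* The 416/473/495 nm LED maxima are assumptions, not instrument values.
* Absolute abundance amplitudes in the succession scenario are free
  parameters; only the qualitative succession shape is constrained.
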