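"""Seven-waveband PSII excitation spectra of F_v and sigma_PII.

The instrument probes each excitation waveband with a single-LED ST pulse
and reports F_v(lambda_ex, 685) and sigma_PII(lambda_ex, 685).  The light
dose per waveband follows one of two schedules: an algae-optimised schedule
anchored on the blue (452 nm) response and a cyanobacteria-optimised
schedule anchored on the orange (594 nm) response.  The schedule is chosen
from the relative F_o response at 452 vs 594 nm — blue-dominated samples
(chlorophyll *b*/*c* present) get the algae schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .protocols import WAVEBANDS, default_led_channels, single_led_protocol
from .st_induction import FlatTraceError, fit_st_trace, simulate_st_trace

__all__ = [
    "ALGAE_MODE",
    "CYANO_MODE",
    "DoseSchedule",
    "ExcitationSpectrum",
    "default_dose_schedule",
    "select_mode",
    "select_mode_for_sample",
    "measure_spectrum",
    "spectrum_contrast",
]

ALGAE_MODE = "algae_optimised"
CYANO_MODE = "cyanobacteria_optimised"

#: reference waveband anchoring each schedule's dose
_REFERENCE_WAVEBAND = {ALGAE_MODE: 452, CYANO_MODE: 594}


@dataclass(frozen=True)
class DoseSchedule:
    """Per-waveband ST-pulse doses (umol photons m^-2 s^-1) for one mode."""

    mode: str
    doses: dict[int, float]

    def __post_init__(self) -> None:
        if set(self.doses) != set(WAVEBANDS):
            raise ValueError("schedule must cover all 7 wavebands")
        maxima = _led_maxima()
        for wl, dose in self.doses.items():
            if not 0 < dose <= maxima[wl] + 1e-9:
                raise ValueError(
                    f"dose at {wl} nm outside (0, {maxima[wl]}]")
        ref = _REFERENCE_WAVEBAND[self.mode]
        if any(self.doses[ref] < d - 1e-9 for d in self.doses.values()):
            raise ValueError(
                f"reference waveband {ref} nm must carry the maximal dose")


def _led_maxima() -> dict[int, float]:
    maxima: dict[int, float] = {}
    for ch in default_led_channels():
        maxima[ch.center_wavelength] = max(
            maxima.get(ch.center_wavelength, 0.0), ch.max_intensity)
    return maxima


def default_dose_schedule(mode: str) -> DoseSchedule:
    """The package-default dose schedule for a mode.

    The instrument's exact scaling law is unpublished; the default aims for
    equal photon dose across wavebands, anchored at the mode's reference
    waveband and capped at each LED's maximum: the algae schedule targets
    the full 452 nm dose (weaker LEDs are capped below it), while the
    cyanobacteria schedule targets the 594 nm LED maximum, attainable at
    every waveband.
    """
    maxima = _led_maxima()
    ref = _REFERENCE_WAVEBAND.get(mode)
    if ref is None:
        raise ValueError(f"unknown mode {mode!r}")
    target = maxima[ref]
    return DoseSchedule(mode=mode, doses={
        wl: min(target, maxima[wl]) for wl in WAVEBANDS})


def select_mode(F_o_452_685: float, F_o_594_685: float,
                threshold_ratio: float = 0.5) -> str:
    """Choose the optimisation mode from the blue vs orange F_o response.

    The blue share F_o(452) / (F_o(452) + F_o(594)) proxies the presence of
    chlorophylls *b* and *c*; at or above ``threshold_ratio`` the algae
    schedule is used. Scale-invariant by construction.
    """
    if F_o_452_685 < 0 or F_o_594_685 < 0:
        raise ValueError("F_o responses must be >= 0")
    total = F_o_452_685 + F_o_594_685
    if total == 0:
        raise ValueError("no F_o signal at 452 or 594 nm")
    return ALGAE_MODE if F_o_452_685 / total >= threshold_ratio else CYANO_MODE


def select_mode_for_sample(sample, probe_dose: float = 2896.0,
                           threshold_ratio: float = 0.5) -> str:
    """Probe a sample's F_o at 452 and 594 nm (equal dose) and select."""
    responses = {}
    for wl in (452, 594):
        proto = single_led_protocol(wl, probe_dose)
        fo, _, _ = sample.st_params(proto, 685, 0.0)
        responses[wl] = fo
    return select_mode(responses[452], responses[594], threshold_ratio)


@dataclass
class ExcitationSpectrum:
    """F_v and sigma_PII per waveband under one dose schedule.

    Failed per-waveband fits are NaN; ``ok`` is False when no waveband
    yielded a fit (e.g. a blank sample).
    """

    wavebands: tuple[int, ...]
    F_v: np.ndarray
    sigma_PII: np.ndarray
    mode: str
    dose: np.ndarray
    ok: bool = True

    def value_at(self, waveband: int, which: str = "F_v") -> float:
        i = self.wavebands.index(waveband)
        return float(getattr(self, which)[i])


def measure_spectrum(sample, mode: str,
                     seed: int | np.random.Generator | None = None,
                     schedule: DoseSchedule | None = None,
                     pulse_length_us: float = 200.0) -> ExcitationSpectrum:
    """Run single-waveband ST fits across the 7 wavebands of a schedule."""
    schedule = schedule or default_dose_schedule(mode)
    if schedule.mode != mode:
        raise ValueError("schedule mode does not match requested mode")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    fv = np.full(len(WAVEBANDS), np.nan)
    sig = np.full(len(WAVEBANDS), np.nan)
    dose = np.array([schedule.doses[wl] for wl in WAVEBANDS])
    n_ok = 0
    for i, wl in enumerate(WAVEBANDS):
        proto = single_led_protocol(wl, schedule.doses[wl],
                                    pulse_length_us=pulse_length_us)
        fo, fm, sigma = sample.st_params(proto, 685, 0.0)
        trace = simulate_st_trace(fo, fm, sigma, proto,
                                  noise_sd=sample.noise_for(fm - fo),
                                  seed=rng)
        try:
            fit = fit_st_trace(trace, proto)
        except FlatTraceError:
            continue
        fv[i] = fit.F_m - fit.F_o
        sig[i] = fit.sigma_PII
        n_ok += 1
    return ExcitationSpectrum(wavebands=tuple(WAVEBANDS), F_v=fv,
                              sigma_PII=sig, mode=mode, dose=dose,
                              ok=n_ok > 0)


def spectrum_contrast(spec: ExcitationSpectrum,
                      blue: tuple[int, ...] = (416, 452),
                      orange: tuple[int, ...] = (594, 622)) -> float:
    """Orange-to-blue F_v balance; > 1 flags phycobilipigment dominance."""
    fv = {wl: spec.value_at(wl) for wl in spec.wavebands}
    blue_vals = [fv[wl] for wl in blue if np.isfinite(fv[wl])]
    orange_vals = [fv[wl] for wl in orange if np.isfinite(fv[wl])]
    if not blue_vals or not orange_vals:
        raise ValueError("need valid blue and orange-red entries")
    denom = float(np.mean(blue_vals))
    if denom == 0:
        raise ValueError("zero blue F_v; contrast undefined")
    return float(np.mean(orange_vals)) / denom
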