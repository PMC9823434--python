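"""Fluorescence light curves (FLCs) and aggregate photophysiology.

An FLC repeats the ST measurement across 12 actinic background irradiances
(0 to 1200 umol photons m^-2 s^-1).  Each step yields light-adapted
(primed) parameters; the per-PSII electron transport rate at a step is

    J_PII = sigma_PII' * E_actinic * 0.602214   (electrons PSII^-1 s^-1)

on the assumption that each photon driving PSII photochemistry transfers
one electron.  F_o, F_v/F_m, alpha_PII and sigma_PII decline along the
light steps, so each is averaged over the first five steps; ETR is the
maximum J_PII across steps, and P_max is the asymptote of an exponential
saturating light-response (Webb) curve fitted to J_PII(E).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .protocols import PHOTONS_NM2_S_PER_UMOL, ExcitationProtocol
from .st_induction import (
    FlatTraceError,
    STFitResult,
    fit_st_trace,
    fvfm,
    simulate_st_trace,
)

__all__ = [
    "FLCStep",
    "PICurveFit",
    "FLCResult",
    "default_actinic_grid",
    "compute_JPII",
    "fit_pi_curve",
    "aggregate_flc",
    "run_flc",
]


def default_actinic_grid(n_steps: int = 12, e_max: float = 1200.0
                         ) -> np.ndarray:
    """The standard 12-step actinic ladder from 0 to 1200."""
    return np.linspace(0.0, e_max, n_steps)


def compute_JPII(sigma_prime: float, actinic_E: float) -> float:
    """Electron transport rate per PSII at one actinic step.

    sigma_prime in nm^2 PSII^-1, actinic_E in umol photons m^-2 s^-1;
    the product with the actinic photon flux (photons nm^-2 s^-1) counts
    photons delivered through the cross-section per second.
    """
    if sigma_prime < 0 or actinic_E < 0:
        raise ValueError("inputs must be >= 0")
    return sigma_prime * actinic_E * PHOTONS_NM2_S_PER_UMOL


@dataclass
class FLCStep:
    """One actinic step of an FLC: the primed ST fit plus J_PII."""

    actinic_E: float
    st_fit: STFitResult
    J_PII: float

    def __post_init__(self) -> None:
        if self.actinic_E < 0 or self.J_PII < 0:
            raise ValueError("actinic_E and J_PII must be >= 0")


@dataclass
class PICurveFit:
    """Webb exponential light-response fit J(E) = P_max (1 - exp(-a E / P_max))."""

    model_name: str = "webb_exponential"
    P_max: float = float("nan")
    alpha_LC: float = float("nan")
    rmse: float = float("nan")
    converged: bool = True
    at_upper_bound: bool = False
    message: str = ""


@dataclass
class FLCResult:
    """An assembled FLC with the aggregate parameters reported per curve."""

    steps: list[FLCStep]
    F_o_mean5: float = float("nan")
    FvFm_mean5: float = float("nan")
    alpha_mean5: float = float("nan")
    sigma_mean5: float = float("nan")
    ETR_max: float = float("nan")
    pi_fit: PICurveFit = field(default_factory=PICurveFit)
    protocol: str = ""
    n_failed: int = 0
    failures: list[str] = field(default_factory=list)
    ok: bool = True

    @property
    def P_max(self) -> float:
        return self.pi_fit.P_max

    @property
    def alpha_LC(self) -> float:
        return self.pi_fit.alpha_LC

    def steps_json(self) -> str:
        """Per-step detail as a compact JSON string (for result tables)."""
        return json.dumps([
            {"E": s.actinic_E, "F_o": s.st_fit.F_o, "F_m": s.st_fit.F_m,
             "sigma": s.st_fit.sigma_PII, "alpha": s.st_fit.alpha_PII,
             "J_PII": s.J_PII, "status": s.st_fit.saturation_status}
            for s in self.steps
        ])


def _webb(E: np.ndarray, p_max: float, alpha_lc: float) -> np.ndarray:
    return p_max * -np.expm1(-alpha_lc * E / p_max)


def fit_pi_curve(E, J, pmax_upper_factor: float = 50.0) -> PICurveFit:
    """Least-squares Webb fit of J_PII against actinic irradiance.

    For data that never saturate (J linear in E) P_max runs into its upper
    box bound ``pmax_upper_factor * max(J)``; the result is then flagged
    ``at_upper_bound`` and only alpha_LC (the initial slope) is meaningful.
    """
    E = np.asarray(E, dtype=float)
    J = np.asarray(J, dtype=float)
    if E.shape != J.shape:
        raise ValueError("E and J lengths differ")
    if np.unique(E).size < 4 or 0.0 not in E:
        raise ValueError("need >= 4 distinct actinic levels including 0")
    jmax = float(np.max(J))
    if jmax <= 0:
        raise ValueError("all-zero light response; nothing to fit")
    nz = (E > 0) & (J > 0)
    slope0 = float(np.median(J[nz] / E[nz])) if np.any(nz) else 1.0
    ub_p = pmax_upper_factor * jmax
    p0 = (min(1.05 * jmax, 0.9 * ub_p), slope0)
    try:
        popt, _ = curve_fit(
            _webb, E, J, p0=p0,
            bounds=((1e-12, 1e-12), (ub_p, np.inf)),
            xtol=1e-14, ftol=1e-14, maxfev=20000,
        )
    except RuntimeError as exc:
        return PICurveFit(converged=False, message=str(exc))
    p_max, alpha_lc = float(popt[0]), float(popt[1])
    rmse = float(np.sqrt(np.mean(np.square(_webb(E, *popt) - J))))
    return PICurveFit(P_max=p_max, alpha_LC=alpha_lc, rmse=rmse,
                      at_upper_bound=p_max > 0.98 * ub_p)


def aggregate_flc(steps: list[FLCStep], protocol: str = "") -> FLCResult:
    """Reduce per-step fits to the per-FLC summary statistics.

    Means of F_o, F_v/F_m, alpha_PII and sigma_PII are taken over the five
    lowest actinic steps (in acquisition order, including the dark step);
    ETR is the maximum J_PII; P_max comes from the Webb fit across all
    steps.
    """
    if len(steps) < 5:
        raise ValueError("need at least 5 FLC steps to aggregate")
    ee = [s.actinic_E for s in steps]
    if ee != sorted(ee):
        raise ValueError("steps must be sorted by actinic_E")
    first5 = steps[:5]
    result = FLCResult(
        steps=list(steps),
        F_o_mean5=float(np.mean([s.st_fit.F_o for s in first5])),
        FvFm_mean5=float(np.mean([fvfm(s.st_fit) for s in first5])),
        alpha_mean5=float(np.mean([s.st_fit.alpha_PII for s in first5])),
        sigma_mean5=float(np.mean([s.st_fit.sigma_PII for s in first5])),
        ETR_max=float(max(s.J_PII for s in steps)),
        protocol=protocol,
    )
    try:
        result.pi_fit = fit_pi_curve([s.actinic_E for s in steps],
                                     [s.J_PII for s in steps])
    except ValueError as exc:
        result.pi_fit = PICurveFit(converged=False, message=str(exc))
    return result


def run_flc(sample, protocol: ExcitationProtocol,
            actinic_grid=None,
            seed: int | np.random.Generator | None = None,
            emission_band: int = 685) -> FLCResult:
    """Measure a full FLC on a (synthetic) sample.

    ``sample`` must provide ``st_params(protocol, emission_band, actinic_E)
    -> (F_o, F_m, sigma_prime)`` and a ``noise_for(F_v)`` absolute noise
    level; the synthetic-community sample in :mod:`mstaf.synthetic_data`
    does.  A step whose trace cannot be fitted (e.g. no biomass) is recorded
    as a failure, not fatal; a curve with no successful step is returned
    flagged ``ok=False`` with NaN aggregates.
    """
    grid = default_actinic_grid() if actinic_grid is None \
        else np.asarray(actinic_grid, dtype=float)
    if np.any(np.diff(grid) < 0):
        raise ValueError("actinic grid must be non-decreasing")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    steps: list[FLCStep] = []
    failures: list[str] = []
    for E in grid:
        fo, fm, sigma_p = sample.st_params(protocol, emission_band, float(E))
        noise = sample.noise_for(fm - fo)
        trace = simulate_st_trace(fo, fm, sigma_p, protocol,
                                  noise_sd=noise, seed=rng,
                                  emission_band=emission_band,
                                  actinic_E=float(E))
        try:
            fit = fit_st_trace(trace, protocol)
        except FlatTraceError as exc:
            failures.append(f"E={E:g}: {exc}")
            continue
        steps.append(FLCStep(actinic_E=float(E), st_fit=fit,
                             J_PII=compute_JPII(fit.sigma_PII, float(E))))
    if len(steps) < 5:
        return FLCResult(steps=steps, protocol=protocol.name,
                         n_failed=len(failures), failures=failures, ok=False)
    result = aggregate_flc(steps, protocol=protocol.name)
    result.n_failed = len(failures)
    result.failures = failures
    return result
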