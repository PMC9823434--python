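"""Synthetic mixed-community scenarios for the analysis pipeline.

Generates the statistical structure the field analysis assumes, for a
two-group (eukaryotic algae / prokaryotic cyanobacteria) freshwater
community:

* group optical models — a seven-waveband sigma_PII spectrum, a maximum
  F_v/F_m, a PSI-chlorophyll emission allocation at 730 nm, and a per-cell
  F_o yield;
* a seasonal succession over ~23 sampling dates (spring algal pulse,
  logistic cyanobacterial rise, multiplicative lognormal noise);
* community-level ST trace parameters per excitation protocol and emission
  band under linear biomass mixing;
* Sedgewick-Rafter microscopy counts with Poisson counting noise.

All optical constants are synthetic package defaults: the physics fixes
their sign and ordering (phycobilipigment absorption peaks in the
green-orange for cyanobacteria, blue for algae; cyanobacteria allocate most
chlorophyll *a* to PSI, which emits near 730 nm and has no variable
fluorescence), not their values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .protocols import (
    PROTOCOL_IDS,
    WAVEBANDS,
    ExcitationProtocol,
    combined_intensity,
)

__all__ = [
    "GroupOpticalModel",
    "CommunityState",
    "SuccessionScenario",
    "SyntheticSample",
    "default_group_models",
    "community_fluorescence",
    "community_st_params",
    "simulate_succession",
    "simulate_microscopy",
    "counting_scale_factor",
]


@dataclass(frozen=True)
class GroupOpticalModel:
    """Optical parameters of one phytoplankton group.

    sigma_spectrum maps each excitation waveband (nm) to the group's
    functional PSII absorption cross-section (nm^2 PSII^-1) at that
    waveband.  psi_fraction_730 is the fraction of the group's dark-level
    emission routed to the 730 nm band (PSI chlorophyll *a* allocation);
    fo_per_cell scales cells mL^-1 into arbitrary fluorescence units.
    """

    name: str
    sigma_spectrum: dict[int, float]
    FvFm_max: float
    psi_fraction_730: float
    fo_per_cell: float

    def __post_init__(self) -> None:
        if set(self.sigma_spectrum) != set(WAVEBANDS):
            raise ValueError("sigma_spectrum must cover all 7 wavebands")
        if any(v < 0 for v in self.sigma_spectrum.values()):
            raise ValueError("sigma values must be >= 0")
        if not 0 <= self.FvFm_max < 1:
            raise ValueError("FvFm_max must be in [0, 1)")
        if not 0 <= self.psi_fraction_730 <= 1:
            raise ValueError("psi_fraction_730 must be in [0, 1]")
        if self.fo_per_cell < 0:
            raise ValueError("fo_per_cell must be >= 0")

    def emission_partition(self, band: int) -> float:
        if band == 730:
            return self.psi_fraction_730
        if band == 685:
            return 1.0 - self.psi_fraction_730
        raise ValueError("emission band must be 685 or 730")


def default_group_models() -> dict[str, GroupOpticalModel]:
    """Package-default optical models for the two groups.

    The algal spectrum peaks in the blue (chlorophylls/carotenoids) and is
    weak in the green-orange; the cyanobacterial spectrum is the mirror
    image (phycobilipigments), and its 730 nm allocation is much larger
    because most of its chlorophyll *a* sits in PSI.  Values are synthetic
    constants chosen so that, at the default LED intensities, a
    cyanobacteria-dominated community gives alpha_PII(GO) just below 0.02
    (an unsaturated green-orange pulse) and alpha_PII(GOR) near 0.03, while
    an algae-dominated community lands blue-protocol alpha_PII inside the
    optimal band.
    """
    algae = GroupOpticalModel(
        name="algae",
        sigma_spectrum={416: 2.0, 452: 2.2, 473: 1.9, 495: 1.4,
                        534: 0.6, 594: 0.3, 622: 0.5},
        FvFm_max=0.55,
        psi_fraction_730=0.12,
        fo_per_cell=4.0e-7,
    )
    cyano = GroupOpticalModel(
        name="cyanobacteria",
        sigma_spectrum={416: 0.7, 452: 0.9, 473: 0.8, 495: 1.0,
                        534: 1.8, 594: 2.7, 622: 3.5},
        FvFm_max=0.45,
        psi_fraction_730=0.45,
        fo_per_cell=2.5e-7,
    )
    return {"algae": algae, "cyanobacteria": cyano}


@dataclass
class CommunityState:
    """Abundances (cells mL^-1) per group on one sampling date."""

    date_index: int
    abundance: dict[str, float]
    temperature: float | None = None

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.abundance.values()):
            raise ValueError("abundances must be >= 0")

    @property
    def total(self) -> float:
        return float(sum(self.abundance.values()))


def _group_excitation_sum(model: GroupOpticalModel,
                          protocol: ExcitationProtocol) -> float:
    """Sum over protocol LEDs of intensity times group sigma at that waveband."""
    return float(sum(
        led.intensity * model.sigma_spectrum[led.channel.center_wavelength]
        for led in protocol.leds
    ))


def community_fluorescence(state: CommunityState,
                           models: dict[str, GroupOpticalModel],
                           protocol: ExcitationProtocol,
                           emission_band: int = 685
                           ) -> tuple[float, float]:
    """Dark-adapted (F_o, F_m) of a mixed community, linear in abundances.

    Each group contributes F_o proportional to abundance x per-cell yield x
    excitation-weighted cross-section x emission partition; its F_m scales
    the contribution by 1/(1 - FvFm_max).
    """
    fo = fm = 0.0
    for name, n in state.abundance.items():
        model = models[name]
        contrib = (n * model.fo_per_cell
                   * _group_excitation_sum(model, protocol)
                   * model.emission_partition(emission_band))
        fo += contrib
        fm += contrib / (1.0 - model.FvFm_max)
    return fo, fm


def community_st_params(state: CommunityState,
                        models: dict[str, GroupOpticalModel],
                        protocol: ExcitationProtocol,
                        emission_band: int = 685
                        ) -> tuple[float, float, float]:
    """Effective (F_o, F_m, sigma_PII) of the mixture for one protocol.

    A mixture's induction curve is a sum of per-group exponentials; the
    generator collapses it to a single effective cross-section — the
    F_v-weighted mean of the groups' excitation-weighted sigma — so that
    simulated traces remain exactly identifiable by the three-parameter
    fit.
    """
    E = combined_intensity(protocol)
    fo, fm = community_fluorescence(state, models, protocol, emission_band)
    wsum = sig = 0.0
    for name, n in state.abundance.items():
        model = models[name]
        s = _group_excitation_sum(model, protocol)
        contrib = (n * model.fo_per_cell * s
                   * model.emission_partition(emission_band))
        fv_g = contrib * model.FvFm_max / (1.0 - model.FvFm_max)
        wsum += fv_g
        sig += fv_g * (s / E)
    sigma_eff = sig / wsum if wsum > 0 else 0.0
    return fo, fm, sigma_eff


@dataclass
class SuccessionScenario:
    """Parameters of the simulated seasonal succession.

    Trajectories (cells mL^-1) on a normalised season axis t in [0, 1]:

    * algae: baseline + spring Gaussian pulse near the first dates + a
      smaller late-season rise;
    * cyanobacteria: logistic rise from a small spring population to summer
      dominance.

    Date-to-date variability is multiplicative lognormal noise with
    ``noise_sd_log`` on the natural-log scale.
    """

    n_dates: int = 23
    seed: int = 0
    algae_amplitude: float = 6000.0
    algae_baseline_frac: float = 0.3
    algae_spring_center: float = 0.03
    algae_spring_width: float = 0.18
    algae_autumn_frac: float = 0.35
    algae_autumn_center: float = 0.95
    algae_autumn_width: float = 0.15
    cyano_amplitude: float = 20000.0
    cyano_rise_rate: float = 8.0
    cyano_rise_midpoint: float = 0.25
    noise_sd_log: float = 0.3
    with_temperature: bool = True

    def __post_init__(self) -> None:
        if self.n_dates < 3:
            raise ValueError("need at least 3 sampling dates")


def _mean_trajectories(scenario: SuccessionScenario
                       ) -> tuple[np.ndarray, np.ndarray]:
    t = np.linspace(0.0, 1.0, scenario.n_dates)
    s = scenario
    algae = s.algae_amplitude * (
        s.algae_baseline_frac
        + np.exp(-((t - s.algae_spring_center) / s.algae_spring_width) ** 2)
        + s.algae_autumn_frac
        * np.exp(-((t - s.algae_autumn_center) / s.algae_autumn_width) ** 2)
    )
    cyano = s.cyano_amplitude / (
        1.0 + np.exp(-s.cyano_rise_rate * (t - s.cyano_rise_midpoint))
    )
    return algae, cyano


def simulate_succession(scenario: SuccessionScenario
                        ) -> list[CommunityState]:
    """Draw one noisy realisation of the seasonal succession."""
    algae, cyano = _mean_trajectories(scenario)
    t = np.linspace(0.0, 1.0, scenario.n_dates)
    rng = np.random.default_rng(np.random.SeedSequence([int(scenario.seed), 101]))
    states = []
    for i in range(scenario.n_dates):
        if scenario.noise_sd_log > 0:
            fa, fc = np.exp(rng.normal(0.0, scenario.noise_sd_log, size=2))
        else:
            fa = fc = 1.0
        temp = None
        if scenario.with_temperature:
            temp = float(10.0 + 8.0 * math.sin(math.pi * t[i]))
        states.append(CommunityState(
            date_index=i,
            abundance={"algae": float(algae[i] * fa),
                       "cyanobacteria": float(cyano[i] * fc)},
            temperature=temp,
        ))
    return states


def counting_scale_factor(n_units: int = 100, unit_volume_ul: float = 1.0
                          ) -> float:
    """Counts-to-density factor: reciprocal of the counted volume in mL.

    100 units of 1 uL give 0.1 mL counted, hence the x10 rule for
    Sedgewick-Rafter counts.
    """
    if n_units <= 0 or unit_volume_ul <= 0:
        raise ValueError("counting geometry must be positive")
    return 1000.0 / (n_units * unit_volume_ul)


def simulate_microscopy(true_density: float, n_units: int = 100,
                        unit_volume_ul: float = 1.0,
                        seed: int | np.random.Generator | None = None
                        ) -> float:
    """Poisson-noised microscopy abundance estimate (cells mL^-1).

    The total count over the randomly selected grid units is Poisson with
    mean density x counted volume; the estimate rescales by the reciprocal
    counted volume (x10 at the 100 x 1 uL default).
    """
    if true_density < 0:
        raise ValueError("true_density must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    counted_ml = n_units * unit_volume_ul / 1000.0
    count = rng.poisson(true_density * counted_ml)
    return float(count) * counting_scale_factor(n_units, unit_volume_ul)


@dataclass
class SyntheticSample:
    """A measurable water sample: community state + optics + noise model.

    ``quench_E50`` (umol photons m^-2 s^-1) sets the light-adapted decline
    of sigma' and F_v with actinic irradiance E through the quenching
    factor q(E) = E50 / (E50 + E) — a simple proxy that produces the
    saturating J(E) shape a Webb fit assumes.  ``noise_frac`` is the trace
    noise standard deviation as a fraction of the sample's F_v, so a
    zero-biomass sample yields exactly flat traces.
    """

    state: CommunityState
    models: dict[str, GroupOpticalModel] = field(
        default_factory=default_group_models)
    quench_E50: float = 300.0
    noise_frac: float = 0.01

    def st_params(self, protocol: ExcitationProtocol, emission_band: int,
                  actinic_E: float = 0.0) -> tuple[float, float, float]:
        fo, fm, sigma = community_st_params(
            self.state, self.models, protocol, emission_band)
        q = self.quench_E50 / (self.quench_E50 + actinic_E)
        return fo, fo + (fm - fo) * q, sigma * q

    def noise_for(self, f_v: float) -> float:
        return self.noise_frac * max(f_v, 0.0)

    def rng_for(self, protocol: ExcitationProtocol, emission_band: int,
                seed: int) -> np.random.Generator:
        """Deterministic substream per (date, protocol, band): adding a
        protocol to a run never perturbs existing draws."""
        pid = PROTOCOL_IDS.get(protocol.name,
                               100 + protocol.wavebands[0])
        return np.random.default_rng(np.random.SeedSequence(
            [int(seed), int(self.state.date_index), pid, int(emission_band)]))
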