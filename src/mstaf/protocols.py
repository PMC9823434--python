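"""Excitation protocols and photon-unit conversions.

A single-turnover active fluorometer (STAF) delivers a saturating flash from
a bank of LEDs centred on seven wavebands (416, 452, 473, 495, 534, 594,
622 nm).  Wavebands are combined into named protocols that target pigment
groups: blue light excites chlorophylls *a*/*b*/*c* and carotenoids (algae),
green-orange light excites phycobilipigments (cyanobacteria).  The photon
irradiance of the ST pulse, E_ST, is the arithmetic sum of the set LED
intensities.

The conversions here tie together the three rate quantities used throughout
the package:

* ``sigma_PII`` — functional absorption cross-section of PSII photochemistry
  (nm^2 per PSII);
* ``alpha_PII`` — initial photon-use rate per PSII during the pulse
  (photons PSII^-1 us^-1), equal to sigma_PII times the pulse photon flux;
* the closed-centre fraction at the end of the pulse, which drives the
  saturation QC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "WAVEBANDS",
    "PHOTONS_NM2_US_PER_UMOL",
    "PHOTONS_NM2_S_PER_UMOL",
    "LEDChannel",
    "ProtocolLED",
    "ExcitationProtocol",
    "ProtocolConfigError",
    "SaturationThresholds",
    "default_led_channels",
    "default_protocols",
    "single_led_protocol",
    "combined_intensity",
    "umol_to_photon_flux",
    "alpha_from_sigma",
    "sigma_from_alpha",
    "expected_closure",
    "classify_saturation",
]

#: Instrument excitation waveband centres (nm).
WAVEBANDS = (416, 452, 473, 495, 534, 594, 622)

#: photons nm^-2 us^-1 delivered by 1 umol photons m^-2 s^-1:
#: N_A * 1e-6 (umol->photons) / 1e18 (m^2->nm^2) / 1e6 (s->us).
PHOTONS_NM2_US_PER_UMOL = 6.02214076e-7

#: photons nm^-2 s^-1 per umol photons m^-2 s^-1 (same bridge on the second).
PHOTONS_NM2_S_PER_UMOL = 0.602214076


class ProtocolConfigError(ValueError):
    """Raised when a protocol definition is inconsistent."""


@dataclass(frozen=True)
class LEDChannel:
    """One excitation LED: waveband centre, maximum intensity, adjustability.

    Only the two blue (452 nm) LEDs adapt their intensity to the sample; all
    other channels run at a fixed maximum.
    """

    center_wavelength: int
    max_intensity: float  # umol photons m^-2 s^-1
    adjustable: bool = False
    label: str = ""
    #: admissible set-intensity window for adjustable LEDs (min, max)
    intensity_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.center_wavelength not in WAVEBANDS:
            raise ProtocolConfigError(
                f"unknown waveband {self.center_wavelength} nm; "
                f"instrument wavebands are {WAVEBANDS}"
            )
        if not self.max_intensity > 0:
            raise ProtocolConfigError("max_intensity must be > 0")


@dataclass(frozen=True)
class ProtocolLED:
    """An LED channel with its set intensity inside a protocol."""

    channel: LEDChannel
    intensity: float  # umol photons m^-2 s^-1

    def __post_init__(self) -> None:
        if not 0 < self.intensity <= self.channel.max_intensity + 1e-9:
            raise ProtocolConfigError(
                f"set intensity {self.intensity} outside (0, "
                f"{self.channel.max_intensity}] for LED "
                f"{self.channel.label or self.channel.center_wavelength}"
            )


# Table-of-record LED bank. G, O, R maxima are the fixed instrument values;
# the two blue LEDs auto-adjust within their printed windows. The 416, 473
# and 495 nm channels have no published maxima and default to the stronger
# blue LED's maximum (config-overridable by constructing your own bank).
_DEFAULT_BANK = (
    LEDChannel(416, 16819.0, label="V"),
    LEDChannel(452, 16819.0, adjustable=True, label="B1",
               intensity_range=(14108.0, 16819.0)),
    LEDChannel(452, 16719.0, adjustable=True, label="B2",
               intensity_range=(14068.0, 16719.0)),
    LEDChannel(473, 16819.0, label="C473"),
    LEDChannel(495, 16819.0, label="C495"),
    LEDChannel(534, 10500.0, label="G"),
    LEDChannel(594, 2896.0, label="O"),
    LEDChannel(622, 7594.0, label="R"),
)

#: protocol name -> (waveband composition, pulse length us, emission bands)
_TABLE1 = {
    "B": ((452, 452), 100.0, (685, 730)),
    "GOR": ((534, 594, 622), 200.0, (685, 730)),
    "GORB": ((452, 452, 534, 594, 622), 200.0, (685,)),
    "GOB": ((452, 452, 534, 594), 200.0, (685,)),
    "GO": ((534, 594), 200.0, (685,)),
}

#: stable small integers used to derive per-protocol random substreams
PROTOCOL_IDS = {"B": 1, "GOR": 2, "GORB": 3, "GOB": 4, "GO": 5}


@dataclass(frozen=True)
class ExcitationProtocol:
    """A named combination of LEDs fired for one ST pulse.

    ``emission_bands`` lists the detection bandpass filters (nm) the
    protocol is recorded through; the dual-waveband protocols (B, GOR)
    record at both 685 and 730 nm.
    """

    name: str
    leds: tuple[ProtocolLED, ...]
    pulse_length_us: float
    emission_bands: tuple[int, ...] = (685,)

    def __post_init__(self) -> None:
        if self.pulse_length_us <= 0:
            raise ProtocolConfigError("pulse_length_us must be > 0")
        if not set(self.emission_bands) <= {685, 730}:
            raise ProtocolConfigError("emission bands limited to 685/730 nm")
        if self.name in _TABLE1:
            wavebands, pulse, _ = _TABLE1[self.name]
            if tuple(sorted(l.channel.center_wavelength for l in self.leds)) \
                    != tuple(sorted(wavebands)):
                raise ProtocolConfigError(
                    f"protocol {self.name} must combine wavebands {wavebands}"
                )
            if self.pulse_length_us != pulse:
                raise ProtocolConfigError(
                    f"protocol {self.name} uses a {pulse:g} us pulse"
                )

    @property
    def wavebands(self) -> tuple[int, ...]:
        return tuple(l.channel.center_wavelength for l in self.leds)

    @property
    def intensities(self) -> tuple[float, ...]:
        return tuple(l.intensity for l in self.leds)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "wavebands": list(self.wavebands),
            "intensities": list(self.intensities),
            "pulse_length_us": self.pulse_length_us,
            "emission_bands": list(self.emission_bands),
        }

    @staticmethod
    def from_dict(d: dict, bank: tuple[LEDChannel, ...] = _DEFAULT_BANK
                  ) -> "ExcitationProtocol":
        """Rebuild a protocol from its serialised form.

        Channels are matched by waveband against the LED bank in bank order;
        duplicated wavebands (the two blues) consume successive channels.
        """
        available = list(bank)
        leds = []
        for wl, inten in zip(d["wavebands"], d["intensities"], strict=True):
            for i, ch in enumerate(available):
                if ch.center_wavelength == wl:
                    leds.append(ProtocolLED(ch, float(inten)))
                    del available[i]
                    break
            else:
                raise ProtocolConfigError(f"no LED channel left for {wl} nm")
        return ExcitationProtocol(
            name=d["name"],
            leds=tuple(leds),
            pulse_length_us=float(d["pulse_length_us"]),
            emission_bands=tuple(d.get("emission_bands", [685])),
        )


def default_led_channels() -> tuple[LEDChannel, ...]:
    """The instrument LED bank (immutable copies)."""
    return _DEFAULT_BANK


def _channel(label: str) -> LEDChannel:
    for ch in _DEFAULT_BANK:
        if ch.label == label:
            return ch
    raise KeyError(label)


def default_protocols(blue_intensities: tuple[float, float] | None = None
                      ) -> dict[str, ExcitationProtocol]:
    """Build the five-named-protocol registry.

    Parameters
    ----------
    blue_intensities
        Set intensities for the two blue LEDs (B1, B2). Defaults to their
        maxima. The instrument adapts these to the sample; here they are a
        user choice inside the admissible window.
    """
    b1, b2 = _channel("B1"), _channel("B2")
    g, o, r = _channel("G"), _channel("O"), _channel("R")
    if blue_intensities is None:
        blue_intensities = (b1.max_intensity, b2.max_intensity)
    # the auto-adjust regime only spans each blue LED's printed window
    for ch, inten in zip((b1, b2), blue_intensities):
        lo, hi = ch.intensity_range
        if not lo <= inten <= hi + 1e-9:
            raise ProtocolConfigError(
                f"blue LED {ch.label} intensity {inten} outside its "
                f"auto-adjust window [{lo}, {hi}]")
    pb1 = ProtocolLED(b1, blue_intensities[0])
    pb2 = ProtocolLED(b2, blue_intensities[1])
    pg = ProtocolLED(g, g.max_intensity)
    po = ProtocolLED(o, o.max_intensity)
    pr = ProtocolLED(r, r.max_intensity)
    combos = {
        "B": (pb1, pb2),
        "GOR": (pg, po, pr),
        "GORB": (pb1, pb2, pg, po, pr),
        "GOB": (pb1, pb2, pg, po),
        "GO": (pg, po),
    }
    return {
        name: ExcitationProtocol(
            name=name, leds=leds,
            pulse_length_us=_TABLE1[name][1],
            emission_bands=_TABLE1[name][2],
        )
        for name, leds in combos.items()
    }


def single_led_protocol(waveband: int, intensity: float | None = None,
                        pulse_length_us: float = 200.0,
                        emission_bands: tuple[int, ...] = (685,),
                        ) -> ExcitationProtocol:
    """An ad-hoc one-LED protocol, used for excitation-spectrum pulses."""
    for ch in _DEFAULT_BANK:
        if ch.center_wavelength == waveband:
            inten = ch.max_intensity if intensity is None else float(intensity)
            return ExcitationProtocol(
                name=f"L{waveband}",
                leds=(ProtocolLED(ch, inten),),
                pulse_length_us=pulse_length_us,
                emission_bands=emission_bands,
            )
    raise ProtocolConfigError(f"no LED at {waveband} nm")


def combined_intensity(protocol: ExcitationProtocol) -> float:
    """E_ST: the summed set intensity (umol photons m^-2 s^-1) of the pulse."""
    if not protocol.leds:
        raise ProtocolConfigError(f"protocol {protocol.name} has no LEDs")
    return float(sum(l.intensity for l in protocol.leds))


def umol_to_photon_flux(E: float) -> float:
    """Convert umol photons m^-2 s^-1 to photons nm^-2 us^-1.

    This is the bridge that makes ``sigma_PII`` (nm^2 PSII^-1) times flux an
    ``alpha_PII`` in photons PSII^-1 us^-1.
    """
    if E < 0:
        raise ValueError("irradiance must be >= 0")
    return E * PHOTONS_NM2_US_PER_UMOL


def alpha_from_sigma(sigma: float, E: float) -> float:
    """alpha_PII (photons PSII^-1 us^-1) from sigma_PII (nm^2) at pulse
    irradiance E (umol photons m^-2 s^-1)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    return sigma * umol_to_photon_flux(E)


def sigma_from_alpha(alpha: float, E: float) -> float:
    """Exact inverse of :func:`alpha_from_sigma` for E > 0."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if E <= 0:
        raise ValueError("irradiance must be > 0 to invert")
    return alpha / umol_to_photon_flux(E)


def expected_closure(alpha: float, pulse_length_us: float) -> float:
    """Fraction of PSII reaction centres closed at pulse end.

    Under the no-connectivity single-turnover model the open fraction decays
    exponentially at rate alpha, so closure is ``1 - exp(-alpha * L)``.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if pulse_length_us <= 0:
        raise ValueError("pulse_length_us must be > 0")
    return -math.expm1(-alpha * pulse_length_us)


@dataclass(frozen=True)
class SaturationThresholds:
    """QC bands for the ST saturation diagnosis.

    alpha in [0.042, 0.064] reflects a well-saturated pulse with a good fit;
    alpha below 0.02 (equivalently, end-of-pulse closure below ~0.98 on a
    200 us pulse) means PSII was not driven to full closure and F_m is an
    extrapolation.
    """

    alpha_optimal: tuple[float, float] = (0.042, 0.064)
    alpha_unsaturated: float = 0.02
    min_closure: float = 0.98


def classify_saturation(alpha: float, pulse_length_us: float,
                        thresholds: SaturationThresholds | None = None) -> str:
    """Classify a fitted pulse as optimal / suboptimal / unsaturated."""
    thr = thresholds or SaturationThresholds()
    if alpha < thr.alpha_unsaturated:
        return "unsaturated"
    if expected_closure(alpha, pulse_length_us) < thr.min_closure:
        return "unsaturated"
    lo, hi = thr.alpha_optimal
    if lo <= alpha <= hi:
        return "optimal"
    return "suboptimal"
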