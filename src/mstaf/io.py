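"""Trace and table round-tripping, run configuration.

All files are UTF-8 tab-separated text with '.' decimal; trace files carry
their metadata in '#'-prefixed header lines. Floats are written with
``repr`` so a write/read round trip is bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .st_induction import STTrace

__all__ = [
    "TraceParseError",
    "RunConfig",
    "read_traces",
    "write_traces",
    "load_config",
    "save_config",
]


class TraceParseError(ValueError):
    """Malformed trace file; message names the offending line."""


def write_traces(traces, path) -> None:
    """Write a sequence of ST traces to one delimited text file."""
    lines: list[str] = []
    for i, tr in enumerate(traces):
        lines.append(f"# trace\t{i}")
        lines.append(f"# protocol\t{tr.protocol}")
        lines.append(f"# emission_nm\t{tr.emission_band}")
        lines.append(f"# actinic_umol\t{repr(float(tr.actinic_E))}")
        lines.append("time_us\tfluorescence")
        for t, f in zip(tr.time, tr.fluorescence):
            lines.append(f"{repr(float(t))}\t{repr(float(f))}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


def read_traces(path) -> list[STTrace]:
    """Read traces written by :func:`write_traces` (bit-exact round trip)."""
    text = Path(path).read_text(encoding="utf-8")
    traces: list[STTrace] = []
    meta: dict[str, str] = {}
    times: list[float] = []
    fluor: list[float] = []
    in_block = False

    def flush(lineno: int) -> None:
        nonlocal meta, times, fluor, in_block
        if not in_block:
            return
        if not times:
            raise TraceParseError(f"line {lineno}: trace block has no rows")
        try:
            trace = STTrace(
                time=np.array(times), fluorescence=np.array(fluor),
                protocol=meta.get("protocol", ""),
                emission_band=int(meta.get("emission_nm", 685)),
                actinic_E=float(meta.get("actinic_umol", 0.0)),
            )
        except ValueError as exc:
            raise TraceParseError(
                f"trace ending at line {lineno}: {exc}") from exc
        traces.append(trace)
        meta, times, fluor, in_block = {}, [], [], False

    lineno = 0
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            flush(lineno)
            continue
        if line.startswith("#"):
            parts = line[1:].strip().split("\t")
            if len(parts) == 2:
                meta[parts[0].strip()] = parts[1].strip()
            in_block = True
            continue
        if line.startswith("time_us"):
            cols = line.split("\t")
            if cols[:2] != ["time_us", "fluorescence"]:
                raise TraceParseError(
                    f"line {lineno}: expected columns time_us, fluorescence")
            in_block = True
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise TraceParseError(f"line {lineno}: missing column")
        try:
            times.append(float(fields[0]))
            fluor.append(float(fields[1]))
        except ValueError as exc:
            raise TraceParseError(f"line {lineno}: {exc}") from exc
        # catch non-monotone time at the offending row, not at flush
        if len(times) > 1 and times[-1] <= times[-2]:
            raise TraceParseError(
                f"line {lineno}: time not strictly increasing")
        in_block = True
    flush(lineno + 1)
    return traces


@dataclass
class RunConfig:
    """Configuration of a full synthetic-scenario pipeline run."""

    seed: int = 1
    out_dir: str = "mstaf_run"
    protocols: list[str] = field(default_factory=lambda: ["B", "GOR"])
    spectra_modes: list[str] = field(
        default_factory=lambda: ["algae_optimised", "cyanobacteria_optimised"])
    n_dates: int = 23
    noise_frac: float = 0.01
    noise_sd_log: float = 0.3
    quench_E50: float = 300.0
    scenario_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        from .protocols import default_protocols
        if self.seed < 0 or int(self.seed) != self.seed:
            raise ValueError("seed must be a nonnegative integer")
        known = set(default_protocols())
        unknown = [p for p in self.protocols if p not in known]
        if unknown:
            raise ValueError(f"unknown protocol(s) {unknown}; "
                             f"choose from {sorted(known)}")
        for mode in self.spectra_modes:
            if mode not in ("algae_optimised", "cyanobacteria_optimised",
                            "auto"):
                raise ValueError(f"unknown spectra mode {mode!r}")


def load_config(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
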