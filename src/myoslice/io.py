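"""Trace file format and run configuration.

Traces are stored as TSV with a ``#``-prefixed header block::

    # format_version = 1
    # chamber_id = bmcc-1
    # sample_rate_Hz = 500.0
    # spring_constant_mN_mm = 75.0
    ...
    time_s<TAB>flux_T<TAB>stim_mA<TAB>tag
    0.000000000<TAB>9.3333e-05<TAB>50<TAB>regular

Header values round-trip losslessly (floats are written with repr
precision); unknown header keys are preserved.  A run configuration is a
small YAML file mirroring the chamber's physical defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .transduce import SpringTransducer
from .twin import SimulationConfig, SliceGeometry, TissueParams, TraceRecording

REQUIRED_HEADER = (
    "format_version",
    "chamber_id",
    "sample_rate_Hz",
    "spring_constant_mN_mm",
    "sensitivity_T_m",
    "baseline_flux_T",
)


class TraceFormatError(ValueError):
    """Malformed trace file (bad header, non-monotone time, ...)."""


def _parse_value(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    return text


def write_trace(path, trace: TraceRecording) -> None:
    """Write a trace as header + TSV rows (lossless round trip)."""
    path = Path(path)
    lines = []
    for key, val in trace.header.items():
        if isinstance(val, str):
            lines.append(f"# {key} = '{val}'")
        elif isinstance(val, (int, np.integer)):
            lines.append(f"# {key} = {int(val)}")
        else:
            lines.append(f"# {key} = {float(val)!r}")
    lines.append("time_s\tflux_T\tstim_mA\ttag")
    for t, b, s, tag in zip(trace.time, trace.flux, trace.stim_current, trace.tags):
        lines.append(f"{float(t)!r}\t{float(b)!r}\t{float(s)!r}\t{tag}")
    path.write_text("\n".join(lines) + "\n")


def read_trace(path) -> TraceRecording:
    """Read a trace file; raises :class:`TraceFormatError` on malformed input."""
    path = Path(path)
    header: dict = {}
    rows_t, rows_b, rows_s, rows_tag = [], [], [], []
    with path.open() as fh:
        saw_columns = False
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "=" not in line:
                    raise TraceFormatError(f"bad header line: {line!r}")
                key, _, val = line[1:].partition("=")
                val = val.strip()
                if val.startswith("'") and val.endswith("'"):
                    header[key.strip()] = val[1:-1]
                else:
                    header[key.strip()] = _parse_value(val)
                continue
            if not saw_columns:
                if line.split("\t")[0] != "time_s":
                    raise TraceFormatError("missing column header line")
                saw_columns = True
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise TraceFormatError(f"expected 4 columns, got {len(parts)}")
            rows_t.append(float(parts[0]))
            rows_b.append(float(parts[1]))
            rows_s.append(float(parts[2]))
            rows_tag.append(parts[3])
    missing = [k for k in REQUIRED_HEADER if k not in header]
    if missing:
        raise TraceFormatError(f"trace header lacks required keys: {missing}")
    time = np.array(rows_t)
    if np.any(np.diff(time) <= 0):
        raise TraceFormatError("time column must be strictly increasing")
    return TraceRecording(
        time=time,
        flux=np.array(rows_b),
        stim_current=np.array(rows_s),
        tags=np.array(rows_tag, dtype=object),
        header=header,
    )


@dataclass
class RunConfig:
    """Simulation run description, loadable from YAML."""

    tissue: TissueParams = field(default_factory=TissueParams)
    transducer: SpringTransducer = field(default_factory=SpringTransducer)
    duration: float = 60.0
    sample_rate: float = 500.0
    rate_hz: float = 0.2
    pulse_mA: float = 50.0
    preload: float = 1.0
    seed: int = 0
    chamber_id: str = "bmcc-1"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for stochastic runs")
        for name in ("duration", "sample_rate", "rate_hz", "pulse_mA"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(
            duration=self.duration, sample_rate=self.sample_rate, seed=self.seed,
            preload=self.preload, transducer=self.transducer,
            chamber_id=self.chamber_id,
        )

    def to_yaml(self, path) -> None:
        doc = {
            "tissue": {
                "geometry": {
                    "length": self.tissue.geometry.length,
                    "width": self.tissue.geometry.width,
                    "thickness": self.tissue.geometry.thickness,
                },
                "peak_twitch_force": self.tissue.peak_twitch_force,
                "time_to_peak": self.tissue.time_to_peak,
                "relaxation_tau": self.tissue.relaxation_tau,
                "refractory_period": self.tissue.refractory_period,
                "threshold_current": self.tissue.threshold_current,
            },
            "transducer": {
                "spring_constant": self.transducer.spring_constant,
                "sensitivity": self.transducer.sensitivity,
                "baseline_flux": self.transducer.baseline_flux,
                "resolution": self.transducer.resolution,
            },
            "run": {
                "duration": self.duration,
                "sample_rate": self.sample_rate,
                "rate_hz": self.rate_hz,
                "pulse_mA": self.pulse_mA,
                "preload": self.preload,
                "seed": self.seed,
                "chamber_id": self.chamber_id,
            },
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        tis = doc.get("tissue", {})
        geo = tis.get("geometry", {})
        tissue = TissueParams(
            geometry=SliceGeometry(**geo) if geo else SliceGeometry(),
            **{k: v for k, v in tis.items() if k != "geometry"},
        )
        transducer = SpringTransducer(**doc.get("transducer", {}))
        return cls(tissue=tissue, transducer=transducer, **doc.get("run", {}))
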