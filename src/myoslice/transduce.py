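"""Elastic force transduction: force <-> spring-tip displacement <-> magnetic flux.

The culture chamber suspends one end of the tissue slice from a steel spring
wire carrying a small permanent magnet.  Contraction deflects the wire; a
magnetic field sensor next to the chamber reads the flux change.  Within the
operating range the chain is affine:

    x  = F / k            (Hooke, k = 75 mN/mm)
    B  = B0 + s * x       (s = 7 T/m at the operating point)

so force is recovered from a flux trace by inverting both maps.  The sensor
range budget is 1.2 mT; excursions beyond it are flagged, never clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

FLUX_BUDGET_T = 1.2e-3  #: sensor range: |flux| beyond this saturates


class SaturationWarning(UserWarning):
    """Flux excursion beyond the 1.2 mT sensor budget."""


class CalibrationError(ValueError):
    """A trace is missing the calibration metadata needed to invert it."""


@dataclass
class SpringTransducer:
    """Calibration constants of the spring/magnet/sensor chain.

    Parameters
    ----------
    spring_constant : float
        Elastic constant of the spring wire, mN/mm.
    sensitivity : float
        Flux change per unit tip displacement, T/m.
    baseline_flux : float
        Flux at zero displacement, T.  Must stay within the sensor budget.
    resolution : float
        One-sigma single-sample displacement resolution, µm.  The per-sample
        flux noise is ``sensitivity * resolution`` (noise_sd).
    """

    spring_constant: float = 75.0
    sensitivity: float = 7.0
    baseline_flux: float = 0.0
    resolution: float = 0.5

    def __post_init__(self) -> None:
        if self.spring_constant <= 0:
            raise ValueError("spring_constant must be positive")
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be positive")
        if abs(self.baseline_flux) > FLUX_BUDGET_T:
            raise ValueError("baseline_flux exceeds the 1.2 mT sensor budget")
        if self.resolution < 0:
            raise ValueError("resolution must be non-negative")

    @property
    def noise_sd(self) -> float:
        """Per-sample flux noise, T (one sigma)."""
        return self.sensitivity * self.resolution * 1e-6

    def header(self) -> dict:
        return {
            "spring_constant_mN_mm": self.spring_constant,
            "sensitivity_T_m": self.sensitivity,
            "baseline_flux_T": self.baseline_flux,
            "resolution_um": self.resolution,
        }

    @classmethod
    def from_header(cls, header: dict) -> "SpringTransducer":
        keys = (
            "spring_constant_mN_mm",
            "sensitivity_T_m",
            "baseline_flux_T",
            "resolution_um",
        )
        missing = [k for k in keys if k not in header]
        if missing:
            raise CalibrationError(f"trace header lacks calibration keys: {missing}")
        return cls(
            spring_constant=float(header["spring_constant_mN_mm"]),
            sensitivity=float(header["sensitivity_T_m"]),
            baseline_flux=float(header["baseline_flux_T"]),
            resolution=float(header["resolution_um"]),
        )


def force_to_displacement(force, transducer: SpringTransducer):
    """Spring-tip displacement (mm) for a tissue force (mN).  Hooke's law."""
    force = np.asarray(force, dtype=float)
    if np.any(force < 0):
        raise ValueError("force must be non-negative")
    out = force / transducer.spring_constant
    return float(out) if out.ndim == 0 else out


def displacement_to_flux(x_mm, transducer: SpringTransducer, *, warn: bool = True):
    """Sensor flux (T) for a tip displacement (mm), affine around baseline.

    Emits :class:`SaturationWarning` (once per call) when the resulting flux
    leaves the ±1.2 mT sensor budget.
    """
    x_mm = np.asarray(x_mm, dtype=float)
    flux = transducer.baseline_flux + transducer.sensitivity * x_mm * 1e-3
    if warn and np.any(np.abs(flux) > FLUX_BUDGET_T):
        warnings.warn(
            "flux excursion beyond the 1.2 mT sensor budget (not clipped)",
            SaturationWarning,
            stacklevel=2,
        )
    return float(flux) if flux.ndim == 0 else flux


def flux_to_force(flux_T, transducer: SpringTransducer):
    """Invert the sensing chain: flux (T) -> force (mN)."""
    flux_T = np.asarray(flux_T, dtype=float)
    x_mm = (flux_T - transducer.baseline_flux) / transducer.sensitivity * 1e3
    out = x_mm * transducer.spring_constant
    return float(out) if out.ndim == 0 else out


def trace_to_force(trace, transducer: SpringTransducer | None = None):
    """Recover the force series (mN) from a recorded trace.

    The calibration is taken from the trace header unless an explicit
    transducer is supplied.  Raises :class:`CalibrationError` when the header
    is incomplete.
    """
    if transducer is None:
        transducer = SpringTransducer.from_header(trace.header)
    return flux_to_force(trace.flux, transducer)
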