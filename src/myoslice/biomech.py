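"""Biomechanics: wall stress, length-tension and force-frequency analysis,
Hill dose-response fitting.

Stresses follow the design rule of the chamber: the 75 mN/mm spring yields
normal systolic wall stress (15 kN/m^2) at ~6% shortening of a
5 x 5 x 0.3 mm slice, and a 1 mN preload corresponds to normal diastolic
wall stress (0.66 kN/m^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .twin import SliceGeometry


class FitConvergenceError(RuntimeError):
    """Dose-response fit failed or the data cannot identify the parameters."""


def wall_stress(force_mN, geometry: SliceGeometry):
    """Wall stress (kN/m^2) for a force (mN) over the slice cross-section.

    1 mN/mm^2 = 1 kN/m^2, so this is simply force / (width x thickness).
    """
    force_mN = np.asarray(force_mN, dtype=float)
    out = force_mN / geometry.cross_section
    return float(out) if out.ndim == 0 else out


def systolic_design_check(
    spring_constant: float, shortening_fraction: float,
    geometry: SliceGeometry | None = None,
) -> float:
    """Wall stress (kN/m^2) when the slice shortens by `shortening_fraction`
    against a spring of `spring_constant` (mN/mm): F = k * s * L."""
    if geometry is None:
        geometry = SliceGeometry()
    force = spring_constant * shortening_fraction * geometry.length
    return float(wall_stress(force, geometry))


@dataclass
class LengthTensionSummary:
    l_max: float                  #: stretch (muscle length, mm) of max active force
    max_active_force: float       #: mN
    length_at_preload: float      #: mm, where passive force = preload_ref
    fraction_at_preload: float    #: length_at_preload / l_max
    degenerate: bool = False


def length_tension_analysis(
    stretch_mm, twitch_amplitudes, passive_forces, preload_ref: float = 1.0
) -> LengthTensionSummary:
    """Locate the optimum length and the operating fraction at preload.

    The stretch of maximal active force is refined by a local quadratic fit
    around the sampled maximum; the length at ``preload_ref`` passive force
    is found by monotone interpolation of the passive curve.  A flat active
    curve is flagged degenerate.
    """
    x = np.asarray(stretch_mm, dtype=float)
    a = np.asarray(twitch_amplitudes, dtype=float)
    p = np.asarray(passive_forces, dtype=float)
    if not (x.size == a.size == p.size) or x.size < 3:
        raise ValueError("need >= 3 matched (stretch, active, passive) samples")
    if np.ptp(a) < 1e-9 * max(np.max(np.abs(a)), 1.0):
        return LengthTensionSummary(np.nan, float(a.mean()), np.nan, np.nan,
                                    degenerate=True)
    i = int(np.argmax(a))
    if 0 < i < x.size - 1:
        # quadratic through the three points around the maximum
        coeff = np.polyfit(x[i - 1:i + 2], a[i - 1:i + 2], 2)
        l_max = float(-coeff[1] / (2 * coeff[0])) if coeff[0] < 0 else float(x[i])
        max_active = float(np.polyval(coeff, l_max)) if coeff[0] < 0 else float(a[i])
    else:
        l_max, max_active = float(x[i]), float(a[i])
    order = np.argsort(p)
    length_at_preload = float(np.interp(preload_ref, p[order], x[order]))
    return LengthTensionSummary(
        l_max=l_max, max_active_force=max_active,
        length_at_preload=length_at_preload,
        fraction_at_preload=length_at_preload / l_max,
    )


@dataclass
class DoseResponse:
    """Dose-response data and (after fitting) Hill parameters."""

    concentrations: np.ndarray
    responses: np.ndarray
    ec50: float | None = None
    emax: float | None = None
    hill_n: float | None = None
    residual_norm: float | None = None
    ec50_unidentifiable: bool = False

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concentrations.shape != self.responses.shape:
            raise ValueError("concentrations and responses must align")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")


def hill(c, emax, ec50, n=1.0):
    """Hill curve R(C) = emax * C^n / (EC50^n + C^n)."""
    c = np.asarray(c, dtype=float)
    cn = np.power(c, n, where=c > 0, out=np.zeros_like(c))
    return emax * cn / (ec50 ** n + cn)


def hill_fit(dr: DoseResponse, fix_hill_n: float | None = None) -> DoseResponse:
    """Least-squares Hill fit with multi-start over log-spaced EC50 seeds.

    ``fix_hill_n`` pins the Hill coefficient (1 for a simple binding
    surface); otherwise it is fitted.  Degenerate all-zero responses return
    emax ~ 0 with the EC50 flagged unidentifiable; non-convergent data raise
    :class:`FitConvergenceError` with diagnostics.
    """
    c, r = dr.concentrations, dr.responses
    if np.unique(c).size < 3:
        raise ValueError("need at least 3 distinct concentrations")
    pos = c[c > 0]
    scale = float(np.max(np.abs(r))) if r.size else 0.0
    if scale < 1e-12:
        dr.emax, dr.ec50, dr.hill_n = 0.0, None, fix_hill_n
        dr.residual_norm = 0.0
        dr.ec50_unidentifiable = True
        return dr

    if fix_hill_n is None:
        def model(cc, emax, log_ec50, n):
            return hill(cc, emax, np.exp(log_ec50), n)
        extra = ([1.0], [0.2], [5.0])
    else:
        def model(cc, emax, log_ec50):
            return hill(cc, emax, np.exp(log_ec50), fix_hill_n)
        extra = ([], [], [])

    best, best_cost = None, np.inf
    seeds = np.geomspace(pos.min(), pos.max(), 7)
    diagnostics = []
    for ec50_seed in seeds:
        p0 = [np.max(r), np.log(ec50_seed), *extra[0]]
        try:
            popt, _ = curve_fit(model, c, r, p0=p0, maxfev=20_000)
        except RuntimeError as exc:
            diagnostics.append(f"seed {ec50_seed:.3g}: {exc}")
            continue
        cost = float(np.sum((model(c, *popt) - r) ** 2))
        if cost < best_cost:
            best, best_cost = popt, cost
    if best is None:
        raise FitConvergenceError(
            "Hill fit failed for every EC50 seed: " + "; ".join(diagnostics)
        )
    dr.emax = float(best[0])
    dr.ec50 = float(np.exp(best[1]))
    dr.hill_n = float(best[2]) if fix_hill_n is None else float(fix_hill_n)
    dr.residual_norm = float(np.sqrt(best_cost))
    if dr.ec50 < pos.min() / 100 or dr.ec50 > pos.max() * 100:
        dr.ec50_unidentifiable = True
    return dr


@dataclass
class FFRSummary:
    rates_bpm: np.ndarray
    normalized: np.ndarray        #: amplitude / amplitude at 60 bpm
    classification: str           #: positive / negative / biphasic
    bradycardia_gain: bool        #: force gain below 60 bpm


def ffr_analysis(rates_bpm, amplitudes) -> FFRSummary:
    """Force-frequency relation: normalise to the 60 bpm reference and
    classify the slope pattern (positive / negative / biphasic)."""
    rates = np.asarray(rates_bpm, dtype=float)
    amps = np.asarray(amplitudes, dtype=float)
    if rates.size != amps.size or rates.size < 2:
        raise ValueError("need >= 2 matched (rate, amplitude) samples")
    order = np.argsort(rates)
    rates, amps = rates[order], amps[order]
    ref = float(np.interp(60.0, rates, amps))
    if ref <= 0:
        raise ValueError("non-positive reference amplitude at 60 bpm")
    norm = amps / ref
    slopes = np.sign(np.diff(norm))
    slopes = slopes[slopes != 0]
    if slopes.size == 0:
        classification = "positive"  # flat counts as non-negative
    elif np.all(slopes > 0):
        classification = "positive"
    elif np.all(slopes < 0):
        classification = "negative"
    else:
        classification = "biphasic"
    below = rates < 60.0
    bradycardia_gain = bool(below.any() and np.any(norm[below] > 1.0 + 1e-9))
    return FFRSummary(rates, norm, classification, bradycardia_gain)
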