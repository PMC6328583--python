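"""Digital twin of a myocardial slice mounted in a biomimetic culture chamber.

The twin represents a 5 x 5 x 0.3 mm slice held between a calibrated spring
wire (75 mN/mm) and a manual linear drive, paced by field stimulation and
read out through a magnetic displacement sensor.  It models:

* excitability: a stimulus activates the tissue iff its charge reaches the
  strength-duration threshold and the interval since the last activation
  exceeds the refractory period;
* twitch force: a difference-of-exponentials waveform scaled by
  length-tension, force-frequency and restitution factors;
* passive mechanics: exponential diastolic force-extension, calibrated so a
  1 mN preload sits the tissue at 83% of the length of maximal active force;
* auxotonic loading: at each sample the tissue force balances the spring,
  so shortening trades off against developed force (Hooke's law is exact);
* pharmacology: Hill-type inotropic scaling, acute refractory-period
  prolongation, and delayed (trafficking-type) refractory prolongation with
  first-order onset kinetics.

Simulated runs are emitted as raw sensor traces (flux vs time with embedded
stimulation markers) through the transduction module, so every analysis
operates on exactly what the real acquisition chain would deliver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .stim import StimulusSchedule
from .transduce import SpringTransducer, displacement_to_flux


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class SliceGeometry:
    """Physical dimensions of the mounted tissue (mm).

    ``length`` is the muscle span between the fixations at the reference
    preload; ``cross_section`` (width x thickness) feeds all stress
    computations.
    """

    length: float = 5.0
    width: float = 5.0
    thickness: float = 0.3

    def __post_init__(self) -> None:
        if min(self.length, self.width, self.thickness) <= 0:
            raise ValueError("all slice dimensions must be strictly positive")

    @property
    def cross_section(self) -> float:
        """Cross-sectional area, mm^2."""
        return self.width * self.thickness


@dataclass(frozen=True)
class LengthTension:
    """Active and passive force dependence on muscle length.

    Active: concave parabola in the length fraction f = L / L_max, normalised
    to 1 at the fraction occupied under the reference preload
    (``frac_at_preload``, calibrated to 0.83).  Passive: exponential in
    strain beyond the slack length, scaled so the passive force at the
    reference mounted length equals ``preload_ref`` (1 mN).
    """

    frac_at_preload: float = 0.83
    curvature: float = 4.0
    slack_fraction: float = 0.9    #: slack length / reference mounted length
    passive_exponent: float = 10.0  #: e-folding per unit strain
    preload_ref: float = 1.0        #: mN of passive force at reference length

    def l_max(self, ref_length: float) -> float:
        """Length of maximal active force, mm."""
        return ref_length / self.frac_at_preload

    def active_factor(self, frac) -> np.ndarray | float:
        """Relative active force at length fraction `frac` (1 at 0.83)."""
        frac = np.asarray(frac, dtype=float)
        norm = 1.0 - self.curvature * (self.frac_at_preload - 1.0) ** 2
        out = np.clip((1.0 - self.curvature * (frac - 1.0) ** 2) / norm, 0.0, None)
        return float(out) if out.ndim == 0 else out

    def _passive_scale(self) -> float:
        return self.preload_ref / math.expm1(
            self.passive_exponent * (1.0 - self.slack_fraction)
        )

    def passive_force(self, length, ref_length: float):
        """Diastolic (passive) force at muscle length `length` (mm) -> mN."""
        length = np.asarray(length, dtype=float)
        slack = self.slack_fraction * ref_length
        strain = np.clip((length - slack) / ref_length, 0.0, None)
        out = self._passive_scale() * np.expm1(self.passive_exponent * strain)
        return float(out) if out.ndim == 0 else out

    def passive_stiffness(self, length, ref_length: float):
        """dF/dL of the passive curve, mN/mm."""
        length = np.asarray(length, dtype=float)
        slack = self.slack_fraction * ref_length
        strain = (length - slack) / ref_length
        b = self.passive_exponent
        out = np.where(
            strain > 0,
            self._passive_scale() * b / ref_length * np.exp(b * np.clip(strain, 0, None)),
            0.0,
        )
        return float(out) if out.ndim == 0 else out

    def length_at_passive(self, force: float, ref_length: float) -> float:
        """Inverse of :meth:`passive_force` (force in mN -> length in mm)."""
        if force < 0:
            raise ValueError("passive force must be non-negative")
        slack = self.slack_fraction * ref_length
        if force == 0:
            return slack
        strain = math.log1p(force / self._passive_scale()) / self.passive_exponent
        return slack + strain * ref_length


#: piecewise-linear force-frequency tables (bpm -> relative amplitude).
#: The cultured set gains force at bradycardia, the fresh set does not;
#: both decline toward 180 bpm.
FFR_CULTURED = ((12.0, 1.25), (60.0, 1.0), (120.0, 0.8), (180.0, 0.6))
FFR_FRESH = ((12.0, 1.0), (60.0, 1.0), (120.0, 0.8), (180.0, 0.6))


@dataclass(frozen=True)
class TissueParams:
    """Ground-truth contractile, excitability and pharmacological state.

    Forces in mN, times in ms unless noted.  ``peak_twitch_force`` is the
    active force at the reference length (0.83 L_max) and reference rate
    (60 bpm).  ``threshold_current`` is the excitation threshold at 1 ms
    pulse width; the strength-duration relation holds threshold charge
    (current x width) constant.
    """

    geometry: SliceGeometry = field(default_factory=SliceGeometry)
    peak_twitch_force: float = 6.0
    time_to_peak: float = 150.0
    relaxation_tau: float = 300.0
    refractory_period: float = 425.0
    threshold_current: float = 30.0
    length_tension: LengthTension = field(default_factory=LengthTension)
    ffr: tuple = FFR_CULTURED
    restitution_depth: float = 0.45
    restitution_tau: float = 150.0

    def __post_init__(self) -> None:
        if self.refractory_period <= 0:
            raise ValueError("refractory_period must be positive")
        if not 0 < self.threshold_current <= 75:
            raise ValueError("threshold_current must lie in (0, 75] mA")
        if self.peak_twitch_force < 0:
            raise ValueError("peak_twitch_force must be non-negative")
        if not 0 <= self.restitution_depth < 1:
            raise ValueError("restitution_depth must lie in [0, 1)")

    # -- twitch waveform ----------------------------------------------------
    @property
    def rise_tau(self) -> float:
        """Rise time constant (ms) solving the difference-of-exponentials
        peak-time equation for the configured time_to_peak."""
        td, tp = self.relaxation_tau, self.time_to_peak

        def peak_time(tr):
            return td * tr / (td - tr) * math.log(td / tr) - tp

        return brentq(peak_time, 1e-3, td * 0.999, xtol=1e-9)

    def twitch_shape(self, t_ms):
        """Unit-peak twitch waveform at times since activation (ms)."""
        t = np.asarray(t_ms, dtype=float)
        tr, td = self.rise_tau, self.relaxation_tau
        raw = np.where(t >= 0, np.exp(-np.clip(t, 0, None) / td)
                       - np.exp(-np.clip(t, 0, None) / tr), 0.0)
        t_pk = td * tr / (td - tr) * math.log(td / tr)
        peak = math.exp(-t_pk / td) - math.exp(-t_pk / tr)
        out = raw / peak
        return float(out) if out.ndim == 0 else out

    def ffr_factor(self, rate_bpm: float) -> float:
        """Force-frequency scaling relative to the 60 bpm reference."""
        pts = np.array(self.ffr)
        return float(np.interp(rate_bpm, pts[:, 0], pts[:, 1]))

    def restitution(self, interval_ms: float) -> float:
        """Amplitude recovery after a preceding activation `interval_ms` ago."""
        if not np.isfinite(interval_ms):
            return 1.0
        dt = interval_ms - self.refractory_period
        if dt <= 0:
            return 1.0 - self.restitution_depth
        return 1.0 - self.restitution_depth * math.exp(-dt / self.restitution_tau)


@dataclass(frozen=True)
class DrugEffect:
    """Pharmacological action applied to the twin.

    mechanism:
      * ``inotropic_scale`` — multiplies peak twitch force by
        1 + (emax - 1) * C^n / (EC50^n + C^n) (emax is the saturating fold);
      * ``rp_acute_hill`` — adds emax * C^n / (EC50^n + C^n) ms to the
        refractory period immediately (direct channel block);
      * ``rp_delayed`` — the same ceiling, scaled by
        1 - exp(-elapsed_days / onset_tau) (impaired channel trafficking,
        ineffective on day 0 and saturating over ~2 weeks).
    """

    name: str
    mechanism: str
    ec50: float
    emax: float
    hill_n: float = 1.0
    onset_tau: float = 5.0
    concentration: float = 0.0

    _MECHANISMS = ("inotropic_scale", "rp_acute_hill", "rp_delayed")

    def __post_init__(self) -> None:
        if self.mechanism not in self._MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.ec50 <= 0 or self.hill_n <= 0:
            raise ValueError("ec50 and hill_n must be positive")
        if self.mechanism == "rp_delayed" and self.onset_tau <= 0:
            raise ValueError("onset_tau must be positive for rp_delayed")
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")

    def occupancy(self) -> float:
        """Hill fractional effect C^n / (EC50^n + C^n) at the current dose."""
        c = self.concentration
        if c == 0:
            return 0.0
        cn = c ** self.hill_n
        return cn / (self.ec50 ** self.hill_n + cn)


def apply_drug(tissue: TissueParams, drug: DrugEffect, elapsed_days: float = 0.0
               ) -> TissueParams:
    """Return the tissue state under the drug's action at `elapsed_days`."""
    if elapsed_days < 0:
        raise ValueError("elapsed_days must be non-negative")
    occ = drug.occupancy()
    if drug.mechanism == "inotropic_scale":
        scale = 1.0 + (drug.emax - 1.0) * occ
        return replace(tissue, peak_twitch_force=tissue.peak_twitch_force * scale)
    if drug.mechanism == "rp_acute_hill":
        return replace(tissue,
                       refractory_period=tissue.refractory_period + drug.emax * occ)
    # rp_delayed
    onset = 1.0 - math.exp(-elapsed_days / drug.onset_tau)
    return replace(tissue,
                   refractory_period=tissue.refractory_period
                   + drug.emax * occ * onset)


@dataclass
class ChamberState:
    """Mechanical state of the chamber mount.

    ``total_span`` is the distance budget shared by muscle length and spring
    deflection (muscle_length + force/k = total_span); moving the linear
    drive changes it.  ``drive_position`` tracks the drive offset relative to
    the freshly mounted position.
    """

    preload: float = 1.0
    drive_position: float = 0.0
    total_span: float = 0.0
    time: float = 0.0
    last_activation_time: float = -math.inf

    def __post_init__(self) -> None:
        if self.preload < 0:
            raise ValueError("preload must be non-negative")


DRIVE_RANGE_MM = 5.0  #: travel of the manual linear drive, +- mm


def adjust_preload(
    tissue: TissueParams,
    target: float,
    transducer: SpringTransducer | None = None,
    state: ChamberState | None = None,
    tol: float = 0.01,
) -> ChamberState:
    """Move the linear drive until the diastolic force matches `target` (mN).

    Mimics the manual adjustment step: the drive is stepped iteratively and
    the diastolic force re-read until it is within `tol` of the target.
    Raises if the required travel exceeds the drive range.
    """
    if target < 0:
        raise ValueError("target preload must be non-negative")
    if transducer is None:
        transducer = SpringTransducer()
    lt, ref = tissue.length_tension, tissue.geometry.length
    if state is None:
        # freshly mounted: slack tissue, zero force
        state = ChamberState(preload=0.0, drive_position=0.0,
                             total_span=lt.slack_fraction * ref)
    span0 = state.total_span - state.drive_position

    def diastolic(span: float) -> float:
        # solve F = passive(span - F/k) by fixed-point Newton
        f = max(target, 0.0)
        for _ in range(60):
            length = span - f / transducer.spring_constant
            g = f - lt.passive_force(length, ref)
            dg = 1.0 + lt.passive_stiffness(length, ref) / transducer.spring_constant
            f_new = max(f - g / dg, 0.0)
            if abs(f_new - f) < 1e-12:
                f = f_new
                break
            f = f_new
        return f

    # iterative drive stepping with a contracting step size
    span = state.total_span
    step = 0.5
    for _ in range(10_000):
        err = diastolic(span) - target
        if abs(err) <= tol:
            break
        span += -step if err > 0 else step
        # shrink the step whenever we overshoot
        if (diastolic(span) - target) * err < 0:
            step *= 0.5
        drive = span - span0
        if abs(drive) > DRIVE_RANGE_MM:
            raise ValueError("target preload unreachable within the drive range")
    else:  # pragma: no cover
        raise RuntimeError("preload adjustment failed to converge")
    force = diastolic(span)
    return ChamberState(preload=force, drive_position=span - span0,
                        total_span=span, time=state.time,
                        last_activation_time=state.last_activation_time)


def diastolic_operating_point(
    tissue: TissueParams, state: ChamberState,
    transducer: SpringTransducer | None = None,
) -> tuple[float, float]:
    """(diastolic force mN, muscle length mm) at the current drive setting."""
    if transducer is None:
        transducer = SpringTransducer()
    lt, ref = tissue.length_tension, tissue.geometry.length
    f = 1.0
    for _ in range(100):
        length = state.total_span - f / transducer.spring_constant
        g = f - lt.passive_force(length, ref)
        dg = 1.0 + lt.passive_stiffness(length, ref) / transducer.spring_constant
        f = max(f - g / dg, 0.0)
        if abs(g) < 1e-12:
            break
    return f, state.total_span - f / transducer.spring_constant


# ---------------------------------------------------------------------------
# operations

def active_force(t_since_activation, tissue: TissueParams,
                 length_fraction: float = 0.83, rate: float = 60.0):
    """Active twitch force (mN) at `t_since_activation` ms after a stimulus.

    Single-peaked difference-of-exponentials waveform; zero at t = 0 and as
    t -> inf.  The peak equals ``peak_twitch_force`` scaled by the
    length-tension factor at `length_fraction` and the force-frequency
    factor at `rate` (bpm).
    """
    t = np.asarray(t_since_activation, dtype=float)
    if np.any(t < 0):
        raise ValueError("time since activation must be non-negative")
    amp = (tissue.peak_twitch_force
           * tissue.length_tension.active_factor(length_fraction)
           * tissue.ffr_factor(rate))
    out = np.asarray(amp * tissue.twitch_shape(t))
    return float(out) if out.ndim == 0 else out


def excitable(t: float, stimulus_current: float, pulse_width: float,
              tissue: TissueParams, state: ChamberState) -> bool:
    """Decide whether a stimulus at time `t` (s) activates the tissue.

    Activation requires the pulse charge (current x width) to reach the
    threshold charge (threshold_current at 1 ms), and the interval since the
    last activation to strictly exceed the refractory period.  On activation
    the chamber state's last_activation_time is updated.
    """
    if stimulus_current < 0 or pulse_width <= 0:
        raise ValueError("stimulus must have non-negative current, positive width")
    charge_ok = stimulus_current * pulse_width >= tissue.threshold_current * 1.0
    interval_ms = (t - state.last_activation_time) * 1e3
    # 1 ns tolerance: an interval exactly equal to the refractory period
    # must fail even under float jitter in event times
    if charge_ok and interval_ms > tissue.refractory_period + 1e-6:
        state.last_activation_time = t
        state.time = t
        return True
    state.time = t
    return False


@dataclass
class SimulationConfig:
    """Run settings for :func:`simulate_run`."""

    duration: float              #: s
    sample_rate: float = 500.0   #: samples per second
    seed: int | None = 0
    noise: bool = True
    preload: float = 1.0         #: mN, diastolic target before the run
    transducer: SpringTransducer = field(default_factory=SpringTransducer)
    chamber_id: str = "bmcc-1"
    #: optional slow multiplicative amplitude modulation (medium-exchange
    #: breakdown/recovery cycles): (period_h, depth) or None
    medium_modulation: tuple | None = None


@dataclass
class TraceRecording:
    """Raw acquisition stream: time (s), flux (T), stimulation markers."""

    time: np.ndarray
    flux: np.ndarray
    stim_current: np.ndarray   #: mA at the sample nearest each pulse, else 0
    tags: np.ndarray           #: "-", "regular" or "extra" per sample
    header: dict = field(default_factory=dict)

    @property
    def sample_rate(self) -> float:
        return float(self.header["sample_rate_Hz"])

    def stim_times(self, tag: str | None = None):
        mask = self.stim_current > 0
        if tag is not None:
            mask &= self.tags == tag
        return self.time[mask]

    def stim_amplitudes(self, tag: str | None = None):
        mask = self.stim_current > 0
        if tag is not None:
            mask &= self.tags == tag
        return self.stim_current[mask]


def _activation_plan(tissue: TissueParams, schedule: StimulusSchedule,
                     state: ChamberState) -> list[tuple[float, float]]:
    """Run the excitability gate over the schedule.

    Returns (activation time s, relative amplitude) pairs; the relative
    amplitude carries the restitution factor for premature beats.
    """
    plan = []
    last = state.last_activation_time
    for ev in schedule:
        charge_ok = (ev.pulse.amplitude * ev.pulse.charge_width
                     >= tissue.threshold_current * 1.0)
        interval_ms = (ev.time - last) * 1e3
        if charge_ok and interval_ms > tissue.refractory_period + 1e-6:
            plan.append((ev.time, tissue.restitution(interval_ms)))
            last = ev.time
    state.last_activation_time = last
    return plan


def simulate_run(tissue: TissueParams, schedule: StimulusSchedule,
                 config: SimulationConfig) -> TraceRecording:
    """Simulate a paced run and emit the raw sensor trace.

    Per sample the auxotonic force balance F = passive(L) + A(t), with
    L = span - F/k, is solved by vectorised Newton iteration; the resulting
    spring-tip displacement is converted to magnetic flux, calibrated sensor
    noise is added, and stimulation markers are embedded.  Bit-reproducible
    for a fixed seed.
    """
    if len(schedule) and schedule.end_time > config.duration:
        raise ValueError("schedule events extend beyond the run duration")
    tr = config.transducer
    k = tr.spring_constant
    lt, ref = tissue.length_tension, tissue.geometry.length

    state = adjust_preload(tissue, config.preload, tr)
    dia_force, dia_length = diastolic_operating_point(tissue, state, tr)
    frac_d = dia_length / lt.l_max(ref)

    # pacing rate for the force-frequency factor, from the regular cadence
    reg_times = np.array([e.time for e in schedule.regular_events()])
    if len(reg_times) > 1:
        rate_bpm = 60.0 / float(np.median(np.diff(reg_times)))
    else:
        rate_bpm = 60.0
    base_amp = (tissue.peak_twitch_force * lt.active_factor(frac_d)
                * tissue.ffr_factor(rate_bpm))

    n = int(round(config.duration * config.sample_rate)) + 1
    t = np.arange(n) / config.sample_rate

    # active drive: superpose twitch waveforms at the activation times
    drive = np.zeros(n)
    support_ms = tissue.relaxation_tau * 12.0
    for t_act, rel in _activation_plan(tissue, schedule, state):
        i0 = int(np.ceil(t_act * config.sample_rate - 1e-9))
        i1 = min(n, i0 + int(support_ms * 1e-3 * config.sample_rate) + 1)
        tt = (t[i0:i1] - t_act) * 1e3
        drive[i0:i1] += base_amp * rel * tissue.twitch_shape(tt)

    if config.medium_modulation is not None:
        # contractility breaks down right after each medium exchange and
        # recovers over the cycle (depth = fractional breakdown)
        period_h, depth = config.medium_modulation
        phase = (t / 3600.0) % period_h / period_h
        drive *= 1.0 - depth * np.exp(-phase / 0.25)

    # vectorised Newton on F = passive(span - F/k) + drive
    span = state.total_span
    force = np.full(n, dia_force) + drive
    for _ in range(60):
        length = span - force / k
        g = force - lt.passive_force(length, ref) - drive
        dg = 1.0 + lt.passive_stiffness(length, ref) / k
        step = g / dg
        force = np.clip(force - step, 0.0, None)
        if np.max(np.abs(step)) < 1e-12:
            break

    x = force / k
    flux = displacement_to_flux(x, tr)
    if config.noise and tr.noise_sd > 0:
        rng = np.random.default_rng(config.seed)
        flux = flux + rng.normal(0.0, tr.noise_sd, size=n)

    stim = np.zeros(n)
    tags = np.full(n, "-", dtype=object)
    for ev in schedule:
        idx = int(round(ev.time * config.sample_rate))
        if 0 <= idx < n:
            stim[idx] = ev.pulse.amplitude
            tags[idx] = ev.tag

    header = {
        "format_version": 1,
        "chamber_id": config.chamber_id,
        "sample_rate_Hz": config.sample_rate,
        "length_mm": tissue.geometry.length,
        "width_mm": tissue.geometry.width,
        "thickness_mm": tissue.geometry.thickness,
        "preload_mN": round(dia_force, 6),
        **tr.header(),
    }
    if config.seed is not None:
        header["seed"] = config.seed
    return TraceRecording(time=t, flux=flux, stim_current=stim, tags=tags,
                          header=header)


def length_tension_sweep(tissue: TissueParams, stretches_mm,
                         transducer: SpringTransducer | None = None):
    """Quasi-static stretch sweep of the twin.

    For each drive setting (span offset in mm relative to the slack mount)
    returns (muscle length mm, passive force mN, twitch amplitude mN).
    Used to generate force-length data for :func:`myoslice.biomech.
    length_tension_analysis`.
    """
    if transducer is None:
        transducer = SpringTransducer()
    lt, ref = tissue.length_tension, tissue.geometry.length
    out = []
    for s in np.asarray(stretches_mm, dtype=float):
        span = lt.slack_fraction * ref + s
        state = ChamberState(preload=0.0, total_span=span)
        passive, length = diastolic_operating_point(tissue, state, transducer)
        frac = length / lt.l_max(ref)
        amp = tissue.peak_twitch_force * lt.active_factor(frac)
        out.append((length, passive, amp))
    arr = np.array(out)
    return arr[:, 0], arr[:, 1], arr[:, 2]
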