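"""Trace analysis: twitch events, refractory period, contracture, summaries.

All estimators work on the calibrated force series recovered from a raw
flux trace (see :mod:`myoslice.transduce`), aligned to the stimulation
markers embedded in the recording.  The refractory period is determined
operationally, exactly as on the bench: the longest paired-pulse interval
that fails to induce two distinct contractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import theilslopes

from .stim import PairedPulseProtocol, StimulusSchedule
from .transduce import SpringTransducer, trace_to_force

#: a premature beat counts as a distinct contraction when its upswing
#: reaches this fraction of the preceding regular twitch amplitude
DISTINCT_THETA = 0.10

#: baseline estimation window before each stimulus, s
BASELINE_WINDOW_S = 0.25


@dataclass(frozen=True)
class TwitchEvent:
    stimulus_time: float
    onset: float
    peak_time: float
    peak_force: float
    diastolic_force: float

    @property
    def amplitude(self) -> float:
        return self.peak_force - self.diastolic_force


@dataclass
class RefractoryResult:
    """Outcome of a paired-pulse refractory determination.

    ``classifications`` maps each tested interval (ms) to "one_contraction"
    or "two_contractions"; ``refractory_period`` is the longest failing
    interval; ``precision`` the interval grid spacing at the transition.
    ``censored`` is None, "low" (RP below the protocol floor) or "high"
    (RP at/above the protocol ceiling).
    """

    classifications: dict = field(default_factory=dict)
    refractory_period: float | None = None
    censored: str | None = None
    precision: float = np.nan

    def to_frame(self) -> pd.DataFrame:
        iv = sorted(self.classifications, reverse=True)
        return pd.DataFrame(
            {"interval_ms": iv,
             "classification": [self.classifications[i] for i in iv]}
        )


def _smooth(force: np.ndarray, samples: int = 5) -> np.ndarray:
    """Moving-average smoothing used before peak measurements."""
    if samples <= 1 or force.size < samples:
        return force
    from scipy.ndimage import uniform_filter1d

    return uniform_filter1d(force, samples, mode="nearest")


def _noise_sd(force: np.ndarray) -> float:
    """Robust per-sample noise estimate from first differences."""
    d = np.diff(force)
    if d.size == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2)


def detect_twitches(
    force: np.ndarray,
    time: np.ndarray,
    stim_times,
    *,
    smooth_samples: int = 5,
    min_amplitude: float | None = None,
) -> pd.DataFrame:
    """Stimulus-aligned twitch detection.

    For each stimulus, the diastolic baseline is the median force over the
    250 ms preceding the stimulus and the peak is the maximum of the
    (lightly smoothed) force up to the next stimulus.  Stimuli whose
    amplitude stays below the detection floor (ineffective stimuli,
    unstimulated traces) yield no event.

    Returns a DataFrame with one row per detected twitch.
    """
    stim_times = np.atleast_1d(np.asarray(stim_times, dtype=float))
    cols = ["stimulus_time", "onset", "peak_time", "peak_force",
            "diastolic_force", "amplitude"]
    if stim_times.size == 0:
        return pd.DataFrame(columns=cols)
    fs = 1.0 / float(np.median(np.diff(time)))
    smoothed = _smooth(np.asarray(force, dtype=float), smooth_samples)
    if min_amplitude is None:
        sigma = _noise_sd(force) / np.sqrt(max(smooth_samples, 1))
        min_amplitude = max(6.0 * sigma, 0.02)

    rows = []
    bounds = np.append(stim_times[1:], time[-1] + 1.0 / fs)
    for t_stim, t_next in zip(stim_times, bounds):
        pre = (time >= t_stim - BASELINE_WINDOW_S) & (time < t_stim)
        win = (time >= t_stim) & (time < t_next)
        if not win.any():
            continue
        if pre.any():
            baseline = float(np.median(smoothed[pre]))
        else:
            # stimulus at the very start of the trace: the sample at the
            # stimulus itself still precedes any force development
            baseline = float(np.asarray(force, dtype=float)[win][0])
        seg, seg_t = smoothed[win], time[win]
        i_pk = int(np.argmax(seg))
        amplitude = float(seg[i_pk]) - baseline
        if amplitude < min_amplitude:
            continue
        above = seg[: i_pk + 1] > baseline + 0.05 * amplitude
        onset = float(seg_t[np.argmax(above)]) if above.any() else float(seg_t[0])
        rows.append(
            {"stimulus_time": float(t_stim), "onset": onset,
             "peak_time": float(seg_t[i_pk]), "peak_force": float(seg[i_pk]),
             "diastolic_force": baseline, "amplitude": amplitude}
        )
    return pd.DataFrame(rows, columns=cols)


def classify_pair(
    force: np.ndarray,
    time: np.ndarray,
    regular_time: float,
    extra_time: float,
    reference_amplitude: float,
    *,
    theta: float = DISTINCT_THETA,
    window: float = 0.6,
    smooth_samples: int = 5,
) -> str:
    """Classify a paired stimulus as "two_contractions" or "one_contraction".

    A distinct second contraction is a force upswing after the extra
    stimulus reaching ``theta`` of the preceding regular twitch amplitude;
    the upswing criterion is insensitive to the decaying tail of the first
    twitch the premature beat rides on.
    """
    if extra_time <= regular_time:
        raise ValueError("extra stimulus must follow the regular one")
    smoothed = _smooth(np.asarray(force, dtype=float), smooth_samples)
    at_extra = float(np.interp(extra_time, time, smoothed))
    win = (time > extra_time) & (time <= extra_time + window)
    if not win.any():
        return "one_contraction"
    upswing = float(np.max(smoothed[win])) - at_extra
    return ("two_contractions"
            if upswing >= theta * reference_amplitude else "one_contraction")


def _pair_intervals(regular_times, extra_times):
    """Match each extra stimulus to its preceding regular; yields
    (regular_time, extra_time, interval_ms)."""
    regular_times = np.asarray(regular_times, dtype=float)
    for t_x in np.asarray(extra_times, dtype=float):
        idx = np.searchsorted(regular_times, t_x) - 1
        if idx < 0:
            continue
        t_r = regular_times[idx]
        yield t_r, t_x, (t_x - t_r) * 1e3


def refractory_period(
    trace,
    protocol: PairedPulseProtocol,
    schedule: StimulusSchedule | None = None,
    transducer: SpringTransducer | None = None,
    *,
    theta: float = DISTINCT_THETA,
    precision: float | None = None,
) -> RefractoryResult:
    """Determine the refractory period from a paired-pulse trace.

    Pairs are grouped by interval step; each step is classified by majority
    vote over its pairs.  The refractory period is the longest interval
    whose majority failed to produce two distinct contractions.  A result is
    censored "low" when every interval succeeded (RP below the protocol
    floor) and "high" when none did.
    """
    force = trace_to_force(trace, transducer)
    time = trace.time
    if schedule is not None:
        reg_times = np.array([e.time for e in schedule.regular_events()])
        ext_times = np.array([e.time for e in schedule.extra_events()])
    else:
        reg_times = trace.stim_times("regular")
        ext_times = trace.stim_times("extra")
    if ext_times.size == 0:
        raise ValueError("trace carries no paired-pulse extra stimuli")
    lo = protocol.end_interval - protocol.decrement
    hi = protocol.start_interval + protocol.decrement
    smoothed = _smooth(force, 5)
    votes: dict[float, list[str]] = {}
    for t_r, t_x, iv in _pair_intervals(reg_times, ext_times):
        if not lo - 1e-6 < iv < hi + 1e-6:
            raise ValueError("trace intervals fall outside the protocol range")
        # reference: the regular twitch's own peak before the extra lands
        pre = (time >= t_r - BASELINE_WINDOW_S) & (time < t_r)
        baseline = float(np.median(force[pre])) if pre.any() else float(force[0])
        win = (time >= t_r) & (time < t_x)
        ref_amp = max(float(np.max(smoothed[win])) - baseline, 0.0) if win.any() else 0.0
        cls = classify_pair(force, time, t_r, t_x, ref_amp, theta=theta)
        votes.setdefault(round(iv, 3), []).append(cls)

    classifications = {
        iv: ("one_contraction"
             if sum(c == "one_contraction" for c in cs) * 2 > len(cs)
             else "two_contractions")
        for iv, cs in votes.items()
    }
    failing = [iv for iv, c in classifications.items() if c == "one_contraction"]
    if precision is None:
        precision = protocol.fine_step if protocol.fine_refine else protocol.decrement
    result = RefractoryResult(classifications=classifications, precision=precision)
    if not failing:
        result.censored = "low"
        result.refractory_period = None
    elif all(c == "one_contraction" for c in classifications.values()):
        result.censored = "high"
        result.refractory_period = max(failing)
    else:
        result.refractory_period = max(failing)
    return result


def contracture(
    force: np.ndarray,
    time: np.ndarray,
    window_min: float = 20.0,
    *,
    bin_s: float = 10.0,
) -> float:
    """Spontaneous rise of diastolic tension over `window_min` minutes (mN).

    The diastolic baseline is tracked as the 10th percentile of force in
    ``bin_s`` bins (insensitive to twitches); its robust (Theil-Sen) linear
    trend is evaluated over the window.  Negative drift is reported as is.
    """
    force = np.asarray(force, dtype=float)
    time = np.asarray(time, dtype=float)
    t_end = min(time[0] + window_min * 60.0, time[-1])
    sel = time <= t_end
    t_sel, f_sel = time[sel], force[sel]
    edges = np.arange(t_sel[0], t_sel[-1] + bin_s, bin_s)
    centres, baselines = [], []
    for lo_e, hi_e in zip(edges[:-1], edges[1:]):
        m = (t_sel >= lo_e) & (t_sel < hi_e)
        if m.sum() < 3:
            continue
        centres.append((lo_e + hi_e) / 2)
        baselines.append(np.percentile(f_sel[m], 10))
    if len(centres) < 2:
        return 0.0
    slope = theilslopes(baselines, centres)[0]
    return float(slope * (t_sel[-1] - t_sel[0]))


def longterm_summary(events: pd.DataFrame, exchange_interval_h: float) -> pd.DataFrame:
    """Per-medium-exchange-cycle summary of a twitch event stream.

    Partitions the timeline into cycles of ``exchange_interval_h`` hours and
    reports, per cycle, the amplitude envelope (min/max), mean diastolic
    force, diastolic drift, and the diastolic/systolic force ratio
    (mean diastolic / mean peak).
    """
    if events.empty:
        return pd.DataFrame(columns=["cycle", "t_start_h", "n_twitches",
                                     "amp_min", "amp_max", "diastolic_mean",
                                     "diastolic_drift", "dia_sys_ratio"])
    ev = events.copy()
    ev["cycle"] = np.floor(ev["stimulus_time"] / (exchange_interval_h * 3600.0)).astype(int)
    rows = []
    for cyc, grp in ev.groupby("cycle"):
        rows.append({
            "cycle": cyc,
            "t_start_h": cyc * exchange_interval_h,
            "n_twitches": len(grp),
            "amp_min": grp["amplitude"].min(),
            "amp_max": grp["amplitude"].max(),
            "diastolic_mean": grp["diastolic_force"].mean(),
            "diastolic_drift": grp["diastolic_force"].iloc[-1]
            - grp["diastolic_force"].iloc[0],
            "dia_sys_ratio": grp["diastolic_force"].mean() / grp["peak_force"].mean(),
        })
    return pd.DataFrame(rows)
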