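"""Charge-balanced biphasic stimulation: pulses, pacing and paired-pulse protocols.

Field stimulation uses constant-current bipolar pulses: a charging phase, a
zero-current gap, and a discharging phase of opposite sign.  Equal phase
charge keeps the net electrode charge at zero, which is what lets graphite
electrodes run for months without electrochemistry.  The current source tops
out at 75 mA and 3 ms per phase.

The refractory-period protocol inserts an extra pulse after each regular
pacing pulse, holding each extra-pulse interval for a fixed step duration and
stepping the interval down from 1000 to 250 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MAX_CURRENT_MA = 75.0
MAX_PHASE_MS = 3.0

#: electric field per unit stimulation current, V/mm per mA (midpoint of the
#: 20 mA -> 0.15 V/mm and 50 mA -> 0.4 V/mm anchor ratios)
FIELD_CAL_V_MM_PER_MA = 0.0078


class StimulusLimitError(ValueError):
    """Requested pulse exceeds the current source's 75 mA / 3 ms ceiling."""


@dataclass(frozen=True)
class PulseShape:
    """Bipolar constant-current pulse (amplitudes mA, widths ms)."""

    amplitude: float = 50.0
    charge_width: float = 1.0
    gap: float = 1.0
    discharge_width: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.amplitude <= MAX_CURRENT_MA:
            raise StimulusLimitError(
                f"amplitude {self.amplitude} mA outside (0, {MAX_CURRENT_MA}] mA"
            )
        for name in ("charge_width", "discharge_width"):
            w = getattr(self, name)
            if not 0 < w <= MAX_PHASE_MS:
                raise StimulusLimitError(f"{name} {w} ms outside (0, {MAX_PHASE_MS}] ms")
        if self.gap < 0:
            raise ValueError("gap must be non-negative")

    @property
    def phase_charge_uC(self) -> float:
        """Charge per phase, µC (mA * ms)."""
        return self.amplitude * self.charge_width

    @property
    def net_charge_uC(self) -> float:
        return self.amplitude * self.charge_width - self.amplitude * self.discharge_width

    @property
    def total_width_ms(self) -> float:
        return self.charge_width + self.gap + self.discharge_width

    def waveform(self, sample_rate: float = 100_000.0):
        """Sampled current waveform (t in s, current in mA) incl. trailing zero."""
        dt = 1.0 / sample_rate
        n1 = int(round(self.charge_width * 1e-3 / dt))
        ng = int(round(self.gap * 1e-3 / dt))
        n2 = int(round(self.discharge_width * 1e-3 / dt))
        n = n1 + ng + n2 + 1
        t = np.arange(n) * dt
        i = np.zeros(n)
        i[:n1] = self.amplitude
        # discharge amplitude rescaled so the sampled phases balance exactly
        i[n1 + ng: n1 + ng + n2] = -self.amplitude * n1 / n2
        return t, i


def make_pulse(
    amplitude: float = 50.0,
    charge_width: float = 1.0,
    gap: float = 1.0,
    discharge_width: float | None = None,
) -> PulseShape:
    """Build a charge-balanced pulse; discharge width defaults to charge width.

    When the widths differ, the discharge amplitude is scaled in
    :meth:`PulseShape.waveform` so the phases still balance exactly.
    """
    if discharge_width is None:
        discharge_width = charge_width
    return PulseShape(amplitude, charge_width, gap, discharge_width)


@dataclass(frozen=True)
class StimEvent:
    time: float  #: s
    pulse: PulseShape
    tag: str = "regular"  #: "regular" or "extra"


@dataclass
class StimulusSchedule:
    """Time-ordered stimulation events."""

    events: list = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def times(self):
        return np.array([e.time for e in self.events])

    @property
    def end_time(self) -> float:
        return self.events[-1].time if self.events else 0.0

    def regular_events(self):
        return [e for e in self.events if e.tag == "regular"]

    def extra_events(self):
        return [e for e in self.events if e.tag == "extra"]


@dataclass(frozen=True)
class PairedPulseProtocol:
    """Descending-interval paired-pulse protocol for refractory testing.

    Intervals step from ``start_interval`` down to ``end_interval`` by
    ``decrement`` (ms), each held for ``step_duration`` seconds of pacing.
    ``fine_refine`` requests a follow-up bisection pass to ``fine_step`` ms
    around the coarse transition.
    """

    start_interval: float = 1000.0
    end_interval: float = 250.0
    step_duration: float = 30.0
    decrement: float = 25.0
    fine_refine: bool = False
    fine_step: float = 1.0

    def __post_init__(self) -> None:
        if not self.start_interval > self.end_interval > 0:
            raise ValueError("need start_interval > end_interval > 0")
        if self.decrement <= 0 or self.fine_step <= 0:
            raise ValueError("decrement and fine_step must be positive")
        if self.step_duration <= 0:
            raise ValueError("step_duration must be positive")

    @property
    def intervals_ms(self):
        """Descending interval ladder, start -> end inclusive."""
        iv = np.arange(self.start_interval, self.end_interval - 1e-9, -self.decrement)
        if iv[-1] > self.end_interval + 1e-9:
            iv = np.append(iv, self.end_interval)
        return iv


def pacing_schedule(
    rate: float, duration: float, pulse: PulseShape | None = None, start: float = 0.0
) -> StimulusSchedule:
    """Regular pacing at `rate` Hz for `duration` s; floor(duration*rate) events."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    if pulse is None:
        pulse = make_pulse()
    n = int(np.floor(duration * rate + 1e-9))
    period = 1.0 / rate
    return StimulusSchedule(
        [StimEvent(start + i * period, pulse, "regular") for i in range(n)]
    )


def paired_pulse_schedule(
    protocol: PairedPulseProtocol,
    base_rate: float = 0.2,
    pulse: PulseShape | None = None,
    intervals_ms=None,
) -> StimulusSchedule:
    """Schedule for the paired-pulse protocol at `base_rate` Hz pacing.

    Each interval (ms) in the ladder is held for ``protocol.step_duration``
    seconds; every regular pulse within a step is followed by an extra pulse
    lagging by the step's interval.  ``intervals_ms`` overrides the ladder
    (used by the fine-refinement pass).
    """
    if pulse is None:
        pulse = make_pulse()
    if intervals_ms is None:
        intervals_ms = protocol.intervals_ms
    period = 1.0 / base_rate
    if max(intervals_ms) * 1e-3 >= period:
        raise ValueError("max paired-pulse interval must be below the pacing period")
    events = []
    t0 = 0.0
    for iv in intervals_ms:
        n = int(np.floor(protocol.step_duration * base_rate + 1e-9))
        for i in range(n):
            t = t0 + i * period
            events.append(StimEvent(t, pulse, "regular"))
            events.append(StimEvent(t + iv * 1e-3, pulse, "extra"))
        t0 += n * period
    return StimulusSchedule(events)


def electric_field(amplitude_mA: float) -> float:
    """Electric field strength (V/mm) produced by a given pulse current."""
    if amplitude_mA < 0:
        raise ValueError("amplitude must be non-negative")
    return FIELD_CAL_V_MM_PER_MA * amplitude_mA
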