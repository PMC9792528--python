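"""Pulse-train protocol modelling and dose bookkeeping.

Electroporation generators deliver trains of short high-voltage pulses in
groups (bursts): short intra-group intervals, with long pauses between
groups to limit Joule heating.  The study protocol modelled here delivers
180 pulses as 20 groups of 9 (pulse width 100 us, pulse interval 2 ms, group
interval 2 s); the dose surrogate is the voltage-to-distance ratio in V/cm.

"Pulse interval" is ambiguous on most generators; both readings are exposed
via ``interval_mode``: ``"gap"`` (default) counts it from pulse end to next
onset, ``"onset"`` counts it onset-to-onset.  The group interval is likewise
read as the gap between the end of a group's last pulse and the onset of the
next group's first (``group_interval_mode="gap"``), or onset-to-onset of
group starts (``"onset"``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ProtocolSpec",
    "PulseSchedule",
    "CurrentTrace",
    "build_schedule",
    "nominal_field_strength",
    "delivered_energy",
]


@dataclass(frozen=True)
class ProtocolSpec:
    pulse_width_us: float = 100.0
    intra_group_interval_ms: float = 2.0
    pulses_per_group: int = 9
    group_count: int = 20
    group_interval_s: float = 2.0
    voltage_V: float = 900.0
    electrode_spacing_mm: float = 5.0
    interval_mode: str = "gap"  # "gap" | "onset"
    group_interval_mode: str = "gap"

    def __post_init__(self) -> None:
        if min(self.pulse_width_us, self.intra_group_interval_ms,
               self.group_interval_s, self.electrode_spacing_mm) <= 0:
            raise ValueError("all protocol durations and spacing must be positive")
        if self.pulses_per_group < 1 or self.group_count < 1:
            raise ValueError("pulse and group counts must be at least 1")
        if self.interval_mode not in ("gap", "onset") or self.group_interval_mode not in ("gap", "onset"):
            raise ValueError("interval modes must be 'gap' or 'onset'")
        if self.interval_mode == "onset" and self.intra_group_interval_ms * 1e-3 <= self.pulse_width_us * 1e-6:
            raise ValueError("onset-to-onset interval must exceed the pulse width")

    @property
    def total_pulses(self) -> int:
        return self.pulses_per_group * self.group_count


@dataclass(frozen=True)
class PulseSchedule:
    """Ordered (onset_s, duration_s) pairs; strictly increasing onsets."""

    onsets_s: np.ndarray
    durations_s: np.ndarray
    spec: ProtocolSpec | None = None

    def __post_init__(self) -> None:
        if len(self.onsets_s) != len(self.durations_s):
            raise ValueError("onsets and durations must have equal length")
        if np.any(np.diff(self.onsets_s) <= 0):
            raise ValueError("pulse onsets must be strictly increasing")
        ends = self.onsets_s[:-1] + self.durations_s[:-1]
        if np.any(self.onsets_s[1:] < ends - 1e-15):
            raise ValueError("pulses must not overlap")

    def __len__(self) -> int:
        return len(self.onsets_s)

    @property
    def total_on_time_s(self) -> float:
        return float(np.sum(self.durations_s))

    @property
    def span_s(self) -> float:
        """First onset to last pulse end."""
        return float(self.onsets_s[-1] + self.durations_s[-1] - self.onsets_s[0])


@dataclass(frozen=True)
class CurrentTrace:
    """Per-pulse peak currents in amperes."""

    peak_currents_A: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.peak_currents_A) < 0):
            raise ValueError("currents must be non-negative")

    def __len__(self) -> int:
        return len(self.peak_currents_A)

    @property
    def mean_current_A(self) -> float:
        return float(np.mean(self.peak_currents_A))


def build_schedule(spec: ProtocolSpec) -> PulseSchedule:
    """Realize the grouped protocol as explicit pulse onsets and durations."""
    width = spec.pulse_width_us * 1e-6
    intra = spec.intra_group_interval_ms * 1e-3
    step = intra + width if spec.interval_mode == "gap" else intra
    group_span = (spec.pulses_per_group - 1) * step + width
    if spec.group_interval_mode == "gap":
        group_step = group_span + spec.group_interval_s
    else:
        group_step = spec.group_interval_s
        if group_step <= group_span:
            raise ValueError("onset-to-onset group interval shorter than a group")
    onsets = (
        np.arange(spec.group_count)[:, None] * group_step
        + np.arange(spec.pulses_per_group)[None, :] * step
    ).ravel()
    durations = np.full(spec.total_pulses, width)
    return PulseSchedule(onsets_s=onsets, durations_s=durations, spec=spec)


def nominal_field_strength(voltage_V: float, spacing_mm: float) -> float:
    """Voltage-to-distance ratio in V/cm (the standard IRE dose surrogate)."""
    if spacing_mm <= 0:
        raise ValueError("electrode spacing must be positive")
    return voltage_V / (spacing_mm / 10.0)


def delivered_energy(
    schedule: PulseSchedule, voltage_V: float, trace: CurrentTrace | float
) -> float:
    """Total delivered energy in joules: sum of V * I * duration per pulse.

    ``trace`` may be a per-pulse :class:`CurrentTrace` (length must match the
    schedule) or a single constant current in amperes.
    """
    if isinstance(trace, CurrentTrace):
        currents = np.asarray(trace.peak_currents_A, dtype=float)
        if len(currents) != len(schedule):
            raise ValueError(
                f"trace length {len(currents)} != pulse count {len(schedule)}"
            )
    else:
        currents = np.full(len(schedule), float(trace))
    return float(np.sum(voltage_V * currents * schedule.durations_s))
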