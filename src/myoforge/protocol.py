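"""Programmed electrical stimulation protocols and stimulus schedules.

An ex-vivo myography run delivers bursts ("trains") of electrical pulses to a
mounted muscle strip at a fixed intra-train pulse frequency, with pauses
between trains and between groups of trains.  This module represents the
programmed protocol, derives its implied quantities (intra-train frequency,
pulse totals, run half-time) and realizes train-onset schedules on a time
axis whose origin is the first stimulus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "StimulationProtocol",
    "StimulusSchedule",
    "ViabilityCheck",
    "default_protocol",
    "default_viability_check",
    "intra_train_frequency",
    "pulse_count",
    "half_time",
    "build_schedule",
    "read_protocol",
    "write_protocol",
    "DEFAULT_TRAIN_PERIOD_S",
]

#: Train-onset period (s) chosen so that a 300-s analysis quadrant contains
#: exactly 248 trains.  The programmed train/group arithmetic does not fix a
#: train length, so the period is an explicit parameter of the schedule.
DEFAULT_TRAIN_PERIOD_S = 1.2097

# Serialization keys for the flat key/value protocol config format.
_CONFIG_KEYS = {
    "pulse_voltage_v": "pulse_voltage",
    "pulse_width_ms": "pulse_width",
    "pulse_interval_ms": "pulse_interval",
    "pulse_frequency_hz": "pulse_frequency",
    "train_pause_ms": "train_pause",
    "trains_per_group": "trains_per_group",
    "n_groups": "n_groups",
    "group_pause_ms": "group_pause",
    "total_runtime_min": "total_runtime",
}


@dataclass(frozen=True)
class StimulationProtocol:
    """Parameters of the programmed stimulation (units in field names below).

    Attributes
    ----------
    pulse_voltage : float
        Pulse amplitude in volts.
    pulse_width : float
        Pulse width in milliseconds.
    pulse_interval : float
        Interval between pulses within a train, milliseconds.
    pulse_frequency : float
        Intra-train pulse frequency in hertz, reported to one decimal; must
        equal ``round(1000 / (pulse_width + pulse_interval), 1)``.
    train_pause : float
        Pause between pulse trains, milliseconds.
    trains_per_group : int
        Number of trains per group.
    n_groups : int
        Number of groups in the run.
    group_pause : float
        Pause between groups of trains, milliseconds.
    total_runtime : float
        Total run time in minutes.
    """

    pulse_voltage: float
    pulse_width: float
    pulse_interval: float
    pulse_frequency: float
    train_pause: float
    trains_per_group: int
    n_groups: int
    group_pause: float
    total_runtime: float

    def __post_init__(self) -> None:
        for name in (
            "pulse_voltage", "pulse_width", "pulse_interval", "pulse_frequency",
            "train_pause", "trains_per_group", "n_groups", "group_pause",
            "total_runtime",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        implied = intra_train_frequency(self.pulse_width, self.pulse_interval)
        if abs(self.pulse_frequency - implied) > 0.05 + 1e-12:
            raise ValueError(
                f"pulse_frequency {self.pulse_frequency} Hz inconsistent with "
                f"width+interval (implies {implied} Hz)"
            )


@dataclass(frozen=True)
class StimulusSchedule:
    """Realized train onsets (s), origin at the first stimulus."""

    onsets: np.ndarray
    train_period: float
    duration: float

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        object.__setattr__(self, "onsets", onsets)
        if onsets.size == 0:
            raise ValueError("schedule must contain at least one onset")
        if onsets[0] != 0.0:
            raise ValueError("first onset must be at t=0")
        if np.any(np.diff(onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if onsets[-1] >= self.duration:
            raise ValueError("all onsets must precede the schedule duration")

    def __len__(self) -> int:
        return int(self.onsets.size)


@dataclass(frozen=True)
class ViabilityCheck:
    """Pre-run viability stimulation: a few biphasic test stimuli.

    The tissue passes the check when every test stimulus elicits at least one
    contraction peak.
    """

    n_stimuli: int = 3
    waveform: str = "biphasic"
    force_setting: float = 10.0   # mN
    voltage: float = 20.0         # V
    pulse_width: float = 25.0     # ms
    run_time: float = 120.0       # s, approximate check window

    def __post_init__(self) -> None:
        if self.n_stimuli <= 0:
            raise ValueError("n_stimuli must be positive")
        if self.force_setting <= 0:
            raise ValueError("force_setting must be positive")


def default_protocol() -> StimulationProtocol:
    """The programmed protocol used throughout: 20 V pulses of 25 ms at 60 ms
    intervals (11.8 Hz intra-train), 500 ms train pause, 500 trains per group,
    10 groups with 60 s group pauses, 45 min total run time."""
    return StimulationProtocol(
        pulse_voltage=20.0,
        pulse_width=25.0,
        pulse_interval=60.0,
        pulse_frequency=11.8,
        train_pause=500.0,
        trains_per_group=500,
        n_groups=10,
        group_pause=60000.0,
        total_runtime=45.0,
    )


def default_viability_check() -> ViabilityCheck:
    return ViabilityCheck()


def intra_train_frequency(pulse_width: float, pulse_interval: float) -> float:
    """Intra-train pulse frequency in Hz, one decimal.

    One pulse period is ``pulse_width + pulse_interval`` milliseconds, so the
    frequency is ``1000 / (width + interval)`` Hz; 25 ms + 60 ms gives 11.8 Hz.
    """
    period = pulse_width + pulse_interval
    if period <= 0:
        raise ValueError("pulse_width + pulse_interval must be positive")
    return round(1000.0 / period, 1)


def pulse_count(duration_s: float, stimuli_per_second: float = 2.0) -> int:
    """Total stimulus pulses over an analysis window: rate × duration, floored.

    The equipment delivers 2 stimuli per second by default.
    """
    if duration_s < 0:
        raise ValueError("duration must be non-negative")
    return int(math.floor(stimuli_per_second * duration_s + 1e-9))


def half_time(protocol: StimulationProtocol) -> float:
    """Half of the total run time, in minutes (fatigue assessment point)."""
    if protocol.total_runtime <= 0:
        raise ValueError("total_runtime must be positive")
    return protocol.total_runtime / 2.0


def build_schedule(
    train_period: float,
    duration: float,
    *,
    trains_per_group: int | None = None,
    group_pause: float | None = None,
) -> StimulusSchedule:
    """Train onsets ``{k·train_period : k·train_period < duration}``.

    By default the sequence is continuous.  Passing both ``trains_per_group``
    and ``group_pause`` (seconds) inserts an extra pause after every
    ``trains_per_group`` onsets (grouped mode).
    """
    if train_period <= 0 or duration <= 0:
        raise ValueError("train_period and duration must be positive")
    if (trains_per_group is None) != (group_pause is None):
        raise ValueError("grouped mode needs both trains_per_group and group_pause")

    if trains_per_group is None:
        n = int(math.ceil(duration / train_period - 1e-12))
        onsets = np.arange(n, dtype=float) * train_period
        onsets = onsets[onsets < duration - 1e-12 * max(1.0, duration)]
    else:
        if trains_per_group <= 0 or group_pause < 0:
            raise ValueError("invalid grouped-mode parameters")
        out: list[float] = []
        t = 0.0
        k_in_group = 0
        while t < duration - 1e-12:
            out.append(t)
            k_in_group += 1
            t += train_period
            if k_in_group == trains_per_group:
                t += group_pause
                k_in_group = 0
        onsets = np.asarray(out, dtype=float)
    return StimulusSchedule(onsets=onsets, train_period=train_period, duration=duration)


def write_protocol(protocol: StimulationProtocol, path: str | Path) -> None:
    """Serialize a protocol to a flat ``key=value`` config file."""
    lines = []
    for key, attr in _CONFIG_KEYS.items():
        value = getattr(protocol, attr)
        lines.append(f"{key}={value!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_protocol(path: str | Path) -> StimulationProtocol:
    """Read a protocol from a flat ``key=value`` config file.

    Missing keys fall back to the default protocol's values.
    """
    defaults = asdict(default_protocol())
    values = dict(defaults)
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"malformed protocol line: {raw!r}")
        key, _, val = line.partition("=")
        key = key.strip()
        if key not in _CONFIG_KEYS:
            raise ValueError(f"unknown protocol key: {key}")
        attr = _CONFIG_KEYS[key]
        caster = int if attr in ("trains_per_group", "n_groups") else float
        values[attr] = caster(float(val.strip()))
    return StimulationProtocol(**values)
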