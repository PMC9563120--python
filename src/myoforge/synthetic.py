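"""Synthetic isometric twitch-force traces.

No recordings from the original myograph runs are publicly deposited, so this
module generates force traces with the statistical structure the analysis
stage assumes: one twitch pair per stimulus train (a tall "major" contraction
followed by a shorter companion), two amplitude patterns observed in tissue
(strictly alternating high/low peaks vs. uniformly high peaks), an optional
fatigue envelope that attenuates amplitudes over the run, baseline drift,
additive Gaussian measurement noise, and a flat sham trace from inert
material.

The twitch waveform is a normalized difference of exponentials

    f(t) = A · c · (exp(-t/tau_decay) - exp(-t/tau_rise)),  t >= 0,

with ``c`` chosen so the maximum equals the amplitude ``A``.  The peak occurs
at ``t* = tau_d·tau_r/(tau_d - tau_r) · ln(tau_d/tau_r)``.  This is minimal
twitch phenomenology, not a cross-bridge or Hill-type muscle model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

from .protocol import StimulusSchedule

__all__ = [
    "TwitchKernel",
    "TraceModel",
    "ForceTrace",
    "twitch",
    "twitch_peak_time",
    "simulate_trace",
    "simulate_sham",
]


@dataclass(frozen=True)
class TwitchKernel:
    """Shape of a single twitch: fast rise, slow decay, peak = amplitude."""

    rise_tau: float = 0.02    # s
    decay_tau: float = 0.12   # s
    amplitude: float = 1.0    # mN

    def __post_init__(self) -> None:
        if not (self.decay_tau > self.rise_tau > 0):
            raise ValueError("require decay_tau > rise_tau > 0")


@dataclass(frozen=True)
class TraceModel:
    """Statistical description of one experimental trace.

    Parameters
    ----------
    pattern : {"alternating", "high_only"}
        Alternating traces pair each major twitch with a clearly smaller
        companion (``minor_ratio`` well below 1); high-only traces have a
        companion nearly as tall as the major.
    major_amp_mean, major_amp_sd : float
        Mean and SD (mN) of the per-train major amplitude, drawn from a
        normal distribution truncated at ``amp_floor`` (default zero) to
        keep forces physical.
    amp_floor : float
        Lower truncation bound (mN) of the amplitude distribution.  A value
        above zero models a preparation whose every stimulus elicits at
        least a minimal measurable contraction, as in fully responsive
        tissue with a large amplitude spread.
    minor_ratio : float
        Companion amplitude as a fraction of the major amplitude.
    intra_pair_delay : float
        Delay (s) from the major twitch onset to its companion; defaults to
        the 500 ms train pause, the only within-train time constant stated
        by the protocol.
    fatigue : {"none", "exponential", "linear"}
        Amplitude-envelope model; ``fatigue_rate`` is per-second for the
        exponential envelope exp(-rate·t) and a fraction/s for the linear
        envelope max(0, 1 - rate·t).
    drift_slope : float
        Baseline drift in mN/s (a rising trend signals viability loss).
    noise_sd : float
        SD of additive Gaussian measurement noise, mN.
    seed : int
        RNG seed; recorded in trace metadata for reproducibility.
    """

    pattern: Literal["alternating", "high_only"] = "alternating"
    major_amp_mean: float = 8.50
    major_amp_sd: float = 0.67
    amp_floor: float = 0.0
    minor_ratio: float | None = None
    intra_pair_delay: float = 0.5
    fatigue: Literal["none", "exponential", "linear"] = "none"
    fatigue_rate: float = 0.0
    drift_slope: float = 0.0
    noise_sd: float = 0.05
    seed: int = 0
    kernel: TwitchKernel = field(default_factory=TwitchKernel)

    def __post_init__(self) -> None:
        if self.pattern not in ("alternating", "high_only"):
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.minor_ratio is None:
            ratio = 0.5 if self.pattern == "alternating" else 0.9
            object.__setattr__(self, "minor_ratio", ratio)
        if not (0 < self.minor_ratio <= 1):
            raise ValueError("minor_ratio must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.amp_floor < 0:
            raise ValueError("amp_floor must be non-negative")
        if self.fatigue not in ("none", "exponential", "linear"):
            raise ValueError(f"unknown fatigue model {self.fatigue!r}")


@dataclass
class ForceTrace:
    """Uniformly sampled force-vs-time recording with metadata."""

    time: np.ndarray          # s, uniform grid from 0
    force: np.ndarray         # mN
    sampling_rate: float      # Hz
    group: str = "experimental"
    sample_id: str = "sample"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.time.shape != self.force.shape:
            raise ValueError("time and force must have equal length")
        if self.time.size == 0:
            raise ValueError("trace must contain at least one sample")

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


def twitch_peak_time(kernel: TwitchKernel) -> float:
    """Time of the kernel maximum: (τd·τr/(τd−τr))·ln(τd/τr)."""
    td, tr = kernel.decay_tau, kernel.rise_tau
    return td * tr / (td - tr) * math.log(td / tr)


def _kernel_norm(kernel: TwitchKernel) -> float:
    t_star = twitch_peak_time(kernel)
    raw = math.exp(-t_star / kernel.decay_tau) - math.exp(-t_star / kernel.rise_tau)
    return 1.0 / raw


def twitch(kernel: TwitchKernel, t: np.ndarray | float) -> np.ndarray | float:
    """Evaluate the twitch waveform at time(s) ``t`` (s) since twitch onset.

    Zero for t < 0; maximum equals ``kernel.amplitude``.
    """
    t_arr = np.asarray(t, dtype=float)
    c = _kernel_norm(kernel)
    out = np.where(
        t_arr >= 0,
        kernel.amplitude
        * c
        * (np.exp(-np.clip(t_arr, 0, None) / kernel.decay_tau)
           - np.exp(-np.clip(t_arr, 0, None) / kernel.rise_tau)),
        0.0,
    )
    return out if isinstance(t, np.ndarray) else float(out)


def _envelope(model: TraceModel, t: np.ndarray) -> np.ndarray:
    if model.fatigue == "none":
        return np.ones_like(t)
    if model.fatigue == "exponential":
        return np.exp(-model.fatigue_rate * t)
    return np.maximum(0.0, 1.0 - model.fatigue_rate * t)


def _draw_amplitudes(model: TraceModel, n: int, rng: np.random.Generator) -> np.ndarray:
    mean, sd = model.major_amp_mean, model.major_amp_sd
    if sd == 0:
        return np.full(n, mean)
    a = (model.amp_floor - mean) / sd  # truncated: forces are physical
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def simulate_trace(
    schedule: StimulusSchedule,
    model: TraceModel,
    sampling_rate: float = 100.0,
) -> ForceTrace:
    """Render a force trace for a stimulus schedule.

    Each train onset contributes a major twitch at the onset and a companion
    twitch ``intra_pair_delay`` later with amplitude ``major × minor_ratio``.
    Major amplitudes are drawn i.i.d. from the truncated normal, multiplied by
    the fatigue envelope evaluated at the onset time; baseline drift and
    Gaussian noise are added last.  Fully reproducible from ``model.seed``.
    """
    if len(schedule) == 0:
        raise ValueError("schedule must be non-empty")
    if sampling_rate < 10.0 / model.intra_pair_delay:
        raise ValueError(
            f"sampling_rate {sampling_rate} Hz too coarse to resolve the twitch "
            f"pair (need >= {10.0 / model.intra_pair_delay} Hz)"
        )

    rng = np.random.default_rng(model.seed)
    onsets = schedule.onsets
    # Extend past the last companion twitch so its decay is recorded.
    t_end = max(schedule.duration,
                onsets[-1] + model.intra_pair_delay + 8 * model.kernel.decay_tau)
    n_samples = int(round(t_end * sampling_rate)) + 1
    time = np.arange(n_samples) / sampling_rate
    force = np.zeros(n_samples)

    majors = _draw_amplitudes(model, len(onsets), rng)
    majors = majors * _envelope(model, onsets)
    minors = majors * model.minor_ratio

    kernel = model.kernel
    support = int(math.ceil((twitch_peak_time(kernel) + 10 * kernel.decay_tau)
                            * sampling_rate))
    base = twitch(TwitchKernel(kernel.rise_tau, kernel.decay_tau, 1.0),
                  np.arange(support + 1) / sampling_rate)
    for onset, amp_major, amp_minor in zip(onsets, majors, minors):
        for start, amp in ((onset, amp_major),
                           (onset + model.intra_pair_delay, amp_minor)):
            i0 = int(round(start * sampling_rate))
            frac = start - i0 / sampling_rate
            if abs(frac) > 1e-9:  # off-grid onset: evaluate kernel exactly
                seg_t = time[i0:i0 + support + 1] - start
                seg = np.where(seg_t >= 0, amp * np.asarray(
                    twitch(TwitchKernel(kernel.rise_tau, kernel.decay_tau, 1.0),
                           np.clip(seg_t, 0, None))), 0.0)
            else:
                seg = amp * base[: n_samples - i0]
            force[i0:i0 + seg.shape[0]] += seg[: n_samples - i0]

    force += model.drift_slope * time
    if model.noise_sd > 0:
        force += rng.normal(0.0, model.noise_sd, size=n_samples)

    meta = {
        "pattern": model.pattern,
        "major_amp_mean": model.major_amp_mean,
        "major_amp_sd": model.major_amp_sd,
        "amp_floor": model.amp_floor,
        "minor_ratio": model.minor_ratio,
        "intra_pair_delay": model.intra_pair_delay,
        "fatigue": model.fatigue,
        "fatigue_rate": model.fatigue_rate,
        "drift_slope": model.drift_slope,
        "noise_sd": model.noise_sd,
        "seed": model.seed,
        "train_period_s": schedule.train_period,
        "schedule_duration_s": schedule.duration,
    }
    return ForceTrace(time=time, force=force, sampling_rate=sampling_rate,
                      group="experimental", metadata=meta)


def simulate_sham(duration: float, noise_sd: float = 0.05, seed: int = 0,
                  sampling_rate: float = 100.0) -> ForceTrace:
    """A sham trace (inert elastic ribbon): zero baseline plus noise only."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration * sampling_rate)) + 1
    time = np.arange(n_samples) / sampling_rate
    force = (rng.normal(0.0, noise_sd, size=n_samples) if noise_sd > 0
             else np.zeros(n_samples))
    meta = {"noise_sd": noise_sd, "seed": seed}
    return ForceTrace(time=time, force=force, sampling_rate=sampling_rate,
                      group="sham", sample_id="sham", metadata=meta)
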