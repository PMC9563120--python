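"""Contraction-trace analysis: peak detection and classification, per-quadrant
frequency, response rate, force statistics, fatigue at half-time, viability.

The procedures mirror how myograph chart recordings are read out by hand:

* every local force maximum above a noise-scaled threshold is a contraction
  peak; within each stimulus-train window the tallest peak is the *major*
  contraction and the second tallest the *minor* companion;
* counts are reported per 5-minute "quadrant" window;
* the response rate is the percentage of programmed trains that elicited at
  least one peak;
* fatigue is the fractional drop of mean major-peak force from the start of
  stimulation to half of the run time;
* a rising trend of the inter-peak trough envelope flags viability loss.

`MyographyModel` wraps these steps in a fit/results interface: construct the
model from a trace (plus its stimulus schedule), call :meth:`fit`, and read
estimates, uncertainties and diagnostics off the returned
:class:`MyographyResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal, stats

from .protocol import StimulusSchedule, ViabilityCheck, build_schedule
from .synthetic import ForceTrace

__all__ = [
    "Peak",
    "QuadrantStats",
    "FatigueResult",
    "estimate_noise_sd",
    "detect_peaks",
    "quadrant_frequency",
    "response_rate",
    "peak_stats",
    "time_to_peak",
    "fatigue_analysis",
    "fit_fatigue_rate",
    "viability_trend",
    "viability_precheck",
    "extract_datapad",
    "MyographyModel",
    "MyographyResults",
]

DEFAULT_QUADRANT_S = 300.0
#: Peak threshold in units of the estimated noise SD.  Chosen so that a
#: 45-minute pure-noise (sham) trace at 100 Hz has an expected spurious-peak
#: count well below one.
NOISE_THRESHOLD_MULTIPLE = 5.0


class InsufficientDataError(ValueError):
    """Raised when a window required by an estimator contains no peaks."""


@dataclass(frozen=True)
class Peak:
    """One detected contraction event."""

    time: float          # s
    height: float        # mN above baseline
    kind: str            # "major" or "minor"
    train_index: int     # index of the assigned (nearest preceding) onset


@dataclass(frozen=True)
class QuadrantStats:
    """Major/minor peak counts in a half-open window [start, end)."""

    window_start: float
    window_end: float
    n_major: int
    n_minor: int


@dataclass(frozen=True)
class FatigueResult:
    """Force decline from the start of stimulation to the run half-time."""

    initial_force: float     # mN, mean major height in the initial window
    half_time_force: float   # mN, mean major height around half-time
    fatigue_percent: float   # 100·(initial − half_time)/initial
    half_time: float         # min


def estimate_noise_sd(force: np.ndarray) -> float:
    """Robust noise SD from first differences of the trace.

    Twitches occupy a large fraction of samples, so a trace-level spread
    statistic is contaminated by signal; differencing suppresses the smooth
    twitch component and ``1.4826·MAD(diff)/sqrt(2)`` estimates the white
    noise SD.
    """
    d = np.diff(np.asarray(force, dtype=float))
    if d.size == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / math.sqrt(2.0)


def _relaxed_baseline(trace: ForceTrace, schedule: StimulusSchedule,
                      window: float = 0.1) -> float:
    """Median force over the ``window`` seconds preceding each train onset.

    Just before an onset the preparation is maximally relaxed (the previous
    twitch pair has decayed), so these samples estimate the resting force
    level without contamination by intra-train troughs.  Falls back to a low
    percentile of the whole trace when no pre-onset samples exist (e.g. a
    single onset at t = 0).
    """
    fs = trace.sampling_rate
    force = trace.force
    chunks = []
    for onset in schedule.onsets:
        i1 = int(round(onset * fs))
        i0 = max(0, i1 - int(round(window * fs)))
        if i1 > i0 and i1 <= force.size:
            chunks.append(force[i0:i1])
    if not chunks:
        return float(np.percentile(force, 25))
    return float(np.median(np.concatenate(chunks)))


def _refine_peak(time: np.ndarray, y: np.ndarray, idx: int) -> tuple[float, float]:
    """Parabolic 3-point refinement of a grid local maximum."""
    if idx <= 0 or idx >= y.size - 1:
        return float(time[idx]), float(y[idx])
    y0, y1, y2 = y[idx - 1], y[idx], y[idx + 1]
    denom = y0 - 2 * y1 + y2
    if denom >= 0:  # not concave at machine precision; keep grid value
        return float(time[idx]), float(y[idx])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    dt = float(time[idx + 1] - time[idx])
    height = y1 - 0.25 * (y0 - y2) * delta
    return float(time[idx] + delta * dt), float(height)


def detect_peaks(
    trace: ForceTrace,
    schedule: StimulusSchedule,
    min_height: float | None = None,
    min_separation: float | None = None,
    intra_pair_delay: float = 0.5,
) -> list[Peak]:
    """Detect contraction peaks and classify them major/minor per train.

    Parameters
    ----------
    min_height : float, optional
        Minimum baseline-corrected height (mN).  Defaults to
        ``NOISE_THRESHOLD_MULTIPLE`` times the estimated noise SD.
    min_separation : float, optional
        Minimum time between peaks (s); defaults to ``0.4·intra_pair_delay``.

    Within each train window ``[onset_k, onset_{k+1})`` the tallest surviving
    peak is labelled major and the second tallest minor; any further peaks in
    the window are discarded as spurious.  Peaks preceding the first onset
    are dropped.  The baseline — the relaxed force level, estimated as the
    median of samples just before each train onset — is subtracted before
    height measurement, so detection is invariant to a constant offset.
    """
    if trace.time.size == 0:
        raise ValueError("empty trace")
    if min_separation is None:
        min_separation = 0.4 * intra_pair_delay
    force = trace.force
    fs = trace.sampling_rate

    distance = max(1, int(round(min_separation * fs)))
    idx, _ = signal.find_peaks(force, distance=distance)
    if idx.size == 0:
        return []

    baseline = _relaxed_baseline(trace, schedule)

    if min_height is None:
        sd = estimate_noise_sd(force)
        min_height = NOISE_THRESHOLD_MULTIPLE * sd if sd > 0 else 1e-12
    if min_height <= 0:
        raise ValueError("min_height must be positive")

    onsets = schedule.onsets
    candidates: dict[int, list[tuple[float, float]]] = {}
    for i in idx:
        t_ref, h_ref = _refine_peak(trace.time, force, int(i))
        height = h_ref - baseline
        if height < min_height:
            continue
        k = int(np.searchsorted(onsets, t_ref + 1e-12, side="right")) - 1
        if k < 0:
            continue  # before the first programmed stimulus
        candidates.setdefault(k, []).append((t_ref, height))

    peaks: list[Peak] = []
    for k in sorted(candidates):
        ranked = sorted(candidates[k], key=lambda th: -th[1])
        peaks.append(Peak(time=ranked[0][0], height=ranked[0][1],
                          kind="major", train_index=k))
        if len(ranked) > 1:
            peaks.append(Peak(time=ranked[1][0], height=ranked[1][1],
                              kind="minor", train_index=k))
    peaks.sort(key=lambda p: p.time)
    return peaks


def quadrant_frequency(
    peaks: list[Peak],
    window: float = DEFAULT_QUADRANT_S,
    start: float = 0.0,
) -> QuadrantStats:
    """Count major/minor peaks in the half-open window [start, start+window)."""
    if window <= 0:
        raise ValueError("window must be positive")
    end = start + window
    n_major = sum(1 for p in peaks if p.kind == "major" and start <= p.time < end)
    n_minor = sum(1 for p in peaks if p.kind == "minor" and start <= p.time < end)
    return QuadrantStats(window_start=start, window_end=end,
                         n_major=n_major, n_minor=n_minor)


def response_rate(n_responding_trains: int, n_programmed_trains: int) -> float:
    """Percentage of programmed trains that elicited ≥1 peak, 1 decimal."""
    if n_programmed_trains <= 0:
        raise ValueError("n_programmed_trains must be positive")
    return round(100.0 * n_responding_trains / n_programmed_trains, 1)


def peak_stats(peaks: list[Peak], kind: str | None = "major") -> tuple[float, float, float]:
    """(mean, SD, median) of peak heights, mN; SD uses the n−1 denominator."""
    heights = np.array([p.height for p in peaks if kind is None or p.kind == kind])
    if heights.size == 0:
        raise InsufficientDataError("no peaks after filtering")
    sd = float(np.std(heights, ddof=1)) if heights.size > 1 else 0.0
    return float(np.mean(heights)), sd, float(np.median(heights))


def time_to_peak(schedule: StimulusSchedule, peak: Peak) -> float:
    """Latency (s) from the peak's assigned train onset to the peak."""
    if peak.train_index < 0 or peak.train_index >= len(schedule):
        raise ValueError("peak is not assigned to a train of this schedule")
    onset = float(schedule.onsets[peak.train_index])
    if peak.time < onset - 1e-9:
        raise ValueError("peak precedes its assigned onset")
    return peak.time - onset


def fatigue_analysis(
    peaks: list[Peak],
    total_runtime_min: float,
    window_half_width: float = 30.0,
) -> FatigueResult:
    """Force decline at half of the run time.

    ``initial_force`` is the mean major height over the first
    ``2·window_half_width`` seconds of stimulation; ``half_time_force`` the
    mean major height within ±``window_half_width`` of half the run time.
    """
    half_t_s = total_runtime_min * 60.0 / 2.0
    majors = [(p.time, p.height) for p in peaks if p.kind == "major"]
    init = [h for t, h in majors if t < 2 * window_half_width]
    half = [h for t, h in majors if abs(t - half_t_s) <= window_half_width]
    if not init or not half:
        raise InsufficientDataError(
            "need major peaks in both the initial and half-time windows")
    initial_force = float(np.mean(init))
    half_time_force = float(np.mean(half))
    fatigue_percent = 100.0 * (initial_force - half_time_force) / initial_force
    return FatigueResult(initial_force=initial_force,
                         half_time_force=half_time_force,
                         fatigue_percent=fatigue_percent,
                         half_time=total_runtime_min / 2.0)


def fit_fatigue_rate(peaks: list[Peak]) -> tuple[float, float]:
    """Exponential fatigue rate (1/s) from major-peak heights.

    Fits log(height) = a − rate·t by least squares; returns (rate, SE).
    """
    pts = [(p.time, p.height) for p in peaks if p.kind == "major" and p.height > 0]
    if len(pts) < 3:
        raise InsufficientDataError("need ≥3 positive major peaks")
    t = np.array([x for x, _ in pts])
    y = np.log(np.array([h for _, h in pts]))
    res = stats.linregress(t, y)
    return -float(res.slope), float(res.stderr)


def viability_trend(trace: ForceTrace, threshold: float = 0.001) -> tuple[float, bool]:
    """Least-squares slope (mN/s) of the inter-peak trough envelope.

    A rising trough envelope (slope above ``threshold``) indicates the
    preparation is losing sustained contractility (incomplete relaxation /
    baseline creep).
    """
    if trace.duration < 60.0:
        raise ValueError("trace must cover at least 60 s")
    force = trace.force
    distance = max(1, int(round(0.2 * trace.sampling_rate)))
    idx, _ = signal.find_peaks(force, distance=distance,
                               prominence=5 * estimate_noise_sd(force) + 1e-12)
    if idx.size >= 3:
        trough_t, trough_v = [], []
        for a, b in zip(idx[:-1], idx[1:]):
            j = int(a + np.argmin(force[a:b + 1]))
            trough_t.append(trace.time[j])
            trough_v.append(force[j])
        t = np.array(trough_t)
        v = np.array(trough_v)
    else:  # flat/sham trace: regress the raw signal
        t, v = trace.time, force
    if np.ptp(t) == 0:
        return 0.0, False
    res = stats.linregress(t, v)
    slope = float(res.slope)
    return slope, bool(slope > threshold)


def viability_precheck(
    trace: ForceTrace,
    check: ViabilityCheck | None = None,
    stimulus_onsets: np.ndarray | None = None,
) -> bool:
    """True iff every pre-run test stimulus elicited at least one peak.

    ``stimulus_onsets`` defaults to ``check.n_stimuli`` stimuli evenly spaced
    over the check window.
    """
    check = check or ViabilityCheck()
    if trace.duration < check.run_time - 1e-9:
        raise ValueError("trace shorter than the viability check window")
    if stimulus_onsets is None:
        stimulus_onsets = np.arange(check.n_stimuli) * (check.run_time
                                                        / check.n_stimuli)
    sched = StimulusSchedule(onsets=np.asarray(stimulus_onsets, dtype=float),
                             train_period=float(check.run_time / check.n_stimuli),
                             duration=float(max(trace.duration,
                                                check.run_time) + 1e-9))
    peaks = detect_peaks(trace, sched)
    responding = {p.train_index for p in peaks}
    return len(responding) == check.n_stimuli


def extract_datapad(
    peaks: list[Peak],
    initial_force: float,
    fraction: float = 0.5,
) -> pd.DataFrame:
    """Table of all peaks plus the first time the major force falls low.

    Returns a DataFrame with columns ``time_s``, ``height_mN``, ``kind`` and a
    boolean ``below_fraction`` marking rows from the earliest major peak whose
    height drops below ``fraction × initial_force`` onward; the attribute
    ``df.attrs["crossing_time_s"]`` holds that time (None if never reached).
    """
    if initial_force <= 0:
        raise ValueError("initial_force must be positive")
    df = pd.DataFrame(
        [(p.time, p.height, p.kind) for p in sorted(peaks, key=lambda p: p.time)],
        columns=["time_s", "height_mN", "kind"],
    )
    crossing = None
    for p in sorted(peaks, key=lambda p: p.time):
        if p.kind == "major" and p.height < fraction * initial_force:
            crossing = p.time
            break
    df["below_fraction"] = (df["time_s"] >= crossing) & (df["kind"] == "major") \
        if crossing is not None else False
    df.attrs["crossing_time_s"] = crossing
    return df


# ---------------------------------------------------------------------------
# Model / Results interface
# ---------------------------------------------------------------------------

class MyographyModel:
    """Analysis model for one force trace under a known stimulus schedule.

    Parameters
    ----------
    trace : ForceTrace
        The recording to analyse.
    schedule : StimulusSchedule, optional
        Programmed train onsets.  If omitted, a continuous schedule is built
        from the trace metadata (``train_period_s``/``schedule_duration_s``)
        or from the default train period over the trace duration.
    quadrant_start, quadrant_window : float
        The analysis quadrant, default the first 5 minutes.
    min_height, min_separation : float, optional
        Peak-detection overrides; see :func:`detect_peaks`.
    total_runtime_min : float, optional
        Run length for the fatigue half-time; defaults to the schedule
        duration.
    """

    def __init__(
        self,
        trace: ForceTrace,
        schedule: StimulusSchedule | None = None,
        *,
        quadrant_start: float = 0.0,
        quadrant_window: float = DEFAULT_QUADRANT_S,
        min_height: float | None = None,
        min_separation: float | None = None,
        total_runtime_min: float | None = None,
    ) -> None:
        from .protocol import DEFAULT_TRAIN_PERIOD_S

        self.trace = trace
        if schedule is None:
            period = float(trace.metadata.get("train_period_s",
                                              DEFAULT_TRAIN_PERIOD_S))
            duration = float(trace.metadata.get("schedule_duration_s",
                                                trace.duration))
            schedule = build_schedule(period, duration)
        self.schedule = schedule
        self.quadrant_start = quadrant_start
        self.quadrant_window = quadrant_window
        self.min_height = min_height
        self.min_separation = min_separation
        self.total_runtime_min = (total_runtime_min if total_runtime_min is not None
                                  else schedule.duration / 60.0)

    @classmethod
    def from_file(cls, path: str | Path, **kwargs) -> "MyographyModel":
        from .trace_io import read_trace
        return cls(read_trace(path), **kwargs)

    def fit(self) -> "MyographyResults":
        """Run detection, counting and the force/fatigue/viability estimators."""
        trace, sched = self.trace, self.schedule
        peaks = detect_peaks(trace, sched, min_height=self.min_height,
                             min_separation=self.min_separation)
        quadrant = quadrant_frequency(peaks, window=self.quadrant_window,
                                      start=self.quadrant_start)

        q_end = self.quadrant_start + self.quadrant_window
        programmed = int(np.sum((sched.onsets >= self.quadrant_start)
                                & (sched.onsets < q_end)))
        in_window = [p for p in peaks
                     if self.quadrant_start <= p.time < q_end]
        responding = len({p.train_index for p in in_window})
        rate = response_rate(responding, programmed) if programmed else float("nan")

        try:
            force_mean, force_sd, force_median = peak_stats(in_window, "major")
            n_major_all = sum(1 for p in in_window if p.kind == "major")
            force_sem = force_sd / math.sqrt(n_major_all) if n_major_all else float("nan")
        except InsufficientDataError:
            force_mean = force_sd = force_median = force_sem = float("nan")

        try:
            fatigue = fatigue_analysis(peaks, self.total_runtime_min)
        except InsufficientDataError:
            fatigue = None

        slope, flagged = viability_trend(trace) if trace.duration >= 60 \
            else (float("nan"), False)

        return MyographyResults(
            model=self,
            peaks=peaks,
            quadrant=quadrant,
            n_programmed_trains=programmed,
            n_responding_trains=responding,
            response_rate_pct=rate,
            force_mean=force_mean,
            force_sd=force_sd,
            force_sem=force_sem,
            force_median=force_median,
            fatigue=fatigue,
            viability_slope=slope,
            viability_flag=flagged,
        )


@dataclass
class MyographyResults:
    """Estimates and diagnostics from :meth:`MyographyModel.fit`."""

    model: MyographyModel
    peaks: list[Peak]
    quadrant: QuadrantStats
    n_programmed_trains: int
    n_responding_trains: int
    response_rate_pct: float
    force_mean: float          # mN, major peaks in the quadrant
    force_sd: float
    force_sem: float
    force_median: float
    fatigue: FatigueResult | None
    viability_slope: float     # mN/s trough-envelope trend
    viability_flag: bool

    @property
    def peaks_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(p.time, p.height, p.kind, p.train_index) for p in self.peaks],
            columns=["time_s", "height_mN", "kind", "train_index"],
        )

    def datapad(self, fraction: float = 0.5) -> pd.DataFrame:
        initial = self.fatigue.initial_force if self.fatigue else self.force_mean
        return extract_datapad(self.peaks, initial, fraction=fraction)

    def summary(self) -> str:
        """Readable per-trace summary table."""
        t = self.model.trace
        lines = [
            "Myography trace analysis",
            "=" * 44,
            f"sample_id            {t.sample_id}",
            f"group                {t.group}",
            f"duration             {t.duration:.1f} s",
            f"quadrant             [{self.quadrant.window_start:.0f}, "
            f"{self.quadrant.window_end:.0f}) s",
            f"major peaks          {self.quadrant.n_major}",
            f"minor peaks          {self.quadrant.n_minor}",
            f"programmed trains    {self.n_programmed_trains}",
            f"response rate        {self.response_rate_pct:.1f} %",
            f"force mean (major)   {self.force_mean:.2f} mN "
            f"(SD {self.force_sd:.2f}, SEM {self.force_sem:.3f})",
            f"force median         {self.force_median:.2f} mN",
        ]
        if self.fatigue is not None:
            f = self.fatigue
            lines += [
                f"initial force        {f.initial_force:.2f} mN",
                f"half-time force      {f.half_time_force:.2f} mN "
                f"(at {f.half_time:.1f} min)",
                f"fatigue              {f.fatigue_percent:.1f} %",
            ]
        lines.append(
            f"viability trend      {self.viability_slope:.5f} mN/s"
            f"{'  ** flagged **' if self.viability_flag else ''}")
        return "\n".join(lines)
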