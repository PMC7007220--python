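"""Whole-body plethysmography breath metrics.

A plethysmography session yields a volume trace from which resting breathing
is summarized over a 30 s analysis window: tidal volume (TV, mean
peak-to-trough amplitude per breath cycle), breathing frequency (f, breaths
per minute) and minute ventilation (MV = TV x f).  Animals are recorded on
three consecutive days and the per-day metrics averaged; experimental values
are expressed as fold change over the matched littermate control in room
air, and the hypercapnic response (5% CO2) as fold change over the same
animal's room-air baseline.  Group comparisons use the unpaired two-tailed
Student's t test.

Tidal volume here is the per-cycle peak-to-trough amplitude in the trace's
calibrated units; conversion to mL is the caller's responsibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

__all__ = [
    "BreathTrace",
    "BreathMetrics",
    "detect_breaths",
    "breath_metrics",
    "session_average",
    "fold_control",
    "hypercapnia_response",
    "compare_groups",
]

METRIC_FIELDS = ("tidal_volume", "frequency_bpm", "minute_ventilation")


@dataclass
class BreathTrace:
    """Respiratory volume series with acquisition and session metadata."""

    volume: np.ndarray
    sampling_rate_hz: float
    condition: str = "room_air"  # or "co2_5pct"
    subject: str = ""
    day: int = 0

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=float)
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if not np.all(np.isfinite(self.volume)):
            raise ValueError("volume trace contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.volume.size / self.sampling_rate_hz


@dataclass
class BreathMetrics:
    """Summary metrics of one analysis window (or averaged sessions)."""

    tidal_volume: float
    frequency_bpm: float
    minute_ventilation: float
    n_breaths: int
    window_s: float
    extras: dict = field(default_factory=dict)


def _smoothed(trace: BreathTrace, smooth_ms: float = 20.0) -> np.ndarray:
    win = max(1, int(round(smooth_ms / 1000.0 * trace.sampling_rate_hz)))
    return np.convolve(trace.volume, np.ones(win) / win, mode="same")


def detect_breaths(trace: BreathTrace, min_cycle_ms: float = 80.0,
                   smooth_ms: float = 20.0) -> np.ndarray:
    """Breath cycle onsets as trough sample indices (trough-to-trough cycles).

    Troughs of the lightly smoothed trace are found with prominence gating
    (a quarter of the robust peak-to-trough range); troughs closer together
    than ``min_cycle_ms`` are rejected.  Each detected trough starts one
    cycle.  Returns an empty array when fewer than two troughs exist (e.g. a
    flat trace).
    """
    if trace.duration_s < 1.0:
        raise ValueError("need at least 1 s of data")
    fs = trace.sampling_rate_hz
    x = _smoothed(trace, smooth_ms)
    lo, hi = np.percentile(x, [5, 95])
    span = hi - lo
    if span <= 0:
        return np.empty(0, dtype=int)
    min_dist = max(1, int(round(min_cycle_ms / 1000.0 * fs)))
    troughs, _ = sps.find_peaks(-x, prominence=0.25 * span, distance=min_dist)
    if troughs.size < 2:
        return np.empty(0, dtype=int)
    return troughs


def breath_metrics(trace: BreathTrace, cycles: np.ndarray | None = None,
                   window_s: float = 30.0,
                   reject_outliers: bool = True) -> BreathMetrics:
    """Tidal volume, frequency and minute ventilation over an analysis window.

    TV is the mean peak-to-trough amplitude per complete cycle (measured on
    the lightly smoothed trace, like the onsets), f the cycle-onset count
    scaled to breaths/min, and MV = TV x f (exact identity).  The analysis
    window is the first ``window_s`` seconds (30 s of resting breathing in
    the reference protocol).  Since resting breaths cannot be hand-picked
    here, a movement-artifact gate drops cycles whose amplitude is a 3xIQR
    outlier when ``reject_outliers`` is set.
    """
    if cycles is None:
        cycles = detect_breaths(trace)
    cycles = np.asarray(cycles, dtype=int)
    fs = trace.sampling_rate_hz
    end = min(trace.volume.size, int(round(window_s * fs)))
    onsets = cycles[cycles < end]
    if onsets.size < 1 or cycles.size < 2:
        raise ValueError("no complete breath cycle in the analysis window")
    x = _smoothed(trace)
    amps = np.array([
        float(x[a:b].max() - x[a:b].min())
        for a, b in zip(cycles[:-1], cycles[1:]) if a < end
    ])
    kept = np.ones(amps.size, dtype=bool)
    if reject_outliers and amps.size >= 4:
        q1, q3 = np.percentile(amps, [25, 75])
        iqr = q3 - q1
        # relative floor so a near-constant amplitude train is never culled
        slack = 3 * iqr + 0.01 * float(np.median(amps))
        kept = (amps >= q1 - slack) & (amps <= q3 + slack)
    window_used = end / fs
    # onset count sets the rate; amplitude comes from complete cycles only
    n = int(onsets.size - (amps.size - kept.sum()))
    tv = float(amps[kept].mean())
    freq = n * 60.0 / window_used
    return BreathMetrics(tv, freq, tv * freq, n, window_used)


def session_average(metrics: list[BreathMetrics]) -> BreathMetrics:
    """Arithmetic mean of each metric across recording days.

    Each field is averaged independently, so the averaged MV can differ from
    averaged-TV x averaged-f; both are kept (the recomputed product is
    reported under ``extras['mv_from_means']``).
    """
    if not metrics:
        raise ValueError("need at least one day of metrics")
    tv = float(np.mean([m.tidal_volume for m in metrics]))
    f = float(np.mean([m.frequency_bpm for m in metrics]))
    mv = float(np.mean([m.minute_ventilation for m in metrics]))
    return BreathMetrics(
        tv, f, mv,
        n_breaths=int(round(np.mean([m.n_breaths for m in metrics]))),
        window_s=float(np.mean([m.window_s for m in metrics])),
        extras={"mv_from_means": tv * f, "n_days": len(metrics)},
    )


def fold_control(experimental: BreathMetrics, control: BreathMetrics) -> dict[str, float]:
    """Per-metric ratio of experimental over matched littermate control."""
    out = {}
    for name in METRIC_FIELDS:
        c = getattr(control, name)
        if c <= 0:
            raise ValueError(f"control {name} must be positive for fold change")
        out[name] = getattr(experimental, name) / c
    return out


def hypercapnia_response(baseline: BreathMetrics, co2: BreathMetrics) -> dict[str, float]:
    """Fold change of each metric under 5% CO2 relative to room-air baseline."""
    out = {}
    for name in METRIC_FIELDS:
        b = getattr(baseline, name)
        if b <= 0:
            raise ValueError(f"baseline {name} must be positive for fold change")
        out[name] = getattr(co2, name) / b
    return out


def compare_groups(values_a, values_b) -> tuple[float, float]:
    """Unpaired two-tailed Student's t test (equal-variance form).

    Degenerate zero-variance groups: equal means give (0, 1); unequal means
    give an infinite statistic with p = 0, flagged by a warning from the
    caller's perspective via the returned values themselves.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
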