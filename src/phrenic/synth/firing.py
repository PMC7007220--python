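"""Synthetic phrenic motor-unit firing and compound nerve signals.

The generator reproduces the two firing regimes seen in neonatal fictive
breathing.  In the control regime, inspiratory bursts consist of periods of
activity interspersed with silent periods that progressively lengthen through
the burst; during activity, motor units fire phase-locked to a common ~30 Hz
clock, so their summed spikes form large-amplitude synchronous compound
action potentials.  In the mutant (or pharmacologically disinhibited) regime
the within-burst inhibition that imposes this structure is absent: units fire
as independent Poisson processes across the burst envelope, with no silent
periods and no preferred frequency.

Defaults for quantities the protocol leaves unstated are chosen once from
neonatal fictive-rhythm physiology (see the methods note): 8 bursts/min,
0.8 s bursts, 250 units (the phrenic nerve carries a few hundred motor axons
at birth), 30 Hz synchronization with 5 ms phase jitter, eight scheduled
silent gaps growing linearly from 12 to 42 ms, a 5 Hz/unit asynchronous
background during activity periods, and 40 Hz/unit Poisson firing in the
mutant regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ..bursts import NerveRecording

__all__ = [
    "FiringSimParams",
    "GroundTruth",
    "DEFAULT_SILENT_SCHEDULE",
    "simulate_population_firing",
    "render_compound_signal",
    "simulate_nerve_recording",
    "spike_waveform",
]

CONDITIONS = ("control", "mutant", "disinhibited")

# (position as fraction of burst, gap duration in ms); durations non-decreasing
# through the burst, emulating silent periods that progressively lengthen.
DEFAULT_SILENT_SCHEDULE: tuple[tuple[float, float], ...] = tuple(
    (float(p), float(d))
    for p, d in zip(np.linspace(0.1, 0.9, 8), np.linspace(12.0, 42.0, 8))
)


@dataclass
class FiringSimParams:
    """Parameters of the population firing simulator.

    ``condition`` selects the regime: ``control`` (phase-locked with silent
    gaps), ``mutant`` (independent Poisson units), or ``disinhibited`` (the
    mutant process applied to the control unit pool, emulating local
    picrotoxin/strychnine application).
    """

    n_units: int = 250
    burst_rate_per_min: float = 8.0
    burst_duration_s: float = 0.8
    sync_freq_hz: float = 30.0
    phase_jitter_ms: float = 5.0
    lock_probability: float = 0.85
    background_rate_hz: float = 5.0  # per unit, within activity periods
    silent_schedule: tuple[tuple[float, float], ...] = DEFAULT_SILENT_SCHEDULE
    condition: str = "control"
    unit_rate_hz: float = 40.0  # per unit, mutant/disinhibited Poisson rate
    duration_s: float = 45.0
    sampling_rate_hz: float = 10_000.0
    noise_sd: float = 0.1
    spike_amplitude: float = 1.0
    spike_width_ms: float = 1.0
    burst_start_jitter_s: float = 0.1
    coincidence_window_ms: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        for name in ("burst_rate_per_min", "burst_duration_s", "sync_freq_hz",
                     "unit_rate_hz", "duration_s", "spike_width_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.sampling_rate_hz < 1600:
            raise ValueError(
                "sampling_rate_hz must be >= 1600 Hz (4 x the 400 Hz analysis band)"
            )
        if self.sampling_rate_hz < 2 * self.sync_freq_hz:
            raise ValueError("sampling rate below Nyquist bound for sync_freq_hz")
        if self.condition == "control":
            durs = [d for _, d in self.silent_schedule]
            if any(b < a for a, b in zip(durs, durs[1:])):
                raise ValueError(
                    "silent-gap durations must be non-decreasing through the burst"
                )
            if any(not (0.0 < p < 1.0) for p, _ in self.silent_schedule):
                raise ValueError("silent-gap positions must lie in (0, 1)")


@dataclass
class GroundTruth:
    """Known truth of a simulated recording, for oracle-style checks.

    ``mask`` is true wherever at least one unit fires within the coincidence
    window; its length matches the rendered recording.
    """

    burst_intervals: np.ndarray  # (n, 2) start_s, end_s
    unit_spike_times: list[np.ndarray]
    mask: np.ndarray
    condition: str
    sampling_rate_hz: float
    duration_s: float

    def all_spikes(self) -> np.ndarray:
        if not self.unit_spike_times:
            return np.empty(0)
        return np.sort(np.concatenate(self.unit_spike_times))


def _burst_starts(params: FiringSimParams, rng: np.random.Generator) -> np.ndarray:
    period = 60.0 / params.burst_rate_per_min
    nominal = []
    k = 0
    while True:
        t = (k + 0.4) * period
        if t + params.burst_duration_s > params.duration_s:
            break
        nominal.append(t)
        k += 1
    starts = np.asarray(nominal)
    if starts.size:
        starts = starts + rng.normal(0.0, params.burst_start_jitter_s, starts.size)
        starts = np.sort(starts)
        # keep bursts separated and inside the recording
        lo = 0.0
        for i in range(starts.size):
            starts[i] = min(
                max(starts[i], lo),
                params.duration_s - params.burst_duration_s,
            )
            lo = starts[i] + params.burst_duration_s + 0.25
    return starts


def _gap_intervals(params: FiringSimParams, start: float) -> np.ndarray:
    gaps = []
    for pos, dur_ms in params.silent_schedule:
        c = start + pos * params.burst_duration_s
        h = dur_ms / 2000.0
        gaps.append((c - h, c + h))
    return np.asarray(gaps).reshape(-1, 2)


def _outside_gaps(t: np.ndarray, gaps: np.ndarray) -> np.ndarray:
    keep = np.ones(t.size, dtype=bool)
    for a, b in gaps:
        keep &= ~((t >= a) & (t < b))
    return keep


def simulate_population_firing(params: FiringSimParams) -> GroundTruth:
    """Simulate per-unit spike times and the population activity mask.

    Deterministic for a fixed seed.  Control: spikes are phase-locked to a
    global ``sync_freq_hz`` clock (Gaussian jitter, per-tick lock probability)
    plus a low-rate asynchronous background, with scheduled silent gaps; all
    spikes stay within burst intervals.  Mutant: independent homogeneous
    Poisson trains across the burst envelope.  Disinhibited: the mutant
    process applied to the control unit pool.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    starts = _burst_starts(params, rng)
    intervals = np.column_stack([starts, starts + params.burst_duration_s])

    unit_spikes: list[list[float]] = [[] for _ in range(params.n_units)]
    jitter_sd = params.phase_jitter_ms / 1000.0
    for start, end in intervals:
        if params.condition == "control":
            gaps = _gap_intervals(params, start)
            ticks = np.arange(start + 0.005, end - 0.002, 1.0 / params.sync_freq_hz)
            ticks = ticks[_outside_gaps(ticks, gaps)]
            for u in range(params.n_units):
                fire = rng.random(ticks.size) < params.lock_probability
                t = ticks[fire] + rng.normal(0.0, jitter_sd, int(fire.sum()))
                # asynchronous background within activity periods
                n_bg = rng.poisson(params.background_rate_hz * (end - start))
                bg = rng.uniform(start, end, n_bg)
                bg = bg[_outside_gaps(bg, gaps)]
                t = np.concatenate([t, bg])
                t = t[_outside_gaps(t, gaps)]
                t = t[(t >= start) & (t < end)]
                unit_spikes[u].extend(t.tolist())
        else:  # mutant / disinhibited: Poisson across the burst envelope
            for u in range(params.n_units):
                n = rng.poisson(params.unit_rate_hz * (end - start))
                t = rng.uniform(start, end, n)
                unit_spikes[u].extend(t.tolist())

    spikes = [np.sort(np.asarray(s)) for s in unit_spikes]
    n_samples = int(round(params.duration_s * params.sampling_rate_hz))
    mask = np.zeros(n_samples, dtype=bool)
    half_w = params.coincidence_window_ms / 2000.0
    fs = params.sampling_rate_hz
    delta = np.zeros(n_samples + 1, dtype=np.int64)
    for t in spikes:
        if t.size == 0:
            continue
        i0 = np.clip(np.ceil((t - half_w) * fs).astype(int), 0, n_samples)
        i1 = np.clip(np.floor((t + half_w) * fs).astype(int) + 1, 0, n_samples)
        np.add.at(delta, i0, 1)
        np.add.at(delta, i1, -1)
    mask = np.cumsum(delta[:-1]) > 0
    return GroundTruth(intervals, spikes, mask, params.condition,
                       params.sampling_rate_hz, params.duration_s)


def spike_waveform(t_s: np.ndarray, width_ms: float = 1.0,
                   amplitude: float = 1.0) -> np.ndarray:
    """Biphasic difference-of-Gaussians extracellular spike, ~``width_ms`` wide.

    Zero outside |t| <= width/2, so a rendered spike has strictly finite
    support and the rendering sum is exactly linear in the spike set.
    """
    t = np.asarray(t_s, dtype=float)
    w = width_ms / 1000.0
    sigma = w / 10.0
    lobe = w / 4.0
    out = amplitude * (
        np.exp(-((t + lobe) ** 2) / (2 * sigma ** 2))
        - np.exp(-((t - lobe) ** 2) / (2 * sigma ** 2))
    )
    out[np.abs(t) > w / 2] = 0.0
    return out


def render_compound_signal(truth: GroundTruth, params: FiringSimParams) -> NerveRecording:
    """Sum of biphasic spike waveforms at the true spike times, plus noise.

    ``signal = sum over spikes of waveform(t - t_spike) + N(0, noise_sd)``;
    with ``noise_sd = 0`` and no spikes the output is identically zero.  The
    waveform is evaluated analytically at each sample time, so a single spike
    renders as the exactly translated waveform and rendering is linear in the
    spike set at zero noise.
    """
    fs = params.sampling_rate_hz
    n = int(round(truth.duration_s * fs))
    w = params.spike_width_ms / 1000.0
    if w > truth.duration_s:
        raise ValueError("spike waveform longer than recording")
    signal = np.zeros(n)
    spikes = truth.all_spikes()
    if spikes.size:
        half = w / 2.0
        L = int(np.ceil(w * fs)) + 2
        base = np.arange(L)
        i0 = np.floor((spikes - half) * fs).astype(int)
        rows = i0[:, None] + base[None, :]
        tt = rows / fs - spikes[:, None]
        vals = spike_waveform(tt, params.spike_width_ms, params.spike_amplitude)
        valid = (rows >= 0) & (rows < n)
        np.add.at(signal, rows[valid], vals[valid])
    if params.noise_sd > 0:
        rng = np.random.default_rng([params.seed, 917])
        signal = signal + rng.normal(0.0, params.noise_sd, n)
    return NerveRecording(signal, fs, 0.0, f"sim-{params.condition}-{params.seed}")


def simulate_nerve_recording(params: FiringSimParams) -> tuple[NerveRecording, GroundTruth]:
    """Convenience: ground truth plus the rendered compound recording."""
    truth = simulate_population_firing(params)
    return render_compound_signal(truth, params), truth


def ground_truth_silent_fraction(truth: GroundTruth, min_silent_ms: float = 5.0) -> float:
    """Mean within-burst silent fraction (%) of the ground-truth mask.

    Uses the same run-length convention as the analysis module: only silent
    runs of at least ``min_silent_ms`` count.
    """
    from ..bursts import ActivityMask, silent_fraction

    fs = truth.sampling_rate_hz
    fracs = []
    for a, b in truth.burst_intervals:
        seg = truth.mask[int(round(a * fs)):int(round(b * fs))]
        fracs.append(silent_fraction(ActivityMask(seg, fs, a), min_silent_ms))
    return float(np.mean(fracs))
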