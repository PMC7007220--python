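"""Shared fixtures.

The nerve-recording summaries are computed once per session: simulating and
analyzing 60 recordings dominates the suite's runtime, and several tests
(condition separation, disinhibition equivalence, spectral-peak recovery)
all consume the same per-seed summaries.
"""

from __future__ import annotations

import numpy as np
import pytest

from phrenic.bursts import analyze_recording
from phrenic.synth import FiringSimParams, simulate_nerve_recording

N_SEEDS = 20
SIM_DURATION_S = 35.0  # covers five bursts at the default 8 bursts/min


def _summarize(condition: str, seed: int) -> dict:
    params = FiringSimParams(condition=condition, seed=seed,
                             duration_s=SIM_DURATION_S)
    rec, truth = simulate_nerve_recording(params)
    res = analyze_recording(rec)
    return {
        "seed": seed,
        "silent_pct": res["mean_silent_fraction_pct"],
        "below75_pct": res["below_pct"],
        "peak_hz": res["peak_hz"],
        "burst_rate": res["burst_rate_per_min"],
        "mean_duration_s": res["mean_duration_s"],
        "avg_spectrum": res["avg_spectrum"],
        "n_bursts_detected": len(res["bursts"]),
        "truth_intervals": truth.burst_intervals,
        "detected_intervals": res["bursts"].intervals,
    }


@pytest.fixture(scope="session")
def nerve_summaries() -> dict[str, list[dict]]:
    """Per-seed analysis summaries for all three firing regimes.

    Control and mutant use seeds 0..19; the disinhibited group uses
    100..119 so its comparison against the mutant group is a genuine
    two-sample test rather than a seed-for-seed identity.
    """
    return {
        "control": [_summarize("control", s) for s in range(N_SEEDS)],
        "mutant": [_summarize("mutant", s) for s in range(N_SEEDS)],
        "disinhibited": [_summarize("disinhibited", 100 + s)
                         for s in range(N_SEEDS)],
    }


def grid_fractions_oracle(image: np.ndarray, centroid: tuple[float, float],
                          span_px: float = 100.0) -> dict[int, float]:
    """Independent per-square pixel sums for the 3x3 orientation grid.

    Explicit per-pixel band assignment with the standard numbering
    (5+6 dorsolateral, 8 medial); centre square excluded.
    """
    from phrenic.dendrites import DEFAULT_GRID_LAYOUT

    r0, c0 = centroid
    cell = 2 * span_px / 3.0
    sums = {sq: 0.0 for sq in range(1, 9)}
    h, w = image.shape
    for r in range(h):
        rb = int(np.floor((r - (r0 - span_px)) / cell))
        if rb < 0 or rb > 2:
            continue
        for c in range(w):
            cb = int(np.floor((c - (c0 - span_px)) / cell))
            if cb < 0 or cb > 2 or (rb, cb) == (1, 1):
                continue
            sums[DEFAULT_GRID_LAYOUT[(rb, cb)]] += image[r, c]
    total = sum(sums.values())
    return {sq: s / total for sq, s in sums.items()}


def silent_fraction_oracle(mask: np.ndarray, fs: float,
                           min_silent_ms: float = 5.0) -> float:
    """Independent run-length enumeration of the silent fraction (%)."""
    min_run = int(np.ceil(min_silent_ms / 1000.0 * fs))
    total = 0
    run = 0
    for active in mask:
        if not active:
            run += 1
        else:
            if run >= min_run:
                total += run
            run = 0
    if run >= min_run:
        total += run
    return 100.0 * total / mask.size
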