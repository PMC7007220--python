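"""Synthetic plethysmography breath traces.

Quasi-sinusoidal volume series with settable tidal volume (peak-to-trough
amplitude), breathing rate and additive Gaussian noise.  Convenience factors
for the mutant-like condition (shallow, fast breathing) and the hypercapnic
response are provided so paired sessions can be simulated consistently.
"""

from __future__ import annotations

import numpy as np

from ..breathing import BreathTrace

__all__ = ["simulate_breath_trace", "CONDITION_FACTORS"]

#: multiplicative (tidal volume, frequency) factors relative to control
#: room air: mutant-like animals breathe shallow and fast; 5% CO2 deepens
#: and speeds up breathing in controls.
CONDITION_FACTORS: dict[str, tuple[float, float]] = {
    "control": (1.0, 1.0),
    "mutant": (0.6, 1.4),
    "co2_response": (1.5, 1.3),
}


def simulate_breath_trace(tidal_volume: float = 0.2,
                          breaths_per_min: float = 150.0,
                          noise_sd: float = 0.005,
                          duration_s: float = 30.0,
                          sampling_rate_hz: float = 1000.0,
                          condition: str = "room_air",
                          subject: str = "",
                          day: int = 0,
                          seed: int = 0) -> BreathTrace:
    """Simulate a volume trace with known tidal volume and rate.

    The waveform is a sinusoid of peak-to-trough amplitude ``tidal_volume``
    at ``breaths_per_min`` cycles per minute plus Gaussian noise;
    deterministic for a fixed seed.
    """
    if tidal_volume <= 0 or breaths_per_min <= 0 or duration_s <= 0:
        raise ValueError("tidal volume, rate and duration must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    f = breaths_per_min / 60.0
    if duration_s < 1.0 / f:
        raise ValueError("duration shorter than one breath cycle")
    n = int(round(duration_s * sampling_rate_hz))
    t = np.arange(n) / sampling_rate_hz
    volume = 0.5 * tidal_volume * np.sin(2 * np.pi * f * t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        volume = volume + rng.normal(0.0, noise_sd, n)
    return BreathTrace(volume, sampling_rate_hz, condition=condition,
                       subject=subject, day=day)
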