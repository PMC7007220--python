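"""Nerve-recording analysis: filtering, detection, silence, spectra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import silent_fraction_oracle
from phrenic.bursts import (
    ActivityMask,
    BurstSet,
    NerveRecording,
    analyze_recording,
    average_spectra,
    band_fraction,
    bandpass,
    burst_durations,
    burst_frequency,
    burst_power_spectrum,
    detect_bursts,
    peak_frequency,
    silent_fraction,
    unit_activity_mask,
)
from phrenic.synth import FiringSimParams, simulate_nerve_recording
from phrenic.synth.firing import simulate_population_firing, render_compound_signal

FS = 10_000.0


def _tone(freq, duration=2.0, fs=FS, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    return NerveRecording(amp * np.sin(2 * np.pi * freq * t), fs)


# ---------------------------------------------------------------------------
# bandpass


def test_bandpass_zero_in_zero_out():
    rec = NerveRecording(np.zeros(1000), FS)
    assert np.allclose(bandpass(rec).samples, 0.0)


def test_bandpass_passes_inband_tone():
    rec = _tone(100.0)
    out = bandpass(rec)
    rms_in = np.sqrt(np.mean(rec.samples**2))
    rms_out = np.sqrt(np.mean(out.samples**2))
    assert abs(rms_out - rms_in) / rms_in < 0.05


def test_bandpass_rejects_subband_tone():
    rec = _tone(1.0, duration=5.0)
    out = bandpass(rec)
    assert np.sqrt(np.mean(out.samples**2)) < 0.1 * np.sqrt(np.mean(rec.samples**2))


def test_bandpass_invalid_band():
    with pytest.raises(ValueError):
        bandpass(_tone(100.0), lo_hz=500.0, hi_hz=100.0)


def test_bandpass_clips_high_cutoff_with_warning():
    rec = NerveRecording(np.random.default_rng(0).normal(size=4000), 4000.0)
    with pytest.warns(UserWarning, match="clipped"):
        bandpass(rec, hi_hz=3000.0)


# ---------------------------------------------------------------------------
# burst detection


def test_detects_five_bursts_within_tolerance():
    """Simulated control recording: every burst found within +/-20 ms."""
    params = FiringSimParams(seed=42, duration_s=40.0)
    rec, truth = simulate_nerve_recording(params)
    bursts = detect_bursts(bandpass(rec))
    assert len(bursts) == len(truth.burst_intervals) >= 5
    err_ms = np.abs(bursts.intervals - truth.burst_intervals) * 1000
    assert err_ms.max() < 20.0


def test_pure_noise_yields_no_bursts():
    rng = np.random.default_rng(1)
    rec = NerveRecording(rng.normal(0, 0.1, 300_000), FS)
    assert len(detect_bursts(bandpass(rec))) == 0


def test_detection_is_deterministic():
    rec, _ = simulate_nerve_recording(FiringSimParams(seed=9, duration_s=20.0))
    filt = bandpass(rec)
    np.testing.assert_array_equal(detect_bursts(filt).intervals,
                                  detect_bursts(filt).intervals)


def test_burst_set_invariants_enforced():
    with pytest.raises(ValueError):
        BurstSet(np.array([[1.0, 0.5]]))
    with pytest.raises(ValueError):
        BurstSet(np.array([[0.0, 2.0], [1.0, 3.0]]))


# ---------------------------------------------------------------------------
# frequency and durations


def test_burst_frequency_arithmetic():
    starts = np.arange(40) * 7.0
    bursts = BurstSet(np.column_stack([starts, starts + 0.8]))
    assert burst_frequency(bursts, window_s=300.0) == pytest.approx(8.0)
    assert burst_frequency(BurstSet(np.empty((0, 2)))) == 0.0
    with pytest.raises(ValueError):
        burst_frequency(bursts, window_s=0.0)


def test_burst_rate_recovered_from_generator_truth():
    """Mean recovered rate over 10 seeds is within 1/min of the set rate."""
    rates = []
    for seed in range(10):
        truth = simulate_population_firing(
            FiringSimParams(seed=seed, duration_s=300.0))
        rates.append(burst_frequency(BurstSet(truth.burst_intervals),
                                     window_s=300.0))
    assert abs(np.mean(rates) - 8.0) <= 1.0


def test_burst_durations():
    bursts = BurstSet(np.array([[1.0, 1.8], [5.0, 5.8]]))
    with pytest.warns(UserWarning):
        durs, mean = burst_durations(bursts, n_bursts=5)
    np.testing.assert_allclose(durs, [0.8, 0.8])
    assert mean == pytest.approx(0.8)
    with pytest.raises(ValueError):
        burst_durations(BurstSet(np.empty((0, 2))))


# ---------------------------------------------------------------------------
# activity mask and silent fraction


def test_activity_mask_matches_truth_on_noiseless_rendering():
    params = FiringSimParams(seed=0, duration_s=20.0, noise_sd=0.0)
    truth = simulate_population_firing(params)
    rec = render_compound_signal(truth, params)
    bursts = BurstSet(truth.burst_intervals)
    fs = params.sampling_rate_hz
    for burst in bursts:
        mask = unit_activity_mask(rec, burst, bursts=bursts)
        s0 = int(round(burst[0] * fs))
        gt = truth.mask[s0:s0 + mask.values.size]
        jaccard = (mask.values & gt).sum() / (mask.values | gt).sum()
        assert jaccard >= 0.9


def test_zero_signal_burst_is_all_silent():
    rec = NerveRecording(np.zeros(20_000), FS)
    mask = unit_activity_mask(rec, (0.5, 1.5))
    assert not mask.values.any()
    assert silent_fraction(mask) == 100.0


def test_saturated_signal_is_all_active():
    x = np.zeros(20_000)
    x[5000:15000] = 5.0  # constant suprathreshold burst on a quiet baseline
    rec = NerveRecording(x, FS)
    mask = unit_activity_mask(rec, (0.5, 1.5), bursts=BurstSet([[0.5, 1.5]]))
    assert mask.values.all()
    assert silent_fraction(mask) == 0.0


def test_silent_fraction_run_length_example():
    """10 + 20 ms silent runs in a 100 ms burst give exactly 30%."""
    fs = 1000.0
    values = np.ones(100, dtype=bool)
    values[10:20] = False   # 10 ms
    values[50:70] = False   # 20 ms
    values[80:83] = False   # 3 ms: below the 5 ms floor, not counted
    assert silent_fraction(ActivityMask(values, fs)) == pytest.approx(30.0)


def test_silent_fraction_invariant_to_amplitude_scaling():
    rec, _ = simulate_nerve_recording(FiringSimParams(seed=2, duration_s=20.0))
    filt = bandpass(rec)
    bursts = detect_bursts(filt)
    burst = tuple(bursts.intervals[0])
    sf = silent_fraction(unit_activity_mask(filt, burst, bursts=bursts))
    scaled = NerveRecording(filt.samples * 13.7, filt.sampling_rate_hz)
    sf_scaled = silent_fraction(unit_activity_mask(scaled, burst, bursts=bursts))
    assert sf == pytest.approx(sf_scaled)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(st.lists(st.booleans(), min_size=10, max_size=400),
       st.sampled_from([1000.0, 2000.0, 10_000.0]))
def test_silent_fraction_equals_oracle_on_arbitrary_masks(bits, fs):
    """Oracle equivalence: exact match with run-length enumeration."""
    values = np.asarray(bits, dtype=bool)
    assert silent_fraction(ActivityMask(values, fs)) == pytest.approx(
        silent_fraction_oracle(values, fs))


# ---------------------------------------------------------------------------
# spectra


def test_tone_spectrum_concentrates_at_tone():
    rec = _tone(30.0)
    spec = burst_power_spectrum(rec, (0.2, 1.8))
    near = np.abs(spec.freqs_hz - 30.0) <= spec.bin_width_hz
    assert spec.rel_power[near].sum() >= 0.9
    assert peak_frequency(spec) == pytest.approx(30.0, abs=spec.bin_width_hz)


def test_spectrum_normalization_and_band():
    rec, _ = simulate_nerve_recording(FiringSimParams(seed=5, duration_s=20.0))
    filt = bandpass(rec)
    burst = tuple(detect_bursts(filt).intervals[0])
    spec = burst_power_spectrum(filt, burst)
    assert spec.rel_power.sum() == pytest.approx(1.0, abs=1e-9)
    assert spec.freqs_hz[0] >= 10.0 and spec.freqs_hz[-1] <= 400.0
    assert spec.bin_width_hz <= 2.5


def test_white_noise_spectrum_has_no_dominant_bin():
    """Across 20 seeds, no bin dominates a burst-averaged noise spectrum.

    The check runs on the five-burst averaged estimator the analysis chain
    reports (a single raw periodogram has exponentially distributed bins, so
    its maximum over ~300 bins is expected to reach 5-6x the mean).
    """
    ok = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        rec = NerveRecording(rng.normal(0, 1, int(4 * FS)), FS)
        spectra = [burst_power_spectrum(rec, (0.8 * k, 0.8 * (k + 1)))
                   for k in range(5)]
        avg = average_spectra(spectra)
        if avg.rel_power.max() < 5 * avg.rel_power.mean():
            ok += 1
    assert ok >= 18


def test_band_fraction_pure_tones():
    below, above = band_fraction(burst_power_spectrum(_tone(30.0), (0.1, 1.9)))
    assert below >= 98.0
    below2, above2 = band_fraction(burst_power_spectrum(_tone(150.0), (0.1, 1.9)))
    assert above2 >= 98.0
    assert below + above == pytest.approx(100.0)
    assert below2 + above2 == pytest.approx(100.0)


def test_average_spectra_identity_and_grid_check():
    spec = burst_power_spectrum(_tone(30.0), (0.2, 1.8))
    avg = average_spectra([spec, spec, spec])
    np.testing.assert_allclose(avg.rel_power, spec.rel_power)
    other = burst_power_spectrum(_tone(30.0), (0.2, 1.8), bin_width_hz=2.0)
    with pytest.raises(ValueError, match="grid"):
        average_spectra([spec, other])


def test_burst_too_short_for_spectrum():
    with pytest.raises(ValueError, match="short"):
        burst_power_spectrum(_tone(30.0), (0.0, 0.1))


# ---------------------------------------------------------------------------
# parameter recovery on the session fixture


def test_control_peak_recovers_sync_frequency(nerve_summaries):
    """Averaged control spectra peak at the 30 Hz generator clock (>=9/10)."""
    hits = sum(
        1 for s in nerve_summaries["control"][:10]
        if abs(s["peak_hz"] - 30.0) <= s["avg_spectrum"].bin_width_hz
    )
    assert hits >= 9


def test_mutant_spectrum_has_no_30hz_structure(nerve_summaries):
    """Mutant spectra show no bin in 25-35 Hz above 3x the median bin."""
    hits = 0
    for s in nerve_summaries["mutant"][:10]:
        spec = s["avg_spectrum"]
        sel = (spec.freqs_hz >= 25.0) & (spec.freqs_hz <= 35.0)
        if spec.rel_power[sel].max() <= 3 * np.median(spec.rel_power):
            hits += 1
    assert hits >= 9


def test_mean_burst_duration_recovered(nerve_summaries):
    durs = [s["mean_duration_s"] for s in nerve_summaries["control"]]
    assert abs(np.mean(durs) - 0.8) <= 0.05


def test_analyze_recording_end_to_end_schema():
    rec, _ = simulate_nerve_recording(FiringSimParams(seed=3, duration_s=35.0))
    res = analyze_recording(rec)
    assert len(res["stats"]) == 5
    assert res["below_pct"] + res["above_pct"] == pytest.approx(100.0)
    assert 10.0 <= res["peak_hz"] <= 400.0
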