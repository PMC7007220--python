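"""Breath metrics, session averaging, fold-control, group comparison."""

import numpy as np
import pytest

from phrenic.breathing import (
    BreathMetrics,
    BreathTrace,
    breath_metrics,
    compare_groups,
    detect_breaths,
    fold_control,
    hypercapnia_response,
    session_average,
)
from phrenic.synth import simulate_breath_trace
from phrenic.synth.breath import CONDITION_FACTORS


def _metrics(tv, f):
    return BreathMetrics(tv, f, tv * f, n_breaths=10, window_s=30.0)


# ---------------------------------------------------------------------------
# cycle detection


def test_noiseless_sinusoid_cycle_count_is_rate_times_duration():
    trace = simulate_breath_trace(tidal_volume=0.2, breaths_per_min=120.0,
                                  noise_sd=0.0, duration_s=30.0)
    assert detect_breaths(trace).size == 60


def test_flat_trace_has_no_cycles():
    trace = BreathTrace(np.zeros(5000), 1000.0)
    assert detect_breaths(trace).size == 0


def test_noisy_cycle_count_within_one_of_truth():
    for seed in range(5):
        trace = simulate_breath_trace(breaths_per_min=150.0, duration_s=30.0,
                                      seed=seed)
        assert abs(detect_breaths(trace).size - 75) <= 1


def test_short_trace_rejected():
    with pytest.raises(ValueError):
        detect_breaths(BreathTrace(np.zeros(100), 1000.0))


# ---------------------------------------------------------------------------
# metrics


def test_noiseless_amplitude_recovered_within_one_percent():
    trace = simulate_breath_trace(tidal_volume=0.37, breaths_per_min=150.0,
                                  noise_sd=0.0)
    m = breath_metrics(trace)
    assert m.tidal_volume == pytest.approx(0.37, rel=0.01)
    assert m.frequency_bpm == pytest.approx(150.0)


def test_minute_ventilation_identity():
    m = _metrics(0.2, 150.0)
    assert m.minute_ventilation == pytest.approx(m.tidal_volume * m.frequency_bpm)
    trace = simulate_breath_trace(seed=1)
    measured = breath_metrics(trace)
    assert measured.minute_ventilation == pytest.approx(
        measured.tidal_volume * measured.frequency_bpm)


def test_metrics_deterministic_for_identical_signal():
    trace = simulate_breath_trace(seed=2)
    a = breath_metrics(trace)
    b = breath_metrics(trace)
    assert (a.tidal_volume, a.frequency_bpm) == (b.tidal_volume, b.frequency_bpm)


def test_recovery_within_tolerances_across_seeds():
    """TV and f recovered within 2% noiseless, 5% at default noise."""
    tv, f = 0.2, 150.0
    for seed in range(20):
        clean = breath_metrics(simulate_breath_trace(noise_sd=0.0, seed=seed))
        assert clean.tidal_volume == pytest.approx(tv, rel=0.02)
        assert clean.frequency_bpm == pytest.approx(f, rel=0.02)
        noisy = breath_metrics(simulate_breath_trace(seed=seed))
        assert noisy.tidal_volume == pytest.approx(tv, rel=0.05)
        assert noisy.frequency_bpm == pytest.approx(f, rel=0.05)


# ---------------------------------------------------------------------------
# averaging, fold-control, hypercapnia


def test_session_average_arithmetic():
    days = [_metrics(1.0, 100.0), _metrics(3.0, 100.0)]
    avg = session_average(days)
    assert avg.tidal_volume == pytest.approx(2.0)
    assert avg.frequency_bpm == pytest.approx(100.0)
    same = session_average([_metrics(0.2, 150.0)] * 3)
    assert same.tidal_volume == pytest.approx(0.2)
    with pytest.raises(ValueError):
        session_average([])


def test_session_average_of_simulated_days_matches_hand_mean():
    per_day = [breath_metrics(simulate_breath_trace(seed=s, day=s))
               for s in range(3)]
    avg = session_average(per_day)
    assert avg.tidal_volume == pytest.approx(
        np.mean([m.tidal_volume for m in per_day]))
    assert avg.minute_ventilation == pytest.approx(
        np.mean([m.minute_ventilation for m in per_day]))


def test_fold_control_identity_and_tradeoff():
    m = _metrics(0.2, 150.0)
    assert all(v == pytest.approx(1.0) for v in fold_control(m, m).values())
    halved = _metrics(0.1, 300.0)
    folds = fold_control(halved, m)
    assert folds["tidal_volume"] == pytest.approx(0.5)
    assert folds["frequency_bpm"] == pytest.approx(2.0)
    assert folds["minute_ventilation"] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        fold_control(m, _metrics(0.0, 1.0))


def test_fold_control_scale_invariance():
    a, c = _metrics(0.3, 120.0), _metrics(0.2, 150.0)
    base = fold_control(a, c)
    scaled = fold_control(_metrics(3.0, 120.0), _metrics(2.0, 150.0))
    assert base["tidal_volume"] == pytest.approx(scaled["tidal_volume"])


def test_mutant_generator_fold_ratios_recovered():
    """Shallow-fast mutant condition: TVx0.6 and fx1.4 within 5%."""
    f_tv, f_bpm = CONDITION_FACTORS["mutant"]
    control = breath_metrics(simulate_breath_trace(seed=10))
    mutant = breath_metrics(simulate_breath_trace(
        tidal_volume=0.2 * f_tv, breaths_per_min=150.0 * f_bpm, seed=11))
    folds = fold_control(mutant, control)
    assert folds["tidal_volume"] == pytest.approx(0.6, rel=0.05)
    assert folds["frequency_bpm"] == pytest.approx(1.4, rel=0.05)


def test_hypercapnia_response():
    base = _metrics(0.2, 150.0)
    assert all(v == pytest.approx(1.0)
               for v in hypercapnia_response(base, base).values())
    co2 = _metrics(0.3, 195.0)  # TVx1.5, fx1.3
    resp = hypercapnia_response(base, co2)
    assert resp["tidal_volume"] == pytest.approx(1.5)
    assert resp["frequency_bpm"] == pytest.approx(1.3)
    assert resp["minute_ventilation"] == pytest.approx(1.95)


def test_simulated_paired_hypercapnia_sessions():
    f_tv, f_bpm = CONDITION_FACTORS["co2_response"]
    base = breath_metrics(simulate_breath_trace(seed=20))
    co2 = breath_metrics(simulate_breath_trace(
        tidal_volume=0.2 * f_tv, breaths_per_min=150.0 * f_bpm,
        condition="co2_5pct", seed=21))
    resp = hypercapnia_response(base, co2)
    assert resp["tidal_volume"] == pytest.approx(1.5, rel=0.05)
    assert resp["frequency_bpm"] == pytest.approx(1.3, rel=0.05)


# ---------------------------------------------------------------------------
# group comparison


def test_identical_groups_t_zero_p_one():
    t, p = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_large_offset_is_significant():
    t, p = compare_groups([1.0, 2.0, 3.0], [101.0, 102.0, 103.0])
    assert p < 0.01
    # textbook check: t = diff / (s_p * sqrt(2/n)); here s_p = 1, n = 3
    assert t == pytest.approx(-100.0 / np.sqrt(2.0 / 3.0))


def test_swapping_groups_flips_sign_only():
    a, b = [1.0, 2.0, 4.0], [2.5, 3.5, 5.0]
    t_ab, p_ab = compare_groups(a, b)
    t_ba, p_ba = compare_groups(b, a)
    assert t_ab == pytest.approx(-t_ba)
    assert p_ab == pytest.approx(p_ba)


def test_degenerate_zero_variance_groups():
    t, p = compare_groups([2.0, 2.0], [2.0, 2.0])
    assert (t, p) == (0.0, 1.0)
    t2, p2 = compare_groups([1.0, 1.0], [2.0, 2.0])
    assert np.isinf(t2) and p2 == 0.0


def test_small_groups_rejected():
    with pytest.raises(ValueError):
        compare_groups([1.0], [1.0, 2.0])
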