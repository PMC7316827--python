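"""FHR series construction, 4 Hz resampling and the clinical report."""

import numpy as np
import pytest

from fecgkit import fhr, simulate
from fecgkit.fhr import (
    baseline_and_fluctuation,
    detect_acc_dec,
    fhr_report,
    resample_4hz,
    rr_to_fhr,
    variability_indices,
)
from fecgkit.io import BeatAnnotations

RATE = 500.0


def _ann_from_rr_ms(rr_ms, rate=RATE, flags=None):
    times = np.concatenate([[0.0], np.cumsum(rr_ms)])
    locs = np.round(times * rate / 1000.0).astype(int)
    return BeatAnnotations(locs, rate, "fetal",
                           flags=None if flags is None else np.asarray(flags))


def test_rr_fhr_worked_values():
    # 421.1 ms is 142.5 bpm; 400 ms is 150 bpm
    series = rr_to_fhr(_ann_from_rr_ms([421.1] * 5, rate=10000.0))
    assert series.fhr_values[0] == pytest.approx(142.5, abs=0.05)
    series2 = rr_to_fhr(_ann_from_rr_ms([400.0] * 5))
    assert series2.fhr_values[0] == pytest.approx(150.0)


def test_fhr_rr_inversion():
    rr = np.array([400.0, 410.0, 420.0, 415.0, 405.0] * 4)
    series = rr_to_fhr(_ann_from_rr_ms(rr, rate=1000.0))
    np.testing.assert_allclose(60000.0 / series.fhr_values, rr)


def test_flag_zero_masks_both_adjacent_intervals():
    flags = [1, 1, 0, 1, 1]
    series = rr_to_fhr(_ann_from_rr_ms([400.0] * 4, flags=flags))
    np.testing.assert_array_equal(series.valid, [True, False, False, True])


def test_physiologic_gate_masks_outliers():
    rr = [400.0, 2000.0, 400.0, 400.0]  # 30 bpm interval masked
    series = rr_to_fhr(_ann_from_rr_ms(rr))
    assert not series.valid[1]
    assert series.valid[[0, 2, 3]].all()


def test_fewer_than_two_beats_gives_empty_series():
    series = rr_to_fhr(BeatAnnotations([100], RATE, "fetal"))
    assert len(series.fhr_values) == 0


def test_constant_rate_grid_no_loss():
    series = rr_to_fhr(_ann_from_rr_ms([400.0] * 750))  # 5 min
    grid, ok = resample_4hz(series)
    assert fhr.signal_loss_pct(ok) < 1.0
    np.testing.assert_allclose(grid[ok], 150.0)


def test_masked_gap_counts_as_loss():
    # 5-minute record with one 30 s unreliable stretch -> ~10% loss
    n = 750
    flags = np.ones(n + 1, dtype=int)
    gap = slice(300, 300 + 75)  # 75 beats x 0.4 s = 30 s
    flags[gap] = 0
    series = rr_to_fhr(_ann_from_rr_ms([400.0] * n, flags=flags))
    _, ok = resample_4hz(series)
    assert fhr.signal_loss_pct(ok) == pytest.approx(10.0, abs=1.0)


def test_single_beat_all_invalid_grid():
    series = rr_to_fhr(BeatAnnotations([0, 1], RATE, "fetal"))
    _, ok = resample_4hz(series)
    assert not ok.any()


def test_constant_trace_baseline_and_zero_fluctuation():
    # 150 bpm = 400 ms, an exact sample count at 500 Hz
    series = rr_to_fhr(_ann_from_rr_ms([400.0] * 1500))
    grid, ok = resample_4hz(series)
    basal, fluct = baseline_and_fluctuation(grid, ok)
    assert basal == pytest.approx(150.0, abs=0.5)
    assert fluct == pytest.approx(0.0, abs=0.2)


def test_sinusoidal_modulation_fluctuation():
    # ±5 bpm slow sinusoid around 140 -> fluctuation ~10 bpm peak-to-peak
    t = 0.0
    rr = []
    while t < 600.0:
        bpm = 140.0 + 5.0 * np.sin(2 * np.pi * 0.02 * t)
        rr.append(60000.0 / bpm)
        t += rr[-1] / 1000.0
    series = rr_to_fhr(_ann_from_rr_ms(rr, rate=1000.0))
    grid, ok = resample_4hz(series)
    basal, fluct = baseline_and_fluctuation(grid, ok)
    assert basal == pytest.approx(140.0, abs=2.0)
    assert fluct == pytest.approx(10.0, abs=1.5)


def _grid_with_bump(baseline=140.0, amp=20.0, onset=120.0, dur=30.0,
                    total=360.0):
    t = np.arange(0, total, 0.25)
    dev = np.where(
        (t >= onset) & (t < onset + dur),
        amp * 0.5 * (1 - np.cos(2 * np.pi * (t - onset) / dur)),
        0.0,
    )
    return baseline + dev, np.ones(t.size, dtype=bool), t


def test_single_programmed_acceleration_detected():
    grid, ok, t = _grid_with_bump(amp=20.0)
    acc, dec = detect_acc_dec(grid, ok, baseline=140.0)
    assert len(acc) == 1 and len(dec) == 0
    assert acc[0].extremum_bpm == pytest.approx(20.0, abs=0.5)


def test_deceleration_sign_symmetric():
    grid, ok, t = _grid_with_bump(amp=-22.0)
    acc, dec = detect_acc_dec(grid, ok, baseline=140.0)
    assert len(acc) == 0 and len(dec) == 1
    assert dec[0].extremum_bpm == pytest.approx(-22.0, abs=0.5)


def test_flat_trace_no_episodes():
    grid = np.full(2000, 140.0)
    ok = np.ones(2000, dtype=bool)
    acc, dec = detect_acc_dec(grid, ok, baseline=140.0)
    assert len(acc) == 0 and len(dec) == 0


def test_boundary_truncated_episode_not_counted():
    # trace starts already below the deceleration threshold
    grid, ok, t = _grid_with_bump(amp=-25.0, onset=0.0, dur=40.0)
    grid[0:40] = 140.0 - 25.0
    acc, dec = detect_acc_dec(grid, ok, baseline=140.0)
    assert len(dec) == 0


def test_sub_threshold_or_short_excursions_ignored():
    grid_small, ok, _ = _grid_with_bump(amp=10.0)  # peak below 15 bpm
    acc, _ = detect_acc_dec(grid_small, ok, baseline=140.0)
    assert len(acc) == 0
    grid_short, ok2, _ = _grid_with_bump(amp=25.0, dur=8.0)  # too short
    acc2, _ = detect_acc_dec(grid_short, ok2, baseline=140.0)
    assert len(acc2) == 0


def test_constant_rr_zero_variability():
    series = rr_to_fhr(_ann_from_rr_ms([420.0] * 600))
    vi = variability_indices(series)
    assert vi["stv_dawes"] == pytest.approx(0.0, abs=0.05)
    assert vi["ltv_dawes"] == pytest.approx(0.0, abs=0.05)
    assert vi["oscillation"] == pytest.approx(0.0, abs=0.2)
    assert vi["lti"] == pytest.approx(0.0, abs=0.05)


def _epoch_oracle_stv_ltv(rr_ms):
    """Direct evaluation of the Dawes epoch definitions on a ZOH 4 Hz grid."""
    series = rr_to_fhr(_ann_from_rr_ms(rr_ms))
    grid, ok = resample_4hz(series)
    step = 15  # 3.75 s x 4 Hz
    epochs = []
    for k in range(len(grid) // step):
        seg_ok = ok[k * step : (k + 1) * step]
        seg = grid[k * step : (k + 1) * step]
        if seg_ok.sum() >= step // 2:
            epochs.append(np.mean(60000.0 / seg[seg_ok]))
        else:
            epochs.append(np.nan)
    epochs = np.asarray(epochs)
    d = np.abs(np.diff(epochs))
    stv = np.nanmean(d[~np.isnan(d)]) if np.any(~np.isnan(d)) else None
    per_min = []
    for k in range(len(epochs) // 16):
        seg = epochs[k * 16 : (k + 1) * 16]
        seg = seg[~np.isnan(seg)]
        if len(seg) >= 8:
            per_min.append(seg.max() - seg.min())
    ltv = float(np.mean(per_min)) if per_min else None
    return stv, ltv


def test_epoch_indices_match_direct_oracle(rng):
    rr = 420.0 + rng.normal(scale=8.0, size=800).cumsum() * 0.01 \
        + rng.normal(scale=5.0, size=800)
    rr = np.clip(rr, 300, 600)
    series = rr_to_fhr(_ann_from_rr_ms(rr))
    vi = variability_indices(series)
    stv, ltv = _epoch_oracle_stv_ltv(rr)
    assert vi["stv_dawes"] == pytest.approx(stv, rel=1e-9)
    assert vi["ltv_dawes"] == pytest.approx(ltv, rel=1e-9)


def test_stv_monotonic_in_programmed_jitter():
    reported = []
    for sigma in (1.0, 4.0, 10.0):
        rng = np.random.default_rng(5)
        rr = 420.0 + rng.normal(scale=sigma, size=700)
        series = rr_to_fhr(_ann_from_rr_ms(rr))
        reported.append(variability_indices(series)["stv_dawes"])
    assert reported[0] < reported[1] < reported[2]


def test_full_report_recovers_programmed_patterns():
    cfg = simulate.SimulationConfig(
        duration_s=1200.0, seed=5, include_direct=False,
        fetal=simulate.FHRProfile(
            baseline_bpm=132.0,
            events=((60, 30, 22), (200, 40, 25), (350, 30, 22),
                    (500, 30, 25), (700, 35, 22), (900, 30, 24),
                    (420, 40, -22), (1000, 35, -25)),
            oscillation=(4.0, 0.05), jitter_ms=2.5,
        ),
    )
    bundle, truth = simulate.generate_record(cfg)
    report = fhr_report(truth.fetal_r)
    assert report.basal == pytest.approx(132.0, abs=2.0)
    assert report.acc_count == 6
    assert report.dec_count == 2
    assert report.loss_pct < 1.0


def test_empty_input_all_missing():
    report = fhr_report(BeatAnnotations(np.empty(0, int), RATE, "fetal"))
    assert report.basal is None
    assert report.loss_pct == 100.0


def test_batch_mean_equals_mean_of_records():
    import pandas as pd

    from fecgkit import reference
    from fecgkit.fhr import aggregate_fhr

    table = reference.b1_fhr_table()
    agg = aggregate_fhr(table)
    assert agg["Basal"] == pytest.approx(table["Basal"].mean())
    assert agg["Basal"] == pytest.approx(142.5, abs=0.051)


def test_time_shift_by_whole_grid_steps_invariant():
    rr = [400.0, 410.0, 405.0, 415.0] * 150
    a1 = _ann_from_rr_ms(rr)
    shifted = BeatAnnotations(a1.locations + 500, RATE, "fetal")  # +1 s
    v1 = variability_indices(rr_to_fhr(a1))
    v2 = variability_indices(rr_to_fhr(shifted))
    assert v1["stv_dawes"] == pytest.approx(v2["stv_dawes"], rel=0.05)
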