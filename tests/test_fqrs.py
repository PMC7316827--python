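"""Fetal QRS detection: function bank, peak picking, Δ selection, direct FECG."""

import numpy as np
import pytest

from fecgkit import fqrs, metrics, simulate
from fecgkit.io import MultichannelSignal

RATE = 500.0


def brute_force_delta(rr):
    """Literal double-difference evaluation of the variability functional."""
    rr = np.asarray(rr, dtype=float)
    i_k = len(rr) + 1  # number of peaks
    if i_k < 4:
        return float("nan")
    total = 0.0
    for i in range(i_k - 3):
        total += abs((rr[i + 2] - rr[i + 1]) - (rr[i + 1] - rr[i]))
    return total / (i_k - 3)


# ---------------------------------------------------------------------------
# RR intervals and the Δ functional
# ---------------------------------------------------------------------------

def test_rr_intervals_are_first_differences():
    c = fqrs.CandidateSeries(np.array([0, 200, 410]), 1)
    np.testing.assert_array_equal(fqrs.rr_intervals(c), [200, 210])


def test_rr_intervals_count():
    c = fqrs.CandidateSeries(np.arange(0, 3000, 300), 1)
    assert len(fqrs.rr_intervals(c)) == len(c.peaks) - 1


def test_delta_zero_for_constant_rr():
    assert fqrs.variability_functional(np.full(20, 300.0)) == 0.0


def test_delta_worked_alternating_sequence():
    # 6 peaks -> RR alternating 400,410,400,410,400 -> Δ = 20
    rr = np.array([400.0, 410.0, 400.0, 410.0, 400.0])
    assert fqrs.variability_functional(rr) == pytest.approx(20.0)


def test_delta_matches_brute_force_on_random_series(rng):
    for _ in range(1000):
        n = int(rng.integers(3, 40))
        rr = rng.uniform(150, 400, size=n)
        assert fqrs.variability_functional(rr) == pytest.approx(
            brute_force_delta(rr), rel=1e-12
        )


def test_delta_undefined_below_four_peaks():
    assert np.isnan(fqrs.variability_functional(np.array([300.0, 310.0])))


def test_spurious_extra_peak_increases_delta():
    peaks = np.arange(0, 6000, 210)
    with_extra = np.sort(np.append(peaks, 2305))
    d_clean = fqrs.variability_functional(np.diff(peaks).astype(float))
    d_spur = fqrs.variability_functional(np.diff(with_extra).astype(float))
    assert d_spur > d_clean


def test_select_optimal_minimum_and_tie_break():
    assert fqrs.select_optimal([5.0, 2.1, 7.3]) == 1
    assert fqrs.select_optimal([2.1, 2.1]) == 0
    assert fqrs.select_optimal([np.nan, 3.0]) == 1
    with pytest.raises(ValueError):
        fqrs.select_optimal([np.nan, np.nan])


# ---------------------------------------------------------------------------
# detection functions
# ---------------------------------------------------------------------------

def test_isolated_template_copy_reaches_unit_correlation():
    t = fqrs.fetal_qrs_seed(RATE)
    x = np.zeros(2000)
    c = 1000
    apex = int(np.argmax(np.abs(t)))
    x[c - apex : c - apex + len(t)] = 5.0 * t
    bank = fqrs.detection_function_bank(x, t, RATE)
    assert bank[0].values[c] == pytest.approx(1.0, abs=1e-9)
    assert np.argmax(bank[0].values) == c


def test_normalized_function_gain_invariant_raw_function_linear(rng):
    t = fqrs.fetal_qrs_seed(RATE)
    x = rng.normal(size=4000)
    bank1 = fqrs.detection_function_bank(x, t, RATE)
    bank2 = fqrs.detection_function_bank(0.5 * x, t, RATE)
    np.testing.assert_allclose(bank2[0].values, bank1[0].values, atol=1e-9)
    np.testing.assert_allclose(bank2[1].values, 0.5 * bank1[1].values, atol=1e-9)


def test_all_zero_template_rejected():
    with pytest.raises(ValueError, match="template"):
        fqrs.detection_function_bank(np.ones(100), np.zeros(21), RATE)


def test_bank_values_nonnegative(short_record):
    bundle, _ = short_record
    x = bundle.abdominal_raw.samples[0][:20000]
    t = fqrs.fetal_qrs_seed(RATE)
    for df in fqrs.detection_function_bank(x, t, RATE):
        assert np.all(df.values >= 0)
        assert np.all(np.isfinite(df.values))


# ---------------------------------------------------------------------------
# adaptive peak picking
# ---------------------------------------------------------------------------

def _spike_train(amps, spacing=210, noise=0.1, seed=3):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, noise, size=spacing * (len(amps) + 2))
    locs = spacing + np.arange(len(amps)) * spacing
    x[locs] = amps
    return fqrs.DetectionFunction(x, 1, "test"), locs


def test_regular_peaks_all_found_no_extras():
    df, locs = _spike_train(np.ones(40))
    c = fqrs.adaptive_peaks(df, RATE)
    np.testing.assert_array_equal(c.peaks, locs)


def test_threshold_adapts_to_amplitude_step():
    amps = np.concatenate([np.ones(30), 0.5 * np.ones(30)])
    df, locs = _spike_train(amps)
    c = fqrs.adaptive_peaks(df, RATE)
    missed = np.setdiff1d(locs, c.peaks)
    # adaptation within ~10 beats of the step: no sustained miss run
    assert len(missed) <= 10
    assert np.all(np.isin(locs[-15:], c.peaks))


def test_flat_input_yields_empty_series():
    df = fqrs.DetectionFunction(np.zeros(5000), 2, "flat")
    assert fqrs.adaptive_peaks(df, RATE).I == 0


# ---------------------------------------------------------------------------
# periodicity quality and channel selection
# ---------------------------------------------------------------------------

def _periodic_train(bpm, duration_s=30.0, rate=RATE):
    x = np.zeros(int(duration_s * rate))
    period = int(rate * 60.0 / bpm)
    t = fqrs.fetal_qrs_seed(rate)
    for c in range(period, len(x) - len(t), period):
        x[c : c + len(t)] += t
    return x


def test_periodic_train_in_range_scores_high():
    assert fqrs.periodicity_quality(_periodic_train(140.0), RATE) > 0.9


def test_white_noise_scores_low(rng):
    x = rng.normal(size=15000)
    assert fqrs.periodicity_quality(x, RATE) < 0.3


def test_out_of_range_periodicity_scores_lower():
    in_range = fqrs.periodicity_quality(_periodic_train(140.0), RATE)
    out_range = fqrs.periodicity_quality(_periodic_train(60.0), RATE)
    assert out_range < in_range


def test_clean_channel_selected_among_noise(rng):
    clean = _periodic_train(140.0)
    chans = np.stack([rng.normal(size=clean.size) for _ in range(3)] + [clean])
    sig = MultichannelSignal(chans, RATE, ("A1", "A2", "A3", "A4"))
    assert fqrs.select_best_channel(sig) == 3


def test_identical_channels_select_first():
    x = _periodic_train(140.0)
    sig = MultichannelSignal(np.tile(x, (4, 1)), RATE, ("A1", "A2", "A3", "A4"))
    assert fqrs.select_best_channel(sig) == 0


# ---------------------------------------------------------------------------
# direct-FECG detection
# ---------------------------------------------------------------------------

def test_clean_direct_fecg_detected_perfectly(short_record):
    bundle, truth = short_record
    ann = fqrs.detect_direct_fqrs(bundle.direct_fecg)
    m = metrics.match_beats(truth.fetal_r_direct, ann, tolerance_ms=40.0)
    p = metrics.performance_indices(m)
    assert p.Se == 100.0
    assert p.PPV >= 99.5


def test_empty_direct_signal_gives_no_beats():
    ann = fqrs.detect_direct_fqrs(np.zeros(5000), 1000.0)
    assert len(ann) == 0


def test_competing_artifact_peaks_rejected_by_cost_rule(rng):
    cfg = simulate.SimulationConfig(duration_s=120.0, seed=21)
    bundle, truth = simulate.generate_record(cfg)
    x = bundle.direct_fecg.samples[0].copy()
    rate_d = 1000.0
    wave, apex = simulate.synth_beat_morphology("fetal", rate_d)
    # insert an artifact (fetal-shaped, comparable amplitude) halfway
    # through every 10th RR interval
    locs = truth.fetal_r_direct.locations
    n_art = 0
    for i in range(4, len(locs) - 1, 10):
        mid = (locs[i] + locs[i + 1]) // 2
        s = mid - apex
        x[s : s + len(wave)] += 28.0 * wave
        n_art += 1
    ann = fqrs.detect_direct_fqrs(x, rate_d)
    m = metrics.match_beats(truth.fetal_r_direct, ann, tolerance_ms=40.0)
    p = metrics.performance_indices(m)
    assert p.Se >= 95.0 and p.PPV >= 95.0


# ---------------------------------------------------------------------------
# full abdominal chain (noise-free)
# ---------------------------------------------------------------------------

def test_noiseless_chain_perfect_detection(noiseless_record):
    from fecgkit import mecg, preprocess

    bundle, truth = noiseless_record
    filt = preprocess.comb_filter(bundle.abdominal_raw)
    fecg, _, _ = mecg.suppress_mecg(filt)
    ann, detail = fqrs.detect_fetal_r(fecg)
    m = metrics.match_beats(truth.fetal_r, ann, tolerance_ms=40.0)
    p = metrics.performance_indices(m)
    assert p.Se == 100.0 and p.PPV == 100.0
    offsets_ms = [
        abs(truth.fetal_r.locations[i] - ann.locations[j]) * 2.0
        for i, j in m.pairs
    ]
    assert np.mean(offsets_ms) <= 2.0


def test_optimal_function_tracks_ground_truth(short_record):
    from fecgkit import mecg, preprocess

    bundle, truth = short_record
    filt = preprocess.comb_filter(bundle.abdominal_raw)
    fecg, _, _ = mecg.suppress_mecg(filt)
    ann, detail = fqrs.detect_fetal_r(fecg)
    m = metrics.match_beats(truth.fetal_r, ann, tolerance_ms=40.0)
    p = metrics.performance_indices(m)
    assert p.Se >= 95.0 and p.PPV >= 95.0
    assert ann.flags is not None and set(ann.flags) <= {0, 1}
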