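"""Fetal heart-rate series construction and clinical variability analysis.

From R-wave annotations the instantaneous rate FHR_i = 60000 / RR_i (ms) is
formed as a time series of events, resampled by zero-order hold onto the
4 Hz grid that fetal monitors use, and summarised by the classic
time-domain report: signal loss, basal FHR, FHR fluctuation, acceleration
and deceleration counts, oscillation range, Dawes/Redman short- and
long-term variability (3.75 s epochs), the de Haan long/short-term
irregularity indices (LTI/STI) and the Yeh interval/differential indices
(II/DI).

Intervals adjacent to a beat carrying reliability flag 0 are masked, as are
intervals outside the 50-250 bpm physiologic gate; masked spans count as
signal loss and are excluded from every statistic.

Accelerations (decelerations) are excursions of at least +15 (-15) bpm from
the baseline lasting at least 15 s.  Episodes truncated by the start or end
of the recording are not counted, since their full extent cannot be
verified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .io import BeatAnnotations

__all__ = [
    "FHRSeries",
    "Episode",
    "FHRReport",
    "rr_to_fhr",
    "resample_4hz",
    "baseline_and_fluctuation",
    "detect_acc_dec",
    "variability_indices",
    "fhr_report",
    "aggregate_fhr",
    "GRID_RATE_HZ",
]

GRID_RATE_HZ = 4.0  # cardiotocography standard
_EPOCH_S = 3.75  # Dawes/Redman epoch (16 per minute)
_ACC_THRESHOLD_BPM = 15.0
_ACC_MIN_DURATION_S = 15.0
_GATE_BPM = (50.0, 250.0)


@dataclass
class FHRSeries:
    """Beat-event FHR series plus its 4 Hz zero-order-hold grid."""

    beat_times_ms: np.ndarray  # time of the end-beat of each interval
    fhr_values: np.ndarray  # bpm per interval
    valid: np.ndarray  # interval mask (False = unreliable)
    duration_ms: float

    @property
    def rr_ms(self) -> np.ndarray:
        return 60000.0 / self.fhr_values

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass(frozen=True)
class Episode:
    onset_s: float
    duration_s: float
    extremum_bpm: float  # signed offset from baseline at the extremum


@dataclass
class FHRReport:
    loss_pct: Optional[float] = None
    basal: Optional[float] = None
    fluctuation: Optional[float] = None
    acc_count: Optional[int] = None
    dec_count: Optional[int] = None
    oscillation: Optional[float] = None
    ltv_dawes: Optional[float] = None
    stv_dawes: Optional[float] = None
    lti: Optional[float] = None
    sti: Optional[float] = None
    ii: Optional[float] = None
    di: Optional[float] = None
    accelerations: tuple = field(default_factory=tuple)
    decelerations: tuple = field(default_factory=tuple)

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "Loss": self.loss_pct,
                "Basal": self.basal,
                "Fluct": self.fluctuation,
                "Acc": self.acc_count,
                "Dec": self.dec_count,
                "Osc": self.oscillation,
                "LTV": self.ltv_dawes,
                "STV": self.stv_dawes,
                "LTI": self.lti,
                "STI": self.sti,
                "II": self.ii,
                "DI": self.di,
            }
        )


def rr_to_fhr(
    annotations: BeatAnnotations,
    rate: Optional[float] = None,
    flags: Optional[np.ndarray] = None,
) -> FHRSeries:
    """Instantaneous FHR per RR interval with reliability masking.

    Both intervals adjoining a flag-0 beat are masked; values outside the
    50-250 bpm gate are masked as non-physiologic.
    """
    if isinstance(annotations, BeatAnnotations):
        locs = annotations.locations
        rate = annotations.rate
        if flags is None:
            flags = annotations.flags
    else:
        locs = np.asarray(annotations, dtype=np.int64)
        if rate is None:
            raise ValueError("rate required with a bare index array")
    times_ms = locs * 1000.0 / rate
    duration = times_ms[-1] if len(times_ms) else 0.0
    if len(locs) < 2:
        empty = np.empty(0)
        return FHRSeries(empty, empty, np.empty(0, dtype=bool), duration)
    rr = np.diff(times_ms)
    fhr = 60000.0 / rr
    valid = (fhr >= _GATE_BPM[0]) & (fhr <= _GATE_BPM[1])
    if flags is not None:
        bad = np.asarray(flags) == 0
        valid &= ~(bad[:-1] | bad[1:])  # an interval touches two beats
    return FHRSeries(times_ms[1:], fhr, valid, duration)


def resample_4hz(series: FHRSeries) -> tuple[np.ndarray, np.ndarray]:
    """Zero-order hold onto the 250 ms grid.

    Each grid point takes the FHR of the interval covering it; grid points
    inside masked intervals, or before the first / after the last beat, are
    invalid.  Returns (grid values in bpm, validity mask).
    """
    step = 1000.0 / GRID_RATE_HZ
    n_grid = max(int(np.floor(series.duration_ms / step)) + 1, 0)
    grid = np.full(n_grid, np.nan)
    ok = np.zeros(n_grid, dtype=bool)
    if len(series.fhr_values) == 0:
        return grid, ok
    t = np.arange(n_grid) * step
    starts = series.beat_times_ms - series.rr_ms
    idx = np.searchsorted(series.beat_times_ms, t, side="left")
    inside = (idx < len(series.beat_times_ms)) & (t >= starts[0])
    idx_c = np.minimum(idx, len(series.beat_times_ms) - 1)
    value = series.fhr_values[idx_c]
    valid = series.valid[idx_c] & inside
    grid[valid] = value[valid]
    ok[valid] = True
    return grid, ok


def signal_loss_pct(ok: np.ndarray) -> float:
    if len(ok) == 0:
        return 100.0
    return float((1.0 - ok.mean()) * 100.0)


def _lowpass_baseline(grid: np.ndarray, ok: np.ndarray) -> np.ndarray:
    """0.04 Hz low-pass of the grid with invalid gaps bridged by interpolation."""
    filled = grid.copy()
    if not ok.all():
        t = np.arange(len(grid))
        if ok.sum() < 2:
            return np.full_like(grid, np.nan)
        filled = np.interp(t, t[ok], grid[ok])
    if len(filled) < 50:
        return np.full_like(grid, np.nanmedian(filled))
    b, a = butter(2, 0.04 / (GRID_RATE_HZ / 2.0))
    return filtfilt(b, a, filled)


def baseline_and_fluctuation(
    grid: np.ndarray, ok: np.ndarray, exclude: Optional[np.ndarray] = None
) -> tuple[Optional[float], Optional[float]]:
    """Basal FHR and mean minute-wise fluctuation around it.

    The basal level starts from the histogram mode (0.5 bpm bins) of a
    0.04 Hz low-passed grid; samples deviating more than 10 bpm from the
    current level (acceleration/deceleration excursions) are excluded and
    the level re-estimated as the median of the remainder, twice.
    Fluctuation is the mean over minutes of the peak-to-peak excursion of
    the valid grid around the basal level.
    """
    if ok.sum() < 4:
        return None, None
    trend = _lowpass_baseline(grid, ok)
    sel = ok.copy()
    basal = None
    for it in range(3):
        vals = trend[sel]
        if len(vals) == 0:
            break
        if it == 0:
            lo, hi = np.nanmin(vals), np.nanmax(vals)
            bins = max(int(np.ceil((hi - lo) / 0.5)), 1)
            hist, edges = np.histogram(vals, bins=bins)
            center = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
        else:
            center = float(np.median(vals))
        basal = float(center)
        sel = ok & (np.abs(trend - basal) <= 10.0)
    if basal is None:
        return None, None

    use = ok if exclude is None else (ok & ~exclude)
    per_min = []
    step = int(60 * GRID_RATE_HZ)
    for s in range(0, len(grid), step):
        seg, seg_ok = grid[s : s + step], use[s : s + step]
        if seg_ok.sum() >= step // 2:
            dev = seg[seg_ok] - basal
            per_min.append(dev.max() - dev.min())
    fluct = float(np.mean(per_min)) if per_min else None
    return basal, fluct


def detect_acc_dec(
    grid: np.ndarray,
    ok: np.ndarray,
    baseline: float,
    threshold_bpm: float = _ACC_THRESHOLD_BPM,
    min_duration_s: float = _ACC_MIN_DURATION_S,
) -> tuple[tuple[Episode, ...], tuple[Episode, ...]]:
    """Acceleration and deceleration episodes relative to the baseline.

    Following obstetric convention, an episode spans the interval during
    which the trace departs from the baseline (onset threshold one third of
    the main threshold); it is counted when its peak excursion reaches the
    threshold (±15 bpm) and its duration reaches the minimum (15 s).
    Episodes already in progress at the record boundaries are discarded,
    since their full extent cannot be verified.
    """
    step_s = 1.0 / GRID_RATE_HZ
    min_len = int(round(min_duration_s / step_s))
    onset_bpm = threshold_bpm / 3.0
    dev = np.where(ok, grid - baseline, 0.0)

    def episodes(sign: float) -> tuple[Episode, ...]:
        above = sign * dev >= onset_bpm
        out = []
        n = len(above)
        s = 0
        while s < n:
            if not above[s]:
                s += 1
                continue
            e = s
            while e < n and above[e]:
                e += 1
            seg = dev[s:e]
            ext = seg.max() if sign > 0 else seg.min()
            if (e - s) >= min_len and abs(ext) >= threshold_bpm and s > 0 and e < n:
                out.append(Episode(s * step_s, (e - s) * step_s, float(ext)))
            s = e
        return tuple(out)

    return episodes(+1.0), episodes(-1.0)


def _epoch_rr(grid: np.ndarray, ok: np.ndarray) -> np.ndarray:
    """Mean RR (ms) per 3.75 s epoch; NaN where fewer than half the samples
    are valid."""
    step = int(round(_EPOCH_S * GRID_RATE_HZ))
    n_ep = len(grid) // step
    out = np.full(n_ep, np.nan)
    for k in range(n_ep):
        seg_ok = ok[k * step : (k + 1) * step]
        seg = grid[k * step : (k + 1) * step]
        if seg_ok.sum() >= step // 2:
            out[k] = np.mean(60000.0 / seg[seg_ok])
    return out


def variability_indices(series: FHRSeries) -> dict[str, Optional[float]]:
    """STV/LTV (Dawes), oscillation, LTI/STI (de Haan) and II/DI (Yeh).

    Epoch-based indices use 3.75 s mean RR values; LTV is the mean of
    minute-wise epoch ranges, STV the mean absolute successive epoch
    difference.  Oscillation is the mean minute-wise peak-to-peak range of
    the fast FHR component (grid minus its 0.04 Hz trend).  Beat-based indices use valid adjacent RR pairs: LTI is the
    interquartile range of sqrt(RR_i^2 + RR_{i+1}^2); STI the interquartile
    range of arctan(RR_{i+1}/RR_i); II the coefficient of variation of RR;
    DI is 1000 x the standard deviation of (RR_{i+1}-RR_i)/(RR_{i+1}+RR_i).
    """
    grid, ok = resample_4hz(series)
    out: dict[str, Optional[float]] = dict.fromkeys(
        ("stv_dawes", "ltv_dawes", "oscillation", "lti", "sti", "ii", "di")
    )

    ep = _epoch_rr(grid, ok)
    dd = np.abs(np.diff(ep))
    dd = dd[~np.isnan(dd)]
    if len(dd):
        out["stv_dawes"] = float(dd.mean())
    per_min_rng, per_min_osc = [], []
    ep_per_min = int(round(60.0 / _EPOCH_S))
    for k in range(len(ep) // ep_per_min):
        seg = ep[k * ep_per_min : (k + 1) * ep_per_min]
        seg = seg[~np.isnan(seg)]
        if len(seg) >= ep_per_min // 2:
            per_min_rng.append(seg.max() - seg.min())
    trend = _lowpass_baseline(grid, ok)
    fast = grid - trend
    step = int(60 * GRID_RATE_HZ)
    for s in range(0, len(grid), step):
        g, go = fast[s : s + step], ok[s : s + step]
        if go.sum() >= step // 2:
            per_min_osc.append(g[go].max() - g[go].min())
    if per_min_rng:
        out["ltv_dawes"] = float(np.mean(per_min_rng))
    if per_min_osc:
        out["oscillation"] = float(np.mean(per_min_osc))

    rr = series.rr_ms
    pair_ok = series.valid[:-1] & series.valid[1:]
    if pair_ok.sum() >= 4:
        r0, r1 = rr[:-1][pair_ok], rr[1:][pair_ok]
        modulus = np.sqrt(r0**2 + r1**2)
        q75, q25 = np.percentile(modulus, [75, 25])
        out["lti"] = float(q75 - q25)
        ang = np.arctan2(r1, r0)
        a75, a25 = np.percentile(ang, [75, 25])
        out["sti"] = float(a75 - a25)
        d = (r1 - r0) / (r1 + r0)
        out["di"] = float(1000.0 * d.std(ddof=1))
    # interval index per minute (short-segment coefficient of variation)
    ii_vals = []
    tms = series.beat_times_ms
    for s in range(0, int(series.duration_ms), 60000):
        in_min = (tms >= s) & (tms < s + 60000) & series.valid
        seg = rr[in_min]
        if len(seg) >= 10:
            ii_vals.append(seg.std(ddof=1) / seg.mean())
    if ii_vals:
        out["ii"] = float(np.mean(ii_vals))
    return out


def fhr_report(
    annotations: BeatAnnotations,
    rate: Optional[float] = None,
    flags: Optional[np.ndarray] = None,
) -> FHRReport:
    """Full clinical FHR report for one record."""
    series = rr_to_fhr(annotations, rate, flags)
    report = FHRReport()
    grid, ok = resample_4hz(series)
    report.loss_pct = signal_loss_pct(ok)
    if ok.sum() == 0:
        return report
    basal, fluct = baseline_and_fluctuation(grid, ok)
    report.basal, report.fluctuation = basal, fluct
    if basal is not None:
        acc, dec = detect_acc_dec(grid, ok, basal)
        report.accelerations, report.decelerations = acc, dec
        report.acc_count, report.dec_count = len(acc), len(dec)
        # fluctuation is a baseline property: exclude episode spans
        exclude = np.zeros(len(grid), dtype=bool)
        for ep in acc + dec:
            s0 = int(ep.onset_s * GRID_RATE_HZ)
            exclude[s0 : s0 + int(ep.duration_s * GRID_RATE_HZ)] = True
        if exclude.any():
            _, fluct = baseline_and_fluctuation(grid, ok, exclude)
            report.fluctuation = fluct
    vi = variability_indices(series)
    report.oscillation = vi["oscillation"]
    report.ltv_dawes = vi["ltv_dawes"]
    report.stv_dawes = vi["stv_dawes"]
    report.lti, report.sti = vi["lti"], vi["sti"]
    report.ii, report.di = vi["ii"], vi["di"]
    return report


def aggregate_fhr(per_record: pd.DataFrame) -> pd.Series:
    """Batch summary over per-record FHR reports (mean of each column)."""
    return per_record.mean(numeric_only=True)
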