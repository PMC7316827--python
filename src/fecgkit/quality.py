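"""Amplitude-relationship (SNR) indices of abdominal signals.

The abdominal signal is decomposed around the two annotation sets: samples
outside every maternal QRS window (100 ms) and fetal QRS window (40 ms)
define the mean interference power P_N; the maternal power P_M is the mean
square inside non-coincident maternal QRS windows minus P_N, and P_F is the
fetal analogue.  From these,

    WM  = 10 log10(P_M / P_N)   [dB]
    WF  = 10 log10(P_F / P_N)   [dB]
    WMF = WM - WF               [dB]

A maternal and a fetal QRS are "coincident" when their windows overlap;
coincident beats are excluded from the power estimates because the two
deflections superimpose there.

QRS energy stability is quantified through per-beat projection coefficients
r_i of each beat onto the mean beat shape,

    r_i = sum_k QRS_avg(k) QRS_i(k) / sum_k QRS_avg(k)^2,

summarised by WEM (maternal) and WEF (fetal) as the RMS of successive
r_i differences divided by the mean r_i; zero when amplitude and shape are
constant.  (The squared-difference form is used so the radicand is always
nonnegative; an absolute-difference variant is available via ``mode``.)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .io import BeatAnnotations, MultichannelSignal, RecordBundle

__all__ = [
    "PowerDecomposition",
    "QualityReport",
    "coincidence_partition",
    "estimate_powers",
    "snr_indices",
    "amplitude_change_coefficients",
    "energy_variation_index",
    "channel_quality",
    "record_quality_report",
    "aggregate_quality",
    "MQRS_WIDTH_MS",
    "FQRS_WIDTH_MS",
]

#: Mean QRS window widths (full width, centred on the R fiducial).
MQRS_WIDTH_MS = 100.0
FQRS_WIDTH_MS = 40.0


@dataclass
class PowerDecomposition:
    P_N: float
    P_M: Optional[float]  # None when no non-coincident maternal beats
    P_F: Optional[float]
    J: int  # non-coincident maternal QRS count
    I: int  # non-coincident fetal QRS count
    clipped_M: bool = False  # P_M went negative and was clipped at 0
    clipped_F: bool = False


@dataclass
class QualityReport:
    """Per-channel WM/WF/WMF/WEM/WEF and their across-channel means."""

    per_channel: pd.DataFrame  # rows = channels, cols = WM, WF, WMF, WEM, WEF
    mean: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self.mean = self.per_channel.mean()


def _windows(locs: np.ndarray, half: int, n: int) -> np.ndarray:
    """(start, stop) half-open sample windows clipped to [0, n)."""
    starts = np.clip(locs - half, 0, n)
    stops = np.clip(locs + half + 1, 0, n)
    return np.column_stack([starts, stops])


def coincidence_partition(
    m_locs: BeatAnnotations | np.ndarray,
    f_locs: BeatAnnotations | np.ndarray,
    rate: float,
    m_width_ms: float = MQRS_WIDTH_MS,
    f_width_ms: float = FQRS_WIDTH_MS,
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of maternal and fetal beats whose QRS windows do not overlap.

    Windows are centred on the R fiducials (m_width_ms and f_width_ms full
    widths).  Returns (non-coincident maternal beat indices, non-coincident
    fetal beat indices); J and I are their lengths.
    """
    m = m_locs.locations if isinstance(m_locs, BeatAnnotations) else np.asarray(m_locs)
    f = f_locs.locations if isinstance(f_locs, BeatAnnotations) else np.asarray(f_locs)
    mh = m_width_ms / 2000.0 * rate
    fh = f_width_ms / 2000.0 * rate
    # windows [c-h, c+h] overlap iff |cm - cf| <= mh + fh
    gap = mh + fh
    m_coinc = np.zeros(len(m), dtype=bool)
    f_coinc = np.zeros(len(f), dtype=bool)
    if len(m) and len(f):
        j = np.searchsorted(f, m)
        for off in (-1, 0):
            k = np.clip(j + off, 0, len(f) - 1)
            hit = np.abs(m - f[k]) <= gap
            m_coinc |= hit
        i = np.searchsorted(m, f)
        for off in (-1, 0):
            k = np.clip(i + off, 0, len(m) - 1)
            f_coinc |= np.abs(f - m[k]) <= gap
    return np.flatnonzero(~m_coinc), np.flatnonzero(~f_coinc)


def estimate_powers(
    channel: np.ndarray,
    m_locs: np.ndarray,
    f_locs: np.ndarray,
    rate: float,
    m_width_ms: float = MQRS_WIDTH_MS,
    f_width_ms: float = FQRS_WIDTH_MS,
) -> PowerDecomposition:
    """P_N / P_M / P_F decomposition of one abdominal channel.

    Assumes the useful deflections and the interference are uncorrelated, so
    the power measured inside a QRS window is the sum of the QRS power and
    P_N.
    """
    x = np.asarray(channel, dtype=float)
    n = len(x)
    m_locs = np.asarray(m_locs, dtype=np.int64)
    f_locs = np.asarray(f_locs, dtype=np.int64)
    mh = int(round(m_width_ms / 2000.0 * rate))
    fh = int(round(f_width_ms / 2000.0 * rate))

    in_any = np.zeros(n, dtype=bool)
    for s, e in _windows(m_locs, mh, n):
        in_any[s:e] = True
    for s, e in _windows(f_locs, fh, n):
        in_any[s:e] = True
    outside = ~in_any
    if not outside.any():
        raise ValueError("no samples outside QRS windows; cannot estimate P_N")
    p_n = float(np.mean(x[outside] ** 2))

    m_free, f_free = coincidence_partition(
        m_locs, f_locs, rate, m_width_ms, f_width_ms
    )

    def window_power(locs: np.ndarray, half: int) -> Optional[float]:
        if len(locs) == 0:
            return None
        seg = np.concatenate([x[s:e] for s, e in _windows(locs, half, n)])
        return float(np.mean(seg**2)) if len(seg) else None

    pm_raw = window_power(m_locs[m_free], mh)
    pf_raw = window_power(f_locs[f_free], fh)
    clipped_m = pm_raw is not None and pm_raw - p_n < 0
    clipped_f = pf_raw is not None and pf_raw - p_n < 0
    return PowerDecomposition(
        P_N=p_n,
        P_M=None if pm_raw is None else max(pm_raw - p_n, 0.0),
        P_F=None if pf_raw is None else max(pf_raw - p_n, 0.0),
        J=len(m_free),
        I=len(f_free),
        clipped_M=clipped_m,
        clipped_F=clipped_f,
    )


def snr_indices(p: PowerDecomposition) -> tuple[float, float, float]:
    """(WM, WF, WMF) in dB; -inf when the respective power is 0 or missing."""
    if p.P_N <= 0:
        raise ValueError("P_N must be positive")

    def db(power: Optional[float]) -> float:
        if power is None or power <= 0:
            return -np.inf
        return 10.0 * np.log10(power / p.P_N)

    wm, wf = db(p.P_M), db(p.P_F)
    return wm, wf, wm - wf


def amplitude_change_coefficients(
    channel: np.ndarray,
    beat_locs: np.ndarray,
    rate: float,
    width_ms: float,
) -> np.ndarray:
    """Projection coefficient r_i of each beat onto the mean beat shape."""
    x = np.asarray(channel, dtype=float)
    locs = np.asarray(beat_locs, dtype=np.int64)
    half = int(round(width_ms / 2000.0 * rate))
    keep = (locs - half >= 0) & (locs + half + 1 <= len(x))
    locs = locs[keep]
    if len(locs) == 0:
        raise ValueError("no complete beat windows")
    beats = np.stack([x[c - half : c + half + 1] for c in locs])
    avg = beats.mean(axis=0)
    denom = float(np.sum(avg**2))
    if denom == 0:
        raise ValueError("zero-energy mean beat")
    return beats @ avg / denom


def energy_variation_index(r: np.ndarray, mode: str = "rms") -> float:
    """WEM/WEF: variation of successive r_i normalised by the mean r.

    ``mode="rms"`` (default) uses sqrt(mean((r_{i+1}-r_i)^2)); ``mode="abs"``
    uses sqrt(mean|r_{i+1}-r_i|), the literal reading of the printed formula.
    """
    r = np.asarray(r, dtype=float)
    if len(r) < 2:
        raise ValueError("need at least two coefficients")
    mean_r = r.mean()
    if mean_r <= 0:
        raise ValueError("mean projection coefficient must be positive")
    d = np.diff(r)
    if mode == "rms":
        num = np.sqrt(np.mean(d**2))
    elif mode == "abs":
        num = np.sqrt(np.mean(np.abs(d)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(num / mean_r)


def channel_quality(
    channel: np.ndarray,
    m_locs: np.ndarray,
    f_locs: np.ndarray,
    rate: float,
) -> pd.Series:
    """All five indices for one channel."""
    p = estimate_powers(channel, m_locs, f_locs, rate)
    wm, wf, wmf = snr_indices(p)
    m_free, f_free = coincidence_partition(m_locs, f_locs, rate)

    def evi(locs: np.ndarray, width: float) -> float:
        try:
            r = amplitude_change_coefficients(channel, locs, rate, width)
            return energy_variation_index(r)
        except ValueError:
            return np.nan

    wem = evi(np.asarray(m_locs)[m_free], MQRS_WIDTH_MS)
    wef = evi(np.asarray(f_locs)[f_free], FQRS_WIDTH_MS)
    return pd.Series({"WM": wm, "WF": wf, "WMF": wmf, "WEM": wem, "WEF": wef})


def record_quality_report(
    bundle_or_signal: RecordBundle | MultichannelSignal,
    maternal_r: Optional[BeatAnnotations] = None,
    fetal_r: Optional[BeatAnnotations] = None,
) -> QualityReport:
    """Per-channel indices and their across-channel mean for one record.

    Fetal annotations given at the direct-FECG rate are re-indexed to the
    abdominal rate first.
    """
    if isinstance(bundle_or_signal, RecordBundle):
        signal = bundle_or_signal.abdominal_raw
        maternal_r = bundle_or_signal.maternal_r
        fetal_r = bundle_or_signal.fetal_r
    else:
        signal = bundle_or_signal
        if maternal_r is None or fetal_r is None:
            raise ValueError("annotations required with a bare signal")
    if fetal_r.rate != signal.rate:
        fetal_r = fetal_r.resampled(signal.rate)
    if maternal_r.rate != signal.rate:
        maternal_r = maternal_r.resampled(signal.rate)
    rows = {
        label: channel_quality(
            signal.samples[i], maternal_r.locations, fetal_r.locations, signal.rate
        )
        for i, label in enumerate(signal.labels)
    }
    return QualityReport(per_channel=pd.DataFrame(rows).T)


def aggregate_quality(per_record: pd.DataFrame) -> pd.Series:
    """Batch summary: arithmetic mean of per-record index values.

    ``per_record`` has one row per record and index columns (e.g. WM, WF,
    WEM, WEF); the same aggregation path serves measured and published
    per-record tables.
    """
    return per_record.mean(numeric_only=True)
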