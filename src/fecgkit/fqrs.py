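"""Fetal QRS detection on MECG-suppressed abdominal signals.

A bank of K = 3 detection functions is computed on the selected FECG
channel:

1. normalized matched filter — correlation with a fetal QRS template
   divided by the local signal energy (Cauchy-Schwarz bound 1 at a perfect
   match), which makes the function invariant to channel gain and much less
   sensitive to broadband EMG bursts;
2. raw matched-filter magnitude;
3. classic band-pass energy (15-45 Hz band-pass, differentiate, square,
   40 ms moving integration).

Each function is peak-picked with an adaptive threshold (half the running
accepted-peak level, 200 ms refractory).  The best function is the one
whose RR series is smoothest, measured by the mean absolute second
difference of the RR intervals,

    Δ_k = sum_i |[RR_k(i+2) - RR_k(i+1)] - [RR_k(i+1) - RR_k(i)]| / (I_k - 3),

and the best channel is chosen beforehand by an autocorrelation
periodicity score searched over the fetal heart-rate lag range.

Since no annotated fetal template exists at run time, the matched-filter
template is bootstrapped from the record itself: a generic narrow biphasic
QRS seed finds the strongest normalized-correlation events, whose aligned
average becomes the working template.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, fftconvolve, filtfilt

from .io import BeatAnnotations, MultichannelSignal

__all__ = [
    "DetectionFunction",
    "CandidateSeries",
    "detection_function_bank",
    "adaptive_peaks",
    "rr_intervals",
    "variability_functional",
    "select_optimal",
    "periodicity_quality",
    "select_best_channel",
    "bootstrap_fetal_template",
    "fetal_qrs_seed",
    "detect_fetal_r",
    "detect_direct_fqrs",
]

BETA = 0.5            # threshold fraction of the running peak level
UPDATE_WEIGHT = 1.0 / 8.0
REFRACTORY_MS = 200.0  # fetal HR <= 300 bpm
FHR_RANGE_BPM = (110.0, 180.0)
TEMPLATE_MS = 40.0     # fetal QRS width


@dataclass
class DetectionFunction:
    values: np.ndarray
    k: int
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class CandidateSeries:
    peaks: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.peaks = np.asarray(self.peaks, dtype=np.int64)

    @property
    def I(self) -> int:
        return len(self.peaks)


def fetal_qrs_seed(rate: float) -> np.ndarray:
    """Generic narrow biphasic QRS seed (~40 ms support) for bootstrapping."""
    half = int(round(TEMPLATE_MS / 2000.0 * rate))
    t_ms = np.arange(-half, half + 1) / rate * 1000.0
    w = (
        np.exp(-0.5 * (t_ms / 4.0) ** 2)
        - 0.10 * np.exp(-0.5 * ((t_ms + 9.0) / 2.6) ** 2)
        - 0.12 * np.exp(-0.5 * ((t_ms - 9.0) / 2.6) ** 2)
    )
    return w / np.abs(w).max()


def _centered_correlation(x: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Correlation of x with the template, aligned on the template apex."""
    apex = int(np.argmax(np.abs(template)))
    corr = fftconvolve(x, template[::-1], mode="full")
    # full-correlation index (len(t)-1 + n) corresponds to template start at n
    start = len(template) - 1 - apex
    return corr[start : start + len(x)]


def _local_energy(x: np.ndarray, width: int, apex: int) -> np.ndarray:
    kernel = np.ones(width)
    e = fftconvolve(x**2, kernel, mode="full")
    start = width - 1 - apex
    return e[start : start + len(x)]


def detection_function_bank(
    fecg: np.ndarray,
    template: np.ndarray,
    rate: float,
) -> list[DetectionFunction]:
    """K = 3 nonnegative detection functions, index-aligned with the input."""
    x = np.asarray(fecg, dtype=float)
    t = np.asarray(template, dtype=float)
    e_t = float(np.sum(t**2))
    if e_t == 0:
        raise ValueError("all-zero template")
    apex = int(np.argmax(np.abs(t)))
    corr = _centered_correlation(x, t)
    e_x = _local_energy(x, len(t), apex)
    floor = 1e-12 * max(e_x.max(), 1e-30)
    nmf = np.abs(corr) / np.sqrt(e_t * np.maximum(e_x, floor))
    nmf = np.minimum(nmf, 1.0)

    mf = np.abs(corr)

    low, high = 15.0 / (rate / 2), min(45.0 / (rate / 2), 0.99)
    b, a = butter(2, [low, high], btype="band")
    bp = filtfilt(b, a, x)
    d = np.gradient(bp) ** 2
    win = max(int(round(0.040 * rate)), 1)
    energy = np.convolve(d, np.ones(win) / win, mode="same")

    return [
        DetectionFunction(nmf, 1, "normalized-matched-filter"),
        DetectionFunction(mf, 2, "matched-filter"),
        DetectionFunction(energy, 3, "bandpass-energy"),
    ]


def adaptive_peaks(
    df: DetectionFunction,
    rate: float,
    beta: float = BETA,
    update_weight: float = UPDATE_WEIGHT,
    refractory_ms: float = REFRACTORY_MS,
) -> CandidateSeries:
    """Peak picking with a continuously updated threshold.

    The threshold is ``beta`` times a robust running level of the accepted
    peak amplitudes — the level is updated exponentially toward the median
    of the last 8 accepted peaks, so isolated spurious accepts cannot drag
    the threshold down.  A 200 ms refractory period enforces the
    physiologic ceiling on fetal heart rate; when two peaks compete inside
    the refractory window the stronger one is kept.
    """
    v = df.values
    if len(v) == 0 or not np.any(v > 0):
        return CandidateSeries(np.empty(0, dtype=np.int64), df.k)
    maxima = np.flatnonzero((v[1:-1] > v[:-2]) & (v[1:-1] >= v[2:])) + 1
    if len(maxima) == 0:
        return CandidateSeries(np.empty(0, dtype=np.int64), df.k)
    refractory = int(round(refractory_ms * rate / 1000.0))
    early = maxima[maxima < int(5 * rate)]
    ev = v[early if len(early) else maxima]
    # strongest early peaks set the starting level; the percentile floor
    # guards against a single artifact dominating the initialisation
    level = float(max(np.percentile(ev, 95), 0.5 * ev.max()))
    if level <= 0:
        return CandidateSeries(np.empty(0, dtype=np.int64), df.k)

    n_recent = 8
    recent: list[float] = [level]
    accepted: list[int] = []
    for p in maxima:
        if accepted and p - accepted[-1] < refractory:
            if v[p] > v[accepted[-1]] and (
                len(accepted) < 2 or p - accepted[-2] >= refractory
            ):
                accepted[-1] = int(p)
                recent[-1] = float(v[p])
            continue
        if v[p] >= beta * level:
            accepted.append(int(p))
            recent.append(float(v[p]))
            if len(recent) > n_recent:
                recent.pop(0)
            level = (1.0 - update_weight) * level + update_weight * float(
                np.median(recent)
            )
    return CandidateSeries(np.asarray(accepted, dtype=np.int64), df.k)


def rr_intervals(c: CandidateSeries) -> np.ndarray:
    """First differences of the peak series (samples); empty if < 2 peaks."""
    if c.I < 2:
        return np.empty(0)
    return np.diff(c.peaks).astype(float)


def variability_functional(rr: np.ndarray) -> float:
    """Mean absolute second difference of the RR series (Δ, samples).

    Undefined (NaN) when the series stems from fewer than 4 peaks.
    """
    rr = np.asarray(rr, dtype=float)
    if len(rr) < 3:
        return float("nan")
    second = (rr[2:] - rr[1:-1]) - (rr[1:-1] - rr[:-2])
    return float(np.mean(np.abs(second)))


def select_optimal(deltas: np.ndarray) -> int:
    """0-based index of the smallest defined Δ; ties go to the smallest k."""
    deltas = np.asarray(deltas, dtype=float)
    if np.all(np.isnan(deltas)):
        raise ValueError(
            "no detection function produced enough beats; use a longer signal"
        )
    return int(np.nanargmin(deltas))


def periodicity_quality(
    channel: np.ndarray,
    rate: float,
    fhr_range_bpm: tuple[float, float] = FHR_RANGE_BPM,
    window_s: float = 4.0,
) -> float:
    """Autocorrelation periodicity score in [0, 1].

    The normalized autocorrelation of consecutive windows is maximised over
    lags corresponding to the expected fetal heart-rate range and averaged
    across windows.  The window length exceeds twice the longest expected
    RR interval.
    """
    x = np.asarray(channel, dtype=float)
    lag_lo = int(np.floor(rate * 60.0 / fhr_range_bpm[1]))
    lag_hi = int(np.ceil(rate * 60.0 / fhr_range_bpm[0]))
    win = int(round(window_s * rate))
    win = max(win, 2 * lag_hi + 1)
    scores = []
    for s in range(0, len(x) - win + 1, win):
        seg = x[s : s + win]
        seg = seg - seg.mean()
        denom = float(np.sum(seg**2))
        if denom == 0:
            continue
        ac = fftconvolve(seg, seg[::-1], mode="full")[win - 1 :] / denom
        if lag_hi < len(ac):
            lags = np.arange(lag_lo, lag_hi + 1)
            unbiased = ac[lags] * win / (win - lags)
            scores.append(float(np.max(unbiased)))
    if not scores:
        return 0.0
    return float(np.clip(np.mean(scores), 0.0, 1.0))


def select_best_channel(fecg: MultichannelSignal,
                        fhr_range_bpm: tuple[float, float] = FHR_RANGE_BPM) -> int:
    """Index of the channel with the highest periodicity score (tie: lowest)."""
    scores = [
        periodicity_quality(ch, fecg.rate, fhr_range_bpm) for ch in fecg.samples
    ]
    return int(np.argmax(scores))


def bootstrap_fetal_template(
    channel: np.ndarray, rate: float, n_events: int = 20
) -> np.ndarray:
    """Data-driven fetal QRS template from the strongest correlation events.

    Runs the normalized matched filter with a generic seed, takes the
    ``n_events`` highest well-separated peaks, and averages the peak-aligned
    signal windows (sign-aligned to the majority polarity).
    """
    x = np.asarray(channel, dtype=float)
    seed = fetal_qrs_seed(rate)
    bank = detection_function_bank(x, seed, rate)
    nmf = bank[0].values
    refractory = int(round(REFRACTORY_MS * rate / 1000.0))
    order = np.argsort(nmf)[::-1]
    chosen: list[int] = []
    half = len(seed) // 2
    for p in order:
        if p < half or p >= len(x) - half:
            continue
        if all(abs(p - q) >= refractory for q in chosen):
            chosen.append(int(p))
        if len(chosen) >= n_events:
            break
    if not chosen:
        return seed
    windows = np.stack([x[p - half : p + half + 1] for p in chosen])
    signs = np.sign(windows[:, half])
    signs[signs == 0] = 1.0
    template = (windows * signs[:, None]).mean(axis=0)
    if np.abs(template).max() == 0:
        return seed
    apex = int(np.argmax(np.abs(template)))
    # re-center so the apex sits mid-window
    shift = apex - half
    if shift:
        template = np.roll(template, -shift)
    return template / np.abs(template).max()


def _flag_unreliable(
    peaks: np.ndarray, df: np.ndarray, rate: float
) -> np.ndarray:
    """Reliability flags: 0 where local detection SNR or RR smoothness fails.

    A beat is flagged unreliable when its detection-function peak is below
    twice the local background level, or when the Δ functional over its
    10-beat neighbourhood exceeds 3x the record median.
    """
    n = len(peaks)
    flags = np.ones(n, dtype=np.int64)
    if n == 0:
        return flags
    half_bg = int(round(0.5 * rate))
    for i, p in enumerate(peaks):
        s, e = max(p - half_bg, 0), min(p + half_bg + 1, len(df))
        background = np.median(df[s:e])
        if background > 0 and df[p] / background < 2.0:
            flags[i] = 0
    if n >= 12:
        rr = np.diff(peaks).astype(float)
        local = np.array(
            [
                variability_functional(rr[max(i - 5, 0) : i + 5])
                for i in range(len(rr))
            ]
        )
        med = np.nanmedian(local)
        if med > 0:
            bad = np.flatnonzero(local > 3.0 * med)
            for b in bad:
                flags[b] = 0
                flags[min(b + 1, n - 1)] = 0
    return flags


def detect_fetal_r(
    fecg: MultichannelSignal,
    template: np.ndarray | None = None,
) -> tuple[BeatAnnotations, dict]:
    """Full fetal detection chain on a suppressed multichannel record.

    Selects the best channel by periodicity, bootstraps the matched-filter
    template, runs the K-function bank, picks the function with minimal Δ,
    and attaches reliability flags.  Returns the annotations and a detail
    dict (channel, k_opt, Δ values, template).
    """
    rate = fecg.rate
    channel_idx = select_best_channel(fecg)
    x = fecg.samples[channel_idx]
    if template is None:
        template = bootstrap_fetal_template(x, rate)
    bank = detection_function_bank(x, template, rate)
    series = [adaptive_peaks(df, rate) for df in bank]
    deltas = np.array([variability_functional(rr_intervals(c)) for c in series])
    k_opt = select_optimal(deltas)
    best = series[k_opt]
    flags = _flag_unreliable(best.peaks, bank[k_opt].values, rate)
    ann = BeatAnnotations(best.peaks, rate, "fetal", flags=flags)
    detail = {
        "channel": channel_idx,
        "k_opt": k_opt + 1,
        "deltas": deltas,
        "template": template,
    }
    return ann, detail


def detect_direct_fqrs(
    direct: np.ndarray | MultichannelSignal,
    rate: float | None = None,
) -> BeatAnnotations:
    """Gold-standard fetal annotations from the direct (scalp) FECG.

    Normalized matched filtering provides candidate peaks; among candidates
    in the plausible window after the last accepted beat, the one whose RR
    interval is closest to a running-median RR prediction is chosen, which
    rejects competing artifact peaks.
    """
    if isinstance(direct, MultichannelSignal):
        rate = direct.rate
        x = direct.samples[0]
    else:
        if rate is None:
            raise ValueError("rate required with a bare array")
        x = np.asarray(direct, dtype=float)
    if len(x) == 0 or not np.any(x):
        return BeatAnnotations(np.empty(0, dtype=np.int64), rate, "fetal")

    template = bootstrap_fetal_template(x, rate)
    bank = detection_function_bank(x, template, rate)
    nmf = bank[0].values
    maxima = np.flatnonzero((nmf[1:-1] > nmf[:-2]) & (nmf[1:-1] >= nmf[2:])) + 1
    cands = maxima[nmf[maxima] >= 0.35]
    if len(cands) == 0:
        return BeatAnnotations(np.empty(0, dtype=np.int64), rate, "fetal")

    min_rr = int(round(REFRACTORY_MS * rate / 1000.0))
    strong = cands[nmf[cands] >= 0.6]
    first = int(strong[0]) if len(strong) else int(cands[np.argmax(nmf[cands])])
    accepted: list[int] = [first]
    rr_hist: list[float] = []
    while True:
        last = accepted[-1]
        rr_pred = float(np.median(rr_hist[-8:])) if rr_hist else None
        if rr_pred is None:
            window = cands[(cands > last + min_rr) & (cands <= last + int(0.6 * rate))]
            if len(window) == 0:
                window = cands[cands > last + min_rr][:1]
            if len(window) == 0:
                break
            nxt = int(window[np.argmax(nmf[window])])
        else:
            lo = last + max(int(0.5 * rr_pred), min_rr)
            hi = last + int(1.6 * rr_pred)
            window = cands[(cands > lo) & (cands <= hi)]
            if len(window) == 0:
                window = cands[cands > last + min_rr][:1]
                if len(window) == 0:
                    break
                nxt = int(window[0])
            else:
                # timing cost decides only among comparably strong candidates
                strong_w = window[nmf[window] >= 0.7 * nmf[window].max()]
                cost = np.abs((strong_w - last) - rr_pred)
                nxt = int(strong_w[np.argmin(cost)])
        rr_hist.append(float(nxt - accepted[-1]))
        accepted.append(nxt)
    peaks = np.unique(np.asarray(accepted, dtype=np.int64))
    return BeatAnnotations(peaks, rate, "fetal")
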