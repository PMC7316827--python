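"""Maternal-ECG detection and template-subtraction suppression.

The maternal electrocardiogram dominates every abdominal lead.  It is
suppressed by subtracting, beat by beat, an amplitude-scaled template of
the full maternal heart cycle (PQRST), built by averaging beat windows
around the detected maternal R waves and updated exponentially so slow
morphology changes are tracked.  Because the fiducials are quantised to
the sampling grid, a term proportional to the first derivative of the QRS
portion of the template is fitted and subtracted as well: a sub-sample
timing offset δ turns a beat x(t-δ) into x(t) - δ x'(t) to first order, so
the derivative term absorbs fiducial jitter that a pure template cannot.

Maternal R waves are located on an auxiliary signal obtained by spatial
averaging of the abdominal channels, in which the (correlated) maternal
QRS adds coherently while fetal beats and EMG, uncorrelated across
electrodes, are attenuated by ~1/sqrt(channels).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .io import BeatAnnotations, MultichannelSignal

__all__ = [
    "HeartbeatTemplate",
    "SubtractionCoefficients",
    "auxiliary_mecg",
    "detect_maternal_r",
    "build_template",
    "subtract_template",
    "suppress_mecg",
]

logger = logging.getLogger(__name__)

#: default template extent around the R fiducial (covers P through T)
PRE_R_MS = 250.0
POST_R_MS = 450.0
#: least-squares fit window around R (scaling is driven by QRS energy)
QRS_FIT_MS = 50.0
N_INIT_BEATS = 8
UPDATE_WEIGHT = 1.0 / 8.0
REFRACTORY_MS = 300.0  # maternal HR <= 200 bpm


@dataclass
class HeartbeatTemplate:
    waveform: np.ndarray
    pre_R_ms: float
    post_R_ms: float
    rate: float
    beats_absorbed: int
    update_weight: float

    @property
    def pre_samples(self) -> int:
        return int(round(self.pre_R_ms * self.rate / 1000.0))

    @property
    def post_samples(self) -> int:
        return int(round(self.post_R_ms * self.rate / 1000.0))

    def qrs_slice(self, half_ms: float = QRS_FIT_MS) -> slice:
        half = int(round(half_ms * self.rate / 1000.0))
        return slice(self.pre_samples - half, self.pre_samples + half + 1)


@dataclass(frozen=True)
class SubtractionCoefficients:
    scale: float
    derivative_scale: float


def auxiliary_mecg(abdominal: MultichannelSignal) -> np.ndarray:
    """Spatial mean of the abdominal channels (maternal-dominated)."""
    if abdominal.n_channels == 1:
        warnings.warn("single abdominal channel: auxiliary MECG is the channel itself")
        return abdominal.samples[0].copy()
    return abdominal.samples.mean(axis=0)


def detect_maternal_r(
    aux: np.ndarray,
    rate: float,
    refractory_ms: float = REFRACTORY_MS,
) -> BeatAnnotations:
    """Locate maternal R apices on the auxiliary signal.

    Energy-based detection (band-pass 8-35 Hz, differentiate, square,
    120 ms integration) with an adaptive threshold at half the running peak
    level, then apex refinement to the extremum of the band-passed signal
    within ±60 ms.  Detection gaps longer than 5 s are logged and skipped.
    """
    x = np.asarray(aux, dtype=float)
    if len(x) < rate:
        return BeatAnnotations(np.empty(0, dtype=np.int64), rate, "maternal")
    b, a = butter(2, [8.0 / (rate / 2), 35.0 / (rate / 2)], btype="band")
    bp = filtfilt(b, a, x)
    d = np.gradient(bp) ** 2
    win = max(int(round(0.120 * rate)), 1)
    df = np.convolve(d, np.ones(win) / win, mode="same")

    peaks = _local_maxima(df)
    if len(peaks) == 0 or df.max() == 0:
        return BeatAnnotations(np.empty(0, dtype=np.int64), rate, "maternal")

    refractory = int(round(refractory_ms * rate / 1000.0))
    level = float(np.percentile(df[peaks[peaks < int(5 * rate)]], 90)) if np.any(
        peaks < int(5 * rate)
    ) else float(np.percentile(df[peaks], 90))
    accepted: list[int] = []
    last = -refractory
    for p in peaks:
        if p - last < refractory:
            if accepted and df[p] > df[accepted[-1]] and p - (
                accepted[-2] if len(accepted) > 1 else -refractory
            ) >= refractory:
                accepted[-1] = p  # keep the stronger peak inside refractory
                last = p
            continue
        if df[p] >= 0.5 * level:
            if accepted and (p - last) > 5 * rate:
                logger.warning(
                    "maternal detection gap of %.1f s before sample %d",
                    (p - last) / rate, p,
                )
            accepted.append(p)
            last = p
            level = (1 - UPDATE_WEIGHT) * level + UPDATE_WEIGHT * df[p]

    half = int(round(0.060 * rate))
    apices = []
    for p in accepted:
        s, e = max(p - half, 0), min(p + half + 1, len(x))
        apices.append(s + int(np.argmax(np.abs(bp[s:e]))))
    apices = np.unique(np.asarray(apices, dtype=np.int64))
    return BeatAnnotations(apices, rate, "maternal")


def _local_maxima(x: np.ndarray) -> np.ndarray:
    interior = (x[1:-1] > x[:-2]) & (x[1:-1] >= x[2:])
    return np.flatnonzero(interior) + 1


def build_template(
    signal: np.ndarray,
    r_locs: np.ndarray,
    rate: float,
    pre_R_ms: float = PRE_R_MS,
    post_R_ms: float = POST_R_MS,
    update_weight: float = UPDATE_WEIGHT,
    n_init: int = N_INIT_BEATS,
) -> HeartbeatTemplate:
    """Average PQRST template with exponential updating.

    The first ``n_init`` complete beat windows are averaged to initialise
    the template; each further beat updates it as T <- (1-w) T + w beat.
    Before updating, samples of the incoming beat that deviate from the
    current template by more than 3 robust standard deviations are clamped
    to that bound: transient bursts (a fetal QRS crossing the window, an
    artifact) must not be absorbed into the maternal pattern, while slow
    morphology drift still passes.  Beats whose windows are clipped by the
    signal edges are skipped.
    """
    x = np.asarray(signal, dtype=float)
    locs = np.asarray(r_locs, dtype=np.int64)
    pre = int(round(pre_R_ms * rate / 1000.0))
    post = int(round(post_R_ms * rate / 1000.0))
    complete = locs[(locs - pre >= 0) & (locs + post + 1 <= len(x))]
    if len(complete) == 0:
        raise ValueError("no complete beat windows to build a template from")
    windows = np.stack([x[c - pre : c + post + 1] for c in complete])
    init = windows[: max(min(n_init, len(windows)), 1)]
    template = np.median(init, axis=0)
    for beat in windows[len(init):]:
        d = beat - template
        mad = np.median(np.abs(d - np.median(d)))
        bound = 3.0 * 1.4826 * mad
        clamped = template + np.clip(d, -bound, bound)
        template = (1.0 - update_weight) * template + update_weight * clamped
    return HeartbeatTemplate(
        waveform=template,
        pre_R_ms=pre_R_ms,
        post_R_ms=post_R_ms,
        rate=rate,
        beats_absorbed=len(windows),
        update_weight=update_weight,
    )


def subtract_template(
    signal: np.ndarray,
    r_locs: np.ndarray,
    template: HeartbeatTemplate,
    derivative_correction: bool = True,
) -> tuple[np.ndarray, list[SubtractionCoefficients]]:
    """Subtract the scaled template (and QRS-derivative term) at each beat.

    For every beat, (scale, derivative_scale) are fitted by least squares
    of the signal onto {template, dQRS/dt} over the QRS ± 50 ms window, then
    the whole cycle is subtracted with the fitted scale; the derivative term
    is subtracted over the QRS window only.  Because a fetal QRS coinciding
    with the maternal one would be absorbed into the fit (and subtracted
    with the template), the per-beat scales are regularised in a second
    pass: the maternal amplitude varies slowly, so a scale that departs
    from the local median by more than the robust scatter of neighbouring
    scales is replaced by that median.  When consecutive fiducials are
    closer than the template span, the windows are truncated at the
    midpoint between them.  Samples outside every template window pass
    through unchanged.
    """
    x = np.asarray(signal, dtype=float)
    residual = x.copy()
    locs = np.asarray(r_locs, dtype=np.int64)
    pre, post = template.pre_samples, template.post_samples
    tpl = template.waveform
    qrs = template.qrs_slice()
    dqrs_local = np.gradient(tpl[qrs])
    dqrs = np.zeros_like(tpl)
    dqrs[qrs] = dqrs_local
    n = len(x)

    # pass 1: per-beat least-squares fits
    windows: list[tuple[int, int, int, int]] = []  # (lo_c, hi_c, ts, te)
    raw_scale = np.zeros(len(locs))
    raw_dscale = np.zeros(len(locs))
    for i, c in enumerate(locs):
        lo = c - pre
        hi = c + post + 1
        # midpoint truncation at short RR
        if i > 0:
            lo = max(lo, (c + locs[i - 1]) // 2 + 1)
        if i + 1 < len(locs):
            hi = min(hi, (c + locs[i + 1]) // 2 + 1)
        lo_c, hi_c = max(lo, 0), min(hi, n)
        ts = lo_c - (c - pre)
        te = ts + (hi_c - lo_c)
        windows.append((lo_c, hi_c, ts, te))
        if hi_c <= lo_c:
            continue
        seg_x = x[lo_c:hi_c]
        # fit on the QRS part of this (possibly truncated) window
        qs = max(qrs.start - ts, 0)
        qe = min(qrs.stop - ts, len(seg_x))
        if qe - qs < 3:
            qs, qe = 0, len(seg_x)
        cols = [tpl[ts:te][qs:qe]]
        if derivative_correction:
            cols.append(dqrs[ts:te][qs:qe])
        A = np.column_stack(cols)
        sol, *_ = np.linalg.lstsq(A, seg_x[qs:qe], rcond=None)
        raw_scale[i] = float(sol[0])
        raw_dscale[i] = float(sol[1]) if derivative_correction else 0.0

    # pass 2: regularise outlier scales toward the local median
    scale = raw_scale.copy()
    if len(locs) >= 5:
        half_w = 4
        med = np.array(
            [
                np.median(raw_scale[max(i - half_w, 0) : i + half_w + 1])
                for i in range(len(locs))
            ]
        )
        dev = np.abs(raw_scale - med)
        mad = np.median(dev)
        cut = 3.5 * 1.4826 * mad + 0.01 * np.abs(med)
        outlier = dev > cut
        scale[outlier] = med[outlier]
        dmed = np.median(np.abs(raw_dscale - np.median(raw_dscale)))
        dcut = 3.5 * 1.4826 * dmed + 0.01 * np.max(np.abs(raw_dscale), initial=0.0)
        d_out = np.abs(raw_dscale - np.median(raw_dscale)) > dcut
        raw_dscale[outlier & d_out] = np.median(raw_dscale)

    coeffs: list[SubtractionCoefficients] = []
    for i, (lo_c, hi_c, ts, te) in enumerate(windows):
        if hi_c <= lo_c:
            coeffs.append(SubtractionCoefficients(0.0, 0.0))
            continue
        residual[lo_c:hi_c] = (
            x[lo_c:hi_c] - scale[i] * tpl[ts:te] - raw_dscale[i] * dqrs[ts:te]
        )
        coeffs.append(SubtractionCoefficients(float(scale[i]), float(raw_dscale[i])))
    return residual, coeffs


def suppress_mecg(
    abdominal: MultichannelSignal,
    maternal_r: BeatAnnotations | None = None,
    derivative_correction: bool = True,
) -> tuple[MultichannelSignal, BeatAnnotations, list[list[SubtractionCoefficients]]]:
    """Full suppression chain on a (preprocessed) multichannel record.

    Detects maternal R waves on the auxiliary spatial-mean signal (unless
    provided), then builds and subtracts a per-channel template.  Returns
    the FECG estimate, the maternal annotations and per-channel per-beat
    coefficients.
    """
    if maternal_r is None:
        aux = auxiliary_mecg(abdominal)
        maternal_r = detect_maternal_r(aux, abdominal.rate)
    residuals = np.empty_like(abdominal.samples)
    all_coeffs: list[list[SubtractionCoefficients]] = []
    for c in range(abdominal.n_channels):
        tpl = build_template(abdominal.samples[c], maternal_r.locations, abdominal.rate)
        res, coeffs = subtract_template(
            abdominal.samples[c], maternal_r.locations, tpl, derivative_correction
        )
        residuals[c] = res
        all_coeffs.append(coeffs)
    return abdominal.with_samples(residuals), maternal_r, all_coeffs
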