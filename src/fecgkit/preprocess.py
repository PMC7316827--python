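"""Multi-notch comb filtering of abdominal and direct FECG signals.

Power-line and slow-changing interference are suppressed with a single FIR
filter whose transfer function at 500 Hz is

    H(z) = z^-50 - (1/36) * ((1 - z^-60) / (1 - z^-10))^2

The rational branch is the square of a 6-tap moving comb, so H expands to an
explicit 101-tap linear-phase FIR: a unit tap at delay 50 minus a triangular
tap pattern (1,2,...,6,...,2,1)/36 at multiples of 10 samples.  The response
is exactly zero at DC and at every multiple of 50 Hz; the first passband
edge sits near 5 Hz, which removes baseline wander while leaving the QRS
band untouched.  For other sampling rates every delay scales by rate/500
(1 kHz: 100/20/120), keeping the notches at multiples of 50 Hz.

Both branches share the same linear-phase group delay (``base_delay``
samples), which :func:`comb_filter` removes so that beat fiducials keep
their sample positions through the filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .io import MultichannelSignal

__all__ = ["CombFilterSpec", "adapt_spec", "comb_taps", "comb_filter",
           "comb_frequency_response"]


class RateError(ValueError):
    """Sampling rate incompatible with integer-delay 50 Hz notch placement."""


@dataclass(frozen=True)
class CombFilterSpec:
    """Integer delays of the notch comb at a given sampling rate."""

    base_delay: int      # delay of the identity branch (50 @ 500 Hz)
    comb_tap_spacing: int  # inner comb delay (10 @ 500 Hz)
    comb_span: int       # outer comb delay (60 @ 500 Hz)
    normalizer: int      # 36 = 6^2
    rate: float

    def __post_init__(self) -> None:
        if self.comb_span != 6 * self.comb_tap_spacing:
            raise RateError("comb_span must be 6 x comb_tap_spacing")
        if self.base_delay != 5 * self.comb_tap_spacing:
            raise RateError("base_delay must be 5 x comb_tap_spacing")
        if self.normalizer != 36:
            raise RateError("normalizer must be 36")

    @property
    def order(self) -> int:
        """FIR order (taps - 1): 100 at 500 Hz."""
        return 2 * self.base_delay


def adapt_spec(rate: float) -> CombFilterSpec:
    """Scale the 500 Hz comb delays to ``rate``.

    The inner comb delay must equal rate/50 samples for the notches to land
    exactly on multiples of 50 Hz, so only rates divisible by 50 (with the
    scaled delays integer) are accepted.
    """
    spacing = rate / 50.0
    if spacing != round(spacing) or spacing <= 0:
        raise RateError(
            f"rate {rate} Hz cannot place 50 Hz notches on integer delays"
        )
    spacing = int(round(spacing))
    return CombFilterSpec(
        base_delay=5 * spacing,
        comb_tap_spacing=spacing,
        comb_span=6 * spacing,
        normalizer=36,
        rate=float(rate),
    )


def comb_taps(spec: CombFilterSpec) -> np.ndarray:
    """Expanded FIR impulse response of H(z).

    The squared 6-tap comb is the self-convolution of ones(6) placed on the
    tap-spacing lattice: a triangle 1..6..1 over 11 lattice points.
    """
    six = np.zeros(spec.comb_span, dtype=float)
    six[:: spec.comb_tap_spacing] = 1.0  # 6 unit taps
    squared = np.convolve(six, six)  # length 2*span-1, support = order+1
    taps = -squared / spec.normalizer
    taps[spec.base_delay] += 1.0
    return taps[: spec.order + 1]


def comb_frequency_response(spec: CombFilterSpec, freqs_hz: np.ndarray) -> np.ndarray:
    """Complex frequency response of H at the given frequencies (Hz)."""
    taps = comb_taps(spec)
    w = 2.0 * np.pi * np.asarray(freqs_hz, dtype=float) / spec.rate
    n = np.arange(len(taps))
    return np.exp(-1j * np.outer(w, n)) @ taps


def _filter_channel(x: np.ndarray, taps: np.ndarray, delay: int) -> np.ndarray:
    # reflect-pad by one filter length so the transient never touches the
    # retained samples; then trim and undo the group delay
    pad = len(taps)
    xp = np.pad(x, pad, mode="reflect")
    y = fftconvolve(xp, taps, mode="full")
    start = pad + delay
    return y[start : start + len(x)]


def comb_filter(
    signal: MultichannelSignal, spec: CombFilterSpec | None = None
) -> MultichannelSignal:
    """Apply the notch comb per channel with group-delay compensation."""
    if spec is None:
        spec = adapt_spec(signal.rate)
    elif spec.rate != signal.rate:
        raise RateError(
            f"filter designed for {spec.rate} Hz applied to {signal.rate} Hz signal"
        )
    if signal.n_samples <= spec.order:
        raise ValueError(
            f"signal of {signal.n_samples} samples shorter than filter order "
            f"{spec.order}"
        )
    taps = comb_taps(spec)
    filtered = np.vstack(
        [_filter_channel(ch, taps, spec.base_delay) for ch in signal.samples]
    )
    return signal.with_samples(filtered)
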