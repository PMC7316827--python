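"""Scoring of detected beat series against a reference annotation.

A detected QRS is accepted when it lies within a ±40 ms window of a
reference marker (the window corresponds to the average fetal QRS width).
Matching is one-to-one and order-preserving: among all monotone pairings
whose offsets stay within the tolerance, the one with the largest number of
pairs is chosen, ties broken by minimal total absolute offset.  From the
resulting TP/FP/FN counts the standard detection-performance indices are
derived:

    PI  = (N - FP - FN) / N * 100
    Acc = TP / (TP + FP + FN) * 100
    Se  = TP / (TP + FN) * 100
    PPV = TP / (TP + FP) * 100
    F1  = 2 * PPV * Se / (PPV + Se) = 2 TP / (2 TP + FN + FP) * 100

RR-interval accuracy is evaluated on intervals whose both endpoints are
matched beats: ΔRR = RR_test - RR_ref, summarised in ms and in bpm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io import BeatAnnotations

__all__ = [
    "MatchResult",
    "PerformanceIndices",
    "AccuracyStats",
    "match_beats",
    "performance_indices",
    "indices_from_se_ppv",
    "rr_accuracy",
]


@dataclass(frozen=True)
class MatchResult:
    TP: int
    FP: int
    FN: int
    pairs: tuple[tuple[int, int], ...]  # (reference index, test index)
    tolerance_ms: float
    N: int  # total reference beats


@dataclass(frozen=True)
class PerformanceIndices:
    PI: Optional[float]
    Acc: Optional[float]
    Se: Optional[float]
    PPV: Optional[float]
    F1: Optional[float]


@dataclass(frozen=True)
class AccuracyStats:
    mean_dRR_ms: float
    mean_abs_dRR_ms: float
    mean_abs_dRR_bpm: float
    sd_dRR_ms: float
    n_intervals: int


def _as_locations(ann, rate: Optional[float]) -> tuple[np.ndarray, float]:
    if isinstance(ann, BeatAnnotations):
        return ann.locations.astype(float), ann.rate
    if rate is None:
        raise ValueError("rate required when passing bare index arrays")
    return np.asarray(ann, dtype=float), rate


def match_beats(
    reference,
    test,
    rate: Optional[float] = None,
    tolerance_ms: float = 40.0,
) -> MatchResult:
    """Optimal order-preserving one-to-one matching within ±tolerance.

    Solved by dynamic programming over (reference, test) prefixes with the
    lexicographic objective (max pairs, min total |offset|); equivalent to
    exhaustive search over monotone assignments.
    """
    if (
        isinstance(reference, BeatAnnotations)
        and isinstance(test, BeatAnnotations)
        and reference.rate != test.rate
    ):
        test = test.resampled(reference.rate)
    ref, rrate = _as_locations(reference, rate)
    tst, trate = _as_locations(test, rate)
    if rrate != trate:
        raise ValueError(f"rates differ: {rrate} vs {trate}")
    tol = tolerance_ms * rrate / 1000.0

    n, m = len(ref), len(tst)
    # dp[i][j] = (pairs, total offset) best over ref[:i], test[:j]
    pairs_dp = np.zeros((n + 1, m + 1), dtype=np.int64)
    cost_dp = np.zeros((n + 1, m + 1), dtype=float)
    take = np.zeros((n + 1, m + 1), dtype=bool)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best_p, best_c, best_take = pairs_dp[i - 1, j], cost_dp[i - 1, j], False
            if pairs_dp[i, j - 1] > best_p or (
                pairs_dp[i, j - 1] == best_p and cost_dp[i, j - 1] < best_c
            ):
                best_p, best_c = pairs_dp[i, j - 1], cost_dp[i, j - 1]
            off = abs(ref[i - 1] - tst[j - 1])
            if off <= tol:
                cand_p = pairs_dp[i - 1, j - 1] + 1
                cand_c = cost_dp[i - 1, j - 1] + off
                if cand_p > best_p or (cand_p == best_p and cand_c < best_c):
                    best_p, best_c, best_take = cand_p, cand_c, True
            pairs_dp[i, j], cost_dp[i, j], take[i, j] = best_p, best_c, best_take

    # backtrack
    pairs: list[tuple[int, int]] = []
    i, j = n, m
    while i > 0 and j > 0:
        if take[i, j]:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif pairs_dp[i - 1, j] == pairs_dp[i, j] and cost_dp[i - 1, j] == cost_dp[i, j]:
            i -= 1
        else:
            j -= 1
    pairs.reverse()

    tp = len(pairs)
    return MatchResult(
        TP=tp,
        FP=m - tp,
        FN=n - tp,
        pairs=tuple(pairs),
        tolerance_ms=tolerance_ms,
        N=n,
    )


def performance_indices(m: MatchResult) -> PerformanceIndices:
    """PI/Acc/Se/PPV/F1 in percent; undefined ratios reported as None."""
    tp, fp, fn, n = m.TP, m.FP, m.FN, m.N
    pi = (n - fp - fn) / n * 100.0 if n > 0 else None
    acc = tp / (tp + fp + fn) * 100.0 if tp + fp + fn > 0 else None
    se = tp / (tp + fn) * 100.0 if tp + fn > 0 else None
    ppv = tp / (tp + fp) * 100.0 if tp + fp > 0 else None
    f1 = 2.0 * tp / (2 * tp + fn + fp) * 100.0 if 2 * tp + fn + fp > 0 else None
    return PerformanceIndices(PI=pi, Acc=acc, Se=se, PPV=ppv, F1=f1)


def indices_from_se_ppv(se: float, ppv: float) -> tuple[float, float]:
    """F1 and Acc implied by a published (Se, PPV) operating point (percent).

    Uses FN/TP = (100-Se)/Se and FP/TP = (100-PPV)/PPV, so
    Acc = 100 / (1 + FN/TP + FP/TP) and F1 is the harmonic mean of Se, PPV.
    """
    f1 = 2.0 * ppv * se / (ppv + se)
    acc = 100.0 / (1.0 + (100.0 - se) / se + (100.0 - ppv) / ppv)
    return f1, acc


def rr_accuracy(
    m: MatchResult,
    reference,
    test,
    rate: Optional[float] = None,
) -> Optional[AccuracyStats]:
    """ΔRR statistics over intervals whose both endpoints are matched."""
    ref, rrate = _as_locations(reference, rate)
    tst, _ = _as_locations(test, rate)
    ms = 1000.0 / rrate

    d_rr: list[float] = []
    d_bpm: list[float] = []
    for (ri0, ti0), (ri1, ti1) in zip(m.pairs[:-1], m.pairs[1:]):
        if ri1 != ri0 + 1 or ti1 != ti0 + 1:
            continue  # a gap (FN/FP) breaks the interval correspondence
        rr_ref = (ref[ri1] - ref[ri0]) * ms
        rr_tst = (tst[ti1] - tst[ti0]) * ms
        d_rr.append(rr_tst - rr_ref)
        d_bpm.append(abs(60000.0 / rr_tst - 60000.0 / rr_ref))
    if not d_rr:
        return None
    arr = np.asarray(d_rr)
    return AccuracyStats(
        mean_dRR_ms=float(arr.mean()),
        mean_abs_dRR_ms=float(np.abs(arr).mean()),
        mean_abs_dRR_bpm=float(np.mean(d_bpm)),
        sd_dRR_ms=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        n_intervals=len(arr),
    )
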