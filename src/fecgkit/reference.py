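"""Published per-record summary tables of the B1/B2 datasets.

The archived datasets ship with per-record SNR quality indices and FHR
analysis results.  They are inlined here so that batch-aggregation code can
be exercised (and its output cross-checked against the published dataset
means) without downloading the recordings, and so that worked examples in
the documentation have concrete inputs.

All values are the dataset's published per-record summaries: WM/WF in dB,
WEM/WEF dimensionless, Loss in %, Basal/Fluct/Osc in bpm, LTV/STV/LTI in
ms, STI/II dimensionless, DI scaled by 1000.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "b1_quality_table",
    "b2_quality_table",
    "b1_fhr_table",
    "b2_fhr_table",
    "dataset_durations_min",
]

_B1_QUALITY = [
    # record, WM, WF, WEM, WEF
    ("B1_Pregnancy_01", 16.5, 5.3, 0.05, 0.45),
    ("B1_Pregnancy_02", 14.1, 4.1, 0.08, 0.48),
    ("B1_Pregnancy_03", 15.0, 5.0, 0.09, 0.40),
    ("B1_Pregnancy_04", 12.5, 4.0, 0.14, 0.51),
    ("B1_Pregnancy_05", 17.5, 8.1, 0.06, 0.18),
    ("B1_Pregnancy_06", 12.9, 4.4, 0.11, 0.31),
    ("B1_Pregnancy_07", 11.6, 0.8, 0.11, 1.06),
    ("B1_Pregnancy_08", 10.9, -1.6, 0.10, 0.41),
    ("B1_Pregnancy_09", 16.9, -0.7, 0.05, 0.79),
    ("B1_Pregnancy_10", 14.9, 5.1, 0.07, 0.59),
]

_B2_QUALITY = [
    ("B2_Labour_01", 10.6, 6.7, 0.20, 0.20),
    ("B2_Labour_02", 12.6, 5.0, 0.10, 0.25),
    ("B2_Labour_03", 7.8, -2.7, 0.30, 0.54),
    ("B2_Labour_04", 11.7, 2.3, 0.13, 0.31),
    ("B2_Labour_05", 9.7, 5.9, 0.28, 0.20),
    ("B2_Labour_06", 12.8, 3.7, 0.10, 0.19),
    ("B2_Labour_07", 11.4, 0.5, 0.27, 0.67),
    ("B2_Labour_08", 10.6, 7.0, 0.18, 0.18),
    ("B2_Labour_09", 11.4, 3.9, 0.15, 0.44),
    ("B2_Labour_10", 11.6, 0.7, 0.11, 0.48),
    ("B2_Labour_11", 8.4, 6.6, 0.21, 0.16),
    ("B2_Labour_12", 6.5, 3.8, 0.36, 0.28),
]

_B1_FHR = [
    # record, Loss, Basal, Fluct, Acc, Dec, Osc, LTV, STV, LTI, STI, II, DI
    ("B1_Pregnancy_01", 0.2, 156.3, 14.1, 10, 0, 17.5, 43.3, 5.2, 25.1, 0.0113, 0.0076, 8.8),
    ("B1_Pregnancy_02", 0.6, 140.3, 11.2, 0, 1, 17.9, 58.6, 8.9, 28.6, 0.0128, 0.0087, 15.3),
    ("B1_Pregnancy_03", 0.6, 128.3, 7.2, 5, 0, 10.3, 38.8, 10.1, 31.0, 0.0201, 0.0050, 13.6),
    ("B1_Pregnancy_04", 0.0, 139.0, 11.7, 3, 0, 10.5, 32.1, 4.0, 17.6, 0.0080, 0.0053, 5.8),
    ("B1_Pregnancy_05", 0.2, 138.8, 10.5, 4, 0, 10.5, 25.3, 2.9, 11.4, 0.0054, 0.0037, 4.4),
    ("B1_Pregnancy_06", 0.2, 144.7, 11.3, 2, 0, 9.0, 25.8, 3.7, 12.9, 0.0070, 0.0042, 5.9),
    ("B1_Pregnancy_07", 1.0, 155.9, 15.4, 2, 0, 13.6, 34.2, 6.6, 14.6, 0.0112, 0.0057, 12.2),
    ("B1_Pregnancy_08", 0.6, 145.8, 12.5, 5, 0, 14.3, 39.8, 5.5, 21.7, 0.0091, 0.0065, 9.4),
    ("B1_Pregnancy_09", 2.5, 143.5, 11.6, 3, 0, 10.2, 30.0, 4.2, 17.1, 0.0080, 0.0049, 6.6),
    ("B1_Pregnancy_10", 11.2, 132.3, 10.0, 6, 2, 15.7, 54.1, 12.6, 45.8, 0.0226, 0.0075, 18.1),
]

_B2_FHR = [
    ("B2_Labour_01", 1.7, 128.7, 7.2, 2, 0, 12.9, 44.9, 6.1, 20.1, 0.0081, 0.0065, 10.3),
    ("B2_Labour_02", 5.8, 131.9, 7.6, 1, 0, 19.9, 66.8, 9.5, 46.9, 0.0163, 0.0108, 13.9),
    ("B2_Labour_03", 27.5, 152.4, 14.7, 0, 0, 20.9, 52.7, 6.8, 21.0, 0.0101, 0.0077, 12.9),
    ("B2_Labour_04", 2.5, 137.5, 9.2, 2, 0, 14.8, 46.7, 9.3, 28.8, 0.0182, 0.0071, 13.3),
    ("B2_Labour_05", 1.7, 132.0, 6.9, 3, 0, 18.6, 66.1, 10.5, 35.7, 0.0122, 0.0081, 16.9),
    ("B2_Labour_06", 0.0, 136.7, 9.5, 1, 0, 10.4, 33.4, 3.1, 19.7, 0.0046, 0.0057, 5.0),
    ("B2_Labour_07", 0.0, 126.2, 6.4, 2, 1, 14.3, 51.9, 10.0, 57.1, 0.0169, 0.0080, 13.7),
    ("B2_Labour_08", 0.0, 128.9, 7.2, 0, 0, 10.4, 36.9, 6.1, 12.9, 0.0092, 0.0048, 9.0),
    ("B2_Labour_09", 0.8, 134.7, 9.0, 0, 0, 10.7, 36.3, 4.0, 19.5, 0.0070, 0.0054, 5.8),
    ("B2_Labour_10", 0.0, 125.4, 6.7, 0, 0, 8.4, 33.1, 4.6, 10.6, 0.0075, 0.0043, 6.3),
    ("B2_Labour_11", 3.3, 130.3, 7.1, 2, 0, 16.8, 56.9, 9.5, 35.6, 0.0141, 0.0086, 14.9),
    ("B2_Labour_12", 0.0, 131.3, 8.1, 0, 0, 8.0, 28.0, 4.3, 18.3, 0.0076, 0.0044, 6.1),
]

_QUALITY_COLS = ["WM", "WF", "WEM", "WEF"]
_FHR_COLS = ["Loss", "Basal", "Fluct", "Acc", "Dec", "Osc",
             "LTV", "STV", "LTI", "STI", "II", "DI"]


def _frame(rows: list[tuple], cols: list[str]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["record"] + cols)
    return df.set_index("record")


def b1_quality_table() -> pd.DataFrame:
    """Per-record SNR indices of the antenatal (B1) dataset."""
    return _frame(_B1_QUALITY, _QUALITY_COLS)


def b2_quality_table() -> pd.DataFrame:
    """Per-record SNR indices of the intrapartum (B2) dataset."""
    return _frame(_B2_QUALITY, _QUALITY_COLS)


def b1_fhr_table() -> pd.DataFrame:
    """Per-record FHR analysis results of the antenatal (B1) dataset."""
    return _frame(_B1_FHR, _FHR_COLS)


def b2_fhr_table() -> pd.DataFrame:
    """Per-record FHR analysis results of the intrapartum (B2) dataset."""
    return _frame(_B2_FHR, _FHR_COLS)


def dataset_durations_min() -> dict[str, float]:
    """Total recorded minutes per dataset and the PhysioNet-shared subset."""
    return {
        "B1": 10 * 20.0,
        "B2": 12 * 5.0,
        "physionet_subset": 5 * 5.0,
    }
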