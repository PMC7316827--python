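"""Plain-text I/O for abdominal-FECG records.

The measurement system stores each record as whitespace-delimited text files:
a sample-by-channel signal matrix (``*_abSignals_X.txt``, 500 Hz abdominal
channels; ``*_dFECG_X.txt``, 1 kHz direct scalp lead) and one R-wave
annotation file per subject (``*_Maternal_R_X.txt``, ``*_Fetal_R_X.txt``).
Fetal annotation files may carry a second column with a 0/1 reliability
flag; flag 0 marks a beat whose position could not be verified because of
interference.

Annotation files on disk store 1-based sample numbers (the common clinical
export convention); in memory all indices are 0-based.  The conversion is
applied symmetrically by :func:`read_annotations` / :func:`write_annotations`
and can be disabled with ``one_based=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "MultichannelSignal",
    "BeatAnnotations",
    "RecordBundle",
    "read_signal_text",
    "write_signal_text",
    "read_annotations",
    "write_annotations",
    "load_record_bundle",
    "save_record_bundle",
    "DATASET_CATALOG",
]

#: Published layout of the two archived datasets: number of records and
#: per-record signal duration in minutes.  The ``physionet_subset`` entry is
#: the number of labour records previously shared through PhysioNet.
DATASET_CATALOG = {
    "B1": {"records": 10, "duration_min": 20.0, "rate_abd": 500.0, "has_direct": False},
    "B2": {"records": 12, "duration_min": 5.0, "rate_abd": 500.0, "rate_direct": 1000.0,
           "has_direct": True, "physionet_subset": 5},
}


class FormatError(ValueError):
    """Raised when a text file does not match the expected layout."""


@dataclass
class MultichannelSignal:
    """Sampled voltage traces (µV) with a common rate and channel labels."""

    samples: np.ndarray  # (n_channels, n_samples)
    rate: float
    labels: tuple[str, ...]
    origin: str = "synthetic"

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.labels = tuple(self.labels)
        if self.samples.shape[0] != len(self.labels):
            raise FormatError(
                f"{self.samples.shape[0]} channels but {len(self.labels)} labels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise FormatError(f"duplicate channel labels: {self.labels}")
        if not self.rate > 0:
            raise FormatError(f"rate must be positive, got {self.rate}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def channel(self, label: str) -> np.ndarray:
        return self.samples[self.labels.index(label)]

    def with_samples(self, samples: np.ndarray) -> "MultichannelSignal":
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass
class BeatAnnotations:
    """Ordered R-wave sample indices, optionally with 0/1 reliability flags."""

    locations: np.ndarray
    rate: float
    subject: str = "fetal"  # "maternal" | "fetal"
    flags: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.locations = np.asarray(self.locations, dtype=np.int64)
        if self.locations.ndim != 1:
            raise FormatError("locations must be one-dimensional")
        if len(self.locations) > 1 and np.any(np.diff(self.locations) <= 0):
            raise FormatError("beat locations must be strictly increasing")
        if self.subject not in ("maternal", "fetal"):
            raise FormatError(f"subject must be maternal|fetal, got {self.subject!r}")
        if self.flags is not None:
            self.flags = np.asarray(self.flags, dtype=np.int64)
            if self.flags.shape != self.locations.shape:
                raise FormatError("flags must parallel locations")
            if not np.isin(self.flags, (0, 1)).all():
                raise FormatError("flags must be 0 or 1")

    def __len__(self) -> int:
        return len(self.locations)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BeatAnnotations):
            return NotImplemented
        if (self.flags is None) != (other.flags is None):
            return False
        return (
            self.subject == other.subject
            and self.rate == other.rate
            and np.array_equal(self.locations, other.locations)
            and (self.flags is None or np.array_equal(self.flags, other.flags))
        )

    def times_ms(self) -> np.ndarray:
        """Beat times in milliseconds from record start."""
        return self.locations * 1000.0 / self.rate

    def resampled(self, rate: float) -> "BeatAnnotations":
        """Re-index the beats onto a signal sampled at ``rate``."""
        locs = np.round(self.locations * rate / self.rate).astype(np.int64)
        return BeatAnnotations(locs, rate, self.subject, self.flags)


@dataclass
class RecordBundle:
    """All files of one record: signals, suppressed-MECG signals, annotations."""

    abdominal_raw: MultichannelSignal
    maternal_r: BeatAnnotations
    fetal_r: BeatAnnotations
    abdominal_fecg: Optional[MultichannelSignal] = None
    direct_fecg: Optional[MultichannelSignal] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.abdominal_raw.n_samples
        rate = self.abdominal_raw.rate
        for ann in (self.maternal_r, self.fetal_r):
            ref = self.direct_fecg if (
                self.direct_fecg is not None and ann.rate == self.direct_fecg.rate
                and ann.rate != rate
            ) else self.abdominal_raw
            if len(ann) and ann.locations[-1] >= ref.n_samples:
                raise FormatError(
                    f"{ann.subject} annotation {ann.locations[-1]} beyond signal "
                    f"end {ref.n_samples}"
                )
        if self.abdominal_fecg is not None and (
            self.abdominal_fecg.samples.shape != self.abdominal_raw.samples.shape
        ):
            raise FormatError("abdominal_fecg must match abdominal_raw shape")


# ---------------------------------------------------------------------------
# signal matrices
# ---------------------------------------------------------------------------

def read_signal_text(
    path: str | Path,
    rate: float,
    labels: Sequence[str],
    origin: str = "synthetic",
) -> MultichannelSignal:
    """Read a whitespace-delimited sample-by-channel matrix.

    One row per sample, one column per channel; columns map onto ``labels``
    in order.  Ragged rows or non-numeric tokens raise :class:`FormatError`.
    """
    path = Path(path)
    try:
        matrix = np.loadtxt(path, ndmin=2)
    except ValueError:
        _diagnose_signal_file(path)  # raises FormatError naming the line
        raise
    if matrix.size == 0:
        raise FormatError(f"{path}: empty signal file")
    if matrix.shape[1] != len(labels):
        raise FormatError(
            f"{path}: {matrix.shape[1]} columns but {len(labels)} labels {tuple(labels)}"
        )
    return MultichannelSignal(matrix.T, rate=rate, labels=tuple(labels), origin=origin)


def _diagnose_signal_file(path: Path) -> None:
    """Pinpoint the offending line of a malformed signal matrix."""
    width: Optional[int] = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if width is None:
                width = len(tokens)
            elif len(tokens) != width:
                raise FormatError(
                    f"{path}:{lineno}: expected {width} columns, got {len(tokens)}"
                )
            for t in tokens:
                try:
                    float(t)
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: non-numeric token {t!r}"
                    ) from None


def write_signal_text(signal: MultichannelSignal, path: str | Path) -> Path:
    """Write the transposed sample matrix with 6 significant digits."""
    path = Path(path)
    np.savetxt(path, signal.samples.T, fmt="%.6g", delimiter="\t")
    return path


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def read_annotations(
    path: str | Path,
    subject: str,
    rate: float,
    one_based: bool = True,
) -> BeatAnnotations:
    """Read an R-wave annotation list (one beat per line).

    Fetal files may carry a second column holding the 0/1 reliability flag;
    a single-column fetal file is accepted with all flags absent.
    """
    path = Path(path)
    locs: list[int] = []
    flags: list[int] = []
    n_cols: Optional[int] = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if n_cols is None:
                n_cols = len(tokens)
                if n_cols not in (1, 2):
                    raise FormatError(f"{path}:{lineno}: expected 1 or 2 columns")
            elif len(tokens) != n_cols:
                raise FormatError(f"{path}:{lineno}: inconsistent column count")
            try:
                locs.append(int(float(tokens[0])))
                if n_cols == 2:
                    flags.append(int(float(tokens[1])))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric token") from exc
    locations = np.asarray(locs, dtype=np.int64)
    if one_based:
        locations = locations - 1
    return BeatAnnotations(
        locations=locations,
        rate=rate,
        subject=subject,
        flags=np.asarray(flags, dtype=np.int64) if n_cols == 2 else None,
    )


def write_annotations(
    annotations: BeatAnnotations,
    path: str | Path,
    one_based: bool = True,
) -> Path:
    """Write annotations as integer sample numbers (plus flag column if set)."""
    path = Path(path)
    locs = annotations.locations + (1 if one_based else 0)
    with path.open("w") as fh:
        if annotations.flags is None:
            for loc in locs:
                fh.write(f"{loc}\n")
        else:
            for loc, flag in zip(locs, annotations.flags):
                fh.write(f"{loc}\t{flag}\n")
    return path


# ---------------------------------------------------------------------------
# record bundles
# ---------------------------------------------------------------------------

_ABD_LABELS = ("A1", "A2", "A3", "A4")


def _record_paths(directory: Path, record_id: str) -> dict[str, Path]:
    dataset = record_id.split("_")[0]
    prefix = dataset
    name = record_id[len(dataset) + 1 :] if "_" in record_id else record_id
    suffix = name.split("_")[-1]
    return {
        "signals": directory / f"{prefix}_abSignals_{suffix}.txt",
        "direct": directory / f"{prefix}_dFECG_{suffix}.txt",
        "maternal": directory / f"{prefix}_Maternal_R_{suffix}.txt",
        "fetal": directory / f"{prefix}_Fetal_R_{suffix}.txt",
    }


def load_record_bundle(
    directory: str | Path,
    record_id: str,
    rate_abd: float = 500.0,
    rate_direct: float = 1000.0,
) -> RecordBundle:
    """Assemble a :class:`RecordBundle` from the text files of one record.

    The signal matrix holds 4 raw abdominal channels; when it has 8 columns
    the second block is the MECG-suppressed version of the first.  A missing
    direct-FECG file is not an error (antenatal records have none); any other
    missing member raises with the expected file names listed.
    """
    directory = Path(directory)
    paths = _record_paths(directory, record_id)
    missing = [
        str(p) for key, p in paths.items() if key != "direct" and not p.exists()
    ]
    if missing:
        raise FileNotFoundError(
            f"record {record_id!r} incomplete in {directory}; expected: "
            + ", ".join(missing)
        )
    dataset = record_id.split("_")[0]

    probe = np.loadtxt(paths["signals"], max_rows=1, ndmin=2)
    n_cols = probe.shape[1]
    if n_cols == 2 * len(_ABD_LABELS):
        labels = _ABD_LABELS + tuple(f"F{i}" for i in range(1, 5))
    elif n_cols == len(_ABD_LABELS):
        labels = _ABD_LABELS
    else:
        raise FormatError(f"{paths['signals']}: expected 4 or 8 columns, got {n_cols}")

    full = read_signal_text(paths["signals"], rate_abd, labels, origin=dataset)
    abdominal_raw = MultichannelSignal(
        full.samples[:4], rate_abd, _ABD_LABELS, origin=dataset
    )
    abdominal_fecg = None
    if n_cols == 8:
        abdominal_fecg = MultichannelSignal(
            full.samples[4:], rate_abd, _ABD_LABELS, origin=dataset
        )

    direct_fecg = None
    if paths["direct"].exists():
        direct_fecg = read_signal_text(paths["direct"], rate_direct, ("D",), origin=dataset)

    fetal_rate = rate_direct if direct_fecg is not None else rate_abd
    maternal_r = read_annotations(paths["maternal"], "maternal", rate_abd)
    fetal_r = read_annotations(paths["fetal"], "fetal", fetal_rate)

    return RecordBundle(
        abdominal_raw=abdominal_raw,
        abdominal_fecg=abdominal_fecg,
        direct_fecg=direct_fecg,
        maternal_r=maternal_r,
        fetal_r=fetal_r,
        meta={"record_id": record_id, "dataset": dataset},
    )


def save_record_bundle(bundle: RecordBundle, directory: str | Path) -> dict[str, Path]:
    """Write a bundle back to the dataset text layout; inverse of loading."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    record_id = bundle.meta.get("record_id", "synthetic_01")
    paths = _record_paths(directory, record_id)
    if bundle.abdominal_fecg is not None:
        stacked = MultichannelSignal(
            np.vstack([bundle.abdominal_raw.samples, bundle.abdominal_fecg.samples]),
            bundle.abdominal_raw.rate,
            bundle.abdominal_raw.labels + tuple(f"F{i}" for i in range(1, 5)),
        )
        write_signal_text(stacked, paths["signals"])
    else:
        write_signal_text(bundle.abdominal_raw, paths["signals"])
    written = {"signals": paths["signals"]}
    if bundle.direct_fecg is not None:
        write_signal_text(bundle.direct_fecg, paths["direct"])
        written["direct"] = paths["direct"]
    write_annotations(bundle.maternal_r, paths["maternal"])
    write_annotations(bundle.fetal_r, paths["fetal"])
    written["maternal"] = paths["maternal"]
    written["fetal"] = paths["fetal"]
    return written
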