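"""Core data model, CSV I/O, and cardiac-cycle segmentation.

A recording is a uniformly sampled single-channel amplitude vector (mV)
with a known sampling rate ``Sr`` (Hz) and a mean heart rate ``Hr``
(beats per second, so 60 bpm corresponds to ``Hr = 1.0``).  The cardiac
cycle length in samples is ``CL = round(Sr / Hr)`` and a trace of ``N``
samples holds ``floor(N / CL)`` complete cycles; the trailing partial
cycle is dropped.  Sample indices are 0-based and cycle intervals are
half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ECG_LABELS = ("P", "Q", "R", "S", "T")
ECG_ENDPOINT_LABELS = ("Ponset", "Poffset", "QRSonset", "QRSoffset", "Tonset", "Toffset")
SCG_LABELS = ("AS", "MC", "IM", "AO", "IC", "RE", "AC", "MO", "RF")

LABEL_SETS = {
    "ECG": set(ECG_LABELS) | set(ECG_ENDPOINT_LABELS),
    "SCG": set(SCG_LABELS),
}


class InvalidParameterError(ValueError):
    """A precondition on a numeric parameter was violated."""


class TooShortError(ValueError):
    """Trace shorter than a single cardiac cycle."""


class ParseError(ValueError):
    """Malformed input file; the message names the offending row."""


@dataclass
class SignalTrace:
    """Uniformly sampled single-channel biosignal.

    Parameters
    ----------
    samples : array of float
        Amplitudes in mV.
    sampling_rate : float
        Sampling frequency Sr in Hz, > 0.
    modality : str
        ``"ECG"`` or ``"SCG"``.
    heart_rate : float
        Mean heart rate Hr in beats per second, > 0.
    subject_id : str
        Opaque label.
    cycle_index : CycleIndex, optional
        Ground-truth cycle boundaries, attached by the synthetic
        generator when beat-to-beat jitter makes fixed tiling inexact.
    """

    samples: np.ndarray
    sampling_rate: float
    modality: str
    heart_rate: float
    subject_id: str = ""
    cycle_index: "CycleIndex | None" = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise InvalidParameterError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidParameterError("samples must all be finite")
        if self.sampling_rate <= 0:
            raise InvalidParameterError("sampling_rate must be > 0")
        if self.heart_rate <= 0:
            raise InvalidParameterError("heart_rate must be > 0")
        if self.modality not in ("ECG", "SCG"):
            raise InvalidParameterError(f"unknown modality {self.modality!r}")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return len(self.samples) / self.sampling_rate


@dataclass
class CycleIndex:
    """Cycle boundaries as ordered, non-overlapping half-open intervals."""

    cycle_length: int
    boundaries: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.cycle_length < 1:
            raise InvalidParameterError("cycle_length must be >= 1")
        prev_end = 0
        for lo, hi in self.boundaries:
            if lo < prev_end or hi <= lo:
                raise InvalidParameterError("boundaries must be ordered and non-overlapping")
            prev_end = hi

    @property
    def n_cycles(self) -> int:
        return len(self.boundaries)

    def __iter__(self):
        return iter(self.boundaries)


@dataclass
class FiducialAnnotation:
    """Per-cycle labeled fiducial points.

    ``entries`` is a DataFrame with columns ``cycle`` (int), ``label``
    (str), ``sample_index`` (int), ``amplitude`` (mV).  At most one
    entry exists per (cycle, label).
    """

    modality: str
    entries: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["cycle", "label", "sample_index", "amplitude"]
        )
    )

    def __post_init__(self) -> None:
        self.entries = self.entries.reset_index(drop=True)
        self.entries["cycle"] = self.entries["cycle"].astype(int)
        self.entries["sample_index"] = self.entries["sample_index"].astype(int)
        self.entries["amplitude"] = self.entries["amplitude"].astype(float)
        if self.entries.duplicated(subset=["cycle", "label"]).any():
            raise InvalidParameterError("duplicate (cycle, label) annotation entry")
        bad = set(self.entries["label"]) - LABEL_SETS[self.modality]
        if bad:
            raise InvalidParameterError(f"labels {sorted(bad)} invalid for {self.modality}")

    @classmethod
    def from_records(cls, modality: str, records: Iterable[tuple]) -> "FiducialAnnotation":
        df = pd.DataFrame(records, columns=["cycle", "label", "sample_index", "amplitude"])
        return cls(modality, df)

    def get(self, cycle: int, label: str) -> tuple[int, float] | None:
        """Return (sample_index, amplitude) or None if absent."""
        m = self.entries[(self.entries["cycle"] == cycle) & (self.entries["label"] == label)]
        if m.empty:
            return None
        row = m.iloc[0]
        return int(row["sample_index"]), float(row["amplitude"])

    def cycles(self) -> list[int]:
        return sorted(self.entries["cycle"].unique())

    def indices(self, label: str) -> np.ndarray:
        """Sample indices of one label across cycles, cycle-sorted."""
        m = self.entries[self.entries["label"] == label].sort_values("cycle")
        return m["sample_index"].to_numpy(dtype=int)


def estimate_cycle_length(sampling_rate: float, heart_rate: float) -> int:
    """Samples per cardiac cycle, CL = round(Sr / Hr), ties to even.

    >>> estimate_cycle_length(1000, 1.0)
    1000
    """
    if sampling_rate <= 0 or heart_rate <= 0:
        raise InvalidParameterError("sampling_rate and heart_rate must be > 0")
    cl = int(round(sampling_rate / heart_rate))
    return max(cl, 1)


def segment_cycles(trace: SignalTrace, anchor: str = "fixed",
                   r_indices: Sequence[int] | None = None) -> CycleIndex:
    """Tile the trace into complete cardiac cycles.

    ``anchor="fixed"`` (default) tiles ``[0, n*CL)`` with the constant
    CL from the trace's mean heart rate.  ``anchor="r"`` re-estimates
    the per-beat cycle length from the median of the last 8 RR
    intervals and places each boundary 30% of the current CL before the
    beat's R peak; it requires ``r_indices``.
    """
    cl = estimate_cycle_length(trace.sampling_rate, trace.heart_rate)
    if anchor == "fixed":
        n = len(trace.samples) // cl
        if n < 1:
            raise TooShortError(
                f"trace of {len(trace.samples)} samples is shorter than one cycle ({cl})"
            )
        return CycleIndex(cl, [(i * cl, (i + 1) * cl) for i in range(n)])
    if anchor != "r":
        raise InvalidParameterError(f"unknown anchor mode {anchor!r}")
    if r_indices is None or len(r_indices) == 0:
        raise InvalidParameterError("anchor='r' requires r_indices")
    r = np.asarray(sorted(int(i) for i in r_indices))
    boundaries: list[tuple[int, int]] = []
    rr_hist: list[int] = []
    prev_end = 0
    for j, rj in enumerate(r):
        if j > 0:
            rr_hist.append(int(rj - r[j - 1]))
        cl_j = int(np.median(rr_hist[-8:])) if rr_hist else cl
        lo = max(prev_end, int(rj - round(0.3 * cl_j)))
        hi = min(len(trace.samples), lo + cl_j)
        if hi <= lo or rj >= hi:
            continue
        boundaries.append((lo, hi))
        prev_end = hi
    if not boundaries:
        raise TooShortError("no complete R-anchored cycles fit in the trace")
    return CycleIndex(cl, boundaries)


def read_trace(path, sampling_rate: float | None = None, modality: str = "ECG",
               heart_rate: float = 1.0, subject_id: str = "") -> SignalTrace:
    """Read a trace from CSV.

    Accepts a single ``amplitude`` column, or two columns
    ``time,amplitude`` (time in seconds, from which the sampling rate
    is inferred when not given explicitly).
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header is line 1
            raise ParseError(f"{path}: non-numeric value in column {col!r} at line {row}")
        df[col] = coerced
    if df.shape[1] == 1:
        samples = df.iloc[:, 0].to_numpy(dtype=float)
        if sampling_rate is None:
            raise InvalidParameterError("sampling_rate required for single-column CSV")
    elif df.shape[1] == 2:
        t = df.iloc[:, 0].to_numpy(dtype=float)
        samples = df.iloc[:, 1].to_numpy(dtype=float)
        if sampling_rate is None:
            dt = np.diff(t)
            if len(dt) == 0 or not np.all(dt > 0):
                raise ParseError(f"{path}: time column not strictly increasing")
            sampling_rate = 1.0 / float(np.median(dt))
    else:
        raise ParseError(f"{path}: expected 1 or 2 columns, got {df.shape[1]}")
    return SignalTrace(samples, sampling_rate, modality, heart_rate, subject_id)


def write_trace(path, trace: SignalTrace, include_time: bool = False) -> None:
    if include_time:
        t = np.arange(len(trace.samples)) / trace.sampling_rate
        pd.DataFrame({"time": t, "amplitude": trace.samples}).to_csv(path, index=False)
    else:
        pd.DataFrame({"amplitude": trace.samples}).to_csv(path, index=False)


def read_annotations(path, modality: str) -> FiducialAnnotation:
    """Read a fiducial annotation CSV (cycle,label,sample_index,amplitude)."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    required = {"cycle", "label", "sample_index", "amplitude"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    for col in ("cycle", "sample_index", "amplitude"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2
            raise ParseError(f"{path}: non-numeric value in column {col!r} at line {row}")
        df[col] = coerced
    return FiducialAnnotation(modality, df[["cycle", "label", "sample_index", "amplitude"]])


def write_annotations(path, annotation: FiducialAnnotation) -> None:
    annotation.entries.to_csv(path, index=False)
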