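"""Rule-based abnormal-morphology detection for ECG cycles.

Each delineated cycle is measured (P/QRS/T wave amplitudes relative to
the per-cycle median baseline, wave durations from the onset/offset
endpoints, and the RR interval from consecutive R peaks) and checked
against a table of referenced normal feature values (RFV).  A wave
check fails when the measured amplitude or duration falls strictly
outside its reference interval; undefined measurements (missing
fiducials, first-cycle RR) are never counted as failures.  Per-wave
abnormality counters are accumulated over groups of ``k`` cycles
(disjoint or sliding), and the per-cycle outcome bit is the OR of the
cycle's check failures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .signals import FiducialAnnotation, InvalidParameterError, SignalTrace

WAVES = ("P", "QRS", "T")


@dataclass
class Bounds:
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise InvalidParameterError(f"bounds must satisfy lo < hi, got [{self.lo}, {self.hi}]")

    def outside(self, value: float) -> bool:
        """Strictly outside: value > hi or value < lo (boundary passes)."""
        return value > self.hi or value < self.lo


def _default_rfv() -> dict[str, Bounds]:
    # Configurable implementation defaults drawn from standard clinical
    # normal ranges; the P and T duration maxima accommodate the
    # endpoint search construction (measured width = range width + 2a
    # on clean morphology).
    return {
        "dur_P": Bounds(0.06, 0.20),
        "dur_QRS": Bounds(0.06, 0.12),
        "dur_T": Bounds(0.10, 0.28),
        "dur_RR": Bounds(0.60, 1.20),
        "dur_PRinv": Bounds(0.12, 0.20),
        "dur_QTinv": Bounds(0.30, 0.45),
        "dur_PRseg": Bounds(0.02, 0.10),
        "dur_STseg": Bounds(0.05, 0.15),
        "amp_P": Bounds(0.05, 0.25),
        "amp_QRS": Bounds(0.50, 2.00),
        "amp_T": Bounds(0.10, 0.50),
    }


@dataclass
class ReferenceValues:
    """Normal min/max bounds per wave amplitude (mV) and duration (s).

    ``extended_checks`` additionally tests the PR and ST segment
    durations; the base rule set checks only P, QRS, T and RR.
    """

    bounds: dict[str, Bounds] = field(default_factory=_default_rfv)
    extended_checks: bool = False

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({k: [b.lo, b.hi] for k, b in self.bounds.items()}, fh)

    @classmethod
    def from_yaml(cls, path, extended_checks: bool = False) -> "ReferenceValues":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls({k: Bounds(float(v[0]), float(v[1])) for k, v in data.items()},
                   extended_checks)


def measure_cycles(annotation: FiducialAnnotation, trace: SignalTrace) -> pd.DataFrame:
    """Per-cycle measurements; NaN marks an undefined field.

    Columns: amp_P, amp_QRS, amp_T (mV, peak minus per-cycle median
    baseline, absolute); dur_P, dur_QRS, dur_T (s, offset - onset);
    dur_RR (s, R(k) - R(k-1), undefined for the first cycle); plus
    dur_PRinv, dur_QTinv, dur_PRseg, dur_STseg for the extended checks.
    """
    sr = trace.sampling_rate
    cycles = annotation.cycles()
    if trace.cycle_index is not None:
        bmap = {c: b for c, b in enumerate(trace.cycle_index.boundaries)}
    else:
        bmap = {}
    rows = []
    prev_r: int | None = None
    for c in cycles:
        def idx(lbl: str) -> int | None:
            e = annotation.get(c, lbl)
            return None if e is None else e[0]

        def amp(lbl: str) -> float | None:
            e = annotation.get(c, lbl)
            return None if e is None else e[1]

        r = idx("R")
        if c in bmap:
            lo, hi = bmap[c]
        elif r is not None:
            cl = int(round(sr / trace.heart_rate))
            lo, hi = max(0, r - cl // 2), min(len(trace.samples), r + cl // 2)
        else:
            lo, hi = 0, len(trace.samples)
        baseline = float(np.median(trace.samples[lo:hi]))

        def rel_amp(lbl: str) -> float:
            a = amp(lbl)
            return np.nan if a is None else abs(a - baseline)

        def span(on: str, off: str) -> float:
            i, j = idx(on), idx(off)
            return np.nan if i is None or j is None else (j - i) / sr

        row = {
            "cycle": c,
            "amp_P": rel_amp("P"),
            "amp_QRS": rel_amp("R"),
            "amp_T": rel_amp("T"),
            "dur_P": span("Ponset", "Poffset"),
            "dur_QRS": span("QRSonset", "QRSoffset"),
            "dur_T": span("Tonset", "Toffset"),
            "dur_PRinv": span("Ponset", "QRSonset"),
            "dur_QTinv": span("QRSonset", "Toffset"),
            "dur_PRseg": span("Poffset", "QRSonset"),
            "dur_STseg": span("QRSoffset", "Tonset"),
            "dur_RR": np.nan if r is None or prev_r is None else (r - prev_r) / sr,
        }
        if r is not None:
            prev_r = r
        rows.append(row)
    return pd.DataFrame(rows).set_index("cycle")


def check_cycles(measurements: pd.DataFrame, rfv: ReferenceValues | None = None) -> pd.DataFrame:
    """Per-cycle pass/fail per wave plus the outcome bit.

    Columns ``fail_P/fail_QRS/fail_T/fail_RR`` (bool) and ``outcome``
    (int bit, 1 iff any check failed).  Undefined (NaN) measurements
    never fail.
    """
    rfv = rfv or ReferenceValues()

    def fails(col: str, key: str) -> pd.Series:
        v = measurements[col]
        return v.notna() & v.apply(lambda x: rfv.bounds[key].outside(x))

    out = pd.DataFrame(index=measurements.index)
    for w in WAVES:
        out[f"fail_{w}"] = fails(f"amp_{w}", f"amp_{w}") | fails(f"dur_{w}", f"dur_{w}")
    out["fail_RR"] = fails("dur_RR", "dur_RR")
    checks = [f"fail_{w}" for w in WAVES] + ["fail_RR"]
    if rfv.extended_checks:
        for key in ("dur_PRinv", "dur_QTinv", "dur_PRseg", "dur_STseg"):
            out[f"fail_{key[4:]}"] = fails(key, key)
            checks.append(f"fail_{key[4:]}")
    out["outcome"] = out[checks].any(axis=1).astype(int)
    return out


@dataclass
class GroupReport:
    start_cycle: int
    counters: dict[str, int]
    outcome_bits: np.ndarray
    dominant: list[str]


def monitor_groups(checks: pd.DataFrame, k: int, mode: str = "disjoint") -> list[GroupReport]:
    """Accumulate per-wave counters over groups of k cycles.

    ``disjoint`` yields floor(n/k) non-overlapping groups; ``sliding``
    yields n-k+1 overlapping groups with counters reset per group.
    The dominant abnormal feature(s) of a group are the argmax
    counters (all maximal ones on ties; empty if all counters are 0).
    """
    if k < 1:
        raise InvalidParameterError("k must be >= 1")
    n = len(checks)
    if k > n:
        warnings.warn(f"group size k={k} exceeds {n} cycles; no groups formed")
        return []
    fail_cols = [col for col in checks.columns if col.startswith("fail_")]
    if mode == "disjoint":
        starts = range(0, n - k + 1, k)
    elif mode == "sliding":
        starts = range(0, n - k + 1)
    else:
        raise InvalidParameterError(f"unknown mode {mode!r}")
    reports = []
    for s in starts:
        grp = checks.iloc[s:s + k]
        counters = {col[5:]: int(grp[col].sum()) for col in fail_cols}
        cmax = max(counters.values())
        dominant = [w for w, v in counters.items() if v == cmax and cmax > 0]
        reports.append(GroupReport(
            start_cycle=int(checks.index[s]),
            counters=counters,
            outcome_bits=grp["outcome"].to_numpy(),
            dominant=dominant,
        ))
    return reports


def monitor_ecg(annotation: FiducialAnnotation, trace: SignalTrace,
                rfv: ReferenceValues | None = None, k: int = 5,
                mode: str = "disjoint") -> tuple[pd.DataFrame, list[GroupReport]]:
    """Measure, check, and group one annotated ECG trace."""
    m = measure_cycles(annotation, trace)
    checks = check_cycles(m, rfv)
    return checks, monitor_groups(checks, k, mode)
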