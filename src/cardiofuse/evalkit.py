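"""Evaluation of automatic against manual fiducial annotations:
tolerance matching, precision/recall/F-measure, mean delineation
error, ROC threshold sweeps, and Cohen's kappa.

Matching is greedy nearest-neighbour, per label, one-to-one: candidate
(auto, manual) pairs within the tolerance are taken in order of
increasing |error| (earliest manual, then earliest auto, on ties).  On
small instances this equals the optimal assignment, which the test
suite verifies against scipy's Hungarian solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signals import CycleIndex, FiducialAnnotation, InvalidParameterError, SignalTrace


@dataclass
class MatchResult:
    tolerance_ms: float
    # per-label: list of (auto_index, manual_index, error_ms)
    matched: dict[str, list[tuple[int, int, float]]] = field(default_factory=dict)
    unmatched_auto: dict[str, list[int]] = field(default_factory=dict)
    unmatched_manual: dict[str, list[int]] = field(default_factory=dict)

    def counts(self, label: str | None = None) -> tuple[int, int, int]:
        """(|Auto|, |Manual|, |matched|), per label or pooled."""
        labels = [label] if label else sorted(set(self.matched) | set(self.unmatched_auto)
                                              | set(self.unmatched_manual))
        n_auto = n_man = n_match = 0
        for l in labels:
            m = len(self.matched.get(l, []))
            n_match += m
            n_auto += m + len(self.unmatched_auto.get(l, []))
            n_man += m + len(self.unmatched_manual.get(l, []))
        return n_auto, n_man, n_match

    def errors_ms(self, label: str) -> np.ndarray:
        return np.array([e for _, _, e in self.matched.get(label, [])], dtype=float)


def _match_label(auto: np.ndarray, manual: np.ndarray, tol_ms: float,
                 sr: float) -> tuple[list, list, list]:
    pairs = []
    for ia, a in enumerate(auto):
        for im, m in enumerate(manual):
            err = abs(a - m) / sr * 1000.0
            if err <= tol_ms:
                pairs.append((err, im, ia))
    pairs.sort()
    used_a: set[int] = set()
    used_m: set[int] = set()
    matched = []
    for err, im, ia in pairs:
        if ia in used_a or im in used_m:
            continue
        used_a.add(ia)
        used_m.add(im)
        matched.append((int(auto[ia]), int(manual[im]),
                        (auto[ia] - manual[im]) / sr * 1000.0))
    un_a = [int(auto[i]) for i in range(len(auto)) if i not in used_a]
    un_m = [int(manual[i]) for i in range(len(manual)) if i not in used_m]
    return matched, un_a, un_m


def match_annotations(auto: FiducialAnnotation, manual: FiducialAnnotation,
                      sampling_rate: float, tolerance_ms: float = 25.0) -> MatchResult:
    """Greedy one-to-one tolerance matching per label."""
    if auto.modality != manual.modality:
        raise InvalidParameterError("annotations must share a modality")
    result = MatchResult(tolerance_ms)
    labels = sorted(set(auto.entries["label"]) | set(manual.entries["label"]))
    for label in labels:
        m, ua, um = _match_label(auto.indices(label), manual.indices(label),
                                 tolerance_ms, sampling_rate)
        result.matched[label] = m
        result.unmatched_auto[label] = ua
        result.unmatched_manual[label] = um
    return result


def prf(n_auto: int, n_manual: int, n_matched: int) -> tuple[float, float, float]:
    """Precision, recall, F-measure from match counts.

    precision = matched/|Auto|, recall = matched/|Manual|,
    F = 2PR/(P+R).  Empty denominators yield NaN (undefined), and
    F = 0 when P + R = 0.
    """
    p = n_matched / n_auto if n_auto > 0 else float("nan")
    r = n_matched / n_manual if n_manual > 0 else float("nan")
    if np.isnan(p) or np.isnan(r):
        f = float("nan")
    elif p + r == 0:
        f = 0.0
    else:
        f = 2 * p * r / (p + r)
    return p, r, f


def prf_report(match: MatchResult, pooled: bool = True) -> pd.DataFrame:
    """P/R/F per label plus (by default) a pooled overall row."""
    rows = []
    labels = sorted(set(match.matched) | set(match.unmatched_auto) | set(match.unmatched_manual))
    for label in labels:
        na, nm, nx = match.counts(label)
        p, r, f = prf(na, nm, nx)
        rows.append({"label": label, "n_auto": na, "n_manual": nm, "n_matched": nx,
                     "precision": p, "recall": r, "f_measure": f})
    if pooled:
        na, nm, nx = match.counts()
        p, r, f = prf(na, nm, nx)
        rows.append({"label": "ALL", "n_auto": na, "n_manual": nm, "n_matched": nx,
                     "precision": p, "recall": r, "f_measure": f})
    return pd.DataFrame(rows)


def delineation_error(match: MatchResult) -> pd.DataFrame:
    """Mean and sample SD (n-1) of |auto - manual| per label, in ms."""
    rows = []
    for label in sorted(match.matched):
        errs = np.abs(match.errors_ms(label))
        if len(errs) == 0:
            continue
        sd = float(errs.std(ddof=1)) if len(errs) > 1 else 0.0
        rows.append({"label": label, "n": len(errs),
                     "mean_ms": float(errs.mean()), "sd_ms": sd})
    return pd.DataFrame(rows)


def roc_sweep(trace: SignalTrace, truth: FiducialAnnotation, sigma_grid,
              which: str = "R", cycles: CycleIndex | None = None,
              tolerance_ms: float = 25.0) -> pd.DataFrame:
    """Sweep the detection threshold and tabulate (sigma, TPR, FPR).

    TPR = matched detections / |truth points|; FPR = unmatched
    detections / total detections (0 when nothing is detected -- the
    precision-complement convention).
    """
    from .ecg_delineate import MISSING, ECGDelineationParams, detect_r
    from .scg_delineate import SCGDelineationParams, detect_ao
    from .signals import segment_cycles

    sigma_grid = list(sigma_grid)
    if not sigma_grid:
        raise InvalidParameterError("sigma_grid must be non-empty")
    if which not in ("R", "AO"):
        raise InvalidParameterError("which must be 'R' or 'AO'")
    if cycles is None:
        cycles = trace.cycle_index or segment_cycles(trace)
    truth_idx = truth.indices(which)
    rows = []
    for sigma in sorted(sigma_grid):
        if which == "R":
            det = detect_r(trace, cycles, ECGDelineationParams(sigma_r=sigma))
        else:
            det = detect_ao(trace, cycles, SCGDelineationParams(sigma_ao=sigma))
        det = det[det != MISSING]
        m, ua, _ = _match_label(det.astype(float), truth_idx.astype(float),
                                tolerance_ms, trace.sampling_rate)
        tpr = len(m) / len(truth_idx) if len(truth_idx) else float("nan")
        fpr = len(ua) / len(det) if len(det) else 0.0
        rows.append({"sigma": float(sigma), "n_detected": int(len(det)),
                     "tpr": tpr, "fpr": fpr})
    return pd.DataFrame(rows)


def cohens_kappa(labels_a, labels_b) -> float:
    """Cohen's kappa = (po - pe) / (1 - pe); NaN when pe = 1."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if len(a) != len(b):
        raise InvalidParameterError("label sequences must have equal length")
    if len(a) == 0:
        raise InvalidParameterError("empty label sequences")
    classes = np.unique(np.concatenate([a, b]))
    po = float(np.mean(a == b))
    pe = sum(float(np.mean(a == c)) * float(np.mean(b == c)) for c in classes)
    if pe >= 1.0:
        return float("nan")
    return (po - pe) / (1.0 - pe)
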