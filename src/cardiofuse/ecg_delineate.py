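"""ECG fiducial delineation: threshold R detection, range-based P/Q/S/T,
and wave onset/offset endpoints.

R detection first locates the global maximum amplitude over all cycles
(``zeta``); within each cycle, local maxima with amplitude at least
``sigma_r * zeta`` are candidate R peaks and the largest candidate is
the cycle's R.  The remaining fiducials are located as the extremum of
the signal inside a search range derived from normal clinical wave and
interval durations around R:

* Q: minimum in ``[R - (dQRS*Sr/2 + a), R]``
* P: maximum in ``[R - (dPR*Sr + a), R]`` excluding the Q sub-range
* S: minimum in ``[R, R + dQRS*Sr/2 + a]``
* T: maximum in ``[R, R + dQT*Sr - dQRS*Sr/2 + a]`` excluding the S
  sub-range

with ``a`` a fixed error-margin in samples (default 20 ms).  Onset and
offset points are the minimum-amplitude sample in a half-wave-width
window on either side of P and T, and the maximum-amplitude sample in
an ``a``-wide window before Q / after S for the QRS complex (a
min-|slope| alternative is available via ``qrs_endpoint_rule``).
Ranges are clipped at the trace edges; an empty range yields a missing
flag, never an exception.  Ties in any extremum go to the earliest
sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signals import (
    CycleIndex,
    FiducialAnnotation,
    InvalidParameterError,
    SignalTrace,
)

MISSING = -1


class NoCandidatesError(ValueError):
    """Zero-variance trace: no local maxima exist anywhere."""


@dataclass
class ECGDelineationParams:
    """Tunables for ECG delineation.

    sigma_r: candidate-R amplitude fraction of the global maximum
        (0.7 chosen experimentally in the source method).
    alpha_s: error-margin in seconds added to every search range
        (stored in seconds; converted to samples per trace).
    Durations are normal clinical reference values in seconds.
    """

    sigma_r: float = 0.7
    alpha_s: float = 0.02
    d_qrs: float = 0.12
    d_pr: float = 0.20
    d_qt: float = 0.45
    d_p: float = 0.12
    d_t: float = 0.20
    qrs_endpoint_rule: str = "max"  # "max" (literal) or "min_slope"

    def __post_init__(self) -> None:
        if not 0 < self.sigma_r < 1:
            raise InvalidParameterError("sigma_r must be in (0, 1)")
        if self.alpha_s < 0:
            raise InvalidParameterError("alpha must be >= 0")
        for d in (self.d_qrs, self.d_pr, self.d_qt, self.d_p, self.d_t):
            if d <= 0:
                raise InvalidParameterError("reference durations must be > 0")

    def alpha(self, sr: float) -> int:
        return int(round(self.alpha_s * sr))


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices i with a rising first difference before and non-rising after."""
    if len(x) < 3:
        return np.array([], dtype=int)
    d = np.diff(x)
    return np.flatnonzero((d[:-1] > 0) & (d[1:] <= 0)) + 1


def detect_r(trace: SignalTrace, cycles: CycleIndex,
             params: ECGDelineationParams | None = None) -> np.ndarray:
    """Per-cycle R sample index; MISSING (-1) where no candidate exists."""
    params = params or ECGDelineationParams()
    if trace.modality != "ECG":
        raise InvalidParameterError("detect_r requires an ECG trace")
    x = trace.samples
    lo0, hi_last = cycles.boundaries[0][0], cycles.boundaries[-1][1]
    zeta = float(np.max(x[lo0:hi_last]))
    if np.ptp(x[lo0:hi_last]) == 0:
        raise NoCandidatesError("zero-variance trace: no R candidates")
    thresh = params.sigma_r * zeta
    out = np.full(cycles.n_cycles, MISSING, dtype=int)
    for c, (lo, hi) in enumerate(cycles.boundaries):
        seg = x[lo:hi]
        cand = _local_maxima(seg)
        cand = cand[seg[cand] >= thresh]
        if len(cand):
            out[c] = lo + int(cand[np.argmax(seg[cand])])
    return out


def _extremum(x: np.ndarray, lo: int, hi: int, mode: str) -> int:
    """Earliest arg-extremum of x[lo:hi] (inclusive bounds), or MISSING."""
    lo, hi = max(lo, 0), min(hi, len(x) - 1)
    if hi < lo:
        return MISSING
    seg = x[lo:hi + 1]
    return lo + int(np.argmin(seg) if mode == "min" else np.argmax(seg))


def delineate_pqst(trace: SignalTrace, cycles: CycleIndex, r_indices: np.ndarray,
                   params: ECGDelineationParams | None = None) -> FiducialAnnotation:
    """Locate P, Q, S, T per cycle relative to detected R peaks."""
    params = params or ECGDelineationParams()
    if len(r_indices) == 0:
        raise InvalidParameterError("r_indices is empty")
    sr = trace.sampling_rate
    a = params.alpha(sr)
    qrs_half = int(round(params.d_qrs * sr / 2))
    pr = int(round(params.d_pr * sr))
    qt = int(round(params.d_qt * sr))
    x = trace.samples
    records = []
    for c, (clo, chi) in enumerate(cycles.boundaries):
        r = int(r_indices[c])
        if r == MISSING:
            continue
        records.append((c, "R", r, x[r]))
        q = _extremum(x, r - (qrs_half + a), r, "min")
        if q != MISSING:
            records.append((c, "Q", q, x[q]))
        # P search excludes the Q sub-range so the Q valley is not captured
        p = _extremum(x, r - (pr + a), r - (qrs_half + a) - 1, "max")
        if p != MISSING:
            records.append((c, "P", p, x[p]))
        s = _extremum(x, r, r + qrs_half + a, "min")
        if s != MISSING:
            records.append((c, "S", s, x[s]))
        t = _extremum(x, r + qrs_half + a + 1, r + qt - qrs_half + a, "max")
        if t != MISSING:
            records.append((c, "T", t, x[t]))
    return FiducialAnnotation.from_records("ECG", records)


def delineate_endpoints(trace: SignalTrace, annotation: FiducialAnnotation,
                        params: ECGDelineationParams | None = None) -> FiducialAnnotation:
    """Augment a P/Q/R/S/T annotation with the six wave endpoints.

    Endpoints whose anchor fiducial is missing are skipped silently.
    """
    params = params or ECGDelineationParams()
    sr = trace.sampling_rate
    a = params.alpha(sr)
    p_half = int(round(params.d_p * sr / 2))
    t_half = int(round(params.d_t * sr / 2))
    x = trace.samples
    records = [tuple(r) for r in annotation.entries.itertuples(index=False)]
    for c in annotation.cycles():
        def anchor(lbl: str) -> int | None:
            e = annotation.get(c, lbl)
            return None if e is None else e[0]

        p, q, s, t = anchor("P"), anchor("Q"), anchor("S"), anchor("T")
        if p is not None:
            for lbl, lo, hi in (("Ponset", p - p_half - a, p), ("Poffset", p, p + p_half + a)):
                idx = _extremum(x, lo, hi, "min")
                if idx != MISSING:
                    records.append((c, lbl, idx, x[idx]))
        if t is not None:
            for lbl, lo, hi in (("Tonset", t - t_half - a, t), ("Toffset", t, t + t_half + a)):
                idx = _extremum(x, lo, hi, "min")
                if idx != MISSING:
                    records.append((c, lbl, idx, x[idx]))
        for lbl, lo, hi in (("QRSonset", None if q is None else q - a, q),
                            ("QRSoffset", s, None if s is None else s + a)):
            if lo is None or hi is None:
                continue
            if params.qrs_endpoint_rule == "max":
                idx = _extremum(x, lo, hi, "max")
            else:  # min_slope: flattest point in the window
                llo, lhi = max(lo, 1), min(hi, len(x) - 2)
                if lhi < llo:
                    idx = MISSING
                else:
                    slopes = np.abs(x[llo + 1:lhi + 2] - x[llo - 1:lhi]) / 2
                    idx = llo + int(np.argmin(slopes))
            if idx != MISSING:
                records.append((c, lbl, idx, x[idx]))
    return FiducialAnnotation.from_records("ECG", records)


def delineate_ecg(trace: SignalTrace, cycles: CycleIndex | None = None,
                  params: ECGDelineationParams | None = None) -> FiducialAnnotation:
    """Full ECG delineation: R detection, P/Q/S/T, endpoints."""
    from .signals import segment_cycles

    params = params or ECGDelineationParams()
    if cycles is None:
        cycles = trace.cycle_index or segment_cycles(trace)
    r = detect_r(trace, cycles, params)
    ann = delineate_pqst(trace, cycles, r, params)
    return delineate_endpoints(trace, ann, params)
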