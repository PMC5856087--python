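"""SCG fiducial delineation: threshold AO detection and trained
per-label search windows for the remaining eight fiducials.

AO (aortic valve opening) is the dominant SCG peak and is detected
like the ECG R: local maxima above ``sigma_ao`` times the global
maximum.  Because normal SCG morphology is not tabulated the way ECG
wave durations are, the offsets of the other fiducials relative to AO
are *learned* from annotated training cycles of healthy subjects: for
each label X the signed window centre ``SW(X)`` is the mean of
``index(X) - index(AO)`` over the training cycles, and the window
half-width is ``max(2 * SD of those offsets, alpha)``.  Delineation
then picks the maximum-amplitude sample (for peak-polarity labels) or
the minimum (valley) inside ``[AO + SW(X) - hw, AO + SW(X) + hw + a]``.
A label whose window is empty after clipping is flagged missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .ecg_delineate import MISSING, NoCandidatesError, _extremum, _local_maxima
from .signals import (
    SCG_LABELS,
    CycleIndex,
    FiducialAnnotation,
    InvalidParameterError,
    SignalTrace,
)

DEFAULT_POLARITY = {
    "AS": "peak", "MC": "valley", "IM": "valley", "AO": "peak", "IC": "valley",
    "RE": "peak", "AC": "valley", "MO": "peak", "RF": "peak",
}


class MissingTrainingError(ValueError):
    """A label was absent from every training cycle."""


@dataclass
class WindowEntry:
    offset: float      # SW(X): mean signed offset from AO, samples
    half_width: float  # search half-width, samples


@dataclass
class SCGDelineationParams:
    """Tunables for SCG delineation.

    sigma_ao: candidate-AO amplitude fraction of the global maximum
        (0.75 chosen experimentally in the source method).
    alpha_s: error margin in seconds (floor for window half-widths and
        the asymmetric extension of the search range).
    window_mode: "trained" scales half-widths with the training SD
        (floored at alpha); "fixed" uses exactly alpha.
    """

    sigma_ao: float = 0.75
    alpha_s: float = 0.02
    window_table: dict[str, WindowEntry] = field(default_factory=dict)
    polarity_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_POLARITY))
    window_mode: str = "trained"

    def __post_init__(self) -> None:
        if not 0 < self.sigma_ao < 1:
            raise InvalidParameterError("sigma_ao must be in (0, 1)")
        if self.alpha_s < 0:
            raise InvalidParameterError("alpha must be >= 0")

    def alpha(self, sr: float) -> int:
        return int(round(self.alpha_s * sr))


def estimate_windows(training: list[FiducialAnnotation], sampling_rate: float,
                     params: SCGDelineationParams | None = None,
                     labels: list[str] | None = None) -> dict[str, WindowEntry]:
    """Learn per-label search windows from annotated training cycles.

    ``SW(X)`` is the mean of the signed offsets ``X - AO`` across every
    training cycle containing both labels; the half-width is
    ``max(2 * sample SD, alpha)``.  Translation-invariant: shifting all
    annotations of a cycle by a constant leaves the table unchanged.
    ``labels`` defaults to the eight non-AO fiducials; a requested
    label absent from every training cycle raises MissingTrainingError.
    """
    params = params or SCGDelineationParams()
    a = params.alpha(sampling_rate)
    if labels is None:
        labels = [l for l in SCG_LABELS if l != "AO"]
    offsets: dict[str, list[float]] = {l: [] for l in labels}
    for ann in training:
        for c in ann.cycles():
            ao = ann.get(c, "AO")
            if ao is None:
                continue
            for label in offsets:
                e = ann.get(c, label)
                if e is not None:
                    offsets[label].append(e[0] - ao[0])
    table: dict[str, WindowEntry] = {}
    for label, offs in offsets.items():
        if not offs:
            raise MissingTrainingError(f"label {label!r} absent from all training cycles")
        arr = np.asarray(offs, dtype=float)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        hw = float(max(2 * sd, a)) if params.window_mode == "trained" else float(a)
        table[label] = WindowEntry(float(arr.mean()), hw)
    return table


def window_table_to_yaml(table: dict[str, WindowEntry], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({l: {"offset": w.offset, "half_width": w.half_width}
                        for l, w in table.items()}, fh)


def window_table_from_yaml(path) -> dict[str, WindowEntry]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return {l: WindowEntry(d["offset"], d["half_width"]) for l, d in data.items()}


def detect_ao(trace: SignalTrace, cycles: CycleIndex,
              params: SCGDelineationParams | None = None) -> np.ndarray:
    """Per-cycle AO sample index; MISSING (-1) where no candidate exists."""
    params = params or SCGDelineationParams()
    if trace.modality != "SCG":
        raise InvalidParameterError("detect_ao requires an SCG trace")
    x = trace.samples
    lo0, hi_last = cycles.boundaries[0][0], cycles.boundaries[-1][1]
    if np.ptp(x[lo0:hi_last]) == 0:
        raise NoCandidatesError("zero-variance trace: no AO candidates")
    thresh = params.sigma_ao * float(np.max(x[lo0:hi_last]))
    out = np.full(cycles.n_cycles, MISSING, dtype=int)
    for c, (lo, hi) in enumerate(cycles.boundaries):
        seg = x[lo:hi]
        cand = _local_maxima(seg)
        cand = cand[seg[cand] >= thresh]
        if len(cand):
            out[c] = lo + int(cand[np.argmax(seg[cand])])
    return out


def delineate_scg(trace: SignalTrace, cycles: CycleIndex, ao_indices: np.ndarray,
                  params: SCGDelineationParams) -> FiducialAnnotation:
    """Locate the eight non-AO fiducials inside their trained windows."""
    missing = [l for l in SCG_LABELS if l != "AO" and l not in params.window_table]
    if missing:
        raise InvalidParameterError(f"window_table lacks labels {missing}")
    sr = trace.sampling_rate
    a = params.alpha(sr)
    x = trace.samples
    records = []
    for c in range(cycles.n_cycles):
        ao = int(ao_indices[c])
        if ao == MISSING:
            continue
        records.append((c, "AO", ao, x[ao]))
        for label in SCG_LABELS:
            if label == "AO":
                continue
            w = params.window_table[label]
            lo = ao + int(round(w.offset - w.half_width))
            hi = ao + int(round(w.offset + w.half_width)) + a
            mode = "max" if params.polarity_map.get(label, "peak") == "peak" else "min"
            idx = _extremum(x, lo, hi, mode)
            if idx != MISSING:
                records.append((c, label, idx, x[idx]))
    return FiducialAnnotation.from_records("SCG", records)


def delineate_scg_full(trace: SignalTrace, training: list[FiducialAnnotation],
                       cycles: CycleIndex | None = None,
                       params: SCGDelineationParams | None = None) -> FiducialAnnotation:
    """AO detection + window training + full nine-point delineation."""
    from .signals import segment_cycles

    params = params or SCGDelineationParams()
    if cycles is None:
        cycles = trace.cycle_index or segment_cycles(trace)
    if not params.window_table:
        params.window_table = estimate_windows(training, trace.sampling_rate, params)
    ao = detect_ao(trace, cycles, params)
    return delineate_scg(trace, cycles, ao, params)
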