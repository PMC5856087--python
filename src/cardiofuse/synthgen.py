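"""Paired synthetic ECG/SCG generation with ground-truth fiducials.

Each beat is rendered as a sum of Gaussian bumps on a flat isoelectric
baseline: one bump per fiducial, signed by its polarity (peak or
valley), with the bump centre defining the analytically known
ground-truth fiducial location.  White Gaussian noise and a
low-frequency sinusoidal baseline wander are added on top.  Bumps are
rendered cycle-locally (truncated at cycle boundaries) so that anomaly
injection into one cycle leaves every other cycle's samples
bit-identical; for the default templates the truncation error is below
1e-3 mV.

The ECG and SCG traces of one synthetic subject share identical
per-beat cycle starts (the electromechanical pairing): within a cycle
the electrical R peak always precedes the mechanical AO peak.

Limits of realism: no physiological ODE dynamics, no respiration
modulation beyond the sinusoidal wander, fixed per-beat morphology
(only timing jitter varies beat to beat unless anomalies are
injected).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .signals import (
    ECG_LABELS,
    SCG_LABELS,
    CycleIndex,
    FiducialAnnotation,
    InvalidParameterError,
    SignalTrace,
    estimate_cycle_length,
)

ANOMALY_KINDS = (
    "amplitude_scale",
    "duration_stretch",
    "rr_prolong",
    "st_shift",
    "drop_fiducial",
    "noise_burst",
)


class InvalidTemplateError(ValueError):
    pass


class InvalidAnomalyError(ValueError):
    pass


@dataclass
class Bump:
    label: str
    offset_ms: float      # centre, ms from cycle start
    amplitude_mv: float   # unsigned magnitude
    width_ms: float       # Gaussian SD
    polarity: str         # "peak" or "valley"

    @property
    def signed_amplitude(self) -> float:
        return self.amplitude_mv if self.polarity == "peak" else -self.amplitude_mv


@dataclass
class BeatTemplate:
    """One beat's morphology as an ordered list of Gaussian bumps."""

    modality: str
    bumps: list[Bump] = field(default_factory=list)

    def __post_init__(self) -> None:
        order = ECG_LABELS if self.modality == "ECG" else SCG_LABELS
        labels = [b.label for b in self.bumps]
        canonical = [l for l in order if l in labels]
        if labels != canonical:
            raise InvalidTemplateError(
                f"bump labels {labels} not in canonical {self.modality} order"
            )
        offsets = [b.offset_ms for b in self.bumps]
        if any(b2 <= b1 for b1, b2 in zip(offsets, offsets[1:])):
            raise InvalidTemplateError("bump offsets must be strictly increasing")
        if any(b.width_ms <= 0 for b in self.bumps):
            raise InvalidTemplateError("bump widths must be > 0")

    def get(self, label: str) -> Bump:
        for b in self.bumps:
            if b.label == label:
                return b
        raise KeyError(label)

    def labels(self) -> list[str]:
        return [b.label for b in self.bumps]

    def to_yaml(self, path) -> None:
        data = {
            "modality": self.modality,
            "bumps": [
                {
                    "label": b.label,
                    "offset_ms": b.offset_ms,
                    "amplitude_mv": b.amplitude_mv,
                    "width_ms": b.width_ms,
                    "polarity": b.polarity,
                }
                for b in self.bumps
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)

    @classmethod
    def from_yaml(cls, path) -> "BeatTemplate":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(data["modality"], [Bump(**b) for b in data["bumps"]])


def default_ecg_template() -> BeatTemplate:
    """Normal-morphology ECG beat sitting inside the default reference bounds."""
    return BeatTemplate("ECG", [
        Bump("P", 150.0, 0.15, 25.0, "peak"),
        Bump("Q", 250.0, 0.10, 8.0, "valley"),
        Bump("R", 280.0, 1.50, 8.0, "peak"),
        Bump("S", 310.0, 0.20, 8.0, "valley"),
        Bump("T", 500.0, 0.30, 40.0, "peak"),
    ])


def default_scg_template() -> BeatTemplate:
    """Tricuspid-site SCG beat; AO is the dominant peak, polarities alternate."""
    return BeatTemplate("SCG", [
        Bump("AS", 300.0, 0.30, 10.0, "peak"),
        Bump("MC", 325.0, 0.40, 8.0, "valley"),
        Bump("IM", 355.0, 0.25, 6.0, "valley"),
        Bump("AO", 380.0, 1.00, 8.0, "peak"),
        Bump("IC", 410.0, 0.50, 8.0, "valley"),
        Bump("RE", 440.0, 0.45, 10.0, "peak"),
        Bump("AC", 560.0, 0.35, 10.0, "valley"),
        Bump("MO", 590.0, 0.40, 10.0, "peak"),
        Bump("RF", 660.0, 0.25, 12.0, "peak"),
    ])


@dataclass
class AnomalySpec:
    """A morphology or rhythm anomaly injected into specific cycles.

    kind:
      amplitude_scale  scale the target fiducial's bump amplitude
      duration_stretch delay the target fiducial and all later
                       fiducials in the cycle by ``magnitude`` seconds
      rr_prolong       lengthen the RR interval ending at the target
                       cycle's R by ``magnitude`` seconds
      st_shift         add ``magnitude`` mV to the ST segment (ECG)
      drop_fiducial    remove the target fiducial's bump
      noise_burst      add white noise of SD ``magnitude`` to the cycle
    """

    kind: str
    cycles: list[int]
    label: str | None = None
    magnitude: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ANOMALY_KINDS:
            raise InvalidAnomalyError(f"unknown anomaly kind {self.kind!r}")
        if not np.isfinite(self.magnitude):
            raise InvalidAnomalyError("magnitude must be finite")
        if self.kind in ("amplitude_scale", "duration_stretch", "drop_fiducial") and not self.label:
            raise InvalidAnomalyError(f"{self.kind} requires a target label")

    @classmethod
    def from_dict(cls, d: dict) -> "AnomalySpec":
        return cls(kind=d["kind"], cycles=list(d["cycles"]),
                   label=d.get("label"), magnitude=float(d.get("magnitude", 0.0)))


def anomalies_from_yaml(path) -> list[AnomalySpec]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return [AnomalySpec.from_dict(d) for d in data]


def _render_cycle(segment: np.ndarray, bumps: list[Bump], sr: float) -> None:
    """Add bump waveforms to one cycle's samples in place."""
    n = len(segment)
    t_ms = np.arange(n) * (1000.0 / sr)
    for b in bumps:
        segment += b.signed_amplitude * np.exp(-0.5 * ((t_ms - b.offset_ms) / b.width_ms) ** 2)


def _truth_entries(cycle: int, start: int, length: int, bumps: list[Bump],
                   sr: float) -> list[tuple[int, str, int]]:
    out = []
    for b in bumps:
        idx = start + int(round(b.offset_ms * sr / 1000.0))
        if start <= idx < start + length:
            out.append((cycle, b.label, idx))
    return out


def generate_paired(
    template_ecg: BeatTemplate | None = None,
    template_scg: BeatTemplate | None = None,
    n_cycles: int = 30,
    heart_rate: float = 1.0,
    sampling_rate: float = 1000.0,
    rr_jitter_sd: float = 0.02,
    noise_sd: float = 0.02,
    baseline_wander_amp: float = 0.05,
    baseline_wander_hz: float = 0.25,
    seed: int | None = None,
    subject_id: str = "synthetic",
) -> tuple[SignalTrace, SignalTrace, FiducialAnnotation, FiducialAnnotation]:
    """Generate time-aligned ECG and SCG traces with ground truth.

    Both traces share identical per-beat cycle starts.  ``rr_jitter_sd``
    is the per-beat multiplicative Gaussian SD on the cycle length,
    truncated at +/-3 SD.  Reproducible for a fixed seed.
    """
    if n_cycles < 1:
        raise InvalidParameterError("n_cycles must be >= 1")
    if seed is None:
        raise InvalidParameterError("a seed is required for reproducibility")
    template_ecg = template_ecg or default_ecg_template()
    template_scg = template_scg or default_scg_template()
    cl = estimate_cycle_length(sampling_rate, heart_rate)
    for tpl in (template_ecg, template_scg):
        if max(b.offset_ms for b in tpl.bumps) * sampling_rate / 1000.0 >= cl:
            raise InvalidTemplateError("template extends beyond the cycle length")

    rng = np.random.default_rng(seed)
    jitter = np.clip(rng.normal(0.0, rr_jitter_sd, n_cycles), -3 * rr_jitter_sd, 3 * rr_jitter_sd) \
        if rr_jitter_sd > 0 else np.zeros(n_cycles)
    lengths = np.maximum((cl * (1.0 + jitter)).round().astype(int), 2)
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    total = int(lengths.sum())

    traces, annos = [], []
    for tpl, modality in ((template_ecg, "ECG"), (template_scg, "SCG")):
        samples = np.zeros(total)
        truth: list[tuple[int, str, int]] = []
        for c in range(n_cycles):
            s, ln = int(starts[c]), int(lengths[c])
            _render_cycle(samples[s:s + ln], tpl.bumps, sampling_rate)
            truth.extend(_truth_entries(c, s, ln, tpl.bumps, sampling_rate))
        if noise_sd > 0:
            samples += rng.normal(0.0, noise_sd, total)
        if baseline_wander_amp > 0:
            phase = rng.uniform(0, 2 * np.pi)
            t = np.arange(total) / sampling_rate
            samples += baseline_wander_amp * np.sin(2 * np.pi * baseline_wander_hz * t + phase)
        trace = SignalTrace(samples, sampling_rate, modality, heart_rate, subject_id)
        trace.cycle_index = CycleIndex(cl, [(int(s), int(s + ln)) for s, ln in zip(starts, lengths)])
        ann = FiducialAnnotation.from_records(
            modality, [(c, l, i, samples[i]) for c, l, i in truth]
        )
        traces.append(trace)
        annos.append(ann)
    return traces[0], traces[1], annos[0], annos[1]


def _modified_template(template: BeatTemplate, spec: AnomalySpec) -> BeatTemplate:
    tpl = copy.deepcopy(template)
    if spec.label is not None and spec.kind in ("amplitude_scale", "duration_stretch", "drop_fiducial"):
        if spec.label not in tpl.labels():
            raise InvalidAnomalyError(
                f"label {spec.label!r} not in {template.modality} template"
            )
    if spec.kind == "amplitude_scale":
        tpl.get(spec.label).amplitude_mv *= spec.magnitude
    elif spec.kind == "duration_stretch":
        shift_ms = spec.magnitude * 1000.0
        started = False
        for b in tpl.bumps:
            if b.label == spec.label:
                started = True
            if started:
                b.offset_ms += shift_ms
    elif spec.kind == "drop_fiducial":
        tpl.bumps = [b for b in tpl.bumps if b.label != spec.label]
    return tpl


def inject_abnormality(
    trace: SignalTrace,
    annotation: FiducialAnnotation,
    spec: AnomalySpec,
    template: BeatTemplate | None = None,
    seed: int = 0,
) -> tuple[SignalTrace, FiducialAnnotation, np.ndarray]:
    """Inject one anomaly; returns (trace, annotation, per-cycle truth bits).

    Only the targeted cycles' samples change.  Morphology anomalies
    (amplitude_scale, duration_stretch, drop_fiducial) re-render the
    affected cycles' bumps and therefore need the generating
    ``template``.  ``rr_prolong`` inserts isoelectric baseline at the
    end of the *preceding* cycle so the targeted cycle's RR interval is
    the one prolonged.
    """
    if trace.cycle_index is None:
        raise InvalidParameterError("trace has no cycle index; generate it with synthgen")
    boundaries = list(trace.cycle_index.boundaries)
    n_cycles = len(boundaries)
    truth = np.zeros(n_cycles, dtype=int)
    for c in spec.cycles:
        if not 0 <= c < n_cycles:
            raise InvalidAnomalyError(f"cycle {c} outside trace ({n_cycles} cycles)")
        truth[c] = 1
    if spec.label is not None and spec.kind in ("amplitude_scale", "duration_stretch",
                                                "drop_fiducial", "st_shift"):
        modality_labels = set((ECG_LABELS if trace.modality == "ECG" else SCG_LABELS))
        if spec.kind != "st_shift" and spec.label not in modality_labels:
            raise InvalidAnomalyError(f"label {spec.label!r} not valid for {trace.modality}")

    sr = trace.sampling_rate
    samples = trace.samples.copy()
    entries = annotation.entries.copy()

    if spec.kind == "rr_prolong":
        ins = int(round(spec.magnitude * sr))
        # process descending so earlier insert offsets stay valid
        for c in sorted(spec.cycles, reverse=True):
            if c == 0:
                raise InvalidAnomalyError("rr_prolong cannot target the first cycle")
            pos = boundaries[c][0]  # end of preceding cycle
            samples = np.concatenate([samples[:pos], np.zeros(ins), samples[pos:]])
            boundaries = [
                (lo + ins if lo >= pos else lo, hi + ins if hi > pos else hi)
                for lo, hi in boundaries
            ]
            shift = entries["sample_index"] >= pos
            entries.loc[shift, "sample_index"] += ins
        new_trace = SignalTrace(samples, sr, trace.modality, trace.heart_rate, trace.subject_id)
        new_trace.cycle_index = CycleIndex(trace.cycle_index.cycle_length, boundaries)
        return new_trace, FiducialAnnotation(trace.modality, entries), truth

    if spec.kind == "noise_burst":
        rng = np.random.default_rng(seed)
        for c in spec.cycles:
            lo, hi = boundaries[c]
            samples[lo:hi] += rng.normal(0.0, spec.magnitude, hi - lo)
    elif spec.kind == "st_shift":
        if trace.modality != "ECG":
            raise InvalidAnomalyError("st_shift applies to ECG only")
        for c in spec.cycles:
            lo, hi = boundaries[c]
            s_entry = annotation.get(c, "S")
            t_entry = annotation.get(c, "T")
            if s_entry is None or t_entry is None:
                raise InvalidAnomalyError(f"cycle {c} lacks S/T fiducials for st_shift")
            a = min(hi, s_entry[0] + int(round(0.020 * sr)))
            b = max(lo, t_entry[0] - int(round(0.080 * sr)))
            if b > a:
                samples[a:b] += spec.magnitude
    else:
        if template is None:
            raise InvalidAnomalyError(f"{spec.kind} requires the generating template")
        new_tpl = _modified_template(template, spec)
        for c in spec.cycles:
            lo, hi = boundaries[c]
            old = np.zeros(hi - lo)
            new = np.zeros(hi - lo)
            _render_cycle(old, template.bumps, sr)
            _render_cycle(new, new_tpl.bumps, sr)
            samples[lo:hi] += new - old
            # rebuild this cycle's ground-truth entries
            entries = entries[entries["cycle"] != c]
            for cc, lbl, idx in _truth_entries(c, lo, hi - lo, new_tpl.bumps, sr):
                entries = pd.concat(
                    [entries, pd.DataFrame([{"cycle": cc, "label": lbl,
                                             "sample_index": idx, "amplitude": 0.0}])],
                    ignore_index=True,
                )

    # refresh amplitudes for entries in affected cycles
    for c in spec.cycles:
        mask = entries["cycle"] == c
        entries.loc[mask, "amplitude"] = samples[entries.loc[mask, "sample_index"].to_numpy(int)]

    new_trace = SignalTrace(samples, sr, trace.modality, trace.heart_rate, trace.subject_id)
    new_trace.cycle_index = trace.cycle_index
    return new_trace, FiducialAnnotation(trace.modality, entries), truth
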