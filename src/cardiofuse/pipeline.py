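"""End-to-end paired ECG+SCG pipeline: simulate -> delineate ->
monitor -> fuse.

This is the driver behind the CLI ``run`` subcommand and the worked
CAI case studies: a calibration stream of clean beats trains the SCG
search windows and the running statistics, then an evaluation group
(optionally carrying injected anomalies) is delineated, checked by
both rule-based monitors, AND-fused per beat, and summarised as a
Cardiac Abnormality Index.

Per-beat abnormality bits can come from the rule-based monitors
(``cc_source="rules"``, used by the case studies) or from Naive Bayes
classifiers trained on a labeled synthetic corpus
(``cc_source="nb"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ecg_monitor as em
from . import fusion, scg_monitor, synthgen
from .ecg_delineate import ECGDelineationParams, delineate_ecg
from .scg_delineate import SCGDelineationParams, delineate_scg_full, estimate_windows
from .signals import FiducialAnnotation, SignalTrace


@dataclass
class CaseResult:
    """Outcome of one paired monitoring case."""

    ecg_bits: np.ndarray          # evaluation-group ECG outcome bits
    scg_bits: np.ndarray          # evaluation-group SCG outcome bits
    joint_bits: np.ndarray
    cai_ecg: float
    cai_scg: float
    cai_joint: float
    ecg_truth: np.ndarray = field(default_factory=lambda: np.array([]))
    scg_truth: np.ndarray = field(default_factory=lambda: np.array([]))
    ecg_checks: pd.DataFrame | None = None
    scg_report: pd.DataFrame | None = None


def run_paired_case(
    n_eval: int = 5,
    n_calibration: int = 20,
    seed: int = 1,
    heart_rate: float = 1.0,
    sampling_rate: float = 1000.0,
    noise_sd: float = 0.0,
    rr_jitter_sd: float = 0.0,
    baseline_wander_amp: float = 0.0,
    ecg_anomalies: list[synthgen.AnomalySpec] | None = None,
    scg_anomalies: list[synthgen.AnomalySpec] | None = None,
    eta: int = 20,
    delta: float = 0.2,
    cc_source: str = "rules",
    nb_models: tuple | None = None,
    robust: bool = True,
) -> CaseResult:
    """Simulate a calibration stream plus an evaluation group and fuse.

    ``n_calibration`` clean beats precede the ``n_eval``-beat
    evaluation group; anomaly specs index cycles within the evaluation
    group (0-based).  With ``cc_source="nb"``, ``nb_models`` must hold
    fitted (ecg_model, scg_model).

    The SCG running stats default to robust mode here (flagged cycles
    are excluded from the state update): folding an outlier back in
    inflates the weighted SD so much that a sustained anomaly stops
    being flagged after its first beat, which defeats group-level
    monitoring of persistent abnormality.
    """
    n_total = n_calibration + n_eval
    tpl_ecg = synthgen.default_ecg_template()
    tpl_scg = synthgen.default_scg_template()
    ecg, scg, ecg_truth_ann, scg_truth_ann = synthgen.generate_paired(
        tpl_ecg, tpl_scg, n_cycles=n_total, heart_rate=heart_rate,
        sampling_rate=sampling_rate, rr_jitter_sd=rr_jitter_sd,
        noise_sd=noise_sd, baseline_wander_amp=baseline_wander_amp, seed=seed,
    )

    ecg_truth = np.zeros(n_total, dtype=int)
    scg_truth = np.zeros(n_total, dtype=int)
    for specs, tpl, which in ((ecg_anomalies, tpl_ecg, "ECG"), (scg_anomalies, tpl_scg, "SCG")):
        for spec in specs or []:
            shifted = synthgen.AnomalySpec(
                kind=spec.kind, cycles=[c + n_calibration for c in spec.cycles],
                label=spec.label, magnitude=spec.magnitude)
            if which == "ECG":
                ecg, ecg_truth_ann, t = synthgen.inject_abnormality(
                    ecg, ecg_truth_ann, shifted, template=tpl, seed=seed + 1)
                ecg_truth |= t
            else:
                scg, scg_truth_ann, t = synthgen.inject_abnormality(
                    scg, scg_truth_ann, shifted, template=tpl, seed=seed + 2)
                scg_truth |= t

    # --- ECG side: delineate and run the reference-value checks -------
    ecg_ann = delineate_ecg(ecg, ecg.cycle_index, ECGDelineationParams())
    measurements = em.measure_cycles(ecg_ann, ecg)
    measurements = measurements.reindex(range(n_total))
    ecg_checks = em.check_cycles(measurements)
    ecg_bits_all = ecg_checks["outcome"].to_numpy(dtype=int)

    # --- SCG side: train windows on the clean calibration truth, ------
    # delineate, calibrate the running stats, evaluate
    calib_truth = FiducialAnnotation(
        "SCG", scg_truth_ann.entries[scg_truth_ann.entries["cycle"] < n_calibration])
    params = SCGDelineationParams()
    params.window_table = estimate_windows([calib_truth], sampling_rate, params)
    scg_ann = delineate_scg_full(scg, [calib_truth], scg.cycle_index, params)
    fv = scg_monitor.compute_feature_variables(scg_ann, sampling_rate)
    fv = fv.reindex(range(n_total))
    scg_report = scg_monitor.monitor_scg(
        fv, eta=eta, cycle_seconds=1.0 / heart_rate, n_calibration=n_calibration,
        robust=robust)
    scg_bits_all = scg_report["outcome"].fillna(0).to_numpy(dtype=int)

    if cc_source == "nb":
        if nb_models is None:
            raise ValueError("cc_source='nb' requires fitted nb_models")
        nb_ecg, nb_scg = nb_models
        ecg_bits_all = fusion.classify_cycles(measurements[list(fusion.ECG_FEATURES)], nb_ecg)
        scg_bits_all = fusion.classify_cycles(fv[list(fusion.SCG_FEATURES)], nb_scg)
    elif cc_source != "rules":
        raise ValueError(f"unknown cc_source {cc_source!r}")

    sl = slice(n_calibration, n_total)
    ecg_bits = ecg_bits_all[sl]
    scg_bits = scg_bits_all[sl]
    joint = fusion.joint_outcome(ecg_bits, scg_bits)
    cai_e, _ = fusion.compute_cai(ecg_bits, delta)
    cai_s, _ = fusion.compute_cai(scg_bits, delta)
    cai_j, _ = fusion.compute_cai(joint, delta)
    return CaseResult(
        ecg_bits=ecg_bits, scg_bits=scg_bits, joint_bits=joint,
        cai_ecg=cai_e, cai_scg=cai_s, cai_joint=cai_j,
        ecg_truth=ecg_truth[sl], scg_truth=scg_truth[sl],
        ecg_checks=ecg_checks, scg_report=scg_report,
    )
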