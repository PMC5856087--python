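"""Per-modality Gaussian Naive Bayes classification, AND-fused joint
outcome, and the Cardiac Abnormality Index (CAI).

Each cardiac cycle is summarised by a per-modality feature vector
(seven ECG features: three wave amplitudes, three wave durations, the
RR interval; six SCG features: the fiducial-pair durations) and
classified *normal* (0) or *abnormal* (1) by a maximum-a-posteriori
rule over class-conditional Gaussians with class-frequency priors.
The factorised posterior is accumulated in log space; missing features
drop out of the product; exact ties resolve to normal.

A beat's joint outcome is the logical AND of the two per-modality
bits: a beat counts as abnormal only when the electrical and the
mechanical channel agree, which suppresses single-channel artifacts.
The CAI of a group of beats is the fraction with joint outcome 1; an
alert is raised when CAI exceeds a threshold delta (0.2 by default --
a deployment choice, in practice set with a cardiologist).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .signals import InvalidParameterError

ECG_FEATURES = ("amp_P", "amp_QRS", "amp_T", "dur_P", "dur_QRS", "dur_T", "dur_RR")
SCG_FEATURES = ("PI_MC_AO", "PI_AO_AC", "PI_MC_MO", "PI_AC_MO", "PI_RBE", "PI_RBF")

NORMAL, ABNORMAL = 0, 1
ABSTAIN = -1
VAR_FLOOR = 1e-6


class FitError(ValueError):
    pass


def feature_names(modality: str) -> tuple[str, ...]:
    return ECG_FEATURES if modality == "ECG" else SCG_FEATURES


@dataclass
class NaiveBayesModel:
    """Class priors and per-feature class-conditional Gaussians."""

    modality: str
    priors: dict[int, float] = field(default_factory=dict)
    means: dict[str, dict[int, float]] = field(default_factory=dict)
    variances: dict[str, dict[int, float]] = field(default_factory=dict)
    var_floor: float = VAR_FLOOR

    def to_yaml(self, path) -> None:
        data = {"modality": self.modality, "var_floor": self.var_floor,
                "priors": {int(k): float(v) for k, v in self.priors.items()},
                "means": {f: {int(k): float(v) for k, v in d.items()}
                          for f, d in self.means.items()},
                "variances": {f: {int(k): float(v) for k, v in d.items()}
                              for f, d in self.variances.items()}}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)

    @classmethod
    def from_yaml(cls, path) -> "NaiveBayesModel":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(d["modality"],
                   {int(k): v for k, v in d["priors"].items()},
                   {f: {int(k): v for k, v in m.items()} for f, m in d["means"].items()},
                   {f: {int(k): v for k, v in m.items()} for f, m in d["variances"].items()},
                   d["var_floor"])


def fit_nb(vectors: pd.DataFrame, labels: np.ndarray, modality: str,
           var_floor: float = VAR_FLOOR) -> NaiveBayesModel:
    """Fit priors and class-conditional Gaussians from labeled vectors.

    ``vectors`` holds one row per cycle with the modality's feature
    columns (NaN allowed); ``labels`` are 0/1.  Requires at least two
    examples per class.  Per-feature statistics use the rows where the
    feature is defined; variances are floored at ``var_floor``.
    """
    labels = np.asarray(labels, dtype=int)
    if len(labels) != len(vectors):
        raise FitError("labels and vectors length mismatch")
    names = feature_names(modality)
    model = NaiveBayesModel(modality, var_floor=var_floor)
    for cls_ in (NORMAL, ABNORMAL):
        n = int(np.sum(labels == cls_))
        if n < 2:
            raise FitError(f"need >= 2 examples of class {cls_}, got {n}")
        model.priors[cls_] = n / len(labels)
    for f in names:
        if f not in vectors.columns:
            raise FitError(f"feature column {f!r} missing")
        model.means[f], model.variances[f] = {}, {}
        for cls_ in (NORMAL, ABNORMAL):
            vals = vectors.loc[labels == cls_, f].dropna().to_numpy(dtype=float)
            if len(vals) < 2:
                raise FitError(f"feature {f!r} has < 2 defined values in class {cls_}")
            model.means[f][cls_] = float(vals.mean())
            model.variances[f][cls_] = max(float(vals.var(ddof=0)), var_floor)
    return model


def _log_gauss(x: float, mu: float, var: float) -> float:
    return -0.5 * (math.log(2 * math.pi * var) + (x - mu) ** 2 / var)


def classify(vector: pd.Series | dict, model: NaiveBayesModel) -> tuple[int, dict[int, float]]:
    """MAP class of one feature vector, with the log-posterior pair.

    Missing (NaN) features are omitted from the product; if every
    feature is missing the classifier abstains (ABSTAIN, treated as
    normal downstream).  A tie resolves to normal.
    """
    logp = {}
    n_used = 0
    for cls_ in (NORMAL, ABNORMAL):
        lp = math.log(model.priors[cls_])
        used = 0
        for f in feature_names(model.modality):
            x = vector.get(f, np.nan)
            if x is None or (isinstance(x, (float, np.floating)) and math.isnan(x)):
                continue
            lp += _log_gauss(float(x), model.means[f][cls_], model.variances[f][cls_])
            used += 1
        logp[cls_] = lp
        n_used = used
    if n_used == 0:
        return ABSTAIN, logp
    if logp[ABNORMAL] > logp[NORMAL]:
        return ABNORMAL, logp
    return NORMAL, logp


def classify_cycles(vectors: pd.DataFrame, model: NaiveBayesModel) -> np.ndarray:
    """Per-cycle 0/1 bits; abstentions map to 0 (normal)."""
    bits = np.zeros(len(vectors), dtype=int)
    for i, (_, row) in enumerate(vectors.iterrows()):
        label, _ = classify(row, model)
        bits[i] = 1 if label == ABNORMAL else 0
    return bits


def joint_outcome(cc_ecg, cc_scg):
    """Logical AND of the per-modality bits (scalar or arrays)."""
    a = np.asarray(cc_ecg, dtype=int)
    b = np.asarray(cc_scg, dtype=int)
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise InvalidParameterError("outcome bits must be 0 or 1")
    out = a & b
    return int(out) if out.ndim == 0 else out


def compute_cai(bits, delta: float = 0.2) -> tuple[float, bool]:
    """CAI = fraction of abnormal beats in a group; alert iff CAI > delta."""
    arr = np.asarray(bits, dtype=float)
    if arr.size == 0:
        raise InvalidParameterError("CAI of an empty group is undefined")
    cai = float(arr.mean())
    return cai, cai > delta


def cai_by_group(bits, k: int, delta: float = 0.2) -> pd.DataFrame:
    """Disjoint k-cycle group CAI table with alert flags."""
    arr = np.asarray(bits, dtype=int)
    rows = []
    for s in range(0, len(arr) - k + 1, k):
        cai, alert = compute_cai(arr[s:s + k], delta)
        rows.append({"start_cycle": s, "k": k, "cai": cai, "alert": alert})
    return pd.DataFrame(rows)
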