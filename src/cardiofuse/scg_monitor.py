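"""SCG feature-variable monitoring with weighted running statistics and
Chauvenet outlier flagging.

Six per-cycle feature-variables, each a duration in seconds between
two SCG fiducials:

=========  =========================================================
PI_MC_AO   mitral closure to aortic opening (isovolumic contraction)
PI_AO_AC   aortic opening to closing (left-ventricular ejection time)
PI_MC_MO   mitral closing to opening (systole)
PI_AC_MO   aortic closing to mitral opening (isovolumic relaxation)
PI_RBE     ventricular blood ejection, RE to AC
PI_RBF     diastolic blood filling, MO to RF
=========  =========================================================

The RBE/RBF endpoint pairs are configurable; RE->AC and MO->RF are the
defaults (the physiology literature does not pin them to specific SCG
fiducials).

For each variable a weighted moving average and SD are learned during
an eta-cycle estimation phase (weights 1..eta, so recent beats count
more), then updated recursively:

    WavgD_k = WavgD_{k-1} + (2 / (eta + 1)) * (D_k - WavgD_{k-1})
    S_k     = S_{k-1} + k * (D_k - WavgD_{k-1}) * (D_k - WavgD_k)
    WstdD_k = sqrt(S_k / (k - 1))

(S is Welford-style and can never go negative: the two deltas share a
sign because the mean moves a fraction < 1 of the way toward D.)

In the evaluation phase (k > eta) a cycle's variable is flagged as an
outlier by Chauvenet's criterion when its standardized deviation
``|D - WavgD| / WstdD`` exceeds ``|Phi^-1(1 / (4k))|``, the tolerance
that expects at most half an outlier among k Gaussian observations.
The cycle outcome bit is the OR of the per-variable flags.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .signals import FiducialAnnotation, InvalidParameterError

FEATURE_VARIABLES = ("PI_MC_AO", "PI_AO_AC", "PI_MC_MO", "PI_AC_MO", "PI_RBE", "PI_RBF")

_PAIRS = {
    "PI_MC_AO": ("MC", "AO"),
    "PI_AO_AC": ("AO", "AC"),
    "PI_MC_MO": ("MC", "MO"),
    "PI_AC_MO": ("AC", "MO"),
    "PI_RBE": ("RE", "AC"),
    "PI_RBF": ("MO", "RF"),
}

# Two cycle durations' worth of float slop when deciding D == WavgD
# under a zero SD (exact noiseless pipelines hit this path).
_ZERO_TOL = 1e-9


def compute_feature_variables(annotation: FiducialAnnotation, sampling_rate: float,
                              pairs: dict[str, tuple[str, str]] | None = None) -> pd.DataFrame:
    """Per-cycle feature-variable durations in seconds; NaN if a
    required fiducial is missing."""
    pairs = pairs or _PAIRS
    rows = []
    for c in annotation.cycles():
        row: dict[str, float] = {"cycle": c}
        for name, (a, b) in pairs.items():
            ea, eb = annotation.get(c, a), annotation.get(c, b)
            row[name] = np.nan if ea is None or eb is None else (eb[0] - ea[0]) / sampling_rate
        rows.append(row)
    return pd.DataFrame(rows).set_index("cycle")


def chauvenet_tolerance(k: int) -> float:
    """|Phi^-1(1/(4k))|, strictly increasing in k; requires k >= 2."""
    if k < 2:
        raise InvalidParameterError("chauvenet_tolerance requires k >= 2")
    return abs(float(norm.ppf(1.0 / (4.0 * k))))


@dataclass
class RunningStats:
    """Weighted running mean/SD state for one feature-variable."""

    eta: int = 20
    k: int = 0
    wavg: float = math.nan
    s: float = 0.0
    wstd: float = math.nan
    buffer: list[float] = field(default_factory=list)
    uniform_weights: bool = False  # degenerate mode: plain mean/SD at k = eta

    def __post_init__(self) -> None:
        if self.eta < 1:
            raise InvalidParameterError("eta must be >= 1")

    @property
    def in_estimation(self) -> bool:
        return self.k < self.eta

    def update(self, d: float) -> "RunningStats":
        """Fold one duration into the state (in place); returns self."""
        if not np.isfinite(d):
            warnings.warn(f"non-finite duration {d!r} rejected; state unchanged")
            return self
        self.k += 1
        if self.k < self.eta:
            self.buffer.append(d)
            self.wavg = d
        elif self.k == self.eta:
            self.buffer.append(d)
            w = np.ones(self.eta) if self.uniform_weights \
                else np.arange(1, self.eta + 1, dtype=float)
            x = np.asarray(self.buffer)
            self.wavg = float(np.sum(w * x) / np.sum(w))
            var_w = float(np.sum(w * (x - self.wavg) ** 2) / np.sum(w))
            self.s = var_w * max(self.k - 1, 1)
            self.wstd = math.sqrt(var_w)
        else:
            prev = self.wavg
            self.wavg = prev + (2.0 / (self.eta + 1)) * (d - prev)
            self.s += self.k * (d - prev) * (d - self.wavg)
            self.wstd = math.sqrt(max(self.s, 0.0) / (self.k - 1))
        return self

    def deviation(self, d: float) -> float:
        """Standardized deviation of d from the current state."""
        if self.wstd > 0:
            return abs(d - self.wavg) / self.wstd
        return 0.0 if abs(d - self.wavg) <= _ZERO_TOL else math.inf

    def to_dict(self) -> dict:
        return {"eta": self.eta, "k": self.k, "wavg": self.wavg, "s": self.s,
                "wstd": self.wstd, "buffer": list(self.buffer)}

    @classmethod
    def from_dict(cls, d: dict) -> "RunningStats":
        st = cls(eta=d["eta"])
        st.k, st.wavg, st.s, st.wstd = d["k"], d["wavg"], d["s"], d["wstd"]
        st.buffer = list(d["buffer"])
        return st


@dataclass
class SCGMonitor:
    """Streaming monitor over the six feature-variables.

    ``normalize`` divides each duration by the concurrent cycle length
    (seconds) before calibration/evaluation, making the reference
    subject- and heart-rate-relative.  ``robust`` excludes flagged
    cycles from the running-state update.  ``strict_band`` additionally
    flags any value outside WavgD +/- WstdD (off by default: it would
    mark ~32% of normal Gaussian cycles, against the design goal of at
    most 5% outliers).
    """

    eta: int = 20
    normalize: bool = True
    robust: bool = False
    strict_band: bool = False
    states: dict[str, RunningStats] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in FEATURE_VARIABLES:
            self.states.setdefault(name, RunningStats(eta=self.eta))

    def _norm(self, d: float, cycle_seconds: float | None) -> float:
        if self.normalize:
            if cycle_seconds is None or cycle_seconds <= 0:
                raise InvalidParameterError("normalize=True requires the cycle length")
            return d / cycle_seconds
        return d

    def calibrate_cycle(self, fv_row: pd.Series, cycle_seconds: float | None = None) -> None:
        """Fold one estimation-phase cycle into every variable's state."""
        for name in FEATURE_VARIABLES:
            d = fv_row.get(name, np.nan)
            if np.isfinite(d):
                self.states[name].update(self._norm(float(d), cycle_seconds))

    def evaluate_cycle(self, fv_row: pd.Series,
                       cycle_seconds: float | None = None) -> tuple[dict[str, bool], int]:
        """Flag one evaluation-phase cycle, then update the state.

        Returns (per-variable flags, outcome bit).  Variables still in
        their estimation phase, or undefined this cycle, are skipped.
        """
        flags: dict[str, bool] = {}
        for name in FEATURE_VARIABLES:
            st = self.states[name]
            d = fv_row.get(name, np.nan)
            if not np.isfinite(d):
                continue
            dn = self._norm(float(d), cycle_seconds)
            if st.k < st.eta:
                st.update(dn)
                continue
            k_next = st.k + 1
            dev = st.deviation(dn)
            tol = chauvenet_tolerance(k_next)
            flag = dev > tol
            if self.strict_band and st.wstd > 0:
                flag = flag or dev > 1.0
            flags[name] = bool(flag)
            if not (self.robust and flag):
                st.update(dn)
        outcome = int(any(flags.values()))
        return flags, outcome

    def to_yaml(self, path) -> None:
        data = {"eta": self.eta, "normalize": self.normalize, "robust": self.robust,
                "strict_band": self.strict_band,
                "states": {n: s.to_dict() for n, s in self.states.items()}}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)

    @classmethod
    def from_yaml(cls, path) -> "SCGMonitor":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        mon = cls(eta=data["eta"], normalize=data["normalize"], robust=data["robust"],
                  strict_band=data["strict_band"])
        mon.states = {n: RunningStats.from_dict(d) for n, d in data["states"].items()}
        return mon


def monitor_scg(fv: pd.DataFrame, eta: int = 20, normalize: bool = True,
                cycle_seconds: float | None = None,
                n_calibration: int | None = None,
                robust: bool = False) -> pd.DataFrame:
    """Run the monitor over a feature-variable table.

    The first ``n_calibration`` cycles (default ``eta``) are the
    estimation phase; every later cycle gets per-variable flags and an
    outcome bit.  Returns a DataFrame indexed like ``fv`` with
    ``flag_<variable>`` booleans and ``outcome`` (NaN during the
    estimation phase, else 0/1).
    """
    mon = SCGMonitor(eta=eta, normalize=normalize, robust=robust)
    n_calibration = eta if n_calibration is None else n_calibration
    rows = []
    for i, (c, row) in enumerate(fv.iterrows()):
        if i < n_calibration:
            mon.calibrate_cycle(row, cycle_seconds)
            rows.append({"cycle": c, "outcome": np.nan})
        else:
            flags, outcome = mon.evaluate_cycle(row, cycle_seconds)
            rec = {"cycle": c, "outcome": float(outcome)}
            rec.update({f"flag_{n}": v for n, v in flags.items()})
            rows.append(rec)
    return pd.DataFrame(rows).set_index("cycle")
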