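"""SCG feature-variables, weighted running statistics, Chauvenet
outlier flagging."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from cardiofuse.scg_monitor import (
    FEATURE_VARIABLES,
    RunningStats,
    SCGMonitor,
    chauvenet_tolerance,
    compute_feature_variables,
    monitor_scg,
)
from cardiofuse.signals import FiducialAnnotation, InvalidParameterError


def _ann_from_times(times_s: dict[str, float], cycle=0) -> FiducialAnnotation:
    return FiducialAnnotation.from_records(
        "SCG", [(cycle, l, int(round(t * 1000)), 0.0) for l, t in times_s.items()])


def test_feature_variables_from_printed_timestamps():
    """Fiducial times 0.48/0.54/0.61/0.73/0.76/0.83 s give the six
    pairwise durations by direct subtraction."""
    ann = _ann_from_times({"MC": 0.48, "AO": 0.54, "RE": 0.61,
                           "AC": 0.73, "MO": 0.76, "RF": 0.83})
    fv = compute_feature_variables(ann, 1000.0)
    assert fv.loc[0, "PI_MC_AO"] == pytest.approx(0.06)
    assert fv.loc[0, "PI_AO_AC"] == pytest.approx(0.19)
    assert fv.loc[0, "PI_MC_MO"] == pytest.approx(0.28)
    assert fv.loc[0, "PI_AC_MO"] == pytest.approx(0.03)
    assert fv.loc[0, "PI_RBE"] == pytest.approx(0.12)
    assert fv.loc[0, "PI_RBF"] == pytest.approx(0.07)


def test_identical_cycles_give_identical_variables():
    t = {"MC": 0.48, "AO": 0.54, "RE": 0.61, "AC": 0.73, "MO": 0.76, "RF": 0.83}
    a0 = _ann_from_times(t, 0).entries
    a1 = _ann_from_times({k: v + 1.0 for k, v in t.items()}, 1).entries
    fv = compute_feature_variables(
        FiducialAnnotation("SCG", pd.concat([a0, a1])), 1000.0)
    pd.testing.assert_series_equal(fv.loc[0], fv.loc[1], check_names=False)


def test_missing_mo_undefines_dependent_variables():
    ann = _ann_from_times({"MC": 0.48, "AO": 0.54, "RE": 0.61, "AC": 0.73, "RF": 0.83})
    fv = compute_feature_variables(ann, 1000.0)
    assert np.isnan(fv.loc[0, "PI_MC_MO"])
    assert np.isnan(fv.loc[0, "PI_AC_MO"])
    assert np.isnan(fv.loc[0, "PI_RBF"])
    assert fv.loc[0, "PI_MC_AO"] == pytest.approx(0.06)


@pytest.mark.parametrize("k, expected", [(20, 2.2414), (2, 1.1503)])
def test_chauvenet_tolerance_matches_normal_quantile(k, expected):
    assert chauvenet_tolerance(k) == pytest.approx(expected, abs=1e-4)
    assert chauvenet_tolerance(k) == pytest.approx(abs(norm.ppf(1 / (4 * k))), abs=1e-12)


def test_chauvenet_tolerance_monotone_and_guarded():
    assert chauvenet_tolerance(100) > chauvenet_tolerance(20)
    with pytest.raises(InvalidParameterError):
        chauvenet_tolerance(1)


def test_constant_stream_has_zero_spread():
    st_ = RunningStats(eta=20)
    for _ in range(30):
        st_.update(0.1)
    assert st_.wavg == pytest.approx(0.1)
    assert st_.wstd == pytest.approx(0.0, abs=1e-12)


def test_weighted_average_of_linear_buffer():
    """Buffer 10,20,...,200 ms with weights 1..20: the weighted mean is
    sum(j * 10j) / sum(j) = 136.666... ms."""
    st_ = RunningStats(eta=20)
    for j in range(1, 21):
        st_.update(0.010 * j)
    assert st_.wavg == pytest.approx(0.1366667, abs=1e-6)
    # independent two-pass weighted oracle
    w = np.arange(1, 21)
    x = 0.010 * np.arange(1, 21)
    assert st_.wavg == pytest.approx(np.sum(w * x) / np.sum(w))
    assert st_.wstd == pytest.approx(
        math.sqrt(np.sum(w * (x - np.sum(w * x) / np.sum(w)) ** 2) / np.sum(w)))


def test_recursive_update_follows_ewma_recurrence():
    rng = np.random.default_rng(3)
    data = rng.normal(0.1, 0.01, 60)
    st_ = RunningStats(eta=20)
    for d in data[:20]:
        st_.update(d)
    wavg, s = st_.wavg, st_.s
    k = 20
    for d in data[20:]:
        k += 1
        new = wavg + (2.0 / 21.0) * (d - wavg)
        s = s + k * (d - wavg) * (d - new)
        wavg = new
        st_.update(d)
        assert st_.wavg == pytest.approx(wavg, rel=1e-12)
        assert st_.wstd == pytest.approx(math.sqrt(s / (k - 1)), rel=1e-12)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(1e-3, 10.0), min_size=1, max_size=80),
       st.integers(2, 20))
def test_variance_accumulator_never_negative(values, eta):
    st_ = RunningStats(eta=eta)
    for v in values:
        st_.update(v)
        assert st_.s >= 0.0
        if not math.isnan(st_.wstd):
            assert st_.wstd >= 0.0


def test_uniform_weights_match_two_pass_mean_and_sd():
    """With the beat weights forced equal, the end-of-calibration
    statistics equal the ordinary two-pass mean and population SD."""
    rng = np.random.default_rng(1)
    data = rng.normal(0.2, 0.05, 50)
    st_ = RunningStats(eta=50, uniform_weights=True)
    for d in data:
        st_.update(d)
    assert st_.wavg == pytest.approx(float(np.mean(data)), rel=1e-9)
    assert st_.wstd == pytest.approx(float(np.std(data)), rel=1e-9)


def test_non_finite_duration_rejected_with_warning():
    st_ = RunningStats(eta=5)
    st_.update(0.1)
    with pytest.warns(UserWarning):
        st_.update(float("nan"))
    assert st_.k == 1


def test_deviation_at_mean_is_zero_and_outlier_flagged():
    rng = np.random.default_rng(7)
    mon = SCGMonitor(eta=20, normalize=False)
    fv = pd.DataFrame({n: rng.normal(0.100, 0.002, 20) for n in FEATURE_VARIABLES})
    for _, row in fv.iterrows():
        mon.calibrate_cycle(row)
    state = mon.states["PI_MC_AO"]
    assert state.deviation(state.wavg) == 0.0
    # a 120 ms beat against ~N(100, 2) ms calibration: dev ~ 10 >> tol ~ 2.25
    row = pd.Series({n: state.wavg for n in FEATURE_VARIABLES})
    row["PI_MC_AO"] = 0.120
    flags, outcome = mon.evaluate_cycle(row)
    assert flags["PI_MC_AO"] and outcome == 1
    assert not flags["PI_AO_AC"]


def test_zero_spread_state_flags_any_departure():
    mon = SCGMonitor(eta=3, normalize=False)
    for _ in range(3):
        mon.calibrate_cycle(pd.Series({n: 0.1 for n in FEATURE_VARIABLES}))
    flags, outcome = mon.evaluate_cycle(pd.Series({n: 0.1 for n in FEATURE_VARIABLES}))
    assert outcome == 0
    flags, outcome = mon.evaluate_cycle(pd.Series({n: 0.11 for n in FEATURE_VARIABLES}))
    assert outcome == 1


def test_long_run_flag_rate_below_five_percent():
    """Chauvenet on a stationary Gaussian stream: <= 5% flagged."""
    rng = np.random.default_rng(42)
    n = 10_000
    fv = pd.DataFrame({n_: rng.normal(0.100, 0.002, n) for n_ in FEATURE_VARIABLES})
    report = monitor_scg(fv, eta=20, normalize=False)
    rate = report["outcome"].fillna(0).mean()
    assert rate <= 0.05


def test_normalization_divides_by_cycle_length():
    mon = SCGMonitor(eta=2, normalize=True)
    row = pd.Series({n: 0.1 for n in FEATURE_VARIABLES})
    mon.calibrate_cycle(row, cycle_seconds=0.8)
    assert mon.states["PI_MC_AO"].wavg == pytest.approx(0.125)
    with pytest.raises(InvalidParameterError):
        mon.calibrate_cycle(row)  # cycle length required when normalizing


def test_state_yaml_round_trip(tmp_path):
    rng = np.random.default_rng(5)
    mon = SCGMonitor(eta=5, normalize=False)
    for _ in range(8):
        mon.calibrate_cycle(pd.Series({n: rng.normal(0.1, 0.01)
                                       for n in FEATURE_VARIABLES}))
    mon.to_yaml(tmp_path / "state.yaml")
    back = SCGMonitor.from_yaml(tmp_path / "state.yaml")
    for n in FEATURE_VARIABLES:
        assert back.states[n].wavg == pytest.approx(mon.states[n].wavg)
        assert back.states[n].k == mon.states[n].k
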