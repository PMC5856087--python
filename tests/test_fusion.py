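"""Naive Bayes classification, AND fusion, and the Cardiac Abnormality
Index."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardiofuse import synthgen
from cardiofuse.fusion import (
    ABNORMAL,
    ABSTAIN,
    ECG_FEATURES,
    NORMAL,
    SCG_FEATURES,
    FitError,
    NaiveBayesModel,
    cai_by_group,
    classify,
    classify_cycles,
    compute_cai,
    fit_nb,
    joint_outcome,
)
from cardiofuse.pipeline import run_paired_case
from cardiofuse.signals import InvalidParameterError


def _toy_model(mu0=0.0, mu1=2.0, var=1.0):
    m = NaiveBayesModel("SCG", priors={NORMAL: 0.5, ABNORMAL: 0.5})
    for f in SCG_FEATURES:
        m.means[f] = {NORMAL: mu0, ABNORMAL: mu1}
        m.variances[f] = {NORMAL: var, ABNORMAL: var}
    return m


def _rand_vectors(rng, n, features, mu, sd):
    return pd.DataFrame({f: rng.normal(mu, sd, n) for f in features})


def test_fit_recovers_class_statistics():
    rng = np.random.default_rng(0)
    v0 = _rand_vectors(rng, 400, ECG_FEATURES, 0.0, 1.0)
    v1 = _rand_vectors(rng, 400, ECG_FEATURES, 3.0, 1.0)
    vectors = pd.concat([v0, v1], ignore_index=True)
    labels = np.r_[np.zeros(400, int), np.ones(400, int)]
    model = fit_nb(vectors, labels, "ECG")
    assert model.priors[NORMAL] == pytest.approx(0.5)
    for f in ECG_FEATURES:
        assert model.means[f][NORMAL] == pytest.approx(0.0, abs=0.2)
        assert model.means[f][ABNORMAL] == pytest.approx(3.0, abs=0.2)
    # decision boundary between the class means on each feature
    mid = pd.Series({f: 1.5 for f in ECG_FEATURES})
    lo = pd.Series({f: 0.5 for f in ECG_FEATURES})
    hi = pd.Series({f: 2.5 for f in ECG_FEATURES})
    assert classify(lo, model)[0] == NORMAL
    assert classify(hi, model)[0] == ABNORMAL


def test_duplicating_training_data_leaves_model_unchanged():
    rng = np.random.default_rng(1)
    vectors = _rand_vectors(rng, 40, SCG_FEATURES, 0.1, 0.02)
    labels = np.r_[np.zeros(20, int), np.ones(20, int)]
    m1 = fit_nb(vectors, labels, "SCG")
    m2 = fit_nb(pd.concat([vectors, vectors], ignore_index=True),
                np.r_[labels, labels], "SCG")
    for f in SCG_FEATURES:
        assert m1.means[f] == pytest.approx(m2.means[f])
        assert m1.variances[f] == pytest.approx(m2.variances[f])


def test_fit_requires_both_classes():
    rng = np.random.default_rng(2)
    vectors = _rand_vectors(rng, 10, SCG_FEATURES, 0.1, 0.02)
    with pytest.raises(FitError):
        fit_nb(vectors, np.zeros(10, int), "SCG")


def test_tie_resolves_to_normal_and_mean_hits_abnormal():
    model = _toy_model()
    midpoint = pd.Series({f: 1.0 for f in SCG_FEATURES})
    assert classify(midpoint, model)[0] == NORMAL
    at_abnormal_mean = pd.Series({f: 2.0 for f in SCG_FEATURES})
    assert classify(at_abnormal_mean, model)[0] == ABNORMAL


def test_all_features_missing_abstains_and_maps_to_normal_bit():
    model = _toy_model()
    empty = pd.Series({f: np.nan for f in SCG_FEATURES})
    assert classify(empty, model)[0] == ABSTAIN
    bits = classify_cycles(pd.DataFrame([empty]), model)
    assert bits.tolist() == [0]


def test_missing_features_drop_out_of_the_product():
    model = _toy_model()
    v = pd.Series({f: np.nan for f in SCG_FEATURES})
    v[SCG_FEATURES[0]] = 2.0
    label, logp = classify(v, model)
    assert label == ABNORMAL
    # exactly one feature contributes: posterior gap is that feature's
    expected_gap = (-0.5 * (2.0 - 2.0) ** 2) - (-0.5 * (2.0 - 0.0) ** 2)
    assert logp[ABNORMAL] - logp[NORMAL] == pytest.approx(expected_gap)


def test_classification_invariant_to_feature_order():
    model = _toy_model()
    rng = np.random.default_rng(3)
    for _ in range(50):
        vals = rng.normal(1.0, 1.5, len(SCG_FEATURES))
        v = dict(zip(SCG_FEATURES, vals))
        v_rev = dict(zip(reversed(SCG_FEATURES), reversed(vals)))
        assert classify(v, model)[0] == classify(v_rev, model)[0]


def test_log_space_agrees_with_density_product_oracle():
    """1000 random vectors: the log-space MAP decision equals the
    brute-force product of Gaussian densities."""
    rng = np.random.default_rng(4)
    model = _toy_model(mu0=0.1, mu1=0.13, var=0.0004)
    for _ in range(1000):
        v = {f: rng.normal(0.115, 0.03) for f in SCG_FEATURES}
        post = {}
        for cls_ in (NORMAL, ABNORMAL):
            p = model.priors[cls_]
            for f in SCG_FEATURES:
                mu = model.means[f][cls_]
                var = model.variances[f][cls_]
                p *= math.exp(-0.5 * (v[f] - mu) ** 2 / var) / math.sqrt(2 * math.pi * var)
            post[cls_] = p
        oracle = ABNORMAL if post[ABNORMAL] > post[NORMAL] else NORMAL
        assert classify(v, model)[0] == oracle


def test_sklearn_gaussian_nb_cross_check():
    """Our fit+classify agrees with scikit-learn's GaussianNB on
    complete-feature data."""
    from sklearn.naive_bayes import GaussianNB

    rng = np.random.default_rng(5)
    n = 300
    v0 = _rand_vectors(rng, n, ECG_FEATURES, 0.0, 1.0)
    v1 = _rand_vectors(rng, n, ECG_FEATURES, 1.0, 1.0)
    X = pd.concat([v0, v1], ignore_index=True)
    y = np.r_[np.zeros(n, int), np.ones(n, int)]
    ours = fit_nb(X, y, "ECG")
    ref = GaussianNB(var_smoothing=0.0).fit(X.to_numpy(), y)
    Xt = _rand_vectors(rng, 200, ECG_FEATURES, 0.5, 1.0)
    ref_pred = ref.predict(Xt.to_numpy())
    our_pred = classify_cycles(Xt, ours)
    assert (our_pred == ref_pred).mean() >= 0.99


def test_synthetic_corpus_heldout_accuracy_above_0p9():
    """NB trained on injection-truth-labeled cycles separates held-out
    normal from R-amplitude-abnormal beats."""
    rng = np.random.default_rng(6)

    def corpus(n, seed):
        ecg, _, truth_ann, _ = synthgen.generate_paired(
            n_cycles=n, noise_sd=0.01, rr_jitter_sd=0.01,
            baseline_wander_amp=0.02, seed=seed)
        tpl = synthgen.default_ecg_template()
        abnormal = sorted(rng.choice(n, size=n // 2, replace=False).tolist())
        ecg, truth_ann, truth = synthgen.inject_abnormality(
            ecg, truth_ann, synthgen.AnomalySpec("amplitude_scale", abnormal, "R", 1.35),
            tpl, seed=seed)
        from cardiofuse.ecg_delineate import delineate_ecg
        from cardiofuse.ecg_monitor import measure_cycles
        ann = delineate_ecg(ecg, ecg.cycle_index)
        m = measure_cycles(ann, ecg).reindex(range(n))
        return m[list(ECG_FEATURES)], truth

    X_train, y_train = corpus(200, seed=10)
    X_test, y_test = corpus(200, seed=11)
    model = fit_nb(X_train, y_train, "ECG")
    pred = classify_cycles(X_test, model)
    assert (pred == y_test).mean() > 0.9


def test_joint_outcome_truth_table():
    assert joint_outcome(0, 0) == 0
    assert joint_outcome(0, 1) == 0
    assert joint_outcome(1, 0) == 0
    assert joint_outcome(1, 1) == 1
    with pytest.raises(InvalidParameterError):
        joint_outcome(2, 0)


@pytest.mark.parametrize(
    "bits, expected",
    [([1, 1, 1, 1, 1], 1.0), ([0, 1, 0, 1, 0], 0.4),
     ([0] * 9 + [1], 0.1), ([0, 0, 0, 0, 0], 0.0)],
)
def test_cai_is_fraction_of_abnormal_beats(bits, expected):
    cai, alert = compute_cai(bits, delta=0.2)
    assert cai == pytest.approx(expected)
    assert alert == (expected > 0.2)


def test_cai_empty_group_invalid():
    with pytest.raises(InvalidParameterError):
        compute_cai([])


def test_cai_by_group_disjoint():
    table = cai_by_group([0, 1, 0, 1, 0, 1, 1, 1, 1, 1], k=5, delta=0.2)
    assert table["cai"].tolist() == [0.4, 1.0]
    assert table["alert"].tolist() == [True, True]


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=1, max_size=50))
def test_joint_cai_never_exceeds_single_modality_cai(pairs):
    e = [a for a, _ in pairs]
    s = [b for _, b in pairs]
    j = joint_outcome(e, s)
    cai_j, _ = compute_cai(j)
    assert cai_j <= min(compute_cai(e)[0], compute_cai(s)[0])


def test_joint_false_positive_rate_below_single_modality():
    """Independent per-modality false positives: AND fusion never has a
    higher false-alarm rate than either channel, across seeds."""
    worse = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        e = (rng.random(200) < 0.1).astype(int)
        s = (rng.random(200) < 0.1).astype(int)
        j = joint_outcome(e, s)
        assert j.mean() <= min(e.mean(), s.mean())
        worse += int(j.mean() == min(e.mean(), s.mean()) and e.mean() > 0)
    assert worse < 20  # fusion strictly helps in at least one seed


def test_nb_wiring_through_pipeline():
    """The end-to-end pipeline accepts NB models as the bit source."""
    rng = np.random.default_rng(8)
    e0 = _rand_vectors(rng, 30, ECG_FEATURES, 0.0, 0.1)
    e1 = _rand_vectors(rng, 30, ECG_FEATURES, 5.0, 0.1)
    s0 = _rand_vectors(rng, 30, SCG_FEATURES, 0.0, 0.1)
    s1 = _rand_vectors(rng, 30, SCG_FEATURES, 5.0, 0.1)
    labels = np.r_[np.zeros(30, int), np.ones(30, int)]
    nb_e = fit_nb(pd.concat([e0, e1], ignore_index=True), labels, "ECG")
    nb_s = fit_nb(pd.concat([s0, s1], ignore_index=True), labels, "SCG")
    case = run_paired_case(n_eval=5, seed=1, cc_source="nb", nb_models=(nb_e, nb_s))
    assert case.cai_joint in [i / 5 for i in range(6)]


def test_model_yaml_round_trip(tmp_path):
    model = _toy_model(0.1, 0.2, 0.01)
    model.to_yaml(tmp_path / "nb.yaml")
    back = NaiveBayesModel.from_yaml(tmp_path / "nb.yaml")
    assert back.priors == model.priors
    assert back.means == model.means
    assert back.variances == model.variances
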