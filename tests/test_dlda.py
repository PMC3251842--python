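"""DLDA classifier: hand-checked arithmetic, the identity-line/tie rule,
invariances, LOOCV behaviour, and exact agreement with a brute-force
diagonal-Gaussian log-density oracle."""

import math

import numpy as np
import pandas as pd
import pytest

from mirsig import (
    DLDAClassifier,
    DeltaCtMatrix,
    ValidationError,
    fit_dlda,
    impute_undetected,
    loocv,
    normalize_delta_ct,
    predict_batch,
    score_sample,
    simulate_card_experiment,
)
from mirsig.simulate import SimulationConfig


def brute_force_call(X_train, y_train, x, variance_floor=1e-8):
    """Independent oracle: full diagonal-Gaussian log-densities per class with
    pooled variances, computed with plain Python loops."""
    classes = sorted(set(y_train))
    means = {}
    n = len(y_train)
    p = len(x)
    for c in classes:
        rows = [X_train[i] for i in range(n) if y_train[i] == c]
        means[c] = [sum(r[j] for r in rows) / len(rows) for j in range(p)]
    pooled = []
    for j in range(p):
        ss = 0.0
        for c in classes:
            rows = [X_train[i] for i in range(n) if y_train[i] == c]
            ss += sum((r[j] - means[c][j]) ** 2 for r in rows)
        pooled.append(max(ss / (n - 2), variance_floor))
    loglik = {}
    for c in classes:
        total = 0.0
        for j in range(p):
            total += -0.5 * math.log(2 * math.pi * pooled[j])
            total += -0.5 * (x[j] - means[c][j]) ** 2 / pooled[j]
        loglik[c] = total
    # identity-line rule with tie -> first (resistant-analogue) class
    return classes[1] if loglik[classes[1]] > loglik[classes[0]] else classes[0]


def _fit(X, y, **kw):
    return DLDAClassifier(**kw).fit(np.asarray(X, float), np.asarray(y))


def test_fit_pooled_variance_hand_example():
    """resistant (0, 2), sensitive (4, 6): μ_R=1, μ_S=5, σ² = 4/2 = 2."""
    clf = _fit([[0.0], [2.0], [4.0], [6.0]],
               ["resistant", "resistant", "sensitive", "sensitive"])
    assert clf.class_means_[0, 0] == 1.0
    assert clf.class_means_[1, 0] == 5.0
    assert clf.pooled_variances_[0] == 2.0
    assert not clf.variance_floored_[0]


def test_degenerate_variance_hits_floor():
    clf = _fit([[0.0], [0.0], [2.0], [2.0]],
               ["resistant", "resistant", "sensitive", "sensitive"])
    assert clf.pooled_variances_[0] == clf.variance_floor
    assert clf.variance_floored_[0]


def test_score_pair_hand_example():
    """μ_R=(0,0), μ_S=(2,2), σ²=(1,4), x=(1,2) → scores (−1.0, −0.5)."""
    clf = DLDAClassifier()
    clf.fit(np.array([[0.0, 0.0], [0.0, 0.0], [2.0, 2.0], [2.0, 2.0]]),
            np.array(["resistant", "resistant", "sensitive", "sensitive"]))
    clf.class_means_ = np.array([[0.0, 0.0], [2.0, 2.0]])
    clf.variances_ = np.array([[1.0, 4.0], [1.0, 4.0]])
    pair = clf.score_pair([1.0, 2.0])
    assert pair.score_resistant == pytest.approx(-1.0)
    assert pair.score_sensitive == pytest.approx(-0.5)
    assert pair.call == "sensitive"
    assert pair.margin == pytest.approx(0.5)


def test_class_mean_scores_and_tie_rule():
    clf = _fit([[0.0, 1.0], [0.4, 1.2], [3.0, 4.0], [3.4, 4.2]],
               ["resistant", "resistant", "sensitive", "sensitive"])
    at_sensitive_mean = clf.score_pair(clf.class_means_[1])
    assert at_sensitive_mean.call == "sensitive"
    assert at_sensitive_mean.score_sensitive == pytest.approx(0.0, abs=1e-12)
    midpoint = clf.class_means_.mean(axis=0)
    tie = clf.score_pair(midpoint)
    assert tie.margin == pytest.approx(0.0, abs=1e-9)
    assert tie.call == "resistant"  # borderline calls are conservative


def test_margin_increases_moving_from_resistant_to_sensitive_mean():
    clf = _fit([[0.0, 0.0], [0.5, 0.2], [2.0, 3.0], [2.5, 3.2]],
               ["resistant", "resistant", "sensitive", "sensitive"])
    ts = np.linspace(0, 1, 9)
    points = np.array([clf.class_means_[0] * (1 - t) + clf.class_means_[1] * t for t in ts])
    margins = clf.decision_function(points)
    assert np.all(np.diff(margins) > 0)


def test_calls_invariant_to_per_probe_shift_and_global_scale():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(10, 4))
    y = np.array(["resistant"] * 5 + ["sensitive"] * 5)
    X[5:] += 1.3
    T = rng.normal(size=(20, 4))
    base = _fit(X, y).predict(T)
    shift = rng.normal(size=4)
    shifted = _fit(X + shift, y).predict(T + shift)
    np.testing.assert_array_equal(base, shifted)
    scaled = _fit(X * 3.7, y).predict(T * 3.7)
    np.testing.assert_array_equal(base, scaled)


def test_validation_errors():
    with pytest.raises(ValidationError, match="fewer than 2"):
        _fit([[0.0], [1.0], [2.0]], ["resistant", "sensitive", "sensitive"])
    clf = _fit([[0.0, 0.0], [1.0, 1.0], [4.0, 4.0], [5.0, 5.0]],
               ["resistant", "resistant", "sensitive", "sensitive"])
    with pytest.raises(ValidationError, match="length 2"):
        score_sample(clf, [1.0, 2.0, 3.0])
    delta = DeltaCtMatrix(
        values=pd.DataFrame({"s1": [1.0]}, index=["p1"]), normalization_mode="per_sample"
    )
    with pytest.raises(ValidationError, match="absent"):
        delta.restrict(["p1", "missing-probe"])


def test_predict_batch_resubstitution_and_empty(default_dataset, default_delta):
    labels = default_dataset.training_labels()
    model = fit_dlda(default_delta, labels, default_dataset.planted)
    table = predict_batch(
        model,
        DeltaCtMatrix(
            values=default_delta.values[default_dataset.training_samples],
            normalization_mode=default_delta.normalization_mode,
        ),
        actual=labels,
    )
    assert (table["call"] == table["actual"]).all()
    empty = predict_batch(
        model,
        DeltaCtMatrix(
            values=default_delta.values.iloc[:, :0], normalization_mode="per_sample"
        ),
    )
    assert empty.empty


def test_calls_match_brute_force_oracle_on_random_instances():
    """Random small instances (2–5 probes, 2–6 samples per class): the
    vectorized classifier and the loop-based log-density oracle must agree on
    every call."""
    rng = np.random.default_rng(2024)
    for _ in range(300):
        p = rng.integers(2, 6)
        n_r = rng.integers(2, 7)
        n_s = rng.integers(2, 7)
        X = rng.normal(scale=rng.uniform(0.3, 3.0), size=(n_r + n_s, p))
        X[n_r:] += rng.normal(scale=2.0, size=p)
        y = np.array(["resistant"] * n_r + ["sensitive"] * n_s)
        clf = _fit(X, y)
        x = rng.normal(scale=2.0, size=p)
        assert clf.score_pair(x).call == brute_force_call(X.tolist(), y.tolist(), x.tolist())


def test_loocv_perfect_on_separable_planted_data(default_dataset, default_delta):
    cv = loocv(default_delta, default_dataset.training_labels(), default_dataset.planted)
    assert cv.accuracy == 1.0
    assert len(cv.per_sample) == 8


def test_loocv_discordant_sample_is_the_single_failure():
    ds = simulate_card_experiment(SimulationConfig(seed=8, discordant_sample=True))
    delta = normalize_delta_ct(impute_undetected(ds.ct))
    cv = loocv(delta, ds.training_labels(), ds.planted)
    ann = ds.annotations
    discordant = ann[(ann["label"] == "resistant") & (ann["true_profile"] == "sensitive")].index[0]
    assert cv.misclassified == [discordant]
    assert cv.accuracy == pytest.approx(7 / 8)


def test_loocv_chance_level_under_label_permutation(default_dataset, default_delta):
    """Permuting the 4v4 class labels destroys the planted signal; held-out
    accuracy over many permutations sits at chance (LOOCV's slight
    anti-learning bias under pure noise keeps it at or below 0.5)."""
    rng = np.random.default_rng(17)
    samples = default_dataset.training_samples
    accs = []
    for _ in range(200):
        perm = rng.permutation(["sensitive"] * 4 + ["resistant"] * 4)
        labels = pd.Series(perm, index=samples)
        accs.append(loocv(default_delta, labels, default_dataset.planted).accuracy)
    assert 0.3 < float(np.mean(accs)) < 0.65


def test_loocv_requires_three_per_class(default_delta):
    labels = pd.Series(
        {"sens-cl-1": "sensitive", "sens-cl-2": "sensitive",
         "res-cl-1": "resistant", "res-cl-2": "resistant", "res-cl-3": "resistant"}
    )
    with pytest.raises(ValidationError, match=">=3"):
        loocv(default_delta, labels, ["hsa-mir-s0001", "hsa-mir-s0002"])
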