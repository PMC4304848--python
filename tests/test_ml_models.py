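import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from quadpot.features import FEATURE_COLUMNS, encode_dataset
from quadpot.ml_models import (ClassifierSpec, compute_metrics,
                               cross_validate, learning_curve,
                               permutation_significance, rank_auc,
                               train_classifier)
from quadpot.mutagenesis import Variant
from quadpot.synthetic_data import generate_variant_dataset


@pytest.fixture(scope="module")
def labeled_table(structure, tess, trained_potential):
    """120 variants labeled by the noiseless residual-score threshold rule."""
    ds = generate_variant_dataset(structure, tess, trained_potential,
                                  n_variants=120, eps=0.0, seed=3)
    variants = [Variant(position=int(r.position), native=r.native,
                        replacement=r.replacement)
                for r in ds.itertuples()]
    return encode_dataset(variants, structure, tess, trained_potential,
                          labels=dict(zip(variants, ds["activity"])))


def test_metrics_perfect_predictions():
    y = ["U"] * 5 + ["A"] * 5
    m = compute_metrics(y, y, [1.0] * 5 + [0.0] * 5)
    assert (m.sensitivity, m.specificity, m.ppv) == (1.0, 1.0, 1.0)
    assert (m.bar, m.mcc, m.auc) == (1.0, 1.0, 1.0)


def test_metrics_hand_computed_confusion():
    # TP=8 FN=2 TN=7 FP=3
    y = ["U"] * 10 + ["A"] * 10
    yhat = ["U"] * 8 + ["A"] * 2 + ["U"] * 3 + ["A"] * 7
    m = compute_metrics(y, yhat)
    assert m.sensitivity == pytest.approx(0.800)
    assert m.specificity == pytest.approx(0.700)
    assert m.ppv == pytest.approx(0.727, abs=5e-4)
    assert m.bar == pytest.approx(0.750)
    assert m.mcc == pytest.approx(0.503, abs=5e-4)


def test_rank_auc_null_is_half():
    rng = np.random.default_rng(0)
    n = 10_000
    y = np.where(rng.random(n) < 0.5, "U", "A")
    scores = rng.random(n)
    assert rank_auc(y, scores) == pytest.approx(0.5, abs=0.02)


def test_rank_auc_equals_trapezoidal_roc():
    rng = np.random.default_rng(1)
    y = np.where(rng.random(300) < 0.4, "U", "A")
    scores = rng.normal(size=300) + (y == "U")  # tie-free
    assert rank_auc(y, scores) == pytest.approx(
        roc_auc_score(y == "U", scores), abs=1e-12)


def test_mcc_bar_bounds_random_confusions():
    rng = np.random.default_rng(2)
    for _ in range(50):
        n = int(rng.integers(4, 50))
        y = rng.choice(["U", "A"], n)
        yhat = rng.choice(["U", "A"], n)
        m = compute_metrics(y, yhat)
        assert -1.0 <= m.mcc <= 1.0
        assert 0.0 <= m.bar <= 1.0


def test_training_set_mcc_one_on_separable_data(labeled_table):
    model = train_classifier(labeled_table, ClassifierSpec("RF", seed=0))
    yhat = model.predict(labeled_table[list(FEATURE_COLUMNS)])
    m = compute_metrics(labeled_table["activity"], yhat)
    assert m.mcc == 1.0


def test_single_class_training_rejected(labeled_table):
    df = labeled_table.copy()
    df["activity"] = "U"
    with pytest.raises(ValueError, match="single class"):
        train_classifier(df, ClassifierSpec("RF"))


def test_same_seed_identical_predictions(labeled_table):
    X = labeled_table[list(FEATURE_COLUMNS)]
    m1 = train_classifier(labeled_table, ClassifierSpec("RF", seed=5))
    m2 = train_classifier(labeled_table, ClassifierSpec("RF", seed=5))
    np.testing.assert_array_equal(m1.predict(X), m2.predict(X))


def test_loocv_is_deterministic(labeled_table):
    spec = ClassifierSpec("DT", seed=1)
    r1 = cross_validate(labeled_table, spec, scheme="loocv")
    r2 = cross_validate(labeled_table, spec, scheme="loocv")
    assert r1.metrics == r2.metrics


def test_loocv_makes_one_prediction_per_instance(labeled_table):
    sub = labeled_table.iloc[:20].reset_index(drop=True)
    if len(set(sub["activity"])) < 2:
        sub = labeled_table.iloc[:30].reset_index(drop=True)
    res = cross_validate(sub, ClassifierSpec("DT", seed=0), scheme="loocv")
    assert len(res.predictions) == len(sub)
    counts = res.metrics
    assert counts.tp + counts.tn + counts.fp + counts.fn == len(sub)


def test_noiseless_rule_is_recoverable(labeled_table):
    res = cross_validate(labeled_table, ClassifierSpec("RF", seed=0),
                         scheme="10fold", n_repeats=2)
    assert res.metrics.bar >= 0.9
    assert len(res.per_repeat) == 2
    assert len(res.seeds) == 2


@pytest.mark.parametrize("algorithm", ["SVM", "NN"])
def test_other_algorithms_learn_the_rule(labeled_table, algorithm):
    spec = ClassifierSpec(algorithm, seed=0,
                          params={"epochs": 300} if algorithm == "NN" else {})
    res = cross_validate(labeled_table, spec, scheme="10fold", n_repeats=1)
    assert res.metrics.bar >= 0.8


def test_permutation_null_centered_at_half(labeled_table):
    spec = ClassifierSpec("DT", seed=0, params={"n_estimators": 5})
    res = permutation_significance(labeled_table, spec, n_permutations=30,
                                   seed=0, scheme="10fold")
    assert abs(res.null_bar.mean() - 0.5) < 0.06
    assert abs(res.null_mcc.mean()) < 0.1
    assert res.p_bar < 0.2  # observed model is far better than the null


def test_permutation_fixed_seed_reproducible(labeled_table):
    spec = ClassifierSpec("DT", seed=0, params={"n_estimators": 3})
    a = permutation_significance(labeled_table, spec, 5, seed=9)
    b = permutation_significance(labeled_table, spec, 5, seed=9)
    np.testing.assert_array_equal(a.null_bar, b.null_bar)


def test_permutation_requires_at_least_one(labeled_table):
    with pytest.raises(ValueError):
        permutation_significance(labeled_table, ClassifierSpec("DT"), 0)


def test_learning_curve_full_size_reduces_to_repeated_cv(labeled_table):
    spec = ClassifierSpec("DT", seed=0, params={"n_estimators": 3})
    curve = learning_curve(labeled_table, spec, sizes=[60, len(labeled_table)],
                           samples_per_size=3, seed=0)
    assert set(curve["size"]) == {60, len(labeled_table)}
    assert set(curve["metric"]) == {"bar", "mcc", "auc"}
    big = curve[(curve["size"] == len(labeled_table))
                & (curve["metric"] == "bar")]["mean"].iloc[0]
    small = curve[(curve["size"] == 60)
                  & (curve["metric"] == "bar")]["mean"].iloc[0]
    # learnable signal: performance does not collapse when data grows
    assert big >= small - 0.1


def test_label_noise_degrades_recovery(structure, tess, trained_potential):
    specs = {}
    for eps in (0.0, 0.4):
        ds = generate_variant_dataset(structure, tess, trained_potential,
                                      n_variants=100, eps=eps, seed=13)
        variants = [Variant(position=int(r.position), native=r.native,
                            replacement=r.replacement)
                    for r in ds.itertuples()]
        table = encode_dataset(variants, structure, tess, trained_potential,
                               labels=dict(zip(variants, ds["activity"])))
        res = cross_validate(table, ClassifierSpec("DT", seed=0,
                                                   params={"n_estimators": 5}),
                             scheme="10fold", n_repeats=1)
        specs[eps] = res.metrics.mcc
    assert specs[0.0] > specs[0.4] + 0.1
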