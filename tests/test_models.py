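"""Cross-validation machinery, metrics, combined classifier, controls."""

import numpy as np
import pandas as pd
import pytest

from tessmut.features import VariantDataset, assemble_dataset
from tessmut.models import (CLASSES, LearnerSpec, ModelError,
                            combined_classifier, compute_metrics,
                            crossvalidate, learning_curve, permutation_control,
                            prediction_array, rank_auc, stratified_performance)


def toy_dataset(n=120, seed=0, separable=True, task="classification"):
    """Two informative numeric features; optionally linearly separable."""
    rng = np.random.default_rng(seed)
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    margin = x1  # axis-aligned boundary: separable for every learner family
    if separable:
        y = np.where(margin > 0, "affected", "unaffected")
    else:
        y = rng.choice(CLASSES, size=n)
    frame = pd.DataFrame({
        "variant": [f"A{i + 1}G" for i in range(n)],
        "f1": x1, "f2": x2,
        "log2_effect": np.where(margin > 0, -3.0, 0.0) + rng.normal(0, 0.1, n),
        "activity_class": y,
    })
    return VariantDataset(frame=frame, mode="monomer-27", task=task)


def test_metric_formulas_against_direct_confusion():
    y_true = ["affected"] * 60 + ["unaffected"] * 60
    y_pred = (["affected"] * 50 + ["unaffected"] * 10
              + ["affected"] * 20 + ["unaffected"] * 40)
    m = compute_metrics(y_true, y_pred)
    assert (m["TP"], m["FN"], m["FP"], m["TN"]) == (50, 10, 20, 40)
    assert m["Se"] == pytest.approx(50 / 60)
    assert m["Sp"] == pytest.approx(40 / 60)
    assert m["PPV"] == pytest.approx(50 / 70)
    assert m["BAR"] == pytest.approx(0.5 * (50 / 60 + 40 / 60))
    # independent direct-formula MCC
    mcc = (50 * 40 - 20 * 10) / np.sqrt((50 + 20) * (50 + 10) * (40 + 20) * (40 + 10))
    assert m["MCC"] == pytest.approx(mcc)


def test_bar_from_se_sp():
    y_true = ["affected"] * 10 + ["unaffected"] * 10
    y_pred = ["affected"] * 9 + ["unaffected"] + ["affected"] * 2 + ["unaffected"] * 8
    m = compute_metrics(y_true, y_pred)
    assert m["BAR"] == pytest.approx(0.5 * (m["Se"] + m["Sp"]))


def test_perfect_predictions_give_unit_mcc_and_auc():
    y = ["affected"] * 5 + ["unaffected"] * 5
    proba = [0.9] * 5 + [0.1] * 5
    m = compute_metrics(y, y, proba)
    assert m["MCC"] == pytest.approx(1.0)
    assert m["AUC"] == pytest.approx(1.0)


def test_single_class_truth_gives_undefined_mcc_auc():
    m = compute_metrics(["affected"] * 4, ["affected"] * 4, [0.9] * 4)
    assert np.isnan(m["MCC"]) and np.isnan(m["AUC"])


@pytest.mark.parametrize("seed", [0, 1])
def test_rank_auc_matches_sklearn(seed):
    from sklearn.metrics import roc_auc_score
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=50).astype(bool)
    scores = np.round(rng.uniform(size=50), 2)  # induce ties
    if y.all() or not y.any():
        y[0] = ~y[0]
    assert rank_auc(y, scores) == pytest.approx(roc_auc_score(y, scores))


def test_loocv_has_one_fold_per_row():
    ds = toy_dataset(n=30)
    res = crossvalidate(ds, LearnerSpec("dt", seed=0), scheme="loo", seed=0)
    assert len(res.y_pred) == 30
    assert set(res.y_pred) <= set(CLASSES)


def test_stratified_kfold_contract():
    ds = toy_dataset(n=100, seed=3)
    y = ds.frame.activity_class.to_numpy()
    from tessmut.models import _folds
    folds = _folds(y, "k10", seed=1, task="classification")
    assert len(folds) == 10
    all_test = np.concatenate([t for _, t in folds])
    assert sorted(all_test) == list(range(100))
    n_aff = (y == "affected").sum()
    for _, test_idx in folds:
        frac = (y[test_idx] == "affected").sum()
        assert abs(frac - n_aff / 10) <= 1


@pytest.mark.parametrize("algo", ["rf", "svm", "dt", "nn"])
def test_separable_dataset_classified_well(algo):
    ds = toy_dataset(n=120, seed=4)
    res = crossvalidate(ds, LearnerSpec(algo, seed=0), scheme="k10", seed=0)
    assert res.metrics["BAR"] > 0.95


def test_determinism_same_seed_same_output():
    ds = toy_dataset(n=80, seed=5)
    a = crossvalidate(ds, LearnerSpec("rf", seed=2), scheme="k10", seed=2)
    b = crossvalidate(ds, LearnerSpec("rf", seed=2), scheme="k10", seed=2)
    assert np.array_equal(a.y_pred, b.y_pred)
    assert a.metrics == b.metrics
    assert np.allclose(a.proba.to_numpy(), b.proba.to_numpy())


def test_regression_threshold_consistency():
    ds = toy_dataset(n=100, seed=6, task="regression")
    res = crossvalidate(ds, LearnerSpec("reptree", seed=0), scheme="k10", seed=0)
    assert "r" in res.metrics and res.metrics["r"] > 0.5
    # thresholding predictions then computing BAR equals the reported BAR
    cls_true = np.where(res.y_true < -2.0, "affected", "unaffected")
    cls_pred = np.where(res.y_pred.astype(float) < -2.0, "affected", "unaffected")
    m = compute_metrics(cls_true, cls_pred)
    assert m["BAR"] == pytest.approx(res.metrics["BAR"])


def test_svr_runs_and_reports_r():
    ds = toy_dataset(n=80, seed=7, task="regression")
    res = crossvalidate(ds, LearnerSpec("svr", seed=0), scheme="k10", seed=0)
    assert np.isfinite(res.metrics["r"])


def test_combined_classifier_averages_probabilities():
    p1 = pd.DataFrame({"affected": [0.9, 0.2], "unaffected": [0.1, 0.8]})
    p2 = pd.DataFrame({"affected": [0.7, 0.4], "unaffected": [0.3, 0.6]})
    out = combined_classifier([p1, p2])
    assert np.allclose(out["proba"]["affected"], [0.8, 0.3])
    assert list(out["predictions"]) == ["affected", "unaffected"]
    # idempotence on identical inputs
    same = combined_classifier([p1, p1])
    assert np.allclose(same["proba"].to_numpy(), p1.to_numpy())


def test_combined_classifier_majority_vote_on_hard_probabilities():
    rng = np.random.default_rng(8)
    votes = rng.integers(0, 2, size=(4, 25))  # 4 classifiers, 25 rows
    probas = [pd.DataFrame({"affected": v.astype(float),
                            "unaffected": 1.0 - v}) for v in votes]
    out = combined_classifier(probas)
    tally = votes.sum(axis=0)
    expected = np.where(tally >= 2, "affected", "unaffected")  # tie -> affected
    assert list(out["predictions"]) == list(expected)


def test_combined_classifier_rejects_mismatched_rows():
    p1 = pd.DataFrame({"affected": [0.9], "unaffected": [0.1]})
    p2 = pd.DataFrame({"affected": [0.9, 0.2], "unaffected": [0.1, 0.8]})
    with pytest.raises(ModelError):
        combined_classifier([p1, p2])


def test_permutation_identity_reproduces_unshuffled():
    ds = toy_dataset(n=60, seed=9)
    spec = LearnerSpec("dt", seed=1)
    observed = crossvalidate(ds, spec, scheme="k10", seed=1)
    y = ds.frame.activity_class.to_numpy()
    identity = crossvalidate(ds, spec, scheme="k10", seed=1, y_override=y)
    assert identity.metrics == observed.metrics


def test_permutation_null_centers_on_chance():
    ds = toy_dataset(n=100, seed=10)
    summary = permutation_control(ds, LearnerSpec("dt", seed=0), scheme="k10",
                                  n_shuffles=20, seed=0)
    assert abs(summary["null_BAR_mean"] - 0.5) < 0.06
    assert abs(summary["null_MCC_mean"]) < 0.12
    # observed BAR on a separable set beats every shuffle
    assert summary["p_BAR"] < 1.0 / 20 + 1e-9


def test_learning_curve_shape_and_improvement():
    ds = toy_dataset(n=200, seed=11)
    spec = LearnerSpec("dt", seed=0)
    table = learning_curve(ds, spec, sizes=[40, 160], reps=4, seed=0)
    assert set(table["size"]) == {40, 160}
    assert set(table["metric"]) == {"BAR", "MCC", "AUC"}
    assert (table["reps"] == 4).all()
    with pytest.raises(ModelError):
        learning_curve(ds, spec, sizes=[10], reps=2, seed=0)
    with pytest.raises(ModelError):
        learning_curve(ds, spec, sizes=[1000], reps=2, seed=0)


def test_stratified_performance_matches_direct_tally():
    ds = toy_dataset(n=100, seed=12)
    res = crossvalidate(ds, LearnerSpec("dt", seed=0), scheme="k10", seed=0)
    groups = np.where(np.arange(100) < 50, "g1", "g2")
    table = stratified_performance(res, groups).set_index("group")
    assert table.loc["g1", "n"] == 50 and table.loc["g2", "n"] == 50
    assert table["pct"].sum() == pytest.approx(100.0)
    mask = groups == "g1"
    direct = compute_metrics(res.y_true[mask], res.y_pred[mask])
    assert table.loc["g1", "BAR"] == pytest.approx(direct["BAR"], nan_ok=True)
    # single group equals overall metrics
    whole = stratified_performance(res, ["all"] * 100)
    assert whole.loc[0, "BAR"] == pytest.approx(res.metrics["BAR"])


def test_prediction_array_reconciles_with_confusion(study):
    ds = assemble_dataset(study.activities, study.tessellation, study.potential,
                          "monomer-27", "classification")
    res = crossvalidate(ds, LearnerSpec("dt", seed=0), scheme="k10", seed=0)
    grid = prediction_array(res)
    values = grid.to_numpy().ravel()
    n_correct = (values == "correct").sum()
    n_incorrect = (values == "incorrect").sum()
    m = res.metrics
    assert n_correct == m["TP"] + m["TN"]
    assert n_incorrect == m["FP"] + m["FN"]
    # native = replacement cells are never variants
    for (chain, pos, native) in grid.columns:
        assert grid.loc[native, (chain, pos, native)] == "not-a-variant"


def test_class_missing_from_dataset_rejected():
    ds = toy_dataset(n=40, seed=13)
    ds.frame["activity_class"] = "affected"
    with pytest.raises(ModelError):
        crossvalidate(ds, LearnerSpec("dt", seed=0), scheme="k10", seed=0)
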