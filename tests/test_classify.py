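import numpy as np
import pandas as pd
import pytest

import sxt_celltyper as sxt
from sxt_celltyper.classify import (
    DEFAULT_GRIDS,
    MODEL_FAMILIES,
    _candidate_params,
    aggregate,
    subsample_per_cell,
)
from sxt_celltyper.extraction import CLASSIFIER_FEATURES


def toy_table(n_cells_per_class=3, n_per_cell=30, gap=3.0, seed=0):
    """Separable two-class vesicle table with cell grouping."""
    rng = np.random.default_rng(seed)
    rows = []
    for cls, shift in (("alpha", gap), ("beta", 0.0)):
        for c in range(n_cells_per_class):
            cid = f"{cls}_{c + 1}"
            for v in range(n_per_cell):
                rec = {
                    "vesicle_id": f"{cid}_v{v}",
                    "cell_id": cid,
                    "cell_class": cls,
                }
                for j, col in enumerate(CLASSIFIER_FEATURES):
                    informative = shift if j < 3 else 0.0
                    rec[col] = rng.normal(informative, 1.0)
                rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# split enumeration
# ---------------------------------------------------------------------------


def test_cohort_split_enumeration_is_exhaustive():
    alpha = [f"a{i}" for i in range(8)]
    beta = [f"b{i}" for i in range(7)]
    plans = sxt.enumerate_splits(alpha, beta)
    assert len(plans) == 56
    assert len({(p.held_out_alpha, p.held_out_beta) for p in plans}) == 56
    for p in plans:
        assert p.held_out_alpha not in p.training_ids
        assert p.held_out_beta not in p.training_ids
        assert len(p.training_ids) == 13


def test_small_enumerations_match_explicit_products():
    assert len(sxt.enumerate_splits(["a"], ["b"])) == 1
    plans = sxt.enumerate_splits(["a1", "a2", "a3"], ["b1", "b2"])
    expected = {(a, b) for a in ("a1", "a2", "a3") for b in ("b1", "b2")}
    assert {(p.held_out_alpha, p.held_out_beta) for p in plans} == expected
    with pytest.raises(ValueError):
        sxt.enumerate_splits(["a", "a"], ["b"])
    with pytest.raises(ValueError):
        sxt.enumerate_splits(["a"], [])


# ---------------------------------------------------------------------------
# tuning
# ---------------------------------------------------------------------------


def test_single_point_grid_is_returned_unchanged():
    table = toy_table()
    model, params = sxt.tune_and_train(
        table, "logistic_regression", seed=0, grids={"logistic_regression": {"model__C": [0.5]}}
    )
    assert params == {"model__C": 0.5}


def test_dominated_hyperparameter_is_rejected():
    """On a separable toy set, a vanishing regularization weight loses LOGO."""
    table = toy_table(gap=4.0)
    _, params = sxt.tune_and_train(
        table,
        "logistic_regression",
        seed=0,
        grids={"logistic_regression": {"model__C": [1e-9, 10.0]}},
    )
    assert params == {"model__C": 10.0}


def test_all_three_model_families_train_and_score():
    table = toy_table()
    for family in MODEL_FAMILIES:
        grids = None
        if family == "xgboost":
            grids = {"xgboost": dict(DEFAULT_GRIDS["xgboost"], n_draws=3)}
        model, _ = sxt.tune_and_train(table, family, seed=1, grids=grids)
        metrics = sxt.evaluate_on_heldout(model, table)
        assert metrics["accuracy"] > 0.9  # separable by construction


def test_training_requires_two_cells_per_class():
    table = toy_table(n_cells_per_class=1)
    with pytest.raises(ValueError):
        sxt.tune_and_train(table, "logistic_regression", seed=0)


def test_xgboost_candidates_are_seeded_draws():
    rng1 = np.random.default_rng(5)
    rng2 = np.random.default_rng(5)
    a = _candidate_params("xgboost", DEFAULT_GRIDS, rng1)
    b = _candidate_params("xgboost", DEFAULT_GRIDS, rng2)
    assert len(a) == 25  # 10 init + 15 iteration budget
    assert a == b
    for p in a:
        assert 0.03 <= p["learning_rate"] <= 0.3
        assert 2 <= p["max_depth"] <= 6


# ---------------------------------------------------------------------------
# held-out metrics and majority vote
# ---------------------------------------------------------------------------


class _ConstantModel:
    classes_ = [0, 1]

    def predict(self, X):
        return np.ones(len(X), dtype=int)


def test_all_one_class_predictor_on_balanced_toy():
    held = toy_table(n_cells_per_class=1, n_per_cell=20)
    metrics = sxt.evaluate_on_heldout(_ConstantModel(), held)
    assert metrics["accuracy"] == pytest.approx(0.5)
    assert metrics["recall"] == pytest.approx(1.0)  # positive class fully found
    assert metrics["precision"] == pytest.approx(0.5)
    assert np.isnan(metrics["roc_auc"])  # no score output


def test_metrics_match_hand_confusion_matrix():
    held = pd.DataFrame(
        {
            "vesicle_id": [f"v{i}" for i in range(10)],
            "cell_id": ["a1"] * 5 + ["b1"] * 5,
            "cell_class": ["alpha"] * 5 + ["beta"] * 5,
            **{c: np.linspace(0, 1, 10) for c in CLASSIFIER_FEATURES},
        }
    )

    class Fixed:
        classes_ = [0, 1]

        def predict(self, X):
            # 4 TP, 1 FN, 2 FP, 3 TN against alpha=positive
            return np.array([1, 1, 1, 1, 0, 1, 1, 0, 0, 0])

    m = sxt.evaluate_on_heldout(Fixed(), held)
    assert m["accuracy"] == pytest.approx(7 / 10)
    assert m["precision"] == pytest.approx(4 / 6)
    assert m["recall"] == pytest.approx(4 / 5)
    assert m["f1"] == pytest.approx(2 * (4 / 6) * (4 / 5) / ((4 / 6) + (4 / 5)))


def test_majority_vote_cell_calls():
    assert sxt.call_cell_identity(["beta"] * 60 + ["alpha"] * 40) == "beta"
    assert sxt.call_cell_identity(["alpha"] * 7) == "alpha"
    assert sxt.call_cell_identity(["alpha", "beta"]) == "indeterminate"
    assert sxt.call_cell_identity(np.array([1, 1, 0])) == "alpha"
    with pytest.raises(ValueError):
        sxt.call_cell_identity([])


# ---------------------------------------------------------------------------
# aggregation and the evaluator
# ---------------------------------------------------------------------------


def test_aggregate_mean_sd_against_brute_force():
    rows = []
    vals = [0.6, 0.7, 0.8, 0.9, 1.0]
    for i, v in enumerate(vals):
        rows.append(
            {"family": "random_forest", "accuracy": v, "precision": v, "recall": v,
             "f1": v, "roc_auc": v, "held_out_alpha": f"a{i}", "held_out_beta": "b0"}
        )
    agg = aggregate(pd.DataFrame(rows))
    assert agg.accuracy_mean.iloc[0] == pytest.approx(np.mean(vals))
    assert agg.accuracy_sd.iloc[0] == pytest.approx(np.std(vals, ddof=1))
    same = pd.DataFrame(rows[:1] * 4)
    agg2 = aggregate(same)
    assert agg2.accuracy_sd.iloc[0] == 0.0


def test_evaluator_detects_leaked_vesicle_ids():
    table = toy_table(n_cells_per_class=2)
    # the same vesicle id in two different cells trips the audit
    leaked = table.copy()
    leaked.loc[leaked.index[-1], "vesicle_id"] = table.vesicle_id.iloc[0]
    ev = sxt.LeavePairOutEvaluator(families=("logistic_regression",), seed=0)
    with pytest.raises(AssertionError, match="leakage"):
        ev.evaluate(leaked)


def test_evaluator_runs_and_is_reproducible():
    table = toy_table(n_cells_per_class=3, n_per_cell=25, gap=2.0)
    ev = sxt.LeavePairOutEvaluator(families=("logistic_regression",), seed=3)
    r1 = ev.evaluate(table)
    r2 = sxt.LeavePairOutEvaluator(families=("logistic_regression",), seed=3).evaluate(table)
    assert r1.n_models == 9  # 3 alpha x 3 beta combinations, one family
    pd.testing.assert_frame_equal(r1.per_combination, r2.per_combination)
    pd.testing.assert_frame_equal(r1.cell_calls, r2.cell_calls)
    assert set(r1.aggregate.family) == {"logistic_regression"}
    # cell-call coherence: with vesicle accuracy > 0.5 on both held-out
    # cells, both identities are called correctly
    good = r1.cell_calls[r1.cell_calls.vesicle_accuracy > 0.5]
    assert (good.true_class == good.called_class).all()


def test_training_subsample_caps_cells_but_not_heldout():
    table = toy_table(n_cells_per_class=2, n_per_cell=40)
    capped = subsample_per_cell(table, 10, seed=0)
    assert capped.groupby("cell_id").size().max() == 10
    assert subsample_per_cell(table, None, seed=0) is table
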