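"""Leave-one-alpha-one-beta-out vesicle-identity classification.

The supervised strategy: vesicle-level features (the 11 LAC parameters plus
diameter; whole-cell morphology is excluded to avoid biasing the model) feed
three model families — logistic regression, random forest and XGBoost.  For
each of the n_alpha x n_beta held-out-pair combinations (56 for the 8+7
cohort), hyperparameters are tuned by maximising mean accuracy under
Leave-One-Group-Out cross-validation over the training cells (a group is all
vesicles from one cell), the model is refit on all training vesicles, and
vesicle-level metrics are scored on the pooled vesicles of the two held-out
cells.  Metrics are averaged over combinations; cell identity is called from
the majority of a cell's predicted vesicle labels.

Logistic regression and random forest are grid-searched; XGBoost, which has
too many knobs for a grid, is tuned with 25 seeded random-search draws.
The glucagon/alpha class is the positive class for metric reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from .extraction import CLASSIFIER_FEATURES

POSITIVE_CLASS = "alpha"  # glucagon vesicles / alpha cells
MODEL_FAMILIES = ("logistic_regression", "random_forest", "xgboost")
METRICS = ("accuracy", "precision", "recall", "f1", "roc_auc")

#: default hyperparameter searches (overridable); XGBoost uses 25 random
#: draws from the listed ranges instead of a grid
DEFAULT_GRIDS = {
    "logistic_regression": {"model__C": [0.01, 0.1, 1.0, 10.0]},
    "random_forest": {"max_depth": [None, 8], "min_samples_leaf": [2]},
    "xgboost": {
        "n_draws": 25,
        "learning_rate": (0.03, 0.3),  # log-uniform
        "max_depth": (2, 6),  # integer-uniform
        "subsample": (0.6, 1.0),
        "colsample_bytree": (0.6, 1.0),
    },
}

RF_N_ESTIMATORS = 60
XGB_N_ESTIMATORS = 60


@dataclass(frozen=True)
class SplitPlan:
    """One held-out alpha/beta pair and the complementary training cells."""

    held_out_alpha: str
    held_out_beta: str
    training_ids: tuple[str, ...]

    @property
    def held_out(self) -> tuple[str, str]:
        return (self.held_out_alpha, self.held_out_beta)


def enumerate_splits(alpha_ids: Sequence[str], beta_ids: Sequence[str]) -> list[SplitPlan]:
    """Cartesian product of held-out pairs, in deterministic order."""
    alpha_ids, beta_ids = list(alpha_ids), list(beta_ids)
    if len(set(alpha_ids)) != len(alpha_ids) or len(set(beta_ids)) != len(beta_ids):
        raise ValueError("duplicate cell ids")
    if set(alpha_ids) & set(beta_ids):
        raise ValueError("a cell id appears in both classes")
    if not alpha_ids or not beta_ids:
        raise ValueError("need at least one cell id per class")
    plans = []
    for a, b in product(alpha_ids, beta_ids):
        train = tuple(x for x in alpha_ids if x != a) + tuple(
            x for x in beta_ids if x != b
        )
        plans.append(SplitPlan(a, b, train))
    return plans


# ---------------------------------------------------------------------------
# models and tuning
# ---------------------------------------------------------------------------


def _make_model(family: str, params: dict, seed: int):
    if family == "logistic_regression":
        # standardization inside the pipeline: fit on training folds only
        model = Pipeline(
            [("scale", StandardScaler()), ("model", LogisticRegression(max_iter=2000))]
        )
        return model.set_params(**params)
    if family == "random_forest":
        return RandomForestClassifier(
            n_estimators=RF_N_ESTIMATORS, random_state=seed, n_jobs=1, **params
        )
    if family == "xgboost":
        return XGBClassifier(
            n_estimators=XGB_N_ESTIMATORS,
            tree_method="hist",
            n_jobs=1,
            eval_metric="logloss",
            random_state=seed,
            **params,
        )
    raise ValueError(f"unknown model family {family!r}")


def _candidate_params(family: str, grids: dict, rng: np.random.Generator) -> list[dict]:
    spec = grids[family]
    if family == "xgboost":
        lo_lr, hi_lr = spec["learning_rate"]
        draws = []
        for _ in range(spec["n_draws"]):
            draws.append(
                {
                    "learning_rate": float(
                        np.exp(rng.uniform(np.log(lo_lr), np.log(hi_lr)))
                    ),
                    "max_depth": int(rng.integers(spec["max_depth"][0], spec["max_depth"][1] + 1)),
                    "subsample": float(rng.uniform(*spec["subsample"])),
                    "colsample_bytree": float(rng.uniform(*spec["colsample_bytree"])),
                }
            )
        return draws
    keys = sorted(spec)
    return [dict(zip(keys, combo)) for combo in product(*(spec[k] for k in keys))]


def _encode(y: np.ndarray) -> np.ndarray:
    return (np.asarray(y) == POSITIVE_CLASS).astype(int)


def tune_and_train(
    train_table: pd.DataFrame,
    model_family: str,
    seed: int = 0,
    feature_columns: Sequence[str] = tuple(CLASSIFIER_FEATURES),
    grids: dict | None = None,
    refit_table: pd.DataFrame | None = None,
) -> tuple[object, dict]:
    """LOGO-tuned model fit on all training vesicles.

    Each hyperparameter candidate is scored by mean accuracy over
    Leave-One-Group-Out folds (one fold per training cell); folds whose
    training side degenerates to a single class are skipped with a warning.
    Ties go to the earliest candidate in deterministic order.  Returns the
    refit model and the chosen hyperparameters.

    ``refit_table`` lets the caller tune on a subsample but fit the final
    model on a larger table from the same cells: hyperparameter selection is
    robust to subsampling while the final fit benefits from more vesicles.
    """
    grids = {**DEFAULT_GRIDS, **(grids or {})}
    cells = sorted(train_table["cell_id"].unique())
    classes_present = train_table.groupby("cell_id")["cell_class"].first()
    if classes_present.nunique() < 2 or min(
        (classes_present == c).sum() for c in classes_present.unique()
    ) < 2:
        raise ValueError("training table needs >= 2 cells per class")

    X = train_table[list(feature_columns)].to_numpy(float)
    y = _encode(train_table["cell_class"].to_numpy())
    groups = train_table["cell_id"].to_numpy()

    rng = np.random.default_rng(seed)
    candidates = _candidate_params(model_family, grids, rng)

    folds = []
    for cell in cells:
        val = groups == cell
        if len(np.unique(y[~val])) < 2:
            warnings.warn(f"LOGO fold {cell}: single-class training side, skipped")
            continue
        folds.append(val)
    if not folds:
        raise ValueError("all LOGO folds degenerate")

    if model_family == "xgboost":
        best_params = _xgb_logo_search(X, y, folds, candidates, seed)
    else:
        best_score, best_params = -np.inf, None
        for params in candidates:
            scores = []
            for val in folds:
                model = _make_model(model_family, params, seed)
                model.fit(X[~val], y[~val])
                scores.append(accuracy_score(y[val], model.predict(X[val])))
            mean = float(np.mean(scores))
            if mean > best_score:
                best_score, best_params = mean, params

    final = _make_model(model_family, best_params, seed)
    if refit_table is not None:
        if set(refit_table["cell_id"]) != set(cells):
            raise ValueError("refit_table must cover exactly the training cells")
        final.fit(
            refit_table[list(feature_columns)].to_numpy(float),
            _encode(refit_table["cell_class"].to_numpy()),
        )
    else:
        final.fit(X, y)
    return final, best_params


def _xgb_logo_search(X, y, folds, candidates, seed):
    """LOGO accuracy search over XGBoost draws via the native train API.

    DMatrix construction is hoisted out of the candidate loop; the selected
    parameters are refit through the sklearn wrapper by the caller.
    """
    import xgboost as xgb

    fold_data = []
    for val in folds:
        fold_data.append(
            (xgb.DMatrix(X[~val], label=y[~val]), xgb.DMatrix(X[val]), y[val])
        )
    best_score, best_params = -np.inf, None
    for params in candidates:
        native = {
            "objective": "binary:logistic",
            "tree_method": "hist",
            "nthread": 1,
            "seed": seed,
            "eta": params["learning_rate"],
            "max_depth": params["max_depth"],
            "subsample": params["subsample"],
            "colsample_bytree": params["colsample_bytree"],
        }
        scores = []
        for dtrain, dval, yval in fold_data:
            booster = xgb.train(native, dtrain, num_boost_round=XGB_N_ESTIMATORS)
            scores.append(float(((booster.predict(dval) > 0.5) == yval).mean()))
        mean = float(np.mean(scores))
        if mean > best_score:
            best_score, best_params = mean, params
    return best_params


def evaluate_on_heldout(
    model,
    heldout_vesicles: pd.DataFrame,
    feature_columns: Sequence[str] = tuple(CLASSIFIER_FEATURES),
) -> dict:
    """Vesicle-level metrics over the pooled held-out vesicles.

    Precision/recall/F1 are reported for the positive (glucagon/alpha)
    class; ROC AUC uses predicted class scores and is NaN when the model
    exposes none.
    """
    if len(heldout_vesicles) == 0:
        raise ValueError("held-out table is empty")
    X = heldout_vesicles[list(feature_columns)].to_numpy(float)
    y = _encode(heldout_vesicles["cell_class"].to_numpy())
    pred = model.predict(X)
    out = {
        "accuracy": accuracy_score(y, pred),
        "precision": precision_score(y, pred, zero_division=0),
        "recall": recall_score(y, pred, zero_division=0),
        "f1": f1_score(y, pred, zero_division=0),
    }
    try:
        score = model.predict_proba(X)[:, list(model.classes_).index(1)]
        out["roc_auc"] = roc_auc_score(y, score) if len(np.unique(y)) == 2 else np.nan
    except AttributeError:
        out["roc_auc"] = np.nan
    return out


def call_cell_identity(vesicle_predictions: Sequence) -> str:
    """Majority-vote cell identity; an exact tie is flagged, never coin-flipped."""
    preds = np.asarray(vesicle_predictions)
    if preds.size == 0:
        raise ValueError("no vesicle predictions")
    n_pos = int((preds == 1).sum() if preds.dtype.kind in "biu" else (preds == POSITIVE_CLASS).sum())
    n_neg = len(preds) - n_pos
    if n_pos > n_neg:
        return "alpha"
    if n_neg > n_pos:
        return "beta"
    return "indeterminate"


def aggregate(per_combination: pd.DataFrame) -> pd.DataFrame:
    """Mean +- SD of each metric per model family over combinations."""
    if len(per_combination) == 0:
        raise ValueError("no combination reports")
    rows = []
    for family, grp in per_combination.groupby("family", sort=True):
        row = {"family": family, "n_combinations": len(grp)}
        for m in METRICS:
            row[f"{m}_mean"] = float(grp[m].mean())
            row[f"{m}_sd"] = float(grp[m].std(ddof=1)) if len(grp) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class EvaluationReport:
    """Results of the full held-out-pair sweep."""

    per_combination: pd.DataFrame  # one row per (combination, family)
    aggregate: pd.DataFrame  # mean +- sd per family
    cell_calls: pd.DataFrame  # per held-out cell majority-vote identity
    n_models: int
    feature_columns: tuple[str, ...]
    seed: int


class LeavePairOutEvaluator:
    """sklearn-style runner for the held-out-pair evaluation sweep.

    Parameters
    ----------
    families : model families to train per combination.
    feature_columns : vesicle features fed to the models.
    max_vesicles_per_cell : optional per-cell subsample (seeded) applied to
        the TRAINING side of each combination during hyperparameter tuning;
        held-out cells are always scored on all their vesicles.  Per-vesicle
        metrics are stable under training subsampling, which keeps the
        56-combination run desk-scale.
    refit_max_vesicles_per_cell : per-cell cap for the FINAL fit after
        tuning (defaults to 5x the tuning cap when that is set): the LOGO
        search is robust to subsampling, while the final model benefits from
        seeing more vesicles per training cell.
    grids : overrides for DEFAULT_GRIDS.
    """

    def __init__(
        self,
        families: Sequence[str] = MODEL_FAMILIES,
        feature_columns: Sequence[str] = tuple(CLASSIFIER_FEATURES),
        max_vesicles_per_cell: int | None = None,
        refit_max_vesicles_per_cell: int | None = None,
        grids: dict | None = None,
        seed: int = 0,
    ):
        self.families = tuple(families)
        self.feature_columns = tuple(feature_columns)
        self.max_vesicles_per_cell = max_vesicles_per_cell
        self.refit_max_vesicles_per_cell = refit_max_vesicles_per_cell
        self.grids = grids
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {
            "families": self.families,
            "feature_columns": self.feature_columns,
            "max_vesicles_per_cell": self.max_vesicles_per_cell,
            "refit_max_vesicles_per_cell": self.refit_max_vesicles_per_cell,
            "grids": self.grids,
            "seed": self.seed,
        }

    def set_params(self, **params) -> "LeavePairOutEvaluator":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def evaluate(self, table: pd.DataFrame, splits: list[SplitPlan] | None = None) -> EvaluationReport:
        train_pool = subsample_per_cell(table, self.max_vesicles_per_cell, self.seed)
        refit_cap = self.refit_max_vesicles_per_cell
        if refit_cap is None and self.max_vesicles_per_cell is not None:
            refit_cap = 5 * self.max_vesicles_per_cell
        refit_pool = (
            train_pool
            if refit_cap is None or self.max_vesicles_per_cell is None
            else subsample_per_cell(table, refit_cap, self.seed)
        )
        if splits is None:
            alpha_ids = sorted(table.loc[table.cell_class == "alpha", "cell_id"].unique())
            beta_ids = sorted(table.loc[table.cell_class == "beta", "cell_id"].unique())
            splits = enumerate_splits(alpha_ids, beta_ids)

        ss = np.random.SeedSequence(self.seed)
        rows, calls = [], []
        separate_refit = refit_pool is not train_pool
        for plan in splits:
            train = train_pool[train_pool.cell_id.isin(plan.training_ids)]
            refit = refit_pool[refit_pool.cell_id.isin(plan.training_ids)]
            held = table[table.cell_id.isin(plan.held_out)]
            # leakage audit: no held-out vesicle may enter tuning/training
            if (set(train.vesicle_id) | set(refit.vesicle_id)) & set(held.vesicle_id):
                raise AssertionError("leakage: held-out vesicles found in training set")
            for family in self.families:
                child = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
                model, params = tune_and_train(
                    train, family, seed=child,
                    feature_columns=self.feature_columns, grids=self.grids,
                    refit_table=refit if separate_refit else None,
                )
                metrics = evaluate_on_heldout(model, held, self.feature_columns)
                rows.append(
                    {
                        "held_out_alpha": plan.held_out_alpha,
                        "held_out_beta": plan.held_out_beta,
                        "family": family,
                        "params": repr(params),
                        **metrics,
                    }
                )
                for cid in plan.held_out:
                    sub = held[held.cell_id == cid]
                    preds = model.predict(sub[list(self.feature_columns)].to_numpy(float))
                    calls.append(
                        {
                            "held_out_alpha": plan.held_out_alpha,
                            "held_out_beta": plan.held_out_beta,
                            "family": family,
                            "cell_id": cid,
                            "true_class": sub.cell_class.iloc[0],
                            "called_class": call_cell_identity(preds),
                            "vesicle_accuracy": float(
                                (preds == _encode(sub.cell_class.to_numpy())).mean()
                            ),
                        }
                    )
        per_comb = pd.DataFrame(rows)
        return EvaluationReport(
            per_combination=per_comb,
            aggregate=aggregate(per_comb),
            cell_calls=pd.DataFrame(calls),
            n_models=len(rows),
            feature_columns=self.feature_columns,
            seed=self.seed,
        )


def subsample_per_cell(
    table: pd.DataFrame, max_per_cell: int | None, seed: int
) -> pd.DataFrame:
    """Seeded per-cell subsample (no-op when ``max_per_cell`` is None)."""
    if max_per_cell is None:
        return table
    rng = np.random.default_rng(seed)
    keep = []
    for cid, grp in table.groupby("cell_id", sort=True):
        if len(grp) <= max_per_cell:
            keep.append(grp)
        else:
            keep.append(grp.sample(n=max_per_cell, random_state=int(rng.integers(2**31))))
    return pd.concat(keep, ignore_index=True)
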