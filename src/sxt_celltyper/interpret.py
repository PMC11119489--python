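"""Model interpretation: permutation importance and structural embeddings.

Permutation feature importance (accuracy drop when one feature column is
shuffled) is diluted when features are collinear — and the 11 LAC parameters
are strongly collinear by construction — so features are first grouped by
hierarchical clustering on 1 - |Pearson r| and one representative per
cluster is reported.  Final importances are averaged over the held-out-pair
combinations whose accuracy exceeds 75%.

UMAP embeddings visualise pooled vesicles (n_neighbors=50, min_dist=0.5) and
whole cells (n_neighbors=4, min_dist=0.2), both with the canberra metric,
whose per-coordinate scaling suits features living on different numerical
scales.  All columns except skew and kurtosis are z-scored first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.metrics import accuracy_score

from .classify import (
    CLASSIFIER_FEATURES,
    SplitPlan,
    _encode,
    enumerate_splits,
    subsample_per_cell,
    tune_and_train,
    _make_model,
)

SKEW_KURTOSIS_COLUMNS = ("lac_skew", "lac_kurtosis")


def canberra_distance(x: Sequence[float], y: Sequence[float]) -> float:
    """Canberra distance: sum_i |x_i - y_i| / (|x_i| + |y_i|).

    Terms where both components are zero contribute nothing.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must have equal length")
    denom = np.abs(x) + np.abs(y)
    num = np.abs(x - y)
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(denom > 0, num / denom, 0.0)
    return float(terms.sum())


# ---------------------------------------------------------------------------
# permutation importance
# ---------------------------------------------------------------------------


def permutation_importance(
    model,
    feature_table: pd.DataFrame,
    labels: Sequence,
    n_repeats: int = 10,
    seed: int = 0,
    feature_columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mean accuracy drop per feature over ``n_repeats`` column shuffles.

    Returns a frame with one row per feature (``importance`` = baseline
    accuracy minus mean permuted accuracy, with its SD over repeats); the
    baseline is stored in ``frame.attrs['baseline_accuracy']``.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if len(feature_table) < 2:
        raise ValueError("need at least two rows to permute")
    cols = list(feature_columns or feature_table.columns)
    X = feature_table[cols].to_numpy(float)
    y = np.asarray(labels)
    if y.dtype.kind not in "biu":
        y = _encode(y)
    rng = np.random.default_rng(seed)
    baseline = accuracy_score(y, model.predict(X))
    rows = []
    for j, col in enumerate(cols):
        drops = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            drops.append(baseline - accuracy_score(y, model.predict(Xp)))
        rows.append(
            {"feature": col, "importance": float(np.mean(drops)), "sd": float(np.std(drops, ddof=0))}
        )
    out = pd.DataFrame(rows)
    out.attrs["baseline_accuracy"] = float(baseline)
    return out


# ---------------------------------------------------------------------------
# multicollinearity clustering
# ---------------------------------------------------------------------------


@dataclass
class FeatureClusterReport:
    correlation: pd.DataFrame
    clusters: dict[str, int]  # feature -> cluster id
    representatives: tuple[str, ...]
    cut_threshold: float
    linkage_method: str

    def members(self, cluster_id: int) -> list[str]:
        return sorted(f for f, c in self.clusters.items() if c == cluster_id)


def correlation_clusters(
    feature_table: pd.DataFrame,
    threshold: float = 0.3,
    linkage_method: str = "average",
    feature_columns: Sequence[str] | None = None,
) -> FeatureClusterReport:
    """Hierarchical clustering of features on 1 - |Pearson r|.

    The dendrogram is cut at ``threshold`` (so features within a cluster
    correlate at |r| >= 1 - threshold along the linkage); the representative
    of each cluster is the member with the highest mean |r| to its cluster
    mates, with ties broken alphabetically so the choice is invariant to
    column order.  Constant features have undefined correlation and are
    isolated into singleton clusters with a warning.
    """
    cols = list(feature_columns or feature_table.columns)
    if len(cols) < 2:
        raise ValueError("need at least two features")
    data = feature_table[cols]
    constant = [c for c in cols if data[c].nunique() <= 1]
    if constant:
        warnings.warn(f"constant features isolated into singleton clusters: {constant}")
    active = [c for c in cols if c not in constant]
    corr = data[active].corr().abs()

    clusters: dict[str, int] = {}
    if len(active) >= 2:
        dist = 1.0 - corr.to_numpy()
        np.fill_diagonal(dist, 0.0)
        dist = np.clip((dist + dist.T) / 2, 0.0, None)
        link = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
        flat = hierarchy.fcluster(link, t=threshold, criterion="distance")
        # renumber clusters by their alphabetically-first member (order invariance)
        groups: dict[int, list[str]] = {}
        for feat, cid in zip(active, flat):
            groups.setdefault(int(cid), []).append(feat)
        for new_id, members in enumerate(
            sorted(groups.values(), key=lambda ms: min(ms)), start=1
        ):
            for feat in members:
                clusters[feat] = new_id
    elif len(active) == 1:
        clusters[active[0]] = 1
    next_id = max(clusters.values(), default=0) + 1
    for feat in sorted(constant):
        clusters[feat] = next_id
        next_id += 1

    reps = []
    for cid in sorted(set(clusters.values())):
        members = sorted(f for f, c in clusters.items() if c == cid)
        if len(members) == 1 or any(m in constant for m in members):
            reps.append(members[0])
            continue
        mean_r = {
            f: corr.loc[f, [m for m in members if m != f]].mean() for f in members
        }
        reps.append(min(members, key=lambda f: (-mean_r[f], f)))

    full_corr = data.corr()
    return FeatureClusterReport(
        correlation=full_corr,
        clusters=clusters,
        representatives=tuple(reps),
        cut_threshold=threshold,
        linkage_method=linkage_method,
    )


@dataclass
class ImportanceReport:
    """Clustered permutation-importance summary over qualifying combinations."""

    correlation: pd.DataFrame
    clusters: dict[str, int]
    representatives: tuple[str, ...]
    per_combination: pd.DataFrame  # importance per (combination, feature)
    averaged: pd.DataFrame  # mean importance over combos with accuracy > threshold
    accuracy_threshold: float
    n_qualifying: int


def clustered_importance(
    table: pd.DataFrame,
    family: str = "random_forest",
    splits: list[SplitPlan] | None = None,
    seed: int = 0,
    n_repeats: int = 10,
    accuracy_threshold: float = 0.75,
    cluster_cut: float = 0.3,
    max_vesicles_per_cell: int | None = None,
    tune: bool = True,
    grids: dict | None = None,
) -> ImportanceReport:
    """Representative-feature permutation importances for one model family.

    For each held-out-pair combination a model is trained on the
    representative features only (tuned by LOGO when ``tune``, else fit at
    package defaults), scored on the held-out vesicles, and permutation
    importances are computed there.  Reported importances average the
    combinations whose held-out accuracy exceeds ``accuracy_threshold``.
    """
    table = subsample_per_cell(table, max_vesicles_per_cell, seed)
    cluster_report = correlation_clusters(
        table, threshold=cluster_cut, feature_columns=list(CLASSIFIER_FEATURES)
    )
    reps = list(cluster_report.representatives)
    if splits is None:
        alpha_ids = sorted(table.loc[table.cell_class == "alpha", "cell_id"].unique())
        beta_ids = sorted(table.loc[table.cell_class == "beta", "cell_id"].unique())
        splits = enumerate_splits(alpha_ids, beta_ids)

    ss = np.random.SeedSequence(seed)
    rows = []
    for plan in splits:
        child = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        train = table[table.cell_id.isin(plan.training_ids)]
        held = table[table.cell_id.isin(plan.held_out)]
        if tune:
            model, _ = tune_and_train(
                train, family, seed=child, feature_columns=reps, grids=grids
            )
        else:
            model = _make_model(family, {}, child)
            model.fit(train[reps].to_numpy(float), _encode(train.cell_class.to_numpy()))
        y_held = _encode(held.cell_class.to_numpy())
        acc = accuracy_score(y_held, model.predict(held[reps].to_numpy(float)))
        imp = permutation_importance(
            model, held, y_held, n_repeats=n_repeats, seed=child, feature_columns=reps
        )
        for _, r in imp.iterrows():
            rows.append(
                {
                    "held_out_alpha": plan.held_out_alpha,
                    "held_out_beta": plan.held_out_beta,
                    "accuracy": float(acc),
                    "feature": r["feature"],
                    "importance": r["importance"],
                }
            )
    per_comb = pd.DataFrame(rows)
    qualifying = per_comb[per_comb.accuracy > accuracy_threshold]
    averaged = (
        qualifying.groupby("feature")["importance"].agg(["mean", "std"]).reset_index()
        .rename(columns={"mean": "importance", "std": "sd"})
        .sort_values("importance", ascending=False, ignore_index=True)
    )
    return ImportanceReport(
        correlation=cluster_report.correlation,
        clusters=cluster_report.clusters,
        representatives=cluster_report.representatives,
        per_combination=per_comb,
        averaged=averaged,
        accuracy_threshold=accuracy_threshold,
        n_qualifying=int(qualifying[["held_out_alpha", "held_out_beta"]].drop_duplicates().shape[0]),
    )


# ---------------------------------------------------------------------------
# embeddings
# ---------------------------------------------------------------------------


class EmbeddingStandardizer(TransformerMixin, BaseEstimator):
    """Z-score all feature columns except skew and kurtosis.

    Skew and kurtosis are already dimensionless shape parameters and pass
    through untouched; zero-variance columns also pass through, with a
    warning.  ``inverse_transform`` recovers the input exactly.
    """

    def __init__(self, exclude: Sequence[str] = SKEW_KURTOSIS_COLUMNS):
        self.exclude = tuple(exclude)

    def fit(self, X: pd.DataFrame, y=None) -> "EmbeddingStandardizer":
        X = pd.DataFrame(X)
        self.columns_ = list(X.columns)
        self.mean_ = {}
        self.scale_ = {}
        for c in self.columns_:
            if c in self.exclude:
                continue
            sd = float(X[c].std(ddof=0))
            if sd == 0.0:
                warnings.warn(f"zero-variance column {c!r} passed through unstandardized")
                continue
            self.mean_[c] = float(X[c].mean())
            self.scale_[c] = sd
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X).copy()
        for c, mu in self.mean_.items():
            X[c] = (X[c] - mu) / self.scale_[c]
        return X

    def inverse_transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X).copy()
        for c, mu in self.mean_.items():
            X[c] = X[c] * self.scale_[c] + mu
        return X

    @property
    def standardized_columns(self) -> tuple[str, ...]:
        return tuple(self.mean_)


@dataclass
class EmbeddingResult:
    coordinates: pd.DataFrame  # columns x, y (one row per input row)
    metadata: pd.DataFrame
    hyperparameters: dict
    standardized_columns: tuple[str, ...]

    def frame(self) -> pd.DataFrame:
        return pd.concat(
            [self.coordinates.reset_index(drop=True), self.metadata.reset_index(drop=True)],
            axis=1,
        )


def _run_umap(
    data: pd.DataFrame,
    metadata: pd.DataFrame,
    seed: int,
    n_neighbors: int,
    min_dist: float,
    metric: str,
) -> EmbeddingResult:
    import umap  # deferred: heavy import

    if len(data) < n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors + 1 = {n_neighbors + 1} rows, got {len(data)}"
        )
    std = EmbeddingStandardizer().fit(data)
    Xs = std.transform(data).to_numpy(float)
    reducer = umap.UMAP(
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        metric=metric,
        random_state=seed,
        n_components=2,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*n_jobs.*")
        coords = reducer.fit_transform(Xs)
    if not np.all(np.isfinite(coords)):
        raise RuntimeError("embedding produced non-finite coordinates")
    return EmbeddingResult(
        coordinates=pd.DataFrame(coords, columns=["x", "y"]),
        metadata=metadata.reset_index(drop=True),
        hyperparameters={
            "n_neighbors": n_neighbors,
            "min_dist": min_dist,
            "metric": metric,
            "seed": seed,
        },
        standardized_columns=std.standardized_columns,
    )


def embed_vesicles(
    feature_table: pd.DataFrame,
    seed: int = 0,
    n_neighbors: int = 50,
    min_dist: float = 0.5,
    metric: str = "canberra",
    feature_columns: Sequence[str] = tuple(CLASSIFIER_FEATURES),
) -> EmbeddingResult:
    """2D UMAP of pooled per-vesicle features (identity/origin metadata kept)."""
    meta_cols = [c for c in ("vesicle_id", "cell_id", "cell_class") if c in feature_table]
    return _run_umap(
        feature_table[list(feature_columns)],
        feature_table[meta_cols + list(feature_columns)],
        seed, n_neighbors, min_dist, metric,
    )


def embed_cells(
    cell_metric_table: pd.DataFrame,
    seed: int = 0,
    n_neighbors: int = 4,
    min_dist: float = 0.2,
    metric: str = "canberra",
    feature_columns: Sequence[str] | None = None,
) -> EmbeddingResult:
    """2D UMAP of whole-cell morphometrics."""
    if feature_columns is None:
        feature_columns = [
            c
            for c in cell_metric_table.columns
            if c not in ("cell_id", "cell_class")
            and pd.api.types.is_numeric_dtype(cell_metric_table[c])
        ]
    meta_cols = [c for c in ("cell_id", "cell_class") if c in cell_metric_table]
    return _run_umap(
        cell_metric_table[list(feature_columns)],
        cell_metric_table[meta_cols],
        seed, n_neighbors, min_dist, metric,
    )
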