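import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import canberra as scipy_canberra
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

import sxt_celltyper as sxt
from sxt_celltyper.interpret import SKEW_KURTOSIS_COLUMNS


# ---------------------------------------------------------------------------
# canberra distance
# ---------------------------------------------------------------------------


def test_canberra_identities():
    assert sxt.canberra_distance([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0
    assert sxt.canberra_distance([1.0, 0.0], [0.0, 1.0]) == pytest.approx(2.0)
    assert sxt.canberra_distance([0.0, 0.0], [0.0, 0.0]) == 0.0  # 0/0 terms vanish


def test_canberra_matches_scipy_on_random_vectors():
    rng = np.random.default_rng(1)
    for _ in range(20):
        x, y = rng.normal(size=5), rng.normal(size=5)
        assert sxt.canberra_distance(x, y) == pytest.approx(scipy_canberra(x, y), rel=1e-12)
    with pytest.raises(ValueError):
        sxt.canberra_distance([1.0], [1.0, 2.0])


# ---------------------------------------------------------------------------
# permutation importance
# ---------------------------------------------------------------------------


def _labelled_frame(n=400, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    return (
        pd.DataFrame(
            {
                "signal": y + rng.normal(0, 0.3, n),
                "noise": rng.normal(size=n),
            }
        ),
        y,
    )


def test_null_feature_importance_is_near_zero():
    X, y = _labelled_frame()
    model = LogisticRegression().fit(X.to_numpy(), y)
    imp = sxt.permutation_importance(model, X, y, n_repeats=30, seed=1)
    noise_drop = imp.set_index("feature").loc["noise", "importance"]
    signal_drop = imp.set_index("feature").loc["signal", "importance"]
    assert abs(noise_drop) < 0.02
    assert signal_drop > 0.2
    assert imp.attrs["baseline_accuracy"] > 0.9


def test_label_copy_feature_drop_approaches_half():
    """Permuting a feature that IS the label costs ~ baseline - chance."""
    rng = np.random.default_rng(2)
    y = rng.integers(0, 2, 600)
    X = pd.DataFrame({"label_copy": y.astype(float)})
    model = RandomForestClassifier(n_estimators=30, random_state=0).fit(X.to_numpy(), y)
    imp = sxt.permutation_importance(model, X, y, n_repeats=20, seed=3)
    base = imp.attrs["baseline_accuracy"]
    drop = imp.importance.iloc[0]
    assert drop == pytest.approx(base - 0.5, abs=0.05)
    with pytest.raises(ValueError):
        sxt.permutation_importance(model, X.iloc[:1], y[:1])


def test_importance_converges_with_repeats():
    X, y = _labelled_frame(seed=5)
    model = LogisticRegression().fit(X.to_numpy(), y)
    few = sxt.permutation_importance(model, X, y, n_repeats=2, seed=0)
    many = sxt.permutation_importance(model, X, y, n_repeats=60, seed=0)
    noise_many = many.set_index("feature").loc["noise"]
    assert abs(noise_many["importance"]) <= max(
        abs(few.set_index("feature").loc["noise", "importance"]), 0.015
    )


# ---------------------------------------------------------------------------
# multicollinearity clustering
# ---------------------------------------------------------------------------


def test_perfectly_correlated_features_share_a_cluster():
    rng = np.random.default_rng(0)
    a = rng.normal(size=300)
    frame = pd.DataFrame({"a": a, "b": 2 * a + 1, "c": rng.normal(size=300)})
    rep = sxt.correlation_clusters(frame, threshold=0.3)
    assert rep.clusters["a"] == rep.clusters["b"]
    assert rep.clusters["c"] != rep.clusters["a"]
    assert len(rep.representatives) == 2


def test_block_diagonal_correlation_gives_two_clusters():
    rng = np.random.default_rng(1)
    u, v = rng.normal(size=500), rng.normal(size=500)
    frame = pd.DataFrame(
        {
            "u1": u + rng.normal(0, 0.1, 500),
            "u2": -u + rng.normal(0, 0.1, 500),
            "v1": v + rng.normal(0, 0.1, 500),
            "v2": v + rng.normal(0, 0.1, 500),
        }
    )
    rep = sxt.correlation_clusters(frame, threshold=0.5)
    assert rep.clusters["u1"] == rep.clusters["u2"]
    assert rep.clusters["v1"] == rep.clusters["v2"]
    assert rep.clusters["u1"] != rep.clusters["v1"]


def test_constant_feature_isolated_with_warning():
    rng = np.random.default_rng(2)
    frame = pd.DataFrame({"a": rng.normal(size=50), "b": np.ones(50)})
    with pytest.warns(UserWarning, match="constant"):
        rep = sxt.correlation_clusters(frame)
    assert rep.members(rep.clusters["b"]) == ["b"]


def test_representatives_invariant_to_column_order():
    rng = np.random.default_rng(3)
    base = rng.normal(size=400)
    frame = pd.DataFrame(
        {
            "w": base + rng.normal(0, 0.05, 400),
            "x": base + rng.normal(0, 0.2, 400),
            "y": rng.normal(size=400),
            "z": base + rng.normal(0, 0.05, 400),
        }
    )
    rep1 = sxt.correlation_clusters(frame)
    rep2 = sxt.correlation_clusters(frame[["z", "y", "x", "w"]])
    assert set(rep1.representatives) == set(rep2.representatives)


def test_lac_parameter_family_collapses_on_default_cohort(default_feature_cohort):
    """Quantile/level statistics cluster together, leaving a compact
    representative set including spread, shape and size parameters."""
    feats, _ = default_feature_cohort
    rep = sxt.correlation_clusters(
        feats, feature_columns=list(sxt.CLASSIFIER_FEATURES), threshold=0.3
    )
    level = ["lac_min", "lac_q25", "lac_mean", "lac_q75", "lac_max", "lac_mode", "lac_median"]
    assert len({rep.clusters[c] for c in level}) == 1
    assert len(rep.representatives) <= 6
    assert "diameter" in rep.representatives
    assert {"lac_skew", "lac_kurtosis"} & set(rep.representatives)


# ---------------------------------------------------------------------------
# standardization and embeddings
# ---------------------------------------------------------------------------


def test_standardizer_zscores_everything_but_shape_columns():
    rng = np.random.default_rng(0)
    frame = pd.DataFrame(
        {
            "lac_mean": rng.normal(0.35, 0.03, 200),
            "diameter": rng.normal(160, 30, 200),
            "lac_skew": rng.normal(0.3, 0.4, 200),
            "lac_kurtosis": rng.normal(-0.5, 0.5, 200),
        }
    )
    std = sxt.EmbeddingStandardizer().fit(frame)
    out = std.transform(frame)
    for col in ("lac_mean", "diameter"):
        assert out[col].mean() == pytest.approx(0.0, abs=1e-12)
        assert out[col].std(ddof=0) == pytest.approx(1.0, rel=1e-12)
    for col in SKEW_KURTOSIS_COLUMNS:
        assert (out[col] == frame[col]).all()  # untouched bit-for-bit
    back = std.inverse_transform(out)
    np.testing.assert_allclose(back.to_numpy(), frame.to_numpy(), rtol=1e-12)


def test_standardizer_warns_on_zero_variance():
    frame = pd.DataFrame({"a": np.ones(10), "lac_skew": np.arange(10.0)})
    with pytest.warns(UserWarning, match="zero-variance"):
        std = sxt.EmbeddingStandardizer().fit(frame)
    assert (std.transform(frame)["a"] == 1.0).all()


def _embedding_frame(n=150, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        cls = "alpha" if i % 2 else "beta"
        shift = 2.0 if cls == "alpha" else 0.0
        rec = {"vesicle_id": f"v{i}", "cell_id": f"{cls}_1", "cell_class": cls}
        for c in sxt.CLASSIFIER_FEATURES:
            rec[c] = rng.normal(shift, 1.0)
        rows.append(rec)
    return pd.DataFrame(rows)


def test_embedding_row_count_and_minimum_rows():
    frame = _embedding_frame(80)
    res = sxt.embed_vesicles(frame, seed=0, n_neighbors=10)
    assert len(res.coordinates) == len(frame)
    assert np.isfinite(res.coordinates.to_numpy()).all()
    with pytest.raises(ValueError, match="n_neighbors"):
        sxt.embed_vesicles(frame.iloc[:5], seed=0, n_neighbors=10)


def test_embedding_reproducible_at_fixed_seed():
    frame = _embedding_frame(100, seed=4)
    a = sxt.embed_vesicles(frame, seed=9, n_neighbors=15)
    b = sxt.embed_vesicles(frame, seed=9, n_neighbors=15)
    np.testing.assert_allclose(a.coordinates.to_numpy(), b.coordinates.to_numpy())
    assert a.hyperparameters["metric"] == "canberra"


def test_duplicate_rows_land_nearby():
    frame = _embedding_frame(90, seed=2)
    dup = pd.concat([frame, frame.iloc[[0]]], ignore_index=True)
    res = sxt.embed_vesicles(dup, seed=0, n_neighbors=10)
    xy = res.coordinates.to_numpy()
    d_dup = np.linalg.norm(xy[0] - xy[-1])
    spread = np.linalg.norm(xy.std(axis=0))
    assert d_dup < 0.25 * spread
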