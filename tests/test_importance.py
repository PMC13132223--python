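"""Consensus feature importance and the feature-count sweep."""

import numpy as np
import pandas as pd
import pytest

from organnet.classify import ModelSpec, build_model, stratified_cv
from organnet.errors import DataError
from organnet.importance import (
    builtin_importance,
    consensus_across_organs,
    consensus_ranking,
    feature_sweep,
    permutation_importance,
    select_best_family,
    shap_importance,
)


def _frame(X):
    return pd.DataFrame(
        X,
        index=[f"s{i}" for i in range(X.shape[0])],
        columns=[f"g{j}" for j in range(X.shape[1])],
    )


@pytest.fixture(scope="module")
def signal_data():
    rng = np.random.default_rng(4)
    n = 120
    y = np.array([0] * 60 + [1] * 60)
    signal = y + 0.4 * rng.normal(size=n)
    X = _frame(np.column_stack([signal, signal + 0.05 * rng.normal(size=n),
                                rng.normal(size=(n, 4))]))
    return X, y


def test_best_family_by_auc_with_forest_tiebreak(signal_data):
    X, y = signal_data
    results = [
        stratified_cv(X, y, ModelSpec(family=f, seed=0), k=5, seed=0)
        for f in ("random_forest", "linear_svm", "l1_logistic")
    ]
    best = select_best_family(results)
    assert best in {"random_forest", "linear_svm", "l1_logistic"}
    top = max(results, key=lambda r: r.auc_mean)
    se = top.auc_sd / np.sqrt(len(top.fold_auc))
    chosen = next(r for r in results if r.family == best)
    # chosen family is within one standard error of the top performer
    assert chosen.auc_mean >= top.auc_mean - se
    # and a clearly dominant family is always selected
    clear = [
        stratified_cv(X[["g0"]], y, ModelSpec(family="l1_logistic", seed=0), k=5, seed=0)
    ]
    assert select_best_family(clear) == "l1_logistic"


def test_duplicated_informative_feature_splits_forest_importance(signal_data):
    X, y = signal_data
    model = build_model(ModelSpec(family="random_forest", seed=0))
    model.fit(X.to_numpy(), y)
    scores = builtin_importance(model, X.columns)
    noise_max = scores[["g2", "g3", "g4", "g5"]].max()
    assert scores["g0"] > noise_max
    assert scores["g1"] > noise_max


def test_single_feature_model_normalizes_to_one(signal_data):
    X, y = signal_data
    spec = ModelSpec(family="l1_logistic", seed=0)
    model = build_model(spec)
    model.fit(X[["g0"]].to_numpy(), y)
    bi = builtin_importance(model, ["g0"])
    pi = permutation_importance(X[["g0"]], y, spec, k=5, repeats=3, seed=0)
    si = shap_importance(model, X[["g0"]])
    table = consensus_ranking(bi, pi, si)
    assert table.loc["g0", "consensus"] == 1.0


def test_permutation_importance_properties(signal_data):
    X, y = signal_data
    X = X.copy()
    X["flat"] = 1.0
    spec = ModelSpec(family="random_forest", seed=0)
    scores = permutation_importance(X, y, spec, k=5, repeats=3, seed=0)
    assert scores["flat"] == 0.0
    assert scores["g0"] > scores[["g2", "g3", "g4", "g5"]].max()
    assert (scores >= 0).all()


def test_sole_predictive_feature_decrease_near_baseline_minus_half(rng):
    n = 200
    y = np.array([0] * 100 + [1] * 100)
    X = _frame(np.column_stack([y + 0.01 * rng.normal(size=n)]))
    spec = ModelSpec(family="l1_logistic", seed=0)
    scores = permutation_importance(X, y, spec, k=5, repeats=10, seed=0)
    # baseline AUC is 1.0; permuting the only feature drops it to ~0.5
    assert scores.iloc[0] == pytest.approx(0.5, abs=0.08)


def test_more_repeats_reduce_estimator_variance(rng):
    n = 80
    y = np.array([0] * 40 + [1] * 40)
    spec = ModelSpec(family="l1_logistic", seed=0)
    single, many = [], []
    for s in range(12):
        X = _frame(
            np.column_stack([y + 0.8 * rng.normal(size=n), rng.normal(size=n)])
        )
        single.append(
            permutation_importance(X, y, spec, k=4, repeats=1, seed=s).iloc[0]
        )
        many.append(
            permutation_importance(X, y, spec, k=4, repeats=10, seed=s).iloc[0]
        )
    assert np.var(many) <= np.var(single)


def test_consensus_identical_rankings_preserved():
    s = pd.Series([3.0, 2.0, 1.0], index=["a", "b", "c"])
    table = consensus_ranking(s, s, s)
    assert list(table.index) == ["a", "b", "c"]
    assert table["consensus"].tolist() == [1.0, 0.5, 0.0]


def test_consensus_symmetric_tie_broken_by_rule():
    idx = ["a", "b", "c"]
    b = pd.Series([1.0, 0.0, 0.0], index=idx)
    p = pd.Series([0.0, 1.0, 0.0], index=idx)
    s = pd.Series([0.0, 0.0, 1.0], index=idx)
    table = consensus_ranking(b, p, s)
    assert np.allclose(table["consensus"], 1 / 3)
    # ties broken by permutation score desc, then gene id
    assert list(table.index) == ["b", "a", "c"]


def test_consensus_invariant_to_affine_rescaling(rng):
    idx = [f"g{i}" for i in range(10)]
    b = pd.Series(rng.uniform(size=10), index=idx)
    p = pd.Series(rng.uniform(size=10), index=idx)
    s = pd.Series(rng.uniform(size=10), index=idx)
    base = consensus_ranking(b, p, s)
    scaled = consensus_ranking(7.0 * b + 3.0, p, 0.1 * s)
    assert list(base.index) == list(scaled.index)
    assert np.allclose(base["consensus"], scaled["consensus"])


def test_consensus_mismatched_features_rejected():
    a = pd.Series([1.0], index=["x"])
    b = pd.Series([1.0], index=["y"])
    with pytest.raises(DataError):
        consensus_ranking(a, a, b)


def test_across_organ_combination_methods():
    t1 = pd.DataFrame(
        {"consensus": [1.0, 0.2], "rank": [1, 2]}, index=["a", "b"]
    )
    t2 = pd.DataFrame(
        {"consensus": [0.4, 0.8], "rank": [2, 1]}, index=["a", "b"]
    )
    mean = consensus_across_organs({"o1": t1, "o2": t2}, method="mean")
    assert mean.loc["a", "consensus"] == pytest.approx(0.7)
    low = consensus_across_organs({"o1": t1, "o2": t2}, method="min")
    assert low.loc["a", "consensus"] == pytest.approx(0.4)
    rm = consensus_across_organs({"o1": t1, "o2": t2}, method="rank-mean")
    assert set(rm.columns) >= {"consensus", "rank"}


def test_sweep_full_count_matches_full_model(signal_data):
    X, y = signal_data
    spec = ModelSpec(family="random_forest", seed=0)
    model = build_model(spec)
    model.fit(X.to_numpy(), y)
    table = consensus_ranking(
        builtin_importance(model, X.columns),
        permutation_importance(X, y, spec, k=5, repeats=3, seed=0),
        shap_importance(model, X),
    )
    sweep = feature_sweep(X, y, table, [1, X.shape[1]], spec, k=5, seed=0)
    full = stratified_cv(X, y, spec, k=5, seed=0)
    assert sweep.iloc[-1]["auc_mean"] == pytest.approx(full.auc_mean, abs=1e-12)
    # a single dominant planted gene already beats chance handily
    assert sweep.iloc[0]["auc_mean"] > 0.8


def test_sweep_grid_validation(signal_data):
    X, y = signal_data
    table = pd.DataFrame(
        {"rank": range(1, X.shape[1] + 1)}, index=X.columns
    )
    spec = ModelSpec(seed=0)
    with pytest.raises(DataError):
        feature_sweep(X, y, table, [3, 2], spec, k=5)
    with pytest.raises(DataError):
        feature_sweep(X, y, table, [0, 2], spec, k=5)
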