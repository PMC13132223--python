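"""Consensus feature importance and the feature-count performance sweep.

Three complementary importance measures are combined: the best-performing
model's built-in scores (impurity importances for forests, |coefficient| on
standardized features for linear families), out-of-fold permutation
importance (mean AUC decrease after permuting each feature within the test
fold), and mean absolute Shapley attributions (exact tree / linear
attribution, see :mod:`organnet._shapley`). Each score vector is min-max
normalized to [0, 1] and the three are averaged into a consensus ranking.
The sweep retrains the classifier on the top-c consensus genes over a grid
of counts c, tracing accuracy/AUC as a function of signature size.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline

from . import _shapley
from .classify import (
    ClassifierResult,
    ModelSpec,
    auc,
    build_model,
    encode_labels,
    model_scores,
    stratified_cv,
)
from .errors import DataError

__all__ = [
    "select_best_family",
    "builtin_importance",
    "permutation_importance",
    "shap_importance",
    "shap_attributions",
    "consensus_ranking",
    "consensus_across_organs",
    "feature_sweep",
]


def select_best_family(results: list[ClassifierResult]) -> str:
    """Family with the highest mean CV AUC, under a one-standard-error rule.

    Families whose mean AUC lies within one standard error of the best are
    treated as tied (with near-saturated AUCs the fold-level resolution
    cannot distinguish them); among tied families the random forest is
    preferred for its richer built-in importances.
    """
    if not results:
        raise DataError("no classifier results to select from")
    best = max(results, key=lambda r: r.auc_mean)
    k = len(best.fold_auc)
    se = best.auc_sd / np.sqrt(k) if k > 1 else 0.0
    tied = [r for r in results if r.auc_mean >= best.auc_mean - se]
    for r in tied:
        if r.family == "random_forest":
            return r.family
    return best.family


def _linear_coef(model) -> np.ndarray:
    final = model[-1] if isinstance(model, Pipeline) else model
    return np.abs(np.asarray(final.coef_, dtype=float).ravel())


def builtin_importance(model, feature_names) -> pd.Series:
    """Model-native raw importance scores for a fitted model."""
    if isinstance(model, Pipeline):
        scores = _linear_coef(model)
    elif hasattr(model, "feature_importances_"):
        scores = np.asarray(model.feature_importances_, dtype=float)
    elif hasattr(model, "coef_"):
        scores = _linear_coef(model)
    else:
        raise DataError("model is not fitted or has no importance accessor")
    return pd.Series(scores, index=list(feature_names), name="builtin")


def permutation_importance(
    X: pd.DataFrame,
    y,
    spec: ModelSpec,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
) -> pd.Series:
    """Out-of-fold permutation importance: mean decrease in test-fold AUC
    after permuting each feature column, averaged over ``repeats``
    permutations and CV folds; negatives floored at 0."""
    y = encode_labels(y)
    Xv = X.to_numpy()
    n_feat = Xv.shape[1]
    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    base = build_model(spec)
    drops = np.zeros(n_feat)
    n_folds = 0
    for train, test in skf.split(np.zeros_like(y)[:, None], y):
        model = clone(base)
        model.fit(Xv[train], y[train])
        Xt, yt = Xv[test], y[test]
        baseline = auc(model_scores(model, Xt), yt)
        # batch all permuted variants into one predict call per repeat
        for _ in range(repeats):
            stack = np.repeat(Xt[None, :, :], n_feat, axis=0)
            for j in range(n_feat):
                stack[j, :, j] = Xt[rng.permutation(Xt.shape[0]), j]
            flat = stack.reshape(n_feat * Xt.shape[0], n_feat)
            scores = model_scores(model, flat).reshape(n_feat, Xt.shape[0])
            for j in range(n_feat):
                drops[j] += baseline - auc(scores[j], yt)
        n_folds += 1
    drops /= n_folds * repeats
    return pd.Series(np.maximum(drops, 0.0), index=list(X.columns), name="permutation")


def shap_attributions(model, X: pd.DataFrame) -> tuple[np.ndarray, float]:
    """Per-sample Shapley attribution matrix and the expected prediction.

    Exact path-dependent tree attribution for forests (explaining the
    class-1 probability); exact linear attribution for linear families
    (explaining the decision function on standardized inputs).
    """
    if hasattr(model, "estimators_"):
        return _shapley.forest_shap(model, X.to_numpy())
    if isinstance(model, Pipeline):
        scaler = model[0]
        final = model[-1]
        Z = scaler.transform(X.to_numpy())
        return _shapley.linear_shap(
            final.coef_, final.intercept_, Z, np.zeros(Z.shape[1])
        )
    if hasattr(model, "coef_"):
        mu = X.to_numpy().mean(axis=0)
        return _shapley.linear_shap(model.coef_, model.intercept_, X.to_numpy(), mu)
    raise DataError("no exact Shapley attribution for this model family")


def shap_importance(model, X: pd.DataFrame) -> pd.Series:
    """Per-feature mean absolute Shapley attribution."""
    phi, _ = shap_attributions(model, X)
    return pd.Series(np.abs(phi).mean(axis=0), index=list(X.columns), name="shap")


def _minmax(scores: pd.Series) -> pd.Series:
    lo, hi = float(scores.min()), float(scores.max())
    if hi == lo:
        # degenerate vector: all-equal positive scores normalize to 1
        # (a single-feature model gets full weight), all-zero to 0
        return pd.Series(np.where(scores > 0, 1.0, 0.0), index=scores.index)
    return (scores - lo) / (hi - lo)


def consensus_ranking(
    builtin: pd.Series, permutation: pd.Series, shap: pd.Series
) -> pd.DataFrame:
    """Min-max normalize the three score vectors and average them.

    Returns a table (gene, builtin, permutation, shap, consensus, rank) with
    rank 1 = most important; ties broken by permutation score then gene id.
    """
    if not (set(builtin.index) == set(permutation.index) == set(shap.index)):
        raise DataError("importance score vectors cover different feature sets")
    genes = list(builtin.index)
    table = pd.DataFrame(
        {
            "builtin": _minmax(builtin.reindex(genes)),
            "permutation": _minmax(permutation.reindex(genes)),
            "shap": _minmax(shap.reindex(genes)),
        },
        index=pd.Index(genes, name="gene_id"),
    )
    table["consensus"] = table[["builtin", "permutation", "shap"]].mean(axis=1)
    order = table.sort_values(
        ["consensus", "permutation", "gene_id"],
        ascending=[False, False, True],
        kind="stable",
    ).index
    table["rank"] = pd.Series(
        np.arange(1, len(order) + 1), index=order
    )
    return table.sort_values("rank")


def consensus_across_organs(
    tables: dict[str, pd.DataFrame], method: str = "mean"
) -> pd.DataFrame:
    """Combine per-organ consensus scores into one prioritized list.

    ``method``: "mean" (default) averages consensus scores across organs,
    "min" takes the weakest organ's score (conservative), "rank-mean"
    averages per-organ ranks (lower = better) and converts back to a score.
    """
    organs = list(tables)
    genes = sorted(set.intersection(*(set(t.index) for t in tables.values())))
    if not genes:
        raise DataError("no shared features across organ importance tables")
    per = pd.DataFrame(
        {o: tables[o].loc[genes, "consensus"] for o in organs}, index=genes
    )
    if method == "mean":
        combined = per.mean(axis=1)
    elif method == "min":
        combined = per.min(axis=1)
    elif method == "rank-mean":
        ranks = pd.DataFrame({o: tables[o].loc[genes, "rank"] for o in organs})
        mean_rank = ranks.mean(axis=1)
        combined = 1.0 - (mean_rank - 1) / max(len(genes) - 1, 1)
    else:
        raise DataError(f"unknown combination method {method!r}")
    out = per.copy()
    out.columns = [f"consensus_{o}" for o in organs]
    out["consensus"] = combined
    out = out.sort_values("consensus", ascending=False, kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    out.index.name = "gene_id"
    return out


def feature_sweep(
    X: pd.DataFrame,
    y,
    ranking: pd.DataFrame,
    grid,
    spec: ModelSpec,
    k: int = 10,
    seed: int = 0,
    cohort: str = "cohort",
) -> pd.DataFrame:
    """Stratified-CV performance on the top-c consensus genes for each count
    c in ``grid`` (strictly increasing, within [1, n_features])."""
    grid = list(grid)
    if any(c2 <= c1 for c1, c2 in zip(grid, grid[1:])):
        raise DataError("feature-count grid must be strictly increasing")
    if grid and (grid[0] < 1 or grid[-1] > X.shape[1]):
        raise DataError("grid counts must lie within [1, n_features]")
    ordered = ranking.sort_values("rank").index.tolist()
    rows = []
    for c in grid:
        # keep X's original column order so the full-grid run is identical
        # to a plain stratified_cv on X
        chosen = set(ordered[:c])
        top = [g for g in X.columns if g in chosen]
        res = stratified_cv(
            X[top], y, spec, k=k, seed=seed, cohort=cohort, feature_set=f"top{c}"
        )
        rows.append(
            (c, res.acc_mean, res.acc_sd, res.auc_mean, res.auc_sd)
        )
    return pd.DataFrame(
        rows, columns=["n_features", "acc_mean", "acc_sd", "auc_mean", "auc_sd"]
    )
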