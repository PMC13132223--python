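"""Module eigengenes and the Welch-based statistical testing layer.

An eigengene is the first principal component of a module's z-scored
expression submatrix: one activity score per sample. Group comparisons use
Welch's t-test and Welch's ANOVA (no equal-variance assumption), with BH
correction across test families. Differential expression between the two
phenotype classes is a per-gene Welch t with BH FDR — a documented surrogate
for moderated-t approaches (no empirical-Bayes variance shrinkage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError
from .network import bh_adjust

__all__ = [
    "EigengeneProfile",
    "TestResult",
    "module_eigengene",
    "welch_t",
    "welch_anova",
    "pairwise_welch",
    "differential_expression",
]


@dataclass
class EigengeneProfile:
    module: str
    scores: pd.Series  # per-sample, zero mean
    variance_explained: float
    orientation_sign: int
    n_genes_used: int


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | tuple[float, float]
    p: float
    groups: tuple[str, ...]
    q: float | None = None


def module_eigengene(expr: pd.DataFrame, module, label: str | None = None) -> EigengeneProfile:
    """First principal component of the z-scored module submatrix.

    ``module`` may be a GeneModule-like object (``members`` attribute) or an
    iterable of gene ids. Genes are z-scored across samples (unbiased sd);
    constant genes are excluded with a warning. The sign is oriented so the
    score correlates non-negatively with the module's mean z-score profile,
    making the eigengene fully deterministic.
    """
    if hasattr(module, "members"):
        genes = sorted(module.members)
        label = label or f"{module.organ}:{module.module_id}"
    else:
        genes = sorted(module)
        label = label or "module"
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise DataError(f"module genes absent from matrix: {missing[:5]}")
    sub = expr.loc[genes]
    if sub.shape[0] < 2 or sub.shape[1] < 3:
        raise DataError("eigengene needs >= 2 genes and >= 3 samples")
    sd = sub.to_numpy().std(axis=1, ddof=1)
    constant = sd == 0
    if constant.all():
        raise DataError("all module genes are constant")
    if constant.any():
        warnings.warn(f"excluding {int(constant.sum())} constant gene(s) from eigengene")
        sub = sub.loc[~constant]
        sd = sd[~constant]
    z = (sub.to_numpy() - sub.to_numpy().mean(axis=1, keepdims=True)) / sd[:, None]
    # samples x genes; columns already centered, so SVD gives the PCA
    mat = z.T
    u, s, _ = np.linalg.svd(mat, full_matrices=False)
    scores = u[:, 0] * s[0]
    variance_explained = float(s[0] ** 2 / np.sum(s**2))
    mean_profile = z.mean(axis=0)
    orient = np.sign(np.dot(scores, mean_profile))
    sign = int(orient) if orient != 0 else 1
    scores = scores * sign
    return EigengeneProfile(
        module=label,
        scores=pd.Series(scores, index=expr.columns, name=label),
        variance_explained=variance_explained,
        orientation_sign=sign,
        n_genes_used=sub.shape[0],
    )


def _check_group(v: np.ndarray, name: str) -> None:
    if v.size < 2:
        raise DataError(f"group {name} needs >= 2 values")


def welch_t(a, b, groups: tuple[str, str] = ("a", "b")) -> TestResult:
    """Welch's two-sample t-test (unequal variances), two-sided.

    With zero variance in both groups: equal means give the t = 0 / p = 1
    convention, unequal means are an error (the statistic is undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_group(a, groups[0])
    _check_group(b, groups[1])
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return TestResult(0.0, float(a.size + b.size - 2), 1.0, tuple(groups))
        raise DataError("zero variance in both groups with unequal means")
    res = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue), tuple(groups))


def welch_anova(groups: dict | list) -> TestResult:
    """Welch's heteroscedastic one-way ANOVA (F* statistic).

    Accepts a dict name -> vector or a list of vectors. Returns the Welch F
    with its (k-1, df2) degrees-of-freedom pair.
    """
    if isinstance(groups, dict):
        names = tuple(groups.keys())
        data = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        data = [np.asarray(v, dtype=float) for v in groups]
        names = tuple(f"g{i}" for i in range(len(data)))
    if len(data) < 2:
        raise DataError("Welch ANOVA needs >= 2 groups")
    for v, name in zip(data, names):
        _check_group(v, name)
        if v.var(ddof=1) == 0:
            raise DataError(f"group {name} has zero variance")
    k = len(data)
    n = np.array([v.size for v in data], dtype=float)
    m = np.array([v.mean() for v in data])
    s2 = np.array([v.var(ddof=1) for v in data])
    w = n / s2
    mw = np.sum(w * m) / np.sum(w)
    a = np.sum(w * (m - mw) ** 2) / (k - 1)
    lam = np.sum((1 - w / np.sum(w)) ** 2 / (n - 1)) / (k**2 - 1)
    f = a / (1 + 2 * lam * (k - 2))
    df1 = k - 1.0
    df2 = 1.0 / (3.0 * lam)
    p = float(sps.f.sf(f, df1, df2))
    return TestResult(float(f), (df1, df2), p, names)


def pairwise_welch(
    groups: dict, reference: str | None = None
) -> list[TestResult]:
    """All pairwise (or each-vs-reference) Welch t-tests with BH q-values."""
    names = list(groups.keys())
    if len(names) < 2:
        raise DataError("need >= 2 groups")
    if reference is not None:
        if reference not in groups:
            raise DataError(f"reference group {reference!r} not present")
        pairs = [(reference, other) for other in names if other != reference]
    else:
        pairs = list(combinations(names, 2))
    results = [welch_t(groups[a], groups[b], groups=(a, b)) for a, b in pairs]
    qvals = bh_adjust([r.p for r in results])
    return [
        TestResult(r.statistic, r.df, r.p, r.groups, q=float(q))
        for r, q in zip(results, qvals)
    ]


def differential_expression(expr: pd.DataFrame, labels) -> pd.DataFrame:
    """Per-gene Welch t between pathological and normal samples.

    ``labels`` maps sample id -> {normal, pathological} (Series or dict).
    log2FC is mean(pathological) - mean(normal), so positive values are
    upregulated in pathological samples. Genes constant in both groups get
    t = 0 / p = 1. Rows sorted by q then descending |log2FC|.
    """
    labels = pd.Series(labels).reindex(expr.columns)
    if labels.isna().any():
        raise DataError("labels missing for some samples")
    classes = set(labels)
    if classes != {"normal", "pathological"}:
        raise DataError(f"need both classes, got {sorted(classes)}")
    norm = expr.loc[:, (labels == "normal").to_numpy()]
    path = expr.loc[:, (labels == "pathological").to_numpy()]
    if norm.shape[1] < 2 or path.shape[1] < 2:
        raise DataError("each class needs >= 2 samples")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = sps.ttest_ind(path.to_numpy(), norm.to_numpy(), axis=1, equal_var=False)
    t = np.array(res.statistic, dtype=float)
    p = np.array(res.pvalue, dtype=float)
    df = np.array(res.df, dtype=float)
    flat = np.isnan(t)  # zero variance in both groups
    t[flat] = 0.0
    p[flat] = 1.0
    df[flat] = norm.shape[1] + path.shape[1] - 2
    log2fc = path.to_numpy().mean(axis=1) - norm.to_numpy().mean(axis=1)
    out = pd.DataFrame(
        {
            "gene_id": expr.index,
            "log2fc": log2fc,
            "t": t,
            "df": df,
            "p": p,
            "q": bh_adjust(p),
        }
    )
    out["abs_fc"] = out["log2fc"].abs()
    out = out.sort_values(["q", "abs_fc"], ascending=[True, False], kind="stable")
    return out.drop(columns="abs_fc").reset_index(drop=True)
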