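"""Binary pathological-vs-normal classification under stratified k-fold CV.

Three model families are supported: a 100-tree random forest, a linear SVM
scored by its signed decision margin, and an L1-regularized logistic
regression with penalty lambda = 0.1 (inverse regularization C = 1/lambda =
10). Features are standardized inside each training fold for the linear
families (no leakage; the forest is scale-invariant). Per-fold accuracy (0.5
probability threshold / margin sign) and rank-based AUC are summarized as
mean +/- sd with 95% CIs of the form mean +/- 1.96 * sd / sqrt(k).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import DataError

__all__ = [
    "FAMILIES",
    "ModelSpec",
    "ClassifierResult",
    "encode_labels",
    "build_model",
    "model_scores",
    "auc",
    "confidence_interval",
    "stratified_cv",
    "external_validate",
]

FAMILIES = ("random_forest", "linear_svm", "l1_logistic")


@dataclass(frozen=True)
class ModelSpec:
    """Family + hyperparameters of one classifier."""

    family: str = "random_forest"
    n_estimators: int = 100
    svm_c: float = 1.0
    lasso_lambda: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise DataError(f"unknown model family {self.family!r}")
        if self.lasso_lambda <= 0:
            raise DataError("lasso_lambda must be > 0")


@dataclass
class ClassifierResult:
    family: str
    cohort: str
    feature_set: str
    n_folds: int
    fold_acc: list[float] = field(default_factory=list)
    fold_auc: list[float] = field(default_factory=list)

    @property
    def acc_mean(self) -> float:
        return float(np.mean(self.fold_acc))

    @property
    def acc_sd(self) -> float:
        return float(np.std(self.fold_acc, ddof=1)) if len(self.fold_acc) > 1 else 0.0

    @property
    def auc_mean(self) -> float:
        return float(np.mean(self.fold_auc))

    @property
    def auc_sd(self) -> float:
        return float(np.std(self.fold_auc, ddof=1)) if len(self.fold_auc) > 1 else 0.0

    @property
    def acc_ci(self) -> tuple[float, float]:
        if len(self.fold_acc) < 2:  # single-evaluation results (validation)
            return (self.acc_mean, self.acc_mean)
        return confidence_interval(self.fold_acc)

    @property
    def auc_ci(self) -> tuple[float, float]:
        if len(self.fold_auc) < 2:
            return (self.auc_mean, self.auc_mean)
        return confidence_interval(self.fold_auc)

    def to_jsonable(self) -> dict:
        return {
            "family": self.family,
            "cohort": self.cohort,
            "feature_set": self.feature_set,
            "n_folds": self.n_folds,
            "fold_acc": self.fold_acc,
            "fold_auc": self.fold_auc,
            "acc_mean": self.acc_mean,
            "acc_sd": self.acc_sd,
            "acc_ci": list(self.acc_ci),
            "auc_mean": self.auc_mean,
            "auc_sd": self.auc_sd,
            "auc_ci": list(self.auc_ci),
        }


def encode_labels(labels) -> np.ndarray:
    """Map {normal, pathological} (or already-binary) labels to {0, 1}."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "ifub":
        y = arr.astype(int)
        if not set(np.unique(y)) <= {0, 1}:
            raise DataError("numeric labels must be binary 0/1")
        return y
    mapping = {"normal": 0, "pathological": 1}
    bad = set(arr) - set(mapping)
    if bad:
        raise DataError(f"unknown labels {sorted(bad)}")
    return np.array([mapping[v] for v in arr], dtype=int)


def build_model(spec: ModelSpec):
    """Instantiate the sklearn estimator for a ModelSpec."""
    if spec.family == "random_forest":
        return RandomForestClassifier(
            n_estimators=spec.n_estimators, random_state=spec.seed
        )
    if spec.family == "linear_svm":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("svm", SVC(kernel="linear", C=spec.svm_c, random_state=spec.seed)),
            ]
        )
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "logreg",
                LogisticRegression(
                    l1_ratio=1,  # pure L1 (lasso) penalty
                    C=1.0 / spec.lasso_lambda,
                    solver="liblinear",
                    random_state=spec.seed,
                ),
            ),
        ]
    )


def model_scores(model, X) -> np.ndarray:
    """Continuous scores for AUC: class-1 probability, or the signed margin
    for margin classifiers without probabilities."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def auc(scores, y) -> float:
    """Rank-based (Mann-Whitney) AUC; ties count 0.5.

    Computed by exact pairwise concordance counting, so it equals the
    brute-force definition to the last bit.
    """
    scores = np.asarray(scores, dtype=float)
    y = encode_labels(y)
    pos = scores[y == 1]
    neg = scores[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise DataError("AUC undefined: only one class present")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (pos.size * neg.size))


def confidence_interval(fold_values) -> tuple[float, float]:
    """mean +/- 1.96 * sd / sqrt(k), clipped to [0, 1]."""
    v = np.asarray(fold_values, dtype=float)
    if v.size < 2:
        raise DataError("confidence interval needs >= 2 fold values")
    mean = v.mean()
    se = v.std(ddof=1) / np.sqrt(v.size)
    return (float(max(0.0, mean - 1.96 * se)), float(min(1.0, mean + 1.96 * se)))


def stratified_cv(
    X: pd.DataFrame,
    y,
    spec: ModelSpec,
    k: int = 10,
    seed: int | None = None,
    cohort: str = "cohort",
    feature_set: str = "features",
) -> ClassifierResult:
    """Stratified k-fold cross-validation of one model family.

    Folds preserve class proportions and depend only on (y, seed). A test
    fold that ends up single-class (cannot happen when both classes have
    >= k members, which is enforced) would be skipped with a warning.
    """
    y = encode_labels(y)
    seed = spec.seed if seed is None else seed
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise DataError(
            f"class with {counts.min()} samples < k={k}; use a smaller k"
        )
    Xv = X.to_numpy() if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    result = ClassifierResult(spec.family, cohort, feature_set, k)
    base = build_model(spec)
    for train, test in skf.split(np.zeros_like(y)[:, None], y):
        if len(set(y[test])) < 2:
            warnings.warn("single-class test fold skipped")
            continue
        model = clone(base)
        model.fit(Xv[train], y[train])
        pred = model.predict(Xv[test])
        result.fold_acc.append(float(np.mean(pred == y[test])))
        result.fold_auc.append(auc(model_scores(model, Xv[test]), y[test]))
    return result


def external_validate(
    X_train: pd.DataFrame,
    y_train,
    X_val: pd.DataFrame,
    y_val,
    spec: ModelSpec,
    cohort: str = "validation",
    feature_set: str = "features",
    max_missing: float = 0.2,
) -> ClassifierResult:
    """Train on the pooled discovery cohorts, score a held-out cohort once.

    Validation features are aligned by gene id; genes absent from the
    validation matrix are imputed as the training-set mean (warned), but an
    error is raised when more than ``max_missing`` of the signature is
    missing. No cross-validation: single ACC/AUC.
    """
    y_tr = encode_labels(y_train)
    y_va = encode_labels(y_val)
    if len(set(y_va)) < 2:
        raise DataError("validation cohort has a single class")
    genes = list(X_train.columns)
    missing = [g for g in genes if g not in X_val.columns]
    if len(missing) > max_missing * len(genes):
        raise DataError(
            f"{len(missing)}/{len(genes)} signature genes missing from validation"
        )
    Xv = pd.DataFrame(index=X_val.index, columns=genes, dtype=float)
    present = [g for g in genes if g in X_val.columns]
    Xv[present] = X_val[present]
    if missing:
        warnings.warn(f"imputing {len(missing)} missing gene(s) with training means")
        for g in missing:
            Xv[g] = float(X_train[g].mean())
    model = build_model(spec)
    model.fit(X_train.to_numpy(), y_tr)
    pred = model.predict(Xv.to_numpy())
    result = ClassifierResult(spec.family, cohort, feature_set, 1)
    result.fold_acc.append(float(np.mean(pred == y_va)))
    result.fold_auc.append(auc(model_scores(model, Xv.to_numpy()), y_va))
    return result
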