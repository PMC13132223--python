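"""Two-stage gene filtering on a log2 expression matrix.

Stage 1 removes genes with low mean intensity (below a configurable quantile
of the gene-mean distribution); stage 2 retains the top fraction of the
remaining genes by sample variance. The composition order matters and is
fixed: expression filter, then variance filter. Both filters are blind to
sample class labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["FilterReport", "filter_low_expression", "filter_top_variance", "preprocess"]


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_after_expression_filter: int
    n_after_variance_filter: int
    mean_quantile: float | None
    mean_threshold: float | None
    variance_fraction: float | None

    def to_jsonable(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_after_expression_filter": self.n_after_expression_filter,
            "n_after_variance_filter": self.n_after_variance_filter,
            "mean_quantile": self.mean_quantile,
            "mean_threshold": self.mean_threshold,
            "variance_fraction": self.variance_fraction,
        }


def filter_low_expression(
    expr: pd.DataFrame, quantile: float = 0.25
) -> tuple[pd.DataFrame, FilterReport]:
    """Drop genes whose mean is strictly below the given quantile of gene means.

    The threshold is the linear-interpolation quantile of the per-gene mean
    distribution (numpy default rule). Survivor order is preserved. With
    ``quantile=0`` no gene is removed; ties at the threshold are retained.
    """
    if expr.shape[0] == 0 or expr.shape[1] == 0:
        raise DataError("empty expression matrix")
    if not 0.0 <= quantile < 1.0:
        raise DataError("quantile must satisfy 0 <= quantile < 1")
    means = expr.to_numpy().mean(axis=1)
    threshold = float(np.quantile(means, quantile))
    keep = means >= threshold
    if not keep.any():
        raise DataError("low-expression filter removed every gene")
    out = expr.loc[keep]
    report = FilterReport(
        n_input=expr.shape[0],
        n_after_expression_filter=int(keep.sum()),
        n_after_variance_filter=int(keep.sum()),
        mean_quantile=quantile,
        mean_threshold=threshold,
        variance_fraction=None,
    )
    return out, report


def filter_top_variance(
    expr: pd.DataFrame, fraction: float = 0.25
) -> tuple[pd.DataFrame, FilterReport]:
    """Retain the ``ceil(fraction * n_genes)`` genes with largest variance.

    Variance is the unbiased (n-1) sample variance. Ties are broken by input
    order (earlier gene wins); survivor order is preserved.
    """
    if expr.shape[0] == 0 or expr.shape[1] == 0:
        raise DataError("empty expression matrix")
    if not 0.0 < fraction <= 1.0:
        raise DataError("fraction must satisfy 0 < fraction <= 1")
    variances = expr.to_numpy().var(axis=1, ddof=1)
    k = ceil(fraction * expr.shape[0])
    # stable sort on -var: equal variances keep input order
    top = np.sort(np.argsort(-variances, kind="stable")[:k])
    out = expr.iloc[top]
    report = FilterReport(
        n_input=expr.shape[0],
        n_after_expression_filter=expr.shape[0],
        n_after_variance_filter=k,
        mean_quantile=None,
        mean_threshold=None,
        variance_fraction=fraction,
    )
    return out, report


def preprocess(
    expr: pd.DataFrame, mean_quantile: float = 0.25, variance_fraction: float = 0.25
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the expression filter then the variance filter."""
    mid, rep1 = filter_low_expression(expr, mean_quantile)
    out, rep2 = filter_top_variance(mid, variance_fraction)
    report = FilterReport(
        n_input=rep1.n_input,
        n_after_expression_filter=rep1.n_after_expression_filter,
        n_after_variance_filter=rep2.n_after_variance_filter,
        mean_quantile=mean_quantile,
        mean_threshold=rep1.mean_threshold,
        variance_fraction=variance_fraction,
    )
    return out, report
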