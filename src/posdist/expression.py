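"""Expressed-gene filter, upper-quartile normalization and co-expression.

A gene counts as expressed when its raw RPKM exceeds 1 in at least two
samples (strict inequality).  Each sample is then rescaled by the 75th
percentile of its expressed-gene values (linear interpolation), times the
across-sample mean of those percentiles so overall magnitudes stay
comparable.  A putative target is co-expressed with its TF when the
Pearson correlation of their normalized profiles over all samples is
strictly above 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CoexpressionCall",
    "filter_expressed",
    "upper_quantile_normalize",
    "coexpression_call",
]


@dataclass(frozen=True)
class CoexpressionCall:
    tf_gene: str
    target_gene: str
    pcc: float  # NaN when either profile has zero variance
    passed: bool


def filter_expressed(
    matrix: pd.DataFrame,
    min_rpkm: float = 1.0,
    min_samples: int = 2,
) -> set[str]:
    """Genes whose raw RPKM is > min_rpkm in at least min_samples samples."""
    counts = (matrix > min_rpkm).sum(axis=1)
    return set(matrix.index[counts >= min_samples])


def upper_quantile_normalize(
    matrix: pd.DataFrame,
    expressed: set[str],
    quantile: float = 75.0,
) -> pd.DataFrame:
    """Per-sample upper-quartile normalization over expressed genes.

    Sample j is divided by the ``quantile``-th percentile of its expressed
    genes' values and multiplied by the mean of those percentiles across
    samples, so that relative profiles change but the overall scale is
    preserved.
    """
    exp_idx = [g for g in matrix.index if g in expressed]
    if not exp_idx:
        raise ValueError("expressed gene set is empty")
    sub = matrix.loc[exp_idx]
    q = np.percentile(sub.to_numpy(), quantile, axis=0)  # linear interpolation
    if (q == 0).any():
        bad = matrix.columns[np.flatnonzero(q == 0)[0]]
        raise ValueError(f"sample {bad!r}: upper quantile of expressed genes is 0")
    return matrix / q * q.mean()


def coexpression_call(
    tf_gene: str,
    target_gene: str,
    matrix: pd.DataFrame,
    threshold: float = 0.8,
    expressed: set[str] | None = None,
) -> CoexpressionCall:
    """Pearson co-expression call between a TF gene and a putative target.

    ``passed`` requires pcc > threshold and, when an expressed set is
    given, both genes in it.  Zero-variance profiles give pcc = NaN and
    never pass.
    """
    for g in (tf_gene, target_gene):
        if g not in matrix.index:
            raise KeyError(f"gene {g!r} not in expression matrix")
    x = matrix.loc[tf_gene].to_numpy(dtype=float)
    y = matrix.loc[target_gene].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        pcc = float("nan")
    else:
        pcc = float(np.corrcoef(x, y)[0, 1])
    both_expressed = (
        True if expressed is None else (tf_gene in expressed and target_gene in expressed)
    )
    passed = bool(np.isfinite(pcc) and pcc > threshold and both_expressed)
    return CoexpressionCall(tf_gene, target_gene, pcc, passed)
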