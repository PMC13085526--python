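"""Normalization and expression filtering applied before any analysis.

Between-lane variation is removed by full-quantile normalization: every
sample (column) is forced onto the common distribution obtained by averaging
the per-rank order statistics across samples. Genes with low maximal
expression (below ``2**5`` by default) are dropped before differential
testing, and genes with a dynamic range (max/min) below 2 are dropped before
correlation analysis, where a flat gene would produce a high but
uninformative correlation coefficient.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .matrix import ExpressionMatrix, MatrixError


def full_quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Full-quantile normalize so every column shares one value multiset.

    Each column's values are replaced by the mean, across columns, of the
    order statistics at the same rank. Ties within a column receive the
    average of their tied ranks' target values, which keeps the procedure
    deterministic and idempotent. The overall matrix mean is preserved.
    """
    if m.scale != "linear":
        raise MatrixError("quantile normalization expects linear-scale values")
    if m.n_samples < 2:
        raise MatrixError("quantile normalization needs >= 2 samples")
    x = m.values.to_numpy(dtype=float)
    target = np.sort(x, axis=0).mean(axis=1)  # per-rank mean distribution
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        order = np.argsort(x[:, j], kind="stable")
        s = x[order, j]
        # tied values receive the mean of their tied ranks' targets
        grp = np.concatenate(([0], np.cumsum(s[1:] != s[:-1])))
        means = np.bincount(grp, weights=target) / np.bincount(grp)
        out[order, j] = means[grp]
    values = m.values.copy()
    values.iloc[:, :] = out
    return replace(m, values=values)


def log2_transform(m: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """``log2(value + offset)``; requires linear input, flags output log2."""
    if m.scale != "linear":
        raise MatrixError("matrix is already log-scaled")
    x = m.values.to_numpy(dtype=float)
    if (x < 0).any():
        raise MatrixError("negative values cannot be log-transformed")
    values = m.values.copy()
    values.iloc[:, :] = np.log2(x + offset)
    return replace(m, values=values, scale="log2")


def filter_low_expression(m: ExpressionMatrix, max_log2_threshold: float = 5.0) -> ExpressionMatrix:
    """Keep genes whose maximum expression reaches the log2 threshold.

    The same number serves shoots and roots: a gene is retained iff its
    maximum over samples is >= ``2**max_log2_threshold`` on the linear scale
    (equivalently >= ``max_log2_threshold`` on the log2 scale).
    """
    mx = m.values.max(axis=1).to_numpy()
    if m.scale == "linear":
        keep = mx >= 2.0 ** max_log2_threshold
    else:
        keep = mx >= max_log2_threshold
    return replace(m, values=m.values.loc[keep])


def dynamic_range_filter(m: ExpressionMatrix, ratio: float = 2.0) -> ExpressionMatrix:
    """Keep genes with max/min >= ratio (a zero min counts as retained).

    On a log2-scale matrix the equivalent criterion max - min >= log2(ratio)
    is applied.
    """
    mx = m.values.max(axis=1).to_numpy()
    mn = m.values.min(axis=1).to_numpy()
    if m.scale == "linear":
        with np.errstate(divide="ignore", invalid="ignore"):
            keep = np.where(mn > 0, mx / np.maximum(mn, 1e-300) >= ratio, mx > 0)
    else:
        keep = (mx - mn) >= np.log2(ratio)
    return replace(m, values=m.values.loc[keep])
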