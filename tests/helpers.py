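"""Shared test utilities and independent brute-force oracles."""

import itertools

import numpy as np
import pandas as pd

from sepsispatterns import ExpressionMatrix


def make_expression(arr, tag="raw_tpm", genes=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"G{i + 1}" for i in range(arr.shape[0])]
    samples = samples or [f"S{j + 1}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples),
                            transform_tag=tag)


def ks_statistic(x, y):
    """sup |ECDF_x - ECDF_y| by direct evaluation at all pooled points."""
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / len(x)
    cdf_y = np.searchsorted(y, pooled, side="right") / len(y)
    return np.abs(cdf_x - cdf_y).max()


def ks_exact_p_enumeration(x, y):
    """Exact two-sided KS p-value by exhausting all C(n+m, n) assignments
    of the pooled values to the two samples (distinct values assumed)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n = len(x)
    d_obs = ks_statistic(x, y)
    total = 0
    extreme = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        total += 1
        xa = pooled[list(idx)]
        ya = np.delete(pooled, list(idx))
        if ks_statistic(xa, ya) >= d_obs - 1e-12:
            extreme += 1
    return extreme / total


def spearman_rho_definition(x, y):
    """Spearman rho by the definitional Pearson correlation of ranks."""
    from scipy.stats import rankdata

    rx = rankdata(x)
    ry = rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))
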