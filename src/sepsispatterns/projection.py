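"""Latent-space projection of external expression data.

Given a fixed amplitude matrix ``A`` learned from a source cohort, an
external (bulk or single-cell) log2 expression matrix is mapped into the
source latent space by solving, over the shared genes, an independent
least-squares problem per target column::

    min_w || d_shared - A_shared @ w ||^2        (ols; minimum-norm if
                                                  rank-deficient)
    min_{w >= 0} || d_shared - A_shared @ w ||^2 (nnls)

No intercept and no target re-centring by default: amplitudes and log2
abundances share a non-negative scale. Optional per-gene centring is
available for targets on a different baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls as _nnls

from .containers import ExpressionMatrix
from .factorization import PCAResult


class ProjectionError(ValueError):
    pass


@dataclass
class ProjectionResult:
    """Pattern weights for target samples/cells over the shared-gene space."""

    weights: pd.DataFrame  # K x target samples
    method_tag: str
    n_shared_genes: int
    shared_fraction: float
    target_ids: pd.Index

    def to_frame(self) -> pd.DataFrame:
        return self.weights


def intersect_genes(A: pd.DataFrame, target: ExpressionMatrix
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Row indices into ``A`` and ``target`` for the exact-match gene
    intersection, ordered by the source (A) gene order."""
    target_pos = {g: i for i, g in enumerate(target.gene_ids)}
    a_idx, t_idx = [], []
    for i, g in enumerate(A.index):
        j = target_pos.get(g)
        if j is not None:
            a_idx.append(i)
            t_idx.append(j)
    if not a_idx:
        raise ProjectionError("no genes shared between source A and target")
    return np.asarray(a_idx), np.asarray(t_idx)


def project_samples(
    A: pd.DataFrame,
    target: ExpressionMatrix,
    method: str = "ols",
    min_shared_fraction: float = 0.5,
    allow_low_overlap: bool = False,
    center_genes: bool = False,
) -> ProjectionResult:
    """Solve per-column pattern weights for a target dataset.

    Parameters
    ----------
    A : genes x K amplitude matrix (DataFrame with gene index).
    target : log2-scale expression matrix to project.
    method : "ols" (minimum-norm least squares) or "nnls".
    min_shared_fraction : minimum fraction of source genes that must be
        found in the target; below it the call fails unless
        ``allow_low_overlap=True`` (then it warns and proceeds).
    center_genes : subtract the shared-gene target means before solving.
    """
    if method not in ("ols", "nnls"):
        raise ProjectionError(f"unknown projection method {method!r}")
    a_idx, t_idx = intersect_genes(A, target)
    shared_fraction = len(a_idx) / A.shape[0]
    if shared_fraction < min_shared_fraction:
        msg = (f"only {len(a_idx)}/{A.shape[0]} source genes "
               f"({shared_fraction:.1%}) found in target")
        if not allow_low_overlap:
            raise ProjectionError(msg + "; pass allow_low_overlap=True to proceed")
        warnings.warn(msg)

    A_shared = A.to_numpy(dtype=float)[a_idx]
    T = target.to_numpy()[t_idx]
    if center_genes:
        T = T - T.mean(axis=1, keepdims=True)

    K = A.shape[1]
    if method == "ols":
        rank = np.linalg.matrix_rank(A_shared)
        if rank < K:
            warnings.warn(
                f"shared amplitude matrix is rank-deficient (rank {rank} < K={K}); "
                "returning minimum-norm solution")
        W, *_ = np.linalg.lstsq(A_shared, T, rcond=None)
    else:
        W = np.empty((K, T.shape[1]))
        for j in range(T.shape[1]):
            W[:, j], _ = _nnls(A_shared, T[:, j])
    weights = pd.DataFrame(W, index=A.columns, columns=target.sample_ids)
    return ProjectionResult(
        weights=weights, method_tag=method,
        n_shared_genes=len(a_idx), shared_fraction=shared_fraction,
        target_ids=target.sample_ids,
    )


def project_onto_pcs(pca: PCAResult, target: ExpressionMatrix) -> pd.DataFrame:
    """Scores of target samples on source principal components.

    Target columns are centred with the stored source gene means
    (restricted to shared genes) and multiplied by the source loadings.
    """
    shared = [g for g in pca.loadings.index if g in set(target.gene_ids)]
    if not shared:
        raise ProjectionError("no genes shared between PCA source and target")
    L = pca.loadings.loc[shared].to_numpy()
    mu = pca.gene_means.loc[shared].to_numpy()
    T = target.values.loc[shared].to_numpy(dtype=float)
    scores = (T - mu[:, None]).T @ L
    return pd.DataFrame(scores, index=target.sample_ids,
                        columns=pca.loadings.columns)
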