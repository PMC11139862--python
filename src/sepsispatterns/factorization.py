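"""Non-negative matrix factorization of expression and the PCA recovery axis.

The decomposition contract is ``D ~ A @ P`` with ``D`` the log2 TPM matrix
(genes x samples), ``A`` the non-negative amplitude matrix (genes x K) and
``P`` the non-negative pattern matrix (K x samples). Each pattern is a
latent expression program; ``A`` says how strongly each gene participates
and ``P`` how strongly each sample expresses it.

The solver is deterministic L1-penalised multiplicative-update NMF with
random restarts, minimising::

    ||D - A P||_F^2 + lambda_A * sum|A| + lambda_P * sum|P|

This trades the posterior machinery of sparse Bayesian NMF samplers for a
reproducible desk-scale optimiser with the same D ~ A.P contract and the
same sparsity intent. :class:`PatternNMF` is the model object;
:meth:`PatternNMF.fit` returns a :class:`PatternNMFResults` carrying A, P,
the per-iteration loss trace and diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

_EPS = 1e-12


class FactorizationError(ValueError):
    pass


def log_transform(D: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(TPM + pseudocount) transform of a raw-TPM matrix.

    Raises if the matrix is already log-transformed or contains negative
    values; the returned matrix carries ``transform_tag="log2_tpm"``.
    """
    if D.transform_tag != "raw_tpm":
        raise FactorizationError(
            f"expected raw_tpm input, got transform_tag={D.transform_tag!r}")
    if pseudocount <= 0:
        raise FactorizationError("pseudocount must be positive")
    arr = D.to_numpy()
    if arr.size and arr.min() < 0:
        raise FactorizationError("negative TPM value in input")
    out = pd.DataFrame(np.log2(arr + pseudocount),
                       index=D.gene_ids, columns=D.sample_ids)
    return ExpressionMatrix(out, transform_tag="log2_tpm")


def filter_genes(D: ExpressionMatrix, min_detected_fraction: float = 0.05
                 ) -> ExpressionMatrix:
    """Drop genes with zero variance or detected (value > 0) in fewer than
    ``min_detected_fraction`` of samples; guards the multiplicative updates
    against degenerate all-zero rows."""
    arr = D.to_numpy()
    detected = (arr > 0).mean(axis=1) >= min_detected_fraction
    varying = arr.var(axis=1) > 0
    keep = detected & varying
    return ExpressionMatrix(D.values.loc[keep], transform_tag=D.transform_tag)


def _objective(D: np.ndarray, A: np.ndarray, P: np.ndarray,
               lam_A: float, lam_P: float) -> float:
    R = D - A @ P
    return float(np.sum(R * R) + lam_A * A.sum() + lam_P * P.sum())


def _mu_fit(D: np.ndarray, K: int, lam_A: float, lam_P: float,
            seed: int, tol: float, max_iter: int) -> tuple[np.ndarray, np.ndarray, list[float], bool]:
    """One multiplicative-update run from a random start."""
    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(D.mean(), _EPS) / K)
    # uniform (0, 1] starts scaled to the data magnitude
    A = (1.0 - rng.random((D.shape[0], K))) * scale
    P = (1.0 - rng.random((K, D.shape[1]))) * scale
    trace = [_objective(D, A, P, lam_A, lam_P)]
    converged = False
    for _ in range(max_iter):
        # L1-penalised multiplicative updates (penalty enters the denominator)
        AtD = A.T @ D
        P *= AtD / (A.T @ A @ P + 0.5 * lam_P + _EPS)
        DPt = D @ P.T
        A *= DPt / (A @ (P @ P.T) + 0.5 * lam_A + _EPS)
        obj = _objective(D, A, P, lam_A, lam_P)
        prev = trace[-1]
        trace.append(obj)
        if prev - obj <= tol * max(prev, _EPS):
            converged = True
            break
    return A, P, trace, converged


@dataclass
class PatternNMFResults:
    """Fitted amplitude/pattern decomposition.

    Attributes
    ----------
    A : DataFrame, genes x K, non-negative amplitudes.
    P : DataFrame, K x samples, non-negative pattern values; each row is
        rescaled to unit maximum with the inverse scale folded into A, so
        ``A @ P`` is unchanged.
    loss_trace : per-iteration penalised Frobenius objective of the winning
        restart (non-increasing).
    """

    model: "PatternNMF"
    A: pd.DataFrame
    P: pd.DataFrame
    K: int
    loss_trace: np.ndarray
    converged: bool
    seed: int
    sparsity_weights: tuple[float, float]
    n_iterations: int
    restart_objectives: list[float] = field(default_factory=list)

    @property
    def pattern_names(self) -> pd.Index:
        return self.P.index

    def reconstruction_error(self, D: ExpressionMatrix | None = None) -> float:
        """Relative Frobenius error ``||D - A P||_F / ||D||_F``."""
        D = D if D is not None else self.model.D
        if D.shape != (self.A.shape[0], self.P.shape[1]):
            raise FactorizationError(
                f"shape mismatch: D is {D.shape}, factorization is "
                f"{(self.A.shape[0], self.P.shape[1])}")
        Dm = D.to_numpy()
        denom = np.linalg.norm(Dm)
        if denom == 0:
            return 0.0
        return float(np.linalg.norm(Dm - self.A.to_numpy() @ self.P.to_numpy())
                     / denom)

    def rank_genes(self, pattern_index: int) -> pd.DataFrame:
        """Genes ordered by descending amplitude in pattern ``pattern_index``
        (1-based). Ties break lexicographically on gene id; rank 1 is the
        highest amplitude. Returns columns (gene, rank, amplitude)."""
        if not 1 <= pattern_index <= self.K:
            raise FactorizationError(
                f"pattern_index {pattern_index} outside 1..{self.K}")
        col = self.A.iloc[:, pattern_index - 1]
        order = sorted(zip(-col.to_numpy(dtype=float), col.index))
        genes = [g for _, g in order]
        amps = [-v for v, _ in order]
        return pd.DataFrame({
            "gene": genes,
            "rank": np.arange(1, len(genes) + 1),
            "amplitude": amps,
        })

    def project(self, target: ExpressionMatrix, method: str = "ols", **kw):
        """Project an external dataset into this latent space; see
        :func:`sepsispatterns.projection.project_samples`."""
        from .projection import project_samples
        return project_samples(self.A, target, method=method, **kw)

    def summary(self) -> str:
        lines = [
            "Pattern NMF (L1-penalised multiplicative updates)",
            "=" * 49,
            f"genes: {self.A.shape[0]}   samples: {self.P.shape[1]}   K: {self.K}",
            f"lambda_A: {self.sparsity_weights[0]:.6g}   "
            f"lambda_P: {self.sparsity_weights[1]:.6g}",
            f"seed: {self.seed}   restarts: {len(self.restart_objectives)}",
            f"iterations (best restart): {self.n_iterations}   "
            f"converged: {self.converged}",
            f"final objective: {self.loss_trace[-1]:.6g}",
            f"relative reconstruction error: {self.reconstruction_error():.4f}",
        ]
        return "\n".join(lines)


class PatternNMF:
    """Non-negative factorization model for a log2 expression matrix.

    Parameters
    ----------
    D : ExpressionMatrix
        log2-transformed genes x samples matrix (non-negative).
    K : int, default 30
        Number of latent patterns (the study configuration used 30).
    sparsity : (float, float) or None
        (lambda_A, lambda_P) L1 weights; default ``0.01 * mean(D)`` each.
    """

    def __init__(self, D: ExpressionMatrix, K: int = 30,
                 sparsity: tuple[float, float] | None = None,
                 tol: float = 1e-5, max_iter: int = 2000,
                 n_restarts: int = 5):
        arr = D.to_numpy()
        if arr.size and arr.min() < 0:
            raise FactorizationError("D must be non-negative for NMF")
        if not 1 <= K <= min(arr.shape):
            raise FactorizationError(
                f"K={K} outside [1, min(genes, samples)={min(arr.shape)}]")
        self.D = D
        self.K = K
        if sparsity is None:
            lam = 0.01 * float(arr.mean())
            sparsity = (lam, lam)
        self.sparsity = (float(sparsity[0]), float(sparsity[1]))
        self.tol = tol
        self.max_iter = max_iter
        self.n_restarts = n_restarts

    def fit(self, seed: int = 0) -> PatternNMFResults:
        """Run ``n_restarts`` multiplicative-update fits (restart ``r`` uses
        seed ``seed + r``) and keep the one with the lowest final objective."""
        D = self.D.to_numpy()
        lam_A, lam_P = self.sparsity
        best = None
        objectives = []
        for r in range(self.n_restarts):
            A, P, trace, conv = _mu_fit(
                D, self.K, lam_A, lam_P, seed + r, self.tol, self.max_iter)
            objectives.append(trace[-1])
            if best is None or trace[-1] < best[2][-1]:
                best = (A, P, trace, conv)
        A, P, trace, conv = best

        # identifiability: unit-maximum pattern rows, scale folded into A
        row_max = P.max(axis=1)
        scale = np.where(row_max > 0, row_max, 1.0)
        P = P / scale[:, None]
        A = A * scale[None, :]

        names = [f"pattern_{k + 1}" for k in range(self.K)]
        return PatternNMFResults(
            model=self,
            A=pd.DataFrame(A, index=self.D.gene_ids, columns=names),
            P=pd.DataFrame(P, index=names, columns=self.D.sample_ids),
            K=self.K,
            loss_trace=np.asarray(trace),
            converged=conv,
            seed=seed,
            sparsity_weights=self.sparsity,
            n_iterations=len(trace) - 1,
            restart_objectives=objectives,
        )


def fit_nmf(D: ExpressionMatrix, K: int, sparsity=None, seed: int = 0,
            tol: float = 1e-5, max_iter: int = 2000,
            n_restarts: int = 5) -> PatternNMFResults:
    """Functional wrapper over :class:`PatternNMF`."""
    return PatternNMF(D, K=K, sparsity=sparsity, tol=tol,
                      max_iter=max_iter, n_restarts=n_restarts).fit(seed=seed)


def reconstruction_error(result: PatternNMFResults, D: ExpressionMatrix) -> float:
    return result.reconstruction_error(D)


def rank_genes_by_amplitude(result: PatternNMFResults, pattern_index: int) -> pd.DataFrame:
    return result.rank_genes(pattern_index)


@dataclass
class PCAResult:
    """Gene-centred PCA of a log2 expression matrix (prcomp-like).

    ``loadings`` (genes x components) are orthonormal right singular
    vectors of the centred data with sign fixed so the largest-magnitude
    loading entry of each component is positive; ``scores`` = centred
    data^T @ loadings (samples x components).
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    explained_variance_fraction: np.ndarray
    gene_means: pd.Series


def run_pca(D: ExpressionMatrix, n_components: int = 2) -> PCAResult:
    """SVD-based PCA treating samples as observations and genes as centred
    variables (no unit-variance scaling)."""
    arr = D.to_numpy()
    n_genes, n_samples = arr.shape
    if n_components > min(n_genes, n_samples):
        raise FactorizationError(
            f"n_components={n_components} exceeds min(genes, samples)")
    gene_means = arr.mean(axis=1)
    X = (arr - gene_means[:, None]).T  # samples x genes
    total_var = np.sum(X * X) / max(n_samples - 1, 1)
    if total_var == 0:
        warnings.warn("constant expression matrix: zero variance; "
                      "returning zero scores")
        load = np.zeros((n_genes, n_components))
        load[:n_components, :n_components] = np.eye(n_components)
        return PCAResult(
            loadings=pd.DataFrame(load, index=D.gene_ids,
                                  columns=[f"PC{i+1}" for i in range(n_components)]),
            scores=pd.DataFrame(np.zeros((n_samples, n_components)),
                                index=D.sample_ids,
                                columns=[f"PC{i+1}" for i in range(n_components)]),
            explained_variance_fraction=np.zeros(n_components),
            gene_means=pd.Series(gene_means, index=D.gene_ids),
        )
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    load = Vt[:n_components].T  # genes x components
    # sign convention: largest-|loading| entry positive
    for j in range(load.shape[1]):
        i = np.argmax(np.abs(load[:, j]))
        if load[i, j] < 0:
            load[:, j] = -load[:, j]
    scores = X @ load
    var = (s[:n_components] ** 2) / max(n_samples - 1, 1)
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        loadings=pd.DataFrame(load, index=D.gene_ids, columns=cols),
        scores=pd.DataFrame(scores, index=D.sample_ids, columns=cols),
        explained_variance_fraction=var / total_var,
        gene_means=pd.Series(gene_means, index=D.gene_ids),
    )


def greedy_match_cosine(P_recovered: pd.DataFrame | np.ndarray,
                        P_true: pd.DataFrame | np.ndarray
                        ) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Greedy 1:1 matching of recovered pattern rows to true rows on the
    cosine-similarity matrix.

    Repeatedly takes the highest remaining cosine pair until every true row
    is matched. Returns the (recovered_index, true_index) pairs and the
    matched cosines, ordered by true row index.
    """
    R = np.asarray(P_recovered, dtype=float)
    T = np.asarray(P_true, dtype=float)
    rn = np.linalg.norm(R, axis=1)
    tn = np.linalg.norm(T, axis=1)
    rn[rn == 0] = 1.0
    tn[tn == 0] = 1.0
    C = (R / rn[:, None]) @ (T / tn[:, None]).T
    pairs: dict[int, tuple[int, float]] = {}
    used_r: set[int] = set()
    used_t: set[int] = set()
    order = np.dstack(np.unravel_index(np.argsort(-C, axis=None), C.shape))[0]
    for i, j in order:
        if i in used_r or j in used_t:
            continue
        used_r.add(int(i))
        used_t.add(int(j))
        pairs[int(j)] = (int(i), float(C[i, j]))
        if len(used_t) == min(C.shape):
            break
    matched = sorted(pairs.items())
    return ([(ri, tj) for tj, (ri, _) in matched],
            np.asarray([c for _, (_, c) in matched]))
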