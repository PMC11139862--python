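"""Permutation and rank-based enrichment tests.

Four null models:

* group-mean permutation — is the mean projected pattern value of one cell
  type higher than expected under random relabelling (group sizes fixed)?
* cumulative/summed rank of a gene set within an amplitude ranking (low sum
  = the set sits at the top of the pattern);
* a background distribution of summed ranks built by drawing ``set_size``
  distinct ranks uniformly, many iterations per pattern;
* exact two-sample two-sided Kolmogorov-Smirnov comparison of rank samples.

All permutation p-values use the add-one estimator ``(r + 1)/(n + 1)``, so
the smallest attainable p is ``1/(n_perm + 1)`` and zero never occurs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import comb

from .containers import GeneSet


class EnrichmentError(ValueError):
    pass


@dataclass
class EnrichmentResult:
    observed: float
    null_mean: float
    null_sd: float
    n_draws: int
    p_value: float
    estimator_tag: str
    seed: int | None = None


def group_mean_permutation_test(
    values,
    labels,
    target_group,
    n_perm: int = 9999,
    seed: int = 0,
    alternative: str = "greater",
) -> EnrichmentResult:
    """Permutation test of one group's mean against relabelled group means.

    ``values`` are per-cell projected pattern values and ``labels`` their
    cell types. The observed statistic is the mean value within
    ``target_group``; the null draws group-size-preserving permutations of
    the labels and records the mean of the cells assigned to the target
    group. p = (r + 1)/(n_perm + 1) with r the count of null means at least
    as extreme as observed.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise EnrichmentError("values and labels differ in length")
    mask = labels == target_group
    g = int(mask.sum())
    if g == 0:
        raise EnrichmentError(f"group {target_group!r} has no members")
    if alternative not in ("greater", "less", "two-sided"):
        raise EnrichmentError(f"unknown alternative {alternative!r}")
    observed = float(values[mask].mean())
    n = len(values)
    n_exact = comb(n, g, exact=True)
    if n_exact <= n_perm:
        # full enumeration of the group assignments; observed is one of them
        null = np.array([values[list(sub)].mean()
                         for sub in itertools.combinations(range(n), g)])
        exact = True
    else:
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        for i in range(n_perm):
            null[i] = values[rng.choice(n, size=g, replace=False)].mean()
        exact = False
    if alternative == "greater":
        r = int((null >= observed).sum())
    elif alternative == "less":
        r = int((null <= observed).sum())
    else:
        centre = null.mean()
        r = int((np.abs(null - centre) >= abs(observed - centre)).sum())
    # exhaustive null already contains the observed assignment, so r/n is a
    # valid p; Monte Carlo uses the add-one estimator
    p = r / len(null) if exact else (r + 1) / (n_perm + 1)
    return EnrichmentResult(
        observed=observed, null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if len(null) > 1 else 0.0,
        n_draws=len(null), p_value=p,
        estimator_tag=("group_mean_exact_" if exact else
                       "group_mean_permutation_") + alternative,
        seed=seed)


def cumulative_rank_statistic(
    ranked_genes: pd.DataFrame,
    gene_set: GeneSet,
) -> tuple[int, pd.Series, list[str]]:
    """Summed rank of a gene set's members within an amplitude ranking.

    ``ranked_genes`` is the (gene, rank, amplitude) table from the
    factorization ranking. Returns (summed rank of the present members,
    per-gene ranks, absent gene names). A low sum means the set concentrates
    at the top of the pattern.
    """
    rank_of = pd.Series(ranked_genes["rank"].to_numpy(),
                        index=ranked_genes["gene"].to_numpy())
    present = [g for g in gene_set.genes if g in rank_of.index]
    absent = [g for g in gene_set.genes if g not in rank_of.index]
    if not present:
        raise EnrichmentError(
            f"no gene of set {gene_set.name!r} present in the ranking")
    ranks = rank_of.loc[present]
    return int(ranks.sum()), ranks, absent


@dataclass
class BackgroundRankModel:
    """Null distribution of summed ranks from random same-size draws."""

    sums: np.ndarray          # (n_patterns, iterations) summed ranks
    mean_sum: float           # grand mean of the draw sums
    mean_rank: float          # grand mean of individual sampled ranks
    set_size: int
    n_genes: int

    def percentile_of(self, value: float) -> float:
        """Fraction of background sums <= value."""
        return float((self.sums.ravel() <= value).mean())


def background_rank_model(
    n_genes: int,
    set_size: int = 20,
    iterations: int = 10_000,
    n_patterns: int = 30,
    seed: int = 0,
) -> BackgroundRankModel:
    """Background of summed ranks: per pattern, ``iterations`` draws of
    ``set_size`` distinct ranks uniform on 1..n_genes.

    When the draw is sparse relative to the rank universe the draws are
    rejection-sampled in vectorised blocks (rows with duplicate ranks are
    redrawn — exactly uniform over distinct-rank sets); dense draws fall
    back to chunked partial permutations.
    """
    if set_size <= 0:
        raise EnrichmentError("set_size must be positive")
    if set_size > n_genes:
        raise EnrichmentError(
            f"set_size={set_size} exceeds n_genes={n_genes}")
    rng = np.random.default_rng(seed)
    total = iterations * n_patterns
    # acceptance probability of an all-distinct row ~ exp(-k(k-1)/2n)
    dense = set_size * (set_size - 1) > n_genes
    if dense:
        chunk = max(1, min(total, 50_000_000 // max(n_genes, 1)))
        parts = []
        done = 0
        while done < total:
            m = min(chunk, total - done)
            keys = rng.random((m, n_genes))
            idx = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
            parts.append(idx + 1)
            done += m
        draws = np.concatenate(parts, axis=0)
    else:
        draws = rng.integers(1, n_genes + 1, size=(total, set_size))
        if set_size > 1:
            while True:
                srt = np.sort(draws, axis=1)
                bad = (np.diff(srt, axis=1) == 0).any(axis=1)
                if not bad.any():
                    break
                draws[bad] = rng.integers(1, n_genes + 1,
                                          size=(int(bad.sum()), set_size))
    sums = draws.sum(axis=1).reshape(n_patterns, iterations)
    return BackgroundRankModel(
        sums=sums,
        mean_sum=float(sums.mean()),
        mean_rank=float(draws.mean()),
        set_size=set_size,
        n_genes=n_genes,
    )


def ks_exact_two_sample(x, y) -> tuple[float, float, str]:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    Returns (D, p, method_tag). The p-value is exact (network algorithm)
    when ``n * m <= 10_000``, asymptotic otherwise (tagged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise EnrichmentError("both samples must be non-empty")
    if np.isnan(x).any() or np.isnan(y).any():
        raise EnrichmentError("NaN values in KS input")
    method = "exact" if x.size * y.size <= 10_000 else "asymp"
    res = stats.ks_2samp(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), method


def gene_set_rank_test(
    gene_statistics: pd.Series,
    gene_set: GeneSet,
    n_perm: int = 9999,
    seed: int = 0,
) -> EnrichmentResult:
    """Mean-rank gene-set test against random same-size draws.

    Genes are ranked by ``gene_statistics`` (descending, average ranks for
    ties; rank 1 = largest statistic). Observed = mean rank of the set's
    present genes; null = mean ranks of uniformly drawn gene subsets of the
    same size; two-sided permutation p.
    """
    present = [g for g in gene_set.genes if g in gene_statistics.index]
    if len(present) < 2:
        raise EnrichmentError(
            f"gene set {gene_set.name!r} has {len(present)} genes in the "
            "ranking; need >= 2")
    ranks = pd.Series(
        stats.rankdata(-gene_statistics.to_numpy(dtype=float)),
        index=gene_statistics.index)
    observed = float(ranks.loc[present].mean())
    rng = np.random.default_rng(seed)
    all_ranks = ranks.to_numpy()
    k, n = len(present), len(all_ranks)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = all_ranks[rng.choice(n, size=k, replace=False)].mean()
    centre = (n + 1) / 2
    r = int((np.abs(null - centre) >= abs(observed - centre)).sum())
    return EnrichmentResult(
        observed=observed, null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if n_perm > 1 else 0.0,
        n_draws=n_perm, p_value=min(1.0, (r + 1) / (n_perm + 1)),
        estimator_tag="mean_rank_permutation_two_sided", seed=seed)
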