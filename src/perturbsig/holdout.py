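"""Holdout validation of consensus signatures with permutation nulls.

A gene's consensus signature is considered validated when two consensus
signatures built from disjoint halves of its reagents agree better than
consensus pairs built from size-matched random groups of reagents
targeting different genes.  The half-vs-half Spearman correlation is
summarized over repeated random partitions by its median; permutation
p-values are compared against a Storey q-value threshold of 0.25.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .core import SignatureMatrix, collapse_dataset, pairwise_correlation_matrix
from .errors import InvalidInputError

Q_THRESHOLD = 0.25
MIN_GROUP = 6


def storey_qvalues(pvals, lambda_: float = 0.5) -> np.ndarray:
    """Storey q-values from a vector of p-values.

    pi0 is estimated with the single-lambda rule at ``lambda_`` and capped
    at 1; q_i = min over observed thresholds t >= p_i of
    pi0 * m * t / #{p <= t}.  Output is monotone non-decreasing in p.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.array([])
    if ((p <= 0) | (p > 1)).any() or np.isnan(p).any():
        raise InvalidInputError("p-values must lie in (0, 1]")
    m = p.size
    pi0 = min(1.0, float(np.mean(p > lambda_)) / (1.0 - lambda_))
    order = np.argsort(p, kind="stable")
    q_sorted = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _partition_median_corr(
    values: np.ndarray,
    n_partitions: int,
    rng: np.random.Generator,
    corr: Optional[np.ndarray] = None,
) -> float:
    """Median over random disjoint-half partitions of the Spearman
    correlation between the two half-consensus signatures."""
    from .consensus import modz_weights  # local import to avoid a cycle

    n = values.shape[1]
    if corr is None:
        corr = pairwise_correlation_matrix(values)
    stats_out = np.empty(n_partitions)
    for t in range(n_partitions):
        perm = rng.permutation(n)
        halves = (perm[: n // 2], perm[n // 2:])
        consensus = []
        for idx in halves:
            if len(idx) == 1:
                consensus.append(values[:, idx[0]])
            else:
                w = modz_weights(corr[np.ix_(idx, idx)])
                consensus.append(values[:, idx] @ w)
        r1 = stats.rankdata(consensus[0])
        r2 = stats.rankdata(consensus[1])
        c = np.corrcoef(r1, r2)[0, 1]
        stats_out[t] = 0.0 if np.isnan(c) else c
    return float(np.median(stats_out))


def holdout_statistic(
    values: np.ndarray,
    n_partitions: int = 30,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Observed holdout statistic for one reagent group (genes x n, n >= 6)."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] < MIN_GROUP:
        raise InvalidInputError(
            f"holdout requires at least {MIN_GROUP} signatures"
        )
    if rng is None:
        rng = np.random.default_rng()
    return _partition_median_corr(values, n_partitions, rng)


def holdout_null(
    pool: SignatureMatrix,
    group_size: int,
    n_null: int = 10000,
    n_partitions: int = 30,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Null holdout statistics from size-matched random reagent groups.

    Each null group draws ``group_size`` reagents with pairwise-distinct
    target genes from the pool (one reagent per gene) and is scored exactly
    like an observed group.
    """
    if rng is None:
        rng = np.random.default_rng()
    if "target_gene" not in pool.meta.columns:
        raise InvalidInputError("pool metadata must define target_gene")
    values = pool.data.to_numpy()
    genes = pool.meta["target_gene"].to_numpy()
    by_gene: dict = {}
    for i, g in enumerate(genes):
        by_gene.setdefault(g, []).append(i)
    gene_keys = sorted(by_gene)
    if len(gene_keys) < group_size:
        raise InvalidInputError(
            f"pool has {len(gene_keys)} distinct genes, need {group_size}"
        )
    out = np.empty(n_null)
    for k in range(n_null):
        chosen_genes = rng.choice(len(gene_keys), size=group_size,
                                  replace=False)
        cols = [
            by_gene[gene_keys[g]][rng.integers(len(by_gene[gene_keys[g]]))]
            for g in chosen_genes
        ]
        out[k] = _partition_median_corr(values[:, cols], n_partitions, rng)
    return out


def permutation_pvalue(observed: float, null: np.ndarray) -> float:
    """Conservative permutation p-value with the +1 pseudocount; null ties
    with the observed value count as exceeding it."""
    null = np.asarray(null, dtype=float)
    return float(1 + np.sum(null >= observed)) / (1 + null.size)


def holdout_analysis(
    dataset: SignatureMatrix,
    n_partitions: int = 30,
    n_null: int = 10000,
    rng: Optional[np.random.Generator] = None,
    q_threshold: float = Q_THRESHOLD,
    min_group: int = MIN_GROUP,
) -> pd.DataFrame:
    """Holdout validation for every eligible (gene, cell line) group.

    Groups need >= ``min_group`` reagents (collapsed signatures) within a
    cell line.  Null distributions are size-matched and drawn from the
    same cell line's pool of reagents; one null set is shared by all
    groups of the same size in a cell line.

    Returns columns: target_gene, cell_line, n_members,
    observed_median_corr, p_value, q_value, significant.
    """
    if rng is None:
        rng = np.random.default_rng()
    from .consensus import _is_collapsed

    collapsed = dataset if _is_collapsed(dataset) else collapse_dataset(dataset)
    meta = collapsed.meta
    rows = []
    for cell, cmeta in meta.groupby("cell_line", sort=True):
        pool = collapsed.subset(list(cmeta.index))
        groups = [
            (gene, list(gmeta.index))
            for gene, gmeta in cmeta.groupby("target_gene", sort=True)
            if len(gmeta) >= min_group and gene is not None
        ]
        if not groups:
            continue
        sizes = sorted({len(ids) for _, ids in groups})
        nulls = {
            size: holdout_null(pool, size, n_null, n_partitions, rng)
            for size in sizes
        }
        for gene, ids in groups:
            obs = holdout_statistic(pool.values_for(ids), n_partitions, rng)
            p = permutation_pvalue(obs, nulls[len(ids)])
            rows.append(dict(target_gene=gene, cell_line=cell,
                             n_members=len(ids), observed_median_corr=obs,
                             p_value=p))
    result = pd.DataFrame(
        rows, columns=["target_gene", "cell_line", "n_members",
                       "observed_median_corr", "p_value"],
    )
    if result.empty:
        import warnings

        warnings.warn("no (gene, cell line) group has enough reagents for "
                      "holdout analysis", stacklevel=2)
        result["q_value"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
        return result
    result["q_value"] = storey_qvalues(result["p_value"].to_numpy())
    result["significant"] = result["q_value"] < q_threshold
    return result
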