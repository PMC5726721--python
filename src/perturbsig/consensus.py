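"""modz consensus signatures (CGS/CSS), target-gene rank, and the
cross-cell-line on-target reagent filter.

A consensus gene signature (CGS) combines the signatures of different
reagents targeting one gene in one cell line into a weighted average,
where each member's weight is the sum of its Spearman correlations to the
other members (diagonal of the correlation matrix set to 0) normalized to
sum to 1.  The consensus seed signature (CSS) is the same construction
over reagents sharing a seed but targeting different genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    SignatureMatrix,
    collapse_dataset,
    modz_weights_from_corr,
    pairwise_correlation_matrix,
    spearman_correlation,
)
from .errors import InvalidGroupingError, InvalidInputError


@dataclass
class ConsensusSignature:
    values: np.ndarray
    weights: np.ndarray
    component_sig_ids: list
    group_key: tuple = ()
    kind: str = "CGS"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.component_sig_ids):
            raise InvalidInputError("one weight per component required")
        if (self.weights < -1e-12).any():
            raise InvalidInputError("consensus weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise InvalidInputError("consensus weights must sum to 1")


def modz_weights(corr: np.ndarray) -> np.ndarray:
    """modz weights from a pairwise correlation matrix: zero the diagonal,
    row-sum, clip negatives to 0, normalize to sum 1 (equal weights if all
    row sums are <= 0)."""
    return modz_weights_from_corr(corr)


def build_consensus(
    values: np.ndarray,
    sig_ids: Optional[Sequence] = None,
    kind: str = "CGS",
    group_key: tuple = (),
    cell_lines: Optional[Sequence] = None,
) -> ConsensusSignature:
    """modz consensus of the columns of a genes x k matrix.

    A singleton group returns its signature with weight [1].  Consensus is
    defined within one cell line; passing mixed ``cell_lines`` raises.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.ndim != 2 or values.shape[1] < 1:
        raise InvalidInputError("need a genes x k matrix with k >= 1")
    if cell_lines is not None and len(set(cell_lines)) > 1:
        raise InvalidGroupingError("consensus groups must not mix cell lines")
    if sig_ids is None:
        sig_ids = list(range(values.shape[1]))
    sig_ids = list(sig_ids)
    if len(sig_ids) != values.shape[1]:
        raise InvalidInputError("one sig_id per column required")
    if values.shape[1] == 1:
        return ConsensusSignature(values[:, 0].copy(), np.array([1.0]),
                                  sig_ids, group_key, kind)
    corr = pairwise_correlation_matrix(values)
    w = modz_weights_from_corr(corr)
    return ConsensusSignature(values @ w, w, sig_ids, group_key, kind)


def leave_one_out_consensus(
    values: np.ndarray,
    held_out_index: int,
    sig_ids: Optional[Sequence] = None,
    kind: str = "CGS",
    group_key: tuple = (),
) -> ConsensusSignature:
    """Consensus over all group members except ``held_out_index``."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise InvalidInputError("leave-one-out requires a group of >= 2")
    if not 0 <= held_out_index < values.shape[1]:
        raise InvalidInputError("held-out index out of range")
    keep = [i for i in range(values.shape[1]) if i != held_out_index]
    if sig_ids is None:
        sig_ids = list(range(values.shape[1]))
    kept_ids = [sig_ids[i] for i in keep]
    return build_consensus(values[:, keep], kept_ids, kind, group_key)


def gene_seed_decomposition_scatter(
    dataset: SignatureMatrix,
    seed_col: str = "seed6",
) -> pd.DataFrame:
    """Per-reagent on-target (CGS) vs off-target (CSS) correlations.

    For every reagent with at least one same-gene peer and at least one
    same-seed peer targeting a different gene (within its cell line), the
    reagent's collapsed signature is correlated against the leave-one-out
    CGS of the same-gene peers and the leave-one-out CSS of the same-seed
    cross-gene peers.  Same-gene peers that also share the reagent's seed
    are excluded from the CGS so the two axes measure distinct effects.

    Returns columns: reagent_id, cell_line, target_gene, seed, cgs_corr,
    css_corr.  Ineligible reagents are omitted.
    """
    collapsed = dataset if _is_collapsed(dataset) else collapse_dataset(dataset)
    meta = collapsed.meta
    if seed_col not in meta.columns or "target_gene" not in meta.columns:
        raise InvalidInputError(f"metadata must define target_gene and {seed_col}")
    rows = []
    for cell, cmeta in meta.groupby("cell_line", sort=True):
        vals = collapsed.values_for(cmeta.index)
        genes = cmeta["target_gene"].to_numpy()
        seeds = cmeta[seed_col].to_numpy()
        for i in range(len(cmeta)):
            if seeds[i] is None or not isinstance(seeds[i], str):
                continue
            same_gene = [
                j for j in range(len(cmeta))
                if j != i and genes[j] == genes[i] and seeds[j] != seeds[i]
            ]
            same_seed = [
                j for j in range(len(cmeta))
                if j != i and seeds[j] == seeds[i] and genes[j] != genes[i]
            ]
            if not same_gene or not same_seed:
                continue
            cgs = build_consensus(vals[:, same_gene], kind="CGS")
            css = build_consensus(vals[:, same_seed], kind="CSS")
            rows.append(
                dict(
                    reagent_id=cmeta["reagent_id"].iloc[i],
                    cell_line=cell,
                    target_gene=genes[i],
                    seed=seeds[i],
                    cgs_corr=spearman_correlation(vals[:, i], cgs.values),
                    css_corr=spearman_correlation(vals[:, i], css.values),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["reagent_id", "cell_line", "target_gene", "seed",
                 "cgs_corr", "css_corr"],
    )


def _is_collapsed(dataset: SignatureMatrix) -> bool:
    if "replicate_group" not in dataset.meta.columns:
        return True
    return not dataset.meta["replicate_group"].duplicated().any()


def target_gene_rank(values: np.ndarray, gene_ids: Sequence[str],
                     target_gene: str) -> int:
    """Rank of the target gene from most down- (1) to most up-regulated
    (n).  Ties are broken by gene-id order for determinism."""
    values = np.asarray(values, dtype=float).ravel()
    gene_ids = list(gene_ids)
    if target_gene not in gene_ids:
        raise InvalidInputError(
            f"target gene {target_gene!r} is not a measured landmark"
        )
    # gene order is canonical (sorted), so a stable sort on values breaks
    # ties by gene id
    order = np.argsort(values, kind="stable")
    pos = gene_ids.index(target_gene)
    return int(np.nonzero(order == pos)[0][0]) + 1


def target_rank_table(dataset: SignatureMatrix,
                      use_consensus: bool = True) -> pd.DataFrame:
    """Target-gene ranks for landmark-targeted perturbations.

    With ``use_consensus`` the rank is measured on the per-(gene, cell
    line) CGS; otherwise on each individual collapsed reagent signature.
    """
    collapsed = dataset if _is_collapsed(dataset) else collapse_dataset(dataset)
    meta = collapsed.meta
    gene_ids = collapsed.genes
    landmark_set = set(gene_ids)
    rows = []
    for (gene, cell), gmeta in meta.groupby(["target_gene", "cell_line"],
                                            sort=True):
        if gene not in landmark_set:
            continue
        vals = collapsed.values_for(gmeta.index)
        if use_consensus:
            cgs = build_consensus(vals, list(gmeta.index), "CGS", (gene, cell))
            rows.append(dict(target_gene=gene, cell_line=cell, sig_id=None,
                             rank=target_gene_rank(cgs.values, gene_ids, gene)))
        else:
            for i, sid in enumerate(gmeta.index):
                rows.append(dict(target_gene=gene, cell_line=cell, sig_id=sid,
                                 rank=target_gene_rank(vals[:, i], gene_ids,
                                                       gene)))
    return pd.DataFrame(rows, columns=["target_gene", "cell_line", "sig_id",
                                       "rank"])


def on_target_filter_crosscell(
    scatter: pd.DataFrame,
    cgs_threshold: float = 0.15,
    css_threshold: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag predominantly on-target reagents and test cross-cell-line
    consistency of the flag.

    A reagent is flagged when |CSS correlation| < ``css_threshold`` (minimal
    off-target activity) and CGS correlation > ``cgs_threshold``
    (substantial on-target activity).  For each pair of cell lines sharing
    >= 2 reagents, a 2x2 contingency table of flags is summarized by its
    odds ratio (Haldane–Anscombe 0.5 correction when any cell is 0) and
    Fisher exact p-value.

    Returns ``(flags, pairs)`` DataFrames.
    """
    flags = scatter.copy()
    flags["on_target"] = (
        (flags["css_corr"].abs() < css_threshold)
        & (flags["cgs_corr"] > cgs_threshold)
    )
    wide = flags.pivot_table(index="reagent_id", columns="cell_line",
                             values="on_target", aggfunc="first")
    cells = list(wide.columns)
    pair_rows = []
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            sub = wide[[cells[i], cells[j]]].dropna()
            if len(sub) < 2:
                continue
            a = sub[cells[i]].astype(bool).to_numpy()
            b = sub[cells[j]].astype(bool).to_numpy()
            table = np.array([
                [np.sum(a & b), np.sum(a & ~b)],
                [np.sum(~a & b), np.sum(~a & ~b)],
            ], dtype=float)
            _, fisher_p = stats.fisher_exact(table)
            if (table == 0).any():
                table = table + 0.5
            odds = (table[0, 0] * table[1, 1]) / (table[0, 1] * table[1, 0])
            pair_rows.append(dict(cell_a=cells[i], cell_b=cells[j],
                                  n_shared=len(sub), odds_ratio=float(odds),
                                  fisher_p=float(fisher_p)))
    pairs = pd.DataFrame(pair_rows, columns=["cell_a", "cell_b", "n_shared",
                                             "odds_ratio", "fisher_p"])
    return flags, pairs
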