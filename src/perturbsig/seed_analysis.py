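"""Quantification of seed-driven off-target structure in RNAi signatures.

Three analyses:

* pair-group correlation distributions — do reagents sharing a miRNA-like
  seed correlate more strongly than reagents sharing a target gene, and
  how often is either significant against the all-pairs background?
* heptamer window scan — at which sense-strand position does sharing a
  7-nt window predict signature correlation (the seed window of the
  dominant Dicer product sits at positions 11-12)?
* seed magnitude consistency — is a seed's mean off-target effect size
  (mean leave-one-out CSS correlation) more consistent across cell lines
  than expected, tested with a variance-ratio F-test?
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .core import SignatureMatrix, collapse_dataset, pairwise_correlation_matrix
from .errors import InvalidInputError
from .holdout import Q_THRESHOLD, storey_qvalues

GROUP_LABELS = ("same_gene", "same_seed6", "same_seed7", "all_pairs")


@dataclass
class PairGroupSummary:
    """Correlation distribution of one pair class plus its significant
    fraction at q < 0.25 against the all-pairs background."""

    group_label: str
    correlations: np.ndarray
    p_values: np.ndarray = field(default_factory=lambda: np.array([]))
    q_values: np.ndarray = field(default_factory=lambda: np.array([]))
    significant_fraction: float = float("nan")

    @property
    def n_pairs(self) -> int:
        return self.correlations.size

    @property
    def median(self) -> float:
        return float(np.median(self.correlations)) if self.n_pairs else float("nan")


def _collapse_if_needed(dataset: SignatureMatrix) -> SignatureMatrix:
    from .consensus import _is_collapsed

    return dataset if _is_collapsed(dataset) else collapse_dataset(dataset)


def pair_group_correlations(
    dataset: SignatureMatrix,
    q_threshold: float = Q_THRESHOLD,
) -> dict[str, PairGroupSummary]:
    """Pairwise-correlation distributions for same-gene, same-seed (6-mer
    and 7-mer), and all reagent pairs.

    Pairs are formed within cell lines; pairs sharing both gene and seed
    are excluded from the focal groups.  Each focal pair's p-value is the
    upper-tail rank of its correlation within the all-pairs distribution
    (the pair itself excluded, +1 pseudocount); q-values are Storey's,
    computed across pairs within each focal group.
    """
    collapsed = _collapse_if_needed(dataset)
    meta = collapsed.meta
    for col in ("target_gene", "seed6", "seed7", "cell_line"):
        if col not in meta.columns:
            raise InvalidInputError(f"metadata must define {col}")
    corrs: dict[str, list[np.ndarray]] = {lab: [] for lab in GROUP_LABELS}
    for _, cmeta in meta.groupby("cell_line", sort=True):
        if len(cmeta) < 2:
            continue
        vals = collapsed.values_for(cmeta.index)
        corr = pairwise_correlation_matrix(vals)
        genes = cmeta["target_gene"].to_numpy()
        s6 = cmeta["seed6"].to_numpy()
        s7 = cmeta["seed7"].to_numpy()
        iu, ju = np.triu_indices(len(cmeta), k=1)
        c = corr[iu, ju]
        same_gene = genes[iu] == genes[ju]
        has_s6 = np.array([isinstance(x, str) for x in s6])
        has_s7 = np.array([isinstance(x, str) for x in s7])
        same_s6 = (s6[iu] == s6[ju]) & has_s6[iu] & has_s6[ju]
        same_s7 = (s7[iu] == s7[ju]) & has_s7[iu] & has_s7[ju]
        corrs["all_pairs"].append(c)
        corrs["same_gene"].append(c[same_gene & ~same_s6])
        corrs["same_seed6"].append(c[same_s6 & ~same_gene])
        corrs["same_seed7"].append(c[same_s7 & ~same_gene])
    out: dict[str, PairGroupSummary] = {}
    all_c = (np.concatenate(corrs["all_pairs"])
             if corrs["all_pairs"] else np.array([]))
    all_sorted = np.sort(all_c)
    n_all = all_sorted.size
    for label in GROUP_LABELS:
        c = (np.concatenate(corrs[label]) if corrs[label] else np.array([]))
        if label == "all_pairs":
            out[label] = PairGroupSummary(label, c)
            continue
        if c.size == 0:
            warnings.warn(f"no {label} pairs in the dataset", stacklevel=2)
            out[label] = PairGroupSummary(label, c)
            continue
        # upper-tail count of all-pairs correlations >= c, minus the focal
        # pair itself (every focal pair is also an all-pair)
        ge = n_all - np.searchsorted(all_sorted, c, side="left") - 1
        p = (1.0 + ge) / (1.0 + n_all)
        q = storey_qvalues(p)
        out[label] = PairGroupSummary(label, c, p, q,
                                      float(np.mean(q < q_threshold)))
    return out


def seed_window_scan(dataset: SignatureMatrix,
                     window: int = 7,
                     min_pairs: int = 50) -> pd.Series:
    """Mean same-heptamer pair correlation for each sense-strand window.

    For each 1-based start position p (1..15 for 21-nt sequences),
    reagents are grouped by the window sequence sense[p..p+6] within each
    cell line, and pairwise Spearman correlations inside multi-member
    groups are averaged.  Positions with no multi-member group, or with
    fewer than ``min_pairs`` supporting pairs in total, are NaN: group pairs
    share reagents, so a mean over a few dozen chance window matches is
    dominated by whichever reagents happen to collide and carries no
    usable information at desk scale
    (``min_pairs=0`` disables the support rule).
    """
    collapsed = _collapse_if_needed(dataset)
    meta = collapsed.meta
    if "sense_sequence" not in meta.columns:
        raise InvalidInputError("metadata must define sense_sequence")
    seqs_all = meta["sense_sequence"]
    keep = seqs_all.apply(lambda s: isinstance(s, str))
    if not keep.any():
        raise InvalidInputError("no sense sequences present")
    if any(len(s) < 21 for s in seqs_all[keep]):
        raise InvalidInputError("sense sequences must be at least 21 nt")
    meta = meta[keep]
    seq_len = min(len(s) for s in meta["sense_sequence"])
    n_pos = seq_len - window + 1
    sums = np.zeros(n_pos)
    counts = np.zeros(n_pos, dtype=int)
    for _, cmeta in meta.groupby("cell_line", sort=True):
        if len(cmeta) < 2:
            continue
        vals = collapsed.values_for(cmeta.index)
        corr = pairwise_correlation_matrix(vals)
        seqs = cmeta["sense_sequence"].to_numpy()
        for p in range(n_pos):
            groups: dict[str, list[int]] = {}
            for i, s in enumerate(seqs):
                groups.setdefault(s[p: p + window], []).append(i)
            for members in groups.values():
                if len(members) < 2:
                    continue
                idx = np.array(members)
                sub = corr[np.ix_(idx, idx)]
                tri = sub[np.triu_indices(len(idx), k=1)]
                sums[p] += tri.sum()
                counts[p] += tri.size
    support = np.maximum(min_pairs, 1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts >= support, sums / np.maximum(counts, 1),
                         np.nan)
    return pd.Series(means, index=pd.RangeIndex(1, n_pos + 1, name="position"),
                     name="mean_same_window_corr")


@dataclass
class SeedConsistencyResult:
    key: str
    cell_line_means: dict
    variance: float
    f_statistic: float
    p_value: float
    q_value: float = float("nan")
    flagged_smaller_variance: bool = False


def seed_magnitude_ftest(
    loo_table: pd.DataFrame,
    key: str = "seed",
    corr_col: str = "css_corr",
    q_threshold: float = Q_THRESHOLD,
) -> pd.DataFrame:
    """Variance-ratio test of effect-magnitude consistency across cell lines.

    For each key (seed by default; pass ``key='target_gene'`` and
    ``corr_col='cgs_corr'`` for the gene analogue) the mean leave-one-out
    consensus correlation is computed per cell line.  The variance of a
    key's cell-line means is compared to the variance of the pooled
    collection of all key-by-cell-line means with a one-sided F-test for
    smaller variance, F = var_key / var_population with (n_cells - 1,
    N - 1) degrees of freedom.  Keys observed in fewer than 2 cell lines
    are omitted.  Flagged keys have q < 0.25 and below-population variance.
    """
    for col in (key, "cell_line", corr_col):
        if col not in loo_table.columns:
            raise InvalidInputError(f"leave-one-out table must define {col}")
    means = (
        loo_table.groupby([key, "cell_line"], sort=True)[corr_col]
        .mean()
        .reset_index()
    )
    if means.empty:
        return pd.DataFrame(columns=[key, "n_cell_lines", "mean", "variance",
                                     "f_statistic", "p_value", "q_value",
                                     "flagged_smaller_variance"])
    pop = means[corr_col].to_numpy()
    pop_var = float(np.var(pop, ddof=1))
    n_pop = pop.size
    if pop_var == 0 or n_pop < 3:
        raise InvalidInputError("population of cell-line means is degenerate")
    rows = []
    for k, kmeans in means.groupby(key, sort=True):
        vals = kmeans[corr_col].to_numpy()
        if vals.size < 2:
            continue
        var = float(np.var(vals, ddof=1))
        f_stat = var / pop_var
        p = float(stats.f.cdf(f_stat, vals.size - 1, n_pop - 1))
        p = min(max(p, np.finfo(float).tiny), 1.0)
        rows.append({key: k, "n_cell_lines": vals.size,
                     "mean": float(vals.mean()), "variance": var,
                     "f_statistic": f_stat, "p_value": p})
    result = pd.DataFrame(rows)
    if result.empty:
        result["q_value"] = pd.Series(dtype=float)
        result["flagged_smaller_variance"] = pd.Series(dtype=bool)
        return result
    result["q_value"] = storey_qvalues(result["p_value"].to_numpy())
    result["flagged_smaller_variance"] = (
        (result["q_value"] < q_threshold) & (result["variance"] < pop_var)
    )
    return result
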