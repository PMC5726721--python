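"""On/off-target decomposition of replicate sets by projection.

Each reagent's replicates are compared to a unit reference direction
estimated from independent same-gene perturbations (a modz consensus of
peers).  The on-target magnitude ``a`` is the mean cosine of the
replicates with the reference; the off-target magnitude ``b`` is derived
from the agreement of the replicate residuals orthogonal to the
reference: ``b = sqrt(max(0, mean over pairs i<j of
(res_i . res_j)/(||rep_i|| ||rep_j||)))``.  With this definition
``a^2 + b^2`` is the reproducible fraction of the signature and is
bounded by 1.

Magnitudes are only reported when the reagent's collapsed signature has
statistically significant cosine similarity to its reference relative to
size-matched null references (consensus vectors of unrelated reagent
groups), at Storey q < 0.25; otherwise either the reagent has no
measurable on-target activity or the reference is a poor estimate of it,
and the decomposition would misattribute on-target signal to ``b``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core import SignatureMatrix, collapse_dataset
from .consensus import _is_collapsed, build_consensus
from .errors import DegenerateDataError, InvalidInputError
from .holdout import Q_THRESHOLD, permutation_pvalue, storey_qvalues


@dataclass
class ProjectionResult:
    reagent_id: str
    cell_line: str
    target_gene: str
    cosine: float
    on_target_p: float
    on_target_q: float = float("nan")
    valid: bool = False
    a: float = float("nan")
    b: float = float("nan")

    @property
    def reproducible_fraction(self) -> float:
        return self.a ** 2 + self.b ** 2


def build_reference(peer_values: np.ndarray) -> np.ndarray:
    """Unit-length modz consensus of same-gene peer signatures."""
    peer_values = np.atleast_2d(np.asarray(peer_values, dtype=float))
    if peer_values.ndim != 2 or peer_values.shape[1] < 1:
        raise InvalidInputError("reference needs at least one peer signature")
    consensus = build_consensus(peer_values).values
    norm = np.linalg.norm(consensus)
    if norm == 0:
        raise DegenerateDataError("peer consensus has zero norm")
    return consensus / norm


def cosine_similarity(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise DegenerateDataError("cosine of a zero-norm vector is undefined")
    return float(x @ y / (nx * ny))


def on_target_significance(
    sig: np.ndarray,
    reference: np.ndarray,
    null_references: np.ndarray,
) -> tuple[float, float]:
    """Observed cosine to the reference and its permutation p-value.

    ``null_references`` is a genes x n matrix of consensus vectors built
    from unrelated same-size reagent groups; p = (1 + #{null cosine >=
    observed}) / (1 + n).  q-values are assigned across all reagents of a
    run by the caller.
    """
    sig = np.asarray(sig, dtype=float).ravel()
    obs = cosine_similarity(sig, reference)
    nulls = np.atleast_2d(np.asarray(null_references, dtype=float))
    if nulls.shape[0] != sig.size:
        raise InvalidInputError("null references must live in gene space")
    norms = np.linalg.norm(nulls, axis=0)
    if (norms == 0).any():
        raise DegenerateDataError("zero-norm null reference")
    null_cos = (sig @ nulls) / (np.linalg.norm(sig) * norms)
    return obs, permutation_pvalue(obs, null_cos)


def project_decompose(reps: np.ndarray,
                      reference: np.ndarray) -> tuple[float, float]:
    """Decompose a replicate set against a unit reference.

    Returns ``(a, b)``: the mean cosine of the replicates with the
    reference, and the square root of the clipped mean pairwise normalized
    inner product of the replicate residuals orthogonal to the reference.
    """
    reps = np.asarray(reps, dtype=float)
    if reps.ndim != 2 or reps.shape[1] < 2:
        raise InvalidInputError("projection requires at least 2 replicates")
    reference = np.asarray(reference, dtype=float).ravel()
    if reps.shape[0] != reference.size:
        raise InvalidInputError("replicates and reference disagree in genes")
    if abs(np.linalg.norm(reference) - 1.0) > 1e-6:
        raise InvalidInputError("reference must be unit length")
    norms = np.linalg.norm(reps, axis=0)
    if (norms == 0).any():
        raise DegenerateDataError("zero-norm replicate")
    proj = reps.T @ reference  # per-replicate inner product with reference
    a = float(np.mean(proj / norms))
    residuals = reps - np.outer(reference, proj)
    gram = residuals.T @ residuals
    iu, ju = np.triu_indices(reps.shape[1], k=1)
    pair_terms = gram[iu, ju] / (norms[iu] * norms[ju])
    b = float(np.sqrt(max(0.0, float(np.mean(pair_terms)))))
    return a, b


def _draw_null_references(
    values: np.ndarray,
    genes: np.ndarray,
    size: int,
    n_null: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """n_null unit consensus vectors from random groups of ``size``
    reagents with pairwise-distinct target genes."""
    by_gene: dict = {}
    for i, g in enumerate(genes):
        by_gene.setdefault(g, []).append(i)
    keys = sorted(by_gene)
    if len(keys) < size:
        raise InvalidInputError("not enough distinct genes for null groups")
    out = np.empty((values.shape[0], n_null))
    for k in range(n_null):
        gsel = rng.choice(len(keys), size=size, replace=False)
        cols = [by_gene[keys[g]][rng.integers(len(by_gene[keys[g]]))]
                for g in gsel]
        ref = build_consensus(values[:, cols]).values
        norm = np.linalg.norm(ref)
        out[:, k] = ref / norm if norm > 0 else 0.0
    return out


def projection_pipeline(
    dataset: SignatureMatrix,
    pert_type: Optional[str] = None,
    rng: Optional[np.random.Generator] = None,
    n_null: int = 1000,
    q_threshold: float = Q_THRESHOLD,
) -> pd.DataFrame:
    """Projection decomposition for every reagent with same-gene peers.

    ``dataset`` must be replicate-level (signatures grouped by
    replicate_group).  Per reagent and cell line: the reference is the
    unit modz consensus of the collapsed signatures of the other same-gene
    reagents; significance of the collapsed signature's cosine to the
    reference is assessed against ``n_null`` size-matched null references;
    reagents passing the q < 0.25 gate get magnitudes (a, b) computed from
    their replicate-level signatures.  Reagents whose gene has no other
    reagent are skipped.
    """
    if rng is None:
        rng = np.random.default_rng()
    if _is_collapsed(dataset):
        raise InvalidInputError(
            "projection needs replicate-level signatures (got collapsed data)"
        )
    if pert_type is not None:
        keep = dataset.meta["pert_type"] == pert_type
        dataset = dataset.subset(list(dataset.meta.index[keep]))
    collapsed = collapse_dataset(dataset)
    results: list[ProjectionResult] = []
    rep_groups = dataset.meta.groupby("replicate_group").groups
    for cell, cmeta in collapsed.meta.groupby("cell_line", sort=True):
        vals = collapsed.values_for(cmeta.index)
        genes = cmeta["target_gene"].to_numpy()
        gene_cols: dict = {}
        for i, g in enumerate(genes):
            gene_cols.setdefault(g, []).append(i)
        sizes_needed = sorted({len(c) - 1 for c in gene_cols.values()
                               if len(c) >= 2})
        null_banks = {
            s: _draw_null_references(vals, genes, s, n_null, rng)
            for s in sizes_needed
        }
        for i, group_key in enumerate(cmeta.index):
            peers = [j for j in gene_cols[genes[i]] if j != i]
            if not peers:
                continue
            reference = build_reference(vals[:, peers])
            obs, p = on_target_significance(vals[:, i], reference,
                                            null_banks[len(peers)])
            res = ProjectionResult(
                reagent_id=cmeta["reagent_id"].iloc[i],
                cell_line=cell, target_gene=genes[i],
                cosine=obs, on_target_p=p,
            )
            rep_ids = list(rep_groups[group_key])
            res._reps = dataset.values_for(rep_ids)  # stashed for the gate
            res._reference = reference
            results.append(res)
    if not results:
        return pd.DataFrame(columns=["reagent_id", "cell_line", "target_gene",
                                     "cosine", "on_target_p", "on_target_q",
                                     "valid", "a", "b",
                                     "reproducible_fraction"])
    qs = storey_qvalues([r.on_target_p for r in results])
    rows = []
    for res, q in zip(results, qs):
        res.on_target_q = float(q)
        res.valid = bool(q < q_threshold)
        if res.valid and res._reps.shape[1] >= 2:
            res.a, res.b = project_decompose(res._reps, res._reference)
        rows.append(dict(
            reagent_id=res.reagent_id, cell_line=res.cell_line,
            target_gene=res.target_gene, cosine=res.cosine,
            on_target_p=res.on_target_p, on_target_q=res.on_target_q,
            valid=res.valid, a=res.a, b=res.b,
            reproducible_fraction=res.reproducible_fraction,
        ))
    return pd.DataFrame(rows)
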