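"""Connectivity queries between consensus signatures.

A query signature (e.g. a CRISPR-derived consensus gene signature) is
scored against a database of consensus signatures by Spearman correlation
in landmark space — the same similarity used throughout the pipeline.
The designated same-gene counterpart's score is assigned a permutation
p-value from its rank among the non-match database members, and Storey
q-values are computed across all queries of a run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .core import SignatureMatrix
from .errors import InvalidInputError
from .holdout import Q_THRESHOLD, storey_qvalues


@dataclass
class QueryResult:
    query_id: str
    table: pd.DataFrame  # database_id, score, rank (scores non-increasing)
    matched_id: Optional[str] = None
    matched_rank: Optional[int] = None
    matched_score: float = float("nan")
    p_value: float = float("nan")


def _spearman_scores(query: np.ndarray, db_values: np.ndarray) -> np.ndarray:
    """Spearman correlation of a query vector against each database column."""
    rq = stats.rankdata(query)
    rdb = stats.rankdata(db_values, axis=0)
    rq = rq - rq.mean()
    rdb = rdb - rdb.mean(axis=0)
    denom = np.linalg.norm(rq) * np.linalg.norm(rdb, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = (rq @ rdb) / denom
    return np.where(np.isfinite(scores), scores, 0.0)


def query_connectivity(
    query: np.ndarray,
    database: SignatureMatrix,
    query_id: str = "query",
    match_id: Optional[str] = None,
) -> QueryResult:
    """Rank every database member by similarity to the query.

    When ``match_id`` names a database member, its permutation p-value is
    (1 + #{non-match scores >= match score}) / (1 + n_nonmatch).
    """
    query = np.asarray(query, dtype=float).ravel()
    if query.size != database.n_genes:
        raise InvalidInputError("query and database gene spaces differ")
    scores = _spearman_scores(query, database.data.to_numpy())
    order = np.argsort(-scores, kind="stable")
    ids = np.array(database.sigs)
    table = pd.DataFrame({
        "database_id": ids[order],
        "score": scores[order],
        "rank": np.arange(1, len(ids) + 1),
    })
    result = QueryResult(query_id=query_id, table=table, matched_id=match_id)
    if match_id is not None and match_id in database.sigs:
        match_pos = database.sigs.index(match_id)
        match_score = scores[match_pos]
        others = np.delete(scores, match_pos)
        result.matched_rank = int(
            table.loc[table["database_id"] == match_id, "rank"].iloc[0]
        )
        result.matched_score = float(match_score)
        result.p_value = (1.0 + np.sum(others >= match_score)) / (1.0 + others.size)
    return result


def cross_technology_report(
    query_cgs: SignatureMatrix,
    db_cgs: SignatureMatrix,
    holdout_query: Optional[pd.DataFrame] = None,
    holdout_db: Optional[pd.DataFrame] = None,
    q_threshold: float = Q_THRESHOLD,
) -> tuple[pd.DataFrame, dict]:
    """Connectivity of one technology's CGSs to another's, per (gene, cell
    line), with optional holdout-validation gating.

    Both consensus matrices must carry ``target_gene`` and ``cell_line``
    metadata.  Each query CGS is scored against the database CGSs of the
    same cell line; the designated match is the same-gene database CGS.
    The summary reports the connected fraction (q < 0.25) over all pairs
    and over the subset where both technologies pass holdout validation.
    """
    for m in (query_cgs, db_cgs):
        for col in ("target_gene", "cell_line"):
            if col not in m.meta.columns:
                raise InvalidInputError(f"consensus metadata must define {col}")
    if query_cgs.genes != db_cgs.genes:
        raise InvalidInputError("query and database gene spaces differ")

    def _passes(table: Optional[pd.DataFrame]):
        if table is None:
            return None
        return {
            (r.target_gene, r.cell_line)
            for r in table.itertuples()
            if bool(r.significant)
        }

    pass_q = _passes(holdout_query)
    pass_db = _passes(holdout_db)
    db_index = {
        (row.target_gene, row.cell_line): sid
        for sid, row in db_cgs.meta.iterrows()
    }
    rows = []
    for sid, row in query_cgs.meta.iterrows():
        key = (row.target_gene, row.cell_line)
        if key not in db_index:
            continue
        cell_ids = list(db_cgs.meta.index[db_cgs.meta["cell_line"] ==
                                          row.cell_line])
        if len(cell_ids) < 2:
            continue
        sub_db = db_cgs.subset(cell_ids)
        res = query_connectivity(query_cgs.data[sid].to_numpy(), sub_db,
                                 query_id=sid, match_id=db_index[key])
        both_pass = (pass_q is None or key in pass_q) and (
            pass_db is None or key in pass_db
        )
        rows.append(dict(target_gene=row.target_gene,
                         cell_line=row.cell_line,
                         matched_rank=res.matched_rank,
                         score=res.matched_score, p_value=res.p_value,
                         both_pass_holdout=bool(both_pass)))
    report = pd.DataFrame(
        rows, columns=["target_gene", "cell_line", "matched_rank", "score",
                       "p_value", "both_pass_holdout"],
    )
    if report.empty:
        import warnings

        warnings.warn("no shared (gene, cell line) pairs between the sets",
                      stacklevel=2)
        report["q_value"] = pd.Series(dtype=float)
        report["connected"] = pd.Series(dtype=bool)
        return report, dict(connected_fraction_all=float("nan"),
                            connected_fraction_both_pass=float("nan"),
                            n_pairs=0, n_both_pass=0)
    report["q_value"] = storey_qvalues(report["p_value"].to_numpy())
    report["connected"] = report["q_value"] < q_threshold
    both = report[report["both_pass_holdout"]]
    summary = dict(
        connected_fraction_all=float(report["connected"].mean()),
        connected_fraction_both_pass=(
            float(both["connected"].mean()) if len(both) else float("nan")
        ),
        n_pairs=int(len(report)),
        n_both_pass=int(len(both)),
    )
    return report, summary
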