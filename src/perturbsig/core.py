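"""Domain containers, rank correlation, GCT I/O, and replicate collapse.

Signatures are vectors of differential-expression z-scores over the 978
L1000 landmark genes.  A :class:`SignatureMatrix` holds a genes x signatures
matrix together with per-signature reagent metadata; it is the exchange
object used by every pipeline stage and maps onto the GCT #1.3 text format
on disk.

All similarity in this package is Spearman rank correlation in landmark
space, matching standard CMAP practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    CorruptFileError,
    InvalidInputError,
    UnsupportedFormatError,
)

META_COLUMNS = [
    "reagent_id",
    "pert_type",
    "target_gene",
    "cell_line",
    "seed6",
    "seed7",
    "replicate_group",
    "sense_sequence",
]

PERT_TYPES = ("shRNA", "sgRNA", "control")


@dataclass
class ReagentMeta:
    """Annotation of one reagent.

    ``seed7`` is the 7-nt seed of the antisense (targeting) strand; for
    shRNAs it is the reverse complement of positions 11-17 (1-based) of the
    21-nt sense strand.  ``seed6`` is its first 6 nt.  Controls carry no
    target gene, and seeds are meaningful only for shRNAs.
    """

    reagent_id: str
    pert_type: str
    target_gene: str | None = None
    cell_line: str | None = None
    seed6: str | None = None
    seed7: str | None = None
    sense_sequence: str | None = None

    def __post_init__(self) -> None:
        if self.pert_type not in PERT_TYPES:
            raise InvalidInputError(f"unknown pert_type {self.pert_type!r}")
        if self.pert_type == "control" and self.target_gene:
            raise InvalidInputError("controls must have a null target_gene")
        if self.seed7 is not None:
            if len(self.seed7) != 7:
                raise InvalidInputError("seed7 must have length 7")
            if self.seed6 is not None and self.seed7[:6] != self.seed6:
                raise InvalidInputError("seed6 must be the first 6 nt of seed7")


@dataclass
class SignatureMatrix:
    """Genes x signatures z-score matrix with aligned signature metadata.

    ``data`` is a DataFrame indexed by gene id with one column per sig_id;
    ``meta`` is indexed by sig_id.  Gene order is canonicalized (sorted by
    gene id) at construction so correlation operations are order-safe.
    """

    data: pd.DataFrame
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            raise InvalidInputError("signature matrix contains missing values")
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise InvalidInputError("duplicate gene or signature ids")
        self.data = self.data.sort_index().astype(float)
        if len(self.meta):
            missing = set(self.data.columns) - set(self.meta.index)
            extra = set(self.meta.index) - set(self.data.columns)
            if missing or extra:
                raise InvalidInputError(
                    f"meta does not match signatures (missing={len(missing)}, "
                    f"extra={len(extra)})"
                )
            self.meta = self.meta.loc[self.data.columns]

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def sigs(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_sigs(self) -> int:
        return self.data.shape[1]

    def values_for(self, sig_ids: Sequence[str]) -> np.ndarray:
        """Genes x len(sig_ids) array for the given signature ids."""
        return self.data[list(sig_ids)].to_numpy()

    def subset(self, sig_ids: Sequence[str]) -> "SignatureMatrix":
        sig_ids = list(sig_ids)
        meta = self.meta.loc[sig_ids] if len(self.meta) else self.meta
        return SignatureMatrix(self.data[sig_ids], meta)


def _check_vector_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise InvalidInputError("length mismatch between signature vectors")
    if x.size < 3:
        raise InvalidInputError("need at least 3 genes for rank correlation")
    if np.isnan(x).any() or np.isnan(y).any():
        raise InvalidInputError("missing values are not allowed")
    return x, y


def spearman_correlation(x, y) -> float:
    """Spearman rank correlation between two z-score vectors.

    Ties get average (mid) ranks.  Constant vectors yield a correlation of
    0.0 rather than NaN: a flat profile carries no rank information.
    """
    x, y = _check_vector_pair(x, y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho = stats.spearmanr(x, y).statistic
    return 0.0 if np.isnan(rho) else float(rho)


def _rank_columns(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, axis=0)


def pairwise_correlation_matrix(values: np.ndarray) -> np.ndarray:
    """All-vs-all Spearman correlation of the columns of a genes x k matrix.

    The diagonal is 1; callers that need a zeroed diagonal (modz) do so
    explicitly.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise InvalidInputError("need a 2-D matrix with >= 2 signatures")
    if values.shape[0] < 3:
        raise InvalidInputError("need at least 3 genes")
    if np.isnan(values).any():
        raise InvalidInputError("missing values are not allowed")
    ranks = _rank_columns(values)
    sd = ranks.std(axis=0)
    constant = sd == 0
    if constant.any():
        # corrcoef of a constant column is NaN; define it as 0 (no rank info)
        ranks = ranks.copy()
        ranks[:, constant] = np.arange(values.shape[0])[:, None]
    corr = np.corrcoef(ranks, rowvar=False)
    if constant.any():
        corr[constant, :] = 0.0
        corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    return corr


# ---------------------------------------------------------------------------
# GCT #1.3 text I/O
# ---------------------------------------------------------------------------

def read_gct(path) -> SignatureMatrix:
    """Read a GCT #1.3 text file into a :class:`SignatureMatrix`.

    Row metadata columns are skipped; column metadata rows are skipped.
    The returned matrix has no reagent metadata attached (see
    :func:`read_meta_tsv`).
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        version = fh.readline().strip()
        if version != "#1.3":
            raise UnsupportedFormatError(
                f"expected GCT version '#1.3', found {version!r}"
            )
        dims = fh.readline().split()
        if len(dims) not in (2, 4):
            raise CorruptFileError("malformed GCT dimensions line")
        n_rows, n_cols = int(dims[0]), int(dims[1])
        n_rmeta = int(dims[2]) if len(dims) == 4 else 0
        n_cmeta = int(dims[3]) if len(dims) == 4 else 0
        header = fh.readline().rstrip("\n").split("\t")
        expected_fields = 1 + n_rmeta + n_cols
        if len(header) != expected_fields:
            raise CorruptFileError(
                f"header has {len(header)} fields, expected {expected_fields}"
            )
        sig_ids = header[1 + n_rmeta:]
        for _ in range(n_cmeta):
            fh.readline()
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != expected_fields:
                raise CorruptFileError("data row width disagrees with header")
            gene_ids.append(fields[0])
            try:
                rows.append([float(v) for v in fields[1 + n_rmeta:]])
            except ValueError as exc:
                raise CorruptFileError(f"non-numeric data value: {exc}") from exc
    if len(gene_ids) != n_rows:
        raise CorruptFileError(
            f"declared {n_rows} rows but found {len(gene_ids)}"
        )
    data = pd.DataFrame(rows, index=gene_ids, columns=sig_ids)
    return SignatureMatrix(data)


def write_gct(matrix: SignatureMatrix, path) -> None:
    """Write a :class:`SignatureMatrix` as GCT #1.3 text.

    Values are written with ``repr`` round-trip precision so that
    ``read_gct(write_gct(m))`` reproduces the matrix bit-exactly.
    """
    if matrix.n_sigs < 1:
        raise InvalidInputError("GCT requires at least one signature column")
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("#1.3\n")
        fh.write(f"{matrix.n_genes}\t{matrix.n_sigs}\t0\t0\n")
        fh.write("id\t" + "\t".join(matrix.sigs) + "\n")
        arr = matrix.data.to_numpy()
        for gene, row in zip(matrix.genes, arr):
            fh.write(gene + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_meta_tsv(path) -> pd.DataFrame:
    """Read a reagent-metadata TSV indexed by sig_id."""
    meta = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "sig_id" not in meta.columns:
        raise InvalidInputError("metadata TSV must have a sig_id column")
    meta = meta.set_index("sig_id")
    meta = meta.replace({"": None})
    return meta


def write_meta_tsv(meta: pd.DataFrame, path) -> None:
    out = meta.reset_index().rename(columns={"index": "sig_id"})
    if out.columns[0] != "sig_id":
        out = out.rename(columns={out.columns[0]: "sig_id"})
    out.to_csv(path, sep="\t", index=False)


def load_dataset(gct_path, meta_path) -> SignatureMatrix:
    """Read signatures and reagent metadata and align them."""
    mat = read_gct(gct_path)
    meta = read_meta_tsv(meta_path)
    return SignatureMatrix(mat.data, meta)


# ---------------------------------------------------------------------------
# Replicate collapse
# ---------------------------------------------------------------------------

def modz_weights_from_corr(corr: np.ndarray) -> np.ndarray:
    """modz weights from a pairwise correlation matrix.

    The diagonal is zeroed, each member's raw weight is its row sum,
    negative row sums are clipped to 0, and weights are normalized to sum
    to 1.  If every row sum is <= 0 the members are weighted equally.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise InvalidInputError("correlation matrix must be square")
    n = corr.shape[0]
    if n < 2:
        raise InvalidInputError("modz weights need at least 2 members")
    if not np.allclose(corr, corr.T, atol=1e-8):
        raise InvalidInputError("correlation matrix must be symmetric")
    work = corr.copy()
    np.fill_diagonal(work, 0.0)
    raw = work.sum(axis=1)
    raw = np.clip(raw, 0.0, None)
    total = raw.sum()
    if total <= 0:
        return np.full(n, 1.0 / n)
    return raw / total


def collapse_replicates(reps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """modz-weighted average of replicate signatures.

    ``reps`` is genes x n_replicates.  Returns ``(collapsed, weights)``.
    A single replicate is returned unchanged with weight [1] and a warning.
    """
    reps = np.asarray(reps, dtype=float)
    if reps.ndim != 2 or reps.shape[1] < 1:
        raise InvalidInputError("need a genes x replicates matrix")
    if reps.shape[1] == 1:
        warnings.warn("single replicate: returned unchanged", stacklevel=2)
        return reps[:, 0].copy(), np.array([1.0])
    corr = pairwise_correlation_matrix(reps)
    w = modz_weights_from_corr(corr)
    return reps @ w, w


def replicate_q75(reps: np.ndarray) -> float:
    """75th percentile (linear interpolation) of the off-diagonal pairwise
    Spearman correlations of a replicate set — the standard CMAP
    reproducibility score."""
    reps = np.asarray(reps, dtype=float)
    if reps.ndim != 2 or reps.shape[1] < 2:
        raise InvalidInputError("need at least 2 replicates")
    corr = pairwise_correlation_matrix(reps)
    iu = np.triu_indices(corr.shape[0], k=1)
    return float(np.percentile(corr[iu], 75, method="linear"))


def collapse_dataset(matrix: SignatureMatrix) -> SignatureMatrix:
    """Collapse replicate-level signatures to one signature per
    replicate_group via the modz weighted average.

    The collapsed matrix keeps one metadata row per group (replicate-level
    sig ids are replaced by the group key).
    """
    if "replicate_group" not in matrix.meta.columns:
        raise InvalidInputError("metadata must define replicate_group")
    groups = matrix.meta.groupby("replicate_group", sort=True).groups
    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for group_key, sig_ids in groups.items():
            vals = matrix.values_for(list(sig_ids))
            collapsed, _ = collapse_replicates(vals)
            cols[str(group_key)] = collapsed
            row = matrix.meta.loc[list(sig_ids)[0]].copy()
            row.name = str(group_key)
            meta_rows.append(row)
    data = pd.DataFrame(cols, index=matrix.data.index)
    meta = pd.DataFrame(meta_rows)
    return SignatureMatrix(data, meta)
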