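"""Global first-principal-component ("generic response") removal.

Large signature collections share one dominant axis of variation that is
independent of the perturbation's gene target — a generic transcriptional
response accounting for a sizeable fraction (on real L1000 data, roughly
10–20%) of signature variance.  Removing the component of every signature
along this globally fitted axis reduces the spurious correlation floor
between unrelated consensus signatures.

:class:`PC1Remover` follows the scikit-learn transformer protocol (rows =
signatures, columns = genes); :func:`fit_global_pca` / :func:`remove_pc1`
wrap it for :class:`~perturbsig.core.SignatureMatrix` objects (genes x
signatures) and a JSON-serializable :class:`PCModel`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .core import SignatureMatrix
from .errors import DegenerateDataError, InvalidInputError


class PC1Remover(TransformerMixin, BaseEstimator):
    """Fit the global PC1 of a signature collection and subtract it.

    ``transform`` mean-centers each signature (per gene), removes the
    component along the fitted first principal axis, and adds the mean
    back: ``x' = mean + (x - mean) - u (uᵀ(x - mean))``.  The operation is
    idempotent and leaves directions orthogonal to PC1 untouched.

    Attributes
    ----------
    mean_ : (n_genes,) per-gene mean z-score over the fitted signatures.
    components_ : (1, n_genes) unit PC1 direction; sign fixed so the
        largest-magnitude loading is positive (SVD sign is arbitrary).
    explained_variance_ratio_ : fraction of total variance per component,
        non-increasing.
    """

    def fit(self, X, y=None):
        X = check_array(X, dtype=float, ensure_min_samples=2)
        self.mean_ = X.mean(axis=0)
        centered = X - self.mean_
        if not np.any(centered):
            raise DegenerateDataError("constant matrix has no principal axes")
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        pc1 = vt[0]
        if pc1[np.argmax(np.abs(pc1))] < 0:
            pc1 = -pc1
        self.components_ = pc1[None, :]
        total = float((s ** 2).sum())
        self.explained_variance_ratio_ = s ** 2 / total
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise InvalidInputError("gene dimension does not match the fit")
        centered = X - self.mean_
        u = self.components_[0]
        return self.mean_ + centered - np.outer(centered @ u, u)


@dataclass
class PCModel:
    """Serializable global PCA summary: per-gene mean, unit PC1 direction,
    and the variance fraction spectrum."""

    gene_ids: list
    mean_vector: np.ndarray
    pc1_direction: np.ndarray
    variance_fractions: np.ndarray

    def __post_init__(self) -> None:
        self.mean_vector = np.asarray(self.mean_vector, dtype=float)
        self.pc1_direction = np.asarray(self.pc1_direction, dtype=float)
        self.variance_fractions = np.asarray(self.variance_fractions,
                                             dtype=float)
        if abs(np.linalg.norm(self.pc1_direction) - 1.0) > 1e-9:
            raise InvalidInputError("pc1_direction must be unit length")
        vf = self.variance_fractions
        if ((vf < -1e-12) | (vf > 1 + 1e-12)).any() or (np.diff(vf) > 1e-12).any():
            raise InvalidInputError(
                "variance fractions must lie in [0,1] and be non-increasing"
            )

    def to_json(self, path) -> None:
        payload = dict(
            gene_ids=list(self.gene_ids),
            mean_vector=self.mean_vector.tolist(),
            pc1_direction=self.pc1_direction.tolist(),
            variance_fractions=self.variance_fractions.tolist(),
        )
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PCModel":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**json.load(fh))


def fit_global_pca(matrix: SignatureMatrix) -> PCModel:
    """Fit the global PCA of a signature collection (signatures as
    samples, genes as features) and return the PC1 summary."""
    if matrix.n_sigs < 2:
        raise InvalidInputError("global PCA needs at least 2 signatures")
    est = PC1Remover().fit(matrix.data.to_numpy().T)
    return PCModel(
        gene_ids=matrix.genes,
        mean_vector=est.mean_,
        pc1_direction=est.components_[0],
        variance_fractions=est.explained_variance_ratio_,
    )


def remove_pc1(matrix: SignatureMatrix, model: PCModel,
               recenter_mean: Optional[np.ndarray] = None) -> SignatureMatrix:
    """Remove the PC1 component from every signature in the matrix.

    The matrix's gene order must match the model's.  The per-gene mean is
    subtracted, the PC1 projection removed, and the mean added back.
    """
    if matrix.genes != list(model.gene_ids):
        raise InvalidInputError("gene order does not match the fitted model")
    u = model.pc1_direction
    mean = model.mean_vector if recenter_mean is None else recenter_mean
    X = matrix.data.to_numpy().T  # signatures x genes
    centered = X - mean
    cleaned = mean + centered - np.outer(centered @ u, u)
    data = matrix.data.copy()
    data.iloc[:, :] = cleaned.T
    return SignatureMatrix(data, matrix.meta)
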