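"""SVD subspace classifier for complex transmission spectra.

Each class's training vectors (columns of X_c) span a subspace estimated by
singular value decomposition; a test vector is scored by the Euclidean norm
of its projection residual onto each class subspace, and the decision value
is the difference of the two distances (bleeding minus healthy, so negative
values favor "bleeding").  The raw complex spectra are classified as-is: no
centering, normalization, or other preprocessing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

from .records import TransmissionRecord

__all__ = [
    "vectorize",
    "ClassSubspace",
    "fit_subspace",
    "subspace_distance",
    "decision_value",
    "residuals_by_dimension",
]


def vectorize(record: TransmissionRecord) -> np.ndarray:
    """Flatten a record to the classifier feature vector.

    Frequency-major order: element ``f * n_pairs + p`` is pair ``p`` at
    frequency ``f``.  267 frequencies x 120 pairs give 32040 elements.  No
    further preprocessing is applied.
    """
    if not np.all(np.isfinite(record.s)):
        raise ValueError("record contains non-finite entries")
    return record.s.ravel(order="C")


@dataclass
class ClassSubspace:
    """Orthonormal basis of one class's training span.

    ``basis`` columns are the leading ``dimension`` left singular vectors of
    the training matrix, ordered by decreasing singular value.
    """

    basis: np.ndarray
    dimension: int
    label: str
    n_train: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.basis = np.asarray(self.basis, dtype=complex)
        if self.basis.ndim != 2 or self.basis.shape[1] != self.dimension:
            raise ValueError("basis must be (n_features, dimension)")
        gram = self.basis.conj().T @ self.basis
        if not np.allclose(gram, np.eye(self.dimension), atol=1e-10):
            raise ValueError("basis columns are not orthonormal")

    def save_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("basis", data=self.basis)
            f.attrs["dimension"] = self.dimension
            f.attrs["label"] = self.label
            f.attrs["n_train"] = self.n_train
            f.attrs["metadata"] = json.dumps(self.metadata, default=str)

    @classmethod
    def load_hdf5(cls, path) -> "ClassSubspace":
        with h5py.File(path, "r") as f:
            return cls(
                basis=f["basis"][...],
                dimension=int(f.attrs["dimension"]),
                label=str(f.attrs["label"]),
                n_train=int(f.attrs["n_train"]),
                metadata=json.loads(f.attrs["metadata"]),
            )


def fit_subspace(vectors, d: int, label: str = "") -> ClassSubspace:
    """Estimate a class subspace of dimension ``d`` from training vectors.

    ``vectors`` is a sequence of complex feature vectors (or an
    (n_features, t_c) matrix whose columns are the vectors).  The thin SVD of
    the n x t_c matrix is used directly, never the n x n Gram matrix.
    """
    X = np.asarray(vectors, dtype=complex)
    if X.ndim == 2 and not isinstance(vectors, np.ndarray):
        X = X.T  # sequence of vectors -> columns
    elif X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError("training data must form a 2D matrix")
    t_c = X.shape[1]
    if not (1 <= d <= t_c):
        raise ValueError(f"subspace dimension {d} not in 1..{t_c}")
    if not np.any(X):
        raise ValueError("training matrix is identically zero")
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    return ClassSubspace(basis=u[:, :d], dimension=d, label=label, n_train=t_c,
                         metadata={"singular_values": s[:d].tolist()})


def subspace_distance(x: np.ndarray, sub: ClassSubspace) -> float:
    """Euclidean norm of the projection residual ``||x - U U^H x||``."""
    x = np.asarray(x, dtype=complex)
    if x.shape != (sub.basis.shape[0],):
        raise ValueError(
            f"vector length {x.shape} does not match subspace "
            f"feature count {sub.basis.shape[0]}")
    coeff = sub.basis.conj().T @ x
    resid = x - sub.basis @ coeff
    return float(np.linalg.norm(resid))


def decision_value(x: np.ndarray, bleed: ClassSubspace,
                   healthy: ClassSubspace) -> float:
    """Distance-to-bleeding minus distance-to-healthy.

    Negative values favor the bleeding class.
    """
    return subspace_distance(x, bleed) - subspace_distance(x, healthy)


def residuals_by_dimension(basis: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Projection-residual norms for every truncation of a fitted basis.

    Given an orthonormal ``basis`` (n_features, d_max) and test vectors as
    columns of ``X`` (n_features, m), returns an array (d_max, m) whose row
    ``d-1`` holds ``||x - U_d U_d^H x||`` for the rank-d truncation.  Used by
    the cross-validation loops to sweep the dimension grid with one SVD.
    """
    coeff = basis.conj().T @ X                       # (d_max, m)
    norms_sq = np.sum(np.abs(X) ** 2, axis=0).real   # (m,)
    captured = np.cumsum(np.abs(coeff) ** 2, axis=0)
    resid_sq = np.maximum(norms_sq[None, :] - captured, 0.0)
    return np.sqrt(resid_sq)
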