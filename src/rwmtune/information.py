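"""Information metrics: the SPD matrix defining the ESJD norm and preconditioner.

The Fisher information :math:`I(\\theta_0)` (or an estimate such as the
standardized observed information) plays two roles in optimal-scaling
analysis: its inverse is the limiting posterior covariance, and it defines
the norm :math:`\\|x\\|_I^2 = x^T I x` in which the expected squared jumping
distance is measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

__all__ = ["InformationMetric"]

_SYM_RTOL = 1e-10


@dataclass(frozen=True)
class InformationMetric:
    """A symmetric positive-definite matrix with its inverse and Cholesky factor.

    Attributes
    ----------
    matrix
        The information matrix ``I`` (d x d, SPD).
    inverse
        ``I^{-1}``, the target covariance.
    chol_factor
        Lower-triangular ``M`` with ``M @ M.T == inverse`` — the
        preconditioner used to build proposal scalings.
    """

    matrix: np.ndarray
    inverse: np.ndarray = field(repr=False)
    chol_factor: np.ndarray = field(repr=False)

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "InformationMetric":
        """Build from the information matrix itself, validating SPD-ness."""
        matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
        _check_spd(matrix)
        inverse = linalg.inv(matrix)
        inverse = 0.5 * (inverse + inverse.T)
        chol = linalg.cholesky(inverse, lower=True)
        return cls(matrix=matrix, inverse=inverse, chol_factor=chol)

    @classmethod
    def from_inverse(cls, inverse: np.ndarray) -> "InformationMetric":
        """Build from the target covariance ``I^{-1}``."""
        inverse = np.atleast_2d(np.asarray(inverse, dtype=float))
        _check_spd(inverse)
        matrix = linalg.inv(inverse)
        matrix = 0.5 * (matrix + matrix.T)
        chol = linalg.cholesky(inverse, lower=True)
        return cls(matrix=matrix, inverse=inverse, chol_factor=chol)

    @classmethod
    def identity(cls, d: int) -> "InformationMetric":
        eye = np.eye(d)
        return cls(matrix=eye, inverse=eye.copy(), chol_factor=eye.copy())

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]

    def norm_sq(self, x: np.ndarray) -> np.ndarray:
        """Quadratic form ``x^T I x``; rows of a 2-D input are treated as vectors."""
        x = np.asarray(x, dtype=float)
        if x.ndim == 1:
            return float(x @ self.matrix @ x)
        return np.einsum("ij,jk,ik->i", x, self.matrix, x)

    def is_scalar_multiple_of_identity(self, rtol: float = 1e-12) -> bool:
        c = self.matrix[0, 0]
        return bool(np.allclose(self.matrix, c * np.eye(self.dim), rtol=rtol,
                                atol=rtol * max(abs(c), 1.0)))


def _check_spd(matrix: np.ndarray) -> None:
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {matrix.shape}")
    scale = np.abs(matrix).max()
    if not np.allclose(matrix, matrix.T, rtol=_SYM_RTOL, atol=_SYM_RTOL * max(scale, 1.0)):
        raise ValueError("information matrix is not symmetric")
    eigvals = linalg.eigvalsh(matrix)
    if eigvals[0] <= 0:
        raise ValueError(
            f"information matrix is not positive definite: smallest eigenvalue {eigvals[0]:.6g}"
        )
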