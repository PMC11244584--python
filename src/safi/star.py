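"""The star operation: elementwise product of two linear projections.

For augmented input x = (x_1..x_d, 1) and weight vectors w1, w2 (bias folded
in as the last element), the scalar star product (w1.x)(w2.x) expands into a
quadratic form over all monomials x_i x_j — a (d+2)(d+1)/2-dimensional
implicit feature space obtained without extra computation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StarOperands",
    "star_product",
    "star_product_expanded",
    "star_coefficients",
    "coefficient_expansion",
    "n_monomials",
]


@dataclass(frozen=True)
class StarOperands:
    """Operands of the scalar star operation.

    w1, w2 : weight vectors of length d+1 (bias appended as last element)
    x      : input vector of length d+1 with trailing 1 appended
    d      : input channel count
    """

    w1: np.ndarray
    w2: np.ndarray
    x: np.ndarray
    d: int

    def __post_init__(self):
        w1 = np.asarray(self.w1, dtype=float)
        w2 = np.asarray(self.w2, dtype=float)
        x = np.asarray(self.x, dtype=float)
        object.__setattr__(self, "w1", w1)
        object.__setattr__(self, "w2", w2)
        object.__setattr__(self, "x", x)
        if self.d < 1:
            raise ValueError("d must be a positive integer")
        n = self.d + 1
        if not (w1.shape == w2.shape == x.shape == (n,)):
            raise ValueError(
                f"w1/w2/x must all have length d+1={n}; "
                f"got {w1.shape}, {w2.shape}, {x.shape}"
            )
        if x[-1] != 1.0:
            raise ValueError("last element of x must be 1 (appended bias input)")

    @classmethod
    def from_raw(cls, w1, b1, w2, b2, x):
        """Build operands from unaugmented weights/biases/input."""
        x = np.asarray(x, dtype=float)
        return cls(
            w1=np.append(np.asarray(w1, dtype=float), b1),
            w2=np.append(np.asarray(w2, dtype=float), b2),
            x=np.append(x, 1.0),
            d=x.size,
        )


def star_product(ops: StarOperands) -> float:
    """(w1.x) * (w2.x)."""
    return float(np.dot(ops.w1, ops.x) * np.dot(ops.w2, ops.x))


def star_product_expanded(ops: StarOperands) -> float:
    """The same value via the explicit double sum over index pairs (i, j)."""
    total = 0.0
    n = ops.d + 1
    for i in range(n):
        for j in range(n):
            total += ops.w1[i] * ops.w2[j] * ops.x[i] * ops.x[j]
    return float(total)


def star_coefficients(ops: StarOperands) -> np.ndarray:
    """Symmetric matrix of monomial coefficients alpha(i, j).

    alpha(i,i) = w1_i w2_i; alpha(i,j) = w1_i w2_j + w1_j w2_i for i != j.
    Summing alpha(i,j) x_i x_j over i <= j reproduces the star product.
    """
    outer = np.outer(ops.w1, ops.w2)
    alpha = outer + outer.T
    np.fill_diagonal(alpha, np.diag(outer))
    return alpha


def coefficient_expansion(ops: StarOperands) -> float:
    """Evaluate sum_{i<=j} alpha(i,j) x_i x_j."""
    alpha = star_coefficients(ops)
    n = ops.d + 1
    iu = np.triu_indices(n)
    return float(np.sum(alpha[iu] * ops.x[iu[0]] * ops.x[iu[1]]))


def n_monomials(d: int) -> int:
    """Number of distinct monomials x_i x_j, i <= j, for input dimension d."""
    return (d + 2) * (d + 1) // 2
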