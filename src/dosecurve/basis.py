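"""Low-rank thin-plate regression spline basis on the log10-dose axis.

Construction follows the eigen-truncation approach for thin-plate regression
splines: the full thin-plate spline on the unique design points is reduced to
a small basis by keeping the leading eigenvectors of the radial-kernel matrix,
with the constant and linear functions spanning the penalty null space.

For one covariate with a second-derivative penalty the radial kernel is
``eta(r) = r**3`` (the constant factor is absorbed by the smoothing
parameter). The resulting basis of total dimension ``J`` has ``J - 2``
penalized columns plus the unpenalized ``[1, x]`` null space, and reproduces
any straight line exactly with zero penalty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = ["SplineBasis", "build_spline_basis"]


class BasisError(ValueError):
    """Raised when a spline basis cannot be constructed from the design."""


def _eta(r: np.ndarray) -> np.ndarray:
    return np.abs(r) ** 3


def _eta_deriv(u: np.ndarray) -> np.ndarray:
    # d|u|^3/du = 3 u |u|
    return 3.0 * u * np.abs(u)


@dataclass
class SplineBasis:
    """Evaluation rule and wiggliness penalty of a rank-``J`` spline basis.

    Columns are ordered ``[1, x, s_1(x), ..., s_{J-2}(x)]``; the penalty
    matrix ``S`` is zero on the first two (null-space) coordinates.
    """

    knots: np.ndarray          # unique design x values
    weights: np.ndarray        # (n_knots, J-2) eigen-truncated kernel weights
    S: np.ndarray              # (J, J) symmetric PSD penalty
    J: int
    nullspace_dim: int = 2

    def evaluate(self, x) -> np.ndarray:
        """Evaluate the J basis functions at ``x``; returns (m, J)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        radial = _eta(x[:, None] - self.knots[None, :]) @ self.weights
        return np.column_stack([np.ones_like(x), x, radial])

    def derivative(self, x) -> np.ndarray:
        """First derivative of each basis function at ``x``; returns (m, J)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        radial = _eta_deriv(x[:, None] - self.knots[None, :]) @ self.weights
        return np.column_stack([np.zeros_like(x), np.ones_like(x), radial])


def build_spline_basis(x_values, J: int = 4) -> SplineBasis:
    """Construct the rank-``J`` thin-plate regression spline basis.

    Parameters
    ----------
    x_values : array-like
        Design points (log10 doses, baseline included). Only the unique
        values act as knots.
    J : int
        Total basis dimension including the 2-dimensional linear null space.
        Degraded to the number of distinct design points when fewer than
        ``J`` are available.
    """
    knots = np.unique(np.asarray(x_values, dtype=float))
    if knots.size < 3:
        raise BasisError(
            f"need at least 3 distinct design points for a spline basis, got {knots.size}"
        )
    J = int(min(J, knots.size))
    if J < 3:
        raise BasisError("basis dimension must be at least 3")

    n_pen = J - 2
    E = _eta(knots[:, None] - knots[None, :])
    T = np.column_stack([np.ones_like(knots), knots])

    # leading eigenvectors of the kernel matrix by magnitude
    eigval, eigvec = linalg.eigh(E)
    order = np.argsort(np.abs(eigval))[::-1]
    # keep enough columns that, after removing the 2 null-space constraints,
    # n_pen penalized directions remain
    k = n_pen + 2
    Uk = eigvec[:, order[:k]]
    Dk = eigval[order[:k]]

    # absorb the thin-plate side constraint T' delta = 0
    Z = linalg.null_space(T.T @ Uk)          # (k, k-2)
    W = Uk @ Z                               # knot weights, (n_knots, n_pen)
    S_pen = Z.T @ (Dk[:, None] * Z)          # = Z' Uk' E Uk Z
    S_pen = 0.5 * (S_pen + S_pen.T)
    # clip numerically negative curvature directions (the constrained kernel
    # quadratic form is PSD in exact arithmetic)
    w, V = linalg.eigh(S_pen)
    S_pen = (V * np.clip(w, 0.0, None)) @ V.T

    S = np.zeros((J, J))
    S[2:, 2:] = S_pen
    return SplineBasis(knots=knots, weights=W, S=S, J=J)
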