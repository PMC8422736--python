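"""Penalized B-spline bases (P-splines) for the habitat-selection GLMs.

Two flavours are provided: an ordinary cubic B-spline basis with a
second-order difference penalty, used for the availability deviation
smooth, and a cyclic (wrapped) variant for periodic covariates such as
hour of day and month of year.  Tensor products of the cyclic bases
carry the joint diurnal x seasonal smooth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "BSplineBasis",
    "CyclicBasis",
    "tensor_design",
    "tensor_penalty",
    "difference_penalty",
    "cyclic_difference_penalty",
]


def difference_penalty(k: int, order: int = 2) -> np.ndarray:
    """Penalty matrix D'D for order-th differences of k coefficients."""
    D = np.diff(np.eye(k), n=order, axis=0)
    return D.T @ D


def cyclic_difference_penalty(k: int, order: int = 2) -> np.ndarray:
    """Cyclic second-difference penalty: differences wrap around the period."""
    D = np.zeros((k, k))
    for i in range(k):
        if order == 2:
            D[i, i] = 1.0
            D[i, (i + 1) % k] = -2.0
            D[i, (i + 2) % k] = 1.0
        else:  # pragma: no cover - only order 2 used
            raise ValueError("only order-2 cyclic penalties supported")
    return D.T @ D


@dataclass
class BSplineBasis:
    """Cubic B-spline basis on [lo, hi] with uniformly spaced knots.

    Parameters
    ----------
    lo, hi : float
        Support of the basis (training range of the covariate).
    n_basis : int
        Number of basis functions (columns).
    """

    lo: float
    hi: float
    n_basis: int = 8
    degree: int = 3
    knots: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.hi <= self.lo:
            raise ValueError("basis support must have positive width")
        n_interior = self.n_basis - self.degree - 1
        if n_interior < 0:
            raise ValueError("n_basis too small for cubic degree")
        interior = np.linspace(self.lo, self.hi, n_interior + 2)[1:-1]
        self.knots = np.concatenate(
            [np.full(self.degree + 1, self.lo), interior, np.full(self.degree + 1, self.hi)]
        )

    def design(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        # clip: evaluation outside the support is the caller's (flagged) choice;
        # the basis extends the boundary value rather than exploding.
        xc = np.clip(x, self.lo, self.hi)
        return BSpline.design_matrix(xc, self.knots, self.degree).toarray()

    def penalty(self) -> np.ndarray:
        return difference_penalty(self.n_basis)


@dataclass
class CyclicBasis:
    """Cubic B-spline basis wrapped on a circle of the given period.

    The unwrapped basis lives on uniformly spaced knots over one period;
    columns whose indices coincide modulo ``n_basis`` are summed so the
    resulting functions (and their derivatives up to order 2) are
    periodic.
    """

    period: float
    n_basis: int = 8
    degree: int = 3

    def design(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float) % self.period
        k, K, P = self.degree, self.n_basis, self.period
        h = P / K
        # knots from -k*h to (K+k)*h cover one period with wrap margins
        t = np.arange(-k, K + k + 1) * h
        full = BSpline.design_matrix(x, t, k).toarray()  # K + k columns... see below
        n_un = len(t) - k - 1
        out = np.zeros((len(x), K))
        for j in range(n_un):
            out[:, j % K] += full[:, j]
        return out

    def penalty(self) -> np.ndarray:
        return cyclic_difference_penalty(self.n_basis)


def tensor_design(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise Kronecker product of two design matrices."""
    n = A.shape[0]
    if B.shape[0] != n:
        raise ValueError("design matrices must have equal row counts")
    return (A[:, :, None] * B[:, None, :]).reshape(n, -1)


def tensor_penalty(Sa: np.ndarray, Sb: np.ndarray) -> np.ndarray:
    """Isotropic tensor-product penalty Sa (x) I + I (x) Sb."""
    ka, kb = Sa.shape[0], Sb.shape[0]
    return np.kron(Sa, np.eye(kb)) + np.kron(np.eye(ka), Sb)
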