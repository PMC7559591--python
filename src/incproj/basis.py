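"""Spline bases, tensor-product designs and random-walk structure matrices.

Building blocks for the smooth model terms: B-spline and M-spline
marginal bases (M-splines are non-negative B-splines rescaled so each
basis function integrates to one), the row-wise Kronecker product that
turns two marginal bases into a tensor-product interaction design, and
the intrinsic structure matrices (second-order random walk, iid) whose
scaled versions act as Gaussian prior precisions on random effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "BasisMatrix",
    "StructureMatrix",
    "bspline_basis",
    "mspline_basis",
    "tensor_product_rows",
    "rw2_structure",
    "iid_structure",
    "second_difference_matrix",
]


@dataclass(frozen=True)
class BasisMatrix:
    """A spline (or tensor-product) design matrix with its knot metadata."""

    values: np.ndarray  # (n observations, q basis functions)
    kind: str  # bspline | mspline | tensor
    knots: np.ndarray
    degree: int

    @property
    def n_basis(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class StructureMatrix:
    """Symmetric PSD prior structure ``Q``; the precision scales it at fit time."""

    Q: np.ndarray
    rank_deficiency: int
    kind: str  # rw2 | iid

    @property
    def n(self) -> int:
        return self.Q.shape[0]

    @property
    def rank(self) -> int:
        return self.n - self.rank_deficiency


def _knot_vector(x: np.ndarray, n_basis: int, degree: int,
                 span: tuple[float, float] | None = None) -> np.ndarray:
    """Clamped knot vector: quantile interior knots, (degree+1)-fold boundary."""
    lo, hi = (float(np.min(x)), float(np.max(x))) if span is None else span
    n_interior = n_basis - degree - 1
    if n_interior > 0:
        probs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(np.asarray(x, dtype=float), probs)
    else:
        interior = np.empty(0)
    return np.concatenate([np.full(degree + 1, lo), interior, np.full(degree + 1, hi)])


def _design(x: np.ndarray, knots: np.ndarray, degree: int) -> np.ndarray:
    B = BSpline.design_matrix(np.asarray(x, dtype=float), knots, degree,
                              extrapolate=False)
    return np.asarray(B.todense())


def bspline_basis(x, n_basis: int, degree: int = 3,
                  span: tuple[float, float] | None = None) -> BasisMatrix:
    """B-spline design matrix on quantile-placed clamped knots.

    Parameters
    ----------
    x : array-like
        Evaluation points; must lie within ``span`` (defaults to the
        range of ``x``).
    n_basis : int
        Number of basis functions; must be at least ``degree + 1``.
    degree : int
        Polynomial degree (0 gives interval indicators).
    span : (lo, hi), optional
        Boundary-knot span; pass explicitly to evaluate a basis built
        on a training range at projection points.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if x.size == 0:
        raise ValueError("x is empty")
    if n_basis < degree + 1:
        raise ValueError(f"n_basis={n_basis} < degree+1={degree + 1}")
    knots = _knot_vector(x, n_basis, degree, span)
    return BasisMatrix(_design(x, knots, degree), "bspline", knots, degree)


def mspline_basis(x, n_basis: int, degree: int = 3,
                  span: tuple[float, float] | None = None) -> BasisMatrix:
    """M-spline basis: each column is the B-spline column rescaled by
    ``(degree + 1) / (support length)`` so it integrates to one."""
    b = bspline_basis(x, n_basis, degree, span)
    t = b.knots
    support = t[degree + 1: degree + 1 + n_basis] - t[:n_basis]
    return BasisMatrix(b.values * ((degree + 1) / support), "mspline", t, degree)


def tensor_product_rows(A: BasisMatrix | np.ndarray,
                        P: BasisMatrix | np.ndarray) -> BasisMatrix:
    """Row-wise Kronecker product: row i of the result is kron(A_i, P_i).

    This is the tensor-product smooth model matrix: with marginal bases
    for age and period sharing observation rows, the product basis spans
    smooth age x period interaction surfaces.
    """
    Av = A.values if isinstance(A, BasisMatrix) else np.asarray(A, dtype=float)
    Pv = P.values if isinstance(P, BasisMatrix) else np.asarray(P, dtype=float)
    if Av.shape[0] != Pv.shape[0]:
        raise ValueError(f"row mismatch: {Av.shape[0]} vs {Pv.shape[0]}")
    Z = np.einsum("ij,ik->ijk", Av, Pv).reshape(Av.shape[0], -1)
    degree = max(
        A.degree if isinstance(A, BasisMatrix) else 0,
        P.degree if isinstance(P, BasisMatrix) else 0,
    )
    return BasisMatrix(Z, "tensor", np.empty(0), degree)


def second_difference_matrix(n: int) -> np.ndarray:
    """(n-2) x n matrix D with rows (1, -2, 1) applying second differences."""
    if n < 3:
        raise ValueError("second differences need n >= 3")
    D = np.zeros((n - 2, n))
    idx = np.arange(n - 2)
    D[idx, idx] = 1.0
    D[idx, idx + 1] = -2.0
    D[idx, idx + 2] = 1.0
    return D


def rw2_structure(n: int) -> StructureMatrix:
    """Second-order random-walk structure ``Q = D'D``.

    ``Q`` penalizes second differences; its null space holds constant
    and linear vectors (rank deficiency 2), so an rw2 prior shrinks
    toward local linear trends and extrapolates them with growing
    variance.
    """
    D = second_difference_matrix(n)
    return StructureMatrix(D.T @ D, rank_deficiency=2, kind="rw2")


def iid_structure(n: int) -> StructureMatrix:
    """Independent-effects structure: the identity, full rank."""
    return StructureMatrix(np.eye(n), rank_deficiency=0, kind="iid")
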