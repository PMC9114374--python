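"""Tensor-product cubic B-spline spaces and Greville collocation operators.

The strong form of the growth equations is collocated at the Greville
abscissae of an open uniform B-spline space.  This module builds the
univariate spaces (Cox-de Boor recursion with the explicit derivative
recursion), the Greville points, and the sparse operators

    N    : coefficients -> values at the collocation lattice
    Du   : coefficients -> d/dx values
    Dv   : coefficients -> d/dy values
    Duu  : coefficients -> d2/dx2 values
    Dvv  : coefficients -> d2/dy2 values

The parametric and physical domains coincide (uniform knot spacing, identity
mapping), so no geometric Jacobian appears anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp

from .errors import (
    AssemblyError,
    DimensionError,
    InvalidSplineSpaceError,
    OutOfDomainError,
)

__all__ = [
    "KnotVector",
    "CollocationGrid",
    "make_open_knot_vector",
    "greville_abscissae",
    "evaluate_basis",
    "collocation_matrix",
    "build_collocation_grid",
    "values_to_coefficients",
    "coefficients_to_values",
]


@dataclass(frozen=True)
class KnotVector:
    """Open uniform knot vector.

    Attributes
    ----------
    degree : int
        Polynomial degree p (>= 1).
    knots : ndarray
        Nondecreasing knot sequence of length ``n + p + 1`` with the first
        and last knot repeated ``p + 1`` times.
    spacing : float
        Interior knot spacing.
    """

    degree: int
    knots: np.ndarray
    spacing: float

    @property
    def n_basis(self) -> int:
        return len(self.knots) - self.degree - 1

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.knots[0]), float(self.knots[-1])


def make_open_knot_vector(n_basis: int, p: int = 3,
                          spacing: float = 1.0,
                          start: float = 0.0) -> KnotVector:
    """Construct an open uniform knot vector with ``n_basis`` functions.

    The domain is ``[start, start + (n_basis - p) * spacing]`` with
    multiplicity ``p + 1`` end knots and uniformly spaced interior knots.

    Raises
    ------
    InvalidSplineSpaceError
        If ``n_basis < p + 1`` or ``spacing <= 0``.
    """
    if p < 1:
        raise InvalidSplineSpaceError(f"degree must be >= 1, got {p}")
    if n_basis < p + 1:
        raise InvalidSplineSpaceError(
            f"need at least p + 1 = {p + 1} basis functions, got {n_basis}")
    if spacing <= 0:
        raise InvalidSplineSpaceError(f"spacing must be > 0, got {spacing}")
    n_spans = n_basis - p
    interior = start + spacing * np.arange(1, n_spans)
    knots = np.concatenate([
        np.full(p + 1, start),
        interior,
        np.full(p + 1, start + n_spans * spacing),
    ])
    return KnotVector(degree=p, knots=knots, spacing=float(spacing))


def greville_abscissae(kv: KnotVector) -> np.ndarray:
    """Greville abscissae: the mean of p consecutive interior knots per basis.

    One point per basis function; for an open vector the first/last points
    coincide with the domain ends.
    """
    p = kv.degree
    n = kv.n_basis
    # g_i = (t_{i+1} + ... + t_{i+p}) / p  with 0-based knot indexing
    csum = np.concatenate([[0.0], np.cumsum(kv.knots)])
    return (csum[p + 1:p + 1 + n] - csum[1:1 + n]) / p


def _find_span(knots: np.ndarray, p: int, n: int, u: float) -> int:
    """Index i with knots[i] <= u < knots[i+1] (last span at the right end)."""
    if u >= knots[n]:
        return n - 1
    if u <= knots[p]:
        return p
    return int(np.searchsorted(knots, u, side="right") - 1)


def _ders_basis_funs(knots: np.ndarray, p: int, span: int, u: float,
                     nders: int) -> np.ndarray:
    """Nonzero basis functions and derivatives at u (Cox-de Boor recursion).

    Returns an array of shape ``(nders + 1, p + 1)``: row k holds the k-th
    derivative of the p + 1 basis functions supported on the span.
    """
    ndu = np.zeros((p + 1, p + 1))
    ndu[0, 0] = 1.0
    left = np.zeros(p + 1)
    right = np.zeros(p + 1)
    for j in range(1, p + 1):
        left[j] = u - knots[span + 1 - j]
        right[j] = knots[span + j] - u
        saved = 0.0
        for r in range(j):
            ndu[j, r] = right[r + 1] + left[j - r]
            temp = ndu[r, j - 1] / ndu[j, r]
            ndu[r, j] = saved + right[r + 1] * temp
            saved = left[j - r] * temp
        ndu[j, j] = saved

    ders = np.zeros((nders + 1, p + 1))
    ders[0, :] = ndu[:, p]
    a = np.zeros((2, p + 1))
    for r in range(p + 1):
        s1, s2 = 0, 1
        a[0, 0] = 1.0
        for k in range(1, nders + 1):
            d = 0.0
            rk = r - k
            pk = p - k
            if r >= k:
                a[s2, 0] = a[s1, 0] / ndu[pk + 1, rk]
                d = a[s2, 0] * ndu[rk, pk]
            j1 = 1 if rk >= -1 else -rk
            j2 = k - 1 if r - 1 <= pk else p - r
            for j in range(j1, j2 + 1):
                a[s2, j] = (a[s1, j] - a[s1, j - 1]) / ndu[pk + 1, rk + j]
                d += a[s2, j] * ndu[rk + j, pk]
            if r <= pk:
                a[s2, k] = -a[s1, k - 1] / ndu[pk + 1, r]
                d += a[s2, k] * ndu[r, pk]
            ders[k, r] = d
            s1, s2 = s2, s1
    # multiply by p! / (p - k)!
    fac = float(p)
    for k in range(1, nders + 1):
        ders[k, :] *= fac
        fac *= p - k
    return ders


def evaluate_basis(kv: KnotVector, u: float,
                   derivative_order: int = 0) -> sp.csr_matrix:
    """Sparse row of basis (or derivative) values at a single point.

    At most ``p + 1`` nonzeros; order-0 rows sum to 1 (partition of unity)
    and derivative rows sum to 0.

    Raises
    ------
    OutOfDomainError
        If ``u`` lies outside the knot span.
    """
    lo, hi = kv.domain
    tol = 1e-9 * max(hi - lo, 1.0)
    if u < lo - tol or u > hi + tol:
        raise OutOfDomainError(f"u = {u} outside domain [{lo}, {hi}]")
    u = min(max(u, lo), hi)
    p = kv.degree
    n = kv.n_basis
    span = _find_span(kv.knots, p, n, float(u))
    ders = _ders_basis_funs(kv.knots, p, span, float(u), derivative_order)
    cols = np.arange(span - p, span + 1)
    return sp.csr_matrix((ders[derivative_order], (np.zeros(p + 1, int), cols)),
                         shape=(1, n))


def collocation_matrix(kv: KnotVector, points: np.ndarray,
                       derivative_order: int = 0) -> sp.csr_matrix:
    """Sparse (len(points) x n_basis) matrix of basis derivative values."""
    p = kv.degree
    n = kv.n_basis
    npts = len(points)
    data = np.empty(npts * (p + 1))
    cols = np.empty(npts * (p + 1), dtype=np.int64)
    lo, hi = kv.domain
    tol = 1e-9 * max(hi - lo, 1.0)
    for i, u in enumerate(points):
        if u < lo - tol or u > hi + tol:
            raise OutOfDomainError(f"u = {u} outside domain [{lo}, {hi}]")
        u = min(max(u, lo), hi)
        span = _find_span(kv.knots, p, n, float(u))
        ders = _ders_basis_funs(kv.knots, p, span, float(u), derivative_order)
        data[i * (p + 1):(i + 1) * (p + 1)] = ders[derivative_order]
        cols[i * (p + 1):(i + 1) * (p + 1)] = np.arange(span - p, span + 1)
    rows = np.repeat(np.arange(npts, dtype=np.int64), p + 1)
    mat = sp.csr_matrix((data, (rows, cols)), shape=(npts, n))
    mat.sum_duplicates()
    return mat


@dataclass
class CollocationGrid:
    """Tensor-product collocation space on the Greville lattice.

    Field arrays are indexed ``F[i, j]`` with axis 0 the u/x direction and
    axis 1 the v/y direction; flattening is C-order, matching the Kronecker
    products ``kron(Op_u, Op_v)``.
    """

    kv_u: KnotVector
    kv_v: KnotVector
    greville_u: np.ndarray
    greville_v: np.ndarray
    # 1D sparse operators per direction
    N1u: sp.csr_matrix
    D1u: sp.csr_matrix
    D2u: sp.csr_matrix
    N1v: sp.csr_matrix
    D1v: sp.csr_matrix
    D2v: sp.csr_matrix
    # 2D sparse operators (coefficients, C-order flattened -> lattice values)
    N: sp.csr_matrix = field(repr=False, default=None)
    Du: sp.csr_matrix = field(repr=False, default=None)
    Dv: sp.csr_matrix = field(repr=False, default=None)
    Duu: sp.csr_matrix = field(repr=False, default=None)
    Dvv: sp.csr_matrix = field(repr=False, default=None)
    # dense 1D copies and LU factors for fast field <-> coefficient transforms
    _dNu: np.ndarray = field(repr=False, default=None)
    _dD1u: np.ndarray = field(repr=False, default=None)
    _dD2u: np.ndarray = field(repr=False, default=None)
    _dNv: np.ndarray = field(repr=False, default=None)
    _dD1v: np.ndarray = field(repr=False, default=None)
    _dD2v: np.ndarray = field(repr=False, default=None)
    _luNu: tuple = field(repr=False, default=None)
    _luNv: tuple = field(repr=False, default=None)

    @property
    def nu(self) -> int:
        return self.kv_u.n_basis

    @property
    def nv(self) -> int:
        return self.kv_v.n_basis

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nu, self.nv)

    @property
    def spacing(self) -> float:
        return self.kv_u.spacing

    @property
    def degree(self) -> int:
        return self.kv_u.degree

    def metadata(self) -> dict:
        """Grid header written into every output snapshot."""
        return {
            "nu": self.nu, "nv": self.nv, "p": self.degree,
            "spacing": self.spacing,
            "u0": float(self.kv_u.knots[0]), "v0": float(self.kv_v.knots[0]),
        }


def _singular_check(dense: np.ndarray, name: str):
    lu, piv = sla.lu_factor(dense, check_finite=False)
    d = np.abs(np.diag(lu))
    if d.min() < 1e-12 * max(d.max(), 1.0):
        raise AssemblyError(f"collocation matrix {name} is singular")
    return lu, piv


def build_collocation_grid(nu: int, nv: int, p: int = 3,
                           spacing: float = 1.0,
                           start_u: float = 0.0,
                           start_v: float = 0.0) -> CollocationGrid:
    """Assemble the full tensor-product collocation grid.

    Value interpolation at Greville points is well posed for open uniform
    knots; a singular value operator signals broken knot construction and
    raises :class:`AssemblyError`.
    """
    kv_u = make_open_knot_vector(nu, p, spacing, start=start_u)
    kv_v = make_open_knot_vector(nv, p, spacing, start=start_v)
    gu = greville_abscissae(kv_u)
    gv = greville_abscissae(kv_v)
    N1u = collocation_matrix(kv_u, gu, 0)
    D1u = collocation_matrix(kv_u, gu, 1)
    D2u = collocation_matrix(kv_u, gu, 2)
    N1v = collocation_matrix(kv_v, gv, 0)
    D1v = collocation_matrix(kv_v, gv, 1)
    D2v = collocation_matrix(kv_v, gv, 2)

    Iv = N1v
    Iu = N1u
    grid = CollocationGrid(
        kv_u=kv_u, kv_v=kv_v, greville_u=gu, greville_v=gv,
        N1u=N1u, D1u=D1u, D2u=D2u, N1v=N1v, D1v=D1v, D2v=D2v,
        N=sp.kron(Iu, Iv, format="csr"),
        Du=sp.kron(D1u, Iv, format="csr"),
        Dv=sp.kron(Iu, D1v, format="csr"),
        Duu=sp.kron(D2u, Iv, format="csr"),
        Dvv=sp.kron(Iu, D2v, format="csr"),
    )
    grid._dNu = N1u.toarray()
    grid._dD1u = D1u.toarray()
    grid._dD2u = D2u.toarray()
    grid._dNv = N1v.toarray()
    grid._dD1v = D1v.toarray()
    grid._dD2v = D2v.toarray()
    grid._luNu = _singular_check(grid._dNu, "N (u-direction)")
    grid._luNv = _singular_check(grid._dNv, "N (v-direction)")
    return grid


def values_to_coefficients(grid: CollocationGrid,
                           values: np.ndarray) -> np.ndarray:
    """Interpolate lattice values: solve ``N1u @ C @ N1v.T = V``.

    Round-trip coefficients -> values -> coefficients is identity to 1e-10.

    Raises
    ------
    DimensionError
        If ``values`` is not shaped ``(nu, nv)``.
    """
    if values.shape != grid.shape:
        raise DimensionError(
            f"values shape {values.shape} != lattice shape {grid.shape}")
    c = sla.lu_solve(grid._luNu, values, check_finite=False)
    c = sla.lu_solve(grid._luNv, c.T, check_finite=False).T
    return c


def coefficients_to_values(grid: CollocationGrid, coeffs: np.ndarray,
                           du: int = 0, dv: int = 0) -> np.ndarray:
    """Evaluate the spline (or a partial derivative) on the Greville lattice."""
    if coeffs.shape != grid.shape:
        raise DimensionError(
            f"coefficients shape {coeffs.shape} != lattice shape {grid.shape}")
    Au = (grid._dNu, grid._dD1u, grid._dD2u)[du]
    Av = (grid._dNv, grid._dD1v, grid._dD2v)[dv]
    return Au @ coeffs @ Av.T


def field_derivatives(grid: CollocationGrid, coeffs: np.ndarray):
    """Values and first/second derivatives on the lattice in one pass.

    Returns ``(f, fx, fy, fxx, fyy)``.
    """
    CNvT = coeffs @ grid._dNv.T
    CD1vT = coeffs @ grid._dD1v.T
    f = grid._dNu @ CNvT
    fx = grid._dD1u @ CNvT
    fy = grid._dNu @ CD1vT
    fxx = grid._dD2u @ CNvT
    fyy = grid._dNu @ (coeffs @ grid._dD2v.T)
    return f, fx, fy, fxx, fyy
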