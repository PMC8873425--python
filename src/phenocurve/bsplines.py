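"""B-spline bases, difference penalties and the P-spline mixed-model form.

A penalized B-spline (P-spline) curve is ``f(t) = B(t) theta`` with a
difference penalty ``lambda * theta' D'D theta`` (order-2 differences by
default).  The mixed-model reparameterization splits the curve into an
unpenalized linear part ``[1 | t]`` and a random smooth part whose
coefficients carry an identity penalty, so that the smoothing parameter
becomes a variance ratio ``lambda = sigma^2 / sigma_u^2`` and the whole
curve can be estimated inside a standard linear mixed model.

Knots are equally spaced and extended beyond the domain (the classical
equidistant P-spline construction).  With this placement the null space of
the order-2 difference penalty maps exactly onto {1, t}, which makes the
penalized fit and the mixed-model fit identical — with replicated boundary
knots the equivalence would only be approximate near the ends.  Evaluation
outside the domain raises ``DomainError`` unless clamping is requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

from .errors import DomainError

__all__ = [
    "BasisSpec",
    "MMBasis",
    "bspline_basis",
    "difference_matrix",
    "mm_transform",
    "derivative_basis",
    "integrate_curve",
]


@dataclass(frozen=True)
class BasisSpec:
    """Specification of a univariate B-spline basis.

    Parameters
    ----------
    domain
        Interval ``[a, b]`` covered by the basis.
    num_basis
        Number of basis functions ``b`` (>= degree + 1).
    degree
        Spline degree (cubic by default).
    penalty_order
        Order of the difference penalty on the coefficients.
    """

    domain: tuple[float, float]
    num_basis: int
    degree: int = 3
    penalty_order: int = 2

    def __post_init__(self):
        a, b = self.domain
        if not (np.isfinite(a) and np.isfinite(b) and a < b):
            raise ValueError(f"invalid domain {self.domain}")
        if self.num_basis < self.degree + 1:
            raise ValueError(
                f"num_basis={self.num_basis} must be >= degree+1={self.degree + 1}"
            )
        if self.penalty_order >= self.num_basis:
            raise ValueError("penalty order must be smaller than the basis dimension")

    @property
    def knots(self) -> np.ndarray:
        """Equidistant knot vector extended ``degree`` steps past each end."""
        a, b = self.domain
        h = (b - a) / (self.num_basis - self.degree)
        return a + h * (np.arange(self.num_basis + self.degree + 1) - self.degree)

    @property
    def greville(self) -> np.ndarray:
        """Greville abscissae (knot averages), affine in the coefficient
        index; linear functions c0 + c1*t are reproduced exactly by
        coefficients c0 + c1*greville."""
        t = self.knots
        d = self.degree
        return np.array(
            [t[j + 1 : j + d + 1].mean() for j in range(self.num_basis)]
        )


def _check_times(spec: BasisSpec, times, clamp: bool) -> np.ndarray:
    x = np.atleast_1d(np.asarray(times, dtype=float))
    a, b = spec.domain
    tol = 1e-10 * (b - a)
    if clamp:
        return np.clip(x, a, b)
    if np.any(x < a - tol) or np.any(x > b + tol):
        raise DomainError(
            f"evaluation points outside basis domain [{a}, {b}]"
        )
    return np.clip(x, a, b)


def bspline_basis(spec: BasisSpec, times, clamp: bool = False) -> np.ndarray:
    """Evaluate all basis functions: matrix of shape (len(times), b)."""
    x = _check_times(spec, times, clamp)
    mat = BSpline.design_matrix(x, spec.knots, spec.degree, extrapolate=False)
    return np.asarray(mat.todense())


def difference_matrix(b: int, order: int) -> np.ndarray:
    """Order-``order`` difference matrix of shape (b-order, b).

    Annihilates coefficient sequences that are polynomials of degree
    < order in the index.
    """
    if order >= b:
        raise ValueError(f"order={order} must be < basis dimension b={b}")
    return np.diff(np.eye(b), n=order, axis=0)


@dataclass(frozen=True)
class MMBasis:
    """Mixed-model reparameterization of a P-spline basis.

    The curve ``B(t) theta`` with penalty ``D'D`` becomes
    ``[1 | t - t_center] beta + Z(t) u`` with ``u ~ N(0, sigma_u^2 I)``;
    ``Z(t) = B(t) U_+ L_+^{-1/2}`` where ``U_+, L_+`` are the eigenvectors
    and positive eigenvalues of ``D'D``.  ``coef_from_mm`` maps mixed-model
    coordinates back to B-spline coefficients (exactly, via Greville
    abscissae for the linear part).
    """

    spec: BasisSpec
    t_center: float
    transform: np.ndarray = field(repr=False)  # (b, b-order) = U_+ L_+^{-1/2}

    @property
    def n_random(self) -> int:
        return self.spec.num_basis - self.spec.penalty_order

    def fixed_matrix(self, times, clamp: bool = False) -> np.ndarray:
        x = _check_times(self.spec, times, clamp)
        return np.column_stack([np.ones_like(x), x - self.t_center])

    def fixed_derivative(self, times) -> np.ndarray:
        x = np.atleast_1d(np.asarray(times, dtype=float))
        return np.column_stack([np.zeros_like(x), np.ones_like(x)])

    def random_matrix(self, times, clamp: bool = False) -> np.ndarray:
        return bspline_basis(self.spec, times, clamp) @ self.transform

    def random_derivative(self, times) -> np.ndarray:
        return derivative_basis(self.spec, times) @ self.transform

    def coef_from_mm(self, beta: np.ndarray, u: np.ndarray) -> np.ndarray:
        """Exact B-spline coefficients of ``[1|t-tc] beta + Z(t) u``."""
        g = self.spec.greville
        theta_lin = beta[0] + beta[1] * (g - self.t_center)
        return theta_lin + self.transform @ u


def mm_transform(spec: BasisSpec, t_center: float | None = None) -> MMBasis:
    """Build the mixed-model reparameterization of a (order-2) P-spline.

    The random block has ``b - penalty_order`` columns; the column span of
    ``[1 | t | Z]`` equals the span of the raw basis, and a penalized
    least-squares fit with smoothing parameter ``lambda`` coincides with
    the mixed-model fit at ``lambda = sigma^2 / sigma_u^2``.
    """
    D = difference_matrix(spec.num_basis, spec.penalty_order)
    evals, evecs = np.linalg.eigh(D.T @ D)
    pos = evals > 1e-10 * evals.max()
    transform = evecs[:, pos] / np.sqrt(evals[pos])
    if t_center is None:
        t_center = 0.5 * (spec.domain[0] + spec.domain[1])
    return MMBasis(spec=spec, t_center=float(t_center), transform=transform)


def derivative_basis(spec: BasisSpec, times, clamp: bool = False) -> np.ndarray:
    """First derivatives of all basis functions: (len(times), b) matrix."""
    x = _check_times(spec, times, clamp)
    t, d, b = spec.knots, spec.degree, spec.num_basis
    # degree-reduction formula: B'_{j,d} = d * (B_{j,d-1}/(t_{j+d}-t_j)
    #                                        - B_{j+1,d-1}/(t_{j+d+1}-t_{j+1}))
    lower = BSpline.design_matrix(x, t, d - 1, extrapolate=False)
    lower = np.asarray(lower.todense())  # columns j = 0..b (one more basis fn)
    out = np.zeros((len(x), b))
    for j in range(b):
        den1 = t[j + d] - t[j]
        den2 = t[j + d + 1] - t[j + 1]
        if den1 > 0:
            out[:, j] += d * lower[:, j] / den1
        if den2 > 0:
            out[:, j] -= d * lower[:, j + 1] / den2
    return out


def integrate_curve(spec: BasisSpec, coefficients, interval=None) -> float:
    """Exact integral of the spline ``B(t) coefficients`` over ``interval``."""
    coefficients = np.asarray(coefficients, dtype=float)
    if coefficients.shape != (spec.num_basis,):
        raise ValueError("coefficient vector length must equal the basis dimension")
    if interval is None:
        interval = spec.domain
    a, b = interval
    lo, hi = spec.domain
    tol = 1e-10 * (hi - lo)
    if a < lo - tol or b > hi + tol:
        raise DomainError(f"integration interval [{a}, {b}] outside domain")
    sp = BSpline(spec.knots, coefficients, spec.degree, extrapolate=False)
    return float(sp.integrate(max(a, lo), min(b, hi)))
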