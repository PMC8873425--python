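"""Sparse linear mixed-model engine.

Model: ``y = X beta + sum_g Z_g u_g + e`` with ``u_g ~ N(0, sigma_g^2 I)``
for each variance group ``g`` (several design blocks may share a group) and
``e ~ N(0, sigma^2 diag(1/w))`` for strictly positive precision weights
``w``.  Estimation is by REML: Henderson's mixed model equations give the
BLUE/BLUP at fixed variances, and the variance components are updated with
the Harville fixed point

    sigma_g^2 <- u_g' u_g / ED_g,
    sigma^2   <- e' W e / (N - rank(X) - sum_g ED_g),

where ``ED_g = q_g - trace(Cinv_gg) / sigma_g^2`` is the effective
dimension of group ``g`` and ``Cinv`` is the inverse of the mixed-model
coefficient matrix in precision form

    C = [X'RX  X'RZ; Z'RX  Z'RZ + Ginv],   R = diag(w) / sigma^2,

so that ``Cinv`` is directly the covariance of ``(beta_hat, u_hat - u)``
and prediction error variances are ``L Cinv L'``.

Small systems are factorised densely (Cholesky, full inverse for effective
dimensions); larger systems fall back to a sparse LU with chunked solves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.linalg import cho_factor, cho_solve

from .errors import ConvergenceError, SingularityError

logger = logging.getLogger(__name__)

DENSE_LIMIT = 2500  # coefficient count below which C is handled densely

__all__ = ["RandomBlock", "LMMSpec", "LMMFit", "henderson_solve", "reml_fit",
           "prediction_error_variance"]


@dataclass
class RandomBlock:
    """One random-effect design block tied to a variance-group label."""

    label: str
    matrix: sp.spmatrix

    @property
    def n_cols(self) -> int:
        return self.matrix.shape[1]


@dataclass
class LMMSpec:
    """A weighted variance-components linear mixed model."""

    y: np.ndarray
    X: np.ndarray | sp.spmatrix
    random_blocks: list[RandomBlock] = field(default_factory=list)
    weights: np.ndarray | None = None
    fixed_names: list[str] | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        n = len(self.y)
        if self.weights is None:
            self.weights = np.ones(n)
        else:
            self.weights = np.asarray(self.weights, dtype=float).ravel()
        if np.any(self.weights <= 0) or not np.all(np.isfinite(self.weights)):
            raise ValueError("precision weights must be positive and finite")
        if self.X.shape[0] != n:
            raise ValueError("X row count does not match the response length")
        if self.X.shape[1] < 1:
            raise ValueError("at least one fixed-effect column is required")
        for blk in self.random_blocks:
            if blk.matrix.shape[0] != n:
                raise ValueError(f"random block {blk.label!r} has wrong row count")

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_fixed(self) -> int:
        return self.X.shape[1]

    @property
    def groups(self) -> list[str]:
        """Variance-group labels in first-appearance order."""
        seen: list[str] = []
        for blk in self.random_blocks:
            if blk.label not in seen:
                seen.append(blk.label)
        return seen

    def group_slices(self) -> dict[str, np.ndarray]:
        """Random-coefficient indices (into the u vector) per group."""
        out: dict[str, list[int]] = {g: [] for g in self.groups}
        offset = 0
        for blk in self.random_blocks:
            out[blk.label].extend(range(offset, offset + blk.n_cols))
            offset += blk.n_cols
        return {g: np.asarray(ix, dtype=int) for g, ix in out.items()}


def _check_fixed_rank(spec: LMMSpec):
    X = spec.X.toarray() if sp.issparse(spec.X) else np.asarray(spec.X, float)
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # name the trailing dependent columns via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(X, pivoting=True, mode="economic")
        bad = sorted(piv[r:])
        names = (
            [spec.fixed_names[j] for j in bad]
            if spec.fixed_names
            else [f"column {j}" for j in bad]
        )
        raise SingularityError(
            f"fixed-effect design is rank deficient (rank {r} < {X.shape[1]}); "
            f"dependent columns: {names}",
            columns=names,
        )
    return r


class MMEInverse:
    """Access to the inverse of the mixed-model coefficient matrix ``C``.

    ``C`` is in precision form, so ``Cinv`` is the joint covariance of the
    fixed estimates and the random prediction errors; any prediction error
    variance is ``L Cinv L'`` computed via solves (dense Cholesky or sparse
    LU), never by forming the full inverse on the sparse path.
    """

    def __init__(self, C: sp.spmatrix, dense: bool):
        self.q = C.shape[0]
        self.dense = dense
        if dense:
            Cd = C.toarray()
            self._cho = cho_factor(Cd, lower=True)
            self._logdet = 2.0 * np.sum(np.log(np.diag(self._cho[0])))
            self._inv = None
        else:
            self._lu = spla.splu(C.tocsc())
            diagL = self._lu.L.diagonal()
            diagU = self._lu.U.diagonal()
            self._logdet = float(np.sum(np.log(np.abs(diagL))) +
                                 np.sum(np.log(np.abs(diagU))))

    @property
    def logdet(self) -> float:
        return self._logdet

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        if self.dense:
            return cho_solve(self._cho, rhs)
        if rhs.ndim == 1:
            return self._lu.solve(rhs)
        return np.column_stack([self._lu.solve(rhs[:, j]) for j in range(rhs.shape[1])])

    def full_inverse(self) -> np.ndarray:
        if not self.dense:
            raise RuntimeError("full inverse only available on the dense path")
        if self._inv is None:
            self._inv = cho_solve(self._cho, np.eye(self.q))
        return self._inv

    def diagonal(self, indices: np.ndarray) -> np.ndarray:
        """Selected diagonal entries of ``Cinv``."""
        if self.dense:
            return self.full_inverse()[indices, indices]
        out = np.empty(len(indices))
        e = np.zeros(self.q)
        for j, ix in enumerate(indices):
            e[ix] = 1.0
            out[j] = self._lu.solve(e)[ix]
            e[ix] = 0.0
        return out

    def quad_form(self, L) -> np.ndarray:
        """``L Cinv L'`` for a conformable (m x q) matrix ``L``."""
        L = L.toarray() if sp.issparse(L) else np.asarray(L, float)
        if L.ndim == 1:
            L = L[None, :]
        if L.shape[1] != self.q:
            raise ValueError(
                f"L has {L.shape[1]} columns, expected {self.q}"
            )
        sol = self.solve(L.T)
        return L @ sol


@dataclass
class HendersonSolution:
    """BLUE/BLUP at fixed variance components, plus inverse access."""

    beta: np.ndarray
    u: np.ndarray
    fitted: np.ndarray
    residual: np.ndarray
    inverse: MMEInverse
    sigma2: float
    variances: dict[str, float]
    ypry_minus: float  # y'Ry - theta'rhs  (the REML quadratic form y'Py)


def _assemble(spec: LMMSpec):
    X = sp.csr_matrix(spec.X)
    if spec.random_blocks:
        Z = sp.hstack([blk.matrix for blk in spec.random_blocks], format="csr")
    else:
        Z = sp.csr_matrix((spec.n_obs, 0))
    return X, Z


def henderson_solve(
    spec: LMMSpec,
    variances: dict[str, float],
    sigma2: float,
    check_rank: bool = True,
) -> HendersonSolution:
    """Solve Henderson's mixed model equations at fixed variances."""
    if sigma2 <= 0 or any(v <= 0 for v in variances.values()):
        raise ValueError("all variance components must be strictly positive")
    if check_rank:
        _check_fixed_rank(spec)
    X, Z = _assemble(spec)
    p, q_u = X.shape[1], Z.shape[1]
    w = spec.weights
    r = w / sigma2
    XtR = X.T.multiply(r)
    ZtR = Z.T.multiply(r)
    ginv_diag = np.concatenate(
        [np.full(blk.n_cols, 1.0 / variances[blk.label]) for blk in spec.random_blocks]
    ) if spec.random_blocks else np.zeros(0)
    C = sp.bmat(
        [
            [XtR @ X, XtR @ Z if q_u else None],
            [ZtR @ X if q_u else None,
             (ZtR @ Z + sp.diags(ginv_diag)) if q_u else None],
        ],
        format="csc",
    ) if q_u else sp.csc_matrix(XtR @ X)
    rhs = np.concatenate([XtR @ spec.y, ZtR @ spec.y if q_u else np.zeros(0)])
    inv = MMEInverse(C, dense=(p + q_u) <= DENSE_LIMIT)
    theta = inv.solve(rhs)
    beta, u = theta[:p], theta[p:]
    fitted = X @ beta + (Z @ u if q_u else 0.0)
    residual = spec.y - fitted
    ypry = float(spec.y @ (r * spec.y) - theta @ rhs)
    return HendersonSolution(
        beta=beta,
        u=u,
        fitted=np.asarray(fitted).ravel(),
        residual=np.asarray(residual).ravel(),
        inverse=inv,
        sigma2=sigma2,
        variances=dict(variances),
        ypry_minus=ypry,
    )


def _minus2_reml(spec: LMMSpec, sol: HendersonSolution) -> float:
    """-2 * restricted log-likelihood (additive constants dropped).

    Uses log|V| + log|X'Vinv X| = sum log(sigma^2/w_i) + log|G| + log|C|.
    """
    n, p = spec.n_obs, spec.n_fixed
    val = float(np.sum(np.log(sol.sigma2 / spec.weights)))
    for blk in spec.random_blocks:
        val += blk.n_cols * np.log(sol.variances[blk.label])
    val += sol.inverse.logdet
    val += sol.ypry_minus
    return val


@dataclass
class LMMFit:
    """A fitted variance-components mixed model."""

    spec: LMMSpec
    beta: np.ndarray
    u: np.ndarray
    fitted: np.ndarray
    residual: np.ndarray
    variances: dict[str, float]
    sigma2: float
    minus2_reml: float
    effective_dims: dict[str, float]
    inverse: MMEInverse
    iterations: list = field(default_factory=list)
    converged: bool = True
    pinned: list = field(default_factory=list)

    def u_block(self, label: str) -> np.ndarray:
        return self.u[self.spec.group_slices()[label]]


def _effective_dims(spec: LMMSpec, sol: HendersonSolution) -> dict[str, float]:
    slices = spec.group_slices()
    p = spec.n_fixed
    eds = {}
    for g, ix in slices.items():
        diag = sol.inverse.diagonal(p + ix)
        eds[g] = float(len(ix) - diag.sum() / sol.variances[g])
    return eds


def reml_fit(
    spec: LMMSpec,
    init: dict[str, float] | None = None,
    tol: float = 1e-8,
    var_tol: float = 1e-6,
    max_iter: int = 200,
    variance_floor: float | None = None,
) -> LMMFit:
    """REML estimation via the effective-dimension fixed point.

    Convergence requires both the relative change of the -2 REML
    log-likelihood below ``tol`` and the maximum variance-component change
    — measured as a share of the response variance, weighting each
    component by its design's mean squared column norm — below
    ``var_tol``.  Components hitting the variance floor are reported
    in ``fit.pinned``.  Raises :class:`ConvergenceError` (carrying the last
    iterate) after ``max_iter`` iterations.
    """
    rank_x = _check_fixed_rank(spec)
    groups = spec.groups
    vary = float(np.var(spec.y)) or 1.0
    if variance_floor is None:
        variance_floor = 1e-10 * vary

    if not groups:  # weighted least squares
        sol = henderson_solve(spec, {}, 1.0, check_rank=False)
        rss = float(sol.residual @ (spec.weights * sol.residual))
        sigma2 = rss / (spec.n_obs - rank_x)
        sol = henderson_solve(spec, {}, sigma2, check_rank=False)
        return LMMFit(
            spec=spec, beta=sol.beta, u=sol.u, fitted=sol.fitted,
            residual=sol.residual, variances={}, sigma2=sigma2,
            minus2_reml=_minus2_reml(spec, sol), effective_dims={},
            inverse=sol.inverse, iterations=[], converged=True,
        )

    start = vary / (len(groups) + 1)
    variances = dict(init) if init else {g: start for g in groups}
    variances = {g: max(v, variance_floor) for g, v in variances.items()}
    sigma2 = max(init.get("__residual__", start) if init else start, variance_floor)

    slices = spec.group_slices()
    dev_prev = np.inf
    log: list[dict] = []
    # variance changes are judged on the response-variance scale: a change
    # of sigma_g^2 matters in proportion to the mean squared column norm of
    # the group's design (slope columns in day units dwarf indicator
    # columns, raw sigma_g^2 values are not comparable across groups)
    n_obs = spec.n_obs
    scale = {}
    for g in groups:
        ssq = sum(
            (blk.matrix.multiply(blk.matrix)).sum()
            for blk in spec.random_blocks if blk.label == g
        )
        scale[g] = max(float(ssq) / n_obs, 1e-300)
    # components decaying geometrically towards a negligible contribution
    # are pinned at the floor; otherwise the fixed point can spend hundreds
    # of iterations approaching it
    for it in range(1, max_iter + 1):
        sol = henderson_solve(spec, variances, sigma2, check_rank=False)
        dev = _minus2_reml(spec, sol)
        eds = _effective_dims(spec, sol)
        new_var = {}
        for g in groups:
            ug = sol.u[slices[g]]
            ed = max(eds[g], 1e-12)
            v_new = max(float(ug @ ug) / ed, variance_floor)
            if v_new * scale[g] < 1e-8 * vary and v_new <= variances[g]:
                v_new = variance_floor
            new_var[g] = v_new
        rss = float(sol.residual @ (spec.weights * sol.residual))
        denom = spec.n_obs - rank_x - sum(eds.values())
        new_sigma2 = max(rss / max(denom, 1e-12), variance_floor)
        rel_var = max(
            abs(new_var[g] - variances[g]) * scale[g] / vary for g in groups
        )
        rel_var = max(rel_var, abs(new_sigma2 - sigma2) / max(vary, variance_floor))
        rel_dev = abs(dev - dev_prev) / max(abs(dev), 1.0)
        log.append(
            {"iteration": it, "minus2_reml": dev, "sigma2": sigma2,
             "variances": dict(variances), "effective_dims": eds,
             "max_rel_change": rel_var}
        )
        converged = rel_dev < tol and rel_var < var_tol
        variances, sigma2, dev_prev = new_var, new_sigma2, dev
        if converged:
            break
    else:
        fit = _finalize(spec, variances, sigma2, log, variance_floor,
                        converged=False)
        raise ConvergenceError(
            f"REML did not converge in {max_iter} iterations", last_fit=fit
        )
    return _finalize(spec, variances, sigma2, log, variance_floor, converged=True)


def _finalize(spec, variances, sigma2, log, floor, converged) -> LMMFit:
    sol = henderson_solve(spec, variances, sigma2, check_rank=False)
    eds = _effective_dims(spec, sol)
    pinned = [g for g, v in variances.items() if v <= floor * (1 + 1e-9)]
    if pinned:
        logger.warning("variance components pinned at the floor: %s", pinned)
    return LMMFit(
        spec=spec, beta=sol.beta, u=sol.u, fitted=sol.fitted,
        residual=sol.residual, variances=dict(variances), sigma2=sigma2,
        minus2_reml=_minus2_reml(spec, sol), effective_dims=eds,
        inverse=sol.inverse, iterations=log, converged=converged,
        pinned=pinned,
    )


def prediction_error_variance(fit: LMMFit | HendersonSolution, L) -> np.ndarray:
    """Covariance of ``L (estimates - truth)``: ``L Cinv L'`` via solves.

    ``L`` has one column per coefficient (fixed first, then random, in
    block order).
    """
    return fit.inverse.quad_form(L)
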