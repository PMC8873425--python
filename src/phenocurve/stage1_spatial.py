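"""Per-time-point spatial mixed-model correction (stage 1).

At every measurement time ``t`` the raw phenotype over the ``r x c`` grid
is decomposed into

    y(t) = intercept + population + design factors + genotype BLUP
           + row/column random effects + smooth spatial surface + residual,

where the surface is a tensor-product P-spline in PS-ANOVA form: a fixed
bilinear part {u, v, u*v} plus five random smooth blocks — f(u), f(v),
u-linear x v-smooth, u-smooth x v-linear, and u-smooth x v-smooth — each
carrying its own variance component.  Smooth blocks are column-centred and
orthogonalised against the bilinear polynomial so the decomposition is
identifiable; the smooth-by-smooth interaction can use nested marginal
bases of half dimension.

The corrected phenotype keeps only the components of interest
(intercept, population, the mean over design-factor levels, the genotype
BLUP) plus the residual; spatial trend and nuisance random effects are
dropped.  Precision weights for stage 2 are the diagonal of the inverse of
``vcov(p_hat) + sigma^2 I``, propagating the stage-1 uncertainty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .bsplines import BasisSpec, mm_transform
from .datamodel import CorrectedSeries, PhenoTable
from .errors import ConvergenceError, DomainError, SkippedTime
from .mixedmodel import LMMFit, LMMSpec, RandomBlock, reml_fit

logger = logging.getLogger(__name__)

__all__ = ["SpatialSpec", "SpatialBlocks", "Stage1Fit", "build_spatial_blocks",
           "fit_timepoint", "correct_timepoint", "stage1_weights", "run_stage1"]


@dataclass
class SpatialSpec:
    """Configuration of the per-time spatial model."""

    rows: int
    cols: int
    b_row: int = 0  # 0 -> default to grid dimension (capped below)
    b_col: int = 0
    nested: bool = True  # half-dimension marginal bases for smooth x smooth
    genotype_as_fixed: bool = False
    per_population_genetic: bool = True
    row_effect: bool = True
    col_effect: bool = True
    reml_tol: float = 1e-8
    max_iter: int = 1000

    def __post_init__(self):
        if self.b_row <= 0:
            self.b_row = max(min(self.rows, 60), 4)
        if self.b_col <= 0:
            self.b_col = max(min(self.cols, 60), 4)


def _indicator(codes: np.ndarray, n_levels: int) -> sp.csr_matrix:
    n = len(codes)
    return sp.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, n_levels)
    )


class SpatialBlocks:
    """PS-ANOVA design blocks, evaluable at arbitrary grid coordinates.

    Stores the centring means and the orthogonalisation coefficients fitted
    on the training coordinates so the estimated surface can be evaluated
    consistently anywhere on the grid.
    """

    def __init__(self, spec: SpatialSpec, u: np.ndarray, v: np.ndarray):
        if np.any(u < 1) or np.any(u > spec.rows) or np.any(v < 1) or np.any(v > spec.cols):
            raise DomainError("coordinates outside the trial grid")
        self.spec = spec
        degree = 3
        self.basis_u = BasisSpec((1.0, float(spec.rows)), spec.b_row, degree)
        self.basis_v = BasisSpec((1.0, float(spec.cols)), spec.b_col, degree)
        self.mm_u = mm_transform(self.basis_u)
        self.mm_v = mm_transform(self.basis_v)
        if spec.nested:
            bu_n = max(spec.b_row // 2, degree + 1)
            bv_n = max(spec.b_col // 2, degree + 1)
        else:
            bu_n, bv_n = spec.b_row, spec.b_col
        self.mm_u_nested = mm_transform(BasisSpec((1.0, float(spec.rows)), bu_n, degree))
        self.mm_v_nested = mm_transform(BasisSpec((1.0, float(spec.cols)), bv_n, degree))
        self.u_center = 0.5 * (1 + spec.rows)
        self.v_center = 0.5 * (1 + spec.cols)

        P, raw = self._raw(u, v)
        self.P = P
        # column means and projection coefficients frozen on training coords
        self.means = {lab: m.mean(axis=0) for lab, m in raw.items()}
        self.proj = {}
        Ppinv = np.linalg.pinv(P)
        self.blocks = {}
        for lab, m in raw.items():
            mc = m - self.means[lab]
            A = Ppinv @ mc
            self.proj[lab] = A
            self.blocks[lab] = mc - P @ A

    def _raw(self, u, v):
        uc = np.asarray(u, float) - self.u_center
        vc = np.asarray(v, float) - self.v_center
        P = np.column_stack([np.ones_like(uc), uc, vc, uc * vc])
        Zu = self.mm_u.random_matrix(u)
        Zv = self.mm_v.random_matrix(v)
        Zun = self.mm_u_nested.random_matrix(u)
        Zvn = self.mm_v_nested.random_matrix(v)
        raw = {
            "spatial:f(u)": Zu,
            "spatial:f(v)": Zv,
            "spatial:u x f(v)": uc[:, None] * Zv,
            "spatial:f(u) x v": Zu * vc[:, None],
            "spatial:f(u) x f(v)": _row_kron(Zun, Zvn),
        }
        return P, raw

    @property
    def labels(self):
        return list(self.blocks)

    def evaluate(self, u, v):
        """Fixed bilinear part and orthogonalised smooth blocks at (u, v)."""
        P, raw = self._raw(u, v)
        out = {}
        for lab, m in raw.items():
            out[lab] = (m - self.means[lab]) - P @ self.proj[lab]
        return P, out


def _row_kron(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-wise Kronecker (face-splitting) product."""
    return (A[:, :, None] * B[:, None, :]).reshape(A.shape[0], -1)


def build_spatial_blocks(spec: SpatialSpec, u, v) -> SpatialBlocks:
    """Build the PS-ANOVA decomposition for plants at grid coords (u, v)."""
    return SpatialBlocks(spec, np.asarray(u), np.asarray(v))


@dataclass
class Stage1Fit:
    """A fitted spatial model at one measurement time."""

    time: float
    fit: LMMFit
    plants: list  # observed plant ids, in design row order
    y: np.ndarray
    spatial: SpatialBlocks
    # fixed-column bookkeeping
    fixed_names: list
    pop_cols: dict  # population level -> fixed column (reference level absent)
    avg_cols: dict  # factor -> (slice of fixed cols, n_levels)
    cond_cols: dict  # condition factor -> {level: fixed col}
    spatial_poly_cols: list
    gen_fixed_cols: dict | None  # genotype -> fixed column (fixed-genotype mode)
    # random-block bookkeeping
    genotype_labels: list  # variance-group labels of genotype blocks
    genotype_units: dict  # label -> list of genotype ids (column order)
    plant_pop: list
    plant_gen: list

    @property
    def sigma2(self) -> float:
        return self.fit.sigma2

    @property
    def genetic_variances(self) -> dict:
        return {lab: self.fit.variances[lab] for lab in self.genotype_labels}

    def genotype_blups(self) -> dict:
        """BLUP per genotype (0 for genotypes unobserved at this time)."""
        out = {}
        for lab in self.genotype_labels:
            ug = self.fit.u_block(lab)
            for g, val in zip(self.genotype_units[lab], ug):
                out[g] = float(val)
        return out

    def spatial_surface(self, u=None, v=None) -> np.ndarray:
        """Evaluate the estimated spatial trend f_t(u, v)."""
        if u is None:
            rr, cc = np.meshgrid(
                np.arange(1, self.spatial.spec.rows + 1),
                np.arange(1, self.spatial.spec.cols + 1),
                indexing="ij",
            )
            u, v = rr.ravel(), cc.ravel()
        P, blocks = self.spatial.evaluate(np.asarray(u), np.asarray(v))
        surf = P[:, 1:] @ self.fit.beta[self.spatial_poly_cols]
        for lab in self.spatial.labels:
            surf = surf + blocks[lab] @ self.fit.u_block(lab)
        return surf


def _prediction_map(s1: Stage1Fit) -> sp.csr_matrix:
    """Coefficient map L with p_hat = L theta for the observed plants."""
    fit = s1.fit
    p = fit.spec.n_fixed
    q = p + sum(b.n_cols for b in fit.spec.random_blocks)
    n = len(s1.plants)
    L = sp.lil_matrix((n, q))
    L[:, 0] = 1.0  # intercept
    for _factor, (cols, n_levels) in s1.avg_cols.items():
        for c in cols:
            L[:, c] = 1.0 / n_levels
    # random-block offsets
    offsets = {}
    off = p
    for blk in fit.spec.random_blocks:
        offsets.setdefault(blk.label, []).append((off, blk.n_cols))
        off += blk.n_cols
    gen_col = {}
    for lab in s1.genotype_labels:
        (o, _nc), = offsets[lab]
        for j, g in enumerate(s1.genotype_units[lab]):
            gen_col[g] = o + j
    for i in range(n):
        pop = s1.plant_pop[i]
        gen = s1.plant_gen[i]
        if s1.gen_fixed_cols is not None:
            c = s1.gen_fixed_cols.get(gen)
            if c is not None:
                L[i, c] = 1.0
        else:
            if pop in s1.pop_cols:
                L[i, s1.pop_cols[pop]] = 1.0
            L[i, gen_col[gen]] = 1.0
    # condition factors other than population keep the plant's own level
    for factor, level_map in s1.cond_cols.items():
        vals = level_map["values"]
        cols = level_map["cols"]
        for i in range(n):
            c = cols.get(vals[i])
            if c is not None:
                L[i, c] = 1.0
    return L.tocsr()


def fit_timepoint(table: PhenoTable, time: float, spec: SpatialSpec) -> Stage1Fit:
    """Fit the spatial mixed model to the observations at one time."""
    df = table.data
    sub = df[(df["time"] == time) & df["value"].notna()]
    if len(sub) == 0:
        raise SkippedTime(f"all values missing at t={time}")
    y = sub["value"].to_numpy(float)
    plants = list(sub["plant"])
    plant_pop = [table.genotype_population[table.plant_genotype[p]] for p in plants]
    plant_gen = [table.plant_genotype[p] for p in plants]
    u = np.array([table.plant_position[p][0] for p in plants], float)
    v = np.array([table.plant_position[p][1] for p in plants], float)
    n = len(y)

    spatial = build_spatial_blocks(spec, u, v)

    fixed_cols = [np.ones(n)]
    fixed_names = ["intercept"]
    pop_cols: dict = {}
    gen_fixed_cols = None
    pops = table.populations
    if spec.genotype_as_fixed:
        gen_fixed_cols = {}
        gens = table.genotypes
        for g in gens[1:]:
            col = np.array([1.0 if gg == g else 0.0 for gg in plant_gen])
            gen_fixed_cols[g] = len(fixed_names)
            fixed_cols.append(col)
            fixed_names.append(f"genotype[{g}]")
    elif len(pops) > 1:
        for plev in pops[1:]:
            col = np.array([1.0 if pp == plev else 0.0 for pp in plant_pop])
            pop_cols[plev] = len(fixed_names)
            fixed_cols.append(col)
            fixed_names.append(f"population[{plev}]")

    avg_cols: dict = {}
    cond_cols: dict = {}
    rand_factor_blocks: list[RandomBlock] = []
    for factor, role in table.factor_roles.items():
        vals = list(sub[factor])
        levels = list(pd.unique(df[factor]))
        if role == "average":
            cols = []
            for lev in levels[1:]:
                col = np.array([1.0 if x == lev else 0.0 for x in vals])
                cols.append(len(fixed_names))
                fixed_cols.append(col)
                fixed_names.append(f"{factor}[{lev}]")
            avg_cols[factor] = (cols, len(levels))
        elif role == "condition":
            colmap = {}
            for lev in levels[1:]:
                col = np.array([1.0 if x == lev else 0.0 for x in vals])
                colmap[lev] = len(fixed_names)
                fixed_cols.append(col)
                fixed_names.append(f"{factor}[{lev}]")
            cond_cols[factor] = {"values": vals, "cols": colmap}
        else:  # random
            codes = np.array([levels.index(x) for x in vals])
            rand_factor_blocks.append(
                RandomBlock(f"factor:{factor}", _indicator(codes, len(levels)))
            )

    # fixed bilinear spatial polynomial (intercept excluded; already present)
    spatial_poly_cols = list(range(len(fixed_names), len(fixed_names) + 3))
    fixed_cols.extend([spatial.P[:, 1], spatial.P[:, 2], spatial.P[:, 3]])
    fixed_names.extend(["spatial:u", "spatial:v", "spatial:u*v"])
    X = np.column_stack(fixed_cols)

    blocks: list[RandomBlock] = []
    genotype_labels: list[str] = []
    genotype_units: dict = {}
    if not spec.genotype_as_fixed:
        if spec.per_population_genetic and len(pops) > 1:
            for plev in pops:
                gens_p = [g for g in table.genotypes
                          if table.genotype_population[g] == plev]
                codes = np.full(n, -1)
                idx = {g: j for j, g in enumerate(gens_p)}
                mat = sp.lil_matrix((n, len(gens_p)))
                for i, g in enumerate(plant_gen):
                    if g in idx:
                        mat[i, idx[g]] = 1.0
                lab = f"genotype[{plev}]"
                blocks.append(RandomBlock(lab, mat.tocsr()))
                genotype_labels.append(lab)
                genotype_units[lab] = gens_p
        else:
            gens = table.genotypes
            idx = {g: j for j, g in enumerate(gens)}
            mat = sp.lil_matrix((n, len(gens)))
            for i, g in enumerate(plant_gen):
                mat[i, idx[g]] = 1.0
            blocks.append(RandomBlock("genotype", mat.tocsr()))
            genotype_labels.append("genotype")
            genotype_units["genotype"] = gens

    if spec.row_effect:
        blocks.append(RandomBlock("row", _indicator((u - 1).astype(int), spec.rows)))
    if spec.col_effect:
        blocks.append(RandomBlock("col", _indicator((v - 1).astype(int), spec.cols)))
    blocks.extend(rand_factor_blocks)
    for lab in spatial.labels:
        blocks.append(RandomBlock(lab, sp.csr_matrix(spatial.blocks[lab])))

    lmm = LMMSpec(y=y, X=X, random_blocks=blocks, fixed_names=fixed_names)
    try:
        fit = reml_fit(lmm, tol=spec.reml_tol, max_iter=spec.max_iter)
    except ConvergenceError as exc:
        raise ConvergenceError(f"t={time}: {exc}", last_fit=exc.last_fit) from exc

    return Stage1Fit(
        time=float(time), fit=fit, plants=plants, y=y, spatial=spatial,
        fixed_names=fixed_names, pop_cols=pop_cols, avg_cols=avg_cols,
        cond_cols=cond_cols, spatial_poly_cols=spatial_poly_cols,
        gen_fixed_cols=gen_fixed_cols, genotype_labels=genotype_labels,
        genotype_units=genotype_units, plant_pop=plant_pop, plant_gen=plant_gen,
    )


def correct_timepoint(s1: Stage1Fit):
    """Corrected values for the observed plants at this time.

    Returns (corrected, prediction, residual) arrays aligned with
    ``s1.plants``; the identity corrected = prediction + residual holds
    exactly.
    """
    L = _prediction_map(s1)
    theta = np.concatenate([s1.fit.beta, s1.fit.u])
    prediction = np.asarray(L @ theta).ravel()
    residual = s1.fit.residual
    return prediction + residual, prediction, residual


def stage1_weights(s1: Stage1Fit) -> np.ndarray:
    """Precision weights: diag of the inverse of vcov(p_hat) + sigma^2 I."""
    L = _prediction_map(s1)
    vcov = s1.fit.inverse.quad_form(L)
    m = vcov + s1.sigma2 * np.eye(vcov.shape[0])
    winv = np.linalg.inv(m)
    w = np.diag(winv).copy()
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise FloatingPointError("non-positive stage-1 weights: ill-conditioned fit")
    return w


def run_stage1(table: PhenoTable, spec: SpatialSpec) -> CorrectedSeries:
    """Fit / correct / weight every measurement time of a validated table.

    Times where REML fails are logged and emitted as missing; the run only
    fails if every time fails.
    """
    if not table.validated:
        from .datamodel import validate_table

        table = validate_table(table)
    records = {}
    report = []
    n_fail = 0
    for t in table.times:
        try:
            s1 = fit_timepoint(table, t, spec)
            corrected, prediction, residual = correct_timepoint(s1)
            w = stage1_weights(s1)
        except SkippedTime:
            logger.warning("t=%s: no observations, skipped", t)
            n_fail += 1
            continue
        except (ConvergenceError, FloatingPointError) as exc:
            logger.warning("t=%s: fit failed (%s); emitted as missing", t, exc)
            n_fail += 1
            report.append({"time": float(t), "converged": False})
            continue
        for plant, yc, pv, rv, wv in zip(s1.plants, corrected, prediction,
                                         residual, w):
            records[(plant, float(t))] = (yc, pv, rv, wv)
        report.append(
            {
                "time": float(t),
                "converged": True,
                "n_obs": len(s1.plants),
                "sigma2": s1.sigma2,
                "variance_components": {k: float(v)
                                        for k, v in s1.fit.variances.items()},
                "effective_dims": {k: float(v)
                                   for k, v in s1.fit.effective_dims.items()},
                "minus2_reml": s1.fit.minus2_reml,
            }
        )
    if n_fail == len(table.times):
        raise ConvergenceError("stage 1 failed at every measurement time")

    rows = []
    for plant in table.plants:
        gen = table.plant_genotype[plant]
        pop = table.genotype_population[gen]
        r, c = table.plant_position[plant]
        for t in table.times:
            rec = records.get((plant, float(t)))
            if rec is None:
                rows.append((pop, gen, plant, r, c, float(t),
                             np.nan, np.nan, np.nan, np.nan, True))
            else:
                rows.append((pop, gen, plant, r, c, float(t), *rec, False))
    df = pd.DataFrame(
        rows,
        columns=["population", "genotype", "plant", "row", "col", "time",
                 "corrected", "prediction", "residual", "weight", "missing"],
    )
    return CorrectedSeries(data=df, table=table, variance_report=report)
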