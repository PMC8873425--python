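"""Three-level nested hierarchical P-spline growth model (stage 2).

The spatially corrected series is decomposed additively over time,

    y~_pgi(t) = f_p(t) + f_pg(t) + f_pgi(t) + eps_pgi(t),

with a population mean curve ``f_p``, a genotype-specific deviation
``f_pg`` and a plant-specific deviation ``f_pgi``.  Each curve is a
penalized cubic B-spline in mixed-model form: an intercept/slope pair plus
a smooth random part with ``b - 2`` coefficients.  The population
intercept and slope are fixed effects; genotype and plant intercepts,
slopes and smooths are independent random effects, giving the variance
components

    {sigma_p^2}_p (one smooth variance per population),
    sigma_gen,0^2, sigma_gen,1^2, sigma_gen^2   (optionally per population),
    sigma_plant,0^2, sigma_plant,1^2, sigma_plant^2, and sigma^2.

Residuals are heteroscedastic through the stage-1 weights: by default the
weights are precisions (residual variance ``sigma^2 / w``); a config
switch selects the literal variance reading (``sigma^2 * w``).

Fitting delegates to the sparse REML engine; curves, deviations, first
derivatives and 95% pointwise confidence bands follow from the coefficient
index maps and the prediction error variance of the corresponding linear
combinations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .bsplines import BasisSpec, MMBasis, mm_transform
from .datamodel import CorrectedSeries, CurveSet
from .errors import ConfigError, DegenerateError, DomainError, UnknownUnit
from .mixedmodel import LMMFit, LMMSpec, RandomBlock, reml_fit

logger = logging.getLogger(__name__)

__all__ = ["HierConfig", "HierDesign", "HierFit", "build_hier_design",
           "fit_growth", "evaluate_curves", "evaluate_derivatives", "mape",
           "model_covariance"]


@dataclass
class HierConfig:
    """Configuration of the hierarchical growth model."""

    b_pop: int = 13
    b_gen: int = 13
    b_plant: int = 13
    per_population_genetic: bool = False
    per_genotype_plant: bool = False
    weight_mode: str = "precision"  # or "variance" (literal reading)
    reml_tol: float = 1e-8
    var_tol: float = 1e-6
    max_iter: int = 500
    variance_floor: float | None = None
    grid_points: int = 401

    def __post_init__(self):
        for b in (self.b_pop, self.b_gen, self.b_plant):
            if b < 4:
                raise ConfigError(f"basis dimension {b} < 4")
        if self.weight_mode not in ("precision", "variance"):
            raise ConfigError(f"unknown weight_mode {self.weight_mode!r}")
        if not (len({self.b_pop, self.b_gen, self.b_plant}) == 1):
            warnings.warn(
                "different basis dimensions across hierarchy levels; equal "
                "dimensions are recommended for stable estimates",
                stacklevel=2,
            )


@dataclass
class HierDesign:
    """Assembled Kronecker-structured design for the growth model."""

    config: HierConfig
    populations: list
    genotypes: list  # population-major order
    plants: list  # genotype-major order
    gen_pop: np.ndarray  # population index per genotype
    plant_gen: np.ndarray  # genotype index per plant
    times: np.ndarray
    mm_pop: MMBasis
    mm_gen: MMBasis
    mm_plant: MMBasis
    y: np.ndarray
    stage1_weights: np.ndarray
    obs_plant: np.ndarray
    obs_time: np.ndarray
    X: sp.csr_matrix
    blocks: list = field(default_factory=list)
    index: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.populations)

    @property
    def L(self) -> int:
        return len(self.genotypes)

    @property
    def M(self) -> int:
        return len(self.plants)

    @property
    def n_coefficients(self) -> int:
        # k*b_pop + L*b_gen + M*b_plant, counted as assembled columns
        return self.X.shape[1] + sum(b.n_cols for b in self.blocks)

    @property
    def variance_groups(self) -> list:
        seen = []
        for b in self.blocks:
            if b.label not in seen:
                seen.append(b.label)
        return seen

    @property
    def n_variance_components(self) -> int:
        """Distinct variance parameters, the residual included."""
        return len(self.variance_groups) + 1

    def lmm_weights(self) -> np.ndarray:
        if self.config.weight_mode == "precision":
            return self.stage1_weights
        return 1.0 / self.stage1_weights


def build_hier_design(series: CorrectedSeries, config: HierConfig) -> HierDesign:
    """Assemble the sparse three-level design from a corrected series.

    Missing observations are dropped from the rows, but every population,
    genotype and plant keeps its full coefficient set, so curves remain
    estimable for units with incomplete records.
    """
    df = series.data
    pops = list(dict.fromkeys(df["population"]))
    pop_idx = {p: j for j, p in enumerate(pops)}
    # genotype order: population-major; plant order: genotype-major
    gp = df[["genotype", "population"]].drop_duplicates()
    gen_pop_map = gp.set_index("genotype")["population"].to_dict()
    gens = [g for p in pops for g in dict.fromkeys(
        df.loc[df["population"] == p, "genotype"])]
    gen_idx = {g: j for j, g in enumerate(gens)}
    plants = [pl for g in gens for pl in dict.fromkeys(
        df.loc[df["genotype"] == g, "plant"])]
    plant_idx = {pl: j for j, pl in enumerate(plants)}
    gen_pop = np.array([pop_idx[gen_pop_map[g]] for g in gens])
    pg = df[["plant", "genotype"]].drop_duplicates().set_index("plant")["genotype"]
    plant_gen = np.array([gen_idx[pg[pl]] for pl in plants])

    times = np.sort(df["time"].unique().astype(float))
    time_idx = {t: j for j, t in enumerate(times)}
    domain = (float(times[0]), float(times[-1]))
    order2 = 2
    mm_pop = mm_transform(BasisSpec(domain, config.b_pop, 3, order2))
    mm_gen = mm_transform(BasisSpec(domain, config.b_gen, 3, order2))
    mm_plant = mm_transform(BasisSpec(domain, config.b_plant, 3, order2))

    obs = df[~df["missing"]]
    y = obs["corrected"].to_numpy(float)
    w = obs["weight"].to_numpy(float)
    obs_plant = obs["plant"].map(plant_idx).to_numpy()
    obs_time = obs["time"].map(time_idx).to_numpy()
    obs_pop = gen_pop[plant_gen[obs_plant]]
    obs_gen = plant_gen[obs_plant]
    N = len(y)
    k, L, M = len(pops), len(gens), len(plants)

    tc = mm_pop.fixed_matrix(times)[:, 1]  # centred times on the grid
    Zt_pop = mm_pop.random_matrix(times)
    Zt_gen = mm_gen.random_matrix(times)
    Zt_plant = mm_plant.random_matrix(times)
    bp, bg, bpl = Zt_pop.shape[1], Zt_gen.shape[1], Zt_plant.shape[1]

    rows = np.arange(N)

    # fixed: population intercept and slope, [Q_pop (x) [1|t]]
    X = sp.csr_matrix(
        (
            np.concatenate([np.ones(N), tc[obs_time]]),
            (np.concatenate([rows, rows]),
             np.concatenate([2 * obs_pop, 2 * obs_pop + 1])),
        ),
        shape=(N, 2 * k),
    )

    def _smooth_block(unit_of_obs, n_units, Zt, nb):
        r = np.repeat(rows, nb)
        c = (unit_of_obs[:, None] * nb + np.arange(nb)[None, :]).ravel()
        d = Zt[obs_time].ravel()
        return sp.csr_matrix((d, (r, c)), shape=(N, n_units * nb))

    def _scalar_block(unit_of_obs, n_units, values):
        return sp.csr_matrix((values, (rows, unit_of_obs)), shape=(N, n_units))

    pop_smooth = _smooth_block(obs_pop, k, Zt_pop, bp)
    gen_int = _scalar_block(obs_gen, L, np.ones(N))
    gen_slope = _scalar_block(obs_gen, L, tc[obs_time])
    gen_smooth = _smooth_block(obs_gen, L, Zt_gen, bg)
    plant_int = _scalar_block(obs_plant, M, np.ones(N))
    plant_slope = _scalar_block(obs_plant, M, tc[obs_time])
    plant_smooth = _smooth_block(obs_plant, M, Zt_plant, bpl)

    blocks: list[RandomBlock] = []

    def _add_per_group(mat_csc, col_group, n_groups, label_fmt, group_names):
        """Split a block's columns by group, one variance label per group."""
        for gidx in range(n_groups):
            cols = np.flatnonzero(col_group == gidx)
            blocks.append(RandomBlock(label_fmt.format(group_names[gidx]),
                                      mat_csc[:, cols]))
            yield gidx, cols

    # population smooth: always one variance per population
    col_pop = np.repeat(np.arange(k), bp)
    pop_smooth_cols = {}
    for gidx, cols in _add_per_group(pop_smooth.tocsc(), col_pop, k,
                                     "pop_smooth[{}]", pops):
        pop_smooth_cols[gidx] = cols

    gen_col_pop = gen_pop  # population of each genotype column
    gen_layout = {}
    if config.per_population_genetic:
        for name, mat, nb in (("gen_int", gen_int, 1), ("gen_slope", gen_slope, 1),
                              ("gen_smooth", gen_smooth, bg)):
            col_group = np.repeat(gen_col_pop, nb)
            start = len(blocks)
            cols_map = {}
            for gidx, cols in _add_per_group(mat.tocsc(), col_group, k,
                                             name + "[{}]", pops):
                cols_map[gidx] = cols
            gen_layout[name] = ("per_pop", start, cols_map)
    else:
        for name, mat in (("gen_int", gen_int), ("gen_slope", gen_slope),
                          ("gen_smooth", gen_smooth)):
            gen_layout[name] = ("shared", len(blocks), None)
            blocks.append(RandomBlock(name, mat.tocsc()))

    plant_layout = {}
    if config.per_genotype_plant:
        plant_col_gen = plant_gen
        for name, mat, nb in (("plant_int", plant_int, 1),
                              ("plant_slope", plant_slope, 1),
                              ("plant_smooth", plant_smooth, bpl)):
            col_group = np.repeat(plant_col_gen, nb)
            start = len(blocks)
            cols_map = {}
            for gidx, cols in _add_per_group(mat.tocsc(), col_group, L,
                                             name + "[{}]", gens):
                cols_map[gidx] = cols
            plant_layout[name] = ("per_gen", start, cols_map)
    else:
        for name, mat in (("plant_int", plant_int), ("plant_slope", plant_slope),
                          ("plant_smooth", plant_smooth)):
            plant_layout[name] = ("shared", len(blocks), None)
            blocks.append(RandomBlock(name, mat.tocsc()))

    design = HierDesign(
        config=config, populations=pops, genotypes=gens, plants=plants,
        gen_pop=gen_pop, plant_gen=plant_gen, times=times,
        mm_pop=mm_pop, mm_gen=mm_gen, mm_plant=mm_plant,
        y=y, stage1_weights=w, obs_plant=obs_plant, obs_time=obs_time,
        X=X, blocks=blocks,
    )
    design.index = _coefficient_index(design, bp, bg, bpl)
    expected = k * config.b_pop + L * config.b_gen + M * config.b_plant
    assert design.n_coefficients == expected, (
        f"coefficient count {design.n_coefficients} != "
        f"k*b_pop + L*b_gen + M*b_plant = {expected}"
    )
    return design


def _coefficient_index(design: HierDesign, bp, bg, bpl) -> dict:
    """Positions of every unit's coefficients in the stacked theta vector."""
    k, L, M = design.k, design.L, design.M
    offsets = []
    off = 2 * k
    for b in design.blocks:
        offsets.append(off)
        off += b.n_cols
    labels = [b.label for b in design.blocks]

    def block_off(label):
        return offsets[labels.index(label)]

    index = {"pop_fixed": {}, "pop_smooth": {}, "gen_int": {}, "gen_slope": {},
             "gen_smooth": {}, "plant_int": {}, "plant_slope": {},
             "plant_smooth": {}}
    for p in range(k):
        index["pop_fixed"][p] = np.array([2 * p, 2 * p + 1])
        o = block_off(f"pop_smooth[{design.populations[p]}]")
        index["pop_smooth"][p] = o + np.arange(bp)

    cfg = design.config
    for g in range(L):
        p = design.gen_pop[g]
        if cfg.per_population_genetic:
            pos_in_pop = int(np.sum(design.gen_pop[:g] == p))
            oi = block_off(f"gen_int[{design.populations[p]}]")
            os_ = block_off(f"gen_slope[{design.populations[p]}]")
            osm = block_off(f"gen_smooth[{design.populations[p]}]")
        else:
            pos_in_pop = g
            oi, os_, osm = (block_off("gen_int"), block_off("gen_slope"),
                            block_off("gen_smooth"))
        index["gen_int"][g] = oi + pos_in_pop
        index["gen_slope"][g] = os_ + pos_in_pop
        index["gen_smooth"][g] = osm + pos_in_pop * bg + np.arange(bg)

    for m in range(M):
        g = design.plant_gen[m]
        if cfg.per_genotype_plant:
            pos = int(np.sum(design.plant_gen[:m] == g))
            oi = block_off(f"plant_int[{design.genotypes[g]}]")
            os_ = block_off(f"plant_slope[{design.genotypes[g]}]")
            osm = block_off(f"plant_smooth[{design.genotypes[g]}]")
        else:
            pos = m
            oi, os_, osm = (block_off("plant_int"), block_off("plant_slope"),
                            block_off("plant_smooth"))
        index["plant_int"][m] = oi + pos
        index["plant_slope"][m] = os_ + pos
        index["plant_smooth"][m] = osm + pos * bpl + np.arange(bpl)
    return index


@dataclass
class HierFit:
    """A fitted hierarchical growth model."""

    design: HierDesign
    fit: LMMFit

    @property
    def theta(self) -> np.ndarray:
        return np.concatenate([self.fit.beta, self.fit.u])

    @property
    def variances(self) -> dict:
        return self.fit.variances

    @property
    def sigma2(self) -> float:
        return self.fit.sigma2

    @property
    def minus2_reml(self) -> float:
        return self.fit.minus2_reml

    def unit_number(self, level: str, unit) -> int:
        d = self.design
        pool = {"population": d.populations, "genotype": d.genotypes,
                "plant": d.plants}.get(level)
        if pool is None:
            raise UnknownUnit(f"unknown level {level!r}")
        try:
            return pool.index(unit)
        except ValueError:
            raise UnknownUnit(f"{level} {unit!r} not in the fit") from None


def fit_growth(design: HierDesign) -> HierFit:
    """Estimate the growth model by REML on the assembled design."""
    cfg = design.config
    spec = LMMSpec(y=design.y, X=design.X, random_blocks=design.blocks,
                   weights=design.lmm_weights())
    fit = reml_fit(spec, tol=cfg.reml_tol, var_tol=cfg.var_tol,
                   max_iter=cfg.max_iter,
                   variance_floor=cfg.variance_floor)
    return HierFit(design=design, fit=fit)


def _unit_rows(hf: HierFit, level: str, unit_no: int, grid: np.ndarray,
               derivative: bool):
    """(cols, vals) pairs defining L-theta for one unit's curve/deviation."""
    d = hf.design
    idx = d.index
    parts = []

    def fixed(mm):
        return mm.fixed_derivative(grid) if derivative else mm.fixed_matrix(grid)

    def smooth(mm):
        return mm.random_derivative(grid) if derivative else mm.random_matrix(grid)

    if level == "population":
        parts.append((idx["pop_fixed"][unit_no], fixed(d.mm_pop)))
        parts.append((idx["pop_smooth"][unit_no], smooth(d.mm_pop)))
    elif level == "genotype":
        parts.append((np.array([idx["gen_int"][unit_no],
                                idx["gen_slope"][unit_no]]), fixed(d.mm_gen)))
        parts.append((idx["gen_smooth"][unit_no], smooth(d.mm_gen)))
    elif level == "plant":
        parts.append((np.array([idx["plant_int"][unit_no],
                                idx["plant_slope"][unit_no]]), fixed(d.mm_plant)))
        parts.append((idx["plant_smooth"][unit_no], smooth(d.mm_plant)))
    else:
        raise UnknownUnit(f"unknown level {level!r}")
    return parts


def _curve_L(hf: HierFit, level: str, unit_no: int, grid: np.ndarray,
             kind: str, derivative: bool) -> sp.csr_matrix:
    d = hf.design
    q = d.n_coefficients
    parts = []
    if kind == "deviation":
        parts += _unit_rows(hf, level, unit_no, grid, derivative)
    else:  # cumulative curve down the hierarchy
        if level == "population":
            chain = [("population", unit_no)]
        elif level == "genotype":
            chain = [("population", int(d.gen_pop[unit_no])),
                     ("genotype", unit_no)]
        else:
            g = int(d.plant_gen[unit_no])
            chain = [("population", int(d.gen_pop[g])), ("genotype", g),
                     ("plant", unit_no)]
        for lev, no in chain:
            parts += _unit_rows(hf, lev, no, grid, derivative)
    L = sp.lil_matrix((len(grid), q))
    for cols, vals in parts:
        L[:, cols] = L[:, cols] + vals
    return L.tocsr()


def _deviation_spline(hf: HierFit, level: str, unit_no: int):
    """Exact B-spline coefficients of a genotype/plant deviation."""
    d, idx = hf.design, hf.design.index
    theta = hf.theta
    if level == "genotype":
        mm = d.mm_gen
        beta = theta[[idx["gen_int"][unit_no], idx["gen_slope"][unit_no]]]
        u = theta[idx["gen_smooth"][unit_no]]
    elif level == "plant":
        mm = d.mm_plant
        beta = theta[[idx["plant_int"][unit_no], idx["plant_slope"][unit_no]]]
        u = theta[idx["plant_smooth"][unit_no]]
    else:
        mm = d.mm_pop
        beta = theta[idx["pop_fixed"][unit_no]]
        u = theta[idx["pop_smooth"][unit_no]]
    return mm.spec, mm.coef_from_mm(beta, u)


def default_grid(design: HierDesign) -> np.ndarray:
    return np.linspace(design.times[0], design.times[-1],
                       design.config.grid_points)


def evaluate_curves(hf: HierFit, level: str, units=None, grid=None,
                    kind: str = "curve") -> CurveSet:
    """Evaluate level curves or deviations with pointwise standard errors.

    ``kind='curve'`` returns the cumulative curve (population; population +
    genotype deviation; population + genotype + plant deviation);
    ``kind='deviation'`` the level-specific deviation alone.  Standard
    errors come from the prediction error variance of the coefficient
    combination, and 95% bands are ``estimate +/- 1.96 se``.
    """
    return _evaluate(hf, level, units, grid, kind, derivative=False)


def evaluate_derivatives(hf: HierFit, level: str, units=None, grid=None,
                         kind: str = "curve") -> CurveSet:
    """First derivatives of level curves/deviations, with standard errors."""
    cs = _evaluate(hf, level, units, grid, kind, derivative=True)
    cs.kind = "first_derivative"
    return cs


def _evaluate(hf: HierFit, level, units, grid, kind, derivative) -> CurveSet:
    d = hf.design
    pool = {"population": d.populations, "genotype": d.genotypes,
            "plant": d.plants}.get(level)
    if pool is None:
        raise UnknownUnit(f"unknown level {level!r}")
    if units is None:
        units = list(pool)
    if grid is None:
        grid = default_grid(d)
    grid = np.asarray(grid, float)
    lo, hi = d.times[0], d.times[-1]
    if grid.min() < lo - 1e-9 or grid.max() > hi + 1e-9:
        raise DomainError(f"grid outside the modelled interval [{lo}, {hi}]")
    theta = hf.theta
    est = np.empty((len(units), len(grid)))
    se = np.empty_like(est)
    splines = [] if (kind == "deviation" and not derivative) else None
    for j, unit in enumerate(units):
        no = hf.unit_number(level, unit)
        L = _curve_L(hf, level, no, grid, kind, derivative)
        est[j] = L @ theta
        pev = hf.fit.inverse.quad_form(L)
        se[j] = np.sqrt(np.maximum(np.diag(pev), 0.0))
        if splines is not None:
            splines.append(_deviation_spline(hf, level, no))
    spline = None
    if splines is not None:
        spec0 = splines[0][0]
        spline = (spec0, np.vstack([c for _, c in splines]))
    return CurveSet(level=level, units=list(units), times=grid, estimates=est,
                    se=se, kind="deviation" if kind == "deviation" else "curve",
                    spline=spline)


def mape(hf: HierFit, series: CorrectedSeries | None = None) -> float:
    """Mean absolute percentage error of the fitted plant curves.

    ``100/N * sum |y~ - y_hat| / |y~|`` over observed records with
    ``|y~| >= eps`` (``eps = 1e-8 * max|y~|``).
    """
    y = hf.design.y
    yhat = hf.fit.fitted
    eps = 1e-8 * np.max(np.abs(y))
    keep = np.abs(y) >= eps
    if not np.any(keep):
        raise DegenerateError("all corrected values are (numerically) zero")
    return float(100.0 * np.mean(np.abs(y[keep] - yhat[keep]) / np.abs(y[keep])))


def model_covariance(hf: HierFit, plant_a, plant_b, times,
                     weights=None) -> np.ndarray:
    """Model-implied covariance between two plant curves at given times.

    Zero across populations; adds the population smooth term within a
    population, the genotype terms within a genotype, and the plant terms
    plus the residual variance for the same plant.  ``weights`` are the
    stage-1 weights at ``times`` for the same-plant residual term
    (defaults to 1).
    """
    d = hf.design
    ma = hf.unit_number("plant", plant_a)
    mb = hf.unit_number("plant", plant_b)
    ga, gb = int(d.plant_gen[ma]), int(d.plant_gen[mb])
    pa, pb = int(d.gen_pop[ga]), int(d.gen_pop[gb])
    times = np.asarray(times, float)
    nt = len(times)
    if pa != pb:
        return np.zeros((nt, nt))
    v = hf.variances
    Zp = d.mm_pop.random_matrix(times)
    cov = v[f"pop_smooth[{d.populations[pa]}]"] * (Zp @ Zp.T)
    if ga == gb:
        Xg = d.mm_gen.fixed_matrix(times)
        Zg = d.mm_gen.random_matrix(times)
        if d.config.per_population_genetic:
            pname = d.populations[pa]
            s0, s1, sm = (v[f"gen_int[{pname}]"], v[f"gen_slope[{pname}]"],
                          v[f"gen_smooth[{pname}]"])
        else:
            s0, s1, sm = v["gen_int"], v["gen_slope"], v["gen_smooth"]
        cov = cov + Xg @ np.diag([s0, s1]) @ Xg.T + sm * (Zg @ Zg.T)
    if ma == mb:
        Xp = d.mm_plant.fixed_matrix(times)
        Zpl = d.mm_plant.random_matrix(times)
        if d.config.per_genotype_plant:
            gname = d.genotypes[ga]
            p0, p1, pm = (v[f"plant_int[{gname}]"], v[f"plant_slope[{gname}]"],
                          v[f"plant_smooth[{gname}]"])
        else:
            p0, p1, pm = v["plant_int"], v["plant_slope"], v["plant_smooth"]
        cov = cov + Xp @ np.diag([p0, p1]) @ Xp.T + pm * (Zpl @ Zpl.T)
        w = np.ones(nt) if weights is None else np.asarray(weights, float)
        resvar = (hf.sigma2 / w if d.config.weight_mode == "precision"
                  else hf.sigma2 * w)
        cov = cov + np.diag(resvar)
    return cov
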