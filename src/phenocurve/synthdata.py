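"""Synthetic high-throughput phenotyping experiments with known truth.

The generator emulates the structure both modelling stages assume: plants
on an ``r x c`` grid measured on a common time grid with missing values; a
smooth bivariate spatial nuisance surface per time whose amplitude drifts
over the experiment; optional categorical design-factor effects; and
three-level growth curves.  Population mean curves are logistic by default
(the canonical shape of canopy growth) or, alternatively, drawn exactly
from the P-spline mixed-model prior; genotype and plant deviations are
always drawn from that prior: random intercept + random slope + smooth
B-spline coefficient draws, with independent variances per term.  Noise is
Gaussian and homoscedastic; records are removed completely at random at
the missingness rate.

All randomness flows from a single seed through named substreams, so the
same seed yields byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bsplines import BasisSpec, MMBasis, mm_transform
from .datamodel import PhenoTable, validate_table
from .errors import ConfigError, UnknownUnit

__all__ = ["SimConfig", "Truth", "simulate_experiment", "truth_curves",
           "series_from_table", "skeleton_series"]

_STREAMS = ("layout", "population", "genotype", "plant", "spatial", "factors",
            "noise", "missing")


@dataclass
class SimConfig:
    """Configuration of a synthetic experiment.

    Default dimensions give a compact two-population trial (k=2, 10
    genotypes per population, 4 plants per genotype, M=80 plants on a
    10 x 8 grid, 15 times over DOY 100-135) with logistic population
    growth, genotype/plant deviations of realistic relative magnitude and
    a smooth drifting spatial nuisance surface.
    """

    k: int = 2
    genotypes_per_population: int = 10
    plants_per_genotype: int = 4
    rows: int = 10
    cols: int = 8
    n_times: int = 15
    time_range: tuple[float, float] = (100.0, 135.0)
    population_mode: str = "logistic"  # or "spline" (exact model prior)
    logistic_K: tuple = (120.0, 90.0)
    logistic_rate: tuple = (0.30, 0.25)
    logistic_t0: tuple = (115.0, 118.0)
    pop_intercept: tuple = (60.0, 45.0)  # spline mode
    pop_slope: tuple = (2.5, 2.0)  # spline mode, per day
    sigma_pop2: tuple = (25.0, 25.0)  # spline mode smooth variance
    sim_basis: int = 7
    sigma_gen0_2: float = 16.0
    sigma_gen1_2: float = 0.04
    sigma_gen_2: float = 4.0
    sigma_plant0_2: float = 4.0
    sigma_plant1_2: float = 0.01
    sigma_plant_2: float = 1.0
    spatial_amplitude: float = 10.0
    spatial_drift: float = 0.5
    design_factors: dict = field(default_factory=dict)
    # e.g. {"lot": {"levels": 2, "effect_sd": 5.0, "role": "average"}}
    residual_sd: float = 2.0
    missingness: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.k < 1 or self.genotypes_per_population < 1 \
                or self.plants_per_genotype < 1:
            raise ConfigError("k, genotypes and plants per group must be >= 1")
        if self.rows * self.cols < self.k * self.genotypes_per_population \
                * self.plants_per_genotype:
            raise ConfigError("grid too small for the number of plants")
        if not (0 <= self.missingness < 1):
            raise ConfigError("missingness must lie in [0, 1)")
        if self.population_mode not in ("logistic", "spline"):
            raise ConfigError(f"unknown population_mode {self.population_mode!r}")
        for name in ("sigma_gen0_2", "sigma_gen1_2", "sigma_gen_2",
                     "sigma_plant0_2", "sigma_plant1_2", "sigma_plant_2"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.residual_sd < 0 or self.spatial_amplitude < 0:
            raise ConfigError("residual_sd and spatial_amplitude must be >= 0")

    @property
    def times(self) -> np.ndarray:
        return np.linspace(*self.time_range, self.n_times)

    @property
    def M(self) -> int:
        return self.k * self.genotypes_per_population * self.plants_per_genotype


def _rngs(seed: int) -> dict:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


@dataclass
class Truth:
    """Every simulated component, for recovery tests."""

    config: SimConfig
    mm: MMBasis  # deviation basis in mixed-model form
    populations: list
    genotypes: list
    plants: list
    gen_pop: dict
    plant_gen: dict
    pop_components: dict  # pop -> {"mode", params or (beta, u)}
    gen_components: dict  # gen -> (beta0, beta1, u)
    plant_components: dict  # plant -> (beta0, beta1, u)
    spatial_phases: tuple
    plant_position: dict
    factor_levels: dict  # factor -> {plant: level}
    factor_effects: dict  # factor -> {level: effect}

    def population_curve(self, pop, grid) -> np.ndarray:
        grid = np.asarray(grid, float)
        comp = self.pop_components[pop]
        if comp["mode"] == "logistic":
            K, r, t0 = comp["K"], comp["rate"], comp["t0"]
            return K / (1.0 + np.exp(-r * (grid - t0)))
        beta, u = comp["beta"], comp["u"]
        return self.mm.fixed_matrix(grid) @ beta + self.mm.random_matrix(grid) @ u

    def deviation(self, level: str, unit, grid) -> np.ndarray:
        grid = np.asarray(grid, float)
        comps = {"genotype": self.gen_components,
                 "plant": self.plant_components}.get(level)
        if comps is None or unit not in comps:
            raise UnknownUnit(f"{level} {unit!r} was not simulated")
        b0, b1, u = comps[unit]
        return (self.mm.fixed_matrix(grid) @ np.array([b0, b1])
                + self.mm.random_matrix(grid) @ u)

    def spatial_surface(self, time: float, u, v) -> np.ndarray:
        cfg = self.config
        if cfg.spatial_amplitude == 0:
            return np.zeros(len(np.atleast_1d(u)))
        p1, p2 = self.spatial_phases
        t0, t1 = cfg.time_range
        tmid = 0.5 * (t0 + t1)
        amp = cfg.spatial_amplitude * (
            1.0 + cfg.spatial_drift * (time - tmid) / (t1 - t0))
        u = np.asarray(u, float)
        v = np.asarray(v, float)
        return amp * np.sin(2 * np.pi * u / cfg.rows + p1) \
            * np.cos(2 * np.pi * v / cfg.cols + p2)

    def to_json(self, path) -> None:
        def _arr(x):
            return np.asarray(x).tolist()

        payload = {
            "populations": self.populations,
            "genotypes": self.genotypes,
            "plants": self.plants,
            "pop_components": {
                p: {key: _arr(val) if isinstance(val, np.ndarray) else val
                    for key, val in comp.items()}
                for p, comp in self.pop_components.items()
            },
            "gen_components": {g: [c[0], c[1], _arr(c[2])]
                               for g, c in self.gen_components.items()},
            "plant_components": {p: [c[0], c[1], _arr(c[2])]
                                 for p, c in self.plant_components.items()},
            "spatial_phases": list(self.spatial_phases),
            "factor_effects": self.factor_effects,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def simulate_experiment(config: SimConfig) -> tuple[PhenoTable, Truth]:
    """Generate a complete experiment and its ground truth."""
    rngs = _rngs(config.seed)
    times = config.times
    domain = (float(times[0]), float(times[-1]))
    mm = mm_transform(BasisSpec(domain, config.sim_basis, 3, 2))
    nb = mm.n_random

    pops = [f"P{p + 1}" for p in range(config.k)]
    genotypes, plants = [], []
    gen_pop, plant_gen = {}, {}
    for p, pop in enumerate(pops):
        for g in range(config.genotypes_per_population):
            gname = f"{pop}_G{g + 1:02d}"
            genotypes.append(gname)
            gen_pop[gname] = pop
            for i in range(config.plants_per_genotype):
                pl = f"{gname}_{i + 1}"
                plants.append(pl)
                plant_gen[pl] = gname

    # spatial layout: random assignment of plants to grid cells
    cells = [(r + 1, c + 1) for r in range(config.rows) for c in range(config.cols)]
    order = rngs["layout"].permutation(len(cells))[: len(plants)]
    plant_position = {pl: cells[j] for pl, j in zip(plants, order)}

    pop_components = {}
    rng_pop = rngs["population"]
    for p, pop in enumerate(pops):
        if config.population_mode == "logistic":
            pop_components[pop] = {
                "mode": "logistic",
                "K": float(config.logistic_K[p % len(config.logistic_K)]),
                "rate": float(config.logistic_rate[p % len(config.logistic_rate)]),
                "t0": float(config.logistic_t0[p % len(config.logistic_t0)]),
            }
        else:
            s2 = config.sigma_pop2[p % len(config.sigma_pop2)]
            pop_components[pop] = {
                "mode": "spline",
                "beta": np.array([
                    config.pop_intercept[p % len(config.pop_intercept)],
                    config.pop_slope[p % len(config.pop_slope)],
                ]),
                "u": rng_pop.normal(0.0, np.sqrt(s2), nb),
            }

    rng_gen = rngs["genotype"]
    gen_components = {
        g: (rng_gen.normal(0.0, np.sqrt(config.sigma_gen0_2)),
            rng_gen.normal(0.0, np.sqrt(config.sigma_gen1_2)),
            rng_gen.normal(0.0, np.sqrt(config.sigma_gen_2), nb))
        for g in genotypes
    }
    rng_plant = rngs["plant"]
    plant_components = {
        pl: (rng_plant.normal(0.0, np.sqrt(config.sigma_plant0_2)),
             rng_plant.normal(0.0, np.sqrt(config.sigma_plant1_2)),
             rng_plant.normal(0.0, np.sqrt(config.sigma_plant_2), nb))
        for pl in plants
    }

    phases = tuple(rngs["spatial"].uniform(0, 2 * np.pi, 2))

    factor_levels, factor_effects, factor_roles = {}, {}, {}
    rng_fac = rngs["factors"]
    for name, fspec in config.design_factors.items():
        n_levels = int(fspec.get("levels", 2))
        role = fspec.get("role", "average")
        if "effects" in fspec:
            effects = list(fspec["effects"])
        else:
            sd = float(fspec.get("effect_sd", 1.0))
            effects = list(rng_fac.normal(0.0, sd, n_levels))
        levels = [f"{name}{j + 1}" for j in range(n_levels)]
        assignment = {pl: levels[rng_fac.integers(n_levels)] for pl in plants}
        factor_levels[name] = assignment
        factor_effects[name] = dict(zip(levels, effects))
        factor_roles[name] = role

    truth = Truth(
        config=config, mm=mm, populations=pops, genotypes=genotypes,
        plants=plants, gen_pop=gen_pop, plant_gen=plant_gen,
        pop_components=pop_components, gen_components=gen_components,
        plant_components=plant_components, spatial_phases=phases,
        plant_position=plant_position, factor_levels=factor_levels,
        factor_effects=factor_effects,
    )

    rng_noise, rng_miss = rngs["noise"], rngs["missing"]
    rows = []
    for pl in plants:
        g = plant_gen[pl]
        pop = gen_pop[g]
        r, c = plant_position[pl]
        signal = (truth.population_curve(pop, times)
                  + truth.deviation("genotype", g, times)
                  + truth.deviation("plant", pl, times))
        surf = np.array([truth.spatial_surface(t, [r], [c])[0] for t in times])
        fac = sum(factor_effects[name][factor_levels[name][pl]]
                  for name in factor_levels)
        noise = rng_noise.normal(0.0, config.residual_sd, len(times))
        values = signal + surf + fac + noise
        miss = rng_miss.random(len(times)) < config.missingness
        for t, val, m in zip(times, values, miss):
            rows.append({
                "population": pop, "genotype": g, "plant": pl,
                "row": r, "col": c, "time": float(t),
                "value": np.nan if m else float(val),
            })
    df = pd.DataFrame(rows)
    for name, assignment in factor_levels.items():
        df[name] = df["plant"].map(assignment)
    table = validate_table(PhenoTable(df, factor_roles=factor_roles))
    return table, truth


def series_from_table(table: PhenoTable, weights=None):
    """Treat raw values as already-corrected observations with unit weights.

    Useful for driving the growth model directly on data without spatial
    nuisance (the correction then has nothing to remove).
    """
    from .datamodel import CorrectedSeries

    table = validate_table(table)
    df = table.data.copy()
    df["corrected"] = df["value"].astype(float)
    df["prediction"] = df["corrected"]
    df["residual"] = 0.0
    df["weight"] = 1.0 if weights is None else weights
    df["missing"] = df["value"].isna()
    df.loc[df["missing"], "weight"] = np.nan
    cols = ["population", "genotype", "plant", "row", "col", "time",
            "corrected", "prediction", "residual", "weight", "missing"]
    return CorrectedSeries(data=df[cols], table=table)


def skeleton_series(k: int, L: int, M: int, n_times: int,
                    time_range=(100.0, 135.0), seed: int = 0):
    """A corrected series with prescribed dimensions only.

    Genotypes are spread as evenly as possible over populations and plants
    over genotypes; values are white noise with unit weights.  Intended for
    design-bookkeeping at realistic platform dimensions without running the
    spatial stage.
    """
    from .datamodel import CorrectedSeries

    if not (k <= L <= M):
        raise ConfigError("need k <= L <= M")
    rng = np.random.default_rng(seed)
    times = np.linspace(*time_range, n_times)
    gen_pop = [p % k for p in range(L)]  # round-robin: even split
    plant_gen = [i % L for i in range(M)]
    rows = []
    for m in range(M):
        g = plant_gen[m]
        rows.append((f"P{gen_pop[g] + 1}", f"G{g + 1:04d}", f"I{m + 1:05d}"))
    base = pd.DataFrame(rows, columns=["population", "genotype", "plant"])
    df = base.loc[base.index.repeat(n_times)].reset_index(drop=True)
    df["row"] = np.repeat(np.arange(M) + 1, n_times)
    df["col"] = 1
    df["time"] = np.tile(times, M)
    df["corrected"] = rng.normal(size=len(df))
    df["prediction"] = df["corrected"]
    df["residual"] = 0.0
    df["weight"] = 1.0
    df["missing"] = False
    return CorrectedSeries(data=df)


def truth_curves(truth: Truth, level: str, unit, grid) -> np.ndarray:
    """Evaluate the true cumulative curve of a unit on a grid."""
    grid = np.asarray(grid, float)
    if level == "population":
        if unit not in truth.pop_components:
            raise UnknownUnit(f"population {unit!r} was not simulated")
        return truth.population_curve(unit, grid)
    if level == "genotype":
        pop = truth.gen_pop.get(unit)
        if pop is None:
            raise UnknownUnit(f"genotype {unit!r} was not simulated")
        return truth.population_curve(pop, grid) + truth.deviation(
            "genotype", unit, grid)
    if level == "plant":
        g = truth.plant_gen.get(unit)
        if g is None:
            raise UnknownUnit(f"plant {unit!r} was not simulated")
        return (truth.population_curve(truth.gen_pop[g], grid)
                + truth.deviation("genotype", g, grid)
                + truth.deviation("plant", unit, grid))
    raise UnknownUnit(f"unknown level {level!r}")
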