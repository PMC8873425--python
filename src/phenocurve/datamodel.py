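"""Core domain types for phenotyping time series.

The data are long-format records ``(population, genotype, plant, row, col,
time, value)`` with a strictly nested hierarchy: every plant belongs to
exactly one genotype, every genotype to exactly one population.  Plants sit
on an ``r x c`` spatial grid (one plant per cell) and are measured on a
common finite time grid ``t_1 < ... < t_n``; individual values may be
missing.  Optional categorical design factors carry a role tag that decides
how stage 1 treats them:

``condition``
    kept in the corrected phenotype (like the population effect),
``average``
    fixed nuisance effects averaged out in the correction,
``random``
    random nuisance effects ignored in the correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GridError, NestingError

REQUIRED_COLUMNS = ("population", "genotype", "plant", "row", "col", "time", "value")

FACTOR_ROLES = ("condition", "average", "random")


@dataclass
class PhenoTable:
    """A validated long-format phenotype table.

    Parameters
    ----------
    data
        Long-format records with at least the columns
        ``population, genotype, plant, row, col, time, value``.
    factor_roles
        Mapping from extra categorical column name to its role
        (``condition`` / ``average`` / ``random``).
    """

    data: pd.DataFrame
    factor_roles: dict[str, str] = field(default_factory=dict)
    validated: bool = False

    # ------ derived dimensions (populated by validate_table) ------
    times: np.ndarray | None = None
    populations: list | None = None
    genotypes: list | None = None
    plants: list | None = None
    genotype_population: dict | None = None
    plant_genotype: dict | None = None
    plant_position: dict | None = None
    n_rows: int = 0
    n_cols: int = 0

    @property
    def k(self) -> int:
        """Number of populations."""
        return len(self.populations) if self.populations is not None else 0

    @property
    def L(self) -> int:
        """Total number of genotypes."""
        return len(self.genotypes) if self.genotypes is not None else 0

    @property
    def M(self) -> int:
        """Total number of plants."""
        return len(self.plants) if self.plants is not None else 0

    @property
    def n_times(self) -> int:
        return len(self.times) if self.times is not None else 0

    @property
    def n_slots(self) -> int:
        """Number of (plant, time) slots, missing values included."""
        return self.M * self.n_times


def validate_table(table: PhenoTable) -> PhenoTable:
    """Validate hierarchy nesting, spatial grid and time grid of a table.

    Idempotent: re-validating a validated table returns it unchanged.

    Raises
    ------
    NestingError
        If a genotype appears under two populations or a plant under two
        genotypes.
    GridError
        If a plant has two grid positions, two plants share a cell, a
        (plant, time) pair is duplicated, or required columns are missing.
    """
    if table.validated:
        return table
    df = table.data
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise GridError(f"missing required columns: {missing_cols}")
    for name, role in table.factor_roles.items():
        if name not in df.columns:
            raise GridError(f"design factor column {name!r} not in table")
        if role not in FACTOR_ROLES:
            raise GridError(f"unknown factor role {role!r} for column {name!r}")

    # hierarchy nesting (ids are opaque; codes assigned in first-appearance order)
    gp = df[["genotype", "population"]].drop_duplicates()
    dup_g = gp["genotype"][gp["genotype"].duplicated()]
    if len(dup_g):
        raise NestingError(
            f"genotype(s) {sorted(set(dup_g))} listed under more than one population"
        )
    pg = df[["plant", "genotype"]].drop_duplicates()
    dup_p = pg["plant"][pg["plant"].duplicated()]
    if len(dup_p):
        raise NestingError(
            f"plant(s) {sorted(set(dup_p))} listed under more than one genotype"
        )

    # spatial grid: one (row, col) per plant, one plant per cell
    pos = df[["plant", "row", "col"]].drop_duplicates()
    dup_pos = pos["plant"][pos["plant"].duplicated()]
    if len(dup_pos):
        raise GridError(f"plant(s) {sorted(set(dup_pos))} have multiple grid positions")
    cell = pos[["row", "col"]]
    if cell.duplicated().any():
        raise GridError("two plants share the same (row, col) grid cell")
    if (pos["row"] < 1).any() or (pos["col"] < 1).any():
        raise GridError("rows and columns are 1-based positive integers")

    # at most one record per (plant, time)
    if df[["plant", "time"]].duplicated().any():
        raise GridError("duplicate (plant, time) records")

    times = np.sort(df["time"].unique().astype(float))
    if not np.all(np.isfinite(times)):
        raise GridError("non-finite measurement times")

    table.times = times
    table.populations = list(pd.unique(df["population"]))
    table.genotypes = list(pd.unique(df["genotype"]))
    table.plants = list(pd.unique(df["plant"]))
    table.genotype_population = dict(zip(gp["genotype"], gp["population"]))
    table.plant_genotype = dict(zip(pg["plant"], pg["genotype"]))
    table.plant_position = {
        p: (int(r), int(c)) for p, r, c in pos.itertuples(index=False)
    }
    table.n_rows = int(pos["row"].max())
    table.n_cols = int(pos["col"].max())
    table.validated = True
    return table


def read_pheno_csv(path, factor_roles: dict[str, str] | None = None) -> PhenoTable:
    """Read a long-format phenotype CSV and validate it.

    Missing values may be encoded as empty fields or ``NA``.
    """
    df = pd.read_csv(path, na_values=["NA", ""])
    return validate_table(PhenoTable(df, factor_roles=dict(factor_roles or {})))


@dataclass
class CorrectedSeries:
    """Spatially corrected phenotypes with stage-1 precision weights.

    One record per (plant, time) slot.  Where the raw value was observed,
    ``corrected = prediction + residual`` holds exactly and ``weight > 0``;
    missing slots keep ``missing=True`` with NaN entries.
    """

    data: pd.DataFrame  # population,genotype,plant,row,col,time,
    #                     corrected,prediction,residual,weight,missing
    table: PhenoTable | None = None
    variance_report: list | None = None

    @property
    def n_slots(self) -> int:
        return len(self.data)

    def observed(self) -> pd.DataFrame:
        return self.data[~self.data["missing"]]

    def to_csv(self, path) -> None:
        cols = [
            "population", "genotype", "plant", "row", "col", "time",
            "corrected", "prediction", "residual", "weight", "missing",
        ]
        self.data[cols].to_csv(path, index=False, float_format="%.10g")


@dataclass
class CurveSet:
    """Evaluated curves for one hierarchy level on a common time grid.

    ``kind`` is one of ``curve`` (level curve, cumulative over the
    hierarchy), ``deviation`` (the level-specific deviation only) or
    ``first_derivative``.  ``estimates`` has one row per unit.  ``spline``
    optionally carries the exact B-spline representation (spec,
    coefficient matrix) of the plotted quantity for downstream exact
    integration.
    """

    level: str
    units: list
    times: np.ndarray
    estimates: np.ndarray  # (n_units, n_times)
    se: np.ndarray  # (n_units, n_times)
    kind: str = "curve"
    spline: tuple | None = None  # (BasisSpec, coef matrix (n_units, b))

    def ci(self, z: float = 1.96):
        """Pointwise normal-approximation confidence bands."""
        return self.estimates - z * self.se, self.estimates + z * self.se

    def unit_index(self, unit) -> int:
        from .errors import UnknownUnit

        try:
            return self.units.index(unit)
        except ValueError:
            raise UnknownUnit(f"unit {unit!r} not in curve set") from None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, unit in enumerate(self.units):
            rows.append(
                pd.DataFrame(
                    {
                        "level": self.level,
                        "unit": str(unit),
                        "time": self.times,
                        "estimate": self.estimates[j],
                        "se": self.se[j],
                        "kind": self.kind,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclass
class TraitTable:
    """Per-genotype time-independent attributes extracted from curves."""

    data: pd.DataFrame  # genotype,population,maxTrait_value,maxTrait_time,
    #                     maxSpeed<k>_value,maxSpeed<k>_time,auc

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.10g")
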