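"""Time-independent attributes extracted from estimated growth curves.

For each genotype the package extracts:

* ``maxTrait`` — the maximum of the genotype growth curve and the time at
  which it occurs;
* ``maxSpeed`` entries — the largest first-derivative value (growth rate)
  inside user-supplied time windows, taken from local maxima of the
  derivative where available;
* ``AUC`` — the exact integral of the genotype-specific deviation over an
  interval (full measured interval by default): positive when the genotype
  outperforms its population average, negative otherwise.

Extrema located on a dense grid are refined with a local three-point
quadratic interpolation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bsplines import integrate_curve
from .datamodel import CurveSet, TraitTable
from .errors import DomainError, EmptyCurve, WindowError
from .stage2_hierarchical import (HierFit, default_grid, evaluate_curves,
                                  evaluate_derivatives)

__all__ = ["max_trait", "derivative_extrema", "max_speeds", "deviation_auc",
           "build_trait_table"]


def _quadratic_refine(t: np.ndarray, y: np.ndarray, i: int):
    """Vertex of the parabola through points i-1, i, i+1 (grid fallback)."""
    if i <= 0 or i >= len(t) - 1:
        return float(t[i]), float(y[i])
    t0, t1, t2 = t[i - 1], t[i], t[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (y0 - 2 * y1 + y2)
    if abs(denom) < 1e-300:
        return float(t1), float(y1)
    h = t1 - t0  # uniform grid assumed for the vertex formula
    dt = 0.5 * h * (y0 - y2) / denom
    dt = float(np.clip(dt, -h, h))
    tv = t1 + dt
    # parabola value at the vertex
    a = denom / (2 * h * h)
    b = (y2 - y0) / (2 * h)
    yv = y1 + b * dt + a * dt * dt
    return float(tv), float(yv)


def max_trait(curve: CurveSet, unit=None) -> tuple[float, float]:
    """Global maximum of a curve: returns ``(time, value)``."""
    if curve.estimates.size == 0 or len(curve.times) == 0:
        raise EmptyCurve("empty curve")
    j = curve.unit_index(unit) if unit is not None else 0
    y = curve.estimates[j]
    i = int(np.argmax(y))
    return _quadratic_refine(curve.times, y, i)


def derivative_extrema(deriv: CurveSet, unit=None) -> list[tuple[float, float, str]]:
    """Interior local extrema of a derivative curve.

    Located as sign changes of the numerically differenced values and
    refined by quadratic interpolation; endpoints are excluded.  Returns
    ``(time, value, 'min'|'max')`` tuples ordered by time.
    """
    j = deriv.unit_index(unit) if unit is not None else 0
    t, y = deriv.times, deriv.estimates[j]
    dy = np.diff(y)
    out = []
    for i in range(1, len(y) - 1):
        if dy[i - 1] > 0 and dy[i] <= 0:
            tv, yv = _quadratic_refine(t, y, i)
            out.append((tv, yv, "max"))
        elif dy[i - 1] < 0 and dy[i] >= 0:
            tv, yv = _quadratic_refine(t, y, i)
            out.append((tv, yv, "min"))
    return out


def max_speeds(deriv: CurveSet, windows, unit=None) -> list[dict]:
    """Largest derivative value in each time window.

    Prefers an interior local maximum of the derivative; if the window
    contains none, falls back to the windowed grid maximum and flags the
    entry with ``interior=False``.
    """
    j = deriv.unit_index(unit) if unit is not None else 0
    t, y = deriv.times, deriv.estimates[j]
    lo, hi = t[0], t[-1]
    extrema = [e for e in derivative_extrema(deriv, unit) if e[2] == "max"]
    out = []
    for a, b in windows:
        if a > b or a < lo - 1e-9 or b > hi + 1e-9:
            raise WindowError(f"window [{a}, {b}] outside domain [{lo}, {hi}]")
        inside = [(tv, yv) for tv, yv, _ in extrema if a <= tv <= b]
        if inside:
            tv, yv = max(inside, key=lambda e: e[1])
            out.append({"time": tv, "value": yv, "interior": True})
        else:
            mask = (t >= a) & (t <= b)
            ys = y[mask]
            ts = t[mask]
            i = int(np.argmax(ys))
            out.append({"time": float(ts[i]), "value": float(ys[i]),
                        "interior": False})
    return out


def deviation_auc(deviation, interval=None, unit=None) -> float:
    """Signed area under a deviation curve over ``interval`` (exact).

    ``deviation`` is either a :class:`CurveSet` carrying its spline
    representation, or a ``(BasisSpec, coefficients)`` pair.
    """
    if isinstance(deviation, CurveSet):
        if deviation.spline is None:
            raise DomainError("curve set carries no spline representation")
        spec, coefs = deviation.spline
        j = deviation.unit_index(unit) if unit is not None else 0
        coef = coefs[j]
    else:
        spec, coef = deviation
        coef = np.asarray(coef, float)
    return integrate_curve(spec, coef, interval)


def build_trait_table(hf: HierFit, windows=None, interval=None,
                      grid=None) -> TraitTable:
    """One row per genotype: maxTrait, per-window maxSpeeds and AUC.

    Deterministic given the fit.  ``windows`` default to the full interval
    (a single maxSpeed); ``interval`` defaults to the complete measured
    time range.
    """
    d = hf.design
    if grid is None:
        grid = default_grid(d)
    if windows is None:
        windows = [(d.times[0], d.times[-1])]
    curves = evaluate_curves(hf, "genotype", grid=grid, kind="curve")
    derivs = evaluate_derivatives(hf, "genotype", grid=grid, kind="curve")
    devs = evaluate_curves(hf, "genotype", grid=grid, kind="deviation")
    rows = []
    for g in d.genotypes:
        no = hf.unit_number("genotype", g)
        pop = d.populations[d.gen_pop[no]]
        mt, mv = max_trait(curves, g)
        row = {"genotype": g, "population": pop,
               "maxTrait_value": mv, "maxTrait_time": mt}
        for kdx, sp_entry in enumerate(max_speeds(derivs, windows, g), start=1):
            row[f"maxSpeed{kdx}_value"] = sp_entry["value"]
            row[f"maxSpeed{kdx}_time"] = sp_entry["time"]
        row["auc"] = deviation_auc(devs, interval, g)
        rows.append(row)
    return TraitTable(pd.DataFrame(rows))
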