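"""Hierarchical growth model: design bookkeeping, REML oracle, curves."""

import numpy as np
import pytest
import scipy.optimize
import scipy.sparse as sp

import phenocurve as pc


# ---------------------------------------------------------------- design ----

@pytest.mark.parametrize(
    "k,L,M,b,per_pop,n_coef,n_vc",
    [
        (4, 180, 1656, 13, False, 23920, 11),   # indoor platform configuration
        (7, 334, 720, 20, True, 21220, 32),     # field platform configuration
        (1, 1, 1, 5, False, 15, 8),
        (2, 6, 12, 5, True, 100, 12),
    ],
)
def test_design_coefficient_and_variance_component_counts(
        k, L, M, b, per_pop, n_coef, n_vc):
    series = pc.skeleton_series(k, L, M, n_times=4)
    design = pc.build_hier_design(series, pc.HierConfig(
        b_pop=b, b_gen=b, b_plant=b, per_population_genetic=per_pop))
    assert design.n_coefficients == n_coef == k * b + L * b + M * b
    assert design.n_variance_components == n_vc
    assert design.X.shape[1] == 2 * k
    n_random = sum(blk.n_cols for blk in design.blocks)
    assert n_random == k * (b - 2) + 2 * L + L * (b - 2) + 2 * M + M * (b - 2)


def test_design_rejects_tiny_basis_and_warns_on_unequal():
    with pytest.raises(pc.ConfigError):
        pc.HierConfig(b_pop=3)
    with pytest.warns(UserWarning):
        pc.HierConfig(b_pop=5, b_gen=6, b_plant=5)


def test_missing_rows_dropped_but_units_keep_coefficients(series_small):
    design = pc.build_hier_design(series_small, pc.HierConfig(
        b_pop=7, b_gen=7, b_plant=7))
    n_missing = int(series_small.data["missing"].sum())
    assert n_missing > 0
    assert len(design.y) == series_small.n_slots - n_missing
    assert design.M == 80 and design.L == 20 and design.k == 2
    assert design.n_coefficients == 7 * (2 + 20 + 80)


# ------------------------------------------------------------ REML oracle ---

def _tiny_fit():
    cfg = pc.SimConfig(seed=31, k=2, genotypes_per_population=2,
                       plants_per_genotype=2, rows=4, cols=2, n_times=6,
                       missingness=0.0, spatial_amplitude=0.0,
                       sim_basis=4, residual_sd=1.5)
    table, _ = pc.simulate_experiment(cfg)
    series = pc.series_from_table(table)
    design = pc.build_hier_design(series, pc.HierConfig(
        b_pop=4, b_gen=4, b_plant=4, reml_tol=1e-12, var_tol=1e-10,
        max_iter=5000))
    return pc.fit_growth(design), design


def _dense_minus2_reml(design, variances, sigma2):
    X = design.X.toarray()
    y = design.y
    floor = 1e-10 * np.var(y)  # same feasible set as the engine
    V = max(sigma2, floor) * np.diag(1.0 / design.lmm_weights())
    for blk in design.blocks:
        Zb = blk.matrix.toarray()
        V += max(variances[blk.label], floor) * (Zb @ Zb.T)
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    return (np.linalg.slogdet(V)[1] + np.linalg.slogdet(XtViX)[1]
            + float(r @ Vi @ r))


def _dense_fitted(design, variances, sigma2):
    X = design.X.toarray()
    y = design.y
    Zd = np.column_stack([b.matrix.toarray() for b in design.blocks])
    G = np.diag(np.concatenate([np.full(b.n_cols, variances[b.label])
                                for b in design.blocks]))
    V = Zd @ G @ Zd.T + sigma2 * np.diag(1.0 / design.lmm_weights())
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    u = G @ Zd.T @ Vi @ (y - X @ beta)
    return X @ beta + Zd @ u


def test_growth_fit_matches_dense_brute_force_reml():
    """Sparse fixed-point REML agrees with a dense-V numeric optimization."""
    hf, design = _tiny_fit()
    labels = design.variance_groups
    ours = _dense_minus2_reml(design, hf.variances, hf.sigma2)
    # our criterion value equals the dense evaluation at our estimates
    assert abs(ours - hf.minus2_reml) < 1e-5 * max(abs(ours), 1.0)
    # fitted values via the dense GLS route coincide
    np.testing.assert_allclose(
        _dense_fitted(design, hf.variances, hf.sigma2), hf.fit.fitted,
        atol=1e-8)

    def obj(logv):
        v = dict(zip(labels, np.exp(logv[:-1])))
        return _dense_minus2_reml(design, v, np.exp(logv[-1]))

    x0 = np.log(np.array([max(hf.variances[g], 1e-8) for g in labels]
                         + [hf.sigma2]))
    res = scipy.optimize.minimize(obj, x0, method="Nelder-Mead",
                                  options={"maxiter": 4000, "xatol": 1e-8,
                                           "fatol": 1e-10})
    # the numeric optimizer cannot improve on the fixed point materially
    assert ours <= res.fun + 1e-5
    v_opt = dict(zip(labels, np.exp(res.x[:-1])))
    np.testing.assert_allclose(
        _dense_fitted(design, v_opt, np.exp(res.x[-1])), hf.fit.fitted,
        atol=1e-5 * np.max(np.abs(hf.fit.fitted)))


def test_single_curve_reduces_to_standalone_pspline():
    """With k = L = M = 1 the model collapses to one penalized curve."""
    cfg = pc.SimConfig(seed=32, k=1, genotypes_per_population=1,
                       plants_per_genotype=1, rows=1, cols=1, n_times=14,
                       missingness=0.0, spatial_amplitude=0.0,
                       residual_sd=1.0)
    table, _ = pc.simulate_experiment(cfg)
    series = pc.series_from_table(table)
    b = 6
    design = pc.build_hier_design(series, pc.HierConfig(
        b_pop=b, b_gen=b, b_plant=b))
    hf = pc.fit_growth(design)
    # standalone P-spline mixed model on the same data
    mm = design.mm_pop
    t = design.times[design.obs_time]
    X = mm.fixed_matrix(t)
    Z = sp.csr_matrix(mm.random_matrix(t))
    alone = pc.reml_fit(pc.LMMSpec(y=design.y, X=X, random_blocks=[
        pc.RandomBlock("s", Z)]))
    np.testing.assert_allclose(hf.fit.fitted, alone.fitted,
                               atol=1e-6 * np.ptp(design.y))


# ------------------------------------------------------------------ curves --

def test_genotype_curve_is_population_plus_deviation(hfit_small, grid_small):
    pops = pc.evaluate_curves(hfit_small, "population", grid=grid_small)
    gens = pc.evaluate_curves(hfit_small, "genotype", grid=grid_small)
    devs = pc.evaluate_curves(hfit_small, "genotype", grid=grid_small,
                              kind="deviation")
    d = hfit_small.design
    for j, g in enumerate(d.genotypes):
        p = d.gen_pop[j]
        np.testing.assert_allclose(
            gens.estimates[j], pops.estimates[p] + devs.estimates[j],
            atol=1e-9)
    assert np.all(gens.se >= 0) and np.all(devs.se >= 0)


def test_plant_curves_reproduce_fitted_values(hfit_small):
    d = hfit_small.design
    curves = pc.evaluate_curves(hfit_small, "plant", grid=d.times)
    est = curves.estimates[d.obs_plant, d.obs_time]
    np.testing.assert_allclose(est, hfit_small.fit.fitted, atol=1e-8)


def test_derivatives_linear_and_match_finite_differences(hfit_small):
    d = hfit_small.design
    grid = np.linspace(d.times[0] + 0.5, d.times[-1] - 0.5, 40)
    h = 1e-4
    dcurv = pc.evaluate_derivatives(hfit_small, "genotype", grid=grid)
    up = pc.evaluate_curves(hfit_small, "genotype", grid=grid + h)
    dn = pc.evaluate_curves(hfit_small, "genotype", grid=grid - h)
    fd = (up.estimates - dn.estimates) / (2 * h)
    scale = np.max(np.abs(dcurv.estimates))
    assert np.max(np.abs(dcurv.estimates - fd)) < 1e-6 * scale
    # linearity: derivative of curve = derivative of population + deviation
    dpop = pc.evaluate_derivatives(hfit_small, "population", grid=grid)
    ddev = pc.evaluate_derivatives(hfit_small, "genotype", grid=grid,
                                   kind="deviation")
    for j in range(len(d.genotypes)):
        p = d.gen_pop[j]
        np.testing.assert_allclose(
            dcurv.estimates[j], dpop.estimates[p] + ddev.estimates[j],
            atol=1e-9)


def test_grid_outside_domain_and_unknown_unit_rejected(hfit_small):
    d = hfit_small.design
    with pytest.raises(pc.DomainError):
        pc.evaluate_curves(hfit_small, "population",
                           grid=[d.times[0] - 5.0, d.times[-1]])
    with pytest.raises(pc.UnknownUnit):
        pc.evaluate_curves(hfit_small, "genotype", units=["nope"])
    with pytest.raises(pc.UnknownUnit):
        pc.evaluate_curves(hfit_small, "clone")


# -------------------------------------------------------------------- MAPE --

def test_mape_properties(hfit_small):
    err = pc.mape(hfit_small)
    assert 0 < err < 50
    # perfect fit: evaluate against the model's own fitted values
    hf, _ = _tiny_fit()
    hf.design.y = hf.fit.fitted.copy()
    hf.fit.fitted = hf.design.y
    assert pc.mape(hf) == 0.0


def test_mape_scale_invariance():
    cfg = pc.SimConfig(seed=33, k=1, genotypes_per_population=3,
                       plants_per_genotype=2, rows=3, cols=2, n_times=8,
                       missingness=0.0, spatial_amplitude=0.0)
    table, _ = pc.simulate_experiment(cfg)
    series = pc.series_from_table(table)
    hc = pc.HierConfig(b_pop=5, b_gen=5, b_plant=5)
    hf1 = pc.fit_growth(pc.build_hier_design(series, hc))
    series2 = pc.series_from_table(table)
    series2.data["corrected"] *= 3.0
    hf2 = pc.fit_growth(pc.build_hier_design(series2, hc))
    assert abs(pc.mape(hf1) - pc.mape(hf2)) < 1e-6 * pc.mape(hf1) + 1e-8


# -------------------------------------------------------- model covariance --

def test_covariance_zero_across_populations(hfit_small):
    d = hfit_small.design
    a = d.plants[0]
    other_pop = next(p for m, p in enumerate(d.plants)
                     if d.gen_pop[d.plant_gen[m]] != d.gen_pop[d.plant_gen[0]])
    times = d.times[[0, 3, 6]]
    cov = pc.model_covariance(hfit_small, a, other_pop, times)
    np.testing.assert_array_equal(cov, 0.0)


def test_covariance_nested_monotonicity(hfit_small):
    d = hfit_small.design
    a = d.plants[0]
    sib = next(pl for m, pl in enumerate(d.plants)
               if m != 0 and d.plant_gen[m] == d.plant_gen[0])
    cousin = next(pl for m, pl in enumerate(d.plants)
                  if d.plant_gen[m] != d.plant_gen[0]
                  and d.gen_pop[d.plant_gen[m]] == d.gen_pop[d.plant_gen[0]])
    times = d.times[[1, 4, 8]]
    c_self = np.diag(pc.model_covariance(hfit_small, a, a, times))
    c_sib = np.diag(pc.model_covariance(hfit_small, a, sib, times))
    c_cousin = np.diag(pc.model_covariance(hfit_small, a, cousin, times))
    assert np.all(c_self >= c_sib - 1e-12)
    assert np.all(c_sib >= c_cousin - 1e-12)


def test_covariance_matches_simulated_curves(hfit_small):
    """Empirical covariance of prior draws reproduces the piecewise formula."""
    d = hfit_small.design
    a = d.plants[0]
    sib = next(pl for m, pl in enumerate(d.plants)
               if m != 0 and d.plant_gen[m] == d.plant_gen[0])
    times = d.times[[0, 4, 9]]
    target = pc.model_covariance(hfit_small, a, sib, times)
    v = hfit_small.variances
    rng = np.random.default_rng(99)
    n_draws = 2000
    Zp = d.mm_pop.random_matrix(times)
    Xg = d.mm_gen.fixed_matrix(times)
    Zg = d.mm_gen.random_matrix(times)
    Xpl = d.mm_plant.fixed_matrix(times)
    Zpl = d.mm_plant.random_matrix(times)
    pop = d.populations[d.gen_pop[d.plant_gen[0]]]
    sp2 = v[f"pop_smooth[{pop}]"]
    ya = np.empty((n_draws, len(times)))
    yb = np.empty_like(ya)
    for r in range(n_draws):
        shared = Zp @ rng.normal(0, np.sqrt(sp2), Zp.shape[1])
        shared += Xg @ rng.normal(0, np.sqrt([v["gen_int"], v["gen_slope"]]))
        shared += Zg @ rng.normal(0, np.sqrt(v["gen_smooth"]), Zg.shape[1])
        for y in (ya, yb):
            own = Xpl @ rng.normal(0, np.sqrt([v["plant_int"], v["plant_slope"]]))
            own += Zpl @ rng.normal(0, np.sqrt(v["plant_smooth"]), Zpl.shape[1])
            own += rng.normal(0, np.sqrt(hfit_small.sigma2), len(times))
            y[r] = shared + own
    emp = np.empty_like(target)
    se = np.empty_like(target)
    for i in range(len(times)):
        for j in range(len(times)):
            prod = (ya[:, i] - ya[:, i].mean()) * (yb[:, j] - yb[:, j].mean())
            emp[i, j] = prod.mean()
            se[i, j] = prod.std(ddof=1) / np.sqrt(n_draws)
    assert np.all(np.abs(emp - target) <= 3.5 * se)


# ------------------------------------------------------- missing robustness -

def test_genotype_curves_robust_to_20pct_missing(series_small, hfit_small,
                                                 grid_small):
    full = pc.evaluate_curves(hfit_small, "genotype", grid=grid_small)
    data = series_small.data.copy()
    obs_idx = data.index[~data["missing"]]
    rng = np.random.default_rng(7)
    drop = rng.choice(obs_idx, size=int(0.2 * len(obs_idx)), replace=False)
    data.loc[drop, ["corrected", "prediction", "residual", "weight"]] = np.nan
    data.loc[drop, "missing"] = True
    thin_series = pc.CorrectedSeries(data=data)
    thin = pc.fit_growth(pc.build_hier_design(
        thin_series, pc.HierConfig(b_pop=7, b_gen=7, b_plant=7)))
    thin_curves = pc.evaluate_curves(thin, "genotype", grid=grid_small)
    halfwidth = 1.96 * full.se
    within = np.abs(thin_curves.estimates - full.estimates) < halfwidth
    assert within.mean() > 0.9


def test_weight_mode_switch_changes_residual_reading():
    """Precision vs. literal-variance weight readings: identical with unit
    weights, genuinely different residual structures otherwise."""
    cfg = pc.SimConfig(seed=34, k=1, genotypes_per_population=3,
                       plants_per_genotype=2, rows=3, cols=2, n_times=8,
                       missingness=0.0, spatial_amplitude=0.0)
    table, _ = pc.simulate_experiment(cfg)
    series = pc.series_from_table(table)
    fits = {}
    for mode in ("precision", "variance"):
        hc = pc.HierConfig(b_pop=5, b_gen=5, b_plant=5, weight_mode=mode)
        fits[mode] = pc.fit_growth(pc.build_hier_design(series, hc))
    # unit weights: the two readings coincide
    np.testing.assert_allclose(fits["precision"].fit.fitted,
                               fits["variance"].fit.fitted, atol=1e-8)
    # non-unit weights: the readings use reciprocal residual structures
    series.data["weight"] = np.linspace(0.5, 2.0, len(series.data))
    d_prec = pc.build_hier_design(series, pc.HierConfig(
        b_pop=5, b_gen=5, b_plant=5, weight_mode="precision"))
    d_var = pc.build_hier_design(series, pc.HierConfig(
        b_pop=5, b_gen=5, b_plant=5, weight_mode="variance"))
    np.testing.assert_allclose(d_prec.lmm_weights() * d_var.lmm_weights(),
                               1.0, atol=1e-12)
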