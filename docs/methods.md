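# Methods

This note documents the statistical machinery of `phenocurve`, the
choices made where the design was genuinely open, and what the synthetic
experiments do and do not establish.

## Data model

Input is a long-format table with one record per (population, genotype,
plant, row, column, time, value). The hierarchy must be strictly nested —
each genotype under exactly one population, each plant under exactly one
genotype — and each plant occupies one cell of an `r × c` grid. All
plants share a common measurement-time grid `t_1 < … < t_n`; missing
values are kept as explicit records so the plant × time slot structure is
preserved end to end. Identifiers are opaque strings; internal integer
codes follow first-appearance order, which makes every downstream
computation deterministic for a given file. Extra categorical columns are
design factors tagged `condition` (kept in the correction), `average`
(fixed nuisance, averaged out) or `random` (random nuisance, dropped).

## P-spline machinery

All curves use cubic B-splines with equidistant knots extended beyond the
data interval and an order-2 difference penalty on the coefficients. With
this knot placement the null space of the penalty is exactly the space of
linear functions, so the mixed-model reparameterization is exact: the
curve splits into an unpenalized `[1 | t − t_c]` part (times are centred
at the domain midpoint for conditioning) and a random part
`Z = B U_+ Λ_+^{−1/2}` built from the positive eigenpairs of `DᵀD`, whose
coefficients carry an identity penalty. A penalized least-squares fit at
smoothing parameter λ and the mixed-model fit at `λ = σ²/σ_u²` produce
identical fitted values; the test suite enforces this to 1e−8. Boundary
knot replication was deliberately avoided because it breaks this exact
equivalence near the interval ends.

Derivatives use the degree-reduction formula and integrals the exact
antiderivative, both through the underlying B-spline representation;
evaluation outside the knot domain raises an error rather than
extrapolating, because penalized spline extrapolation is linear and
silently misleading for growth curves.

## Mixed-model engine

The engine accepts arbitrary sparse fixed and random design blocks, each
random block tagged with a variance-group label (blocks sharing a label
share one variance). Residuals are `σ²·diag(1/w)` for positive precision
weights `w`. At fixed variances, Henderson's equations are assembled in
precision form, so the inverse coefficient matrix is directly the joint
covariance of the fixed estimates and random prediction errors; any
prediction error variance is `L C⁻¹ Lᵀ`, computed via solves. Systems
with up to 2500 coefficients are factorised densely (Cholesky; the full
inverse is cached because every REML iteration needs all diagonal
entries); larger systems use a sparse LU with fill-reducing ordering and
chunked solves.

REML uses the effective-dimension fixed point: with
`ED_g = q_g − trace(C⁻¹_gg)/σ_g²`,

    σ_g² ← û_gᵀû_g / ED_g,    σ² ← ε̂ᵀWε̂ / (N − rank(X) − Σ_g ED_g).

Convergence requires the relative change of the −2 REML log-likelihood
below 1e−8 *and* the largest variance-component change below 1e−6 —
where each component's change is measured as a share of the response
variance, weighted by the mean squared column norm of its design. The
scale-aware weighting matters: a slope-block variance expressed per
squared day is numerically tiny yet influential, while a raw relative
criterion lets practically irrelevant components (a smooth variance
estimated at 1e−7 of the signal, still creeping linearly toward zero)
stall the iteration for hundreds of rounds. Components whose
contribution falls below 1e−8 of the response variance while shrinking
are pinned at the variance floor (1e−10 × var(y)) and reported as pinned;
starting values are `var(y)/(n_groups+1)` for every component. The
fixed point is validated in the tests against closed-form REML (balanced
one-way ANOVA), a dense grid search, and numeric optimization of the
dense restricted likelihood.

## Stage 1: spatial correction

One mixed model per measurement time: intercept, population fixed
effects (reference coding), average-over design factors, random row and
column effects, genotype BLUPs with one genetic variance per population,
and a PS-ANOVA spatial surface — fixed bilinear part {u, v, u·v} plus
five smooth blocks (f(u), f(v), u·f(v), f(u)·v, f(u)⊗f(v)), each with its
own variance. Smooth blocks are column-centred and orthogonalised against
the bilinear polynomial for identifiability; the centring means and
projection coefficients are frozen on the training coordinates so the
fitted surface is evaluable anywhere on the grid. Marginal basis
dimensions default to the grid dimensions (capped at 60); the
smooth-by-smooth interaction uses nested marginal bases of half dimension
by default, which keeps the interaction coefficient count quadratic in
the halved dimensions.

The corrected value keeps intercept + population + the mean over each
average-factor's levels + genotype BLUP + residual; the identity
`ỹ = p̂ + ε̂` holds exactly by construction. With reference coding the
average over a factor's levels is `sum(β̂)/c_r` (the reference level
contributes zero), which makes the correction invariant to relabelling
the factor's levels. Weights take the diagonal of the full inverse of
`vcov(p̂) + σ̂²I` as defined — an `M×M` dense inverse per time, acceptable
at platform sizes. Plants unobserved at a time stay missing (their
genotype BLUP exists, but no residual does); times where REML fails are
logged and emitted as missing rather than aborting the run. Genotypes can
alternatively be modelled as fixed; on synthetic data the corrected
values under the two codings correlate above 0.99, because BLUP shrinkage
is compensated by the residual term in the correction.

## Stage 2: hierarchical growth model

Ordering is population-major for genotypes and genotype-major for plants.
The fixed block is `Q_pop ⊗ [1|t]` (2k columns); random blocks are the
population smooths (one variance per population), genotype intercepts,
slopes and smooths (shared variances, or per-population when configured),
and plant intercepts, slopes and smooths (shared, or per-genotype). The
coefficient count is `k·b_pop + L·b_gen + M·b_plant`, asserted at build
time. Missing observations drop rows, never coefficients, so curves stay
estimable for incomplete units. The same basis dimension at all three
levels is the default and a warning is raised otherwise — unequal
dimensions have proven unreliable in this model class.

The stage-1 weights enter as precisions (residual variance `σ²/w`). The
growth-model notation can also be read literally as residual variance
`σ²·w`; both readings are implemented (`weight_mode="precision"` /
`"variance"`) and precision is the default, since the weights are
defined in stage 1 as an inverse variance. Intercept–slope covariance
within the genotype or plant level is not modelled: the covariance
structure is diagonal by specification.

Curves, deviations and first derivatives are linear in the coefficient
vector; pointwise standard errors come from `L C⁻¹ Lᵀ` and 95% bands use
the 1.96 normal multiplier. The model-implied covariance between two
plant curves follows the nested piecewise form: zero across populations;
population smooth term within a population; plus genotype terms within a
genotype; plus plant terms and the residual for the same plant. The mean
absolute percentage error (MAPE) between corrected observations and
fitted plant curves uses a cutoff `|ỹ| ≥ 1e−8·max|ỹ|`; note MAPE is
scale-free but degenerates when observations approach zero, which
synthetic logistic curves do on early days while real platform traits do
not.

## Trait extraction

Curves are evaluated on a 401-point grid by default. Extrema are located
as sign changes of the differenced grid values and refined by a
three-point quadratic interpolation; the refinement makes the extracted
times stable under grid refinement, which the tests check. `maxSpeed` windows are
user-supplied, since meaningful windows are dataset-specific (cold
spells, recovery phases); a window without an interior derivative maximum
falls back to the windowed grid maximum and is flagged. The AUC of a
genotype deviation is computed exactly from the deviation's B-spline
coefficients — obtained by mapping the mixed-model coordinates back
through the Greville abscissae — not by grid quadrature.

## Synthetic data generator

The generator emulates the structures both stages assume: logistic
population curves (default parameters: plateaus 120/90, rates 0.30/0.25,
inflections at days 115/118 over a day 100–135 window — typical of maize
leaf-area growth over a one-month platform experiment), genotype and
plant deviations drawn from the P-spline mixed-model prior (random
intercept + random slope + smooth coefficient draws; default variances
16/0.04/4 at the genotype level and 4/0.01/1 at the plant level, i.e.
genotype spread of a few percent of the plateau and plant spread about
half that), a per-time smooth spatial surface (sinusoid product with
amplitude 10 and a linear amplitude drift over the experiment), optional
categorical factor effects, homoscedastic Gaussian noise (sd 2), and
completely-at-random missingness (5%). The default trial has 2
populations × 10 genotypes × 4 plants on a 10×8 grid with 15 measurement
days. A `spline` population mode draws the population curves from the
mixed-model prior too, giving exact model simulation for variance
recovery studies. All draws flow from one seed through named substreams;
identical seeds give byte-identical tables.

What passing tests show — and what they do not. On data simulated this
way, the pipeline recovers population curves within 5% relative RMSE,
variance components within 30% (empirically ~11% at worst) averaged over
20 replicates, and 95% intervals cover at ~0.95. Real platform data
differ in ways the generator does not emulate: spatial patterns that are
not low-frequency sinusoids, non-Gaussian and serially correlated
measurement error, imaging artefacts, and missingness that is not
completely at random. Results on synthetic data therefore validate the
implementation, not the model's adequacy for any particular platform.

## Problem sizes and numerical choices

Simulation-based tests use compact trials (≈80 plants, 10–15 days), where
every REML system stays in the dense regime; the published platform
configurations are exercised structurally (design assembly and counts at
1656 plants × 32 days and 720 plots × 23 days) rather than refitted,
which keeps the full suite to a few minutes. Degenerate inputs are
handled explicitly: all-missing times raise a typed error and are skipped
by the pipeline loop; rank-deficient fixed designs name the offending
columns; variance components at the floor are reported; REML
non-convergence carries the last iterate. Ties in extremum refinement
fall back to the grid point. Floating-point output uses 10 significant
digits.

## Known limitations

Stage 1 treats times independently — no smoothness is borrowed across
measurement days (a deliberate property of the two-stage design; one-stage
spatio-temporal models are out of scope). The stage-1 weight computation
is dense in the number of plants per time and would need structured
approximations well beyond ~5000 plants. Crossed (non-nested) grouping
structures, AR1-type residual correlation, intercept–slope covariances
and factor-analytic genetic structures are not supported. GLAM-style
array acceleration is not implemented; the sparse path is the correctness
path and is fast enough at the supported scales.
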