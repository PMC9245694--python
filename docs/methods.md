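# Methods

`lakehybrid` models deep-water dissolved oxygen (DO_B) in a large monomictic
lake by coupling an empirical dynamic modelling (EDM) core to a two-box
oxygen/physics model, and uses the coupled ("hybrid") model to explore
climate-warming x phosphorus-management scenarios.  This note documents the
models, their assumptions, the tunable parameters, the synthetic test bed,
and the numerical and design choices, in that order.

## 1. Empirical dynamic modelling core

### State-space reconstruction

All EDM operations act on a *state matrix*: one row per month, one column per
embedding coordinate `(variable, lag)`.  Coordinates are z-normalized with
statistics computed over library rows only and frozen; distances are
Euclidean on the normalized coordinates.  Rows with any missing lagged
component are masked, never imputed (interpolation happens only in
`regularize`, which fills gaps of at most `max_gap` grid steps — default 3 —
linearly and leaves longer gaps missing).

### Simplex projection

A forecast at horizon `tp` is the weighted mean of the targets of the `E+1`
nearest library neighbours, with weights `exp(-d_i/d_min)` where `d_min` is
the nearest distance.  If `d_min = 0`, zero-distance neighbours take weight
one and the rest drop out.  Neighbour ties are broken by earlier time index,
so results are exactly reproducible.  The prediction target's own row, and
optionally all rows within an exclusion radius of it (default: the
embedding's maximum lag), are excluded from its library to prevent temporal
leakage in leave-one-out evaluation.

### S-map

For each target state `x(t)` the library is weighted by

    w_i = exp(-theta * d_i / dbar),   dbar = mean library distance to x(t),

and a weighted least-squares regression of `target(t+tp)` on the normalized
coordinates plus an intercept is solved by SVD (`numpy.linalg.lstsq`;
rank-deficient designs fall back to the minimum-norm solution with a logged
warning).  At `theta = 0` all weights are equal and every local fit collapses
to one global linear regression — a multivariate autoregressive (MAR) model;
this equivalence is verified against an independent ordinary-least-squares
oracle to 1e-8.  `theta` is tuned by `theta_scan`: leave-one-out skill
(Pearson rho) over a grid of 0 plus a log-spread up to 10.  The gain of the
best theta over theta=0 is the nonlinearity (state-dependence) test: a
linear stochastic system shows no gain, the synthetic lake shows a large one
on its bloom dynamics.

Coefficients are reported in raw units (`c_normalized / sd_coordinate`), so
the coefficient on coordinate `x_j` estimates the Jacobian element
`d target(t+tp) / d x_j(t)` along the trajectory.  `bin_against` summarizes a
coefficient series against a conditioning variable (default: ten equal-count
bins, bootstrap CI of the bin mean).

### Convergent cross-mapping

CCM asks whether the effect's delay embedding can estimate the putative
cause.  The protocol: select `E*` in [1, 15] to maximize cross-map skill at
`tp = 0` with the maximal library (ties to the smallest E), then measure
convergence at `tp = floor(-E*/2)` — estimating the cause at the middle of
the embedding vector, which penalizes contemporaneous overfitting.  For each
library size, libraries are drawn randomly without replacement (contiguous
blocks optional), 100 subsamples by default.  The verdict is *convergent*
when

1. mean skill rises by more than `delta` from the smallest to the largest
   library, and
2. the large-library skill exceeds `rho_crit`, by default the 95th
   percentile of a phase-randomized (Ebisuzaki-style) surrogate null of the
   cause (200 surrogates), which preserves the power spectrum — including
   any seasonal cycle — while destroying state-dependent coupling.

`delta` defaults to 0.25.  This value was calibrated on the coupled-logistic
benchmark: under strong one-way forcing the driven variable partially
synchronizes to its driver, so the non-causal direction shows genuine but
*plateauing* cross-map skill (convergence gain ~0.2) that a smaller
threshold would misclassify, and occasional independent-pair curves drift by
up to ~0.17 (smooth fields on an attractor have few effective degrees of
freedom, so their correlations are wide-tailed — wider than the
phase-surrogate null suggests).

**Limitation.** For strongly seasonal or trending archives the verdict is
deliberately conservative in the opposite direction: a smooth declining
driver (e.g. the phosphorus trend) saturates even small libraries (little
convergence gain), and its phase surrogates retain the seasonal spectrum
(high `rho_crit`).  On such data the cross-map *skill* still ranks true
edges far above noise edges, but binary verdicts should not be expected to
recover the full causal graph; the discrimination power of the verdict is
demonstrated on the chaotic benchmark.

## 2. Two-box oxygen physics

Box geometry comes from a hypsometry (depth-area) table by trapezoidal
integration; the boundary sits at the thermocline (capped at 240 m in winter
so the deep box always corresponds to the deep-water monitoring layer).
Moving the boundary entrains water volume-weighted and conserves oxygen mass
exactly; homogenization to a mixing depth conserves mass to machine
precision (verified: relative drift ~1e-16 over 1e4 random steps).

Processes, each a parameter of `PhysicsParams`:

* **Gas exchange** — surface DO relaxes toward temperature-dependent
  saturation with piston velocity `k_gas` (default 1 m/d), integrated
  exactly (exponential step).  Saturation follows the standard
  Benson-Krause freshwater solubility relation, scaled by ambient pressure
  (default 0.956 atm, a ~370 m altitude).
* **River underflow** — in winter the plunging river injects water saturated
  at river temperature into the deep box as a replacement flux
  `Q * river_underflow_fraction / V_low` (default fraction 0.3: only part of
  the discharge reaches the deep layer); in summer the river enters the
  surface box.
* **Winter deep respiration** — a constant deep-box consumption
  (`deep_consumption`, default 0.004 mg/L/d) stands in for the
  biogeochemical sink outside the EDM-covered season.
* **Summer surface oxygen** — `dC/dt = kappa (C_sat - C) + p * CHL` with
  `p = chl_production` (default 0.01 mg O2/L/d per ug/L); the production
  term is a configurable plug-in (`surface_production_fn`) because the
  appropriate surface source parameterization is site-specific.

The physics is driven by a daily `ForcingSeries` that is either read from an
external hydrodynamic model's tabular output (`read_forcing`, with a column
dialect and an explicit gap policy) or produced by `surrogate_physics`: a
seasonal thermocline cycle deepening through winter toward a per-winter
maximal mixing depth drawn stochastically, with the probability of a deep
(>= 250 m) mixing winter falling with the DJF air-temperature anomaly
through a logistic link `p = 1/(1+exp((anom - a)/b))` (defaults a = -0.4,
b = 1, i.e. p = 0.4 in a normal winter and ~0.03 at +3 degC).  The random
draws are consumed in fixed order, so two runs differing only by a uniform
temperature offset share their random stream and warming can only remove
deep-mixing winters.

## 3. The hybrid model

The hybrid alternates seasonally, exploiting the separation between the
physical oxygen *source* (winter mixing) and the biogeochemical *sink*
(summer depletion):

* **Summer (May-October)**: three frozen S-map predictors — for DO_B,
  chlorophyll, and surface phosphorus — iterate monthly (6 steps over the
  180-day stratified season).  Physical coordinates come from the forcing,
  whole-lake phosphorus from the scenario or archive, and chlorophyll /
  surface phosphorus from their own predictors, so biology is internal to
  the empirical component.  Query states are clamped to the training range
  coordinate-wise (local linear fits are unreliable off the attractor) and
  flagged when farther than `extrapolation_radius` (default 6 z-units) from
  the library centroid.
* **End of October**: the predicted DO_B is handed to the physics as the
  deep box's initial condition — the only feedback between components.
* **Winter (November-April)**: daily box physics (mixing, gas exchange,
  underflow, deep respiration).  The winter surface box is initialized by
  volume-averaging the summer surface box with an assumed intermediate-depth
  oxygen (`intermediate_do`, default 9 mg/L) for the unmodelled mid-column.

Predictors are trained once, with normalization and libraries frozen;
`training_end` caps the library for strict out-of-sample use.  A single
initialization then propagates for decades with no re-anchoring to
observations.  `HybridModel.with_theta(0.0)` rebuilds the identical pipeline
with every predictor forced linear — the fixed-coefficient ablation used as
the comparison baseline.

Hindcast design: the validation hindcast trains on the full synthetic
archive and re-simulates it from a single initialization (iterated
prediction, not a fit), because a temporal train/test split is uninformative
on a monotonically trending record — the held-out phosphorus regime lies
entirely outside the training attractor.  Skill is `evaluate_hindcast`:
Pearson rho, MAE, and mean bias on the month-aligned overlap.

## 4. Scenario engine

Scenarios reanalyse a historical (or surrogate) meteorological record:
air temperature is OLS-detrended and shifted uniformly by `dT` (default set
{0, 1, 3} degC), all other drivers pass through unchanged, and whole-lake
phosphorus is held constant (default 65 down to 15 ug/L in 1 ug/L steps;
3 x 51 = 153 scenarios).  Each scenario's forcing is regenerated under its
own seed, derived as `master_seed XOR crc32(label)` so that adding scenarios
never shifts existing results and the grid is order-independent.  The score
is the *hypoxia fraction*: the percent of time DO_B sits strictly below
4 mg/L (the Swiss deep-water management benchmark), step-counted on uniform
grids and trapezoid-weighted on uneven ones (calendar-month spacing counts
as uniform).

## 5. The synthetic lake generator

`simulate_lake` is a discrete-time (monthly) process model — not an ODE — so
that the interaction Jacobians along the trajectory are exact analytic
expressions (verified against centered finite differences of the update maps
to 1e-6).  It emulates the phenomenology the analyses assume:

* seasonal air/surface temperature and discharge cycles with AR(1)
  anomalies;
* a multidecadal, noisy but monotone decline of whole-lake phosphorus
  (60 -> 15 ug/L over 37 years by default) with a seasonal surface
  drawdown;
* chlorophyll as a seasonally forced Ricker map, growth Michaelis-Menten in
  phosphorus and carrying capacity saturating in phosphorus.  The
  overcompensating density dependence makes summer blooms chaotic — which is
  precisely what defeats a global linear predictor while remaining
  predictable by state-dependent local regression (theta gain ~0.18);
* a deep-oxygen sink (mg/L/d) `monod(DO) * [base + loading(P) +
  c * e(P) * f(T) * CHL + warm-surface term]` with superlinear loading
  (`P^1.5`, normalized at 40 ug/L), a logistic export gate `e(P)` centred at
  18 ug/L, the seasonal production factor `f(T)`, and Monod oxygen
  limitation.  The gate reproduces the management-relevant sign structure:
  the chlorophyll effect on deep oxygen is essentially zero in the eutrophic
  state and turns negative only under reoligotrophication; loading plus gate
  produce a U-shaped total depletion with its minimum near 25-30 ug/L;
* intermittent winter deep mixing (same logistic climate link as the physics
  surrogate) that partially renews deep oxygen, plus the winter river
  underflow, mirroring the box physics.

What the generator does **not** emulate: spatial structure, ice cover,
multiple phytoplankton guilds, sediment oxygen demand dynamics, measurement
gaps/irregular cadence (observation noise is i.i.d. Gaussian at 1.5% of each
variable's sd).  Passing the battery therefore shows that the pipeline
recovers known structure from lake-like data of this kind, not that it would
perform identically on any specific monitoring archive.

## 6. Validation battery and problem sizes

`lakehybrid.validation` (run by `scripts/acceptance.py` and asserted in
`tests/test_acceptance.py`) computes, at sizes chosen to keep the full
battery under a few minutes on one CPU:

1. MAR equivalence on 20 random fixtures (n 50-200, 1-4 covariates);
2. theta-scan gains on a 3-variable MAR(1) null (n = 400) and the default
   37-y lake (n = 444 months);
3. Jacobian recovery on one default lake; coefficient series vs analytic
   truth, plus 4-bin regime summaries against whole-lake phosphorus;
4. CCM on coupled logistic maps (n = 1000, forcing 0.32), 30 subsamples,
   100 surrogates, and five independent pairs for the null;
5. conservation over 1e4 random mixing steps and the 180-day surface ODE
   closed form;
6. hybrid-vs-ablation hindcasts on three replicate 37-y lakes (replication
   averages out single-archive luck in the skill gap);
7. the scenario battery: 7 phosphorus levels x {0, +3} degC x 40 years,
   averaged over two independently trained lake instances; U-shape arms are
   means over adjacent phosphorus levels ({15,20} vs {25,30,35} vs {60,65})
   to suppress the Monte-Carlo noise of individual winter-mixing histories.

## 7. Known limitations

* **Chlorophyll-to-oxygen coefficient bias.**  The S-map coefficient on
  chlorophyll in the DO_B embedding carries a small systematic positive
  offset (~+0.01-0.02 mg/L per ug/L) that persists at zero observation and
  process noise, for any theta in [2, 10] and 4-6-coordinate embeddings.
  Chlorophyll is dynamically slaved to the same seasonal/trend coordinates
  that carry most of the oxygen update, so local linear fits apportion part
  of that signal to it.  The true effect (reaching ~-0.03 to -0.05 at low
  phosphorus in summer) is of the same magnitude, so while the
  phosphorus-to-chlorophyll Jacobian is recovered almost perfectly
  (series correlation ~0.98), the chlorophyll-to-oxygen *sign regime* is not
  reliably recovered on this generator and the corresponding validation
  check fails by design honesty rather than being relaxed.  Users tracking
  weak interactions embedded in strongly autocorrelated targets should
  treat S-map coefficient levels (as opposed to trends in strongly varying
  coefficients) with caution.
* **Binary CCM verdicts on seasonal/trending data** are conservative (see
  section 1); use the skill curves, not only the verdicts.
* The hybrid carries a positive oxygen bias of ~1-2 mg/L against the
  generator truth (winter initialization of the unmodelled mid-column and
  the constant winter respiration are approximate); correlation-based skill
  is unaffected, absolute levels should be calibrated per site.
* Scenario air-temperature offsets push summer surface temperature beyond
  the training range; coordinate clamping makes the empirical component
  respond as at the warmest observed states, so the direct metabolic effect
  of warming is likely underestimated while the mixing-frequency effect
  (carried by the physics) is fully expressed.
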