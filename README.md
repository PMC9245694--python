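# lakehybrid

Hybrid empirical-parametric modelling of deep-lake dissolved oxygen.

Deep temperate lakes receive oxygen at depth almost exclusively through
winter mixing and lose it to biogeochemical consumption through the
stratified season.  Management of such lakes faces two entangled pressures:
nutrient (phosphorus) loading, whose reduction ("reoligotrophication")
reshapes the food web and with it the oxygen sink, and atmospheric warming,
which suppresses the winter mixing that resupplies oxygen.  Fixed-parameter
biogeochemical models struggle here because the relationships among
phosphorus (TP), chlorophyll (CHL) and deep-water oxygen (DO_B) are
*state-dependent*: they change as the lake moves between trophic states.

`lakehybrid` is a toolkit for limnologists and ecosystem modellers that
addresses this with **empirical dynamic modelling (EDM)** for the biology
and a **two-box physical model** for the oxygen source, coupled seasonally:

* **S-map forecasting** — locally weighted linear regression in a
  reconstructed state space, with weights
  `w_i = exp(-theta d_i / dbar)` on the Euclidean distance `d_i` to the
  target state.  At `theta = 0` it *is* a multivariate autoregressive (MAR)
  model; `theta > 0` lets the coefficients vary with lake state, and the
  local coefficients estimate time-varying Jacobian elements such as
  `dCHL/dTP` and `dDO_B/dCHL`.
* **Convergent cross-mapping (CCM)** — causal inference for coupled
  dynamical systems, with embedding dimension `E*` chosen in [1, 15] at
  horizon `tp = 0` and convergence measured at `tp = floor(-E*/2)`, judged
  against phase-randomized surrogates.
* **Two-box oxygen physics** — hypsometric box volumes at the thermocline,
  winter mixing-depth homogenization, Benson-Krause saturation gas
  exchange, and a river underflow oxygenating the deep box.
* **The hybrid model** — winter evolved by the physics, summer DO_B
  depletion by iterated monthly S-map prediction (CHL and surface TP
  predicted internally), with end-of-October deep oxygen fed back to the
  physics.  One initialization propagates for decades.
* **A scenario engine** — detrended air temperature shifted by {0, 1, 3}
  degC crossed with constant TP from 65 down to 15 ug/L (153 scenarios),
  scored by the percent of time DO_B < 4 mg/L, the Swiss deep-water
  management benchmark.
* **Synthetic generators** — a seeded monthly lake model with known causal
  graph and *analytic* interaction Jacobians (plus coupled logistic maps
  and a MAR null), so every stage is testable against ground truth without
  any monitoring archive.

## Worked example

Track the state-dependence of the phosphorus-chlorophyll interaction on a
synthetic reoligotrophication archive, and verify it against the
generator's exact Jacobian:

```python
import numpy as np
import lakehybrid as lh
from lakehybrid.edm import (EmbeddingSpec, build_state_matrix, theta_scan,
                            smap_forecast, interaction_coefficients, bin_against)

ts, truth = lh.simulate_lake(seed=1)          # 37 y, monthly, 8 variables
spec = EmbeddingSpec((("chl", 0), ("TP_surf", 0), ("T_surf", 0)), "chl", tp=1)
sm = build_state_matrix(ts.data, spec)

scan = theta_scan(sm, ts.data["chl"].to_numpy(), tp=1)
print(f"linear (theta=0) skill: {scan.table.rho.iloc[0]:.3f}")
print(f"best theta: {scan.best_theta:g}  skill: {scan.best_rho:.3f}  gain: {scan.delta_rho:.3f}")

fit = smap_forecast(sm, ts.data["chl"].to_numpy(), theta=scan.best_theta,
                    tp=1, exclusion_radius=1)
coef = interaction_coefficients(fit, "TP_surf")      # dCHL(t+1)/dTP_surf(t)
print(bin_against(coef, ts.data["TP_lake"], n_bins=4, seed=0)
      [["bin_center", "mean", "ci_lo", "ci_hi"]].round(3).to_string(index=False))

ok = coef.notna() & truth.jacobians["dchl_dtp"].notna()
print(f"correlation with analytic Jacobian: "
      f"{np.corrcoef(coef[ok], truth.jacobians['dchl_dtp'][ok])[0, 1]:.3f}")
```

Output:

```
linear (theta=0) skill: 0.789
best theta: 10  skill: 0.982  gain: 0.193
 bin_center  mean  ci_lo  ci_hi
     20.228 0.143  0.126  0.162
     32.095 0.115  0.099  0.130
     43.051 0.088  0.078  0.102
     54.934 0.075  0.066  0.086
correlation with analytic Jacobian: 0.986
```

Reading it: the bloom dynamics are strongly nonlinear (forecast skill jumps
from 0.79 to 0.98 when the S-map is tuned away from the linear model), and
the tracked coefficient shows phosphorus limitation emerging as the lake
reoligotrophies — the chlorophyll response to phosphorus roughly doubles
(0.075 -> 0.143 ug CHL per ug TP) as whole-lake TP falls from ~55 to
~20 ug/L, and the series tracks the generator's exact Jacobian at r = 0.99.

The same pipeline is exposed on the command line:

```sh
lakehybrid simulate --seed 1 --out lake.csv --truth truth.csv
lakehybrid smap --input lake.csv --target chl --variables chl,TP_surf,T_surf --out fit.csv
lakehybrid ccm --input lake.csv --pairs chl,TP_lake --seed 42 --out ccm.csv
lakehybrid hybrid --input lake.csv --forcing forcing.csv --out dob_sim.csv
lakehybrid scenario --input lake.csv --dt 0,1,3 --tp 15:65:1 --out grid.csv
```

Every command writes a small JSON manifest (config hash, seed, versions)
beside its outputs; identical manifests reproduce byte-identical numbers.

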