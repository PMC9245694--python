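"""End-to-end validation battery on synthetic data with known ground truth.

Each function runs one self-contained experiment — generating its own inputs
from seeded generators, exercising the corresponding pipeline stage, and
returning measured quantities.  The battery doubles as the reproducibility
entry point: ``scripts/acceptance.py`` runs it and writes the numbers to JSON.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .ccm import ccm
from .edm import (
    EmbeddingSpec,
    bin_against,
    build_state_matrix,
    interaction_coefficients,
    smap_forecast,
    theta_scan,
)
from .hybrid import HybridModel, evaluate_hindcast
from .physics import (
    PhysicsParams,
    do_saturation,
    make_box_state,
    surface_do_update,
    winter_mix_step,
)
from .scenarios import (
    default_forcing_factory,
    hypoxia_fraction,
    make_grid,
    run_grid,
)
from .synthetic import (
    GeneratorParams,
    forcing_from_lake,
    simulate_coupled_logistic,
    simulate_lake,
    simulate_mar,
    synthetic_hypsometry,
)


def _sub_seed(seed: int, k: int) -> int:
    return (int(seed) * 1_000_003 + k) % (2**31 - 1)


# ---------------------------------------------------------------------------
# 1. MAR equivalence of the theta=0 S-map
# ---------------------------------------------------------------------------


def mar_equivalence_error(seed: int = 0, n_fixtures: int = 20) -> float:
    """Max |theta=0 S-map coefficient - OLS oracle| over random fixtures.

    The oracle is a direct least-squares solve on the raw (unnormalized)
    design — an independent code path from the S-map's weighted normalized
    regression.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_fixtures):
        n = int(rng.integers(50, 200))
        k = int(rng.integers(1, 5))
        X = rng.normal(size=(n, k)) * rng.uniform(0.5, 20.0, k)
        beta = rng.normal(size=k)
        y = X @ beta + rng.normal(0, 0.5, n) + rng.normal() * 3
        cols = [f"v{j}" for j in range(k)]
        df = pd.DataFrame(X, columns=cols)
        df["y"] = y
        sm = build_state_matrix(df, EmbeddingSpec(tuple((c, 0) for c in cols), "y", 0))
        fit = smap_forecast(sm, y, theta=0.0, tp=0)
        coefs = fit.coefficients.dropna()
        # oracle: lstsq on [X, 1]
        A = np.column_stack([X, np.ones(n)])
        ols = np.linalg.lstsq(A, y, rcond=None)[0]
        est = coefs.iloc[0][cols + ["intercept"]].to_numpy(float)
        worst = max(worst, float(np.abs(est - ols).max()))
        worst = max(
            worst,
            float(coefs[cols].std().max()),  # identical at every target time
        )
    return worst


# ---------------------------------------------------------------------------
# 2. Nonlinearity contrast (theta scan)
# ---------------------------------------------------------------------------


def nonlinearity_contrast(seed: int = 0) -> dict:
    """Best-theta skill gain on a linear MAR null vs the nonlinear lake."""
    mar = simulate_mar(
        np.array([[0.6, 0.2, 0.0], [0.1, 0.5, -0.2], [0.0, 0.1, 0.4]]),
        n=400,
        seed=_sub_seed(seed, 1),
    )
    smm = build_state_matrix(
        mar, EmbeddingSpec((("x0", 0), ("x1", 0), ("x2", 0)), "x0", 1)
    )
    gain_mar = theta_scan(smm, mar["x0"].to_numpy(), tp=1).delta_rho

    ts, _ = simulate_lake(seed=_sub_seed(seed, 2))
    d = ts.data
    sm_chl = build_state_matrix(
        d, EmbeddingSpec((("chl", 0), ("TP_surf", 0), ("T_surf", 0)), "chl", 1)
    )
    scan_chl = theta_scan(sm_chl, d["chl"].to_numpy(), tp=1)
    sm_do = build_state_matrix(
        d,
        EmbeddingSpec(
            (("DO_B", 0), ("chl", 0), ("TP_surf", 0), ("TP_lake", 0),
             ("h_mix", 0), ("T_surf", 0)),
            "DO_B",
            1,
        ),
    )
    scan_do = theta_scan(sm_do, d["DO_B"].to_numpy(), tp=1)
    return {
        "gain_mar": float(gain_mar),
        "gain_lake_chl": float(scan_chl.delta_rho),
        "gain_lake_do_b": float(scan_do.delta_rho),
        "best_theta_chl": float(scan_chl.best_theta),
    }


# ---------------------------------------------------------------------------
# 3. Jacobian (interaction) recovery
# ---------------------------------------------------------------------------


def jacobian_recovery(seed: int = 0) -> dict:
    """S-map coefficient tracking vs the generator's analytic Jacobians.

    The phosphorus-to-chlorophyll coefficient is compared as a monthly series
    (correlation) and both coefficients are compared in their binned
    state-regime structure: the chlorophyll response to phosphorus is
    positive under P-limitation and shrinks toward zero in the eutrophic
    state; the deep-oxygen response to chlorophyll is significantly negative
    only at low phosphorus.
    """
    ts, truth = simulate_lake(seed=_sub_seed(seed, 3))
    d = ts.data
    tr = truth.jacobians

    sm_c = build_state_matrix(
        d, EmbeddingSpec((("chl", 0), ("TP_surf", 0), ("T_surf", 0)), "chl", 1)
    )
    scan = theta_scan(sm_c, d["chl"].to_numpy(), tp=1)
    fit_c = smap_forecast(
        sm_c, d["chl"].to_numpy(), theta=scan.best_theta, tp=1, exclusion_radius=1
    )
    est_c = interaction_coefficients(fit_c, "TP_surf")
    ok = est_c.notna() & tr["dchl_dtp"].notna()
    corr_chl = float(np.corrcoef(est_c[ok], tr["dchl_dtp"][ok])[0, 1])
    binned_c = bin_against(est_c[ok], d["TP_lake"][ok], n_bins=4, seed=0)

    sm_d = build_state_matrix(
        d,
        EmbeddingSpec(
            (("DO_B", 0), ("chl", 0), ("TP_lake", 0), ("T_surf", 0), ("h_mix", 0)),
            "DO_B",
            1,
        ),
    )
    fit_d = smap_forecast(sm_d, d["DO_B"].to_numpy(), theta=3.0, tp=1,
                          exclusion_radius=1)
    est_d = interaction_coefficients(fit_d, "chl")
    okd = (tr["mix_fraction"] == 0) & est_d.notna() & tr["ddo_dchl"].notna()
    corr_do = float(np.corrcoef(est_d[okd], tr["ddo_dchl"][okd])[0, 1])
    binned_d = bin_against(est_d[okd], d["TP_lake"][okd], n_bins=4, seed=0)

    lo_c, hi_c = binned_c["mean"].iloc[0], binned_c["mean"].iloc[-1]
    lo_d = binned_d.iloc[0]
    hi_d = binned_d.iloc[-1]
    return {
        "corr_chl_tp": corr_chl,
        "corr_do_chl": corr_do,
        "chl_tp_low_p_mean": float(lo_c),
        "chl_tp_high_p_mean": float(hi_c),
        "chl_tp_regime_ok": bool(lo_c > 1.5 * hi_c and hi_c > -0.01),
        "do_chl_low_p_mean": float(lo_d["mean"]),
        "do_chl_high_p_mean": float(hi_d["mean"]),
        "do_chl_regime_ok": bool(
            lo_d["ci_hi"] < 0 and abs(hi_d["mean"]) < 0.5 * abs(lo_d["mean"])
        ),
    }


# ---------------------------------------------------------------------------
# 4. CCM protocol on coupled logistic maps
# ---------------------------------------------------------------------------


def ccm_benchmark(
    seed: int = 0,
    n_subsamples: int = 30,
    n_surrogates: int = 100,
    n_null_pairs: int = 5,
) -> dict:
    """Directionality on the canonical forced pair + flat independent null."""
    pair = simulate_coupled_logistic(n=1000, seed=_sub_seed(seed, 4))
    fwd = ccm(
        pair["y"], pair["x"], n_subsamples=n_subsamples,
        n_surrogates=n_surrogates, seed=_sub_seed(seed, 5),
    )
    rev = ccm(
        pair["x"], pair["y"], n_subsamples=n_subsamples,
        n_surrogates=n_surrogates, seed=_sub_seed(seed, 5),
    )
    null_rhos = []
    for k in range(n_null_pairs):
        ind = simulate_coupled_logistic(b_yx=0.0, n=1000, seed=_sub_seed(seed, 10 + k))
        r = ccm(
            ind["y"], ind["x"], n_subsamples=10, n_surrogates=20,
            seed=_sub_seed(seed, 30 + k),
        )
        null_rhos.append(abs(float(r.skill_mean[-1])))
    return {
        "forward_convergent": bool(fwd.convergent),
        "reverse_convergent": bool(rev.convergent),
        "forward_rho_lmax": float(fwd.skill_mean[-1]),
        "reverse_rho_lmax": float(rev.skill_mean[-1]),
        "tp_protocol_ok": bool(
            fwd.tp_used == math.floor(-fwd.E_star / 2)
            and rev.tp_used == math.floor(-rev.E_star / 2)
        ),
        "null_mean_abs_rho": float(np.mean(null_rhos)),
    }


# ---------------------------------------------------------------------------
# 5. Physics conservation and closed forms
# ---------------------------------------------------------------------------


def physics_conservation(seed: int = 0, n_steps: int = 10_000) -> dict:
    """Mass drift under pure mixing, exact homogenization, ODE closed form."""
    h = synthetic_hypsometry()
    pure = PhysicsParams(k_gas=0.0, river_underflow=False, deep_consumption=0.0)
    state = make_box_state(h, 240.0, do_up=10.0, do_low=4.0)
    mass0 = state.total_mass
    rng = np.random.default_rng(seed)
    for depth in rng.uniform(20.0, h.z_max, n_steps):
        state = winter_mix_step(state, h, float(depth), t_surf=6.0, params=pure)
    drift = abs(state.total_mass - mass0) / mass0

    full = winter_mix_step(
        make_box_state(h, 240.0, do_up=10.0, do_low=4.0), h, h.z_max,
        t_surf=6.0, params=pure,
    )
    homog_gap = abs(full.do_up - full.do_low)

    # surface ODE vs closed form over 180 days
    params = PhysicsParams(river_underflow=False, deep_consumption=0.0)
    s = make_box_state(h, 17.5, do_up=7.0, do_low=5.0)
    sat = float(do_saturation(18.0, params.pressure_atm))
    kappa = params.k_gas * h.surface_area / s.v_up
    c_eq = sat + params.chl_production * 6.0 / kappa
    max_err = 0.0
    for day in range(1, 181):
        s = surface_do_update(s, h, chl=6.0, t_surf=18.0, params=params)
        expect = c_eq + (7.0 - c_eq) * np.exp(-kappa * day)
        max_err = max(max_err, abs(s.do_up - expect))
    return {
        "mass_drift_rel": float(drift),
        "full_mix_homogenization_gap": float(homog_gap),
        "surface_ode_max_abs_err": float(max_err),
    }


# ---------------------------------------------------------------------------
# 6. Hybrid hindcast vs theta=0 ablation
# ---------------------------------------------------------------------------


def hybrid_vs_ablation(seed: int = 0, n_lakes: int = 3) -> dict:
    """Replicated 37-year hindcasts: tuned hybrid vs fixed-coefficient ablation."""
    rhos, rhos0, maes = [], [], []
    for k in range(n_lakes):
        ts, truth = simulate_lake(seed=_sub_seed(seed, 40 + k))
        model = HybridModel().fit(ts)
        forcing = forcing_from_lake(truth)
        hyp = synthetic_hypsometry()
        may = ts.data.index[ts.data.index.month == 5][0]
        do0 = float(truth.clean["DO_B"].loc[may])
        sim, _ = model.run(forcing, truth.clean["TP_lake"], hyp, do_b_init=do0)
        sim0, _ = model.with_theta(0.0).run(
            forcing, truth.clean["TP_lake"], hyp, do_b_init=do0
        )
        m = evaluate_hindcast(sim, ts.data["DO_B"])
        m0 = evaluate_hindcast(sim0, ts.data["DO_B"])
        rhos.append(m["rho"])
        rhos0.append(m0["rho"])
        maes.append(m["mae"])
    return {
        "hybrid_rho_mean": float(np.mean(rhos)),
        "ablation_rho_mean": float(np.mean(rhos0)),
        "rho_gap_mean": float(np.mean(rhos) - np.mean(rhos0)),
        "hybrid_mae_mean": float(np.mean(maes)),
    }


# ---------------------------------------------------------------------------
# 7. Scenario engine
# ---------------------------------------------------------------------------

SCENARIO_TP_VALUES = (15.0, 20.0, 25.0, 30.0, 35.0, 60.0, 65.0)


def scenario_battery(seed: int = 0, years: int = 30, archive_years: int = 60) -> dict:
    """Hypoxia benchmark fixtures, grid arithmetic, and the U-shape/warming
    structure of the scenario response.

    The training archive is longer than the scenario runs (60 y by default)
    so that the low-phosphorus regime — which the scenarios revisit from
    well-oxygenated starts — is represented in the predictors' libraries.
    """
    idx = pd.date_range("2000-01-31", periods=6, freq="ME")
    fixture = hypoxia_fraction(
        pd.Series([1.0, 2, 3, 5, 6, 7], index=idx), threshold=4.0
    )
    grid_size = len(make_grid())  # 3 offsets x 65..15 by 1

    grid = [
        sc
        for sc in make_grid(dT_set=(0.0, 3.0), TP_min=15, TP_max=65, TP_step=5)
        if sc.TP_const in SCENARIO_TP_VALUES
    ]
    # two independently trained lake instances, each with its own forcing
    # stream: both predictor-estimation bias and the Monte-Carlo noise of the
    # winter deep-mixing history average out across replicates
    pivots = []
    for rep in range(2):
        ts, truth = simulate_lake(
            GeneratorParams(span_years=archive_years),
            seed=_sub_seed(seed, 60 + 7 * rep),
        )
        model = HybridModel().fit(ts)
        t_atm = forcing_from_lake(truth).data["T_atm_C"].iloc[: 365 * years]
        _, summary = run_grid(
            grid,
            model,
            default_forcing_factory(t_atm),
            synthetic_hypsometry(),
            master_seed=_sub_seed(seed, 80 + rep),
        )
        pivots.append(
            summary.pivot(index="TP_const", columns="dT_air", values="hypoxia_pct")
        )
    piv = (pivots[0] + pivots[1]) / 2
    h0, h3 = piv[0.0], piv[3.0]
    # arms of the U: averages over neighbouring phosphorus levels, which
    # suppresses the Monte-Carlo noise of individual 30-y mixing histories
    low_arm = float(h0.loc[[15.0, 20.0]].mean())
    mid_arm = float(h0.loc[[25.0, 30.0, 35.0]].mean())
    high_arm = float(h0.loc[[60.0, 65.0]].mean())
    return {
        "hypoxia_fixture_pct": float(fixture),
        "grid_size_default": int(grid_size),
        "hypoxia_dt0_tp65": float(h0.loc[65.0]),
        "hypoxia_dt0_tp15": float(h0.loc[15.0]),
        "hypoxia_dt0_low_arm": low_arm,
        "hypoxia_dt0_mid_min": mid_arm,
        "hypoxia_dt0_high_arm": high_arm,
        "u_shape_ok": bool(high_arm > mid_arm and low_arm > mid_arm),
        "warming_increase_mean": float((h3 - h0).mean()),
        "warming_ordering_ok": bool(((h3 - h0) > -5.0).all()),
        "hypoxia_dt3_mean": float(h3.mean()),
    }
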