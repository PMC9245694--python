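"""Seeded synthetic generators with known causal structure and Jacobians.

:func:`simulate_lake` produces a monthly, multi-decadal series of the eight
monitored lake variables from a discrete-time process model built to emulate
the phenomenology of a deep monomictic lake under reoligotrophication:
seasonal temperature/discharge cycles, a declining whole-lake phosphorus
trend, intermittent winter deep-mixing that resupplies deep oxygen, and —
crucially — state-dependent biogeochemical coupling:

* chlorophyll responds to surface phosphorus through a saturating
  (Michaelis-Menten) uptake, so d CHL / d TP is essentially zero at high
  phosphorus and positive once phosphorus becomes limiting;
* the deep-oxygen sink responds to chlorophyll through a phosphorus-gated
  export fraction, so d DO_B / d CHL is essentially zero in the eutrophic
  state and turns negative only at low phosphorus;
* a direct loading term makes total depletion high at high phosphorus, dip at
  intermediate levels, and rise again at low phosphorus (a U-shaped response).

Because the model is discrete-time, the interaction Jacobians along the
trajectory are exact analytic expressions, returned alongside the series as
ground truth for validating S-map coefficient tracking.

:func:`simulate_coupled_logistic` and :func:`simulate_mar` provide the
canonical cross-mapping benchmark pair and the linear (multivariate
autoregressive) null used by the nonlinearity test.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DataError
from .physics import Hypsometry
from .timeseries import LakeTimeSeries

DAYS_PER_MONTH = 30.44


def synthetic_hypsometry(
    z_max: float = 310.0, surface_area: float = 580e6, shape: float = 0.8
) -> Hypsometry:
    """A smooth basin: area shrinking with depth like (1 - z/(1.1 z_max))^shape."""
    z = np.linspace(0.0, z_max, 63)
    a = surface_area * (1.0 - z / (1.1 * z_max)) ** shape
    return Hypsometry(z, a)


@dataclass
class GeneratorParams:
    """Defaults emulate ~37 years of monthly monitoring of a deep alpine lake."""

    span_years: int = 37
    start_year: int = 1981
    # air temperature: seasonal cycle + AR(1) anomalies
    t_atm_mean: float = 11.0
    t_atm_amp: float = 9.0
    t_atm_noise_sd: float = 1.0
    t_atm_ar: float = 0.5
    t_atm_offset: float = 0.0
    # surface temperature response
    t_surf_min: float = 5.0
    t_surf_response: float = 0.85
    # river discharge
    q_mean: float = 180.0
    q_seasonal_amp: float = 110.0
    q_noise_sd: float = 20.0
    # whole-lake phosphorus trend (ug/L), linear decline + AR noise
    tp_start: float = 60.0
    tp_end: float = 15.0
    tp_noise_sd: float = 0.8
    # surface phosphorus: seasonal biological drawdown
    tp_surf_drawdown: float = 0.30
    tp_surf_noise_sd: float = 1.0
    # chlorophyll dynamics: seasonally forced Ricker map with Michaelis-Menten
    # phosphorus limitation of the growth rate:
    #   CHL(t+1) = CHL exp(g (1 - CHL/Kc) - m0) + imm,
    #   g = rmax f(T) P/(K+P)
    chl_rmax: float = 3.6  # max per-month growth exponent (chaotic blooms)
    chl_mort: float = 0.25  # background loss exponent per month
    chl_half_sat: float = 10.0  # ug/L phosphorus half-saturation
    chl_capacity_max: float = 12.0  # ug/L asymptotic carrying capacity
    chl_capacity_half: float = 15.0  # ug/L phosphorus half-saturation of capacity
    chl_immigration: float = 0.2  # ug/L seed stock per month
    chl_noise_sd: float = 0.25
    # deep-oxygen sink (mg/L/d): s0 + sP*P + c_exp*e(P)*CHL + sT*max(Ts-18,0)
    sink_base: float = 4.0e-4
    sink_per_tp: float = 1.8e-4  # loading rate at the 40 ug/L reference level
    sink_tp_exponent: float = 1.5  # mild superlinearity of loading in P
    sink_per_chl: float = 4.0e-3
    export_gate_mid: float = 18.0  # ug/L, midpoint of the export gate e(P)
    export_gate_width: float = 3.0  # ug/L
    sink_per_warm_degree: float = 4.0e-4
    do_half_sat: float = 1.2  # mg/L, Monod oxygen limitation of the sink
    do_noise_sd: float = 0.02
    do_init: float = 9.5
    do_mix_source: float = 11.0  # mg/L, DO of the winter mixed layer
    # winter deep-mixing regime: logistic link on DJF air-temperature anomaly
    mix_logit_a: float = -0.4
    mix_logit_b: float = 1.0
    deep_mix_range: tuple[float, float] = (250.0, 310.0)
    shallow_mix_range: tuple[float, float] = (60.0, 180.0)
    winter_temp_ref: float = 2.5
    boundary_cap: float = 240.0  # m, top of the deep box for mixing renewal
    summer_thermocline: float = 17.5
    river_underflow: bool = True  # winter Rhone-style plunge into the deep box
    river_underflow_fraction: float = 0.3  # share of discharge reaching depth
    # observation noise, as a fraction of each variable's signal sd
    obs_noise_frac: float = 0.015
    hypsometry: Hypsometry = field(default_factory=synthetic_hypsometry)

    def validate(self):
        for name in (
            "t_atm_noise_sd", "q_noise_sd", "tp_noise_sd", "tp_surf_noise_sd",
            "chl_noise_sd", "do_noise_sd", "obs_noise_frac",
        ):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be >= 0")
        if self.span_years < 2:
            raise DataError("span_years must be >= 2")


# -- pure update maps (exact Jacobians differentiate these) -----------------


def growth_factor(t_surf: float, p: GeneratorParams) -> float:
    """Seasonal (temperature/light) growth multiplier f(T) in [0, 1]."""
    return float(np.clip((t_surf - 4.0) / 16.0, 0.0, 1.0))


def chl_capacity(tp_surf: float, p: GeneratorParams) -> float:
    """Phosphorus-set carrying capacity (saturating, so it is phosphorus-
    insensitive in the eutrophic state)."""
    return p.chl_capacity_max * tp_surf / (p.chl_capacity_half + tp_surf)


def chl_update(chl: float, tp_surf: float, t_surf: float, p: GeneratorParams) -> float:
    """Deterministic chlorophyll map: seasonally forced Ricker with MM uptake.

    Growth rate is phosphorus-limited (Michaelis-Menten) and the carrying
    capacity scales with phosphorus, so mean biomass declines under
    reoligotrophication.  The overcompensating density dependence makes summer
    blooms irregular (chaotic), which is what defeats global linear predictors
    while remaining predictable by local (state-dependent) ones.
    """
    g = p.chl_rmax * growth_factor(t_surf, p) * tp_surf / (p.chl_half_sat + tp_surf)
    kc = chl_capacity(tp_surf, p)
    return chl * np.exp(g * (1.0 - chl / kc) - p.chl_mort) + p.chl_immigration


def dchl_dtp(
    chl: float, tp_surf: float, t_surf: float, p: GeneratorParams
) -> float:
    """Analytic d CHL(t+1) / d TP_surf(t): vanishes at high phosphorus.

    Phosphorus acts through the growth exponent (sensitivity decaying like
    K/(K+P)^2) and through the carrying capacity; both channels weaken as
    phosphorus rises, so the chlorophyll response is essentially zero in the
    eutrophic state and grows under phosphorus limitation.
    """
    gf = growth_factor(t_surf, p)
    g = p.chl_rmax * gf * tp_surf / (p.chl_half_sat + tp_surf)
    dg_dp = p.chl_rmax * gf * p.chl_half_sat / (p.chl_half_sat + tp_surf) ** 2
    kc = chl_capacity(tp_surf, p)
    dkc_dp = (
        p.chl_capacity_max
        * p.chl_capacity_half
        / (p.chl_capacity_half + tp_surf) ** 2
    )
    core = chl * np.exp(g * (1.0 - chl / kc) - p.chl_mort)
    return core * (dg_dp * (1.0 - chl / kc) + g * chl / kc**2 * dkc_dp)


def export_gate(tp_lake: float, p: GeneratorParams) -> float:
    """Phosphorus-gated export fraction e(P) in (0, 1): ~0 when eutrophic."""
    return 1.0 / (1.0 + np.exp((tp_lake - p.export_gate_mid) / p.export_gate_width))


def sink_rate(
    chl: float, tp_lake: float, t_surf: float, do_b: float, p: GeneratorParams
) -> float:
    """Deep-oxygen depletion rate, mg/L/d, with Monod oxygen limitation.

    The chlorophyll-driven component is gated both by the phosphorus-dependent
    export fraction e(P) (food-web rearrangement under reoligotrophication)
    and by the seasonal production factor (organic export to depth follows the
    productive season).
    """
    monod = do_b / (do_b + p.do_half_sat)
    loading = p.sink_per_tp * 40.0 * (tp_lake / 40.0) ** p.sink_tp_exponent
    return monod * (
        p.sink_base
        + loading
        + p.sink_per_chl * export_gate(tp_lake, p) * growth_factor(t_surf, p) * chl
        + p.sink_per_warm_degree * max(t_surf - 18.0, 0.0)
    )


def do_update(
    do_b: float,
    chl: float,
    tp_lake: float,
    t_surf: float,
    p: GeneratorParams,
    mix_fraction: float = 0.0,
) -> float:
    """Deterministic deep-oxygen map: monthly sink, then partial winter renewal."""
    x = do_b - DAYS_PER_MONTH * sink_rate(chl, tp_lake, t_surf, do_b, p)
    if mix_fraction > 0:
        x = x + mix_fraction * (p.do_mix_source - x)
    return max(x, 0.0)


def ddo_dchl(
    tp_lake: float,
    p: GeneratorParams,
    mix_fraction: float = 0.0,
    do_b: float = 8.0,
    t_surf: float = 18.0,
) -> float:
    """Analytic d DO_B(t+1) / d CHL(t): negative only at low phosphorus."""
    monod = do_b / (do_b + p.do_half_sat)
    return (
        -(1.0 - mix_fraction)
        * DAYS_PER_MONTH
        * monod
        * p.sink_per_chl
        * export_gate(tp_lake, p)
        * growth_factor(t_surf, p)
    )


def mixing_probability(djf_anomaly: float, p: GeneratorParams) -> float:
    """Logistic probability of a deep-mixing winter vs DJF air anomaly."""
    return 1.0 / (1.0 + np.exp((djf_anomaly - p.mix_logit_a) / p.mix_logit_b))


def _winter_phase(month: int) -> float:
    """Monthly deepening profile of the mixed layer, peaking in February."""
    return {11: 0.25, 12: 0.5, 1: 0.75, 2: 1.0, 3: 0.6, 4: 0.2}.get(month, 0.0)


@dataclass
class LakeGroundTruth:
    """Noise-free state, analytic Jacobians, and mixing history."""

    clean: pd.DataFrame  # noise-free values of the eight variables
    jacobians: pd.DataFrame  # dchl_dtp, ddo_dchl, mix_fraction per month
    winter_depths: pd.Series  # max mixing depth per winter (keyed by year)
    deep_mix_years: list


def simulate_lake(
    params: GeneratorParams | None = None, seed: int | None = 1
) -> tuple[LakeTimeSeries, LakeGroundTruth]:
    """Simulate the eight-variable monthly lake series with known ground truth."""
    p = params or GeneratorParams()
    p.validate()
    rng = np.random.default_rng(seed)
    n = p.span_years * 12
    idx = pd.date_range(f"{p.start_year}-01-01", periods=n, freq="MS")
    month = idx.month.to_numpy()
    tfrac = np.arange(n) / max(n - 1, 1)

    # --- exogenous drivers -------------------------------------------------
    season = np.cos(2 * np.pi * (month - 1.5) / 12.0)  # -1 in mid summer
    anom = np.zeros(n)
    eps = rng.normal(0, p.t_atm_noise_sd, n)
    for t in range(1, n):
        anom[t] = p.t_atm_ar * anom[t - 1] + eps[t]
    t_atm = p.t_atm_mean - p.t_atm_amp * season + anom + p.t_atm_offset
    smoothed = np.convolve(t_atm, [0.5, 0.5], mode="full")[:n]
    t_surf = np.maximum(
        p.t_surf_min, p.t_surf_min + p.t_surf_response * (smoothed - 2.0)
    )
    q = (
        p.q_mean
        + p.q_seasonal_amp * np.cos(2 * np.pi * (month - 6) / 12.0)
        + rng.normal(0, p.q_noise_sd, n)
    )
    q = np.maximum(q, 10.0)

    tp_lake = p.tp_start + (p.tp_end - p.tp_start) * tfrac
    tp_noise = np.zeros(n)
    eps = rng.normal(0, p.tp_noise_sd, n)
    for t in range(1, n):
        tp_noise[t] = 0.7 * tp_noise[t - 1] + eps[t]
    tp_lake = np.maximum(tp_lake + tp_noise, 1.0)

    bloom = np.maximum(0.0, np.sin(np.pi * (month - 4) / 6.0))
    tp_surf = np.maximum(
        tp_lake * (1.0 - p.tp_surf_drawdown * bloom)
        + rng.normal(0, p.tp_surf_noise_sd, n),
        0.5,
    )

    # --- winter mixing regime ---------------------------------------------
    winter_key = idx.year.to_numpy() + (month >= 11).astype(int)
    hyp = p.hypsometry
    v_deep_total = hyp.volume_between(p.boundary_cap, hyp.z_max)
    winter_depths, deep_years = {}, []
    for wk in np.unique(winter_key):
        sel = ((month == 12) | (month <= 2)) & (winter_key == wk)
        if not sel.any():
            continue
        djf_anom = t_atm[sel].mean() - p.winter_temp_ref
        prob = mixing_probability(djf_anom, p)
        u = rng.uniform()
        deep_draw = rng.uniform(*p.deep_mix_range)
        shallow_draw = rng.uniform(*p.shallow_mix_range)
        if u < prob:
            winter_depths[wk] = deep_draw
            deep_years.append(int(wk))
        else:
            winter_depths[wk] = shallow_draw

    h_mix = np.full(n, p.summer_thermocline)
    for t in range(n):
        ph = _winter_phase(int(month[t]))
        if ph > 0 and winter_key[t] in winter_depths:
            target = winter_depths[winter_key[t]]
            h_mix[t] = p.summer_thermocline + ph * (target - p.summer_thermocline)

    mix_fraction = np.zeros(n)
    for t in range(n):
        if month[t] == 2 and winter_key[t] in winter_depths:
            d = winter_depths[winter_key[t]]
            if d > p.boundary_cap:
                mix_fraction[t] = hyp.volume_between(p.boundary_cap, d) / v_deep_total

    # --- endogenous biology/oxygen ----------------------------------------
    # winter river underflow: replacement fraction of the deep box per month,
    # with river water saturated at river temperature (mirrors the box physics)
    from .physics import do_saturation

    t_river = np.maximum(1.0, 0.6 * t_atm + 3.0)
    c_river = do_saturation(t_river, 0.956)
    in_winter_month = (month >= 11) | (month <= 4)
    river_frac = np.where(
        in_winter_month & p.river_underflow,
        np.minimum(
            1.0,
            p.river_underflow_fraction * q * 86_400.0 * DAYS_PER_MONTH / v_deep_total,
        ),
        0.0,
    )

    chl = np.empty(n)
    do_b = np.empty(n)
    chl[0] = 6.0
    do_b[0] = p.do_init
    jac_c = np.full(n, np.nan)
    jac_d = np.full(n, np.nan)
    for t in range(n - 1):
        jac_c[t] = dchl_dtp(chl[t], tp_surf[t], t_surf[t], p)
        jac_d[t] = ddo_dchl(
            tp_lake[t], p, mix_fraction[t + 1], do_b[t], t_surf[t]
        ) * (1.0 - river_frac[t + 1])
        chl[t + 1] = max(
            chl_update(chl[t], tp_surf[t], t_surf[t], p)
            + rng.normal(0, p.chl_noise_sd),
            0.05,
        )
        x = do_update(
            do_b[t], chl[t], tp_lake[t], t_surf[t], p, mix_fraction[t + 1]
        )
        x = x + river_frac[t + 1] * (c_river[t + 1] - x)
        do_b[t + 1] = max(x + rng.normal(0, p.do_noise_sd), 0.0)

    clean = pd.DataFrame(
        {
            "DO_B": do_b,
            "chl": chl,
            "TP_surf": tp_surf,
            "TP_lake": tp_lake,
            "h_mix": h_mix,
            "T_surf": t_surf,
            "T_atm": t_atm,
            "Q": q,
        },
        index=idx,
    )

    observed = clean.copy()
    if p.obs_noise_frac > 0:
        for col in observed.columns:
            sd = observed[col].std()
            observed[col] = observed[col] + rng.normal(
                0, p.obs_noise_frac * sd, n
            )
        for col in ("DO_B", "chl", "TP_surf", "TP_lake", "Q"):
            observed[col] = observed[col].clip(lower=0.0)
        observed["h_mix"] = observed["h_mix"].clip(1.0, hyp.z_max)

    jac = pd.DataFrame(
        {"dchl_dtp": jac_c, "ddo_dchl": jac_d, "mix_fraction": mix_fraction},
        index=idx,
    )
    truth = LakeGroundTruth(
        clean,
        jac,
        pd.Series(winter_depths).sort_index(),
        deep_years,
    )
    return LakeTimeSeries(observed), truth


def forcing_from_lake(truth: LakeGroundTruth, z_max: float = 310.0):
    """Daily ForcingSeries consistent with a simulated lake's physical truth.

    Monthly noise-free physical drivers are linearly interpolated to a daily
    grid; the daily mixing depth follows the interpolated mixed-layer depth,
    so its winter maximum equals the generator's drawn winter mixing depth.
    This is the synthetic stand-in for an external hydrodynamic model's output
    when exercising the hybrid pipeline end to end.
    """
    from .physics import ForcingSeries

    clean = truth.clean
    daily = pd.date_range(clean.index[0], clean.index[-1], freq="D")
    t_m = clean.index.view("int64") / 86_400e9
    t_d = daily.view("int64") / 86_400e9

    def interp(col):
        return np.interp(t_d, t_m, clean[col].to_numpy(float))

    df = pd.DataFrame(
        {
            "thermocline_depth_m": np.clip(interp("h_mix"), 1.0, z_max),
            "T_surf_C": interp("T_surf"),
            "mixing_depth_m": np.clip(interp("h_mix"), 1.0, z_max),
            "Q_m3s": interp("Q"),
            "T_river_C": np.maximum(1.0, interp("T_atm") * 0.6 + 3.0),
            "T_atm_C": interp("T_atm"),
        },
        index=daily,
    )
    return ForcingSeries(df, z_max)


# ---------------------------------------------------------------------------
# Canonical benchmark systems
# ---------------------------------------------------------------------------


def simulate_coupled_logistic(
    r_x: float = 3.7,
    r_y: float = 3.8,
    b_xy: float = 0.0,
    b_yx: float = 0.32,
    n: int = 1000,
    seed: int | None = 0,
    transient: int = 100,
) -> pd.DataFrame:
    """Coupled logistic maps: x(t+1) = x [r_x (1-x) - b_xy y], analogously y.

    ``b_yx`` is the strength with which x forces y (appears in y's equation);
    with ``b_yx > 0 = b_xy`` the ground truth is the single causal edge
    x -> y.  Deterministic given seed (which only sets initial conditions).
    """
    if not (3.5 < r_x < 4.0 and 3.5 < r_y < 4.0):
        raise DataError("r parameters must lie in (3.5, 4.0)")
    if b_xy < 0 or b_yx < 0:
        raise DataError("couplings must be >= 0")
    if n < 100:
        raise DataError("n must be >= 100")
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.2, 0.6)
    y = rng.uniform(0.2, 0.6)
    xs = np.empty(n + transient)
    ys = np.empty(n + transient)
    for t in range(n + transient):
        x, y = (
            x * (r_x * (1.0 - x) - b_xy * y),
            y * (r_y * (1.0 - y) - b_yx * x),
        )
        x = min(max(x, 1e-9), 1.0)
        y = min(max(y, 1e-9), 1.0)
        xs[t], ys[t] = x, y
    return pd.DataFrame({"x": xs[transient:], "y": ys[transient:]})


def simulate_mar(
    coeff: np.ndarray,
    noise_sd: float = 1.0,
    n: int = 400,
    seed: int | None = 0,
    transient: int = 50,
) -> pd.DataFrame:
    """Stationary Gaussian MAR(1) realization: x(t+1) = A x(t) + eps.

    The linear-stochastic null for the nonlinearity (theta-scan) test:
    state-dependence is absent by construction.
    """
    A = np.asarray(coeff, float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise DataError("coefficient matrix must be square")
    radius = max(abs(np.linalg.eigvals(A)))
    if radius >= 1.0:
        raise DataError(f"spectral radius {radius:.3f} >= 1: MAR(1) not stationary")
    rng = np.random.default_rng(seed)
    k = A.shape[0]
    x = np.zeros(k)
    out = np.empty((n + transient, k))
    for t in range(n + transient):
        x = A @ x + rng.normal(0, noise_sd, k)
        out[t] = x
    return pd.DataFrame(out[transient:], columns=[f"x{i}" for i in range(k)])
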