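"""Two-box lake oxygen/volume bookkeeping and physical forcing.

The lake is split into a surface and a deep box at a time-varying boundary
(the thermocline, or a capped winter boundary).  Winter dynamics are mixing
events that homogenize the water column down to a daily mixing depth,
air-water gas exchange that relaxes surface oxygen toward temperature-
dependent saturation, and a river underflow that plunges oxygen-rich water
into the deep box.  Summer surface oxygen follows a linear
saturation-relaxation plus chlorophyll-proportional net production law,
integrated exactly (exponential integrator) over each step.

The hydrodynamic forcing (thermocline depth, winter mixing depth, surface
temperature, river discharge/temperature) is either read from an external
model's tabular output (:func:`read_forcing`) or produced by the built-in
stochastic surrogate (:func:`surrogate_physics`), which generates a seasonal
thermocline cycle and winter deep-mixing events whose probability falls with
winter air-temperature anomaly through a logistic link.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ForcingError

logger = logging.getLogger(__name__)

SECONDS_PER_DAY = 86_400.0

FORCING_COLUMNS = (
    "thermocline_depth_m",
    "T_surf_C",
    "mixing_depth_m",
    "Q_m3s",
    "T_river_C",
    "T_atm_C",
)


# ---------------------------------------------------------------------------
# Oxygen solubility
# ---------------------------------------------------------------------------


def do_saturation(t_c, pressure_atm: float = 1.0):
    """Freshwater dissolved-oxygen saturation (mg/L) vs temperature.

    Benson-Krause solubility relation (as used in standard water-quality
    practice), scaled linearly by ambient pressure in atmospheres to account
    for lake altitude.
    """
    t_k = np.asarray(t_c, float) + 273.15
    ln_c = (
        -139.34411
        + 1.575701e5 / t_k
        - 6.642308e7 / t_k**2
        + 1.2438e10 / t_k**3
        - 8.621949e11 / t_k**4
    )
    return np.exp(ln_c) * pressure_atm


# ---------------------------------------------------------------------------
# Hypsometry and box geometry
# ---------------------------------------------------------------------------


@dataclass
class Hypsometry:
    """Depth-area curve of the basin; volumes by trapezoidal integration."""

    depths: np.ndarray  # m, 0 (surface) .. z_max, strictly increasing
    areas: np.ndarray  # m^2, strictly positive, nonincreasing with depth

    def __post_init__(self):
        self.depths = np.asarray(self.depths, float)
        self.areas = np.asarray(self.areas, float)
        if self.depths.ndim != 1 or self.depths.shape != self.areas.shape:
            raise ForcingError("depth and area grids must be 1-D and equal length")
        if not np.all(np.diff(self.depths) > 0):
            raise ForcingError("depth grid must be strictly increasing")
        if np.any(self.areas <= 0):
            raise ForcingError("areas must be strictly positive")
        if np.any(np.diff(self.areas) > 0):
            raise ForcingError("area must be nonincreasing with depth")

    @property
    def z_max(self) -> float:
        return float(self.depths[-1])

    @property
    def surface_area(self) -> float:
        return float(self.areas[0])

    def area_at(self, depth) -> np.ndarray:
        return np.interp(depth, self.depths, self.areas)

    def volume_between(self, z1: float, z2: float) -> float:
        """Water volume between two depths (trapezoid on the area curve)."""
        if z2 < z1:
            z1, z2 = z2, z1
        z1 = max(z1, 0.0)
        z2 = min(z2, self.z_max)
        if z2 <= z1:
            return 0.0
        zs = self.depths[(self.depths > z1) & (self.depths < z2)]
        grid = np.concatenate(([z1], zs, [z2]))
        return float(np.trapezoid(self.area_at(grid), grid))

    @property
    def total_volume(self) -> float:
        return self.volume_between(0.0, self.z_max)


def box_volumes(h: Hypsometry, thermocline_depth: float) -> tuple[float, float]:
    """Upper/lower box volumes for a boundary at the thermocline depth."""
    if not (0 < thermocline_depth <= h.z_max):
        raise ForcingError(
            f"thermocline depth {thermocline_depth} outside (0, {h.z_max}]"
        )
    v_up = h.volume_between(0.0, thermocline_depth)
    return v_up, h.total_volume - v_up


@dataclass
class BoxState:
    """Two-box oxygen state: concentrations, volumes, boundary depth."""

    do_up: float  # mg/L
    do_low: float  # mg/L
    v_up: float  # m^3
    v_low: float  # m^3
    boundary_depth: float  # m
    date: pd.Timestamp | None = None

    @property
    def total_mass(self) -> float:
        """Total O2 mass in g (mg/L == g/m^3)."""
        return self.do_up * self.v_up + self.do_low * self.v_low

    @property
    def volume_mean_do(self) -> float:
        return self.total_mass / (self.v_up + self.v_low)


def make_box_state(
    h: Hypsometry, boundary_depth: float, do_up: float, do_low: float, date=None
) -> BoxState:
    v_up, v_low = box_volumes(h, boundary_depth)
    return BoxState(do_up, do_low, v_up, v_low, boundary_depth, date)


def repartition(state: BoxState, h: Hypsometry, new_depth: float) -> BoxState:
    """Move the box boundary, conserving oxygen mass.

    Deepening entrains former deep water into the surface box (volume-weighted
    mixing); shoaling detrains surface water into the deep box.
    """
    if abs(new_depth - state.boundary_depth) < 1e-12:
        return replace(state, boundary_depth=new_depth)
    v_up_new, v_low_new = box_volumes(h, new_depth)
    if new_depth > state.boundary_depth:
        dv = v_up_new - state.v_up
        do_up = (state.do_up * state.v_up + state.do_low * dv) / v_up_new
        do_low = state.do_low if v_low_new > 0 else 0.0
    else:
        dv = v_low_new - state.v_low
        do_low = (state.do_low * state.v_low + state.do_up * dv) / v_low_new
        do_up = state.do_up
    return BoxState(do_up, do_low, v_up_new, v_low_new, new_depth, state.date)


# ---------------------------------------------------------------------------
# Physics parameters and process steps
# ---------------------------------------------------------------------------


@dataclass
class PhysicsParams:
    """Tunable coefficients of the box-oxygen processes.

    k_gas : air-water gas-exchange (piston) velocity, m/d.
    pressure_atm : ambient pressure for saturation (altitude correction).
    chl_production : net surface production per unit chlorophyll,
        (mg O2 / L / d) per (ug chl / L).  The summer surface-oxygen law is a
        configurable plug-in; this linear default can be swapped via
        ``surface_production_fn(chl, t_surf) -> mg O2/L/d``.
    river_underflow : if True, winter river water (saturated at river
        temperature) plunges into the deep box; in summer the river enters the
        surface box.
    """

    k_gas: float = 1.0
    pressure_atm: float = 0.956  # ~372 m altitude
    chl_production: float = 0.01
    river_underflow: bool = True
    river_underflow_fraction: float = 0.3  # share of discharge plunging to depth
    deep_consumption: float = 0.004  # mg O2/L/d, winter deep-box respiration
    surface_production_fn: object = None

    def production(self, chl: float, t_surf: float) -> float:
        if self.surface_production_fn is not None:
            return float(self.surface_production_fn(chl, t_surf))
        return self.chl_production * chl


def _clip_do(value: float, where: str) -> float:
    if value < 0:
        logger.warning("negative DO after %s; flooring at 0", where)
        return 0.0
    return value


def _gas_exchange(do_up, t_surf, v_up, area, params, dt):
    """Exact exponential relaxation of surface DO toward saturation."""
    if params.k_gas <= 0 or v_up <= 0:
        return do_up
    sat = float(do_saturation(t_surf, params.pressure_atm))
    kappa = params.k_gas * area / v_up  # 1/d
    return sat + (do_up - sat) * np.exp(-kappa * dt)


def _river_exchange(do, volume, q_m3s, t_river, params, dt):
    """Replacement flux: river water saturated at river temperature."""
    if q_m3s is None or q_m3s <= 0 or volume <= 0:
        return do
    frac = min(1.0, q_m3s * SECONDS_PER_DAY * dt / volume)
    c_river = float(do_saturation(t_river, params.pressure_atm))
    return do + frac * (c_river - do)


def winter_mix_step(
    state: BoxState,
    h: Hypsometry,
    mixing_depth: float,
    t_surf: float,
    dt: float = 1.0,
    params: PhysicsParams | None = None,
    q_m3s: float | None = None,
    t_river: float | None = None,
) -> BoxState:
    """One winter step: homogenization, gas exchange, river underflow.

    The column above ``mixing_depth`` is homogenized: if the mixing depth
    reaches below the box boundary, the mixed fraction of the deep box is
    volume-weighted into the mixed layer (full-depth mixing equalizes both
    boxes and conserves total oxygen mass exactly).  Surface DO then relaxes
    toward saturation, and the river underflow (winter pathway) injects
    oxygen-saturated water into the deep box.
    """
    params = params or PhysicsParams()
    if not (0 < mixing_depth <= h.z_max):
        raise ForcingError(f"mixing depth {mixing_depth} outside (0, {h.z_max}]")
    do_up, do_low = state.do_up, state.do_low
    if params.deep_consumption > 0:
        do_low = max(do_low - params.deep_consumption * dt, 0.0)
    if mixing_depth > state.boundary_depth:
        v_mix = h.volume_between(state.boundary_depth, mixing_depth)
        v_mix = min(v_mix, state.v_low)
        mixed = (do_up * state.v_up + do_low * v_mix) / (state.v_up + v_mix)
        do_up = mixed
        if state.v_low > 0:
            do_low = (do_low * (state.v_low - v_mix) + mixed * v_mix) / state.v_low
    do_up = _gas_exchange(do_up, t_surf, state.v_up, h.surface_area, params, dt)
    if params.river_underflow and q_m3s is not None and t_river is not None:
        do_low = _river_exchange(
            do_low,
            state.v_low,
            q_m3s * params.river_underflow_fraction,
            t_river,
            params,
            dt,
        )
    do_up = _clip_do(do_up, "winter_mix_step")
    do_low = _clip_do(do_low, "winter_mix_step")
    return replace(state, do_up=do_up, do_low=do_low)


def surface_do_update(
    state: BoxState,
    h: Hypsometry,
    chl: float,
    t_surf: float,
    dt: float = 1.0,
    params: PhysicsParams | None = None,
    q_m3s: float | None = None,
    t_river: float | None = None,
) -> BoxState:
    """One summer step of surface-box oxygen.

    Default plug-in: dC/dt = kappa (C_sat - C) + p * CHL with
    kappa = k_gas * A / V_up, solved exactly over the step (linear ODE with
    constant coefficients).  At chl = 0 and C = C_sat the state is a fixed
    point.  In summer the river enters the surface box.  The production term
    is a configurable plug-in (see :class:`PhysicsParams`).
    """
    params = params or PhysicsParams()
    sat = float(do_saturation(t_surf, params.pressure_atm))
    prod = params.production(chl, t_surf)  # mg O2 / L / d
    kappa = params.k_gas * h.surface_area / state.v_up  # 1/d
    if kappa > 0:
        c_eq = sat + prod / kappa
        do_up = c_eq + (state.do_up - c_eq) * np.exp(-kappa * dt)
    else:
        do_up = state.do_up + prod * dt
    if q_m3s is not None and t_river is not None:
        do_up = _river_exchange(do_up, state.v_up, q_m3s, t_river, params, dt)
    do_up = _clip_do(do_up, "surface_do_update")
    return replace(state, do_up=do_up)


# ---------------------------------------------------------------------------
# Forcing series: container, file I/O, and the built-in surrogate
# ---------------------------------------------------------------------------


@dataclass
class ForcingSeries:
    """Daily physical drivers of the box model.

    Columns: thermocline depth (m), surface temperature (degC), mixing depth
    (m; the depth to which the column is homogenized that day — per winter its
    running maximum is the deepest homogenized depth), river discharge (m3/s),
    river temperature (degC), air temperature (degC).
    """

    data: pd.DataFrame
    z_max: float = 310.0

    def __post_init__(self):
        missing = [c for c in FORCING_COLUMNS if c not in self.data.columns]
        if missing:
            raise ForcingError(f"forcing is missing required columns: {missing}")
        if not isinstance(self.data.index, pd.DatetimeIndex):
            self.data = self.data.copy()
            self.data.index = pd.DatetimeIndex(self.data.index)
        if not self.data.index.is_monotonic_increasing or self.data.index.has_duplicates:
            raise ForcingError("forcing dates must be strictly increasing")
        for col in ("thermocline_depth_m", "mixing_depth_m"):
            v = self.data[col].to_numpy(float)
            ok = np.isnan(v) | ((v > 0) & (v <= self.z_max))
            if not ok.all():
                raise ForcingError(f"{col} must lie in (0, {self.z_max}]")

    @property
    def time(self) -> pd.DatetimeIndex:
        return self.data.index

    def slice(self, start, end) -> "ForcingSeries":
        return ForcingSeries(self.data.loc[start:end], self.z_max)

    def winter_max_mixing_depth(self) -> pd.Series:
        """Deepest homogenized depth per winter (Nov-Apr), keyed by the year
        the winter ends (i.e. the following summer's year)."""
        d = self.data["mixing_depth_m"]
        month = d.index.month
        winter = (month >= 11) | (month <= 4)
        key = d.index.year + (month >= 11).astype(int)
        return d[winter].groupby(key[winter]).max()


def read_forcing(path, dialect: dict | None = None, on_gap: str = "error") -> ForcingSeries:
    """Read daily forcing from CSV, with optional column renaming.

    ``dialect`` maps file column names to the canonical names.  A missing
    calendar day raises unless ``on_gap='ffill'``, in which case the previous
    day's values are carried forward.
    """
    df = pd.read_csv(path)
    if dialect:
        df = df.rename(columns=dialect)
    date_col = "date" if "date" in df.columns else df.columns[0]
    df = df.set_index(pd.DatetimeIndex(pd.to_datetime(df[date_col]))).drop(
        columns=[date_col]
    )
    df = df.sort_index()
    full = pd.date_range(df.index[0], df.index[-1], freq="D")
    if len(full) != len(df.index):
        if on_gap == "ffill":
            df = df.reindex(full).ffill()
        else:
            raise ForcingError(
                "forcing has missing calendar days (pass on_gap='ffill' to fill)"
            )
    return ForcingSeries(df)


def write_forcing(forcing: ForcingSeries, path) -> None:
    out = forcing.data.copy()
    out.index.name = "date"
    out.to_csv(path, date_format="%Y-%m-%d")


@dataclass
class SurrogatePhysicsParams:
    """Parameters of the built-in stochastic physics surrogate.

    The surrogate stands in for an external hydrodynamic model: a seasonal
    thermocline cycle (shallow in summer, deepening through winter toward that
    winter's maximal mixing depth), winter deep-mixing events whose
    probability decreases with the winter air-temperature anomaly via a
    logistic link, and seasonal river discharge/temperature.
    """

    summer_thermocline: float = 17.5  # m
    z_max: float = 310.0
    # logistic link for P(deep mixing): p = 1 / (1 + exp((anom - a) / b))
    mix_logit_a: float = -0.4  # degC anomaly at which p = 0.5
    mix_logit_b: float = 1.0  # degC scale
    deep_mix_range: tuple[float, float] = (250.0, 310.0)
    shallow_mix_range: tuple[float, float] = (60.0, 180.0)
    winter_temp_ref: float = 2.5  # degC, reference DJF mean air temperature
    t_surf_min: float = 5.0  # degC
    t_surf_response: float = 0.85  # degC surface per degC smoothed air
    q_mean: float = 180.0  # m3/s
    q_seasonal_amp: float = 110.0
    q_noise_sd: float = 20.0
    t_river_mean: float = 8.5
    t_river_amp: float = 5.5
    seasonal_amplitude: float = 1.0  # scales the thermocline seasonal cycle


def surrogate_physics(
    t_atm: pd.Series,
    params: SurrogatePhysicsParams | None = None,
    seed: int | None = 0,
) -> ForcingSeries:
    """Generate a daily ForcingSeries from daily air temperature.

    Deterministic given the seed; the per-winter random draws are consumed in
    a fixed order regardless of outcomes, so two runs differing only in a
    uniform air-temperature offset share their underlying random stream (and a
    warmer stream can only lose deep-mixing winters, never gain them).
    """
    p = params or SurrogatePhysicsParams()
    rng = np.random.default_rng(seed)
    t_atm = t_atm.astype(float)
    idx = t_atm.index
    if not isinstance(idx, pd.DatetimeIndex):
        raise ForcingError("t_atm must have a DatetimeIndex (daily)")
    n = len(idx)
    month = idx.month.to_numpy()
    doy = idx.dayofyear.to_numpy()

    # winter keys: Nov..Apr belongs to the winter ending in the later year
    winter_key = idx.year.to_numpy() + (month >= 11).astype(int)
    in_winter = (month >= 11) | (month <= 4)
    djf = (month == 12) | (month <= 2)

    winters = np.unique(winter_key[in_winter])
    max_depth = {}
    for wk in winters:
        sel = djf & (winter_key == wk)
        anom = (t_atm.to_numpy()[sel].mean() - p.winter_temp_ref) if sel.any() else 0.0
        prob_deep = 1.0 / (1.0 + np.exp((anom - p.mix_logit_a) / p.mix_logit_b))
        # fixed draw order keeps the stream aligned across scenarios
        u = rng.uniform()
        deep_draw = rng.uniform(*p.deep_mix_range)
        shallow_draw = rng.uniform(*p.shallow_mix_range)
        max_depth[wk] = deep_draw if u < prob_deep else shallow_draw

    thermo = np.full(n, p.summer_thermocline)
    mixing = np.full(n, p.summer_thermocline)
    # winter ramp: deepen from Nov 1 to a mid-February maximum, restratify by May 1
    for i in range(n):
        if not in_winter[i]:
            continue
        wk = winter_key[i]
        target = p.summer_thermocline + p.seasonal_amplitude * (
            max_depth[wk] - p.summer_thermocline
        )
        # phase within the winter: Nov 1 (0) .. Feb 15 (1) .. Apr 30 (back to 0)
        if month[i] >= 11:
            phase = (doy[i] - 305) / (365 - 305 + 46)  # Nov 1 .. Feb 15
        elif doy[i] <= 46:
            phase = (doy[i] + 60) / 106.0
        else:
            phase = max(0.0, 1.0 - (doy[i] - 46) / (120 - 46))
        phase = min(max(phase, 0.0), 1.0)
        depth = p.summer_thermocline + phase * (target - p.summer_thermocline)
        thermo[i] = depth
        mixing[i] = depth
    # surface temperature: smoothed air temperature response with a floor
    smoothed = t_atm.rolling(30, min_periods=1).mean().to_numpy()
    t_surf = np.maximum(p.t_surf_min, p.t_surf_min + p.t_surf_response * (smoothed - 2.0))
    q = (
        p.q_mean
        + p.q_seasonal_amp * np.cos(2 * np.pi * (doy - 170) / 365.25)
        + rng.normal(0, p.q_noise_sd, n)
    )
    q = np.maximum(q, 10.0)
    t_river = np.maximum(
        1.0, p.t_river_mean + p.t_river_amp * np.cos(2 * np.pi * (doy - 200) / 365.25)
    )
    df = pd.DataFrame(
        {
            "thermocline_depth_m": np.clip(thermo, 1.0, p.z_max),
            "T_surf_C": t_surf,
            "mixing_depth_m": np.clip(mixing, 1.0, p.z_max),
            "Q_m3s": q,
            "T_river_C": t_river,
            "T_atm_C": t_atm.to_numpy(),
        },
        index=idx,
    )
    return ForcingSeries(df, p.z_max)
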