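"""Seasonal coupling of parametric physics and empirical S-map predictors.

Deep-water oxygen in a monomictic lake is governed by two processes that
separate cleanly in time: winter mixing *sources* oxygen to depth (well
captured by box physics driven by a hydrodynamic model), while summer
biogeochemistry *sinks* it (poorly captured by fixed parameterizations, well
captured by state-dependent S-map regression).  The hybrid model alternates
between the two: each winter (November-April) the two-box physics evolves the
state daily — mixing-depth homogenization, gas exchange, river underflow —
and each summer (May-October) the S-map predictors iterate monthly, predicting
chlorophyll and surface phosphorus internally and advancing deep oxygen with
them.  The deep-oxygen value at the end of October is fed back to the physics
as the deep box's initial condition; a single initialization then propagates
over decades.

Predictors are trained once on a historical window, with normalization
statistics and libraries frozen, and never re-anchored to observations during
a run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .edm import (
    DEFAULT_THETA_GRID,
    EmbeddingSpec,
    build_state_matrix,
    smap_forecast,
    theta_scan,
)
from .errors import DataError
from .physics import (
    ForcingSeries,
    Hypsometry,
    PhysicsParams,
    do_saturation,
    make_box_state,
    surface_do_update,
    winter_mix_step,
)
from .timeseries import LakeTimeSeries

logger = logging.getLogger(__name__)

SUMMER_MONTHS = (5, 6, 7, 8, 9, 10)  # May .. October
DAYS_PER_MONTH = 30.44


@dataclass
class PredictorConfig:
    """One S-map predictor: embedding variables (lag 0) and nonlinearity."""

    target: str
    variables: tuple[str, ...]
    theta: float | str = "auto"  # 'auto': tuned by leave-one-out theta scan
    tp: int = 1


def default_predictors() -> dict[str, PredictorConfig]:
    """Mechanistic embeddings for the three internally predicted variables."""
    return {
        "DO_B": PredictorConfig(
            "DO_B", ("DO_B", "chl", "TP_surf", "TP_lake", "h_mix", "T_surf")
        ),
        "chl": PredictorConfig("chl", ("chl", "TP_surf", "T_surf", "TP_lake")),
        "TP_surf": PredictorConfig("TP_surf", ("TP_surf", "TP_lake", "T_surf")),
    }


@dataclass
class HybridConfig:
    """Configuration of the hybrid run.

    ``feedback_month`` is the month whose end-of-month deep oxygen is handed
    back to the physics (end of October).  ``training_end`` caps the training
    library so that predictors never see data past the simulation start
    (leakage guard).  ``extrapolation_radius`` is the z-space distance beyond
    which a query state is flagged as outside the training attractor.
    """

    predictors: dict[str, PredictorConfig] = field(default_factory=default_predictors)
    theta_grid: tuple = DEFAULT_THETA_GRID
    feedback_month: int = 10
    winter_boundary: float = 240.0  # m, deep-box top during winter physics
    summer_thermocline: float = 17.5  # m, surface-box boundary in summer
    intermediate_do: float = 9.0  # mg/L assumed for unmodelled mid-depths
    training_end: pd.Timestamp | None = None
    extrapolation_radius: float = 6.0
    physics: PhysicsParams = field(default_factory=PhysicsParams)


class SMapPredictor:
    """A frozen S-map forecaster for one variable (one-step, monthly)."""

    def __init__(self, config: PredictorConfig, training: pd.DataFrame, theta_grid):
        self.config = config
        spec = EmbeddingSpec(
            tuple((v, 0) for v in config.variables), config.target, config.tp
        )
        self.sm = build_state_matrix(training, spec)
        y = training[config.target].to_numpy(float)
        if config.theta == "auto":
            scan = theta_scan(self.sm, y, theta_grid, tp=config.tp)
            self.theta = scan.best_theta
        else:
            self.theta = float(config.theta)
        self.spec = spec
        self._y = y
        lib = np.flatnonzero(self.sm.valid & np.isfinite(self._shift(y, config.tp)))
        self._lib = lib
        self._X = np.column_stack([self.sm.values[lib], np.ones(lib.size)])
        self._ylib = self._shift(y, config.tp)[lib]

    @staticmethod
    def _shift(x, tp):
        n = len(x)
        out = np.full(n, np.nan)
        if tp > 0:
            out[: n - tp] = x[tp:]
        elif tp < 0:
            out[-tp:] = x[:tp]
        else:
            out = x.copy()
        return out

    def predict(self, state: dict) -> tuple[float, bool]:
        """One-step forecast from a raw state dict; returns (value, extrapolating).

        Query coordinates are clamped to the training range: local linear
        fits are unreliable outside the attractor sampled by the library, so
        states beyond it are evaluated at the nearest observed regime (and
        flagged via the extrapolation radius check, which uses the unclamped
        state).
        """
        raw = np.array([state[v] for v, _ in self.spec.coordinates], float)
        lo = self.sm.raw[self._lib].min(axis=0)
        hi = self.sm.raw[self._lib].max(axis=0)
        z_unclamped = self.sm.normalize_row(raw)
        raw = np.clip(raw, lo, hi)
        z = self.sm.normalize_row(raw)
        d = np.sqrt(((self.sm.values[self._lib] - z) ** 2).sum(axis=1))
        dbar = d.mean()
        if dbar == 0:
            raise DataError("degenerate library (all points coincide)")
        w = np.exp(-self.theta * d / dbar)
        sw = np.sqrt(w)
        c, *_ = np.linalg.lstsq(self._X * sw[:, None], self._ylib * sw, rcond=None)
        pred = float(np.dot(z, c[:-1]) + c[-1])
        # extrapolation flag: z-space distance from the library centroid
        centroid = self.sm.values[self._lib].mean(axis=0)
        extrapolating = bool(np.linalg.norm(z_unclamped - centroid) > self._radius)
        return pred, extrapolating

    _radius: float = 6.0


class HybridModel:
    """Fitted hybrid model: frozen S-map predictors + box physics."""

    def __init__(self, config: HybridConfig | None = None):
        self.config = config or HybridConfig()
        self.predictors: dict[str, SMapPredictor] = {}
        self.training: pd.DataFrame | None = None

    # -- training ----------------------------------------------------------

    def fit(self, ts: LakeTimeSeries) -> "HybridModel":
        """Train the S-map predictors on a (regularized monthly) archive."""
        df = ts.data if isinstance(ts, LakeTimeSeries) else pd.DataFrame(ts)
        if self.config.training_end is not None:
            df = df.loc[: self.config.training_end]
        self.training = df
        for name, pc in self.config.predictors.items():
            pred = SMapPredictor(pc, df, self.config.theta_grid)
            pred._radius = self.config.extrapolation_radius
            self.predictors[name] = pred
            logger.info("predictor %s: theta=%s", name, pred.theta)
        return self

    def with_theta(self, theta: float) -> "HybridModel":
        """A refit copy with every predictor forced to a fixed theta
        (theta=0 gives the fully linear, fixed-coefficient ablation)."""
        cfg = replace(
            self.config,
            predictors={
                k: replace(pc, theta=theta) for k, pc in self.config.predictors.items()
            },
        )
        other = HybridModel(cfg)
        other.fit(LakeTimeSeries(self.training.copy()))
        return other

    def _climatology(self, month: int, tp_lake: float, var: str, bw: float = 5.0):
        """Training-mean of `var` in a given month, kernel-weighted toward
        states with a similar whole-lake phosphorus level."""
        df = self.training
        sel = df.index.month == month
        sub = df.loc[sel, [var, "TP_lake"]].dropna()
        w = np.exp(-0.5 * ((sub["TP_lake"] - tp_lake) / bw) ** 2) + 1e-12
        return float(np.average(sub[var], weights=w))

    # -- summer phase ------------------------------------------------------

    def summer_depletion(
        self,
        do_b_init: float,
        tp_lake,
        forcing: ForcingSeries,
        year: int,
        chl_init: float | None = None,
        tp_surf_init: float | None = None,
        t_atm_offset: float = 0.0,
    ) -> tuple[pd.Series, float, list[str]]:
        """Iterate the S-map predictors monthly over one stratified season.

        Starting from deep oxygen at the onset of May, chlorophyll and surface
        phosphorus are predicted by their own S-maps while the physical
        coordinates come from the forcing; returns the six end-of-month deep
        oxygen values (May-Oct), the seasonally averaged depletion rate in
        mg/L/d over the 180-day window, and any extrapolation warnings.
        """
        if do_b_init <= 0:
            raise DataError("do_b_init must be > 0")
        tp_vec = (
            np.full(7, float(tp_lake))
            if np.isscalar(tp_lake)
            else np.asarray(tp_lake, float)
        )
        monthly = forcing.data.resample("MS").mean()
        chl = (
            chl_init
            if chl_init is not None
            else self._climatology(5, tp_vec[0], "chl")
        )
        tp_surf = (
            tp_surf_init
            if tp_surf_init is not None
            else self._climatology(5, tp_vec[0], "TP_surf")
        )
        do_b = float(do_b_init)
        out, warnings_ = [], []
        for i, month in enumerate(SUMMER_MONTHS):
            t = pd.Timestamp(year=year, month=month, day=1)
            try:
                row = monthly.loc[t]
            except KeyError as exc:
                raise DataError(f"forcing does not cover {t.date()}") from exc
            state = {
                "DO_B": do_b,
                "chl": chl,
                "TP_surf": tp_surf,
                "TP_lake": tp_vec[i],
                "h_mix": row["thermocline_depth_m"],
                "T_surf": row["T_surf_C"],
                "T_atm": row["T_atm_C"] + t_atm_offset,
                "Q": row["Q_m3s"],
            }
            nxt = {}
            flagged = False
            for name, pred in self.predictors.items():
                val, extra = pred.predict(state)
                nxt[name] = val
                flagged = flagged or extra
            if flagged:
                warnings_.append(f"{year}-{month:02d}: state outside training hull")
            do_b = max(nxt["DO_B"], 0.0)
            chl = max(nxt["chl"], 0.05)
            tp_surf = max(nxt["TP_surf"], 0.5)
            out.append(do_b)
        idx = [
            pd.Timestamp(year=year, month=m, day=1) + pd.offsets.MonthEnd(0)
            for m in SUMMER_MONTHS
        ]
        traj = pd.Series(out, index=pd.DatetimeIndex(idx), name="DO_B")
        rate = (do_b_init - out[-1]) / 180.0
        return traj, rate, warnings_

    # -- full seasonal alternation ----------------------------------------

    def run(
        self,
        forcing: ForcingSeries,
        tp_lake,
        hypsometry: Hypsometry,
        do_b_init: float = 9.5,
        do_up_init: float | None = None,
        t_atm_offset: float = 0.0,
    ):
        """Multi-decadal hybrid simulation (single initialization).

        ``tp_lake`` is either a constant (scenario mode) or a monthly series
        covering the forcing span (hindcast mode).  Returns ``(monthly DO_B
        series, per-year diagnostics DataFrame)``.
        """
        cfg = self.config
        f = forcing.data
        years = sorted(set(f.index.year))
        start_year = years[0]
        end_year = years[-1]

        def tp_at(ts_):
            if np.isscalar(tp_lake):
                return float(tp_lake)
            s = tp_lake
            if isinstance(s, pd.Series):
                pos = s.index.searchsorted(ts_)
                pos = min(max(pos, 0), len(s) - 1)
                return float(s.iloc[pos])
            raise DataError("tp_lake must be a scalar or a pandas Series")

        sim_idx, sim_val = [], []
        diags = []
        all_warnings: list[str] = []
        do_b = float(do_b_init)
        do_up = do_up_init
        year = start_year
        while year <= end_year:
            may = pd.Timestamp(year=year, month=5, day=1)
            oct_end = pd.Timestamp(year=year, month=10, day=31)
            if may < f.index[0] or oct_end > f.index[-1]:
                break
            # --- summer: iterated EDM depletion ---------------------------
            tp_vec = [
                tp_at(pd.Timestamp(year=year, month=m, day=1)) for m in SUMMER_MONTHS
            ] + [tp_at(oct_end)]
            traj, rate, warns = self.summer_depletion(
                max(do_b, 0.05),
                np.asarray(tp_vec),
                forcing,
                year,
                t_atm_offset=t_atm_offset,
            )
            all_warnings.extend(warns)
            sim_idx.extend(traj.index)
            sim_val.extend(traj.values)
            do_b = float(traj.iloc[-1])  # end-of-October feedback

            # --- winter: daily box physics --------------------------------
            nov = pd.Timestamp(year=year, month=11, day=1)
            apr_end = pd.Timestamp(year=year + 1, month=4, day=30)
            if apr_end > f.index[-1]:
                diags.append(
                    {"year": year, "depletion_rate": rate, "winter_mix_depth": np.nan}
                )
                break
            winter = f.loc[nov:apr_end]
            t_surf_now = float(winter["T_surf_C"].iloc[0])
            if do_up is None:
                do_up = float(do_saturation(t_surf_now, cfg.physics.pressure_atm))
            # initial winter state: surface box diluted with intermediate water
            v_surf = hypsometry.volume_between(0.0, cfg.summer_thermocline)
            v_upper = hypsometry.volume_between(0.0, cfg.winter_boundary)
            do_up_winter = (
                do_up * v_surf + cfg.intermediate_do * (v_upper - v_surf)
            ) / v_upper
            state = make_box_state(
                hypsometry, cfg.winter_boundary, do_up_winter, do_b, date=nov
            )
            for ts_, row in winter.iterrows():
                mix_d = float(
                    np.clip(row["mixing_depth_m"], 1.0, hypsometry.z_max)
                )
                state = winter_mix_step(
                    state,
                    hypsometry,
                    mix_d,
                    float(row["T_surf_C"]),
                    dt=1.0,
                    params=cfg.physics,
                    q_m3s=float(row["Q_m3s"]),
                    t_river=float(row["T_river_C"]),
                )
                if ts_.is_month_end:
                    sim_idx.append(ts_)
                    sim_val.append(state.do_low)
            do_b = state.do_low
            do_up = state.do_up
            diags.append(
                {
                    "year": year,
                    "depletion_rate": rate,
                    "winter_mix_depth": float(winter["mixing_depth_m"].max()),
                    "post_winter_do_b": do_b,
                }
            )
            year += 1
        sim = pd.Series(sim_val, index=pd.DatetimeIndex(sim_idx), name="DO_B")
        sim = sim[~sim.index.duplicated()].sort_index()
        diag = pd.DataFrame(diags)
        diag.attrs["extrapolation_warnings"] = all_warnings
        return sim, diag


def evaluate_hindcast(simulated: pd.Series, observed: pd.Series) -> dict:
    """Pearson correlation, mean absolute error, and mean bias on the overlap.

    Series are aligned on (year, month); a zero-variance input yields an
    undefined (NaN) correlation, reported as such.
    """

    def keyed(s):
        return pd.Series(
            s.values, index=pd.MultiIndex.from_arrays([s.index.year, s.index.month])
        )

    a, b = keyed(simulated).dropna(), keyed(observed).dropna()
    common = a.index.intersection(b.index)
    if len(common) < 3:
        raise DataError("need at least 3 overlapping points")
    a, b = a.loc[common].astype(float), b.loc[common].astype(float)
    if a.std() == 0 or b.std() == 0:
        rho = float("nan")
    else:
        rho = float(np.corrcoef(a, b)[0, 1])
    return {
        "rho": rho,
        "mae": float((a - b).abs().mean()),
        "bias": float((a - b).mean()),
        "n": int(len(common)),
    }
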