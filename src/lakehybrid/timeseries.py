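"""Containers and I/O for multivariate lake monitoring time series.

The central object is :class:`LakeTimeSeries`, a thin validated wrapper around a
time-indexed :class:`pandas.DataFrame` holding the eight monitored lake
variables (deep-water dissolved oxygen, chlorophyll-a, two phosphorus averages,
mixed-layer depth, surface and air temperature, river discharge).  Monitoring
archives of this kind are bimonthly-to-monthly and gappy; :func:`regularize`
puts them on the uniform monthly grid that state-space reconstruction requires,
interpolating only across short gaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

#: Canonical variable names and units for the lake archive.
#: DO_B is the deep-water (260-310 m mean) dissolved oxygen; chl the 0-30 m mean
#: chlorophyll-a; TP_surf the volume-weighted 0-20 m total phosphorus;
#: TP_lake the hypsometry-integrated whole-lake phosphorus; h_mix the mixed-layer
#: (thermocline) depth; Q the river discharge.
LAKE_VARIABLES: dict[str, str] = {
    "DO_B": "mg/L",
    "chl": "ug/L",
    "TP_surf": "ug/L",
    "TP_lake": "ug/L",
    "h_mix": "m",
    "T_surf": "degC",
    "T_atm": "degC",
    "Q": "m3/s",
}

#: Variables that must be non-negative wherever observed.
NONNEGATIVE_VARIABLES = ("DO_B", "chl", "TP_surf", "TP_lake", "Q")


@dataclass
class LakeTimeSeries:
    """Regular- or irregular-grid multivariate lake observations.

    Parameters
    ----------
    data : pandas.DataFrame
        Time-indexed (DatetimeIndex) frame; one column per variable. Missing
        observations are NaN.
    units : dict, optional
        Unit registry per column; defaults filled from :data:`LAKE_VARIABLES`.
    max_depth : float
        Maximum lake depth in metres, used to validate ``h_mix``.
    """

    data: pd.DataFrame
    units: dict[str, str] = field(default_factory=dict)
    max_depth: float = 310.0

    def __post_init__(self):
        if not isinstance(self.data.index, pd.DatetimeIndex):
            self.data = self.data.copy()
            self.data.index = pd.DatetimeIndex(self.data.index)
        if len(self.data.index) > 1 and not self.data.index.is_monotonic_increasing:
            raise DataError("time index must be strictly increasing")
        if self.data.index.has_duplicates:
            raise DataError("time index contains duplicate timestamps")
        for var in self.data.columns:
            self.units.setdefault(var, LAKE_VARIABLES.get(var, ""))
        for var in NONNEGATIVE_VARIABLES:
            if var in self.data.columns:
                vals = self.data[var].to_numpy(float)
                if np.nanmin(vals, initial=np.inf) < 0:
                    raise DataError(f"{var} contains negative values")
        if "h_mix" in self.data.columns:
            h = self.data["h_mix"].to_numpy(float)
            ok = np.isnan(h) | ((h > 0) & (h <= self.max_depth))
            if not ok.all():
                raise DataError(
                    f"h_mix must lie in (0, {self.max_depth}] m where observed"
                )

    # -- convenience -------------------------------------------------------

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def __len__(self) -> int:
        return len(self.data)

    def __getitem__(self, var: str) -> pd.Series:
        return self.data[var]

    @property
    def time(self) -> pd.DatetimeIndex:
        return self.data.index

    def copy(self) -> "LakeTimeSeries":
        return LakeTimeSeries(self.data.copy(), dict(self.units), self.max_depth)


def _monthly_grid(index: pd.DatetimeIndex) -> pd.DatetimeIndex:
    start = index[0].to_period("M").to_timestamp()
    end = index[-1].to_period("M").to_timestamp()
    return pd.date_range(start, end, freq="MS")


def regularize(
    raw: LakeTimeSeries,
    step: str = "MS",
    max_gap: int = 3,
) -> LakeTimeSeries:
    """Resample onto a uniform grid, interpolating only across short gaps.

    Linear interpolation is applied between neighbouring observations whose
    separation is at most ``max_gap`` grid steps; grid points inside longer
    gaps, or outside the observed support of a variable, stay missing.  A
    series already on the target grid is returned unchanged (up to dtype).

    Parameters
    ----------
    raw : LakeTimeSeries
    step : str
        Pandas frequency of the target grid (default monthly, month-start).
    max_gap : int
        Largest gap, in grid steps, across which interpolation is allowed.
    """
    df = raw.data
    if step in ("MS", "M"):
        grid = _monthly_grid(df.index)
    else:
        grid = pd.date_range(df.index[0], df.index[-1], freq=step)
    if len(grid) < 2:
        raise DataError("series too short to regularize (need >= 2 grid points)")
    step_days = (grid[1] - grid[0]) / pd.Timedelta(days=1)
    t_grid = grid.view("int64") / 86_400e9  # days since epoch

    out = {}
    for var in df.columns:
        col = df[var]
        obs = col.dropna()
        if obs.empty:
            raise DataError(f"variable {var!r} has no observations")
        if len(obs) < 2:
            raise DataError(f"variable {var!r} has fewer than 2 observations")
        t_obs = obs.index.view("int64") / 86_400e9
        v_obs = obs.to_numpy(float)
        vals = np.interp(t_grid, t_obs, v_obs, left=np.nan, right=np.nan)
        # mask points bridged by a gap longer than max_gap steps
        right = np.searchsorted(t_obs, t_grid, side="left")
        for i, r in enumerate(right):
            if r == 0 or r == len(t_obs):
                if not np.isclose(t_grid[i], t_obs[0]) and not np.isclose(
                    t_grid[i], t_obs[-1]
                ):
                    vals[i] = np.nan
                continue
            if np.isclose(t_obs[r - 1], t_grid[i]) or np.isclose(t_obs[r], t_grid[i]):
                continue
            gap = t_obs[r] - t_obs[r - 1]
            if gap > max_gap * step_days * (1 + 1e-9):
                vals[i] = np.nan
        out[var] = vals
    res = pd.DataFrame(out, index=grid)
    return LakeTimeSeries(res, dict(raw.units), raw.max_depth)


# -- CSV round-tripping ----------------------------------------------------


def read_timeseries_csv(path, format: str = "auto") -> LakeTimeSeries:
    """Read a lake series from CSV, tidy (date, variable, value[, unit]) or wide."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    tidy = {"date", "variable", "value"} <= set(cols)
    if format == "tidy" or (format == "auto" and tidy):
        if not tidy:
            raise DataError("tidy CSV requires columns date, variable, value")
        units = {}
        if "unit" in cols:
            units = (
                df.groupby(cols["variable"])[cols["unit"]].first().dropna().to_dict()
            )
        wide = df.pivot_table(
            index=cols["date"], columns=cols["variable"], values=cols["value"]
        )
        wide.index = pd.DatetimeIndex(wide.index)
        wide = wide.sort_index()
        wide.columns.name = None
        return LakeTimeSeries(wide, units)
    date_col = cols.get("date", df.columns[0])
    df = df.set_index(date_col)
    df.index = pd.DatetimeIndex(df.index)
    df.index.name = "date"
    return LakeTimeSeries(df.sort_index())


def write_timeseries_csv(ts: LakeTimeSeries, path, format: str = "wide") -> None:
    if format == "wide":
        out = ts.data.copy()
        out.index.name = "date"
        out.to_csv(path, date_format="%Y-%m-%d")
        return
    rows = ts.data.stack(future_stack=True).rename("value").reset_index()
    rows.columns = ["date", "variable", "value"]
    rows["unit"] = rows["variable"].map(ts.units)
    rows = rows.dropna(subset=["value"])
    rows.to_csv(path, index=False, date_format="%Y-%m-%d")
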