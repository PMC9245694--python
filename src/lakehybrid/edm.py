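"""Empirical dynamic modelling core: state-space reconstruction, simplex
projection, S-map locally weighted regression, and interaction tracking.

The S-map is the workhorse.  For a target state vector x(t) it weights every
library exemplar x_i by ``w_i = exp(-theta * d_i / dbar)`` where ``d_i`` is the
Euclidean distance (on z-normalized coordinates) from x(t) to x_i and ``dbar``
is the mean library distance, then solves a weighted least-squares regression
of the target one prediction step ahead on the embedding coordinates plus an
intercept.  ``theta`` tunes locality: at ``theta = 0`` every exemplar carries
equal weight and the fit collapses to a single global linear (multivariate
autoregressive) model; larger ``theta`` makes the regression increasingly
state-dependent.  The fitted local coefficients approximate the Jacobian
partial derivatives of the dynamics when the embedding contains the key causal
variables, which is how state-dependent interaction strengths (e.g. the effect
of phosphorus on chlorophyll) are tracked through time.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import EmbeddingError, InsufficientLibraryError, ZeroVarianceError
from .timeseries import LakeTimeSeries

logger = logging.getLogger(__name__)

#: Default theta grid: 0 plus a log-spread up to 10.
DEFAULT_THETA_GRID: tuple[float, ...] = (
    0.0, 1e-4, 3e-4, 1e-3, 3e-3, 0.01, 0.03, 0.1, 0.3, 0.5,
    0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 7.5, 10.0,
)


# ---------------------------------------------------------------------------
# Embedding specification and state matrix
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EmbeddingSpec:
    """A multivariate delay embedding: (variable, lag) coordinates plus target.

    ``tp`` is the prediction horizon in grid steps; negative horizons are used
    by cross-mapping (estimating a putative cause earlier than the embedding
    vector's anchor time).
    """

    coordinates: tuple[tuple[str, int], ...]
    target: str
    tp: int = 1

    def __post_init__(self):
        coords = tuple((str(v), int(l)) for v, l in self.coordinates)
        object.__setattr__(self, "coordinates", coords)
        if not coords:
            raise EmbeddingError("embedding must have at least one coordinate")
        if len(set(coords)) != len(coords):
            raise EmbeddingError("duplicate (variable, lag) coordinates")
        if any(l < 0 for _, l in coords):
            raise EmbeddingError("lags must be >= 0")

    @property
    def E(self) -> int:
        return len(self.coordinates)

    @property
    def max_lag(self) -> int:
        return max(l for _, l in self.coordinates)

    @property
    def labels(self) -> list[str]:
        return [v if l == 0 else f"{v}(t-{l})" for v, l in self.coordinates]


def univariate_spec(variable: str, E: int, tp: int = 1) -> EmbeddingSpec:
    """Standard delay embedding: E successive lags of one variable."""
    return EmbeddingSpec(tuple((variable, l) for l in range(E)), variable, tp)


@dataclass
class StateMatrix:
    """Row-per-time-point embedding matrix with frozen normalization.

    ``values`` holds z-normalized rows (statistics computed over the library
    rows only, recorded in ``mean``/``sd``); rows with any missing lagged
    component are masked out of ``valid``.
    """

    values: np.ndarray
    valid: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    spec: EmbeddingSpec
    index: pd.Index
    raw: np.ndarray

    @property
    def E(self) -> int:
        return self.values.shape[1]

    @property
    def max_lag(self) -> int:
        return self.spec.max_lag

    def normalize_row(self, raw_row: np.ndarray) -> np.ndarray:
        """Apply the frozen normalization to a new raw coordinate vector."""
        return (np.asarray(raw_row, float) - self.mean) / self.sd


def _as_frame(ts) -> pd.DataFrame:
    if isinstance(ts, LakeTimeSeries):
        return ts.data
    if isinstance(ts, pd.DataFrame):
        return ts
    raise EmbeddingError(f"expected LakeTimeSeries or DataFrame, got {type(ts)}")


def build_state_matrix(
    ts, spec: EmbeddingSpec, norm_rows: np.ndarray | None = None
) -> StateMatrix:
    """Construct the lagged, z-normalized state matrix for an embedding.

    Row t holds ``(x_j(t - lag_j))_j``.  Normalization statistics are computed
    over ``norm_rows`` (default: all valid rows) so that library and query
    points share one frozen scale.
    """
    df = _as_frame(ts)
    for var, _ in spec.coordinates:
        if var not in df.columns:
            raise EmbeddingError(f"unknown variable {var!r} in embedding")
    n = len(df)
    if spec.max_lag >= n:
        raise EmbeddingError("lag exceeds series length")
    raw = np.full((n, spec.E), np.nan)
    for j, (var, lag) in enumerate(spec.coordinates):
        x = df[var].to_numpy(float)
        if lag == 0:
            raw[:, j] = x
        else:
            raw[lag:, j] = x[:-lag]
    valid = ~np.isnan(raw).any(axis=1)
    if not valid.any():
        raise EmbeddingError("all embedding rows are masked (missing data)")
    rows = valid if norm_rows is None else (np.asarray(norm_rows, bool) & valid)
    if not rows.any():
        raise EmbeddingError("no valid rows available for normalization")
    mean = raw[rows].mean(axis=0)
    sd = raw[rows].std(axis=0, ddof=0)
    for j, s in enumerate(sd):
        if s == 0 or not np.isfinite(s):
            raise ZeroVarianceError(spec.coordinates[j])
    values = (raw - mean) / sd
    return StateMatrix(values, valid, mean, sd, spec, df.index, raw)


def target_at_horizon(ts, target: str, tp: int) -> np.ndarray:
    """y[t] = target(t + tp), NaN outside the series support."""
    x = _as_frame(ts)[target].to_numpy(float)
    n = len(x)
    y = np.full(n, np.nan)
    if tp >= 0:
        if tp < n:
            y[: n - tp] = x[tp:]
    else:
        y[-tp:] = x[:tp]
    return y


# ---------------------------------------------------------------------------
# Simplex projection
# ---------------------------------------------------------------------------


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        return np.nan
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class SimplexResult:
    predictions: np.ndarray
    observed: np.ndarray
    skill: float
    mae: float
    pred_idx: np.ndarray


def _eligible_rows(sm: StateMatrix, y: np.ndarray, idx) -> np.ndarray:
    base = sm.valid & np.isfinite(y)
    if idx is None:
        return np.flatnonzero(base)
    idx = np.asarray(idx, int)
    return idx[base[idx]]


def simplex_project(
    sm: StateMatrix,
    target: np.ndarray,
    tp: int | None = None,
    lib: np.ndarray | None = None,
    pred: np.ndarray | None = None,
    n_neighbors: int | None = None,
    exclusion_radius: int = 0,
) -> SimplexResult:
    """Nearest-neighbor (simplex) forecasting in embedding space.

    Each prediction is the weighted mean of the targets of the ``E+1`` nearest
    library rows, weights ``exp(-d_i / d_min)`` with ``d_min`` the nearest
    distance.  A library row at zero distance takes weight one (and crowds out
    finite-distance rows).  The prediction target's own row, and rows within
    ``exclusion_radius`` time steps of it, are always excluded from its
    library.

    ``target`` may be a raw series (aligned with ``sm``; shifted internally by
    ``tp``) or, if ``tp`` is None, an already-shifted response vector.
    """
    target = np.asarray(target, float)
    y = target if tp is None else _shift(target, tp)
    lib_rows = _eligible_rows(sm, y, lib)
    pred_rows = np.flatnonzero(sm.valid) if pred is None else np.asarray(pred, int)
    pred_rows = pred_rows[sm.valid[pred_rows]]
    k = (sm.E + 1) if n_neighbors is None else int(n_neighbors)
    preds = np.full(sm.values.shape[0], np.nan)
    D = cdist(sm.values[pred_rows], sm.values[lib_rows])
    # temporal exclusion: the query's own row and rows within the radius
    excl = np.abs(lib_rows[None, :] - pred_rows[:, None]) <= exclusion_radius
    D[excl] = np.inf
    avail = np.isfinite(D).sum(axis=1)
    if (avail < k).any():
        p = pred_rows[int(np.argmin(avail))]
        raise InsufficientLibraryError(
            f"need {k} library points, have {int(avail.min())} for row {p}"
        )
    part = np.argpartition(D, k - 1, axis=1)[:, :k]
    dsel = np.take_along_axis(D, part, axis=1)
    # order the k neighbours by distance, ties broken by earlier library time
    tsel = lib_rows[part]
    for i in range(len(pred_rows)):
        o = np.lexsort((tsel[i], dsel[i]))
        part[i] = part[i][o]
        dsel[i] = dsel[i][o]
    d_min = dsel[:, 0]
    with np.errstate(invalid="ignore", divide="ignore", under="ignore"):
        w = np.exp(-dsel / np.where(d_min > 0, d_min, np.nan)[:, None])
    zero_rows = d_min == 0
    if zero_rows.any():
        w[zero_rows] = np.where(dsel[zero_rows] == 0, 1.0, 0.0)
    yv = y[lib_rows[part]]
    preds[pred_rows] = (w * yv).sum(axis=1) / w.sum(axis=1)
    obs_ok = pred_rows[np.isfinite(y[pred_rows])]
    skill = _pearson(preds[obs_ok], y[obs_ok])
    mae = float(np.nanmean(np.abs(preds[obs_ok] - y[obs_ok]))) if obs_ok.size else np.nan
    return SimplexResult(preds, y, skill, mae, pred_rows)


def _shift(x: np.ndarray, tp: int) -> np.ndarray:
    n = len(x)
    y = np.full(n, np.nan)
    if tp == 0:
        return x.copy()
    if tp > 0:
        if tp < n:
            y[: n - tp] = x[tp:]
    else:
        y[-tp:] = x[:tp]
    return y


# ---------------------------------------------------------------------------
# S-map
# ---------------------------------------------------------------------------


@dataclass
class SMapFit:
    """Result of an S-map forecast: predictions, skill, local coefficients.

    ``coefficients`` holds raw-unit local regression coefficients (one row per
    target time, one column per coordinate plus ``intercept``): the entry for
    coordinate ``x_j`` estimates the Jacobian element d target(t+tp) / d x_j(t).
    ``coefficients_norm`` holds the same fits on normalized coordinates.
    """

    theta: float
    tp: int
    predictions: np.ndarray
    observed: np.ndarray
    skill: float
    mae: float
    coefficients: pd.DataFrame
    coefficients_norm: pd.DataFrame
    spec: EmbeddingSpec | None = None
    sm: StateMatrix | None = None

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {"observed": self.observed, "predicted": self.predictions},
            index=self.coefficients.index,
        )
        return out.join(self.coefficients)


def smap_forecast(
    sm: StateMatrix,
    target: np.ndarray,
    theta: float,
    tp: int | None = 1,
    lib: np.ndarray | None = None,
    pred: np.ndarray | None = None,
    exclusion_radius: int | None = None,
) -> SMapFit:
    """S-map: sequentially locally weighted linear forecasting.

    For each prediction row the library is weighted by
    ``w_i = exp(-theta * d_i / dbar)`` (``dbar`` = mean library distance to the
    query) and a weighted least-squares regression of the response on the
    normalized embedding coordinates plus intercept is solved by SVD.  With
    ``exclusion_radius=None`` the library is fixed (no per-target exclusion),
    so ``theta = 0`` reproduces one global linear regression at every target
    time; with an integer radius, rows within that many time steps of the
    query (including itself) are dropped for leave-one-out evaluation.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0")
    target = np.asarray(target, float)
    y = target if tp is None else _shift(target, tp)
    tp_eff = 0 if tp is None else tp
    lib_rows = _eligible_rows(sm, y, lib)
    pred_rows = np.flatnonzero(sm.valid) if pred is None else np.asarray(pred, int)
    pred_rows = pred_rows[sm.valid[pred_rows]]
    E = sm.E
    if lib_rows.size < E + 2:
        raise InsufficientLibraryError(
            f"S-map needs at least E+2={E + 2} library rows, have {lib_rows.size}"
        )
    n = sm.values.shape[0]
    preds = np.full(n, np.nan)
    coef_n = np.full((n, E + 1), np.nan)
    D = cdist(sm.values[pred_rows], sm.values[lib_rows])
    rank_deficient = 0
    for i, p in enumerate(pred_rows):
        if exclusion_radius is None:
            cand = np.arange(lib_rows.size)
        else:
            cand = np.flatnonzero(np.abs(lib_rows - p) > exclusion_radius)
        if cand.size < E + 2:
            continue
        d = D[i, cand]
        dbar = d.mean()
        if dbar == 0:
            raise EmbeddingError("all library points coincide (dbar = 0)")
        w = np.exp(-theta * d / dbar)
        if (w > 1e-12).sum() < E + 2:
            continue
        sw = np.sqrt(w)
        X = np.column_stack([sm.values[lib_rows[cand]], np.ones(cand.size)])
        A = X * sw[:, None]
        b = y[lib_rows[cand]] * sw
        c, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
        if rank < E + 1:
            rank_deficient += 1
        coef_n[p] = c
        preds[p] = float(np.dot(sm.values[p], c[:E]) + c[E])
    if rank_deficient:
        logger.warning(
            "rank-deficient S-map design at %d target times; minimum-norm "
            "solution used", rank_deficient,
        )
    obs_ok = pred_rows[np.isfinite(y[pred_rows])]
    skill = _pearson(preds[obs_ok], y[obs_ok])
    mae = float(np.nanmean(np.abs(preds[obs_ok] - y[obs_ok]))) if obs_ok.size else np.nan
    labels = sm.spec.labels
    cn = pd.DataFrame(coef_n, index=sm.index, columns=labels + ["intercept"])
    raw = coef_n.copy()
    raw[:, :E] = coef_n[:, :E] / sm.sd
    raw[:, E] = coef_n[:, E] - (coef_n[:, :E] * (sm.mean / sm.sd)).sum(axis=1)
    cr = pd.DataFrame(raw, index=sm.index, columns=labels + ["intercept"])
    return SMapFit(theta, tp_eff, preds, y, skill, mae, cr, cn, sm.spec, sm)


# ---------------------------------------------------------------------------
# Theta scan (nonlinearity test)
# ---------------------------------------------------------------------------


@dataclass
class ThetaScanResult:
    table: pd.DataFrame  # columns: theta, rho, mae
    best_theta: float
    best_rho: float
    delta_rho: float  # best vs theta=0 skill gain

    def __repr__(self):
        return (
            f"ThetaScanResult(best_theta={self.best_theta}, "
            f"best_rho={self.best_rho:.3f}, delta_rho={self.delta_rho:.3f})"
        )


def theta_scan(
    sm: StateMatrix,
    target: np.ndarray,
    theta_grid=DEFAULT_THETA_GRID,
    tp: int | None = 1,
    exclusion_radius: int | str = "auto",
) -> ThetaScanResult:
    """Leave-one-out S-map skill over a theta grid (nonlinearity test).

    The exclusion radius defaults to the embedding's maximum lag so that
    temporally overlapping vectors never inform their own prediction.  The
    gain of the best theta over theta=0 measures state dependence: a linear
    stochastic system shows none, a nonlinear one a positive gain.
    """
    thetas = list(theta_grid)
    if not thetas:
        raise ValueError("theta_grid must be non-empty")
    if 0.0 not in thetas:
        thetas = [0.0] + thetas
    radius = max(sm.max_lag, 1) if exclusion_radius == "auto" else int(exclusion_radius)
    rows = []
    for th in thetas:
        try:
            fit = smap_forecast(sm, target, th, tp=tp, exclusion_radius=radius)
        except Exception as exc:  # propagate with the offending theta named
            raise type(exc)(f"theta={th}: {exc}") from exc
        rows.append({"theta": th, "rho": fit.skill, "mae": fit.mae})
    table = pd.DataFrame(rows)
    ib = int(table["rho"].idxmax())
    best_theta = float(table.loc[ib, "theta"])
    best_rho = float(table.loc[ib, "rho"])
    rho0 = float(table.loc[table["theta"] == 0.0, "rho"].iloc[0])
    return ThetaScanResult(table, best_theta, best_rho, best_rho - rho0)


def select_univariate_E(
    ts,
    variable: str,
    E_range=range(1, 11),
    tp: int = 1,
) -> tuple[int, pd.DataFrame]:
    """Univariate simplex embedding-dimension choice: argmax leave-one-out skill."""
    df = _as_frame(ts)
    rows = []
    for E in E_range:
        spec = univariate_spec(variable, E, tp)
        sm = build_state_matrix(df, spec)
        res = simplex_project(
            sm, df[variable].to_numpy(float), tp=tp, exclusion_radius=E
        )
        rows.append({"E": E, "rho": res.skill})
    table = pd.DataFrame(rows)
    best = int(table.loc[table["rho"].idxmax(), "E"])
    return best, table


# ---------------------------------------------------------------------------
# Sequential multivariate embedding comparison
# ---------------------------------------------------------------------------


@dataclass
class EmbeddingComparison:
    table: pd.DataFrame
    best_spec: EmbeddingSpec
    best_theta: float


def sequential_embedding_comparison(
    ts,
    target: str,
    base_vars,
    added_vars,
    theta_grid=DEFAULT_THETA_GRID,
    tp: int = 1,
    include_target: bool = True,
) -> EmbeddingComparison:
    """Evaluate a baseline embedding, then each prefix of added variables.

    Mirrors the additive multivariate comparison used to test whether
    biogeochemical variables add predictability beyond the physical baseline
    (mixed-layer depth, surface/air temperature, discharge): each candidate
    embedding is scored by its best leave-one-out S-map skill over the theta
    grid, and the best-scoring ("mechanistic") embedding is returned.
    """
    base_vars = list(base_vars)
    added_vars = list(added_vars)
    if set(base_vars) & set(added_vars):
        raise EmbeddingError("base_vars and added_vars must be disjoint")
    df = _as_frame(ts)
    y = df[target].to_numpy(float)

    def make_spec(extra):
        coords = []
        if include_target:
            coords.append((target, 0))
        coords += [(v, 0) for v in base_vars + extra if (v, 0) not in coords]
        return EmbeddingSpec(tuple(coords), target, tp)

    rows, specs = [], []
    prefixes = [[]] + [added_vars[: i + 1] for i in range(len(added_vars))]
    for extra in prefixes:
        spec = make_spec(extra)
        sm = build_state_matrix(df, spec)
        scan = theta_scan(sm, y, theta_grid, tp=tp)
        label = "+".join(base_vars + extra) or "(empty)"
        rows.append(
            {
                "embedding": label,
                "n_coords": spec.E,
                "best_theta": scan.best_theta,
                "best_rho": scan.best_rho,
                "rho_linear": float(
                    scan.table.loc[scan.table["theta"] == 0.0, "rho"].iloc[0]
                ),
            }
        )
        specs.append(spec)
    table = pd.DataFrame(rows)
    ib = int(table["best_rho"].idxmax())
    return EmbeddingComparison(table, specs[ib], float(table.loc[ib, "best_theta"]))


# ---------------------------------------------------------------------------
# Interaction (Jacobian) tracking
# ---------------------------------------------------------------------------


def interaction_coefficients(fit: SMapFit, coordinate) -> pd.Series:
    """Extract the raw-unit local coefficient series for one embedding coordinate.

    ``coordinate`` may be a variable name (lag 0) or a ``(variable, lag)``
    pair.  The returned series estimates the time-varying partial derivative
    d target(t+tp) / d coordinate(t).
    """
    if isinstance(coordinate, tuple):
        var, lag = coordinate
        label = var if lag == 0 else f"{var}(t-{lag})"
    else:
        label = coordinate
    if label not in fit.coefficients.columns:
        raise EmbeddingError(
            f"coordinate {coordinate!r} not in fit (have {list(fit.coefficients.columns)})"
        )
    return fit.coefficients[label]


def bin_against(
    coef: pd.Series,
    conditioning: pd.Series,
    n_bins: int = 10,
    n_boot: int = 500,
    ci: float = 0.95,
    seed: int = 0,
    equal_count: bool = True,
) -> pd.DataFrame:
    """Bin a coefficient series against a conditioning variable.

    Returns per-bin mean with a bootstrap confidence interval — the standard
    presentation of state-dependent interaction strength against, e.g., the
    whole-lake phosphorus level.
    """
    joined = pd.DataFrame({"c": coef, "x": conditioning}).dropna()
    if joined.empty:
        raise EmbeddingError("no overlapping finite values to bin")
    x = joined["x"].to_numpy()
    if equal_count:
        qs = np.quantile(x, np.linspace(0, 1, n_bins + 1))
        edges = np.unique(qs)
    else:
        edges = np.linspace(x.min(), x.max(), n_bins + 1)
    which = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, len(edges) - 2)
    rng = np.random.default_rng(seed)
    alpha = (1 - ci) / 2
    rows = []
    for b in range(len(edges) - 1):
        vals = joined["c"].to_numpy()[which == b]
        if vals.size == 0:
            continue
        boot = rng.choice(vals, size=(n_boot, vals.size), replace=True).mean(axis=1)
        rows.append(
            {
                "bin_lo": edges[b],
                "bin_hi": edges[b + 1],
                "bin_center": 0.5 * (edges[b] + edges[b + 1]),
                "n": vals.size,
                "mean": vals.mean(),
                "ci_lo": float(np.quantile(boot, alpha)),
                "ci_hi": float(np.quantile(boot, 1 - alpha)),
            }
        )
    return pd.DataFrame(rows)
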