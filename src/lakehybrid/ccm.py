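"""Convergent cross-mapping (CCM) causal inference between variable pairs.

CCM asks whether the historical states of a putative *effect* contain enough
information to estimate the *cause*: if x forces y, the attractor
reconstructed from y's lags maps onto x, and the cross-map skill rises
(converges) as the library of exemplars grows.  The protocol used here first
selects the embedding dimension E* in [1, 15] that maximizes cross-map skill
at horizon tp = 0, then measures convergence at tp = floor(-E*/2) — the middle
of the embedding vector — which guards against overfitting the contemporaneous
map.  Significance is judged against phase-randomized (Ebisuzaki-style)
surrogates of the cause, which preserve the power spectrum (including any
seasonal cycle) while destroying state-dependent coupling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .edm import (
    EmbeddingSpec,
    StateMatrix,
    build_state_matrix,
    simplex_project,
    univariate_spec,
)
from .errors import DataError, InsufficientLibraryError
from .timeseries import LakeTimeSeries


def phase_randomize(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Ebisuzaki surrogate: randomize Fourier phases, preserve the spectrum."""
    x = np.asarray(x, float)
    n = len(x)
    mu = x.mean()
    xf = np.fft.rfft(x - mu)
    phases = rng.uniform(0, 2 * np.pi, len(xf))
    phases[0] = 0.0
    if n % 2 == 0:
        phases[-1] = 0.0
    sur = np.fft.irfft(np.abs(xf) * np.exp(1j * phases), n=n)
    return sur + mu


@dataclass
class CCMResult:
    """Cross-map of `cause` from `effect`'s delay embedding over library sizes."""

    cause: str
    effect: str
    E_star: int
    tp_used: int
    library_sizes: np.ndarray
    skill_mean: np.ndarray
    skill_lo: np.ndarray  # 2.5% quantile over subsamples
    skill_hi: np.ndarray  # 97.5% quantile over subsamples
    convergent: bool | None
    rho_crit: float
    delta: float
    flags: list[str] = field(default_factory=list)

    @property
    def skill_curve(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "L": self.library_sizes,
                "rho_mean": self.skill_mean,
                "rho_lo": self.skill_lo,
                "rho_hi": self.skill_hi,
            }
        )

    def summary(self) -> dict:
        return {
            "cause": self.cause,
            "effect": self.effect,
            "E_star": self.E_star,
            "tp_used": self.tp_used,
            "rho_Lmin": float(self.skill_mean[0]),
            "rho_Lmax": float(self.skill_mean[-1]),
            "rho_crit": self.rho_crit,
            "convergent": self.convergent,
            "flags": ";".join(self.flags),
        }


def _series(data, name) -> np.ndarray:
    if isinstance(data, (pd.Series, np.ndarray, list)):
        return np.asarray(data, float)
    raise DataError(f"cannot interpret {name} as a series")


def _cross_map_skill(
    sm: StateMatrix, cause: np.ndarray, tp: int, lib: np.ndarray | None = None
) -> float:
    res = simplex_project(sm, cause, tp=tp, lib=lib, exclusion_radius=0)
    return res.skill


def select_ccm_E(
    effect,
    cause,
    E_range=(1, 15),
    effect_name: str = "effect",
) -> tuple[int, pd.DataFrame]:
    """Choose E* maximizing cross-map skill at tp = 0 with the maximal library.

    Ties favour the smallest E.  If the series is too short for the top of the
    range, the range is shrunk with a warning.
    """
    eff = _series(effect, "effect")
    cau = _series(cause, "cause")
    n = len(eff)
    E_lo, E_hi = int(E_range[0]), int(E_range[-1])
    feasible_hi = min(E_hi, n - 4)
    if feasible_hi < E_hi:
        warnings.warn(
            f"series too short for E up to {E_hi}; shrinking to {feasible_hi}",
            stacklevel=2,
        )
    rows = []
    df = pd.DataFrame({"effect": eff})
    for E in range(E_lo, feasible_hi + 1):
        sm = build_state_matrix(df, univariate_spec("effect", E, tp=0))
        try:
            rho = _cross_map_skill(sm, cau, tp=0)
        except InsufficientLibraryError:
            warnings.warn(
                f"series too short for E >= {E}; shrinking range", stacklevel=2
            )
            break
        rows.append({"E": E, "rho": rho})
    if not rows:
        raise InsufficientLibraryError("series too short for any embedding dimension")
    table = pd.DataFrame(rows)
    best = int(table.loc[table["rho"].idxmax(), "E"])  # idxmax: first max => smallest E
    return best, table


def ccm(
    effect,
    cause,
    E_star: int | None = None,
    tp: int | None = None,
    library_sizes=None,
    n_subsamples: int = 100,
    seed: int | None = 0,
    sampling: str = "random",
    delta: float = 0.25,
    rho_crit="surrogate",
    n_surrogates: int = 200,
    surrogate_quantile: float = 0.95,
    cause_name: str = "cause",
    effect_name: str = "effect",
) -> CCMResult:
    """Convergent cross-mapping of ``cause`` from ``effect``'s embedding.

    For each library size L, ``n_subsamples`` libraries are drawn (random
    without replacement, or random contiguous blocks with
    ``sampling='contiguous'``) and the cause is simplex-estimated at horizon
    ``tp`` (default floor(-E*/2)).  The pair is judged convergent when the mean
    skill rises by more than ``delta`` from the smallest to the largest
    library AND the large-library skill exceeds ``rho_crit`` (a number, or
    ``'surrogate'`` for the ``surrogate_quantile`` of a phase-randomized
    null).
    """
    eff = _series(effect, "effect")
    cau = _series(cause, "cause")
    if len(eff) != len(cau):
        raise DataError("effect and cause series must have equal length")
    rng = np.random.default_rng(seed)
    if E_star is None:
        E_star, _ = select_ccm_E(eff, cau)
    E_star = int(E_star)
    if E_star < 1:
        raise ValueError("E_star must be >= 1")
    if tp is None:
        tp = math.floor(-E_star / 2)
    df = pd.DataFrame({"effect": eff})
    sm = build_state_matrix(df, univariate_spec("effect", E_star, tp=tp))
    from .edm import _shift  # shared horizon-shift helper

    y = _shift(cau, tp)
    eligible = np.flatnonzero(sm.valid & np.isfinite(y))
    L_max_avail = eligible.size
    if library_sizes is None:
        L_min = max(E_star + 2, 10)
        library_sizes = np.unique(
            np.round(np.geomspace(L_min, L_max_avail, 8)).astype(int)
        )
    library_sizes = np.asarray(sorted(set(int(L) for L in library_sizes)))
    if library_sizes[0] < E_star + 2:
        raise InsufficientLibraryError(
            f"smallest library size {library_sizes[0]} < E*+2 = {E_star + 2}"
        )
    if library_sizes[-1] > L_max_avail:
        raise InsufficientLibraryError(
            f"largest library size {library_sizes[-1]} exceeds available rows "
            f"({L_max_avail})"
        )
    flags: list[str] = []
    means, los, his = [], [], []
    for L in library_sizes:
        skills = np.empty(n_subsamples)
        for s in range(n_subsamples):
            if L == L_max_avail:
                lib = eligible
            elif sampling == "contiguous":
                start = rng.integers(0, L_max_avail - L + 1)
                lib = eligible[start : start + L]
            else:
                lib = rng.choice(eligible, size=L, replace=False)
            skills[s] = _cross_map_skill(sm, cau, tp=tp, lib=lib)
        means.append(np.nanmean(skills))
        los.append(np.nanquantile(skills, 0.025))
        his.append(np.nanquantile(skills, 0.975))
    means = np.asarray(means)

    if rho_crit == "surrogate":
        null = np.empty(n_surrogates)
        for s in range(n_surrogates):
            sur = phase_randomize(cau, rng)
            null[s] = _cross_map_skill(sm, sur, tp=tp)
        rho_crit_val = float(np.nanquantile(null, surrogate_quantile))
    else:
        rho_crit_val = float(rho_crit)

    if len(library_sizes) < 2:
        convergent = None
        flags.append("insufficient L range")
    else:
        convergent = bool(
            (means[-1] - means[0] > delta) and (means[-1] > rho_crit_val)
        )
    return CCMResult(
        cause_name,
        effect_name,
        E_star,
        int(tp),
        library_sizes,
        means,
        np.asarray(los),
        np.asarray(his),
        convergent,
        rho_crit_val,
        delta,
        flags,
    )


def ccm_matrix(ts, variables=None, **settings) -> pd.DataFrame:
    """Run CCM over all ordered variable pairs; long-format summary table.

    Self-pairs are excluded by construction.  Per-pair seeds are derived
    deterministically from the base seed and the pair label, so adding
    variables never shifts existing results.
    """
    df = ts.data if isinstance(ts, LakeTimeSeries) else pd.DataFrame(ts)
    variables = list(variables) if variables is not None else list(df.columns)
    base_seed = settings.pop("seed", 0)
    rows = []
    for cause in variables:
        for effect in variables:
            if cause == effect:
                continue
            pair_seed = (
                int(base_seed)
                + int(np.frombuffer(f"{cause}->{effect}".encode(), dtype=np.uint8).sum())
            ) % (2**31 - 1)
            res = ccm(
                df[effect].to_numpy(float),
                df[cause].to_numpy(float),
                seed=pair_seed,
                cause_name=cause,
                effect_name=effect,
                **settings,
            )
            rows.append(res.summary())
    cols = [
        "cause", "effect", "E_star", "tp_used",
        "rho_Lmin", "rho_Lmax", "rho_crit", "convergent", "flags",
    ]
    return pd.DataFrame(rows, columns=cols)
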