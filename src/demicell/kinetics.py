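"""Half-life estimation from transcription-chase data.

The estimation pipeline mirrors the imaging assay: per time point, bootstrap
resampling (by default 5 rounds of 500 cells) yields a median fluorescence
with a bootstrap spread; the median curve is normalized to its t = 0 value
and a single exponential ``N(t) = N0 * exp(-lambda * t)`` is fitted by
nonlinear least squares.  ``t_half = ln(2) / lambda`` exactly.  A quadratic
growth-rate model ``log(t_half) = a*mu^2 + b*mu + c`` (natural log) can be
evaluated and fitted on (growth rate, median half-life) points.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import DegenerateDataError, ParameterError

__all__ = [
    "BootstrapConfig",
    "DecayFit",
    "GrowthRateModel",
    "background_subtract",
    "bootstrap_medians",
    "fit_decay",
    "estimate_half_life",
    "stratified_half_lives",
    "evaluate_growth_model",
    "fit_growth_model",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class BootstrapConfig:
    n_rounds: int = 5
    n_cells_per_round: int = 500
    seed: int | None = None

    def validate(self) -> None:
        if self.n_rounds <= 0 or self.n_cells_per_round <= 0:
            raise ParameterError("bootstrap counts must be positive")


@dataclass
class DecayFit:
    """Fitted single-exponential decay.  ``t_half`` is ln(2)/lambda, exactly."""

    n0: float
    lam: float
    t_half: float
    rmse: float
    n_cells_per_timepoint: dict[float, int]
    bootstrap_sd: float = float("nan")  # sd of t_half over per-round refits
    non_decaying: bool = False

    def __post_init__(self) -> None:
        if not self.non_decaying:
            assert math.isclose(self.t_half * self.lam, LN2, rel_tol=1e-12)


def background_subtract(values: np.ndarray, background: float) -> tuple[np.ndarray, int]:
    """``raw - background`` floored at 0; returns (corrected, n_floored)."""
    if background < 0:
        raise ParameterError("background must be non-negative")
    values = np.asarray(values, dtype=float)
    corrected = values - background
    floored = corrected < 0
    corrected[floored] = 0.0
    if len(values) and np.all(values <= background):
        warnings.warn("background exceeds every signal; output is all zero", stacklevel=2)
    return corrected, int(floored.sum())


def bootstrap_medians(
    dataset: pd.DataFrame,
    config: BootstrapConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-time-point bootstrap medians.

    For each time point, draw ``n_rounds`` resamples of ``n_cells_per_round``
    cells with replacement and take the median of each; report the mean and
    sd of the round medians.  Columns: time_min, median, sd, n_cells.
    """
    config = config or BootstrapConfig()
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows = []
    for t, group in dataset.groupby("time_min", sort=True):
        vals = group["fluorescence"].to_numpy(dtype=float)
        if len(vals) == 0:
            raise DegenerateDataError(f"time point {t} has no cells")
        if len(vals) < config.n_cells_per_round:
            warnings.warn(
                f"time point {t}: only {len(vals)} cells for rounds of "
                f"{config.n_cells_per_round}; resampling with replacement from what exists",
                stacklevel=2,
            )
        meds = np.array(
            [
                np.median(rng.choice(vals, size=config.n_cells_per_round, replace=True))
                for _ in range(config.n_rounds)
            ]
        )
        rows.append(dict(time_min=float(t), median=float(meds.mean()),
                         sd=float(meds.std(ddof=1) if config.n_rounds > 1 else 0.0),
                         n_cells=len(vals)))
    return pd.DataFrame(rows)


def _fit_exponential(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Nonlinear least-squares fit of N0*exp(-lam*t); returns (n0, lam)."""
    pos = y > 0
    if pos.sum() >= 2 and np.ptp(y[pos]) > 0:
        slope, icept = np.polyfit(t[pos], np.log(y[pos]), 1)
        p0 = [math.exp(icept), -slope]
    else:
        p0 = [max(y.max(), 1e-9), 0.01]

    def resid(p):
        return p[0] * np.exp(-p[1] * t) - y

    sol = optimize.least_squares(resid, p0, method="lm", max_nfev=10000)
    return float(sol.x[0]), float(sol.x[1])


def fit_decay(
    time_points: np.ndarray,
    values: np.ndarray,
    n_cells: dict[float, int] | None = None,
) -> DecayFit:
    """Fit a single exponential to (time, normalized median) points.

    Needs >= 3 time points.  Non-decaying data (fitted lambda <= 0) are
    flagged and reported with infinite half-life.
    """
    t = np.asarray(time_points, dtype=float)
    y = np.asarray(values, dtype=float)
    if len(t) < 3 or len(t) != len(y):
        raise ParameterError("need >= 3 matched time points")
    if not np.all(np.isfinite(y)):
        raise ParameterError("values must be finite")
    n0, lam = _fit_exponential(t, y)
    rmse = float(np.sqrt(np.mean((n0 * np.exp(-lam * t) - y) ** 2)))
    n_cells = n_cells or {}
    if lam <= 0:
        return DecayFit(n0, lam, float("inf"), rmse, n_cells, non_decaying=True)
    return DecayFit(n0, lam, LN2 / lam, rmse, n_cells)


def estimate_half_life(
    dataset: pd.DataFrame,
    config: BootstrapConfig | None = None,
    rng: np.random.Generator | None = None,
) -> DecayFit:
    """Full pipeline: bootstrap medians -> t=0 normalization -> exponential fit.

    The bootstrap sd of ``t_half`` is the sd over per-round refits (each
    round's median curve fitted independently).
    """
    config = config or BootstrapConfig()
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    t_arr = np.array(sorted(dataset["time_min"].unique()), dtype=float)
    groups = {float(t): g["fluorescence"].to_numpy(dtype=float)
              for t, g in dataset.groupby("time_min")}
    for t, vals in groups.items():
        if len(vals) == 0:
            raise DegenerateDataError(f"time point {t} has no cells")
    round_meds = np.empty((config.n_rounds, len(t_arr)))
    for i in range(config.n_rounds):
        for j, t in enumerate(t_arr):
            round_meds[i, j] = np.median(
                rng.choice(groups[t], size=config.n_cells_per_round, replace=True)
            )
    mean_meds = round_meds.mean(axis=0)
    if mean_meds[0] <= 0:
        raise DegenerateDataError("median at t=0 is non-positive; cannot normalize")
    n_cells = {t: len(groups[t]) for t in t_arr}
    fit = fit_decay(t_arr, mean_meds / mean_meds[0], n_cells)
    # per-round refits for the bootstrap spread of t_half
    halves = []
    for i in range(config.n_rounds):
        if round_meds[i, 0] <= 0:
            continue
        try:
            f = fit_decay(t_arr, round_meds[i] / round_meds[i, 0], n_cells)
        except (ParameterError, DegenerateDataError):
            continue
        if not f.non_decaying:
            halves.append(f.t_half)
    if len(halves) > 1:
        fit.bootstrap_sd = float(np.std(halves, ddof=1))
    return fit


def stratified_half_lives(
    dataset: pd.DataFrame,
    config: BootstrapConfig | None = None,
    rng: np.random.Generator | None = None,
    flag_col: str = "cluster_flag",
) -> dict[bool, DecayFit]:
    """Run the half-life pipeline independently per cluster stratum.

    A stratum missing any time point is skipped with a warning.  Returns a
    dict keyed by the flag value (True = cluster-positive cells).
    """
    config = config or BootstrapConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    all_t = set(dataset["time_min"].unique())
    out: dict[bool, DecayFit] = {}
    for flag in (False, True):
        sub = dataset[dataset[flag_col] == flag]
        if set(sub["time_min"].unique()) != all_t:
            warnings.warn(f"stratum {flag_col}={flag} misses time points; skipped", stacklevel=2)
            continue
        out[bool(flag)] = estimate_half_life(sub, config, rng)
    return out


@dataclass(frozen=True)
class GrowthRateModel:
    """``log(t_half) = a*mu^2 + b*mu + c`` with natural log, mu in 1/h, t_half in min."""

    a: float
    b: float
    c: float


def evaluate_growth_model(model: GrowthRateModel, mu: float) -> float:
    """Half-life (min) predicted at growth rate ``mu`` (1/h)."""
    if mu < 0:
        raise ParameterError("growth rate must be non-negative")
    return math.exp(model.a * mu**2 + model.b * mu + model.c)


def fit_growth_model(points: list[tuple[float, float]]) -> GrowthRateModel:
    """Least-squares quadratic in mu on log(t_half); exact for 3 points."""
    if len(points) < 3:
        raise ParameterError("need at least 3 (mu, t_half) points")
    mu = np.array([p[0] for p in points], dtype=float)
    th = np.array([p[1] for p in points], dtype=float)
    if len(np.unique(mu)) < 3:
        raise ParameterError("need at least 3 distinct growth rates")
    if np.any(th <= 0):
        raise ParameterError("half-lives must be positive")
    a, b, c = np.polyfit(mu, np.log(th), 2)
    return GrowthRateModel(float(a), float(b), float(c))
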