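"""Banister fitness–fatigue impulse-response models, 1-D and 3-system.

Performance on day t is p(t) = k1·g(t) − k2·h(t), where fitness g and
fatigue h are first-order filters of the daily training load w(t):

    impulse variant:  g(t) = g(t−1)·e^(−1/τ1) + w(t)
    ewma variant:     g(t) = g(t−1)·e^(−1/τ1) + w(t)·(1 − e^(−1/τ1))

(and likewise for h with τ2). The ewma form is the chronic-training-load
(CTL) recursion of popular training platforms; its steady state under
constant load equals the load itself. Fatigue carries a larger weight
and a shorter time constant than fitness, so performance dips before it
rises and peaks some days after a training block ends.

The 3-system variant runs three independent models — one per energy
system (CP, W′, Pmax) — fed by the per-system strain scores, and maps
each performance trace into physical units via an affine scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
from scipy import optimize

__all__ = [
    "IRParams",
    "LoadSeries",
    "IRTrajectory",
    "SystemScaling",
    "ThreeSystemResult",
    "FitResult",
    "SYSTEMS",
    "DEFAULT_PARAMS",
    "simulate_banister",
    "simulate_3d",
    "ctl",
    "fit_ir_params",
]

#: Canonical order of the three energy systems.
SYSTEMS = ("cp", "w", "pmax")

Variant = Literal["impulse", "ewma"]


@dataclass(frozen=True)
class IRParams:
    """Weights and time constants of one fitness–fatigue model.

    k1/k2 are the dimensionless fitness/fatigue weights; tau1/tau2 the
    corresponding time constants in days. Platform convention, absent an
    individual fit, is τ1 = 42 d and τ2 = 7 d.
    """

    k1: float = 1.0
    k2: float = 1.5
    tau1: float = 42.0
    tau2: float = 7.0

    def __post_init__(self) -> None:
        if self.k1 < 0 or self.k2 < 0:
            raise ValueError("k1 and k2 must be non-negative")
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("tau1 and tau2 must be positive")


#: Per-system defaults when no individual fit is available.
DEFAULT_PARAMS: Mapping[str, IRParams] = {
    "cp": IRParams(),
    "w": IRParams(),
    "pmax": IRParams(),
}


@dataclass(frozen=True)
class LoadSeries:
    """Daily training loads on consecutive days.

    ``w[i]`` is the load on day ``start_day + i`` (arbitrary units,
    typically strain score). Multiple sessions on one day are summed
    before modelling; missing days are zero-load days.
    """

    w: np.ndarray
    start_day: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.w, dtype=float)
        if arr.ndim != 1:
            raise ValueError("loads must be one-dimensional")
        if arr.size and arr.min() < 0:
            raise ValueError("training loads must be non-negative")
        if not np.all(np.isfinite(arr)):
            raise ValueError("loads contain non-finite values")
        object.__setattr__(self, "w", arr)

    def __len__(self) -> int:
        return int(self.w.size)

    @property
    def days(self) -> np.ndarray:
        return self.start_day + np.arange(len(self))

    @property
    def total(self) -> float:
        return float(self.w.sum())

    @classmethod
    def from_days(cls, days, w) -> "LoadSeries":
        """Build from (day, load) pairs; gaps become zero-load days."""
        days = np.asarray(days, dtype=int)
        w = np.asarray(w, dtype=float)
        if days.size != w.size:
            raise ValueError("days and loads differ in length")
        if days.size == 0:
            return cls(w=np.empty(0))
        if np.any(np.diff(days) <= 0):
            raise ValueError("days must be strictly increasing")
        start = int(days[0])
        full = np.zeros(int(days[-1]) - start + 1)
        full[days - start] = w
        return cls(w=full, start_day=start)


@dataclass(frozen=True)
class IRTrajectory:
    """Day-indexed fitness g, fatigue h and performance p = k1·g − k2·h."""

    days: np.ndarray
    g: np.ndarray
    h: np.ndarray
    p: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"day": self.days, "g": self.g, "h": self.h, "p": self.p})


@dataclass(frozen=True)
class SystemScaling:
    """Affine map from performance arbitrary units to physical units.

    value = offset + gain · p. Default is the identity (gain 1, offset
    0), leaving values in arbitrary units; a calibrated athlete model
    supplies its own gain/offset per system (W for CP and Pmax, kJ for W′).
    """

    gain: float = 1.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")

    def apply(self, p: np.ndarray) -> np.ndarray:
        return self.offset + self.gain * np.asarray(p, dtype=float)


def _filter(w: np.ndarray, tau: float, variant: Variant, y0: float) -> np.ndarray:
    decay = math.exp(-1.0 / tau)
    gain = (1.0 - decay) if variant == "ewma" else 1.0
    out = np.empty_like(w)
    y = y0
    for i, wi in enumerate(w):
        y = y * decay + wi * gain
        out[i] = y
    return out


def simulate_banister(
    loads: LoadSeries,
    params: IRParams,
    variant: Variant = "impulse",
    g0: float = 0.0,
    h0: float = 0.0,
) -> IRTrajectory:
    """Run one fitness–fatigue model over a daily load series.

    The stimulus interval is fixed at one day. Initial conditions default
    to a fully rested, untrained state (g0 = h0 = 0).
    """
    if variant not in ("impulse", "ewma"):
        raise ValueError(f"unknown variant {variant!r}")
    g = _filter(loads.w, params.tau1, variant, g0)
    h = _filter(loads.w, params.tau2, variant, h0)
    return IRTrajectory(days=loads.days, g=g, h=h, p=params.k1 * g - params.k2 * h)


@dataclass(frozen=True)
class ThreeSystemResult:
    """Three parallel trajectories plus physically scaled outputs.

    ``scaled`` maps system → array: CP and Pmax in watts, W′ in kJ
    (identity scaling leaves arbitrary units).
    """

    trajectories: Mapping[str, IRTrajectory]
    scaled: Mapping[str, np.ndarray]


def simulate_3d(
    loads: Mapping[str, LoadSeries],
    params: Mapping[str, IRParams] | None = None,
    scaling: Mapping[str, SystemScaling] | None = None,
    variant: Variant = "impulse",
) -> ThreeSystemResult:
    """Run the three independent per-energy-system models.

    *loads* must provide series for 'cp', 'w' and 'pmax' covering the
    same day range. Each system evolves with its own parameters; no
    cross-talk between systems.
    """
    params = dict(DEFAULT_PARAMS) if params is None else params
    scaling = scaling or {}
    missing = [s for s in SYSTEMS if s not in loads]
    if missing:
        raise ValueError(f"missing load series for systems: {missing}")
    ranges = {
        s: (loads[s].start_day, loads[s].start_day + len(loads[s])) for s in SYSTEMS
    }
    if len(set(ranges.values())) != 1:
        raise ValueError(f"day ranges differ across systems: {ranges}")
    trajectories = {
        s: simulate_banister(loads[s], params[s], variant) for s in SYSTEMS
    }
    scaled = {
        s: scaling.get(s, SystemScaling()).apply(trajectories[s].p) for s in SYSTEMS
    }
    return ThreeSystemResult(trajectories=trajectories, scaled=scaled)


def ctl(loads: LoadSeries, tau1: float = 42.0) -> np.ndarray:
    """Chronic training load: the EWMA fitness recursion.

    CTL(t) = CTL(t−1)·e^(−1/τ1) + w(t)·(1 − e^(−1/τ1)); under constant
    load it converges to the load itself.
    """
    if tau1 <= 0:
        raise ValueError("tau1 must be positive")
    return _filter(loads.w, tau1, "ewma", 0.0)


@dataclass(frozen=True)
class FitResult:
    """Fitted parameters plus diagnostics."""

    params: IRParams
    rmse: float
    sse: float
    n_obs: int
    identifiable: bool
    message: str = ""


def _obs_design(
    loads: LoadSeries, obs_idx: np.ndarray, taus: np.ndarray, variant: Variant
) -> np.ndarray:
    """Filter responses at observation indices for a grid of time constants."""
    out = np.empty((taus.size, obs_idx.size))
    for j, tau in enumerate(taus):
        out[j] = _filter(loads.w, tau, variant, 0.0)[obs_idx]
    return out


def _solve_weights(g: np.ndarray, h: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Non-negative least squares for (k1, k2) in y ≈ k1·g − k2·h."""
    a = np.column_stack([g, -h])
    coef, _ = optimize.nnls(a, y)
    resid = y - a @ coef
    return float(coef[0]), float(coef[1]), float(resid @ resid)


def fit_ir_params(
    loads: LoadSeries,
    obs_days: np.ndarray,
    obs_p: np.ndarray,
    variant: Variant = "impulse",
    tau_bounds: tuple[float, float] = (1.0, 100.0),
    k_max: float = 1e4,
) -> FitResult:
    """Least-squares fit of (k1, k2, τ1, τ2) to sparse performance data.

    A coarse grid at 1-day resolution over (τ1, τ2) — with the optimal
    non-negative (k1, k2) solved in closed form at each node — seeds a
    Nelder–Mead refinement of the time constants. Deterministic given
    the inputs. At least 4 observations are required (4 free
    parameters); constant observations under constant load are flagged
    as unidentifiable.
    """
    obs_days = np.asarray(obs_days, dtype=int)
    obs_p = np.asarray(obs_p, dtype=float)
    if obs_days.size != obs_p.size:
        raise ValueError("observation days and values differ in length")
    if obs_days.size < 4:
        raise ValueError(
            f"need at least 4 observations to fit 4 parameters, got {obs_days.size}"
        )
    obs_idx = obs_days - loads.start_day
    if obs_idx.min() < 0 or obs_idx.max() >= len(loads):
        raise ValueError("observation days fall outside the load series")

    identifiable = True
    message = ""
    if np.ptp(obs_p) == 0 and np.ptp(loads.w) == 0:
        identifiable = False
        message = "constant observations under constant load: parameters not identifiable"

    lo, hi = tau_bounds
    if lo < 1:
        raise ValueError("tau lower bound must be at least 1 day")
    taus = np.arange(math.ceil(lo), math.floor(hi) + 1, dtype=float)
    g_grid = _obs_design(loads, obs_idx, taus, variant)
    h_grid = g_grid  # same filter family; rows indexed by tau

    best = (np.inf, 0.0, 0.0, taus[0], taus[0])
    for i1 in range(taus.size):
        g = g_grid[i1]
        for i2 in range(taus.size):
            k1, k2, sse = _solve_weights(g, h_grid[i2], obs_p)
            if sse < best[0]:
                best = (sse, k1, k2, taus[i1], taus[i2])

    def objective(x: np.ndarray) -> float:
        t1 = min(max(x[0], lo), hi)
        t2 = min(max(x[1], lo), hi)
        g = _filter(loads.w, t1, variant, 0.0)[obs_idx]
        h = _filter(loads.w, t2, variant, 0.0)[obs_idx]
        return _solve_weights(g, h, obs_p)[2]

    res = optimize.minimize(
        objective,
        x0=np.array([best[3], best[4]]),
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-12, "maxiter": 400},
    )
    t1 = float(min(max(res.x[0], lo), hi))
    t2 = float(min(max(res.x[1], lo), hi))
    g = _filter(loads.w, t1, variant, 0.0)[obs_idx]
    h = _filter(loads.w, t2, variant, 0.0)[obs_idx]
    k1, k2, sse = _solve_weights(g, h, obs_p)
    if sse > best[0]:  # refinement must never lose to the grid
        sse, k1, k2, t1, t2 = best
    k1 = min(k1, k_max)
    k2 = min(k2, k_max)
    return FitResult(
        params=IRParams(k1=k1, k2=k2, tau1=t1, tau2=t2),
        rmse=math.sqrt(sse / obs_p.size),
        sse=sse,
        n_obs=int(obs_p.size),
        identifiable=identifiable,
        message=message,
    )
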