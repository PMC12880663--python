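"""Synthetic workout and training-history generators.

Emulates the session shapes the model is designed for — steady efforts,
on/off interval sets, stochastic rides — and multi-week training
histories (constant, variable block-periodized, or volume-to-intensity
periodized), so analyses and tests run without any recorded data.
All stochastic output is reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .impulse import IRParams, LoadSeries, SYSTEMS, simulate_banister
from .power_duration import PowerSeries

__all__ = [
    "WorkoutSpec",
    "TrainingHistory",
    "SYSTEM_SHARES",
    "gen_steady",
    "gen_intervals",
    "gen_training_history",
    "gen_observed_performance",
]

#: Default share of a total daily load attributed to each energy system,
#: mirroring the 80/18/2 CP/W'/Pmax daily loads of the reference
#: three-system simulation.
SYSTEM_SHARES: Mapping[str, float] = {"cp": 0.80, "w": 0.18, "pmax": 0.02}


@dataclass(frozen=True)
class WorkoutSpec:
    """A workout as ordered (power [W], duration [s]) segments.

    Optional Gaussian jitter (std ``jitter_sigma`` W, truncated at 0 W)
    makes rides stochastic; a fixed ``seed`` makes them reproducible.
    """

    segments: Sequence[tuple[float, float]]
    jitter_sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for p, d in self.segments:
            if d <= 0:
                raise ValueError(f"segment duration must be positive, got {d}")
            if p < 0:
                raise ValueError(f"segment power must be non-negative, got {p}")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be non-negative")

    def to_series(self, dt: float = 1.0) -> PowerSeries:
        parts = [
            np.full(max(int(round(d / dt)), 1), float(p)) for p, d in self.segments
        ]
        power = np.concatenate(parts) if parts else np.empty(0)
        if self.jitter_sigma > 0:
            rng = np.random.default_rng(self.seed)
            power = np.maximum(power + rng.normal(0.0, self.jitter_sigma, power.size), 0.0)
        return PowerSeries(power=power, dt=dt)


def gen_steady(p: float, duration: float, dt: float = 1.0) -> PowerSeries:
    """Constant-power effort: *duration* seconds at *p* watts, 1 Hz default."""
    return WorkoutSpec(segments=[(p, duration)]).to_series(dt)


def gen_intervals(
    p_on: float,
    t_on: float,
    p_off: float,
    t_off: float | None,
    reps: int,
    dt: float = 1.0,
) -> PowerSeries:
    """On/off interval session: *reps* × (t_on at p_on / t_off at p_off).

    ``t_off`` of 0 (or None with reps=1) degenerates to a steady effort.
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    if t_on <= 0:
        raise ValueError("t_on must be positive")
    segments: list[tuple[float, float]] = []
    for _ in range(reps):
        segments.append((p_on, t_on))
        if t_off:
            segments.append((p_off, t_off))
    return WorkoutSpec(segments=segments).to_series(dt)


@dataclass(frozen=True)
class TrainingHistory:
    """Per-system daily load series with a convenience total."""

    loads: Mapping[str, LoadSeries]

    @property
    def total(self) -> LoadSeries:
        w = sum(self.loads[s].w for s in SYSTEMS)
        return LoadSeries(w=w, start_day=self.loads["cp"].start_day)


# Length and composition of one build/recover training block [days].
_BLOCK = 14
_BUILD_DAYS = 11
_RECOVER_FRACTION = 0.25


def _variable_pattern(n_days: int, mean_load: float, rng: np.random.Generator) -> np.ndarray:
    """Build/recover blocks with jittered build days, exact total preserved.

    Blocks are aligned to the *end* of the program so it finishes on a
    recovery phase (the usual pre-peak arrangement); the schedule is
    rescaled so its sum equals n_days·mean_load exactly.
    """
    w = np.empty(n_days)
    # day's position within its block, counted back from the final day
    back = np.arange(n_days - 1, -1, -1) % _BLOCK
    recover = back < (_BLOCK - _BUILD_DAYS)
    w[~recover] = 1.0 + rng.uniform(-0.2, 0.2, int((~recover).sum()))
    w[recover] = _RECOVER_FRACTION
    target = n_days * mean_load
    return w * (target / w.sum())


def _periodized_shares(n_days: int) -> np.ndarray:
    """Per-day (cp, w, pmax) shares drifting from volume to intensity.

    The aerobic share falls linearly from 0.95 to 0.65 across the
    program while the glycolytic and alactic shares grow in a 9:1 ratio.
    Rows sum to 1.
    """
    t = np.linspace(0.0, 1.0, n_days) if n_days > 1 else np.zeros(1)
    cp = 0.95 - 0.30 * t
    rest = 1.0 - cp
    return np.column_stack([cp, 0.9 * rest, 0.1 * rest])


def gen_training_history(
    n_days: int,
    schedule: str = "constant",
    mean_load: float = 50.0,
    seed: int | None = None,
) -> TrainingHistory:
    """Generate a per-system daily training-load history.

    ``constant``: every day equals *mean_load*. ``variable``: seeded
    build/recover blocks with exactly the same total load as the
    constant schedule. ``periodized``: constant daily total whose
    per-system split drifts from volume-early to intensity-late.
    The daily total is split across systems by :data:`SYSTEM_SHARES`
    except under ``periodized``, which uses its own drifting shares.
    """
    if n_days < 1:
        raise ValueError("n_days must be at least 1")
    if mean_load < 0:
        raise ValueError("mean_load must be non-negative")
    if schedule == "constant":
        total = np.full(n_days, float(mean_load))
    elif schedule == "variable":
        rng = np.random.default_rng(seed)
        total = _variable_pattern(n_days, mean_load, rng)
    elif schedule == "periodized":
        total = np.full(n_days, float(mean_load))
    else:
        raise ValueError(f"unknown schedule {schedule!r}")

    if schedule == "periodized":
        shares = _periodized_shares(n_days)
        loads = {
            s: LoadSeries(w=total * shares[:, i]) for i, s in enumerate(SYSTEMS)
        }
    else:
        loads = {s: LoadSeries(w=total * SYSTEM_SHARES[s]) for s in SYSTEMS}
    return TrainingHistory(loads=loads)


def gen_observed_performance(
    loads: LoadSeries,
    true_params: IRParams,
    obs_days: Sequence[int] | np.ndarray,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    variant: str = "impulse",
) -> tuple[np.ndarray, np.ndarray]:
    """Model performance sampled on *obs_days*, plus seeded Gaussian noise.

    Ground truth for parameter-recovery experiments: returns
    ``(days, values)`` where values are the simulated p(t) at the
    requested days with N(0, noise_sigma²) noise added.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    obs_days = np.asarray(obs_days, dtype=int)
    traj = simulate_banister(loads, true_params, variant=variant)
    idx = obs_days - loads.start_day
    if idx.size and (idx.min() < 0 or idx.max() >= len(loads)):
        raise ValueError("observation days fall outside the load series")
    values = traj.p[idx].copy()
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sigma, values.size)
    return obs_days, values
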