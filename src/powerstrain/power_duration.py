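"""Three-parameter critical-power model: power-duration curve, W' balance, MPA.

The model describes an athlete by three parameters:

* ``cp`` — critical power [W], the highest power with a metabolic steady
  state; the ceiling of sustainable aerobic (oxidative) energy provision.
* ``w_prime`` — W' [J], the finite work capacity available above CP,
  a proxy for glycolytic/anaerobic capacity.
* ``pmax`` — maximal instantaneous power [W] in a fatigue-free state,
  attributed to the alactic (phosphocreatine) system.

Exercising above CP draws down W'. The highest power currently producible,
the *maximum power available* (MPA), falls from Pmax toward CP as W' is
expended; for constant supra-CP efforts, task failure occurs when the
demanded power meets MPA, not when W' reaches zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "AthleteProfile",
    "PowerSeries",
    "WPrimeState",
    "ContributionSplit",
    "MpaVariant",
    "RecoveryModel",
    "SessionTrace",
    "UnboundedDurationError",
    "InfeasiblePowerError",
    "validate_profile",
    "time_to_exhaustion",
    "sustainable_power",
    "mpa",
    "fresh_state",
    "step_w_prime",
    "trace_session",
    "split_power",
]


class UnboundedDurationError(ValueError):
    """Requested power is at or below CP: sustainable indefinitely."""


class InfeasiblePowerError(ValueError):
    """Requested power exceeds what the model allows (above Pmax)."""


class MpaVariant(str, Enum):
    """How MPA declines with expended W'.

    ``linear``: MPA = Pmax − (Pmax−CP)·(W'exp/W').
    ``squared``: the depletion fraction is raised to the 2nd power, which
    keeps MPA high until W' is mostly spent (used for interval-session
    illustration; linear is the default).
    """

    LINEAR = "linear"
    SQUARED = "squared"


class RecoveryModel(str, Enum):
    """W' balance behaviour below CP.

    ``none``: no recovery; W'exp only ever grows (classic integral model).
    ``skiba_differential``: dW'bal/dt = (CP − P)·(W' − W'bal)/W', an
    exponential approach to full recovery whose rate scales with the gap
    below CP.
    """

    NONE = "none"
    SKIBA = "skiba_differential"


@dataclass(frozen=True)
class AthleteProfile:
    """An athlete's power-duration signature.

    Parameters
    ----------
    cp : float
        Critical power [W], > 0.
    w_prime : float
        Work capacity above CP [J], > 0.
    pmax : float
        Maximal fatigue-free power [W], must exceed ``cp``.
    ftp : float, optional
        Functional threshold power [W] used for TSS; defaults to ``cp``
        (FTP and CP assumed equal when unspecified).
    """

    cp: float
    w_prime: float
    pmax: float
    ftp: float | None = None

    def __post_init__(self) -> None:
        if not (self.cp > 0 and math.isfinite(self.cp)):
            raise ValueError(f"cp must be positive and finite, got {self.cp}")
        if not (self.w_prime > 0 and math.isfinite(self.w_prime)):
            raise ValueError(f"w_prime must be positive and finite, got {self.w_prime}")
        if not (self.pmax > self.cp):
            raise ValueError(
                f"pmax ({self.pmax}) must exceed cp ({self.cp}): the 3-parameter "
                "model needs headroom above critical power"
            )
        if self.ftp is None:
            object.__setattr__(self, "ftp", float(self.cp))
        elif not (self.ftp > 0):
            raise ValueError(f"ftp must be positive, got {self.ftp}")


def validate_profile(profile: AthleteProfile) -> AthleteProfile:
    """Return *profile* unchanged if its invariants hold; raise otherwise.

    Construction already validates; this re-checks an instance that may
    have been built by other means (e.g. deserialised).
    """
    AthleteProfile(profile.cp, profile.w_prime, profile.pmax, profile.ftp)
    return profile


@dataclass(frozen=True)
class PowerSeries:
    """A uniformly sampled power recording.

    ``power`` holds non-negative watts; ``dt`` is the sampling interval in
    seconds (1 s for ordinary head-unit recordings).
    """

    power: np.ndarray
    dt: float = 1.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.power, dtype=float)
        if arr.ndim != 1:
            raise ValueError("power must be one-dimensional")
        if not np.all(np.isfinite(arr)):
            raise ValueError("power contains non-finite samples")
        if arr.size and arr.min() < 0:
            i = int(np.argmin(arr))
            raise ValueError(f"negative power {arr[i]} W at sample {i}")
        if not (self.dt > 0):
            raise ValueError(f"dt must be positive, got {self.dt}")
        object.__setattr__(self, "power", arr)

    def __len__(self) -> int:
        return int(self.power.size)

    @property
    def duration_s(self) -> float:
        """Total recording duration in seconds."""
        return float(self.power.size * self.dt)

    @property
    def work_kj(self) -> float:
        """Total mechanical work in kilojoules."""
        return float(self.power.sum() * self.dt / 1000.0)


@dataclass(frozen=True)
class WPrimeState:
    """Instantaneous W' bookkeeping: expended, remaining, resulting MPA."""

    w_exp: float
    w_bal: float
    mpa: float
    overdraw: bool = False


@dataclass(frozen=True)
class ContributionSplit:
    """Watts attributed to each energy system at one instant.

    ``p_cp`` (aerobic), ``p_w`` (glycolytic), ``p_pmax`` (alactic); the
    three sum to the input power.
    """

    p_cp: float
    p_w: float
    p_pmax: float

    @property
    def total(self) -> float:
        return self.p_cp + self.p_w + self.p_pmax


def time_to_exhaustion(profile: AthleteProfile, p: float) -> float:
    """Limit duration [s] for constant power *p* under the 3-parameter model.

    t_lim = W'/(P−CP) − W'/(Pmax−CP). Returns 0 at p = pmax.

    Raises
    ------
    UnboundedDurationError
        If p ≤ cp (sustainable indefinitely; no finite answer exists).
    InfeasiblePowerError
        If p > pmax.
    """
    if p <= profile.cp:
        raise UnboundedDurationError(
            f"power {p} W is at or below CP ({profile.cp} W); duration is unbounded"
        )
    if p > profile.pmax:
        raise InfeasiblePowerError(
            f"power {p} W exceeds Pmax ({profile.pmax} W)"
        )
    return profile.w_prime / (p - profile.cp) - profile.w_prime / (profile.pmax - profile.cp)


def sustainable_power(profile: AthleteProfile, t: float) -> float:
    """Highest constant power [W] sustainable for duration *t* seconds.

    P(t) = CP + (Pmax−CP)·W' / (W' + (Pmax−CP)·t); P(0) = Pmax and
    P → CP as t → ∞. Inverse of :func:`time_to_exhaustion` on (cp, pmax).
    """
    if t < 0:
        raise ValueError(f"duration must be non-negative, got {t}")
    span = profile.pmax - profile.cp
    return profile.cp + span * profile.w_prime / (profile.w_prime + span * t)


def mpa(
    profile: AthleteProfile,
    w_exp: float,
    variant: MpaVariant | str = MpaVariant.LINEAR,
) -> float:
    """Maximum power available [W] given expended work *w_exp* above CP.

    Linear: MPA = Pmax − (Pmax−CP)·(w_exp/W'); squared raises the
    depletion fraction to the 2nd power. Both map w_exp=0 → Pmax and
    w_exp=W' → CP.
    """
    if not (0 <= w_exp <= profile.w_prime):
        raise ValueError(
            f"w_exp={w_exp} outside [0, W'={profile.w_prime}]"
        )
    frac = w_exp / profile.w_prime
    if MpaVariant(variant) is MpaVariant.SQUARED:
        frac = frac * frac
    return profile.pmax - (profile.pmax - profile.cp) * frac


def fresh_state(
    profile: AthleteProfile, variant: MpaVariant | str = MpaVariant.LINEAR
) -> WPrimeState:
    """State of a fully recovered athlete: W'exp = 0, MPA = Pmax."""
    return WPrimeState(w_exp=0.0, w_bal=profile.w_prime, mpa=profile.pmax)


def _step_w_exp(
    profile: AthleteProfile,
    w_exp: float,
    p: float,
    dt: float,
    recovery: RecoveryModel,
) -> float:
    """Advance expended W' by one forward-Euler sample; returns new w_exp."""
    if p > profile.cp:
        w_exp = w_exp + (p - profile.cp) * dt
        if w_exp > profile.w_prime:
            w_exp = profile.w_prime
    elif recovery is RecoveryModel.SKIBA and w_exp > 0 and p < profile.cp:
        # dW'bal/dt = (CP − P)(W' − W'bal)/W'; note W' − W'bal = w_exp
        w_exp = w_exp - (profile.cp - p) * w_exp / profile.w_prime * dt
        if w_exp < 0:
            w_exp = 0.0
    return w_exp


def step_w_prime(
    profile: AthleteProfile,
    state: WPrimeState,
    p: float,
    dt: float = 1.0,
    recovery: RecoveryModel | str = RecoveryModel.NONE,
    variant: MpaVariant | str = MpaVariant.LINEAR,
) -> WPrimeState:
    """Advance the W' state by one sample of power *p* over *dt* seconds.

    Above CP, w_exp grows by (p − cp)·dt, clamped at W'. At or below CP
    the balance either stays put (``none``) or recovers along the
    differential model (``skiba_differential``). The overdraw flag marks
    samples where demanded power exceeds the entering MPA — i.e. exercise
    past the model's task-failure point (sensor spikes, or continuing a
    constant effort beyond t_lim).
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if p < 0:
        raise ValueError(f"power must be non-negative, got {p}")
    recovery = RecoveryModel(recovery)
    variant = MpaVariant(variant)
    overdraw = p > state.mpa
    w_exp = _step_w_exp(profile, state.w_exp, p, dt, recovery)
    return WPrimeState(
        w_exp=w_exp,
        w_bal=profile.w_prime - w_exp,
        mpa=mpa(profile, w_exp, variant),
        overdraw=overdraw,
    )


@dataclass(frozen=True)
class SessionTrace(Sequence):
    """Per-sample W' states for a traced session.

    Array attributes (one entry per sample, values *after* that sample's
    update): ``w_exp``, ``w_bal``, ``mpa``, ``overdraw``. ``mpa_pre``
    holds the MPA *entering* each sample, which is what strain metrics
    use. Indexing yields :class:`WPrimeState` objects.
    """

    w_exp: np.ndarray
    w_bal: np.ndarray
    mpa: np.ndarray
    mpa_pre: np.ndarray
    overdraw: np.ndarray
    dt: float

    def __len__(self) -> int:
        return int(self.w_exp.size)

    def __getitem__(self, i):
        if isinstance(i, slice):
            raise TypeError("SessionTrace does not support slicing")
        return WPrimeState(
            w_exp=float(self.w_exp[i]),
            w_bal=float(self.w_bal[i]),
            mpa=float(self.mpa[i]),
            overdraw=bool(self.overdraw[i]),
        )

    def __iter__(self) -> Iterator[WPrimeState]:
        for i in range(len(self)):
            yield self[i]

    @property
    def peak_w_exp(self) -> float:
        return float(self.w_exp.max()) if len(self) else 0.0

    @property
    def overdraw_samples(self) -> int:
        return int(self.overdraw.sum())


def trace_session(
    profile: AthleteProfile,
    series: PowerSeries,
    recovery: RecoveryModel | str = RecoveryModel.NONE,
    variant: MpaVariant | str = MpaVariant.LINEAR,
) -> SessionTrace:
    """Trace W' expenditure/recovery and MPA through a whole recording.

    Starts from a fresh state (sessions do not carry fatigue over) and
    applies :func:`step_w_prime` semantics sample by sample.
    """
    recovery = RecoveryModel(recovery)
    variant = MpaVariant(variant)
    n = len(series)
    power = series.power
    dt = series.dt
    cp, wp, pmax = profile.cp, profile.w_prime, profile.pmax
    span = pmax - cp
    squared = variant is MpaVariant.SQUARED
    skiba = recovery is RecoveryModel.SKIBA

    w_exp_arr = np.empty(n)
    mpa_arr = np.empty(n)
    mpa_pre_arr = np.empty(n)
    over_arr = np.zeros(n, dtype=bool)

    w_exp = 0.0
    mpa_now = pmax
    for i in range(n):
        p = power[i]
        mpa_pre_arr[i] = mpa_now
        if p > mpa_now:
            over_arr[i] = True
        if p > cp:
            w_exp += (p - cp) * dt
            if w_exp > wp:
                w_exp = wp
        elif skiba and w_exp > 0.0 and p < cp:
            w_exp -= (cp - p) * w_exp / wp * dt
            if w_exp < 0.0:
                w_exp = 0.0
        frac = w_exp / wp
        mpa_now = pmax - span * (frac * frac if squared else frac)
        w_exp_arr[i] = w_exp
        mpa_arr[i] = mpa_now

    return SessionTrace(
        w_exp=w_exp_arr,
        w_bal=wp - w_exp_arr,
        mpa=mpa_arr,
        mpa_pre=mpa_pre_arr,
        overdraw=over_arr,
        dt=dt,
    )


def split_power(profile: AthleteProfile, p: float) -> ContributionSplit:
    """Attribute power *p* to the three energy systems.

    At or below CP everything is aerobic. Above CP the alactic share is
    (P−CP)²/(Pmax−CP) — zero at CP, the whole supra-CP excess at Pmax —
    and the glycolytic system supplies the remainder. Components always
    sum to *p* exactly.
    """
    if p < 0:
        raise ValueError(f"power must be non-negative, got {p}")
    if p > profile.pmax:
        raise InfeasiblePowerError(
            f"power {p} W exceeds Pmax ({profile.pmax} W)"
        )
    if p <= profile.cp:
        return ContributionSplit(p_cp=float(p), p_w=0.0, p_pmax=0.0)
    excess = p - profile.cp
    p_pmax = excess * excess / (profile.pmax - profile.cp)
    return ContributionSplit(
        p_cp=float(profile.cp),
        p_w=float(excess - p_pmax),
        p_pmax=float(p_pmax),
    )
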