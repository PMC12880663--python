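"""Strain-based training load metrics, plus the legacy NP/IF/TSS comparators.

The strain coefficient expresses how close to the current performance
ceiling an athlete is working:

    k_strain = (Pmax − MPA + CP) / (Pmax − P + CP)

It equals 1 when power meets MPA (task failure) and is smallest when
fresh at low power. Strain rate SR = k_strain · P [W] is accumulated
second-by-second and normalised so that one hour at CP in a fresh state
scores exactly 100:

    SS = Σ SR · dt · (Pmax / CP²) · (100 / 3600)

The score splits into SS_CP, SS_W′ and SS_Pmax by applying the same
normalisation to the per-system power contributions, giving one training
load per energy system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .power_duration import (
    AthleteProfile,
    MpaVariant,
    PowerSeries,
    RecoveryModel,
    SessionTrace,
    split_power,
    trace_session,
)

__all__ = [
    "SessionStrain",
    "LegacyMetrics",
    "SessionReport",
    "k_strain",
    "strain_rate",
    "strain_score",
    "normalized_power",
    "intensity_factor",
    "tss",
    "session_report",
]

#: Seconds in an hour; the 100-points-per-hour-at-threshold anchor shared
#: by TSS and the strain score.
_HOUR = 3600.0


@dataclass(frozen=True)
class SessionStrain:
    """Total and per-energy-system strain scores for one session."""

    ss_total: float
    ss_cp: float
    ss_w: float
    ss_pmax: float
    work_kj: float
    duration_s: float


@dataclass(frozen=True)
class LegacyMetrics:
    """Normalized power, intensity factor and TSS for comparison."""

    np: float
    intensity_factor: float
    tss: float


@dataclass(frozen=True)
class SessionReport:
    """Everything computed for one session: strain, legacy metrics, trace summary."""

    strain: SessionStrain
    legacy: LegacyMetrics
    peak_w_exp: float
    overdraw_samples: int


def k_strain(profile: AthleteProfile, p: float, mpa: float) -> float:
    """Strain coefficient in (0, 1] for power *p* at current MPA *mpa*.

    Clamped at 1 when p exceeds mpa (exercise past the task-failure
    point, e.g. recording spikes): strain there is that of P = MPA.
    """
    if p < 0:
        raise ValueError(f"power must be non-negative, got {p}")
    if not (profile.cp <= mpa <= profile.pmax):
        raise ValueError(
            f"mpa={mpa} outside [cp={profile.cp}, pmax={profile.pmax}]"
        )
    k = (profile.pmax - mpa + profile.cp) / (profile.pmax - p + profile.cp)
    return min(k, 1.0)


def strain_rate(profile: AthleteProfile, p: float, mpa: float) -> float:
    """Strain rate SR = k_strain · P, in watts."""
    return k_strain(profile, p, mpa) * p


def _ss_norm(profile: AthleteProfile) -> float:
    # Pmax/CP^2 * 100/3600 makes a fresh hour at CP worth 100 points.
    return profile.pmax / profile.cp**2 * 100.0 / _HOUR


def strain_score(
    profile: AthleteProfile,
    series: PowerSeries,
    recovery: RecoveryModel | str = RecoveryModel.NONE,
    variant: MpaVariant | str = MpaVariant.LINEAR,
    trace: SessionTrace | None = None,
) -> SessionStrain:
    """Accumulate total and per-system strain scores over a recording.

    Each sample's strain uses the MPA *entering* that sample (a fresh
    1-s sprint at Pmax scores with MPA = Pmax). Per-system scores apply
    the sample's k_strain to the watts attributed to each system; they
    sum to the total by construction. Power above Pmax is clamped to
    Pmax for the split (k_strain is already 1 there).

    A pre-computed *trace* may be passed to avoid re-tracing.
    """
    if trace is None:
        trace = trace_session(profile, series, recovery, variant)
    n = len(series)
    if n == 0:
        return SessionStrain(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

    cp, pmax = profile.cp, profile.pmax
    span = pmax - cp
    p = np.minimum(series.power, pmax)
    k = (pmax - trace.mpa_pre + cp) / (pmax - p + cp)
    np.minimum(k, 1.0, out=k)

    p_cp = np.minimum(p, cp)
    excess = np.maximum(p - cp, 0.0)
    p_pmax = excess * excess / span
    p_w = excess - p_pmax

    norm = _ss_norm(profile) * series.dt
    ss_cp = float(np.dot(k, p_cp) * norm)
    ss_w = float(np.dot(k, p_w) * norm)
    ss_pmax = float(np.dot(k, p_pmax) * norm)
    return SessionStrain(
        ss_total=ss_cp + ss_w + ss_pmax,
        ss_cp=ss_cp,
        ss_w=ss_w,
        ss_pmax=ss_pmax,
        work_kj=series.work_kj,
        duration_s=series.duration_s,
    )


def normalized_power(series: PowerSeries, window_s: float = 30.0) -> float:
    """Normalized power: fourth-power mean of the 30-s rolling average.

    Uses a simple (unweighted) trailing moving average over full windows
    only — the standard dialect of the algorithm.
    """
    window = int(round(window_s / series.dt))
    if window < 1:
        raise ValueError("window shorter than one sample")
    if len(series) < window:
        raise ValueError(
            f"series of {series.duration_s:.0f} s is shorter than the "
            f"{window_s:.0f}-s rolling window"
        )
    rolled = np.convolve(series.power, np.full(window, 1.0 / window), mode="valid")
    return float(np.mean(rolled**4) ** 0.25)


def intensity_factor(series: PowerSeries, ftp: float) -> float:
    """IF = NP / FTP."""
    if ftp <= 0:
        raise ValueError(f"ftp must be positive, got {ftp}")
    return normalized_power(series) / ftp


def tss(series: PowerSeries, ftp: float) -> float:
    """Training stress score: t·NP·IF/FTP · 100/3600; one hour at FTP = 100."""
    if ftp <= 0:
        raise ValueError(f"ftp must be positive, got {ftp}")
    np_ = normalized_power(series)
    if_ = np_ / ftp
    return series.duration_s * np_ * if_ / ftp * 100.0 / _HOUR


def session_report(
    profile: AthleteProfile,
    series: PowerSeries,
    recovery: RecoveryModel | str = RecoveryModel.NONE,
    variant: MpaVariant | str = MpaVariant.LINEAR,
) -> SessionReport:
    """Full per-session bundle: strain scores, NP/IF/TSS, trace summary.

    For sessions shorter than the 30-s NP window the legacy metrics are
    reported as zero (NP undefined); strain scores are always computed.
    """
    trace = trace_session(profile, series, recovery, variant)
    strain = strain_score(profile, series, recovery, variant, trace=trace)
    try:
        np_ = normalized_power(series)
        if_ = np_ / profile.ftp
        tss_ = series.duration_s * np_ * if_ / profile.ftp * 100.0 / _HOUR
    except ValueError:
        np_, if_, tss_ = 0.0, 0.0, 0.0
    return SessionReport(
        strain=strain,
        legacy=LegacyMetrics(np=np_, intensity_factor=if_, tss=tss_),
        peak_w_exp=trace.peak_w_exp,
        overdraw_samples=trace.overdraw_samples,
    )
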