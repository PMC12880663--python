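"""Readers and writers for the package's plain-text interchange formats.

Formats (all comma-separated, UTF-8, ``.`` decimal, ISO-8601 dates):

* power recording — CSV with header ``time_s,power_w``; seconds monotone
  non-decreasing, gaps filled with zero-power samples (warning logged);
* athlete profile — YAML or JSON with keys ``cp_w``, ``w_prime_j``,
  ``pmax_w`` and optional ``ftp_w``;
* daily loads — CSV ``date,ss_cp,ss_w,ss_pmax``;
* session report — JSON; PMC — CSV with one row per day per system.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .impulse import IRTrajectory, LoadSeries, SYSTEMS
from .power_duration import AthleteProfile, PowerSeries, validate_profile
from .strain import SessionReport

__all__ = [
    "read_power_csv",
    "write_power_csv",
    "read_profile",
    "read_loads_csv",
    "write_loads_csv",
    "write_report",
    "read_report",
    "write_pmc",
    "read_pmc",
]

logger = logging.getLogger(__name__)


def read_power_csv(path: str | Path) -> PowerSeries:
    """Read a 1-Hz power recording; fill time gaps with zero-power samples.

    Rejects missing/incorrect headers, negative power (naming the
    offending row) and non-monotone timestamps.
    """
    path = Path(path)
    df = pd.read_csv(path)
    expected = ["time_s", "power_w"]
    if list(df.columns[:2]) != expected:
        raise ValueError(
            f"{path}: expected header {','.join(expected)}, got {','.join(df.columns)}"
        )
    if df[expected].isna().any().any():
        row = int(df[expected].isna().any(axis=1).idxmax())
        raise ValueError(f"{path}: malformed row {row + 2}")
    t = df["time_s"].to_numpy(dtype=float)
    p = df["power_w"].to_numpy(dtype=float)
    if p.size == 0:
        return PowerSeries(power=np.empty(0))
    neg = np.flatnonzero(p < 0)
    if neg.size:
        raise ValueError(
            f"{path}: negative power {p[neg[0]]} W at row {neg[0] + 2}"
        )
    if np.any(np.diff(t) < 0):
        raise ValueError(f"{path}: time_s is not monotone non-decreasing")

    t_idx = np.round(t - t[0]).astype(int)
    n = t_idx[-1] + 1
    power = np.zeros(n)
    power[t_idx] = p
    n_gap = n - t_idx.size
    if n_gap > 0:
        logger.warning(
            "%s: %d missing sample(s) filled with zero power", path, n_gap
        )
    return PowerSeries(power=power, dt=1.0)


def write_power_csv(path: str | Path, series: PowerSeries) -> None:
    """Write a recording in the ``time_s,power_w`` format (1-s timestamps)."""
    t = np.arange(len(series)) * series.dt
    pd.DataFrame({"time_s": t, "power_w": series.power}).to_csv(path, index=False)


def read_profile(path: str | Path) -> AthleteProfile:
    """Load and validate an athlete profile from YAML or JSON."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)  # YAML is a JSON superset
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of profile keys")
    required = ["cp_w", "w_prime_j", "pmax_w"]
    missing = [k for k in required if k not in data]
    if missing:
        raise ValueError(f"{path}: missing required key(s): {', '.join(missing)}")
    profile = AthleteProfile(
        cp=float(data["cp_w"]),
        w_prime=float(data["w_prime_j"]),
        pmax=float(data["pmax_w"]),
        ftp=float(data["ftp_w"]) if data.get("ftp_w") is not None else None,
    )
    return validate_profile(profile)


def read_loads_csv(path: str | Path) -> Mapping[str, LoadSeries]:
    """Read per-system daily loads (``date,ss_cp,ss_w,ss_pmax``).

    Dates are ISO-8601; missing calendar days become zero-load days.
    Day 0 is the first date in the file.
    """
    path = Path(path)
    df = pd.read_csv(path)
    cols = ["date", "ss_cp", "ss_w", "ss_pmax"]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s): {', '.join(missing)}")
    dates = pd.to_datetime(df["date"])
    days = (dates - dates.iloc[0]).dt.days.to_numpy()
    out = {}
    for sys_name, col in zip(SYSTEMS, ["ss_cp", "ss_w", "ss_pmax"]):
        out[sys_name] = LoadSeries.from_days(days, df[col].to_numpy(dtype=float))
    return out


def write_loads_csv(
    path: str | Path,
    loads: Mapping[str, LoadSeries],
    start_date: str = "2024-01-01",
) -> None:
    """Write per-system daily loads with ISO dates starting at *start_date*."""
    n = len(loads["cp"])
    dates = pd.date_range(start_date, periods=n, freq="D").strftime("%Y-%m-%d")
    pd.DataFrame(
        {
            "date": dates,
            "ss_cp": loads["cp"].w,
            "ss_w": loads["w"].w,
            "ss_pmax": loads["pmax"].w,
        }
    ).to_csv(path, index=False)


def write_report(path: str | Path, report: SessionReport) -> None:
    """Write a session report as JSON (documented flat schema)."""
    payload = {
        "ss_total": report.strain.ss_total,
        "ss_cp": report.strain.ss_cp,
        "ss_w": report.strain.ss_w,
        "ss_pmax": report.strain.ss_pmax,
        "work_kj": report.strain.work_kj,
        "duration_s": report.strain.duration_s,
        "np": report.legacy.np,
        "if": report.legacy.intensity_factor,
        "tss": report.legacy.tss,
        "peak_w_exp": report.peak_w_exp,
        "overdraw_samples": report.overdraw_samples,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_report(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def write_pmc(
    path: str | Path,
    trajectories: Mapping[str, IRTrajectory],
    start_date: str = "2024-01-01",
) -> None:
    """Write a performance-management chart: one row per day per system."""
    frames = []
    for sys_name, traj in trajectories.items():
        dates = pd.to_datetime(start_date) + pd.to_timedelta(
            traj.days - traj.days[0], unit="D"
        )
        frames.append(
            pd.DataFrame(
                {
                    "date": dates.strftime("%Y-%m-%d"),
                    "system": sys_name,
                    "g": traj.g,
                    "h": traj.h,
                    "p": traj.p,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_pmc(path: str | Path) -> Mapping[str, IRTrajectory]:
    """Read a PMC CSV back into per-system trajectories."""
    df = pd.read_csv(path)
    out = {}
    for sys_name, grp in df.groupby("system", sort=False):
        dates = pd.to_datetime(grp["date"])
        days = (dates - dates.iloc[0]).dt.days.to_numpy()
        out[sys_name] = IRTrajectory(
            days=days,
            g=grp["g"].to_numpy(dtype=float),
            h=grp["h"].to_numpy(dtype=float),
            p=grp["p"].to_numpy(dtype=float),
        )
    return out
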