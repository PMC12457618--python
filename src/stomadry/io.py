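"""File formats: series CSV, trajectory CSV, trace-pair text, fit JSON.

All formats are plain text.  A drying series is a CSV with columns
``time_h, water_wt_pct, light, plant_id, genotype``; THz pulses are
two-column delimited text files (time_ps, amplitude) paired by the filename
convention ``<id>_sample.txt`` / ``<id>_ref.txt``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import FitResult
from .model import Trajectory
from .series import WaterContentSeries
from .thz import TimeTrace

__all__ = [
    "load_series",
    "save_series",
    "save_trajectory",
    "load_trace",
    "save_trace",
    "load_trace_pair",
    "fit_result_to_dict",
    "save_fit_result",
    "load_fit_summary",
]

logger = logging.getLogger(__name__)

SERIES_COLUMNS = ("time_h", "water_wt_pct", "light", "plant_id", "genotype")


def load_series(path: str | Path, sort: bool = False) -> WaterContentSeries:
    """Read a water-content series CSV, validating the schema.

    ``sort=True`` sorts shuffled rows by time instead of rejecting them.
    Cadence irregularities are logged, not fatal.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in SERIES_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing columns {missing}")
    light_num = pd.to_numeric(df["light"], errors="coerce")
    bad = light_num.isna() | ~light_num.isin([0, 1])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"{path.name}: malformed light flag {df['light'].iloc[row]!r} "
            f"at data row {row}")
    df["light"] = light_num.astype(int)
    if sort:
        df = df.sort_values("time_h", kind="stable")
    t = df["time_h"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path.name}: time_h not strictly increasing "
                         "(pass sort=True to sort rows)")
    dt = np.diff(t)
    if dt.size and (dt.max() - dt.min()) > 1e-6:
        logger.info("%s: irregular cadence (%.3f-%.3f h)", path.name,
                    dt.min(), dt.max())
    return WaterContentSeries(
        times_h=t,
        water_wt_pct=df["water_wt_pct"].to_numpy(dtype=float),
        light=df["light"].to_numpy(dtype=bool),
        plant_id=str(df["plant_id"].iloc[0]) if "plant_id" in df else path.stem,
        genotype=str(df["genotype"].iloc[0]) if "genotype" in df else "unknown",
    )


def save_series(series: WaterContentSeries, path: str | Path) -> None:
    df = pd.DataFrame({
        "time_h": series.times_h,
        "water_wt_pct": series.water_wt_pct,
        "light": series.light.astype(int),
        "plant_id": series.plant_id,
        "genotype": series.genotype,
    })
    df.to_csv(path, index=False)


def save_trajectory(traj: Trajectory, path: str | Path) -> None:
    cols = {
        "time_h": traj.times_h,
        "a_l": traj.a_l,
        "a_s": traj.a_s,
        "light": traj.light.astype(int),
        "k1": traj.k1_t,
        "k2": traj.k2_t,
    }
    if traj.water_wt_pct is not None:
        cols["water_wt_pct"] = traj.water_wt_pct
    pd.DataFrame(cols).to_csv(path, index=False)


def save_trace(trace: TimeTrace, path: str | Path) -> None:
    np.savetxt(path, np.column_stack([trace.times_ps, trace.field]),
               fmt="%.9g", header="time_ps amplitude")


def load_trace(path: str | Path) -> TimeTrace:
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError(f"{Path(path).name}: expected two columns "
                         "(time_ps, amplitude)")
    return TimeTrace(data[:, 0], data[:, 1])


def load_trace_pair(sample_path: str | Path) -> tuple[TimeTrace, TimeTrace]:
    """Load ``<id>_sample.txt`` and its sibling ``<id>_ref.txt``."""
    sample_path = Path(sample_path)
    if not sample_path.name.endswith("_sample.txt"):
        raise ValueError("sample file must be named <id>_sample.txt")
    ref_path = sample_path.with_name(
        sample_path.name.replace("_sample.txt", "_ref.txt"))
    if not ref_path.exists():
        raise FileNotFoundError(f"missing reference trace {ref_path.name}")
    return load_trace(sample_path), load_trace(ref_path)


def fit_result_to_dict(fr: FitResult) -> dict:
    p = dataclasses.asdict(fr.params)
    return {
        "plant_id": fr.plant_id,
        "genotype": fr.genotype,
        "params": p,
        "stderr": {k: (None if v is None else float(v))
                   for k, v in fr.stderr.items()},
        "r_squared": fr.r_squared,
        "t_half_h": fr.t_half_h,
        "t_half_stderr_h": fr.t_half_stderr_h,
        "converged": fr.converged,
        "objective": fr.objective,
        "n_starts": fr.n_starts,
    }


def save_fit_result(fr: FitResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(fit_result_to_dict(fr), indent=2))


def load_fit_summary(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
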