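"""Reduction of measured cell-tip trajectories to lumped parameters.

A stretching experiment records the cell-tip position over time while
the drive voltage is switched on and off in cycles.  This module loads
such trajectories from delimited text, extracts the steady-state plateau
elongation of each record, summarizes on/off cycles (peak elongation,
recovery fraction, peak drop), and feeds the reduced ``(L*, V, R, d, w)``
tuples into the lumped-model fit of ``S`` per cell and per cell type.

A seeded synthetic generator stands in for the study's video data: it
emulates the experimental design (by default three cell types, sixteen
cells per condition, a 3 x 3 grid of electrode widths and gaps at fixed
drive) with single-exponential saturating kinetics, lognormal
cell-to-cell scatter of the lumped parameter and additive tracking
noise.  Kinetics never enter the fitted quantities; only plateaus do.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .lumped_model import GammaTable, LumpedFit, fit_S, interpolate_gamma

TRAJECTORY_COLUMNS = [
    "cell_id",
    "type",
    "t_s",
    "elong_um",
    "V_pp",
    "freq_hz",
    "w_um",
    "d_um",
    "R_um",
    "phase",
]


class TrajectorySchemaError(ValueError):
    """Trajectory file violates the documented column/monotonicity schema."""


@dataclass
class Trajectory:
    """One cell's tip-elongation record with its experimental condition."""

    cell_id: str
    cell_type: str
    t_s: np.ndarray
    elong_um: np.ndarray
    v_pp: float
    freq_hz: float
    w_um: float
    d_um: float
    r_um: float
    phase: np.ndarray | None = None  # "on"/"off" per sample

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t_s) <= 0):
            raise TrajectorySchemaError(
                f"cell {self.cell_id}: time must be strictly increasing"
            )
        if not np.all(np.isfinite(self.elong_um)):
            raise TrajectorySchemaError(f"cell {self.cell_id}: non-finite elongation")


@dataclass(frozen=True)
class PlateauResult:
    """Steady-state elongation of one trajectory (plateau in um, L*, convergence flag)."""

    l_plateau_um: float
    lstar: float
    converged: bool


@dataclass(frozen=True)
class CyclesSummary:
    """Per-cycle peaks, recovery fractions over off-intervals, and peak drop."""

    peaks_um: np.ndarray
    recovery_fraction: np.ndarray  # clipped to [0, 1]
    peak_drop_fraction: float  # (first peak - last peak)/first peak


def load_trajectories(path: str | Path) -> list[Trajectory]:
    """Load trajectories from delimited text with the documented columns.

    Rows with unparseable numeric fields are rejected with their line
    numbers; a missing mandatory column raises a schema error.
    """
    df = pd.read_csv(path)
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise TrajectorySchemaError(f"missing mandatory columns: {sorted(missing)}")
    numeric = ["t_s", "elong_um", "V_pp", "freq_hz", "w_um", "d_um", "R_um"]
    coerced = df[numeric].apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna().any(axis=1)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        raise TrajectorySchemaError(f"malformed numeric fields at lines {lines}")
    df[numeric] = coerced
    out = []
    for cid, grp in df.groupby("cell_id", sort=True):
        grp = grp.reset_index(drop=True)
        out.append(
            Trajectory(
                cell_id=str(cid),
                cell_type=str(grp["type"].iloc[0]),
                t_s=grp["t_s"].to_numpy(),
                elong_um=grp["elong_um"].to_numpy(),
                v_pp=float(grp["V_pp"].iloc[0]),
                freq_hz=float(grp["freq_hz"].iloc[0]),
                w_um=float(grp["w_um"].iloc[0]),
                d_um=float(grp["d_um"].iloc[0]),
                r_um=float(grp["R_um"].iloc[0]),
                phase=grp["phase"].to_numpy(dtype=object),
            )
        )
    return out


def steady_state_elongation(
    traj: Trajectory, window_s: float = 10.0, tol: float = 0.02
) -> PlateauResult:
    """Trailing-window plateau of the on-phase elongation.

    The plateau is the mean over the trailing ``window_s`` of the record
    (restricted to the voltage-on phase when annotated); it counts as
    converged when the fitted slope over that window, extrapolated across
    the window, stays below ``tol`` of the plateau.  A non-converged
    record is flagged, not raised.
    """
    t, y = traj.t_s, traj.elong_um
    if traj.phase is not None:
        on = np.asarray([p == "on" for p in traj.phase])
        if on.any():
            # first contiguous on-interval
            start = int(np.argmax(on))
            stop = start
            while stop < len(on) and on[stop]:
                stop += 1
            t, y = t[start:stop], y[start:stop]
    if t[-1] - t[0] < window_s:
        raise ValueError(
            f"trajectory spans {t[-1] - t[0]:.1f} s < window {window_s} s"
        )
    sel = t >= t[-1] - window_s
    tw, yw = t[sel], y[sel]
    plateau = float(yw.mean())
    slope = float(np.polyfit(tw, yw, 1)[0])
    converged = bool(abs(slope) * window_s <= tol * max(abs(plateau), 1e-300))
    return PlateauResult(
        l_plateau_um=plateau,
        lstar=plateau / traj.r_um,
        converged=converged,
    )


def cycle_summary(traj: Trajectory) -> CyclesSummary:
    """Peak elongation per on-interval and recovery per following off-interval.

    Recovery is ``1 - residual/peak`` with the residual taken at the end
    of the off-interval, clipped to [0, 1]; the peak drop is the relative
    decline from the first to the last cycle's peak.
    """
    if traj.phase is None:
        raise ValueError("trajectory has no on/off phase annotations")
    phase = np.asarray([str(p) for p in traj.phase])
    if not (phase == "on").any():
        raise ValueError("no 'on' interval annotated")
    # contiguous runs of equal phase
    change = np.flatnonzero(phase[1:] != phase[:-1]) + 1
    bounds = np.concatenate([[0], change, [len(phase)]])
    peaks, recoveries = [], []
    last_peak = np.nan
    for a, b in zip(bounds[:-1], bounds[1:]):
        seg = traj.elong_um[a:b]
        if phase[a] == "on":
            last_peak = float(seg.max())
            peaks.append(last_peak)
        elif np.isfinite(last_peak) and last_peak != 0:
            residual = float(seg[-1])
            recoveries.append(float(np.clip(1.0 - residual / last_peak, 0.0, 1.0)))
    peaks_arr = np.asarray(peaks)
    drop = 0.0
    if len(peaks_arr) >= 2 and peaks_arr[0] != 0:
        drop = float((peaks_arr[0] - peaks_arr[-1]) / peaks_arr[0])
    return CyclesSummary(
        peaks_um=peaks_arr,
        recovery_fraction=np.asarray(recoveries),
        peak_drop_fraction=drop,
    )


def reduce_trajectories(
    trajectories: list[Trajectory], window_s: float = 10.0, tol: float = 0.02
) -> pd.DataFrame:
    """Reduce trajectories to one (L*, condition) row each, keeping flags."""
    rows = []
    for traj in trajectories:
        res = steady_state_elongation(traj, window_s, tol)
        rows.append(
            {
                "cell_id": traj.cell_id,
                "type": traj.cell_type,
                "Lstar": res.lstar,
                "V_pp": traj.v_pp,
                "R_um": traj.r_um,
                "d_um": traj.d_um,
                "w_um": traj.w_um,
                "converged": res.converged,
            }
        )
    return pd.DataFrame(rows)


def estimate_S(
    trajectories: list[Trajectory],
    gamma_table: GammaTable,
    *,
    per_type: bool = True,
    window_s: float = 10.0,
    tol: float = 0.02,
) -> pd.DataFrame | LumpedFit:
    """Lumped parameter from trajectories: pooled fit per cell type (default).

    Each trajectory is reduced to its plateau L* and fitted with
    ``lumped_model.fit_S``.  With ``per_type=True`` returns a table with
    one row per cell type (pooled S, standard error, per-cell mean and
    SE); single-cell types get a NaN standard error rather than a value.
    """
    reduced = reduce_trajectories(trajectories, window_s, tol)
    if not per_type:
        return fit_S(reduced, gamma_table)
    rows = []
    for cell_type, grp in reduced.groupby("type", sort=True):
        fit = fit_S(grp, gamma_table)
        per_cell_s = fit.per_cell["S"].to_numpy() if fit.per_cell is not None else None
        rows.append(
            {
                "type": cell_type,
                "S": fit.s,
                "stderr": fit.stderr,
                "n_cells": fit.n_cells,
                "n_points": fit.n_points,
                "S_cell_mean": float(np.mean(per_cell_s))
                if per_cell_s is not None
                else np.nan,
                "S_cell_se": float(np.std(per_cell_s, ddof=1) / np.sqrt(len(per_cell_s)))
                if per_cell_s is not None and len(per_cell_s) > 1
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


def default_conditions() -> pd.DataFrame:
    """The default experimental design: 3 widths x 3 gaps at fixed drive.

    Nine conditions per cell type, matching the measurement campaign's
    layout (three electrode widths, three gaps, one voltage/frequency).
    """
    rows = [
        {"V_pp": 8.0, "freq_hz": 3e6, "w_um": w, "d_um": d, "R_um": 4.0}
        for w in (10.0, 30.0, 50.0)
        for d in (20.0, 45.0, 70.0)
    ]
    return pd.DataFrame(rows)


def synth_trajectories(
    s_true: dict[str, float],
    gamma_table: GammaTable,
    *,
    conditions: pd.DataFrame | None = None,
    n_cells: int = 16,
    tau_s: float = 10.0,
    duration_s: float = 60.0,
    dt_s: float = 0.5,
    noise_cv: float = 0.05,
    tracking_noise_um: float = 0.02,
    n_cycles: int = 0,
    recovery: float = 1.0,
    seed: int = 0,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Generate synthetic tip trajectories with the lumped-law structure.

    Each cell's plateau is ``L* = S_cell V^2 gamma(R, d, w)`` with
    ``S_cell`` lognormally scattered around its type's ``s_true`` with
    coefficient of variation ``noise_cv``; the rise is a single
    exponential with time constant ``tau_s`` plus additive Gaussian
    tracking noise.  With ``n_cycles > 0`` the record alternates equal
    on/off intervals, relaxing towards ``(1 - recovery)`` of the peak
    during each off phase.  Fully seeded and reproducible.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    conditions = conditions if conditions is not None else default_conditions()
    rng = np.random.default_rng(seed)
    sigma_ln = np.sqrt(np.log1p(noise_cv**2))
    records = []
    for cell_type, s_type in sorted(s_true.items()):
        for ci, cond in conditions.reset_index(drop=True).iterrows():
            gamma = interpolate_gamma(
                gamma_table, cond["R_um"], cond["d_um"], cond["w_um"]
            )
            for k in range(n_cells):
                s_cell = s_type * rng.lognormal(-0.5 * sigma_ln**2, sigma_ln)
                plateau_um = s_cell * cond["V_pp"] ** 2 * gamma * cond["R_um"]
                t, y, phase = _one_trace(
                    plateau_um, tau_s, duration_s, dt_s, n_cycles, recovery
                )
                y = y + rng.normal(0.0, tracking_noise_um, size=y.shape)
                cid = f"{cell_type}_c{ci:02d}_{k:02d}"
                records.append(
                    pd.DataFrame(
                        {
                            "cell_id": cid,
                            "type": cell_type,
                            "t_s": t,
                            "elong_um": y,
                            "V_pp": cond["V_pp"],
                            "freq_hz": cond["freq_hz"],
                            "w_um": cond["w_um"],
                            "d_um": cond["d_um"],
                            "R_um": cond["R_um"],
                            "phase": phase,
                        }
                    )
                )
    df = pd.concat(records, ignore_index=True)
    if path is not None:
        df.to_csv(path, index=False)
    return df


def _one_trace(
    plateau_um: float,
    tau_s: float,
    duration_s: float,
    dt_s: float,
    n_cycles: int,
    recovery: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if n_cycles <= 0:
        t = np.arange(0.0, duration_s + dt_s / 2, dt_s)
        y = plateau_um * (1.0 - np.exp(-t / tau_s))
        phase = np.full(t.shape, "on", dtype=object)
        return t, y, phase
    seg = np.arange(0.0, duration_s + dt_s / 2, dt_s)
    t_parts, y_parts, p_parts = [], [], []
    baseline = 0.0
    t0 = 0.0
    for _ in range(n_cycles):
        rise = baseline + (plateau_um - baseline) * (1.0 - np.exp(-seg / tau_s))
        t_parts.append(t0 + seg)
        y_parts.append(rise)
        p_parts.append(np.full(seg.shape, "on", dtype=object))
        t0 += duration_s + dt_s
        peak = rise[-1]
        residual = (1.0 - recovery) * peak
        fall = residual + (peak - residual) * np.exp(-seg / tau_s)
        t_parts.append(t0 + seg)
        y_parts.append(fall)
        p_parts.append(np.full(seg.shape, "off", dtype=object))
        t0 += duration_s + dt_s
        baseline = fall[-1]
    return (
        np.concatenate(t_parts),
        np.concatenate(y_parts),
        np.concatenate(p_parts),
    )
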