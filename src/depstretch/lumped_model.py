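"""The lumped elongation law ``L* = S V^2 gamma(R, d, w)`` and its calibration.

The simulated elongation factorizes into the drive (exactly quadratic in
the applied voltage), a dielectric-contrast power law
``(eps_m - eps_c)^alpha`` and a purely geometric factor
``gamma(R, d, w)`` tabulated by simulation and normalized to 1 at a
reference configuration.  Everything cell-specific (mechanics and
dielectrics) collapses into a single lumped parameter ``S`` with units
1/V^2, fitted per cell or per cell type by least squares through the
origin of ``L*`` against ``V^2 gamma``.

The contrast exponent ``alpha`` is estimated by minimizing, over a
candidate grid plus a bounded refinement, the worst-case relative spread
of ``L* / contrast^alpha`` across contrast levels within each geometry.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.optimize import minimize_scalar

from .pipeline import StretchConfig, simulate_stretch


class ExtrapolationError(ValueError):
    """Query outside the gamma-table hull."""


class GammaTableError(RuntimeError):
    """One or more grid-point simulations failed while building a table."""


@dataclass(frozen=True)
class GammaTable:
    """Geometry factor gamma on a (R, d, w) grid, 1 at the reference point."""

    r_axis_um: np.ndarray
    d_axis_um: np.ndarray
    w_axis_um: np.ndarray
    values: np.ndarray  # (nR, nd, nw), > 0
    reference_um: tuple[float, float, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = (len(self.r_axis_um), len(self.d_axis_um), len(self.w_axis_um))
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != grid {expected}")
        if not np.all(self.values > 0):
            raise ValueError("gamma must be positive everywhere")

    def to_frame(self) -> pd.DataFrame:
        rr, dd, ww = np.meshgrid(
            self.r_axis_um, self.d_axis_um, self.w_axis_um, indexing="ij"
        )
        return pd.DataFrame(
            {
                "R_um": rr.ravel(),
                "d_um": dd.ravel(),
                "w_um": ww.ravel(),
                "gamma": self.values.ravel(),
            }
        )

    def to_csv(self, path: str | Path) -> None:
        buf = io.StringIO()
        for key, val in {
            "reference_R_um": self.reference_um[0],
            "reference_d_um": self.reference_um[1],
            "reference_w_um": self.reference_um[2],
            **self.provenance,
        }.items():
            buf.write(f"# {key}: {val}\n")
        self.to_frame().to_csv(buf, index=False)
        Path(path).write_text(buf.getvalue())

    @classmethod
    def from_csv(cls, path: str | Path) -> "GammaTable":
        text = Path(path).read_text()
        meta: dict = {}
        lines = []
        for line in text.splitlines():
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
            else:
                lines.append(line)
        df = pd.read_csv(io.StringIO("\n".join(lines)))
        r_axis = np.unique(df["R_um"].to_numpy())
        d_axis = np.unique(df["d_um"].to_numpy())
        w_axis = np.unique(df["w_um"].to_numpy())
        values = (
            df.sort_values(["R_um", "d_um", "w_um"])["gamma"]
            .to_numpy()
            .reshape(len(r_axis), len(d_axis), len(w_axis))
        )
        ref = (
            float(meta.pop("reference_R_um")),
            float(meta.pop("reference_d_um")),
            float(meta.pop("reference_w_um")),
        )
        return cls(r_axis, d_axis, w_axis, values, ref, meta)


@dataclass(frozen=True)
class AlphaFit:
    """Fitted contrast exponent and the collapse quality it achieves."""

    alpha: float
    max_relative_deviation: float  # worst-case spread over geometries, fraction
    per_geometry_deviation: pd.Series | None = None
    alpha_grid_min: float = np.nan  # best alpha on the coarse grid, pre-refinement


@dataclass(frozen=True)
class LumpedFit:
    """Least-squares lumped parameter S (1/V^2) with its standard error."""

    s: float
    stderr: float
    n_cells: int
    n_points: int
    residual_rms: float
    per_cell: pd.DataFrame | None = None
    d_mech: float | None = None  # D = S / contrast^alpha when a contrast is supplied


def build_gamma_table(
    r_grid_um,
    d_grid_um,
    w_grid_um,
    base_config: StretchConfig,
    reference_um: tuple[float, float, float] | None = None,
) -> GammaTable:
    """Tabulate gamma by running the simulator at every (R, d, w) grid point.

    All drive/material settings come from ``base_config``; gamma is the
    elongation normalized by the reference-point elongation, making the
    table independent of the (V, E) used to generate it.
    """
    r_grid = np.asarray(sorted(r_grid_um), dtype=float)
    d_grid = np.asarray(sorted(d_grid_um), dtype=float)
    w_grid = np.asarray(sorted(w_grid_um), dtype=float)
    if reference_um is None:
        reference_um = (
            float(r_grid[len(r_grid) // 2]),
            float(d_grid[len(d_grid) // 2]),
            float(w_grid[len(w_grid) // 2]),
        )

    values = np.empty((len(r_grid), len(d_grid), len(w_grid)))
    failures: list[str] = []
    for i, r in enumerate(r_grid):
        for j, d in enumerate(d_grid):
            for k, w in enumerate(w_grid):
                try:
                    values[i, j, k] = _lstar_at(base_config, r, d, w)
                except Exception as exc:  # noqa: BLE001 - collected and re-raised
                    failures.append(f"(R={r}, d={d}, w={w}): {exc}")
                    values[i, j, k] = np.nan
    if failures:
        raise GammaTableError(
            "gamma-table simulations failed at:\n  " + "\n  ".join(failures)
        )

    ref_lstar = _lstar_at(base_config, *reference_um)
    table = GammaTable(
        r_axis_um=r_grid,
        d_axis_um=d_grid,
        w_axis_um=w_grid,
        values=values / ref_lstar,
        reference_um=reference_um,
        provenance={
            "eps_m": base_config.eps_m,
            "eps_c": base_config.eps_c,
            "voltage": base_config.voltage,
            "youngs_modulus_pa": base_config.props.youngs_modulus_pa,
            "poisson_ratio": base_config.props.poisson_ratio,
            "nodes_per_radius": base_config.resolution.nodes_per_radius,
            "left_shape": base_config.pair.left_shape,
            "right_shape": base_config.pair.right_shape,
        },
    )
    return table


def _lstar_at(base: StretchConfig, r_um: float, d_um: float, w_um: float) -> float:
    cfg = replace(
        base,
        pair=replace(base.pair, width_um=w_um, gap_um=d_um),
        cell_radius_um=r_um,
        on_overlap="allow",
    )
    return simulate_stretch(cfg).lstar


def interpolate_gamma(
    table: GammaTable, r_um: float, d_um: float, w_um: float
) -> float:
    """Trilinear interpolation of gamma; queries outside the grid hull raise."""
    interp = RegularGridInterpolator(
        (table.r_axis_um, table.d_axis_um, table.w_axis_um),
        table.values,
        method="linear",
        bounds_error=True,
    )
    try:
        return float(interp([[r_um, d_um, w_um]])[0])
    except ValueError as exc:
        raise ExtrapolationError(
            f"(R={r_um}, d={d_um}, w={w_um}) outside the gamma-table hull"
        ) from exc


def _collapse_spread(df: pd.DataFrame, alpha: float) -> pd.Series:
    """Per-geometry relative spread (max-min)/mean of Lstar / contrast^alpha."""
    ratio = df["Lstar"] / df["delta_eps"] ** alpha
    grouped = ratio.groupby(df["geometry"])
    return (grouped.max() - grouped.min()) / grouped.mean()


def fit_alpha(
    elongations: pd.DataFrame,
    alpha_grid: np.ndarray | None = None,
    *,
    refine: bool = True,
) -> AlphaFit:
    """Contrast exponent minimizing the worst-case per-geometry collapse spread.

    ``elongations`` needs columns ``Lstar``, ``delta_eps`` (positive
    contrast magnitude) and ``geometry`` (hashable id), with at least
    three contrast levels per geometry.  A coarse grid search (default
    0.5-1.2, step 0.01) is refined by bounded scalar minimization.
    """
    required = {"Lstar", "delta_eps", "geometry"}
    missing = required - set(elongations.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    levels = elongations.groupby("geometry")["delta_eps"].nunique()
    if (levels < 3).any():
        bad = levels[levels < 3].index.tolist()
        raise ValueError(f"need >= 3 contrast levels per geometry; short: {bad}")
    if alpha_grid is None:
        alpha_grid = np.arange(0.5, 1.2001, 0.01)
    alpha_grid = np.asarray(alpha_grid, dtype=float)

    def worst(alpha: float) -> float:
        return float(_collapse_spread(elongations, alpha).max())

    spreads = np.array([worst(a) for a in alpha_grid])
    best_idx = int(np.argmin(spreads))
    alpha_best = float(alpha_grid[best_idx])
    alpha_coarse = alpha_best
    if refine and len(alpha_grid) > 2:
        lo = alpha_grid[max(best_idx - 1, 0)]
        hi = alpha_grid[min(best_idx + 1, len(alpha_grid) - 1)]
        res = minimize_scalar(worst, bounds=(lo, hi), method="bounded")
        if res.fun <= spreads[best_idx]:
            alpha_best = float(res.x)
    per_geo = _collapse_spread(elongations, alpha_best)
    return AlphaFit(
        alpha=alpha_best,
        max_relative_deviation=float(per_geo.max()),
        per_geometry_deviation=per_geo,
        alpha_grid_min=alpha_coarse,
    )


def fit_S(
    measurements: pd.DataFrame,
    table: GammaTable,
    *,
    delta_eps: float | None = None,
    alpha: float | None = None,
) -> LumpedFit:
    """Fit the lumped parameter by least squares through the origin.

    ``measurements`` needs columns ``Lstar``, ``V_pp``, ``R_um``,
    ``d_um``, ``w_um`` and optionally ``cell_id``.  With ``x = V^2 gamma``
    the estimate is ``S = sum(x y) / sum(x^2)``; the standard error comes
    from the residuals.  When a contrast magnitude and exponent are
    supplied, the mechanics-only factor ``D = S / contrast^alpha`` is
    also reported.
    """
    required = {"Lstar", "V_pp", "R_um", "d_um", "w_um"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if len(measurements) < 1:
        raise ValueError("need at least one measurement")
    gamma = np.array(
        [
            interpolate_gamma(table, r, d, w)
            for r, d, w in measurements[["R_um", "d_um", "w_um"]].to_numpy()
        ]
    )
    x = measurements["V_pp"].to_numpy(dtype=float) ** 2 * gamma
    y = measurements["Lstar"].to_numpy(dtype=float)
    sxx = float(x @ x)
    if sxx == 0:
        raise ZeroDivisionError("degenerate design: all V^2 gamma are zero")
    s = float(x @ y) / sxx
    resid = y - s * x
    dof = max(len(y) - 1, 1)
    stderr = float(np.sqrt(resid @ resid / dof / sxx))

    per_cell = None
    n_cells = len(y)
    if "cell_id" in measurements.columns:
        rows = []
        for cid, grp_idx in measurements.groupby("cell_id").groups.items():
            xi, yi = x[measurements.index.get_indexer(grp_idx)], y[
                measurements.index.get_indexer(grp_idx)
            ]
            si = float(xi @ yi) / float(xi @ xi)
            rows.append({"cell_id": cid, "S": si, "n": len(xi)})
        per_cell = pd.DataFrame(rows)
        n_cells = len(per_cell)

    d_mech = None
    if delta_eps is not None and alpha is not None:
        d_mech = s / delta_eps**alpha
    return LumpedFit(
        s=s,
        stderr=stderr,
        n_cells=n_cells,
        n_points=len(y),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        per_cell=per_cell,
        d_mech=d_mech,
    )


def predict_elongation(
    s: float, voltage: float, r_um: float, d_um: float, w_um: float, table: GammaTable
) -> float:
    """Predicted normalized elongation ``L* = S V^2 gamma(R, d, w)``."""
    return s * voltage**2 * interpolate_gamma(table, r_um, d_um, w_um)


def load_default_gamma() -> GammaTable:
    """The gamma table shipped with the package (generated by this simulator)."""
    path = Path(__file__).parent / "data" / "gamma_default.csv"
    return GammaTable.from_csv(path)
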