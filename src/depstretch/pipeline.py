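"""End-to-end stretch simulation: geometry -> field -> traction -> deformation -> L*.

``simulate_stretch`` runs the one-way-coupled chain for a single
configuration and returns the :class:`ElongationResult`.  Because every
stage is linear, the elongation is exactly quadratic in the drive
voltage and exactly inversely proportional to the Young's modulus; these
identities are asserted by the test suite rather than enforced here.

``mesh_independence`` walks a refinement ladder until one further
refinement changes L* by less than a tolerance, mirroring the standard
mesh-independence study that precedes production runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dielectrics import EPS0
from .elastic_response import (
    ElasticProperties,
    ElongationResult,
    deform_disk,
    elongation,
    equilibrate_traction,
)
from .geometry_field import (
    COARSE,
    ChipGeometry,
    ElectrodePair,
    RefinementError,
    Resolution,
    build_geometry,
    refine,
    solve_potential,
)
from .maxwell_stress import net_force, surface_traction


@dataclass(frozen=True)
class StretchConfig:
    """Complete configuration of one stretch simulation.

    Permittivities are relative; the drive ``voltage`` is the
    peak-to-peak potential difference between the electrodes.
    """

    pair: ElectrodePair
    cell_radius_um: float
    eps_m: float = 80.0
    eps_c: float = 120.0
    voltage: float = 10.0
    props: ElasticProperties = field(default_factory=ElasticProperties)
    resolution: Resolution = field(default_factory=Resolution)
    time_average: bool = False
    on_overlap: str = "error"
    domain_factor: float = 4.0
    axis: tuple[float, float] = (1.0, 0.0)

    def geometry(self) -> ChipGeometry:
        return build_geometry(
            self.pair,
            self.cell_radius_um,
            domain_factor=self.domain_factor,
            on_overlap=self.on_overlap,  # type: ignore[arg-type]
        )


def simulate_stretch(config: StretchConfig) -> ElongationResult:
    """Run the full chain and return the elongation with stage diagnostics.

    Deterministic for a fixed configuration and resolution.  Stage errors
    propagate with the failing stage named in the exception message.
    """
    log: dict = {}
    try:
        geom = config.geometry()
    except Exception as exc:
        raise type(exc)(f"[build_geometry] {exc}") from exc
    try:
        sol = solve_potential(
            geom, config.eps_m, config.eps_c, config.voltage, config.resolution
        )
        log["field_nodes"] = sol.meta.get("nx", 0) * sol.meta.get("ny", 0)
        log["max_E_vm"] = float(np.max(np.hypot(sol.ex, sol.ey)))
    except Exception as exc:
        raise type(exc)(f"[solve_potential] {exc}") from exc
    try:
        traction = surface_traction(
            sol,
            config.eps_m * EPS0,
            config.eps_c * EPS0,
            time_average=config.time_average,
        )
        log["max_traction_pa"] = float(np.max(np.abs(traction.f)))
        log["net_force_npm"] = [float(v) for v in net_force(traction, config.cell_radius_um)]
        balanced = equilibrate_traction(traction)
    except Exception as exc:
        raise type(exc)(f"[surface_traction] {exc}") from exc
    try:
        disp = deform_disk(balanced, config.cell_radius_um, config.props)
        result = elongation(disp, config.cell_radius_um, config.axis)
    except Exception as exc:
        raise type(exc)(f"[deform_disk] {exc}") from exc
    log["u_tip_um"] = result.u_tip_um
    return ElongationResult(
        u_tip_um=result.u_tip_um,
        cell_radius_um=result.cell_radius_um,
        max_boundary_strain=result.max_boundary_strain,
        log=log,
    )


def mesh_independence(
    config: StretchConfig,
    tol: float = 0.01,
    *,
    start: Resolution = COARSE,
    factor: float = 1.5,
    max_refinements: int = 6,
) -> Resolution:
    """Coarsest resolution at which one refinement changes L* by < ``tol``.

    Walks ``nodes_per_radius`` up by ``factor`` per step; raises
    :class:`RefinementError` if the ladder does not settle.
    """
    if not tol > 0:
        raise ValueError("tol must be > 0")
    res = start
    prev = simulate_stretch(replace(config, resolution=res)).lstar
    if np.isinf(tol):
        return res
    for _ in range(max_refinements):
        finer = refine(res, factor)
        cur = simulate_stretch(replace(config, resolution=finer)).lstar
        if abs(cur - prev) <= tol * abs(prev):
            return res
        res, prev = finer, cur
    raise RefinementError(
        f"elongation not mesh-independent at tol={tol} within "
        f"{max_refinements} refinements"
    )
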