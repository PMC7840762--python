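"""Maxwell stress tensor and the electrical surface traction on the cell boundary.

The Maxwell stress tensor in the absence of a magnetic field is
``sigma_ij = eps (E_i E_j - 1/2 delta_ij |E|^2)``.  Its jump across the
cell-medium interface gives the dielectrophoretic surface traction

    f = eps_m [(E_out.n) E_out - 1/2 |E_out|^2 n]
      - eps_c [(E_in .n) E_in  - 1/2 |E_in |^2 n]

which drives the cell deformation.  The point-dipole force expression is
provided as an independent cross-check: it vanishes in a uniform field
and agrees with the integrated MST force in the small-particle limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dielectrics import EPS0
from .geometry_field import FieldSolution


@dataclass(frozen=True)
class SurfaceTraction:
    """Traction samples (N/m^2, per unit depth) at angles ``theta`` on the cell boundary."""

    theta: np.ndarray  # (K,) angular stations in [0, 2pi)
    f: np.ndarray  # (K, 2) in-plane traction vectors
    normals: np.ndarray  # (K, 2) outward unit normals

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.f)):
            raise ValueError("traction must be finite")

    @property
    def f_radial(self) -> np.ndarray:
        return np.einsum("ki,ki->k", self.f, self.normals)

    @property
    def f_tangential(self) -> np.ndarray:
        t = np.column_stack([-self.normals[:, 1], self.normals[:, 0]])
        return np.einsum("ki,ki->k", self.f, t)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "theta_rad": self.theta,
                "f_r": self.f_radial,
                "f_theta": self.f_tangential,
                "f_x": self.f[:, 0],
                "f_y": self.f[:, 1],
            }
        )


def mst_tensor(e: np.ndarray, eps: float) -> np.ndarray:
    """Maxwell stress tensor ``eps (E_i E_j - 1/2 delta_ij |E|^2)`` for an in-plane field.

    ``e`` is a 2-vector in V/m, ``eps`` the absolute permittivity (F/m);
    returns the symmetric, trace-free 2x2 tensor in N/m^2.  Its
    eigenvalues are ``+-eps |E|^2 / 2``: tension along the field and equal
    compression across it.
    """
    e = np.asarray(e, dtype=float)
    if not np.all(np.isfinite(e)):
        raise ValueError("field must be finite")
    e2 = float(e @ e)
    return eps * (np.outer(e, e) - 0.5 * e2 * np.eye(2))


def surface_traction(
    solution: FieldSolution,
    eps_m: float,
    eps_c: float,
    *,
    time_average: bool = False,
) -> SurfaceTraction:
    """MST traction jump on the cell boundary from interface field samples.

    ``eps_m``/``eps_c`` are absolute permittivities (F/m).  The default
    uses the field amplitudes directly (peak-of-cycle traction); with
    ``time_average=True`` the AC time average is reported (factor 1/2).
    """
    if solution.theta.size == 0:
        raise ValueError("field solution carries no interface samples")
    n = solution.normals
    f = _jump_traction(solution.e_out, solution.e_in, n, eps_m, eps_c)
    if time_average:
        f = 0.5 * f
    return SurfaceTraction(theta=solution.theta, f=f, normals=n)


def _jump_traction(
    e_out: np.ndarray,
    e_in: np.ndarray,
    normals: np.ndarray,
    eps_m: float,
    eps_c: float,
) -> np.ndarray:
    def side(e: np.ndarray, eps: float) -> np.ndarray:
        en = np.einsum("ki,ki->k", e, normals)
        e2 = np.einsum("ki,ki->k", e, e)
        return eps * (en[:, None] * e - 0.5 * e2[:, None] * normals)

    return side(e_out, eps_m) - side(e_in, eps_c)


def net_force(traction: SurfaceTraction, cell_radius_um: float) -> np.ndarray:
    """Net in-plane force per unit depth (N/m): integral of f over the circle."""
    r_m = cell_radius_um * 1e-6
    # uniform angular stations: periodic trapezoid = mean * circumference
    return traction.f.mean(axis=0) * 2.0 * np.pi * r_m


def dipole_force(
    radius_m: float,
    eps_m: float,
    k_real: float,
    grad_e2: np.ndarray,
) -> np.ndarray:
    """Time-averaged point-dipole DEP force ``2 pi r^3 eps0 eps_m Re(K) grad|E|^2`` (N).

    The 3-D spherical-particle expression; ``eps_m`` is the relative
    medium permittivity and ``grad_e2`` the gradient of the squared field
    magnitude (V^2/m^3).  Used only as a cross-check: it assumes an
    undisturbed field and predicts no force in a uniform one.
    """
    if not radius_m > 0:
        raise ValueError("radius must be > 0")
    return 2.0 * np.pi * radius_m**3 * EPS0 * eps_m * k_real * np.asarray(grad_e2, dtype=float)


def dipole_force_per_depth(
    radius_m: float,
    eps_m: float,
    eps_p: float,
    grad_e2: np.ndarray,
) -> np.ndarray:
    """Plane (cylinder) dipole DEP force per unit depth (N/m), peak-of-cycle.

    For a dielectric cylinder the polarizability contrast is
    ``K2 = (eps_p - eps_m)/(eps_p + eps_m)`` and the force per depth is
    ``pi r^2 eps0 eps_m K2 grad|E|^2 / 2 * 2`` = ``pi r^2 eps0 eps_m K2 grad|E|^2``.
    This is the quantity the integrated 2-D MST force approaches as
    ``R/d -> 0`` and is the dimensionally consistent analogue of the
    spherical point-dipole formula in the plane model.
    """
    if not radius_m > 0:
        raise ValueError("radius must be > 0")
    k2 = (eps_p - eps_m) / (eps_p + eps_m)
    return np.pi * radius_m**2 * EPS0 * eps_m * k2 * np.asarray(grad_e2, dtype=float)
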