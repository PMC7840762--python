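"""Linear-elastic deformation of the circular cell under the MST surface traction.

The cell is modelled as a homogeneous linear-elastic disk (plane stress
by default) loaded by the surface traction from the Maxwell stress
jump — a one-way coupling: the field is not re-solved on the deformed
shape.  The boundary-value problem on the disk is solved exactly per
angular harmonic with the Michell (Airy-function) solution: the traction
is Fourier-decomposed at the boundary stations, each harmonic maps onto
the two regular Airy terms ``r^n`` and ``r^{n+2}``, and displacements
follow in closed form.  Rigid-body (net force/torque) content must be
removed first, which :func:`equilibrate_traction` does.

The headline scalar is the normalized elongation ``L* = (L - R)/R`` where
``L = R + u_tip`` and ``u_tip`` is the tip displacement along the
stretching axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .maxwell_stress import SurfaceTraction


class UnequilibratedTractionError(ValueError):
    """Traction carries net force/torque; run equilibrate_traction first."""


@dataclass(frozen=True)
class ElasticProperties:
    """Isotropic elastic disk: Young's modulus (Pa), Poisson ratio, 2-D regime."""

    youngs_modulus_pa: float = 100.0
    poisson_ratio: float = 0.49
    regime: str = "plane_stress"

    def __post_init__(self) -> None:
        if not self.youngs_modulus_pa > 0:
            raise ValueError("Young's modulus must be > 0")
        if not -1.0 < self.poisson_ratio < 0.5:
            raise ValueError("Poisson ratio must be in (-1, 0.5)")
        if self.regime not in ("plane_stress", "plane_strain"):
            raise ValueError("regime must be plane_stress or plane_strain")

    @property
    def shear_modulus_pa(self) -> float:
        return self.youngs_modulus_pa / (2.0 * (1.0 + self.poisson_ratio))

    @property
    def kolosov_kappa(self) -> float:
        nu = self.poisson_ratio
        if self.regime == "plane_strain":
            return 3.0 - 4.0 * nu
        return (3.0 - nu) / (1.0 + nu)


@dataclass(frozen=True)
class ElongationResult:
    """Tip displacement and normalized elongation of one simulated/measured stretch."""

    u_tip_um: float
    cell_radius_um: float
    max_boundary_strain: float = 0.0
    log: dict = field(default_factory=dict)

    @property
    def deformed_semi_axis_um(self) -> float:
        """L = R + u_tip."""
        return self.cell_radius_um + self.u_tip_um

    @property
    def lstar(self) -> float:
        """Normalized elongation L* = (L - R)/R = u_tip/R."""
        return self.u_tip_um / self.cell_radius_um

    def to_record(self) -> dict:
        return {
            "u_tip_um": self.u_tip_um,
            "L_um": self.deformed_semi_axis_um,
            "Lstar": self.lstar,
            "R_um": self.cell_radius_um,
            "max_boundary_strain": self.max_boundary_strain,
        }


def traction_resultants(
    traction: SurfaceTraction, cell_radius_um: float = 1.0
) -> tuple[np.ndarray, float]:
    """Net force per depth (N/m) and net torque per depth (N) of a traction field."""
    r_m = cell_radius_um * 1e-6
    force = traction.f.mean(axis=0) * 2.0 * np.pi * r_m
    torque = traction.f_tangential.mean() * 2.0 * np.pi * r_m**2
    return force, torque


def equilibrate_traction(traction: SurfaceTraction) -> SurfaceTraction:
    """Remove net-force and net-torque content so the static problem is well-posed.

    The net force lives in the theta-constant part of the Cartesian
    traction components; the net torque in the mean tangential traction.
    Subtracting both leaves the deformation-driving content untouched.
    """
    f = traction.f.copy()
    f -= f.mean(axis=0, keepdims=True)
    tangents = np.column_stack([-traction.normals[:, 1], traction.normals[:, 0]])
    mean_ft = np.einsum("ki,ki->k", f, tangents).mean()
    f -= mean_ft * tangents
    return SurfaceTraction(theta=traction.theta, f=f, normals=traction.normals)


@dataclass
class DiskDisplacement:
    """Closed-form displacement field of the loaded disk.

    Stores the per-harmonic Airy coefficients (nondimensionalized by the
    disk radius); ``displacement(rho, theta)`` evaluates the displacement
    in micrometres at normalized radius ``rho = r/R``.
    """

    cell_radius_um: float
    props: ElasticProperties
    n: np.ndarray  # harmonic indices >= 0
    a_hat: np.ndarray  # complex, coefficient of the r^n Airy term
    b_hat: np.ndarray  # complex, coefficient of the r^{n+2} Airy term
    g0: float = 0.0  # residual uniform boundary shear (torsion), N/m^2

    def displacement_polar(
        self, rho: np.ndarray, theta: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """(u_r, u_theta) in um at (rho, theta); arrays broadcast together."""
        rho = np.asarray(rho, dtype=float)
        theta = np.asarray(theta, dtype=float)
        mu = self.props.shear_modulus_pa
        kappa = self.props.kolosov_kappa
        r_m = self.cell_radius_um * 1e-6
        u_r = np.zeros(np.broadcast(rho, theta).shape, dtype=complex)
        u_t = np.zeros_like(u_r)
        for n, a, b in zip(self.n, self.a_hat, self.b_hat):
            if n == 0:
                # a_hat holds the uniform radial traction F0 here
                u_r = u_r + a * (kappa - 1.0) / 2.0 * rho
                u_t = u_t + self.g0 * 2.0 * rho**2  # u_theta = G0 R rho^2 / mu
                continue
            w = 2.0  # real-signal reconstruction weight for n >= 1
            phase = np.exp(1j * n * theta)
            rn1 = rho ** (n - 1)
            rp1 = rho ** (n + 1)
            u_r = u_r + w * (-n * a * rn1 + (kappa - n - 1.0) * b * rp1) * phase
            u_t = u_t + w * (-1j * n * a * rn1 - 1j * (kappa + n + 1.0) * b * rp1) * phase
        scale = r_m / (2.0 * mu) * 1e6  # -> um
        return np.real(u_r) * scale, np.real(u_t) * scale

    def displacement_cartesian(
        self, rho: np.ndarray, theta: np.ndarray
    ) -> np.ndarray:
        u_r, u_t = self.displacement_polar(rho, theta)
        ux = u_r * np.cos(theta) - u_t * np.sin(theta)
        uy = u_r * np.sin(theta) + u_t * np.cos(theta)
        return np.stack([ux, uy], axis=-1)


def deform_disk(
    traction: SurfaceTraction,
    cell_radius_um: float,
    props: ElasticProperties | None = None,
    *,
    equilibrium_rtol: float = 1e-6,
    strain_warn: float = 0.2,
) -> DiskDisplacement:
    """Solve the disk elastostatic problem for a self-equilibrated boundary traction.

    Fourier-decomposes ``(f_r, f_theta)`` over the uniform angular
    stations and inverts the 2x2 Michell system per harmonic.  Raises
    :class:`UnequilibratedTractionError` when the traction still carries
    net force or torque relative to its own magnitude.
    """
    props = props or ElasticProperties()
    k = len(traction.theta)
    f_r = traction.f_radial
    f_t = traction.f_tangential
    scale = float(np.max(np.abs(traction.f))) if traction.f.size else 0.0
    force, torque = traction_resultants(traction, cell_radius_um)
    r_m = cell_radius_um * 1e-6
    if scale > 0:
        rel_force = np.linalg.norm(force) / (scale * 2.0 * np.pi * r_m)
        rel_torque = abs(torque) / (scale * 2.0 * np.pi * r_m**2)
        if rel_force > equilibrium_rtol or rel_torque > equilibrium_rtol:
            raise UnequilibratedTractionError(
                f"net force/torque not removed (relative {rel_force:.2e}/"
                f"{rel_torque:.2e}); call equilibrate_traction first"
            )

    fr_hat = np.fft.rfft(f_r) / k
    ft_hat = np.fft.rfft(f_t) / k
    n_max = fr_hat.size - 1
    ns = np.arange(n_max + 1)
    a_hat = np.zeros(n_max + 1, dtype=complex)
    b_hat = np.zeros(n_max + 1, dtype=complex)

    # n = 0: uniform pressure (stored in a_hat[0]) and residual torsion
    a_hat[0] = fr_hat[0].real
    g0 = ft_hat[0].real

    for n in range(1, n_max + 1):
        fn, gn = fr_hat[n], ft_hat[n]
        if k % 2 == 0 and n == k // 2:
            continue  # drop the unpaired Nyquist harmonic
        if n == 1:
            # single regular Airy term r^3; solvable iff self-equilibrated
            b_hat[1] = fn / 2.0
            continue
        m11 = n * (1.0 - n)
        m12 = n + 2.0 - n * n
        m21 = -1j * n * (n - 1.0)
        m22 = -1j * n * (n + 1.0)
        det = m11 * m22 - m12 * m21
        a_hat[n] = (m22 * fn - m12 * gn) / det
        b_hat[n] = (-m21 * fn + m11 * gn) / det

    disp = DiskDisplacement(
        cell_radius_um=cell_radius_um,
        props=props,
        n=ns,
        a_hat=a_hat,
        b_hat=b_hat,
        g0=g0,
    )
    u_r, u_t = disp.displacement_polar(1.0, traction.theta)
    max_strain = float(np.max(np.hypot(u_r, u_t)) / cell_radius_um) if k else 0.0
    if max_strain > strain_warn:
        import warnings

        warnings.warn(
            f"max boundary displacement {max_strain:.2f} R exceeds the "
            "small-strain regime",
            stacklevel=2,
        )
    return disp


def elongation(
    displacement: DiskDisplacement,
    cell_radius_um: float,
    axis: tuple[float, float] = (1.0, 0.0),
) -> ElongationResult:
    """Normalized elongation along ``axis``: mean outward tip displacement over R.

    ``u_tip`` is the average of the two tip displacements projected on the
    outward axis directions, ``L = R + u_tip`` and ``L* = u_tip / R``.
    """
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    th0 = float(np.arctan2(ax[1], ax[0]))
    u = displacement.displacement_cartesian(
        np.array([1.0, 1.0]), np.array([th0, th0 + np.pi])
    )
    u_tip = 0.5 * (u[0] @ ax + u[1] @ (-ax))
    th = np.linspace(0, 2 * np.pi, 256, endpoint=False)
    u_r, u_t = displacement.displacement_polar(1.0, th)
    max_strain = float(np.max(np.hypot(u_r, u_t)) / cell_radius_um)
    return ElongationResult(
        u_tip_um=float(u_tip),
        cell_radius_um=cell_radius_um,
        max_boundary_strain=max_strain,
    )
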