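"""Complex permittivities, the single-shell cell model, and the Clausius-Mossotti factor.

A cell in an AC field responds through its complex permittivity
``eps* = eps - j*sigma/omega``: the real part stores polarization, the
imaginary part carries ohmic conduction.  A membrane-bounded cell is
reduced to a homogeneous sphere with an *effective* permittivity by the
single-shell mixing rule, which depends on the ratio of membrane
thickness to cell radius.  The Clausius-Mossotti factor
``K = (eps_p* - eps_m*)/(eps_p* + 2 eps_m*)`` sets the sign and strength
of the dipole dielectrophoretic response of that equivalent sphere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: vacuum permittivity, F/m
EPS0 = 8.8541878128e-12


class InvalidFrequencyError(ValueError):
    """Angular frequency must be strictly positive."""


class SingularContrastError(ZeroDivisionError):
    """Denominator of a dielectric contrast factor vanished."""


@dataclass(frozen=True)
class DielectricMaterial:
    """A linear isotropic dielectric with ohmic conduction.

    Parameters
    ----------
    eps_r : float
        Relative permittivity (dimensionless, > 0).
    sigma : float
        Conductivity in S/m (>= 0).
    """

    eps_r: float
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if not self.eps_r > 0:
            raise ValueError(f"eps_r must be > 0, got {self.eps_r}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")


@dataclass(frozen=True)
class ShellCell:
    """Single-shell cell: a cytoplasmic sphere wrapped in a thin membrane.

    Lengths are in micrometres; ``0 < membrane_thickness_um < radius_um``.
    """

    radius_um: float
    membrane_thickness_um: float
    membrane: DielectricMaterial
    cytoplasm: DielectricMaterial

    def __post_init__(self) -> None:
        if not self.radius_um > 0:
            raise ValueError("radius_um must be > 0")
        if not 0 < self.membrane_thickness_um < self.radius_um:
            raise ValueError(
                "membrane thickness must satisfy 0 < t < R, got "
                f"t={self.membrane_thickness_um}, R={self.radius_um}"
            )


@dataclass(frozen=True)
class Drive:
    """AC drive: peak-to-peak voltage (V) and frequency (Hz)."""

    voltage_vpp: float
    frequency_hz: float

    def __post_init__(self) -> None:
        if not self.voltage_vpp > 0:
            raise ValueError("voltage_vpp must be > 0")
        if not self.frequency_hz > 0:
            raise ValueError("frequency_hz must be > 0")

    @property
    def omega(self) -> float:
        """Angular frequency, rad/s."""
        return 2.0 * np.pi * self.frequency_hz


def complex_permittivity(
    material: DielectricMaterial, omega: float, *, relative: bool = False
) -> complex:
    """Complex permittivity ``eps* = eps - j*sigma/omega`` at ``omega`` (rad/s).

    Returns the absolute form ``eps_r*EPS0 - j*sigma/omega`` by default;
    with ``relative=True`` returns ``eps_r - j*sigma/(omega*EPS0)``.
    """
    if not omega > 0:
        raise InvalidFrequencyError(f"omega must be > 0, got {omega}")
    eps = material.eps_r * EPS0 - 1j * material.sigma / omega
    return eps / EPS0 if relative else eps


def clausius_mossotti(eps_p_star: complex, eps_m_star: complex) -> complex:
    """Clausius-Mossotti factor ``(eps_p* - eps_m*) / (eps_p* + 2 eps_m*)``.

    Both permittivities must be on the same scale (both absolute or both
    relative); the factor is invariant under a joint positive rescaling.
    """
    denom = eps_p_star + 2.0 * eps_m_star
    if denom == 0:
        raise SingularContrastError("eps_p* + 2*eps_m* = 0")
    return (eps_p_star - eps_m_star) / denom


def shell_effective_permittivity(
    cell: ShellCell, omega: float, *, relative: bool = False
) -> complex:
    """Effective complex permittivity of a single-shell cell.

    Concentric-sphere mixing rule with ``a = R/(R - t)``::

        eps_c* = eps_mem* * (a^3 + 2X) / (a^3 - X),
        X = (eps_cyt* - eps_mem*) / (eps_cyt* + 2 eps_mem*)

    As the membrane thins (t -> 0) the result approaches the cytoplasm
    permittivity; a membrane matching the cytoplasm returns it exactly.
    """
    eps_mem = complex_permittivity(cell.membrane, omega)
    eps_cyt = complex_permittivity(cell.cytoplasm, omega)
    a = cell.radius_um / (cell.radius_um - cell.membrane_thickness_um)
    x = clausius_mossotti(eps_cyt, eps_mem)
    denom = a**3 - x
    if denom == 0:
        raise SingularContrastError("singular shell: a^3 - X = 0")
    eps_eff = eps_mem * (a**3 + 2.0 * x) / denom
    return eps_eff / EPS0 if relative else eps_eff


def permittivity_contrast(
    eps_m_star: complex, eps_c_star: complex
) -> tuple[float, int]:
    """Real-part permittivity contrast ``|Re(eps_m*) - Re(eps_c*)|`` and its sign.

    The lumped elongation law raises the medium-cell contrast to a
    fractional power, which needs a nonnegative base; the magnitude of
    the real-part difference is used, with the sign (+1 if the medium is
    the more polarizable, -1 otherwise, 0 if matched) reported separately.
    """
    diff = eps_m_star.real - eps_c_star.real
    return abs(diff), int(np.sign(diff))
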