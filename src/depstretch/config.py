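"""Structured-text (YAML/JSON) configuration loading.

Schema (all keys optional unless noted; units in the key names)::

    electrodes:
      width_um: 30          # required
      gap_um: 45            # required
      left_shape: rectangular | triangular | elliptical
      right_shape: rectangular
      apex_half_angle_deg: 30
      ellipse_axis_ratio: 0.5
    cell:
      radius_um: 4          # required
      # either a plain relative permittivity ...
      eps_r: 120
      # ... or a single-shell description (overrides eps_r):
      shell:
        membrane_thickness_um: 0.008
        membrane: {eps_r: 6, sigma_s_per_m: 1e-7}
        cytoplasm: {eps_r: 60, sigma_s_per_m: 0.5}
    medium:
      eps_r: 80
      sigma_s_per_m: 0.0
    drive:
      voltage_vpp: 10       # peak-to-peak volts
      frequency_hz: 3e6
    elastic:
      youngs_modulus_pa: 100
      poisson_ratio: 0.49
      regime: plane_stress
    numerics:
      nodes_per_radius: 20
      stations: 360
      on_overlap: error | allow

With a shell section, the cell's relative permittivity entering the
field solve is the real part of the single-shell effective complex
permittivity at the drive frequency.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .dielectrics import (
    DielectricMaterial,
    Drive,
    ShellCell,
    shell_effective_permittivity,
)
from .elastic_response import ElasticProperties
from .geometry_field import ElectrodePair, Resolution
from .pipeline import StretchConfig


def _material(section: dict) -> DielectricMaterial:
    return DielectricMaterial(
        eps_r=float(section["eps_r"]),
        sigma=float(section.get("sigma_s_per_m", 0.0)),
    )


def load_stretch_config(path: str | Path) -> StretchConfig:
    """Read a stretch-simulation configuration from a YAML (or JSON) file."""
    data = yaml.safe_load(Path(path).read_text())
    return stretch_config_from_dict(data)


def stretch_config_from_dict(data: dict) -> StretchConfig:
    el = data["electrodes"]
    pair = ElectrodePair(
        width_um=float(el["width_um"]),
        gap_um=float(el["gap_um"]),
        left_shape=el.get("left_shape", "rectangular"),
        right_shape=el.get("right_shape", "rectangular"),
        apex_half_angle_deg=float(el.get("apex_half_angle_deg", 30.0)),
        ellipse_axis_ratio=float(el.get("ellipse_axis_ratio", 0.5)),
    )
    cell = data["cell"]
    drive_sec = data.get("drive", {})
    drive = Drive(
        voltage_vpp=float(drive_sec.get("voltage_vpp", 10.0)),
        frequency_hz=float(drive_sec.get("frequency_hz", 3e6)),
    )
    if "shell" in cell:
        sh = cell["shell"]
        shell = ShellCell(
            radius_um=float(cell["radius_um"]),
            membrane_thickness_um=float(sh["membrane_thickness_um"]),
            membrane=_material(sh["membrane"]),
            cytoplasm=_material(sh["cytoplasm"]),
        )
        eps_c = shell_effective_permittivity(
            shell, drive.omega, relative=True
        ).real
    else:
        eps_c = float(cell.get("eps_r", 120.0))
    medium = data.get("medium", {})
    elastic = data.get("elastic", {})
    numerics = data.get("numerics", {})
    res_kwargs = {
        k: numerics[k]
        for k in ("nodes_per_radius", "mid_factor", "growth", "stations", "max_harmonic")
        if k in numerics
    }
    return StretchConfig(
        pair=pair,
        cell_radius_um=float(cell["radius_um"]),
        eps_m=float(medium.get("eps_r", 80.0)),
        eps_c=eps_c,
        voltage=drive.voltage_vpp,
        props=ElasticProperties(
            youngs_modulus_pa=float(elastic.get("youngs_modulus_pa", 100.0)),
            poisson_ratio=float(elastic.get("poisson_ratio", 0.49)),
            regime=elastic.get("regime", "plane_stress"),
        ),
        resolution=Resolution(**res_kwargs),
        on_overlap=numerics.get("on_overlap", "error"),
    )
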