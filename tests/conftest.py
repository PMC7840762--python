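"""Shared fixtures: coarse field solves and small gamma tables, computed once."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from depstretch import (
    COARSE,
    ElectrodePair,
    Resolution,
    StretchConfig,
    solve_potential,
    solve_uniform_field_disk,
)

warnings.filterwarnings("ignore", message="max boundary displacement")


@pytest.fixture(scope="session")
def uniform_disk_solution():
    """Dielectric cylinder (eps 120) in a uniform 1e5 V/m field in medium eps 80."""
    return solve_uniform_field_disk(
        4.0, 80.0, 120.0, 1e5, resolution=Resolution(nodes_per_radius=20)
    )


@pytest.fixture(scope="session")
def chip_config():
    """Reference chip: rect/rect, w=30, d=45 um, R=4 um cell, 80/120, 10 V."""
    return StretchConfig(
        pair=ElectrodePair(width_um=30.0, gap_um=45.0),
        cell_radius_um=4.0,
        resolution=Resolution(nodes_per_radius=10, stations=180),
    )


@pytest.fixture(scope="session")
def chip_solution(chip_config):
    geom = chip_config.geometry()
    return solve_potential(
        geom, chip_config.eps_m, chip_config.eps_c, chip_config.voltage,
        chip_config.resolution,
    )


@pytest.fixture(scope="session")
def coarse_resolution():
    return COARSE


@pytest.fixture(scope="session")
def tiny_gamma_table():
    """2x2x2 gamma table simulated at very coarse resolution (fast)."""
    from depstretch import build_gamma_table
    from depstretch.electrode_optimizer import default_base_config

    base = default_base_config(Resolution(nodes_per_radius=6, stations=120))
    return build_gamma_table([3.0, 5.0], [30.0, 60.0], [20.0, 40.0], base)


@pytest.fixture(scope="session")
def default_gamma():
    from depstretch import load_default_gamma

    return load_default_gamma()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
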