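"""Shared fixtures: reference cell/medium/drive, synthetic fields, and the
session-scoped device solves used by the slower physics tests."""

from __future__ import annotations

import numpy as np
import pytest

from depmc import (
    DriveSettings,
    ElectrodeLayout,
    MediumParams,
    ShellCellModel,
    SimulationGrid,
    compute_field,
    effective_polarizability,
    solve_device,
)
from depmc.field import FieldGrid


@pytest.fixture(scope="session")
def cell():
    return ShellCellModel()


@pytest.fixture(scope="session")
def medium():
    return MediumParams()


@pytest.fixture(scope="session")
def drive():
    return DriveSettings()


@pytest.fixture(scope="session")
def alpha_1mhz(cell, medium, drive):
    return effective_polarizability(cell, medium, drive.omega)


def make_uniform_field(grid: SimulationGrid, e_vec) -> FieldGrid:
    """Synthetic spatially uniform E_rms field (zero DEP force)."""
    nx, ny, nz = grid.shape
    e_vec = np.asarray(e_vec, float)
    fg = FieldGrid(grid=grid, potential=np.zeros(grid.shape))
    fg.erms = np.broadcast_to(e_vec, (nx, ny, nz, 3)).copy()
    fg.erms_sq = np.full(grid.shape, float(e_vec @ e_vec))
    fg.grad_erms_sq = np.zeros((nx, ny, nz, 3))
    return fg


def make_synthetic_field(grid: SimulationGrid, erms_sq: np.ndarray,
                         erms: np.ndarray | None = None) -> FieldGrid:
    """Synthetic field with prescribed |E_rms|^2 (and optional vectors)."""
    nx, ny, nz = grid.shape
    fg = FieldGrid(grid=grid, potential=np.zeros(grid.shape))
    fg.erms = (erms if erms is not None
               else np.zeros((nx, ny, nz, 3)))
    fg.erms_sq = erms_sq
    d = grid.spacing
    fg.grad_erms_sq = np.zeros((nx, ny, nz, 3))
    for axis, n in enumerate((nx, ny, nz)):
        if n >= 2:  # degenerate axes keep zero gradient
            fg.grad_erms_sq[..., axis] = np.gradient(erms_sq, d, axis=axis)
    return fg


@pytest.fixture(scope="session")
def scaled_layout():
    # quarter-scale device: 400 um box with proportionally scaled electrodes
    return ElectrodeLayout(half_gap_D=97.5e-6, extent_L=115e-6)


@pytest.fixture(scope="session")
def scaled_grid():
    return SimulationGrid((400e-6, 400e-6, 400e-6), 6.2e-6)


@pytest.fixture(scope="session")
def scaled_field(scaled_layout, scaled_grid, drive):
    return solve_device(scaled_layout, scaled_grid, drive)


@pytest.fixture(scope="session")
def device_layout():
    return ElectrodeLayout()


@pytest.fixture(scope="session")
def device_grid():
    return SimulationGrid()


@pytest.fixture(scope="session")
def device_field(device_layout, device_grid, drive):
    """Full-resolution reference device solve (6.2 um grid); shared by the
    capture-depth and concentration-factor checks."""
    return solve_device(device_layout, device_grid, drive, coarsen_levels=3)
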