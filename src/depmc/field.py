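"""Polynomial-electrode geometry and the 3D Laplace field solve.

Four planar electrodes with hyperbolic edges (``u^2 - v^2 = D^2`` along each
half-axis, truncated at ``u = L``) sit on the bottom plane of a closed
chamber and are driven in antiphase.  The quasi-static potential is obtained
from one Laplace solve at the peak drive amplitude on a node-centered cubic
grid (7-point finite differences, red-black SOR with nested coarse-to-fine
initialization); the oscillation enters only through the rms convention
``E_rms = E_peak / sqrt(2)``.

Boundary conditions: Dirichlet (+/- amplitude) on electrode nodes; all other
chamber walls are insulating (homogeneous Neumann) by default, with a
grounded-wall option for sensitivity checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .dielectric import DomainError, DriveSettings


class GeometryError(ValueError):
    """Electrode layout incompatible with the grid."""


class SolverError(RuntimeError):
    """Laplace iteration failed to reach the residual tolerance."""

    def __init__(self, msg: str, residual: float):
        super().__init__(msg)
        self.residual = residual


# ---------------------------------------------------------------------------
# geometry containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ElectrodeLayout:
    """Quadrupole polynomial-electrode layout.

    ``half_gap_D`` is half the tip-to-tip distance of opposing electrodes
    (the electrode tip sits at distance D from the center); ``extent_L``
    truncates each electrode with a straight cut at axis coordinate L.
    ``edge_convention`` selects which algebraic reading of the edge curve is
    used to rasterize each electrode; the two readings describe conjugate
    branches of the same hyperbola family and yield the identical
    four-electrode union.
    """

    half_gap_D: float = 390e-6   # m
    extent_L: float = 460e-6     # m
    signs: tuple[int, ...] = (1, -1, 1, -1)   # +x, +y, -x, -y
    edge_convention: str = "hyperbola"        # or "conjugate"
    truncation_margin: float = 0.0            # extra extent past L (m)

    def __post_init__(self):
        if not 0 < self.half_gap_D < self.extent_L:
            raise DomainError("require 0 < D < L")
        if len(self.signs) != 4 or set(self.signs) - {1, -1}:
            raise DomainError("signs must be four +1/-1 values")
        if self.signs[0] != self.signs[2] or self.signs[1] != self.signs[3] \
                or self.signs[0] == self.signs[1]:
            raise DomainError("opposite electrodes share sign, adjacent differ")
        if self.edge_convention not in ("hyperbola", "conjugate"):
            raise DomainError("edge_convention must be hyperbola|conjugate")


@dataclass(frozen=True)
class SimulationGrid:
    """Node-centered cubic lattice over the chamber.

    Origin at the box center in x, y and at the bottom plane in z; spacing
    defaults to the cell radius so MC particles live on field nodes.
    """

    box: tuple[float, float, float] = (1600e-6, 1600e-6, 1500e-6)
    spacing: float = 6.2e-6

    def __post_init__(self):
        if self.spacing <= 0 or any(b <= 0 for b in self.box):
            raise DomainError("box dimensions and spacing must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(int(round(b / self.spacing)) + 1 for b in self.box)

    @property
    def x(self) -> np.ndarray:
        n = self.shape[0]
        return (np.arange(n) - (n - 1) / 2.0) * self.spacing

    @property
    def y(self) -> np.ndarray:
        n = self.shape[1]
        return (np.arange(n) - (n - 1) / 2.0) * self.spacing

    @property
    def z(self) -> np.ndarray:
        return np.arange(self.shape[2]) * self.spacing

    @property
    def n_nodes(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    def coarsened(self, factor: int) -> "SimulationGrid":
        return SimulationGrid(self.box, self.spacing * factor)


@dataclass
class FieldGrid:
    """Solved field on the simulation grid.

    Holds the scalar potential (V) and, after :func:`compute_field`, the rms
    field vector (V/m), its squared magnitude and the gradient of the squared
    magnitude, all on grid nodes.
    """

    grid: SimulationGrid
    potential: np.ndarray
    electrode_sign: np.ndarray | None = None   # (nx, ny) int8 bottom plane
    erms: np.ndarray | None = None             # (nx, ny, nz, 3)
    erms_sq: np.ndarray | None = None          # (nx, ny, nz)
    grad_erms_sq: np.ndarray | None = None     # (nx, ny, nz, 3)


# ---------------------------------------------------------------------------
# electrode rasterization
# ---------------------------------------------------------------------------


def _electrode_regions(layout: ElectrodeLayout, X, Y):
    """Boolean masks for the four electrodes, order (+x, +y, -x, -y)."""
    D, L = layout.half_gap_D, layout.extent_L + layout.truncation_margin
    # boundary-inclusive rasterization: nodes exactly on the edge curve
    # (e.g. the tip at u = D) belong to the electrode despite float rounding
    tol = 1e-9 * D
    if layout.edge_convention == "hyperbola":
        # electrode along +u: D <= u <= L, |v| <= sqrt(u^2 - D^2)
        def along(u, v):
            return ((u >= D - tol) & (u <= L + tol)
                    & (u**2 - v**2 >= D**2 - 2 * D * tol))
    else:
        # conjugate reading: edge v = +/- sqrt(u'^2 + D^2) bounds the same
        # region seen from the transverse axis: u >= sqrt(v^2 + D^2), u <= L
        def along(u, v):
            return (u <= L + tol) & (u >= np.sqrt(v**2 + D**2) - tol)
    return [along(X, Y), along(Y, X), along(-X, Y), along(-Y, X)]


def build_electrode_mask(
    layout: ElectrodeLayout, grid: SimulationGrid
) -> np.ndarray:
    """Rasterize the four electrodes onto the bottom plane.

    Returns an (nx, ny) int8 array: 0 off-electrode, otherwise the drive
    sign (+1/-1) of the electrode covering that node.  A node belongs to an
    electrode when its center lies inside the electrode region.
    """
    X, Y = np.meshgrid(grid.x, grid.y, indexing="ij")
    regions = _electrode_regions(layout, X, Y)
    sign = np.zeros(X.shape, dtype=np.int8)
    covered = np.zeros(X.shape, dtype=bool)
    for reg, s in zip(regions, layout.signs):
        if not reg.any():
            raise GeometryError(
                "an electrode rasterizes to zero nodes (grid too coarse)"
            )
        if (covered & reg).any():
            raise GeometryError("electrode regions overlap on the grid")
        covered |= reg
        sign[reg] = s
    return sign


def characteristic_gaps(layout: ElectrodeLayout) -> tuple[float, float]:
    """Gap widths (L1, L2) between opposing electrode pairs.

    L1 = 2D is the tip-to-tip gap through the center; L2 is the corner
    distance between adjacent electrodes across the diagonal,
    sqrt(2) (L - sqrt(L^2 - D^2)).  L2 -> 0 as L -> inf (the hyperbola
    approaches its asymptote).
    """
    D, L = layout.half_gap_D, layout.extent_L
    if L <= D:
        raise DomainError("require L > D")
    return 2.0 * D, math.sqrt(2.0) * (L - math.sqrt(L * L - D * D))


# ---------------------------------------------------------------------------
# Laplace solver (7-point FD, red-black SOR)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _sor_sweep(phi, fixed, relax):
    nx, ny, nz = phi.shape
    for color in range(2):
        for i in range(nx):
            im = i - 1 if i > 0 else 1
            ip = i + 1 if i < nx - 1 else nx - 2
            for j in range(ny):
                jm = j - 1 if j > 0 else 1
                jp = j + 1 if j < ny - 1 else ny - 2
                k0 = (color + i + j) % 2
                for k in range(k0, nz, 2):
                    if fixed[i, j, k]:
                        continue
                    km = k - 1 if k > 0 else 1
                    kp = k + 1 if k < nz - 1 else nz - 2
                    s = (phi[im, j, k] + phi[ip, j, k]
                         + phi[i, jm, k] + phi[i, jp, k]
                         + phi[i, j, km] + phi[i, j, kp])
                    phi[i, j, k] += relax * (s / 6.0 - phi[i, j, k])


@njit(cache=True)
def _residual_norm(phi, fixed):
    nx, ny, nz = phi.shape
    acc = 0.0
    for i in range(nx):
        im = i - 1 if i > 0 else 1
        ip = i + 1 if i < nx - 1 else nx - 2
        for j in range(ny):
            jm = j - 1 if j > 0 else 1
            jp = j + 1 if j < ny - 1 else ny - 2
            for k in range(nz):
                if fixed[i, j, k]:
                    continue
                km = k - 1 if k > 0 else 1
                kp = k + 1 if k < nz - 1 else nz - 2
                r = (phi[im, j, k] + phi[ip, j, k]
                     + phi[i, jm, k] + phi[i, jp, k]
                     + phi[i, j, km] + phi[i, j, kp]) - 6.0 * phi[i, j, k]
                acc += r * r
    return math.sqrt(acc)


def solve_laplace(
    fixed_mask: np.ndarray,
    fixed_values: np.ndarray,
    tol: float = 1e-6,
    max_sweeps: int | None = None,
    relax: float | None = None,
    initial: np.ndarray | None = None,
    check_every: int = 25,
) -> np.ndarray:
    """Solve the discrete Laplace equation with mixed Dirichlet/Neumann BCs.

    ``fixed_mask`` marks Dirichlet nodes (held at ``fixed_values``); every
    unmasked boundary face is treated as insulating (mirror ghost nodes).
    The relative residual is measured against the residual of the
    boundary-data-only state, so it is independent of the initial guess.
    """
    if not fixed_mask.any():
        raise DomainError("at least one Dirichlet node required")
    shape = fixed_mask.shape
    n_max = max(shape)
    if relax is None:
        relax = 2.0 / (1.0 + math.sin(math.pi / n_max))
    if max_sweeps is None:
        max_sweeps = max(200, 40 * n_max)

    fixed = np.ascontiguousarray(fixed_mask.astype(np.uint8))
    bc_only = np.zeros(shape)
    bc_only[fixed_mask] = fixed_values[fixed_mask]
    scale = _residual_norm(bc_only, fixed)
    if scale == 0.0:
        scale = 1.0  # all-zero boundary data: exact solution is zero

    if initial is not None:
        phi = np.ascontiguousarray(initial.astype(float).copy())
    else:
        phi = bc_only.copy()
    phi[fixed_mask] = fixed_values[fixed_mask]

    residual = _residual_norm(phi, fixed) / scale
    sweeps = 0
    while residual > tol:
        if sweeps >= max_sweeps:
            raise SolverError(
                f"SOR did not reach tol={tol:g} in {sweeps} sweeps "
                f"(relative residual {residual:.3e})",
                residual,
            )
        for _ in range(min(check_every, max_sweeps - sweeps)):
            _sor_sweep(phi, fixed, relax)
            sweeps += 1
        residual = _residual_norm(phi, fixed) / scale
    return phi


def _dirichlet_arrays(sign2d, grid, amplitude, boundary):
    nx, ny, nz = grid.shape
    fixed = np.zeros((nx, ny, nz), dtype=bool)
    vals = np.zeros((nx, ny, nz))
    fixed[:, :, 0] = sign2d != 0
    vals[:, :, 0] = sign2d * amplitude
    if boundary == "dirichlet0":
        fixed[0, :, :] = fixed[-1, :, :] = True
        fixed[:, 0, :] = fixed[:, -1, :] = True
        fixed[:, :, -1] = True
        # electrode values on the bottom edge rows take precedence
        vals[0, :, :] = vals[-1, :, :] = 0.0
        vals[:, 0, :] = vals[:, -1, :] = 0.0
        vals[:, :, -1] = 0.0
        vals[:, :, 0] = sign2d * amplitude
        fixed[:, :, 0] = sign2d != 0
    elif boundary != "neumann":
        raise DomainError("boundary must be neumann|dirichlet0")
    return fixed, vals


def solve_potential(
    sign2d: np.ndarray,
    grid: SimulationGrid,
    drive: DriveSettings,
    tol: float = 1e-6,
    boundary: str = "neumann",
    initial: np.ndarray | None = None,
    max_sweeps: int | None = None,
) -> FieldGrid:
    """Solve for the peak-drive potential of a rasterized electrode plane."""
    fixed, vals = _dirichlet_arrays(sign2d, grid, drive.peak_amplitude, boundary)
    phi = solve_laplace(fixed, vals, tol=tol, initial=initial,
                        max_sweeps=max_sweeps)
    return FieldGrid(grid=grid, potential=phi, electrode_sign=sign2d)


def solve_device(
    layout: ElectrodeLayout,
    grid: SimulationGrid,
    drive: DriveSettings,
    tol: float = 1e-6,
    boundary: str = "neumann",
    coarsen_levels: int = 2,
) -> FieldGrid:
    """Full device solve: rasterize, nested coarse-to-fine SOR, then fields.

    The coarse-level solutions serve purely as initial guesses; the fine
    level is always iterated to the requested tolerance.
    """
    from scipy.interpolate import RegularGridInterpolator

    phi_prev = None
    grids = [grid.coarsened(2**lvl) for lvl in range(coarsen_levels, -1, -1)]
    for g in grids:
        sign2d = build_electrode_mask(layout, g)
        initial = None
        if phi_prev is not None:
            gp = g_prev
            interp = RegularGridInterpolator(
                (gp.x, gp.y, gp.z), phi_prev, bounds_error=False, fill_value=None
            )
            XX, YY, ZZ = np.meshgrid(g.x, g.y, g.z, indexing="ij")
            pts = np.stack([XX.ravel(), YY.ravel(), ZZ.ravel()], axis=1)
            initial = interp(pts).reshape(g.shape)
        fg = solve_potential(sign2d, g, drive, tol=tol, boundary=boundary,
                             initial=initial)
        phi_prev, g_prev = fg.potential, g
    return compute_field(fg)


def compute_field(fg: FieldGrid) -> FieldGrid:
    """Fill E_rms, |E_rms|^2 and grad|E_rms|^2 from the stored potential.

    Centered differences in the interior, one-sided at boundaries
    (``np.gradient``); the rms convention divides the peak field by sqrt(2).
    """
    if fg.potential is None:
        raise DomainError("potential must be solved first")
    d = fg.grid.spacing
    gx, gy, gz = np.gradient(fg.potential, d, d, d)
    erms = np.stack([-gx, -gy, -gz], axis=-1) / math.sqrt(2.0)
    erms_sq = np.einsum("...c,...c->...", erms, erms)
    ggx, ggy, ggz = np.gradient(erms_sq, d, d, d)
    fg.erms = erms
    fg.erms_sq = erms_sq
    fg.grad_erms_sq = np.stack([ggx, ggy, ggz], axis=-1)
    return fg
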