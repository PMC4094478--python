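"""Metropolis equilibration of interacting particles on the lattice.

Particles perform single-node jumps on the cubic lattice (6- or 26-neighbor
move set); a proposed move is accepted with the Metropolis probability
min(1, exp(-dE/kT)), which makes the chain converge to the Boltzmann
distribution of the configuration energy.  Proposals that leave the box or
violate hard-sphere exclusion are rejected (reflecting walls, no periodic
images).  Iteration counts refer to proposals, not accepted moves.

The mapping from Monte Carlo events to physical time treats the hop
sequence as an effective diffusion: the mean time between two consecutive
displacement events of the whole system is

    N dt = (1/6) dd^2 / D_Brownian,   D = kT / (c pi eta a)

with c = 3 as printed in the source model ("paper" mode) or the
Stokes-Einstein c = 6 ("stokes" mode).  The mapping affects reporting only,
never the equilibrium distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .dielectric import DomainError, MediumParams
from .energy import Configuration, ExclusionError
from .field import FieldGrid, SimulationGrid
from .units import EPS0, KB


class DensityError(RuntimeError):
    """Random placement failed: the requested density is too high."""


@dataclass(frozen=True)
class MCSettings:
    """Iteration budget, RNG seed and move rules of one equilibration run."""

    iterations: int = 10_000_000
    seed: int = 0
    temperature: float = 295.15          # K
    move_set: str = "6"                  # "6" or "26" neighbor jumps
    displacement: float | None = None    # dd (m); default = lattice spacing
    cutoff: float = 124e-6               # pair-interaction cutoff (m)
    sampling_interval: int | None = None # default iterations // 100
    time_mode: str = "paper"             # "paper" (3 pi eta a) or "stokes"
    acceptance_rule: str = "metropolis"  # or "glauber"

    def __post_init__(self):
        if self.iterations <= 0:
            raise DomainError("iterations must be > 0")
        if self.temperature <= 0:
            raise DomainError("temperature must be > 0")
        if self.move_set not in ("6", "26"):
            raise DomainError("move_set must be '6' or '26'")
        if self.time_mode not in ("paper", "stokes"):
            raise DomainError("time_mode must be paper|stokes")
        if self.acceptance_rule not in ("metropolis", "glauber"):
            raise DomainError("acceptance_rule must be metropolis|glauber")


@dataclass
class Trajectory:
    """Sampled snapshots of an equilibration run (positions in node units)."""

    iterations: np.ndarray          # (S,) proposal counts, strictly increasing
    times: np.ndarray               # (S,) mapped physical time (s)
    positions: np.ndarray           # (S, N, 3) int
    dep_energy: np.ndarray          # (S,)
    pair_energy: np.ndarray         # (S,)
    acceptance_rate: float
    settings: MCSettings
    grid: SimulationGrid

    @property
    def total_energy(self) -> np.ndarray:
        return self.dep_energy + self.pair_energy

    def final_configuration(self, radius: float, alpha: float) -> Configuration:
        return Configuration(self.grid, self.positions[-1].copy(),
                             radius, alpha)


# ---------------------------------------------------------------------------
# initialization and elementary steps (python contract level)
# ---------------------------------------------------------------------------


def particles_for_density(density_per_ml: float, grid: SimulationGrid) -> int:
    """Particle count matching a target concentration in the box volume."""
    if density_per_ml < 0:
        raise DomainError("density must be >= 0")
    vol_ml = np.prod([b * 1e2 for b in grid.box])  # m -> cm, cm^3 == ml
    return int(round(density_per_ml * vol_ml))


def init_random(n_particles: int, grid: SimulationGrid, seed: int,
                radius: float, alpha: float,
                exclusion_radius_nodes: float = 2.0,
                max_tries_per_particle: int = 2000) -> Configuration:
    """Seeded uniform random non-overlapping placement on the lattice."""
    rng = np.random.default_rng(seed)
    cfg = Configuration(grid, np.empty((0, 3), dtype=np.int64), radius, alpha,
                        exclusion_radius_nodes=exclusion_radius_nodes)
    shape = grid.shape
    placed = []
    for i in range(n_particles):
        for attempt in range(max_tries_per_particle):
            node = tuple(int(rng.integers(0, n)) for n in shape)
            if cfg.is_free(node):
                cfg._occupancy[node] = i
                placed.append(node)
                break
        else:
            raise DensityError(
                f"could not place particle {i} of {n_particles}")
    cfg.positions = np.array(placed, dtype=np.int64).reshape(-1, 3)
    return cfg


_MOVES_6 = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0],
                     [0, -1, 0], [0, 0, 1], [0, 0, -1]], dtype=np.int64)
_MOVES_26 = np.array([[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1)
                      for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)],
                     dtype=np.int64)


def move_offsets(move_set: str) -> np.ndarray:
    return _MOVES_6 if move_set == "6" else _MOVES_26


def propose_move(config: Configuration, rng: np.random.Generator,
                 move_set: str = "6") -> tuple[int, tuple[int, int, int]]:
    """Uniform particle, uniform neighbor target (may be invalid: the caller
    rejects out-of-box or excluded targets)."""
    if len(config) == 0:
        raise DomainError("empty configuration")
    offsets = move_offsets(move_set)
    idx = int(rng.integers(0, len(config)))
    off = offsets[int(rng.integers(0, len(offsets)))]
    target = tuple(int(c) for c in config.positions[idx] + off)
    return idx, target


def metropolis_accept(delta_e: float, temperature: float,
                      rng: np.random.Generator) -> bool:
    """Standard Metropolis rule: accept with probability min(1, e^(-dE/kT))."""
    if temperature <= 0:
        raise DomainError("temperature must be > 0")
    if delta_e <= 0:
        return True
    x = delta_e / (KB * temperature)
    if x > 700:
        return False
    return float(rng.random()) < math.exp(-x)


def physical_time_per_event(mc: MCSettings, medium: MediumParams,
                            cell_radius: float, n_particles: int,
                            displacement: float | None = None) -> float:
    """Physical time per proposal event (s) from the diffusive mapping."""
    if n_particles <= 0 or cell_radius <= 0:
        raise DomainError("n_particles and cell_radius must be > 0")
    dd = displacement if displacement is not None else mc.displacement
    if dd is None:
        raise DomainError("displacement required (none set in MCSettings)")
    c = 3.0 if mc.time_mode == "paper" else 6.0
    drag = c * math.pi * medium.viscosity * cell_radius
    return dd * dd * drag / (6.0 * n_particles * KB * mc.temperature)


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _pair_u(k_pair, xi, yi, zi, xj, yj, zj,
            ei0, ei1, ei2, ej0, ej1, ej2):
    rx = xj - xi
    ry = yj - yi
    rz = zj - zi
    r2 = rx * rx + ry * ry + rz * rz
    r = math.sqrt(r2)
    mi = math.sqrt(ei0 * ei0 + ei1 * ei1 + ei2 * ei2)
    mj = math.sqrt(ej0 * ej0 + ej1 * ej1 + ej2 * ej2)
    ci = (rx * ei0 + ry * ei1 + rz * ei2) / (r * mi) if mi > 0.0 else 0.0
    cj = (rx * ej0 + ry * ej1 + rz * ej2) / (r * mj) if mj > 0.0 else 0.0
    eiej = ei0 * ej0 + ei1 * ej1 + ei2 * ej2
    return k_pair * (1.0 - 3.0 * ci * cj) / (r2 * r) * eiej


@njit(cache=True)
def _pair_sum_around(node_i, ix, iy, iz, pos, x, y, z, erms,
                     head, nxt, s_cell, ncx, ncy, ncz, cut2, k_pair, skip):
    """Sum of pair energies between a (virtual) particle at lattice node
    (ix,iy,iz) and all real particles within the cutoff, excluding ``skip``."""
    xi, yi, zi = x[ix], y[iy], z[iz]
    ei0, ei1, ei2 = erms[ix, iy, iz, 0], erms[ix, iy, iz, 1], erms[ix, iy, iz, 2]
    ci = ix // s_cell
    cj = iy // s_cell
    ck = iz // s_cell
    acc = 0.0
    for di in range(-1, 2):
        a = ci + di
        if a < 0 or a >= ncx:
            continue
        for dj in range(-1, 2):
            b = cj + dj
            if b < 0 or b >= ncy:
                continue
            for dk in range(-1, 2):
                c = ck + dk
                if c < 0 or c >= ncz:
                    continue
                j = head[(a * ncy + b) * ncz + c]
                while j >= 0:
                    if j != skip:
                        jx, jy, jz = pos[j, 0], pos[j, 1], pos[j, 2]
                        dxm = x[jx] - xi
                        dym = y[jy] - yi
                        dzm = z[jz] - zi
                        d2 = dxm * dxm + dym * dym + dzm * dzm
                        if 0.0 < d2 <= cut2:
                            acc += _pair_u(
                                k_pair, xi, yi, zi, x[jx], y[jy], z[jz],
                                ei0, ei1, ei2,
                                erms[jx, jy, jz, 0], erms[jx, jy, jz, 1],
                                erms[jx, jy, jz, 2])
                    j = nxt[j]
    return acc


@njit(cache=True)
def _cell_index(ix, iy, iz, s_cell, ncy, ncz):
    return ((ix // s_cell) * ncy + (iy // s_cell)) * ncz + (iz // s_cell)


@njit(cache=True)
def _cell_remove(head, nxt, cell, p):
    j = head[cell]
    if j == p:
        head[cell] = nxt[p]
        return
    while nxt[j] != p:
        j = nxt[j]
    nxt[j] = nxt[p]


@njit(cache=True)
def _mc_kernel(pos, x, y, z, erms, udep, occupancy,
               excl_offsets, moves, k_pair, cut2, s_cell, kT,
               n_steps, seed, sample_interval, glauber,
               samples, samp_iter, samp_dep, samp_pair):
    np.random.seed(seed)
    nx, ny, nz = udep.shape
    n = pos.shape[0]
    n_moves = moves.shape[0]
    n_excl = excl_offsets.shape[0]
    ncx = (nx + s_cell - 1) // s_cell
    ncy = (ny + s_cell - 1) // s_cell
    ncz = (nz + s_cell - 1) // s_cell

    head = np.full(ncx * ncy * ncz, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    for p in range(n):
        occupancy[pos[p, 0], pos[p, 1], pos[p, 2]] = p
        c = _cell_index(pos[p, 0], pos[p, 1], pos[p, 2], s_cell, ncy, ncz)
        nxt[p] = head[c]
        head[c] = p

    dep_sum = 0.0
    pair_sum = 0.0
    for p in range(n):
        dep_sum += udep[pos[p, 0], pos[p, 1], pos[p, 2]]
        pair_sum += 0.5 * _pair_sum_around(
            p, pos[p, 0], pos[p, 1], pos[p, 2], pos, x, y, z, erms,
            head, nxt, s_cell, ncx, ncy, ncz, cut2, k_pair, p)

    n_samp = 0
    samples[0] = pos
    samp_iter[0] = 0
    samp_dep[0] = dep_sum
    samp_pair[0] = pair_sum
    n_samp = 1

    accepted = 0
    for step in range(n_steps):
        if n > 0:
            p = np.random.randint(0, n)
            m = np.random.randint(0, n_moves)
            ox, oy, oz = pos[p, 0], pos[p, 1], pos[p, 2]
            tx = ox + moves[m, 0]
            ty = oy + moves[m, 1]
            tz = oz + moves[m, 2]
            ok = (0 <= tx < nx) and (0 <= ty < ny) and (0 <= tz < nz)
            if ok:
                for e in range(n_excl):
                    q = occupancy[tx + excl_offsets[e, 0],
                                  ty + excl_offsets[e, 1],
                                  tz + excl_offsets[e, 2]] \
                        if (0 <= tx + excl_offsets[e, 0] < nx
                            and 0 <= ty + excl_offsets[e, 1] < ny
                            and 0 <= tz + excl_offsets[e, 2] < nz) else -1
                    if q >= 0 and q != p:
                        ok = False
                        break
            if ok:
                d_dep = udep[tx, ty, tz] - udep[ox, oy, oz]
                u_new = _pair_sum_around(p, tx, ty, tz, pos, x, y, z, erms,
                                         head, nxt, s_cell, ncx, ncy, ncz,
                                         cut2, k_pair, p)
                u_old = _pair_sum_around(p, ox, oy, oz, pos, x, y, z, erms,
                                         head, nxt, s_cell, ncx, ncy, ncz,
                                         cut2, k_pair, p)
                d_e = d_dep + (u_new - u_old)
                xr = d_e / kT
                if glauber:
                    if xr > 700.0:
                        acc = False
                    elif xr < -700.0:
                        acc = True
                    else:
                        acc = np.random.random() < 1.0 / (1.0 + math.exp(xr))
                else:
                    if xr <= 0.0:
                        acc = True
                    elif xr > 700.0:
                        acc = False
                    else:
                        acc = np.random.random() < math.exp(-xr)
                if acc:
                    occupancy[ox, oy, oz] = -1
                    occupancy[tx, ty, tz] = p
                    c_old = _cell_index(ox, oy, oz, s_cell, ncy, ncz)
                    c_new = _cell_index(tx, ty, tz, s_cell, ncy, ncz)
                    if c_old != c_new:
                        _cell_remove(head, nxt, c_old, p)
                        nxt[p] = head[c_new]
                        head[c_new] = p
                    pos[p, 0] = tx
                    pos[p, 1] = ty
                    pos[p, 2] = tz
                    dep_sum += d_dep
                    pair_sum += u_new - u_old
                    accepted += 1
        if (step + 1) % sample_interval == 0:
            samples[n_samp] = pos
            samp_iter[n_samp] = step + 1
            samp_dep[n_samp] = dep_sum
            samp_pair[n_samp] = pair_sum
            n_samp += 1
    return accepted, n_samp


def run(config: Configuration, fg: FieldGrid, mc: MCSettings,
        medium: MediumParams) -> Trajectory:
    """Equilibrate ``config`` in the solved field under ``mc`` settings.

    Returns the sampled trajectory, including the initial state as snapshot
    zero and the final (equilibrated) state as the last snapshot.  Identical
    (seed, settings) yield bit-identical trajectories.
    """
    if fg.erms is None or fg.erms_sq is None:
        raise DomainError("field must have E_rms computed (compute_field)")
    if tuple(fg.grid.shape) != tuple(config.grid.shape):
        raise DomainError("configuration and field grids differ")
    grid = config.grid
    nx, ny, nz = grid.shape
    n = len(config)
    interval = mc.sampling_interval or max(1, mc.iterations // 100)
    n_samples = mc.iterations // interval + 1

    if n == 0:
        its = np.arange(0, mc.iterations + 1, interval, dtype=np.int64)
        zeros = np.zeros(its.size)
        return Trajectory(its, zeros.copy(), np.zeros((its.size, 0, 3),
                          dtype=np.int64), zeros.copy(), zeros.copy(),
                          0.0, mc, grid)

    pos = np.ascontiguousarray(config.positions.copy())
    occupancy = np.full((nx, ny, nz), -1, dtype=np.int64)
    udep = np.ascontiguousarray(-0.5 * config.alpha * fg.erms_sq)
    erms = np.ascontiguousarray(fg.erms)

    excl2 = config.exclusion_radius_nodes**2
    r = int(math.ceil(config.exclusion_radius_nodes))
    excl_offsets = np.array(
        [(i, j, k) for i in range(-r, r + 1) for j in range(-r, r + 1)
         for k in range(-r, r + 1) if 0 <= i * i + j * j + k * k < excl2],
        dtype=np.int64)
    moves = move_offsets(mc.move_set)
    k_pair = config.alpha**2 / (4.0 * math.pi * medium.eps_rel * EPS0)
    s_cell = max(1, int(math.ceil(mc.cutoff / grid.spacing)))

    samples = np.zeros((n_samples + 1, max(n, 1), 3), dtype=np.int64)
    samp_iter = np.zeros(n_samples + 1, dtype=np.int64)
    samp_dep = np.zeros(n_samples + 1)
    samp_pair = np.zeros(n_samples + 1)

    accepted, n_samp = _mc_kernel(
        pos, np.ascontiguousarray(grid.x), np.ascontiguousarray(grid.y),
        np.ascontiguousarray(grid.z), erms, udep, occupancy,
        excl_offsets, moves, k_pair, mc.cutoff * mc.cutoff, s_cell,
        KB * mc.temperature, mc.iterations, mc.seed, interval,
        mc.acceptance_rule == "glauber",
        samples, samp_iter, samp_dep, samp_pair)

    dd = mc.displacement if mc.displacement is not None else grid.spacing
    dt = physical_time_per_event(mc, medium, config.radius, max(n, 1),
                                 displacement=dd)
    its = samp_iter[:n_samp]
    traj = Trajectory(
        iterations=its.copy(),
        times=its * dt,
        positions=samples[:n_samp, :n].copy(),
        dep_energy=samp_dep[:n_samp].copy(),
        pair_energy=samp_pair[:n_samp].copy(),
        acceptance_rate=accepted / mc.iterations,
        settings=mc,
        grid=grid,
    )
    # reflect the equilibrated state back into the caller's configuration
    config.positions = pos
    config._occupancy.clear()
    for idx, node in enumerate(map(tuple, pos)):
        config._occupancy[node] = idx
    config.dep_sum = float(samp_dep[n_samp - 1])
    config.pair_sum = float(samp_pair[n_samp - 1])
    return traj
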