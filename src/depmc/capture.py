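"""Device design metrics: DEP concentration factor, capture depth,
interaction-free concentration thresholds, and chain statistics.

The settling picture behind the thresholds: induced-dipole interactions
between neighbouring cells become significant when the ratio of cell
spacing to cell diameter drops below about 5.  If all cells settle
uniformly onto the chamber floor, the spacing at concentration C is
1/(d sqrt(h C)), giving the bound C < 1/(25 d^2 h).  Two corrections tie
the bound to the actual device physics: the DEP force concentrates settled
cells at electrode edges by the factor

    r_DEP = max |grad E^2| / < |grad E^2| >        (chamber floor)

and only cells within the capture depth z_capture — the depth from which a
cell reaches the floor within the deposition time at the Stokes terminal
velocity of the laterally averaged vertical DEP force — settle at all.
The improved threshold is base * (h / z_capture) / r_DEP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial import cKDTree

from .dielectric import DomainError, MediumParams
from .energy import Configuration
from .field import FieldGrid


@dataclass
class CaptureReport:
    """Design-rule summary for one device/run."""

    r_dep: float
    z_capture: float                  # m
    c_threshold_uniform: float        # cells/ml
    c_threshold_improved: float       # cells/ml
    t_dep: float                      # s
    chamber_height: float             # m
    cell_diameter: float              # m
    height_factor: float = field(init=False)

    def __post_init__(self):
        self.height_factor = self.chamber_height / self.z_capture \
            if self.z_capture > 0 else math.inf

    def as_dict(self) -> dict:
        return {
            "r_dep": self.r_dep,
            "z_capture_um": self.z_capture * 1e6,
            "c_threshold_uniform_per_ml": self.c_threshold_uniform,
            "c_threshold_improved_per_ml": self.c_threshold_improved,
            "t_dep_s": self.t_dep,
            "chamber_height_um": self.chamber_height * 1e6,
            "cell_diameter_um": self.cell_diameter * 1e6,
            "height_factor": self.height_factor,
        }


@dataclass
class ChainStats:
    """Cluster/chain statistics of a particle configuration."""

    n_particles: int
    n_clusters: int
    size_histogram: dict[int, int]
    max_chain_length: int
    fraction_in_chains: float         # particles in clusters of size >= 3
    mean_orientation_deg: float | None
    cluster_sizes: list[int]
    cluster_members: list[list[int]]

    def as_dict(self) -> dict:
        return {
            "n_particles": self.n_particles,
            "n_clusters": self.n_clusters,
            "size_histogram": {str(k): v
                               for k, v in sorted(self.size_histogram.items())},
            "max_chain_length": self.max_chain_length,
            "fraction_in_chains": self.fraction_in_chains,
            "mean_orientation_deg": self.mean_orientation_deg,
        }


# ---------------------------------------------------------------------------
# field-derived metrics
# ---------------------------------------------------------------------------


def r_dep(fg: FieldGrid, plane_index: int = 1,
          half_width: float | None = None,
          footprint_mask: np.ndarray | None = None) -> float:
    """DEP concentration factor: max/mean of |grad E_rms^2| on the floor.

    Evaluated on the first interior grid plane by default (the nodal
    gradient is singular at electrode edges on the boundary plane itself).
    The averaging footprint is the full chamber cross-section unless
    restricted to |x|, |y| <= ``half_width`` (m) or to an explicit boolean
    ``footprint_mask`` (nx, ny); the device-level report restricts it to
    the electrode bounding box, where the settled cells actually land.
    >= 1 by construction and invariant under uniform scaling of the drive
    amplitude.  Note the edge singularity of the gradient makes the value
    grid-dependent; compare devices at a fixed spacing.
    """
    if fg.grad_erms_sq is None:
        raise DomainError("field gradients not computed")
    g = np.linalg.norm(fg.grad_erms_sq[:, :, plane_index, :], axis=-1)
    if footprint_mask is None and half_width is not None:
        X, Y = np.meshgrid(fg.grid.x, fg.grid.y, indexing="ij")
        footprint_mask = (np.abs(X) <= half_width) & (np.abs(Y) <= half_width)
    if footprint_mask is not None:
        g = g[footprint_mask]
    mean = float(np.mean(g))
    if mean == 0.0:
        raise DomainError("identically zero gradient field")
    return float(np.max(g)) / mean


def mean_vertical_force_profile(fg: FieldGrid, alpha: float) -> np.ndarray:
    """Lateral average of the vertical DEP potential gradient per z-plane.

    Returns an (nz, 2) array of (z in m, <dU_eff/dz>) with
    U_eff = -(1/2) alpha |E_rms|^2.  For positive alpha above bottom
    electrodes the average is positive (the force -dU/dz points downward).
    """
    if fg.erms_sq is None:
        raise DomainError("field not computed")
    u_eff = -0.5 * alpha * fg.erms_sq
    du_dz = np.gradient(u_eff, fg.grid.spacing, axis=2)
    prof = du_dz.mean(axis=(0, 1))
    return np.stack([fg.grid.z, prof], axis=1)


def z_capture(profile: np.ndarray, t_dep: float, medium: MediumParams,
              r_cell: float, chamber_height: float | None = None) -> float:
    """Capture depth: deepest start z* whose floor travel time is <= t_dep.

    The cell moves at the Stokes terminal velocity
    v_z(z) = <dU_eff/dz>(z) / (6 pi mu r_cell); the capture depth solves
    the travel-time condition  integral_0^{z*} dz / v_z(z) = t_dep.
    Where the force vanishes (or reverses) before the time budget is spent,
    the depth saturates at that point; z* is capped at the chamber height.
    """
    if t_dep < 0:
        raise DomainError("t_dep must be >= 0")
    z = profile[:, 0]
    v = profile[:, 1] / (6.0 * math.pi * medium.viscosity * r_cell)
    if t_dep == 0.0:
        return 0.0
    # positive v = downward drift speed; stop at the first non-positive value
    n_ok = v.size
    for k, vk in enumerate(v):
        if vk <= 0.0:
            n_ok = k
            break
    if n_ok < 2:
        return 0.0
    zz, vv = z[:n_ok], v[:n_ok]
    tt = cumulative_trapezoid(1.0 / vv, zz, initial=0.0)
    cap = chamber_height if chamber_height is not None else z[-1]
    if t_dep >= tt[-1]:
        return float(min(zz[-1], cap))
    zstar = float(np.interp(t_dep, tt, zz))
    return float(min(zstar, cap))


# ---------------------------------------------------------------------------
# concentration thresholds
# ---------------------------------------------------------------------------


def threshold_uniform(h: float, d: float, mode: str = "settling") -> float:
    """Interaction-free concentration bound for uniform settling (cells/ml).

    mode="settling" is the first-principles spacing bound C = 1/(25 d^2 h)
    (delta/d = 5 exactly at the returned concentration).  mode="printed"
    evaluates the literal published prefactor form 4e8/(h d^2) with h and d
    in micrometres; the two modes disagree by a large factor and the
    printed form does not reproduce its own quoted example, so "settling"
    is the default.
    """
    if h <= 0 or d <= 0:
        raise DomainError("h and d must be > 0")
    if mode == "settling":
        per_m3 = 1.0 / (25.0 * d * d * h)
        return per_m3 * 1e-6                       # m^-3 -> ml^-1
    if mode == "printed":
        return 4e8 / ((h * 1e6) * (d * 1e6) ** 2)
    raise DomainError("mode must be settling|printed")


def threshold_improved(base: float, h: float, z_cap: float,
                       r_dep_value: float) -> float:
    """Device-corrected threshold base * (h / z_capture) / r_DEP (cells/ml).

    Reduces to ``base`` when the whole chamber is captured (z_cap = h) and
    the force is laterally uniform (r_DEP = 1).
    """
    if base <= 0 or h <= 0 or z_cap <= 0 or r_dep_value <= 0:
        raise DomainError("all arguments must be > 0")
    if z_cap > h * (1 + 1e-12):
        raise DomainError("z_capture cannot exceed the chamber height")
    return base * (h / z_cap) / r_dep_value


# ---------------------------------------------------------------------------
# chain statistics
# ---------------------------------------------------------------------------


def detect_chains(config: Configuration, fg: FieldGrid | None = None,
                  contact_threshold: float | None = None,
                  z_max: float | None = None) -> ChainStats:
    """Cluster the configuration by center contact and measure chains.

    Clusters are connected components under center distance <= the contact
    threshold (default one particle diameter plus half a lattice spacing,
    absorbing lattice discretization).  Chain length is the graph-geodesic
    extent (number of particles on the longest shortest path) within a
    cluster; orientation compares each >= 3 cluster's principal axis with
    the local E_rms direction at its centroid.  ``z_max`` restricts the
    analysis to particles at height <= z_max (m), e.g. near the floor.
    """
    grid = config.grid
    if contact_threshold is None:
        contact_threshold = 2.0 * config.radius + grid.spacing / 2.0
    pos = config.positions
    pos_m = np.stack([grid.x[pos[:, 0]], grid.y[pos[:, 1]],
                      grid.z[pos[:, 2]]], axis=1)
    if z_max is not None:
        keep = pos_m[:, 2] <= z_max
        pos_m = pos_m[keep]
    n = pos_m.shape[0]
    if n == 0:
        return ChainStats(0, 0, {}, 0, 0.0, None, [], [])
    tree = cKDTree(pos_m)
    pairs = np.array(sorted(tree.query_pairs(contact_threshold)), dtype=int)
    if pairs.size:
        adj = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
            shape=(n, n)).tocsr()
        n_comp, labels = connected_components(adj, directed=False)
    else:
        n_comp, labels = n, np.arange(n)

    sizes, members = [], []
    hist: dict[int, int] = {}
    max_chain = 1 if n else 0
    orientations = []
    for c in range(n_comp):
        idx = np.flatnonzero(labels == c)
        members.append(idx.tolist())
        s = idx.size
        sizes.append(int(s))
        hist[s] = hist.get(s, 0) + 1
        if s >= 2 and pairs.size:
            sub = np.isin(pairs, idx).all(axis=1)
            sub_pairs = pairs[sub]
            remap = {g: l for l, g in enumerate(idx)}
            rows = [remap[i] for i in sub_pairs[:, 0]]
            cols = [remap[j] for j in sub_pairs[:, 1]]
            a = coo_matrix((np.ones(len(rows)), (rows, cols)),
                           shape=(s, s)).tocsr()
            d = shortest_path(a, directed=False, unweighted=True)
            extent = int(d[np.isfinite(d)].max()) + 1
            max_chain = max(max_chain, extent)
        if s >= 3:
            pts = pos_m[idx]
            centered = pts - pts.mean(axis=0)
            _, _, vt = np.linalg.svd(centered, full_matrices=False)
            axis = vt[0]
            if fg is not None and fg.erms is not None:
                centroid = pts.mean(axis=0)
                from .energy import erms_at
                e_local = erms_at(fg, centroid)
                e_norm = np.linalg.norm(e_local)
                if e_norm > 0:
                    cosang = abs(float(axis @ e_local) / e_norm)
                    orientations.append(
                        math.degrees(math.acos(min(1.0, cosang))))
    in_chains = sum(s for s in sizes if s >= 3)
    return ChainStats(
        n_particles=n,
        n_clusters=n_comp,
        size_histogram=hist,
        max_chain_length=max_chain,
        fraction_in_chains=in_chains / n,
        mean_orientation_deg=(float(np.mean(orientations))
                              if orientations else None),
        cluster_sizes=sizes,
        cluster_members=members,
    )


def capture_report(fg: FieldGrid, alpha: float, medium: MediumParams,
                   r_cell: float, t_dep: float,
                   base_threshold: float | None = None,
                   footprint_half_width: float | None = None) -> CaptureReport:
    """Assemble the full design-rule report for a solved device field.

    ``footprint_half_width`` restricts the r_DEP averaging footprint to the
    electrode bounding box (pass the electrode extent L); the vertical force
    profile always averages over the full cross-section, describing settling
    from the whole chamber.
    """
    h = float(fg.grid.z[-1])
    d = 2.0 * r_cell
    prof = mean_vertical_force_profile(fg, alpha)
    zc = z_capture(prof, t_dep, medium, r_cell, chamber_height=h)
    r = r_dep(fg, half_width=footprint_half_width)
    base = (base_threshold if base_threshold is not None
            else threshold_uniform(h, d))
    improved = threshold_improved(base, h, zc, r) if zc > 0 else 0.0
    return CaptureReport(
        r_dep=r, z_capture=zc, c_threshold_uniform=base,
        c_threshold_improved=improved, t_dep=t_dep,
        chamber_height=h, cell_diameter=d,
    )
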