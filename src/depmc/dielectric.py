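"""Single-shell cell dielectric model and Clausius-Mossotti response.

A biological cell in a weakly conducting buffer is modelled as a conducting
aqueous interior wrapped in a thin, nearly insulating membrane.  The shell is
collapsed into one homogeneous sphere with an effective complex permittivity,
from which the Clausius-Mossotti factor

    f_CM(w) = (e_p - e_m) / (e_p + 2 e_m)

and the effective (in-phase) polarizability

    alpha_eff = 3 V Re(e_m) Re f_CM(w)

follow.  ``Re f_CM > 0`` means positive dielectrophoresis: the cell is pulled
toward high-field regions.  All permittivities here are complex,
``e = eps0*eps_rel - i sigma/w``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .units import EPS0


class DomainError(ValueError):
    """An argument is outside the operation's physical domain."""


class SingularityError(ZeroDivisionError):
    """A model denominator vanished (non-physical parameter combination)."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MediumParams:
    """Suspending-medium properties (relative permittivity, conductivity,
    viscosity, temperature), all SI."""

    eps_rel: float = 78.0          # aqueous sucrose buffer at 22 C
    sigma: float = 30e-3           # S/m
    viscosity: float = 0.95e-3     # Pa s, water at 22 C
    temperature: float = 295.15    # K

    def __post_init__(self):
        if self.eps_rel <= 0:
            raise DomainError("eps_rel must be > 0")
        if self.sigma < 0:
            raise DomainError("sigma must be >= 0")
        if self.viscosity <= 0:
            raise DomainError("viscosity must be > 0")
        if self.temperature <= 0:
            raise DomainError("temperature must be > 0")


@dataclass(frozen=True)
class ShellCellModel:
    """Geometric and dielectric parameters of a single-shell cell.

    Defaults are the MDA-MB-231 breast-cancer-cell parameter set:
    radius 6.2 um, membrane thickness 10 nm, interior 50 eps0 / 0.2 S/m,
    membrane 24 eps0 / 1e-7 S/m.
    """

    radius_a: float = 6.2e-6        # m
    membrane_thickness_d: float = 10e-9  # m
    eps_in_rel: float = 50.0
    eps_me_rel: float = 24.0
    sigma_in: float = 0.2           # S/m
    sigma_me: float = 1e-7          # S/m

    def __post_init__(self):
        if self.radius_a <= 0:
            raise DomainError("radius_a must be > 0")
        if self.membrane_thickness_d < 0:
            raise DomainError("membrane_thickness_d must be >= 0")
        if self.membrane_thickness_d >= self.radius_a:
            raise DomainError("membrane must be much thinner than the radius")

    @property
    def outer_radius(self) -> float:
        return self.radius_a + self.membrane_thickness_d

    @property
    def radius_ratio(self) -> float:
        """d_r = a / (a + d), in (0, 1]."""
        return self.radius_a / self.outer_radius

    @property
    def volume(self) -> float:
        """Particle volume using the outer radius (a + d).

        With d/a ~ 1.6e-3 the inner/outer choice is numerically negligible
        but is fixed here for reproducibility.
        """
        return 4.0 / 3.0 * math.pi * self.outer_radius**3


@dataclass(frozen=True)
class DriveSettings:
    """AC drive: amplitude, frequency and the per-electrode phase signs.

    ``amplitude_convention`` resolves the printed-formula ambiguity
    ``V1(t) = Vpp sin(2 pi f t)``: with ``"peak"`` (default) the configured
    amplitude is the sine amplitude; ``"peak_to_peak"`` halves it.
    """

    amplitude_V: float = 8.0
    frequency: float = 1e6
    phase_pattern: tuple[int, ...] = (1, -1, 1, -1)  # +x, +y, -x, -y electrodes
    amplitude_convention: str = "peak"

    def __post_init__(self):
        if self.frequency <= 0:
            raise DomainError("frequency must be > 0")
        if self.amplitude_convention not in ("peak", "peak_to_peak"):
            raise DomainError("amplitude_convention must be peak|peak_to_peak")
        if set(self.phase_pattern) - {1, -1} or len(self.phase_pattern) != 4:
            raise DomainError("phase_pattern must be four +1/-1 signs")
        if self.phase_pattern[0] != self.phase_pattern[2] or \
           self.phase_pattern[1] != self.phase_pattern[3] or \
           self.phase_pattern[0] == self.phase_pattern[1]:
            raise DomainError("electrodes must be driven in antiphase pairs")

    @property
    def omega(self) -> float:
        return 2.0 * math.pi * self.frequency

    @property
    def peak_amplitude(self) -> float:
        if self.amplitude_convention == "peak_to_peak":
            return 0.5 * self.amplitude_V
        return self.amplitude_V


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def complex_permittivity(eps_rel: float, sigma: float, omega: float) -> complex:
    """Complex permittivity ``eps0*eps_rel - i sigma/omega`` (F/m).

    The DC limit must be taken analytically (conductivity-contrast limit of
    the Clausius-Mossotti factor), not by passing omega = 0.
    """
    if omega <= 0:
        raise DomainError("omega must be > 0 (no DC evaluation)")
    return EPS0 * eps_rel - 1j * sigma / omega


def clausius_mossotti(eps_p: complex, eps_m: complex) -> complex:
    """Clausius-Mossotti factor (e_p - e_m)/(e_p + 2 e_m)."""
    den = eps_p + 2.0 * eps_m
    if den == 0:
        raise SingularityError("eps_p + 2 eps_m vanishes")
    return (eps_p - eps_m) / den


def shell_effective_permittivity(cell: ShellCellModel, omega: float) -> complex:
    """Effective complex permittivity of the single-shell sphere.

    With d_r = a/(a+d) and A the interior/membrane contrast factor,

        e_eff = e_me * (1 + 2 d_r^3 A) / (1 - d_r^3 A).

    The membrane prefactor e_me is part of the standard single-shell result
    (it is required for the d -> 0 limit to collapse onto the interior
    permittivity) and is included here.
    """
    e_in = complex_permittivity(cell.eps_in_rel, cell.sigma_in, omega)
    e_me = complex_permittivity(cell.eps_me_rel, cell.sigma_me, omega)
    a_factor = clausius_mossotti(e_in, e_me)  # same algebraic form
    dr3 = cell.radius_ratio**3
    den = 1.0 - dr3 * a_factor
    if den == 0:
        raise SingularityError("1 - d_r^3 A vanishes")
    return e_me * (1.0 + 2.0 * dr3 * a_factor) / den


def effective_polarizability(
    cell: ShellCellModel, medium: MediumParams, omega: float
) -> float:
    """Effective (real, in-phase) polarizability 3 V Re(e_m) Re f_CM (F m^2).

    Exactly linear in the particle volume; its sign is the sign of Re f_CM
    and therefore decides positive vs negative dielectrophoresis.
    """
    e_p = shell_effective_permittivity(cell, omega)
    e_m = complex_permittivity(medium.eps_rel, medium.sigma, omega)
    f_cm = clausius_mossotti(e_p, e_m)
    return 3.0 * cell.volume * e_m.real * f_cm.real


def cm_spectrum(
    cell: ShellCellModel, medium: MediumParams, freq_grid
) -> np.ndarray:
    """Re f_CM over a frequency grid; returns an (n, 2) array of
    (frequency_Hz, Re f_CM) preserving the input order."""
    freqs = np.asarray(freq_grid, dtype=float)
    if np.any(freqs <= 0):
        raise DomainError("all frequencies must be > 0")
    out = np.empty((freqs.size, 2))
    for k, f in enumerate(freqs.ravel()):
        omega = 2.0 * math.pi * f
        e_p = shell_effective_permittivity(cell, omega)
        e_m = complex_permittivity(medium.eps_rel, medium.sigma, omega)
        out[k, 0] = f
        out[k, 1] = clausius_mossotti(e_p, e_m).real
    return out
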