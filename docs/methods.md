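# Methods

## Physical model

**Cell dielectrics.** Each cell is a single-shell sphere: a conducting
aqueous interior (ε_in′ = 50 ε₀, σ_in = 0.2 S/m) wrapped in a thin, nearly
insulating membrane (d = 10 nm, ε_me′ = 24 ε₀, σ_me = 10⁻⁷ S/m), defaults
chosen for the MDA-MB-231 breast-cancer line with a = 6.2 μm. The shell
collapses to an effective homogeneous complex permittivity
ε̃_eff = ε̃_me (1 + 2d_r³A)/(1 − d_r³A) with d_r = a/(a+d) and
A = (ε̃_in − ε̃_me)/(ε̃_in + 2ε̃_me). The membrane prefactor ε̃_me is part of
the standard single-shell result; without it the d → 0 limit fails to
collapse onto the interior permittivity (an algebraic identity the test
suite asserts to machine precision). Particle volume uses the outer radius
a + d; at d/a ≈ 1.6×10⁻³ the inner/outer choice is numerically negligible
but is fixed for reproducibility.

The suspending buffer's relative permittivity (78, aqueous sucrose at
22 °C) and viscosity (0.95 mPa·s) are package defaults exposed in the
config; only its conductivity (30 mS/m) is pinned by the reference
experiment. Shifting ε_m′ moves the Clausius–Mossotti crossover
frequencies, so reproduced spectra should be read with that caveat.

**Energies.** The single-particle DEP potential is −½ α_eff |E_rms|² with
α_eff = 3V Re(ε̃_m) Re f_CM(ω); the pair term is the time-averaged
interaction of the dipoles induced by the external field,
U_ij = α² (1 − 3cosθ_i cosθ_j)/(4π Re ε_m R³) · (E_rms,i · E_rms,j).
Dipole moments use the real (in-phase) polarizability and the local rms
field; mutual polarization, multipoles beyond the dipole, and the
out-of-phase torque channel are deliberately outside the model. Pair sums
use a spherical cutoff (default 10 cell diameters = 124 μm) with cell
lists; on a 100-particle device fixture the 10→20 diameter change moves the
total energy by <0.1% (R⁻³ decay plus field localization near the
electrodes), which the suite checks.

## Electrode geometry and field solve

Four planar electrodes sit on the chamber floor, one per half-axis, each
the region between the branches of the hyperbola u² − v² = D² (tip at
u = D) cut off straight at u = L; the published parametric form is
ambiguous, and this reading is the one that reproduces the tip-to-tip gap
L₁ = 2D exactly and gives the diagonal gap
L₂ = √2 (L − √(L² − D²)) (= 305.57 μm for D = 390, L = 460 μm). The
alternative algebraic reading (v = ±√(u² + D²)) describes the conjugate
branches of the same family: the four-electrode union is the identical
point set, which a test asserts on the rasterized masks. The straight cut
at L and the cell-center rasterization rule (no partial coverage) are
documented choices; a `truncation_margin` parameter extends the cut for
sensitivity studies.

The quasi-static approximation does one Laplace solve at the peak drive
amplitude; time dependence enters only through E_rms = E_peak/√2. The
printed drive formula uses the peak-to-peak symbol as a sine amplitude, so
the default convention is `peak` (8 V); `peak_to_peak` halves it. The
solver is a 7-point finite-difference Laplacian with red-black SOR
(numba), nested coarse-to-fine initialization (4Δ → 2Δ → Δ), and a
residual tolerance of 10⁻⁶ relative to the boundary-data residual (guess
independent). Dirichlet values hold on electrode nodes; all other walls
are homogeneous Neumann (insulating) by default — the far-field condition
is unstated in the source problem and Neumann avoids imposing a fictitious
ground; a grounded-wall option exists for sensitivity checks. The solver
is validated against the parallel-plate closed form, the harmonic
polynomial x² − z², the discrete maximum principle, drive-sign antisymmetry
and amplitude scaling. The full-scale solve (259×259×243 nodes at
Δ = 6.2 μm) takes ~1–2 minutes on one CPU.

## Monte Carlo

Hard spheres live on the field lattice (spacing = cell radius). With that
spacing, centers closer than two lattice units overlap physically, so the
exclusion rule forbids squared lattice distances < 4 (configurable via
`exclusion_radius_nodes`). Moves are single-node jumps (6-neighbor default,
26-neighbor option), one uniformly chosen particle and direction per
proposal; out-of-box and excluded targets are rejected, making the walls
reflecting. The acceptance rule is standard Metropolis
min(1, e^(−ΔE/kT)) — the universal default for equilibration under a
configuration energy, with Glauber dynamics behind a flag; iteration counts
refer to proposals. T defaults to 295.15 K (22 °C). Correctness is checked
three ways: a two-level Boltzmann occupancy test, an exhaustive-enumeration
detailed-balance test on a 3×3×3 lattice with two interacting particles
(kernel vs the pure-Python energy path), and free-lattice diffusion MSD.
Running energy sums are compared against fresh recomputation after ~10⁴
accepted moves (agreement at ~10⁻¹⁵ relative).

The physical-time mapping treats the hop sequence as effective diffusion:
N·Δt = Δd²/(6D). The source model prints the drag as 3πηa ("paper" mode,
default, Δt = 87.28 s per event at N = 1, Δd = a); the Stokes–Einstein
drag for a sphere is 6πηa ("stokes" mode, 174.55 s). The mapping affects
reported times only, never the equilibrium distribution. A cell–wall
friction force mentioned but never specified in the source description is
omitted; it is the likely cause of residual central-region discrepancies
between simulated and observed distributions.

## Design metrics

**r_DEP** is max/mean of |∇|E_rms|²| on the first interior floor plane (the
nodal gradient is singular on the electrode edge at z = 0 itself). The
averaging footprint is a genuine ambiguity: the full chamber cross-section
gives 177 at Δ = 6.2 μm, the electrode bounding box (|x|, |y| ≤ L) gives
76. The device-level report defaults to the electrode bounding box — r_DEP
describes how strongly settled cells concentrate where they land, i.e. over
the electrode region — and this reading also matches the published figure
of merit (≈85). The edge singularity makes the value grid-dependent
(electrode footprint: 12 at Δ = 24.8 μm, 33 at 12.4 μm, 76 at 6.2 μm), so
comparisons are only meaningful at the pinned Δ = a grid.

**z_capture** solves the travel-time condition ∫₀^z* dz / v_z(z) = t_dep
with v_z = ⟨∂_z U_eff⟩/(6πμ r_cell); the published statement equates an
integral of velocity over depth to a time, which is dimensionally
inconsistent, and the travel-time form is the standard settling statement
it abbreviates. The lateral average runs over the full cross-section
(settling happens everywhere in the chamber, not only above the
electrodes). For the reference device at t_dep = 180 s the depth is 267 μm
(273/262/267 μm at Δ = 24.8/12.4/6.2 μm — grid-stable), about h/5.6,
against the published ≈280 μm ≅ h/5 from a finite-element field of unknown
resolution and domain.

**Concentration thresholds.** The settling bound C < 1/(25 d²h) (spacing
over diameter > 5) gives 1.73×10⁵ cells/ml for h = 1500 μm, d = 12.4 μm.
The published prefactor form (4×10⁸/(h d²)) does not reproduce its own
quoted example of 5×10⁵ cells/ml under any unit convention we tried; both
modes are provided (`settling` default, `printed` literal), and the
improved-threshold chain C·(h/z_capture)/r_DEP is anchored to the published
5×10⁵ baseline, which does reproduce the published 3×10⁴ cells/ml.

**Chains** are connected components under center distance ≤ 2a + Δ/2 (the
half-spacing slack absorbs lattice discretization); chain length is the
graph-geodesic extent in particles, and orientation compares each cluster's
principal axis with the local field. "Near the floor" means z ≤ 25 μm
(two cell diameters), the layer where settled chains live.

## Scaled study conditions

The chain-regime comparison runs in a quarter-scale device (400³ μm³ box,
D = 97.5 μm, L = 115 μm, same drive and grid spacing) so that six seeds at
two densities complete in minutes: 5×10⁵ cells/ml (32 particles — the
experimental density) versus 10⁴ cells/ml (1 particle — the dilute regime),
10⁷ proposals each. At the high density over half of the near-floor
particles end in clusters of ≥3 across seeds; at the low density the
fraction is identically zero, and the bootstrap 95% intervals over seeds do
not overlap. The full-scale reference condition (1920 cells at 5×10⁵
cells/ml, 2×10⁸ proposals) runs through the same code path via
`depmc simulate` but is outside the test budget.

## What the synthetic conditions do and do not show

The generator places cells uniformly at random (seeded, non-overlapping),
matching a freshly pipetted suspension. It does not model sedimentation
under gravity, hydrodynamic or electro-thermal flow, cell size/property
dispersity, wall friction, or cell–cell adhesion; passing tests demonstrate
the correctness of the interacting-dipole equilibrium model under those
idealizations, not that real distributions are free of these effects.
Off-lattice dynamics and flow-through separation are out of scope.

## Numerical choices

SOR relaxation factor 2/(1 + sin(π/n_max)); convergence is declared at
relative residual ≤ 10⁻⁶ (configurable), with a sweep cap raising a solver
error carrying the residual. Gradients use centered differences (one-sided
at boundaries, via `np.gradient`). Field values at particle positions are
nodal lookups (trilinear interpolation is provided and exact on nodes).
Cutoff ties at exactly R = cutoff are resolved by the same squared-distance
comparison in the Python energy path, the incremental update, and the MC
kernel. Metropolis exponents are clamped at |ΔE/kT| = 700 to avoid
overflow; exact ties ΔE = 0 always accept. Configs serialize in SI base
units so parse → dump → parse is bit-exact; scaled units (μm, MHz, …) are
accepted on input.
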