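# depmc

Coupled Monte Carlo–Poisson simulation of polarizable cells in
dielectrophoretic (DEP) devices with polynomial (quadrupole) electrodes.

`depmc` is for microfluidic-device designers and biophysicists who need to
know how suspended cells actually distribute in a DEP trap — including the
cell–cell induced-dipole interactions that standard single-particle kinetics
ignore. At the cell densities used in practice those interactions dominate
the distribution near the electrodes, organizing cells into field-aligned
*pearl chains* instead of the clean point traps a non-interacting model
predicts.

## Model

A cell of radius *a* with a thin membrane (thickness *d*) is a single-shell
dielectric sphere with effective complex permittivity

    ε̃_eff = ε̃_me (1 + 2 d_r³A) / (1 − d_r³A),   d_r = a/(a+d),
    A = (ε̃_in − ε̃_me) / (ε̃_in + 2 ε̃_me),       ε̃ = ε − iσ/ω,

giving the Clausius–Mossotti factor f_CM = (ε̃_eff − ε̃_m)/(ε̃_eff + 2ε̃_m)
and the in-phase polarizability α_eff = 3V Re(ε̃_m) Re f_CM. In a
non-uniform AC field the single-particle potential is
U_eff(r) = −½ α_eff |E_rms(r)|², and two particles i, j interact through the
time-averaged dipole–dipole energy

    U_ij = α_i α_j (1 − 3 cosθ_i cosθ_j) / (4π Re(ε_m) R³) · (E_rms,i · E_rms,j).

The drive field of four hyperbola-edged electrodes (x² − y² = D², truncated
at L, antiphase drive) is obtained from one 3D Laplace solve; hard spheres
on a cubic lattice (spacing = cell radius) are then equilibrated by seeded
Metropolis Monte Carlo under the total configuration energy. Device design
metrics follow from the solved field: the floor concentration factor
r_DEP = max|∇E²|/⟨|∇E²|⟩, the capture depth z_capture from Stokes settling
in the laterally averaged vertical DEP force, and interaction-free
concentration thresholds C < C_base · (h/z_capture)/r_DEP.

## Worked example

```python
import depmc as dm

cell, medium, drive = dm.ShellCellModel(), dm.MediumParams(), dm.DriveSettings()
alpha = dm.effective_polarizability(cell, medium, drive.omega)
print(f"Re f_CM sign via alpha: {alpha:.3e} F m^2")

# quarter-scale device so the example runs in seconds
layout = dm.ElectrodeLayout(half_gap_D=97.5e-6, extent_L=115e-6)
grid = dm.SimulationGrid((400e-6, 400e-6, 400e-6), cell.radius_a)
field = dm.solve_device(layout, grid, drive)

n = dm.particles_for_density(5e5, grid)          # 32 cells at 5e5 /ml
config = dm.init_random(n, grid, seed=42, radius=cell.outer_radius, alpha=alpha)
traj = dm.run(config, field, dm.MCSettings(iterations=10_000_000, seed=42), medium)
stats = dm.detect_chains(config, field, z_max=25e-6)
print(f"acceptance rate {traj.acceptance_rate:.4f}")
print(f"near-floor particles {stats.n_particles}, "
      f"chain fraction {stats.fraction_in_chains:.2f}, "
      f"longest chain {stats.max_chain_length}")
```

prints (seed 42):

```
Re f_CM sign via alpha: 1.336e-24 F m^2
acceptance rate 0.0004
near-floor particles 29, chain fraction 0.66, longest chain 4
```

The positive polarizability (1.34×10⁻²⁴ F·m²) means positive DEP at 1 MHz:
cells move toward the electrode edges. After 10⁷ proposals most particles
have settled near the floor and over half of those sit in clusters of three
or more — pearl chains. Rerunning with `--density 1e4` leaves the chain
fraction at zero: the dilute regime is interaction-free.

The same pipeline is scriptable from the shell:

```bash
depmc cm-spectrum -o out        # Re f_CM vs frequency, CSV
depmc solve-field -o out        # device Laplace solve, VTK + npz export
depmc simulate  -o out          # MC equilibration, extended-XYZ trajectory
depmc analyze   -c run.yaml -o out out/trajectory.xyz
depmc thresholds -o out         # r_DEP, z_capture, concentration thresholds
```

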