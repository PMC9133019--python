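# gotensor

Coarse-grained mechanics of proteins and protein complexes: a Gō-model
C-alpha simulator, a second-rank tensor descriptor of protein shape, and the
identification of continuum-scale stresses from residue-level interactions
by power equivalence.

## The problem

Simulating a whole protein complex residue-by-residue is expensive. An
alternative is to keep the residue-level description for *one* protein and
its links to neighbors, summarize each protein's around-center motion by a
single tensor, and promote the interactions to continuum stress fields. This
package implements that pipeline end to end, for structural modellers who
want to study translocation, unfolding and complex mechanics without a full
atomistic treatment:

1. **Structure-based chain model.** The potential

   V_tot = Σ k_h/2 (r−R)² + Σ k_θ/2 (θ−Θ)² + Σ k_φ¹[1−cos(φ−Φ)] +
   k_φ³[1−cos3(φ−Φ)] + Σ_{|j−i|>3} V_nb(r_ij)

   has its minimum at the native structure; non-adjacent residues closer than
   the cutoff R_c in the native state attract through a 12-10 well of depth
   ε, all others repel through a soft core (10/3)(σ/r)¹². Dynamics is
   Langevin (underdamped BAOAB or overdamped Euler–Maruyama), with optional
   confinement in a smooth channel potential V_pore and an axial drive on the
   foremost residue (nanopore translocation).

2. **Shape tensor.** Residue velocities are decomposed as
   w_i = v + ν̇ r_i + c_i, with ν̇ the least-squares affine velocity
   gradient about the mass center. Integrating ν̇ gives the shape tensor ν,
   whose polar decomposition ν = RU yields an ellipsoid (semi-axes from U's
   eigenvalues) that tracks folding, stretching and squeezing.

3. **Stress identification.** For a statistical box e of linked proteins,
   equating the volume-scaled discrete power (minus fluctuation power) to the
   continuum inner power P·Dv + z·ν̇ + S·Dν̇ identifies the
   Piola–Kirchhoff stress P, the self-action z and the microstress S as
   virial-type sums over link and intra-protein forces, together with their
   Eulerian counterparts σ, z_a, S_a through the deformation gradient F.
   The couple balance quantifies how the microstructure breaks Cauchy-stress
   symmetry at second order in the strain.

Everything runs in code units (ε = 1, k_B = 1, lengths in Å, m = 1,
γ = 1); defaults follow the reference parameter set (R_c = 7.5 Å,
σ = 4.5 Å, T = 0.75, pore R_p = 10 Å, q = 1, α = 3 Å⁻², V0 = 2ε).

## Worked example

```python
import numpy as np
from gotensor import (FixtureSpec, GoParameters, Conformation, DynamicsConfig,
                      make_toy_protein, run_simulation, center_frame,
                      fit_affine_velocity, polar_ellipsoid)

params = GoParameters(temperature=0.75)
coords, topo = make_toy_protein(FixtureSpec(kind="helix", n_residues=50), params)
print(f"native contacts: {topo.n_native}")

cfg = DynamicsConfig(dt=0.002, n_steps=20_000, mode="overdamped",
                     seed=7, record_every=2_000)
traj = run_simulation(topo, Conformation(coords), params, None, cfg)
print(f"frames: {len(traj.frames)}, final total energy: "
      f"{traj.energies[-1]['total']:.3f}")

prev, cur = traj.frames[-2], traj.frames[-1]
_, _, rel_prev, _ = center_frame(prev)
_, _, rel, _ = center_frame(cur)
dt_frames = cur.time - prev.time
fit = fit_affine_velocity(0.5 * (rel + rel_prev), (rel - rel_prev) / dt_frames)
nu = np.eye(3) + dt_frames * fit.nu_dot
shape = polar_ellipsoid(nu)
print("ellipsoid semi-axes:", np.round(shape.semi_axes, 4))
```

prints

```
native contacts: 46
frames: 11, final total energy: 14.648
ellipsoid semi-axes: [1.099  1.0207 0.9784]
```

The 50-residue helix has 46 native contacts at R_c = 7.5 Å. After 20 000
overdamped steps at T = 0.75 the chain has absorbed thermal energy (the
native minimum is −46ε; the reported total sits 60.6ε above it in elastic
excitation). The affine fit of the last frame-to-frame
displacement gives a shape-tensor increment whose ellipsoid is slightly
prolate (axes 1.10 ≥ 1.02 ≥ 0.98): the thermalized coil is stretching along
one axis and contracting along another while its volume stays nearly
constant.

## Command line

```sh
gotensor generate --kind helix --n 50 --seed 7 --out fixture.xyz
gotensor simulate --config run.toml --seed 1 --out-dir run/
gotensor translocate --config pore.toml --seed 1 --out-dir pore_run/
gotensor fit-shape --traj run/trajectory.xyz --dt 0.2 --out shape.tsv
gotensor identify --assembly lattice.toml --seed 3 --out actions.json
```

Config files are TOML with sections `[go]`, `[pore]`, `[dynamics]`,
`[paths]`, `[lattice]`; CLI flags override config keys. Runs write
trajectories (multi-frame XYZ), per-frame energy tables (TSV), shape time
series (TSV), identified actions (JSON) and a provenance record (full
config + seed + version) sufficient to reproduce outputs bit-exactly.

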