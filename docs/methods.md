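# Methods

## Model

A protein is reduced to its C-alpha trace of N beads of equal mass m. The
reference ("crystallized") coordinates define the ground state of a
structure-based (Go-like) potential

    V_tot = Σ_{i=1}^{N-1} (k_h/2)(r_{i,i+1} − R_{i,i+1})²
          + Σ_{i=2}^{N-1} (k_θ/2)(θ_i − Θ_i)²
          + Σ_{i=3}^{N-2} k_φ¹[1 − cos(φ_i − Φ_i)] + k_φ³[1 − cos 3(φ_i − Φ_i)]
          + Σ_{|j−i|>3} V_nb(r_ij),

with the non-bonded term branching on the *reference* distance R_ij:

    V_nb = ε [5 (R_ij/r)¹² − 6 (R_ij/r)¹⁰]   if R_ij < R_c   (native contact)
    V_nb = ε (10/3)(σ/r)¹²                    otherwise        (soft core).

The native branch has its minimum −ε at r = R_ij; the pair partition is
strict (R_ij = R_c exactly falls on the repulsive branch, consistent with the
"lower than the cutoff" rule; an equality case is measure-zero for real
coordinates but the tie is documented here and fixed in code).

Angles θ_i span beads (i−1, i, i+1) for i = 2..N−1. Torsions φ_i span
(i−2, i−1, i, i+1) with the IUPAC sign convention and run i = 3..N−2; this
deliberately drops the last admissible quadruple. We treat the truncated
range as part of the model definition and keep it literal; a
`literal_dihedral_range=False` switch restores the full i = 3..N−1 set
(used, e.g., by the internal-coordinate round-trip test, where every bead
beyond the third needs a torsion to be placeable).

Each bead obeys the Langevin equation m r̈ = −γ ṙ − ∂V/∂r + Γ(t) with
Gaussian white noise Γ whose amplitude is fixed by fluctuation–dissipation
at temperature T (k_B = 1). Two integrators are provided:

* **underdamped** — BAOAB splitting; the friction/noise sub-step is the exact
  Ornstein–Uhlenbeck update, so the stationary velocity distribution is
  unbiased at any stable dt and equipartition diagnostics are meaningful;
* **overdamped** (default) — Euler–Maruyama on γ ṙ = F + Γ, the high-friction
  limit the model is normally run in; per-component displacement variance is
  2(T/γ)dt.

Stability heuristic for the stiffest term: dt ≤ 0.1 √(m/k_h); the default
dt = 0.002 satisfies it for the default k_h = 100.

Translocation adds the channel potential

    V_pore = V0 ((x2² + x3²)/R_p²)^q · Θ̃[x1(L − x1)],   Θ̃(s) = [1 + tanh(αs)]/2,

plus a constant axial drive on the foremost bead whose x1 lies in the
capture interval [−2, 0] ∪ [0, L] (ties broken toward the lower bead
index). The tanh argument is clamped to ±50, which is exact in double
precision and removes overflow. On-axis beads feel no radial pore force (the
x2, x3 prefactor vanishes), and the q < 1 axis singularity is cut off at
ρ = 0 for the same reason.

## Shape tensor

Residue velocities are decomposed as w_i = v + ν̇ r_i + c_i, with r_i
relative to the mass center. (v, ν̇) minimize Σ|w_i − v − ν̇ r_i|²
(unweighted, as the kinetic-energy best fit demands for equal masses); the
solution is the centered normal-equation one, ν̇ = B J⁻¹ with
B = Σ(w−w̄)⊗(r−r̄), J = Σ(r−r̄)⊗(r−r̄), falling back to the pseudo-inverse
with a warning when the bead cloud is degenerate (rank < 3 is reported).
The residuals then satisfy Σc_i = 0 and Σc_i⊗r_i = 0 identically.

ν integrates ν̇ from the identity (explicit Euler; the crystallized shape
maps to itself at t = 0). Its right polar decomposition ν = RU is computed
from the eigendecomposition of νᵀν; reflections (det ν ≤ 0) are rejected
rather than silently absorbed into R. Following the source model the
ellipsoid semi-axes are reported as the *square roots* of U's eigenvalues,
even though those eigenvalues are already stretches; this is a convention we
reproduce literally rather than endorse.

Three estimators of the shape driving tensor z_s are provided:

* **A** — the identification-by-power expression
  |ê|⁻¹(Σ f_i⊗r_i + ΣΣ h_ij⊗r_i);
* **B** — the pair sum replaced by Σ (|r_j|/r_g0) |h_ij|⊗∂_t|r_j| with
  componentwise absolute values (projection onto the first octant);
* **C** — Σ sign(|r_ij|−|r_ij0|)(|r_j|/r_g0)(h_ij·l_ij) ι⊗∂_t|r_j| with
  ι = (1,1,1) and sign(0) = 0.

Variants B and C take the componentwise absolute value *first* and then the
finite difference between the two supplied frames. The normalization r_g0
and reference separations come from the crystallized structure; r_j is read
relative to the instantaneous mass center. Both variants keep the |ê|⁻¹
prefactor of variant A (they replace the pair sum inside it). The pair-force
bookkeeping is switchable: `newtonian` (h_ji = −h_ij, what the dynamics
obeys) or `symmetric` (h_ji = h_ij, the convention the power sums adopt);
both are exercised in the tests and neither is privileged by the code.

The dissipation coefficient a in z_d = aν̇ is a positive constant (default
1); the dissipation monitor a|ν̇|² ≥ 0 is reported per evolution step.

## Discrete-to-continuum identification

A statistical box e (volume |e|) holds proteins α with intra-protein pair
forces h_(kh) and inter-protein link forces t_ij. The equivalence criterion

    |e|⁻¹(P_int − P_self-fluc − P_inter-fluc) = P·Dv + z·ν̇ + S·Dν̇

identifies the first Piola–Kirchhoff stress P, the self-action z, and the
third-rank microstress S; Eulerian counterparts divide by det F and use
current center separations, and referential center separations are pulled
back by F⁻¹ (flat metrics throughout, so formal adjoints are transposes and
duality pairings are full index contractions).

Conventions, fixed once so the criterion is an exact identity:

* t_ij is the force exerted **on** residue (α, i) **by** residue (β, j);
  r_βα = x_β − x_α points toward the acting protein. Tensile links then give
  positive normal stress (the standard virial sign).
* Inter-protein sums count each stored link **once**: the Newtonian reaction
  term contributes the identical dyad, so single counting is the virial
  convention and matches the worked single-link example (P¹² = 0.25 for
  t = e1, separation 2 e2, |e| = 8).
* Intra-protein sums run over ordered pairs (both directions of each stored
  pair) under the chosen bookkeeping, and the self-action lever arm is the
  *recipient* residue: z = |e|⁻¹ Σ h_(kh)⊗r_αk. This keeps the self-power
  pairing h_(kh)·(ν̇ r_αk + c_αk) and the identification consistent for both
  bookkeeping modes.
* The relative velocity of linked residues is modeled at continuum scale as
  Δw = (Dv)r̂_βα + Dν̇:(r_αi⊗r̂_βα) + (Dc)r̂_αi — the leg pairing under
  which the identified S = |e|⁻¹ Σ t⊗r_αi⊗r̂_βα makes the equivalence
  criterion close term by term.

The couple balance produces a skew tensor M_ij = ē_ijk b_k with
b = A(ν):z + (∇A):S and A(ν) = νē − ēν (so A(ν)q is the commutator of ν
with the spin tensor of q, vanishing at ν = I); ξ is M's characteristic
vector and skw(PFᵀ) = M/2. Because A(I) = 0 and the linear constitutive
response makes |z|, |S|, |∇A| all O(η) on a small-strain family
ν = I + ηG, the induced skew stress is O(η²): discrete central-spring
assemblies give exactly symmetric σ, so this second-order statement is only
observable through the couple-balance right-hand side, and the scaling test
regresses log|skw| against log η there (slope ≈ 2).

## Synthetic data

The generators produce every input the tests need, reproducibly from a seed:

* toy chains — extended (3.8 Å spacing), generic helix (rise 1.5 Å, twist
  100°, radius 2.3 Å; plumbing constants, not a measured protein), and
  seeded self-avoiding coils (3.8 Å steps, 3.8 Å exclusion);
* cubic-lattice complexes — translated copies of a toy chain, one central
  spring (at rest length) between the closest residue pair of each adjacent
  protein pair, |e| = number of cells × spacing³;
* affine velocity fields — w = v + ν̇r + c with the fluctuations re-centered
  so Σc = 0 exactly, returning the ground-truth fields for recovery tests;
* fully random assemblies (random coils, prescribed non-central link and
  intra-pair forces, random continuum fields with det F > 0) for the
  power-equivalence identity under generic inputs.

What these fixtures do *not* emulate: real native topologies (contact order,
secondary-structure statistics), sequence-dependent contact energies,
solvent or electrostatics, and thermalized (non-affine) deformation of the
lattice complexes. Passing tests therefore certify the mechanics and the
identification algebra, not the biophysical fidelity of any particular
protein system.

## Numerical choices and problem sizes

* Bending force regularizes 1/sin θ with floor 1e−8; degenerate (collinear)
  torsion quadruples contribute energy but no force, since no torsion
  direction exists there.
* Volume of a single protein |ê|: supplied by the caller (the gyration-based
  (4/3)π r_g0³ is a reasonable default for toy fixtures).
* Thermostat check: 50 noninteracting beads, 10⁶ underdamped steps at
  dt = 0.002, first 10 % discarded, standard errors from 20-block averaging
  of the equipartition series sampled every 100 steps.
* Fluctuation–dissipation check: one overdamped bead in a unit harmonic
  well, 1.5×10⁵ steps at dt = 0.01 (≈ 1500 relaxation times), block
  standard errors.
* Power-equivalence sweep: 100 random assemblies of 4 proteins × 6 residues.
* Force validation: 50 random 8-bead conformations, central differences with
  step 1e−6 Å, relative error ≤ 1e−5.

## Known limitations

* The continuum balance PDEs are not solved; only their ingredient tensors,
  powers and residuals are computed.
* The non-native repulsion is evaluated over all pairs (no cutoff), O(N²)
  per step; adequate for the chain sizes used here.
* The octant-projected z_s estimators (B, C) are empirical and frame-
  dependent by construction (they are not rotation-equivariant); they are
  provided as described, with variant A as the mechanically grounded choice.
* Gradients Dv, Dν̇ on multi-cell assemblies are accepted as prescribed
  fields; finite-differencing them across a box-cell grid is not implemented
  for irregular assemblies.
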