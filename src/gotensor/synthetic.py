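"""Seeded generators for toy structures, lattice complexes and affine fields.

Everything the tests and examples need is produced here, reproducibly from a
seed: no external structure files are required.  The toy geometries are
plumbing defaults chosen to look like a C-alpha trace (3.8 A virtual bond
length; a generic helix with 1.5 A rise, 100 degree twist and 2.3 A radius),
not measurements of any particular protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures import (
    ChainTopology,
    Conformation,
    GoParameters,
    build_chain_topology,
    center_frame,
)
from .potentials import pair_force_table
from .identification import ComplexAssembly, ContinuumFields, InterLink, ProteinInstance

__all__ = [
    "FixtureSpec",
    "make_toy_protein",
    "make_complex_lattice",
    "make_affine_field",
    "make_random_assembly",
]

CA_SPACING = 3.8      # A, virtual C-alpha bond length
HELIX_RISE = 1.5      # A per residue
HELIX_TWIST = 100.0   # degrees per residue
HELIX_RADIUS = 2.3    # A


@dataclass(frozen=True)
class FixtureSpec:
    kind: str = "helix"           # helix | extended | random_coil | lattice_complex
    n_residues: int = 20
    n_proteins: int = 8
    spacing: float = 20.0         # lattice constant for complexes, A
    rise: float = HELIX_RISE
    twist: float = HELIX_TWIST
    radius: float = HELIX_RADIUS
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 1 or self.n_proteins < 1:
            raise ValueError("counts must be >= 1")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")


def make_toy_protein(spec: FixtureSpec, params: GoParameters | None = None):
    """Return (native_coords, ChainTopology) for a toy chain."""
    params = params or GoParameters()
    if spec.kind == "helix":
        coords = _helix(spec.n_residues, spec.rise, spec.twist, spec.radius)
    elif spec.kind == "extended":
        coords = np.zeros((spec.n_residues, 3))
        coords[:, 0] = CA_SPACING * np.arange(spec.n_residues)
    elif spec.kind == "random_coil":
        coords = _self_avoiding_walk(spec.n_residues, spec.seed)
    else:
        raise ValueError(f"unknown toy kind {spec.kind!r}")
    return coords, build_chain_topology(coords, params)


def _helix(n, rise, twist_deg, radius):
    t = np.deg2rad(twist_deg) * np.arange(n)
    return np.column_stack([rise * np.arange(n),
                            radius * np.cos(t),
                            radius * np.sin(t)])


def _self_avoiding_walk(n, seed, min_sep=CA_SPACING, max_retries=200):
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        pts = [np.zeros(3)]
        ok = True
        for _ in range(n - 1):
            placed = False
            for _ in range(100):
                step = rng.standard_normal(3)
                step *= CA_SPACING / np.linalg.norm(step)
                cand = pts[-1] + step
                if all(np.linalg.norm(cand - p) >= min_sep for p in pts[:-1]) or len(pts) == 1:
                    pts.append(cand)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return np.array(pts)
    raise RuntimeError(f"self-avoiding walk failed after {max_retries} retries (seed {seed})")


def make_complex_lattice(spec: FixtureSpec, params: GoParameters | None = None,
                         grid: tuple | None = None,
                         link_stiffness: float = 1.0) -> ComplexAssembly:
    """Copies of a toy protein on a cubic lattice with nearest-neighbor links.

    Each adjacent protein pair is joined by one central spring between the
    closest residue pair, at its rest length; the box volume is the number of
    cells times the cell volume spacing^3.
    """
    params = params or GoParameters()
    if grid is None:
        k = round(spec.n_proteins ** (1.0 / 3.0))
        if k**3 != spec.n_proteins:
            raise ValueError("n_proteins must be a perfect cube (or pass grid=)")
        grid = (k, k, k)
    nx, ny, nz = grid
    coords, topo = make_toy_protein(spec, params)
    _, _, rel, _ = center_frame(Conformation(coords))

    if spec.spacing <= 0:
        raise ValueError("overlapping placements: spacing must be > 0")
    cells = [(a, b, c) for a in range(nx) for b in range(ny) for c in range(nz)]
    centers = [spec.spacing * np.array(cell, dtype=float) for cell in cells]

    proteins = []
    for ctr in centers:
        conf = Conformation(rel + ctr)
        proteins.append(ProteinInstance(
            topology=topo, conformation=conf, com=ctr,
            intra_pair_forces=pair_force_table(conf, topo, params),
        ))

    links = []
    index = {cell: n for n, cell in enumerate(cells)}
    for (a, b, c), alpha in index.items():
        for da, db, dc in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
            nb = (a + da, b + db, c + dc)
            if nb in index:
                beta = index[nb]
                i, j = _closest_pair(proteins[alpha], proteins[beta])
                rest = float(np.linalg.norm(
                    proteins[beta].conformation.positions[j]
                    - proteins[alpha].conformation.positions[i]))
                links.append(InterLink(alpha, i, beta, j,
                                       stiffness=link_stiffness, rest_length=rest))

    vol = len(cells) * spec.spacing**3
    center = np.mean(centers, axis=0)
    return ComplexAssembly(proteins=proteins, inter_links=links,
                           box_volume=vol, box_center=center)


def _closest_pair(pa: ProteinInstance, pb: ProteinInstance):
    A = pa.conformation.positions
    B = pb.conformation.positions
    d = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=-1)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    return int(i), int(j)


def make_affine_field(rel_positions: np.ndarray, v=None, nu_dot=None,
                      noise: float = 0.0, seed: int = 0):
    """Residue velocities w_i = v + nu_dot r_i + c_i with seeded fluctuations.

    The fluctuations are zero-mean isotropic Gaussian of amplitude ``noise``,
    re-centered so that sum c_i = 0 exactly.  Returns (velocities, v, nu_dot, c).
    """
    r = np.asarray(rel_positions, dtype=float)
    v = np.zeros(3) if v is None else np.asarray(v, dtype=float)
    nu_dot = np.zeros((3, 3)) if nu_dot is None else np.asarray(nu_dot, dtype=float)
    rng = np.random.default_rng(seed)
    c = noise * rng.standard_normal(r.shape) if noise > 0 else np.zeros_like(r)
    if noise > 0:
        c -= c.mean(axis=0)
    w = v + r @ nu_dot.T + c
    return w, v, nu_dot, c


def make_random_assembly(seed: int = 0, n_proteins: int = 4, n_residues: int = 6,
                         spacing: float = 12.0):
    """Small random assembly plus random continuum fields and fluctuations.

    Proteins are random coils at jittered lattice positions, joined in a chain
    of random (generally non-central) prescribed link forces, with random
    intra-protein pair forces; used to exercise the power-equivalence identity
    under fully generic inputs.  Returns (assembly, fields, fluctuations).
    """
    rng = np.random.default_rng(seed)
    proteins = []
    for alpha in range(n_proteins):
        rel = rng.standard_normal((n_residues, 3)) * 3.0
        rel -= rel.mean(axis=0)
        com = spacing * rng.standard_normal(3)
        conf = Conformation(rel + com)
        pairs = []
        for _ in range(n_residues):
            k, h = rng.choice(n_residues, size=2, replace=False)
            pairs.append((int(k), int(h), rng.standard_normal(3)))
        proteins.append(ProteinInstance(topology=None, conformation=conf,
                                        com=com, intra_pair_forces=pairs))
    links = []
    for alpha in range(n_proteins - 1):
        links.append(InterLink(
            alpha, int(rng.integers(n_residues)),
            alpha + 1, int(rng.integers(n_residues)),
            force=rng.standard_normal(3),
        ))
    F = np.eye(3) + 0.1 * rng.standard_normal((3, 3))
    if np.linalg.det(F) <= 0.1:
        F = np.eye(3)
    fields = ContinuumFields(
        v=rng.standard_normal(3),
        nu_dot=rng.standard_normal((3, 3)),
        Dv=rng.standard_normal((3, 3)),
        Dnu_dot=rng.standard_normal((3, 3, 3)),
        Dc=rng.standard_normal((3, 3)),
        F=F,
    )
    flucs = [0.1 * rng.standard_normal((n_residues, 3)) for _ in range(n_proteins)]
    asm = ComplexAssembly(proteins=proteins, inter_links=links,
                          box_volume=n_proteins * spacing**3,
                          box_center=np.zeros(3))
    return asm, fields, flucs
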