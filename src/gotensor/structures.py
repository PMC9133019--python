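"""Native-structure bookkeeping for the structure-based (Go-like) chain model.

A protein is reduced to its C-alpha trace.  The reference ("crystallized")
coordinates fix the ground state of the potential: native bond lengths
``R_{i,i+1}``, bending angles ``Theta_i`` (beads i-1, i, i+1), torsion angles
``Phi_i`` (beads i-2, i-1, i, i+1, IUPAC sign convention), and the native
contact map.  A pair (i, j) with ``|j - i| > 3`` is a *native contact* when its
reference distance is strictly below the cutoff radius ``R_c``; every other
such pair interacts through a soft repulsive core.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GoParameters",
    "ChainTopology",
    "Conformation",
    "build_chain_topology",
    "center_frame",
    "bond_lengths",
    "bend_angles",
    "torsion_angles",
]


class InvalidStructureError(ValueError):
    """Raised for coordinates the chain model cannot digest."""


@dataclass(frozen=True)
class GoParameters:
    """Parameters of the Go-like potential and the Langevin bath.

    Energies are in code units (epsilon = 1 by convention, k_B = 1),
    lengths in Angstrom.
    """

    k_h: float = 100.0          # bond stiffness, energy / A^2
    k_theta: float = 20.0       # bending stiffness, energy / rad^2
    k_phi1: float = 1.0         # torsion 1-fold coefficient, energy
    k_phi3: float = 0.5         # torsion 3-fold coefficient, energy
    epsilon: float = 1.0        # contact energy scale
    R_c: float = 7.5            # native-contact cutoff radius, A
    sigma: float = 4.5          # repulsive core, A
    mass: float = 1.0           # bead mass, code units
    gamma: float = 1.0          # friction coefficient, code units
    temperature: float = 0.75   # bath temperature, code units (k_B = 1)
    # Literal torsion sum runs i = 3..N-2 (1-based); set False to extend to N-1.
    literal_dihedral_range: bool = True

    def __post_init__(self) -> None:
        for name in ("k_h", "k_theta", "k_phi1", "k_phi3", "gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("epsilon", "sigma", "mass"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.R_c < 0:
            raise ValueError("R_c must be >= 0")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")


@dataclass(frozen=True)
class ChainTopology:
    """Ground-state geometry of one chain plus its contact partition."""

    N: int
    bond_R: np.ndarray          # (N-1,) native distances R_{i,i+1}
    angle_Theta: np.ndarray     # (N-2,) native angles, bead index i = 2..N-1
    dihedral_Phi: np.ndarray    # native torsions, bead index i = 3..N-2 (literal)
    native_contacts: np.ndarray   # (n_nat, 2) int pairs, 0-based, i < j
    native_R: np.ndarray          # (n_nat,) reference distances R_ij
    nonnative_pairs: np.ndarray   # (n_non, 2) int pairs, 0-based, i < j
    native_coords: np.ndarray = field(repr=False, default=None)

    @property
    def n_native(self) -> int:
        return len(self.native_contacts)


@dataclass
class Conformation:
    """Positions (A) and velocities (A / code time) of all beads at one time."""

    positions: np.ndarray
    velocities: np.ndarray | None = None
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise InvalidStructureError("positions must be (N, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise InvalidStructureError("non-finite coordinates")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.positions.shape:
                raise InvalidStructureError("velocities must match positions")

    @property
    def N(self) -> int:
        return len(self.positions)

    def copy(self) -> "Conformation":
        vel = None if self.velocities is None else self.velocities.copy()
        return Conformation(self.positions.copy(), vel, self.time)


# ---------------------------------------------------------------------------
# internal-coordinate measurements


def bond_lengths(coords: np.ndarray) -> np.ndarray:
    d = np.diff(coords, axis=0)
    return np.linalg.norm(d, axis=1)


def bend_angles(coords: np.ndarray) -> np.ndarray:
    """Angles at beads 2..N-1 (1-based), i.e. one per interior bead."""
    u = coords[:-2] - coords[1:-1]
    v = coords[2:] - coords[1:-1]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    cos = np.einsum("ij,ij->i", u, v) / (nu * nv)
    return np.arccos(np.clip(cos, -1.0, 1.0))


def torsion_angles(coords: np.ndarray, literal_range: bool = True) -> np.ndarray:
    """Signed IUPAC torsions over beads (i-2, i-1, i, i+1).

    With ``literal_range`` the sum index runs i = 3..N-2 (1-based), dropping
    the final admissible quadruple ending at bead N; otherwise i = 3..N-1.
    """
    n = len(coords)
    hi = n - 2 if literal_range else n - 1  # 1-based upper bead index i
    quads = [(i - 3, i - 2, i - 1, i) for i in range(3, hi + 1)]
    out = np.empty(len(quads))
    for k, (a, b, c, d) in enumerate(quads):
        out[k] = _dihedral(coords[a], coords[b], coords[c], coords[d])
    return out


def _dihedral(p1, p2, p3, p4) -> float:
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.arctan2(m @ n2, n1 @ n2))


# ---------------------------------------------------------------------------
# operations


def build_chain_topology(native_coords: np.ndarray, params: GoParameters) -> ChainTopology:
    """Measure the ground-state internal coordinates and classify contacts.

    Pairs with ``|j - i| > 3`` are split strictly: attractive (native) iff the
    reference distance is < R_c, repulsive otherwise (equality is non-native).
    """
    coords = np.asarray(native_coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise InvalidStructureError("native coordinates must be (N, 3)")
    if not np.all(np.isfinite(coords)):
        raise InvalidStructureError("non-finite native coordinates")
    n = len(coords)
    if n < 5:
        raise InvalidStructureError(f"need at least 5 beads, got {n}")

    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    iu = np.triu_indices(n, k=1)
    if np.any(dist[iu] == 0.0):
        raise InvalidStructureError("duplicate coordinates")

    ii, jj = np.triu_indices(n, k=4)  # |j - i| > 3
    rr = dist[ii, jj]
    nat = rr < params.R_c
    native_contacts = np.column_stack([ii[nat], jj[nat]]).astype(int)
    nonnative_pairs = np.column_stack([ii[~nat], jj[~nat]]).astype(int)

    return ChainTopology(
        N=n,
        bond_R=bond_lengths(coords),
        angle_Theta=bend_angles(coords),
        dihedral_Phi=torsion_angles(coords, params.literal_dihedral_range),
        native_contacts=native_contacts,
        native_R=rr[nat],
        nonnative_pairs=nonnative_pairs,
        native_coords=coords.copy(),
    )


def center_frame(conf: Conformation, masses: np.ndarray | None = None):
    """Mass-center framing of a conformation.

    Returns ``(com, com_velocity, rel_positions, gyration_radius)`` with
    ``sum_i m_i rel_i = 0`` and ``r_g = sqrt(sum m_i |rel_i|^2 / sum m_i)``.
    ``com_velocity`` is None when the conformation carries no velocities.
    """
    pos = conf.positions
    if masses is None:
        masses = np.ones(len(pos))
    masses = np.asarray(masses, dtype=float)
    total = masses.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    com = masses @ pos / total
    rel = pos - com
    r_g = float(np.sqrt(masses @ np.einsum("ij,ij->i", rel, rel) / total))
    com_v = None
    if conf.velocities is not None:
        com_v = masses @ conf.velocities / total
    return com, com_v, rel, r_g
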