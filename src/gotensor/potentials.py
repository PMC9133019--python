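"""Energies and analytic forces: Go-like chain potential, pore channel, drive.

The chain potential is

    V_tot = sum k_h/2 (r - R)^2                          (bonds)
          + sum k_theta/2 (theta - Theta)^2              (bending)
          + sum k_phi1 [1 - cos(phi - Phi)]
                + k_phi3 [1 - cos 3(phi - Phi)]          (torsions)
          + sum_{|j-i|>3} V_nb(r_ij)                     (non-bonded)

with the non-bonded term branching on the *reference* distance:

    V_nb = epsilon [5 (R/r)^12 - 6 (R/r)^10]     native  (R_ij < R_c)
    V_nb = epsilon (10/3) (sigma/r)^12           otherwise.

The native branch has its minimum -epsilon at r = R_ij.

The pore is a smooth channel around the x1 axis:

    V_pore = V0 ((x2^2 + x3^2) / R_p^2)^q * Theta~[x1 (L - x1)],
    Theta~(s) = [1 + tanh(alpha s)] / 2,

active (to machine precision) only for x1 in [0, L].  A constant axial drive
acts on the foremost bead inside the capture region union the pore.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import ChainTopology, Conformation, GoParameters

__all__ = [
    "PoreParameters",
    "go_energy_forces",
    "pore_energy_forces",
    "drive_force",
    "native_pair_energy",
    "nonnative_pair_energy",
    "pair_force_table",
]

_SIN_FLOOR = 1e-8     # regularizes the 1/sin(theta) bending factor
_TANH_CLAMP = 50.0    # tanh(50) == 1.0 in double precision


class SingularGeometryError(ValueError):
    """Two interacting beads coincide."""


@dataclass(frozen=True)
class PoreParameters:
    """Channel potential and drive parameters (lengths in A, energies in code units)."""

    V0: float = 2.0               # amplitude, = 2 epsilon at the default energy scale
    R_p: float = 10.0             # pore radius
    q: float = 1.0                # radial exponent
    alpha: float = 3.0            # step sharpness, A^-2
    L: float = 200.0              # pore length
    capture_interval: tuple = (-2.0, 0.0)
    drive_magnitude: float = 0.0  # axial force on the foremost active bead

    def __post_init__(self) -> None:
        if self.V0 < 0:
            raise ValueError("V0 must be >= 0")
        for name in ("R_p", "q", "alpha", "L"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.drive_magnitude < 0:
            raise ValueError("drive_magnitude must be >= 0")


def native_pair_energy(r, R, epsilon):
    """12-10 contact form, minimum -epsilon at r = R."""
    x = R / r
    return epsilon * (5.0 * x**12 - 6.0 * x**10)


def nonnative_pair_energy(r, sigma, epsilon):
    """Soft repulsive core (10/3)(sigma/r)^12."""
    return epsilon * (10.0 / 3.0) * (sigma / r) ** 12


def go_energy_forces(conf: Conformation, topo: ChainTopology, params: GoParameters):
    """Return (energy_terms dict, total, forces) for the chain potential.

    Forces are the analytic negative gradient; the per-term breakdown has keys
    bond, angle, dihedral, native, nonnative.
    """
    pos = conf.positions
    if len(pos) != topo.N:
        raise ValueError("conformation size does not match topology")
    forces = np.zeros_like(pos)
    terms = {}

    # --- bonds
    d = pos[1:] - pos[:-1]
    r = np.linalg.norm(d, axis=1)
    if np.any(r == 0.0):
        raise SingularGeometryError("coincident bonded beads")
    dr = r - topo.bond_R
    terms["bond"] = 0.5 * params.k_h * float(dr @ dr)
    # dV/dr * unit vector; force on i is +, on i+1 is -
    f_pair = (params.k_h * dr / r)[:, None] * d
    np.add.at(forces, np.arange(topo.N - 1), f_pair)
    np.add.at(forces, np.arange(1, topo.N), -f_pair)

    # --- bending angles (beads a=i-1, b=i, c=i+1), batched over interior beads
    u = pos[:-2] - pos[1:-1]
    v = pos[2:] - pos[1:-1]
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    cos_t = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
    theta = np.arccos(cos_t)
    dtheta = theta - topo.angle_Theta
    terms["angle"] = float(0.5 * params.k_theta * dtheta @ dtheta)
    sin_t = np.maximum(np.sqrt(1.0 - cos_t * cos_t), _SIN_FLOOR)
    ga = (cos_t[:, None] * u / nu[:, None] - v / nv[:, None]) / (nu * sin_t)[:, None]
    gc = (cos_t[:, None] * v / nv[:, None] - u / nu[:, None]) / (nv * sin_t)[:, None]
    coef = (-params.k_theta * dtheta)[:, None]
    idx = np.arange(topo.N - 2)
    np.add.at(forces, idx, coef * ga)
    np.add.at(forces, idx + 1, coef * (-ga - gc))
    np.add.at(forces, idx + 2, coef * gc)

    # --- torsions (beads i-2, i-1, i, i+1), batched over quadruples
    n_dih = len(topo.dihedral_Phi)
    if n_dih:
        p1 = pos[:n_dih]
        p2 = pos[1:n_dih + 1]
        p3 = pos[2:n_dih + 2]
        p4 = pos[3:n_dih + 3]
        b1 = p2 - p1
        b2 = p3 - p2
        b3 = p4 - p3
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2, axis=1)
        m = np.cross(n1, b2 / nb2[:, None])
        phi = np.arctan2(np.einsum("ij,ij->i", m, n2),
                         np.einsum("ij,ij->i", n1, n2))
        dphi = phi - topo.dihedral_Phi
        terms["dihedral"] = float(
            np.sum(params.k_phi1 * (1.0 - np.cos(dphi))
                   + params.k_phi3 * (1.0 - np.cos(3.0 * dphi))))
        dV = params.k_phi1 * np.sin(dphi) + 3.0 * params.k_phi3 * np.sin(3.0 * dphi)
        # analytic torsion gradient (signs match the atan2 convention above);
        # degenerate (collinear) quadruples have no defined torsion direction,
        # so they contribute energy but no force
        sq1 = np.einsum("ij,ij->i", n1, n1)
        sq2 = np.einsum("ij,ij->i", n2, n2)
        ok = (sq1 >= 1e-14) & (sq2 >= 1e-14)
        dV = np.where(ok, dV, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            a_vec = (nb2 / np.where(ok, sq1, 1.0))[:, None] * n1
            b_vec = (nb2 / np.where(ok, sq2, 1.0))[:, None] * n2
        c12 = (np.einsum("ij,ij->i", b1, b2) / (nb2 * nb2))[:, None]
        c32 = (np.einsum("ij,ij->i", b3, b2) / (nb2 * nb2))[:, None]
        dVc = dV[:, None]
        idx = np.arange(n_dih)
        np.add.at(forces, idx, -dVc * a_vec)
        np.add.at(forces, idx + 1, -dVc * (-(1.0 + c12) * a_vec - c32 * b_vec))
        np.add.at(forces, idx + 2, -dVc * (c12 * a_vec + (1.0 + c32) * b_vec))
        np.add.at(forces, idx + 3, -dVc * (-b_vec))
    else:
        terms["dihedral"] = 0.0

    # --- non-bonded: native contacts
    e_nat = 0.0
    if topo.n_native:
        ii = topo.native_contacts[:, 0]
        jj = topo.native_contacts[:, 1]
        dv = pos[ii] - pos[jj]
        rr = np.linalg.norm(dv, axis=1)
        if np.any(rr == 0.0):
            raise SingularGeometryError("coincident native-contact beads")
        x = topo.native_R / rr
        e_nat = float(params.epsilon * np.sum(5.0 * x**12 - 6.0 * x**10))
        # dV/dr = (60 eps / r) (x^10 - x^12)
        dVdr = 60.0 * params.epsilon * (x**10 - x**12) / rr
        fpair = (-dVdr / rr)[:, None] * dv  # force on i
        np.add.at(forces, ii, fpair)
        np.add.at(forces, jj, -fpair)
    terms["native"] = e_nat

    # --- non-bonded: soft repulsion
    e_non = 0.0
    if len(topo.nonnative_pairs):
        ii = topo.nonnative_pairs[:, 0]
        jj = topo.nonnative_pairs[:, 1]
        dv = pos[ii] - pos[jj]
        rr = np.linalg.norm(dv, axis=1)
        if np.any(rr == 0.0):
            raise SingularGeometryError("coincident repulsive beads")
        s = params.sigma / rr
        e_non = float(params.epsilon * (10.0 / 3.0) * np.sum(s**12))
        dVdr = -40.0 * params.epsilon * s**12 / rr
        fpair = (-dVdr / rr)[:, None] * dv
        np.add.at(forces, ii, fpair)
        np.add.at(forces, jj, -fpair)
    terms["nonnative"] = e_non

    total = float(sum(terms.values()))
    return terms, total, forces


def _step(s, alpha):
    arg = np.clip(alpha * s, -_TANH_CLAMP, _TANH_CLAMP)
    return 0.5 * (1.0 + np.tanh(arg))


def pore_energy_forces(positions: np.ndarray, pore: PoreParameters):
    """Channel potential energy and analytic forces on every bead."""
    pos = np.asarray(positions, dtype=float)
    x1 = pos[:, 0]
    rho2 = pos[:, 1] ** 2 + pos[:, 2] ** 2
    s = x1 * (pore.L - x1)
    step = _step(s, pore.alpha)
    radial = (rho2 / pore.R_p**2) ** pore.q
    energy = float(pore.V0 * np.sum(radial * step))

    forces = np.zeros_like(pos)
    # axial: dV/dx1 = V0 radial * step'(s) * (L - 2 x1)
    arg = np.clip(pore.alpha * s, -_TANH_CLAMP, _TANH_CLAMP)
    dstep = 0.5 * pore.alpha * (1.0 - np.tanh(arg) ** 2)
    forces[:, 0] = -pore.V0 * radial * dstep * (pore.L - 2.0 * x1)
    # radial: d radial/dx2 = q (rho2/Rp^2)^(q-1) * 2 x2 / Rp^2
    # on-axis beads feel no radial force (the x2, x3 prefactor vanishes)
    with np.errstate(divide="ignore", invalid="ignore"):
        dfac = np.where(
            rho2 > 0.0,
            pore.q * (rho2 / pore.R_p**2) ** (pore.q - 1.0) / pore.R_p**2,
            0.0,
        )
    dfac = np.nan_to_num(dfac, nan=0.0, posinf=0.0)
    forces[:, 1] = -pore.V0 * step * dfac * 2.0 * pos[:, 1]
    forces[:, 2] = -pore.V0 * step * dfac * 2.0 * pos[:, 2]
    return energy, forces


def drive_force(positions: np.ndarray, pore: PoreParameters, f_magnitude: float):
    """Axial drive (f, 0, 0) on the foremost bead in capture U [0, L].

    Ties on the maximal axial coordinate go to the lowest bead index.  Returns
    an all-zero field when no bead is active or f_magnitude == 0.
    """
    if f_magnitude < 0:
        raise ValueError("f_magnitude must be >= 0")
    pos = np.asarray(positions, dtype=float)
    forces = np.zeros_like(pos)
    if f_magnitude == 0.0:
        return forces
    x1 = pos[:, 0]
    lo, hi = pore.capture_interval
    active = ((x1 >= lo) & (x1 <= hi)) | ((x1 >= 0.0) & (x1 <= pore.L))
    if not np.any(active):
        return forces
    masked = np.where(active, x1, -np.inf)
    idx = int(np.argmax(masked))  # argmax returns the first (lowest) index on ties
    forces[idx, 0] = f_magnitude
    return forces


def pair_force_table(conf: Conformation, topo: ChainTopology, params: GoParameters):
    """Per-pair non-bonded forces as (i, j, force_on_i) triples.

    Newtonian bookkeeping: the stored vector is the force exerted on bead i by
    bead j; the reaction on j is its negative.  Used by the identification
    sums, which need pair-resolved interactions rather than net bead forces.
    """
    pos = conf.positions
    out = []
    for (pairs, natR, native) in (
        (topo.native_contacts, topo.native_R, True),
        (topo.nonnative_pairs, None, False),
    ):
        for k in range(len(pairs)):
            i, j = int(pairs[k][0]), int(pairs[k][1])
            dv = pos[i] - pos[j]
            r = np.linalg.norm(dv)
            if r == 0.0:
                raise SingularGeometryError("coincident beads in pair table")
            if native:
                x = natR[k] / r
                dVdr = 60.0 * params.epsilon * (x**10 - x**12) / r
            else:
                s = params.sigma / r
                dVdr = -40.0 * params.epsilon * s**12 / r
            out.append((i, j, -dVdr * dv / r))
    return out
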