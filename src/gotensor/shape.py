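"""Tensor shape descriptor of a protein.

Residue velocities are decomposed as

    w_i = v + nu_dot r_i + c_i,

with v the mass-center velocity, r_i positions relative to the mass center,
and nu_dot the best-fit (least-squares) velocity gradient of the affine
around-center motion; c_i are the residual (thermal) fluctuations.  The shape
tensor nu integrates nu_dot in time from the identity (the crystallized
reference maps to itself).  Its polar factors nu = R U give an ellipsoid
representation: the square roots of U's eigenvalues are taken as semi-axes.

Besides the plain identification-by-power estimator (variant A, the dyadic sum
of forces and lever arms), two empirical estimators of the shape driving
tensor z_s are provided (variants B and C) that project the dynamics onto the
first octant via componentwise absolute values; they trade fidelity of the
affine fit for robustness under strong thermal fluctuation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AffineFit",
    "ShapeState",
    "ZsEstimatorState",
    "fit_affine_velocity",
    "polar_ellipsoid",
    "zs_estimate",
    "evolve_nu",
    "expand_pair_forces",
    "plot_ellipsoid",
]


class ImproperConfigurationError(ValueError):
    """nu has non-positive determinant: no proper rotation factor exists."""


@dataclass(frozen=True)
class AffineFit:
    v: np.ndarray             # (3,) mass-center velocity
    nu_dot: np.ndarray        # (3, 3) fitted affine velocity gradient
    residuals: np.ndarray     # (N, 3) c_i = w_i - v - nu_dot r_i
    second_moment: np.ndarray  # (3, 3) J = sum r_i (x) r_i
    rank: int

    def objective(self) -> float:
        return float(np.sum(self.residuals**2))


@dataclass(frozen=True)
class ShapeState:
    nu: np.ndarray        # (3, 3)
    rotation: np.ndarray  # (3, 3) proper orthogonal
    stretch: np.ndarray   # (3, 3) symmetric positive definite
    semi_axes: np.ndarray  # (3,) sqrt of U's eigenvalues, descending


@dataclass(frozen=True)
class ZsEstimatorState:
    """Context for the octant-projected z_s estimators.

    r_g0 is the gyration radius of the crystallized structure and
    reference_rel_positions its center-framed coordinates; `a_coefficient`
    is the (constant, positive) dissipation coefficient of z^d = a nu_dot.
    """

    variant: str                           # "A" | "B" | "C"
    r_g0: float
    reference_rel_positions: np.ndarray
    a_coefficient: float = 1.0

    def __post_init__(self) -> None:
        if self.variant not in ("A", "B", "C"):
            raise ValueError("variant must be A, B or C")
        if self.r_g0 <= 0:
            raise ValueError("r_g0 must be > 0")
        if self.a_coefficient <= 0:
            raise ValueError("a_coefficient must be > 0")


def fit_affine_velocity(rel_positions: np.ndarray, velocities: np.ndarray,
                        masses: np.ndarray | None = None) -> AffineFit:
    """Least-squares affine decomposition of residue velocities.

    Minimizes sum_i |w_i - v - nu_dot r_i|^2 (unweighted, as the kinetic-energy
    best fit demands for equal masses).  The exact solution is computed from
    the centroid-centered normal equations; when the positional second moment
    is rank deficient (beads collinear/coplanar) the pseudo-inverse solution is
    returned with a warning and the rank reported.

    ``masses`` is accepted for interface symmetry with the center framing but
    does not weight the fit: the objective is the plain (unweighted) sum of
    squared velocity residuals.
    """
    r = np.asarray(rel_positions, dtype=float)
    w = np.asarray(velocities, dtype=float)
    if len(r) == 0:
        raise ValueError("empty input")
    if r.shape != w.shape or r.shape[1] != 3:
        raise ValueError("rel_positions and velocities must both be (N, 3)")

    r_bar = r.mean(axis=0)
    w_bar = w.mean(axis=0)
    rc = r - r_bar
    J_c = rc.T @ rc
    B = (w - w_bar).T @ rc          # sum (w - wbar) (x) (r - rbar)
    rank = int(np.linalg.matrix_rank(J_c, tol=1e-10 * max(1.0, np.trace(J_c))))
    if rank < 3:
        warnings.warn(f"rank-deficient positional second moment (rank {rank}); "
                      "using pseudo-inverse", stacklevel=2)
        nu_dot = B @ np.linalg.pinv(J_c)
    else:
        nu_dot = np.linalg.solve(J_c.T, B.T).T
    v = w_bar - nu_dot @ r_bar
    c = w - v - r @ nu_dot.T
    return AffineFit(v=v, nu_dot=nu_dot, residuals=c,
                     second_moment=r.T @ r, rank=rank)


def polar_ellipsoid(nu: np.ndarray) -> ShapeState:
    """Right polar decomposition nu = R U and the ellipsoid semi-axes.

    U is the principal square root of nu^T nu; R = nu U^{-1} is then proper
    orthogonal.  Semi-axes are sqrt(eigenvalues of U), descending.  A
    non-positive determinant is rejected (no silent reflection).
    """
    nu = np.asarray(nu, dtype=float)
    if nu.shape != (3, 3):
        raise ValueError("nu must be 3x3")
    det = np.linalg.det(nu)
    if det <= 0:
        raise ImproperConfigurationError(f"det(nu) = {det:g} <= 0")
    evals, evecs = np.linalg.eigh(nu.T @ nu)
    evals = np.clip(evals, 0.0, None)
    sq = np.sqrt(evals)
    U = evecs @ np.diag(sq) @ evecs.T
    R = nu @ (evecs @ np.diag(1.0 / sq) @ evecs.T)
    semi = np.sort(np.sqrt(sq))[::-1]
    return ShapeState(nu=nu, rotation=R, stretch=U, semi_axes=semi)


def expand_pair_forces(pair_forces, n: int | None = None, bookkeeping: str = "newtonian"):
    """Expand one-sided (i, j, h_on_i) triples to both ordered directions.

    ``bookkeeping="newtonian"`` stores the reaction as -h (action-reaction, the
    convention the dynamics obeys); ``"symmetric"`` stores h_ji = h_ij, the
    bookkeeping the power sums adopt in the identification scheme.
    """
    if bookkeeping not in ("newtonian", "symmetric"):
        raise ValueError("bookkeeping must be 'newtonian' or 'symmetric'")
    sgn = -1.0 if bookkeeping == "newtonian" else 1.0
    out = []
    for i, j, h in pair_forces:
        h = np.asarray(h, dtype=float)
        out.append((int(i), int(j), h))
        out.append((int(j), int(i), sgn * h))
    return out


def zs_estimate(variant: str, pair_forces, rel_positions: np.ndarray,
                prev_rel_positions: np.ndarray | None, dt: float | None,
                state: ZsEstimatorState, external_forces: np.ndarray | None,
                volume: float, bookkeeping: str = "newtonian") -> np.ndarray:
    """Estimate the shape driving tensor z_s from one snapshot.

    ``pair_forces`` is a list of one-sided (i, j, h_on_i_from_j) triples over
    interacting intra-protein pairs; both ordered directions enter the sums
    under the chosen bookkeeping.  ``rel_positions`` are relative to the
    instantaneous mass center.  Variants:

    * A — volume^-1 (sum f_i (x) r_i + sum_ij h_ij (x) r_i), the
      identification-by-power expression.
    * B — the pair sum is replaced by sum k2_j |h_ij| (x) d/dt |r_j| with
      componentwise absolute values, k2_j = |r_j| / r_g0.
    * C — pair sum replaced by sum k3_ij (h_ij . l_ij) iota (x) d/dt |r_j|,
      l_ij the unit vector from i to j, iota = (1,1,1), and
      k3_ij = sign(|r_ij| - |r_ij0|) |r_j| / r_g0 (sign(0) = 0).

    B and C need the previous frame and dt for the finite-difference time
    derivative of the octant-projected positions.
    """
    if volume <= 0:
        raise ValueError("volume must be > 0")
    r = np.asarray(rel_positions, dtype=float)
    n = len(r)
    z = np.zeros((3, 3))
    if external_forces is not None:
        f = np.asarray(external_forces, dtype=float)
        z += f.T @ r  # sum f_i (x) r_i
    expanded = expand_pair_forces(pair_forces, n, bookkeeping)

    if variant == "A":
        for i, j, h in expanded:
            z += np.outer(h, r[i])
        return z / volume

    if prev_rel_positions is None or dt is None or dt <= 0:
        raise ValueError("variants B and C need prev_rel_positions and dt > 0")
    r_prev = np.asarray(prev_rel_positions, dtype=float)
    drdt_plus = (np.abs(r) - np.abs(r_prev)) / dt  # d/dt of |r^G_j| componentwise
    k2 = np.linalg.norm(r, axis=1) / state.r_g0

    if variant == "B":
        for i, j, h in expanded:
            z += k2[j] * np.outer(np.abs(h), drdt_plus[j])
        return z / volume

    if variant == "C":
        iota = np.ones(3)
        r0 = np.asarray(state.reference_rel_positions, dtype=float)
        for i, j, h in expanded:
            d = r[j] - r[i]
            dist = np.linalg.norm(d)
            if dist == 0.0:
                continue
            l_ij = d / dist
            dist0 = np.linalg.norm(r0[j] - r0[i])
            k3 = np.sign(dist - dist0) * k2[j]
            z += k3 * float(h @ l_ij) * np.outer(iota, drdt_plus[j])
        return z / volume

    raise ValueError(f"unknown variant {variant!r}")


def evolve_nu(zs_series: np.ndarray, a: float, nu0: np.ndarray, dt: float):
    """Explicit-Euler integration of nu' = z_s.

    Returns ``(nu_series, dissipation)`` where nu_series has one more entry
    than zs_series (nu0 first) and dissipation[k] = a |nu'_k|^2 >= 0 is the
    per-step mechanical dissipation monitor (z^d . nu' with z^d = a nu').
    """
    if a <= 0:
        raise ValueError("a must be > 0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    zs = np.asarray(zs_series, dtype=float)
    if zs.ndim == 2:
        zs = zs[None]
    nu = np.empty((len(zs) + 1, 3, 3))
    nu[0] = np.asarray(nu0, dtype=float)
    diss = np.empty(len(zs))
    for k in range(len(zs)):
        if not np.all(np.isfinite(zs[k])):
            raise ValueError(f"non-finite z_s at step {k}")
        nu[k + 1] = nu[k] + dt * zs[k]
        diss[k] = a * float(np.sum(zs[k] ** 2))
    return nu, diss


def plot_ellipsoid(state: ShapeState, ax=None, n_grid: int = 24, **surface_kw):
    """Draw the ellipsoid representing a shape state on a 3D axis.

    The unit sphere is mapped through R U; requires matplotlib (an optional
    dependency).  Returns the axis.
    """
    import matplotlib.pyplot as plt  # local import: plotting is optional

    if ax is None:
        fig = plt.figure()
        ax = fig.add_subplot(projection="3d")
    u = np.linspace(0.0, 2 * np.pi, n_grid)
    v = np.linspace(0.0, np.pi, n_grid)
    sphere = np.stack([np.outer(np.cos(u), np.sin(v)),
                       np.outer(np.sin(u), np.sin(v)),
                       np.outer(np.ones_like(u), np.cos(v))])
    pts = np.einsum("ij,jkl->ikl", state.nu, sphere)
    surface_kw.setdefault("alpha", 0.4)
    ax.plot_surface(*pts, **surface_kw)
    ax.set_box_aspect((1, 1, 1))
    return ax
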