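"""Power bookkeeping and discrete-to-continuum identification.

A statistical box ``e`` holds one or more proteins plus the inter-protein
links crossing it.  Discrete powers are summed literally over the box and
equated, per unit reference volume, to the continuum inner power

    |e|^-1 (P_int - P_self_fluc - P_inter_fluc) = P . Dv + z . nu_dot + S . Dnu_dot

whose arbitrariness in the continuum rates yields the virial-type
identifications

    P = |e|^-1  sum t_ij (x) r_hat_ba                (first Piola-Kirchhoff)
    z = |e|^-1  sum h_kh (x) r_ak                    (self-action)
    S = |e|^-1  sum t_ij (x) r_ai (x) r_hat_ba       (microstress)

with Eulerian counterparts sigma, z_a, S_a carrying current-configuration
center separations and a 1/det F factor.  Conventions (fixed here once, and
kept mutually consistent so the power equivalence is an exact identity):

* ``t_ij`` is the force exerted on residue i of protein alpha by residue j of
  protein beta (tensile links then give positive normal stress);
* ``r_ba = x_beta - x_alpha`` points from the receiving protein's center to
  the acting one's;
* hatted vectors are referential pullbacks ``r_hat = F^-1 r`` (flat metrics);
* inter-protein sums count each stored link once (the Newtonian reaction
  contributes the identical dyad, so single counting is the standard virial
  convention); intra-protein sums run over ordered pairs Cont(k), i.e. both
  directions of every stored pair, under the chosen bookkeeping.

The relative velocity of linked residues is modeled, at continuum scale, as

    w_ai - w_bj = (Dv) r_hat_ba + Dnu_dot : (r_ai (x) r_hat_ba) + (Dc) r_hat_ai,

the leg pairing that makes the printed stress formulas and the equivalence
criterion agree term by term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures import ChainTopology, Conformation

__all__ = [
    "InterLink",
    "ProteinInstance",
    "ComplexAssembly",
    "ContinuumFields",
    "ContinuumActions",
    "PowerLedger",
    "CoupleTerms",
    "single_protein_identify",
    "complex_powers",
    "identify_stresses",
    "power_equivalence_residual",
    "couple_terms",
    "ricci_alternator",
    "couple_skew_scaling",
]

_TINY = 1e-300


def ricci_alternator() -> np.ndarray:
    """The alternating (Levi-Civita) symbol as a (3, 3, 3) array."""
    e = np.zeros((3, 3, 3))
    e[0, 1, 2] = e[1, 2, 0] = e[2, 0, 1] = 1.0
    e[0, 2, 1] = e[2, 1, 0] = e[1, 0, 2] = -1.0
    return e


_EPS3 = ricci_alternator()


@dataclass
class InterLink:
    """One inter-protein link realizing the interaction force t_ij.

    By default a central harmonic spring (force along the current separation,
    magnitude stiffness * (distance - rest_length)).  A prescribed ``force``
    overrides the spring and may be non-central (used to probe the loss of
    Cauchy-stress symmetry).
    """

    alpha: int
    i: int
    beta: int
    j: int
    stiffness: float = 1.0
    rest_length: float = 0.0
    force: np.ndarray | None = None


@dataclass
class ProteinInstance:
    """One protein placed in the box.

    ``intra_pair_forces`` holds one-sided (k, h, force_on_k_from_h) triples
    over interacting intra-protein pairs (h_(kh) in the self-action sums).
    """

    topology: ChainTopology | None
    conformation: Conformation
    com: np.ndarray
    intra_pair_forces: list = field(default_factory=list)

    @property
    def rel_positions(self) -> np.ndarray:
        return self.conformation.positions - self.com


@dataclass
class ComplexAssembly:
    proteins: list
    inter_links: list
    box_volume: float
    box_center: np.ndarray = None

    def __post_init__(self) -> None:
        if self.box_volume <= 0:
            raise ValueError("box_volume must be > 0")
        if self.box_center is None:
            self.box_center = np.zeros(3)
        self.box_center = np.asarray(self.box_center, dtype=float)
        for ln in self.inter_links:
            for a, k in ((ln.alpha, ln.i), (ln.beta, ln.j)):
                if not 0 <= a < len(self.proteins):
                    raise ValueError(f"link references protein {a}")
                if not 0 <= k < self.proteins[a].conformation.N:
                    raise ValueError(f"link references residue {k} of protein {a}")

    # --- index sets of the nested sums ---------------------------------
    def pr_e(self):
        return list(range(len(self.proteins)))

    def cont_alpha(self, alpha: int):
        out = set()
        for ln in self.inter_links:
            if ln.alpha == alpha:
                out.add(ln.beta)
            if ln.beta == alpha:
                out.add(ln.alpha)
        return sorted(out)

    def link_force(self, ln: InterLink) -> np.ndarray:
        """t_ij: force on residue (alpha, i) from residue (beta, j)."""
        if ln.force is not None:
            return np.asarray(ln.force, dtype=float)
        pa = self.proteins[ln.alpha].conformation.positions[ln.i]
        pb = self.proteins[ln.beta].conformation.positions[ln.j]
        d = pb - pa
        dist = np.linalg.norm(d)
        if dist == 0.0:
            raise ValueError("coincident linked residues")
        return ln.stiffness * (dist - ln.rest_length) * d / dist

    def link_terms(self):
        """Yield (alpha, i, t_vec, center_sep, r_alpha_i), one term per link.

        ``t_vec`` acts on residue (alpha, i); ``center_sep = x_beta - x_alpha``
        points toward the acting protein.  Each stored link contributes a
        single term to the interaction sums (its Newtonian reaction would
        duplicate the same dyad, so pairs are counted once, as in the
        standard virial).
        """
        for ln in self.inter_links:
            t = self.link_force(ln)
            ca = np.asarray(self.proteins[ln.alpha].com, dtype=float)
            cb = np.asarray(self.proteins[ln.beta].com, dtype=float)
            ra = self.proteins[ln.alpha].rel_positions[ln.i]
            yield ln.alpha, ln.i, t, cb - ca, ra

    def ordered_intra_terms(self, bookkeeping: str = "newtonian"):
        """Yield (alpha, k, h_vec) over ordered intra-protein pairs."""
        sgn = -1.0 if bookkeeping == "newtonian" else 1.0
        for alpha, prot in enumerate(self.proteins):
            for k, h, vec in prot.intra_pair_forces:
                vec = np.asarray(vec, dtype=float)
                yield alpha, int(k), vec
                yield alpha, int(h), sgn * vec

    def neighbor_condition(self):
        """Max |r_ai - r_bj| over links, relative to the bounding diameter.

        The continuum description presumes linked residues sit at nearly the
        same offset from their respective mass centers; this reports how well
        the assembly satisfies that (smaller is better)."""
        worst = 0.0
        for ln in self.inter_links:
            ra = self.proteins[ln.alpha].rel_positions[ln.i]
            rb = self.proteins[ln.beta].rel_positions[ln.j]
            worst = max(worst, float(np.linalg.norm(ra - rb)))
        diam = 0.0
        for prot in self.proteins:
            rel = prot.rel_positions
            diam = max(diam, 2.0 * float(np.max(np.linalg.norm(rel, axis=1), initial=0.0)))
        return worst, diam


@dataclass(frozen=True)
class ContinuumFields:
    """Continuum rates at the box center (k_B-free mechanical fields).

    Dv, Dnu_dot, Dc are referential gradients; Dnu_dot is indexed
    [h, k, L] = d(nu_dot[h, k]) / dx_L.
    """

    v: np.ndarray = None
    nu_dot: np.ndarray = None
    Dv: np.ndarray = None
    Dnu_dot: np.ndarray = None
    Dc: np.ndarray = None
    F: np.ndarray = None

    def __post_init__(self):
        z2, z3 = np.zeros((3, 3)), np.zeros((3, 3, 3))
        object.__setattr__(self, "v", _default(self.v, np.zeros(3)))
        object.__setattr__(self, "nu_dot", _default(self.nu_dot, z2))
        object.__setattr__(self, "Dv", _default(self.Dv, z2))
        object.__setattr__(self, "Dnu_dot", _default(self.Dnu_dot, z3))
        object.__setattr__(self, "Dc", _default(self.Dc, z2))
        object.__setattr__(self, "F", _default(self.F, np.eye(3)))


def _default(x, z):
    return z if x is None else np.asarray(x, dtype=float)


@dataclass(frozen=True)
class ContinuumActions:
    P: np.ndarray        # (3, 3) first Piola-Kirchhoff
    z: np.ndarray        # (3, 3) self-action
    S: np.ndarray        # (3, 3, 3) microstress
    sigma: np.ndarray    # (3, 3) Cauchy
    z_a: np.ndarray      # (3, 3)
    S_a: np.ndarray      # (3, 3, 3)
    F: np.ndarray        # (3, 3), det > 0


@dataclass(frozen=True)
class PowerLedger:
    total: float
    self_power: float
    interaction_power: float
    self_fluctuation: float
    interaction_fluctuation: float


@dataclass(frozen=True)
class CoupleTerms:
    A: np.ndarray               # (3, 3, 3), A(nu) q linear in q
    xi: np.ndarray              # (3,) characteristic couple vector
    skew_residual: np.ndarray   # (3, 3) implied skew part of P F^T


# ---------------------------------------------------------------------------
# single protein


def single_protein_identify(external_forces, pair_forces, rel_positions,
                            residual_velocities=None, volume: float = 1.0,
                            v=None, nu_dot=None, bookkeeping: str = "newtonian"):
    """Identify (f, z_s) for one protein and return the power ledger.

    ``pair_forces`` holds one-sided (i, j, h_on_i) triples; ordered-pair sums
    use the chosen bookkeeping (Newtonian reaction by default, symmetric
    available).  The ledger reports the total discrete power with the
    environmental-force part in ``self_power``, the pair part in
    ``interaction_power``, and the fluctuation powers computed against the
    residual velocities c_i (zero if not given).
    """
    if volume <= 0:
        raise ValueError("volume must be > 0")
    r = np.asarray(rel_positions, dtype=float)
    n = len(r)
    f_ext = np.zeros((n, 3)) if external_forces is None else np.asarray(external_forces, float)
    c = np.zeros((n, 3)) if residual_velocities is None else np.asarray(residual_velocities, float)
    v = np.zeros(3) if v is None else np.asarray(v, dtype=float)
    nu_dot = np.zeros((3, 3)) if nu_dot is None else np.asarray(nu_dot, dtype=float)

    from .shape import expand_pair_forces

    expanded = expand_pair_forces(pair_forces, n, bookkeeping)
    f_vec = f_ext.sum(axis=0)
    z_s = f_ext.T @ r
    h_sum = np.zeros(3)
    for i, j, h in expanded:
        h_sum += h
        z_s += np.outer(h, r[i])
    f_vec = (f_vec + h_sum) / volume
    z_s = z_s / volume

    w = v + r @ nu_dot.T + c
    ext_power = float(np.einsum("ij,ij->", f_ext, w))
    pair_power = 0.0
    ext_fluc = float(np.einsum("ij,ij->", f_ext, c))
    pair_fluc = 0.0
    for i, j, h in expanded:
        pair_power += float(h @ w[i])
        pair_fluc += float(h @ c[i])
    ledger = PowerLedger(
        total=ext_power + pair_power,
        self_power=ext_power,
        interaction_power=pair_power,
        self_fluctuation=ext_fluc,
        interaction_fluctuation=pair_fluc,
    )
    return f_vec, z_s, ledger


# ---------------------------------------------------------------------------
# complexes


def _rel_velocity_model(fields: ContinuumFields, center_sep_hat, r_ai, r_ai_hat):
    """Modeled w_ai - w_bj for one ordered link term (see module docstring)."""
    return (
        fields.Dv @ center_sep_hat
        + np.einsum("hkl,k,l->h", fields.Dnu_dot, r_ai, center_sep_hat)
        + fields.Dc @ r_ai_hat
    )


def complex_powers(assembly: ComplexAssembly, fields: ContinuumFields,
                   fluctuations=None, bookkeeping: str = "newtonian") -> PowerLedger:
    """Literal summation of the box powers.

    ``fluctuations`` is an optional list of per-protein (N, 3) arrays with the
    residue fluctuation velocities c_ai; residue velocities then follow the
    affine decomposition w = v + nu_dot r + c.  The self-power pairs every
    intra-protein force with nu_dot r_ak + c_ak; the interaction power uses the
    continuum model of relative velocities of linked residues.
    """
    F_inv = np.linalg.inv(fields.F)

    def c_of(alpha, k):
        if fluctuations is None:
            return np.zeros(3)
        return np.asarray(fluctuations[alpha][k], dtype=float)

    p_self = 0.0
    p_self_fluc = 0.0
    for alpha, k, h in assembly.ordered_intra_terms(bookkeeping):
        r_ak = assembly.proteins[alpha].rel_positions[k]
        c_ak = c_of(alpha, k)
        p_self += float(h @ (fields.nu_dot @ r_ak + c_ak))
        p_self_fluc += float(h @ c_ak)

    p_inter = 0.0
    p_inter_fluc = 0.0
    for alpha, i, t, csep, r_ai in assembly.link_terms():
        csep_hat = F_inv @ csep
        r_hat = F_inv @ r_ai
        dw = _rel_velocity_model(fields, csep_hat, r_ai, r_hat)
        p_inter += float(t @ dw)
        p_inter_fluc += float(t @ (fields.Dc @ r_hat))

    return PowerLedger(
        total=p_self + p_inter,
        self_power=p_self,
        interaction_power=p_inter,
        self_fluctuation=p_self_fluc,
        interaction_fluctuation=p_inter_fluc,
    )


def identify_stresses(assembly: ComplexAssembly, F=None,
                      bookkeeping: str = "newtonian") -> ContinuumActions:
    """Virial-type identification of P, z, S and their Eulerian counterparts.

    Referential center separations are pulled back by F^-1 (flat metrics);
    Eulerian tensors use current separations and divide by det F.
    """
    F = np.eye(3) if F is None else np.asarray(F, dtype=float)
    detF = np.linalg.det(F)
    if detF <= 0:
        raise ValueError("det F must be > 0")
    F_inv = np.linalg.inv(F)
    vol = assembly.box_volume

    P = np.zeros((3, 3))
    S = np.zeros((3, 3, 3))
    sigma = np.zeros((3, 3))
    S_a = np.zeros((3, 3, 3))
    for alpha, i, t, csep, r_ai in assembly.link_terms():
        csep_hat = F_inv @ csep
        P += np.outer(t, csep_hat)
        S += np.einsum("h,k,l->hkl", t, r_ai, csep_hat)
        sigma += np.outer(t, csep)
        S_a += np.einsum("h,k,l->hkl", t, r_ai, csep)
    z = np.zeros((3, 3))
    for alpha, k, h in assembly.ordered_intra_terms(bookkeeping):
        z += np.outer(h, assembly.proteins[alpha].rel_positions[k])

    return ContinuumActions(
        P=P / vol,
        z=z / vol,
        S=S / vol,
        sigma=sigma / (vol * detF),
        z_a=z / (vol * detF),
        S_a=S_a / (vol * detF),
        F=F,
    )


def power_equivalence_residual(assembly: ComplexAssembly, fields: ContinuumFields,
                               actions: ContinuumActions, fluctuations=None,
                               bookkeeping: str = "newtonian") -> float:
    """Relative mismatch of the discrete-to-continuum equivalence criterion.

    lhs = |e|^-1 (P_int - P_self_fluc - P_inter_fluc);
    rhs = P . Dv + z . nu_dot + S . Dnu_dot (full index contractions).
    Returns |lhs - rhs| / max(|lhs|, |rhs|, tiny).
    """
    ledger = complex_powers(assembly, fields, fluctuations, bookkeeping)
    lhs = (ledger.total - ledger.self_fluctuation - ledger.interaction_fluctuation) \
        / assembly.box_volume
    rhs = (
        float(np.sum(actions.P * fields.Dv))
        + float(np.sum(actions.z * fields.nu_dot))
        + float(np.sum(actions.S * fields.Dnu_dot))
    )
    return abs(lhs - rhs) / max(abs(lhs), abs(rhs), _TINY)


# ---------------------------------------------------------------------------
# couples


def couple_operator(nu: np.ndarray) -> np.ndarray:
    """A(nu) = nu e - e nu as a (3, 3, 3) array with A(nu) q = nu W(q) - W(q) nu,
    W(q) being the skew tensor e q."""
    nu = np.asarray(nu, dtype=float)
    return np.einsum("kj,jnm->knm", nu, _EPS3) - np.einsum("kjm,jn->knm", _EPS3, nu)


def couple_terms(nu: np.ndarray, z: np.ndarray, S: np.ndarray,
                 DA_context: np.ndarray | None = None) -> CoupleTerms:
    """Local couple induced by the microstructure.

    The couple balance produces a skew tensor with components
    M_ij = e_ijk b_k, where b_k = A_knm z_mn + (grad_k A_rnm) S_mnr; xi is its
    characteristic vector (M a = xi x a for every a, giving xi = -b with the
    alternator placed as printed).  The gradient term is zero unless
    ``DA_context`` supplies grad A as a (3, 3, 3, 3) array indexed
    [r, n, m, k] (last index = spatial derivative).  ``skew_residual`` is the
    implied skew part of P F^T, namely M / 2.
    """
    A = couple_operator(nu)
    z = np.asarray(z, dtype=float)
    S = np.asarray(S, dtype=float)
    b = np.einsum("knm,mn->k", A, z)
    if DA_context is not None:
        b = b + np.einsum("rnmk,mnr->k", np.asarray(DA_context, float), S)
    M = np.einsum("ijk,k->ij", _EPS3, b)
    xi = -b  # axial vector: (M a)_i = e_ijk b_k a_j = (a x b)_i = (-b) x a
    return CoupleTerms(A=A, xi=xi, skew_residual=0.5 * M)


def couple_skew_scaling(etas, seed: int = 0):
    """Magnitude of the couple-induced skew stress on a small-strain family.

    Builds nu(eta) = I + eta G with a fixed random direction G and a linear
    constitutive response z(eta) = eta Z0, S(eta) = eta S0, Dnu(eta) = eta H0
    (quadratic energy, center-symmetric box), and returns
    ``(magnitudes, slope)`` where magnitudes[k] = |skew_residual(eta_k)| and
    slope is the log-log regression slope.  Because A(I) = 0, the induced
    skew part is a second-order perturbation: the slope is ~2.
    """
    rng = np.random.default_rng(seed)
    G = rng.standard_normal((3, 3))
    G /= np.linalg.norm(G)
    Z0 = rng.standard_normal((3, 3))
    S0 = rng.standard_normal((3, 3, 3))
    H0 = rng.standard_normal((3, 3, 3))
    etas = np.asarray(etas, dtype=float)
    mags = np.empty(len(etas))
    for k, eta in enumerate(etas):
        nu = np.eye(3) + eta * G
        DA = _grad_couple_operator(eta * H0)
        ct = couple_terms(nu, eta * Z0, eta * S0, DA_context=DA)
        mags[k] = np.linalg.norm(ct.skew_residual)
    slope = float(np.polyfit(np.log(etas), np.log(mags), 1)[0])
    return mags, slope


def _grad_couple_operator(Dnu: np.ndarray) -> np.ndarray:
    """grad A(nu) for A = nu e - e nu, indexed [r, n, m, k] (k = d/dx_k).

    Dnu is indexed [i, j, k] = d(nu_ij)/dx_k; the commutator structure of A
    passes to the gradient leg by leg.
    """
    Dnu = np.asarray(Dnu, dtype=float)
    return (
        np.einsum("rjk,jnm->rnmk", Dnu, _EPS3)
        - np.einsum("rjm,jnk->rnmk", _EPS3, Dnu)
    )
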