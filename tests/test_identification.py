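import numpy as np
import pytest

from gotensor.structures import Conformation
from gotensor.identification import (
    ComplexAssembly,
    ContinuumFields,
    InterLink,
    ProteinInstance,
    complex_powers,
    couple_operator,
    couple_skew_scaling,
    couple_terms,
    identify_stresses,
    power_equivalence_residual,
    ricci_alternator,
    single_protein_identify,
)
from gotensor.synthetic import make_random_assembly


def two_protein_assembly(t_force=None, stiffness=1.0, rest=0.0, sep=10.0):
    """Two 2-bead proteins on the x axis with one link between bead 0 of each."""
    proteins = []
    for ctr in (np.zeros(3), np.array([sep, 0.0, 0.0])):
        rel = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
        proteins.append(ProteinInstance(topology=None,
                                        conformation=Conformation(rel + ctr),
                                        com=ctr))
    link = InterLink(0, 0, 1, 0, stiffness=stiffness, rest_length=rest,
                     force=t_force)
    return ComplexAssembly(proteins=proteins, inter_links=[link],
                           box_volume=2 * sep**3)


class TestSingleProteinIdentify:
    def test_newtonian_pairs_cancel_in_force(self, rng):
        r = rng.standard_normal((5, 3))
        pairs = [(0, 1, rng.standard_normal(3)), (2, 4, rng.standard_normal(3))]
        f, z_s, _ = single_protein_identify(None, pairs, r, volume=3.0)
        assert np.allclose(f, 0.0, atol=1e-14)  # action-reaction

    def test_pair_sum_structure_without_externals(self, rng):
        # with no external forces z_s reduces to the double pair sum
        r = rng.standard_normal((4, 3))
        h = rng.standard_normal(3)
        pairs = [(1, 3, h)]
        _, z_s, _ = single_protein_identify(None, pairs, r, volume=2.0)
        expected = (np.outer(h, r[1]) + np.outer(-h, r[3])) / 2.0
        assert np.allclose(z_s, expected)

    def test_three_bead_hand_computed(self):
        r = np.array([[1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])
        f_ext = np.array([[0.0, 0, 1.0], [0, 0, 0], [1.0, 0, 0]])
        h01 = np.array([2.0, 0, 0])
        vol = 4.0
        f, z_s, ledger = single_protein_identify(f_ext, [(0, 1, h01)], r,
                                                 volume=vol)
        # hand sums: external (1,0,1); pair h01 + h10 = 0
        assert np.allclose(f, np.array([1.0, 0, 1.0]) / vol)
        expected_z = (np.outer(f_ext[0], r[0]) + np.outer(f_ext[2], r[2])
                      + np.outer(h01, r[0]) + np.outer(-h01, r[1])) / vol
        assert np.allclose(z_s, expected_z)

    def test_power_ledger_decomposition(self, rng):
        r = rng.standard_normal((6, 3))
        f_ext = rng.standard_normal((6, 3))
        c = rng.standard_normal((6, 3))
        v = rng.standard_normal(3)
        nu_dot = rng.standard_normal((3, 3))
        pairs = [(0, 5, rng.standard_normal(3))]
        _, _, led = single_protein_identify(f_ext, pairs, r, residual_velocities=c,
                                            volume=1.0, v=v, nu_dot=nu_dot)
        assert led.total == pytest.approx(led.self_power + led.interaction_power)
        # fluctuation parts recompute directly
        w = v + r @ nu_dot.T + c
        assert led.self_power == pytest.approx(np.einsum("ij,ij->", f_ext, w))
        assert led.self_fluctuation == pytest.approx(np.einsum("ij,ij->", f_ext, c))

    def test_bad_volume(self):
        with pytest.raises(ValueError):
            single_protein_identify(None, [], np.zeros((2, 3)), volume=-1.0)


class TestComplexPowers:
    def test_all_zero_forces(self):
        asm = two_protein_assembly(t_force=np.zeros(3))
        fields = ContinuumFields(nu_dot=np.eye(3), Dv=np.eye(3))
        led = complex_powers(asm, fields)
        assert led.interaction_power == 0.0
        assert led.self_power == 0.0
        assert led.total == 0.0

    def test_zero_fluctuation_field_zero_fluc_power(self):
        # c == 0 and Dc == 0 -> both fluctuation powers vanish identically
        import dataclasses
        asm, fields, _ = make_random_assembly(seed=11)
        fields0 = dataclasses.replace(fields, Dc=np.zeros((3, 3)))
        led = complex_powers(asm, fields0, fluctuations=None)
        assert led.self_fluctuation == 0.0
        assert led.interaction_fluctuation == 0.0

    def test_two_protein_single_link_oracle(self, rng):
        t = rng.standard_normal(3)
        asm = two_protein_assembly(t_force=t)
        fields = ContinuumFields(Dv=rng.standard_normal((3, 3)),
                                 Dnu_dot=rng.standard_normal((3, 3, 3)),
                                 Dc=rng.standard_normal((3, 3)))
        led = complex_powers(asm, fields)
        # independent single-term evaluation of t . (w_1i - w_2j)
        csep = np.array([10.0, 0, 0])
        r_ai = np.array([1.0, 0, 0])
        dw = (fields.Dv @ csep
              + np.einsum("hkl,k,l->h", fields.Dnu_dot, r_ai, csep)
              + fields.Dc @ r_ai)
        assert led.interaction_power == pytest.approx(float(t @ dw))

    def test_self_power_lever_arm(self, rng):
        asm = two_protein_assembly(t_force=np.zeros(3))
        h = rng.standard_normal(3)
        asm.proteins[0].intra_pair_forces = [(0, 1, h)]
        nu_dot = rng.standard_normal((3, 3))
        led = complex_powers(asm, ContinuumFields(nu_dot=nu_dot))
        r = asm.proteins[0].rel_positions
        expected = float(h @ (nu_dot @ r[0])) + float(-h @ (nu_dot @ r[1]))
        assert led.self_power == pytest.approx(expected)


class TestIdentifyStresses:
    def test_no_links_no_macro_stress(self, rng):
        asm = two_protein_assembly()
        asm.inter_links = []
        h = rng.standard_normal(3)
        asm.proteins[0].intra_pair_forces = [(0, 1, h)]
        act = identify_stresses(asm)
        assert np.allclose(act.P, 0.0)
        assert np.allclose(act.S, 0.0)
        r = asm.proteins[0].rel_positions
        expected_z = (np.outer(h, r[0]) + np.outer(-h, r[1])) / asm.box_volume
        assert np.allclose(act.z, expected_z)

    def test_single_link_worked_example(self):
        # t = (1,0,0), center separation (0,2,0), |e| = 8, F = I -> P12 = 0.25
        proteins = []
        for ctr in (np.zeros(3), np.array([0.0, 2.0, 0.0])):
            rel = np.array([[0.5, 0, 0], [-0.5, 0, 0]])
            proteins.append(ProteinInstance(None, Conformation(rel + ctr), ctr))
        link = InterLink(0, 0, 1, 0, force=np.array([1.0, 0, 0]))
        asm = ComplexAssembly(proteins, [link], box_volume=8.0)
        act = identify_stresses(asm)
        expected = np.zeros((3, 3))
        expected[0, 1] = 0.25
        assert np.allclose(act.P, expected)
        assert np.allclose(act.sigma, act.P)  # F = I

    def test_lattice_virial_oracle_and_symmetry(self):
        from gotensor.synthetic import FixtureSpec, make_complex_lattice
        spec = FixtureSpec(kind="helix", n_residues=8, n_proteins=8,
                           spacing=18.0)
        asm = make_complex_lattice(spec)
        # stretch the assembly isotropically so central springs carry load
        for prot in asm.proteins:
            rel = prot.rel_positions.copy()
            prot.com = prot.com * 1.05
            prot.conformation.positions[:] = rel + prot.com
        act = identify_stresses(asm)
        # brute-force virial oracle over links
        sigma_o = np.zeros((3, 3))
        for ln in asm.inter_links:
            t = asm.link_force(ln)
            csep = asm.proteins[ln.beta].com - asm.proteins[ln.alpha].com
            sigma_o += np.outer(t, csep)
        sigma_o /= asm.box_volume
        assert np.allclose(act.sigma, sigma_o, atol=1e-12)
        assert np.trace(act.sigma) > 0  # stretched springs -> tension
        # residue-level springs are only nearly central w.r.t. the protein
        # centers: the skew part is small relative to the pressure scale
        skew = np.abs(act.sigma - act.sigma.T).max()
        assert skew < 0.5 * abs(np.trace(act.sigma)) / 3

        # with forces made exactly central (parallel to the center separation)
        # the Cauchy stress is symmetric to machine precision
        for ln in asm.inter_links:
            csep = asm.proteins[ln.beta].com - asm.proteins[ln.alpha].com
            ln.force = 0.05 * csep
        act_c = identify_stresses(asm)
        assert np.abs(act_c.sigma - act_c.sigma.T).max() < 1e-10

    def test_transverse_link_breaks_symmetry(self):
        asm = two_protein_assembly(t_force=np.array([0.0, 1.0, 0.0]))
        act = identify_stresses(asm)
        assert np.abs(act.sigma - act.sigma.T).max() > 1e-3

    def test_piola_cauchy_consistency(self, rng):
        asm, fields, _ = make_random_assembly(seed=21)
        F = np.eye(3) + 0.2 * rng.standard_normal((3, 3))
        assert np.linalg.det(F) > 0
        act = identify_stresses(asm, F)
        sigma_from_P = act.P @ F.T / np.linalg.det(F)
        assert np.abs(act.sigma - sigma_from_P).max() < 1e-10
        assert np.abs(act.z_a - act.z / np.linalg.det(F)).max() < 1e-12

    def test_improper_deformation_rejected(self):
        asm = two_protein_assembly()
        with pytest.raises(ValueError):
            identify_stresses(asm, np.diag([-1.0, 1.0, 1.0]))


class TestPowerEquivalence:
    def test_zero_forces_zero_residual(self):
        asm = two_protein_assembly(t_force=np.zeros(3))
        fields = ContinuumFields(Dv=np.eye(3))
        act = identify_stresses(asm, fields.F)
        assert power_equivalence_residual(asm, fields, act) == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_fields_give_machine_zero_residual(self, seed):
        asm, fields, flucs = make_random_assembly(seed=seed)
        act = identify_stresses(asm, fields.F)
        res = power_equivalence_residual(asm, fields, act, fluctuations=flucs)
        assert res <= 1e-10

    def test_fluctuations_do_not_bias_residual(self):
        asm, fields, flucs = make_random_assembly(seed=77)
        act = identify_stresses(asm, fields.F)
        res0 = power_equivalence_residual(asm, fields, act, fluctuations=None)
        res1 = power_equivalence_residual(asm, fields, act, fluctuations=flucs)
        assert res0 <= 1e-10 and res1 <= 1e-10


class TestCoupleTerms:
    def test_identity_shape_tensor_annihilates(self, rng):
        ct = couple_terms(np.eye(3), rng.standard_normal((3, 3)),
                          np.zeros((3, 3, 3)))
        assert np.allclose(ct.A, 0.0)
        assert np.allclose(ct.xi, 0.0)
        assert np.allclose(ct.skew_residual, 0.0)

    def test_zero_actions_zero_couple(self, rng):
        nu = np.eye(3) + 0.3 * rng.standard_normal((3, 3))
        ct = couple_terms(nu, np.zeros((3, 3)), np.zeros((3, 3, 3)))
        assert np.allclose(ct.xi, 0.0)

    def test_operator_is_commutator_with_spin(self, rng):
        nu = rng.standard_normal((3, 3))
        q = rng.standard_normal(3)
        e = ricci_alternator()
        W = np.einsum("jnm,m->jn", e, q)
        Aq = np.einsum("knm,m->kn", couple_operator(nu), q)
        assert np.allclose(Aq, nu @ W - W @ nu, atol=1e-14)

    def test_xi_against_brute_force_contraction(self, rng):
        nu = rng.standard_normal((3, 3))
        z = rng.standard_normal((3, 3))
        e = ricci_alternator()
        A = couple_operator(nu)
        # index-by-index oracle for b_k = A_knm z_mn, M_ij = e_ijk b_k
        b = np.zeros(3)
        for k in range(3):
            for n in range(3):
                for m in range(3):
                    b[k] += A[k, n, m] * z[m, n]
        M = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    M[i, j] += e[i, j, k] * b[k]
        ct = couple_terms(nu, z, np.zeros((3, 3, 3)))
        assert np.allclose(ct.skew_residual, 0.5 * M, atol=1e-14)
        assert np.allclose(ct.xi, -b, atol=1e-14)
        # skew_residual is skew and xi its (negated) characteristic vector
        assert np.allclose(ct.skew_residual, -ct.skew_residual.T)

    def test_small_strain_skew_is_second_order(self):
        etas = np.logspace(-3, -1, 7)
        mags, slope = couple_skew_scaling(etas, seed=4)
        assert 1.8 <= slope <= 2.2
        assert np.all(np.diff(mags) > 0)


def test_assembly_validation():
    asm = two_protein_assembly()
    with pytest.raises(ValueError):
        ComplexAssembly(asm.proteins, [InterLink(0, 0, 5, 0)], box_volume=1.0)
    with pytest.raises(ValueError):
        ComplexAssembly(asm.proteins, [InterLink(0, 9, 1, 0)], box_volume=1.0)
    with pytest.raises(ValueError):
        ComplexAssembly(asm.proteins, [], box_volume=0.0)


def test_neighbor_condition_reporting():
    asm = two_protein_assembly()
    worst, diam = asm.neighbor_condition()
    # linked beads sit at identical offsets from their centers here
    assert worst == pytest.approx(0.0)
    assert diam == pytest.approx(2.0)
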