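"""Equations of motion against dense determinant-space oracles."""

import numpy as np
import pytest

from rtcc import eom
from rtcc.fci import DenseSystem
from rtcc.system import make_fixture

from conftest import random_antisym_t2


def _random_cc_state(method, rng, no=2, nv=2, scale=0.1):
    t1 = rng.normal(scale=scale, size=(nv, no)) + 1j * rng.normal(
        scale=scale, size=(nv, no)
    )
    t2 = random_antisym_t2(rng, no, nv, scale)
    l1 = rng.normal(scale=scale, size=(no, nv)) + 1j * rng.normal(
        scale=scale, size=(no, nv)
    )
    l2 = random_antisym_t2(rng, no, nv, scale).transpose(2, 3, 0, 1)
    return eom.ClusterState(method, no, no + nv, t1=t1, t2=t2, l1=l1, l2=l2)


class TestCCSDResiduals:
    def test_match_dense_similarity_transform(self, ints2e, dense2e, rng):
        """<mu|e^-T H e^T|ref> from the term tables equals the dense build."""
        st = _random_cc_state("ccsd", rng)
        E, r1, r2, _ = eom.residuals(st, ints2e)
        E_o, r1_o, r2_o = dense2e.cc_residuals(t1=st.t1, t2=st.t2)
        assert abs(E - E_o) < 1e-12  # dense Hamiltonian includes e_nuc
        np.testing.assert_allclose(r1, r1_o, atol=1e-12)
        np.testing.assert_allclose(r2, r2_o, atol=1e-12)

    def test_hamilton_function_matches_dense_bracket(self, ints2e, dense2e, rng):
        st = _random_cc_state("ccsd", rng)
        lam = dense2e.lambda_row(l1=st.l1, l2=st.l2)
        H_o = dense2e.hamilton_function(lam, t1=st.t1, t2=st.t2)
        assert abs(eom.hamilton_function(st, ints2e) - H_o) < 1e-12


@pytest.mark.parametrize("method", ["ccsd", "cc2", "cc2b"])
class TestCCDerivatives:
    def test_stationary_at_ground_state(
        self, method, ints2e, gs_ccsd, gs_cc2, gs_cc2b
    ):
        gs = {"ccsd": gs_ccsd, "cc2": gs_cc2, "cc2b": gs_cc2b}[method]
        d = eom.derivative(gs.state, ints2e)
        for part in (d.t1, d.t2, d.l1, d.l2):
            assert np.abs(part).max() < 1e-9

    def test_field_linearity(self, method, ints2e, rng):
        """The Hamiltonian is affine in the field, so derivative differences
        between fields E and 2E are exactly linear."""
        st = _random_cc_state(method, rng)
        V = -0.01 * ints2e.dipole[2]
        d0 = eom.derivative(st, ints2e, None)
        d1 = eom.derivative(st, ints2e, V)
        d2 = eom.derivative(st, ints2e, 2 * V)
        for name in ("t1", "t2", "l1", "l2"):
            a, b, c = (getattr(d, name) for d in (d0, d1, d2))
            np.testing.assert_allclose(c - b, b - a, atol=1e-12)

    def test_lambda_derivatives_are_lagrangian_gradients(
        self, method, ints2e, rng
    ):
        """lambda-dot equals i times the numerical t-gradient of H."""
        st = _random_cc_state(method, rng)
        d = eom.derivative(st, ints2e)
        eps = 1e-6
        dt2 = random_antisym_t2(rng, 2, 2, 1.0)
        dt1 = rng.normal(size=(2, 2)) + 1j * rng.normal(size=(2, 2))

        def H(x1, x2):
            s = eom.ClusterState(
                method, 2, 4, t1=st.t1 + x1, t2=st.t2 + x2, l1=st.l1, l2=st.l2
            )
            return eom.hamilton_function(s, ints2e)

        num2 = (H(0, eps * dt2) - H(0, -eps * dt2)) / (2 * eps)
        pred2 = 0.25 * np.sum(-1j * d.l2.transpose(2, 3, 0, 1) * dt2)
        assert abs(num2 - pred2) < 1e-8
        num1 = (H(eps * dt1, 0) - H(-eps * dt1, 0)) / (2 * eps)
        pred1 = np.sum(-1j * d.l1.T * dt1)
        assert abs(num1 - pred1) < 1e-8


class TestCC2Variants:
    def test_cc2_and_cc2b_coincide_at_zero_singles(self, ints2e, rng):
        t2 = random_antisym_t2(rng, 2, 2)
        l2 = random_antisym_t2(rng, 2, 2).transpose(2, 3, 0, 1)
        kw = dict(t2=t2, l2=l2)
        d_a = eom.derivative(eom.ClusterState("cc2", 2, 4, **kw), ints2e)
        d_b = eom.derivative(eom.ClusterState("cc2b", 2, 4, **kw), ints2e)
        # amplitude flows and the doubles conjugate flow coincide exactly;
        # lambda1 flows differ because the two Hamilton functions carry
        # different t1-dependence even where the dressing is the identity
        for name in ("t1", "t2", "l2"):
            np.testing.assert_allclose(
                getattr(d_a, name), getattr(d_b, name), atol=1e-13
            )

    def test_cc2_differs_from_ccsd_doubles(self, ints2e, rng):
        st2 = _random_cc_state("cc2", rng)
        st_full = _random_cc_state("ccsd", rng)
        st_full.t1, st_full.t2 = st2.t1, st2.t2
        _, _, r2_cc2, _ = eom.residuals(st2, ints2e)
        _, _, r2_ccsd, _ = eom.residuals(st_full, ints2e)
        assert np.abs(r2_cc2 - r2_ccsd).max() > 1e-6

    def test_method_mismatch_rejected(self, ints2e, rng):
        st = _random_cc_state("ccsd", rng)
        with pytest.raises(eom.InvalidStateError):
            eom.cc2_derivative(st, ints2e)


class TestOMP2:
    def test_stationary_at_ground_state(self, ints2e, gs_omp2):
        d = eom.derivative(gs_omp2.state, ints2e)
        kdot = np.linalg.solve(gs_omp2.state.Q, d.Q)
        assert np.abs(d.t2).max() < 1e-9
        assert np.abs(kdot).max() < 1e-9

    def test_densities(self, ints2e, rng):
        from scipy.linalg import expm

        t2 = random_antisym_t2(rng, 2, 2)
        kv = rng.normal(scale=0.2, size=(2, 2)) + 1j * rng.normal(
            scale=0.2, size=(2, 2)
        )
        km = np.zeros((4, 4), complex)
        km[2:, :2] = kv
        km[:2, 2:] = -kv.conj().T
        st = eom.ClusterState("omp2", 2, 4, t2=t2, Q=expm(km))
        gamma, Gamma = eom.omp2_densities(st, ints2e)
        assert abs(np.trace(gamma) - 2) < 1e-12
        np.testing.assert_allclose(gamma, gamma.conj().T, atol=1e-12)
        np.testing.assert_allclose(
            Gamma, Gamma.transpose(2, 3, 0, 1).conj(), atol=1e-12
        )
        # only the occupied-occupied and virtual-virtual blocks are populated
        assert np.abs(gamma[:2, 2:]).max() == 0.0
        assert np.abs(gamma[2:, :2]).max() == 0.0

    def test_reference_density_at_zero_amplitudes(self, ints2e):
        st = eom.ClusterState("omp2", 2, 4)
        gamma, _ = eom.omp2_densities(st, ints2e)
        expected = np.zeros((4, 4))
        expected[:2, :2] = np.eye(2)
        np.testing.assert_allclose(gamma, expected, atol=1e-14)

    def test_lambda_is_conjugate_of_t(self, ints2e, rng):
        """With Hermitian integrals the lambda2 equation of motion is the
        complex conjugate of the t2 equation, so one set suffices."""
        st = eom.ClusterState("omp2", 2, 4, t2=random_antisym_t2(rng, 2, 2))
        d = eom.derivative(st, ints2e)
        _, g2 = eom.lambda_residuals(st, ints2e)
        l2dot = 1j * g2.transpose(2, 3, 0, 1)
        np.testing.assert_allclose(
            l2dot, d.t2.conj().transpose(2, 3, 0, 1), atol=1e-12
        )

    def test_kappa_solution_satisfies_linear_system(self, ints2e, rng):
        st = eom.ClusterState("omp2", 2, 4, t2=random_antisym_t2(rng, 2, 2))
        d = eom.derivative(st, ints2e)
        fr = eom._Frame(st, ints2e, None)
        table = eom.H_TABLES["omp2"]
        D1 = table.vjp(fr.ops, 2, 4, "h")
        D2 = table.vjp(fr.ops, 2, 4, "v")
        G = fr.transform_gradient(D1, D2)
        kdot = np.linalg.solve(st.Q, d.Q)
        gm = D1.T
        comm = gm @ kdot - kdot @ gm
        assert np.abs(1j * comm[:2, 2:] - G[2:, :2].T).max() < 1e-10
        assert np.abs(1j * comm[2:, :2] - G[:2, 2:].T).max() < 1e-10

    def test_singular_density_system_raises(self):
        g = np.diag([0.5, 0.5])
        with pytest.raises(eom.OrbitalSingularityError, match="singular value"):
            eom._solve_kappa_block(g, g, np.ones((2, 2)))

    def test_mean_field_limit_matches_exact_one_particle_dynamics(self):
        """With v = 0 the orbital equations reduce to i kappa_ia = h_ia, the
        exact single-determinant dynamics up to redundant oo/vv rotations."""
        ints = make_fixture(5, 2, 2, coupling_scale=0.0)
        st = eom.ClusterState("omp2", 2, 4)
        d = eom.derivative(st, ints)
        kdot = np.linalg.solve(st.Q, d.Q)
        np.testing.assert_allclose(
            1j * kdot[:2, 2:], ints.h[:2, 2:], atol=1e-12
        )


class TestNOMP2:
    def test_specializes_to_omp2(self, ints2e, rng):
        from scipy.linalg import expm

        t2 = random_antisym_t2(rng, 2, 2)
        kv = rng.normal(scale=0.1, size=(2, 2)) + 1j * rng.normal(
            scale=0.1, size=(2, 2)
        )
        km = np.zeros((4, 4), complex)
        km[2:, :2] = kv
        km[:2, 2:] = -kv.conj().T
        Q = expm(km)
        d_o = eom.derivative(
            eom.ClusterState("omp2", 2, 4, t2=t2, Q=Q), ints2e
        )
        d_n = eom.derivative(
            eom.ClusterState(
                "nomp2",
                2,
                4,
                t2=t2,
                l2=t2.conj().transpose(2, 3, 0, 1),
                Q=Q,
                QL=Q.conj().T,
            ),
            ints2e,
        )
        np.testing.assert_allclose(d_n.t2, d_o.t2, atol=1e-10)
        np.testing.assert_allclose(d_n.Q, d_o.Q, atol=1e-10)
        np.testing.assert_allclose(
            d_n.l2, d_o.t2.conj().transpose(2, 3, 0, 1), atol=1e-10
        )

    def test_lambda_gradient_matches_numerics(self, ints2e, rng):
        t2 = random_antisym_t2(rng, 2, 2)
        l2 = random_antisym_t2(rng, 2, 2).transpose(2, 3, 0, 1)
        st = eom.ClusterState("nomp2", 2, 4, t2=t2, l2=l2)
        d = eom.derivative(st, ints2e)
        dt2 = random_antisym_t2(rng, 2, 2, 1.0)
        eps = 1e-6

        def H(x):
            s = eom.ClusterState("nomp2", 2, 4, t2=t2 + x, l2=l2)
            return eom.hamilton_function(s, ints2e)

        num = (H(eps * dt2) - H(-eps * dt2)) / (2 * eps)
        pred = 0.25 * np.sum(-1j * d.l2.transpose(2, 3, 0, 1) * dt2)
        assert abs(num - pred) < 1e-8


class TestExpectation:
    def test_particle_number(self, ints2e, gs_ccsd):
        val = eom.expectation_value(gs_ccsd.state, ints2e, np.eye(4))
        assert abs(val - 2.0) < 1e-10

    def test_reference_dipole(self, ints2e):
        st = eom.ClusterState("ccsd", 2, 4)
        val = eom.expectation_value(st, ints2e, ints2e.dipole[2])
        assert abs(val - np.trace(ints2e.dipole[2][:2, :2])) < 1e-12

    def test_hamiltonian_expectation_equals_energy(self, ints2e, gs_omp2):
        val = eom.expectation_value(
            gs_omp2.state, ints2e, ints2e.h, op2=ints2e.v
        )
        assert abs(val + ints2e.e_nuc - gs_omp2.energy) < 1e-10

    def test_dipole_time_derivative_consistency(self, ints2e, gs_omp2):
        """d<mu>/dt from a tiny propagated step matches the directional
        derivative of <mu> along the returned state derivative."""
        from rtcc.fields import FieldSpec
        from rtcc.propagation import IntegratorSpec, propagate

        st = gs_omp2.state
        fld = FieldSpec(kind="ramped_cosine", strength=5e-3, omega=0.5)
        t0 = 3.0  # evaluate away from the ramp start
        pre = propagate(
            st, ints2e, fld, IntegratorSpec(dt=0.05), t_final=t0, record_every=60
        )
        y = pre.final_state.pack()
        from rtcc.fields import interaction_matrix

        V = interaction_matrix(fld, t0, ints2e.dipole)
        dvec = eom.derivative(pre.final_state, ints2e, V).pack()
        eps = 1e-5
        mu_p = eom.dipole_expectation(st.unpack(y + eps * dvec), ints2e).real
        mu_m = eom.dipole_expectation(st.unpack(y - eps * dvec), ints2e).real
        directional = (mu_p - mu_m) / (2 * eps)
        # short true propagation across t0
        dt = 1e-3
        fwd = propagate(
            pre.final_state, ints2e, fld,
            IntegratorSpec(dt=dt), t_final=t0 + dt, t_start=t0, record_every=1,
        )
        true_rate = (fwd.dipole[-1] - fwd.dipole[0]) / dt
        np.testing.assert_allclose(directional, true_rate, atol=1e-5)
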