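"""Structural constraints and exact identities of the GSOP parameterization."""

import numpy as np
import pytest

from gsop import autodiff as ad
from gsop.core import (InvalidInputError, ReducedState, SingularMatrixError,
                       StructuredDriftModel, assemble_M, assemble_W,
                       convert_form, langevin_as_gsop)


class TestAssembly:
    def test_zero_A_gives_alpha_identity(self):
        np.testing.assert_allclose(assemble_M(np.zeros((3, 3)), 0.1),
                                   0.1 * np.eye(3))

    def test_lower_triangle_product_by_hand(self):
        A = np.array([[1.0, 0.0], [2.0, 3.0]])
        np.testing.assert_allclose(assemble_M(A, 0.1),
                                   [[1.1, 2.0], [2.0, 13.1]])

    def test_eigenvalues_bounded_below_by_alpha(self, rng):
        for _ in range(20):
            M = assemble_M(rng.normal(size=(4, 4)), 0.1)
            assert np.linalg.eigvalsh(M).min() >= 0.1 - 1e-12

    def test_W_from_strict_upper_entry(self):
        A = np.array([[0.0, 5.0], [0.0, 0.0]])
        np.testing.assert_array_equal(assemble_W(A), [[0.0, 5.0], [-5.0, 0.0]])

    def test_W_exactly_antisymmetric_and_zero_diagonal(self, rng):
        W = assemble_W(rng.normal(size=(5, 5)))
        assert np.array_equal(W + W.T, np.zeros((5, 5)))
        assert np.array_equal(np.diag(W), np.zeros(5))

    def test_nonfinite_input_rejected(self):
        bad = np.full((2, 2), np.nan)
        with pytest.raises(InvalidInputError):
            assemble_M(bad, 0.1)
        with pytest.raises(InvalidInputError):
            assemble_W(bad)


class TestPotential:
    def test_reduces_to_confining_quadratic_with_zero_networks(self):
        m = StructuredDriftModel(d=2, m=4, beta=1.0, seed=0)
        for p in m.u_net.parameters:
            p.data[...] = 0.0
        m.gamma.data[...] = 0.0
        assert np.isclose(m.potential(np.array([1.0, 1.0])), 2.0)

    def test_single_linear_square_term(self):
        # m=1, U(z) = z1, gamma = 0, beta = 0 -> V = z1^2/2
        m = StructuredDriftModel(d=2, m=1, u_hidden=(1,), beta=0.0,
                                 activation="relu", seed=0)
        for p in m.u_net.parameters:
            p.data[...] = 0.0
        m.u_net.weights[0].data[0, 0] = 1.0   # hidden = relu(z1)
        m.u_net.weights[1].data[0, 0] = 1.0   # U = hidden  (= z1 for z1 > 0)
        m.gamma.data[...] = 0.0
        assert np.isclose(m.potential(np.array([2.0, 5.0])), 2.0)

    def test_lower_bound_beta_z_squared(self, small_model, rng):
        z = 5.0 * rng.normal(size=(200, 3))
        V = small_model.potential(z)
        assert np.all(V - small_model.beta * (z ** 2).sum(-1) >= -1e-12)

    def test_gradient_matches_central_differences(self, small_model, rng):
        z = rng.normal(size=(10, 3))
        g = small_model.potential_grad(z)
        eps = 1e-5
        for b in range(10):
            for j in range(3):
                zp, zm = z[b].copy(), z[b].copy()
                zp[j] += eps
                zm[j] -= eps
                num = (small_model.potential(zp) - small_model.potential(zm)) / (2 * eps)
                assert abs(g[b, j] - num) <= 1e-5 * (1 + abs(num))


class TestDrift:
    def test_quadratic_identity_case(self):
        """With M=I, W=0 and V=½|z|² the drift is -z."""
        from gsop.rollout import CallableModel
        m = CallableModel(2, lambda z: -z, potential_fn=lambda z: 0.5 * z @ z)
        z = np.array([[1.0, 2.0]])
        np.testing.assert_allclose(m.drift(z), -z)

    def test_hand_value_with_rotation(self):
        # f = -(M+W) z for M=I, W=[[0,1],[-1,0]], V=½|z|², z=(1,2) -> (-3,-1)
        MW = np.eye(2) + np.array([[0.0, 1.0], [-1.0, 0.0]])
        f = -MW @ np.array([1.0, 2.0])
        np.testing.assert_allclose(f, [-3.0, -1.0])

    def test_model_drift_equals_minus_MW_gradV(self, small_model, rng):
        z = rng.normal(size=(6, 3))
        f = small_model.drift(z)
        M, W = small_model.M_W(z)
        g = small_model.potential_grad(z)
        np.testing.assert_allclose(f, -np.einsum("bij,bj->bi", M + W, g),
                                   rtol=1e-12, atol=1e-12)

    def test_energy_identity_antisymmetric_quadratic_form(self, small_model, rng):
        """∇Vᵀ W ∇V = 0 exactly: antisymmetric quadratic forms vanish."""
        z = rng.normal(size=(100, 3))
        g = small_model.potential_grad(z)
        _, W = small_model.M_W(z)
        q = np.einsum("bi,bij,bj->b", g, W, g)
        np.testing.assert_allclose(q, 0.0, atol=1e-10)


class TestSigma:
    def test_diag_constant_is_z_independent_abs(self, rng):
        m = StructuredDriftModel(d=3, sigma_spec="diag_constant", seed=0)
        m.sigma_param.data[:] = [1.0, -2.0, 3.0]
        s1 = m.sigma(rng.normal(size=3))
        s2 = m.sigma(rng.normal(size=3))
        np.testing.assert_allclose(s1, np.diag([1.0, 2.0, 3.0]))
        np.testing.assert_array_equal(s1, s2)

    def test_general_net_shape(self):
        m = StructuredDriftModel(d=3, p=3, sigma_spec="general_net", seed=0)
        assert m.sigma(np.zeros(3)).shape == (3, 3)


class TestConvertForm:
    def test_identity_fixed_point(self):
        fb = convert_form(np.eye(2), np.zeros((2, 2)), np.eye(2))
        np.testing.assert_allclose(fb.M_tilde, np.eye(2))
        np.testing.assert_allclose(fb.W_tilde, np.zeros((2, 2)))
        np.testing.assert_allclose(fb.sigma_tilde, np.eye(2))

    def test_hand_2x2_inverse(self):
        M, W = np.eye(2), np.array([[0.0, 1.0], [-1.0, 0.0]])
        fb = convert_form(M, W, np.eye(2))
        np.testing.assert_allclose(fb.M_tilde, 0.5 * np.eye(2))
        np.testing.assert_allclose(fb.W_tilde, [[0.0, -0.5], [0.5, 0.0]])
        np.testing.assert_allclose(fb.sigma_tilde, 0.5 * np.array([[1.0, -1.0],
                                                                   [1.0, 1.0]]))

    def test_round_trip_involution(self, rng):
        for _ in range(100):
            d = rng.integers(2, 5)
            L = rng.normal(size=(d, d))
            M = L @ L.T + 0.5 * np.eye(d)
            A = rng.normal(size=(d, d))
            W = A - A.T
            sigma = rng.normal(size=(d, d))
            fb = convert_form(M, W, sigma)
            back = convert_form(fb.M_tilde, fb.W_tilde, fb.sigma_tilde)
            np.testing.assert_allclose(back.M_tilde, M, atol=1e-10)
            np.testing.assert_allclose(back.W_tilde, W, atol=1e-10)
            np.testing.assert_allclose(back.sigma_tilde, sigma, atol=1e-10)

    def test_singular_input_raises_with_location(self):
        M = np.zeros((2, 2))
        with pytest.raises(SingularMatrixError, match="z="):
            convert_form(M, np.zeros((2, 2)), np.eye(2), z=np.array([1.0, 2.0]))


class TestLangevinEmbedding:
    def test_example_display_values(self):
        g = langevin_as_gsop(1.0, 1.0, 1.0)
        np.testing.assert_allclose(g.M_tilde, [[1.0, 0.0], [0.0, 0.0]])
        np.testing.assert_allclose(g.W_tilde, [[0.0, 1.0], [-1.0, 0.0]])
        np.testing.assert_allclose(g.Sigma, [[np.sqrt(2.0)], [0.0]])

    def test_kinetic_energy_only(self):
        g = langevin_as_gsop(1.0, 1.0, 1.0)
        assert np.isclose(g.potential(0.0, 2.0), 2.0)

    def test_form_b_eliminates_to_second_order_equation(self):
        """(M̃+W̃)(dx,dv) = -∇V dt reproduces m ẍ = -U' - mγ₁ẋ for U = ½kx²."""
        mass, g1, k = 2.0, 3.0, 4.0
        g = langevin_as_gsop(mass, g1, 1.0, U=lambda x: 0.5 * k * np.asarray(x) ** 2)
        x, v = 0.7, -1.3
        gradV = np.array([k * x, mass * v])
        rhs = -gradV
        A = g.M_tilde + g.W_tilde
        dxdv = np.linalg.solve(A, rhs)   # noise-free time derivatives
        assert np.isclose(dxdv[0], v)                       # dx/dt = v
        assert np.isclose(mass * dxdv[1], -k * x - mass * g1 * v)

    def test_nonpositive_constants_rejected(self):
        with pytest.raises(InvalidInputError):
            langevin_as_gsop(-1.0, 1.0, 1.0)


class TestInvariantsBulk:
    def test_structural_invariants_many_random_inputs(self, rng):
        """M symmetric with eigenvalues ≥ α, W+Wᵀ = 0, V ≥ β|z|² in bulk."""
        model = StructuredDriftModel(d=3, m=8, u_hidden=(16,), a_hidden=(8, 8),
                                     alpha=0.1, beta=0.01, seed=3)
        z = 10.0 * rng.normal(size=(10_000, 3))
        M, W = model.M_W(z)
        np.testing.assert_allclose(M, np.swapaxes(M, -1, -2), atol=1e-13)
        assert np.array_equal(W + np.swapaxes(W, -1, -2), np.zeros_like(W))
        eig_min = np.linalg.eigvalsh(M)[:, 0].min()
        assert eig_min >= model.alpha - 1e-10
        V = model.potential(z)
        assert np.all(V - model.beta * (z ** 2).sum(-1) >= -1e-10)

    def test_drift_zero_at_potential_minimum(self):
        """Critical points of V are fixed points of the dynamics."""
        m = StructuredDriftModel(d=2, m=2, u_hidden=(4,), beta=0.5, seed=0)
        for p in m.u_net.parameters:
            p.data[...] = 0.0
        m.gamma.data[...] = 0.0   # V = β|z|², minimum at the origin
        np.testing.assert_allclose(m.drift(np.zeros(2)), np.zeros(2), atol=1e-14)


class TestReducedState:
    def test_partition_into_macro_and_closure(self):
        s = ReducedState(np.array([1.0, 2.0, 3.0]), d_star=1)
        assert s.d == 3
        np.testing.assert_array_equal(s.z_star, [1.0])
        np.testing.assert_array_equal(s.z_hat, [2.0, 3.0])

    def test_invalid_states_rejected(self):
        with pytest.raises(InvalidInputError):
            ReducedState(np.array([np.inf, 0.0]))
        with pytest.raises(InvalidInputError):
            ReducedState(np.array([1.0]), d_star=2)


def test_checkpoint_round_trip(tmp_path, small_model, rng):
    z = rng.normal(size=(4, 3))
    f0 = small_model.drift(z)
    path = tmp_path / "model.npz"
    small_model.save(path)
    loaded = StructuredDriftModel.load(path)
    np.testing.assert_array_equal(loaded.drift(z), f0)
    assert loaded.alpha == small_model.alpha
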