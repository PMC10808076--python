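"""Bead-rod Brownian dynamics: constraints, statistics and observables."""

import numpy as np
import pytest

from gsop.polymer import (ControlResult, PolymerParams, PolymerState,
                          init_equilibrated_chain, nonconstraint_forces,
                          observables, random_walk_chain, run_control,
                          simulate_stretch, solve_tensions, step)


def _straight_chain(N, b=1.0, direction=(1.0, 0.0, 0.0)):
    d = np.asarray(direction) / np.linalg.norm(direction)
    r = np.arange(N)[:, None] * b * d[None, :]
    return r - r.mean(axis=0)


class TestInitialization:
    def test_random_walk_exact_rod_lengths(self, rng):
        p = PolymerParams(N=20, t_equil=0.0)
        r = random_walk_chain(p, rng)
        np.testing.assert_allclose(np.linalg.norm(np.diff(r, axis=0), axis=1),
                                   1.0, atol=1e-12)

    def test_equilibrated_bonds_and_com(self):
        p = PolymerParams(N=12, t_equil=1.0)
        st = init_equilibrated_chain(p, seed=4)
        assert np.abs(st.bond_lengths() - 1.0).max() < 1e-8
        np.testing.assert_allclose(st.positions.mean(axis=0), 0.0, atol=1e-10)

    def test_ideal_chain_end_to_end_scaling(self):
        """Ensemble ⟨R²⟩ ≈ (N-1)b² for equilibrated phantom chains; the
        excluded-volume interaction can only swell the coil."""
        p = PolymerParams(N=8, t_equil=5.0, mu=0.0)
        r2 = []
        for s in range(80):
            st = init_equilibrated_chain(p, seed=s)
            r2.append(np.sum((st.positions[-1] - st.positions[0]) ** 2))
        mean_r2 = np.mean(r2)
        assert abs(mean_r2 - (p.N - 1)) / (p.N - 1) < 0.15

        p_ev = PolymerParams(N=8, t_equil=5.0, mu=10.0)
        ends = [init_equilibrated_chain(p_ev, seed=s).positions[[0, -1]]
                for s in range(40)]
        r2_ev = np.mean([np.sum((e[1] - e[0]) ** 2) for e in ends])
        assert r2_ev > mean_r2


class TestForces:
    def test_ev_zero_without_overlaps(self):
        # straight chain: all pair distances >= b, so no EV contribution
        st = PolymerState(_straight_chain(6))
        pev = PolymerParams(N=6, kBT=1e-300)  # negligible Brownian amplitude
        Fe, _ = nonconstraint_forces(st, pev, flow_on=False,
                                     rng=np.random.default_rng(0))
        np.testing.assert_allclose(Fe, 0.0, atol=1e-12)

    def test_two_bead_overlap_constant_magnitude(self):
        p = PolymerParams(N=2, kBT=1e-18, mu=10.0)
        r = np.array([[0.0, 0.0, 0.0], [0.5, 0.0, 0.0]])
        Fe, _ = nonconstraint_forces(PolymerState(r), p, False,
                                     np.random.default_rng(0))
        np.testing.assert_allclose(Fe[0, 0], -10.0, atol=1e-6)
        np.testing.assert_allclose(Fe[1, 0], 10.0, atol=1e-6)
        np.testing.assert_allclose(Fe[0] + Fe[1], 0.0, atol=1e-6)

    def test_brownian_variance_fluctuation_dissipation(self):
        """Sample variance of Brownian force components = 2kBTζ/Δt within 1%."""
        p = PolymerParams(N=2000, kBT=1.3, zeta=0.7, dt=2e-4, mu=0.0)
        rng = np.random.default_rng(8)
        samples = []
        for _ in range(167):  # ~1e6 components
            F, _ = nonconstraint_forces(PolymerState(
                _straight_chain(p.N, b=1.0)), p, False, rng)
            samples.append(F.ravel())
        var = np.concatenate(samples).var()
        target = 2 * p.kBT * p.zeta / p.dt
        assert abs(var - target) / target < 0.01

    def test_flow_velocities_planar_elongational(self, rng):
        p = PolymerParams(N=3, kBT=1.0, eps_dot=0.3)
        r = np.array([[1.0, 2.0, 3.0], [0.0, 0.0, 0.0], [-1.0, 1.0, -2.0]])
        _, u = nonconstraint_forces(PolymerState(r), p, True, rng)
        np.testing.assert_allclose(u[:, 0], 0.3 * r[:, 0])
        np.testing.assert_allclose(u[:, 1], -0.3 * r[:, 1])
        np.testing.assert_allclose(u[:, 2], 0.0)


class TestTensions:
    def test_straight_chain_no_forces_zero_tensions(self):
        p = PolymerParams(N=5, kBT=1.0)
        st = PolymerState(_straight_chain(5))
        T = solve_tensions(st, st.positions.copy(), p)
        np.testing.assert_allclose(T, 0.0, atol=1e-12)

    def test_correction_restores_bonds(self, rng):
        p = PolymerParams(N=10, kBT=1.0)
        st = PolymerState(_straight_chain(10))
        pred = st.positions + 0.01 * rng.normal(size=(10, 3))
        T = solve_tensions(st, pred, p)
        bvec = st.bond_vectors()
        bvec /= np.linalg.norm(bvec, axis=1, keepdims=True)
        Fc = np.zeros((10, 3))
        Fc[:-1] += T[:, None] * bvec
        Fc[1:] -= T[:, None] * bvec
        corrected = pred + (p.dt / p.zeta) * Fc
        lens = np.linalg.norm(np.diff(corrected, axis=0), axis=1)
        assert np.abs(lens - 1.0).max() < 1e-10

    def test_three_bead_flow_stretch_against_brute_force(self):
        """Flow-only x-aligned 3-bead chain: rods under positive tension,
        matching an independent 2-unknown nonlinear solve."""
        from scipy.optimize import fsolve
        p = PolymerParams(N=3, kBT=1.0, eps_dot=0.5)
        st = PolymerState(_straight_chain(3))
        r = st.positions
        pred = r + p.dt * p.eps_dot * np.stack(
            [r[:, 0], -0.0 * r[:, 1], 0.0 * r[:, 2]], axis=1)
        T = solve_tensions(st, pred, p)
        assert np.all(T > 0)

        bvec = st.bond_vectors()
        bvec /= np.linalg.norm(bvec, axis=1, keepdims=True)
        c = p.dt / p.zeta
        d0 = np.diff(pred, axis=0)

        def resid(Tv):
            e0 = d0[0] + c * (Tv[1] * bvec[1] - 2 * Tv[0] * bvec[0])
            e1 = d0[1] + c * (Tv[0] * bvec[0] - 2 * Tv[1] * bvec[1])
            return [e0 @ e0 - 1.0, e1 @ e1 - 1.0]

        T_ref = fsolve(resid, [0.0, 0.0], xtol=1e-13)
        np.testing.assert_allclose(T, T_ref, rtol=1e-8)


class TestStepping:
    def test_zero_temperature_no_flow_fixed_point(self):
        p = PolymerParams(N=6, kBT=1e-300)
        st = PolymerState(_straight_chain(6))
        st2 = step(st, p)
        np.testing.assert_allclose(st2.positions, st.positions, atol=1e-12)

    def test_bond_lengths_invariant_over_many_steps(self):
        from gsop.polymer import _advance
        p = PolymerParams(N=16, t_equil=0.5)
        st = init_equilibrated_chain(p, seed=2)
        r = st.positions.copy()
        _advance(r, 10_000, p, 0.0, False, np.random.default_rng(0))
        assert np.abs(np.linalg.norm(np.diff(r, axis=0), axis=1) - 1.0).max() < 1e-8

    def test_com_diffusion_stokes_einstein(self):
        """Free-chain COM diffusion = kBT/(Nζ) within 5% (internal forces cancel)."""
        from gsop.polymer import _advance
        p = PolymerParams(N=16, t_equil=0.2)
        n_paths, T_run, interval = 200, 10.0, 1.0
        K = int(T_run / interval)
        rng = np.random.default_rng(77)
        sq = []
        st0 = init_equilibrated_chain(p, seed=0)
        steps = int(round(interval / p.dt))
        for j in range(n_paths):
            r = st0.positions.copy()
            coms = [r.mean(axis=0)]
            for _ in range(K):
                _advance(r, steps, p, 0.0, False, rng)
                coms.append(r.mean(axis=0))
            inc = np.diff(np.asarray(coms), axis=0)
            sq.append((inc ** 2).sum(axis=1))
        msd = np.mean(sq)  # per interval, 3-D
        D = msd / (6.0 * interval)
        target = p.kBT / (p.N * p.zeta)
        assert abs(D - target) / target < 0.05

    def test_flow_advection_matches_affine_rate_early(self):
        """kBT=0, no EV, 45°-inclined straight chain: extension grows ~ e^{εt}."""
        from gsop.polymer import _advance
        p = PolymerParams(N=16, kBT=1e-300, mu=0.0, eps_dot=0.1)
        r = _straight_chain(16, direction=(1.0, 1.0, 0.0))
        ext0 = observables(r)[0]
        rng = np.random.default_rng(0)
        for t_end in (0.25, 0.5):
            rr = r.copy()
            _advance(rr, int(t_end / p.dt), p, p.eps_dot, True, rng)
            growth = observables(rr)[0] / ext0
            affine = np.exp(p.eps_dot * t_end)
            assert abs(growth - affine) / (affine - 1.0) < 0.10


class TestTrajectories:
    def test_snapshot_count_formula(self):
        p = PolymerParams(N=4, t_prod=10.0, t_rec=1.0, t_equil=0.1)
        times, pos = simulate_stretch(p, seed=1)
        assert pos.shape[0] == 11
        # full-scale profile arithmetic: 10^4 τ_d at 10 τ_d spacing -> 1001
        pp = PolymerParams.full_scale_profile()
        assert int(round(pp.t_prod / pp.t_rec)) + 1 == 1001

    def test_seed_reproducibility(self):
        p = PolymerParams(N=8, t_prod=2.0, t_equil=0.5)
        _, a = simulate_stretch(p, seed=9)
        _, b = simulate_stretch(p, seed=9)
        np.testing.assert_array_equal(a, b)

    def test_supercritical_flow_stretches_ensemble(self):
        p = PolymerParams(N=16, t_prod=40.0, t_equil=5.0, eps_dot=0.2)
        ext0, extT = [], []
        for s in range(4):
            _, pos = simulate_stretch(p, seed=s)
            ext0.append(observables(pos[0])[0])
            extT.append(observables(pos[-1])[0])
        assert np.mean(extT) > 2.5 * np.mean(ext0)


class TestObservables:
    def test_straight_chain_values(self):
        r = _straight_chain(10)
        ext, e2e, fold = observables(r)
        assert np.isclose(ext, 9.0) and np.isclose(e2e, 9.0)
        assert np.isclose(fold, 0.0, atol=1e-12)

    def test_perfect_hairpin(self):
        # fold the chain back on itself: ends share the same x
        r = np.zeros((6, 3))
        r[:3, 0] = [0.0, 1.0, 2.0]
        r[3:, 0] = [2.0, 1.0, 0.0]
        r[3:, 1] = 0.1
        ext, e2e, fold = observables(r)
        x_com = r[:, 0].mean()
        assert np.isclose(e2e, 0.0)
        assert np.isclose(fold, 2 * abs(0.0 - x_com))

    def test_translation_invariance_in_y_z(self, rng):
        r = rng.normal(size=(7, 3))
        shifted = r + np.array([0.0, 3.0, -2.0])
        assert observables(r) == observables(shifted)


class TestControlProtocol:
    def _setup(self):
        p = PolymerParams(N=8, t_prod=5.0, t_equil=0.5, t_rec=0.5,
                          eps_dot=0.3, unfold_threshold_frac=0.6)
        st = init_equilibrated_chain(p, seed=3)
        saddle = np.array([3.0, 0.0, 0.0])
        direction = np.array([0.0, 1.0, 0.0])
        return p, st, saddle, direction

    def test_always_aligned_turns_flow_on_immediately(self):
        p, st, saddle, direction = self._setup()
        res = run_control(p, lambda x, t: np.array([1.0, 0.5, 0.5]), saddle,
                          direction, st, comp_indices=(1, 2),
                          align_threshold_deg=180.0, t_cap=100.0, t_max=40.0,
                          seed=1)
        assert res.flow_on_time == 0.0

    def test_constant_misalignment_caps_at_t_cap(self):
        p, st, saddle, direction = self._setup()
        # δZ always orthogonal to the target direction -> never aligned
        res = run_control(p, lambda x, t: saddle + np.array([0.0, 0.0, 1.0]),
                          saddle, direction, st, comp_indices=(1, 2),
                          align_threshold_deg=5.0, t_cap=3.0, t_max=40.0, seed=1)
        assert np.isclose(res.flow_on_time, 3.0)

    def test_alignment_trigger_fires_early(self):
        p, st, saddle, direction = self._setup()
        calls = {"n": 0}

        def reduce_fn(x, t):
            calls["n"] += 1
            if calls["n"] >= 4:   # aligned from the 4th record on
                return saddle + np.array([0.0, 1.0, 0.0])
            return saddle + np.array([0.0, 0.0, 1.0])

        res = run_control(p, reduce_fn, saddle, direction, st,
                          comp_indices=(1, 2), align_threshold_deg=5.0,
                          t_cap=100.0, t_max=40.0, seed=1)
        assert np.isclose(res.flow_on_time, 3 * p.t_rec)

    def test_missing_direction_is_error(self):
        p, st, saddle, _ = self._setup()
        with pytest.raises(ValueError, match="direction"):
            run_control(p, lambda x, t: saddle, saddle, None, st)
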