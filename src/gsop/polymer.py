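"""Brownian dynamics of a touching-bead bead-rod chain in planar elongational flow.

The chain is N beads joined by N-1 inextensible rods of length b.  Inertia
is neglected, so each bead moves by

    dr_i/dt = u(r_i) + (F^ev + F^c + F^br) / ζ,

with u = ε̇(x x̂ - y ŷ) the elongational flow, F^ev a constant-magnitude
short-range repulsion (gradient of E^ev = -Σ μ r_ij for r_ij < r), F^br
Brownian forces satisfying the fluctuation-dissipation theorem
(per-component variance 2 k_B T ζ / Δt), and F^c = T_i b_i - T_{i-1} b_{i-1}
rod-tension constraint forces.  A predictor-corrector scheme is used: an
unconstrained Euler-Maruyama predictor followed by a tension projection in
which the tensions solve the bond-length equations by Newton's method with
a tridiagonal Jacobian.  Non-convergent steps are retried with halved
sub-steps.  Everything is nondimensionalized with b = ζ = k_B T = 1, so
the rod diffusion time τ_d = b²ζ/k_BT = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .encoder import MicroTrajectorySet


@dataclass
class PolymerParams:
    """Bead-rod chain and simulation constants (time unit: τ_d).

    The default profile is a desk-scale configuration (N = 32, short
    production window).  ``full_scale_profile`` returns the full-scale settings.
    """

    N: int = 32
    b: float = 1.0
    r: float | None = None        # bead diameter; defaults to b (touching beads)
    zeta: float = 1.0
    kBT: float = 1.0
    mu: float = 10.0              # excluded-volume force magnitude
    eps_dot: float = 0.1          # strain rate, 1/τ_d (pilot-calibrated for N=32)
    dt: float = 5e-4              # time step, τ_d
    t_equil: float = 200.0
    t_prod: float = 500.0
    t_rec: float = 1.0            # recording interval, τ_d
    unfold_threshold_frac: float = 0.8  # of contour length (N-1)b

    def __post_init__(self):
        if self.r is None:
            self.r = self.b
        for name in ("N", "b", "zeta", "kBT", "dt", "t_rec"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        n_sub = self.t_rec / self.dt
        if abs(n_sub - round(n_sub)) > 1e-9:
            raise ValueError("t_rec must be a multiple of dt")

    @property
    def tau_d(self) -> float:
        return self.b ** 2 * self.zeta / self.kBT

    @property
    def contour_length(self) -> float:
        return (self.N - 1) * self.b

    @property
    def unfold_threshold(self) -> float:
        return self.unfold_threshold_frac * self.contour_length

    @classmethod
    def full_scale_profile(cls, **overrides) -> "PolymerParams":
        kw = dict(N=300, t_equil=1e4, t_prod=1e4, t_rec=10.0)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class PolymerState:
    positions: np.ndarray          # (N, 3)
    flow_on: bool = False

    def bond_vectors(self) -> np.ndarray:
        return np.diff(self.positions, axis=0)

    def bond_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.bond_vectors(), axis=1)


# ================================================================ numba core

@njit(cache=True, fastmath=True)
def _ev_forces(r, mu, rcut, F):
    """Constant-magnitude pair repulsion for r_ij < rcut; fills F in place."""
    N = r.shape[0]
    for i in range(N):
        for j in range(i + 1, N):
            dx = r[i, 0] - r[j, 0]
            dy = r[i, 1] - r[j, 1]
            dz = r[i, 2] - r[j, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < rcut * rcut:
                d = np.sqrt(d2)
                if d < 1e-12:
                    # coincident beads: deterministic tiny symmetric-breaking offset
                    dx, dy, dz, d = 1e-10, 0.0, 0.0, 1e-10
                s = mu / d
                F[i, 0] += s * dx
                F[i, 1] += s * dy
                F[i, 2] += s * dz
                F[j, 0] -= s * dx
                F[j, 1] -= s * dy
                F[j, 2] -= s * dz


@njit(cache=True, fastmath=True)
def _attempt_step_ws(r, rnew, dt, zeta, kBT, mu, rcut, b_len, eps_dot, flow_on,
                     noise, use_noise,
                     F, rstar, bvec, dstar, T, e, g, lo, di, up, rhs, dT):
    """One predictor-corrector step into ``rnew`` using preallocated buffers.

    ``noise`` is an (N, 3) block of standard normals when ``use_noise``;
    otherwise fresh draws are taken from the kernel RNG (retry sub-steps).
    """
    N = r.shape[0]
    nb = N - 1
    for i in range(N):
        F[i, 0] = 0.0
        F[i, 1] = 0.0
        F[i, 2] = 0.0
    if mu > 0.0:
        _ev_forces(r, mu, rcut, F)
    amp = np.sqrt(2.0 * kBT * zeta / dt) if kBT > 0.0 else 0.0
    for i in range(N):
        ux = eps_dot * r[i, 0] if flow_on else 0.0
        uy = -eps_dot * r[i, 1] if flow_on else 0.0
        if amp > 0.0:
            if use_noise:
                fbx = amp * noise[i, 0]
                fby = amp * noise[i, 1]
                fbz = amp * noise[i, 2]
            else:
                fbx = amp * np.random.standard_normal()
                fby = amp * np.random.standard_normal()
                fbz = amp * np.random.standard_normal()
        else:
            fbx = 0.0
            fby = 0.0
            fbz = 0.0
        rstar[i, 0] = r[i, 0] + dt * (ux + (F[i, 0] + fbx) / zeta)
        rstar[i, 1] = r[i, 1] + dt * (uy + (F[i, 1] + fby) / zeta)
        rstar[i, 2] = r[i, 2] + dt * (F[i, 2] + fbz) / zeta
    for i in range(nb):
        bx = r[i + 1, 0] - r[i, 0]
        by = r[i + 1, 1] - r[i, 1]
        bz = r[i + 1, 2] - r[i, 2]
        bn = np.sqrt(bx * bx + by * by + bz * bz)
        bvec[i, 0] = bx / bn
        bvec[i, 1] = by / bn
        bvec[i, 2] = bz / bn
        dstar[i, 0] = rstar[i + 1, 0] - rstar[i, 0]
        dstar[i, 1] = rstar[i + 1, 1] - rstar[i, 1]
        dstar[i, 2] = rstar[i + 1, 2] - rstar[i, 2]
        T[i] = 0.0
    c = dt / zeta
    tol = 2.0 * b_len * b_len * 1e-10
    ok = _newton_tensions(dstar, bvec, c, b_len * b_len, T, 50, tol,
                          e, g, lo, di, up, rhs, dT)
    if not ok:
        return False
    for i in range(N):
        for k in range(3):
            fc = 0.0
            if i < nb:
                fc += T[i] * bvec[i, k]
            if i > 0:
                fc -= T[i - 1] * bvec[i - 1, k]
            rnew[i, k] = rstar[i, k] + c * fc
    return True


@njit(cache=True, fastmath=True)
def _newton_tensions(dstar, bvec, c, b2, T, max_iter, tol,
                     e, g, lo, di, up, rhs, dT):
    """Newton iteration on the bond-length residuals with a tridiagonal Jacobian."""
    n = dstar.shape[0]
    for _ in range(max_iter):
        for i in range(n):
            for k in range(3):
                v = dstar[i, k] - 2.0 * c * T[i] * bvec[i, k]
                if i > 0:
                    v += c * T[i - 1] * bvec[i - 1, k]
                if i < n - 1:
                    v += c * T[i + 1] * bvec[i + 1, k]
                e[i, k] = v
            g[i] = e[i, 0] ** 2 + e[i, 1] ** 2 + e[i, 2] ** 2 - b2
        gmax = 0.0
        for i in range(n):
            if abs(g[i]) > gmax:
                gmax = abs(g[i])
        if gmax < tol:
            return True
        for i in range(n):
            di[i] = -4.0 * c * (e[i, 0] * bvec[i, 0] + e[i, 1] * bvec[i, 1]
                                + e[i, 2] * bvec[i, 2])
            lo[i] = 2.0 * c * (e[i, 0] * bvec[i - 1, 0] + e[i, 1] * bvec[i - 1, 1]
                               + e[i, 2] * bvec[i - 1, 2]) if i > 0 else 0.0
            up[i] = 2.0 * c * (e[i, 0] * bvec[i + 1, 0] + e[i, 1] * bvec[i + 1, 1]
                               + e[i, 2] * bvec[i + 1, 2]) if i < n - 1 else 0.0
            rhs[i] = -g[i]
        for i in range(1, n):
            if abs(di[i - 1]) < 1e-300:
                return False
            w = lo[i] / di[i - 1]
            di[i] -= w * up[i - 1]
            rhs[i] -= w * rhs[i - 1]
        if abs(di[n - 1]) < 1e-300:
            return False
        dT[n - 1] = rhs[n - 1] / di[n - 1]
        for i in range(n - 2, -1, -1):
            dT[i] = (rhs[i] - up[i] * dT[i + 1]) / di[i]
        for i in range(n):
            T[i] += dT[i]
    return False


@njit(cache=True, fastmath=True)
def _run_chunk(r, n_steps, dt, zeta, kBT, mu, rcut, b_len, eps_dot, flow_on,
               noise):
    """Advance n_steps; non-convergent steps are retried with halved dt.

    ``noise`` holds (n_steps, N, 3) standard normals generated in bulk by
    the caller; retry sub-steps fall back to the kernel RNG.  Returns the
    number of halving-retry events (negative on hard failure).
    """
    N = r.shape[0]
    nb = N - 1
    F = np.empty((N, 3))
    rstar = np.empty((N, 3))
    rnew = np.empty((N, 3))
    bvec = np.empty((nb, 3))
    dstar = np.empty((nb, 3))
    T = np.empty(nb)
    e = np.empty((nb, 3))
    g = np.empty(nb)
    lo = np.empty(nb)
    di = np.empty(nb)
    up = np.empty(nb)
    rhs = np.empty(nb)
    dT = np.empty(nb)
    rtmp = np.empty((N, 3))
    retries = 0
    for s in range(n_steps):
        ok = _attempt_step_ws(r, rnew, dt, zeta, kBT, mu, rcut, b_len, eps_dot,
                              flow_on, noise[s], True, F, rstar, bvec, dstar,
                              T, e, g, lo, di, up, rhs, dT)
        if ok:
            r[:] = rnew
            continue
        done = False
        n_sub = 2
        level = 1
        while level <= 6 and not done:
            rtmp[:] = r
            sub_ok = True
            for _s in range(n_sub):
                ok2 = _attempt_step_ws(rtmp, rnew, dt / n_sub, zeta, kBT, mu, rcut,
                                       b_len, eps_dot, flow_on, noise[s], False,
                                       F, rstar, bvec, dstar, T, e, g, lo, di,
                                       up, rhs, dT)
                if not ok2:
                    sub_ok = False
                    break
                rtmp[:] = rnew
            if sub_ok:
                r[:] = rtmp
                done = True
            else:
                level += 1
                n_sub *= 2
        if not done:
            return -1
        retries += 1
    return retries


@njit(cache=True, fastmath=True)
def _seed_numba(seed):
    np.random.seed(seed)


def _advance(r: np.ndarray, n_steps: int, params: "PolymerParams",
             eps_dot: float, flow_on: bool, rng: np.random.Generator,
             chunk: int = 8192) -> int:
    """Drive the kernel in chunks, generating Brownian noise in bulk."""
    retries = 0
    left = n_steps
    while left > 0:
        n = min(chunk, left)
        if params.kBT > 0:
            noise = rng.standard_normal((n, params.N, 3))
        else:
            noise = np.empty((n, params.N, 3))
        code = _run_chunk(r, n, params.dt, params.zeta, params.kBT, params.mu,
                          params.r, params.b, eps_dot, flow_on, noise)
        if code < 0:
            raise RuntimeError("bead-rod step failed after 6 halvings")
        retries += code
        left -= n
    return retries


# ============================================================== python layer

def nonconstraint_forces(state: PolymerState, params: PolymerParams,
                         flow_on: bool, rng: np.random.Generator):
    """Excluded-volume + Brownian forces and the ambient flow velocities.

    The Brownian per-component variance is 2 k_B T ζ / Δt
    (fluctuation-dissipation at drag ζ and step Δt).
    """
    r = state.positions
    N = params.N
    F = np.zeros((N, 3))
    _ev_forces(r, params.mu, params.r, F)
    amp = np.sqrt(2.0 * params.kBT * params.zeta / params.dt)
    F_br = amp * rng.standard_normal((N, 3))
    u = np.zeros((N, 3))
    if flow_on:
        u[:, 0] = params.eps_dot * r[:, 0]
        u[:, 1] = -params.eps_dot * r[:, 1]
    return F + F_br, u


def solve_tensions(state: PolymerState, predicted: np.ndarray,
                   params: PolymerParams) -> np.ndarray:
    """Rod tensions restoring every bond length to b for a predicted move."""
    bvec = state.bond_vectors()
    bvec = bvec / np.linalg.norm(bvec, axis=1, keepdims=True)
    dstar = np.diff(np.asarray(predicted, dtype=np.float64), axis=0)
    nb = params.N - 1
    T = np.zeros(nb)
    ws = [np.empty((nb, 3))] + [np.empty(nb) for _ in range(6)]
    ok = _newton_tensions(dstar, bvec, params.dt / params.zeta,
                          params.b ** 2, T, 50, 2.0 * params.b ** 2 * 1e-12,
                          ws[0], ws[1], ws[2], ws[3], ws[4], ws[5], ws[6])
    if not ok:
        raise RuntimeError("tension Newton iteration did not converge")
    return T


def step(state: PolymerState, params: PolymerParams,
         rng: np.random.Generator | None = None) -> PolymerState:
    """Single predictor-corrector step."""
    rng = rng if rng is not None else np.random.default_rng(0)
    r = state.positions.copy()
    _advance(r, 1, params, params.eps_dot if state.flow_on else 0.0,
             state.flow_on, rng)
    return PolymerState(r, state.flow_on)


def random_walk_chain(params: PolymerParams, rng: np.random.Generator) -> np.ndarray:
    """Freely-jointed random-walk configuration with exact rod lengths."""
    steps = rng.standard_normal((params.N - 1, 3))
    steps *= params.b / np.linalg.norm(steps, axis=1, keepdims=True)
    r = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    return r - r.mean(axis=0)


def init_equilibrated_chain(params: PolymerParams, seed: int = 0) -> PolymerState:
    """Random-walk start followed by t_equil of flow-off relaxation; COM at origin."""
    rng = np.random.default_rng(seed)
    r = random_walk_chain(params, rng)
    _seed_numba(int(rng.integers(0, 2 ** 31 - 1)))
    n_steps = int(round(params.t_equil / params.dt))
    if n_steps > 0:
        _advance(r, n_steps, params, 0.0, False, rng)
    r -= r.mean(axis=0)
    return PolymerState(r, flow_on=False)


def observables(X: np.ndarray) -> tuple[float, float, float]:
    """(extension, projected end-to-end distance, foldedness) of a configuration.

    extension = max_i x_i - min_i x_i (projected chain length on the
    elongational axis); end-to-end = |x_N - x_1|; foldedness = |x_1 + x_N|
    evaluated on the center-of-mass-centered chain.
    """
    r = np.asarray(X, dtype=np.float64).reshape(-1, 3)
    x = r[:, 0]
    xc = x - r.mean(axis=0)[0]
    return (float(x.max() - x.min()), float(abs(x[-1] - x[0])),
            float(abs(xc[0] + xc[-1])))


def extension_map(X: np.ndarray) -> np.ndarray:
    """Macroscopic observable map for training: projected chain extension."""
    x = np.asarray(X, dtype=np.float64).reshape(-1, 3)[:, 0]
    return np.array([x.max() - x.min()])


def simulate_stretch(params: PolymerParams, seed: int = 0,
                     state0: PolymerState | None = None):
    """Equilibrate (flow off) then record a stretching trajectory (flow on).

    Returns (times, positions) with positions of shape (n_rec+1, N, 3),
    recorded every t_rec starting from the flow-on instant t = 0.
    """
    state = state0 if state0 is not None else init_equilibrated_chain(params, seed)
    run_seed = (seed * 2654435761 + 97) % (2 ** 31 - 1)
    _seed_numba(run_seed)
    rng = np.random.default_rng(run_seed)
    steps_per_rec = int(round(params.t_rec / params.dt))
    n_rec = int(round(params.t_prod / params.t_rec))
    r = state.positions.copy()
    out = np.empty((n_rec + 1, params.N, 3))
    r -= r.mean(axis=0)
    out[0] = r
    for k in range(n_rec):
        _advance(r, steps_per_rec, params, params.eps_dot, True, rng)
        # COM frame: the chain is held at the flow's stagnation point.  The
        # linear flow makes internal dynamics independent of the COM, whose
        # unstable advection (x ~ e^{eps*t}) would otherwise destroy
        # floating-point precision on long runs.
        r -= r.mean(axis=0)
        out[k + 1] = r
    times = np.arange(n_rec + 1) * params.t_rec
    _check_bonds(out, params)
    return times, out


def simulate_ensemble(params: PolymerParams, n_traj: int, seed: int = 0) -> MicroTrajectorySet:
    """Independent stretching trajectories flattened to (M, Nt+1, 3N)."""
    all_pos = []
    times = None
    for j in range(n_traj):
        times, pos = simulate_stretch(params, seed=seed * 100003 + j)
        all_pos.append(pos.reshape(pos.shape[0], -1))
    return MicroTrajectorySet(times, np.stack(all_pos), source="polymer")


def _check_bonds(positions: np.ndarray, params: PolymerParams) -> None:
    d = np.diff(positions, axis=-2)
    lens = np.sqrt((d ** 2).sum(axis=-1))
    worst = float(np.abs(lens - params.b).max())
    if worst > 1e-8 * params.b:
        raise RuntimeError(f"rigid-rod violation {worst:.3e} exceeds 1e-8 b")


# ------------------------------------------------------------------ control

@dataclass
class ControlResult:
    times: np.ndarray
    positions: np.ndarray
    flow_on_time: float
    unfolding_time: float
    censored: bool


def run_control(params: PolymerParams, reduce_fn, saddle_location: np.ndarray,
                manifold_direction: np.ndarray, state0: PolymerState,
                comp_indices: tuple = (1, 2), align_threshold_deg: float = 15.0,
                t_cap: float = 100.0, t_max: float = 500.0, seed: int = 0) -> ControlResult:
    """Saddle-escape control: flow off, wait for manifold alignment, flow on.

    At every recording time the reduced deviation δZ = Z - Z_saddle is
    computed from ``reduce_fn`` (a map from the flattened configuration and
    time to the d reduced coordinates).  The flow is re-enabled once the
    angle between the selected components of δZ and the target manifold
    direction (as a line, sign-free) drops below ``align_threshold_deg``,
    or when the flow-off time reaches ``t_cap``.  The run then continues
    until the extension reaches the unfolding threshold or ``t_max``.
    """
    if manifold_direction is None:
        raise ValueError("control protocol requires a manifold direction")
    run_seed = (seed * 7919 + 13) % (2 ** 31 - 1)
    _seed_numba(run_seed)
    rng = np.random.default_rng(run_seed)
    steps_per_rec = int(round(params.t_rec / params.dt))
    n_rec_max = int(round(t_max / params.t_rec))
    comp = list(comp_indices)
    target = np.asarray(manifold_direction, dtype=float)[comp]
    target = target / np.linalg.norm(target)
    cos_thresh = np.cos(np.deg2rad(align_threshold_deg))

    r = state0.positions.copy()
    recs = [r.copy()]
    flow_on = False
    flow_on_time = np.nan
    t = 0.0
    for k in range(n_rec_max):
        if not flow_on:
            z = np.asarray(reduce_fn(r.reshape(-1), t), dtype=float)
            delta = (z - np.asarray(saddle_location, dtype=float))[comp]
            nd = np.linalg.norm(delta)
            aligned = nd > 0 and abs(delta @ target) / nd >= cos_thresh
            if aligned or t >= t_cap:
                flow_on = True
                flow_on_time = t
        _advance(r, steps_per_rec, params, params.eps_dot if flow_on else 0.0,
                 flow_on, rng)
        r -= r.mean(axis=0)  # COM frame, as in simulate_stretch
        t += params.t_rec
        recs.append(r.copy())
        if flow_on and observables(r)[0] >= params.unfold_threshold:
            break
    positions = np.stack(recs)
    times = np.arange(len(recs)) * params.t_rec
    ext = np.array([observables(p)[0] for p in positions])
    from .rollout import first_passage_time
    t_unfold, censored = first_passage_time(times, ext, params.unfold_threshold)
    return ControlResult(times, positions, float(flow_on_time), t_unfold, censored)


def calibrate_strain_rate(params: PolymerParams, target_frac: float = 0.9,
                          n_pilot: int = 8, seed: int = 0,
                          max_doublings: int = 6) -> float:
    """Smallest doubling of ε̇ for which ≥ target_frac of a pilot ensemble unfolds."""
    from dataclasses import replace
    eps = params.eps_dot
    for _ in range(max_doublings):
        p = replace(params, eps_dot=eps)
        n_unfold = 0
        for j in range(n_pilot):
            times, pos = simulate_stretch(p, seed=seed * 7 + j)
            ext = np.array([observables(x)[0] for x in pos])
            if ext.max() >= p.unfold_threshold:
                n_unfold += 1
        if n_unfold >= target_frac * n_pilot:
            return eps
        eps *= 2.0
    return eps
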