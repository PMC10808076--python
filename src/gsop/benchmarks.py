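"""Ground-truth dissipative SDE systems for end-to-end validation.

These generators produce trajectory data from systems whose (M, W, V, σ)
are known exactly, so the full training loop can be scored against the
truth.  Note the gauge freedom (M, V) -> (cM, V/c): only the product drift
-(M+W)∇V and the diffusion σσᵀ are identifiable from data, so recovery
metrics compare those, never raw M or V.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_lyapunov

from .encoder import MicroTrajectorySet


@dataclass
class GroundTruth:
    """Record of the generating system for recovery scoring."""

    d: int
    drift: object               # callable z (B,d) -> (B,d)
    sigma: np.ndarray           # constant d×p
    M: np.ndarray | None = None
    W: np.ndarray | None = None
    H: np.ndarray | None = None  # Hessian of quadratic V

    def sigma2(self) -> np.ndarray:
        return self.sigma @ self.sigma.T


def make_ou_benchmark(d: int, M_true: np.ndarray, W_true: np.ndarray,
                      H_true: np.ndarray, sigma_true: np.ndarray,
                      n_traj: int, Nt: int, dt: float, seed: int = 0,
                      substeps: int = 10, z0_scale: float = 1.0):
    """Linear (Ornstein-Uhlenbeck) GSOP: V = ½ zᵀHz, drift f = -(M+W)Hz.

    Trajectories are generated by Euler-Maruyama at ``substeps`` fine steps
    per observation interval, keeping discretization bias well below the
    recovery tolerances.  Returns (MicroTrajectorySet in reduced space,
    GroundTruth).
    """
    M_true = np.atleast_2d(np.asarray(M_true, dtype=float))
    W_true = np.atleast_2d(np.asarray(W_true, dtype=float))
    H_true = np.atleast_2d(np.asarray(H_true, dtype=float))
    sigma_true = np.atleast_2d(np.asarray(sigma_true, dtype=float))
    A = (M_true + W_true) @ H_true
    eigs = np.linalg.eigvals(A)
    if np.any(eigs.real <= 0):
        import warnings
        warnings.warn("drift spectrum is not strictly stable")
    rng = np.random.default_rng(seed)
    h = dt / substeps
    z = z0_scale * rng.standard_normal((n_traj, d))
    out = np.empty((n_traj, Nt + 1, d))
    out[:, 0] = z
    p = sigma_true.shape[1]
    for i in range(Nt):
        for _ in range(substeps):
            xi = rng.standard_normal((n_traj, p))
            z = z - (z @ A.T) * h + np.sqrt(h) * xi @ sigma_true.T
        out[:, i + 1] = z
    times = np.arange(Nt + 1) * dt

    def drift(zz):
        return -np.atleast_2d(zz) @ A.T

    truth = GroundTruth(d=d, drift=drift, sigma=sigma_true, M=M_true,
                        W=W_true, H=H_true)
    return MicroTrajectorySet(times, out, source="external"), truth


def ou_stationary_cov(M, W, H, sigma) -> np.ndarray:
    """Stationary covariance from the Lyapunov equation A C + C Aᵀ = σσᵀ."""
    A = (np.atleast_2d(M) + np.atleast_2d(W)) @ np.atleast_2d(H)
    S = np.atleast_2d(sigma) @ np.atleast_2d(sigma).T
    return solve_lyapunov(A, S)  # solves A C + C A^T = S for the drift -Az


def make_langevin_double_well(mass: float = 1.0, gamma1: float = 5.0,
                              kBT: float = 0.5, n_traj: int = 100,
                              T: float = 20.0, dt_obs: float = 0.1,
                              dt_sim: float = 1e-3, seed: int = 0,
                              x0: float = -1.0):
    """Underdamped Langevin particle in the double well U(x) = (x²-1)².

    Simulates (x, v) with dx = v dt, dv = (-U'(x) - mγ₁v)/m dt +
    √(2γ₁kBT/m) dB and returns the microscopic (x, v) trajectory set
    together with the reduction map φ(x, v) = x.  The long-run x histogram
    follows the Boltzmann marginal ∝ exp(-U/kBT).
    """
    rng = np.random.default_rng(seed)
    n_obs = int(round(T / dt_obs))
    sub = int(round(dt_obs / dt_sim))
    x = np.full(n_traj, float(x0)) + 0.05 * rng.standard_normal(n_traj)
    v = np.sqrt(kBT / mass) * rng.standard_normal(n_traj)
    out = np.empty((n_traj, n_obs + 1, 2))
    out[:, 0, 0], out[:, 0, 1] = x, v
    amp = np.sqrt(2.0 * gamma1 * kBT / mass)
    for i in range(n_obs):
        for _ in range(sub):
            xi = rng.standard_normal(n_traj)
            a = (-4.0 * x * (x * x - 1.0) - mass * gamma1 * v) / mass
            x = x + v * dt_sim
            v = v + a * dt_sim + amp * np.sqrt(dt_sim) * xi
        out[:, i + 1, 0], out[:, i + 1, 1] = x, v
    times = np.arange(n_obs + 1) * dt_obs
    data = MicroTrajectorySet(times, out, source="external")

    def phi(xv):
        return np.atleast_2d(xv)[..., :1]

    return data, phi


def recovery_report(model, truth: GroundTruth, grid: np.ndarray) -> dict:
    """Score a trained model against the generating system on a grid.

    drift_rel_L2: relative L2 error of the learned drift field;
    diffusion_err: relative Frobenius error of σσᵀ; potential_shape_err:
    relative L2 error of V after least-squares matching of the scale/offset
    gauge (V and cV + const generate the same data when M absorbs 1/c).
    """
    grid = np.atleast_2d(np.asarray(grid, dtype=float))
    if grid.shape[-1] != truth.d:
        grid = grid.reshape(-1, truth.d)
    f_model = np.atleast_2d(model.drift(grid))
    f_true = np.atleast_2d(truth.drift(grid))
    num = np.linalg.norm(f_model - f_true)
    den = np.linalg.norm(f_true)
    drift_rel = float(num / den) if den > 0 else float(num)

    sig_m = model.sigma(grid[:1])[0]
    s2_m = sig_m @ sig_m.T
    s2_t = truth.sigma2()
    diffusion_err = float(np.linalg.norm(s2_m - s2_t) /
                          max(np.linalg.norm(s2_t), 1e-300))

    potential_shape_err = np.nan
    if truth.H is not None:
        V_t = 0.5 * np.einsum("bi,ij,bj->b", grid, truth.H, grid)
        V_m = np.atleast_1d(model.potential(grid))
        X = np.stack([V_t, np.ones_like(V_t)], axis=1)
        coef, *_ = np.linalg.lstsq(X, V_m, rcond=None)
        resid = V_m - X @ coef
        potential_shape_err = float(np.linalg.norm(resid) /
                                    max(np.linalg.norm(V_m - V_m.mean()), 1e-300))
    return dict(drift_rel_L2=drift_rel, diffusion_err=diffusion_err,
                potential_shape_err=potential_shape_err)
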