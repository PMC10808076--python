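"""Integration of the learned reduced SDE and ensemble statistics.

Uses the Euler-Maruyama scheme, the same discretization under which the
model was trained, so the default rollout time step equals the training
observation interval.  Stiff learned models may need a smaller step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde


@dataclass
class ReducedEnsemble:
    """Ensemble of reduced trajectories: paths (n_paths, n_steps+1, d)."""

    times: np.ndarray
    paths: np.ndarray
    nan_flagged: np.ndarray  # (n_paths,) True where the path went non-finite

    @property
    def n_paths(self) -> int:
        return self.paths.shape[0]


class CallableModel:
    """Adapter giving analytic (drift, σ, V) triples the model interface.

    Useful for closed-form oracles: e.g. a quadratic potential with M = I.
    """

    def __init__(self, d: int, drift_fn, sigma=None, potential_fn=None):
        self.d = d
        self._drift = drift_fn
        self._sigma = sigma if sigma is not None else np.zeros((d, d))
        self._potential = potential_fn
        self.sigma_spec = "callable"

    def drift(self, z):
        z = np.atleast_2d(z)
        try:  # vectorized evaluation when the callable broadcasts over rows
            out = np.asarray(self._drift(z))
            if out.shape == z.shape:
                return out
        except Exception:
            pass
        return np.apply_along_axis(self._drift, -1, z)

    def sigma(self, z):
        if callable(self._sigma):
            return self._sigma(np.atleast_2d(z))
        return np.broadcast_to(self._sigma, (np.atleast_2d(z).shape[0],) + self._sigma.shape)

    def potential(self, z):
        return np.apply_along_axis(self._potential, -1, np.atleast_2d(z))


def simulate_sde(model, z0, dt: float, T: float, n_paths: int = 1,
                 seed: int = 0) -> ReducedEnsemble:
    """Euler-Maruyama rollout: Z_{i+1} = Z_i + f(Z_i)Δt + σ(Z_i)√Δt ξ_i.

    ``z0`` is a single d-vector (shared by all paths) or an (n_paths, d)
    array.  Paths that turn non-finite are frozen at their last finite
    state and flagged; the rest continue.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    z0 = np.asarray(z0, dtype=np.float64)
    if z0.ndim == 1:
        z0 = np.broadcast_to(z0, (n_paths, z0.shape[0])).copy()
    n_paths, d = z0.shape
    n_steps = int(round(T / dt))
    out = np.empty((n_paths, n_steps + 1, d))
    out[:, 0] = z0
    alive = np.ones(n_paths, dtype=bool)
    z = z0.copy()
    sqdt = np.sqrt(dt)
    for i in range(n_steps):
        f = np.asarray(model.drift(z))
        sig = np.asarray(model.sigma(z))  # (n_paths, d, p)
        xi = rng.standard_normal((n_paths, sig.shape[-1]))
        znew = z + f * dt + sqdt * np.einsum("bip,bp->bi", sig, xi)
        bad = ~np.all(np.isfinite(znew), axis=-1)
        newly = bad & alive
        if np.any(newly):
            znew[newly] = z[newly]
            alive &= ~newly
        znew[~alive] = z[~alive]
        z = znew
        out[:, i + 1] = z
    times = np.arange(n_steps + 1) * dt
    return ReducedEnsemble(times, out, ~alive)


def ensemble_stats(ens: ReducedEnsemble) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise ensemble mean and (n-1)-normalized standard deviation."""
    if ens.n_paths < 1:
        raise ValueError("empty ensemble")
    mean = ens.paths.mean(axis=0)
    if ens.n_paths == 1:
        warnings.warn("single path: standard deviation reported as 0")
        std = np.zeros_like(mean)
    else:
        std = ens.paths.std(axis=0, ddof=1)
    return mean, std


def first_passage_time(times: np.ndarray, series: np.ndarray,
                       threshold: float) -> tuple[float, bool]:
    """First time the series reaches the threshold, linearly interpolated.

    Returns (time, censored); ``censored`` is True when the threshold is
    never reached within the record.
    """
    series = np.asarray(series, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    hit = series >= threshold
    if hit[0]:
        return 0.0, False
    idx = np.argmax(hit)
    if idx == 0:  # never reached
        return float("nan"), True
    y0, y1 = series[idx - 1], series[idx]
    t0, t1 = times[idx - 1], times[idx]
    frac = (threshold - y0) / (y1 - y0) if y1 != y0 else 0.0
    return float(t0 + frac * (t1 - t0)), False


def unfolding_time_pdf(fpts: np.ndarray, grid: np.ndarray | None = None):
    """Gaussian-kernel density (Silverman bandwidth) of first-passage times.

    Censored values (NaN) are dropped.  Returns (grid, density).
    """
    fpts = np.asarray(fpts, dtype=np.float64)
    fpts = fpts[np.isfinite(fpts)]
    if fpts.size < 2:
        raise ValueError("need at least 2 uncensored passage times")
    kde = gaussian_kde(fpts, bw_method="silverman")
    if grid is None:
        lo, hi = fpts.min(), fpts.max()
        pad = 0.2 * (hi - lo + 1e-12)
        grid = np.linspace(lo - pad, hi + pad, 256)
    return grid, kde(grid)


@dataclass
class DissipationReport:
    """Noise-free audit of the energy-dissipation law dV/dt = -||∇V||²_M ≤ 0."""

    times: np.ndarray
    V: np.ndarray
    max_violation: float   # largest positive increment of V along the path

    def passes(self, tol: float) -> bool:
        return self.max_violation <= tol


class _NoNoise:
    def __init__(self, model):
        self._m = model
        self.d = model.d

    def drift(self, z):
        return self._m.drift(np.atleast_2d(z))

    def sigma(self, z):
        return np.zeros((np.atleast_2d(z).shape[0], self.d, 1))


def dissipation_audit(model, z0, dt: float, T: float) -> DissipationReport:
    """Integrate the drift with σ forced to 0 and check V is non-increasing.

    For the GSOP structure dV/dt = -∇Vᵀ M ∇V ≤ -α|∇V|² in the noise-free
    limit; positive increments beyond the integrator tolerance signal a
    broken model structure or a too-large time step.
    """
    ens = simulate_sde(_NoNoise(model), np.asarray(z0, dtype=np.float64),
                       dt, T, n_paths=1, seed=0)
    path = ens.paths[0]
    V = np.asarray([float(np.atleast_1d(model.potential(p))[0]) for p in path])
    inc = np.diff(V)
    max_violation = float(inc.max(initial=0.0))
    return DissipationReport(ens.times, V, max_violation)
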