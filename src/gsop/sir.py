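"""Stochastic spatial SIR lattice model: the second microscopic data generator.

Susceptible and infective densities on an n×n grid evolve by the
reaction-diffusion system

    dS/dt = -β I S + δ ∇² S + σ Ḃ₁,
    dI/dt =  β I S - γ I + δ ∇² I + σ Ḃ₂,

discretized with the 5-point Laplacian (grid steps δx, δy) and integrated
with explicit Euler-Maruyama.  Recovered individuals leave the system at
rate γ and are not tracked.  Boundaries are zero-flux (reflecting), which
conserves total mass under pure diffusion; additive noise can drive
densities slightly negative, which is clipped to zero after every step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoder import MicroTrajectorySet


class SIRConfigError(ValueError):
    pass


@dataclass
class SIRParams:
    n: int = 16
    beta: float = 0.3        # transmission rate
    gamma: float = 0.13      # recovery (removal) rate
    delta: float = 0.5       # diffusion coefficient
    sigma_noise: float = 0.03
    dx: float = 2.0 / 3.0
    dy: float = 2.0 / 3.0
    dt: float = 0.03
    origin: float = -5.0     # x_i = origin + i*dx
    boundary: str = "neumann"  # or "periodic"

    def __post_init__(self):
        if min(self.beta, self.gamma, self.delta, self.sigma_noise) < 0:
            raise SIRConfigError("rates must be nonnegative")
        if self.boundary not in ("neumann", "periodic"):
            raise SIRConfigError(f"unknown boundary {self.boundary!r}")
        # explicit-scheme stability guard
        if self.delta > 0 and self.dt * self.delta / min(self.dx, self.dy) ** 2 >= 0.5:
            raise SIRConfigError(
                "unstable configuration: dt*delta/dx^2 must be < 0.5")

    @property
    def xs(self) -> np.ndarray:
        return self.origin + np.arange(self.n) * self.dx

    @property
    def ys(self) -> np.ndarray:
        return self.origin + np.arange(self.n) * self.dy


@dataclass
class SIRField:
    S: np.ndarray
    I: np.ndarray

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=np.float64)
        self.I = np.asarray(self.I, dtype=np.float64)
        if self.S.shape != self.I.shape:
            raise SIRConfigError("S and I must have identical shapes")
        if not (np.all(np.isfinite(self.S)) and np.all(np.isfinite(self.I))):
            raise SIRConfigError("non-finite field values")

    def flatten(self) -> np.ndarray:
        """Concatenated (I, S) vector of length 2n², the encoder input."""
        return np.concatenate([self.I.ravel(), self.S.ravel()])


def _laplacian(F: np.ndarray, params: SIRParams) -> np.ndarray:
    if params.boundary == "periodic":
        up, dn = np.roll(F, 1, axis=0), np.roll(F, -1, axis=0)
        lf, rt = np.roll(F, 1, axis=1), np.roll(F, -1, axis=1)
    else:  # zero-flux: edge-replicated ghost cells
        P = np.pad(F, 1, mode="edge")
        up, dn = P[:-2, 1:-1], P[2:, 1:-1]
        lf, rt = P[1:-1, :-2], P[1:-1, 2:]
    return (up - 2 * F + dn) / params.dx ** 2 + (lf - 2 * F + rt) / params.dy ** 2


def sir_step(field: SIRField, params: SIRParams,
             rng: np.random.Generator) -> SIRField:
    """One Euler-Maruyama update of the discretized reaction-diffusion system."""
    S, I = field.S, field.I
    dt = params.dt
    lap_S = params.delta * _laplacian(S, params)
    lap_I = params.delta * _laplacian(I, params)
    react = params.beta * I * S
    dS = (-react + lap_S) * dt
    dI = (react - params.gamma * I + lap_I) * dt
    if params.sigma_noise > 0:
        sq = params.sigma_noise * np.sqrt(dt)
        dS = dS + sq * rng.standard_normal(S.shape)
        dI = dI + sq * rng.standard_normal(I.shape)
    return SIRField(np.clip(S + dS, 0.0, None), np.clip(I + dI, 0.0, None))


def init_condition(params: SIRParams, seed: int = 0) -> SIRField:
    """Random infective cluster over a fixed two-cluster susceptible field.

    I₀ = 5 exp(-(x-x₀)² - (y-y₀)²) with (x₀, y₀) uniform in the unit
    square; S₀ = 5 exp(-(x-1)² - (y-1)²) + 5 exp(-(x-1)² - (y+2)²).
    """
    rng = np.random.default_rng(seed)
    x0, y0 = rng.uniform(0.0, 1.0, size=2)
    X, Y = np.meshgrid(params.xs, params.ys, indexing="ij")
    I0 = 5.0 * np.exp(-(X - x0) ** 2 - (Y - y0) ** 2)
    S0 = (5.0 * np.exp(-(X - 1.0) ** 2 - (Y - 1.0) ** 2)
          + 5.0 * np.exp(-(X - 1.0) ** 2 - (Y + 2.0) ** 2))
    return SIRField(S0, I0)


def sir_observables(field: SIRField, params: SIRParams) -> tuple[float, float, float]:
    """(Z₁, Z₂, IS_mean): spatial averages δxδy ΣI, δxδy ΣS and overlap δxδy ΣIS."""
    w = params.dx * params.dy
    return (float(w * field.I.sum()), float(w * field.S.sum()),
            float(w * (field.I * field.S).sum()))


def macro_map(params: SIRParams):
    """Observable map for training: X = (I, S) flattened -> (Z₁, Z₂)."""
    w = params.dx * params.dy
    n2 = params.n * params.n

    def _map(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        return np.array([w * x[..., :n2].sum(axis=-1), w * x[..., n2:].sum(axis=-1)])

    return _map


def simulate_sir(params: SIRParams, T: float, seed: int = 0,
                 stride: int = 1):
    """Integrate one realization; returns (times, fields, observables).

    ``fields`` is a list of SIRField snapshots every ``stride`` steps
    (including the initial condition); ``observables`` the matching
    (Z₁, Z₂, IS_mean) series.
    """
    rng = np.random.default_rng(seed + 1)
    field = init_condition(params, seed)
    n_steps = int(round(T / params.dt))
    fields = [field]
    obs = [sir_observables(field, params)]
    for k in range(n_steps):
        field = sir_step(field, params, rng)
        if (k + 1) % stride == 0:
            fields.append(field)
            obs.append(sir_observables(field, params))
    times = np.arange(len(fields)) * params.dt * stride
    return times, fields, np.asarray(obs)


def simulate_sir_ensemble(params: SIRParams, T: float, n_traj: int,
                          seed: int = 0, stride: int = 1) -> MicroTrajectorySet:
    """Ensemble of realizations flattened to (M, Nt+1, 2n²) for training."""
    states = []
    times = None
    for j in range(n_traj):
        times, fields, _ = simulate_sir(params, T, seed=seed * 99991 + j,
                                        stride=stride)
        states.append(np.stack([f.flatten() for f in fields]))
    return MicroTrajectorySet(times, np.stack(states), source="sir")
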