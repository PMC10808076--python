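"""Structured parameterization of the generalized stochastic Onsager principle.

The reduced dynamics is the SDE

    dZ = -(M(Z) + W(Z)) ∇V(Z) dt + σ(Z) dB,

with M symmetric positive definite (dissipation), W antisymmetric
(conservative coupling), V a lower-bounded generalized potential and σ the
diffusion matrix.  The structural constraints are built into the
parameterization rather than penalized:

* a network A: R^d -> R^{d×d}; its lower triangle L1 (including the
  diagonal) gives M = L1 L1^T + αI, its strict upper triangle L2 gives
  W = L2 - L2^T;
* V(Z) = 1/2 Σ_i (U_i(Z) + Σ_j γ_ij Z_j)^2 + β|Z|^2, a sum of squares
  plus a confining quadratic, so V ≥ β|Z|^2 everywhere;
* σ is either a z-independent trainable diagonal (reported through an
  absolute value) or a general network output reshaped to d×p.

∇V is evaluated analytically (an in-graph vector-Jacobian product through
the U network), never by finite differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nets import MLP, _t2


class InvalidInputError(ValueError):
    pass


class SingularMatrixError(np.linalg.LinAlgError):
    pass


# --------------------------------------------------------------- domain types

@dataclass
class ReducedState:
    """d-dimensional thermodynamic coordinates Z = (Z*, Ẑ).

    The leading ``d_star`` components are the user-designated macroscopic
    observables; the rest are learned closure coordinates.
    """

    z: np.ndarray
    d_star: int = 1

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=np.float64)
        if not np.all(np.isfinite(self.z)):
            raise InvalidInputError("reduced state contains non-finite entries")
        if not (self.z.shape[-1] >= self.d_star >= 1):
            raise InvalidInputError("require d >= d_star >= 1")

    @property
    def d(self) -> int:
        return self.z.shape[-1]

    @property
    def z_star(self) -> np.ndarray:
        return self.z[..., : self.d_star]

    @property
    def z_hat(self) -> np.ndarray:
        return self.z[..., self.d_star:]


@dataclass
class GSOPFormB:
    """The (M̃, W̃, σ̃) form: (M̃+W̃) dZ = -∇V dt + σ̃ dB."""

    M_tilde: np.ndarray
    W_tilde: np.ndarray
    sigma_tilde: np.ndarray


# ------------------------------------------------------- assembly (stateless)

def assemble_M(a_matrix: np.ndarray, alpha: float) -> np.ndarray:
    """M = L1 L1^T + αI with L1 the lower triangle (incl. diagonal) of A."""
    a = np.asarray(a_matrix, dtype=np.float64)
    if not np.all(np.isfinite(a)):
        raise InvalidInputError("non-finite entries in A matrix")
    if not alpha > 0:
        raise InvalidInputError("alpha must be positive")
    L1 = np.tril(a)
    return L1 @ np.swapaxes(L1, -1, -2) + alpha * np.eye(a.shape[-1])


def assemble_W(a_matrix: np.ndarray) -> np.ndarray:
    """W = L2 - L2^T with L2 the strict upper triangle of A (exactly antisymmetric)."""
    a = np.asarray(a_matrix, dtype=np.float64)
    if not np.all(np.isfinite(a)):
        raise InvalidInputError("non-finite entries in A matrix")
    L2 = np.triu(a, k=1)
    return L2 - np.swapaxes(L2, -1, -2)


def convert_form(M: np.ndarray, W: np.ndarray, sigma: np.ndarray,
                 cond_cap: float = 1e12, z=None) -> GSOPFormB:
    """Convert (M, W, σ) to the equivalent (M̃, W̃, σ̃) form.

    M̃ is the symmetric part and W̃ the antisymmetric part of (M+W)^{-1},
    and σ̃ = (M+W)^{-1} σ.  The construction is an involution: applying it
    to (M̃, W̃, σ̃) recovers (M, W, σ).
    """
    A = np.asarray(M, dtype=float) + np.asarray(W, dtype=float)
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > cond_cap:
        where = "" if z is None else f" at z={np.asarray(z)!r}"
        raise SingularMatrixError(
            f"M+W is singular or ill-conditioned (cond={cond:.3g}){where}")
    Ainv = np.linalg.inv(A)
    M_t = 0.5 * (Ainv + Ainv.T)
    W_t = 0.5 * (Ainv - Ainv.T)
    return GSOPFormB(M_t, W_t, Ainv @ np.asarray(sigma, dtype=float))


@dataclass
class LangevinGSOP:
    """Example: underdamped Langevin dynamics written as a GSOP on (x, v)."""

    M_tilde: np.ndarray
    W_tilde: np.ndarray
    Sigma: np.ndarray
    potential: object  # callable V(x, v)


def langevin_as_gsop(mass: float, gamma1: float, kBT: float, gradU=None,
                     U=None) -> LangevinGSOP:
    """Cast m ẍ = -∇U - mγ₁ ẋ + √(2mγ₁kBT) R(t) into form-B GSOP.

    Returns M̃ = [[mγ₁,0],[0,0]], W̃ = [[0,m],[-m,0]], Σ = (√(2mγ₁kBT), 0)^T
    and V(x,v) = U(x) + ½mv².
    """
    if not (mass > 0 and gamma1 > 0 and kBT > 0):
        raise InvalidInputError("mass, gamma1 and kBT must be positive")
    U = U if U is not None else (lambda x: 0.0 * np.asarray(x))
    M_t = np.array([[mass * gamma1, 0.0], [0.0, 0.0]])
    W_t = np.array([[0.0, mass], [-mass, 0.0]])
    Sigma = np.array([[np.sqrt(2.0 * mass * gamma1 * kBT)], [0.0]])

    def V(x, v):
        return U(x) + 0.5 * mass * np.asarray(v) ** 2

    return LangevinGSOP(M_t, W_t, Sigma, V)


# ------------------------------------------------------------------ the model

class StructuredDriftModel:
    """Trainable (M, W, V, σ) with the GSOP structural constraints built in.

    Parameters
    ----------
    d : reduced dimension.
    m : number of squared terms in the potential (output width of U).
    alpha : lower bound on the eigenvalues of M.
    beta : coefficient of the confining quadratic in V.
    sigma_spec : "diag_constant" (trainable length-d vector, z-independent)
        or "general_net" (network output reshaped d×p).
    """

    def __init__(self, d: int, d_star: int = 1, m: int = 50, p: int | None = None,
                 alpha: float = 0.1, beta: float = 0.01,
                 a_hidden: tuple = (20, 20), u_hidden: tuple = (128,),
                 activation: str = "requr", sigma_spec: str = "diag_constant",
                 sigma_init: float = 0.1, seed: int = 0,
                 input_loc=None, input_scale=None):
        if alpha <= 0 or beta < 0:
            raise InvalidInputError("require alpha > 0 and beta >= 0")
        if sigma_spec not in ("diag_constant", "general_net"):
            raise InvalidInputError(f"unknown sigma_spec {sigma_spec!r}")
        self.d, self.d_star, self.m = d, d_star, m
        self.p = d if p is None else p
        self.alpha, self.beta = float(alpha), float(beta)
        self.activation = activation
        self.sigma_spec = sigma_spec
        rng = np.random.default_rng(seed)
        # A-network outputs d^2 numbers, row-major
        self.a_net = MLP([d, *a_hidden, d * d], activation="tanh", rng=rng,
                         out_scale=0.1)
        self.u_net = MLP([d, *u_hidden, m], activation=activation, rng=rng,
                         out_scale=0.1)
        self.gamma = ad.parameter(rng.normal(0.0, 0.1, size=(m, d)))
        if sigma_spec == "diag_constant":
            self.sigma_param = ad.parameter(np.full(d, float(sigma_init)))
        else:
            self.sigma_net = MLP([d, 32, d * self.p], activation="tanh", rng=rng,
                                 out_scale=0.1)
        self._tril = np.tril(np.ones((d, d)))
        self._triu = np.triu(np.ones((d, d)), k=1)
        self._eye = np.eye(d)
        # fixed affine input standardization for the networks (pure
        # reparameterization; keeps optimization well conditioned when the
        # reduced coordinates live on very different scales)
        self.input_loc = np.zeros(d) if input_loc is None else \
            np.asarray(input_loc, dtype=np.float64).copy()
        self.input_scale = np.ones(d) if input_scale is None else \
            np.asarray(input_scale, dtype=np.float64).copy()
        if np.any(self.input_scale <= 0):
            raise InvalidInputError("input_scale must be positive")

    # ---------------------------------------------------------- parameters
    @property
    def parameters(self) -> list[Tensor]:
        ps = self.a_net.parameters + self.u_net.parameters + [self.gamma]
        if self.sigma_spec == "diag_constant":
            ps.append(self.sigma_param)
        else:
            ps += self.sigma_net.parameters
        return ps

    # ------------------------------------------------------------- pieces
    def _check(self, z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=np.float64))
        if z.shape[-1] != self.d:
            raise InvalidInputError(f"expected dimension {self.d}, got {z.shape[-1]}")
        if not np.all(np.isfinite(z)):
            raise InvalidInputError("non-finite reduced state")
        return z

    def _norm(self, z: Tensor) -> Tensor:
        return (z - self.input_loc) * (1.0 / self.input_scale)

    def assemble_MW(self, z: Tensor) -> tuple[Tensor, Tensor]:
        """Batched (M(z), W(z)) as graph tensors of shape (B, d, d)."""
        B = z.shape[0]
        A = ad.reshape(self.a_net(self._norm(z)), (B, self.d, self.d))
        L1 = A * self._tril
        L2 = A * self._triu
        M = ad.matmul(L1, ad.swap_last(L1)) + self.alpha * self._eye
        W = L2 - ad.swap_last(L2)
        return M, W

    def potential_t(self, z: Tensor) -> Tensor:
        zn = self._norm(z)
        u = self.u_net(zn)
        g = u + ad.matmul(zn, _t2(self.gamma))
        return 0.5 * ad.tsum(ad.square(g), axis=-1) + self.beta * ad.tsum(ad.square(z), axis=-1)

    def potential_and_grad_t(self, z: Tensor) -> tuple[Tensor, Tensor]:
        """(V(z), ∇V(z)) with the gradient as an in-graph analytic expression."""
        zn = self._norm(z)
        u, cache = self.u_net.forward(zn, return_cache=True)
        g = u + ad.matmul(zn, _t2(self.gamma))
        V = 0.5 * ad.tsum(ad.square(g), axis=-1) + self.beta * ad.tsum(ad.square(z), axis=-1)
        gradV = (self.u_net.vjp(g, cache) + ad.matmul(g, self.gamma)) \
            * (1.0 / self.input_scale) + (2.0 * self.beta) * z
        return V, gradV

    def drift_t(self, z: Tensor) -> Tensor:
        _, gradV = self.potential_and_grad_t(z)
        M, W = self.assemble_MW(z)
        B = z.shape[0]
        g3 = ad.reshape(gradV, (B, self.d, 1))
        f = ad.matmul(M + W, g3)
        return ad.reshape(-f, (B, self.d))

    def sigma_t(self, z: Tensor) -> Tensor:
        """Diffusion matrix, shape (B, d, p)."""
        B = z.shape[0]
        if self.sigma_spec == "diag_constant":
            s = ad.sqrt(ad.square(self.sigma_param))  # |s|; z-independent
            diag = ad.reshape(s, (1, 1, self.d)) * self._eye[None]
            return _bcast(diag, B)
        return ad.reshape(self.sigma_net(z), (B, self.d, self.p))

    def sigma2_diag_t(self) -> Tensor:
        """Diagonal of σσᵀ for the constant-diagonal spec (length d)."""
        if self.sigma_spec != "diag_constant":
            raise InvalidInputError("sigma2_diag_t requires diag_constant sigma")
        return ad.square(self.sigma_param)

    # -------------------------------------------------- numpy convenience
    def potential(self, z) -> np.ndarray:
        """V(z) for a point (d,) or batch (B, d); nonnegative scalar(s)."""
        z = self._check(z)
        out = self.potential_t(ad.constant(z)).data
        return out if out.size > 1 else float(out[0])

    def potential_grad(self, z) -> np.ndarray:
        z2 = self._check(z)
        g = self.potential_and_grad_t(ad.constant(z2))[1].data
        return g if np.asarray(z).ndim > 1 else g[0]

    def drift(self, z) -> np.ndarray:
        """f(z) = -(M(z)+W(z)) ∇V(z)."""
        z2 = self._check(z)
        f = self.drift_t(ad.constant(z2)).data
        return f if np.asarray(z).ndim > 1 else f[0]

    def M_W(self, z) -> tuple[np.ndarray, np.ndarray]:
        z2 = self._check(z)
        M, W = self.assemble_MW(ad.constant(z2))
        if np.asarray(z).ndim > 1:
            return M.data, W.data
        return M.data[0], W.data[0]

    def sigma(self, z) -> np.ndarray:
        """σ(z), shape (d, p) for a point or (B, d, p) for a batch."""
        z2 = self._check(z)
        if self.sigma_spec == "diag_constant":
            s = np.abs(self.sigma_param.data)
            out = np.broadcast_to(np.diag(s), (z2.shape[0], self.d, self.d)).copy()
        else:
            out = self.sigma_t(ad.constant(z2)).data
        return out if np.asarray(z).ndim > 1 else out[0]

    def drift_jacobian(self, z) -> np.ndarray:
        """Jacobian ∂f/∂z at a single point via reverse-mode autodiff."""
        z0 = np.asarray(z, dtype=np.float64).reshape(1, self.d)
        J = np.empty((self.d, self.d))
        for i in range(self.d):
            zt = ad.parameter(z0)
            f = self.drift_t(zt)
            f[(0, i)].backward()
            J[i] = zt.grad[0]
        return J

    def potential_hessian(self, z) -> np.ndarray:
        """Hessian ∇²V at a single point (backprop of the analytic gradient)."""
        z0 = np.asarray(z, dtype=np.float64).reshape(1, self.d)
        H = np.empty((self.d, self.d))
        for i in range(self.d):
            zt = ad.parameter(z0)
            _, g = self.potential_and_grad_t(zt)
            g[(0, i)].backward()
            H[i] = zt.grad[0]
        return 0.5 * (H + H.T)

    # --------------------------------------------------------- persistence
    def save(self, path) -> None:
        """Single-file checkpoint: parameter arrays + JSON metadata block."""
        meta = dict(d=self.d, d_star=self.d_star, m=self.m, p=self.p,
                    alpha=self.alpha, beta=self.beta, activation=self.activation,
                    sigma_spec=self.sigma_spec,
                    a_hidden=self.a_net.sizes[1:-1], u_hidden=self.u_net.sizes[1:-1],
                    input_loc=self.input_loc.tolist(),
                    input_scale=self.input_scale.tolist())
        arrays = {f"param_{i}": p.data for i, p in enumerate(self.parameters)}
        np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "StructuredDriftModel":
        with np.load(path) as f:
            meta = json.loads(bytes(f["meta"]).decode())
            model = cls(d=meta["d"], d_star=meta["d_star"], m=meta["m"], p=meta["p"],
                        alpha=meta["alpha"], beta=meta["beta"],
                        a_hidden=tuple(meta["a_hidden"]), u_hidden=tuple(meta["u_hidden"]),
                        activation=meta["activation"], sigma_spec=meta["sigma_spec"],
                        input_loc=meta.get("input_loc"),
                        input_scale=meta.get("input_scale"))
            for i, p in enumerate(model.parameters):
                p.data = f[f"param_{i}"].astype(np.float64).copy()
        return model


def _bcast(diag: Tensor, B: int) -> Tensor:
    """Broadcast a (1, d, d) graph tensor to batch size B (gradient sums back)."""
    out = Tensor(np.broadcast_to(diag.data, (B,) + diag.shape[1:]).copy(),
                 parents=(diag,))

    def bw(g):
        if diag.requires_grad:
            diag.grad += g.sum(axis=0, keepdims=True)

    out._backward = bw if out.requires_grad else None
    return out
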