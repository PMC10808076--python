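"""Closure-coordinate construction: whitened PCA plus residual network corrections.

Closure coordinates are built from microscopic snapshots X ∈ R^D as

    Ẑ = P_d X + NN_e(X),          P_d = Λ_{1:k}^{-1/2} E_{1:k}^T,

where (Λ, E) is the eigendecomposition of the sample covariance of the
per-snapshot-centered training data and k is the number of closure
coordinates.  Reconstruction uses the adjoint whitening map plus another
residual network,

    X̃ = P_d^† Ẑ + NN_d(Ẑ),       P_d^† = E_{1:k} Λ_{1:k}^{1/2}.

With the networks zeroed this reduces exactly to whitened PCA.  The
designated macroscopic observables Z* are computed from *raw* snapshots;
the encoder always consumes centered ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .core import InvalidInputError
from .nets import MLP

EPS_LOG = 1e-12  # floor inside the regularizer logs


class ZeroGradientError(ValueError):
    pass


@dataclass
class MicroTrajectorySet:
    """Ensemble of microscopic trajectories on a uniform time grid.

    states has shape (M, Nt+1, D): M trajectories, Nt+1 snapshots, D
    coordinates per snapshot.
    """

    times: np.ndarray
    states: np.ndarray
    source: str = "external"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        self.states = np.asarray(self.states, dtype=np.float64)
        if self.states.ndim != 3:
            raise InvalidInputError("states must be (M, Nt+1, D)")
        if self.times.shape[0] != self.states.shape[1]:
            raise InvalidInputError("times length does not match snapshot count")
        dts = np.diff(self.times)
        if len(dts) and not np.allclose(dts, dts[0], rtol=1e-8, atol=1e-12):
            raise InvalidInputError("time grid is not uniform")

    @property
    def n_traj(self) -> int:
        return self.states.shape[0]

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def D(self) -> int:
        return self.states.shape[2]


def center_per_snapshot(data: MicroTrajectorySet) -> tuple[MicroTrajectorySet, np.ndarray]:
    """Remove the per-time-index ensemble mean; returns (centered set, means)."""
    if data.n_traj < 2:
        warnings.warn("single trajectory: centering removes the trajectory itself")
    means = data.states.mean(axis=0)  # (Nt+1, D)
    centered = MicroTrajectorySet(data.times, data.states - means[None], data.source)
    return centered, means


def fit_pca(flat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the sample covariance of column-stacked snapshots.

    ``flat`` has shape (D, n_samples).  Returns eigenvalues Λ in
    non-increasing order and the matching orthonormal eigenvector columns E.
    Sample (1/(n-1)) normalization is used.
    """
    D, n = flat.shape
    if n < 2:
        raise InvalidInputError("need at least 2 samples for PCA")
    cov = (flat @ flat.T) / (n - 1)
    lam, E = np.linalg.eigh(cov)
    order = np.argsort(lam)[::-1]
    lam, E = lam[order], E[:, order]
    lam = np.clip(lam, 0.0, None)
    if lam[0] <= 0:
        warnings.warn("zero-variance data: whitening unavailable")
    return lam, E


class EncoderDecoder:
    """PCA-ResNet encoder φ̂ and decoder ψ with stored centering statistics."""

    def __init__(self, eig_values: np.ndarray, eig_vectors: np.ndarray,
                 n_closure: int, snapshot_means: np.ndarray, times: np.ndarray,
                 nn_e: MLP | None = None, nn_d: MLP | None = None,
                 rho1: float = 1.0, use_decoder: bool = True,
                 hidden: tuple = (128, 128), seed: int = 0):
        self.eig_values = np.asarray(eig_values, dtype=np.float64)
        self.eig_vectors = np.asarray(eig_vectors, dtype=np.float64)
        self.n_closure = int(n_closure)
        self.snapshot_means = np.asarray(snapshot_means, dtype=np.float64)
        self.times = np.asarray(times, dtype=np.float64)
        self.rho1 = float(rho1)
        D = self.eig_vectors.shape[0]
        k = self.n_closure
        lam_k = self.eig_values[:k]
        if np.any(lam_k <= 0):
            warnings.warn("non-positive leading eigenvalues; whitening clamped")
            lam_k = np.clip(lam_k, 1e-300, None)
        self.P_d = (self.eig_vectors[:, :k] / np.sqrt(lam_k)).T       # (k, D)
        self.P_d_dagger = self.eig_vectors[:, :k] * np.sqrt(lam_k)    # (D, k)
        rng = np.random.default_rng(seed)
        self.nn_e = nn_e if nn_e is not None else MLP(
            [D, *hidden, k], activation="tanh", rng=rng, out_scale=0.01)
        if use_decoder:
            self.nn_d = nn_d if nn_d is not None else MLP(
                [k, *hidden, D], activation="tanh", rng=rng, out_scale=0.01)
        else:
            self.nn_d = None

    # ------------------------------------------------------------------
    @classmethod
    def fit(cls, data: MicroTrajectorySet, n_closure: int, rho1: float = 1.0,
            use_decoder: bool = True, hidden: tuple = (128, 128),
            seed: int = 0) -> tuple["EncoderDecoder", MicroTrajectorySet]:
        """Center the data, run PCA and initialize the residual networks.

        Returns the encoder and the centered trajectory set.
        """
        centered, means = center_per_snapshot(data)
        flat = centered.states.reshape(-1, data.D).T  # (D, Nt*M)
        lam, E = fit_pca(flat)
        enc = cls(lam, E, n_closure, means, data.times, rho1=rho1,
                  use_decoder=use_decoder, hidden=hidden, seed=seed)
        return enc, centered

    @property
    def parameters(self):
        ps = list(self.nn_e.parameters)
        if self.nn_d is not None:
            ps += self.nn_d.parameters
        return ps

    def mean_at(self, t: float) -> np.ndarray:
        """Centering mean for an arbitrary time: nearest grid snapshot's mean."""
        idx = int(np.argmin(np.abs(self.times - t)))
        return self.snapshot_means[idx]

    # ------------------------------------------------------------- mapping
    def encode_t(self, x_centered: Tensor) -> Tensor:
        """Ẑ = P_d X + NN_e(X) on a batch of centered snapshots (graph op)."""
        x_centered = ad.constant(x_centered)
        if x_centered.shape[-1] != self.P_d.shape[1]:
            raise InvalidInputError("encoder dimension mismatch")
        return ad.matmul(x_centered, Tensor(self.P_d.T)) + self.nn_e(x_centered)

    def decode_t(self, z_hat: Tensor) -> Tensor:
        """X̃ = P_d† Ẑ + NN_d(Ẑ) in centered coordinates (graph op)."""
        if self.nn_d is None:
            raise InvalidInputError("this encoder was configured without a decoder")
        z_hat = ad.constant(z_hat)
        if z_hat.shape[-1] != self.n_closure:
            raise InvalidInputError("decoder dimension mismatch")
        return ad.matmul(z_hat, Tensor(self.P_d_dagger.T)) + self.nn_d(z_hat)

    def encode(self, x_centered: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x_centered, dtype=np.float64))
        out = self.encode_t(Tensor(x)).data
        return out if np.asarray(x_centered).ndim > 1 else out[0]

    def decode(self, z_hat: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z_hat, dtype=np.float64))
        out = self.decode_t(Tensor(z)).data
        return out if np.asarray(z_hat).ndim > 1 else out[0]

    def uncenter(self, x_centered: np.ndarray, t: float) -> np.ndarray:
        """Add back the snapshot mean closest to time t."""
        return np.asarray(x_centered) + self.mean_at(t)

    # ---------------------------------------------------------------- loss
    def reconstruction_loss_t(self, x_centered: Tensor) -> Tensor:
        """loss_Rec = |X-X̃|² + ρ₁ ReLU(log|X-X̃|² - log E_pca), batch-averaged.

        E_pca is the plain PCA reconstruction error of the same batch; the
        regularizer activates only when the network does worse than PCA.
        """
        x_centered = ad.constant(x_centered)
        z_hat = self.encode_t(x_centered)
        x_rec = self.decode_t(z_hat)
        err = ad.tmean(ad.tsum(ad.square(x_centered - x_rec), axis=-1))
        xd = x_centered.data
        e_pca = float(np.mean(np.sum((xd - xd @ self.P_d.T @ self.P_d_dagger.T) ** 2,
                                     axis=-1)))
        reg = ad.relu(ad.log(err + EPS_LOG) - np.log(e_pca + EPS_LOG))
        return err + self.rho1 * reg

    def pca_reconstruction_error(self, x_centered: np.ndarray) -> float:
        xd = np.atleast_2d(x_centered)
        return float(np.mean(np.sum((xd - xd @ self.P_d.T @ self.P_d_dagger.T) ** 2,
                                    axis=-1)))


def assemble_reduced_state(x_raw: np.ndarray, macro_map, enc: EncoderDecoder,
                           t: float = 0.0) -> np.ndarray:
    """Concatenate Z = (Z*, Ẑ): observables from raw X, closure from centered X."""
    x_raw = np.asarray(x_raw, dtype=np.float64)
    z_star = np.atleast_1d(np.asarray(macro_map(x_raw), dtype=np.float64))
    z_hat = enc.encode(x_raw - enc.mean_at(t))
    return np.concatenate([z_star, np.atleast_1d(z_hat)])


def grad_perturb(z_fn, x: np.ndarray, k: int, c: float) -> tuple[np.ndarray, np.ndarray]:
    """Perturb a configuration along ± the gradient of reduced coordinate k.

    ``z_fn`` maps a (1, D) graph tensor to a (1, d) graph tensor of reduced
    coordinates.  Returns (X+, X-) with X± = X ± ε_k ∂Z_k/∂X and
    ε_k = c / ||∂Z_k/∂X||₂, the steepest-change conformations at scale c.
    """
    x = np.asarray(x, dtype=np.float64)
    xt = ad.parameter(x.reshape(1, -1))
    z = z_fn(xt)
    z[(0, int(k))].backward()
    g = xt.grad[0]
    norm = float(np.linalg.norm(g))
    if norm < 1e-14:
        raise ZeroGradientError(f"zero gradient of coordinate {k}: direction undefined")
    step = (c / norm) * g
    return x + step, x - step
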