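"""Maximum-likelihood training of the reduced SDE.

The Euler-Maruyama discretization of the reduced dynamics makes each
transition conditionally Gaussian, giving the per-tuple negative
log-likelihood (additive constants dropped)

    1/2 log det(σσᵀ) + (Δt/2) rᵀ (σσᵀ)⁻¹ r,    r = ΔZ/Δt - f(Z_i).

Training runs in two phases: phase 1 optimizes the drift/diffusion model
jointly with the encoder (total loss = loss_MLE + ρ·loss_Rec); phase 2
freezes the coordinate maps and fine-tunes the dynamics alone (ρ = 0).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Tensor
from .core import InvalidInputError, StructuredDriftModel
from .encoder import EncoderDecoder, MicroTrajectorySet


@dataclass
class TransitionDataset:
    """Consecutive-snapshot tuples (Z(t_i), Z(t_{i+1}), Δt), never crossing trajectories."""

    z0: np.ndarray          # (n, d)
    z1: np.ndarray          # (n, d)
    dt: float
    traj_id: np.ndarray     # (n,)
    x0: np.ndarray | None = None   # paired centered micro states for loss_Rec
    x1: np.ndarray | None = None

    def __len__(self):
        return self.z0.shape[0]


@dataclass
class TrainConfig:
    rho: float = 0.01            # weight of the reconstruction loss in phase 1
    rho1: float = 1.0            # weight of the worse-than-PCA regularizer
    phase1_steps: int = 5000
    phase2_steps: int = 5000
    learning_rate: float = 1e-3  # decayed x0.3 at 1/3 and 2/3 of each phase
    batch_size: int = 256
    seed: int = 0
    variance_floor: float = 1e-8
    val_frac: float = 0.15       # train/validation split, by trajectory
    use_decoder: bool = True

    def __post_init__(self):
        if self.rho < 0:
            raise InvalidInputError("rho must be nonnegative")
        if self.variance_floor <= 0:
            raise InvalidInputError("variance_floor must be positive")


def build_transitions(trajectories: np.ndarray, times: np.ndarray,
                      states: np.ndarray | None = None) -> TransitionDataset:
    """Flatten reduced trajectories (M, Nt+1, d) into ordered transition tuples."""
    trajs = np.asarray(trajectories, dtype=np.float64)
    times = np.asarray(times, dtype=np.float64)
    dts = np.diff(times)
    bad = np.where(~np.isclose(dts, dts[0], rtol=1e-8, atol=1e-12))[0]
    if bad.size:
        raise InvalidInputError(f"non-uniform time spacing at step indices {bad.tolist()}")
    M, n_snap, d = trajs.shape
    z0 = trajs[:, :-1].reshape(-1, d)
    z1 = trajs[:, 1:].reshape(-1, d)
    tid = np.repeat(np.arange(M), n_snap - 1)
    x0 = x1 = None
    if states is not None:
        D = states.shape[-1]
        x0 = states[:, :-1].reshape(-1, D)
        x1 = states[:, 1:].reshape(-1, D)
    return TransitionDataset(z0, z1, float(dts[0]), tid, x0, x1)


# ------------------------------------------------------------------- losses

def _nll_graph(z0: Tensor, z1: Tensor, dt: float, model: StructuredDriftModel,
               variance_floor: float) -> Tensor:
    """In-graph loss_MLE for a batch of transitions (diagonal constant σ)."""
    f = model.drift_t(z0)
    r = (z1 - z0) * (1.0 / dt) - f
    if model.sigma_spec == "diag_constant":
        s2 = model.sigma2_diag_t() + variance_floor        # (d,)
        quad = ad.tsum(ad.square(r) / ad.reshape(s2, (1, model.d)), axis=-1)
        logdet = ad.tsum(ad.log(s2))
        per = 0.5 * logdet + (dt / 2.0) * quad
        return ad.tmean(per)
    raise NotImplementedError(
        "in-graph MLE is implemented for the diagonal constant diffusion; "
        "use transition_nll for evaluation of general σ")


def transition_nll(batch: TransitionDataset, model: StructuredDriftModel,
                   variance_floor: float = 1e-8) -> float:
    """Mean Euler-Maruyama negative log-likelihood of a transition dataset."""
    z0, z1, dt = batch.z0, batch.z1, batch.dt
    if model.sigma_spec == "diag_constant":
        t = _nll_graph(Tensor(z0), Tensor(z1), dt, model, variance_floor)
        return float(t.data)
    f = model.drift(z0)
    r = (z1 - z0) / dt - f
    sig = model.sigma(z0)
    cov = np.einsum("bip,bjp->bij", sig, sig) + variance_floor * np.eye(model.d)
    sign, logdet = np.linalg.slogdet(cov)
    if np.any(sign <= 0):
        raise np.linalg.LinAlgError("sigma sigma^T not positive definite after floor")
    sol = np.linalg.solve(cov, r[..., None])[..., 0]
    quad = np.einsum("bi,bi->b", r, sol)
    return float(np.mean(0.5 * logdet + 0.5 * dt * quad))


def total_loss(batch: TransitionDataset, model: StructuredDriftModel,
               enc: EncoderDecoder | None, rho: float,
               variance_floor: float = 1e-8) -> float:
    """loss = loss_MLE + ρ·loss_Rec (Z taken as given in the batch)."""
    nll = transition_nll(batch, model, variance_floor)
    if rho == 0.0 or enc is None or enc.nn_d is None or batch.x0 is None:
        return nll
    rec = float(enc.reconstruction_loss_t(Tensor(batch.x0)).data)
    return nll + rho * rec


# -------------------------------------------------------------------- Adam

class Adam:
    """Standard Adam with an optional piecewise-constant learning-rate decay."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if g is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------- training

def _macro_series(data: MicroTrajectorySet, macro_map) -> np.ndarray:
    M, n_snap, _ = data.states.shape
    out = np.stack([
        np.stack([np.atleast_1d(macro_map(data.states[j, i]))
                  for i in range(n_snap)])
        for j in range(M)
    ])
    return out.astype(np.float64)


def train_two_phase(data: MicroTrajectorySet, macro_map, d: int, d_star: int,
                    config: TrainConfig, model_kwargs: dict | None = None,
                    enc_kwargs: dict | None = None):
    """Joint closure-coordinate + dynamics training, then dynamics fine-tuning.

    Phase 1 updates the drift/diffusion model together with the encoder
    (and decoder when present); phase 2 freezes the coordinate maps bitwise
    and continues on loss_MLE alone.  Fully seeded and deterministic.

    Returns ``(model, enc, history)`` where ``enc`` is None when d == d_star
    and ``history`` is a DataFrame with per-step losses.
    """
    rng = np.random.default_rng(config.seed)
    n_closure = d - d_star
    model_kwargs = dict(model_kwargs or {})

    z_star = _macro_series(data, macro_map) if macro_map is not None \
        else data.states[..., :d_star]
    if z_star.shape[-1] != d_star:
        raise InvalidInputError("macro_map output does not match d_star")

    # standardize network inputs: macroscopic components by their data
    # statistics, closure components are whitened by construction
    if "input_loc" not in model_kwargs:
        loc = np.zeros(d)
        scale = np.ones(d)
        loc[:d_star] = z_star.reshape(-1, d_star).mean(axis=0)
        scale[:d_star] = np.maximum(z_star.reshape(-1, d_star).std(axis=0), 1e-12)
        model_kwargs["input_loc"] = loc
        model_kwargs["input_scale"] = scale
    model = StructuredDriftModel(d=d, d_star=d_star, seed=config.seed,
                                 **model_kwargs)

    enc = None
    centered = None
    if n_closure > 0:
        enc, centered = EncoderDecoder.fit(
            data, n_closure, rho1=config.rho1, use_decoder=config.use_decoder,
            seed=config.seed, **(enc_kwargs or {}))

    # --- train/validation split by trajectory
    M = data.n_traj
    perm = rng.permutation(M)
    n_val = max(1, int(round(config.val_frac * M))) if M > 1 else 0
    val_ids, train_ids = perm[:n_val], perm[n_val:]

    dt = data.dt
    n_snap = data.states.shape[1]

    def _flat(ids):
        zs = z_star[ids]
        xs = centered.states[ids] if centered is not None else None
        return zs, xs

    zs_tr, xs_tr = _flat(train_ids)
    n_trans = len(train_ids) * (n_snap - 1)

    history: list[dict] = []
    backup = [p.data.copy() for p in model.parameters + (enc.parameters if enc else [])]

    def _snapshot():
        return [p.data.copy() for p in model.parameters + (enc.parameters if enc else [])]

    def _restore(snap):
        for p, a in zip(model.parameters + (enc.parameters if enc else []), snap):
            p.data = a

    # ------------------------------------------------------------- phase 1
    # With a trainable encoder, σ is held at the whitened unit scale during
    # phase 1: a trainable log det(σσᵀ) otherwise rewards collapsing the
    # closure coordinates (shrinking Ẑ drives σ, hence the NLL, to -∞
    # faster than ρ·loss_Rec can penalize).  σ is released in phase 2 once
    # the coordinate maps are frozen.
    freeze_sigma = enc is not None and model.sigma_spec == "diag_constant"
    if freeze_sigma:
        model.sigma_param.data[:] = 1.0
        params1 = [p for p in model.parameters if p is not model.sigma_param]
    else:
        params1 = list(model.parameters)
    params1 += enc.parameters if enc else []
    opt = Adam(params1, lr=config.learning_rate)
    idx_all = np.arange(n_trans)
    traj_of = idx_all // (n_snap - 1)
    step_of = idx_all % (n_snap - 1)
    aborted = False
    for step in range(config.phase1_steps):
        if step in (config.phase1_steps // 3, 2 * config.phase1_steps // 3):
            opt.lr *= 0.3
        sel = rng.choice(n_trans, size=min(config.batch_size, n_trans), replace=False)
        ti, si = traj_of[sel], step_of[sel]
        zst0 = Tensor(zs_tr[ti, si])
        zst1 = Tensor(zs_tr[ti, si + 1])
        if enc is not None:
            x0 = Tensor(xs_tr[ti, si])
            x1 = Tensor(xs_tr[ti, si + 1])
            z0 = ad.concat([zst0, enc.encode_t(x0)], axis=-1)
            z1 = ad.concat([zst1, enc.encode_t(x1)], axis=-1)
        else:
            z0, z1 = zst0, zst1
        nll = _nll_graph(z0, z1, dt, model, config.variance_floor)
        rec_val = 0.0
        if enc is not None and enc.nn_d is not None and config.rho > 0:
            rec = enc.reconstruction_loss_t(x0)
            loss = nll + config.rho * rec
            rec_val = float(rec.data)
        else:
            loss = nll
        if not np.isfinite(loss.data):
            _restore(backup)
            aborted = True
            break
        loss.backward()
        opt.step()
        if step % 100 == 0:
            backup = _snapshot()
        history.append(dict(step=step, phase=1, loss_mle=float(nll.data),
                            loss_rec=rec_val, total=float(loss.data)))

    # ------------------------------------------------------------- phase 2
    # encoder frozen: cache reduced coordinates once, then train dynamics only
    if enc is not None:
        z_hat_tr = np.stack([enc.encode(xs_tr[j]) for j in range(len(train_ids))])
        z_all = np.concatenate([zs_tr, z_hat_tr], axis=-1)
    else:
        z_all = zs_tr
    z0_cache = z_all[:, :-1].reshape(-1, d)
    z1_cache = z_all[:, 1:].reshape(-1, d)
    opt2 = Adam(model.parameters, lr=config.learning_rate)
    for step in range(0 if aborted else config.phase2_steps):
        if step in (config.phase2_steps // 3, 2 * config.phase2_steps // 3):
            opt2.lr *= 0.3
        sel = rng.choice(len(z0_cache), size=min(config.batch_size, len(z0_cache)),
                         replace=False)
        nll = _nll_graph(Tensor(z0_cache[sel]), Tensor(z1_cache[sel]), dt,
                         model, config.variance_floor)
        if not np.isfinite(nll.data):
            _restore(backup)
            break
        nll.backward()
        opt2.step()
        if step % 100 == 0:
            backup = _snapshot()
        history.append(dict(step=config.phase1_steps + step, phase=2,
                            loss_mle=float(nll.data), loss_rec=0.0,
                            total=float(nll.data)))

    hist = pd.DataFrame(history)
    # validation NLL on held-out trajectories for the record
    if len(val_ids):
        zs_v = z_star[val_ids]
        if enc is not None:
            zh_v = np.stack([enc.encode(centered.states[j]) for j in val_ids])
            zv = np.concatenate([zs_v, zh_v], axis=-1)
        else:
            zv = zs_v
        batch = build_transitions(zv, data.times)
        hist.attrs["val_nll"] = transition_nll(batch, model, config.variance_floor)
        hist.attrs["val_ids"] = val_ids.tolist()
        hist.attrs["train_ids"] = train_ids.tolist()
    return model, enc, hist
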