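"""Analysis of the learned generalized free-energy landscape.

Minima of V are (meta)stable states and index-1 saddles are transition
states of the reduced dynamics; because the dynamics is not a gradient
flow, stability is classified from the Jacobian of the drift, not from the
Hessian of V.  Critical points are located by minimizing |∇V|² with BFGS
(plain descent on V cannot converge to saddles).  The planar winding index
is the elementary index-theory tool that rules out two-dimensional reduced
models with the stable-state arrangement imposed by the physics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar


class OnCurveZeroError(ValueError):
    pass


@dataclass
class CriticalPoint:
    location: np.ndarray
    grad_norm: float
    jacobian: np.ndarray
    eigenvalues: np.ndarray
    kind: str                          # stable_node | saddle_index_1 | other
    unstable_direction: np.ndarray | None = None
    stable_basis: list | None = None


@dataclass
class QuadraticExpansion:
    """Nested-square (ordered LDLᵀ) form of the local quadratic of V.

    δV ≈ Σ_i c_i (δZ_i + Σ_{j>i} u_ij δZ_j)², the pattern
    a₁(δZ₁ - a₄δZ₂)² + a₂δZ₂² + a₃δZ₃² in three dimensions with a₄ = -u₁₂.
    """

    base_point: np.ndarray
    hessian: np.ndarray
    coeffs: list | None     # list of (c_i, u_i) with u_i the later-coordinate mixing
    available: bool = True

    def quad_form(self, delta: np.ndarray) -> float:
        """Evaluate the completed-square form; equals ½ δᵀHδ when available."""
        if not self.available:
            raise ValueError("nested-square coefficients unavailable (zero pivot)")
        delta = np.asarray(delta, dtype=np.float64)
        total, d = 0.0, delta.shape[0]
        for i, (c, u) in enumerate(self.coeffs):
            term = delta[i] + float(u @ delta[i + 1:]) if i + 1 < d else delta[i]
            total += c * term ** 2
        return float(total)

    @property
    def leading(self) -> dict | None:
        """(a₁..a₄) convenience view for d = 3."""
        if not self.available or len(self.coeffs) != 3:
            return None
        (c1, u1), (c2, _), (c3, _) = self.coeffs
        return dict(a1=c1, a2=c2, a3=c3, a4=-float(u1[0]))


# ------------------------------------------------------------ critical points

def find_critical_points(model, init_points: np.ndarray | None = None,
                         tol: float = 1e-5, dedup_radius: float | None = None,
                         bounds: np.ndarray | None = None, n_init: int = 200,
                         seed: int = 0) -> list[np.ndarray]:
    """Locate zeros of ∇V by BFGS on the squared gradient norm |∇V(z)|².

    ``init_points`` defaults to ``n_init`` uniform samples from ``bounds``
    (an axis-aligned bounding box, shape (2, d)); converged points within
    ``dedup_radius`` of each other are merged (first found wins).
    """
    if init_points is None:
        if bounds is None:
            raise ValueError("provide init_points or bounds")
        rng = np.random.default_rng(seed)
        lo, hi = np.asarray(bounds, dtype=float)
        init_points = rng.uniform(lo, hi, size=(n_init, len(lo)))
    init_points = np.atleast_2d(init_points)
    if dedup_radius is None:
        span = init_points.max(axis=0) - init_points.min(axis=0)
        dedup_radius = 1e-3 * max(float(np.linalg.norm(span)), 1.0)

    def obj(z):
        g = model.potential_grad(z)
        return float(g @ g)

    found: list[np.ndarray] = []
    for z0 in init_points:
        res = minimize(obj, z0, method="BFGS",
                       options=dict(gtol=1e-12, maxiter=500))
        g = model.potential_grad(res.x)
        if np.linalg.norm(g) >= tol:
            continue
        if any(np.linalg.norm(res.x - p) < dedup_radius for p in found):
            continue
        found.append(res.x.copy())
    return found


def classify_critical_point(model, z_star: np.ndarray,
                            hyperbolic_tol: float = 1e-8) -> CriticalPoint:
    """Classify a critical point from the eigenvalues of J = ∂f/∂z.

    stable_node: all real parts negative.  saddle_index_1: exactly one
    positive real part; its eigenvector is the unstable-manifold direction
    and the real/imaginary parts of the contracting eigenvectors span the
    stable manifold.  Near-imaginary eigenvalues give kind "other".
    """
    z_star = np.asarray(z_star, dtype=np.float64)
    J = model.drift_jacobian(z_star)
    eigvals, eigvecs = np.linalg.eig(J)
    grad_norm = float(np.linalg.norm(model.potential_grad(z_star)))
    re = eigvals.real
    if np.any(np.abs(re) < hyperbolic_tol):
        return CriticalPoint(z_star, grad_norm, J, eigvals, "other")
    n_pos = int(np.sum(re > 0))
    if n_pos == 0:
        return CriticalPoint(z_star, grad_norm, J, eigvals, "stable_node")
    if n_pos == 1:
        i_pos = int(np.argmax(re))
        v = eigvecs[:, i_pos].real
        nv = np.linalg.norm(v)
        if nv < 1e-12:  # purely imaginary eigenvector component
            v = eigvecs[:, i_pos].imag
            nv = np.linalg.norm(v)
        unstable = v / nv
        basis = []
        for i in np.where(re < 0)[0]:
            vr, vi = eigvecs[:, i].real, eigvecs[:, i].imag
            if np.linalg.norm(vr) > 1e-12:
                basis.append(vr / np.linalg.norm(vr))
            if np.linalg.norm(vi) > 1e-12:
                basis.append(vi / np.linalg.norm(vi))
        return CriticalPoint(z_star, grad_norm, J, eigvals, "saddle_index_1",
                             unstable, basis)
    return CriticalPoint(z_star, grad_norm, J, eigvals, "other")


# ---------------------------------------------------------------- projection

def project_potential(model, axes: tuple[int, int], grid1: np.ndarray,
                      grid2: np.ndarray, comp_bounds: np.ndarray,
                      n_starts: int = 5, seed: int = 0):
    """2-D landscape projection by minimization over the other coordinates.

    V_proj(z_a, z_b) = min_{rest} V(z); each cell runs a multi-start
    bounded minimization over the complementary coordinates.  Returns
    (surface, ok_mask); cells whose minimization failed are flagged False,
    never silently filled.
    """
    d = model.d
    comp = [i for i in range(d) if i not in axes]
    lo, hi = np.asarray(comp_bounds, dtype=float)
    rng = np.random.default_rng(seed)
    surface = np.full((len(grid1), len(grid2)), np.nan)
    ok = np.zeros(surface.shape, dtype=bool)
    starts = rng.uniform(lo, hi, size=(n_starts, len(comp)))

    def V_at(za, zb, rest):
        z = np.empty(d)
        z[axes[0]], z[axes[1]] = za, zb
        z[comp] = rest
        return float(np.atleast_1d(model.potential(z))[0])

    for i, za in enumerate(grid1):
        for j, zb in enumerate(grid2):
            best = np.inf
            success = False
            for s in starts:
                res = minimize(lambda r: V_at(za, zb, r), s, method="L-BFGS-B",
                               bounds=list(zip(lo, hi)))
                if res.success or res.fun < best:
                    best = min(best, float(res.fun))
                    success = success or bool(res.success)
            if success:
                surface[i, j] = best
                ok[i, j] = True
    return surface, ok


def quadratic_expansion(model, base_point: np.ndarray,
                        grad_tol: float = 1e-3,
                        pivot_tol: float = 1e-12) -> QuadraticExpansion:
    """Local equation of state: nested-square coefficients of ½ δᵀ(∇²V)δ.

    The base point must be (approximately) critical so that the expansion
    has no linear term.  Pivot order is the coordinate order (Z₁, Z₂, Z₃),
    matching the completed-square patterns reported around the stable and
    saddle states.  A vanishing pivot leaves only the raw Hessian.
    """
    base_point = np.asarray(base_point, dtype=np.float64)
    g = model.potential_grad(base_point)
    if np.linalg.norm(g) > grad_tol:
        raise ValueError(f"base point is not critical: |gradV| = {np.linalg.norm(g):.3g}")
    H = model.potential_hessian(base_point)
    Q = 0.25 * (H + H.T)  # ½ of the symmetrized Hessian
    d = Q.shape[0]
    coeffs = []
    R = Q.copy()
    for i in range(d):
        c = R[0, 0]
        if abs(c) < pivot_tol:
            return QuadraticExpansion(base_point, H, None, available=False)
        u = R[0, 1:] / c
        coeffs.append((float(c), u.copy()))
        R = R[1:, 1:] - c * np.outer(u, u)
    return QuadraticExpansion(base_point, H, coeffs, available=True)


# -------------------------------------------------------------- winding index

def winding_index(field, curve: np.ndarray, tol: float = 1e-12) -> int:
    """Integer winding number of a planar vector field along a closed curve.

    Accumulates unwrapped angle increments of (f₁, f₂) over the ordered
    polyline vertices and divides by 2π; equals the sum of the indices of
    the enclosed critical points (+1 for a node or focus, -1 for a saddle).
    """
    curve = np.atleast_2d(np.asarray(curve, dtype=np.float64))
    if not np.allclose(curve[0], curve[-1]):
        curve = np.vstack([curve, curve[0]])
    f = np.asarray([np.asarray(field(p), dtype=float) for p in curve])
    norms = np.hypot(f[:, 0], f[:, 1])
    if np.any(norms < tol):
        raise OnCurveZeroError("vector field vanishes on the curve")
    angles = np.unwrap(np.arctan2(f[:, 1], f[:, 0]))
    return int(round((angles[-1] - angles[0]) / (2.0 * np.pi)))
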