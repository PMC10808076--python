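# Methods

This note documents the model, the numerical choices, and what the
synthetic generators do and do not emulate.

## Reduced model: generalized stochastic Onsager principle

The package learns a closed stochastic model for a small set of
thermodynamic coordinates Z = (Z*, Ẑ) ∈ R^d extracted from microscopic
trajectories X(t) ∈ R^D.  Z* are user-designated macroscopic observables
(polymer: the chain extension along the elongational axis; epidemics: the
spatial averages of infective and susceptible densities); Ẑ are learned
closure coordinates.  The dynamics is constrained to the dissipative form

    dZ = -(M(Z) + W(Z)) ∇V(Z) dt + σ(Z) dB(t),

with M symmetric positive definite (friction/dissipation; Onsager
reciprocity), W antisymmetric (conservative coupling, does no work:
∇VᵀW∇V = 0 identically), V a lower-bounded generalized potential and σ the
thermal noise amplitude.  In the noise-free limit V is a Lyapunov function
(dV/dt = -∇VᵀM∇V ≤ -α|∇V|²), so learned models are long-time stable by
construction; with noise, E[V] obeys a dissipation law with a heating term
½Tr[σσᵀ∇²V], which `rollout.dissipation_audit` and the test suite verify.

### Parameterization

* A network A: R^d → R^{d×d} (two tanh layers of width 20 by default)
  supplies both matrices: its lower triangle L₁ (including the diagonal)
  gives M = L₁L₁ᵀ + αI, the strict upper triangle L₂ gives W = L₂ - L₂ᵀ.
  The diagonal is used only by L₁, which removes any double-use ambiguity;
  a diagonal in L₂ would cancel in L₂ - L₂ᵀ anyway.
* V(Z) = ½ Σᵢ (Uᵢ(Z) + Σⱼ γᵢⱼZⱼ)² + β|Z|², a sum of m squares (m = 50)
  plus a confining quadratic, so V ≥ β|Z|² everywhere.  U is a single
  hidden layer of 128 units with the rectified-quadratic activation
  ReQUr(x) = max(x,0)² - max(x-½,0)², quadratic near zero and
  asymptotically linear, keeping ∇V Lipschitz.  The exact form of this
  activation in the literature varies; ours is one concrete choice and the
  activation is pluggable.
* σ is a z-independent trainable diagonal by default (reported through an
  absolute value); a general network d×p diffusion is available but the
  constant diagonal is what the training pipeline optimizes.
* ∇V is evaluated analytically as an in-graph vector-Jacobian product
  through U, so the drift is exact (no finite differences) and remains
  differentiable with respect to all parameters.  A minimal reverse-mode
  autodiff engine on numpy arrays (`gsop.autodiff`) backs all of this;
  gradients are verified against central differences at 1e-5 relative in
  the test suite.
* Defaults: α = 0.1 (polymer configuration) or 0.001 (epidemics), β = 0.01.
  α sets a floor on the dissipation spectrum; β fixes the coercivity of V.
* Network inputs are standardized internally, z ↦ (z - loc)/scale, with
  fixed constants taken from the training data (macroscopic components by
  their mean/std; closure components are whitened by construction).  This
  is a pure reparameterization — γ on standardized coordinates equals
  γ/scale on raw ones — but it matters in practice: with raw inputs the
  mixed coordinate scales (extension O(25) against closure O(1)) leave the
  structured optimization unable to fit the sparsely sampled unfolding
  transient, while an unstructured regression has no difficulty.  All
  structural invariants are unaffected.

There is a known gauge freedom: (M, V) → (cM, V/c) leaves the law of the
SDE invariant, so only the drift -(M+W)∇V and σσᵀ are identified by
maximum likelihood.  Recovery metrics in `gsop.benchmarks` compare those,
and compare potentials only up to affine gauge.

## Closure coordinates

Snapshots are centered per time index (the ensemble mean of the training
set at each recording time is subtracted), then PCA is run on the pooled
centered snapshots with sample (1/(n-1)) covariance normalization.  The
encoder is whitened PCA plus a residual correction,

    Ẑ = P_d X + NN_e(X),     P_d = Λ^{-1/2}_{1:k} E^T_{1:k},

and the decoder is the adjoint map plus another residual network.  With
the networks zeroed this is exactly whitened PCA, which anchors the
coordinates: the residual networks only have to learn corrections.  The
number of closure coordinates is k = d - d_star (polymer: d = 3, d_star =
1; epidemics: d = 3, d_star = 2, and no decoder is used since field
reconstruction is not needed).  The reconstruction loss is the squared
error plus ρ₁·ReLU(log err - log E_pca), penalizing only reconstructions
worse than plain PCA; logs are floored at 1e-12 so perfect reconstruction
stays finite.  For times off the training grid (control runs) the nearest
grid snapshot's mean is used for centering — an explicit approximation.

Coordinates are interpreted by steepest-change perturbations X ± ε ∂Z_k/∂X
with ε = c/||∂Z_k/∂X||₂ (`encoder.grad_perturb`), the same device used to
identify the closure coordinates with projected end-to-end distance and
foldedness in the polymer problem.

## Training

Transitions (Z(tᵢ), Z(tᵢ₊₁), Δt) never straddle trajectory boundaries.
The Euler-Maruyama discretization makes each transition conditionally
Gaussian; the loss is the mean negative log-likelihood (additive constants
dropped) plus ρ times the reconstruction loss (ρ = 0.01).  Training is
two-phase with Adam: phase 1 updates encoder, decoder and dynamics
jointly; phase 2 freezes the coordinate maps bitwise and fine-tunes the
dynamics alone.  Defaults: learning rate 1e-3 decayed ×0.3 at ⅓ and ⅔ of
each phase, batch 256, 5 000 + 5 000 steps, 85/15 train/validation split
by trajectory, all seeded and exactly reproducible.

One schedule detail is our own: during phase 1 the diagonal σ is frozen at
the whitened unit scale and is only trained in phase 2.  With σ trainable
jointly, the log det(σσᵀ) term rewards collapsing the closure coordinates
(the residual encoder learns to cancel P_dX, σ → 0, and the likelihood
diverges) faster than ρ·loss_Rec penalizes at the data scales we train
at.  Freezing σ bounds that payoff at ~½|r|² and the reconstruction term
then dominates; once the coordinates are frozen, σ has a well-defined
maximum-likelihood value (in 1-D with f ≡ 0 it is mean((ΔZ)²/Δt), which
the tests verify against the closed form).  A variance floor of 1e-8 on
the diagonal of σσᵀ keeps the first steps finite when σ is initialized
small.

## Microscopic generator 1: bead-rod polymer in elongational flow

Touching-bead chain, N beads joined by N-1 rigid rods of length b,
overdamped motion with excluded-volume, Brownian, tension and drag
forces; planar elongational flow u = ε̇(x x̂ - y ŷ).  Nondimensionalized
with b = ζ = k_BT = 1 so the rod diffusion time τ_d = b²ζ/k_BT = 1.
Time step 5×10⁻⁴ τ_d.  The predictor is an unconstrained Euler-Maruyama
step; the corrector projects with rod tensions solving the bond-length
equations by Newton iteration on a tridiagonal system, to |len - b| ≤
1e-10 b (bond drift over a full trajectory stays below 1e-8 b, enforced).
Non-convergent steps (rare) are retried with halved sub-steps.  The
excluded-volume force has constant magnitude μ = 10 inside the bead
diameter; the physical magnitude commonly used for touching-bead DNA
models (35 pN at b = 10 nm, i.e. μb/k_BT ≈ 85 at room temperature) is
stiffer than necessary at our time step, and μ = 10 keeps chain crossings
rare while remaining configurable.

The chain is simulated in the center-of-mass frame (the COM is reset at
each recording interval).  The flow is linear, so internal dynamics are
independent of the COM; physically this is the stagnation-point trap that
holds the molecule in the corresponding experiments, and numerically it
avoids the exponential advection of the COM (x ~ e^{ε̇t}) that would
otherwise destroy floating-point precision on long runs.  Observables are
COM-centered by definition.

Desk-scale profile: N = 32, equilibration 200 τ_d (flow off), production
500 τ_d (flow on), recording every 1 τ_d.  The strain rate is not a
universal constant; the default ε̇ = 0.1/τ_d was fixed once by the
calibration rule "smallest doubling for which ≥90% of an 8-trajectory
pilot ensemble unfolds within the production window"
(`polymer.calibrate_strain_rate`).  The full-scale profile (N = 300,
10⁴ τ_d horizons, recording every 10 τ_d, 1 001 snapshots) is available
via `PolymerParams.full_scale_profile()` but is not exercised by the tests.
Unfolding is defined as the extension first reaching 0.8 of the contour
length (configurable); first-passage times are linearly interpolated
between recordings.

What the generator does not emulate: hydrodynamic interactions (drag is
free-draining by construction), bending stiffness, and any non-linear
flow profile.  Passing tests therefore validate the learning machinery on
a faithful free-draining bead-rod fluid-mechanics model, not on a
quantitative model of a specific DNA experiment.

### Saddle-escape control

`polymer.run_control` implements the protocol: flow off; at each
recording time compute the reduced deviation δZ from the saddle; once the
selected components of δZ align (as a line, sign-free) with the target
manifold direction within a threshold angle — or after a 100 τ_d cap —
re-enable the flow and run to unfolding.  Speed-up targets the unstable
manifold direction, slow-down the stable one.  The protocol logic is
exercised by deterministic unit tests; the ensemble-level effect on
unfolding times is a research-scale experiment and is not asserted by the
suite.

## Microscopic generator 2: stochastic spatial SIR

n×n lattice (n = 16) of susceptible/infective densities with transmission
β = 0.3, recovery γ = 0.13, diffusion δ = 0.5 via the 5-point Laplacian
(grid steps δx = δy = 2/3, domain origin -5), additive per-site noise
σ = 0.03, explicit Euler-Maruyama with dt = 0.03 (stability guard
dt·δ/δx² < ½ enforced at construction).  Initial conditions: a fixed
two-cluster susceptible field and a unit-square-random infective cluster,
both Gaussian with peak 5.  Boundaries are zero-flux (edge-replicated),
which conserves mass exactly under pure diffusion; periodic boundaries
are available.  Additive noise can push densities negative; they are
clipped to zero after each step — a small bias, negligible at σ = 0.03
for these field scales.  The noise is independent per site and per field;
a spatially common noise is the other defensible reading of a single
scalar Wiener term per field equation, and the choice is recorded here.
Observables: Z₁ = δxδy ΣI, Z₂ = δxδy ΣS and the overlap δxδy ΣIS.

## Validation benchmarks

* Linear (Ornstein-Uhlenbeck) systems of any dimension with known
  (M, W, H, σ),
  generated at 10 fine sub-steps per observation interval so that
  discretization bias stays below the recovery tolerances.  The stationary
  covariance is cross-checked against the Lyapunov equation.  End-to-end:
  training on 200 trajectories × 200 steps recovers the drift within 10%
  relative L2 on the central 80% of the data and σ² within 15% (3-seed
  median).
* An underdamped Langevin particle in the double well U(x) = (x²-1)²,
  which embeds exactly into the two-coordinate GSOP form (the kinetic +
  potential energy is the generalized potential).  The reduction fixture
  trains a 1-D model on the position coordinate alone and compares
  well-crossing-time distributions with the microscopic ones by a
  two-sample KS test.  The fixture is deliberately placed in the strongly
  overdamped regime (γ₁ = 50, observation spacing 1.0 ≫ velocity
  correlation time 1/γ₁): there the position is approximately Markovian
  and the reduced model is theoretically adequate.  In moderately damped
  regimes even a 1-D model built from the exact empirical conditional
  moments fails the same comparison — the discrepancy is reduction error,
  not training error — so the regime choice is a validity condition of
  the check, not a tuning knob.

## Landscape analysis

Critical points solve ∇V = 0, located by BFGS on |∇V(z)|² (plain descent
on V cannot reach saddles) from 200 seeded starts in the bounding box of
the training coordinates, de-duplicated within 1e-3 of the box diagonal.
Classification uses the Jacobian of the drift (the dynamics is not a
gradient flow): all eigenvalue real parts negative → stable node; exactly
one positive → index-1 saddle, whose eigenvector is the unstable-manifold
direction and whose contracting eigenvectors' real/imaginary parts span
the stable manifold; near-imaginary eigenvalues are reported as
non-hyperbolic.  2-D projections take the minimum of V over the
complementary coordinate per grid cell (bounded multi-start 1-D
minimization; failed cells are flagged, not filled).  Local equations of
state come from the Hessian of V (analytic, via backprop through the
analytic gradient): an ordered completed-square (LDLᵀ-style)
decomposition of ½∇²V with pivot order (Z₁, Z₂, Z₃) reproduces the
nested-square pattern a₁(δZ₁ - a₄δZ₂)² + a₂δZ₂² + a₃δZ₃², with the exact
reconstruction identity checked to 1e-10.  The planar winding index is
computed by unwrapped angle accumulation along the polyline (integer-exact
and refinement-stable, equivalent to the contour integral in the
refinement limit): +1 for nodes/foci, -1 for saddles, additive over
enclosed critical points — the index-theoretic argument for why two
reduced coordinates cannot support the required pair of symmetric stable
states plus saddles.

## Problem sizes used by the test suite

The suite runs the full workflow at desk scale: 60 trajectories of an
N = 32 chain (700 τ_d each at dt 5×10⁻⁴), d = 3 training at the default
schedule, 450-path rollouts, and 10⁴-state invariant sweeps.  These sizes
were chosen as the smallest at which the pipeline's statistical targets
(ground-truth recovery, held-out rollout agreement, landscape structure)
are meaningful; the full-scale profiles remain available through
configuration.

## Known limitations

* The GSOP ansatz cannot represent non-dissipative (e.g. chaotic)
  macroscopic dynamics, and the stability theory assumes weak noise.
* The constant-diagonal σ ignores state dependence of the fluctuations;
  the general network σ is implemented for evaluation but not exercised
  by the training pipeline.
* Per-snapshot centering ties the closure coordinates to the training
  ensemble's time grid; off-grid times reuse the nearest snapshot mean.
* The desk-scale polymer data sample the folded/transition region only
  through fast unfolding events, so saddle detection at this scale is
  qualitative; the stable stretched states are robust.
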