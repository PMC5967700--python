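# Methods

## Model and control problem

The network state is z = [x, y]ᵀ ∈ ℝ²ᴺ with one Duffing oscillator per
region:

    ẋᵢ = yᵢ
    ẏᵢ = −αᵢ xᵢ − γ xᵢ³ + β Σⱼ Wⱼᵢ xⱼ

W is a symmetric matrix of connection densities (dimensionless, [0, 1],
zero diagonal), so the coupling term is β(Wᵀx)ᵢ. For γ = 0 an uncoupled
node oscillates at f = √α/2π; for γ > 0 the cubic term is hardening, so the
frequency grows with amplitude. The uncontrolled network conserves

    H = Σᵢ (yᵢ²/2 + αᵢ xᵢ²/2 + γ xᵢ⁴/4) − (β/2) Σᵢⱼ Wⱼᵢ xᵢ xⱼ,

which the tests use as an integration-fidelity probe.

Two operating points encode the disease contrast:

| state        | α (s⁻²)              | x₀ (mV) | band                 |
|--------------|----------------------|---------|----------------------|
| pathological | (2π·6.4)² ≈ 1617.0   | 1.0     | theta, high amplitude|
| healthy      | (2π·8.0)² ≈ 2526.6   | 0.1     | alpha, low amplitude |

The α defaults are the closed-form γ = 0 values; `calibrate_alpha`
(bisection on [0.25, 4]·(2πf)² against the simulated spectral peak) refines
them when a γ > 0 operating point at a given amplitude is wanted. Initial
amplitudes are package choices — the qualitative contrast (high-amplitude
slow vs low-amplitude fast) is what matters. β defaults to 50 s⁻², small
against α so each node keeps its band identity under coupling; γ is swept
over {0, 100, 200, 300} s⁻²mV⁻², with 200 as the typical nonlinear case.

The control task tracks the healthy trajectory: e = z_p − z_h obeys
ė = A(e)e + Bu + d(t) with the exact state-dependent factorization

    A₂₁ = −diag(α_p) − γ diag(x_p² + x_p x_h + x_h²) + βWᵀ,
    d   = −(α_p − α_h) x_h(t)   (y-block),

and B a unit vector in the input region's y-entry. At every gain-update
instant the LQR problem for (A(e), B, Q = qI, R = r) is solved and
u = −Ke held until the next update.

## Numerical choices

**Integrator.** Local Linearization: z_{k+1} = z_k + Φ₁(J)·f(z_k) with
Φ₁ = ∫₀^dt e^{Js} ds, J the local Jacobian. Because J = [[0, I], [S, 0]]
with S symmetric, Φ₁ is evaluated exactly from the N×N eigendecomposition
of S with per-mode sine/cosine (or hyperbolic) formulas; a generic
(2N+1)-augmented matrix-exponential route is retained for asymmetric
couplings and as a cross-check (the two agree to rounding). The scheme is
exact for linear systems and globally second order on nonlinear ones;
measured phase error for the γ = 200 operating point is ≈ 0.25·(dt/1 ms)²
state units over 5 s, so dt = 1 ms is used for control experiments (the
feedback loop tolerates integration phase error) and dt = 20 µs where
trajectories are compared against a high-order adaptive Runge–Kutta oracle
at the 1e-4 level.

**Riccati solver.** Primary route: a structure-exploiting spectral
factorization.  In the eigenbasis of the SDC block S (symmetric, N×N) the
optimal closed-loop poles satisfy the scalar secular equation
F(w) = 1 + (q/r)Σᵢ uᵢ²(1−w)/(w−λᵢ)² = 0 with w = s², whose roots are the
eigenvalues of the N×N quadratic matrix polynomial (wI−Λ)² + (q/r)(1−w)uuᵀ,
solved through its 2N×2N companion linearization; the Hamiltonian
eigenvectors are closed-form resolvent expressions and P follows from the
stable-subspace basis.  This is ~5× faster than the dense 4N×4N
Hamiltonian eigendecomposition (Laub's method, kept as the first fallback)
and ~15× faster than scipy's generalized-pencil `solve_continuous_are`
(second fallback, with a few Newton–Kleinman Lyapunov polishing steps when
its raw residual misses tolerance); against scipy it agrees to ≤1e-6
relative on P across random SDC systems. A gain is
*accepted* only if P is finite, symmetric, positive definite, the relative
residual ‖AᵀP + PA − PBR⁻¹BᵀP + Q‖_F / (1 + ‖P‖_F) is below 1e-8, and the
closed loop A − BK is strictly stable. The residual test is relative
because float64 CARE residuals scale with ‖A‖·‖P‖·eps — with ‖P‖ ≈ 1e5–1e6
at this model's stiffness an absolute threshold near machine epsilon is
unattainable; measured relative residuals separate cleanly (≈ 1e-12
controllable vs ≥ 1e-7 uncontrollable). Any rejection marks the task
uncontrollable (cost +∞, inverse cost 0); integration overflow is flagged
separately as `failed`.

**Kalman rank.** The controllability-matrix rank is computed as the Krylov
space dimension via Arnoldi iteration with full reorthogonalization; raw
normalized powers of A are Vandermonde-conditioned and misreport rank even
at n = 16. The test is refused for n > 60 and serves as a small-system
oracle only — the production verdict is always CARE acceptance, and the two
agree on every node of the engineered test networks at both moderate and
model stiffness.

**Gain update interval.** Default 10 ms (10 integration steps). The held
gain lags the oscillating SDC diagonal, so *absolute* costs depend on the
interval (≈ −16% from 1 ms to 10 ms at γ = 100); the across-node cost
*ordering*, which the region ranking uses, is stable (Spearman ρ ≈ 0.9
between 1 and 10 ms). All experiments in one comparison therefore use one
interval.

**Tracking metric and the success flag.** `tracking_error` is the relative
RMS of the x-error over the final 5 s (final 25% when T < 20 s), in units
of the healthy-state RMS amplitude; `success` requires it below 0.05.
These are deliberately distinct from `controllable`: the affine residual
d(t) = −(α_p − α_h)x_h(t) drives *every* node's y-equation while u enters
one node, and the N−1 input-free rows of the closed loop force a steady
error of roughly the healthy amplitude at the non-input nodes regardless of
the feedback law. Under the default operating points the tracking floor is
therefore ≈ 1 (100%) and the strict 5% success flag is rarely raised, while
the control signal stays persistent — feedback still shrinks the error well
below the uncontrolled level (closed-loop benefit, asserted for every
controllable task). d is excluded from gain design by default (regulator
formulation); a config flag can absorb it into A's diagonal where
|e_x| ≥ 1e-6 mV, which changes the gain trajectory but cannot lift the
structural floor above.

**Energy.** Default `l2sq` (trapezoidal ∫u²dt, the LQR energy); `l1`
(∫|u|dt) is always logged alongside because "time-integral of the norm" is
ambiguous. Costs are reported in model units.

## Synthetic cohorts

Real connection-density matrices come from diffusion-MRI tractography; the
generator emulates their statistical shape, not their anatomy:

- base network: stochastic block model, N = 78 regions and 4 modules by
  default, intra-module edges 3× denser than inter-module, overall edge
  density 0.3, weights Beta(2, 5) (mean ≈ 0.29, right-skewed like
  tractography densities), forced connected;
- subjects: edge-wise multiplicative log-normal noise (σ = 0.15),
  re-symmetrized and clipped to [0, 1] — global measures (path length,
  clustering, efficiency) then vary across subjects;
- backbone: maximum-weight spanning tree of the cohort-average network
  plus strongest remaining average edges until mean degree ≥ 6 (the
  published backbone's threshold is not stated; 6 is typical for masked
  structural networks and configurable), applied as a mask to every
  subject, guaranteeing connectedness.

What this does *not* emulate: hemispheric or lobe structure, real region
identities (labels are opaque strings), distance-dependent connection
probability, and tractography's systematic biases. Passing tests therefore
validate the machinery and the qualitative topology–cost relationships,
not any anatomical claim about specific regions.

The engineered *twin-symmetric* network (two nodes with identical
connections and a mutual edge) is a known-negative control: the
antisymmetric twin mode is invisible to inputs outside the pair, so those
tasks are provably uncontrollable — inputs at a twin itself remain
controllable, which both the Arnoldi rank and the CARE verdict reproduce.

## Experiment scales

Desk-scale defaults keep the full pipeline in minutes on one core: the
linear-case controllability experiment uses 5 subjects × 20 regions at
γ = 0, T = 10 s; the nonlinear cost-vs-topology experiment 20 subjects ×
20 regions at γ = 200, T = 10 s — the horizon matters scientifically, not
just for budget: the energy of a task splits into a transient part (damping
the initial error, roughly *anti*-correlated with node strength) and a
steady part (rejecting the persistent α-mismatch disturbance, strongly
*positively* correlated with strength and growing ∝ T).  Long-horizon
experiments live in the steady regime; at γ = 200 the crossover sits near
T ≈ 6–8 s, so T = 3 s would measure the transient regime and reverse the
sign of the cost–strength relationship.  The frequency-variability
experiment uses one
subject with 10 realizations of per-node uniform α factors in [1−p, 1+p]
(one factor scales both α_p and α_h — a node time constant). Full-scale
runs (78 regions, tens of subjects, T = 200 s, four γ values) use the
same code paths and are supported but long-running.

## Known limitations

- The success flag is conservative by construction (see tracking floor
  above); region comparisons should use inverse cost, as the ranking does.
- Costs depend on the gain-update interval and on T; only like-for-like
  comparisons are meaningful.
- The Hamiltonian-eigenvector Riccati route can mislabel a pathologically
  near-uncontrollable system; the acceptance checks (residual, definiteness,
  closed-loop stability) bound the damage by falling back or rejecting.
- No stochastic forcing, no neural-mass sigmoids, no EEG forward model:
  x is read directly as the band-limited source signal.
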