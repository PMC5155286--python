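# Methods

This note documents the model, the numerical choices, and the design
decisions behind `strecg`, in enough detail to reproduce or audit any part of
the pipeline. Nothing here states an empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Forward model

The torso is treated as a homogeneous, isotropic, source-free volume
conductor bounded outside by the body surface S_B (insulated: ∂Φ/∂n = 0) and
inside by the heart surface S_H. For the harmonic potential Φ in that
volume, Green's second identity yields, for an observation point p on either
surface,

    Ω(p) Φ(p) = ∫_{S_B} Φ dΩ_B − ∫_{S_H} Φ dΩ_H − ∫_{S_H} (∂Φ/∂n_H) / r dS,

where Ω(p) is the solid angle the conducting volume subtends at p and dΩ_S is
the signed solid-angle element of surface S with its outward normal.
Collocating at mesh nodes with linear (vertex-based) shape functions over
flat triangles gives two matrix equations,

    A_BB y + A_BH x + M_BH g = 0        (p on S_B)
    A_HB y + A_HH x + M_HH g = 0        (p on S_H)

in the body potentials y, heart potentials x, and heart normal derivatives g.
Eliminating g:

    R = −(A_BB − M_BH M_HH⁻¹ A_HB)⁻¹ (A_BH − M_BH M_HH⁻¹ A_HH),
    D = −M_HH⁻¹ (A_HB R + A_HH),

with y = R x and g = D x. D is the normal-derivative operator used as the
first-order constraint in the Tikhonov/L1 baselines.

Numerical choices:

* **Double layer.** Per-triangle signed solid angles are computed with the
  van Oosterom–Strackee formula (exact); linear-shape weights come from a
  7-point degree-5 Gauss rule on the triangle with an *additive* correction
  that forces the three weights to sum to the exact solid angle. Closed-
  surface identities (Σω = 4π inside, 0 outside, interior angle on the
  surface) therefore hold to machine precision, and a constant potential
  with zero normal current satisfies both collocation equations exactly.
  Triangles incident to the observation node are coplanar with it and
  subtend zero angle, so principal values need no special handling.
* **Single layer.** 7-point Gauss quadrature for well-separated triangles,
  one extra two-level 4-way subdivision when the observation point is within
  two triangle diameters, and a Duffy-type radial substitution for
  vertex-incident triangles (the u-integral is then analytic; the remaining
  1-D integral uses 16-point Gauss–Legendre). Accuracy is validated against
  the analytic two-sphere forward solution rather than assumed: the relative
  L2 error of R x_analytic vs y_analytic on the 184-node spheres is ≈ 0.2 %
  and decreases monotonically with refinement (asserted at 46 → 92 → 184
  nodes).
* **No deflation.** The Dirichlet(S_H)/Neumann(S_B) mixed problem is
  uniquely solvable, so the eliminated system is nonsingular and R needs no
  constant-potential deflation; R·1 = 1 emerges from the construction and is
  asserted to 1e−10. The conductivity σ cancels in the potential-to-
  potential map and is kept as metadata (σ = 1 in the study).

## Ground truth: central dipole between concentric spheres

For a current dipole p(t) at the center of a homogeneous sphere of radius
r_B insulated at its boundary, the interior potential is the ℓ = 1 harmonic

    Φ(r, t) = p(t)·r̂ / (4πσ) · (1/r² + 2 r / r_B³),

which satisfies Laplace's equation and ∂Φ/∂r = 0 at r_B (both verified by
finite differences in the tests). Sampling at r_H = 1.0 and r_B = 1.5 gives
the reference pair x(s, t), y(s, t). Note y is *analytic*, not R x, so the
inversion faces genuine model (discretization) error — no inverse crime.

The dipole trajectory is a smooth rotating loop,

    p(t) = A (sin ωt, sin 2ωt, cos ωt),   ω = 2π/300 ms⁻¹,  t = 0…300 ms,

sampled at 1 ms (T = 301, configurable). The amplitude A is set in closed
form so the inner-sphere potential peaks at 2.5 mV (the reference maps span
−2.5…2.5 mV); with that calibration, injected noise with σ_ε = 0.1 mV is
≈ 10 % of the outer-surface RMS signal, matching the study's noise-level
labels (10 %…50 % for σ_ε = 0.1…0.5).

## Spatial and temporal penalties

* **Mesh surface Laplacian Δ_s.** For node i with neighbors j at edge
  lengths d_ij and mean edge length d̄_i, neighbor values are linearly
  interpolated to the common distance d̄_i along each edge,
  x̃_j = x_i + (d̄_i/d_ij)(x_j − x_i); their average approximates the ring
  average at radius d̄_i, and the 2-D mean-value property gives
  (Δ_s x)_i = (4/d̄_i²)(mean_j x̃_j − x_i). On a square lattice this reduces
  exactly to the 5-point stencil (x_1+x_2+x_3+x_4−4x_0)/d², and on a sphere
  mesh the ℓ = 1 field z reproduces the Laplace–Beltrami eigenvalue
  −ℓ(ℓ+1)/r² = −2 within ≈ 15 % (best-fit eigenvalue −1.7…−1.9 for 64…400
  nodes; the operator is first-order accurate on irregular meshes and the
  test band is ±30 %). Rows sum to zero; the matrix is not symmetrized (the
  construction is row-wise), but the penalty ‖Δ_s x‖² is symmetric PSD
  regardless.
* **Temporal penalty.** Σ_t Σ_{k=1..w} ‖x_t − x_{t+k}‖², each unordered pair
  counted once and the window truncated at the record boundaries (no
  wraparound). With this convention the quadratic contribution of an
  interior time t is exactly 2wλ_t‖x_t‖², i.e. the per-time block carries
  the 2wλ_t I diagonal term the solver expects. (The once-vs-twice counting
  only rescales λ_t by 2; the convention is fixed by that diagonal
  structure.)

## Solvers

* **Tikhonov (orders 0/1):** closed-form normal equations per time slice;
  verified against SVD filter factors (Γ = I) and an independent stacked
  least-squares route.
* **L1 first-order:** ADMM on z = Γx with a cached Cholesky factor and
  standard residual-balancing adaptation of the penalty parameter;
  convergence is declared when the relative objective change stays below
  1e−8 over 10 iterations. Verified against an independent proximal-
  gradient (ISTA) solver on small instances.
* **Direct spatiotemporal solve:** the objective is an unconstrained convex
  quadratic whose normal equations are the Sylvester system
  (RᵀR + λ_s Δ_sᵀΔ_s) X + λ_t X L_T = RᵀY, with L_T the graph Laplacian of
  the path-with-window time graph. Both coefficient matrices are symmetric
  PSD, so the system is diagonalized exactly by their eigenbases; the solve
  costs O(N³ + T³ + NT(N+T)) and is exact up to the eigendecompositions.
  Semidefinite modes (possible only at λ_t = 0 with rank-deficient R and
  Δ_s) fall back to the minimum-norm solution with a warning.
* **Dipole multiplicative update:** x_t = x⁺ − x⁻ with x⁺, x⁻ ≥ 0. Per
  forward Gauss–Seidel sweep over t (temporal neighbors at latest values),
  the block quadratic x_tᵀA_t x_t − 2b_tᵀx_t with
  A_t = RᵀR + λ_s Δ_sᵀΔ_s + λ_t n_t I (n_t = number of window pairs at t)
  and b_t = Rᵀy_t + λ_t Σ_{0<|k|≤w} x_{t+k} is decreased by the
  multiplicative nonnegative-QP update: with A⁺/A⁻ the elementwise
  positive/negative parts of A_t, a = A⁺x⁺ + A⁻x⁻ and c = A⁻x⁺ + A⁺x⁻,

      x⁺ ← x⁺ (b + √(b² + 4ac)) / (2a),    x⁻ ← x⁻ (−b + √(b² + 4ac)) / (2c).

  The multiplicative form preserves nonnegativity exactly and never
  increases the objective (asserted on every tested instance). Denominators
  carry a 1e−12 floor. Initialization is uniform(0, 1) positive random
  matrices with an explicit seed; the objective is convex, so the seed only
  affects the iteration count (asserted). Default stopping: relative
  objective change < 1e−8 per sweep, cap 5000 sweeps. Run to stagnation
  (tol = 0) the solution matches the direct solve to ≤ 1e−5 relative L2 on
  random instances up to N = 50, T = 20 — the central correctness property.
  The benchmark studies use the direct solver by default; because the two
  agree to 1e−5, all reported relative errors are solver-independent at the
  printed precision.

## Parameter selection

The spatiotemporal weights in the benchmark are the study constants
λ_s = 0.015, λ_t = 0.5, w = 2 (torso-heart pathway: λ_s = 2.0, λ_t = 0.005).

For the baselines, the package provides L-curve machinery (log–log sweep,
spline curvature, maximum-curvature corner; corner selection is invariant
under rescaling either axis). On the two-sphere study, however, R is square
and invertible, so the λ → 0 branch of the L-curve fits the injected noise
itself; the curve has two bends and the sharpest corner — which
maximum-curvature selection finds — sits on the noise-overfitting branch and
under-regularizes badly. The benchmark therefore selects each baseline's λ
by the Morozov discrepancy principle: the smallest λ whose residual reaches
the known injected-noise norm √(N_B T)·σ_ε (bisection in log λ, using the
monotonicity of the residual in λ). This rule has no free parameters and
uses only information the study actually has (σ_ε is set by the protocol).
Selection runs once per (method, noise level) on the first replicate and the
weight is held fixed across replicates. The noise-free condition is
evaluated at the weight selected for the smallest nonzero study level
(σ_ε = 0.1): real recordings always carry measurement noise, and with zero
injected noise the discrepancy rule has no floor.

## What the synthetic study does and does not emulate

The generator reproduces the study conditions exactly as stated: concentric
spheres, central ℓ = 1 dipole, i.i.d. Gaussian sensor noise at fixed σ_ε,
20 replicates per noise level with per-replicate seeds (base_seed +
replicate). It does not emulate: realistic torso/heart geometry (available
only through the external-data pathway), inhomogeneous conductivity,
correlated or signal-dependent sensor noise, geometric uncertainty, or
multi-source activity. Passing benchmarks therefore demonstrate correctness
of the solvers and the forward model under the stated simulation conditions,
not clinical-grade reconstruction accuracy.

Two quantitative caveats for anyone comparing against previously reported
relative errors on this geometry:

* **The spatial-penalty scale couples to λ_s.** The penalty is
  λ_s‖Δ_s x‖², so any rescaling of Δ_s rescales the effective λ_s
  quadratically. With the mean-value-correct operator used here (ℓ = 1
  eigenvalue ≈ −2 on the unit sphere, R's ℓ = 1 gain ≈ 0.84), λ_s = 0.015
  implies an irreducible ℓ = 1 shrinkage bias of ≈ 8 % that is independent
  of the data amplitude; the noise-free spatiotemporal RE is therefore
  ≈ 0.10 on this setup, and implementations whose Laplacian omits the
  4/d̄² prefactor will report much smaller noise-free REs at the same
  nominal λ_s. No fixed linear estimator can combine a sub-1 % noise-free
  RE with a nearly noise-flat RE curve (bias–variance: RE² = bias² + cσ²).
* **Forward-model accuracy sets the baseline REs.** The BEM here reaches
  ≈ 0.2 % forward error at 184 nodes; with discrepancy-selected weights the
  first-order Tikhonov baseline then lands near RE ≈ 0.03–0.04 at low
  noise. Coarser forward models produce proportionally larger baseline REs
  under the identical protocol.

## Known limitations

* The interpolation Laplacian is first-order on irregular meshes; a
  cotangent/FEM Laplace–Beltrami operator would be more accurate but is a
  different operator (deliberately out of scope).
* The L1 solver's optimum on this geometry is genuinely worse than
  first-order Tikhonov (the normal-derivative image of the ℓ = 1 signal is
  dense, so the L1 shrinkage bias has no sparsity to exploit).
* The multiplicative update converges sublinearly near the optimum; for
  production-size problems the exact direct solve is preferred, with the
  multiplicative route retained as the constrained-splitting reference
  implementation.
* The torso-heart pathway requires user-supplied geometry and recordings
  (nothing is downloaded); its REs depend on uncontrolled preprocessing of
  the external data and are not asserted by the tests, which cover shapes
  and end-to-end execution on synthetic stand-ins only.
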