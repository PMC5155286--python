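# strecg — spatiotemporal regularization for the inverse ECG problem

`strecg` reconstructs heart-surface potential maps x(s, t) from body-surface
potential maps y(s, t) (electrocardiographic imaging). The two are linked by
the linear volume-conductor model

    y(s, t) = R x(s, t) + ε,

where the transfer matrix **R** follows from Laplace's equation in the
source-free, homogeneous torso between the heart surface S_H and the insulated
body surface S_B, discretized by a boundary-element method (BEM) on triangle
meshes. Because R is severely ill-conditioned, the inversion is stabilized by
a spatiotemporal penalty (STRE):

    min_X  Σ_t ‖y_t − R x_t‖² + λ_s Σ_t ‖Δ_s x_t‖² + λ_t Σ_t Σ_{k=1..w} ‖x_t − x_{t+k}‖²

with Δ_s a surface Laplacian built on the irregular heart mesh (neighbor
values linearly interpolated to the mean edge length d̄_i, then the mean-value
identity ∇²x ≈ (4/d̄_i²)(x̄ − x_i)), and a windowed temporal-difference
penalty. The objective is solved either exactly (a double spectral
decomposition of the block normal equations) or by the *dipole multiplicative
update*: x_t is split into nonnegative parts x_t = x⁺ − x⁻ — mirroring the
positive and negative poles of the bioelectric field — and Sha–Saul–Lee
multiplicative nonnegative-QP updates are swept over t, which preserves
nonnegativity exactly and never increases the objective.

Baselines included for benchmarking: zero-order Tikhonov (ridge), first-order
Tikhonov and first-order L1 (ADMM), the latter two with the heart-surface
normal-derivative operator Γx = ∂x/∂n recovered from the same BEM blocks.

The package is aimed at researchers in cardiac electrophysiology and
biomedical inverse problems who want a fully self-contained, text-input
pipeline: mesh generation, BEM assembly, analytic ground truth, inversion,
parameter selection, and replicated noise benchmarks.

## Worked example

The fully synthetic study: two concentric spheres (r_H = 1.0, r_B = 1.5,
184 nodes / 364 triangles each), a central time-varying dipole over
t = 0…300 ms whose inner-sphere potential spans −2.5…2.5 mV, analytic
ground truth on both spheres, and the solvers applied to the outer-sphere
data.

```python
import numpy as np
from strecg import STREInverse
from strecg.experiments import build_two_sphere_problem, relative_error

prob = build_two_sphere_problem(nodes=184, dt_ms=1.0)
print(prob.R.shape, round(prob.cond_R, 1))

est = STREInverse(lambda_s=0.015, lambda_t=0.5, window=2,
                  laplacian=prob.laplacian).fit(prob.R, prob.Y.values)
print(round(relative_error(est.X_, prob.X), 4))
```

prints

```
(184, 184) 314.9
0.0985
```

i.e. a 184 × 184 transfer matrix with condition number ≈ 315, and a
noise-free relative error
RE = ‖X̂ − X‖_F / ‖X‖_F ≈ 0.098 for the spatiotemporal solution at the study
weights λ_s = 0.015, λ_t = 0.5, w = 2. The same study is scriptable from the
shell:

```bash
strecg mesh make-sphere --radius 1.0 --nodes 184 --out heart.off
strecg simulate two-sphere --nodes 184 --dt 1 --out sim/
strecg bench two-sphere --replicates 20 --out results.csv
```

`docs/methods.md` documents the model, the parameter-selection protocol
(discrepancy-based for the baselines and why), numerical choices, and known
limitations — including a quantitative account of how the spatial-penalty
scale couples to λ_s, which matters when comparing against previously
reported relative errors.

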