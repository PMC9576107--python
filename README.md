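# screwaxis

Estimation of the **average screw axis (ASA)** of a joint from motion-capture
pose data, with a statistical analysis of the dispersion of the
**instantaneous screw axes (ISAs)** around it.

In clinical movement analysis and robotics, the functional rotation axis of a
hinge-like joint (a knee, an ankle, a mechanical pivot) is located from the
recorded relative motion of the two segments rather than from anatomy. By the
Mozzi–Chasles theorem, each velocity sample defines an ISA — the line about
which the segment instantaneously rotates — and the joint axis is estimated
as the line closest and most parallel to the whole set. The classical
instantaneous-approach estimators need an angular-speed threshold (~0.3 rad/s)
to discard samples where the ISA is ill-defined, and break down for
hinge-like motion where the pseudo-intersection of near-parallel axes is
singular. This package implements a threshold-free, velocity-weighted,
regularized estimator and the accompanying uncertainty analysis.

## Model

From consecutive relative poses `T_k ∈ SE(3)` sampled at interval `Δt`, the
screw twist `(ω, v₀)` is extracted via the matrix logarithm,
`[[ω]ₓ v₀; 0 0] = logm(T_{k+1} T_k⁻¹)/Δt`. Then:

* **Direction** — `n_asa = argmax_{‖n‖=1} (1/N) Σᵢ (ωᵢ·n)²`, i.e. the
  dominant eigenvector of the second-moment matrix
  `C_ω = (1/N) Σᵢ ωᵢωᵢᵀ`. Each sample is implicitly weighted by `‖ωᵢ‖`,
  which removes the need for any threshold.
* **Position** — the damped least-squares pseudo-intersection
  `S_asa = (1/N Σᵢ [ωᵢ]ₓ[ωᵢ]ₓᵀ + εI)⁻¹ (1/N Σᵢ [ωᵢ]ₓ v₀ᵢ + εS₀)`,
  where the regularizer anchors the component of the position that is
  undefined for pure hinge motion to a prior point `S₀` (ideally the
  geometric joint center).
* **Dispersion** — eigen-decomposition of `C_ω` and of the position
  covariance `C_S = σ̂² (trace(C_ω)I − C_ω)⁻¹` gives 95% confidence
  ellipsoids (axis magnitudes `γ·√λᵢ` with `γ = √χ²₀.₉₅,₃ ≈ 2.7955`) and the
  hinge-likeness ratios `ρ₁ = (λ₂+λ₃)/λ₁`, `ρ₂ = λ₃/λ₂`, alongside the
  conventional threshold-based RMSE dispersion metrics.

A right-handed coordinate frame is attached to the ASA (x: axis direction,
y: normal to the plane of largest ISA variation, origin at `S_asa`).

The package also ships synthetic motion generators (ideal cylindrical joint,
damped hinge swing, ball-and-socket swing), a fixed-magnitude SE(3)
pose-noise model, the threshold-based baseline estimator, and scripted
regularization / noise-sensitivity / dispersion study protocols.

## Worked example

```python
import numpy as np
from screwaxis import (AsaConfig, CylindricalJointConfig, estimate_asa,
                       generate_cylindrical, dispersion_study)

ps = generate_cylindrical(CylindricalJointConfig())          # 101 poses, 100 Hz
res = estimate_asa(ps, AsaConfig(epsilon=0.01, S0=np.array([0.0, -0.25, 0.0])))
print("n_asa       =", np.round(res.axis.n, 6))
print("S_asa [m]   =", np.round(res.axis.S, 6))

rep = dispersion_study(ps, epsilon=0.01, S0=(0.0, -0.25, 0.0))
print("ellipsoid [rad/s] =", np.round(rep.orientation.magnitudes, 3))
print("rho1, rho2        =", np.round(rep.orientation_ratios, 3))
print("SoA RMSE [deg]    =", round(rep.rmse_angle_deg, 3))
```

prints

```
n_asa       = [0. 0. 1.]
S_asa [m]   = [ 0.   -0.25  0.  ]
ellipsoid [rad/s] = [9.753 0.    0.   ]
rho1, rho2        = [0. 0.]
SoA RMSE [deg]    = 0.0
```

The estimator recovers the generator axis — direction `(0,0,1)` through
`(0,−0.25,0)` m — exactly. The orientation confidence ellipsoid degenerates
to a single axis (second/third magnitudes 0, `ρ₁ = 0`): every ISA of this
purely rotational motion coincides with the ASA, and the conventional RMSE
dispersion is likewise zero.

The same pipeline is available from the shell:

```sh
screwaxis simulate cylindrical --out poses.csv
screwaxis estimate --poses poses.csv --epsilon 0.01 --prior 0,-0.25,0 --out report.json
screwaxis study sensitivity --poses poses.csv --reps 100 --seed 1 --out sens.json
```

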