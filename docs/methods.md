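# Methods

## Model

`aclthreshold` implements a two-dimensional, frontal-plane torque balance
about the lateral femoral condyle for a single-leg landing with a fully
extended knee. The shank makes an angle α with the vertical; the trunk is
assumed vertical. The vertical ground-reaction-force component Fy generates
an abduction (valgus) torque with lever

    M_abd(α) = Fy · L · (sin α − μ · cos α),   clamped at 0,

where L is the ground-to-lateral-condyle distance and μ the Coulomb
shoe–surface traction coefficient: a horizontal component Fx = μ·Fy opposes
the lateral slide of the foot with lever L·cos α. μ = 0 is the slippery
boundary condition (the foot slides freely), the worst case for the ACL.

The adduction side sums, each force times its moment arm about the lateral
condyle:

    M_add(α) = f_lig · (F_ACL · d_ACL + F_MCL · d_MCL)
             + f_quad · F_quad · d_IC / 2
             + f_semit · (k · m · g) · d_MCL
             + m · g · (d_hip + T · sin α)
             [+ f_gastroc · F_gastroc · d_gastroc, optional]

with d_ACL, d_MCL the ligament moment arms, d_IC the intercondylar
distance (the patellar tendon is taken to act midway between the condyles,
hence the /2), k the semitendinosus force in bodyweight multiples (sharing
the MCL moment arm, which lies on the same medial line of action), d_hip the
bi-acetabular half-distance, T the thigh length, and f_* activation
fractions in [0, 1]. Full activation everywhere is the default, so the
threshold is a conservative upper bound: any neuromuscular deficit lowers
it.

The critical GRF at angle α solves M_abd = M_add in closed form:

    Fy*(α) = (C + m·g·T·sin α) / (L · (sin α − μ·cos α)),

with C the α-independent part of M_add. Where sin α ≤ μ·cos α the foot
cannot load the abduction axis and the threshold is infinite (scalar queries
raise `NoSolutionError`; grids carry an `inf` sentinel). The **angle of
damage** inverts this: the smallest α at which a given Fy reaches the
threshold, `arcsin(C / (Fy·L − m·g·T))` for μ = 0 and a bracketed Brent
root-find on the torque residual otherwise.

## Parameters

Tissue defaults (newtons; literature maxima for young healthy adults):
ACL 2300, MCL 799, quadriceps 8000, gastrocnemius medialis 931,
semitendinosus–semimembranosus 2 bodyweights. The gastrocnemius term is off
by default because no moment arm was measured for it; it can be enabled by
supplying one.

Anthropometric defaults (cohort of 15 healthy male athletes, MRI-measured
knee distances plus external anthropometrics, mean ± SD in mm):
lateral condyle–ACL 26.06 ± 1.7, lateral condyle–MCL 68.8 ± 3.27,
intercondylar 58.46 ± 2.82, ground–lateral condyle 594.86 ± 13.89,
thigh (lateral condyle–greater trochanter) 461.8 ± 9.33; bi-acetabular
half-distance 123.78 mm (literature constant, SD 0 unless supplied); body
mass 80.2 ± 6.8 kg. Body height is not a model input and is not stored.

g defaults to 10 m/s²: the model's reference bodyweight of 802 N for
80.2 kg implies this rounding, and the default reproduces the reference
coefficients bit-for-bit. It is configurable via the `g` keyword.

Files carry mm and kg (the units the statistics were measured in); all
internal computation is in m, kg, N, N·m. Angles are degrees at every
interface.

## Synthetic cohort generator

`synthesize_cohort` draws each variable independently from a Gaussian with
the population mean and SD, truncated below at max(mean − 4·SD, 1) in file
units so lengths and masses stay physical; with the default SDs the
truncation shifts the mean by well under 10⁻³ SD. Streams are spawned per
variable from a single `SeedSequence`, so identical seeds give bit-identical
cohorts. A 7×7 correlation matrix can be supplied (no cross-variable
covariances were measured, so independence is the default); correlated
draws use a multivariate normal with an eigenvalue factorisation (the
covariance is only positive semi-definite when any SD is zero) and are
clipped at the floor rather than properly truncated — an approximation
acceptable at 4 SD.

What the generator emulates: the marginal distributions of one small,
homogeneous male athlete cohort. What it does not: inter-variable
correlations (real limb dimensions covary), measurement error, asymmetry,
female anthropometrics, and any variability in tissue strengths (the
balance fixes those at literature maxima). Passing tests therefore
demonstrate correctness of the propagation machinery, not population
realism.

## Numerical choices

- Curve grid: 0.01° steps on [0.01°, 90°] (9000 points), matching the
  reference generation procedure; the grid starts above zero because the
  μ = 0 threshold diverges at α = 0.
- Inversion: closed-form arcsin for μ = 0, evaluated in extended precision
  with an ulp-level clamp at s = 1 — arcsin is ill-conditioned near 90° and
  double rounding alone cannot meet the 10⁻⁶-degree round-trip contract
  there. For μ > 0, Brent's method bracketed between the lever singularity
  arctan(μ) and 90°, xtol 10⁻¹².
- Risk classification is strict (abduction > adduction ⇒ at risk; exact
  balance is safe) but applied above a torque resolution of 10⁻⁹ N·m, since
  floating rounding can push the margin at the computed threshold a few
  10⁻¹³ N·m either side of zero.
- Percentile bands use the linear-interpolation order-statistic definition
  (`numpy.percentile`, `method="linear"`); band values depend on this
  choice, so it is fixed and recorded in each result's parameter sidecar.
- Sweeps are one-at-a-time: the swept parameter varies, everything else
  stays at defaults.
- Torques are reported as unsigned magnitudes with a fixed sign convention
  (abduction positive in the net torque); the frame-dependent
  clockwise/counter-clockwise language of diagrams is not preserved.

## Problem sizes used in tests and the acceptance script

Coefficient checks are closed-form (instant). Cohort recovery uses
n = 10⁵ (sample mean of a 1.7 mm-SD variable then has SE ≈ 0.005 mm,
an order below the 0.05 mm acceptance band). Monte Carlo convergence of
the cohort median uses n = 10⁴; oracle-equivalence grids use 1° steps and
the monotonicity check the full 0.01° grid, all vectorised.

## Known limitations

Two-dimensional and frontal-plane only: no tibial rotation, anterior
translation, knee-flexion dependence, hamstring-to-quadriceps ratio, or
trunk lean. The threshold is deterministic given parameters — uncertainty
enters only through the anthropometric cohort, not through tissue strengths
(an exposed but disabled refinement, since only the MCL has a published
spread). Outputs are model thresholds, not injury epidemiology. The μ > 0
extension is a Coulomb slip limit, not a measured traction model;
experimental shoe–surface data would be needed to calibrate it.
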