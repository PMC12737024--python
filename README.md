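# aclthreshold

A frontal-plane torque-balance model of non-contact anterior cruciate
ligament (ACL) injury risk during single-leg landing, for biomechanics
researchers and sports-medicine practitioners studying how shin angle,
shoe–surface traction and muscle activation shape the injury threshold.

## The model

During a single-leg landing with the knee fully extended, the vertical
ground-reaction force Fy generates an abduction (valgus) torque about the
lateral femoral condyle; the ACL, MCL, quadriceps (via the patellar
tendon), semitendinosus and bodyweight resist it. With shin angle α from
the vertical and Coulomb traction coefficient μ, the balance

    Fy · L · (sin α − μ cos α)
      = F_ACL·d_ACL + F_MCL·d_MCL + F_quad·d_IC/2
        + k·m·g·d_MCL + m·g·(d_hip + T·sin α)

defines the **critical GRF** Fy\*(α) — the vertical force above which the
model flags a significant ACL injury risk — and its inverse, the **angle of
damage** at a given force. Steeper shin lean lowers the threshold; traction
raises it; any activation deficit lowers it. The package adds a synthetic
anthropometric cohort generator and Monte Carlo propagation of
inter-individual variability. See `docs/methods.md` for the full model,
parameter provenance and numerical choices.

## Worked example

```python
from aclthreshold import (LandingScenario, SurfaceState, angle_of_damage,
                          average_profile, classify_risk, cohort_thresholds,
                          critical_grf, synthesize_cohort)

profile = average_profile()          # cohort-average geometry, 80.2 kg
fy30 = critical_grf(30.0, profile)   # frictionless threshold at 30 deg
fy90 = critical_grf(90.0, profile)
print(f"critical GRF at 30 deg: {fy30:.1f} N ({fy30/profile.weight():.2f} BW)")
print(f"critical GRF at 90 deg: {fy90:.1f} N ({fy90/profile.weight():.2f} BW)")
print(f"angle of damage at 2500 N: {angle_of_damage(2500.0, profile):.2f} deg")
print(f"critical GRF at 30 deg, mu=0.3: "
      f"{critical_grf(30.0, profile, surface=SurfaceState(mu=0.3)):.1f} N")
risk = classify_risk(LandingScenario(30.0, 3000.0, profile))
print(f"3000 N at 30 deg: at_risk={risk.at_risk}, margin={risk.margin_nm:.1f} N*m")

cohort = synthesize_cohort(n=10_000, seed=1)
print(cohort_thresholds(cohort, [30.0]).bands.round(1).to_string(index=False))
```

prints

```
critical GRF at 30 deg: 2499.9 N (3.12 BW)
critical GRF at 90 deg: 1561.3 N (1.95 BW)
angle of damage at 2500 N: 30.00 deg
critical GRF at 30 deg, mu=0.3: 5204.0 N
3000 N at 30 deg: at_risk=True, margin=148.7 N*m
 percentile  angle_deg  critical_grf_N
          5       30.0          2280.2
         25       30.0          2410.2
         50       30.0          2498.8
         75       30.0          2593.9
         95       30.0          2729.0
```

A landing at 30° shin lean becomes dangerous above ~2.5 kN (≈3.1
bodyweights); at a horizontal shank any force above ~1.56 kN (≈1.9 BW)
suffices. Traction of μ = 0.3 more than doubles the 30° threshold, and
across a synthetic 10 000-subject cohort the central 90% of thresholds at
30° spans roughly 2.28–2.73 kN.

## Command line

```sh
acl-threshold curve --out results          # threshold curve CSV + PNG + sidecar
acl-threshold angle-of-damage --grf 2500
acl-threshold classify --angle 30 --grf 3000
acl-threshold cohort -n 15 --seed 1 --out results
acl-threshold sweep --parameter mu --values 0,0.2,0.4 --out results
acl-threshold curve --show-config          # dump effective defaults (YAML)
```

Every output file is paired with a machine-readable parameter sidecar that
re-runs to identical results.

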