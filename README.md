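# scarabwing

Tools for comparing **elastic wing deformation** and **wing-shape
evolution** in scarab beetles. The package re-implements, as a tested and
reusable pipeline, the computational chain needed to relate flapping-wing
compliance to wing morphology across species:

1. **Flapping kinematics** — reconstruct the body frame from three thorax
   points and describe wing motion by three time-varying angles (flapping,
   deviation, incidence) measured against the stroke plane; derive wingbeat
   frequency from stroke reversals, the stroke-plane inclination, the
   advance ratio `J = V / (2 Φ f R)` and the vertical force
   `Fv = m (g + a_v)`.
2. **Elastic deformation** — fit the rigid leading-edge plane (wing base,
   marginal joint, wing tip) per frame and measure the signed,
   wing-length-normalized deflection of four trailing-edge vein tips
   (RP, MP, CuA, AA) perpendicular to it, positive toward the pressure
   side; summarize per half-stroke at mid-stroke; fit the deflection–force
   allometry `β = a Fv^b`; compare wings of different chord by the
   stiffness proxy `l³/β`.
3. **Static bending** — estimate flexural stiffness from point loads on a
   cantilevered wing, `EI = F l³ / (k β)` with `k = 3` for an end-loaded
   uniform beam, and form the dorsal/ventral and wing-base-only (WB) versus
   wing-base-plus-leading-edge (WBLE) support contrasts over the six-point
   measurement layout.
4. **Geometric morphometrics** — generalized Procrustes alignment of
   25-landmark wing configurations, shape PCA, per-landmark variance
   contributions, thin-plate-spline warps between mean shapes, and
   phylogenetically corrected PCA of species means under a Brownian-motion
   model (`C_ij` = shared root-to-MRCA path length; GLS root state
   `a = (1'C⁻¹1)⁻¹ 1'C⁻¹X`; evolutionary covariance
   `R = (X−1a)' C⁻¹ (X−1a)/(n−1)`).
5. **Wing planform geometry** — span, area, aspect ratio `AR = b²/S`,
   chord distribution and the non-dimensional radius of the second moment
   of wing area `r̂₂ = √(S₂/(S b²))`.

No specimen recordings ship with the package; a synthetic-data module
generates flight recordings, shape radiations on a tree, bending
experiments and allometry tables with fully known ground truth, so every
stage is testable end to end.

The Procrustes, PCA and phylogenetic-PCA components are scikit-learn style
estimators (`GeneralizedProcrustesAnalysis`, `ShapePCA`, `PhylogeneticPCA`,
`ThinPlateSpline`, `AllometricPowerLaw`) and compose with sklearn
pipelines; module-level functions (`gpa`, `shape_pca`, `phylo_pca`, …) are
thin wrappers returning plain dataclasses.

## Worked example

```python
import numpy as np
from scarabwing import (FlightSimParams, simulate_flight, wing_angles,
                        deflection_series, midstroke_values, flexural_stiffness)

params = FlightSimParams(frequency_f=118.0, wing_length_R=20.0, seed=0)
rec = simulate_flight(params)               # 3 cycles at 5 kHz, 7 wing landmarks
kin = wing_angles(rec)
print(round(kin.frequency, 2), round(kin.stroke_plane_angle, 1))
# 118.0 34.0   -> wingbeat frequency (Hz) and stroke-plane angle (deg)

defl = deflection_series(rec, R=params.wing_length_R)
down, up = midstroke_values(kin, defl)
print({k: round(v, 3) for k, v in down.items()})
# {'RP': 0.05, 'MP': 0.09, 'CuA': 0.12, 'AA': 0.1}
# normalized mid-downstroke deflections; CuA deflects most, as commanded

print(flexural_stiffness(F=1.518e-4, l=8.4e-3, beta=1e-3))
# 3.0000221760000006e-08   -> EI in N m^2 for a 1 mm press at 0.42 wing length
```

The command line mirrors the library:

```bash
scarabwing demo --seed 7 --out demo_out   # full two-species synthetic study
scarabwing simulate-flight --seed 0 --out rec.csv
scarabwing kinematics rec.csv --out kin.json
```

`demo` simulates a compliant species (2× proximal trailing-edge
deflection) against a stiff one, runs the kinematics/deformation stages on
noisy recordings of both, tests the contrast by permutation, fits the
allometry, inverts simulated bending measurements and analyses a 20-species
shape radiation by GPA, PCA and phylo-PCA, writing all summary tables.

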