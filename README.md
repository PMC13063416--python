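# cellcharge

Single-cell electrokinetic tracking: measure the **effective surface charge**
of individual non-motile bacteria from their drift in a uniform electric
field.

Population-averaged zeta potentials hide the cell-to-cell charge
heterogeneity that controls how bacteria move in electric-field water
treatment (e.g. locally enhanced electric field treatment, LEEFT, where
transport into high-field zones is charge-dependent). This package
implements the in situ alternative: track each cell in time-lapse DIC-style
microscopy while a known uniform field is applied, and invert per-cell drift
into per-cell charge.

## The model

A spherical cell of radius *r* carrying effective charge *q* in a uniform
field *E* experiences an electrostatic force *qE* and a Stokes drag
*6πηrv*. At micrometre scale the inertial time is negligible, so drift is at
steady state and the net force vanishes:

```
F_net = qE − 6πηrv = 0   ⟹   q = 6πηr v / E
```

with *v* the signed time-averaged cell velocity along the anode→cathode
axis, measured while the field is on. Brownian motion is isotropic, so its
contribution to the time average decays as 1/√K with the number of steps K;
the residual noise floor on q̂ is `6πηr·√(2D/Δt)/(E√K)` (≈ 4.4 × 10⁻¹⁸ C at
E = 380 V/m, D = 0.16 μm²/s, K = 50).

Field-off recordings provide the control: the ensemble mean-squared
displacement must be linear in lag (slope = 4D for 2-D diffusion), step
directions uniform on the circle (Rayleigh test), and the axis-projected
mean velocity zero.

The pipeline is: **segmentation** (Gaussian blur, adaptive threshold,
morphological cleanup, contour gates on area > 50 px² and minimum enclosing
radius > 4 px) → **tracking** (Hungarian frame-to-frame assignment with a
100 px gate, gap tolerance, morphology/zero-velocity/completeness filters) →
**kinematics** (velocities, MSD → D, isotropy) → **electrokinetics** (charge
inversion and population statistics: histograms, field-independence Pearson
test, growth-phase ANOVA, isoelectric-point scan).

Because raw experimental videos of this kind are rarely shareable, the
package includes a first-class **synthetic microscopy generator**: cells as
rendered anti-aliased disks undergoing overdamped Brownian + electrophoretic
motion, with PSF blur and camera noise, plus an exact ground-truth table, so
every stage is scored against known truth.

## Worked example

```python
import numpy as np
from cellcharge import synthetic as syn, segmentation as sg, tracking as trk
from cellcharge.model import ForceBalanceModel
from cellcharge.types import *

scene = SceneSpec(width_px=1500, height_px=800, n_frames=50, noise_sigma=3.0, seed=8)
cells = syn.sample_charge_population(30, seed=8)            # lognormal |q|, all negative
cells = syn.place_cells(cells, scene, x_banded=True, y_band_px=(700, 780), seed=9)
medium = MediumConditions(diffusion_um2_per_s=0.16)
field = FieldSchedule(E_V_per_m=380.0)
stack, truth, gt = syn.simulate_scene(cells, medium, field, scene)

detections = sg.segment_stack(stack)
params = TrackingParams(seed=10)
retained, subset = trk.filter_tracks(trk.build_tracks(detections, params), params)

res = ForceBalanceModel(retained, FieldConditions(E_V_per_m=380.0), medium=medium,
                        pixel_scale_um=scene.pixel_scale_um,
                        frame_interval_s=scene.frame_interval_s).fit()
print(res.summary())
```

```
Effective surface charge (force-balance inversion)
==================================================
cells                            26
E [V/m]                       380.0
eta [Pa s]                 1.00e-03
r [m]                      5.00e-07
mean |q|  [C]             3.196e-17
median |q| [C]            2.091e-17
IQR |q| [C]               2.838e-17
range |q| [C]             3.470e-19 .. 9.547e-17
sign                   25/26 charges negative
```

26 of the 30 simulated cells survive segmentation, linking and the
quality filters; the recovered median magnitude (2.1 × 10⁻¹⁷ C) matches the
generator's 2 × 10⁻¹⁷ C median. One weakly charged cell (|q| near 10⁻¹⁸ C,
an order of magnitude below the Brownian noise floor of the inversion) flips
sign — exactly the behaviour the noise-floor formula predicts.

The same stages are available from a shell:

```
cellcharge simulate --seed 1 --out run/         # TIFF + ground truth
cellcharge track    --seed 1 --out run/ run/stack.tif
cellcharge analyze  --seed 1 --out run/ run/tracks.csv
cellcharge run      --seed 1 --out run/         # everything, with a JSON report
cellcharge validate-config my_config.yaml
```

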