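# Methods

## Physical model

The package targets non-motile, near-spherical bacteria (the coccoid
*Staphylococcus* regime) suspended in a low-conductivity medium inside a
microchannel with a spatially uniform in-plane electric field. Each cell is
treated as a rigid sphere of effective hydrodynamic radius *r* carrying an
effective surface charge *q* — the charge outside the hydrodynamic slip
plane that actually drives electrophoresis, which is orders of magnitude
smaller than the total envelope charge. In-plane motion is overdamped
Langevin dynamics:

    x(t+Δt) = x(t) + v_drift Δt · 1{field on} + √(2DΔt) ξ,   ξ ~ N(0, I₂)

with v_drift = qE/(6πηr) along the anode→cathode axis and D the
translational diffusion coefficient. Setting the net force to zero
(electrostatic force balancing Stokes drag) and solving for q gives the
inversion q = 6πηr·v/E, applied to each track's time-averaged signed axis
velocity over field-on windows only.

Assumptions: steady-state drift (momentum relaxation ~10⁻⁷ s ≪ frame
interval); no active swimming; no electroosmotic flow; field uniform over
the field of view; 2-D motion (cells leaving the focal plane simply end
their track); sphere drag (no orientation-dependent tensor).

**Sign convention.** Image coordinates (origin top-left, y down); the field
axis unit vector points anode→cathode, default +y. A negative cell drifts
antiparallel to the axis (toward the anode), so its axis velocity and its
charge are both negative. Reports of |q| always carry an explicit sign
annotation.

**Noise floor.** The per-step axis velocity has sd √(2D/Δt); averaging K
steps and propagating through the inversion predicts
SE(q̂) = 6πηr√(2D/Δt)/(E√K) ≈ 4.4 × 10⁻¹⁸ C at E = 380 V/m, D = 0.16 μm²/s,
Δt = 0.2 s, K = 50. The test suite verifies the empirical scatter of q̂ over
200 simulated cells stays within a factor 1.3 of this prediction. Cells with
|q| below this floor can have their sign flipped by Brownian noise; this is
reported, not suppressed.

## Key parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| viscosity η | 1e-3 | Pa·s | water at room temperature |
| cell radius r | 5e-7 | m | effective radius of a ~1 μm coccus |
| pixel scale | 0.093 | μm/px | typical 63×-objective CCD calibration |
| frame interval Δt | 0.2 | s | standard video rate for these drifts |
| diffusion D | 0.16 | μm²/s | measured Brownian scale for 1 μm particles in this geometry; supplied directly, not derived from Stokes–Einstein (wall drag and crowding suppress D below the free-solution ~0.44 μm²/s) |
| field E | 380 | V/m | working field of the charge analysis; may instead be derived as E = I/(σA) from current, conductivity and electrode cross-section |
| area gate | >50 | px² | rejects noise specks and debris (strict inequality) |
| enclosing-radius gate | >4 | px | rejects sub-cellular fragments (strict inequality) |
| association gate | ≤100 | px | far larger than any plausible per-frame motion; boundary inclusive |
| max gap | 2 | frames | Brownian step ≪ gate, so short dropouts are recoverable |
| area-change gate | 0.5 | fraction | operationalises "irregular morphological change" (merge/division/defocus) |
| min track length | 10 | frames | incomplete-measurement filter |
| min path length | 2 | px | zero-velocity-artifact filter |
| reporting subset | 30 | tracks | seeded uniform sample for per-cell displays |

Every default lives in the run configuration and is echoed into the run log;
none is hard-coded in an operation.

On Ohm's-law field derivation: with I = 5 × 10⁻⁷ A, σ = 13.37 μS/cm and
A = 2 × 10⁻⁶ m², E = I/(σA) = 187 V/m. Because instrument geometry factors
can make the directly-measured field differ from this estimate, `E` may be
supplied directly (the path used for all charge analyses here, at 380 V/m);
the run log records which path was taken.

## Synthetic data generator

The generator emulates: dark disk-shaped cells on a light background
(8-bit), sub-pixel anti-aliased placement, Gaussian PSF blur, additive
Gaussian camera noise clipped to [0, 255]; Brownian + field-gated drift
motion; absorbing boundaries (a cell leaving the frame ends its
ground-truth track, mirroring cells leaving the field of view); an on/off
field schedule; and a long-tailed charge population — lognormal on |q| with
median 2 × 10⁻¹⁷ C and log-sd 1.0, truncated to [10⁻¹⁸, 1.8 × 10⁻¹⁶] C,
all-negative — spanning the two-decade heterogeneity observed for
stationary-phase cells at pH 5.8.

It does **not** emulate: DIC shadow-pair appearance (plain dark disks
suffice for centroid-level validation), defocus/z-motion, cell division,
active motility, cell–cell collisions, electroosmotic flow profiles, or
intensity fluctuations. Consequently, passing the benchmarks demonstrates
correctness of the measurement chain (segmentation → linking → inversion)
under realistic kinematics and photon noise, not robustness to every
real-world imaging artifact.

A single run seed spawns independent child streams (population, placement,
motion, camera noise, subset sampling), so each stage is reproducible in
isolation and full re-runs are byte-identical.

## Numerical and estimator choices

- **Adaptive threshold**: Gaussian-weighted local mean (block 51 px) plus a
  positive offset of 5 grey levels, computed on the polarity-normalised
  (inverted) frame; flat noise therefore yields an empty mask. Blur sigma
  2 px; opening+closing with a radius-1 disk — the smallest settings that
  pass the fidelity benchmarks.
- **Centroids** are binary-mask centroids (intensity-unweighted), sub-pixel.
  The minimum enclosing radius is computed exactly on pixel centres.
- **Assignment**: gated pairs receive a large finite pseudo-cost before the
  Hungarian solve, which maximises the number of in-gate matches and then
  minimises total distance; candidate tracks are ordered by id for
  deterministic tie-breaking.
- **MSD**: overlapping time-average within each track, then unweighted
  ensemble average across tracks; lag 0 omitted. The default fit uses lags
  up to a quarter of the track length (beyond that, window averages are too
  correlated) with an intercept retained to absorb localisation noise.
  D = slope/4. An ensemble-only estimator is available by fitting fewer
  lags; the default is the time-averaged form.
- **Isotropy**: Rayleigh test on pooled step angles (zero-length steps are
  excluded from the angle pool).
- **Charge statistics**: Pearson correlation for field independence;
  one-way ANOVA with Welch pairwise t-tests, Bonferroni-corrected, for
  group comparisons; the isoelectric point is the linear-interpolated zero
  crossing of mean signed charge vs pH, reported as a bracketing interval
  (`none` if the sign never changes).
- **Degenerate inputs** raise explicit errors: inversion at E = 0,
  correlation on constant inputs, groups smaller than 3, MSD fits with
  fewer than 3 lags, tracks shorter than 2 frames.

## Benchmark problem sizes

The validation battery uses: 100-cell rendered field-off scenes
(1040 × 1040 px, 150 frames) for diffusion recovery and detection fidelity;
a 100-cell rendered field-on scene (5000 × 1000 px, 50 frames, one cell per
x-band so that drift-sorted overtaking cannot cause lateral merges) for
end-to-end charge recovery; 200 random ≤6×6 instances against an exhaustive
permutation oracle for assignment optimality; and trajectory-level
simulations (no rendering) for the noise-floor, field-independence and
round-trip checks. These sizes give Monte-Carlo error comfortably below the
tolerances being checked while keeping a full run in the minutes range.

## Known limitations

- The sphere-drag inversion is biased for rod-shaped or flagellated cells;
  extending to orientation-averaged drag tensors is future work.
- Effective charge is not absolute envelope charge; converting to zeta
  potential would require a soft-particle electrophoresis model, which is
  out of scope.
- Touching cells are not split (no watershed); the generator's ground truth
  flags unresolvable overlaps instead.
- The Brownian-noise floor sets a hard detection limit near 10⁻¹⁸ C for
  50-step tracks; longer recordings or stronger fields are the only remedies.
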