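# Methods

## The physical problem

Phone speakers and microphones contain button permanent magnets.  On a
plane a few centimetres above the screen they produce two localized maxima
of the static field magnitude — an *upper* and a *lower hot spot* — whose
peaks decay steeply with distance.  The package models each hot spot as a
**single loop of current (SLC)**: a circular loop of radius `r` carrying
current `I` around an idealized core of relative permeability `µ_r`,
buried at half the phone thickness `T` below the screen with its axis
along the screen normal.  On the loop axis, with `z` measured from the
screen,

    B(z) = µ_r µ0 I r² / ( 2 [ (z + T/2)² + r² ]^(3/2) )        [µT out]

and the analytic gradient is

    dB/dz = −3 µ_r µ0 I r² (z + T/2) / ( 2 [ (z + T/2)² + r² ]^(5/2) ).

`µ_r` enters only as a scalar prefactor multiplying the free-space loop
field.  This is an idealization of the magnet core, **not** a
magnetostatic boundary-value solution; consequently `µ_r` and `I` are
perfectly degenerate (only their product is identified) and `µ_r` is held
fixed at 5000, never fitted.  The same prefactor convention is used by the
3D Biot–Savart engine so that the on-axis closed form and the 3D solution
agree by construction.

Two conventional comparison regressions are provided: exponential
`a·e^(−bz)` (amplitude reported in mT; its `a` *is* the screen value) and
power-law `a·z^(−b)` (amplitude in µT; divergent at `z = 0`, so it has no
finite screen extrapolation).

## Processing order for measured or simulated maps

Grid maps are 13 × 21 tri-axial readings on a 120 × 200 mm grid at 10 mm
pitch, in triplicate, at heights z = 15, 20, 25, 30, 55 mm.  The pipeline
always:

1. averages replicates **component-wise** (the repeatability SD is taken
   on the replicate *magnitudes*, matching how results are reported);
2. subtracts the averaged ambient (no-phone) map **as a vector**;
3. takes the magnitude.

`|mean(B) − B_bg|` differs from `mean(|B|) − |B_bg|`; subtracting vectors
first preserves directional information for as long as possible.  The test
suite pins this ordering with worked counter-examples.

Hot spots are strict local maxima over the 8-neighborhood exceeding the
map median by a prominence threshold (default: three times the median
per-node repeatability SD, so noiseless maps accept any strict maximum).
At most one spot per half-plane is kept (UPPER for y > 0, LOWER for
y < 0); ties break toward larger |B|, then smaller |y|.  The spot position
found on the lowest-z map is held fixed across heights when assembling the
decay curve.

## Uncertainty budget

Each |B| reading carries a four-term combined uncertainty,

    Uc² = sd² + u_zero² + (0.005·B)² + u_grad²,

with `sd` the triplicate repeatability, `u_zero = 2 µT` the sensor zeroing
bound, 0.5% the calibration error applied to the measured reading, and
`u_grad = |dB/dz| · 1.6 mm` the height-positioning term (1.6 mm is the
midpoint of the evaluated 1.5–1.7 mm range).  The gradient entering
`u_grad` is taken from model-free finite differences of the measured curve
(the steeper of the two intervals adjacent to each height), so the error
bar assumes no decay model; the fitted-model gradient can be substituted
afterwards.  Near the screen `u_grad` dominates; at 55 mm, where fields
are ~10 µT, the zeroing bound dominates.

## Fitting and derived quantities

All three families are fit by unweighted least squares on the original µT
scale (no transformation), with R² = 1 − SSres/SStot reported on that same
scale; a 1/Uc² weighted option exists but is off by default.  The SLC fit
optimizes (r, I) with bounds r ∈ [1, 30] mm and I ∈ [0.05, 200] mA
(rescaled by 5000/µ_r when a different permeability is requested),
starting from r₀ = 8 mm with I₀ chosen to pass through the first curve
point, and up to five deterministic ±50% jitters of r₀ on non-convergence.
Constant curves (SStot = 0) are rejected rather than reported as R² = 1.

Derived per hot spot:

* **B@0** — the closed-form field at z = 0 (reported to 3 significant
  figures in mT);
* **screen gradient** — |dB/dz| at z = 0 (2 significant figures, mT/mm);
* **threshold distance z\*** — the unique z ≥ 0 where |dB/dz| equals the
  0.02 mT/mm neuronal-blockade threshold, solved by bisection (scipy
  `brentq`, 10⁻³ mm tolerance) on [0, 200] mm after verifying the bracket;
  the gradient magnitude has at most one interior maximum (at
  z = r/2 − T/2 when positive) and is monotone beyond it, so a verified
  sign change implies uniqueness.  Reports round z\* to the nearest mm;
* **skull check** — whether both |B| and |dB/dz| still exceed the
  literature thresholds (0.025 mT, 0.02 mT/mm) at 4 mm depth, the
  conservative end of the 3–4 mm temporal-bone range;
* **induced-rate estimate** — B_peak/duration, the order-of-magnitude
  dB/dt transient of bringing the phone to the head, for comparison with
  the 2.7 T/s motion-induced reference level.

## 3D engine and head maps

`loop_field_at_points` discretizes the loop into n straight segments
(default 360) evaluated at their midpoints, `B = µ_r µ0 I/(4π) Σ dl×r/|r|³`.
The midpoint polygon rule converges as ~n⁻²: on-axis error is below 0.1%
at 360 segments and below 10⁻⁵ at 3600 (asserted against the closed
form).  Points within 10⁻⁶ mm of the wire (10⁻³ mm for mesh vertices)
raise a singularity error naming the offending vertex.

Head maps superpose all loops plus an optional uniform geomagnetic vector
(warned outside 25–65 µT, rejected above 100 µT) on the vertices of a
triangulated mesh.  The default pose presses the screen tangent to the
mesh at its maximum-x "ear" vertex with the screen normal pointing into
the head and the phone's length axis along the projection of head-up onto
the tangent plane; the screen point in contact is configurable and is
normally the upper hot spot — in an ongoing call the speaker sits at the
ear.  The bundled head is a synthetic ellipsoid icosphere fixture
(semi-axes 75/95/105 mm by default), a stand-in geometry: head-map results
are therefore qualitative (dynamic range, hot-spot visibility), not
vertex-wise anatomy.

The hypomagnetic-zone search scans |B_total| on a coarse grid (2 mm
default) over a user box, refines each local minimum by bounded
Nelder–Mead to 0.01 mm, and returns deduplicated points with
|B_total| < ε (default 1 µT).  When the background opposes the loop axis
with a magnitude between the on-axis field at the box boundaries, the
axial zero is found at the height where the loop field equals the
background — the closed form inverts to z ≈ 36 mm for the strongest upper
source against 50 µT.

## Synthetic campaigns: what they emulate, and what they do not

The generator produces the full campaign (triplicates at the five heights
plus triplicate ambient maps) from ideal loop sources via the 3D engine,
with four corruption mechanisms mirroring the budget:

| parameter | default | emulates |
|---|---|---|
| `sensor_noise_rms_uT` | 0.1 µT | ambient AC noise floor per axis/reading |
| `zero_offset_bound_uT` | 2 µT | zeroing bias; one uniform draw per axis per dataset |
| `cal_scale_error` | 0.005 | calibration scale; one draw per dataset |
| `z_offset_sd_mm` | 1.6 mm | systematic spacer-stack height error; one Gaussian draw per dataset |
| `z_jitter_sd_mm` | 0.15 mm | residual per-map height scatter |

The split of the 1.5–1.7 mm height uncertainty into a dominant systematic
offset plus a small per-map jitter is deliberate: the measured decay fits
reach R² = 0.996–0.999, which bounds *independent* per-height scatter to
roughly 0.1–0.2 mm (a ~6 µT residual rms against a ~45 µT/mm near-screen
slope), while an i.i.d. 1.6 mm per-map error would make the curves far
rougher than observed and (r, I) practically unidentifiable.  A stack of
machined spacers errs coherently, not independently, per session.

Height errors shift the true evaluation height but never the recorded
nominal z — exactly the mechanism the `u_grad` budget term quantifies.
Because zeroing and calibration draws are per-dataset constants, ambient
subtraction cancels them exactly in simulation; their budget terms are
correspondingly conservative there.  Sensor quantization, temperature
drift, and spacer mechanics are not emulated.  Bit-reproducibility:
identical seed and parameters give identical datasets (sub-seeds are
derived per map from one seed stream).

Passing recovery tests on these campaigns shows the pipeline is unbiased
under this error structure; it does not certify real-magnetometer effects
outside it.

## Sensitivity of the screen extrapolation (known limitation)

B@0 is an extrapolation from z ≥ 15 mm down to 0 and inherits extreme
sensitivity to the systematic height error: a −2 mm offset alone is
absorbed by the fit almost perfectly (R² ≈ 0.99998) while tripling the
extrapolated B@0; +2 mm deflates it by roughly a third.  Single-campaign
screen values are therefore order-of-magnitude estimates; the package's
recovery criterion is accordingly stated on the *median* across repeated
campaigns (within 15% at the default noise), which the test suite
verifies over 50 seeds.  With both magnets present, each curve's 55 mm
tail also picks up a few-percent contribution from the other magnet, so
exact parameter recovery holds only for single-source phones (asserted at
10⁻⁴); two-source recovery is asserted at the cross-talk level.

## Numerical and reporting conventions

Bench units everywhere at the interfaces (µT, mm, mA; mT only where
conventional: B@0, gradients in mT/mm); SI only inside field kernels.
Grid CSVs are y-major, ascending, 6 significant digits, with physical mm
coordinates (node indices never leak into files).  Reports round B@0 to 3
significant figures, gradients to 2, threshold distances to the nearest
mm.  All constants live in the study config with the defaults above;
stages never hard-code them.
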