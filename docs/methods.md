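# Methods

## The problem and the model

High-NA objectives form a diffraction-limited focus only in the geometry they
were designed for. Focusing into the lumen of a glass capillary — the
geometry of lumen-based organ-on-a-chip devices — sends every ray through two
curved glass interfaces, producing tens of radians of wavefront error,
dominated by astigmatism. Nonlinear (e.g. two-photon) microscopy cannot
recover this in post-processing: the signal is generated by the focal
intensity itself.

`tubeao` computes the correction a priori, from geometry alone. The sample is
a *digital twin*: two infinite coaxial cylinders (outer radius, shell
thickness, shell index) filled and surrounded by media of known index, with
the tube axis in the x–y plane at a configurable rotation about the optical
axis. The optical axis is +z, pointing from the objective into the sample;
all lengths are µm, angles rad.

A virtual point source is placed at the desired focus inside the lumen. A fan
of rays covering the objective's acceptance cone is traced out through both
cylinder surfaces — vectorial Snell refraction at each interface, optical
pathlength (OPL) accumulated as geometric length × local index — and then
through an idealised Abbe-sine objective onto the virtual SLM plane. The
correction is the phase conjugate of the accumulated pathlength error,

    phi(x, y) = -k0 · OPL(x, y),        k0 = 2π/λ.

### The ideal objective

Rather than modelling lens internals, the objective is the Abbe-sine mapping
r/R = n·sin(θ)/NA between exit-ray angle and normalised pupil radius
(azimuth preserved), plus an OPL reference: for a ray at exit point P with
direction d, the pathlength difference against the design ray of equal angle
from the nominal focus F is

    OPD = OPL_accumulated − n_outside · (P − F) · d,

the far-field limit of referencing against a sphere centred on F. An
unaberrated point source at F gives identically zero OPD at every pupil
position, which the test suite asserts to 1e-9 µm. Rays that suffer total
internal reflection or leave the acceptance cone are masked dead, never
extrapolated; all downstream sums run over valid pixels only.

### Sampling and rasterisation

The fan samples the cone uniformly in pupil area on a Fibonacci
(golden-angle) spiral — deterministic, seed-free, and well conditioned for
triangulation at the pupil rim. The default budget is 250,000 rays on a
512×512 SLM raster with the pupil inscribed in the grid. Scattered per-ray
OPD samples are rasterised by piecewise-linear interpolation on their
Delaunay triangulation (`scipy.spatial`); pixels outside the convex hull
carry a validity mask. Unit tests verify exact reproduction of linear
fields and convergence on smooth fields under refinement.

### Defocus and tilt removal

The raw pattern contains a large defocus term that an SLM should not carry
(steep gradients degrade diffraction efficiency) and that a stage translation
removes for free. Following the same logic as the experimental procedure,
the virtual objective is translated along the optical axis to minimise the
mean squared finite-difference phase gradient over valid pixels. The
translation enters the traced scene only through the OPL reference — ray
trajectories and pupil positions are unchanged — so the trace and
triangulation are cached and each translation is a cheap re-projection.

The 1-D search uses AMSGrad (lr 0.5 µm, β1 = 0.9, β2 = 0.999, ≤500
iterations, stop at |Δ| < 1 nm) with central finite-difference gradients,
followed by a few exact parabolic-vertex steps: the objective is locally
quadratic in the translation, and plain first-order descent stalls a few
hundredths of a µm short of the vertex, which would leave a spurious
residual defocus. A flat valley is tie-broken toward zero translation.
Tests verify that a pure source displacement is recovered exactly, that the
procedure is idempotent, and that the residual axial-defocus component of
the capillary patterns stays below one wavelength.

Tilt (a linear phase; shifts the image without degrading it) is removed by
subtracting the mean finite-difference phase gradient over valid pixels,
which equals the rays' average tilt for a fan sampled uniformly in pupil
area and leaves a residual mean gradient of exactly zero.

Phase is stored unwrapped; wrapping to [0, 2π) is a display view applied
only at PNG export.

## Sensitivity metric

Two patterns are compared by the overlap coefficient

    γ = Σ_xy A² exp(i(φ2 + φd − φ1)),     0 ≤ |γ|² ≤ 1,

with A the measured-beam Gaussian amplitude (waist 1.18 pupil radii,
normalised to unit power over the contributing pixels) and φd the axial
defocus phase

    φd = z_d · k0 · sqrt(n² − (r·NA/R)²)

scanned over z_d (default ±20 µm, 401 samples, one parabolic refinement) to
absorb focus-shift mismatch. |γ|² is the fraction of pupil energy in the
corrected mode — the Strehl ratio of the resulting focus. Property tests pin
the Cauchy–Schwarz bound, piston invariance, the swap symmetry
(φ1 ↔ φ2, z_d → −z_d) and the Maréchal regime |γ|² ≈ exp(−σ²) within 2% for
weak aberrations.

The sensitivity sweep perturbs one tube parameter at a time (outer radius,
shell thickness, shell index, axis rotation), recomputes the full pattern
and evaluates |γ|² against the nominal pattern; non-physical values yield
flagged NaN entries.

## Zernike decomposition and the sensorless-AO baseline

Patterns are decomposed by unweighted least squares over valid pixels onto
Zernike modes up to radial order 8 (default). Modes are stored unit-RMS
(orthonormal, ANSI (n, m) indexing); published amplitude tables often use
the unit-peak convention (radial part 1 at the rim), and the exact
convention behind the reference amplitudes is not recoverable, so
coefficients convert between the two via the factor sqrt(2(n+1)) (m ≠ 0)
and the acceptance comparison accepts either scale. When ranking modes,
piston, tilt and defocus (2, 0) are excluded by default: they are removable
by stage/objective motion and carry no aberration content.

The sensorless-AO baseline reproduces an exhaustive experimental search on
the digital twin: the feedback signal is the defocus-optimised |γ|² of a
candidate two-mode pattern against the ray-traced truth (monotone in focus
quality, maximal iff the candidate matches up to piston/defocus). A
brute-force Cartesian grid (21×21 default) over the two dominant mode
amplitudes is interpolated bicubically to locate the continuous optimum;
because a bicubic surface overshoots near a sharp peak, the interpolated
optimum is kept only if one verification measurement there beats the best
node. Boundary optima are flagged. Rotation alignment scans rigid rotations
of a pattern against the same feedback; on a twin whose tube is rotated the
scene rotates rigidly, so the calibration recovers the angle to well under
0.1°.

## Contrast metric

Image improvement is quantified by correlation disattenuation:

    η_σ = sqrt((σ²_corrected − σ²_background) / (σ²_uncorrected − σ²_background)),

with variances over (sub)stacks and the background variance taken from a
measurement with no signal present, assuming additive noise uncorrelated
with the signal. A non-positive denominator is flagged undefined, never
clipped. Percentile projections (e.g. 99.5) are provided for visualising
stacks.

## Synthetic data

* `capillary_scene` is the nominal study tube: outer radius 286.5 ± 1.5 µm,
  shell 215.5 ± 1.6 µm (inner diameter 142 µm), shell index 1.5106 ± 0.0005,
  with presets Top/Centre/Bottom/Side placed 5 µm inside the inner wall
  (configurable — the exact experimental focus coordinates are not
  published). The instrument (NA, wavelength, immersion) describes the
  microscope, not the sample, and must be supplied explicitly. The test
  suite and the acceptance script fix a reference instrument chosen a
  priori as typical for two-photon imaging of such samples: water-dipping
  objective, NA 0.8, vacuum wavelength 0.804 µm, n = 1.33 for lumen and
  immersion.
* `slab_scene` realises the plane-parallel-plate limit (outer radius 2×10⁸
  µm at fixed shell thickness) together with a closed-form OPD oracle
  derived independently from 2-D trigonometry; the tracer matches it to
  better than 1e-6 µm, which exercises the numerically stable ray–cylinder
  quadratic.
* `synth_stack` plants exact signal variances in bead-like stacks plus
  independent Gaussian noise, so the contrast metric's recovery can be
  checked against ground truth (within 5% at 74×64×64 voxels).

What the synthetic scenes do *not* emulate: the microscope slide under the
tube, polarisation and Fresnel amplitude losses, diffraction, photon noise,
and image formation of the scanning microscope. Passing tests therefore
validate the geometric-optics correction model and its metrics, not
experimental image quality.

## Numerical choices and limitations

* Rays refract at the inner then the outer cylinder; re-entrant paths
  (possible only for exotic index orderings) are not followed.
* The ray–cylinder intersection uses the cancellation-safe quadratic
  (q = −(b + sign(b)√disc)/2) so the slab limit holds at radii of 10⁸ µm.
* Problem sizes: unit tests run at 5,000–30,000 rays on 64–128 pixel
  rasters; the acceptance checks run the full 250,000 rays on 512×512,
  matching the pattern-computation conditions of the study.
* Degenerate inputs: collinear pupil samples, sources outside the lumen,
  empty projection axes and ill-conditioned Zernike fits raise; dead rays
  and non-physical sweep values are masked/flagged, never silently fixed.
* The published model-derived amplitudes depend on the (unpublished)
  instrument parameters; with the reference instrument above the pattern
  structure (astigmatism dominance, mode identities and signs, symmetry,
  sensitivity floors, flat-pattern overlap ≈ 0.05) reproduces closely,
  while individual amplitudes differ by up to ~20%.
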