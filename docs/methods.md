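# Methods

`holoshear` re-implements, end to end, the analysis chain used to study
preferential particle orientation in stratified oceanic shear: in-line
holographic imaging of the particle field, per-particle morphometry and
orientation, depth-resolved statistics, turbulence and stratification
diagnostics from co-located point measurements, and the Jeffery model of
spheroid rotation that the measured orientation PDFs are compared against.
Because the original field data (holograms, velocimeter and CTD records)
are not publicly deposited, every stage is validated against ground-truthed
synthetic data generated under the study's own conditions.

## Imaging model and reconstruction

The instrument is collimated in-line holography: a 660 nm plane wave
crosses a 4 cm sample path and a 2048×2048 sensor at 4.59 μm/pixel records
the interference between the undisturbed beam and light diffracted by
particles (3.53 mL per frame). Numerical refocusing uses the
angular-spectrum propagator — the exact scalar solution, which reduces to
Fresnel propagation in the paraxial regime and remains valid over the whole
path. Frames are refocused in 500 μm steps; the 2.5 mm adjacent to each
sampling window is excluded (window boundary layers), leaving 70 planes.

Synthetic holograms render particles as opaque amplitude silhouettes:
the unit field is propagated plane to plane, masked at each particle, and
propagated to the sensor; Gaussian sensor noise and an optional vignette
are added, and the frame is normalised to [0, 1]. Phase objects, Mie
scattering and bubbles are out of scope. Reconstruction back-propagates
the recorded (real) intensity; the twin image and the quadratic intensity
term are not suppressed, exactly as in the original processing.

## Focus consolidation

Each reconstructed stack collapses to one composite image by choosing, per
128×128 sub-window, the plane with the sharpest in-focus content, plus a
per-pixel minimum-intensity fallback mode. The selection criterion is the
count of sub-threshold (dark) pixels weighted by Tenengrad (squared-Sobel)
edge energy, with a per-window threshold `dark_w + 0.1 (median − dark_w)`.
Two numerical findings drove this choice, both reproducible with the
package's own simulators:

- dispersion-based thresholds (e.g. mean − 3 robust SD) sit inside the
  long non-Gaussian fringe tail of reconstructed backgrounds and flood the
  count with background pixels;
- an elongated opaque particle casts a *dark shadow column* toward the
  sensor that stays as dark as the focused silhouette over many planes, so
  darkness alone selects defocused planes; only the focused plane has
  sharp edges, which the gradient weighting rewards.

Per-particle axial depth is likewise the argmax of Tenengrad energy over
the region's own pixels. On 200 seeded synthetic particles (250–450 μm,
aspect 3–8) this recovers depth within one 500 μm plane for 100% and
orientation within 1° for ~98%; intensity-minimum criteria managed 65–92%.

## Segmentation and morphometry

Composites are smoothed with a 2×2 box filter (the smallest
mean-preserving low-pass) and thresholded at 0.4× the image median —
particle silhouettes are near zero, the background defines the median, and
a fraction-of-background cut is immune to the extreme class imbalance that
defeats bimodal-histogram rules on sparse scenes. 8-connected components
of at least 5 pixels (105 μm², equivalent diameter 11.6 μm) count as
particles. Interior holes are filled before computing the area used for
the equivalent spherical diameter D = √(4A/π).

Diatom chains segment into discrete cells; cells whose boundary gap is
within 30 μm (configurable) are merged transitively (union-find).
Re-connection is restricted to *solidly dark* regions (min intensity
≤ 0.05× median): residual diffraction-fringe fragments hover just below
the segmentation threshold and must not be absorbed into a neighbouring
particle. Small low-contrast blobs within 200 μm of a ≥5×-larger dark
region are discarded entirely as fringe satellites of that particle.

The major axis is the particle-extrema line (farthest boundary-pixel
pair). Its *angle* is refined by iterated tip-cap centroids: the centroid
of the pixels in a cap at each end lies on the symmetry axis, giving
sub-pixel tip localisation (≤0.35° error at 65 px length, versus ~1.4° for
the raw farthest pair). The minor axis is the maximal extent perpendicular
to the major axis (+0.5 px pixel-extent correction); the aspect ratio is
their quotient. Orientation is measured from the image horizontal,
positive for positive slope with a bottom-left origin, and the platform's
tilt-sensor pitch is subtracted before any statistics. Slightly curved
chains whose skeleton geodesic exceeds the chord by >10% are flagged, but
the straight-line length is retained.

Overlapping particles are detected by the convex-hull-to-filled-area ratio
(threshold 1.5, configurable). Flagged regions are examined along depth:
two prominent minima of the region-mean intensity profile at distinct
planes split the region (each pixel assigned to the depth at which it is
darker); a single minimum discards both candidates.

## Flow diagnostics

Dissipation is estimated from the vertical-velocity frequency spectrum
(Welch, Hann, 256-sample segments, 50% overlap; at least 256 samples per
3 m depth bin) by fitting the inertial subrange under the
frozen-turbulence mapping κ = 2πf/U. The spectrum convention is
S(f) = C ε^{2/3} κ(f)^{−5/3} with C = 0.65 (vertical) or 0.49
(horizontal); the estimator is its exact algebraic inverse,
ε = [S f^{5/3}/C]^{3/2} (2π/U)^{5/2}, averaged over the fit band (default:
the upper 40% of frequencies below Nyquist/1.5). Fits whose log-log slope
deviates from −5/3 by more than 0.3 are rejected rather than reported.
The synthetic velocity generator builds series by Fourier synthesis with
model-spectrum amplitudes and random phases, so generator and estimator
close an exact loop on noiseless spectra and a ~±30% loop (median over
seeds) on 60 s casts — 960 samples, the length a 3 m bin yields at the
instrument's 5 cm/s descent.

Microscales follow the closed forms η = (ν³/ε)^{1/4} and
λB = (ν D²/ε)^{1/4} (ν = 1.1×10⁻⁶ m²/s, D = 10⁻⁹ m²/s); note λB/η =
√(D/ν) identically. N² is computed from σT profiles by centred differences
with depth positive down; Ri = N²/S² with S² from centred differences of
bin-mean horizontal velocities, flagged undefined at zero shear and stable
at Ri ≥ 0.25.

A caveat on Parseval: Welch with 256-sample segments cannot represent
power below the segment-length frequency, so for steep −5/3 spectra the
integral of S(f) understates the series variance. The identity is exact
(within 5%) for signals whose power is resolved within a segment, which is
how the test suite checks it (white noise).

## Particle statistics

Concentration is Pv = P/(nV) per 20 cm depth bin. Cast subsampling uses
every third hologram descending and every second ascending, because the
per-frame platform displacement (3.3–4.0 mm at 15 Hz and 5–6 cm/s) times
three exceeds the 9.4 mm field of view. Size spectra use 24 logarithmic
bins over 11.6–1000 μm, nondimensionalised by bin width and volume; Junge
slopes are least-squares fits of log n(D) vs log D over occupied bins,
optionally segmented at a 250 μm knee. Orientation PDFs use nine 20° bins
over (−90°, +90°], particles with r > 3 only, normalised per degree within
each depth bin; bins with fewer than 30 particles are flagged, since a
couple of stray particles can fabricate an orientation peak.

## Jeffery model

A spheroid of aspect ratio r in constant shear S rotates with
ω(θ) = S/(r²+1)·(r² sin²θ + cos²θ), period T = (2π/S)(r + 1/r). The model
orientation PDF is the occupancy time per angle bin over one period,
computed by fixed-step RK4 (dt = T/n_steps, default n_steps = 10,000, dt
coarser than T/1000 refused) with each step's duration distributed across
bin boundaries by linear interpolation, making the histogram second-order
accurate. It matches the closed-form occupancy density ∝ 1/ω(θ) — bin
probability [atan(r tan b) − atan(r tan a)]/π — to better than 0.5% per
bin, is exactly uniform (1/180 per degree) at r = 1, and is independent of
S and of the initial angle. The closed-form orbit used as the oracle is
tan θ(t) = tan(2πt/T)/r, the parametrisation whose derivative reproduces
ω (slow at θ = 0, fast at ±90°). Model assumptions (rotational Péclet ≫ 1,
negligible inertia and interactions, particle Reynolds ≪ 1) are documented
constraints, not runtime checks.

The projection of a 3D orientation (θp from vertical, azimuth θa about the
vertical) onto the image plane is θ = atan(cot θp / cos θa). The
"uniform3D" generator draws both angles uniformly — the convention under
which random orientations project with excess density at ±90°, so measured
horizontal-alignment PDFs are lower bounds. A truly isotropic axis
distribution (also provided, as `isotropic`) projects to a *flat* angle
PDF; the distinction matters and is tested.

## Synthetic study conditions and their limits

Scene defaults: 20 particles/mL, Junge exponent 1.8 over 30–300 μm
equivalent diameter, aspect ratios log-uniform in [2, 8], Poisson counts,
particles fully inside the volume; chains are k ∈ [3, 7] collinear cells
with ≤2 px gaps, restricted to particles ≥150 μm. Round-trip studies use a
512×512 sensor at the instrument's pixel pitch (2.35 mm field) with the
full 4 cm path and all 70 planes — the physics per particle is unchanged;
only the field of view is smaller. Sizes in those studies are 250–450 μm
so that the ±1° orientation target is meaningful against pixel
quantisation (~0.9° at 65 px).

What the generator does not emulate: phase/semi-transparent particles,
polydisperse shapes beyond ellipses and chains, particle motion within an
exposure, camera nonlinearity, and real oceanic background (Schlieren,
large out-of-volume scatterers). Passing round trips therefore demonstrate
the correctness and internal consistency of the processing chain, not
field-grade detection performance; on real data the segmentation
threshold, chain gap and hull-ratio threshold would need calibration.

Known limitations: circular particles near the sensor have mm-scale
geometric depth of field and can localise 1–2 planes off; very dense
scenes (several particles per mm² of sensor) produce fringe speckle that
survives satellite suppression and inflates counts by a few percent;
upcast wake turbulence and IMU bias-drift correction of the velocimeter
are out of scope.
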