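# holoshear

Do suspended particles in the ocean align with the flow? Elongated
particles — diatom chains above all — rotating in laminar shear spend most
of each Jeffery orbit aligned with the flow direction, which biases optical
backscatter and light harvesting. Testing this in the field takes an
in-line holographic imager (3D particle positions, sizes and orientations
in an undisturbed volume) profiled together with a point velocimeter and a
CTD. `holoshear` is a complete, tested re-implementation of that analysis
chain for researchers in ocean optics, plankton ecology and small-scale
turbulence:

- **synthetic data** — ground-truthed particle scenes, in-line holograms
  (angular-spectrum diffraction of opaque silhouettes), velocity series
  with a κ^−5/3 inertial subrange of known dissipation rate ε, two-layer
  density profiles;
- **holography** — ensemble background subtraction, numerical refocusing
  in 500 μm steps (70 planes over the 4 cm path), per-sub-window focus
  consolidation into a composite image;
- **particle metrics** — segmentation (≥5 px), chain re-connection,
  filled-area equivalent diameter D = √(4A/π), extrema-line major axis,
  aspect ratio r, pitch-corrected orientation θ ∈ (−90°, +90°];
- **flow analysis** — Welch spectra, inertial-subrange dissipation
  ε = [S(f) f^{5/3}/C]^{3/2} (2π/U)^{5/2} under Taylor's frozen-turbulence
  mapping κ = 2πf/U, Kolmogorov η = (ν³/ε)^{1/4} and Batchelor
  λ_B = (νD²/ε)^{1/4} scales, shear, N², Richardson number Ri = N²/S²;
- **particle statistics** — concentration Pv = P/(nV) in 20 cm bins,
  aspect-ratio breakdowns, log-binned size spectra with segmented Junge
  slopes n(D) = n₀(D/D₀)^−γ, depth-resolved orientation PDFs (nine 20°
  bins, r > 3);
- **Jeffery model** — ω(θ) = S/(r²+1)·(r² sin²θ + cos²θ),
  T = (2π/S)(r + 1/r), and occupancy-time orientation PDFs for comparison
  with the measurements.

See `docs/methods.md` for the model details and design choices.

## Worked example

The numbered scripts under `analysis/` run a miniature simulated campaign
(tables under `results/`, hologram TIFFs under `scratch/`):

```sh
python analysis/01_simulate_campaign.py 1   # scenes, holograms, ADV + CTD casts
python analysis/02_process_holograms.py     # reconstruct + measure particles
python analysis/03_flow_diagnostics.py      # spectra, epsilon, Ri per 3 m bin
python analysis/04_particle_statistics.py   # concentration, PSD, orientation
python analysis/05_jeffery_comparison.py    # model PDFs vs measurement
```

Output of the run checked into `results/` (seed 1):

```
simulated 24 holograms, 119 particles
122 particles from 24 holograms -> results/particles.csv
chains re-connected: 10; unresolvable overlaps discarded: 0

median recovered epsilon: 1.1e-07 m^2 s^-3 (true 1e-07); eta 1.82-1.92 mm
122 particles; mean concentration 23.0 per mL
Junge slope 50-250 um: 1.84 (9 bins; small-sample estimate from 122 particles)
thin-layer orientation PDF peaks at +0 deg (pdf 0.0167 per deg)

thin layer, central bin: measured 0.0167 vs model 0.0259 per degree
```

Reading this: the hologram round trip recovers the simulated particle
population (122 measured vs 119 generated); the dissipation fit lands
within 10% of the true ε = 10⁻⁷ m² s⁻³, giving millimetre-scale Kolmogorov
eddies — so most particles experience laminar shear; the size spectrum
returns the generating Junge exponent (γ = 1.8); and the pycnocline layer,
populated with shear-aligned particles, shows an orientation PDF peaked at
the horizontal, below the single-aspect-ratio Jeffery curve because the
measured population mixes aspect ratios and projections.

## Library use

```python
from holoshear import (OpticalConfig, SceneConfig, make_scene,
                       render_hologram, Hologram, process_hologram)

optics = OpticalConfig(sensor_px=(512, 512))       # 2.35 mm field of view
scene = make_scene(SceneConfig(seed=1), optics)    # ground-truthed particles
frame = render_hologram(scene, optics, noise_sd=0.005, seed=1)
result = process_hologram(Hologram(intensity=frame), optics)
for p in result.records:
    print(f"D = {p.equiv_diam_um:.0f} um, r = {p.aspect_ratio:.1f}, "
          f"theta = {p.theta_deg:+.1f} deg at z = {p.z_mm:.2f} mm")
```

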