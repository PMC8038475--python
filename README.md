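# fringeftp

Simulate-and-reconstruct toolkit for laser-based structured-light surface
measurement of biological targets (faces, skin-like phantoms) with one-shot
**Fourier transform profilometry (FTP)**.

Conventional fringe projectors (DLP) emit broadband, unpolarized light and
suffer gamma distortion, which rules out optical tricks against ambient light
and subsurface scatter. A monochromatic projector built from a 532 nm laser, a
binary grating, a Fourier lens and a ±1-order spatial filter produces a *truly
sinusoidal*, linearly polarized fringe pattern — so a 10 nm bandpass filter can
reject background illumination and an analysing polarizer can reject the
depolarized photons that multiply scatter below the skin surface. A single
camera frame then suffices to reconstruct the 3-D surface.

This package implements the whole measurement numerically:

- **`fringeftp.optics`** — scalar Fresnel diffraction simulation of the
  projector train (point source → grating → lens → spatial filter →
  observation plane), plus the closed-form result: field
  `U(x₃) ∝ circ(2f|x₃|/(H·Z₃)) · cos(2π f x₃/(d·Z₃))`, i.e. intensity fringes
  of frequency `2f/(d·Z₃)` inside a spot of radius `H·Z₃/(2f)`.
- **`fringeftp.scene`** — synthetic ground-truth surfaces (spherical-cap
  phantom with closed-form geometry; seeded face-like phantom) and a
  photometric renderer with the three-component reflectance model
  (polarized direct reflection, Gaussian-blurred subsurface scatter,
  broadband background), bandpass filter, polarizer, fixed exposure with
  saturation, and shot + read noise.
- **`fringeftp.ftp`** — one-shot FTP: carrier estimation, Hann-window
  sideband isolation, quality-guided 2-D phase unwrapping, and
  phase-to-height conversion `h = L·Δφ / (Δφ − 2π f₀ D)` for the
  crossed-optical-axes triangulation geometry (camera distance `L`,
  projector baseline `D`, carrier `f₀`).
- **`fringeftp.evaluate`** — Michelson contrast, offset-free height RMSE,
  and the experiment matrix over carrier frequency × background illuminance
  × filter/polarizer × static/dynamic, graded High/Moderate/Low/Unable.
- **`fringeftp.io` / CLI** — YAML configs, checksummed artifact manifests,
  and the `fringeftp` command (`simulate`, `render`, `reconstruct`,
  `evaluate`).

## Worked example

```python
from fringeftp import (
    OpticalSetup, GridSpec, simulate_fringe_numeric, measure_fringe_frequency,
    michelson_contrast, ProjectionGeometry, PhotometricScene, CameraModel,
    make_spherical_cap, render_frame, reconstruct, surface_rmse,
)

setup = OpticalSetup()          # 532 nm, 50 lp/mm grating, f = 150 mm, Z3 = 3 m
pattern = simulate_fringe_numeric(setup, GridSpec())
print(f"fringe frequency : {measure_fringe_frequency(pattern):.3f} cycles/mm")
print(f"fringe contrast  : {michelson_contrast(pattern.intensity, pattern.spot_mask(0.5)):.3f}")

geom = ProjectionGeometry(L=1000, D=300, f0=1.0)
cap = make_spherical_cap(base_radius=40, cap_height=10, pitch=0.25)
scene = PhotometricScene(direct_albedo=0.5, scatter_fraction=0.0)
camera = CameraModel(photon_fullwell=None, read_noise=0.0)
frame = render_frame(cap, geom, scene, camera, seed=0)
result = reconstruct(frame.image, frame.pitch, geom)
rmse_mm, rmse_pct = surface_rmse(result.surface, cap)
print(f"cap height RMSE  : {rmse_mm:.4f} mm ({rmse_pct:.2f}% of the 10 mm apex)")
```

prints

```
fringe frequency : 5.000 cycles/mm
fringe contrast  : 1.000
cap height RMSE  : 0.0155 mm (0.15% of the 10 mm apex)
```

The simulated projector at a 3 m throw produces 5.0 cycles/mm fringes of unit
Michelson contrast — the diffraction chain agrees with the analytic two-beam
prediction — and the one-shot reconstruction recovers the 10 mm silicone-cap
phantom to 15 µm RMS in the clean limit.

The same pipeline is available from the shell:

```sh
fringeftp simulate --mode both --out out/sim
fringeftp render   --seed 3 --out out/render
fringeftp reconstruct out/render/frame.npz --out out/recon
fringeftp evaluate --seed 1 --out out/matrix
```

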