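# Methods

## The measurement being simulated

A monochromatic fringe projector is modelled as a four-plane optical train:
a point laser source (λ = 532 nm) at distance `Z0` illuminates a binary
rectangular grating (period `d` = 0.02 mm, i.e. 50 lp/mm; open-slit width
`a`, duty `a/d` = 0.5) over a circular spot of diameter `H` = 2 mm; a
positive lens of focal length `f` = 150 mm sits at `Z1` beyond the grating;
an adjustable spatial-frequency filter of two slits (width 0.5 mm, standing
in for the instrument's V-shaped aperture whose effective slit width varies
with insertion depth) at `Z2`; and the observation plane at throw `Z3`.
In the ideal layout — grating at the front focal plane (`Z1 = f`), filter at
the back focal plane (`Z2 = f`), collimated illumination — the filter sees
the grating orders as sharp sinc(am/d)-weighted Airy-type lobes at positions
`m·λf/d`, and passing only the ±1 orders leaves two parallel beams that
diverge from their focal spots and interfere at `Z3` as a pure two-beam
pattern: intensity `cos²` fringes of frequency `2f/(d·Z3)` cycles/mm inside
a circle of radius `H·Z3/(2f)`, with Michelson contrast exactly 1 on a dark
background. The throw distance alone tunes the projected frequency
(frequency × Z3 = 2f/d is invariant), which is how the 0.3 and 1.0 lp/mm
operating points are realised.

Geometry notes discovered the hard way and worth stating: the front-focal
placement of the grating is not cosmetic. For `Z1 ≠ f` each diffraction
order leaves the lens with residual tilt `±(λ/d)(1 − Z1/f)`; at metre-scale
throws the two beams walk apart laterally and stop overlapping, and no
fringe pattern forms. Similarly the source stand-off `Z0` must be large
(default 10⁵ mm, an effectively collimated beam) or the orders focus beyond
the filter plane and the closed form degrades; `OpticalSetup` exposes a
`fourier_plane_condition` flag recording whether the closed form applies.

## Numerical diffraction

Fields are complex grids with physical pitch. Two discrete Fresnel
propagators are implemented and selected automatically by the standard
crossover `z_c = N·pitch²/λ`:

* transfer-function (angular-spectrum) method for `z ≤ z_c` — exactly
  unitary, pitch-preserving, used for the lens→filter hop;
* single-FFT Fresnel scaling method for `z ≥ z_c` — output pitch
  `λz/(N·pitch)`, used for the grating→lens and filter→observation hops
  where the transfer-function kernel would alias.

Requesting a method outside its validity range raises a `SamplingError`
naming the maximal (or minimal) safe distance. The default grid is 4096²
with grating-plane pitch `max(d/16, 2.5H/N)`: 16 samples per grating period
and the laser spot within 40% of the grid extent. At 8 samples per period
the sampled carrier acquires a slow phase drift that caps the agreement with
the closed form near 0.974; at 16 it reaches 0.993–0.999. Grating edge
pixels are area-weighted (gray) so the sampled duty cycle equals `a/d`
exactly — with hard edges the even diffraction orders are only ~10⁻³
suppressed instead of ~10⁻⁴. A full chain run takes ~25 s per throw setting
on one CPU.

Known, accepted imperfections of the numeric route: the hard-edged filter
slits truncate the Airy ringing of the order lobes, leaving a few percent of
envelope ripple in each beam (so a single-slit pattern is "flat" only up to
~6–8% ripple; the meaningful flatness statement, asserted in tests, is the
absence of carrier-frequency modulation) and passing ~5% less power than
the ideal Fourier-series value `2(1/π)²` of the incident light.

## Triangulation and rendering model

The camera is telecentric and near-axis with the standard crossed-optical-axes
geometry: reference-plane distance `L` = 1000 mm, projector baseline
`D` = 300 mm, carrier `f0` on the reference plane. A point at height `h`
displaces the observed carrier by `u = D·h/(L−h)`, i.e. phase
`Δφ = −2π f0 D h/(L−h)`; the reconstructor inverts this exactly. The
renderer does not reuse the phase formula: it samples the projected pattern
at the displaced coordinate `x − u`, which reduces to the same phase for the
analytic carrier and is validated against a brute-force projector-ray
intersection in the tests. A simulated `FringePattern` can replace the
analytic carrier; it is coordinate-stretched so its carrier lands on `f0`
(magnifying its spot by the same factor) and cubically interpolated.

Measured irradiance is a three-component sum, in units of the boosted
projector's fringe-crest irradiance:

| component | model | polarization | bandpass gain |
|---|---|---|---|
| direct | albedo × projected pattern | linear, projector angle | 1 (laser line) |
| subsurface scatter | `scatter_fraction` × Gaussian blur (σ = 2.5 mm, the green-light skin penetration scale) | unpolarized | 1 (laser line) |
| background | κ × illuminance, κ = 1/200 per Lux | unpolarized | fwhm/band = 10/300 when on |

An ideal co-aligned polarizer passes the direct component at
`cos²(angle)` = 1 and unpolarized light at exactly ½. Defaults:
`direct_albedo` 0.1 (skin reflects only a few percent to tens of percent of
the laser line directly), `scatter_fraction` 0.5, and projector power 0.2
for the 0.3 lp/mm series versus 1.0 for the boosted 1.0 lp/mm series. The
κ anchor (200 Lux ⇔ background equals the boosted fringe crest) is a
declared calibration: absolute radiometry is not recoverable from desk
parameters.

The camera applies a *fixed exposure*, auto-set once on the projector-only
scene with 1.25× headroom. This is the mechanism that makes strong ambient
light genuinely destructive: with the filter off, a 200 Lux-equivalent
background is several times full scale, the sensor saturates, the fringes
vanish, and carrier detection fails — matching the "fringes completely
buried" regime. With a spatially uniform background and unlimited dynamic
range, band-pass FTP would otherwise shrug off arbitrary DC offsets, which
is unrealistically forgiving. Shot noise is `sqrt(I/fullwell)` (default
full well 10⁴ at full scale) plus additive read noise (3×10⁻⁴); noise is
seeded and frames are bit-reproducible from (config, seed).

## Synthetic surfaces

* **Spherical cap** (silicone-phantom stand-in): base radius 40 mm, apex
  10 mm, parent sphere `R = (r²+h²)/(2h)` = 85 mm; closed-form mean height
  versus grid mean is a generator test.
* **Face phantom** (synthetic, seeded): a sum of Gaussian features (skull
  dome, nose ridge and tip, cheeks, brow, chin) jittered by seed, under a
  super-Gaussian facial window so the relief meets the reference plane
  smoothly; peak ≈ 25 mm over ≈ 150 mm. Feature slopes keep the modulated
  carrier's instantaneous frequency within ±f0/3 of the carrier at both
  operating points — a surface outside that band is not reconstructible by
  one-shot FTP by construction, not by implementation defect. A seeded
  skin-albedo texture (mean 0.1, smooth blotches plus darker patches) and a
  rigid in-plane motion sequence (±4 mm shifts, ±2° rotations; one-shot
  reconstruction sees each frame independently) complete the scene
  generator. What the generator does *not* emulate: perspective distortion,
  shadowing/occlusion, specular highlights, spatially varying ambient
  light, and real skin BRDF — so passing matrix grades show the *optical
  mechanisms* (filtering, polarization gating, carrier choice) behave as
  claimed, not that a specific clinical accuracy would be met on real faces.

## Reconstruction

One-shot FTP: 2-D FFT; carrier located as the strongest non-DC peak
(half-plane search, DC exclusion 0.15 cycles/mm, sub-bin centroid; the peak
must exceed 3× the 99th-percentile spectral floor — a median-based floor
would false-trigger on pure noise); Hann window of half-width `f0/2` along
and across the carrier (window touching DC is an error); inverse FFT to the
analytic image whose magnitude (≈ b/2) is the quality map; carrier-ramp
subtraction; quality-guided flood-fill unwrapping (binary heap, decreasing
amplitude, index tie-breaks, low-quality pixels masked at 5% of the median,
Itoh row-wise fallback available; the unwrapped map is wrapped + 2πk with
integer k so re-wrapping is exact); global offset fixed by zeroing the
median phase over the border ring (reference plane by convention, a
reference frame may be subtracted instead); then the exact phase-to-height
inverse with pixels masked where the denominator vanishes. Residue density
above 10% warns and masks. The in-package unwrapper is cross-checked against
scikit-image's reliability-sorted implementation in the tests.

## Evaluation

Michelson contrast uses 1st/99th-percentile extrema. Height RMSE removes
the global offset implied by the reference convention and reports mm and %
of the truth peak. Grades are fixed declared conventions: High ≤ 5%,
Moderate ≤ 10%, Low ≤ 25% of peak height, else Unable (reconstruction
failures count as Unable); a dynamic cell's grade is its worst frame. The
experiment matrix crosses {0.3, 1.0 lp/mm} × {0, 50, 175, 200 Lux-eq} ×
{filter+polarizer on/off} × {static, dynamic} on the face phantom at
0.25 mm/px over 192 mm. Robust reproduced structure: unfiltered strong
background → Unable (saturation); all filtered 1.0 lp/mm cells → High
(~0.1% RMSE), static and dynamic; and a ~50× RMSE advantage of 1.0 over
0.3 lp/mm (band-width limited detail). The finer Moderate/Low labels of the
low-frequency column depend on the phantom's high-frequency content and are
reported but not asserted.

## Reproducibility and problem sizes

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`). The acceptance script runs the diffraction
chain at 4096² for three throws (3, 6, 12 m), the cap recovery at 480², and
eight matrix cells at 768² (five frames for the dynamic cell), finishing in
about two minutes; the full test suite runs in about the same.

## Limitations

Scalar paraxial diffraction only (no polarization-resolved vector fields,
aberrations, speckle or temporal coherence); ideal polarizer (a finite
extinction ratio is not modelled); top-hat spectral filter against a flat
background spectrum; orthographic rendering; no radiative-transfer model of
subsurface scatter (a lateral Gaussian kernel stands in); phase unwrapping
assumes a mostly connected, residue-sparse field, as FTP requires.
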