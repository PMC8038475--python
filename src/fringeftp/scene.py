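"""Synthetic measurement scenes: ground-truth surfaces and rendered frames.

This module is the package's synthetic-data generator.  It produces

* ground-truth heightmaps — a silicone-like spherical cap with closed-form
  geometry and a procedural face-like phantom, both on uniform mm grids;
* single-shot camera frames of the projected fringes under a
  three-component photometric model: the directly reflected (linearly
  polarized) fringe signal, the multiply-scattered (depolarized)
  subsurface component modelled as a lateral Gaussian blur, and a
  broadband unpolarized background;
* the camera: a 532 nm / 10 nm-FWHM bandpass filter, an ideal analysing
  polarizer, fixed exposure with saturation, shot + read noise, and
  optional bit-depth quantization on export.

Heights are mm above the reference plane; the carrier varies along image
columns (the x axis).  Irradiance is expressed in units of the projected
fringe-crest irradiance of the boosted projector setting, and background
illuminance E (Lux-equivalent) is mapped to irradiance by the calibration
kappa = 1/200 per Lux: 200 Lux matches the fringe crest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "SurfaceMap",
    "ProjectionGeometry",
    "PhotometricScene",
    "CameraModel",
    "RenderedFrame",
    "make_spherical_cap",
    "make_face_phantom",
    "make_skin_albedo",
    "phase_modulation",
    "render_frame",
    "rigid_motion_sequence",
]

KAPPA_PER_LUX = 1.0 / 200.0  # background irradiance per Lux-equivalent
VISIBLE_BAND_NM = (400.0, 700.0)  # flat background spectrum support


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SurfaceMap:
    """Heightmap h(x, y) in mm on a uniform grid, relative to the
    reference plane; ``mask`` marks the object region (heights are zero
    on the reference plane outside it)."""

    heights: np.ndarray
    pitch: float
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        h = np.asarray(self.heights, dtype=float)
        if h.ndim != 2:
            raise ValueError("heights must be a 2D grid")
        if not np.all(np.isfinite(h)):
            raise ValueError("heights must be finite")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        self.heights = h
        if self.mask is None:
            self.mask = np.ones_like(h, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != h.shape:
                raise ValueError("mask shape must match heights")

    @property
    def peak(self) -> float:
        return float(self.heights[self.mask].max()) if self.mask.any() else 0.0

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        ny, nx = self.heights.shape
        x = (np.arange(nx) - nx // 2) * self.pitch
        y = (np.arange(ny) - ny // 2) * self.pitch
        return x, y


@dataclass(frozen=True)
class ProjectionGeometry:
    """Crossed-optical-axes triangulation geometry.

    L is the camera-to-reference-plane distance, D the projector–camera
    baseline, f0 the carrier frequency on the reference plane.  The
    camera is telecentric (orthographic) and near-axis, the standard
    small-angle fringe-projection framework, under which a point at
    height h shifts the observed carrier phase by
    ``dphi = -2 pi f0 D h / (L - h)``.
    """

    L: float = 1000.0
    D: float = 300.0
    f0: float = 1.0
    fringe_axis: str = "x"

    def __post_init__(self) -> None:
        if self.L <= 0 or self.D <= 0 or self.f0 <= 0:
            raise ValueError("L, D and f0 must be strictly positive")
        if self.fringe_axis != "x":
            raise ValueError("carrier along image columns ('x') is the only "
                             "supported fringe axis")


@dataclass
class PhotometricScene:
    """Per-component radiometry of the measured reflectance.

    ``direct_albedo`` is the surface reflectance seen by the direct
    (polarized) fringe signal — a scalar or a 2D texture;
    ``scatter_fraction`` the share of projected light re-emerging after
    subsurface multiple scattering (depolarized), spread laterally by
    ``scatter_sigma`` mm (the green-light skin penetration scale);
    ``background_illuminance`` the broadband ambient level in
    Lux-equivalent; ``projector_power`` scales the projected irradiance
    (1.0 = the boosted high-frequency series, 0.2 = the low-frequency
    series).
    """

    direct_albedo: float | np.ndarray = 0.1
    scatter_fraction: float = 0.5
    scatter_sigma: float = 2.5
    background_illuminance: float = 0.0
    projector_power: float = 1.0

    def __post_init__(self) -> None:
        alb = np.asarray(self.direct_albedo, dtype=float)
        if np.any(alb < 0):
            raise ValueError("direct_albedo must be nonnegative")
        if not 0 <= self.scatter_fraction <= 1:
            raise ValueError("scatter_fraction must be in [0, 1]")
        if self.scatter_fraction + float(alb.max()) > 1.0 + 1e-9:
            raise ValueError("scatter_fraction + direct reflectance must be <= 1")
        if self.scatter_sigma < 0 or self.background_illuminance < 0:
            raise ValueError("radiometric parameters must be nonnegative")
        if self.projector_power <= 0:
            raise ValueError("projector_power must be positive")


@dataclass
class CameraModel:
    """Camera with bandpass filter, analysing polarizer, fixed exposure
    and a shot + read noise model.

    The filter passes the 532 nm laser line at unit transmission and, for
    a flat background spectrum over the visible band, attenuates the
    broadband background by fwhm / band-width (10/300 by default).  The
    polarizer is ideal: the co-aligned direct (polarized) component is
    transmitted at cos^2(polarizer_angle) and unpolarized components at
    exactly 1/2.  Exposure is fixed by auto-exposing once on the
    projector-only scene with ``exposure_headroom`` above its brightest
    pixel; ambient light on top of that saturates the sensor.
    ``photon_fullwell`` sets shot noise (sigma = sqrt(I/fullwell) at
    normalized irradiance I); ``None`` disables noise entirely.
    """

    filter_on: bool = True
    filter_center_nm: float = 532.0
    filter_fwhm_nm: float = 10.0
    polarizer_on: bool = True
    polarizer_angle: float = 0.0
    photon_fullwell: float | None = 10_000.0
    read_noise: float = 3e-4
    bit_depth: int = 8
    exposure_headroom: float = 1.25

    def __post_init__(self) -> None:
        if self.filter_fwhm_nm <= 0:
            raise ValueError("filter_fwhm_nm must be positive")
        if self.photon_fullwell is not None and self.photon_fullwell <= 0:
            raise ValueError("photon_fullwell must be positive or None")
        if self.read_noise < 0:
            raise ValueError("read_noise must be nonnegative")
        if self.exposure_headroom <= 1.0:
            raise ValueError("exposure_headroom must exceed 1")

    @property
    def direct_gain(self) -> float:
        return float(np.cos(self.polarizer_angle) ** 2) if self.polarizer_on else 1.0

    @property
    def unpolarized_gain(self) -> float:
        return 0.5 if self.polarizer_on else 1.0

    @property
    def background_filter_gain(self) -> float:
        if not self.filter_on:
            return 1.0
        lo, hi = VISIBLE_BAND_NM
        return min(1.0, self.filter_fwhm_nm / (hi - lo))


@dataclass
class RenderedFrame:
    """A single exposure-normalized camera frame in [0, 1]."""

    image: np.ndarray
    pitch: float
    saturation_fraction: float
    full_scale: float
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Ground-truth surfaces
# ---------------------------------------------------------------------------


def make_spherical_cap(
    base_radius: float = 40.0,
    cap_height: float = 10.0,
    pitch: float = 0.25,
    extent: float | None = None,
) -> SurfaceMap:
    """Spherical cap of base radius r and apex height h on the reference
    plane — the silicone-rubber validation phantom.

    The parent sphere radius is R = (r^2 + h^2) / (2 h); the cap surface
    is ``sqrt(R^2 - rho^2) - (R - h)`` inside the base circle and zero
    outside.
    """
    if cap_height <= 0:
        raise ValueError("cap_height must be positive")
    if base_radius <= 0:
        raise ValueError("base_radius must be positive")
    R = (base_radius**2 + cap_height**2) / (2.0 * cap_height)
    if cap_height > R:
        raise ValueError("nonphysical geometry: cap taller than parent sphere")
    if extent is None:
        extent = 3.0 * base_radius
    n = int(round(extent / pitch))
    x = (np.arange(n) - n // 2) * pitch
    xx, yy = np.meshgrid(x, x, indexing="xy")
    rho2 = xx**2 + yy**2
    inside = rho2 <= base_radius**2
    heights = np.zeros_like(xx)
    heights[inside] = np.sqrt(R**2 - rho2[inside]) - (R - cap_height)
    heights = np.clip(heights, 0.0, None)
    return SurfaceMap(heights, pitch, mask=inside)


_FACE_FEATURES = (
    # (amplitude mm, x0, y0, sigma_x, sigma_y)  — a stylized face relief
    (16.0, 0.0, 0.0, 42.0, 55.0),    # skull dome
    (7.0, 0.0, -5.0, 8.0, 30.0),     # nose ridge
    (3.0, 0.0, -20.0, 7.5, 9.0),     # nose tip
    (3.5, -28.0, -8.0, 16.0, 14.0),  # left cheek
    (3.5, 28.0, -8.0, 16.0, 14.0),   # right cheek
    (2.5, 0.0, 24.0, 30.0, 8.0),     # brow
    (2.0, 0.0, -48.0, 12.0, 10.0),   # chin
)


def make_face_phantom(
    seed: int,
    pitch: float = 0.25,
    extent: float = 192.0,
    amplitude: float = 1.0,
) -> SurfaceMap:
    """Deterministic-by-seed face-like heightmap.

    A sum of smooth Gaussian features (dome, nose ridge and tip, cheeks,
    brow, chin) whose positions and amplitudes are jittered by the seed,
    windowed by a super-Gaussian face ellipse so the relief meets the
    reference plane smoothly (C^1).  Peak height ~20–30 mm, lateral
    extent ~150 mm; slopes are kept gentle enough that the modulated
    carrier stays inside the spectral band a one-shot reconstruction can
    isolate.  ``amplitude`` scales the whole relief (0 gives the flat
    reference plane).
    """
    rng = np.random.default_rng(seed)
    n = int(round(extent / pitch))
    x = (np.arange(n) - n // 2) * pitch
    xx, yy = np.meshgrid(x, x, indexing="xy")
    heights = np.zeros_like(xx)
    for amp, x0, y0, sx, sy in _FACE_FEATURES:
        amp = amp * (1.0 + 0.1 * rng.standard_normal())
        x0 = x0 + 2.0 * rng.standard_normal()
        y0 = y0 + 2.0 * rng.standard_normal()
        heights += amp * np.exp(
            -((xx - x0) ** 2) / (2 * sx**2) - ((yy - y0) ** 2) / (2 * sy**2)
        )
    # smooth face-boundary window (super-Gaussian ellipse)
    r2 = (xx / 65.0) ** 2 + (yy / 80.0) ** 2
    window = np.exp(-2.0 * r2**3)
    heights = amplitude * heights * window
    mask = window > 0.05
    return SurfaceMap(heights, pitch, mask=mask)


def make_skin_albedo(
    seed: int,
    shape: tuple[int, int],
    pitch: float,
    mean: float = 0.1,
    contrast: float = 0.35,
    blotch_scale: float = 12.0,
) -> np.ndarray:
    """Smooth multiplicative skin-like albedo texture.

    Gaussian-filtered white noise (correlation length ``blotch_scale``
    mm) around ``mean`` with relative modulation ``contrast``, plus a few
    darker seeded patches standing in for brows/blemishes.  Values are
    clipped to [0.25, 1.75] x mean.
    """
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=blotch_scale / pitch)
    smooth /= max(smooth.std(), 1e-12)
    albedo = mean * (1.0 + contrast * smooth)
    ny, nx = shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    for _ in range(4):
        cy, cx = rng.integers(ny // 4, 3 * ny // 4), rng.integers(nx // 4, 3 * nx // 4)
        ry, rx = 6.0 / pitch, 14.0 / pitch
        patch = np.exp(-(((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2))
        albedo *= 1.0 - 0.5 * patch
    return np.clip(albedo, 0.25 * mean, 1.75 * mean)


# ---------------------------------------------------------------------------
# Height-to-phase model and the renderer
# ---------------------------------------------------------------------------


def phase_modulation(surface: SurfaceMap, geom: ProjectionGeometry):
    """Ground-truth carrier-phase deviation of a surface.

    ``dphi(x, y) = -2 pi f0 D h / (L - h)``; exact algebraic inverse of
    :func:`fringeftp.ftp.phase_to_height`.
    """
    from .ftp import PhaseMap  # deferred: ftp imports SurfaceMap from here

    h = surface.heights
    if np.any(h >= geom.L):
        raise ValueError("surface height reaches the camera plane (h >= L)")
    dphi = -2.0 * np.pi * geom.f0 * geom.D * h / (geom.L - h)
    return PhaseMap(
        values=dphi,
        state="unwrapped",
        carrier_frequency=geom.f0,
        fringe_axis=geom.fringe_axis,
        pitch=surface.pitch,
    )


def _projected_irradiance(
    surface: SurfaceMap, geom: ProjectionGeometry, fringe=None
) -> np.ndarray:
    """Projector irradiance seen at each camera pixel, peak-normalized.

    The observed pattern is the reference-plane pattern sampled at the
    triangulation-displaced coordinate x - u with u = D h / (L - h), so
    its phase is ``2 pi f0 x + dphi``.  With ``fringe`` supplied, the
    simulated pattern is rescaled so its carrier lands on f0 and is
    interpolated at the displaced coordinates (its circular spot then
    limits the illuminated region); otherwise an ideal full-frame cosine
    carrier is used.
    """
    h = surface.heights
    u = geom.D * h / (geom.L - h)
    x, _ = surface.coords()
    xs = x[np.newaxis, :] - u  # displaced reference-plane coordinate
    if fringe is None:
        return 0.5 * (1.0 + np.cos(2.0 * np.pi * geom.f0 * xs))
    # stretch the simulated pattern so its carrier lands on f0: sampling at
    # x * f0 / f_pattern maps cos^2(pi f_pat u) onto cos^2(pi f0 x) and
    # magnifies the spot radius by f_pat / f0
    scale = geom.f0 / fringe.predicted_intensity_frequency
    inten = fringe.intensity / max(fringe.intensity.max(), 1e-300)
    nf = inten.shape[0]
    _, y = surface.coords()
    cols = xs * scale / fringe.pitch + nf // 2
    rows = (y[:, np.newaxis] * scale / fringe.pitch + nf // 2) * np.ones_like(cols)
    resampled = ndimage.map_coordinates(inten, [rows, cols], order=3, cval=0.0)
    return np.clip(resampled, 0.0, None)


def render_frame(
    surface: SurfaceMap,
    geom: ProjectionGeometry,
    scene: PhotometricScene,
    camera: CameraModel,
    fringe=None,
    seed: int = 0,
    return_components: bool = False,
):
    """Render one camera frame of the fringe-projected scene.

    The sensor irradiance is the polarizer/filter-weighted sum of the
    direct fringe reflection, the Gaussian-blurred subsurface-scatter
    component and the broadband background, normalized by the fixed
    exposure and degraded by seeded shot + read noise; values beyond
    full scale clip and the clipped fraction is reported.

    With ``return_components=True`` the pre-exposure irradiance
    components are returned instead (no noise), for radiometric tests.
    """
    proj = scene.projector_power * _projected_irradiance(surface, geom, fringe)
    albedo = np.broadcast_to(np.asarray(scene.direct_albedo, float),
                             proj.shape)
    direct = albedo * proj
    if scene.scatter_fraction > 0 and scene.scatter_sigma > 0:
        blurred = ndimage.gaussian_filter(proj, scene.scatter_sigma / surface.pitch)
        scatter = scene.scatter_fraction * blurred
    else:
        scatter = scene.scatter_fraction * proj
    background = KAPPA_PER_LUX * scene.background_illuminance

    g_dir = camera.direct_gain
    g_unp = camera.unpolarized_gain
    g_bg = camera.background_filter_gain  # laser line passes at gain 1

    if return_components:
        return {
            "direct": g_dir * direct,
            "scatter": g_unp * scatter,
            "background": g_unp * g_bg * background * np.ones_like(proj),
        }

    projector_only = g_dir * direct + g_unp * scatter
    full_scale = camera.exposure_headroom * float(projector_only.max())
    if full_scale <= 0:
        raise ValueError("projector-only scene is dark; cannot set exposure")
    total = (projector_only + g_unp * g_bg * background) / full_scale

    rng = np.random.default_rng(seed)
    if camera.photon_fullwell is not None:
        shot = np.sqrt(np.clip(total, 0.0, None) / camera.photon_fullwell)
        total = total + rng.standard_normal(total.shape) * shot
        if camera.read_noise > 0:
            total = total + rng.normal(0.0, camera.read_noise, total.shape)
    saturated = float(np.mean(total >= 1.0))
    image = np.clip(total, 0.0, 1.0)
    return RenderedFrame(
        image=image,
        pitch=surface.pitch,
        saturation_fraction=saturated,
        full_scale=full_scale,
        meta={
            "seed": seed,
            "f0": geom.f0,
            "background_illuminance": scene.background_illuminance,
            "filter_on": camera.filter_on,
            "polarizer_on": camera.polarizer_on,
            "projector_power": scene.projector_power,
        },
    )


def quantize(frame: RenderedFrame, bit_depth: int | None = None) -> np.ndarray:
    """Export quantization of a frame to unsigned integers."""
    bits = bit_depth if bit_depth is not None else 8
    levels = 2**bits - 1
    dtype = np.uint8 if bits <= 8 else np.uint16
    return np.round(frame.image * levels).astype(dtype)


def rigid_motion_sequence(
    surface: SurfaceMap,
    n_frames: int = 5,
    max_shift: float = 4.0,
    max_rotation_deg: float = 2.0,
    seed: int = 0,
) -> list[SurfaceMap]:
    """Rigid in-plane motion of the ground truth across frames.

    Each frame is the surface shifted by up to ``max_shift`` mm and
    rotated by up to ``max_rotation_deg`` about the grid center; a
    one-shot reconstruction sees each frame independently, so motion only
    changes the per-frame ground truth.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for _ in range(n_frames):
        dx, dy = rng.uniform(-max_shift, max_shift, size=2) / surface.pitch
        ang = rng.uniform(-max_rotation_deg, max_rotation_deg)
        h = ndimage.rotate(surface.heights, ang, reshape=False, order=1, cval=0.0)
        h = ndimage.shift(h, (dy, dx), order=1, cval=0.0)
        m = ndimage.rotate(surface.mask.astype(float), ang, reshape=False,
                           order=0, cval=0.0)
        m = ndimage.shift(m, (dy, dx), order=0, cval=0.0) > 0.5
        frames.append(SurfaceMap(np.clip(h, 0.0, None), surface.pitch, mask=m))
    return frames
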