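"""Fourier-optics simulation of the monochromatic sinusoidal fringe projector.

The projector is a 4-plane train: a point laser source illuminates a binary
rectangular grating (plane P0), a positive lens (P1) forms the grating's
diffraction-order spectrum at its back focal plane (P2) where an adjustable
spatial-frequency filter passes only the ±1 orders, and the two surviving
plane-wave components interfere at the distant observation plane (P3) as a
pure two-beam sinusoidal fringe pattern.

Two routes to the P3 pattern are provided and cross-validated:

* :func:`simulate_fringe_numeric` — chains discrete scalar-diffraction steps
  (grating transmission, Fresnel propagation, lens phase, spectral slits).
* :func:`closed_form_fringe` — the analytic result: a cosine carrier of
  intensity frequency ``2 f / (d Z3)`` confined to a circle of radius
  ``H Z3 / (2 f)``.

All lengths are millimetres internally; wavelengths enter in nanometres.
Complex fields live on square, power-of-two grids (:class:`SampledField`)
with a physical pixel pitch, the currency of every propagation step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.fft import fft2, fftfreq, fftshift, ifft2, ifftshift
from scipy.special import j1

__all__ = [
    "SamplingError",
    "OpticalSetup",
    "GridSpec",
    "SampledField",
    "FringePattern",
    "grating_transmission",
    "fresnel_propagate",
    "lens_transmit",
    "closed_form_spectrum",
    "spatial_filter",
    "closed_form_fringe",
    "simulate_fringe_numeric",
    "measure_fringe_frequency",
]

NM_TO_MM = 1e-6


class SamplingError(ValueError):
    """Grid sampling cannot support the requested optical operation."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OpticalSetup:
    """Geometric and optical parameters of the fringe-projector train.

    Parameters
    ----------
    wavelength_nm:
        Laser wavelength (default 532 nm, green CW laser).
    Z0, Z1, Z2, Z3:
        Plane separations in mm: source->grating, grating->lens,
        lens->filter, filter->observation.  ``Z1`` and ``Z2`` default to
        the focal length: the grating at the front focal plane makes the
        lens cancel each diffraction order's tilt (telecentric output,
        so the ±1 beams stay parallel and overlap at P3), and the filter
        at the back focal plane sees the orders focused to sharp,
        separable lobes.  ``Z0`` defaults to a large stand-off so the
        grating illumination is effectively collimated.
    focal_length:
        Focal length f of the Fourier-transform lens (mm).
    grating_period:
        Grating period d (mm); 0.02 mm is a 50 lp/mm grating.
    grating_slit:
        Open-slit width a of the binary grating (mm); duty cycle a/d.
    illum_diameter:
        Diameter H of the laser spot on the grating (mm).
    filter_order:
        Diffraction order m selected by the spatial filter (default ±1).
    filter_slit_width:
        Width of each filter slit (mm).
    """

    wavelength_nm: float = 532.0
    Z0: float = 100_000.0
    Z1: float = 150.0
    Z2: float = 150.0
    Z3: float = 3_000.0
    focal_length: float = 150.0
    grating_period: float = 0.02
    grating_slit: float = 0.01
    illum_diameter: float = 2.0
    filter_order: int = 1
    filter_slit_width: float = 0.5

    def __post_init__(self) -> None:
        for name in ("wavelength_nm", "Z0", "Z1", "Z2", "Z3", "focal_length",
                     "grating_period", "grating_slit", "illum_diameter",
                     "filter_slit_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not self.grating_slit < self.grating_period:
            raise ValueError("grating_slit a must satisfy 0 < a < d")
        if self.filter_order < 1:
            raise ValueError("filter_order m must be a positive integer")

    @property
    def wavelength_mm(self) -> float:
        return self.wavelength_nm * NM_TO_MM

    @property
    def wavenumber(self) -> float:
        """k = 2*pi/lambda in rad/mm (derived, never stored)."""
        return 2.0 * np.pi / self.wavelength_mm

    @property
    def duty_cycle(self) -> float:
        return self.grating_slit / self.grating_period

    @property
    def fourier_plane_condition(self) -> bool:
        """True when the filter sits at the back focal plane of an
        effectively collimated beam, the regime in which the closed-form
        sinusoidal output holds."""
        collimated = (self.Z0 + self.Z1) >= 10.0 * self.focal_length
        at_back_focal = abs(self.Z2 - self.focal_length) <= 1e-9 * self.focal_length
        at_front_focal = abs(self.Z1 - self.focal_length) <= 0.05 * self.focal_length
        return bool(collimated and at_back_focal and at_front_focal)

    @property
    def order_position(self) -> float:
        """Position of the +1st-order lobe at the filter plane: lambda*f/d."""
        return self.wavelength_mm * self.focal_length / self.grating_period

    @property
    def predicted_intensity_frequency(self) -> float:
        """Intensity fringe frequency at P3 in cycles/mm: 2f/(d*Z3).

        The field cosine has frequency f/(d*Z3); squaring doubles it.
        """
        return 2.0 * self.focal_length / (self.grating_period * self.Z3)

    @property
    def predicted_radius(self) -> float:
        """Radius of the fringe spot at P3: H*Z3/(2f)."""
        return self.illum_diameter * self.Z3 / (2.0 * self.focal_length)


@dataclass(frozen=True)
class GridSpec:
    """Sampling request for the simulation grids.

    ``pitch`` is the sample spacing at the grating plane; ``None`` picks
    the finest pitch that still keeps the laser spot within 40% of the
    grid extent (wrap-around safety), never finer than d/16 (little
    accuracy is gained below that) and never coarser than the d/8
    grating-resolution bound.
    """

    n: int = 4096
    pitch: float | None = None

    def __post_init__(self) -> None:
        if self.n < 16 or (self.n & (self.n - 1)) != 0:
            raise ValueError("grid side n must be a power of two >= 16")
        if self.pitch is not None and self.pitch <= 0:
            raise ValueError("pitch must be positive")

    def resolve_pitch(self, setup: OpticalSetup) -> float:
        if self.pitch is not None:
            return self.pitch
        d = setup.grating_period
        return max(d / 16.0, 2.5 * setup.illum_diameter / self.n)


@dataclass
class SampledField:
    """Complex scalar field on a uniform square grid with physical pitch."""

    amplitude: np.ndarray
    pitch: float
    plane_label: str = "P0"

    def __post_init__(self) -> None:
        amp = np.asarray(self.amplitude)
        if amp.ndim != 2 or amp.shape[0] != amp.shape[1]:
            raise ValueError("field grid must be square 2D")
        n = amp.shape[0]
        if n & (n - 1):
            raise ValueError("grid side must be a power of two")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")
        self.amplitude = amp.astype(np.complex128, copy=False)

    @property
    def n(self) -> int:
        return self.amplitude.shape[0]

    @property
    def extent(self) -> float:
        return self.n * self.pitch

    def coords(self) -> np.ndarray:
        """Centered physical coordinates of the samples along one axis."""
        return (np.arange(self.n) - self.n // 2) * self.pitch

    @property
    def power(self) -> float:
        """Total power: sum |U|^2 * pitch^2."""
        return float(np.sum(np.abs(self.amplitude) ** 2) * self.pitch**2)

    @property
    def intensity(self) -> np.ndarray:
        return np.abs(self.amplitude) ** 2


@dataclass
class FringePattern:
    """Intensity of the projected fringe pattern at the observation plane."""

    intensity: np.ndarray
    pitch: float
    predicted_intensity_frequency: float
    predicted_radius: float
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        inten = np.asarray(self.intensity, dtype=float)
        if np.any(inten < -1e-12):
            raise ValueError("intensity must be nonnegative")
        self.intensity = np.clip(inten, 0.0, None)

    def coords(self) -> np.ndarray:
        n = self.intensity.shape[0]
        return (np.arange(n) - n // 2) * self.pitch

    def spot_mask(self, fraction: float = 1.0) -> np.ndarray:
        """Boolean mask of the circular fringe spot (optionally shrunk)."""
        x = self.coords()
        xx, yy = np.meshgrid(x, x, indexing="xy")
        return xx**2 + yy**2 <= (fraction * self.predicted_radius) ** 2


# ---------------------------------------------------------------------------
# Elementary operations of the optical train
# ---------------------------------------------------------------------------


def grating_transmission(setup: OpticalSetup, grid: GridSpec) -> SampledField:
    """Field right behind the grating at P0.

    A diverging spherical wave from the point source at distance ``Z0``
    is multiplied by the binary grating transmission (a rect of width
    ``a`` convolved with a comb of period ``d``, i.e. duty cycle a/d)
    windowed by the circular laser spot of diameter ``H``.
    """
    pitch = grid.resolve_pitch(setup)
    d = setup.grating_period
    if pitch > d / 8.0 + 1e-12 * d:
        raise SamplingError(
            f"pitch {pitch:g} mm too coarse for grating period {d:g} mm; "
            f"need >= 8 samples per period (pitch <= {d / 8.0:g} mm)"
        )
    extent = grid.n * pitch
    if setup.illum_diameter > extent:
        raise SamplingError(
            f"illumination spot H={setup.illum_diameter:g} mm exceeds grid "
            f"extent {extent:g} mm"
        )
    if setup.illum_diameter > extent / 2.0:
        warnings.warn(
            "laser spot occupies more than half the grid extent; "
            "wrap-around leakage may contaminate propagation",
            stacklevel=2,
        )

    x = (np.arange(grid.n) - grid.n // 2) * pitch
    xx, yy = np.meshgrid(x, x, indexing="xy")

    # binary grating with area-weighted (gray) edge pixels so the sampled
    # duty cycle equals a/d exactly; slit centered on x = 0 so the fringe
    # cosine peaks on-axis at P3
    a = setup.grating_slit
    y0 = ((x + d / 2.0) % d) - d / 2.0  # position within the period
    cover = np.zeros_like(y0)
    for shift in (-d, 0.0, d):  # neighbouring-period slits for edge pixels
        lo = np.maximum(y0 - pitch / 2.0, shift - a / 2.0)
        hi = np.minimum(y0 + pitch / 2.0, shift + a / 2.0)
        cover += np.clip(hi - lo, 0.0, None)
    t0 = np.broadcast_to((cover / pitch)[np.newaxis, :], xx.shape).copy()
    spot = xx**2 + yy**2 <= (setup.illum_diameter / 2.0) ** 2
    t0 *= spot

    k = setup.wavenumber
    illum = (1.0 / setup.Z0) * np.exp(
        1j * k * setup.Z0 + 1j * k * (xx**2 + yy**2) / (2.0 * setup.Z0)
    )
    return SampledField(illum * t0, pitch, plane_label="P0")


def _critical_distance(n: int, pitch: float, wl_mm: float) -> float:
    """z = N * pitch^2 / lambda, the crossover between the transfer-function
    and single-FT Fresnel propagators for an N-sample grid."""
    return n * pitch**2 / wl_mm


def fresnel_propagate(
    fld: SampledField,
    distance: float,
    wavelength_nm: float,
    method: str = "auto",
) -> SampledField:
    """Fresnel diffraction of a sampled field over ``distance`` mm.

    Two discrete propagators are provided, selected by the standard
    sampling criterion z_c = N*pitch^2/lambda:

    ``"transfer"``
        Angular-spectrum method with the Fresnel transfer function
        ``exp(-i*pi*lambda*z*(fx^2+fy^2))``.  Exactly unitary, pitch
        preserved; valid (chirp adequately sampled in frequency) for
        z <= z_c.
    ``"single_ft"``
        Single-FFT Fresnel scaling propagator; output pitch is
        lambda*z/(N*pitch).  Valid (spatial chirp adequately sampled)
        for z >= z_c.
    ``"auto"``
        Chooses by comparing z with z_c.

    Raises
    ------
    SamplingError
        If the explicitly requested method violates its aliasing bound;
        the message names the maximal (or minimal) safe distance.
    """
    if distance <= 0:
        raise ValueError("propagation distance must be positive")
    wl = wavelength_nm * NM_TO_MM
    n, pitch = fld.n, fld.pitch
    z_c = _critical_distance(n, pitch, wl)

    if method == "auto":
        method = "transfer" if distance <= z_c else "single_ft"
    if method == "transfer":
        if distance > z_c * (1 + 1e-9):
            raise SamplingError(
                f"transfer-function propagator aliases at z={distance:g} mm; "
                f"maximal safe distance for this grid is {z_c:g} mm"
            )
        return _propagate_transfer(fld, distance, wl)
    if method == "single_ft":
        if distance < z_c * (1 - 1e-9):
            raise SamplingError(
                f"single-FT propagator under-samples its chirp at "
                f"z={distance:g} mm; minimal safe distance is {z_c:g} mm"
            )
        return _propagate_single_ft(fld, distance, wl)
    raise ValueError(f"unknown propagation method {method!r}")


def _propagate_transfer(fld: SampledField, z: float, wl: float) -> SampledField:
    fq = fftfreq(fld.n, d=fld.pitch)
    fx, fy = np.meshgrid(fq, fq, indexing="xy")
    kernel = np.exp(1j * 2 * np.pi * z / wl) * np.exp(
        -1j * np.pi * wl * z * (fx**2 + fy**2)
    )
    out = fftshift(ifft2(fft2(ifftshift(fld.amplitude)) * kernel))
    return SampledField(out, fld.pitch, plane_label=fld.plane_label)


def _propagate_single_ft(fld: SampledField, z: float, wl: float) -> SampledField:
    n, dx1 = fld.n, fld.pitch
    k = 2 * np.pi / wl
    dx2 = wl * z / (n * dx1)
    x1 = fld.coords()
    xx1, yy1 = np.meshgrid(x1, x1, indexing="xy")
    pre = fld.amplitude * np.exp(1j * k * (xx1**2 + yy1**2) / (2 * z))
    spec = fftshift(fft2(ifftshift(pre)))
    x2 = (np.arange(n) - n // 2) * dx2
    xx2, yy2 = np.meshgrid(x2, x2, indexing="xy")
    out = (
        (dx1**2 / (1j * wl * z))
        * np.exp(1j * k * z)
        * np.exp(1j * k * (xx2**2 + yy2**2) / (2 * z))
        * spec
    )
    return SampledField(out, dx2, plane_label=fld.plane_label)


def lens_transmit(
    fld: SampledField, focal_length: float, wavelength_nm: float
) -> SampledField:
    """Thin-lens transmission: multiply by exp(-i*k*(x^2+y^2)/(2f)).

    A pure phase element; |output| = |input| everywhere.
    """
    if focal_length <= 0:
        raise ValueError("focal_length must be positive")
    wl = wavelength_nm * NM_TO_MM
    k = 2 * np.pi / wl
    x = fld.coords()
    xx, yy = np.meshgrid(x, x, indexing="xy")
    tL = np.exp(-1j * k * (xx**2 + yy**2) / (2 * focal_length))
    return SampledField(fld.amplitude * tL, fld.pitch, plane_label=fld.plane_label)


# ---------------------------------------------------------------------------
# Filter-plane spectrum: closed form and slit mask
# ---------------------------------------------------------------------------


def closed_form_spectrum(
    setup: OpticalSetup, x2: np.ndarray, max_order: int | None = None
) -> np.ndarray:
    """Analytic diffraction-order spectrum at the filter plane.

    Sum over grating orders m of sinc(a*m/d)-weighted Airy-type lobes
    ``J1(pi*H*(fx - m/d)) / (fx - m/d)`` centered at spatial frequency
    fx = m/d, where fx = x2/(lambda*f) maps filter-plane position to
    frequency.  The overall complex constant is dropped: only relative
    magnitudes are contracted.
    """
    if not setup.fourier_plane_condition:
        raise ValueError(
            "closed-form spectrum requires the Fourier-plane condition "
            "(Z2 = f, effectively collimated illumination)"
        )
    x2 = np.asarray(x2, dtype=float)
    wl, f = setup.wavelength_mm, setup.focal_length
    d, a, H = setup.grating_period, setup.grating_slit, setup.illum_diameter
    fx = x2 / (wl * f)
    if max_order is None:
        max_order = int(np.ceil(np.max(np.abs(fx)) * d)) + 2
    out = np.zeros_like(fx)
    for m in range(-max_order, max_order + 1):
        u = fx - m / d
        small = np.abs(u) < 1e-12
        lobe = np.where(
            small, np.pi * H / 2.0, j1(np.pi * H * u) / np.where(small, 1.0, u)
        )
        out = out + np.sinc(a * m / d) * lobe
    return (a / d) * out


def spatial_filter(
    fld: SampledField,
    setup: OpticalSetup,
    orders: tuple[int, ...] | None = None,
) -> SampledField:
    """Pass only the selected diffraction orders through slit windows.

    Each slit is a full-height rectangular window of width
    ``filter_slit_width`` centered on the order position m*lambda*f/d.
    Everything else — including the strong zero order — is blocked.
    """
    m = setup.filter_order
    if orders is None:
        orders = (m, -m)
    w = setup.filter_slit_width
    centers = [o * setup.order_position for o in orders]
    for c in centers:
        if abs(c) <= w / 2.0:
            raise ValueError(
                f"filter slit at {c:g} mm (width {w:g} mm) overlaps the zero "
                "order; orders are not separable at this geometry"
            )
    x = fld.coords()
    mask_1d = np.zeros(fld.n, dtype=bool)
    for c in centers:
        mask_1d |= np.abs(x - c) <= w / 2.0
    out = fld.amplitude * mask_1d[np.newaxis, :]
    return SampledField(out, fld.pitch, plane_label="P2")


# ---------------------------------------------------------------------------
# Fringe pattern: closed form and full numeric chain
# ---------------------------------------------------------------------------


def closed_form_fringe(
    setup: OpticalSetup, n: int = 2048, pitch: float | None = None
) -> FringePattern:
    """Analytic fringe intensity at the observation plane P3.

    The field is ``Ca * Cb * circ(2f|x3| / (H Z3)) * cos(2 pi f x3 / (d Z3))``
    with ``Ca = (2f / (Z0 Z3 pi)) * sin(a pi / d)`` real and ``|Cb| = 1``,
    so the intensity is ``Ca^2 cos^2`` inside a circle of radius
    ``H Z3 / (2 f)`` and zero outside.  Michelson contrast inside the
    circle is exactly unity.
    """
    if not setup.fourier_plane_condition:
        raise ValueError(
            "closed-form fringe requires the Fourier-plane condition"
        )
    if pitch is None:
        pitch = default_p3_pitch(setup, GridSpec(n=n))
    x = (np.arange(n) - n // 2) * pitch
    xx, yy = np.meshgrid(x, x, indexing="xy")
    f, d, H, Z3 = (
        setup.focal_length,
        setup.grating_period,
        setup.illum_diameter,
        setup.Z3,
    )
    Ca = (2.0 * f / (setup.Z0 * Z3 * np.pi)) * np.sin(
        setup.grating_slit * np.pi / d
    )
    radius = setup.predicted_radius
    inside = xx**2 + yy**2 <= radius**2
    fieldvals = Ca * np.cos(2 * np.pi * f * xx / (d * Z3)) * inside
    return FringePattern(
        intensity=fieldvals**2,
        pitch=pitch,
        predicted_intensity_frequency=setup.predicted_intensity_frequency,
        predicted_radius=radius,
        diagnostics={"route": "closed_form", "Ca": Ca},
    )


def default_p3_pitch(setup: OpticalSetup, grid: GridSpec) -> float:
    """Observation-plane pitch produced by the numeric chain for this grid.

    The two single-FT hops give dx3 = Z3 * dx0 / Z2 (independent of
    wavelength), which also fixes the samples-per-fringe count to
    d / (2 * dx0).
    """
    return setup.Z3 * grid.resolve_pitch(setup) / setup.Z2


def simulate_fringe_numeric(
    setup: OpticalSetup,
    grid: GridSpec = GridSpec(),
    orders: tuple[int, ...] | None = None,
) -> FringePattern:
    """Run the full discrete diffraction chain P0 -> P3.

    Steps: grating transmission, Fresnel hop to the lens, thin-lens phase,
    Fresnel hop to the filter plane, slit filtering of the ±m orders,
    Fresnel hop to the observation plane.  Per-step sampling diagnostics
    (method, pitch, power) are recorded on the returned pattern.
    """
    diag: dict = {"route": "numeric", "steps": []}

    def log(stage: str, f: SampledField, **extra) -> None:
        diag["steps"].append(
            {"stage": stage, "pitch": f.pitch, "power": f.power, **extra}
        )

    u0 = grating_transmission(setup, grid)
    log("grating", u0)
    u1p = fresnel_propagate(u0, setup.Z1, setup.wavelength_nm)
    u1p.plane_label = "P1"
    log("propagate_Z1", u1p, distance=setup.Z1)
    u1 = lens_transmit(u1p, setup.focal_length, setup.wavelength_nm)
    log("lens", u1)
    u2p = fresnel_propagate(u1, setup.Z2, setup.wavelength_nm)
    u2p.plane_label = "P2"
    log("propagate_Z2", u2p, distance=setup.Z2)
    u2 = spatial_filter(u2p, setup, orders=orders)
    log("filter", u2, passed_fraction=u2.power / max(u2p.power, 1e-300))
    u3 = fresnel_propagate(u2, setup.Z3, setup.wavelength_nm)
    u3.plane_label = "P3"
    log("propagate_Z3", u3, distance=setup.Z3)

    return FringePattern(
        intensity=u3.intensity,
        pitch=u3.pitch,
        predicted_intensity_frequency=setup.predicted_intensity_frequency,
        predicted_radius=setup.predicted_radius,
        diagnostics=diag,
    )


def measure_fringe_frequency(pattern: FringePattern) -> float:
    """Measured intensity-fringe frequency (cycles/mm) of a pattern.

    Averages the intensity over the central rows of the spot and locates
    the dominant non-DC peak of its one-dimensional spectrum, refined to
    sub-bin precision by a local centroid.
    """
    inten = pattern.intensity
    n = inten.shape[0]
    half = max(4, int(0.2 * pattern.predicted_radius / pattern.pitch))
    rows = inten[n // 2 - half : n // 2 + half, :]
    profile = rows.mean(axis=0)
    profile = profile - profile.mean()
    window = np.hanning(n)
    spec = np.abs(np.fft.rfft(profile * window))
    freqs = np.fft.rfftfreq(n, d=pattern.pitch)
    # exclude the spot-envelope band around DC before peak picking
    f_lo = max(4.0 / (n * pattern.pitch),
               0.3 * pattern.predicted_intensity_frequency)
    spec[freqs < f_lo] = 0.0
    peak = int(np.argmax(spec))
    lo, hi = max(peak - 2, 0), min(peak + 3, spec.size)
    weights = spec[lo:hi] ** 2
    return float(np.sum(freqs[lo:hi] * weights) / np.sum(weights))
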