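"""One-shot Fourier-transform profilometry (FTP) reconstruction.

A single fringe-projected frame ``g = a + b cos(2 pi f0 x + dphi)`` is
processed by: 2D FFT, isolation of the +1 carrier lobe with a smooth
raised-cosine window, inverse FFT to the complex analytic image, carrier
removal (wrapped phase), quality-guided 2D phase unwrapping, reference
offset removal, and phase-to-height conversion

    h = L * dphi / (dphi - 2 pi f0 D)

— the exact inverse of the renderer's triangulation model.  The analytic
amplitude |b|/2 doubles as the unwrapping quality map and as the validity
mask for error statistics.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.fft import fft2, fftfreq, fftshift, ifft2, ifftshift

__all__ = [
    "CarrierNotFoundError",
    "BandOverlapError",
    "PhaseMap",
    "ReconstructionResult",
    "estimate_carrier",
    "extract_wrapped_phase",
    "unwrap_phase",
    "phase_to_height",
    "reconstruct",
    "wrap",
    "count_residues",
]

TWO_PI = 2.0 * np.pi


class CarrierNotFoundError(ValueError):
    """No dominant fringe carrier in the image spectrum."""


class BandOverlapError(ValueError):
    """Band-selection window would overlap the DC lobe."""


def wrap(phase: np.ndarray) -> np.ndarray:
    """Wrap phase values into (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(phase), TWO_PI)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class PhaseMap:
    """Wrapped or unwrapped phase field in radians with carrier metadata."""

    values: np.ndarray
    state: str
    carrier_frequency: float
    fringe_axis: str = "x"
    pitch: float = 1.0
    quality: np.ndarray | None = None
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("phase values must be a 2D grid")
        if self.state not in ("wrapped", "unwrapped"):
            raise ValueError("state must be 'wrapped' or 'unwrapped'")
        if self.state == "wrapped" and (v.max() > np.pi + 1e-9 or v.min() <= -np.pi - 1e-9):
            raise ValueError("wrapped phase must lie in (-pi, pi]")
        self.values = v
        if self.mask is None:
            self.mask = np.ones_like(v, dtype=bool)


@dataclass
class ReconstructionResult:
    """Recovered surface plus per-stage diagnostics for one frame."""

    surface: "object"  # SurfaceMap; typed loosely to avoid a module cycle
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Carrier estimation and phase extraction
# ---------------------------------------------------------------------------


def estimate_carrier(
    image: np.ndarray,
    pitch: float,
    f_min: float = 0.15,
    peak_threshold: float = 3.0,
) -> tuple[float, str, tuple[float, float]]:
    """Locate the dominant non-DC spectral peak of a fringe image.

    Returns ``(f0, axis, (fx, fy))`` with the carrier magnitude in
    cycles/mm, the dominant image axis and the full 2D frequency.  The
    search excludes a disk of radius ``f_min`` cycles/mm around DC (slow
    albedo/illumination structure) and one half-plane (conjugate
    symmetry).  The peak is refined to sub-bin precision by a local
    centroid and must exceed ``peak_threshold`` times the median non-DC
    spectral magnitude.
    """
    img = np.asarray(image, dtype=float)
    ny, nx = img.shape
    spec = np.abs(fftshift(fft2(img - img.mean())))
    fx = fftshift(fftfreq(nx, d=pitch))
    fy = fftshift(fftfreq(ny, d=pitch))
    fxx, fyy = np.meshgrid(fx, fy, indexing="xy")
    fr = np.hypot(fxx, fyy)
    half_plane = (fxx > 0) | ((fxx == 0) & (fyy > 0))
    candidate = (fr > f_min) & half_plane
    if not candidate.any():
        raise CarrierNotFoundError("search region is empty; grid too small")
    # robust noise floor: the extreme of a flat (pure-noise) spectrum sits
    # near 3-4x its median, so the median alone cannot reject noise; the
    # 99th percentile tracks the noise tail while a real carrier still
    # towers above it
    floor = float(np.percentile(spec[fr > f_min], 99.0))
    masked = np.where(candidate, spec, 0.0)
    iy, ix = np.unravel_index(int(np.argmax(masked)), spec.shape)
    if spec[iy, ix] < peak_threshold * max(floor, 1e-300):
        raise CarrierNotFoundError(
            f"no carrier detected: strongest non-DC peak is only "
            f"{spec[iy, ix] / max(floor, 1e-300):.2f}x the spectral noise floor"
        )
    sl_y = slice(max(iy - 1, 0), min(iy + 2, ny))
    sl_x = slice(max(ix - 1, 0), min(ix + 2, nx))
    w = spec[sl_y, sl_x] ** 2
    fx_hat = float(np.sum(fxx[sl_y, sl_x] * w) / np.sum(w))
    fy_hat = float(np.sum(fyy[sl_y, sl_x] * w) / np.sum(w))
    axis = "x" if abs(fx_hat) >= abs(fy_hat) else "y"
    return float(np.hypot(fx_hat, fy_hat)), axis, (fx_hat, fy_hat)


def extract_wrapped_phase(
    image: np.ndarray,
    pitch: float,
    carrier_frequency: float,
    halfwidth: tuple[float, float] | None = None,
) -> PhaseMap:
    """Isolate the +1 carrier lobe and return the wrapped phase deviation.

    A raised-cosine (Hann) window of half-widths ``halfwidth`` (cycles/mm
    along and transverse to the carrier axis; default f0/2 each) is
    applied around (+f0, 0) in the shifted spectrum; the inverse FFT
    gives the complex analytic image whose argument, minus the carrier
    ramp ``2 pi f0 x``, is the wrapped phase.  The analytic amplitude
    (≈ |b|/2) is attached as the quality map.
    """
    img = np.asarray(image, dtype=float)
    ny, nx = img.shape
    f0 = float(carrier_frequency)
    if halfwidth is None:
        halfwidth = (f0 / 2.0, f0 / 2.0)
    hw_par, hw_perp = halfwidth
    if hw_par <= 0 or hw_perp <= 0:
        raise ValueError("window half-widths must be positive")
    if f0 - hw_par <= 0:
        raise BandOverlapError(
            "band-selection window overlaps DC; reduce the window or raise f0"
        )
    fx = fftshift(fftfreq(nx, d=pitch))
    fy = fftshift(fftfreq(ny, d=pitch))
    fxx, fyy = np.meshgrid(fx, fy, indexing="xy")
    r = np.sqrt(((fxx - f0) / hw_par) ** 2 + (fyy / hw_perp) ** 2)
    window = np.where(r < 1.0, np.cos(np.pi * r / 2.0) ** 2, 0.0)
    spec = fftshift(fft2(img))
    analytic = ifft2(ifftshift(spec * window))
    x = (np.arange(nx) - nx // 2) * pitch
    ramp = np.exp(-1j * TWO_PI * f0 * x)[np.newaxis, :]
    demod = analytic * ramp
    return PhaseMap(
        values=np.angle(demod),
        state="wrapped",
        carrier_frequency=f0,
        fringe_axis="x",
        pitch=pitch,
        quality=np.abs(analytic),
    )


# ---------------------------------------------------------------------------
# 2D phase unwrapping
# ---------------------------------------------------------------------------


def count_residues(wrapped: np.ndarray) -> np.ndarray:
    """Boolean map of phase residues (nonzero 2x2 loop integrals)."""
    d1 = wrap(wrapped[:-1, 1:] - wrapped[:-1, :-1])
    d2 = wrap(wrapped[1:, 1:] - wrapped[:-1, 1:])
    d3 = wrap(wrapped[1:, :-1] - wrapped[1:, 1:])
    d4 = wrap(wrapped[:-1, :-1] - wrapped[1:, :-1])
    loop = d1 + d2 + d3 + d4
    return np.abs(loop) > np.pi  # loop is a multiple of 2*pi up to roundoff


def unwrap_phase(
    pmap: PhaseMap,
    quality: np.ndarray | None = None,
    mask_threshold: float = 0.05,
    method: str = "quality",
) -> PhaseMap:
    """Unwrap a wrapped phase map.

    ``method="quality"`` (default) is a quality-guided flood fill: pixels
    are admitted in decreasing order of the quality map (the analytic
    amplitude), each unwrapped against its already-unwrapped neighbour,
    with deterministic index tie-breaking.  Pixels below
    ``mask_threshold`` x median quality are masked out.  The unwrapped
    map is wrapped-phase + 2*pi*k with integer k, so re-wrapping
    reproduces the input on every visited pixel.  ``method="itoh"`` is
    the classic row-wise 1D fallback (no quality guidance).

    If the residue density among valid pixels exceeds 10%, a warning is
    issued and pixels adjacent to residues are masked.
    """
    if pmap.state != "wrapped":
        raise ValueError("unwrap_phase expects a wrapped PhaseMap")
    wrapped = pmap.values
    q = quality if quality is not None else pmap.quality
    if q is None:
        q = np.ones_like(wrapped)
    valid = q >= mask_threshold * float(np.median(q))
    valid &= pmap.mask

    residues = count_residues(wrapped)
    density = float(residues.mean()) if residues.size else 0.0
    if density > 0.10:
        warnings.warn(
            f"residue density {density:.1%} exceeds 10%; masking affected "
            "region", stacklevel=2,
        )
        bad = np.zeros_like(valid)
        bad[:-1, :-1] |= residues
        bad[:-1, 1:] |= residues
        bad[1:, :-1] |= residues
        bad[1:, 1:] |= residues
        valid &= ~bad

    if method == "itoh":
        unwrapped = np.unwrap(wrapped, axis=1)
        col = np.unwrap(unwrapped[:, 0])
        unwrapped = unwrapped + (col - unwrapped[:, 0])[:, np.newaxis]
        k_int = np.round((unwrapped - wrapped) / TWO_PI)
        unwrapped = wrapped + TWO_PI * k_int
        return PhaseMap(unwrapped, "unwrapped", pmap.carrier_frequency,
                        pmap.fringe_axis, pmap.pitch, quality=q, mask=valid)
    if method != "quality":
        raise ValueError(f"unknown unwrapping method {method!r}")

    ny, nx = wrapped.shape
    k = np.zeros((ny, nx), dtype=np.int64)
    visited = np.zeros((ny, nx), dtype=bool)
    flat_w = wrapped.ravel()
    flat_q = q.ravel()
    flat_valid = valid.ravel()
    flat_k = k.ravel()

    if not flat_valid.any():
        return PhaseMap(wrapped.copy(), "unwrapped", pmap.carrier_frequency,
                        pmap.fringe_axis, pmap.pitch, quality=q, mask=valid)

    seed = int(np.argmax(np.where(flat_valid, flat_q, -np.inf)))
    visited_flat = visited.ravel()
    visited_flat[seed] = True
    heap: list[tuple[float, int, int]] = []

    def push_neighbors(idx: int) -> None:
        iy, ix = divmod(idx, nx)
        for jy, jx in ((iy - 1, ix), (iy + 1, ix), (iy, ix - 1), (iy, ix + 1)):
            if 0 <= jy < ny and 0 <= jx < nx:
                j = jy * nx + jx
                if not visited_flat[j] and flat_valid[j]:
                    heapq.heappush(heap, (-flat_q[j], j, idx))

    push_neighbors(seed)
    while heap:
        _, j, src = heapq.heappop(heap)
        if visited_flat[j]:
            continue
        visited_flat[j] = True
        flat_k[j] = flat_k[src] - int(round((flat_w[j] - flat_w[src]) / TWO_PI))
        push_neighbors(j)

    unwrapped = wrapped + TWO_PI * k
    mask_out = valid & visited
    return PhaseMap(unwrapped, "unwrapped", pmap.carrier_frequency,
                    pmap.fringe_axis, pmap.pitch, quality=q, mask=mask_out)


# ---------------------------------------------------------------------------
# Phase-to-height and the end-to-end pipeline
# ---------------------------------------------------------------------------


def phase_to_height(pmap: PhaseMap, geom) -> "object":
    """Convert an unwrapped, reference-subtracted phase map to heights.

    ``h = L * dphi / (dphi - 2 pi f0 D)`` pixelwise; pixels whose
    denominator is near zero are masked.  Exact inverse of the
    triangulation phase model.
    """
    from .scene import SurfaceMap  # deferred: scene imports PhaseMap from here

    if pmap.state != "unwrapped":
        raise ValueError("phase_to_height expects an unwrapped PhaseMap")
    dphi = pmap.values
    denom = dphi - TWO_PI * geom.f0 * geom.D
    ok = np.abs(denom) > 1e-9 * TWO_PI * geom.f0 * geom.D
    heights = np.zeros_like(dphi)
    heights[ok] = geom.L * dphi[ok] / denom[ok]
    return SurfaceMap(heights, pmap.pitch, mask=pmap.mask & ok)


def reconstruct(
    image: np.ndarray,
    pitch: float,
    geom,
    carrier: float | str = "auto",
    halfwidth: tuple[float, float] | None = None,
    reference_image: np.ndarray | None = None,
    border_fraction: float = 0.05,
    unwrap_method: str = "quality",
) -> ReconstructionResult:
    """Full one-shot FTP pipeline on a single frame.

    Composes carrier estimation (or takes ``carrier`` as a known
    frequency), band-pass phase extraction, quality-guided unwrapping,
    global offset removal (median phase over the image border ring is
    forced to zero — the border is reference plane by convention; with a
    ``reference_image`` the reference frame's analytic phase is
    subtracted instead), and phase-to-height conversion with the
    calibrated geometry.  Deterministic given inputs and options.
    """
    img = np.asarray(image, dtype=float)
    if carrier == "auto":
        f0_est, axis, fvec = estimate_carrier(img, pitch)
    else:
        f0_est, axis, fvec = float(carrier), "x", (float(carrier), 0.0)

    pm = extract_wrapped_phase(img, pitch, f0_est, halfwidth=halfwidth)
    if reference_image is not None:
        pm_ref = extract_wrapped_phase(np.asarray(reference_image, float),
                                       pitch, f0_est, halfwidth=halfwidth)
        pm = PhaseMap(
            wrap(pm.values - pm_ref.values), "wrapped", pm.carrier_frequency,
            pm.fringe_axis, pitch, quality=pm.quality,
        )
    un = unwrap_phase(pm, method=unwrap_method)

    ny, nx = img.shape
    bw = max(2, int(border_fraction * min(ny, nx)))
    ring = np.zeros((ny, nx), dtype=bool)
    ring[:bw, :] = ring[-bw:, :] = True
    ring[:, :bw] = ring[:, -bw:] = True
    ring &= un.mask
    offset = float(np.median(un.values[ring])) if ring.any() else 0.0
    centered = PhaseMap(un.values - offset, "unwrapped", un.carrier_frequency,
                        un.fringe_axis, pitch, quality=un.quality, mask=un.mask)

    surface = phase_to_height(centered, geom)
    residues = count_residues(pm.values)
    diagnostics = {
        "carrier_estimate": f0_est,
        "carrier_vector": fvec,
        "carrier_axis": axis,
        "window_halfwidth": halfwidth or (f0_est / 2.0, f0_est / 2.0),
        "residue_count": int(residues.sum()),
        "residue_density": float(residues.mean()),
        "masked_fraction": float(1.0 - surface.mask.mean()),
        "phase_offset": offset,
    }
    return ReconstructionResult(surface=surface, diagnostics=diagnostics)
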