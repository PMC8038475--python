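"""Configuration, logging and artifact I/O.

A single YAML document (:class:`RunConfig`) carries every parameter of a
run — optical train, sampling grid, triangulation geometry, photometric
scene, camera and reconstruction options — validated with field-path
error reporting and rejecting unknown keys.  Artifacts are written with a
manifest listing every file and its SHA-256 checksum; images export as
8/16-bit PNG/TIFF for viewing while the authoritative numeric format is
a lossless float container (``.npz``) with a YAML sidecar.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from . import __version__
from .optics import GridSpec, OpticalSetup
from .scene import CameraModel, PhotometricScene, ProjectionGeometry, SurfaceMap

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "save_config",
    "save_artifacts",
    "save_surface",
    "load_surface",
    "save_image",
    "get_logger",
]

logger = logging.getLogger("fringeftp")


def get_logger(name: str = "fringeftp") -> logging.Logger:
    """Package logger: structured, stage-timed messages at INFO."""
    log = logging.getLogger(name)
    if not log.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        log.addHandler(handler)
        log.setLevel(logging.INFO)
    return log


class ConfigError(ValueError):
    """Configuration failed validation; message lists field paths."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class OpticalConfig(_Strict):
    wavelength_nm: float = 532.0
    Z0: float = 100_000.0
    Z1: float = 150.0
    Z2: float = 150.0
    Z3: float = 3_000.0
    focal_length: float = 150.0
    grating_period: float = 0.02
    grating_slit: float = Field(default=0.01, description="slit width a < d")
    illum_diameter: float = 2.0
    filter_order: int = 1
    filter_slit_width: float = 0.5

    @model_validator(mode="after")
    def _invariants(self):
        for name in ("wavelength_nm", "Z0", "Z1", "Z2", "Z3", "focal_length",
                     "grating_period", "grating_slit", "illum_diameter",
                     "filter_slit_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"optical.{name} must be strictly positive")
        if self.grating_slit >= self.grating_period:
            raise ValueError("optical.grating_slit must be smaller than "
                             "optical.grating_period")
        return self

    def to_setup(self) -> OpticalSetup:
        return OpticalSetup(**self.model_dump())


class GridConfig(_Strict):
    n: int = 2048
    pitch: float | None = None

    def to_grid(self) -> GridSpec:
        return GridSpec(**self.model_dump())


class GeometryConfig(_Strict):
    L: float = 1000.0
    D: float = 300.0
    f0: float = 1.0
    fringe_axis: str = "x"

    def to_geometry(self) -> ProjectionGeometry:
        return ProjectionGeometry(**self.model_dump())


class SurfaceConfig(_Strict):
    kind: str = "cap"  # cap | face | flat
    base_radius: float = 40.0
    cap_height: float = 10.0
    pitch: float = 0.25
    extent: float | None = None
    seed: int = 0
    amplitude: float = 1.0

    @model_validator(mode="after")
    def _check_kind(self):
        if self.kind not in ("cap", "face", "flat"):
            raise ValueError("surface.kind must be one of cap|face|flat")
        return self


class SceneConfig(_Strict):
    direct_albedo: float = 0.1
    scatter_fraction: float = 0.5
    scatter_sigma: float = 2.5
    background_illuminance: float = 0.0
    projector_power: float = 1.0
    textured_albedo: bool = False
    albedo_seed: int = 1

    def to_scene(self, shape=None, pitch=None) -> PhotometricScene:
        albedo: float | np.ndarray = self.direct_albedo
        if self.textured_albedo and shape is not None:
            from .scene import make_skin_albedo

            albedo = make_skin_albedo(self.albedo_seed, shape, pitch,
                                      mean=self.direct_albedo)
        return PhotometricScene(
            direct_albedo=albedo,
            scatter_fraction=self.scatter_fraction,
            scatter_sigma=self.scatter_sigma,
            background_illuminance=self.background_illuminance,
            projector_power=self.projector_power,
        )


class CameraConfig(_Strict):
    filter_on: bool = True
    filter_center_nm: float = 532.0
    filter_fwhm_nm: float = 10.0
    polarizer_on: bool = True
    polarizer_angle: float = 0.0
    photon_fullwell: float | None = 10_000.0
    read_noise: float = 3e-4
    bit_depth: int = 8
    exposure_headroom: float = 1.25

    def to_camera(self) -> CameraModel:
        return CameraModel(**self.model_dump())


class ReconConfig(_Strict):
    carrier: str | float = "auto"
    border_fraction: float = 0.05
    unwrap_method: str = "quality"


class RunConfig(_Strict):
    """Top-level run configuration; round-trips losslessly through YAML."""

    optical: OpticalConfig = OpticalConfig()
    grid: GridConfig = GridConfig()
    geometry: GeometryConfig = GeometryConfig()
    surface: SurfaceConfig = SurfaceConfig()
    scene: SceneConfig = SceneConfig()
    camera: CameraConfig = CameraConfig()
    recon: ReconConfig = ReconConfig()
    seed: int = 0


def _format_validation_error(exc: ValidationError) -> str:
    parts = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        parts.append(f"{loc}: {err['msg']}")
    return "; ".join(parts)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Schema violations raise :class:`ConfigError` naming the offending
    field paths; unknown keys are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(_format_validation_error(exc)) from exc


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.model_dump(), sort_keys=False)
    )


def build_surface(cfg: SurfaceConfig) -> SurfaceMap:
    """Materialize the configured ground-truth surface."""
    from .scene import make_face_phantom, make_spherical_cap

    if cfg.kind == "cap":
        return make_spherical_cap(cfg.base_radius, cfg.cap_height, cfg.pitch,
                                  extent=cfg.extent)
    if cfg.kind == "face":
        return make_face_phantom(cfg.seed, pitch=cfg.pitch,
                                 extent=cfg.extent or 192.0,
                                 amplitude=cfg.amplitude)
    n = int(round((cfg.extent or 120.0) / cfg.pitch))
    return SurfaceMap(np.zeros((n, n)), cfg.pitch)


# ---------------------------------------------------------------------------
# Artifacts
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def save_image(array: np.ndarray, path: str | Path, bit_depth: int = 16) -> None:
    """Export a nonnegative float array as 8/16-bit grayscale PNG/TIFF,
    scaled to full range."""
    arr = np.asarray(array, dtype=float)
    top = arr.max() if arr.max() > 0 else 1.0
    levels = 2**bit_depth - 1
    scaled = np.round(np.clip(arr / top, 0, 1) * levels)
    dtype = np.uint8 if bit_depth <= 8 else np.uint16
    iio.imwrite(Path(path), scaled.astype(dtype))


def save_surface(surface: SurfaceMap, stem: str | Path, meta: dict | None = None) -> list[Path]:
    """Write a surface as a lossless float container plus YAML sidecar."""
    stem = Path(stem)
    npz = stem.with_suffix(".npz")
    np.savez_compressed(npz, heights=surface.heights,
                        mask=surface.mask.astype(np.uint8))
    sidecar = stem.with_suffix(".yaml")
    sidecar.write_text(yaml.safe_dump({
        "pitch": float(surface.pitch),
        "shape": list(surface.heights.shape),
        "package_version": __version__,
        **(meta or {}),
    }, sort_keys=False))
    return [npz, sidecar]


def load_surface(stem: str | Path) -> SurfaceMap:
    """Bit-exact inverse of :func:`save_surface`."""
    stem = Path(stem)
    data = np.load(stem.with_suffix(".npz"))
    meta = yaml.safe_load(stem.with_suffix(".yaml").read_text())
    return SurfaceMap(data["heights"], float(meta["pitch"]),
                      mask=data["mask"].astype(bool))


def save_artifacts(out_dir: str | Path, files: list[Path],
                   meta: dict | None = None) -> Path:
    """Write a manifest for a run's artifacts: every file with its size
    and SHA-256 checksum, plus the exact run metadata."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "meta": meta or {},
        "files": [
            {
                "path": str(Path(f).relative_to(out_dir))
                if Path(f).is_relative_to(out_dir) else str(f),
                "bytes": Path(f).stat().st_size,
                "sha256": _sha256(Path(f)),
            }
            for f in files
        ],
    }
    manifest_path = out_dir / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest_path
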