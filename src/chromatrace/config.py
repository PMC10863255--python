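"""Pipeline configuration: loading, validation, filename decoding.

A single ``parameters.json`` drives the whole pipeline.  The document is
organized as per-module sub-objects (``acquisition``, ``projection``,
``registration``, ``detection``, ``tracing``, ``matrices``, ``runtime``)
so each stage reads only its own section.  Unknown keys warn rather than
error, so configs written for newer versions still load.

Physical coordinates are always micrometres; voxel indices are 0-based
``(z, y, x)``; physical coordinate = index x pixel size.
"""

from __future__ import annotations

import json
import logging
import re
import warnings
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

logger = logging.getLogger("chromatrace")

ChannelRole = Literal["fiducial", "barcode", "mask_nuclei", "mask_library", "rna"]

#: reference filename dialect, the one the simulator writes:
#: ``scan_ROI001_RT05_ch00.tif``  (cycle ``DAPI`` for the nuclear channel)
DEFAULT_FILENAME_PATTERN = (
    r"scan_(?P<roi>[^_]+)_(?P<cycle>[^_]+)_(?P<channel>[^_.]+)\.tiff?$"
)


class ConfigError(ValueError):
    """Configuration schema violation; message names the offending key."""


class _Section(BaseModel):
    model_config = ConfigDict(extra="allow", validate_assignment=True)

    @model_validator(mode="after")
    def _warn_unknown(self):
        extra = getattr(self, "model_extra", None) or {}
        for key in extra:
            warnings.warn(
                f"unknown configuration key {key!r} in section "
                f"{type(self).__name__}; ignored",
                stacklevel=2,
            )
        return self


class AcquisitionConfig(_Section):
    pixel_size_xy: float = Field(0.1, gt=0, description="lateral pixel size, um/px")
    pixel_size_z: float = Field(0.25, gt=0, description="axial plane spacing, um/plane")
    filename_pattern: str = DEFAULT_FILENAME_PATTERN
    #: role of each channel, per cycle; the "default" entry applies to any
    #: cycle without its own override.  Roles: fiducial, barcode,
    #: mask_nuclei, mask_library, rna.
    channel_roles: dict[str, dict[str, ChannelRole]] = Field(
        default_factory=lambda: {
            "default": {"ch00": "fiducial", "ch01": "barcode"},
            "DAPI": {"ch00": "fiducial", "ch01": "mask_nuclei"},
        }
    )
    reference_cycle: Optional[str] = None  # None -> first non-mask cycle seen

    @field_validator("filename_pattern")
    @classmethod
    def _pattern_has_groups(cls, v: str) -> str:
        try:
            pat = re.compile(v)
        except re.error as exc:
            raise ConfigError(f"filename_pattern does not compile: {exc}") from exc
        missing = {"roi", "cycle", "channel"} - set(pat.groupindex)
        if missing:
            raise ConfigError(
                f"filename_pattern lacks named group(s) {sorted(missing)}"
            )
        return v


class ProjectionConfig(_Section):
    mode: Literal["maximum", "sum"] = "maximum"
    mask_mode: Literal["maximum", "sum"] = "sum"  # recommended for masks
    z_range_mode: Literal["manual", "automatic"] = "automatic"
    z_manual: Optional[tuple[int, int]] = None
    z_window: int = Field(5, ge=0, description="half-window around focus, planes")
    block_size: int = Field(64, gt=0, description="focus-finding block, px")


class RegistrationConfig(_Section):
    block_size_2d: int = Field(128, gt=0)
    block_size_3d: tuple[int, int, int] = (0, 128, 128)  # 0 = full z extent
    upsample_factor: int = Field(100, ge=1)
    polling_tolerance: float = Field(1.0, gt=0, description="shift bin width, px")
    shift_error_max: float = Field(5.0, gt=0)
    correction_cap: float = Field(3.0, gt=0, description="max |local correction|, px/axis")
    interpolation: Literal["spline", "fourier"] = "spline"
    upsample_factor_3d: int = Field(20, ge=1)
    #: how a localization picks up its local 3D correction: value of the
    #: containing block, or a smooth bilinear surface fitted to the
    #: per-block corrections at their signal anchors (tracks smooth
    #: deformation fields better than the piecewise-constant lookup)
    local_interpolation: Literal["block", "surface_fit"] = "surface_fit"


class SpotDetectionConfig(_Section):
    name: str = "log"  # plugin name in the detector registry
    threshold_k: float = Field(8.0, gt=0, description="MAD multiples above median")
    min_distance: int = Field(2, ge=1, description="min separation of maxima, px")


class DetectionConfig(_Section):
    spot_detection: SpotDetectionConfig = Field(default_factory=SpotDetectionConfig)
    psf_sigma_xy: float = Field(0.13, gt=0, description="um")
    psf_sigma_z: float = Field(0.35, gt=0, description="um")
    fit_box: tuple[int, int, int] = (7, 9, 9)
    intensity_min: float = Field(0.0, ge=0, description="counts")
    sigma_xy_bounds: tuple[float, float] = (0.02, 0.6)  # um
    sigma_z_bounds: tuple[float, float] = (0.05, 1.5)  # um
    mask_size_bounds: tuple[int, int] = (200, 2_000_000)  # voxels
    mask_smooth_sigma: float = Field(1.0, ge=0, description="px")
    mask_seed_min_distance: int = Field(10, ge=1, description="px")
    mask_segmenter: str = "classical"  # plugin name in the segmenter registry
    sharpness_bounds: tuple[float, float] = (0.2, 2.0)
    roundness_max: float = Field(0.5, gt=0)


class TracingConfig(_Section):
    mode: Literal["masking", "clustering"] = "masking"
    clustering_radius: float = Field(0.5, gt=0, description="um")
    mask_assign_majority: float = Field(0.5, ge=0, le=1)
    min_barcodes: int = Field(1, ge=1)


class MatrixConfig(_Section):
    proximity_threshold: float = Field(0.25, gt=0, description="um")
    kde_bandwidth: str | float = "scott"  # "scott" or a fixed bandwidth in um
    kde_n_min: int = Field(10, ge=1)
    proximity_denominator: Literal["codetection", "all_traces"] = "codetection"

    @field_validator("kde_bandwidth")
    @classmethod
    def _bandwidth_valid(cls, v):
        if isinstance(v, str):
            if v != "scott":
                raise ConfigError("kde_bandwidth must be 'scott' or a positive number")
            return v
        if v <= 0:
            raise ConfigError("kde_bandwidth must be 'scott' or a positive number")
        return float(v)


class RuntimeConfig(_Section):
    n_workers: int = Field(1, ge=1)
    seed: Optional[int] = None  # seeds trace UUIDs when set


class PipelineConfig(_Section):
    acquisition: AcquisitionConfig = Field(default_factory=AcquisitionConfig)
    projection: ProjectionConfig = Field(default_factory=ProjectionConfig)
    registration: RegistrationConfig = Field(default_factory=RegistrationConfig)
    detection: DetectionConfig = Field(default_factory=DetectionConfig)
    tracing: TracingConfig = Field(default_factory=TracingConfig)
    matrices: MatrixConfig = Field(default_factory=MatrixConfig)
    runtime: RuntimeConfig = Field(default_factory=RuntimeConfig)

    def role_of(self, cycle: str, channel: str) -> ChannelRole:
        """Role of *channel* in *cycle*, falling back to the default map."""
        roles = self.acquisition.channel_roles
        table = roles.get(cycle, roles.get("default", {}))
        if channel not in table:
            raise ConfigError(
                f"no channel role configured for cycle={cycle!r} channel={channel!r}"
            )
        return table[channel]

    def to_dict(self) -> dict:
        return json.loads(self.model_dump_json())


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate ``parameters.json``.

    Unspecified keys take the documented defaults; the effective merged
    configuration is echoed to the run log at INFO level.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"configuration file not found: {path}")
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"{path} is not valid JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path} must contain a JSON object at top level")
    try:
        config = PipelineConfig.model_validate(raw)
    except ConfigError:
        raise
    except Exception as exc:  # pydantic ValidationError carries the key path
        raise ConfigError(f"invalid configuration in {path}: {exc}") from exc
    logger.info("effective configuration: %s", json.dumps(config.to_dict(), indent=2))
    return config


def write_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(config.to_dict(), indent=2) + "\n")


class FileRecord(BaseModel):
    """One input TIFF, with the identity decoded from its filename."""

    path: Path
    roi: str
    cycle: str
    channel: str
    role: ChannelRole


class DecodeError(ValueError):
    pass


def decode_filename(
    name: str | Path, config: PipelineConfig, path: str | Path | None = None
) -> FileRecord:
    """Decode roi/cycle/channel from a filename via the configured regex."""
    base = Path(name).name
    pattern = re.compile(config.acquisition.filename_pattern)
    m = pattern.search(base)
    if m is None:
        raise DecodeError(
            f"filename {base!r} does not match pattern "
            f"{config.acquisition.filename_pattern!r}"
        )
    roi, cycle, channel = m.group("roi"), m.group("cycle"), m.group("channel")
    return FileRecord(
        path=Path(path) if path is not None else Path(name),
        roi=roi,
        cycle=cycle,
        channel=channel,
        role=config.role_of(cycle, channel),
    )


def encode_filename(roi: str, cycle: str, channel: str) -> str:
    """Reference naming scheme (the dialect the simulator writes)."""
    return f"scan_{roi}_{cycle}_{channel}.tif"


def scan_directory(directory: str | Path, config: PipelineConfig) -> list[FileRecord]:
    """Decode every TIFF in *directory*; non-matching files are skipped with a log line."""
    records = []
    for path in sorted(Path(directory).glob("*.tif*")):
        try:
            records.append(decode_filename(path.name, config, path=path))
        except DecodeError:
            logger.warning("skipping %s: does not match filename pattern", path.name)
    return records
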