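"""3D image stacks: the raw input unit of the pipeline.

A stack is a multi-page grayscale TIFF read as a ``(z, y, x)`` voxel
array, tagged with the ROI / hybridization cycle / channel role decoded
from its filename.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .config import FileRecord, PipelineConfig


class StackFormatError(ValueError):
    pass


@dataclass
class ImageStack:
    voxels: np.ndarray  # (z, y, x), non-negative integers
    roi: str
    cycle: str
    role: str
    pixel_size_xy: float  # um/px
    pixel_size_z: float  # um/plane

    def __post_init__(self) -> None:
        if self.voxels.ndim == 2:
            self.voxels = self.voxels[None]
        if self.voxels.ndim != 3:
            raise StackFormatError(
                f"stack must be 3D (z,y,x); got shape {self.voxels.shape}"
            )
        if self.voxels.shape[0] < 1:
            raise StackFormatError("stack has no planes")

    @property
    def n_planes(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def to_um(self, zyx_px: np.ndarray) -> np.ndarray:
        """Convert (z,y,x) pixel coordinates to micrometres."""
        scale = np.array([self.pixel_size_z, self.pixel_size_xy, self.pixel_size_xy])
        return np.asarray(zyx_px, dtype=float) * scale


def read_stack(record: FileRecord, config: PipelineConfig) -> ImageStack:
    """Read a multi-page grayscale TIFF as an ImageStack."""
    data = tifffile.imread(record.path)
    if data.ndim == 3 and data.shape[-1] in (3, 4) and data.shape[-1] < data.shape[-2]:
        raise StackFormatError(f"{record.path}: RGB(A) TIFF, expected grayscale stack")
    if data.ndim not in (2, 3):
        raise StackFormatError(
            f"{record.path}: expected 2D or 3D grayscale data, got shape {data.shape}"
        )
    return ImageStack(
        voxels=np.asarray(data),
        roi=record.roi,
        cycle=record.cycle,
        role=record.role,
        pixel_size_xy=config.acquisition.pixel_size_xy,
        pixel_size_z=config.acquisition.pixel_size_z,
    )


def write_stack(voxels: np.ndarray, path: str | Path) -> None:
    """Write a (z,y,x) array as a multi-page 16-bit TIFF."""
    voxels = np.asarray(voxels)
    if voxels.dtype != np.uint16:
        voxels = np.clip(voxels, 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(Path(path), voxels)
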