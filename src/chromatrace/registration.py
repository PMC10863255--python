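"""Drift correction from fiducial images.

Two levels of registration:

* **global 2D** — per-cycle rigid shift of the z-reprojected fiducial
  against the reference cycle.  A plain whole-image cross-correlation is
  fragile when fiducial images contain impurities that vary between
  cycles, so the robust path tiles the image into blocks, registers each
  block independently, and polls for the most popular shift
  (``align_by_block``).
* **local 3D** — after global correction, the fiducial stacks are tiled
  into 3D blocks and each block is re-registered by 3D cross-correlation,
  capturing smooth sample deformations in the hundreds-of-nm range that
  a rigid shift cannot.

Sign convention (used everywhere): the stored shift is the vector ADDED
to moving-image coordinates to land in reference coordinates.  The same
vector, applied to the moving image with :func:`apply_shift`, aligns it
onto the reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.registration import phase_cross_correlation

__all__ = [
    "phase_shift",
    "align_by_block",
    "apply_shift",
    "apply_shift_stack",
    "align_3d_blocks",
    "BlockDiagnostics",
]


class RegistrationError(ValueError):
    pass


def phase_shift(
    reference: np.ndarray, moving: np.ndarray, upsample_factor: int = 100
) -> tuple[float, float, float]:
    """Sub-pixel rigid shift between two 2D images.

    Returns ``(dy, dx, error)``: the translation that maps *moving* onto
    *reference* at precision ``1/upsample_factor``, from the Fourier
    cross-correlation peak with local upsampling; *error* is the
    normalized RMS residual of the registration.
    """
    reference = np.asarray(reference, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if reference.shape != moving.shape:
        raise RegistrationError(
            f"shape mismatch {reference.shape} vs {moving.shape}"
        )
    if np.ptp(reference) == 0 or np.ptp(moving) == 0:
        raise RegistrationError("constant image: no correlation peak")
    shift, error, _ = phase_cross_correlation(
        reference, moving, upsample_factor=upsample_factor, normalization=None
    )
    return float(shift[0]), float(shift[1]), float(error)


@dataclass
class BlockDiagnostics:
    """Per-block registration outcomes behind one polled global shift."""

    block_shifts: np.ndarray  # (n, 2) sub-pixel per-block shifts
    block_errors: np.ndarray
    winner_mask: np.ndarray  # blocks in the winning poll bin
    winning_fraction: float
    n_valid_blocks: int
    fallback: bool = False  # True when whole-image registration was used


def _tile_slices(n: int, block: int) -> list[slice]:
    return [slice(i * block, (i + 1) * block) for i in range(n // block)]


def align_by_block(
    reference: np.ndarray,
    moving: np.ndarray,
    block_size: int = 128,
    tolerance: float = 1.0,
    upsample_factor: int = 100,
) -> tuple[tuple[float, float], BlockDiagnostics]:
    """Impurity-robust global 2D registration by block polling.

    Both images are tiled into non-overlapping ``block_size`` squares and
    each pair of blocks is registered independently.  Block shifts are
    clustered by rounding to *tolerance*-wide bins; the most populated
    bin wins and the returned global shift is the mean of its members'
    sub-pixel shifts.  Ties break by lower mean registration error, then
    by smaller shift magnitude.  Stage drift is shared by every block
    while impurity-driven shifts are dispersed, which is what makes the
    poll robust.
    """
    reference = np.asarray(reference, dtype=float)
    moving = np.asarray(moving, dtype=float)
    ny, nx = reference.shape
    shifts, errors = [], []
    for ys in _tile_slices(ny, block_size):
        for xs in _tile_slices(nx, block_size):
            ref_b, mov_b = reference[ys, xs], moving[ys, xs]
            if np.ptp(ref_b) == 0 or np.ptp(mov_b) == 0:
                continue
            dy, dx, err = phase_shift(ref_b, mov_b, upsample_factor)
            shifts.append((dy, dx))
            errors.append(err)

    if len(shifts) < 2:
        dy, dx, err = phase_shift(reference, moving, upsample_factor)
        diag = BlockDiagnostics(
            block_shifts=np.array([[dy, dx]]), block_errors=np.array([err]),
            winner_mask=np.array([True]), winning_fraction=1.0,
            n_valid_blocks=len(shifts), fallback=True,
        )
        return (dy, dx), diag

    shifts_arr = np.asarray(shifts)
    errors_arr = np.asarray(errors)
    bins = np.round(shifts_arr / tolerance).astype(int)
    candidates: dict[tuple[int, int], np.ndarray] = {}
    for key in {tuple(b) for b in bins}:
        candidates[key] = np.all(bins == key, axis=1)

    def rank(key):
        members = candidates[key]
        return (
            -members.sum(),
            errors_arr[members].mean(),
            np.linalg.norm(shifts_arr[members].mean(axis=0)),
        )

    winner = min(candidates, key=rank)
    members = candidates[winner]
    # combine winning blocks weighted by inverse squared registration error:
    # blocks with more fiducial signal register better and count for more
    weights = 1.0 / np.maximum(errors_arr[members], 1e-6) ** 2
    global_shift = (shifts_arr[members] * weights[:, None]).sum(axis=0) \
        / weights.sum()
    diag = BlockDiagnostics(
        block_shifts=shifts_arr, block_errors=errors_arr, winner_mask=members,
        winning_fraction=members.sum() / len(shifts_arr),
        n_valid_blocks=len(shifts_arr),
    )
    return (float(global_shift[0]), float(global_shift[1])), diag


def apply_shift(
    image: np.ndarray, shift: tuple[float, float], method: str = "spline"
) -> np.ndarray:
    """Translate a 2D image by a sub-pixel shift (out-of-field pixels -> 0)."""
    if not np.all(np.isfinite(shift)):
        raise RegistrationError(f"non-finite shift {shift}")
    image = np.asarray(image, dtype=float)
    if method == "spline":
        return ndimage.shift(image, shift, order=3, mode="constant", cval=0.0)
    if method == "fourier":
        out = np.fft.ifftn(ndimage.fourier_shift(np.fft.fftn(image), shift)).real
        return out
    raise ValueError(f"unknown interpolation method {method!r}")


def apply_shift_stack(stack: np.ndarray, shift: tuple[float, float],
                      method: str = "spline") -> np.ndarray:
    """Apply a 2D (dy, dx) shift to every plane of a (z,y,x) stack."""
    return np.stack([apply_shift(plane, shift, method) for plane in
                     np.asarray(stack, dtype=float)])


def align_3d_blocks(
    reference: np.ndarray,
    moving: np.ndarray,
    global_shift: tuple[float, float],
    block_size_3d: tuple[int, int, int] = (0, 128, 128),
    correction_cap: float = 3.0,
    upsample_factor: int = 10,
) -> pd.DataFrame:
    """Local 3D registration of fiducial stacks after global 2D correction.

    The moving stack is first corrected plane-wise by *global_shift*,
    then both stacks are tiled into 3D blocks (a z size of 0 means the
    full z extent) and each block pair is registered by 3D Fourier
    cross-correlation.  Corrections larger than *correction_cap* on any
    axis, and blocks without usable signal, are replaced by (0,0,0) and
    flagged low-quality.

    Returns the local-correction table: one row per block with the block
    index, voxel bounds, the (dz, dy, dx) correction to ADD to
    globally-corrected coordinates, and a quality score (normalized
    cross-correlation after correction, in [-1, 1]).
    """
    reference = np.asarray(reference, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if reference.shape != moving.shape:
        raise RegistrationError(
            f"shape mismatch {reference.shape} vs {moving.shape}"
        )
    corrected = apply_shift_stack(moving, global_shift)
    nz, ny, nx = reference.shape
    bz = block_size_3d[0] if block_size_3d[0] > 0 else nz
    by, bx = block_size_3d[1], block_size_3d[2]

    z_slices = _tile_slices(nz, bz) or [slice(0, nz)]
    y_slices = _tile_slices(ny, by) or [slice(0, ny)]
    x_slices = _tile_slices(nx, bx) or [slice(0, nx)]

    rows = []
    for iz, zs in enumerate(z_slices):
        for iy, ys in enumerate(y_slices):
            for ix, xs in enumerate(x_slices):
                ref_b = reference[zs, ys, xs]
                mov_b = corrected[zs, ys, xs]
                row = {
                    "block_z": iz, "block_y": iy, "block_x": ix,
                    "z_min": zs.start, "z_max": zs.stop,
                    "y_min": ys.start, "y_max": ys.stop,
                    "x_min": xs.start, "x_max": xs.stop,
                    "anchor_z": (zs.start + zs.stop - 1) / 2,
                    "anchor_y": (ys.start + ys.stop - 1) / 2,
                    "anchor_x": (xs.start + xs.stop - 1) / 2,
                    "dz_px": 0.0, "dy_px": 0.0, "dx_px": 0.0,
                    "quality": 0.0, "flagged": True,
                }
                # the measured correction reflects the deformation where the
                # block's signal actually sits; anchor it at the intensity
                # centroid rather than the geometric center
                w = np.clip(ref_b - np.median(ref_b), 0, None)
                if w.sum() > 0:
                    gz, gy, gx = np.meshgrid(
                        np.arange(zs.start, zs.stop, dtype=float),
                        np.arange(ys.start, ys.stop, dtype=float),
                        np.arange(xs.start, xs.stop, dtype=float),
                        indexing="ij", sparse=True)
                    row["anchor_z"] = float((w * gz).sum() / w.sum())
                    row["anchor_y"] = float((w * gy).sum() / w.sum())
                    row["anchor_x"] = float((w * gx).sum() / w.sum())
                if np.ptp(ref_b) > 0 and np.ptp(mov_b) > 0:
                    shift, _, _ = phase_cross_correlation(
                        ref_b, mov_b, upsample_factor=upsample_factor,
                        normalization=None,
                    )
                    if np.all(np.abs(shift) <= correction_cap):
                        realigned = ndimage.shift(mov_b, shift, order=1,
                                                  mode="constant", cval=0.0)
                        r = np.corrcoef(ref_b.ravel(), realigned.ravel())[0, 1]
                        row.update(
                            dz_px=float(shift[0]), dy_px=float(shift[1]),
                            dx_px=float(shift[2]),
                            quality=float(r) if np.isfinite(r) else 0.0,
                            flagged=False,
                        )
                rows.append(row)

    table = pd.DataFrame(rows)
    table.attrs["units"] = {c: "pix" for c in table.columns
                            if c.endswith(("_px", "_min", "_max"))}
    table.attrs["meta"] = {
        "global_shift_dy_px": float(global_shift[0]),
        "global_shift_dx_px": float(global_shift[1]),
        "correction_cap_px": correction_cap,
    }
    return table


def global_shift_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble the per-(roi, cycle) global shift table."""
    table = pd.DataFrame(
        rows,
        columns=["roi", "cycle", "dy_px", "dx_px", "rms_error",
                 "n_blocks_agreeing", "method"],
    )
    table.attrs["units"] = {"dy_px": "pix", "dx_px": "pix"}
    return table
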