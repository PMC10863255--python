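"""DNA-FISH spot localization and nuclear/library mask segmentation.

The 3D path detects candidate spots with a Laplacian-of-Gaussian matched
to the PSF scale, then refines each candidate by least-squares fitting
of an anisotropic 3D Gaussian (shared lateral sigma, separate axial
sigma) over a small crop.  The fast 2D path localizes spots on
registered projections with a DAOFIND-style matched filter plus
sharpness/roundness gates.  Masks are segmented by a classical
smoothing / thresholding / watershed chain.

Both the spot detector and the mask segmenter are named plugins: a
deep-learning segmenter (StarDist, Cellpose, ...) can be registered
under a new name and used by the pipeline without touching any
downstream code.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import least_squares
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from .config import DetectionConfig, PipelineConfig
from .stack import ImageStack

__all__ = [
    "detect_spot_candidates",
    "fit_gaussian_3d",
    "locate_spots_3d",
    "segment_masks_3d",
    "segment_masks_2d",
    "locate_spots_2d",
    "filter_localizations",
    "register_localizations",
    "register_spot_detector",
    "register_mask_segmenter",
]

LOC_UNITS = {
    "z_px": "pix", "y_px": "pix", "x_px": "pix",
    "z_um": "um", "y_um": "um", "x_um": "um",
    "sigma_xy_um": "um", "sigma_z_um": "um",
    "amplitude": "ct", "background": "ct",
}


# --------------------------------------------------------------------------
# plugin registries

SPOT_DETECTORS: dict[str, Callable] = {}
MASK_SEGMENTERS: dict[str, Callable] = {}


def register_spot_detector(name: str):
    """Register ``f(voxels, sigma_px, **params) -> (n, 3) candidate array``."""
    def deco(fn):
        SPOT_DETECTORS[name] = fn
        return fn
    return deco


def register_mask_segmenter(name: str):
    """Register ``f(voxels, config) -> integer label array``."""
    def deco(fn):
        MASK_SEGMENTERS[name] = fn
        return fn
    return deco


# --------------------------------------------------------------------------
# 3D spot detection

def _mad(a: np.ndarray) -> float:
    med = np.median(a)
    return float(np.median(np.abs(a - med)))


@register_spot_detector("log")
def _log_detector(voxels: np.ndarray, sigma_px: tuple[float, float],
                  threshold_k: float = 8.0, min_distance: int = 2) -> np.ndarray:
    """Laplacian-of-Gaussian at the PSF scale + adaptive local-maxima threshold.

    The threshold is ``median + k * MAD`` of the LoG response, which adapts
    to the noise floor without assuming a background level.
    """
    sz, sxy = sigma_px
    response = -ndimage.gaussian_laplace(
        np.asarray(voxels, dtype=float), sigma=(sz, sxy, sxy)
    )
    thr = np.median(response) + threshold_k * _mad(response)
    peaks = peak_local_max(
        response, min_distance=min_distance, threshold_abs=thr,
        exclude_border=2,  # the LoG response is unreliable at the boundary
    )
    return peaks.astype(float)


def detect_spot_candidates(stack: ImageStack, config: DetectionConfig) -> np.ndarray:
    """Candidate spot centroids (z,y,x voxels) via the configured detector plugin."""
    det = config.spot_detection
    if det.name not in SPOT_DETECTORS:
        raise KeyError(
            f"unknown spot detector {det.name!r}; registered: "
            f"{sorted(SPOT_DETECTORS)}"
        )
    sigma_px = (config.psf_sigma_z / stack.pixel_size_z,
                config.psf_sigma_xy / stack.pixel_size_xy)
    return SPOT_DETECTORS[det.name](
        stack.voxels, sigma_px,
        threshold_k=det.threshold_k, min_distance=det.min_distance,
    )


# --------------------------------------------------------------------------
# 3D Gaussian fitting

def _gauss3d(params, zz, yy, xx):
    amp, z0, y0, x0, sz, sxy, bg = params
    return bg + amp * np.exp(
        -((zz - z0) ** 2) / (2 * sz ** 2)
        - ((yy - y0) ** 2) / (2 * sxy ** 2)
        - ((xx - x0) ** 2) / (2 * sxy ** 2)
    )


def fit_gaussian_3d(
    voxels: np.ndarray,
    centroid: tuple[float, float, float],
    box: tuple[int, int, int] = (7, 9, 9),
    sigma_init_px: tuple[float, float] = (1.5, 1.3),
) -> dict:
    """Least-squares fit of an anisotropic 3D Gaussian around a candidate.

    The model is ``amplitude * G(z, y, x; center, sigma_z, sigma_xy) +
    background`` over the cropped box.  Initial values: center = the
    intensity-weighted centroid of the (background-subtracted) box,
    sigmas = the configured PSF scales, background = the box median.
    Non-converged fits keep the candidate centroid with ``converged=False``.
    """
    voxels = np.asarray(voxels, dtype=float)
    nz, ny, nx = voxels.shape
    cz, cy, cx = (int(round(c)) for c in centroid)
    hz, hy, hx = box[0] // 2, box[1] // 2, box[2] // 2
    zlo, zhi = max(0, cz - hz), min(nz, cz + hz + 1)
    ylo, yhi = max(0, cy - hy), min(ny, cy + hy + 1)
    xlo, xhi = max(0, cx - hx), min(nx, cx + hx + 1)
    crop = voxels[zlo:zhi, ylo:yhi, xlo:xhi]

    failed = {
        "z_px": float(centroid[0]), "y_px": float(centroid[1]),
        "x_px": float(centroid[2]), "sigma_z_px": np.nan, "sigma_xy_px": np.nan,
        "amplitude": np.nan, "background": np.nan, "residual": np.nan,
        "converged": False,
    }
    if crop.size < 27 or np.ptp(crop) == 0:
        return failed

    bg0 = float(np.median(crop))
    w = np.clip(crop - bg0, 0, None)
    zz, yy, xx = np.meshgrid(
        np.arange(zlo, zhi, dtype=float),
        np.arange(ylo, yhi, dtype=float),
        np.arange(xlo, xhi, dtype=float),
        indexing="ij",
    )
    wsum = w.sum()
    if wsum <= 0:
        return failed
    z0 = float((w * zz).sum() / wsum)
    y0 = float((w * yy).sum() / wsum)
    x0 = float((w * xx).sum() / wsum)
    amp0 = max(float(crop.max() - bg0), 1.0)
    p0 = [amp0, z0, y0, x0, sigma_init_px[0], sigma_init_px[1], bg0]
    lower = [0.0, zlo - 1, ylo - 1, xlo - 1, 0.2, 0.2, -np.inf]
    upper = [np.inf, zhi, yhi, xhi, (zhi - zlo) * 2.0, (yhi - ylo) * 2.0, np.inf]

    try:
        res = least_squares(
            lambda p: (_gauss3d(p, zz, yy, xx) - crop).ravel(),
            p0, bounds=(lower, upper), method="trf", xtol=1e-10, ftol=1e-10,
        )
    except Exception:
        return failed
    amp, zf, yf, xf, szf, sxyf, bgf = res.x
    rms = float(np.sqrt(np.mean(res.fun ** 2)))
    converged = bool(res.success) and amp > 0 and np.isfinite(res.x).all()
    if not converged:
        return failed
    return {
        "z_px": float(zf), "y_px": float(yf), "x_px": float(xf),
        "sigma_z_px": float(szf), "sigma_xy_px": float(sxyf),
        "amplitude": float(amp), "background": float(bgf), "residual": rms,
        "converged": True,
    }


def locate_spots_3d(stack: ImageStack, config: DetectionConfig,
                    barcode: int = 0) -> pd.DataFrame:
    """Detect + fit all spots of one cycle; returns a localization table."""
    candidates = detect_spot_candidates(stack, config)
    sigma_init = (config.psf_sigma_z / stack.pixel_size_z,
                  config.psf_sigma_xy / stack.pixel_size_xy)
    rows = []
    for i, c in enumerate(candidates):
        fit = fit_gaussian_3d(stack.voxels, tuple(c), box=config.fit_box,
                              sigma_init_px=sigma_init)
        rows.append({
            "spot_id": i,
            "roi": stack.roi,
            "cycle": stack.cycle,
            "barcode": barcode,
            "z_px": fit["z_px"], "y_px": fit["y_px"], "x_px": fit["x_px"],
            "z_um": fit["z_px"] * stack.pixel_size_z,
            "y_um": fit["y_px"] * stack.pixel_size_xy,
            "x_um": fit["x_px"] * stack.pixel_size_xy,
            "sigma_xy_um": fit["sigma_xy_px"] * stack.pixel_size_xy,
            "sigma_z_um": fit["sigma_z_px"] * stack.pixel_size_z,
            "amplitude": fit["amplitude"],
            "background": fit["background"],
            "residual": fit["residual"],
            "converged": fit["converged"],
            "registered": False,
            "block_quality": 0.0,
            "mode": "3d",
        })
    table = pd.DataFrame(rows, columns=list(_EMPTY_LOC_SCHEMA))
    table = table.astype(_EMPTY_LOC_SCHEMA) if len(table) else empty_localizations()
    table.attrs["units"] = dict(LOC_UNITS)
    table.attrs["meta"] = {"detector": config.spot_detection.name}
    return table


_EMPTY_LOC_SCHEMA = {
    "spot_id": "int64", "roi": "object", "cycle": "object", "barcode": "int64",
    "z_px": "float64", "y_px": "float64", "x_px": "float64",
    "z_um": "float64", "y_um": "float64", "x_um": "float64",
    "sigma_xy_um": "float64", "sigma_z_um": "float64",
    "amplitude": "float64", "background": "float64", "residual": "float64",
    "converged": "bool", "registered": "bool", "block_quality": "float64",
    "mode": "object",
}


def empty_localizations() -> pd.DataFrame:
    table = pd.DataFrame({c: pd.Series(dtype=t)
                          for c, t in _EMPTY_LOC_SCHEMA.items()})
    table.attrs["units"] = dict(LOC_UNITS)
    table.attrs["meta"] = {}
    return table


# --------------------------------------------------------------------------
# mask segmentation

@register_mask_segmenter("classical")
def _classical_segmenter(voxels: np.ndarray, config: DetectionConfig) -> np.ndarray:
    """Smooth -> Otsu -> fill holes -> distance-seeded watershed -> size filter."""
    img = np.asarray(voxels, dtype=float)
    if config.mask_smooth_sigma > 0:
        img = ndimage.gaussian_filter(img, config.mask_smooth_sigma)
    if np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=np.int32)
    thr = threshold_otsu(img)
    binary = img > thr
    binary = ndimage.binary_fill_holes(binary)
    if not binary.any():
        return np.zeros(img.shape, dtype=np.int32)
    distance = ndimage.distance_transform_edt(binary)
    seeds = peak_local_max(
        distance, min_distance=config.mask_seed_min_distance,
        labels=binary, exclude_border=False,
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    for i, s in enumerate(seeds, start=1):
        markers[tuple(s)] = i
    labels = watershed(-distance, markers, mask=binary)
    return labels.astype(np.int32)


def _postprocess_labels(labels: np.ndarray,
                        size_bounds: tuple[int, int]) -> np.ndarray:
    """Drop labels outside the size bounds and relabel contiguously 1..K."""
    out = np.zeros_like(labels, dtype=np.int32)
    next_label = 1
    for lab in np.unique(labels):
        if lab == 0:
            continue
        mask = labels == lab
        size = int(mask.sum())
        if size_bounds[0] <= size <= size_bounds[1]:
            out[mask] = next_label
            next_label += 1
    return out


def segment_masks_3d(stack: ImageStack, config: DetectionConfig) -> np.ndarray:
    """3D nuclear / library mask segmentation via the configured plugin.

    Size bounds are applied after segmentation and the surviving labels
    are renumbered 1..K.  An image with no foreground yields K=0.
    """
    name = config.mask_segmenter
    if name not in MASK_SEGMENTERS:
        raise KeyError(f"unknown mask segmenter {name!r}; registered: "
                       f"{sorted(MASK_SEGMENTERS)}")
    labels = MASK_SEGMENTERS[name](stack.voxels, config)
    return _postprocess_labels(labels, config.mask_size_bounds)


def segment_masks_2d(image: np.ndarray, config: DetectionConfig,
                     size_bounds: tuple[int, int] | None = None) -> np.ndarray:
    """Planar variant of the classical mask chain, for the fast 2D mode."""
    labels = _classical_segmenter(np.asarray(image, dtype=float)[None], config)[0]
    if size_bounds is None:
        # areas scale as the 2/3 power of the volume bounds
        lo, hi = config.mask_size_bounds
        size_bounds = (max(1, int(lo ** (2 / 3))), int(hi ** (2 / 3)) + 1)
    return _postprocess_labels(labels, size_bounds)


# --------------------------------------------------------------------------
# 2D spot localization (fast mode)

def _gauss2d(params, yy, xx):
    amp, y0, x0, s, bg = params
    return bg + amp * np.exp(-((yy - y0) ** 2 + (xx - x0) ** 2) / (2 * s ** 2))


def locate_spots_2d(
    image: np.ndarray,
    config: DetectionConfig,
    pixel_size_xy: float,
    focus_plane: int = 0,
    pixel_size_z: float = 1.0,
    roi: str = "",
    cycle: str = "",
    barcode: int = 0,
) -> pd.DataFrame:
    """DAOFIND-style sub-pixel 2D spot localization on a projection.

    The image is cross-correlated with a Gaussian kernel at the PSF
    scale; local maxima of the matched-filter response above an adaptive
    ``median + k*MAD`` threshold become candidates.  Each candidate is
    gated on sharpness (peak over matched-filter response) and roundness
    (second-moment anisotropy), then refined with a 2D Gaussian fit.
    The z column is set to the projection's focus plane and the row is
    flagged ``mode="2d"`` so 2D tables stay schema-compatible with 3D.
    """
    img = np.asarray(image, dtype=float)
    table = empty_localizations()
    if np.ptp(img) == 0:
        return table
    sigma = config.psf_sigma_xy / pixel_size_xy
    bg = np.median(img)
    # matched filter scaled so a matched Gaussian keeps its peak amplitude
    density = ndimage.gaussian_filter(img - bg, sigma) * 2.0
    thr = np.median(density) + config.spot_detection.threshold_k * _mad(density)
    peaks = peak_local_max(density, min_distance=config.spot_detection.min_distance,
                           threshold_abs=thr, exclude_border=False)
    rows = []
    h = 4
    ny, nx = img.shape
    for py, px in peaks:
        ylo, yhi = max(0, py - h), min(ny, py + h + 1)
        xlo, xhi = max(0, px - h), min(nx, px + h + 1)
        crop = img[ylo:yhi, xlo:xhi] - bg
        if crop.size < 9 or np.ptp(crop) == 0:
            continue
        sharp = img[py, px] - bg
        sharpness = sharp / density[py, px] if density[py, px] > 0 else 0.0
        w = np.clip(crop, 0, None)
        yy, xx = np.meshgrid(np.arange(ylo, yhi, dtype=float),
                             np.arange(xlo, xhi, dtype=float), indexing="ij")
        wsum = w.sum()
        if wsum <= 0:
            continue
        my = (w * (yy - (w * yy).sum() / wsum) ** 2).sum() / wsum
        mx = (w * (xx - (w * xx).sum() / wsum) ** 2).sum() / wsum
        roundness = 2 * (my - mx) / (my + mx) if (my + mx) > 0 else 0.0
        lo_s, hi_s = config.sharpness_bounds
        if not (lo_s <= sharpness <= hi_s) or abs(roundness) > config.roundness_max:
            continue
        p0 = [max(sharp, 1.0), float(py), float(px), sigma, 0.0]
        try:
            res = least_squares(
                lambda p: (_gauss2d(p, yy, xx) - crop).ravel(), p0,
                bounds=([0, ylo - 1, xlo - 1, 0.2, -np.inf],
                        [np.inf, yhi, xhi, (yhi - ylo) * 2.0, np.inf]),
            )
        except Exception:
            continue
        amp, yf, xf, sf, bgf = res.x
        rows.append({
            "spot_id": len(rows), "roi": roi, "cycle": cycle, "barcode": barcode,
            "z_px": float(focus_plane), "y_px": float(yf), "x_px": float(xf),
            "z_um": focus_plane * pixel_size_z,
            "y_um": yf * pixel_size_xy, "x_um": xf * pixel_size_xy,
            "sigma_xy_um": sf * pixel_size_xy, "sigma_z_um": np.nan,
            "amplitude": float(amp), "background": float(bgf + bg),
            "residual": float(np.sqrt(np.mean(res.fun ** 2))),
            "converged": bool(res.success), "registered": False,
            "block_quality": 0.0, "mode": "2d",
        })
    if rows:
        table = pd.DataFrame(rows).astype(_EMPTY_LOC_SCHEMA)
        table.attrs["units"] = dict(LOC_UNITS)
        table.attrs["meta"] = {"detector": "daofind2d"}
    return table


# --------------------------------------------------------------------------
# filtering and registration of localization tables

def filter_localizations(
    table: pd.DataFrame,
    intensity_min: float = 0.0,
    sigma_xy_bounds: tuple[float, float] | None = None,
    sigma_z_bounds: tuple[float, float] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Quality-filter a localization table (non-destructive: new table).

    Keeps rows that converged, with amplitude >= *intensity_min* and
    fitted sigmas within bounds.  Returns the filtered table and a report
    of row counts removed per criterion.
    """
    keep = table["converged"].to_numpy(dtype=bool)
    report = {"input": int(len(table)),
              "removed_not_converged": int((~keep).sum())}

    amp_ok = table["amplitude"].to_numpy() >= intensity_min
    report["removed_intensity"] = int((keep & ~amp_ok).sum())
    keep &= amp_ok

    if sigma_xy_bounds is not None:
        is3d = table["mode"].to_numpy() != "2d"
        s = table["sigma_xy_um"].to_numpy()
        ok = (s >= sigma_xy_bounds[0]) & (s <= sigma_xy_bounds[1])
        report["removed_sigma_xy"] = int((keep & ~ok).sum())
        keep &= ok
        if sigma_z_bounds is not None:
            sz = table["sigma_z_um"].to_numpy()
            okz = ~is3d | ((sz >= sigma_z_bounds[0]) & (sz <= sigma_z_bounds[1]))
            report["removed_sigma_z"] = int((keep & ~okz).sum())
            keep &= okz

    out = table.loc[keep].reset_index(drop=True)
    out.attrs["units"] = dict(table.attrs.get("units", LOC_UNITS))
    out.attrs["meta"] = dict(table.attrs.get("meta", {}))
    report["kept"] = int(len(out))
    out.attrs["meta"]["filter_report"] = report
    return out, report


class RegistrationStateError(RuntimeError):
    pass


def _local_lookup(local: pd.DataFrame, points: np.ndarray,
                  mode: str = "surface_fit") -> tuple[np.ndarray, np.ndarray]:
    """Correction (dz, dy, dx) and quality for each (z, y, x) point.

    ``block`` mode returns the value of the containing block (zero for
    flagged or missing blocks); ``surface_fit`` fits a smooth bilinear
    surface to the good blocks' corrections at their intensity-centroid
    anchors, which tracks smooth deformation fields far better than the
    piecewise-constant lookup.
    """
    n = len(points)
    corr = np.zeros((n, 3))
    quality = np.zeros(n)
    if local is None or not len(local):
        return corr, quality

    bz = np.sort(local.block_z.unique())
    by = np.sort(local.block_y.unique())
    bx = np.sort(local.block_x.unique())
    shape = (len(bz), len(by), len(bx))
    vals = np.full(shape + (3,), np.nan)
    qual = np.zeros(shape)
    centers = [np.zeros(len(bz)), np.zeros(len(by)), np.zeros(len(bx))]
    for r in local.itertuples():
        iz = np.searchsorted(bz, r.block_z)
        iy = np.searchsorted(by, r.block_y)
        ix = np.searchsorted(bx, r.block_x)
        centers[0][iz] = (r.z_min + r.z_max - 1) / 2
        centers[1][iy] = (r.y_min + r.y_max - 1) / 2
        centers[2][ix] = (r.x_min + r.x_max - 1) / 2
        if not bool(r.flagged):
            vals[iz, iy, ix] = (r.dz_px, r.dy_px, r.dx_px)
            qual[iz, iy, ix] = r.quality
    valid = ~np.isnan(vals[..., 0])
    if not valid.any():
        return corr, quality
    if not valid.all():
        # back-fill flagged blocks from the nearest valid block
        from scipy.ndimage import distance_transform_edt
        _, idx = distance_transform_edt(~valid, return_indices=True)
        vals = vals[idx[0], idx[1], idx[2]]

    # containing-block indices (clipped), for quality and "block" mode
    def _contain(axis_vals, coords, blocks, lo_col, hi_col):
        edges = np.sort(local[lo_col].unique())
        return np.clip(np.searchsorted(edges, coords, side="right") - 1,
                       0, len(axis_vals) - 1)

    iz = _contain(bz, points[:, 0], bz, "z_min", "z_max")
    iy = _contain(by, points[:, 1], by, "y_min", "y_max")
    ix = _contain(bx, points[:, 2], bx, "x_min", "x_max")
    quality = qual[iz, iy, ix]

    if mode == "block":
        block_corr = np.where(valid[iz, iy, ix, None], vals[iz, iy, ix], 0.0)
        return block_corr, quality

    # smooth-surface fit: the measured correction of each block samples the
    # deformation field where the block's fiducial signal sits (its
    # intensity-centroid anchor).  A bilinear surface a + b*y + c*x + d*y*x
    # per component, least-squares fitted over all good blocks, denoises
    # the per-block estimates and evaluates anywhere in the FOV.
    good = local[~local.flagged.astype(bool)]
    if {"anchor_y", "anchor_x"} <= set(local.columns):
        ay = good.anchor_y.to_numpy()
        ax = good.anchor_x.to_numpy()
    else:  # older tables: geometric centers
        ay = ((good.y_min + good.y_max - 1) / 2).to_numpy()
        ax = ((good.x_min + good.x_max - 1) / 2).to_numpy()
    values = good[["dz_px", "dy_px", "dx_px"]].to_numpy()
    if len(good) < 4 or np.ptp(ay) < 1e-9 or np.ptp(ax) < 1e-9:
        corr[:] = values.mean(axis=0) if len(good) else 0.0
        return corr, quality
    sy, sx = max(np.ptp(ay), 1.0), max(np.ptp(ax), 1.0)  # conditioning
    ny_, nx_ = (ay - ay.mean()) / sy, (ax - ax.mean()) / sx
    design = np.column_stack([np.ones_like(ny_), ny_, nx_, ny_ * nx_])
    coef, *_ = np.linalg.lstsq(design, values, rcond=None)
    qy = (points[:, 1] - ay.mean()) / sy
    qx = (points[:, 2] - ax.mean()) / sx
    qdesign = np.column_stack([np.ones_like(qy), qy, qx, qy * qx])
    return qdesign @ coef, quality


def register_localizations(
    table: pd.DataFrame,
    global_shifts: pd.DataFrame,
    local_corrections: dict[tuple[str, str], pd.DataFrame] | None,
    pixel_size_xy: float,
    pixel_size_z: float,
    local_interpolation: str = "surface_fit",
) -> pd.DataFrame:
    """Translate localizations into the reference-cycle frame.

    Each row is shifted by its cycle's global (dy, dx) plus the local
    (dz, dy, dx) correction evaluated at its position (containing block
    or fitted correction surface; zero when no usable block exists).  The um columns are recomputed and the ``registered`` flag
    set; registering an already-registered table is refused.
    """
    if len(table) and table["registered"].any():
        raise RegistrationStateError("table is already registered")
    out = table.copy()
    shifts = {(r.roi, r.cycle): (r.dy_px, r.dx_px)
              for r in global_shifts.itertuples()}
    for (roi, cycle), group in table.groupby(["roi", "cycle"], sort=False):
        if (roi, cycle) not in shifts:
            raise KeyError(f"no global shift for roi={roi!r} cycle={cycle!r}")
        dy, dx = shifts[(roi, cycle)]
        local = (local_corrections or {}).get((roi, cycle))
        points = np.column_stack([
            group.z_px.to_numpy(),
            group.y_px.to_numpy() + dy,
            group.x_px.to_numpy() + dx,
        ])
        corr, quality = _local_lookup(local, points, mode=local_interpolation)
        dz_loc, dy_loc, dx_loc = corr[:, 0], corr[:, 1], corr[:, 2]
        idx = group.index
        out.loc[idx, "z_px"] = group.z_px + dz_loc
        out.loc[idx, "y_px"] = group.y_px + dy + dy_loc
        out.loc[idx, "x_px"] = group.x_px + dx + dx_loc
        out.loc[idx, "block_quality"] = quality
    out["z_um"] = out["z_px"] * pixel_size_z
    out["y_um"] = out["y_px"] * pixel_size_xy
    out["x_um"] = out["x_px"] * pixel_size_xy
    out["registered"] = True
    out.attrs["units"] = dict(table.attrs.get("units", LOC_UNITS))
    out.attrs["meta"] = dict(table.attrs.get("meta", {}))
    return out


def segment_2d(image: np.ndarray, config: PipelineConfig, role: str,
               **kwargs) -> tuple[np.ndarray, pd.DataFrame]:
    """Fast-2D entry point: masks for mask roles, spots for barcode roles."""
    det = config.detection
    if role in ("mask_nuclei", "mask_library"):
        return segment_masks_2d(image, det), empty_localizations()
    table = locate_spots_2d(
        image, det, pixel_size_xy=config.acquisition.pixel_size_xy,
        pixel_size_z=config.acquisition.pixel_size_z, **kwargs,
    )
    return np.zeros(image.shape, dtype=np.int32), table
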