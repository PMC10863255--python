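"""Synthetic multi-cycle DNA-FISH dataset generator with full ground truth.

The simulator emulates a sequential-imaging chromatin tracing
acquisition: one genomic barcode is revealed per hybridization cycle and
imaged as a diffraction-limited 3D Gaussian spot, together with a
fiducial bead channel shared by all cycles.  Ground truth is retained
for every quantity the pipeline estimates — trace geometry, spot
positions, per-cycle stage drift, smooth local deformation fields,
fiducial positions and nuclear mask labels — so each stage can be tested
against known answers.

Image formation per cycle:

* chromatin traces are 3D Gaussian chains anchored at nucleus centers;
* each non-dropped spot of the cycle's barcode is rendered as an
  anisotropic 3D Gaussian at its true position displaced by the cycle's
  rigid drift plus the local deformation field;
* fiducial beads are rendered identically in every cycle apart from that
  cycle's drift/deformation (the invariant registration exploits);
* background = level x (1 + low-order 2D polynomial inhomogeneity),
  shaped along z by a smooth envelope; Poisson photon noise and Gaussian
  read noise are added and the result quantized to 16 bits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field
from scipy.interpolate import RegularGridInterpolator

from . import ecsv
from .config import PipelineConfig, encode_filename, write_config

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "DeformationField",
    "simulate_chain",
    "build_ground_truth",
    "render_cycle",
    "render_mask_cycle",
    "simulate_dataset",
    "PRESETS",
]


class SimulationParams(BaseModel):
    """Study conditions for one synthetic acquisition."""

    model_config = ConfigDict(validate_assignment=True)

    n_fov: int = Field(1, ge=1)
    fov_shape: tuple[int, int, int] = (30, 256, 256)  # (z, y, x) px
    pixel_size_xy: float = Field(0.1, gt=0)  # um/px
    pixel_size_z: float = Field(0.25, gt=0)  # um/plane
    n_nuclei: int = Field(20, ge=1)
    n_barcodes: int = Field(10, ge=1)
    chain_step: float = Field(0.1, gt=0)  # um between successive barcodes
    nucleus_radius_xy: float = Field(1.8, gt=0)  # um
    nucleus_radius_z: float = Field(1.4, gt=0)  # um
    psf_sigma_xy: float = Field(0.13, gt=0)  # um
    psf_sigma_z: float = Field(0.35, gt=0)  # um
    amplitude_range: tuple[float, float] = (500.0, 1500.0)  # peak counts
    fiducial_amplitude: float = Field(4000.0, gt=0)
    background_level: float = Field(100.0, ge=0)  # counts
    background_inhomogeneity: float = Field(0.3, ge=0)  # relative amplitude
    read_noise_sd: float = Field(3.0, ge=0)  # counts
    n_fiducials: int = Field(20, ge=0)
    drift_max: float = Field(5.0, ge=0)  # px per lateral axis, incl. sub-pixel
    drift_max_z: float = Field(1.0, ge=0)  # planes
    deformation_amplitude: float = Field(0.2, ge=0)  # um, <= "hundreds of nm"
    deformation_grid: tuple[int, int, int] = (2, 2, 2)
    dropout: float = Field(0.0, ge=0, lt=1)
    mask_level: float = Field(3000.0, gt=0)
    seed: int = 0


#: named parameter presets; "small" is the reference acquisition used
#: throughout the test-bench (20 traces, SNR well above 8, +-5 px drifts)
PRESETS: dict[str, dict] = {
    "small": {},
    "medium": {"n_nuclei": 40, "n_barcodes": 20, "fov_shape": (40, 384, 384)},
}


@dataclass
class DeformationField:
    """Smooth per-cycle 3D displacement field.

    A coarse grid of random displacement vectors (um) spanning the FOV,
    interpolated (tri)linearly; displacement magnitudes are bounded by
    the configured amplitude.
    """

    grid_um: np.ndarray  # (gz, gy, gx, 3) displacement vectors, um
    fov_shape: tuple[int, int, int]
    pixel_size_xy: float
    pixel_size_z: float
    _interps: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        gz, gy, gx, _ = self.grid_um.shape
        axes = [
            np.linspace(0, self.fov_shape[0] - 1, gz),
            np.linspace(0, self.fov_shape[1] - 1, gy),
            np.linspace(0, self.fov_shape[2] - 1, gx),
        ]
        self._interps = [
            RegularGridInterpolator(axes, self.grid_um[..., k], bounds_error=False,
                                    fill_value=None)
            for k in range(3)
        ]

    def displacement_px(self, zyx_px: np.ndarray) -> np.ndarray:
        """Displacement (dz, dy, dx) in pixel units at pixel positions."""
        pts = np.atleast_2d(np.asarray(zyx_px, dtype=float))
        um = np.stack([f(pts) for f in self._interps], axis=-1)
        scale = np.array([self.pixel_size_z, self.pixel_size_xy, self.pixel_size_xy])
        return um / scale

    def block_average_px(self, z_sl: slice, y_sl: slice, x_sl: slice,
                         step: int = 8) -> np.ndarray:
        """Field averaged over a block, in pixels (oracle for local registration)."""
        zz, yy, xx = np.meshgrid(
            np.arange(z_sl.start, z_sl.stop, max(1, step // 4)),
            np.arange(y_sl.start, y_sl.stop, step),
            np.arange(x_sl.start, x_sl.stop, step),
            indexing="ij",
        )
        pts = np.column_stack([zz.ravel(), yy.ravel(), xx.ravel()])
        return self.displacement_px(pts).mean(axis=0)


@dataclass
class GroundTruth:
    """Everything the pipeline is supposed to recover."""

    params: SimulationParams
    traces: pd.DataFrame  # one row per (trace, barcode): true positions + flags
    drifts: dict[str, dict[str, np.ndarray]]  # roi -> cycle -> (dz,dy,dx) px
    deformations: dict[str, dict[str, DeformationField]]  # roi -> cycle -> field
    fiducials: dict[str, np.ndarray]  # roi -> (n, 3) positions, px
    nuclei: dict[str, pd.DataFrame]  # roi -> (label, center z/y/x px, radii px)
    cycles: list[str]
    rois: list[str]

    def cycle_of_barcode(self, barcode: int) -> str:
        return self.cycles[barcode]


def simulate_chain(
    n_barcodes: int, step: float, origin: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian-chain conformation: successive displacements are isotropic
    normal with per-axis sd ``step/sqrt(3)``, so E||x_i - x_j||^2 = step^2 |i-j|.

    Returns an ``(n_barcodes, 3)`` array of (z, y, x) positions in um.
    """
    if n_barcodes < 1:
        raise ValueError("n_barcodes must be >= 1")
    if step <= 0:
        raise ValueError("step must be > 0")
    origin = np.asarray(origin, dtype=float)
    steps = rng.normal(scale=step / np.sqrt(3.0), size=(n_barcodes - 1, 3))
    return origin + np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])


def _place_nuclei(params: SimulationParams, rng: np.random.Generator) -> pd.DataFrame:
    """Rejection-sample non-overlapping ellipsoid nuclei (centers/radii in px)."""
    nz, ny, nx = params.fov_shape
    rxy = params.nucleus_radius_xy / params.pixel_size_xy
    rz = params.nucleus_radius_z / params.pixel_size_z
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < params.n_nuclei and attempts < 20000:
        attempts += 1
        c = np.array([
            rng.uniform(rz, nz - rz) if nz > 2 * rz else nz / 2,
            rng.uniform(rxy + 6, ny - rxy - 6),
            rng.uniform(rxy + 6, nx - rxy - 6),
        ])
        # lateral separation check only: nuclei live in one z-layer
        if all(np.hypot(*(c[1:] - o[1:])) > 2.05 * rxy for o in centers):
            centers.append(c)
    if len(centers) < params.n_nuclei:
        raise ValueError(
            f"could not place {params.n_nuclei} non-overlapping nuclei in "
            f"FOV {params.fov_shape}; reduce n_nuclei or radii"
        )
    return pd.DataFrame({
        "label": np.arange(1, len(centers) + 1, dtype=np.int64),
        "z_px": [c[0] for c in centers],
        "y_px": [c[1] for c in centers],
        "x_px": [c[2] for c in centers],
        "rz_px": rz,
        "rxy_px": rxy,
    })


def _chain_in_nucleus(chain_um, center_um, params) -> bool:
    d = chain_um - center_um
    r = (
        (d[:, 0] / (0.85 * params.nucleus_radius_z)) ** 2
        + (d[:, 1] / (0.85 * params.nucleus_radius_xy)) ** 2
        + (d[:, 2] / (0.85 * params.nucleus_radius_xy)) ** 2
    )
    return bool(np.all(r <= 1.0))


def build_ground_truth(params: SimulationParams) -> GroundTruth:
    """Sample traces, drifts, deformations, beads and nuclei for all FOVs."""
    rng = np.random.default_rng(params.seed)
    rois = [f"{i + 1:03d}" for i in range(params.n_fov)]
    cycles = [f"RT{i + 1:02d}" for i in range(params.n_barcodes)]
    scale_um = np.array([params.pixel_size_z, params.pixel_size_xy,
                         params.pixel_size_xy])

    rows = []
    drifts: dict[str, dict[str, np.ndarray]] = {}
    deformations: dict[str, dict[str, DeformationField]] = {}
    fiducials: dict[str, np.ndarray] = {}
    nuclei: dict[str, pd.DataFrame] = {}
    trace_counter = 0

    for roi in rois:
        nuc = _place_nuclei(params, rng)
        nuclei[roi] = nuc

        for _, n in nuc.iterrows():
            center_um = np.array([n.z_px, n.y_px, n.x_px]) * scale_um
            for _ in range(50):
                chain = simulate_chain(params.n_barcodes, params.chain_step,
                                       center_um, rng)
                if _chain_in_nucleus(chain, center_um, params):
                    break
            dropped = rng.random(params.n_barcodes) < params.dropout
            for b in range(params.n_barcodes):
                rows.append({
                    "trace_index": trace_counter,
                    "roi": roi,
                    "mask_label": int(n.label),
                    "barcode": b + 1,
                    "cycle": cycles[b],
                    "z_um": chain[b, 0],
                    "y_um": chain[b, 1],
                    "x_um": chain[b, 2],
                    "z_px": chain[b, 0] / scale_um[0],
                    "y_px": chain[b, 1] / scale_um[1],
                    "x_px": chain[b, 2] / scale_um[2],
                    "amplitude": rng.uniform(*params.amplitude_range),
                    "dropped": bool(dropped[b]),
                    "in_field": True,
                })
            trace_counter += 1

        nz, ny, nx = params.fov_shape
        beads = np.column_stack([
            rng.uniform(0.25 * nz, 0.75 * nz, params.n_fiducials),
            rng.uniform(8, ny - 8, params.n_fiducials),
            rng.uniform(8, nx - 8, params.n_fiducials),
        ])
        fiducials[roi] = beads

        drifts[roi] = {}
        deformations[roi] = {}
        all_cycles = cycles + ["DAPI"]
        for i, cyc in enumerate(all_cycles):
            if cyc == cycles[0]:  # reference cycle is drift-free by definition
                d = np.zeros(3)
            else:
                d = np.array([
                    rng.uniform(-params.drift_max_z, params.drift_max_z),
                    rng.uniform(-params.drift_max, params.drift_max),
                    rng.uniform(-params.drift_max, params.drift_max),
                ])
            drifts[roi][cyc] = d
            grid = rng.uniform(-1, 1, size=params.deformation_grid + (3,))
            norms = np.linalg.norm(grid, axis=-1, keepdims=True)
            grid = np.where(norms > 1e-12, grid / np.maximum(norms, 1e-12), 0.0)
            grid *= rng.uniform(0, params.deformation_amplitude,
                                size=params.deformation_grid + (1,))
            if cyc == cycles[0]:
                grid[:] = 0.0
            deformations[roi][cyc] = DeformationField(
                grid_um=grid, fov_shape=params.fov_shape,
                pixel_size_xy=params.pixel_size_xy,
                pixel_size_z=params.pixel_size_z,
            )

    traces = pd.DataFrame(rows)
    return GroundTruth(
        params=params, traces=traces, drifts=drifts, deformations=deformations,
        fiducials=fiducials, nuclei=nuclei, cycles=cycles, rois=rois,
    )


def _render_spots(
    image: np.ndarray,
    positions_px: np.ndarray,
    amplitudes: np.ndarray,
    sigma_px: tuple[float, float],
) -> np.ndarray:
    """Add 3D Gaussian spots into *image* (in place); returns in-field mask."""
    nz, ny, nx = image.shape
    sz, sxy = sigma_px
    hz, hxy = int(np.ceil(4 * sz)), int(np.ceil(4 * sxy))
    in_field = np.zeros(len(positions_px), dtype=bool)
    for i, (p, amp) in enumerate(zip(positions_px, amplitudes)):
        z0, y0, x0 = p
        if not (0 <= z0 < nz and 0 <= y0 < ny and 0 <= x0 < nx):
            continue
        in_field[i] = True
        zlo, zhi = max(0, int(z0) - hz), min(nz, int(z0) + hz + 1)
        ylo, yhi = max(0, int(y0) - hxy), min(ny, int(y0) + hxy + 1)
        xlo, xhi = max(0, int(x0) - hxy), min(nx, int(x0) + hxy + 1)
        zz = np.arange(zlo, zhi, dtype=float)[:, None, None]
        yy = np.arange(ylo, yhi, dtype=float)[None, :, None]
        xx = np.arange(xlo, xhi, dtype=float)[None, None, :]
        g = amp * np.exp(
            -((zz - z0) ** 2) / (2 * sz ** 2)
            - ((yy - y0) ** 2) / (2 * sxy ** 2)
            - ((xx - x0) ** 2) / (2 * sxy ** 2)
        )
        image[zlo:zhi, ylo:yhi, xlo:xhi] += g
    return in_field


def _background(params: SimulationParams, rng: np.random.Generator) -> np.ndarray:
    """Smooth inhomogeneous background: per-plane 2D quadratic x z-envelope."""
    nz, ny, nx = params.fov_shape
    yy, xx = np.meshgrid(np.linspace(-1, 1, ny), np.linspace(-1, 1, nx),
                         indexing="ij")
    coef = rng.uniform(-1, 1, size=6)
    poly = (coef[0] * yy + coef[1] * xx + coef[2] * yy * xx
            + coef[3] * yy ** 2 + coef[4] * xx ** 2 + coef[5])
    if np.ptp(poly) > 0:
        poly = (poly - poly.min()) / np.ptp(poly) * 2 - 1  # rescale to [-1, 1]
    z = np.linspace(-1, 1, nz)
    envelope = 1.0 - 0.3 * z ** 2
    bg2d = params.background_level * (1 + params.background_inhomogeneity * poly)
    return envelope[:, None, None] * bg2d[None]


def _add_noise(photons: np.ndarray, params: SimulationParams,
               rng: np.random.Generator) -> np.ndarray:
    noisy = rng.poisson(np.clip(photons, 0, None)).astype(float)
    if params.read_noise_sd > 0:
        noisy += rng.normal(scale=params.read_noise_sd, size=noisy.shape)
    return np.clip(noisy, 0, np.iinfo(np.uint16).max).astype(np.uint16)


def _cycle_rng(params: SimulationParams, roi: str, cycle: str, salt: int) -> np.random.Generator:
    import zlib

    tag = zlib.crc32(f"{roi}/{cycle}".encode()) % (2**31)
    return np.random.default_rng([params.seed, salt, tag])


def render_cycle(
    truth: GroundTruth, roi: str, cycle: str, *, noise: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Render one hybridization cycle of one FOV.

    Returns ``(barcode_stack, fiducial_stack)`` as uint16 (z,y,x) arrays.
    Spots falling outside the FOV after drift/deformation are clipped and
    flagged ``in_field=False`` in the ground-truth table.
    """
    params = truth.params
    rng = _cycle_rng(params, roi, cycle, salt=1)
    drift = truth.drifts[roi][cycle]
    fieldd = truth.deformations[roi][cycle]
    sigma_px = (params.psf_sigma_z / params.pixel_size_z,
                params.psf_sigma_xy / params.pixel_size_xy)

    sel = (truth.traces.roi == roi) & (truth.traces.cycle == cycle) \
        & (~truth.traces.dropped)
    spots = truth.traces.loc[sel]
    signal = np.zeros(params.fov_shape, dtype=float)
    if len(spots):
        pos = spots[["z_px", "y_px", "x_px"]].to_numpy()
        pos = pos + drift + fieldd.displacement_px(pos)
        in_field = _render_spots(signal, pos, spots.amplitude.to_numpy(), sigma_px)
        truth.traces.loc[spots.index, "in_field"] = in_field

    fid = np.zeros(params.fov_shape, dtype=float)
    beads = truth.fiducials[roi]
    bead_pos = beads + drift + fieldd.displacement_px(beads)
    _render_spots(fid, bead_pos, np.full(len(beads), params.fiducial_amplitude),
                  sigma_px)

    bg = _background(params, rng)
    if noise:
        return _add_noise(signal + bg, params, rng), _add_noise(fid + bg, params, rng)
    clip = lambda a: np.clip(a, 0, np.iinfo(np.uint16).max).astype(np.uint16)
    return clip(signal + bg), clip(fid + bg)


def render_mask_cycle(truth: GroundTruth, roi: str, *, noise: bool = True
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render the nuclear-mask (DAPI) cycle: filled ellipsoids + fiducials.

    Returns ``(mask_stack, fiducial_stack, label_truth)`` where
    *label_truth* is the drift-free integer label image.
    """
    params = truth.params
    rng = _cycle_rng(params, roi, "DAPI", salt=2)
    drift = truth.drifts[roi]["DAPI"]
    fieldd = truth.deformations[roi]["DAPI"]

    nz, ny, nx = params.fov_shape
    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx),
                             indexing="ij", sparse=True)
    labels = np.zeros(params.fov_shape, dtype=np.int32)
    shifted = np.zeros(params.fov_shape, dtype=float)
    for _, n in truth.nuclei[roi].iterrows():
        r2 = (((zz - n.z_px) / n.rz_px) ** 2 + ((yy - n.y_px) / n.rxy_px) ** 2
              + ((xx - n.x_px) / n.rxy_px) ** 2)
        labels[r2 <= 1.0] = int(n.label)
        # as-imaged nuclei carry the DAPI cycle's drift
        c = np.array([n.z_px, n.y_px, n.x_px])
        c = c + drift + fieldd.displacement_px(c)[0]
        r2d = (((zz - c[0]) / n.rz_px) ** 2 + ((yy - c[1]) / n.rxy_px) ** 2
               + ((xx - c[2]) / n.rxy_px) ** 2)
        shifted[r2d <= 1.0] = params.mask_level

    fid = np.zeros(params.fov_shape, dtype=float)
    beads = truth.fiducials[roi]
    bead_pos = beads + drift + fieldd.displacement_px(beads)
    sigma_px = (params.psf_sigma_z / params.pixel_size_z,
                params.psf_sigma_xy / params.pixel_size_xy)
    _render_spots(fid, bead_pos, np.full(len(beads), params.fiducial_amplitude),
                  sigma_px)

    bg = _background(params, rng)
    if noise:
        return (_add_noise(shifted + bg, params, rng),
                _add_noise(fid + bg, params, rng), labels)
    clip = lambda a: np.clip(a, 0, np.iinfo(np.uint16).max).astype(np.uint16)
    return clip(shifted + bg), clip(fid + bg), labels


def _truth_trace_table(truth: GroundTruth, rng: np.random.Generator) -> pd.DataFrame:
    """Ground-truth trace table in the pipeline's TraceTable schema."""
    import uuid

    t = truth.traces
    uuids = {}
    for idx in sorted(t.trace_index.unique()):
        uuids[idx] = str(uuid.UUID(bytes=rng.bytes(16), version=4))
    table = pd.DataFrame({
        "trace_id": t.trace_index.map(uuids),
        "spot_id": np.arange(len(t), dtype=np.int64),
        "barcode": t.barcode.astype(np.int64),
        "x_um": t.x_um, "y_um": t.y_um, "z_um": t.z_um,
        "mask_label": t.mask_label.astype(np.int64),
        "roi": t.roi.astype(str),
        "label": "",
        "dropped": t.dropped.astype(bool),
    })
    table.attrs["units"] = {"x_um": "um", "y_um": "um", "z_um": "um"}
    table.attrs["meta"] = {"source": "simulator ground truth",
                           "seed": truth.params.seed}
    return table


def _pipeline_config(params: SimulationParams) -> PipelineConfig:
    cfg = PipelineConfig()
    cfg.acquisition.pixel_size_xy = params.pixel_size_xy
    cfg.acquisition.pixel_size_z = params.pixel_size_z
    cfg.detection.psf_sigma_xy = params.psf_sigma_xy
    cfg.detection.psf_sigma_z = params.psf_sigma_z
    return cfg


def simulate_dataset(params: SimulationParams, outdir: str | Path) -> GroundTruth:
    """Write a complete synthetic dataset to *outdir*.

    Per FOV: one barcode + one fiducial TIFF per hybridization cycle,
    plus a DAPI mask channel with its own fiducial; a ``parameters.json``
    matched to the simulated optics; ground-truth ECSV tables under
    ``ground_truth/``.
    """
    from .stack import write_stack

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = build_ground_truth(params)

    for roi in truth.rois:
        for cycle in truth.cycles:
            sig, fid = render_cycle(truth, roi, cycle)
            write_stack(sig, outdir / encode_filename(roi, cycle, "ch01"))
            write_stack(fid, outdir / encode_filename(roi, cycle, "ch00"))
        mask, fid, labels = render_mask_cycle(truth, roi)
        write_stack(mask, outdir / encode_filename(roi, "DAPI", "ch01"))
        write_stack(fid, outdir / encode_filename(roi, "DAPI", "ch00"))

    write_config(_pipeline_config(params), outdir / "parameters.json")

    gt_dir = outdir / "ground_truth"
    gt_dir.mkdir(exist_ok=True)
    rng = np.random.default_rng([params.seed, 99])
    ecsv.write_ecsv(_truth_trace_table(truth, rng), gt_dir / "traces.ecsv")

    drift_rows = [
        {"roi": roi, "cycle": cyc, "dz_px": d[0], "dy_px": d[1], "dx_px": d[2]}
        for roi, per in truth.drifts.items() for cyc, d in per.items()
    ]
    dt = pd.DataFrame(drift_rows)
    dt.attrs["units"] = {"dz_px": "pix", "dy_px": "pix", "dx_px": "pix"}
    ecsv.write_ecsv(dt, gt_dir / "drifts.ecsv")

    fid_rows = [
        {"roi": roi, "z_px": p[0], "y_px": p[1], "x_px": p[2]}
        for roi, pos in truth.fiducials.items() for p in pos
    ]
    ecsv.write_ecsv(pd.DataFrame(fid_rows), gt_dir / "fiducials.ecsv")

    (gt_dir / "params.json").write_text(params.model_dump_json(indent=2))
    return truth
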