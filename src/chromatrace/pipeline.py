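"""Pipeline orchestration: canonical stage chain over a dataset directory.

Stages run in the canonical order ``project -> register -> detect ->
trace -> matrix``; any subset can be requested and each stage persists
its outputs (ECSV tables, npy arrays) so later stages can resume from
disk.  Per-cycle work items map over a process pool; results are
collected in a deterministic order so ``workers=1`` and ``workers=N``
produce identical tables.

Two execution modes: the full ``3d`` pipeline (3D fitting, local 3D
registration, 3D masks) and the fast ``2d`` mode, which projects spots
and masks and runs registration/localization/tracing on the projections
— a quick data-quality pass before committing to the 3D analysis.
"""

from __future__ import annotations

import hashlib
import json
import multiprocessing
import re
import time
from dataclasses import dataclass, field
from functools import partial
from pathlib import Path

import numpy as np
import pandas as pd

from . import ecsv
from .config import FileRecord, PipelineConfig, scan_directory
from .detection import (
    filter_localizations,
    locate_spots_2d,
    locate_spots_3d,
    register_localizations,
    segment_masks_2d,
    segment_masks_3d,
)
from .projection import find_focus, project
from .registration import (
    align_3d_blocks,
    align_by_block,
    apply_shift,
    apply_shift_stack,
    global_shift_table,
)
from .stack import ImageStack, read_stack
from .tracing import (
    build_traces_by_clustering,
    build_traces_by_mask,
    trace_filter,
)
from .matrices import build_matrix

STAGES = ("project", "register", "detect", "trace", "matrix")


class PrerequisiteError(RuntimeError):
    """A requested stage is missing inputs; names the stage to run first."""


@dataclass
class RunManifest:
    mode: str
    workers: int
    config: dict
    stages: list[dict] = field(default_factory=list)

    def record(self, name: str, status: str, seconds: float,
               outputs: list[Path]) -> None:
        self.stages.append({
            "stage": name,
            "status": status,
            "wall_seconds": round(seconds, 3),
            "outputs": {str(p): _sha256(p) for p in outputs if p.exists()},
        })

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(
            {"mode": self.mode, "workers": self.workers,
             "stages": self.stages, "config": self.config}, indent=2))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _pmap(fn, items, workers: int):
    items = list(items)
    if workers <= 1 or len(items) <= 1:
        return [fn(i) for i in items]
    with multiprocessing.Pool(workers) as pool:
        return pool.map(fn, items)


def _barcode_of(cycle: str) -> int:
    digits = re.sub(r"\D", "", cycle)
    return int(digits) if digits else 0


def _reference_cycle(config: PipelineConfig, records: list[FileRecord]) -> str:
    if config.acquisition.reference_cycle:
        return config.acquisition.reference_cycle
    barcode_cycles = sorted({r.cycle for r in records if r.role == "barcode"})
    if barcode_cycles:
        return barcode_cycles[0]
    return sorted({r.cycle for r in records})[0]


# --------------------------------------------------------------------------
# stage: project

def _project_item(args: tuple, config_json: str, data_dir: str, outdir: str):
    config = PipelineConfig.model_validate_json(config_json)
    record = FileRecord.model_validate_json(args)
    stack = read_stack(record, config)
    proj_cfg = config.projection
    focus = find_focus(stack, block_size=proj_cfg.block_size)
    mode = proj_cfg.mask_mode if record.role in ("mask_nuclei", "mask_library") \
        else proj_cfg.mode
    if record.role == "fiducial" or proj_cfg.z_range_mode == "manual":
        z_range = proj_cfg.z_manual
        img = project(stack, mode=mode, z_range=z_range)
    else:
        img = project(stack, mode=mode, z_window=proj_cfg.z_window, focus=focus)
    key = f"{record.roi}_{record.cycle}_{record.channel}"
    np.save(Path(outdir) / "projections" / f"{key}.npy", img)
    return {"key": key, "roi": record.roi, "cycle": record.cycle,
            "channel": record.channel, "role": record.role,
            "focus": focus.global_focus,
            "low_confidence": focus.low_confidence}


def stage_project(config: PipelineConfig, data_dir: Path, outdir: Path,
                  workers: int = 1) -> list[Path]:
    records = scan_directory(data_dir, config)
    if not records:
        raise PrerequisiteError(f"no decodable TIFFs in {data_dir}")
    (outdir / "projections").mkdir(parents=True, exist_ok=True)
    fn = partial(_project_item, config_json=config.model_dump_json(),
                 data_dir=str(data_dir), outdir=str(outdir))
    meta = _pmap(fn, [r.model_dump_json() for r in
                      sorted(records, key=lambda r: (r.roi, r.cycle, r.channel))],
                 workers)
    meta_path = outdir / "projections" / "meta.json"
    meta_path.write_text(json.dumps({m["key"]: m for m in meta}, indent=2,
                                    sort_keys=True))
    return [meta_path]


# --------------------------------------------------------------------------
# stage: register

def _load_projection_meta(outdir: Path) -> dict:
    meta_path = outdir / "projections" / "meta.json"
    if not meta_path.exists():
        raise PrerequisiteError("projections missing: run the 'project' stage first")
    return json.loads(meta_path.read_text())


def _local_item(args: tuple, config_json: str, data_dir: str, outdir: str):
    config = PipelineConfig.model_validate_json(config_json)
    ref_json, mov_json, dy, dx = args
    ref_rec = FileRecord.model_validate_json(ref_json)
    mov_rec = FileRecord.model_validate_json(mov_json)
    ref = read_stack(ref_rec, config)
    mov = read_stack(mov_rec, config)
    reg = config.registration
    table = align_3d_blocks(
        ref.voxels, mov.voxels, (dy, dx),
        block_size_3d=reg.block_size_3d,
        correction_cap=reg.correction_cap,
        upsample_factor=reg.upsample_factor_3d,
    )
    table.attrs["meta"]["roi"] = mov_rec.roi
    table.attrs["meta"]["cycle"] = mov_rec.cycle
    path = Path(outdir) / "registration" / f"local_{mov_rec.roi}_{mov_rec.cycle}.ecsv"
    ecsv.write_ecsv(table, path)
    return str(path)


def stage_register(config: PipelineConfig, data_dir: Path, outdir: Path,
                   mode: str = "3d", workers: int = 1) -> list[Path]:
    meta = _load_projection_meta(outdir)
    records = scan_directory(data_dir, config)
    fiducials = [r for r in records if r.role == "fiducial"]
    reference = _reference_cycle(config, records)
    reg = config.registration
    (outdir / "registration").mkdir(parents=True, exist_ok=True)

    rows = []
    by_roi: dict[str, dict[str, FileRecord]] = {}
    for r in fiducials:
        by_roi.setdefault(r.roi, {})[r.cycle] = r
    local_items = []
    for roi in sorted(by_roi):
        cycles = by_roi[roi]
        if reference not in cycles:
            raise PrerequisiteError(
                f"reference cycle {reference!r} has no fiducial in roi {roi!r}")
        ref_key = f"{roi}_{reference}_{cycles[reference].channel}"
        ref_proj = np.load(outdir / "projections" / f"{ref_key}.npy")
        for cycle in sorted(cycles):
            if cycle == reference:
                rows.append({"roi": roi, "cycle": cycle, "dy_px": 0.0,
                             "dx_px": 0.0, "rms_error": 0.0,
                             "n_blocks_agreeing": 0, "method": "reference"})
                continue
            key = f"{roi}_{cycle}_{cycles[cycle].channel}"
            proj = np.load(outdir / "projections" / f"{key}.npy")
            (dy, dx), diag = align_by_block(
                ref_proj, proj, block_size=reg.block_size_2d,
                tolerance=reg.polling_tolerance,
                upsample_factor=reg.upsample_factor,
            )
            rows.append({
                "roi": roi, "cycle": cycle, "dy_px": dy, "dx_px": dx,
                "rms_error": float(diag.block_errors[diag.winner_mask].mean()),
                "n_blocks_agreeing": int(diag.winner_mask.sum()),
                "method": "global" if diag.fallback else "block_polling",
            })
            if mode == "3d":
                local_items.append((
                    cycles[reference].model_dump_json(),
                    cycles[cycle].model_dump_json(), dy, dx,
                ))

    shifts = global_shift_table(rows)
    shifts_path = outdir / "registration" / "global_shifts.ecsv"
    ecsv.write_ecsv(shifts, shifts_path)

    outputs = [shifts_path]
    if local_items:
        fn = partial(_local_item, config_json=config.model_dump_json(),
                     data_dir=str(data_dir), outdir=str(outdir))
        outputs += [Path(p) for p in _pmap(fn, local_items, workers)]
    return outputs


# --------------------------------------------------------------------------
# stage: detect

def _detect_item_3d(args: str, config_json: str):
    config = PipelineConfig.model_validate_json(config_json)
    record = FileRecord.model_validate_json(args)
    stack = read_stack(record, config)
    return locate_spots_3d(stack, config.detection,
                           barcode=_barcode_of(record.cycle))


def _detect_item_2d(args: tuple, config_json: str, outdir: str):
    config = PipelineConfig.model_validate_json(config_json)
    key, roi, cycle, focus = args
    img = np.load(Path(outdir) / "projections" / f"{key}.npy")
    return locate_spots_2d(
        img, config.detection,
        pixel_size_xy=config.acquisition.pixel_size_xy,
        pixel_size_z=config.acquisition.pixel_size_z,
        focus_plane=focus, roi=roi, cycle=cycle,
        barcode=_barcode_of(cycle),
    )


def _load_global_shifts(outdir: Path) -> pd.DataFrame:
    path = outdir / "registration" / "global_shifts.ecsv"
    if not path.exists():
        raise PrerequisiteError(
            "global shifts missing: run the 'register' stage first")
    return ecsv.read_ecsv(path)


def _load_local_corrections(outdir: Path) -> dict[tuple[str, str], pd.DataFrame]:
    local = {}
    for path in sorted((outdir / "registration").glob("local_*.ecsv")):
        table = ecsv.read_ecsv(path)
        m = table.attrs.get("meta", {})
        local[(str(m.get("roi")), str(m.get("cycle")))] = table
    return local


def stage_detect(config: PipelineConfig, data_dir: Path, outdir: Path,
                 mode: str = "3d", workers: int = 1) -> list[Path]:
    shifts = _load_global_shifts(outdir)
    records = scan_directory(data_dir, config)
    acq = config.acquisition
    (outdir / "localizations").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    outputs = []

    barcode_recs = sorted((r for r in records if r.role == "barcode"),
                          key=lambda r: (r.roi, r.cycle))
    if mode == "3d":
        fn = partial(_detect_item_3d, config_json=config.model_dump_json())
        tables = _pmap(fn, [r.model_dump_json() for r in barcode_recs], workers)
    else:
        meta = _load_projection_meta(outdir)
        items = [
            (m["key"], m["roi"], m["cycle"], m["focus"])
            for m in sorted(meta.values(), key=lambda m: m["key"])
            if m["role"] == "barcode"
        ]
        fn = partial(_detect_item_2d, config_json=config.model_dump_json(),
                     outdir=str(outdir))
        tables = _pmap(fn, items, workers)

    raw = pd.concat(tables, ignore_index=True) if tables else \
        tables[0] if tables else None
    if raw is None or len(raw) == 0:
        from .detection import empty_localizations
        raw = empty_localizations()
    raw["spot_id"] = np.arange(len(raw), dtype=np.int64)  # unique across cycles
    raw.attrs["units"] = tables[0].attrs.get("units", {}) if tables else {}
    raw.attrs["meta"] = {"mode": mode}
    raw_path = outdir / "localizations" / f"localizations_{mode}.ecsv"
    ecsv.write_ecsv(raw, raw_path)

    det = config.detection
    filtered, report = filter_localizations(
        raw, intensity_min=det.intensity_min,
        sigma_xy_bounds=det.sigma_xy_bounds if mode == "3d" else None,
        sigma_z_bounds=det.sigma_z_bounds,
    )
    filt_path = outdir / "localizations" / f"localizations_{mode}_filtered.ecsv"
    ecsv.write_ecsv(filtered, filt_path)

    local = _load_local_corrections(outdir) if mode == "3d" else {}
    registered = register_localizations(
        filtered, shifts, local,
        pixel_size_xy=acq.pixel_size_xy, pixel_size_z=acq.pixel_size_z,
        local_interpolation=config.registration.local_interpolation,
    )
    reg_path = outdir / "localizations" / f"localizations_{mode}_registered.ecsv"
    ecsv.write_ecsv(registered, reg_path)
    outputs += [raw_path, filt_path, reg_path]

    # masks, brought into the reference frame via their cycle's global shift
    shift_map = {(r.roi, r.cycle): (r.dy_px, r.dx_px)
                 for r in shifts.itertuples()}
    mask_recs = [r for r in records if r.role in ("mask_nuclei", "mask_library")]
    for rec in sorted(mask_recs, key=lambda r: (r.roi, r.cycle)):
        stack = read_stack(rec, config)
        shift = shift_map.get((rec.roi, rec.cycle), (0.0, 0.0))
        if mode == "3d":
            vox = apply_shift_stack(stack.voxels, shift) \
                if any(shift) else stack.voxels
            aligned = ImageStack(np.asarray(vox), rec.roi, rec.cycle, rec.role,
                                 acq.pixel_size_xy, acq.pixel_size_z)
            labels = segment_masks_3d(aligned, det)
        else:
            img = project(stack, mode=config.projection.mask_mode)
            img = apply_shift(img.astype(float), shift) if any(shift) else img
            labels = segment_masks_2d(img, det)
        path = outdir / "masks" / f"{rec.roi}_labels.npy"
        np.save(path, labels)
        outputs.append(path)
    return outputs


# --------------------------------------------------------------------------
# stage: trace

def stage_trace(config: PipelineConfig, outdir: Path, mode: str = "3d") -> list[Path]:
    reg_path = outdir / "localizations" / f"localizations_{mode}_registered.ecsv"
    if not reg_path.exists():
        raise PrerequisiteError(
            "registered localizations missing: run the 'detect' stage first")
    locs = ecsv.read_ecsv(reg_path)
    acq = config.acquisition
    rng = (np.random.default_rng(config.runtime.seed)
           if config.runtime.seed is not None else None)

    if config.tracing.mode == "masking":
        tables = []
        total_report: dict = {}
        for roi in sorted(locs.roi.unique()):
            mask_path = outdir / "masks" / f"{roi}_labels.npy"
            if not mask_path.exists():
                raise PrerequisiteError(
                    f"mask labels for roi {roi!r} missing: run the 'detect' "
                    "stage first")
            masks = np.load(mask_path)
            table, report = build_traces_by_mask(
                locs[locs.roi == roi], masks,
                pixel_size_xy=acq.pixel_size_xy, pixel_size_z=acq.pixel_size_z,
                rng=rng,
            )
            tables.append(table)
            total_report[roi] = report
        traces = pd.concat(tables, ignore_index=True) if tables else None
        if traces is not None and tables:
            traces.attrs["units"] = tables[0].attrs["units"]
            traces.attrs["meta"] = {"tracing_mode": "masking",
                                    "report": total_report}
    else:
        traces, report = build_traces_by_clustering(
            locs, radius_um=config.tracing.clustering_radius, rng=rng)

    if config.tracing.min_barcodes > 1:
        traces = trace_filter(traces, min_barcodes=config.tracing.min_barcodes)
    traces.attrs.setdefault("meta", {})
    traces.attrs["meta"]["mode"] = mode

    (outdir / "traces").mkdir(parents=True, exist_ok=True)
    path = outdir / "traces" / "traces.ecsv"
    ecsv.write_ecsv(traces, path)
    return [path]


# --------------------------------------------------------------------------
# stage: matrix

def stage_matrix(config: PipelineConfig, outdir: Path) -> list[Path]:
    path = outdir / "traces" / "traces.ecsv"
    if not path.exists():
        raise PrerequisiteError("trace table missing: run the 'trace' stage first")
    traces = ecsv.read_ecsv(path)
    deduped = trace_filter(traces, deduplicate=True)
    mx = config.matrices
    use_z = traces.attrs.get("meta", {}).get("mode") != "2d"
    ms = build_matrix(
        deduped, threshold_um=mx.proximity_threshold,
        bandwidth=mx.kde_bandwidth, n_min=mx.kde_n_min,
        proximity_denominator=mx.proximity_denominator, use_z=use_z,
    )
    mat_dir = outdir / "matrices"
    ms.save(mat_dir)
    for name, m in (("median_pwd", ms.median_pwd), ("mode_pwd", ms.mode_pwd),
                    ("proximity", ms.proximity), ("n", ms.n_matrix)):
        np.save(mat_dir / f"matrix_{name}.npy", m)
    return sorted(mat_dir.glob("matrix_*"))


# --------------------------------------------------------------------------
# orchestration

def run_pipeline(
    config: PipelineConfig,
    data_dir: str | Path,
    outdir: str | Path,
    stages: tuple[str, ...] | list[str] | None = None,
    mode: str = "3d",
    workers: int | None = None,
    write_reports: bool = True,
) -> RunManifest:
    """Execute the requested *stages* in canonical order.

    Raises :class:`PrerequisiteError` when a requested stage lacks the
    outputs of an earlier, unrequested stage.
    """
    if mode not in ("3d", "2d"):
        raise ValueError(f"mode must be '3d' or '2d', got {mode!r}")
    data_dir, outdir = Path(data_dir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    workers = workers if workers is not None else config.runtime.n_workers
    requested = list(stages) if stages else list(STAGES)
    unknown = set(requested) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s) {sorted(unknown)}; valid: {STAGES}")

    manifest = RunManifest(mode=mode, workers=workers, config=config.to_dict())
    for name in STAGES:
        if name not in requested:
            continue
        t0 = time.perf_counter()
        if name == "project":
            outputs = stage_project(config, data_dir, outdir, workers)
        elif name == "register":
            outputs = stage_register(config, data_dir, outdir, mode, workers)
        elif name == "detect":
            outputs = stage_detect(config, data_dir, outdir, mode, workers)
        elif name == "trace":
            outputs = stage_trace(config, outdir, mode)
        else:
            outputs = stage_matrix(config, outdir)
        manifest.record(name, "ok", time.perf_counter() - t0, outputs)

    if write_reports:
        from .report import write_report
        write_report(outdir, config, [s["stage"] for s in manifest.stages])
    manifest.save(outdir / "manifest.json")
    return manifest
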