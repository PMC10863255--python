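"""Markdown QC reports with snapshot images, one page per stage.

Reports let the user judge each analysis step at a glance: projection
snapshots, registration overlays (reference vs corrected fiducial) with
the shift table, detection snapshots with localization circles, filter
counts, trace statistics and the final matrices.  File layout and
content are deterministic — re-running a stage regenerates an identical
page (no timestamps).
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import ecsv
from .config import PipelineConfig
from .registration import apply_shift

__all__ = ["write_report"]


def _norm(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    lo, hi = np.percentile(img, [1, 99.8])
    if hi <= lo:
        return np.zeros_like(img)
    return np.clip((img - lo) / (hi - lo), 0, 1)


def _overlay(reference: np.ndarray, corrected: np.ndarray) -> np.ndarray:
    """RGB overlay: reference in magenta, corrected image in green."""
    r = _norm(reference)
    g = _norm(corrected)
    return np.stack([r, g, r], axis=-1)


def _md_table(df: pd.DataFrame, cols: list[str]) -> str:
    lines = ["| " + " | ".join(cols) + " |",
             "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in df.iterrows():
        cells = []
        for c in cols:
            v = row[c]
            cells.append(f"{v:.3f}" if isinstance(v, float) else str(v))
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)


def write_report(outdir: str | Path, config: PipelineConfig,
                 stages: list[str]) -> list[Path]:
    """Write one markdown page (plus PNGs) per executed stage."""
    outdir = Path(outdir)
    rep = outdir / "reports"
    rep.mkdir(parents=True, exist_ok=True)
    pages = []
    for stage in stages:
        writer = {
            "project": _report_project,
            "register": _report_register,
            "detect": _report_detect,
            "trace": _report_trace,
            "matrix": _report_matrix,
        }.get(stage)
        if writer is None:
            continue
        page = writer(outdir, rep, config)
        if page is not None:
            pages.append(page)
    return pages


def _report_project(outdir: Path, rep: Path, config: PipelineConfig):
    meta_path = outdir / "projections" / "meta.json"
    if not meta_path.exists():
        return None
    meta = json.loads(meta_path.read_text())
    lines = ["# Projection report", ""]
    for key in sorted(meta):
        m = meta[key]
        img = np.load(outdir / "projections" / f"{key}.npy")
        png = rep / f"project_{key}.png"
        plt.imsave(png, _norm(img), cmap="gray")
        flag = " (low confidence)" if m["low_confidence"] else ""
        lines += [f"## {key}", "",
                  f"role: {m['role']}; in-focus plane: {m['focus']}{flag}", "",
                  f"![{key}]({png.name})", ""]
    page = rep / "project.md"
    page.write_text("\n".join(lines))
    return page


def _report_register(outdir: Path, rep: Path, config: PipelineConfig):
    shifts_path = outdir / "registration" / "global_shifts.ecsv"
    if not shifts_path.exists():
        return None
    shifts = ecsv.read_ecsv(shifts_path)
    meta = json.loads((outdir / "projections" / "meta.json").read_text()) \
        if (outdir / "projections" / "meta.json").exists() else {}
    fid_keys = {(m["roi"], m["cycle"]): m["key"] for m in meta.values()
                if m["role"] == "fiducial"}
    lines = ["# Registration report", "", "## Global shifts", "",
             _md_table(shifts, ["roi", "cycle", "dy_px", "dx_px",
                                "rms_error", "n_blocks_agreeing", "method"]),
             ""]
    for roi in sorted(shifts.roi.unique()):
        sub = shifts[shifts.roi == roi]
        ref_row = sub[sub.method == "reference"]
        if not len(ref_row):
            continue
        ref_key = fid_keys.get((roi, ref_row.iloc[0].cycle))
        if ref_key is None:
            continue
        ref_img = np.load(outdir / "projections" / f"{ref_key}.npy")
        lines += [f"## Overlays, ROI {roi} (reference magenta / corrected green)",
                  ""]
        for r in sub.itertuples():
            key = fid_keys.get((roi, r.cycle))
            if key is None or r.method == "reference":
                continue
            mov = np.load(outdir / "projections" / f"{key}.npy")
            corrected = apply_shift(mov.astype(float), (r.dy_px, r.dx_px))
            png = rep / f"register_{roi}_{r.cycle}.png"
            plt.imsave(png, _overlay(ref_img, corrected))
            lines += [f"### cycle {r.cycle}: shift ({r.dy_px:.2f}, "
                      f"{r.dx_px:.2f}) px", "", f"![{r.cycle}]({png.name})", ""]
    page = rep / "register.md"
    page.write_text("\n".join(lines))
    return page


def _report_detect(outdir: Path, rep: Path, config: PipelineConfig):
    loc_dir = outdir / "localizations"
    paths = sorted(loc_dir.glob("localizations_*_registered.ecsv"))
    if not paths:
        return None
    locs = ecsv.read_ecsv(paths[0])
    lines = ["# Detection report", ""]
    if len(locs) == 0:
        lines += ["**0 localizations** — nothing detected or everything "
                  "filtered; check thresholds.", ""]
    else:
        filt = sorted(loc_dir.glob("localizations_*_filtered.ecsv"))
        if filt:
            meta = ecsv.read_ecsv(filt[0]).attrs.get("meta", {})
            report = meta.get("filter_report", {})
            if report:
                lines += ["## Filter counts", ""]
                lines += [f"- {k}: {v}" for k, v in report.items()]
                lines += [""]
        for (roi, cycle), g in locs.groupby(["roi", "cycle"]):
            lines += [f"## ROI {roi}, cycle {cycle}: {len(g)} localizations", ""]
            key = f"{roi}_{cycle}"
            proj_meta = outdir / "projections" / "meta.json"
            if proj_meta.exists():
                meta = json.loads(proj_meta.read_text())
                cand = [m for m in meta.values()
                        if m["roi"] == roi and m["cycle"] == cycle
                        and m["role"] == "barcode"]
                if cand:
                    img = np.load(outdir / "projections" /
                                  f"{cand[0]['key']}.npy")
                    fig, ax = plt.subplots(figsize=(4, 4))
                    ax.imshow(_norm(img), cmap="gray")
                    ax.scatter(g.x_px, g.y_px, s=40, facecolors="none",
                               edgecolors="yellow", linewidths=0.8)
                    ax.set_axis_off()
                    png = rep / f"detect_{key}.png"
                    fig.savefig(png, dpi=100, bbox_inches="tight")
                    plt.close(fig)
                    lines += [f"![{key}]({png.name})", ""]
    page = rep / "detect.md"
    page.write_text("\n".join(lines))
    return page


def _report_trace(outdir: Path, rep: Path, config: PipelineConfig):
    path = outdir / "traces" / "traces.ecsv"
    if not path.exists():
        return None
    traces = ecsv.read_ecsv(path)
    lines = ["# Tracing report", ""]
    if len(traces) == 0:
        lines += ["**0 localizations in traces.**", ""]
    else:
        n_traces = traces.trace_id.nunique()
        sizes = traces.groupby("trace_id").size()
        lines += [f"- traces: {n_traces}",
                  f"- localizations: {len(traces)}",
                  f"- mean localizations per trace: {sizes.mean():.2f}", ""]
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.hist(sizes, bins=np.arange(0.5, sizes.max() + 1.5), color="steelblue")
        ax.set_xlabel("localizations per trace")
        ax.set_ylabel("traces")
        fig.tight_layout()
        png = rep / "trace_sizes.png"
        fig.savefig(png, dpi=100)
        plt.close(fig)
        lines += [f"![trace sizes]({png.name})", ""]
    page = rep / "trace.md"
    page.write_text("\n".join(lines))
    return page


def _report_matrix(outdir: Path, rep: Path, config: PipelineConfig):
    mat_dir = outdir / "matrices"
    if not (mat_dir / "matrix_heatmaps.png").exists():
        return None
    lines = ["# Matrix report", "",
             f"proximity threshold: {config.matrices.proximity_threshold} um",
             "", "![heatmaps](../matrices/matrix_heatmaps.png)", ""]
    n = np.load(mat_dir / "matrix_n.npy")
    lines += [f"- barcode pairs with co-detections: "
              f"{int((n > 0).sum() // 2)}",
              f"- max co-detections on a pair: {int(n.max())}", ""]
    page = rep / "matrix.md"
    page.write_text("\n".join(lines))
    return page
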