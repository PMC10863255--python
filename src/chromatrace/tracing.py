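"""Group registered localizations into single-cell chromatin traces.

A *trace* is the set of 3D barcode coordinates belonging to one copy of
the imaged locus in one cell.  Two grouping strategies are provided:
mask-based (spots sharing a nuclear or library mask label form a trace)
and spatial clustering (single-linkage connected components of the
radius graph, built with a KD-tree; suitable for low-density samples).

Every trace is stamped with an RFC-4122 v4 UUID so tables from
different FOVs or experiments can be merged without collisions.  No
correction for missing or duplicated barcodes is applied at build time;
that is the province of the post-processing filters below, because the
right policy is sample-dependent.
"""

from __future__ import annotations

import uuid
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from . import ecsv

__all__ = [
    "build_traces_by_mask",
    "build_traces_by_clustering",
    "trace_filter",
    "trace_filter_advanced",
    "trace_assign_mask",
    "trace_merge",
    "trace_analyzer",
]

TRACE_SCHEMA = {
    "trace_id": "object", "spot_id": "int64", "barcode": "int64",
    "x_um": "float64", "y_um": "float64", "z_um": "float64",
    "mask_label": "int64", "roi": "object", "label": "object",
    "amplitude": "float64",
}
TRACE_UNITS = {"x_um": "um", "y_um": "um", "z_um": "um", "amplitude": "ct"}


def _uuid4(rng: np.random.Generator | None) -> str:
    if rng is None:
        return str(uuid.uuid4())
    return str(uuid.UUID(bytes=rng.bytes(16), version=4))


def empty_traces(meta: dict | None = None) -> pd.DataFrame:
    t = pd.DataFrame({c: pd.Series(dtype=d) for c, d in TRACE_SCHEMA.items()})
    t.attrs["units"] = dict(TRACE_UNITS)
    t.attrs["meta"] = dict(meta or {})
    return t


def _finalize(rows: list[dict], meta: dict) -> pd.DataFrame:
    if not rows:
        return empty_traces(meta)
    table = pd.DataFrame(rows).astype(TRACE_SCHEMA)
    table.attrs["units"] = dict(TRACE_UNITS)
    table.attrs["meta"] = meta
    return table


def _mask_label_at(masks: np.ndarray, z: float, y: float, x: float) -> int:
    """Mask label at the rounded voxel; outside the image counts as background."""
    idx = (int(round(y)), int(round(x))) if masks.ndim == 2 else \
        (int(round(z)), int(round(y)), int(round(x)))
    if any(i < 0 or i >= s for i, s in zip(idx, masks.shape)):
        return 0
    return int(masks[idx])


def build_traces_by_mask(
    locs: pd.DataFrame,
    masks: np.ndarray,
    pixel_size_xy: float,
    pixel_size_z: float,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """One trace per mask label: spots sharing a mask form a trace.

    Localizations falling on background (label 0) or outside the mask
    image are discarded and counted in the report.  The grouping is
    deterministic and independent of input row order.
    """
    rows = []
    n_background = 0
    assignments: dict[tuple[str, int], list] = {}
    for r in locs.itertuples():
        lab = _mask_label_at(masks, r.z_px, r.y_px, r.x_px)
        if lab == 0:
            n_background += 1
            continue
        assignments.setdefault((r.roi, lab), []).append(r)
    for (roi, lab) in sorted(assignments):
        tid = _uuid4(rng)
        for r in assignments[(roi, lab)]:
            rows.append({
                "trace_id": tid, "spot_id": r.spot_id, "barcode": r.barcode,
                "x_um": r.x_um, "y_um": r.y_um, "z_um": r.z_um,
                "mask_label": lab, "roi": roi, "label": "",
                "amplitude": r.amplitude,
            })
    report = {"input": int(len(locs)), "background_dropped": n_background,
              "n_traces": len(assignments)}
    meta = {"tracing_mode": "masking", "report": report}
    return _finalize(rows, meta), report


def build_traces_by_clustering(
    locs: pd.DataFrame,
    radius_um: float,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Single-linkage spatial clustering of localizations into traces.

    Links every pair of localizations within *radius_um* (KD-tree range
    query) and takes connected components, per ROI.  Emits a density
    warning in the report when traces are closer than twice the linking
    radius on average, the regime where single linkage starts bridging.
    """
    rows = []
    n_traces = 0
    nn_spacings = []
    for roi, group in locs.groupby("roi", sort=True):
        pts = group[["z_um", "y_um", "x_um"]].to_numpy()
        if len(pts) == 0:
            continue
        tree = cKDTree(pts)
        pairs = tree.query_pairs(radius_um, output_type="ndarray")
        n = len(pts)
        graph = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        ) if len(pairs) else coo_matrix((n, n))
        n_comp, comp = connected_components(graph, directed=False)
        order = sorted(range(n_comp),
                       key=lambda c: int(np.where(comp == c)[0].min()))
        centroids = []
        for c in order:
            members = group.iloc[np.where(comp == c)[0]]
            tid = _uuid4(rng)
            centroids.append(members[["z_um", "y_um", "x_um"]].mean().to_numpy())
            for r in members.itertuples():
                rows.append({
                    "trace_id": tid, "spot_id": r.spot_id, "barcode": r.barcode,
                    "x_um": r.x_um, "y_um": r.y_um, "z_um": r.z_um,
                    "mask_label": 0, "roi": roi, "label": "",
                    "amplitude": r.amplitude,
                })
        n_traces += n_comp
        if len(centroids) > 1:
            ctree = cKDTree(np.asarray(centroids))
            d, _ = ctree.query(np.asarray(centroids), k=2)
            nn_spacings.extend(d[:, 1])
    density_warning = bool(nn_spacings) and \
        float(np.mean(nn_spacings)) < 2 * radius_um
    report = {"input": int(len(locs)), "n_traces": n_traces,
              "density_warning": density_warning}
    meta = {"tracing_mode": "clustering", "radius_um": radius_um,
            "report": report}
    return _finalize(rows, meta), report


# --------------------------------------------------------------------------
# post-processing toolbox

def _copy_attrs(out: pd.DataFrame, src: pd.DataFrame) -> pd.DataFrame:
    out.attrs["units"] = dict(src.attrs.get("units", TRACE_UNITS))
    out.attrs["meta"] = dict(src.attrs.get("meta", {}))
    return out


def trace_filter(
    table: pd.DataFrame,
    drop_barcodes: Sequence[int] = (),
    deduplicate: bool = False,
    keep_region: tuple[tuple[float, float], tuple[float, float],
                       tuple[float, float]] | None = None,
    min_barcodes: int = 1,
) -> pd.DataFrame:
    """General trace filtering.

    * *drop_barcodes* — remove the listed barcodes everywhere;
    * *deduplicate* — within a trace, a barcode appearing several times
      keeps only its brightest row (ties go to the lowest spot id);
    * *keep_region* — axis-aligned um box ((xlo,xhi),(ylo,yhi),(zlo,zhi));
      rows outside are dropped;
    * *min_barcodes* — traces with fewer distinct barcodes are removed.
    """
    out = table.copy()
    if drop_barcodes:
        out = out[~out.barcode.isin(list(drop_barcodes))]
    if keep_region is not None:
        (xlo, xhi), (ylo, yhi), (zlo, zhi) = keep_region
        out = out[(out.x_um >= xlo) & (out.x_um <= xhi)
                  & (out.y_um >= ylo) & (out.y_um <= yhi)
                  & (out.z_um >= zlo) & (out.z_um <= zhi)]
    if deduplicate and len(out):
        out = out.sort_values(
            ["trace_id", "barcode", "amplitude", "spot_id"],
            ascending=[True, True, False, True],
        ).drop_duplicates(["trace_id", "barcode"], keep="first")
    if min_barcodes > 1 and len(out):
        counts = out.groupby("trace_id")["barcode"].nunique()
        out = out[out.trace_id.map(counts) >= min_barcodes]
    out = out.sort_index().reset_index(drop=True)
    return _copy_attrs(out, table)


def trace_filter_advanced(table: pd.DataFrame, distance_cutoff: float) -> pd.DataFrame:
    """Distance-constrained deduplication.

    Within a trace, rows of a duplicated barcode whose mutual distance
    exceeds *distance_cutoff* (um) are all removed as ambiguous;
    otherwise they are merged to the brightest row.
    """
    keep = np.ones(len(table), dtype=bool)
    positions = table[["x_um", "y_um", "z_um"]].to_numpy()
    for (_, _), idx in table.groupby(["trace_id", "barcode"]).groups.items():
        idx = np.asarray(idx)
        if len(idx) < 2:
            continue
        pts = positions[[table.index.get_loc(i) for i in idx]]
        dmax = max(
            np.linalg.norm(pts[a] - pts[b])
            for a in range(len(pts)) for b in range(a + 1, len(pts))
        )
        locs = [table.index.get_loc(i) for i in idx]
        if dmax > distance_cutoff:
            for l in locs:
                keep[l] = False
        else:
            amps = table.iloc[locs]["amplitude"].to_numpy()
            best = locs[int(np.argmax(amps))]
            for l in locs:
                keep[l] = l == best
    out = table.iloc[keep].reset_index(drop=True)
    return _copy_attrs(out, table)


def trace_assign_mask(
    table: pd.DataFrame,
    masks: np.ndarray,
    label: str,
    pixel_size_xy: float,
    pixel_size_z: float,
    majority: float = 0.5,
) -> pd.DataFrame:
    """Append *label* to traces whose localizations majority-overlap the mask.

    A trace is labeled when the fraction of its localizations falling on
    nonzero mask voxels exceeds *majority* (strict).  Labels accumulate
    comma-separated; existing labels are never overwritten.
    """
    out = table.copy()
    for tid, group in table.groupby("trace_id"):
        inside = 0
        for r in group.itertuples():
            z = r.z_um / pixel_size_z
            y = r.y_um / pixel_size_xy
            x = r.x_um / pixel_size_xy
            if _mask_label_at(masks, z, y, x) != 0:
                inside += 1
        if inside / len(group) > majority:
            idx = group.index
            current = out.loc[idx, "label"]
            out.loc[idx, "label"] = [
                f"{c},{label}" if c else label for c in current
            ]
    return _copy_attrs(out, table)


class UUIDCollisionError(ValueError):
    pass


def trace_merge(tables: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate trace tables from different FOVs or experiments.

    UUID collisions across tables are an error (they would silently fuse
    unrelated traces); provenance metadata is unioned.
    """
    tables = list(tables)
    if not tables:
        return empty_traces()
    seen: set[str] = set()
    for t in tables:
        ids = set(t.trace_id.unique())
        clash = seen & ids
        if clash:
            raise UUIDCollisionError(
                f"trace UUID collision while merging: {sorted(clash)[:3]}..."
            )
        seen |= ids
    out = pd.concat(tables, ignore_index=True)
    out.attrs["units"] = dict(tables[0].attrs.get("units", TRACE_UNITS))
    meta: dict = {"merged_from": len(tables)}
    for t in tables:
        for k, v in t.attrs.get("meta", {}).items():
            meta.setdefault(k, v)
    out.attrs["meta"] = meta
    return out


def radius_of_gyration(points_um: np.ndarray) -> float:
    pts = np.asarray(points_um, dtype=float)
    return float(np.sqrt(((pts - pts.mean(axis=0)) ** 2).sum(axis=1).mean()))


def trace_analyzer(
    table: pd.DataFrame, outdir: str | Path | None = None
) -> dict[str, pd.DataFrame]:
    """Summary statistics of a trace table.

    Computes the distribution of barcodes detected per trace, per-barcode
    detection and duplication frequencies, per-trace radius of gyration,
    and nearest-neighbor distances between trace centroids.  When
    *outdir* is given the tables are written as ECSV and histograms as
    PNG.
    """
    if len(table) == 0:
        raise ValueError("empty trace table")
    per_trace = []
    centroids = []
    for tid, g in table.groupby("trace_id"):
        pts = g[["x_um", "y_um", "z_um"]].to_numpy()
        per_trace.append({
            "trace_id": tid,
            "n_localizations": len(g),
            "n_barcodes": int(g.barcode.nunique()),
            "rg_um": radius_of_gyration(pts),
            "roi": g.roi.iloc[0],
        })
        centroids.append(pts.mean(axis=0))
    per_trace = pd.DataFrame(per_trace)
    per_trace.attrs["units"] = {"rg_um": "um"}

    n_traces = len(per_trace)
    per_barcode = []
    for b, g in table.groupby("barcode"):
        appearances = g.groupby("trace_id").size()
        per_barcode.append({
            "barcode": int(b),
            "n_traces_detected": int(len(appearances)),
            "detection_frequency": float(len(appearances) / n_traces),
            "duplication_frequency": float((appearances > 1).mean()),
        })
    per_barcode = pd.DataFrame(per_barcode)

    cents = np.asarray(centroids)
    if len(cents) > 1:
        tree = cKDTree(cents)
        d, _ = tree.query(cents, k=2)
        nn = d[:, 1]
    else:
        nn = np.array([np.nan])
    spacing = pd.DataFrame({"nn_distance_um": nn})
    spacing.attrs["units"] = {"nn_distance_um": "um"}

    results = {"per_trace": per_trace, "per_barcode": per_barcode,
               "trace_spacing": spacing}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, tab in results.items():
            ecsv.write_ecsv(tab, outdir / f"{name}.ecsv")
        _analyzer_plots(results, outdir)
    return results


def _analyzer_plots(results: dict[str, pd.DataFrame], outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2))
    axes[0].hist(results["per_trace"].n_barcodes, bins=20, color="steelblue")
    axes[0].set_xlabel("barcodes per trace")
    axes[1].hist(results["per_trace"].rg_um, bins=20, color="darkorange")
    axes[1].set_xlabel("radius of gyration (um)")
    axes[2].hist(results["trace_spacing"].nn_distance_um.dropna(), bins=20,
                 color="seagreen")
    axes[2].set_xlabel("nearest trace distance (um)")
    for ax in axes:
        ax.set_ylabel("count")
    fig.tight_layout()
    fig.savefig(outdir / "trace_statistics.png", dpi=100)
    plt.close(fig)
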