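"""Pairwise-distance, proximity and detection-count maps from trace tables.

For every unordered pair of barcodes co-detected in a trace, the 3D
Euclidean distance contributes one sample to that pair's distance
distribution.  The distribution is summarized three ways:

* **median PWD matrix** — per-pair sample median (um);
* **KDE-mode PWD matrix** — the maximum of a Gaussian kernel-density
  estimate of the distribution, a robust location of the typical
  distance when the distribution is skewed (um);
* **proximity matrix** — the fraction of samples below a user-chosen
  threshold distance, the imaging analog of a contact frequency;
* **N matrix** — the number of co-detections per pair, the fundamental
  detection-efficiency diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

__all__ = ["MatrixSet", "pairwise_distances", "kde_mode", "build_matrix"]


class DuplicatedBarcodeError(ValueError):
    pass


@dataclass
class MatrixSet:
    barcodes: list[int]
    median_pwd: np.ndarray  # um; NaN where no samples
    mode_pwd: np.ndarray  # um; NaN where < n_min samples
    proximity: np.ndarray  # fraction in [0, 1]; NaN where no samples
    n_matrix: np.ndarray  # co-detection counts; 0 on the diagonal
    threshold_um: float
    samples: dict[tuple[int, int], np.ndarray] = field(repr=False,
                                                       default_factory=dict)

    def save(self, outdir: str | Path, stem: str = "matrix") -> None:
        """Write each matrix as CSV with barcode headers, plus heatmap PNGs."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        names = {"median_pwd": self.median_pwd, "mode_pwd": self.mode_pwd,
                 "proximity": self.proximity, "n": self.n_matrix}
        labels = [str(b) for b in self.barcodes]
        for name, m in names.items():
            pd.DataFrame(m, index=labels, columns=labels).to_csv(
                outdir / f"{stem}_{name}.csv")
        _heatmaps(self, outdir, stem)


def pairwise_distances(table: pd.DataFrame,
                       use_z: bool = True) -> dict[tuple[int, int], np.ndarray]:
    """Per-pair distance sample lists across all traces.

    For each trace and each unordered barcode pair present in it, one
    Euclidean distance (um) is appended to that pair's sample list — 3D
    by default, lateral (x, y) only with ``use_z=False`` as used by the
    fast 2D mode, where the z column is a per-cycle focus plane rather
    than a measured coordinate.  A
    duplicated barcode inside a trace is ambiguous and raises; resolve it
    first with ``trace_filter(deduplicate=True)`` or
    ``trace_filter_advanced``.
    """
    samples: dict[tuple[int, int], list[float]] = {}
    for tid, g in table.groupby("trace_id", sort=False):
        barcodes = g.barcode.to_numpy()
        if len(np.unique(barcodes)) != len(barcodes):
            dupes = pd.Series(barcodes).value_counts()
            dupes = sorted(dupes[dupes > 1].index.tolist())
            raise DuplicatedBarcodeError(
                f"trace {tid} contains duplicated barcode(s) {dupes}; "
                "deduplicate with trace_filter before building matrices"
            )
        cols = ["x_um", "y_um", "z_um"] if use_z else ["x_um", "y_um"]
        pts = g[cols].to_numpy()
        order = np.argsort(barcodes)
        barcodes, pts = barcodes[order], pts[order]
        for a in range(len(barcodes)):
            diffs = pts[a + 1:] - pts[a]
            dists = np.sqrt((diffs ** 2).sum(axis=1))
            for b, d in zip(barcodes[a + 1:], dists):
                samples.setdefault((int(barcodes[a]), int(b)), []).append(float(d))
    return {k: np.asarray(v) for k, v in samples.items()}


def kde_mode(
    samples: np.ndarray,
    bandwidth: str | float = "scott",
    n_min: int = 10,
    grid_step_factor: float = 0.1,
) -> tuple[float, bool]:
    """Maximum of a Gaussian KDE of a distance distribution.

    Evaluates the density on a uniform grid from 0 to
    ``max(samples) + 3*bandwidth`` with step ``bandwidth/10`` and returns
    the argmax.  With fewer than *n_min* samples the mode is unreliable
    and ``(nan, False)`` is returned.  A degenerate sample (zero spread)
    returns the common value directly.
    """
    samples = np.asarray(samples, dtype=float)
    if len(samples) < n_min:
        return float("nan"), False
    if np.ptp(samples) == 0:  # degenerate: all samples identical
        return float(samples[0]), True
    sd = samples.std(ddof=1)
    if bandwidth == "scott":
        bw = sd * len(samples) ** (-1 / 5)
    else:
        bw = float(bandwidth)
    try:
        kde = gaussian_kde(samples, bw_method=bw / sd)
    except np.linalg.LinAlgError:  # numerically singular spread
        return float(np.median(samples)), True
    grid = np.arange(0.0, samples.max() + 3 * bw, bw * grid_step_factor)
    density = kde(grid)
    return float(grid[int(np.argmax(density))]), True


def build_matrix(
    table: pd.DataFrame,
    threshold_um: float = 0.25,
    bandwidth: str | float = "scott",
    n_min: int = 10,
    proximity_denominator: str = "codetection",
    barcodes: list[int] | None = None,
    use_z: bool = True,
) -> MatrixSet:
    """Build the full matrix set from a (deduplicated) trace table.

    proximity[i, j] = (# samples < threshold) / N[i, j] by default
    (*codetection* normalization); with ``proximity_denominator=
    "all_traces"`` the denominator is the total trace count, which makes
    maps comparable across datasets with different detection
    efficiencies.
    """
    samples = pairwise_distances(table, use_z=use_z)
    if barcodes is None:
        barcodes = sorted(table.barcode.unique().tolist())
    barcodes = [int(b) for b in barcodes]
    index = {b: i for i, b in enumerate(barcodes)}
    k = len(barcodes)
    median = np.full((k, k), np.nan)
    mode = np.full((k, k), np.nan)
    proximity = np.full((k, k), np.nan)
    n_matrix = np.zeros((k, k), dtype=np.int64)
    n_traces = table.trace_id.nunique()

    for (a, b), d in samples.items():
        if a not in index or b not in index:
            continue
        i, j = index[a], index[b]
        med = float(np.median(d))
        mod, _ = kde_mode(d, bandwidth=bandwidth, n_min=n_min)
        denom = len(d) if proximity_denominator == "codetection" else n_traces
        prox = float((d < threshold_um).sum() / denom) if denom else np.nan
        for (r, c) in ((i, j), (j, i)):
            median[r, c] = med
            mode[r, c] = mod
            proximity[r, c] = prox
            n_matrix[r, c] = len(d)
    np.fill_diagonal(median, np.nan)
    np.fill_diagonal(mode, np.nan)
    np.fill_diagonal(proximity, np.nan)
    np.fill_diagonal(n_matrix, 0)
    return MatrixSet(
        barcodes=barcodes, median_pwd=median, mode_pwd=mode,
        proximity=proximity, n_matrix=n_matrix, threshold_um=threshold_um,
        samples=samples,
    )


def _heatmaps(ms: MatrixSet, outdir: Path, stem: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    panels = [("median PWD (um)", ms.median_pwd, "viridis"),
              ("KDE-mode PWD (um)", ms.mode_pwd, "viridis"),
              (f"proximity (< {ms.threshold_um} um)", ms.proximity, "magma"),
              ("N (co-detections)", ms.n_matrix.astype(float), "cividis")]
    fig, axes = plt.subplots(1, 4, figsize=(16, 3.6))
    for ax, (title, m, cmap) in zip(axes, panels):
        im = ax.imshow(m, cmap=cmap)
        ax.set_title(title, fontsize=9)
        ax.set_xlabel("barcode")
        ax.set_ylabel("barcode")
        fig.colorbar(im, ax=ax, fraction=0.046)
    fig.tight_layout()
    fig.savefig(outdir / f"{stem}_heatmaps.png", dpi=100)
    plt.close(fig)
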