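"""Trace building (mask and clustering modes) and the post-processing toolbox."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from chromatrace.tracing import (
    UUIDCollisionError,
    build_traces_by_clustering,
    build_traces_by_mask,
    trace_analyzer,
    trace_assign_mask,
    trace_filter,
    trace_filter_advanced,
    trace_merge,
)


def _locs(rows):
    """Localization table from (spot_id, barcode, z_px, y_px, x_px) tuples."""
    df = pd.DataFrame(rows, columns=["spot_id", "barcode", "z_px", "y_px", "x_px"])
    df["roi"] = "001"
    df["cycle"] = ["RT%02d" % b for b in df.barcode]
    df["z_um"] = df.z_px * 0.25
    df["y_um"] = df.y_px * 0.1
    df["x_um"] = df.x_px * 0.1
    df["amplitude"] = 500.0
    df["registered"] = True
    return df


def _trace_table(groups):
    """Trace table from {trace_id: [(spot, barcode, x, y, z, amp), ...]}."""
    rows = []
    for tid, items in groups.items():
        for (spot, barcode, x, y, z, amp) in items:
            rows.append({"trace_id": tid, "spot_id": spot, "barcode": barcode,
                         "x_um": x, "y_um": y, "z_um": z, "mask_label": 0,
                         "roi": "001", "label": "", "amplitude": amp})
    return pd.DataFrame(rows)


class TestBuildByMask:
    def _masks(self):
        masks = np.zeros((10, 40, 40), dtype=np.int32)
        masks[:, 5:15, 5:15] = 5
        masks[:, 25:35, 25:35] = 9
        return masks

    def test_groups_by_mask_label(self):
        locs = _locs([(0, 1, 5, 10, 10), (1, 2, 5, 11, 9), (2, 3, 5, 9, 12),
                      (3, 1, 5, 30, 30), (4, 2, 5, 31, 29)])
        table, report = build_traces_by_mask(locs, self._masks(), 0.1, 0.25)
        sizes = table.groupby("trace_id").size().sort_values()
        assert list(sizes) == [2, 3]
        assert report["n_traces"] == 2
        assert set(table.mask_label) == {5, 9}

    def test_background_localization_dropped_and_counted(self):
        locs = _locs([(0, 1, 5, 10, 10), (1, 2, 5, 20, 20)])  # second in bg
        table, report = build_traces_by_mask(locs, self._masks(), 0.1, 0.25)
        assert len(table) == 1
        assert report["background_dropped"] == 1

    def test_out_of_image_treated_as_background(self):
        locs = _locs([(0, 1, 5, 100, 100)])
        table, report = build_traces_by_mask(locs, self._masks(), 0.1, 0.25)
        assert len(table) == 0
        assert report["background_dropped"] == 1

    def test_partition_invariant_to_row_order(self, rng):
        locs = _locs([(i, i + 1, 5, 10 + (i % 3), 10 + (i % 2)) for i in range(6)]
                     + [(10 + i, i + 1, 5, 30 + (i % 3), 30) for i in range(4)])
        perm = locs.sample(frac=1, random_state=1).reset_index(drop=True)
        t1, _ = build_traces_by_mask(locs, self._masks(), 0.1, 0.25)
        t2, _ = build_traces_by_mask(perm, self._masks(), 0.1, 0.25)
        # same partition of spot ids (UUIDs differ)
        p1 = t1.groupby("trace_id").spot_id.apply(frozenset)
        p2 = t2.groupby("trace_id").spot_id.apply(frozenset)
        assert set(p1) == set(p2)

    def test_duplicated_barcode_passes_through_unchanged(self):
        """No barcode correction happens at build time."""
        locs = _locs([(0, 7, 5, 10, 10), (1, 7, 5, 11, 11), (2, 1, 5, 9, 9)])
        table, _ = build_traces_by_mask(locs, self._masks(), 0.1, 0.25)
        assert len(table) == 3
        assert list(table.barcode).count(7) == 2

    def test_seeded_uuids_reproducible(self):
        locs = _locs([(0, 1, 5, 10, 10)])
        t1, _ = build_traces_by_mask(locs, self._masks(), 0.1, 0.25,
                                     rng=np.random.default_rng(5))
        t2, _ = build_traces_by_mask(locs, self._masks(), 0.1, 0.25,
                                     rng=np.random.default_rng(5))
        assert list(t1.trace_id) == list(t2.trace_id)


class TestBuildByClustering:
    def test_two_separated_clusters(self):
        locs = _locs([(0, 1, 0, 0, 0), (1, 2, 0, 1, 1),
                      (2, 1, 0, 100, 100), (3, 2, 0, 101, 101)])
        table, report = build_traces_by_clustering(locs, radius_um=0.5)
        assert report["n_traces"] == 2

    def test_chain_links_transitively(self):
        # consecutive points 0.3 um apart with radius 0.4: one trace
        locs = _locs([(i, i + 1, 0, 3 * i, 0) for i in range(5)])
        table, report = build_traces_by_clustering(locs, radius_um=0.4)
        assert report["n_traces"] == 1
        assert table.trace_id.nunique() == 1

    def test_density_warning_when_crowded(self):
        locs = _locs([(i, 1, 0, 2 * i, 0) for i in range(6)])
        _, rep_crowded = build_traces_by_clustering(locs, radius_um=0.19)
        assert rep_crowded["density_warning"]

    def test_matches_truth_partition_on_chains(self, small_truth):
        """Clustering ground-truth coordinates recovers the true traces."""
        gt = small_truth.traces
        locs = pd.DataFrame({
            "spot_id": np.arange(len(gt)), "barcode": gt.barcode,
            "z_px": gt.z_px, "y_px": gt.y_px, "x_px": gt.x_px,
            "z_um": gt.z_um, "y_um": gt.y_um, "x_um": gt.x_um,
            "roi": gt.roi, "cycle": gt.cycle, "amplitude": gt.amplitude,
            "registered": True,
        })
        table, _ = build_traces_by_clustering(locs, radius_um=0.4)
        merged = table.merge(gt.reset_index(), left_on="spot_id",
                             right_on="index")
        ari = adjusted_rand_score(merged.trace_index,
                                  pd.factorize(merged.trace_id)[0])
        assert ari >= 0.99


class TestTraceFilter:
    def test_noop_filter_is_identity(self):
        t = _trace_table({"t1": [(0, 1, 0, 0, 0, 500), (1, 2, 1, 1, 1, 600)]})
        out = trace_filter(t)
        pd.testing.assert_frame_equal(out, t)

    def test_dedup_keeps_brightest(self):
        t = _trace_table({"t1": [(0, 7, 0, 0, 0, 900), (1, 7, 1, 0, 0, 400),
                                 (2, 1, 0, 0, 0, 100)]})
        out = trace_filter(t, deduplicate=True)
        b7 = out[out.barcode == 7]
        assert len(b7) == 1 and b7.iloc[0].amplitude == 900

    def test_dedup_tie_keeps_lowest_spot_id(self):
        t = _trace_table({"t1": [(4, 7, 0, 0, 0, 500), (2, 7, 1, 0, 0, 500)]})
        out = trace_filter(t, deduplicate=True)
        assert list(out.spot_id) == [2]

    def test_min_barcodes_drops_small_traces(self):
        t = _trace_table({
            "a": [(i, i, 0, 0, 0, 1) for i in range(2)],
            "b": [(10 + i, i, 0, 0, 0, 1) for i in range(3)],
            "c": [(20 + i, i, 0, 0, 0, 1) for i in range(5)],
        })
        out = trace_filter(t, min_barcodes=3)
        sizes = sorted(out.groupby("trace_id").size())
        assert sizes == [3, 5]

    def test_drop_barcodes_and_region(self):
        t = _trace_table({"t1": [(0, 1, 0.5, 0.5, 0.5, 1),
                                 (1, 2, 5.0, 5.0, 5.0, 1)]})
        out = trace_filter(t, drop_barcodes=[2])
        assert set(out.barcode) == {1}
        out2 = trace_filter(t, keep_region=((0, 1), (0, 1), (0, 1)))
        assert len(out2) == 1

    def test_output_rows_subset_of_input(self):
        t = _trace_table({"t1": [(0, 1, 0, 0, 0, 1), (1, 1, 9, 9, 9, 2)]})
        out = trace_filter(t, deduplicate=True, min_barcodes=1)
        assert set(out.spot_id) <= set(t.spot_id)


class TestTraceFilterAdvanced:
    def test_close_duplicates_merge_to_brightest(self):
        t = _trace_table({"t1": [(0, 7, 0.0, 0.0, 0.0, 300),
                                 (1, 7, 0.05, 0.0, 0.0, 800),
                                 (2, 1, 1, 1, 1, 100)]})
        out = trace_filter_advanced(t, distance_cutoff=0.2)
        assert len(out) == 2
        assert 800 in set(out.amplitude)

    def test_distant_duplicates_all_removed(self):
        t = _trace_table({"t1": [(0, 7, 0.0, 0.0, 0.0, 300),
                                 (1, 7, 5.0, 0.0, 0.0, 800),
                                 (2, 1, 1, 1, 1, 100)]})
        out = trace_filter_advanced(t, distance_cutoff=0.2)
        assert set(out.barcode) == {1}


class TestAssignMask:
    def _mask(self):
        m = np.zeros((40, 40), dtype=np.int32)
        m[:20, :20] = 1
        return m

    def test_majority_inside_gets_label(self):
        t = _trace_table({"t1": [(i, i, 0, 0.5, 0.5, 1) for i in range(5)]})
        out = trace_assign_mask(t, self._mask(), "mesoderm", 0.1, 0.25)
        assert (out.label == "mesoderm").all()

    def test_minority_inside_not_labeled(self):
        items = [(0, 1, 0.5, 0.5, 0), (1, 2, 3.0, 3.0, 0), (2, 3, 3.0, 3.0, 0),
                 (3, 4, 3.0, 3.0, 0), (4, 5, 3.0, 3.0, 0)]
        t = _trace_table({"t1": [(s, b, x, y, z, 1) for s, b, x, y, z in items]})
        out = trace_assign_mask(t, self._mask(), "mesoderm", 0.1, 0.25)
        assert (out.label == "").all()

    def test_second_label_appends(self):
        t = _trace_table({"t1": [(0, 1, 0.5, 0.5, 0, 1)]})
        out = trace_assign_mask(t, self._mask(), "a", 0.1, 0.25)
        out = trace_assign_mask(out, self._mask(), "b", 0.1, 0.25)
        assert list(out.label) == ["a,b"]


class TestMergeAndAnalyze:
    def test_merge_disjoint_sums_rows(self):
        a = _trace_table({"t1": [(0, 1, 0, 0, 0, 1)]})
        b = _trace_table({"t2": [(1, 1, 0, 0, 0, 1)]})
        out = trace_merge([a, b])
        assert len(out) == 2

    def test_merge_collision_raises(self):
        a = _trace_table({"t1": [(0, 1, 0, 0, 0, 1)]})
        b = _trace_table({"t1": [(1, 1, 0, 0, 0, 1)]})
        with pytest.raises(UUIDCollisionError):
            trace_merge([a, b])

    def test_merge_single_table_identity(self):
        a = _trace_table({"t1": [(0, 1, 0, 0, 0, 1)]})
        out = trace_merge([a])
        pd.testing.assert_frame_equal(out, a)

    def test_analyzer_barcode_count_histogram(self, tmp_path):
        t = _trace_table({"t1": [(0, 1, 0, 0, 0, 1), (1, 2, 1, 0, 0, 1),
                                 (2, 3, 0, 1, 0, 1)]})
        res = trace_analyzer(t, outdir=tmp_path)
        assert res["per_trace"].n_barcodes.tolist() == [3]
        assert (tmp_path / "per_trace.ecsv").exists()
        assert (tmp_path / "trace_statistics.png").exists()

    def test_identical_points_zero_rg(self):
        t = _trace_table({"t1": [(i, i, 1.0, 2.0, 3.0, 1) for i in range(4)]})
        res = trace_analyzer(t)
        assert res["per_trace"].rg_um.iloc[0] == 0.0

    def test_rg_matches_brute_force_on_chains(self, small_truth):
        """Mean radius of gyration agrees with direct computation on truth."""
        gt = small_truth.traces
        rows = []
        for idx, g in gt.groupby("trace_index"):
            rows.extend({"trace_id": f"t{idx}", "spot_id": r.Index,
                         "barcode": r.barcode, "x_um": r.x_um, "y_um": r.y_um,
                         "z_um": r.z_um, "mask_label": 0, "roi": "001",
                         "label": "", "amplitude": 1.0}
                        for r in g.itertuples())
        res = trace_analyzer(pd.DataFrame(rows))
        direct = []
        for idx, g in gt.groupby("trace_index"):
            pts = g[["x_um", "y_um", "z_um"]].to_numpy()
            direct.append(np.sqrt(((pts - pts.mean(0)) ** 2).sum(1).mean()))
        assert np.isclose(res["per_trace"].rg_um.mean(), np.mean(direct))
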