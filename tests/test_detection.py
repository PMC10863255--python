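"""Spot detection, 3D Gaussian fitting, mask segmentation, filtering,
and application of registration corrections to localization tables."""

import numpy as np
import pandas as pd
import pytest
from scipy.ndimage import gaussian_filter

from chromatrace.config import DetectionConfig
from chromatrace.detection import (
    RegistrationStateError,
    detect_spot_candidates,
    filter_localizations,
    fit_gaussian_3d,
    locate_spots_2d,
    locate_spots_3d,
    register_localizations,
    segment_masks_2d,
    segment_masks_3d,
    register_spot_detector,
    SPOT_DETECTORS,
)
from chromatrace.registration import global_shift_table
from chromatrace.stack import ImageStack


def _render(positions, shape=(20, 96, 96), amp=800.0, sigma=(1.4, 1.3), bg=100.0):
    vol = np.full(shape, bg)
    zz, yy, xx = np.indices(shape).astype(float)
    for p in np.atleast_2d(positions):
        vol += amp * np.exp(-((zz - p[0]) ** 2) / (2 * sigma[0] ** 2)
                            - ((yy - p[1]) ** 2) / (2 * sigma[1] ** 2)
                            - ((xx - p[2]) ** 2) / (2 * sigma[1] ** 2))
    return vol


def _stack(vox):
    return ImageStack(np.asarray(vox), "001", "RT01", "barcode", 0.1, 0.25)


@pytest.fixture()
def det_config():
    return DetectionConfig()


class TestDetectCandidates:
    def test_blank_stack_few_false_positives(self, det_config):
        """Background + noise only: at most one spurious candidate per FOV."""
        fps = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            vox = rng.poisson(100, size=(16, 128, 128)).astype(float)
            vox += rng.normal(0, 3, vox.shape)
            fps.append(len(detect_spot_candidates(_stack(vox), det_config)))
        assert np.mean(fps) <= 1.0

    def test_well_separated_spots_all_found(self, det_config, rng):
        pos = np.column_stack([
            rng.uniform(4, 15, 20), rng.uniform(8, 88, 20), rng.uniform(8, 88, 20)])
        # enforce separation
        keep = [pos[0]]
        for p in pos[1:]:
            if all(np.linalg.norm(p[1:] - q[1:]) > 10 for q in keep):
                keep.append(p)
        pos = np.array(keep)
        vox = rng.poisson(_render(pos)).astype(float)
        found = detect_spot_candidates(_stack(vox), det_config)
        assert len(found) == len(pos)
        for p in pos:
            assert np.min(np.linalg.norm(found - p, axis=1)) <= 1.8

    def test_detector_plugin_registry(self, det_config):
        @register_spot_detector("null")
        def null_detector(voxels, sigma_px, **kw):
            return np.zeros((0, 3))

        det_config.spot_detection.name = "null"
        vox = _render([(10, 48, 48)])
        assert len(detect_spot_candidates(_stack(vox), det_config)) == 0
        SPOT_DETECTORS.pop("null")
        det_config.spot_detection.name = "missing"
        with pytest.raises(KeyError, match="missing"):
            detect_spot_candidates(_stack(vox), det_config)


class TestFitGaussian3D:
    def test_noiseless_subpixel_center_recovered(self):
        true = (9.3, 47.6, 50.2)
        vox = _render([true])
        fit = fit_gaussian_3d(vox, (9, 48, 50), box=(9, 11, 11),
                              sigma_init_px=(1.4, 1.3))
        assert fit["converged"]
        assert abs(fit["z_px"] - true[0]) < 1e-3
        assert abs(fit["y_px"] - true[1]) < 1e-3
        assert abs(fit["x_px"] - true[2]) < 1e-3

    def test_poisson_noise_rmse_below_bound(self):
        """SNR ~ 10: center RMSE < 0.15 px per axis over repeats."""
        rng = np.random.default_rng(99)
        errs = []
        for _ in range(60):
            true = (9.0 + rng.uniform(-0.5, 0.5),
                    47.0 + rng.uniform(-0.5, 0.5),
                    50.0 + rng.uniform(-0.5, 0.5))
            vox = rng.poisson(_render([true], amp=110.0)).astype(float)
            fit = fit_gaussian_3d(vox, tuple(round(c) for c in true),
                                  box=(9, 11, 11), sigma_init_px=(1.4, 1.3))
            assert fit["converged"]
            errs.append([fit["z_px"] - true[0], fit["y_px"] - true[1],
                         fit["x_px"] - true[2]])
        rmse = np.sqrt((np.array(errs) ** 2).mean(axis=0))
        assert np.all(rmse < 0.15)

    def test_flat_box_not_converged_keeps_centroid(self):
        vox = np.full((20, 40, 40), 55.0)
        fit = fit_gaussian_3d(vox, (10, 20, 20))
        assert not fit["converged"]
        assert (fit["z_px"], fit["y_px"], fit["x_px"]) == (10.0, 20.0, 20.0)


class TestSegmentMasks:
    def _ellipsoids(self, centers, radii=(4.5, 11, 11), shape=(24, 128, 128)):
        zz, yy, xx = np.indices(shape).astype(float)
        vol = np.full(shape, 60.0)
        labels = np.zeros(shape, dtype=int)
        for i, c in enumerate(centers, start=1):
            r2 = (((zz - c[0]) / radii[0]) ** 2 + ((yy - c[1]) / radii[1]) ** 2
                  + ((xx - c[2]) / radii[2]) ** 2)
            vol[r2 <= 1] = 3000.0
            labels[r2 <= 1] = i
        return vol, labels

    def test_disjoint_ellipsoids_high_jaccard(self, det_config):
        vol, truth = self._ellipsoids([(12, 32, 32), (12, 90, 90)])
        out = segment_masks_3d(
            ImageStack(vol, "001", "DAPI", "mask_nuclei", 0.1, 0.25), det_config)
        assert out.max() == 2
        for lab in (1, 2):
            t = truth == lab
            # find matching output label by overlap
            olab = np.bincount(out[t].ravel()).argmax()
            o = out == olab
            jaccard = (t & o).sum() / (t | o).sum()
            assert jaccard >= 0.95

    def test_touching_ellipsoids_split_by_watershed(self, det_config):
        vol, _ = self._ellipsoids([(12, 60, 54), (12, 60, 73)])
        out = segment_masks_3d(
            ImageStack(vol, "001", "DAPI", "mask_nuclei", 0.1, 0.25), det_config)
        assert out.max() == 2

    def test_speckle_noise_removed_by_size_filter(self, det_config):
        rng = np.random.default_rng(0)
        vol = np.full((16, 64, 64), 50.0)
        idx = rng.integers(0, vol.size, 60)
        vol.ravel()[idx] = 5000.0
        out = segment_masks_3d(
            ImageStack(vol, "001", "DAPI", "mask_nuclei", 0.1, 0.25), det_config)
        assert out.max() == 0

    def test_2d_variant(self, det_config):
        img = np.full((128, 128), 60.0)
        yy, xx = np.indices(img.shape)
        img[((yy - 40) ** 2 + (xx - 40) ** 2) < 15 ** 2] = 3000.0
        img[((yy - 95) ** 2 + (xx - 95) ** 2) < 15 ** 2] = 3000.0
        out = segment_masks_2d(img, det_config, size_bounds=(100, 10000))
        assert out.max() == 2


class TestLocateSpots2D:
    def test_single_gaussian_subpixel(self, det_config):
        yy, xx = np.indices((64, 64)).astype(float)
        img = 50 + 900 * np.exp(-((yy - 30.4) ** 2 + (xx - 33.7) ** 2)
                                / (2 * 1.3 ** 2))
        table = locate_spots_2d(img, det_config, pixel_size_xy=0.1,
                                focus_plane=7, roi="001", cycle="RT01")
        assert len(table) == 1
        assert abs(table.y_px[0] - 30.4) < 0.1
        assert abs(table.x_px[0] - 33.7) < 0.1
        assert table.z_px[0] == 7.0
        assert (table["mode"] == "2d").all()

    def test_elongated_artifact_rejected_by_roundness(self, det_config):
        yy, xx = np.indices((64, 64)).astype(float)
        img = 50 + 900 * np.exp(-((yy - 30.0) ** 2) / (2 * 1.0 ** 2)
                                - ((xx - 32.0) ** 2) / (2 * 8.0 ** 2))
        table = locate_spots_2d(img, det_config, pixel_size_xy=0.1)
        assert len(table) == 0

    def test_empty_image_empty_table(self, det_config):
        table = locate_spots_2d(np.zeros((32, 32)), det_config, pixel_size_xy=0.1)
        assert len(table) == 0


def _loc_table():
    return pd.DataFrame({
        "spot_id": np.arange(10, dtype=np.int64),
        "roi": ["001"] * 10,
        "cycle": ["RT01"] * 5 + ["RT02"] * 5,
        "barcode": np.array([1] * 5 + [2] * 5, dtype=np.int64),
        "z_px": np.linspace(4, 8, 10),
        "y_px": np.linspace(10, 60, 10),
        "x_px": np.linspace(12, 62, 10),
        "z_um": np.linspace(4, 8, 10) * 0.25,
        "y_um": np.linspace(10, 60, 10) * 0.1,
        "x_um": np.linspace(12, 62, 10) * 0.1,
        "sigma_xy_um": 0.13, "sigma_z_um": 0.35,
        "amplitude": np.linspace(100, 1000, 10),
        "background": 100.0, "residual": 1.0,
        "converged": True, "registered": False,
        "block_quality": 0.0, "mode": "3d",
    })


class TestFilterLocalizations:
    def test_all_above_thresholds_identity(self):
        table = _loc_table()
        out, report = filter_localizations(table, intensity_min=0.0)
        pd.testing.assert_frame_equal(
            out.reset_index(drop=True), table.reset_index(drop=True))

    def test_intensity_filter_counts(self):
        table = _loc_table()  # amplitudes 100..1000
        out, report = filter_localizations(table, intensity_min=350.0)
        assert report["removed_intensity"] == 3
        assert len(out) == 7
        assert set(out.spot_id) <= set(table.spot_id)

    def test_never_increases_rows(self):
        table = _loc_table()
        table.loc[3, "converged"] = False
        out, _ = filter_localizations(table, intensity_min=0.0,
                                      sigma_xy_bounds=(0.02, 0.6),
                                      sigma_z_bounds=(0.05, 1.5))
        assert len(out) <= len(table)
        assert 3 not in set(out.spot_id)


class TestRegisterLocalizations:
    def _shifts(self, dy1=0.0, dx1=0.0, dy2=0.0, dx2=0.0):
        return global_shift_table([
            {"roi": "001", "cycle": "RT01", "dy_px": dy1, "dx_px": dx1,
             "rms_error": 0.0, "n_blocks_agreeing": 4, "method": "reference"},
            {"roi": "001", "cycle": "RT02", "dy_px": dy2, "dx_px": dx2,
             "rms_error": 0.0, "n_blocks_agreeing": 4, "method": "block_polling"},
        ])

    def test_zero_shifts_sets_flag_only(self):
        table = _loc_table()
        out = register_localizations(table, self._shifts(), None, 0.1, 0.25)
        assert out.registered.all()
        np.testing.assert_allclose(out.y_px, table.y_px)
        assert len(out) == len(table)

    def test_global_shift_arithmetic(self):
        table = _loc_table()
        out = register_localizations(table, self._shifts(dy2=2.0, dx2=-1.5),
                                     None, 0.1, 0.25)
        rt2 = out[out.cycle == "RT02"]
        orig = table[table.cycle == "RT02"]
        np.testing.assert_allclose(rt2.y_px, orig.y_px + 2.0)
        np.testing.assert_allclose(rt2.x_px, orig.x_px - 1.5)
        np.testing.assert_allclose(rt2.y_um, (orig.y_px + 2.0) * 0.1)
        # non-coordinate columns untouched
        np.testing.assert_allclose(rt2.amplitude, orig.amplitude)

    def test_double_registration_refused(self):
        table = _loc_table()
        out = register_localizations(table, self._shifts(), None, 0.1, 0.25)
        with pytest.raises(RegistrationStateError):
            register_localizations(out, self._shifts(), None, 0.1, 0.25)

    def test_missing_cycle_named_in_error(self):
        table = _loc_table()
        shifts = self._shifts().iloc[:1]
        with pytest.raises(KeyError, match="RT02"):
            register_localizations(table, shifts, None, 0.1, 0.25)

    def test_full_3d_localization_on_rendered_stack(self):
        cfg = DetectionConfig()
        rng = np.random.default_rng(5)
        pos = np.array([[8.2, 20.5, 30.1], [10.7, 60.3, 70.8], [6.1, 70.2, 20.4]])
        vox = rng.poisson(_render(pos)).astype(float)
        table = locate_spots_3d(_stack(vox), cfg, barcode=3)
        assert len(table) == 3
        assert (table.barcode == 3).all()
        for p in pos:
            d = np.linalg.norm(
                table[["z_px", "y_px", "x_px"]].to_numpy() - p, axis=1)
            assert d.min() < 0.2
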