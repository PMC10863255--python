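"""Global 2D registration (block polling) and local 3D block registration."""

import numpy as np
import pytest
from scipy.ndimage import fourier_shift, gaussian_filter

from chromatrace.registration import (
    RegistrationError,
    align_3d_blocks,
    align_by_block,
    apply_shift,
    apply_shift_stack,
    phase_shift,
)


def _bead_image(shape=(128, 128), n=25, seed=0):
    rng = np.random.default_rng(seed)
    img = np.zeros(shape)
    img[rng.integers(8, shape[0] - 8, n), rng.integers(8, shape[1] - 8, n)] = 4000
    return gaussian_filter(img, 1.3) + 100


def _subpixel_shift(img, shift):
    return np.fft.ifftn(fourier_shift(np.fft.fftn(img), shift)).real


class TestPhaseShift:
    def test_identity(self):
        img = _bead_image()
        dy, dx, err = phase_shift(img, img)
        assert (dy, dx) == (0.0, 0.0)

    def test_integer_roll_recovered_exactly(self):
        img = _bead_image()
        moving = np.roll(img, (3, -2), axis=(0, 1))  # content displaced +3, -2
        dy, dx, _ = phase_shift(img, moving)
        assert (dy, dx) == (-3.0, 2.0)

    def test_subpixel_shift_recovered(self):
        img = _bead_image()
        moving = _subpixel_shift(img, (-0.5, 0.25))
        dy, dx, _ = phase_shift(img, moving, upsample_factor=100)
        assert abs(dy - 0.5) < 0.05 and abs(dx + 0.25) < 0.05

    def test_antisymmetry(self):
        img = _bead_image()
        moving = _subpixel_shift(img, (1.3, -2.7))
        f = phase_shift(img, moving, upsample_factor=50)
        b = phase_shift(moving, img, upsample_factor=50)
        assert abs(f[0] + b[0]) <= 1 / 50 + 1e-9
        assert abs(f[1] + b[1]) <= 1 / 50 + 1e-9

    def test_constant_image_rejected(self):
        img = _bead_image()
        with pytest.raises(RegistrationError, match="constant"):
            phase_shift(img, np.zeros_like(img))


class TestAlignByBlock:
    def test_uniform_shift_full_consensus(self):
        img = _bead_image((256, 256), n=120)
        moving = np.roll(img, (1, -1), axis=(0, 1))
        (dy, dx), diag = align_by_block(img, moving, block_size=64)
        # beads cut by block borders bias single blocks; the poll averages out
        assert abs(dy + 1.0) < 0.15 and abs(dx - 1.0) < 0.15
        assert diag.winning_fraction == 1.0

    def test_robust_to_contaminated_blocks(self):
        """Impurities pasted into a minority of blocks do not move the poll."""
        rng = np.random.default_rng(4)
        img = _bead_image((256, 256), n=120)
        moving = np.roll(img, (2, 0), axis=(0, 1)).copy()
        blocks = [(by, bx) for by in range(4) for bx in range(4)]
        rng.shuffle(blocks)
        for by, bx in blocks[:4]:
            yy, xx = by * 64 + 20, bx * 64 + 20
            moving[yy:yy + 10, xx:xx + 10] += 50000
        (dy, dx), diag = align_by_block(img, moving, block_size=64)
        assert abs(dy + 2.0) < 0.2 and abs(dx) < 0.2

    def test_tie_breaks_by_lower_error(self):
        # half the blocks carry a pristine copy (shift 2,0), half a noisy
        # decoy pattern; the pristine bin must win via the error tie-break
        img = np.zeros((256, 256))
        rng = np.random.default_rng(1)
        for by in range(4):
            for bx in range(4):
                tile = _bead_image((64, 64), n=10, seed=by * 4 + bx)
                img[by * 64:(by + 1) * 64, bx * 64:(bx + 1) * 64] = tile
        moving = np.roll(img, (2, 0), axis=(0, 1)).copy()
        # decoys: replace 8 blocks with an unrelated pattern rolled by (5,5)
        cells = [(by, bx) for by in range(4) for bx in range(4)][:8]
        for by, bx in cells:
            decoy = np.roll(_bead_image((64, 64), n=10, seed=100 + by * 4 + bx)
                            + rng.normal(0, 60, (64, 64)), (5, 5), axis=(0, 1))
            moving[by * 64:(by + 1) * 64, bx * 64:(bx + 1) * 64] = decoy
        (dy, dx), diag = align_by_block(img, moving, block_size=64)
        assert abs(dy + 2.0) < 0.3 and abs(dx) < 0.3

    def test_fallback_to_whole_image(self):
        img = _bead_image((64, 64), n=10)
        moving = np.roll(img, (1, 1), axis=(0, 1))
        (dy, dx), diag = align_by_block(img, moving, block_size=64)
        assert diag.fallback
        assert abs(dy + 1.0) < 0.05


class TestApplyShift:
    def test_zero_shift_identity(self):
        img = _bead_image()
        np.testing.assert_allclose(apply_shift(img, (0, 0)), img, atol=1e-9)

    def test_integer_shift_matches_roll_interior(self):
        img = _bead_image()
        out = apply_shift(img, (3, -2))
        rolled = np.roll(img, (3, -2), axis=(0, 1))
        interior = (slice(5, -5), slice(5, -5))
        np.testing.assert_allclose(out[interior], rolled[interior], atol=1e-6)

    def test_forward_backward_near_inverse(self):
        img = gaussian_filter(_bead_image(), 2.0)  # smooth test image
        out = apply_shift(apply_shift(img, (1.7, -0.4)), (-1.7, 0.4))
        interior = (slice(6, -6), slice(6, -6))
        err = np.abs(out[interior] - img[interior]).max()
        assert err < 0.01 * np.ptp(img)

    def test_registration_sign_convention(self):
        """The stored shift maps moving-image coordinates to reference."""
        img = _bead_image()
        moving = np.roll(img, (4, 0), axis=(0, 1))  # content displaced +4 in y
        dy, dx, _ = phase_shift(img, moving)
        assert dy == -4.0  # coordinate in moving + (-4) = coordinate in reference
        realigned = apply_shift(moving, (dy, dx))
        interior = (slice(6, -6), slice(6, -6))
        np.testing.assert_allclose(realigned[interior], img[interior], atol=1e-3)


class TestAlign3DBlocks:
    def _stack(self, shape=(12, 128, 128), n=40, seed=0):
        rng = np.random.default_rng(seed)
        vol = np.zeros(shape)
        vol[rng.integers(2, shape[0] - 2, n),
            rng.integers(6, shape[1] - 6, n),
            rng.integers(6, shape[2] - 6, n)] = 5000
        return gaussian_filter(vol, (1.2, 1.3, 1.3)) + 50

    def test_identical_stacks_zero_corrections(self):
        vol = self._stack()
        table = align_3d_blocks(vol, vol, (0.0, 0.0), block_size_3d=(0, 64, 64))
        assert np.allclose(table[["dz_px", "dy_px", "dx_px"]].to_numpy(), 0)
        assert (table.quality > 0.99).all()

    def test_uniform_3d_shift_recovered_per_block(self):
        vol = self._stack()
        moving = np.roll(vol, (1, 2, -1), axis=(0, 1, 2))
        # global 2D correction handles (2, -1); blocks recover dz = -1
        table = align_3d_blocks(vol, moving, (-2.0, 1.0),
                                block_size_3d=(0, 64, 64))
        good = table[~table.flagged]
        assert len(good) == 4
        np.testing.assert_allclose(good.dz_px, -1.0, atol=0.2)
        np.testing.assert_allclose(good.dy_px, 0.0, atol=0.2)

    def test_empty_block_flagged_zero(self):
        vol = self._stack()
        empty = vol.copy()
        empty[:, :64, :64] = 50.0  # constant block: no beads
        table = align_3d_blocks(empty, empty, (0.0, 0.0),
                                block_size_3d=(0, 64, 64))
        row = table[(table.block_y == 0) & (table.block_x == 0)].iloc[0]
        assert row.flagged and row.quality == 0.0
        assert (row.dz_px, row.dy_px, row.dx_px) == (0.0, 0.0, 0.0)

    def test_oversize_correction_capped_to_zero(self):
        vol = self._stack()
        moving = np.roll(vol, (0, 10, 0), axis=(0, 1, 2))  # beyond the 3 px cap
        table = align_3d_blocks(vol, moving, (0.0, 0.0),
                                block_size_3d=(0, 64, 64), correction_cap=3.0)
        assert table.flagged.all()

    def test_apply_shift_stack_planewise(self):
        vol = self._stack((6, 64, 64), n=15)
        out = apply_shift_stack(vol, (2.0, -1.0))
        for z in range(6):
            np.testing.assert_allclose(out[z], apply_shift(vol[z], (2.0, -1.0)))
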