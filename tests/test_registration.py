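"""Rasterization, rigid/non-rigid estimation and point transfer."""

import numpy as np
import pytest

from spatimm.registration import (
    DeformationField,
    MarkerPointPattern,
    RasterGrid,
    RigidTransform,
    _ncc,
    _resample_rigid,
    _warp,
    align_to_reference,
    rasterize,
    register_nonrigid,
    register_rigid,
    upsample_and_transform,
)

EXTENT = (0.0, 0.0, 2000.0, 2000.0)


def textured_image(seed=1, side=256):
    """Smooth random texture standing in for a density raster."""
    from scipy import ndimage

    r = np.random.default_rng(seed)
    img = ndimage.gaussian_filter(r.uniform(0, 1, (side, side)), 6)
    return img - img.min()


class TestRasterize:
    def test_single_center_point_single_bin(self):
        pat = MarkerPointPattern("m", np.array([[1000.0, 1000.0]]), EXTENT)
        img, grid = rasterize(pat, target_side=100, sigma=0.0)
        assert img.sum() == 1
        iy, ix = np.unravel_index(np.argmax(img), img.shape)
        assert (iy, ix) == (50, 50)

    def test_mass_conservation_pre_smoothing(self, rng):
        pts = rng.uniform(0, 2000, size=(777, 2))
        img, _ = rasterize(MarkerPointPattern("m", pts, EXTENT), 128, sigma=0.0)
        assert img.sum() == 777

    def test_translated_pattern_peaks_at_offset(self, rng):
        pts = rng.uniform(200, 1800, size=(400, 2))
        img0, grid = rasterize(MarkerPointPattern("m", pts, EXTENT), 100, sigma=2.0)
        shift_um = 10 * grid.scale  # ten working pixels in x
        img1, _ = rasterize(MarkerPointPattern("m", pts + [shift_um, 0], EXTENT), 100, sigma=2.0)
        # brute-force correlation oracle over integer offsets
        best = max(
            ((dx, dy, (np.roll(np.roll(img0, dy, 0), dx, 1) * img1).sum())
             for dx in range(-15, 16) for dy in range(-4, 5)),
            key=lambda t: t[2],
        )
        assert (best[0], best[1]) == (10, 0)

    def test_empty_pattern_warns_zero_image(self):
        with pytest.warns(UserWarning):
            img, _ = rasterize(MarkerPointPattern("m", np.empty((0, 2)), EXTENT), 100)
        assert img.sum() == 0

    def test_small_target_rejected(self):
        with pytest.raises(ValueError):
            rasterize(MarkerPointPattern("m", np.array([[1.0, 1.0]]), EXTENT), 32)


class TestRegisterRigid:
    def test_identity_on_equal_images(self):
        img = textured_image()
        t, score = register_rigid(img, img)
        assert abs(t.rotation_deg) < 0.1
        assert np.hypot(*t.shift) < 0.5

    def test_planted_rotation_and_shift_recovered(self):
        img = textured_image(2)
        planted = RigidTransform(5.0, (8.0, -3.0), RigidTransform.identity(256).center)
        fixed = _resample_rigid(img, planted)
        est, _ = register_rigid(img, fixed)
        # estimated map composed with planted inverse should be near identity
        assert est.rotation_deg == pytest.approx(5.0, abs=0.5)
        assert np.hypot(est.shift[0] - 8.0, est.shift[1] + 3.0) < 1.0

    def test_score_never_below_identity(self):
        a, b = textured_image(3), textured_image(4)
        _, score = register_rigid(a, b)
        assert score >= _ncc(a, b) - 1e-12

    def test_flat_image_returns_identity_with_warning(self):
        img = textured_image(5)
        with pytest.warns(UserWarning):
            t, _ = register_rigid(np.zeros_like(img), img)
        assert t.rotation_deg == 0 and t.shift == (0.0, 0.0)


class TestRegisterNonrigid:
    def test_equal_images_give_negligible_field(self):
        img = textured_image(6)
        u = register_nonrigid(img, img, window_sizes=(128, 64))
        assert np.abs(u).max() < 0.3

    def test_planted_sinusoidal_warp_recovered(self):
        img = textured_image(7, side=500)
        n = 500
        yy, xx = np.mgrid[0:n, 0:n].astype(float)
        u_true = np.stack(
            [3.0 * np.sin(2 * np.pi * xx / 300) + 2.0 * np.sin(2 * np.pi * (xx + yy) / 400),
             2.5 * np.cos(2 * np.pi * yy / 350)], -1,
        )
        fixed = _warp(img, u_true)  # fixed(x) = moving(x + u_true(x))
        u = register_nonrigid(img, fixed, window_sizes=(200, 120, 80))
        err = np.linalg.norm(u - u_true, axis=-1)[40:-40, 40:-40]
        assert err.mean() < 1.5

    def test_dissimilarity_never_increased(self):
        a, b = textured_image(8), textured_image(9)
        u = register_nonrigid(a, b, window_sizes=(128, 64))
        assert _ncc(_warp(a, u), b) >= _ncc(a, b) - 1e-12


class TestPointTransfer:
    def make_field(self, u, scale=0.2, side=100):
        grid = RasterGrid(origin=(0.0, 0.0), scale=scale, side=side)
        return DeformationField(RigidTransform.identity(side), u, grid)

    def test_zero_field_is_identity(self, rng):
        side = 100
        field = self.make_field(np.zeros((side, side, 2)), scale=20.0)
        pat = MarkerPointPattern("m", rng.uniform(0, 2000, (50, 2)), EXTENT)
        out, n_out = upsample_and_transform(field, pat)
        assert np.allclose(out.points, pat.points)
        assert n_out == 0

    def test_constant_5px_field_at_02um_resolution_shifts_1um(self):
        # a uniform 5-pixel displacement at 0.2 µm/pixel is exactly +1 µm in x
        side = 100
        u = np.zeros((side, side, 2))
        u[..., 0] = 5.0
        field = self.make_field(u, scale=0.2, side=side)
        pat = MarkerPointPattern("m", np.array([[10.0, 10.0], [3.0, 7.0]]), (0, 0, 20, 20))
        out, _ = upsample_and_transform(field, pat)
        assert np.allclose(out.points - pat.points, [[1.0, 0.0], [1.0, 0.0]])

    def test_out_of_domain_points_counted_and_warned(self):
        side = 100
        field = self.make_field(np.zeros((side, side, 2)), scale=1.0, side=side)
        pat = MarkerPointPattern("m", np.array([[50.0, 50.0], [500.0, 50.0]]), (0, 0, 600, 600))
        with pytest.warns(UserWarning):
            _, n_out = upsample_and_transform(field, pat)
        assert n_out == 1

    def test_field_npz_round_trip(self, tmp_path, rng):
        side = 64
        u = rng.normal(0, 2, (side, side, 2))
        grid = RasterGrid(origin=(3.0, -4.0), scale=4.0, side=side)
        field = DeformationField(
            RigidTransform(2.5, (1.0, -2.0), (31.5, 31.5)), u, grid, "CK", "CD3"
        )
        field.save_npz(tmp_path / "f.npz")
        back = DeformationField.load_npz(tmp_path / "f.npz")
        assert np.array_equal(back.u, field.u)
        assert back.rigid == field.rigid
        assert back.grid == field.grid
        assert (back.moving_id, back.fixed_id) == ("CK", "CD3")

    def test_nonfinite_field_rejected(self):
        side = 100
        u = np.zeros((side, side, 2))
        u[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            self.make_field(u)


class TestAlignToReference:
    def test_single_slide_identity(self, rng):
        pat = MarkerPointPattern("m", rng.uniform(0, 2000, (100, 2)), EXTENT)
        res = align_to_reference([pat], target_side=100)
        assert len(res) == 1 and res[0].is_reference
        assert np.allclose(res[0].transformed.points, pat.points)

    def test_seven_slides_six_registrations_reference_index_3(self, rng):
        slides = [
            MarkerPointPattern(f"m{i}", rng.uniform(400, 1600, (150, 2)), EXTENT)
            for i in range(7)
        ]
        res = align_to_reference(slides, target_side=100, nonrigid=False)
        assert sum(r.is_reference for r in res) == 1
        assert res[3].is_reference  # middle of a 7-slide stack
        assert sum(not r.is_reference for r in res) == 6

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            align_to_reference([])

    def test_resolution_consistency(self, rng):
        # the full-resolution pixel size only converts coordinates; the
        # transferred µm positions must not depend on it
        pts = rng.uniform(400, 1600, (200, 2))
        outs = []
        for resolution in (0.1, 0.2):
            slides = [
                MarkerPointPattern("a", pts, EXTENT, resolution=resolution),
                MarkerPointPattern("b", pts + [15.0, -8.0], EXTENT, resolution=resolution),
                MarkerPointPattern("c", pts, EXTENT, resolution=resolution),
            ]
            res = align_to_reference(slides, target_side=250, nonrigid=False)
            outs.append(res[1].transformed.points)
        assert np.abs(outs[0] - outs[1]).max() < 2000.0 / 250  # < 1 working px
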