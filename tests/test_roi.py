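import numpy as np
import pytest

from vesselfd.roi import (
    ODGeometry,
    ROISpec,
    circular_roi_mask,
    detect_fovea,
    estimate_od_geometry,
    fit_ellipse,
    gaussian_color_transform,
    inpaint_vessels,
)


def disc_image(radius=40, size=200, axes=None, center=(100, 100)):
    """Bright yellow disc (or ellipse) on a flat fundus-coloured background."""
    rr, cc = np.ogrid[:size, :size]
    if axes is None:
        inside = np.hypot(rr - center[0], cc - center[1]) <= radius
    else:
        a, b = axes
        inside = ((rr - center[0]) / a) ** 2 + ((cc - center[1]) / b) ** 2 <= 1
    img = np.zeros((size, size, 3))
    img[..., 0] = 0.75 + 0.20 * inside
    img[..., 1] = 0.45 + 0.30 * inside
    img[..., 2] = 0.20 + 0.04 * inside
    return img


class TestColorTransform:
    @pytest.mark.parametrize(
        "rgb,expected",
        [
            ((0, 0, 0), (0.0, 0.0, 0.0)),
            ((1, 1, 1), (1.00, 0.00, -0.16)),
            ((1, 0, 0), (0.06, 0.19, 0.22)),
            ((0, 1, 0), (0.63, 0.18, -0.44)),
            ((0, 0, 1), (0.31, -0.37, 0.06)),
        ],
    )
    def test_basis_vectors(self, rgb, expected):
        img = np.broadcast_to(np.array(rgb, float), (2, 2, 3))
        planes = gaussian_color_transform(img)
        got = (planes.e[0, 0], planes.e_lambda[0, 0], planes.e_lambda_lambda[0, 0])
        assert got == pytest.approx(expected, abs=1e-12)

    def test_exact_linearity(self, rng):
        x = rng.random((8, 8, 3))
        y = rng.random((8, 8, 3))
        a, b = 2.5, -0.7
        lhs = gaussian_color_transform(a * x + b * y)
        rx, ry = gaussian_color_transform(x), gaussian_color_transform(y)
        assert np.allclose(lhs.e, a * rx.e + b * ry.e, atol=1e-12)
        assert np.allclose(lhs.e_lambda, a * rx.e_lambda + b * ry.e_lambda, atol=1e-12)

    def test_two_channel_input_rejected(self):
        with pytest.raises(ValueError, match="3-channel"):
            gaussian_color_transform(np.zeros((4, 4, 2)))


class TestEllipseFit:
    def test_exact_circle_recovered(self):
        theta = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        r = 17.3
        pts = np.stack([50 + r * np.sin(theta), 80 + r * np.cos(theta)], axis=1)
        (cr, cc), major, minor, _, resid = fit_ellipse(pts)
        assert (cr, cc) == pytest.approx((50, 80), abs=1e-6)
        assert major == pytest.approx(r, abs=1e-6)
        assert minor == pytest.approx(r, abs=1e-6)
        assert resid < 1e-6

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="6"):
            fit_ellipse(np.zeros((5, 2)))


class TestODGeometry:
    def test_synthetic_disc_radius_within_3_percent(self):
        geom = estimate_od_geometry(disc_image(radius=40), (100, 100), 80)
        assert geom.od_radius == pytest.approx(40, rel=0.03)

    def test_synthetic_ellipse_mean_radius(self):
        geom = estimate_od_geometry(disc_image(axes=(50, 40)), (100, 100), 90)
        assert geom.od_radius == pytest.approx(45, abs=2)

    def test_center_outside_image_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            estimate_od_geometry(disc_image(), (500, 500), 50)

    def test_phantom_recovery_ensemble(self, phantom_ensemble):
        errs = []
        for b in phantom_ensemble:
            geom = estimate_od_geometry(b.image, b.od_geometry.center, 72)
            errs.append(abs(geom.od_radius - b.od_geometry.od_radius)
                        / b.od_geometry.od_radius)
        assert float(np.mean(errs)) <= 0.05

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            ODGeometry(center=(0, 0), major_radius=5, minor_radius=8)


class TestFovea:
    def test_single_dark_dot_in_uniform_ring(self):
        img = np.full((300, 300), 0.6)
        od = ODGeometry(center=(150, 40), major_radius=20, minor_radius=20)
        img[150, 145] = 0.0    # dot at ~5.25 ODr from the disc centre
        pos = detect_fovea(img, od, np.zeros_like(img, bool),
                           fov_mask=np.ones_like(img, bool))
        assert np.hypot(pos[0] - 150, pos[1] - 145) <= 20

    def test_phantom_fovea_within_quarter_odr(self, phantom_ensemble):
        for b in phantom_ensemble[:10]:
            pos = detect_fovea(b.image, b.od_geometry, b.truth_vessels,
                               fov_mask=b.fov_mask)
            err = np.hypot(pos[0] - b.fovea_center[0], pos[1] - b.fovea_center[1])
            assert err <= 0.25 * b.od_geometry.od_radius

    def test_ring_outside_image_rejected(self):
        od = ODGeometry(center=(5, 5), major_radius=200, minor_radius=200)
        with pytest.raises(ValueError, match="ring"):
            detect_fovea(np.full((64, 64), 0.5), od, np.zeros((64, 64), bool),
                         fov_mask=np.ones((64, 64), bool))

    def test_inpainting_respects_neighbour_range(self, small_phantom):
        img = small_phantom.image[..., 1]
        vessels = small_phantom.truth_vessels
        filled = inpaint_vessels(img, vessels)
        assert np.array_equal(filled[~vessels], img[~vessels])
        # inpainted values stay within the local non-vessel range
        from scipy import ndimage as ndi

        lo = ndi.grey_erosion(np.where(vessels, np.inf, img), size=13)
        hi = ndi.grey_dilation(np.where(vessels, -np.inf, img), size=13)
        sel = vessels & np.isfinite(lo) & np.isfinite(hi)
        assert (filled[sel] >= lo[sel] - 1e-6).all()
        assert (filled[sel] <= hi[sel] + 1e-6).all()


class TestROIMask:
    def test_half_pixel_radius_is_centre_only(self):
        spec = ROISpec(center=(10, 10), k=1.0, od_radius=0.5, anchor="od_center")
        mask = circular_roi_mask(spec, (21, 21))
        assert mask.sum() == 1 and mask[10, 10]

    def test_area_matches_pi_r_squared(self):
        spec = ROISpec(center=(150, 150), k=1.0, od_radius=100.0, anchor="od_center")
        mask = circular_roi_mask(spec, (301, 301))
        assert mask.sum() == pytest.approx(np.pi * 100 ** 2, rel=0.01)

    def test_nesting_in_k(self):
        masks = {
            k: circular_roi_mask(
                ROISpec(center=(128, 128), k=k, od_radius=20.0, anchor="fovea"),
                (256, 256),
            )
            for k in (4, 5, 6)
        }
        assert not (masks[4] & ~masks[5]).any()
        assert not (masks[5] & ~masks[6]).any()

    def test_area_scales_as_k_squared(self):
        a4 = circular_roi_mask(
            ROISpec(center=(300, 300), k=4, od_radius=20.0, anchor="fovea"), (601, 601)
        ).sum()
        a6 = circular_roi_mask(
            ROISpec(center=(300, 300), k=6, od_radius=20.0, anchor="fovea"), (601, 601)
        ).sum()
        assert a6 / a4 == pytest.approx((6 / 4) ** 2, rel=0.01)

    def test_invalid_anchor_rejected(self):
        with pytest.raises(ValueError, match="anchor"):
            ROISpec(center=(0, 0), k=4, od_radius=10.0, anchor="macula")
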