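import numpy as np
import pytest
from scipy import ndimage as ndi

from vesselfd.fractal import compute_fd
from vesselfd.segmentation import segmentation_quality
from vesselfd.synthetic import (
    CameraProfile,
    PhantomSpec,
    emulate_camera,
    emulate_observer,
    make_analytic_fractal,
    make_vascular_phantom,
    render_probability_map,
)

from conftest import fovea_roi, small_spec


class TestAnalyticFractals:
    def test_filled_square_all_set(self):
        assert make_analytic_fractal("filled_square", 0, 256).all()

    def test_single_point_one_pixel(self):
        assert make_analytic_fractal("single_point", 0, 256).sum() == 1

    def test_sierpinski_cell_count(self):
        assert make_analytic_fractal("sierpinski_triangle", 7, 128).sum() == 3 ** 7

    def test_depth_too_large_names_maximum(self):
        with pytest.raises(ValueError, match="maximum feasible depth is 5"):
            make_analytic_fractal("sierpinski_triangle", 9, 32)

    def test_non_power_of_two_grid_rejected(self):
        with pytest.raises(ValueError, match="power of 2"):
            make_analytic_fractal("sierpinski_triangle", 3, 100)

    def test_block_upscaling_preserves_count_scaling(self):
        # depth 4 on a 64 grid: each cell becomes a 4x4 block
        m = make_analytic_fractal("sierpinski_triangle", 4, 64)
        assert m.sum() == 3 ** 4 * 16


class TestPhantom:
    def test_same_seed_bitwise_identical(self):
        a = make_vascular_phantom(small_spec(seed=7))
        b = make_vascular_phantom(small_spec(seed=7))
        assert np.array_equal(a.truth_vessels, b.truth_vessels)
        assert np.array_equal(a.image, b.image)

    def test_different_seeds_differ(self):
        a = make_vascular_phantom(small_spec(seed=7))
        b = make_vascular_phantom(small_spec(seed=8))
        assert not np.array_equal(a.truth_vessels, b.truth_vessels)

    def test_vessels_confined_to_fov(self, phantom_ensemble):
        for b in phantom_ensemble[:5]:
            assert not (b.truth_vessels & ~b.fov_mask).any()

    def test_unbranched_roots_give_n_components(self):
        spec = small_spec(seed=3, branch_prob=0.0, side_twig_prob=0.0,
                          n_peripapillary=0, subject_variability=0.0,
                          n_roots=3, angle_jitter_deg=4.0, max_depth=0)
        bundle = make_vascular_phantom(spec)
        _, n = ndi.label(bundle.truth_vessels)
        assert n == 3

    def test_subpixel_width_rejected(self):
        with pytest.raises(ValueError, match="sub-pixel"):
            small_spec(min_width_px=0.5)

    def test_fovea_disc_distance_invariant(self):
        with pytest.raises(ValueError, match="5 x od_radius"):
            PhantomSpec(od_center=(256.0, 50.0))

    def test_truth_dimension_in_curve_plane_range(self, phantom_ensemble):
        for b in phantom_ensemble:
            d = compute_fd(b.truth_vessels, fovea_roi(b, 5.0)).d_b
            assert 1.0 < d < 2.0


class TestObserver:
    def test_zero_caliber_is_identity(self, small_phantom):
        out = emulate_observer(small_phantom.truth_vessels, 0.0)
        assert np.array_equal(out, small_phantom.truth_vessels)

    def test_thin_stroke_removed_thick_kept(self):
        m = np.zeros((64, 64), bool)
        m[10, 5:60] = True                   # 1-px stroke
        m[30:35, 5:60] = True                # 5-px stroke
        out = emulate_observer(m, 3.0)
        assert not out[10, 5:60].any()
        assert out[30:35, 10:55].all()

    def test_output_subset_of_input(self, small_phantom):
        out = emulate_observer(small_phantom.truth_vessels, 2.0)
        assert not (out & ~small_phantom.truth_vessels).any()

    def test_monotone_in_caliber(self, small_phantom):
        prev = small_phantom.truth_vessels
        for cal in (1.0, 2.0, 3.0, 5.0):
            cur = emulate_observer(small_phantom.truth_vessels, cal)
            assert not (cur & ~prev).any()
            prev = cur


class TestProbabilityMap:
    def test_no_blur_no_noise_equals_truth(self, small_phantom):
        p = render_probability_map(small_phantom.truth_vessels, 0.0, 0.0)
        assert np.array_equal(p, small_phantom.truth_vessels.astype(float))

    def test_deterministic_per_seed(self, small_phantom):
        a = render_probability_map(small_phantom.truth_vessels, 1.5, 0.05, seed=4)
        b = render_probability_map(small_phantom.truth_vessels, 1.5, 0.05, seed=4)
        assert np.array_equal(a, b)

    def test_half_threshold_recovers_truth_well(self, default_phantom):
        # the half-threshold loses only the 1-px twigs whose blurred peak
        # falls below 0.5; everything else is recovered
        p = render_probability_map(default_phantom.truth_vessels, 1.5, 0.05, seed=9)
        q = segmentation_quality(p >= 0.5, default_phantom.truth_vessels)
        assert q.mcc > 0.85
        thick = emulate_observer(default_phantom.truth_vessels, 2.0)
        p2 = render_probability_map(thick, 1.5, 0.05, seed=9)
        q2 = segmentation_quality(p2 >= 0.5, thick)
        assert q2.mcc > 0.9

    def test_values_in_unit_interval(self, small_phantom):
        p = render_probability_map(small_phantom.truth_vessels, 2.0, 0.2, seed=1)
        assert p.min() >= 0.0 and p.max() <= 1.0


class TestCamera:
    def test_neutral_profile_is_identity(self, small_phantom):
        shot = emulate_camera(small_phantom, CameraProfile("neutral"), 1)
        assert np.array_equal(shot.image, small_phantom.image)
        assert np.array_equal(shot.truth_vessels, small_phantom.truth_vessels)

    def test_half_resolution_halves_geometry(self, small_phantom):
        prof = CameraProfile("half", resolution_scale=0.5)
        shot = emulate_camera(small_phantom, prof, 1)
        assert shot.image.shape[0] == small_phantom.image.shape[0] // 2
        assert shot.od_geometry.od_radius == pytest.approx(
            small_phantom.od_geometry.od_radius / 2
        )

    def test_jitter_produces_bounded_translations(self, small_phantom):
        prof = CameraProfile("jittery", acquisition_jitter_px=2.0)
        base = small_phantom.truth_vessels.astype(float)
        fbase = np.fft.rfft2(base)
        n = small_phantom.image.shape[0]
        images = set()
        for acq in range(1, 6):
            shot = emulate_camera(small_phantom, prof, acq)
            corr = np.fft.irfft2(np.fft.rfft2(shot.truth_vessels.astype(float))
                                 * np.conj(fbase), s=base.shape)
            idx = np.unravel_index(np.argmax(corr), corr.shape)
            dr = idx[0] if idx[0] < n // 2 else idx[0] - n
            dc = idx[1] if idx[1] < n // 2 else idx[1] - n
            assert abs(dr) <= 2 and abs(dc) <= 2
            images.add(shot.image.tobytes())
        assert len(images) >= 2  # acquisitions differ

    def test_acquisition_is_reproducible(self, small_phantom):
        prof = CameraProfile("noisy", noise_sigma=0.02, acquisition_jitter_px=1.0)
        a = emulate_camera(small_phantom, prof, 3)
        b = emulate_camera(small_phantom, prof, 3)
        assert np.array_equal(a.image, b.image)

    def test_invalid_profile_rejected(self):
        with pytest.raises(ValueError):
            CameraProfile("bad", resolution_scale=0.0)
        with pytest.raises(ValueError):
            CameraProfile("bad", resolution_scale=3.0)


def test_save_bundle_writes_sidecar(tmp_path, small_phantom):
    from vesselfd.synthetic import save_bundle

    sidecar = save_bundle(small_phantom, tmp_path, stem="p")
    assert (tmp_path / "p_image.png").exists()
    assert (tmp_path / "p_truth.png").exists()
    assert sidecar["spec"]["seed"] == small_phantom.spec.seed
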