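import math

import numpy as np
import pytest

from zsted import (
    ImageStack,
    MembraneScene,
    Plane,
    Profile1D,
    extract_profile,
    fit_fwhm,
    hollowness_contrast,
    image_scene,
    make_preset,
    render_scene,
    resolve_two_peaks,
    richardson_lucy,
)

_SQRT_8LN2 = math.sqrt(8 * math.log(2))


def gaussian_profile(center=0.0, sigma=45.86, spacing=5.0, half=600.0,
                     amp=1.0, base=0.0):
    x = np.arange(-half, half + spacing / 2, spacing) + 0.0
    y = amp * np.exp(-0.5 * ((x - center) / sigma) ** 2) + base
    return Profile1D(positions=x, values=y)


class TestExtractProfile:
    @pytest.fixture
    def stack(self, rng):
        vox = np.tile(np.exp(-0.5 * ((np.arange(40) - 20) / 4.0) ** 2)[:, None, None],
                      (1, 8, 6))
        return ImageStack(voxels=vox, origin=(-400.0, 0.0, 0.0))

    def test_roi_average_equals_line_for_uniform_image(self, stack):
        line = extract_profile(stack, axis="z", line=(3, 2))
        roi = extract_profile(stack, axis="z", roi=(slice(1, 6), slice(0, 4)))
        full = extract_profile(stack, axis="z")
        assert np.allclose(line.values, roi.values)
        assert np.allclose(line.values, full.values)

    def test_profile_spans_stack_extent(self, stack):
        prof = extract_profile(stack, axis="z")
        assert len(prof.values) == stack.voxels.shape[0]
        assert prof.positions[0] == stack.origin[0]

    def test_out_of_bounds_line_rejected(self, stack):
        with pytest.raises(IndexError):
            extract_profile(stack, axis="z", line=(100, 0))

    def test_unknown_axis_rejected(self, stack):
        with pytest.raises(ValueError):
            extract_profile(stack, axis="w")


class TestFitFwhm:
    def test_sigma_to_fwhm_conversion(self):
        res = fit_fwhm(gaussian_profile(sigma=45.86))
        assert res.ok
        assert res.fwhm == pytest.approx(45.86 * _SQRT_8LN2, rel=1e-6)
        assert res.fwhm == pytest.approx(108.0, abs=0.1)

    def test_translation_invariance(self):
        a = fit_fwhm(gaussian_profile(center=0.0))
        b = fit_fwhm(gaussian_profile(center=150.0))
        assert b.fwhm == pytest.approx(a.fwhm, rel=1e-9)
        assert b.center - a.center == pytest.approx(150.0, abs=1e-6)

    def test_baseline_does_not_bias_width(self):
        res = fit_fwhm(gaussian_profile(base=0.3))
        assert res.ok
        assert res.fwhm == pytest.approx(45.86 * _SQRT_8LN2, rel=1e-6)

    def test_two_equal_peaks_flagged(self):
        x = np.arange(-600, 601, 10.0)
        y = (np.exp(-0.5 * ((x + 200) / 50) ** 2)
             + np.exp(-0.5 * ((x - 200) / 50) ** 2))
        res = fit_fwhm(Profile1D(positions=x, values=y))
        assert not res.ok
        assert "peaks" in res.message

    def test_peak_at_edge_flagged(self):
        x = np.arange(0, 300, 10.0)
        y = np.exp(-0.5 * (x / 80) ** 2)
        res = fit_fwhm(Profile1D(positions=x, values=y))
        assert not res.ok

    def test_flat_profile_flagged(self):
        res = fit_fwhm(Profile1D(positions=np.arange(5) * 10.0,
                                 values=np.ones(5)))
        assert not res.ok


class TestResolveTwoPeaks:
    def test_two_well_separated_gaussians(self):
        x = np.arange(-500, 701, 20.0)
        y = (np.exp(-0.5 * (x / 50) ** 2)
             + np.exp(-0.5 * ((x - 200) / 50) ** 2))
        res = resolve_two_peaks(Profile1D(positions=x, values=y))
        assert res.n_peaks == 2
        assert res.separation == pytest.approx(200.0, abs=1.0)

    def test_single_gaussian(self):
        res = resolve_two_peaks(gaussian_profile())
        assert res.n_peaks == 1
        assert res.separation is None

    def test_flat_profile_has_no_peaks(self):
        res = resolve_two_peaks(Profile1D(positions=np.arange(10) * 20.0,
                                          values=np.ones(10)))
        assert res.n_peaks == 0

    def test_shallow_dip_between_twin_peaks_not_resolved(self):
        """Two equal maxima separated by a 2% dip are one unresolved blob
        under the 10% valley-depth criterion."""
        x = np.arange(-400, 501, 20.0)
        y = (np.exp(-0.5 * (x / 60) ** 2)
             + np.exp(-0.5 * ((x - 100) / 60) ** 2))
        res = resolve_two_peaks(Profile1D(positions=x, values=y))
        assert res.n_peaks == 1


class TestHollownessContrast:
    def test_filled_disk_not_hollow(self):
        x = np.arange(-300, 301, 20.0)
        prof = Profile1D(positions=x, values=np.exp(-0.5 * (x / 150) ** 2))
        assert hollowness_contrast(prof) <= 0

    def test_ideal_rim_with_zero_center(self):
        y = np.zeros(21)
        y[4] = y[16] = 5.0
        prof = Profile1D(positions=np.arange(21) * 20.0, values=y)
        assert hollowness_contrast(prof) == pytest.approx(1.0)

    def test_zero_profile_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            hollowness_contrast(Profile1D(positions=np.arange(9) * 20.0,
                                          values=np.zeros(9)))


@pytest.fixture(scope="module")
def zsted_plane_image():
    scene = MembraneScene((Plane(z0=0.0),),
                          extent=((-1810, 1810), (-600, 600), (-600, 600)))
    return image_scene(render_scene(scene), make_preset("z_sted"))


class TestRichardsonLucy:
    def test_zero_iterations_is_identity(self, zsted_plane_image, zsted_vol):
        out = richardson_lucy(zsted_plane_image, zsted_vol, iterations=0)
        assert np.array_equal(out.voxels, zsted_plane_image.voxels)

    def test_uniform_image_is_fixed_point(self, zsted_vol):
        stack = ImageStack(voxels=np.full((121, 21, 21), 3.0))
        out = richardson_lucy(stack, zsted_vol, iterations=3)
        assert np.allclose(out.voxels, 3.0, rtol=1e-6)

    def test_negative_input_rejected(self, zsted_vol):
        stack = ImageStack(voxels=np.ones((121, 21, 21)))
        stack.voxels[0, 0, 0] = -1.0  # bypasses the constructor check
        with pytest.raises(ValueError, match="non-negative"):
            richardson_lucy(stack, zsted_vol, iterations=1)

    def test_side_lobe_suppression_and_conservation(self, zsted_plane_image,
                                                    zsted_vol):
        """20 RL iterations suppress the z-STED lobe shadow by >= 5x while
        conserving total intensity."""
        dec = richardson_lucy(zsted_plane_image, zsted_vol, iterations=20)

        def lobe_ratio(stack):
            prof = extract_profile(stack, axis="z")
            main = prof.values[np.abs(prof.positions) <= 200].max()
            lobe = prof.values[np.abs(prof.positions - 800) <= 200].max()
            return lobe / main

        assert lobe_ratio(zsted_plane_image) == pytest.approx(0.15, rel=0.05)
        assert lobe_ratio(zsted_plane_image) / lobe_ratio(dec) >= 5.0
        assert dec.total == pytest.approx(zsted_plane_image.total, rel=1e-3)

    def test_updates_monotonically_increase_poisson_likelihood(self, zsted_vol):
        """RL is EM for the Poisson imaging model, so every iteration must
        increase the Poisson log-likelihood of the observed image."""
        from zsted.scenes import convolve_reflect, psf_kernel

        vox = np.zeros((121, 21, 21))
        vox[60, 10, 10] = 500.0
        vox[45, 6, 14] = 300.0
        truth = ImageStack(voxels=vox)
        obs = image_scene(truth, zsted_vol, noise=True, seed=1)
        kernel = psf_kernel(zsted_vol, truth.voxel_size)

        def loglik(est):
            mu = np.maximum(convolve_reflect(est.voxels, kernel), 1e-300)
            return float(np.sum(obs.voxels * np.log(mu) - mu))

        lls = [loglik(richardson_lucy(obs, zsted_vol, iterations=i))
               for i in range(6)]
        assert np.all(np.diff(lls) > -1e-6 * abs(lls[0]))
        assert lls[-1] > lls[0]
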