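import math

import numpy as np
import pytest

from zsted import (
    ImageStack,
    MembraneScene,
    Plane,
    SphereShell,
    Torus,
    Tube,
    image_scene,
    make_spectral_scene,
    render_scene,
)
from zsted.scenes import convolve_reflect, psf_kernel, read_tiff, write_tiff


def small_extent(z_half=400.0, lat_half=420.0):
    return ((-z_half - 10, z_half + 10), (-lat_half, lat_half), (-lat_half, lat_half))


class TestRenderScene:
    def test_single_plane_occupies_one_slice(self):
        scene = MembraneScene(primitives=(Plane(z0=0.0),), extent=small_extent())
        stack = render_scene(scene)
        nonzero_slices = np.flatnonzero(stack.voxels.sum(axis=(1, 2)))
        assert len(nonzero_slices) == 1
        assert stack.axis_coords(0)[nonzero_slices[0]] == pytest.approx(0.0)

    def test_two_planes_two_slices_at_correct_distance(self):
        scene = MembraneScene(primitives=(Plane(z0=0.0), Plane(z0=160.0)),
                              extent=small_extent())
        stack = render_scene(scene)
        nz = np.flatnonzero(stack.voxels.sum(axis=(1, 2)))
        assert len(nz) == 2
        z = stack.axis_coords(0)
        assert z[nz[1]] - z[nz[0]] == pytest.approx(160.0)

    @pytest.mark.parametrize("prim,area", [
        (SphereShell(center=(0, 0, 0), radius=200.0), 4 * math.pi * 200.0**2),
        (Tube(center_zx=(0, 0), radius=150.0, length=600.0),
         2 * math.pi * 150.0 * 600.0),
        (Torus(center=(0, 0, 0), ring_radius=250.0, tube_radius=100.0),
         4 * math.pi**2 * 250.0 * 100.0),
    ])
    def test_total_intensity_equals_surface_area(self, prim, area):
        scene = MembraneScene(primitives=(prim,), extent=small_extent())
        stack = render_scene(scene)
        assert stack.total == pytest.approx(area, rel=1e-6)

    def test_primitive_outside_extent_rejected(self):
        with pytest.raises(ValueError, match="outside the scene extent"):
            MembraneScene(primitives=(SphereShell(center=(0, 0, 0), radius=900.0),),
                          extent=small_extent())

    def test_label_density_scales_intensity(self):
        ext = small_extent()
        s1 = render_scene(MembraneScene((SphereShell((0, 0, 0), 200.0, 1.0),), ext))
        s3 = render_scene(MembraneScene((SphereShell((0, 0, 0), 200.0, 3.0),), ext))
        assert s3.total == pytest.approx(3 * s1.total, rel=1e-12)


class TestImageScene:
    def test_delta_impulse_returns_sampled_psf(self, zsted_vol):
        vox = np.zeros((121, 21, 21))
        vox[60, 10, 10] = 1.0
        truth = ImageStack(voxels=vox, origin=(-1200.0, -400.0, -400.0))
        image = image_scene(truth, zsted_vol)
        kernel = psf_kernel(zsted_vol, truth.voxel_size)
        kz, ky, kx = (s // 2 for s in kernel.shape)
        crop = image.voxels[60 - kz:60 + kz + 1, 10 - ky:10 + ky + 1,
                            10 - kx:10 + kx + 1]
        assert np.allclose(crop, kernel, atol=1e-12)

    def test_noiseless_convolution_conserves_intensity(self, confocal_vol):
        scene = MembraneScene((Plane(z0=0.0),),
                              extent=((-1810, 1810), (-600, 600), (-600, 600)))
        truth = render_scene(scene)
        image = image_scene(truth, confocal_vol, photons_per_unit=2.0)
        assert image.total == pytest.approx(2.0 * truth.total, rel=1e-6)

    def test_wider_psf_never_increases_peak(self, confocal_vol, zsted_vol):
        scene = MembraneScene((Plane(z0=0.0),),
                              extent=((-1810, 1810), (-600, 600), (-600, 600)))
        truth = render_scene(scene)
        img_conf = image_scene(truth, confocal_vol)
        img_zsted = image_scene(truth, zsted_vol)
        assert img_conf.voxels.max() <= img_zsted.voxels.max()
        assert img_conf.voxels.max() <= truth.voxels.max()

    def test_zsted_side_lobe_shadow_amplitude(self, zsted_vol):
        scene = MembraneScene((Plane(z0=0.0),),
                              extent=((-1810, 1810), (-600, 600), (-600, 600)))
        image = image_scene(render_scene(scene), zsted_vol)
        prof = image.voxels.mean(axis=(1, 2))
        z = image.axis_coords(0)
        main = prof[np.abs(z) <= 200].max()
        lobe = prof[np.abs(z - 800) <= 200].max()
        assert lobe / main == pytest.approx(zsted_vol.side_lobe_rel_amp, rel=0.02)

    def test_poisson_noise_seed_determinism(self, zsted_vol):
        scene = MembraneScene((Plane(z0=0.0),),
                              extent=((-1210, 1210), (-600, 600), (-600, 600)))
        truth = render_scene(scene)
        a = image_scene(truth, zsted_vol, noise=True, seed=5)
        b = image_scene(truth, zsted_vol, noise=True, seed=5)
        c = image_scene(truth, zsted_vol, noise=True, seed=6)
        assert np.array_equal(a.voxels, b.voxels)
        assert not np.array_equal(a.voxels, c.voxels)

    def test_kernel_larger_than_stack_rejected(self, confocal_vol):
        truth = ImageStack(voxels=np.ones((10, 10, 10)))
        with pytest.raises(ValueError, match="pad"):
            image_scene(truth, confocal_vol)


class TestSpectralScene:
    def test_gp_zero_gives_equal_channels(self):
        scene = MembraneScene((Plane(z0=0.0),), extent=small_extent())
        pair = make_spectral_scene(scene, gp_map=[0.0])
        assert np.allclose(pair.green.voxels, pair.red.voxels)

    def test_gp_one_gives_zero_red(self):
        scene = MembraneScene((Plane(z0=0.0),), extent=small_extent())
        pair = make_spectral_scene(scene, gp_map=[1.0])
        assert np.all(pair.red.voxels == 0)
        assert pair.green.voxels.sum() > 0

    def test_out_of_range_gp_rejected(self):
        scene = MembraneScene((Plane(z0=0.0),), extent=small_extent())
        with pytest.raises(ValueError, match=r"\[-1, 1\]"):
            make_spectral_scene(scene, gp_map=[1.5])

    def test_gp_map_length_must_match(self):
        scene = MembraneScene((Plane(z0=0.0),), extent=small_extent())
        with pytest.raises(ValueError, match="one GP value per primitive"):
            make_spectral_scene(scene, gp_map=[0.1, 0.2])


class TestTiffIO:
    def test_round_trip_with_metadata(self, tmp_path):
        stack = ImageStack(voxels=np.random.default_rng(0).random((5, 4, 3)),
                           voxel_size=(20.0, 40.0, 40.0),
                           origin=(-40.0, -60.0, -40.0),
                           meta={"mode": "z_sted", "seed": 3})
        path = tmp_path / "stack.tif"
        write_tiff(stack, path)
        back = read_tiff(path)
        assert np.allclose(back.voxels, stack.voxels, atol=1e-7)  # float32 file
        assert back.voxel_size == stack.voxel_size
        assert back.origin == stack.origin
        assert back.meta["mode"] == "z_sted"


class TestConvolveReflect:
    def test_matches_direct_spatial_convolution(self, rng):
        """FFT-with-reflect-padding equals scipy.ndimage direct convolution
        in reflect mode on a small stack."""
        from scipy.ndimage import convolve as direct

        arr = rng.random((9, 8, 7))
        kernel = rng.random((5, 3, 3))
        kernel /= kernel.sum()
        ours = convolve_reflect(arr, kernel)
        ref = direct(arr, kernel, mode="mirror")  # ndimage 'mirror' == np.pad 'reflect'
        assert np.allclose(ours, ref, atol=1e-10)
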