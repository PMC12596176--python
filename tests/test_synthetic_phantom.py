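"""Phantom layouts, rasterization ground truth, and the scan simulator."""

import numpy as np
import pytest

import lungqct as lq
from lungqct.synthetic_phantom import (CONFIGURATIONS, _insert_mask,
                                       default_grid)


class TestBuildLayout:
    def test_configuration_iv_insert_set(self):
        """The single-series configuration packs water, air, the MTF cube and
        a lung sample into the large tube."""
        labels = {i.label for i in lq.build_layout("iv").measured_inserts}
        assert {"water_vial_1", "water_vial_2", "air", "mtf_cube",
                "lung_sample_A"} <= labels

    def test_configuration_i_has_cube_and_foams(self):
        labels = {i.label for i in lq.build_layout("i").measured_inserts}
        assert "mtf_cube" in labels
        assert {"nist4", "nist8", "nist12"} <= labels

    def test_unknown_configuration_rejected_naming_options(self):
        with pytest.raises(ValueError, match="i, ii, iii, iv"):
            lq.build_layout("v")

    @pytest.mark.parametrize("config", list(CONFIGURATIONS))
    def test_insert_centers_inside_body(self, config):
        layout = lq.build_layout(config)
        hx, hy = layout.body_extent[0] / 2, layout.body_extent[1] / 2
        for ins in layout.inserts:
            assert abs(ins.center[0]) <= hx and abs(ins.center[1]) <= hy

    def test_layout_json_roundtrip(self, tmp_path, layout_i):
        path = tmp_path / "layout.json"
        layout_i.to_json(path)
        back = lq.PhantomLayout.from_json(path)
        assert [i.label for i in back.inserts] == [i.label for i in layout_i.inserts]
        assert back.inserts[0].center == layout_i.inserts[0].center


class TestRasterize:
    def test_air_insert_exactly_nominal(self, coarse_truth_i):
        truth, labels = coarse_truth_i
        assert (truth.voxels[labels.mask("air")] == -1000.0).all()

    def test_label_counts_match_point_in_shape_oracle(self):
        """Voxel counts per label equal a brute-force per-voxel geometric
        test on a small grid."""
        layout = lq.build_layout("i")
        spacing = (2.0, 2.0, 3.0)
        vol, lab = lq.rasterize(layout, spacing=spacing,
                                grid_shape=(140, 120, 50))
        xs, ys, zs = vol.world_axes()
        for ins in layout.measured_inserts:
            count = 0
            if ins.shape == "cylinder":
                for x in xs:
                    for y in ys:
                        if (x - ins.center[0]) ** 2 + (y - ins.center[1]) ** 2 \
                                <= ins.radius_or_halfedge ** 2:
                            count += np.count_nonzero(
                                np.abs(zs - ins.center[2]) <= ins.length / 2)
            else:
                R = ins.rotation()
                for i, x in enumerate(xs):
                    for j, y in enumerate(ys):
                        for k, z in enumerate(zs):
                            u = R.T @ np.array([x - ins.center[0],
                                                y - ins.center[1],
                                                z - ins.center[2]])
                            count += int(np.max(np.abs(u))
                                         <= ins.radius_or_halfedge)
            assert lab.mask(ins.label).sum() == count

    def test_default_grid_covers_inserts(self, layout_i):
        shape, origin = default_grid(layout_i)
        assert shape[0] == 512 and shape[1] == 512
        z_hi = origin[2] + (shape[2] - 1) * 0.5
        assert all(ins.z_extent()[1] <= z_hi for ins in layout_i.inserts)

    def test_grid_too_small_rejected(self, layout_i):
        with pytest.raises(ValueError, match="grid too small"):
            lq.rasterize(layout_i, spacing=(1.02, 1.02, 1.5),
                         grid_shape=(256, 256, 10))

    def test_nonpositive_spacing_rejected(self, layout_i):
        with pytest.raises(ValueError):
            lq.rasterize(layout_i, spacing=(0.0, 1.0, 1.0),
                         grid_shape=(64, 64, 8))

    def test_untextured_rasterization_seed_independent(self):
        layout = lq.build_layout("i")
        kwargs = dict(spacing=(2.04, 2.04, 3.0), grid_shape=(128, 112, 48))
        v1, _ = lq.rasterize(layout, texture_seed=1, **kwargs)
        v2, _ = lq.rasterize(layout, texture_seed=2, **kwargs)
        untextured = np.ones(v1.shape, dtype=bool)
        _, lab = lq.rasterize(layout, texture_seed=1, **kwargs)
        for name in ("lung_sample_A", "lung_foam"):
            untextured &= ~lab.mask(name)
        assert (v1.voxels[untextured] == v2.voxels[untextured]).all()

    def test_textured_material_has_stated_sd(self, coarse_truth_i):
        truth, labels = coarse_truth_i
        vals = truth.voxels[labels.mask("lung_sample_A")]
        assert vals.mean() == pytest.approx(-655.6, abs=1e-9)
        assert vals.std() == pytest.approx(130.0, rel=1e-9)


class TestSimulateScan:
    def test_identity_without_psf_and_noise(self, coarse_truth_i):
        truth, _ = coarse_truth_i
        acq = lq.AcquisitionModel(psf_sigma_inplane=0.0, psf_sigma_z=0.0,
                                  noise_sd_at_reference=0.0)
        out = lq.simulate_scan(truth, acq)
        assert np.array_equal(out.voxels, truth.voxels)

    def test_quarter_dose_doubles_noise_sd(self):
        truth = lq.VoxelVolume(np.zeros((64, 64, 32)), spacing=(1, 1, 1))
        base = lq.AcquisitionModel(ctdi_vol=2.22, reference_ctdi=2.22,
                                   noise_sd_at_reference=15.4,
                                   psf_sigma_inplane=0, psf_sigma_z=0, seed=3)
        quarter = lq.AcquisitionModel(ctdi_vol=2.22 / 4, reference_ctdi=2.22,
                                      noise_sd_at_reference=15.4,
                                      psf_sigma_inplane=0, psf_sigma_z=0, seed=3)
        sd = lq.simulate_scan(truth, quarter).voxels.std()
        assert truth.voxels.size >= 1e5
        assert sd == pytest.approx(2 * 15.4, rel=0.05)
        assert sd > lq.simulate_scan(truth, base).voxels.std()

    def test_noise_sd_scales_as_inverse_sqrt_dose(self):
        """log SD vs log CTDIvol regression slope is -0.5 over a 16x range."""
        truth = lq.VoxelVolume(np.zeros((64, 64, 32)), spacing=(1, 1, 1))
        doses = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        sds = []
        for i, d in enumerate(doses):
            acq = lq.AcquisitionModel(ctdi_vol=d, reference_ctdi=4.0,
                                      noise_sd_at_reference=15.0,
                                      psf_sigma_inplane=0, psf_sigma_z=0,
                                      seed=100 + i)
            sds.append(lq.simulate_scan(truth, acq).voxels.std())
        slope = np.polyfit(np.log(doses), np.log(sds), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.05)

    def test_deterministic_given_seed(self, coarse_truth_i):
        truth, _ = coarse_truth_i
        a = lq.simulate_scan(truth, lq.AcquisitionModel(seed=9))
        b = lq.simulate_scan(truth, lq.AcquisitionModel(seed=9))
        assert np.array_equal(a.voxels, b.voxels)

    def test_blur_preserves_uniform_region_mean(self, coarse_truth_i):
        truth, labels = coarse_truth_i
        acq = lq.AcquisitionModel(noise_sd_at_reference=0.0)
        out = lq.simulate_scan(truth, acq)
        from scipy import ndimage
        core = ndimage.binary_erosion(labels.mask("air"), iterations=4)
        assert out.voxels[core].mean() == pytest.approx(
            truth.voxels[core].mean(), abs=0.1)

    def test_nonfinite_input_rejected(self):
        arr = np.zeros((4, 4, 4))
        vol = lq.VoxelVolume(arr, spacing=(1, 1, 1))
        vol.voxels[0, 0, 0] = np.inf  # bypass constructor validation
        with pytest.raises(ValueError):
            lq.simulate_scan(vol, lq.AcquisitionModel())

    def test_invalid_acquisition_rejected(self):
        with pytest.raises(ValueError):
            lq.AcquisitionModel(ctdi_vol=0.0)
        with pytest.raises(ValueError):
            lq.AcquisitionModel(psf_sigma_inplane=-1.0)


class TestAnalyticCube:
    def test_zero_sigma_matches_point_in_shape(self):
        vol = lq.analytic_cube_volume((40, 40, 40), (1.0, 1.0, 1.0),
                                      (0.3, -0.2, 0.1), sigma=0.0)
        xs, ys, zs = vol.world_axes()
        from lungqct.synthetic_phantom import InsertSpec, MATERIALS
        ins = InsertSpec("cube", MATERIALS["hdpe"], "cube", (0.3, -0.2, 0.1),
                         10.0, tilt_deg=(3.0, 3.0))
        mask = _insert_mask(ins, xs, ys, zs)
        assert np.array_equal(vol.voxels == MATERIALS["hdpe"].nominal_hu, mask)

    def test_anisotropic_requires_no_tilt(self):
        with pytest.raises(ValueError, match="untilted"):
            lq.analytic_cube_volume((10, 10, 10), (1, 1, 1), (0, 0, 0),
                                    sigma=(0.3, 0.3, 0.8), tilt_deg=(3, 3))
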