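import numpy as np
import pytest

from doctk import contrast as C
from doctk.phantom import (
    build_kidney_phantom,
    ground_truth_maps,
    rasterize_tube,
    simulate_frame_stack,
)

from conftest import make_uniform_phantom


class TestPresets:
    def test_normal_has_tubes_and_no_shell(self, normal_phantom):
        masks = normal_phantom.structure_masks
        assert masks["tubule_wall"].sum() > 0
        assert masks["superficial_shell"].sum() == 0
        assert normal_phantom.validate() == []

    def test_obstructed_2w_has_shell_and_no_tubes(self, obstructed_2w_phantom):
        ph = obstructed_2w_phantom
        masks = ph.structure_masks
        assert masks["tubule_wall"].sum() == 0
        shell = masks["superficial_shell"]
        assert shell.sum() > 0
        # shell voxels lie within 60 um of the local surface
        zz = np.arange(ph.grid_shape[0])[:, None, None]
        depth_um = (zz - ph.surface_height[None, :, :]) * ph.pixel_pitch_um[0]
        assert np.all(depth_um[shell] >= 0)
        assert np.all(depth_um[shell] < 60.0)
        assert ph.validate() == []

    def test_obstructed_1w_keeps_small_residual_segments(self):
        ph = build_kidney_phantom("obstructed_1w", seed=7)
        normal = build_kidney_phantom("normal", seed=7)
        n_res = ph.structure_masks["tubule_wall"].sum()
        assert 0 < n_res < 0.5 * normal.structure_masks["tubule_wall"].sum()
        assert ph.structure_masks["superficial_shell"].sum() > 0

    def test_unknown_preset_lists_valid_ones(self):
        with pytest.raises(ValueError, match="normal.*obstructed_1w.*obstructed_2w"):
            build_kidney_phantom("sick", seed=0)

    def test_tube_mask_diameter_matches_spec(self):
        # straight tube: wall-to-wall extent must equal the nominal diameter
        # to within one pixel of the lateral pitch
        shape, pitch = (64, 128, 16), (7.24, 3000.0 / 512, 3000.0 / 128)
        line = np.array([[30 * 7.24, 64 * pitch[1], 1 * pitch[2]],
                         [30 * 7.24, 64 * pitch[1], 14 * pitch[2]]])
        wall, lumen = rasterize_tube(line, shape, pitch, 40.0, 22.0)
        xs = np.where((wall | lumen).any(axis=(0, 2)))[0]
        extent_um = (xs.max() - xs.min() + 1) * pitch[1]
        assert abs(extent_um - 40.0) <= pitch[1]
        # lumen is hollow and strictly inside the wall
        assert lumen.sum() > 0
        assert not np.any(wall & lumen)

    def test_tubes_lie_in_superficial_slab(self, normal_phantom):
        ph = normal_phantom
        tube = ph.structure_masks["tubule_wall"] | ph.structure_masks["tubule_lumen"]
        zz = np.arange(ph.grid_shape[0])[:, None, None]
        depth_um = (zz - ph.surface_height[None, :, :]) * ph.pixel_pitch_um[0]
        assert np.all(depth_um[tube] >= 0)
        assert np.all(depth_um[tube] <= 724.0)

    def test_ground_truth_export_is_lossless(self, normal_phantom):
        truth = ground_truth_maps(normal_phantom)
        assert np.array_equal(truth["tau"], normal_phantom.tau_map)
        for name, mask in normal_phantom.structure_masks.items():
            assert np.array_equal(truth[f"mask_{name}"], mask)
            assert truth[f"mask_{name}"].sum() == normal_phantom.meta["mask_voxels"][name]
        # mutating the export must not touch the phantom
        truth["tau"][...] = -1
        assert np.all(normal_phantom.tau_map > 0)


class TestSignalModel:
    def test_frozen_field_when_fully_static(self):
        ph = make_uniform_phantom(tau=1e9, static_fraction=1.0, snr_db=300)
        st = simulate_frame_stack(ph, 0, np.arange(8) * 0.4096)
        assert np.allclose(st.frames, st.frames[0], atol=1e-10)

    def test_lag1_autocorrelation_matches_ar1_theory(self):
        # tau = 0.1 s, dt = 0.4096 s, f = 0, no noise: |rho_1| = exp(-dt/tau)
        tau, dt = 0.1, 0.4096
        ph = make_uniform_phantom(tau=tau, snr_db=300, shape=(64, 256, 1))
        st = simulate_frame_stack(ph, 0, np.arange(16) * dt)
        a = st.frames
        num = np.sum(np.conj(a[:-1]) * a[1:])
        den = np.sqrt(np.sum(np.abs(a[:-1]) ** 2) * np.sum(np.abs(a[1:]) ** 2))
        rho = abs(num) / den
        n_samples = a[:-1].size
        se = 3.0 / np.sqrt(n_samples)  # 3 Monte-Carlo standard errors
        assert rho == pytest.approx(np.exp(-dt / tau), abs=se)

    def test_noise_only_voxels_carry_sigma2(self):
        ph = make_uniform_phantom(tau=0.1, backscatter=0.0)
        ph.noise_variance = 1.3
        st = simulate_frame_stack(ph, 0, np.arange(4) * 0.0128)
        assert np.mean(np.abs(st.frames) ** 2) == pytest.approx(1.3, rel=0.05)

    def test_stationary_mean_intensity(self):
        # time-averaged intensity converges to I + sigma_n^2
        ph = make_uniform_phantom(tau=0.05, static_fraction=0.3, snr_db=10,
                                  shape=(32, 64, 1))
        st = simulate_frame_stack(ph, 0, np.arange(256) * 0.0128)
        mean_i = np.mean(np.abs(st.frames) ** 2)
        assert mean_i == pytest.approx(1.0 + ph.noise_variance, rel=0.05)

    def test_reproducibility_bit_identical(self, normal_phantom):
        ts = np.arange(4) * 0.0128
        a = simulate_frame_stack(normal_phantom, 3, ts)
        b = simulate_frame_stack(normal_phantom, 3, ts)
        assert np.array_equal(a.frames, b.frames)

    def test_locations_draw_independent_streams(self, normal_phantom):
        ts = np.arange(4) * 0.0128
        a = simulate_frame_stack(normal_phantom, 3, ts)
        b = simulate_frame_stack(normal_phantom, 4, ts)
        assert not np.array_equal(a.frames, b.frames)

    def test_non_increasing_timestamps_rejected(self, normal_phantom):
        with pytest.raises(ValueError):
            simulate_frame_stack(normal_phantom, 0, np.array([0.0, 0.0, 0.1]))

    def test_dynamics_ordering_wall_liv_above_parenchyma(self):
        # the mechanism behind the tubule phenotype, on fresh realizations
        for seed in (11, 12, 13):
            ph = build_kidney_phantom("normal", seed=seed)
            wall_vals, par_vals = [], []
            for y in range(0, ph.grid_shape[2], 4):
                st = simulate_frame_stack(ph, y, np.arange(16) * 0.4096)
                lv = C.liv(C.to_db_intensity(st.frames)).values
                wall_vals.append(lv[ph.structure_masks["tubule_wall"][:, :, y]])
                par_vals.append(lv[ph.structure_masks["parenchyma"][:, :, y]])
            assert np.concatenate(wall_vals).mean() > np.concatenate(par_vals).mean()
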