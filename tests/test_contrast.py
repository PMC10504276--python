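import numpy as np
import pytest

from doctk import contrast as C
from doctk.phantom import simulate_frame_stack

from conftest import make_uniform_phantom


def brute_force_liv(db_frames):
    """Independent two-pass population-variance oracle (explicit loops)."""
    n, nz, nx = db_frames.shape
    out = np.zeros((nz, nx))
    for i in range(nz):
        for j in range(nx):
            m = sum(db_frames[k, i, j] for k in range(n)) / n
            out[i, j] = sum((db_frames[k, i, j] - m) ** 2 for k in range(n)) / n
    return out


class TestDbIntensity:
    @pytest.mark.parametrize(
        "amplitude,expected_db",
        [(1.0, 0.0), (10.0, 20.0)],
    )
    def test_known_intensities(self, amplitude, expected_db):
        assert C.to_db_intensity(np.array(amplitude + 0j)) == pytest.approx(
            expected_db, abs=1e-9
        )

    def test_zero_amplitude_floored_by_eps(self):
        assert C.to_db_intensity(np.array(0j), eps=1e-12) == pytest.approx(-120.0)


class TestLiv:
    def test_matches_brute_force_oracle(self, rng):
        db = rng.normal(5.0, 3.0, size=(7, 12, 9))
        assert np.allclose(C.liv(db).values, brute_force_liv(db), atol=1e-10)

    def test_constant_frames_give_zero(self):
        db = np.full((16, 8, 8), 37.2)
        assert np.all(C.liv(db).values == 0)

    def test_two_frame_example(self):
        db = np.zeros((2, 1, 1))
        db[0], db[1] = 10.0, 20.0
        # mean 15, ((5)^2 + (5)^2)/2 = 25
        assert C.liv(db).values[0, 0] == pytest.approx(25.0)

    def test_shift_invariance(self, rng):
        db = rng.normal(0, 2, size=(8, 16, 16))
        assert np.allclose(C.liv(db).values, C.liv(db + 13.7).values, atol=1e-9)

    def test_frame_order_invariance(self, rng):
        db = rng.normal(0, 2, size=(8, 16, 16))
        perm = rng.permutation(8)
        assert np.allclose(C.liv(db).values, C.liv(db[perm]).values, atol=1e-10)

    def test_expectation_for_iid_gaussian(self, rng):
        # E[population variance] = sigma^2 (N-1)/N at N = 16
        sigma2, n = 4.0, 16
        db = rng.normal(0.0, np.sqrt(sigma2), size=(n, 400, 300))
        vals = C.liv(db).values
        expected = sigma2 * (n - 1) / n
        se = vals.std() / np.sqrt(vals.size)
        assert vals.mean() == pytest.approx(expected, abs=3 * se)

    def test_rejects_single_frame_and_nonfinite(self):
        with pytest.raises(ValueError):
            C.liv(np.zeros((1, 4, 4)))
        bad = np.zeros((3, 4, 4))
        bad[1, 2, 2] = np.nan
        with pytest.raises(ValueError):
            C.liv(bad)


class TestBulkPhaseCorrection:
    def test_global_phase_offsets_removed(self, rng):
        base = (rng.standard_normal((6, 32, 32)) * 0 + 1) * (
            rng.standard_normal((1, 32, 32)) + 1j * rng.standard_normal((1, 32, 32))
        )
        phases = rng.uniform(-np.pi, np.pi, 6)
        frames = base * np.exp(1j * phases)[:, None, None]
        corrected, _, skipped = C.bulk_phase_correct(frames)
        assert not skipped.any()
        assert np.allclose(corrected, corrected[0], atol=1e-9)

    def test_aligned_frames_unchanged(self, rng):
        frames = np.repeat(
            (rng.standard_normal((1, 16, 16)) + 1j * rng.standard_normal((1, 16, 16))),
            4,
            axis=0,
        )
        corrected, phases, _ = C.bulk_phase_correct(frames)
        assert np.allclose(corrected, frames, atol=1e-12)
        assert np.allclose(phases, 0.0, atol=1e-12)

    def test_static_speckle_recorrelates_above_0p999(self, rng):
        field = rng.standard_normal((48, 64)) + 1j * rng.standard_normal((48, 64))
        phases = rng.uniform(-np.pi, np.pi, 4)
        frames = field[None] * np.exp(1j * phases)[:, None, None]
        corrected, _, _ = C.bulk_phase_correct(frames)
        for i in range(3):
            num = abs(np.sum(np.conj(corrected[i]) * corrected[i + 1]))
            den = np.sqrt(
                np.sum(np.abs(corrected[i]) ** 2) * np.sum(np.abs(corrected[i + 1]) ** 2)
            )
            assert num / den >= 0.999

    def test_all_zero_frame_skipped_and_flagged(self):
        frames = np.ones((3, 8, 8), dtype=complex)
        frames[1] = 0
        _, _, skipped = C.bulk_phase_correct(frames)
        assert skipped.any()


class TestFastDoct:
    def test_identical_noiseless_frames_give_zero(self, rng):
        frame = rng.standard_normal((32, 32)) + 1j * rng.standard_normal((32, 32))
        frames = np.repeat(frame[None], 4, axis=0)
        fd = C.fast_doct(frames, noise_variance=0.0)
        assert np.allclose(fd.values, 0.0, atol=1e-9)
        assert fd.valid.all()

    def test_independent_frames_hit_coherence_floor(self, rng):
        # the kernel map of independent data sits at 1 - sqrt(pi/4M), not at 1:
        # a finite-sample magnitude bias that vanishes in the pooled estimate
        frames = (
            rng.standard_normal((4, 120, 200)) + 1j * rng.standard_normal((4, 120, 200))
        ) / np.sqrt(2)
        fd = C.fast_doct(frames, noise_variance=0.0)
        m = 9 * 3
        expected = 1.0 - C.coherence_floor(m)
        assert fd.values.mean() == pytest.approx(expected, abs=0.01)
        # growing the kernel pushes the map toward full decorrelation
        fd_big = C.fast_doct(frames, noise_variance=0.0, kernel=(9, 9))
        assert fd_big.values.mean() > fd.values.mean()
        # pooled over the whole region the decorrelation exceeds 0.9
        assert C.pooled_decorrelation(frames, 0.0) > 0.9

    def test_values_in_unit_interval(self, rng):
        frames = rng.standard_normal((4, 40, 40)) + 1j * rng.standard_normal((4, 40, 40))
        fd = C.fast_doct(frames, noise_variance=0.5)
        assert np.all(fd.values >= 0) and np.all(fd.values <= 1)

    def test_frame_order_matters(self, rng):
        ph = make_uniform_phantom(tau=0.02, shape=(32, 64, 1), seed=5)
        st = simulate_frame_stack(ph, 0, np.arange(4) * 0.0128)
        fd_fwd = C.fast_doct(st.frames, ph.noise_variance)
        fd_rev = C.fast_doct(st.frames[[0, 2, 1, 3]], ph.noise_variance)
        assert not np.allclose(fd_fwd.values, fd_rev.values)

    def test_kernel_larger_than_frame_rejected(self, rng):
        frames = rng.standard_normal((4, 8, 8)) + 0j
        with pytest.raises(ValueError):
            C.fast_doct(frames, 0.0, kernel=(9, 9))

    @pytest.mark.parametrize("tau_ms", [5, 20, 100])
    def test_pooled_decorrelation_matches_ar1_theory(self, tau_ms):
        tau = tau_ms / 1000.0
        ph = make_uniform_phantom(tau=tau, snr_db=30, shape=(64, 256, 1), seed=2)
        ts = np.arange(4) * 0.0128
        st = simulate_frame_stack(ph, 0, ts)
        d = C.pooled_decorrelation(st.frames, ph.noise_variance)
        assert d == pytest.approx(1.0 - np.exp(-0.0128 / tau), abs=0.02)

    def test_monotone_in_tau(self):
        means = []
        for tau in (0.2, 0.05, 0.01):
            ph = make_uniform_phantom(tau=tau, shape=(48, 96, 1), seed=9)
            st = simulate_frame_stack(ph, 0, np.arange(4) * 0.0128)
            means.append(C.fast_doct(st.frames, ph.noise_variance).values.mean())
        assert means[0] < means[1] < means[2]

    def test_scale_separation_slow_dynamics(self):
        # tau = 1.5 s: invisible to the millisecond contrast, fully resolved
        # by LIV over the 6.14 s window
        ph = make_uniform_phantom(
            tau=1.5, static_fraction=0.1, snr_db=20, shape=(48, 128, 1), seed=4
        )
        st_fast = simulate_frame_stack(ph, 0, np.arange(4) * 0.0128)
        fd = C.fast_doct(st_fast.frames, ph.noise_variance)
        assert fd.values[fd.valid].mean() < 0.1
        st_slow = simulate_frame_stack(ph, 0, np.arange(16) * 0.4096)
        lv = C.liv(C.to_db_intensity(st_slow.frames)).values
        ph_par = make_uniform_phantom(
            tau=30.0, static_fraction=0.98, snr_db=20, shape=(48, 128, 1), seed=4
        )
        st_par = simulate_frame_stack(ph_par, 0, np.arange(16) * 0.4096)
        lv_par = C.liv(C.to_db_intensity(st_par.frames)).values
        assert lv.mean() >= 3 * lv_par.mean()


class TestNoiseHandling:
    def test_noise_only_flagged_invalid_with_true_sigma(self, rng):
        noise = (
            rng.standard_normal((4, 100, 120)) + 1j * rng.standard_normal((4, 100, 120))
        ) / np.sqrt(2)
        fd = C.fast_doct(noise, noise_variance=1.0)
        assert (~fd.valid).mean() >= 0.9

    def test_noise_without_correction_reads_highly_decorrelated(self, rng):
        noise = (
            rng.standard_normal((4, 100, 120)) + 1j * rng.standard_normal((4, 100, 120))
        ) / np.sqrt(2)
        fd = C.fast_doct(noise, noise_variance=0.0)
        assert fd.valid.all()
        assert C.pooled_decorrelation(noise, 0.0) > 0.9
        assert fd.values.mean() > 0.8  # kernel map, bounded by the M=27 floor

    def test_estimate_noise_variance_from_air(self):
        ph = make_uniform_phantom(tau=0.1, backscatter=0.0, seed=6, shape=(64, 200, 1))
        ph.noise_variance = 1.0
        st = simulate_frame_stack(ph, 0, np.arange(4) * 0.0128)
        air = np.ones((64, 200), dtype=bool)
        est = C.estimate_noise_variance(st.frames, air)
        assert est == pytest.approx(1.0, rel=0.03)

    def test_zero_noise_simulation_estimates_zero(self):
        ph = make_uniform_phantom(tau=0.1, backscatter=0.0)
        ph.noise_variance = 0.0
        st_frames = np.zeros((4, 8, 8), dtype=complex)
        st_frames += 1e-30  # keep stack constructor happy about finiteness
        est = C.estimate_noise_variance(st_frames, np.ones((8, 8), bool))
        assert est == pytest.approx(0.0, abs=1e-12)

    def test_tissue_mask_biases_estimate_high(self):
        ph = make_uniform_phantom(tau=0.1, snr_db=20, seed=8, shape=(32, 128, 1))
        st = simulate_frame_stack(ph, 0, np.arange(4) * 0.0128)
        est = C.estimate_noise_variance(st.frames, np.ones((32, 128), bool))
        assert est > 5 * ph.noise_variance  # detectable against a config bound

    def test_empty_mask_rejected(self, rng):
        frames = rng.standard_normal((4, 8, 8)) + 0j
        with pytest.raises(ValueError, match="config"):
            C.estimate_noise_variance(frames, np.zeros((8, 8), bool))


class TestTauEstimation:
    @pytest.mark.parametrize("tau_ms", [5, 20, 100])
    def test_region_estimate_recovers_tau(self, tau_ms):
        tau = tau_ms / 1000.0
        ph = make_uniform_phantom(tau=tau, snr_db=30, shape=(64, 256, 1), seed=3)
        ts = np.arange(4) * 0.0128
        st = simulate_frame_stack(ph, 0, ts)
        est = C.estimate_tau(st.frames, ts, ph.noise_variance)
        assert est == pytest.approx(tau, rel=0.2)

    def test_tau_map_median_recovers_tau(self):
        tau = 0.05
        ph = make_uniform_phantom(tau=tau, snr_db=30, shape=(64, 128, 1), seed=4)
        ts = np.arange(4) * 0.0128
        st = simulate_frame_stack(ph, 0, ts)
        tau_map = C.estimate_tau_map(st.frames, ts, ph.noise_variance)
        assert np.nanmedian(tau_map) == pytest.approx(tau, rel=0.2)


class TestVolumeAssembly:
    def test_assembles_in_index_order_regardless_of_input_order(self, rng):
        imgs = {i: rng.normal(size=(6, 5)) for i in range(4)}
        shuffled = [(i, imgs[i]) for i in (2, 0, 3, 1)]
        v1 = C.volume_assemble(imgs, (7.24, 5.86, 23.4), "LIV")
        v2 = C.volume_assemble(shuffled, (7.24, 5.86, 23.4), "LIV")
        assert np.array_equal(v1.data, v2.data)
        assert v1.data.shape == (6, 5, 4)

    def test_single_location_gives_depth_one_volume(self, rng):
        v = C.volume_assemble({0: rng.normal(size=(6, 5))}, (7.24, 5.86, 23.4), "dB")
        assert v.data.shape == (6, 5, 1)

    def test_missing_location_rejected(self, rng):
        with pytest.raises(ValueError, match="missing"):
            C.volume_assemble({0: np.zeros((4, 4)), 2: np.zeros((4, 4))},
                              (7.24, 5.86, 23.4), "LIV")
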