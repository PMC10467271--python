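import numpy as np
import pytest

import fnirsnet as fn
from fnirsnet.preprocess import (
    bandpass,
    correct_motion_artifacts,
    detect_motion_artifacts,
    hemo_to_od,
    intensity_to_od,
    load_extinction_table,
    od_to_hemo,
    od_to_intensity,
    run_preprocessing,
)
from fnirsnet.recording import OpticalRecording

from _oracles import artifact_window_oracle


def make_intensity(data):
    return OpticalRecording(data, "intensity", fs_hz=11.0, wavelengths_nm=(730.0, 808.0, 850.0))


def make_od(data):
    return OpticalRecording(data, "od", fs_hz=11.0, wavelengths_nm=(730.0, 808.0, 850.0))


class TestOpticalDensity:
    def test_constant_intensity_gives_zero_od(self):
        rec = make_intensity(np.full((2, 3, 100), 1.7))
        od = intensity_to_od(rec)
        assert np.allclose(od.data, 0.0)

    def test_tenfold_drop_gives_od_one(self):
        data = np.ones((1, 3, 1000))
        data[0, :, 500] = 0.1
        rec = make_intensity(data)
        od = intensity_to_od(rec)
        i0 = data.mean(axis=-1)  # ~0.9991
        expected = -np.log10(0.1 / i0[0, 0])
        assert od.data[0, 0, 500] == pytest.approx(expected, rel=1e-12)

    def test_round_trip_with_inverse_oracle(self, rng):
        data = np.exp(rng.normal(0, 0.1, size=(3, 3, 200)))
        rec = make_intensity(data)
        od = intensity_to_od(rec)
        i0 = data.mean(axis=-1, keepdims=True)
        back = od_to_intensity(od, i0=i0)
        assert np.allclose(back, data, atol=1e-12)

    def test_nonpositive_intensity_names_channel(self):
        data = np.ones((3, 3, 50))
        data[1, 0, 10] = 0.0
        with pytest.raises(ValueError, match="channel 2"):
            make_intensity(data)


class TestArtifactDetection:
    def test_smooth_sinusoid_not_flagged(self):
        t = np.arange(2000) / 11.0
        data = np.sin(2 * np.pi * 0.05 * t)[None, None, :] * np.ones((2, 3, 1))
        mask = detect_motion_artifacts(make_od(data))
        assert not mask.flags.any()

    def test_injected_step_flags_exactly_that_window(self, rng):
        n_t = 2200
        data = rng.normal(0, 1.0, size=(1, 3, n_t))
        sd = data.std(axis=-1)
        # a 10x-SD step inside window 100 (samples 500..505 of a 5-sample window)
        win = round(0.5 * 11)
        w_target = 100
        data[0, :, w_target * win + 2] += 10 * sd[0]
        mask = detect_motion_artifacts(make_od(data))
        assert mask.flags[0, w_target]
        # by-hand check of the flagged window's range criterion
        seg = data[0, 0, w_target * win : (w_target + 1) * win]
        assert seg.max() - seg.min() > 6 * data[0, 0].std()

    def test_flag_decisions_match_brute_force_oracle(self, rng):
        for _ in range(100):
            data = rng.normal(0, 1, size=(2, 2, int(rng.integers(40, 300))))
            if rng.random() < 0.5:  # occasionally inject a big excursion
                ch = int(rng.integers(0, 2))
                i = int(rng.integers(0, data.shape[-1]))
                data[ch, :, i] += rng.choice([-12, 12])
            rec = OpticalRecording(data, "od", fs_hz=11.0, wavelengths_nm=(730.0, 808.0))
            mask = detect_motion_artifacts(rec)
            expected = artifact_window_oracle(data, 11.0, 0.5, 6.0)
            assert np.array_equal(mask.flags, expected)

    def test_zero_variance_channel_warns_without_flags(self):
        data = np.zeros((1, 3, 110))
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            mask = detect_motion_artifacts(make_od(data))
        assert not mask.flags.any()

    def test_window_too_small_raises(self):
        rec = make_od(np.zeros((1, 3, 110)))
        with pytest.raises(ValueError):
            detect_motion_artifacts(rec, window_s=0.05)


class TestArtifactCorrection:
    def test_empty_mask_is_noop(self, rng):
        data = rng.normal(size=(2, 3, 220))
        rec = make_od(data)
        mask = detect_motion_artifacts(rec)
        assert not mask.flags.any()
        out = correct_motion_artifacts(rec, mask)
        assert np.array_equal(out.data, rec.data)

    def test_spike_on_cubic_polynomial_recovered(self):
        # spline interpolation through clean samples restores a cubic exactly
        # up to a small residual: RMSE < 5% of the spike amplitude
        t = np.linspace(0, 1, 550)
        clean = 2 * t**3 - t**2 + 0.5 * t
        spike_amp = 50 * clean.std()
        data = np.tile(clean, (1, 3, 1)).astype(float)
        corrupted = data.copy()
        corrupted[0, :, 300:305] += spike_amp
        rec = make_od(corrupted)
        mask = detect_motion_artifacts(rec)
        assert mask.flags.any()
        out = correct_motion_artifacts(rec, mask)
        rmse = np.sqrt(np.mean((out.data[0, 0] - clean) ** 2))
        assert rmse < 0.05 * spike_amp

    def test_unflagged_samples_untouched_bitwise(self, rng):
        data = rng.normal(size=(1, 3, 550))
        data[0, :, 220:224] += 15 * data[0, 0].std()
        rec = make_od(data)
        mask = detect_motion_artifacts(rec)
        out = correct_motion_artifacts(rec, mask)
        smask = mask.sample_mask(550)
        assert np.array_equal(out.data[:, :, ~smask[0]], rec.data[:, :, ~smask[0]])

    def test_no_jump_at_window_borders(self, rng):
        t = np.arange(1100) / 11.0
        clean = np.sin(2 * np.pi * 0.05 * t)
        data = np.tile(clean, (1, 1, 1))
        data[0, 0, 550:555] += 20 * clean.std()
        rec = OpticalRecording(data, "od", fs_hz=11.0, wavelengths_nm=(730.0,))
        mask = detect_motion_artifacts(rec)
        out = correct_motion_artifacts(rec, mask)
        inc = np.abs(np.diff(out.data[0, 0]))
        clean_inc = np.abs(np.diff(clean)).max()
        assert inc.max() <= 10 * clean_inc

    def test_fully_flagged_channel_raises(self, rng):
        from fnirsnet.preprocess import ArtifactMask

        data = rng.normal(size=(1, 1, 110))
        rec = OpticalRecording(data, "od", fs_hz=11.0, wavelengths_nm=(730.0,))
        win = round(0.5 * 11)
        mask = ArtifactMask(flags=np.ones((1, int(np.ceil(110 / win))), dtype=bool),
                            window_samples=win)
        with pytest.raises(ValueError, match="entirely flagged"):
            correct_motion_artifacts(rec, mask)

    def test_edge_window_extrapolates_with_warning(self, rng):
        data = rng.normal(0, 0.01, size=(1, 1, 550))
        data[0, 0, :4] += 5.0  # artifact at the very start
        rec = OpticalRecording(data, "od", fs_hz=11.0, wavelengths_nm=(730.0,))
        mask = detect_motion_artifacts(rec)
        assert mask.flags[0, 0]
        out = correct_motion_artifacts(rec, mask)
        assert np.all(np.isfinite(out.data))

    def test_idempotent_on_clean_data(self):
        # correcting twice, with a mask recomputed in between, changes
        # nothing further on artifact-free data
        t = np.arange(550) / 11.0
        clean = np.sin(2 * np.pi * 0.07 * t) + 0.1 * np.cos(2 * np.pi * 0.02 * t)
        data = np.tile(clean, (2, 3, 1))
        rec = make_od(data)
        out1 = correct_motion_artifacts(rec, detect_motion_artifacts(rec))
        out2 = correct_motion_artifacts(out1, detect_motion_artifacts(out1))
        assert np.array_equal(out1.data, rec.data)
        assert np.array_equal(out2.data, out1.data)


class TestBandpass:
    def make_hbo(self, x):
        return OpticalRecording(x[None, :], "hbo", fs_hz=11.0, wavelengths_nm=None)

    def test_dc_removed(self):
        rec = self.make_hbo(np.full(4000, 3.0))
        out = bandpass(rec)
        assert abs(out.data.mean()) < 1e-6 * 3.0

    def test_passband_sinusoid_preserved(self):
        t = np.arange(6000) / 11.0
        x = np.sin(2 * np.pi * 0.05 * t)
        out = bandpass(self.make_hbo(x))
        # FFT amplitude ratio at 0.05 Hz
        f = np.fft.rfftfreq(len(t), 1 / 11.0)
        k = np.argmin(np.abs(f - 0.05))
        ratio = np.abs(np.fft.rfft(out.data[0])[k]) / np.abs(np.fft.rfft(x)[k])
        assert 0.9 <= ratio <= 1.1

    def test_cardiac_band_attenuated(self):
        t = np.arange(6000) / 11.0
        x = np.sin(2 * np.pi * 1.2 * t)
        out = bandpass(self.make_hbo(x))
        f = np.fft.rfftfreq(len(t), 1 / 11.0)
        k = np.argmin(np.abs(f - 1.2))
        ratio = np.abs(np.fft.rfft(out.data[0])[k]) / np.abs(np.fft.rfft(x)[k])
        assert ratio < 0.1  # >= 20 dB

    def test_too_short_recording_raises(self):
        rec = self.make_hbo(np.ones(30))
        with pytest.raises(ValueError, match="too short"):
            bandpass(rec)

    def test_invalid_band_raises(self):
        rec = self.make_hbo(np.ones(4000))
        with pytest.raises(ValueError):
            bandpass(rec, 0.2, 0.01)


class TestBeerLambert:
    def test_zero_od_gives_zero_concentrations(self):
        rec = make_od(np.zeros((2, 3, 50)))
        hbo, hbr = od_to_hemo(rec, return_hbr=True)
        assert np.allclose(hbo.data, 0) and np.allclose(hbr, 0)

    def test_forward_inverse_round_trip(self, rng):
        hbo = rng.normal(0, 0.5, size=(4, 300))
        hbr = rng.normal(0, 0.2, size=(4, 300))
        od = hemo_to_od(hbo, hbr, (730.0, 808.0, 850.0))
        rec = make_od(od)
        hbo2, hbr2 = od_to_hemo(rec, return_hbr=True)
        assert np.allclose(hbo2.data, hbo, rtol=1e-9, atol=1e-12)
        assert np.allclose(hbr2, hbr, rtol=1e-9, atol=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        od = rng.normal(size=(2, 3, 40))
        rec = make_od(od)
        hbo, hbr = od_to_hemo(rec, return_hbr=True)
        from fnirsnet.preprocess import _extinction_design

        E = _extinction_design((730.0, 808.0, 850.0), 6.0, 3.0, load_extinction_table())
        for ch in range(2):
            for s in range(0, 40, 7):
                exp = np.linalg.lstsq(E, od[ch, :, s], rcond=None)[0]
                assert hbo.data[ch, s] == pytest.approx(exp[0], rel=1e-10)
                assert hbr[ch, s] == pytest.approx(exp[1], rel=1e-10)

    def test_duplicate_wavelengths_rejected(self):
        rec = OpticalRecording(np.zeros((1, 2, 50)), "od", fs_hz=11.0,
                               wavelengths_nm=(730.0, 730.0))
        with pytest.raises(ValueError, match="duplicate"):
            od_to_hemo(rec)


class TestPipeline:
    def test_stage_order_recorded_in_history(self, intensity_subject):
        out = run_preprocessing(intensity_subject.recording)
        assert out.history[-4:] == [
            "intensity_to_od",
            "correct_motion_artifacts",
            "bandpass[0.01,0.2]",
            "od_to_hemo",
        ]
        assert out.stage == "hbo"

    def test_end_to_end_recovery_on_artifact_free_subject(self, intensity_subject):
        out = run_preprocessing(intensity_subject.recording)
        gt = intensity_subject.ground_truth.hbo_clean
        for ch in range(out.n_channels):
            assert np.corrcoef(out.data[ch], gt[ch])[0, 1] >= 0.95
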