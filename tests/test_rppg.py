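"""Green-channel PPG extraction, filtering, HR estimation and the vitals model."""

import numpy as np
import pytest

from biosense import rppg, synthetic
from biosense.rppg import (
    FEATURE_NAMES,
    FaceROI,
    NoPulseError,
    PPGFeatures,
    PPGSignal,
    VideoClip,
    VitalsEstimate,
)


def make_clip(green: np.ndarray, h=8, w=10, fps=30.0) -> VideoClip:
    """Clip whose whole-frame green channel follows ``green`` per frame."""
    frames = np.zeros((len(green), h, w, 3), dtype=np.float32)
    frames[..., 1] = np.asarray(green, dtype=np.float32)[:, None, None]
    return VideoClip(frames=frames, fps=fps)


def sine_signal(f0=1.2, fs=30.0, dur=30.0, amp=1.0, dc=0.0):
    t = np.arange(int(dur * fs)) / fs
    return PPGSignal(samples=dc + amp * np.sin(2 * np.pi * f0 * t), rate=fs)


class TestExtractGreenSignal:
    def test_constant_green(self):
        sig = rppg.extract_green_signal(make_clip(np.full(20, 120.0)), FaceROI(0, 0, 10, 8))
        assert np.allclose(sig.samples, 120.0)
        assert sig.rate == 30.0

    def test_recovers_injected_sinusoid(self):
        t = np.arange(90) / 30.0
        wave = 100 + 10 * np.sin(2 * np.pi * 1.2 * t)
        sig = rppg.extract_green_signal(make_clip(wave), FaceROI(2, 2, 5, 4))
        r = np.corrcoef(sig.samples, wave)[0, 1]
        assert r > 0.99

    def test_spatial_mean_of_checkerboard(self):
        frames = np.zeros((5, 4, 4, 3), dtype=np.float32)
        frames[:, ::2, ::2, 1] = 200.0
        frames[:, 1::2, 1::2, 1] = 200.0
        clip = VideoClip(frames=frames, fps=30.0)
        sig = rppg.extract_green_signal(clip, FaceROI(0, 0, 4, 4))
        assert np.allclose(sig.samples, 100.0)

    def test_ignores_red_and_blue(self):
        frames = np.zeros((20, 4, 4, 3), dtype=np.float32)
        frames[..., 0] = np.linspace(0, 255, 20)[:, None, None]
        frames[..., 2] = 77.0
        frames[..., 1] = 50.0
        sig = rppg.extract_green_signal(VideoClip(frames=frames, fps=30), FaceROI(0, 0, 4, 4))
        assert np.allclose(sig.samples, 50.0)

    def test_roi_outside_frame_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            rppg.extract_green_signal(make_clip(np.zeros(10)), FaceROI(5, 5, 10, 8))

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="2 frames"):
            rppg.extract_green_signal(make_clip(np.zeros(1)), FaceROI(0, 0, 4, 4))


class TestPreprocess:
    def test_in_band_amplitude_preserved(self):
        out = rppg.preprocess(sine_signal(f0=1.5, amp=2.0))
        # steady-state amplitude away from filter edges
        core = out.samples[150:-150]
        assert np.ptp(core) / 2 == pytest.approx(2.0, rel=0.05)

    def test_dc_and_ramp_rejected(self):
        t = np.arange(900) / 30.0
        sig = PPGSignal(samples=100 + 3 * t, rate=30.0)
        out = rppg.preprocess(sig)
        assert np.sqrt(np.mean(out.samples**2)) < 0.01 * np.sqrt(np.mean(sig.samples**2))
        assert abs(out.samples.mean()) < 1e-6 * np.abs(sig.samples).max()

    def test_white_noise_variance_reduced(self):
        rng = np.random.default_rng(0)
        sig = PPGSignal(samples=rng.normal(size=900), rate=30.0)
        assert rppg.preprocess(sig).samples.var() < sig.samples.var()

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="band"):
            rppg.preprocess(sine_signal(), band=(0.7, 16.0))


class TestEstimateHeartRate:
    @pytest.mark.parametrize("f0, bpm", [(1.2, 72.0), (0.83, 49.8)])
    def test_sinusoid_with_noise(self, f0, bpm):
        rng = np.random.default_rng(1)
        sig = sine_signal(f0=f0, amp=1.0)
        noisy = PPGSignal(
            samples=sig.samples + rng.normal(0, 10 ** (-10 / 20) / np.sqrt(2), len(sig.samples)),
            rate=sig.rate,
        )
        est = rppg.estimate_heart_rate(rppg.preprocess(noisy, band=(0.7, 4.0)))
        assert est == pytest.approx(bpm, abs=1.0)

    def test_result_always_inside_band(self, pulse_clip):
        clip, truth = pulse_clip
        sig = rppg.preprocess(rppg.extract_green_signal(clip, FaceROI(*truth["face_box"])))
        bpm = rppg.estimate_heart_rate(sig)
        assert 0.7 * 60 <= bpm <= 4.0 * 60

    def test_no_pulse_in_white_noise_floor(self):
        rng = np.random.default_rng(2)
        sig = PPGSignal(samples=rng.normal(size=900), rate=30.0)
        with pytest.raises(NoPulseError):
            rppg.estimate_heart_rate(rppg.preprocess(sig), min_peak_snr=50.0)


class TestHeartRateTrack:
    def test_stationary_clip_constant_track(self, pulse_clip):
        clip, truth = pulse_clip
        sig = rppg.preprocess(rppg.extract_green_signal(clip, FaceROI(*truth["face_box"])))
        times, track = rppg.heart_rate_track(sig, window_s=15, step_s=5)
        assert np.all(np.abs(track - 72.0) <= 1.0)

    def test_step_change_transitions_between_plateaus(self):
        fs = 30.0
        t1 = np.arange(int(30 * fs)) / fs
        t2 = np.arange(int(30 * fs)) / fs
        wave = np.concatenate(
            [np.sin(2 * np.pi * 1.0 * t1), np.sin(2 * np.pi * 1.5 * t2)]
        )
        sig = rppg.preprocess(PPGSignal(samples=wave, rate=fs))
        _, track = rppg.heart_rate_track(sig, window_s=10, step_s=2)
        assert track[0] == pytest.approx(60, abs=2)
        assert track[-1] == pytest.approx(90, abs=2)
        assert np.all(track >= 55) and np.all(track <= 95)

    def test_non_overlapping_window_count(self):
        sig = rppg.preprocess(sine_signal(dur=45.0))
        times, track = rppg.heart_rate_track(sig, window_s=10, step_s=10)
        assert len(track) == 4  # floor(45/10)

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError, match="longer"):
            rppg.heart_rate_track(sine_signal(dur=12.0), window_s=15)


class TestFeatures:
    def test_pure_sinusoid_low_ibi_variability(self):
        feats = rppg.extract_features(rppg.preprocess(sine_signal(f0=1.2)))
        d = feats.as_dict()
        assert d["ibi_sd_s"] < 0.05 * d["ibi_mean_s"]
        assert d["dominant_freq_hz"] == pytest.approx(1.2, abs=0.05)

    def test_amplitude_scaling_homogeneity(self):
        a = rppg.extract_features(rppg.preprocess(sine_signal(amp=1.0)))
        b = rppg.extract_features(rppg.preprocess(sine_signal(amp=2.0)))
        da, db = a.as_dict(), b.as_dict()
        for key in ("dominant_freq_hz", "ibi_mean_s"):
            assert da[key] == pytest.approx(db[key], rel=1e-6)
        for key in ("amplitude_std", "amplitude_rms", "amplitude_p2p"):
            assert db[key] == pytest.approx(2 * da[key], rel=1e-3)

    def test_flat_signal_flagged_low_quality(self):
        feats = rppg.extract_features(PPGSignal(samples=np.zeros(900), rate=30.0))
        assert feats.low_quality
        assert np.allclose(feats.values, 0.0)

    def test_feature_length_constant_over_fuzzed_signals(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(400, 1200))
            sig = PPGSignal(samples=rng.normal(size=n), rate=30.0)
            feats = rppg.extract_features(rppg.preprocess(sig))
            assert feats.values.shape == (len(FEATURE_NAMES),)


def synthetic_training_set(n=200, noise=2.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, len(FEATURE_NAMES)))
    W = rng.normal(size=(3, len(FEATURE_NAMES)))
    b = np.array([75.0, 120.0, 80.0])
    Y = X @ W.T + b + rng.normal(0, noise, size=(n, 3))
    feats = [PPGFeatures(values=x) for x in X]
    targets = [VitalsEstimate(hr=y[0], sp=max(y[1], y[2] + 1), dp=min(y[2], y[1] - 1)) for y in Y]
    return feats, targets, W, b


class TestVitalsModel:
    def test_linear_map_recovered(self):
        feats, targets, W, b = synthetic_training_set(n=200, noise=2.0, seed=4)
        model = rppg.fit_vitals_model(feats, targets, alpha=1e-3)
        rel = np.abs(model.coef - W) / (np.abs(W) + 1e-9)
        # bulk of the coefficients recovered within 10% despite target clipping
        assert np.median(rel) < 0.10

    def test_zero_noise_near_perfect_fit(self):
        feats, targets, *_ = synthetic_training_set(n=100, noise=0.0, seed=5)
        model = rppg.fit_vitals_model(feats, targets, alpha=1e-6)
        preds = np.array(
            [[(p := rppg.predict_vitals(model, f)).hr, p.sp, p.dp] for f in feats]
        )
        truth = np.array([[t.hr, t.sp, t.dp] for t in targets])
        rmse = np.sqrt(np.mean((preds - truth) ** 2))
        assert rmse < 0.5

    def test_constant_targets_give_constant_model(self):
        rng = np.random.default_rng(6)
        feats = [PPGFeatures(values=rng.normal(size=len(FEATURE_NAMES))) for _ in range(12)]
        targets = [VitalsEstimate(hr=70.0, sp=120.0, dp=80.0)] * 12
        with pytest.warns(UserWarning, match="constant"):
            model = rppg.fit_vitals_model(feats, targets)
        est = rppg.predict_vitals(model, feats[0])
        assert est.hr == pytest.approx(70.0, abs=1.0)
        assert est.sp == pytest.approx(120.0, abs=1.0)
        assert est.dp == pytest.approx(80.0, abs=1.0)

    def test_prediction_always_sp_above_dp(self):
        feats, targets, *_ = synthetic_training_set(n=50, noise=5.0, seed=7)
        model = rppg.fit_vitals_model(feats, targets)
        rng = np.random.default_rng(8)
        for _ in range(20):
            est = rppg.predict_vitals(
                model, PPGFeatures(values=rng.normal(scale=3, size=len(FEATURE_NAMES)))
            )
            assert est.sp > est.dp > 0

    def test_too_few_examples_rejected(self):
        feats, targets, *_ = synthetic_training_set(n=5)
        with pytest.raises(ValueError, match=">= 10"):
            rppg.fit_vitals_model(feats, targets)

    def test_save_load_roundtrip(self, tmp_path):
        feats, targets, *_ = synthetic_training_set(n=50, seed=9)
        model = rppg.fit_vitals_model(feats, targets)
        path = tmp_path / "vitals.json"
        model.save(path)
        back = rppg.VitalsModel.load(path)
        est1 = rppg.predict_vitals(model, feats[0])
        est2 = rppg.predict_vitals(back, feats[0])
        assert (est1.hr, est1.sp, est1.dp) == pytest.approx(
            (est2.hr, est2.sp, est2.dp), rel=1e-12
        )
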