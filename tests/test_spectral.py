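import numpy as np
import pytest

from biovad.spectral import (
    SPECTRAL_FEATURE_NAMES,
    accgyro_feature_vector,
    framed_features,
    fullsegment_fft_features,
    highpass_voicing,
)

FS = 1000.0


class TestHighpassVoicing:
    def test_walking_band_removed(self):
        t = np.arange(0, 30, 1 / FS)
        x = np.sin(2 * np.pi * 2.0 * t)
        y = highpass_voicing(x, FS)
        assert np.sqrt(np.mean(y**2)) < 0.01 * np.sqrt(np.mean(x**2))

    def test_voiced_band_preserved(self):
        t = np.arange(0, 30, 1 / FS)
        x = np.sin(2 * np.pi * 200.0 * t)
        y = highpass_voicing(x, FS)
        mid = slice(1000, -1000)
        assert np.sqrt(np.mean(y[mid] ** 2)) == pytest.approx(
            np.sqrt(np.mean(x[mid] ** 2)), rel=0.02
        )

    def test_zero_in_zero_out(self):
        assert np.allclose(highpass_voicing(np.zeros(5000), FS), 0.0)

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            highpass_voicing(np.zeros(5000), 100.0, cutoff=75.0)


class TestFramedFeatures:
    def test_pure_tone(self):
        # frame-aligned tone (integer cycles per 2048-sample frame) so the
        # rectangular-frame spectrum is leakage-free
        tone = 205 * FS / 2048  # ~100.1 Hz
        t = np.arange(30000) / FS
        x = np.sin(2 * np.pi * tone * t)
        f = framed_features(x, FS)
        bin_hz = FS / 2048
        assert abs(f["centroid"] - tone) < bin_hz
        assert f["bandwidth"] < bin_hz
        assert f["zcr"] == pytest.approx(2 * tone / FS, abs=0.01)
        assert f["flatness"] < 0.05

    def test_noise_is_flat(self, rng):
        x = rng.normal(size=30000)
        f = framed_features(x, FS)
        assert f["flatness"] > 0.5
        assert f["zcr"] > 0.3

    def test_constant_zero_frame(self):
        f = framed_features(np.zeros(2048), FS)
        assert f["rms"] == 0.0
        assert f["zcr"] == 0.0

    def test_short_segment_raises(self):
        with pytest.raises(ValueError):
            framed_features(np.zeros(1000), FS)

    def test_rolloff_monotonic_on_random_segments(self, rng):
        for _ in range(20):
            x = rng.normal(size=4096) * rng.uniform(0.1, 2.0)
            f = framed_features(x, FS)
            assert f["rolloff25"] <= f["rolloff50"] <= f["rolloff85"]


class TestFullSegmentFFT:
    def test_tone_degenerate_distribution(self):
        # a bin-aligned tone concentrates the spectrum in one bin
        n = 30000
        t = np.arange(n) / FS
        x = np.sin(2 * np.pi * 100.0 * t)  # 100 Hz is bin-aligned: 100/ (1000/30000)
        f = fullsegment_fft_features(x, FS)
        assert f["crest"] > 0.9
        assert f["entropy"] < 1.0

    def test_flat_spectrum_limits(self):
        # an impulse has an exactly flat magnitude spectrum
        x = np.zeros(4096)
        x[0] = 1.0
        f = fullsegment_fft_features(x, FS)
        n_bins = 2048
        assert f["crest"] == pytest.approx(1.0 / n_bins, rel=1e-9)
        assert f["entropy"] == pytest.approx(np.log2(n_bins), rel=1e-9)

    def test_symmetric_two_tone_zero_skew(self):
        n = 30000
        t = np.arange(n) / FS
        x = np.sin(2 * np.pi * 100.0 * t) + np.sin(2 * np.pi * 200.0 * t)
        f = fullsegment_fft_features(x, FS)
        assert abs(f["skewness"]) < 0.05

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            fullsegment_fft_features(np.zeros(4096), FS)

    def test_sign_flip_invariance(self, rng):
        x = rng.normal(size=4096)
        a = fullsegment_fft_features(x, FS)
        b = fullsegment_fft_features(-x, FS)
        for k in a:
            assert a[k] == pytest.approx(b[k])


class TestAccGyroVector:
    def make_channels(self, rng, voiced=False):
        n = 30000
        t = np.arange(n) / FS
        out = {}
        for name in ("acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z"):
            x = rng.normal(0, 0.02, n)
            if voiced:
                gain = 1.0 if name == "acc_z" else 0.3
                x = x + gain * 0.15 * np.sin(2 * np.pi * 150.0 * t)
            out[name] = highpass_voicing(x, FS)
        return out

    def test_84_named_fields(self, rng):
        v = accgyro_feature_vector(self.make_channels(rng), FS)
        assert len(v) == 84
        assert {f"acc_z_{k}" for k in SPECTRAL_FEATURE_NAMES} <= set(v)

    def test_voiced_discriminative_direction(self, rng):
        voiced = accgyro_feature_vector(self.make_channels(rng, voiced=True), FS)
        silent = accgyro_feature_vector(self.make_channels(rng, voiced=False), FS)
        assert voiced["acc_z_rms"] > silent["acc_z_rms"]
        assert voiced["acc_z_crest"] > silent["acc_z_crest"]
        assert voiced["acc_z_entropy"] < silent["acc_z_entropy"]

    def test_silent_gyro_noise_like_entropy(self, rng):
        v = accgyro_feature_vector(self.make_channels(rng), FS)
        n_bins = 15000
        assert v["gyro_x_entropy"] > 0.9 * np.log2(n_bins)

    def test_channel_mismatch_raises(self, rng):
        ch = self.make_channels(rng)
        del ch["gyro_z"]
        with pytest.raises(ValueError):
            accgyro_feature_vector(ch, FS)
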