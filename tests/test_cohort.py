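import numpy as np
import pytest
from scipy.signal import welch

from biovad.breath import detect_breaths
from biovad.cohort import (
    SubjectProfile,
    simulate_accgyro,
    simulate_breath_cycles,
    simulate_cohort,
    simulate_free_living,
    simulate_respiration,
)
from biovad.protocol import Condition, Posture, ProtocolBlock
from biovad.spectral import highpass_voicing


def silent_block(dur=30.0):
    return ProtocolBlock(Condition.BASELINE, Posture.SITTING, False, dur)


def speech_block(dur=30.0, cond=Condition.READING):
    return ProtocolBlock(cond, Posture.SITTING, True, dur)


class TestSimulateRespiration:
    def test_silent_rate_recovered(self):
        prof = SubjectProfile(rr_silent=16.0, ie_silent=0.85)
        x = simulate_respiration(prof, [silent_block()], 128, 1, noise_sd=0, drift_amp=0)
        b = detect_breaths(x, 128)
        rr = 60.0 / np.mean(b.duration)
        assert abs(rr - 16.0) < 1.0

    def test_speech_ie_ratio_recovered(self):
        prof = SubjectProfile(ie_speech=0.65)
        x = simulate_respiration(prof, [speech_block(60.0)], 128, 2, noise_sd=0, drift_amp=0)
        b = detect_breaths(x, 128)
        assert 0.55 < np.mean(b.ti / b.te) < 0.75

    def test_degenerate_amplitudes_equal(self):
        prof = SubjectProfile(amp_sd=0.0)
        cycles = simulate_breath_cycles(prof, [silent_block()], 3)
        assert all(c.amp == prof.amp_mean for c in cycles)
        x = simulate_respiration(prof, [silent_block()], 128, 3, noise_sd=0, drift_amp=0)
        b = detect_breaths(x, 128)
        # sampled peaks sit within one grid step of the true equal amplitude
        assert np.allclose(b.amp_insp, prof.amp_mean, atol=5e-3)

    def test_cardiac_artifact_needs_adequate_fs(self):
        prof = SubjectProfile()
        from biovad.cohort import render_respiration

        cycles = simulate_breath_cycles(prof, [silent_block()], 0)
        with pytest.raises(ValueError):
            render_respiration(cycles, 30.0, 2.0, 0, cardiac=True)

    def test_rejects_low_fs(self):
        with pytest.raises(ValueError):
            simulate_respiration(SubjectProfile(), [silent_block()], 20, 0)

    def test_cycles_are_ground_truth_for_waveform(self):
        """The detector applied to the noise-free waveform recovers the
        generator's per-breath Ti and Te within one sample period."""
        prof = SubjectProfile()
        seq = np.random.SeedSequence(5)
        s_cyc, s_noise = seq.spawn(2)
        cycles = simulate_breath_cycles(prof, [silent_block(60.0)], s_cyc)
        x = simulate_respiration(prof, [silent_block(60.0)], 128, 5, noise_sd=0, drift_amp=0)
        b = detect_breaths(x, 128)
        n = min(b.n_cycles, len(cycles))
        ti_true = np.array([c.ti for c in cycles[:n]])
        te_true = np.array([c.te for c in cycles[:n]])
        assert np.max(np.abs(b.ti[:n] - ti_true)) <= 1.0 / 128 + 1e-9
        assert np.max(np.abs(b.te[:n] - te_true)) <= 1.0 / 128 + 1e-9


class TestSimulateAccGyro:
    def test_speech_band_power_exceeds_silent(self):
        sched = [speech_block(), silent_block()]
        ch = simulate_accgyro(SubjectProfile(f0=200.0, n_harmonics=2), sched, 1000, 3)
        f, p_speech = welch(ch["acc_z"][:30000], 1000, nperseg=2048)
        _, p_silent = welch(ch["acc_z"][30000:], 1000, nperseg=2048)
        band = f >= 75
        assert p_speech[band].sum() / p_silent[band].sum() > 10

    def test_walking_vanishes_after_highpass(self):
        sched = [
            ProtocolBlock(Condition.WALKING_READING, Posture.WALKING, False, 30),
            ProtocolBlock(Condition.BASELINE, Posture.STANDING, False, 30),
        ]
        ch = simulate_accgyro(SubjectProfile(), sched, 1000, 4)
        walk = highpass_voicing(ch["acc_z"][:30000], 1000)
        still = highpass_voicing(ch["acc_z"][30000:], 1000)
        assert np.std(walk) / np.std(still) == pytest.approx(1.0, abs=0.05)

    def test_zero_duty_disables_voicing(self):
        sched = [speech_block(), silent_block()]
        ch = simulate_accgyro(SubjectProfile(voicing_duty=0.0), sched, 1000, 5)
        rms_speech = np.std(ch["acc_z"][:30000])
        rms_silent = np.std(ch["acc_z"][30000:])
        assert rms_speech == pytest.approx(rms_silent, rel=0.05)

    def test_rejects_aliasing_stack(self):
        with pytest.raises(ValueError):
            simulate_accgyro(
                SubjectProfile(f0=200.0, n_harmonics=3), [speech_block()], 1000, 0
            )

    def test_rejects_low_fs(self):
        with pytest.raises(ValueError):
            simulate_accgyro(SubjectProfile(), [speech_block()], 400, 0)

    def test_sagittal_axis_strongest(self):
        ch = simulate_accgyro(SubjectProfile(f0=120.0), [speech_block()], 1000, 6)
        rms = {k: np.std(highpass_voicing(v, 1000)) for k, v in ch.items()}
        assert rms["acc_z"] > rms["acc_x"]
        assert rms["acc_z"] > rms["gyro_z"]


class TestSubjectProfile:
    def test_rejects_inverted_ie_contrast(self):
        with pytest.raises(ValueError):
            SubjectProfile(ie_silent=0.6, ie_speech=0.8)

    def test_rejects_out_of_band_f0(self):
        with pytest.raises(ValueError):
            SubjectProfile(f0=60.0)

    def test_rejects_inverted_te_variability(self):
        with pytest.raises(ValueError):
            SubjectProfile(te_sd_silent=0.4, te_sd_speech=0.2)


class TestSimulateCohort:
    def test_deterministic_under_seed(self):
        a = next(simulate_cohort(10, 7))
        b = next(simulate_cohort(10, 7))
        for name in a.channels:
            assert np.array_equal(a.channels[name].samples, b.channels[name].samples)
        assert np.array_equal(a.ground_truth, b.ground_truth)

    def test_cohort_segment_accounting(self):
        # 54 subjects x 66 segments = 3564; count labels without holding signals
        total = 0
        for rec in simulate_cohort(54, 0, include_vib=False, fs_resp=32, fs_imp=32):
            total += len(rec.ground_truth)
        assert total == 3564

    def test_f0_within_voiced_band(self):
        for rec in simulate_cohort(2, 1, include_vib=False):
            assert 85.0 <= rec.truth["profile"].f0 <= 255.0

    def test_both_classes_for_every_subject(self):
        for rec in simulate_cohort(3, 9, include_vib=False):
            assert set(np.unique(rec.ground_truth)) == {0, 1}

    def test_rejects_single_subject(self):
        with pytest.raises(ValueError):
            list(simulate_cohort(1, 0))


def test_free_living_fractional_labels():
    rec = simulate_free_living(300.0, seed=3, fs_vib=512)
    frac = rec.ground_truth
    assert len(frac) == 10
    assert np.all((0.0 <= frac) & (frac <= 1.0 + 1e-9))
    assert np.any((frac > 0) & (frac < 1))  # genuinely partial windows
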