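"""Online feedback chain: amplitude estimator, EOG calibration, artifact
rejection, color mapping, session orchestration."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import spearmanr

import fmtheta as fm
from fmtheta.feedback import ArtifactBand, BaselineReference
from fmtheta.synthetic import BLINK_TOPOGRAPHY, blink_waveform, one_over_f_noise

FS = 250.0


# ---------------------------------------------------------------------------
# sliding_band_amplitude

def test_sinusoid_amplitude_recovered():
    t = np.arange(int(300 * FS)) / FS
    x = 10.0 * np.sin(2 * np.pi * 6.0 * t + 0.7)
    times, amps = fm.sliding_band_amplitude(x, FS, (5.0, 7.0))
    assert len(amps) == 1491                     # (300 - 2) / 0.2 + 1
    assert np.abs(amps - 10.0).max() < 0.5
    assert times[0] == 0.0 and times[1] == pytest.approx(0.2)


def test_zero_signal_gives_zero_amplitude():
    amps = fm.sliding_band_amplitude(np.zeros(2000), FS, (5.0, 7.0))[1]
    assert np.all(amps == 0.0)


def test_estimator_is_linear_in_signal_scale():
    rng = np.random.default_rng(3)
    x = rng.standard_normal(4000)
    a1 = fm.sliding_band_amplitude(x, FS, (4.0, 8.0))[1]
    a3 = fm.sliding_band_amplitude(3.0 * x, FS, (4.0, 8.0))[1]
    assert np.allclose(a3, 3.0 * a1, rtol=1e-12)


def test_band_and_length_validation():
    x = np.zeros(1000)
    with pytest.raises(ValueError):
        fm.sliding_band_amplitude(x, FS, (100.0, 130.0))   # above Nyquist
    with pytest.raises(ValueError):
        fm.sliding_band_amplitude(np.zeros(100), FS, (5.0, 7.0))  # too short


# ---------------------------------------------------------------------------
# EOG calibration and artifact detection

def _calibration(profile_seed=5, rec_seed=23, rate=0.2, duration=60.0):
    config = fm.GeneratorConfig()
    profile = fm.generate_subject_profile(profile_seed, config)
    profile.blink_rate_hz = rate
    return fm.generate_calibration_recording(profile, rec_seed, config,
                                             duration_s=duration), config, profile


def test_calibration_is_deterministic_and_low_frequency():
    rec, _, _ = _calibration()
    a = fm.calibrate_eog(rec)
    b = fm.calibrate_eog(rec)
    assert a == b
    assert a.center_hz < 4.0            # blink energy is low-frequency
    assert a.band[0] >= 0.0 and a.band[0] < a.band[1]
    assert a.amplitude_threshold_uv > 0


def test_calibration_fails_without_artifacts():
    rec, _, _ = _calibration(rate=0.0)
    assert len(rec.blink_events) == 0
    with pytest.raises(fm.CalibrationError):
        fm.calibrate_eog(rec, amplitude_threshold_uv=np.abs(rec.data).max() + 1.0)


def test_calibration_requires_frontopolar_channels():
    rec, _, _ = _calibration()
    bad = fm.EEGRecording(rec.sampling_rate_hz, ("Fz", "Cz"), rec.data[:2],
                          rec.segments, rec.blink_events)
    with pytest.raises(fm.CalibrationError, match="Fp1"):
        fm.calibrate_eog(bad)


def test_injected_blink_windows_are_all_flagged():
    rec, config, profile = _calibration(rate=0.0, duration=30.0)
    band = _calibrated_band()
    # inject one blink at exactly t = 10 s
    wave = blink_waveform(FS, config.blink_duration_s)
    pattern = np.array([BLINK_TOPOGRAPHY[ch] for ch in rec.channel_labels])
    center = int(10.0 * FS)
    a = center - len(wave) // 2
    rec.data[:, a:a + len(wave)] += 150.0 * np.outer(pattern, wave)
    mask = fm.detect_artifact_windows(rec, band)
    starts = np.arange(mask.size) * 0.2
    overlapping = (starts <= 10.0) & (starts + 2.0 >= 10.0)
    assert mask[overlapping].all()


def _calibrated_band():
    rec, _, _ = _calibration()
    return fm.calibrate_eog(rec)


def test_false_positive_rate_on_blink_free_recording():
    band = _calibrated_band()
    rec, _, _ = _calibration(profile_seed=5, rec_seed=77, rate=0.0, duration=120.0)
    mask = fm.detect_artifact_windows(rec, band)
    assert mask.mean() < 0.05


def test_zero_threshold_flags_everything():
    rec, _, _ = _calibration(rate=0.0, duration=20.0)
    band = ArtifactBand(center_hz=1.5, band=(0.5, 2.5), amplitude_threshold_uv=0.0)
    assert fm.detect_artifact_windows(rec, band).all()


# ---------------------------------------------------------------------------
# color mapping

REF = BaselineReference(mean_uv=2.0, p2_5_uv=1.0, p97_5_uv=3.5)


def test_color_anchors_exact():
    assert fm.map_feedback_color(REF.mean_uv, REF) == 0
    assert fm.map_feedback_color(REF.p97_5_uv, REF) == 20
    assert fm.map_feedback_color(REF.p97_5_uv + 5.0, REF) == 20
    assert fm.map_feedback_color(REF.p2_5_uv, REF) == -20
    assert fm.map_feedback_color(0.0, REF) == -20
    assert fm.map_feedback_color(2.4, REF) > 0       # red above baseline mean
    assert fm.map_feedback_color(1.6, REF) < 0       # blue below


def test_color_scale_has_41_attainable_values_and_is_monotone():
    grid = np.linspace(0.0, 5.0, 20_001)
    steps = np.array([fm.map_feedback_color(a, REF) for a in grid])
    assert np.all(np.diff(steps) >= 0)
    assert set(steps) == set(range(-20, 21))


@given(st.floats(0.0, 10.0), st.floats(0.0, 10.0))
def test_color_mapping_monotone_property(a, b):
    lo, hi = sorted((a, b))
    assert fm.map_feedback_color(lo, REF) <= fm.map_feedback_color(hi, REF)


def test_degenerate_baseline_rejected():
    with pytest.raises(fm.ConfigurationError):
        fm.map_feedback_color(1.0, BaselineReference(2.0, 2.0, 2.0))


# ---------------------------------------------------------------------------
# run_session

def test_constant_recording_gives_equal_segment_means(fast_config):
    config = fm.GeneratorConfig(segment_duration_s=10.0, noise_sd_uv=0.0,
                                blink_rate_hz=0.0)
    profile = fm.generate_subject_profile(8, config)
    profile.responsiveness = 0.0
    profile.blink_rate_hz = 0.0
    eeg = fm.generate_session_eeg(profile, 1, 50, config)
    band = ArtifactBand(1.5, (0.5, 2.5), amplitude_threshold_uv=1e9)
    record, frames = fm.run_session(profile, eeg, band, session_index=1)
    assert np.ptp(record.segment_amp_uv) < 0.02 * record.segment_amp_uv.mean()
    assert record.n_windows_rejected.sum() == 0
    # frames only during blocks, on the 250-ms clock, colors within scale
    assert len(frames) == 6 * int(10.0 / 0.25)
    assert frames["color_step"].between(-20, 20).all()


def test_positive_responsiveness_raises_block_means(fast_config):
    config = fm.GeneratorConfig(segment_duration_s=20.0)
    profile = fm.generate_subject_profile(10, config)
    profile.responsiveness = 1.5
    cal = fm.generate_calibration_recording(profile, 60, config, duration_s=60.0)
    band = fm.calibrate_eog(cal)
    eeg = fm.generate_session_eeg(profile, 8, 61, config)
    record, _ = fm.run_session(profile, eeg, band, session_index=8)
    blocks = record.segment_amp_uv[1:7]
    assert blocks.mean() > record.amplitude("start_baseline")
    assert (record.n_windows_used + record.n_windows_rejected
            == record.n_windows_used[0] + record.n_windows_rejected[0]).all()


def test_blink_injection_leaves_clean_mean_invariant():
    """Rejection makes segment means robust to added blinks (< 1% shift)."""
    config = fm.GeneratorConfig()
    profile = fm.generate_subject_profile(12, config)
    band = _calibrated_band()
    rng = np.random.default_rng(90)
    n = int(300 * FS)
    t = np.arange(n) / FS
    theta = 2.0 * np.sin(2 * np.pi * 6.0 * t)
    fcz = theta + one_over_f_noise(n, FS, 5.0, 1.0, rng)
    fp = 0.3 * theta + one_over_f_noise(n, FS, 5.0, 1.0, rng)
    base = fm.sliding_band_amplitude(fcz, FS, (5.0, 7.0))[1].mean()

    fcz_b, fp_b = fcz.copy(), fp.copy()
    wave = blink_waveform(FS, config.blink_duration_s)
    for k in range(10):                          # ten blinks into the block
        c = int((20.0 + 25.0 * k) * FS)
        a = c - len(wave) // 2
        fp_b[a:a + len(wave)] += 150.0 * wave
        fcz_b[a:a + len(wave)] += 150.0 * BLINK_TOPOGRAPHY["FCz"] * wave
    rec = fm.EEGRecording(FS, ("FCz", "Fp1", "Fp2"),
                          np.vstack([fcz_b, fp_b, fp_b]),
                          [("block", 0.0, 300.0)], np.array([]))
    mask = fm.detect_artifact_windows(rec, band)
    amps = fm.sliding_band_amplitude(fcz_b, FS, (5.0, 7.0))[1]
    assert mask.sum() >= 10
    clean_mean = amps[~mask].mean()
    assert abs(clean_mean - base) / base < 0.01


def test_session_requires_protocol_segments(fast_config):
    profile = fm.generate_subject_profile(14, fast_config)
    cal = fm.generate_calibration_recording(profile, 70, fast_config)
    band = ArtifactBand(1.5, (0.5, 2.5), 1e9)
    with pytest.raises(fm.ConfigurationError):
        fm.run_session(profile, cal, band)


def test_end_to_end_responsiveness_recovery(cohort40):
    """Generator responsiveness orders measured training gain (rho > 0.7)."""
    df = cohort40.success
    rho = spearmanr(df["responsiveness"], df["success_L1"]).statistic
    assert rho > 0.7
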