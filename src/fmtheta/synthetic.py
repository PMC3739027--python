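"""Synthetic cohort generator: subjects, EEG sessions, task epochs, morphometry.

The generator emulates the statistical structure the downstream analysis
assumes, so that every stage is testable without access to raw recordings:

* each subject has an individual theta peak in 4-8 Hz that is stable across
  sessions, embedded in 1/f background noise;
* eye blinks are smooth ~400 ms biphasic transients dominant at Fp1/Fp2;
* theta amplitude during feedback blocks grows linearly within and across
  sessions, scaled by a latent responsiveness ``rho``;
* ``rho`` is a weighted sum of the subject's morphometry z-scores, so that
  regional brain structure predicts training success with configurable signs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CHANNELS, CONDITIONS, SEGMENT_LABELS, GeneratorConfig
from .errors import ConfigurationError
from .rois import canonical_roi_columns, volume_mean

# Fixed spatial patterns (gain per channel) for the two signal sources.
# Theta is fronto-central-midline maximal; blinks are frontopolar maximal
# with a frontal-to-central falloff.
THETA_TOPOGRAPHY = {
    "Fz": 0.8, "FC1": 0.8, "FCz": 1.0, "FC2": 0.8, "Cz": 0.7,
    "Fp1": 0.3, "Fp2": 0.3,
}
BLINK_TOPOGRAPHY = {
    "Fp1": 1.0, "Fp2": 0.95, "Fz": 0.35, "FC1": 0.2, "FCz": 0.2,
    "FC2": 0.2, "Cz": 0.1,
}


@dataclass
class SubjectProfile:
    """Ground-truth description of one synthetic participant."""

    subject_id: str
    theta_peak_hz: float
    theta_band: tuple[float, float]
    responsiveness: float
    baseline_theta_amp_uv: float
    blink_rate_hz: float
    artifact_band: object | None = None      # set by EOG calibration
    #: latent morphometry z-scores, aligned with ``canonical_roi_columns()``
    morphometry_z: np.ndarray | None = None
    #: true task-burst frequencies per condition (profiling ground truth)
    burst_freqs_hz: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 4.0 <= self.theta_peak_hz <= 8.0:
            raise ConfigurationError("theta_peak_hz must lie in [4, 8]")
        lo, hi = self.theta_band
        if not lo < hi or not lo <= self.theta_peak_hz <= hi:
            raise ConfigurationError("theta_band must contain theta_peak_hz with low < high")
        if self.baseline_theta_amp_uv <= 0:
            raise ConfigurationError("baseline_theta_amp_uv must be > 0")
        if self.blink_rate_hz < 0:
            raise ConfigurationError("blink_rate_hz must be >= 0")


@dataclass
class EEGRecording:
    """Multi-channel recording in microvolt with labeled segments."""

    sampling_rate_hz: float
    channel_labels: tuple[str, ...]
    data: np.ndarray                                  # channels x samples
    segments: list[tuple[str, float, float]]          # (label, start_s, end_s)
    blink_events: np.ndarray                          # ground-truth times (s)

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.channel_labels):
            raise ConfigurationError("data must have one row per channel label")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_labels.index(label)]

    def segment_slice(self, label: str) -> slice:
        for seg_label, start, end in self.segments:
            if seg_label == label:
                fs = self.sampling_rate_hz
                return slice(int(round(start * fs)), int(round(end * fs)))
        raise KeyError(f"no segment labeled {label!r}")


@dataclass
class TaskEpochs:
    """Single-channel task epochs for the four battery conditions."""

    sampling_rate_hz: float
    times: np.ndarray                       # seconds relative to stimulus
    epochs: dict[str, np.ndarray]           # condition -> (n_epochs, n_times)
    contaminated: dict[str, np.ndarray]     # condition -> bool mask
    burst_freqs_hz: dict[str, float]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def one_over_f_noise(n: int, fs: float, sd: float, alpha: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with a 1/f^alpha power spectrum, scaled to ``sd``."""
    if sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = freqs[nonzero] ** (-alpha / 2.0)
    shaping[0] = 0.0                       # no DC offset
    x = np.fft.irfft(spectrum * shaping, n=n)
    x *= sd / x.std()
    return x


def blink_waveform(fs: float, duration_s: float) -> np.ndarray:
    """Smooth biphasic transient with unit peak amplitude."""
    n = max(int(round(duration_s * fs)), 4)
    t = np.arange(n) / (n - 1)
    w = np.sin(2 * np.pi * t) * np.sin(np.pi * t) ** 2
    return w / np.abs(w).max()


def _draw_morphometry_z(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    cols = canonical_roi_columns()
    z = rng.standard_normal(len(cols))
    # Correlate left-CB volume and right-CB concentration so that a
    # suppression configuration (opposite-signed weights on positively
    # correlated predictors) can arise in the regressions.
    c = config.cingulate_coupling
    i_vol = cols.index("wm_vol_cb_l")
    i_conc = cols.index("wm_conc_cb_r")
    z[i_conc] = c * z[i_vol] + np.sqrt(max(1.0 - c * c, 0.0)) * z[i_conc]
    return z


def generate_subject_profile(seed, config: GeneratorConfig,
                             subject_id: str = "S000") -> SubjectProfile:
    """Draw one subject: theta peak, baseline amplitude, responsiveness.

    The responsiveness is a weighted sum of the subject's latent morphometry
    z-scores (weights from ``config.morphometry_weights``) plus Gaussian
    noise, centred on ``config.responsiveness_mean``.
    """
    config.validate()
    rng = _rng(seed)
    cols = canonical_roi_columns()
    unknown = set(config.morphometry_weights) - set(cols)
    if unknown:
        raise ConfigurationError(f"unknown morphometry weight columns: {sorted(unknown)}")

    peak = float(rng.uniform(*config.theta_peak_range_hz))
    z = _draw_morphometry_z(config, rng)
    rho = config.responsiveness_mean + sum(
        w * z[cols.index(name)] for name, w in config.morphometry_weights.items()
    ) + config.responsiveness_noise_sd * rng.standard_normal()
    baseline = max(0.25 * config.baseline_amp_mean_uv,
                   rng.normal(config.baseline_amp_mean_uv, config.baseline_amp_sd_uv))
    # Condition bursts stay a margin inside 4-8 Hz: ERSP peak picking needs
    # interior local maxima, and the dB normalization against a 1/f baseline
    # skews detected peaks slightly upward.
    offsets = np.asarray(config.burst_freq_offsets_hz, dtype=float)
    bursts = {cond: float(np.clip(peak + off, 4.4, 7.5))
              for cond, off in zip(CONDITIONS, offsets)}
    return SubjectProfile(
        subject_id=subject_id,
        theta_peak_hz=peak,
        theta_band=(peak - 1.0, peak + 1.0),
        responsiveness=float(rho),
        baseline_theta_amp_uv=float(baseline),
        blink_rate_hz=config.blink_rate_hz,
        morphometry_z=z,
        burst_freqs_hz=bursts,
    )


def generate_cohort_profiles(config: GeneratorConfig, seed) -> list[SubjectProfile]:
    """Draw ``config.n_subjects`` independent subjects from a root seed."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(config.n_subjects)
    return [
        generate_subject_profile(np.random.default_rng(child), config, f"S{i:03d}")
        for i, child in enumerate(children)
    ]


def block_amplitude(profile: SubjectProfile, config: GeneratorConfig,
                    block: int, session_index: int) -> float:
    """Closed-form theta amplitude of training block ``block`` (1-6)."""
    gain = 1.0 + profile.responsiveness * (
        config.within_session_gain * block
        + config.across_session_gain * (session_index - 1)
    )
    return profile.baseline_theta_amp_uv * max(gain, 0.0)


def _inject_blinks(data: np.ndarray, fs: float, rate_hz: float, amp_mean: float,
                   amp_cv: float, duration_s: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Add Poisson blink transients in place; return event times in seconds."""
    n = data.shape[1]
    total_s = n / fs
    n_events = rng.poisson(rate_hz * total_s)
    wave = blink_waveform(fs, duration_s)
    half = len(wave) // 2
    pattern = np.array([BLINK_TOPOGRAPHY[ch] for ch in CHANNELS])
    events = np.sort(rng.uniform(0, total_s, size=n_events))
    sigma = np.sqrt(np.log(1.0 + amp_cv ** 2)) if amp_cv > 0 else 0.0
    for t in events:
        center = int(round(t * fs))
        amp = amp_mean * np.exp(sigma * rng.standard_normal() - 0.5 * sigma ** 2)
        a = max(center - half, 0)
        b = min(center - half + len(wave), n)
        wa, wb = a - (center - half), b - (center - half)
        data[:, a:b] += amp * np.outer(pattern, wave[wa:wb])
    return events


def _segment_signal(profile: SubjectProfile, config: GeneratorConfig,
                    amp_uv: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """One segment: theta oscillator + independent 1/f noise per channel."""
    fs = config.sampling_rate_hz
    t = np.arange(n) / fs
    theta = amp_uv * np.sin(2 * np.pi * profile.theta_peak_hz * t + rng.uniform(0, 2 * np.pi))
    pattern = np.array([THETA_TOPOGRAPHY[ch] for ch in CHANNELS])
    data = np.outer(pattern, theta)
    for ch in range(len(CHANNELS)):
        data[ch] += one_over_f_noise(n, fs, config.noise_sd_uv, config.noise_alpha, rng)
    return data


def generate_session_eeg(profile: SubjectProfile, session_index: int, seed,
                         config: GeneratorConfig) -> EEGRecording:
    """Simulate one full training session (8 segments of 5 min each).

    Training blocks carry the feedback-driven amplitude gain given by
    :func:`block_amplitude`; the start and end baselines carry the plain
    baseline amplitude.
    """
    if not 1 <= session_index <= 8:
        raise ConfigurationError("session_index must be in 1..8")
    config.validate()
    rng = _rng(seed)
    fs = config.sampling_rate_hz
    n_seg = int(round(config.segment_duration_s * fs))

    chunks = []
    segments = []
    for i, label in enumerate(SEGMENT_LABELS):
        if label.startswith("block_"):
            amp = block_amplitude(profile, config, int(label.split("_")[1]), session_index)
        else:
            amp = profile.baseline_theta_amp_uv
        chunks.append(_segment_signal(profile, config, amp, n_seg, rng))
        segments.append((label, i * n_seg / fs, (i + 1) * n_seg / fs))

    data = np.concatenate(chunks, axis=1)
    events = _inject_blinks(data, fs, profile.blink_rate_hz, config.blink_amp_mean_uv,
                            config.blink_amp_cv, config.blink_duration_s, rng)
    return EEGRecording(fs, tuple(CHANNELS), data, segments, events)


def generate_calibration_recording(profile: SubjectProfile, seed,
                                   config: GeneratorConfig,
                                   duration_s: float = 60.0,
                                   blink_rate_hz: float | None = None) -> EEGRecording:
    """Pre-session EOG calibration recording (single labeled segment)."""
    config.validate()
    rng = _rng(seed)
    fs = config.sampling_rate_hz
    n = int(round(duration_s * fs))
    data = _segment_signal(profile, config, profile.baseline_theta_amp_uv, n, rng)
    rate = profile.blink_rate_hz if blink_rate_hz is None else blink_rate_hz
    events = _inject_blinks(data, fs, rate, config.blink_amp_mean_uv,
                            config.blink_amp_cv, config.blink_duration_s, rng)
    return EEGRecording(fs, tuple(CHANNELS), data, [("calibration", 0.0, duration_s)], events)


def generate_task_epochs(profile: SubjectProfile, n_epochs_per_condition: int,
                         seed, config: GeneratorConfig) -> TaskEpochs:
    """Single-channel task epochs with a condition-specific theta burst.

    Each epoch covers [-epoch_pre_s, epoch_post_s] around the stimulus; the
    post-stimulus interval contains a Hann-enveloped burst at the condition's
    frequency (near the subject's theta peak).  A small fraction of epochs is
    marked blink-contaminated and carries a blink transient; the profiling
    stage excludes those.
    """
    if n_epochs_per_condition < 1:
        raise ConfigurationError("n_epochs_per_condition must be >= 1")
    config.validate()
    rng = _rng(seed)
    fs = config.sampling_rate_hz
    n_t = int(round((config.epoch_pre_s + config.epoch_post_s) * fs))
    times = np.arange(n_t) / fs - config.epoch_pre_s

    burst_start, burst_len = 0.1, 1.8     # seconds after stimulus
    in_burst = (times >= burst_start) & (times < burst_start + burst_len)
    envelope = np.zeros(n_t)
    envelope[in_burst] = np.sin(np.pi * (times[in_burst] - burst_start) / burst_len) ** 2
    wave = blink_waveform(fs, config.blink_duration_s)
    p_blink = min(profile.blink_rate_hz * (config.epoch_pre_s + config.epoch_post_s), 1.0)

    epochs: dict[str, np.ndarray] = {}
    contaminated: dict[str, np.ndarray] = {}
    for cond in CONDITIONS:
        f_burst = profile.burst_freqs_hz[cond]
        block = np.empty((n_epochs_per_condition, n_t))
        mask = rng.random(n_epochs_per_condition) < p_blink
        for i in range(n_epochs_per_condition):
            x = one_over_f_noise(n_t, fs, config.noise_sd_uv, config.noise_alpha, rng)
            x += config.burst_amp_uv * envelope * np.sin(
                2 * np.pi * f_burst * times + rng.uniform(0, 2 * np.pi))
            if mask[i]:
                pos = rng.integers(0, n_t - len(wave))
                x[pos:pos + len(wave)] += (config.blink_amp_mean_uv
                                           * BLINK_TOPOGRAPHY["FCz"] * wave)
            block[i] = x
        epochs[cond] = block
        contaminated[cond] = mask
    return TaskEpochs(fs, times, epochs, contaminated, dict(profile.burst_freqs_hz))


def generate_morphometry_table(profiles: list[SubjectProfile],
                               config: GeneratorConfig, seed) -> pd.DataFrame:
    """Materialize the 40-column ROI morphometry table for a cohort.

    Latent z-scores (drawn with each profile) are mapped to measurement
    scales -- log-normal volumes around region-typical means, concentrations
    near 0.5 clipped to [0, 1] -- after adding independent measurement noise
    of SD ``morphometry_noise_sd``.
    """
    if not profiles:
        raise ConfigurationError("need at least one profile")
    config.validate()
    rng = _rng(seed)
    cols = canonical_roi_columns()
    z = np.vstack([p.morphometry_z for p in profiles])
    z = z + config.morphometry_noise_sd * rng.standard_normal(z.shape)

    table = np.empty_like(z)
    for j, col in enumerate(cols):
        if "_vol_" in col:
            table[:, j] = volume_mean(col) * np.exp(0.15 * z[:, j])
        else:
            table[:, j] = np.clip(0.5 + 0.08 * z[:, j], 0.0, 1.0)
    return pd.DataFrame(table, columns=cols,
                        index=pd.Index([p.subject_id for p in profiles], name="subject_id"))
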