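"""Real-time feedback engine emulation.

Implements the online processing chain of the training protocol: per-session
EOG calibration, sliding 2-s Hamming-FFT band-amplitude estimation on a
200-ms grid, rejection of artifact-contaminated windows, the 40-step
baseline-referenced color mapping (gray at the start-baseline mean, maximal
red/blue at its 97.5th/2.5th percentile), and session orchestration yielding
per-segment mean theta amplitudes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .config import SEGMENT_LABELS
from .errors import CalibrationError, ConfigurationError
from .synthetic import EEGRecording, SubjectProfile


@dataclass
class ArtifactBand:
    """Individualized eye-artifact frequency band from EOG calibration."""

    center_hz: float
    band: tuple[float, float]
    amplitude_threshold_uv: float

    def __post_init__(self) -> None:
        lo, hi = self.band
        if lo < 0 or lo >= hi:
            raise ConfigurationError("artifact band must satisfy 0 <= low < high")
        if self.amplitude_threshold_uv < 0:
            raise ConfigurationError("amplitude threshold must be >= 0")


@dataclass
class BaselineReference:
    """Summary of the session's start-baseline amplitude distribution."""

    mean_uv: float
    p2_5_uv: float
    p97_5_uv: float


@dataclass
class SessionRecord:
    """Per-segment outcome of one training session."""

    session_index: int
    segment_labels: tuple[str, ...]
    segment_amp_uv: np.ndarray
    n_windows_used: np.ndarray
    n_windows_rejected: np.ndarray
    baseline_reference: BaselineReference
    low_quality_segments: tuple[str, ...] = ()

    def amplitude(self, label: str) -> float:
        return float(self.segment_amp_uv[self.segment_labels.index(label)])


def sliding_band_amplitude(x: np.ndarray, sampling_rate_hz: float,
                           band: tuple[float, float], window_s: float = 2.0,
                           step_s: float = 0.2,
                           taper: str = "hamming") -> tuple[np.ndarray, np.ndarray]:
    """Band amplitude (uV) from a Hamming-tapered FFT on a sliding window.

    The estimate is the amplitude of the sinusoid whose power equals the
    taper-gain-corrected spectral power summed over the FFT bins inside
    ``band``: ``a = 2 * sqrt(sum |X_k|^2 / (N * sum w^2))``.  For a pure
    sinusoid at a band-interior bin frequency this recovers its amplitude
    exactly, and the estimator is linear in the signal scale.

    Returns (window start times in s, amplitudes in uV); one window per
    ``step_s``, i.e. ``(len(x) - N) // step + 1`` windows.
    """
    x = np.asarray(x, dtype=float)
    nyquist = sampling_rate_hz / 2.0
    if not 0 <= band[0] < band[1] <= nyquist:
        raise ValueError(f"band {band} must lie within (0, Nyquist={nyquist}]")
    n_win = int(round(window_s * sampling_rate_hz))
    n_step = int(round(step_s * sampling_rate_hz))
    if x.size < n_win:
        raise ValueError("recording shorter than one analysis window")

    frames = np.lib.stride_tricks.sliding_window_view(x, n_win)[::n_step]
    w = signal.get_window(taper, n_win)
    spectra = np.fft.rfft(frames * w, axis=1)
    freqs = np.fft.rfftfreq(n_win, d=1.0 / sampling_rate_hz)
    sel = (freqs >= band[0]) & (freqs <= band[1]) & (freqs > 0)
    if not sel.any():
        raise ValueError(f"no FFT bin falls inside band {band}")
    band_energy = (np.abs(spectra[:, sel]) ** 2).sum(axis=1)
    amps = 2.0 * np.sqrt(band_energy / (n_win * np.sum(w ** 2)))
    times = np.arange(len(frames)) * n_step / sampling_rate_hz
    return times, amps


def _window_view(x: np.ndarray, n_win: int, n_step: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(x, n_win)[::n_step]


def calibrate_eog(recording: EEGRecording, threshold_quantile: float = 0.99,
                  halfwidth_hz: float = 1.0, window_s: float = 2.0,
                  step_s: float = 0.2,
                  amplitude_threshold_uv: float | None = None,
                  clean_margin: float = 2.0) -> ArtifactBand:
    """Derive the individualized eye-artifact band from a calibration run.

    Windows whose frontopolar peak amplitude ``max(|Fp1|, |Fp2|)`` exceeds
    the ``threshold_quantile`` quantile of the windowed peak-amplitude
    distribution (or an explicit ``amplitude_threshold_uv``) mark artifact
    time frames; these windows are pooled and their mean Hamming-FFT
    amplitude spectrum yields the artifact spectral peak.  The detection
    band is ``peak +/- halfwidth_hz``; the in-band rejection threshold is
    the maximum artifact-band amplitude over the artifact-free calibration
    windows, where "artifact-free" means a window peak below ``clean_margin``
    times the median window peak (blinks are several times larger than
    background, so this keeps sub-threshold blinks out of the reference set).
    """
    for ch in ("Fp1", "Fp2"):
        if ch not in recording.channel_labels:
            raise CalibrationError(f"calibration recording lacks channel {ch}")
    fs = recording.sampling_rate_hz
    fp1, fp2 = recording.channel("Fp1"), recording.channel("Fp2")
    envelope = np.maximum(np.abs(fp1), np.abs(fp2))

    n_win = int(round(window_s * fs))
    n_step = int(round(step_s * fs))
    if envelope.size < n_win:
        raise CalibrationError("calibration recording shorter than one window")
    window_peak = _window_view(envelope, n_win, n_step).max(axis=1)
    thr = (np.quantile(window_peak, threshold_quantile)
           if amplitude_threshold_uv is None else amplitude_threshold_uv)
    # >= : the top quantile may fall on a plateau of windows sharing one
    # blink's peak sample; an explicit threshold above the maximum still fails.
    exceed = window_peak >= thr
    clean = window_peak <= clean_margin * np.median(window_peak)
    if not exceed.any():
        raise CalibrationError("no window exceeds the amplitude threshold")
    if not clean.any():
        raise CalibrationError("no artifact-free window available for thresholding")

    pooled = _window_view(0.5 * (fp1 + fp2), n_win, n_step)[exceed]
    taper = signal.get_window("hamming", n_win)
    spectrum = np.abs(np.fft.rfft(pooled * taper, axis=1)).mean(axis=0)
    freqs = np.fft.rfftfreq(n_win, d=1.0 / fs)
    searchable = freqs > 0
    center = float(freqs[searchable][np.argmax(spectrum[searchable])])
    band = (max(center - halfwidth_hz, 0.0), center + halfwidth_hz)

    clean_amp = _band_amplitude_fp(fp1, fp2, fs, band, window_s, step_s)[clean]
    return ArtifactBand(center_hz=center, band=band,
                        amplitude_threshold_uv=float(clean_amp.max()))


def _band_amplitude_fp(fp1: np.ndarray, fp2: np.ndarray, fs: float,
                       band: tuple[float, float], window_s: float,
                       step_s: float) -> np.ndarray:
    # Rejection uses an untapered window: a Hamming taper would mask a blink
    # sitting at the window edge, letting the window pass as artifact-free.
    a1 = sliding_band_amplitude(fp1, fs, band, window_s, step_s, taper="boxcar")[1]
    a2 = sliding_band_amplitude(fp2, fs, band, window_s, step_s, taper="boxcar")[1]
    return np.maximum(a1, a2)


def detect_artifact_windows(recording: EEGRecording, artifact_band: ArtifactBand,
                            window_s: float = 2.0, step_s: float = 0.2,
                            sample_range: slice | None = None) -> np.ndarray:
    """Boolean mask: window contains an eye artifact.

    A window is flagged when the artifact-band amplitude of either
    frontopolar channel exceeds the calibrated threshold.
    """
    sl = sample_range if sample_range is not None else slice(None)
    fp1 = recording.channel("Fp1")[sl]
    fp2 = recording.channel("Fp2")[sl]
    amps = _band_amplitude_fp(fp1, fp2, recording.sampling_rate_hz,
                              artifact_band.band, window_s, step_s)
    return amps > artifact_band.amplitude_threshold_uv


def map_feedback_color(theta_amp_uv: float, baseline_reference: BaselineReference) -> int:
    """Map an amplitude onto the 40-step color scale (-20 blue .. +20 red).

    The start-baseline mean maps to 0 (gray); amplitudes are scaled linearly
    so that the 97.5th baseline percentile reaches +20 (maximal red) and the
    2.5th percentile -20 (maximal blue), clamping beyond.
    """
    ref = baseline_reference
    if not ref.p2_5_uv < ref.mean_uv < ref.p97_5_uv:
        raise ConfigurationError("degenerate baseline reference (zero spread)")
    if theta_amp_uv >= ref.mean_uv:
        step = round(20.0 * (theta_amp_uv - ref.mean_uv) / (ref.p97_5_uv - ref.mean_uv))
        return int(min(20, step))
    step = round(20.0 * (ref.mean_uv - theta_amp_uv) / (ref.mean_uv - ref.p2_5_uv))
    return -int(min(20, step))


def run_session(profile: SubjectProfile, eeg: EEGRecording,
                artifact_band: ArtifactBand, session_index: int = 1,
                feedback_channel: str = "FCz", theta_band: tuple[float, float] | None = None,
                window_s: float = 2.0, step_s: float = 0.2, update_s: float = 0.25,
                ) -> tuple[SessionRecord, pd.DataFrame]:
    """Process one 8-segment session through the online chain.

    Returns the per-segment mean theta amplitudes (artifact windows excluded)
    and the stream of feedback frames.  Frames are emitted on the ``update_s``
    clock during training blocks only, holding the most recent completed
    sliding-window estimate; artifact frames are forced to gray (step 0).
    """
    band = theta_band if theta_band is not None else profile.theta_band
    labels = [seg[0] for seg in eeg.segments]
    if labels != list(SEGMENT_LABELS):
        raise ConfigurationError(
            f"recording must contain the 8 protocol segments in order, got {labels}")

    x = eeg.channel(feedback_channel)
    means = np.full(len(SEGMENT_LABELS), np.nan)
    n_used = np.zeros(len(SEGMENT_LABELS), dtype=int)
    n_rej = np.zeros(len(SEGMENT_LABELS), dtype=int)
    low_quality: list[str] = []
    baseline_ref: BaselineReference | None = None
    frames: list[pd.DataFrame] = []

    for i, (label, start_s, end_s) in enumerate(eeg.segments):
        sl = eeg.segment_slice(label)
        times, amps = sliding_band_amplitude(x[sl], eeg.sampling_rate_hz, band,
                                             window_s, step_s)
        artifact = detect_artifact_windows(eeg, artifact_band, window_s, step_s,
                                           sample_range=sl)
        clean = amps[~artifact]
        n_used[i] = clean.size
        n_rej[i] = int(artifact.sum())
        if artifact.mean() > 0.5:
            warnings.warn(f"segment {label}: >50% of windows rejected", stacklevel=2)
            low_quality.append(label)
        if clean.size:
            means[i] = clean.mean()
        if label == "start_baseline":
            ref_amps = clean if clean.size else amps
            baseline_ref = BaselineReference(
                mean_uv=float(ref_amps.mean()),
                p2_5_uv=float(np.percentile(ref_amps, 2.5)),
                p97_5_uv=float(np.percentile(ref_amps, 97.5)))
        elif label.startswith("block_") and baseline_ref is not None:
            frames.append(_feedback_frames(times, amps, artifact, baseline_ref,
                                           start_s, end_s - start_s,
                                           window_s, step_s, update_s))

    record = SessionRecord(
        session_index=session_index, segment_labels=tuple(SEGMENT_LABELS),
        segment_amp_uv=means, n_windows_used=n_used, n_windows_rejected=n_rej,
        baseline_reference=baseline_ref, low_quality_segments=tuple(low_quality))
    frame_df = (pd.concat(frames, ignore_index=True) if frames
                else pd.DataFrame(columns=["time_s", "theta_amp_uv", "color_step", "artifact"]))
    return record, frame_df


def _feedback_frames(win_times: np.ndarray, amps: np.ndarray, artifact: np.ndarray,
                     ref: BaselineReference, seg_start_s: float, seg_dur_s: float,
                     window_s: float, step_s: float, update_s: float) -> pd.DataFrame:
    """Sample-and-hold coupling of the FFT grid onto the color-update clock."""
    clock = np.arange(update_s, seg_dur_s + 1e-9, update_s)
    # latest window whose data are fully acquired by the frame time
    idx = np.floor((clock - window_s) / step_s + 1e-9).astype(int)
    rows = []
    for t, j in zip(clock, idx):
        if j < 0:
            rows.append((seg_start_s + t, np.nan, 0, False))
            continue
        j = min(j, len(amps) - 1)
        bad = bool(artifact[j])
        color = 0 if bad else map_feedback_color(float(amps[j]), ref)
        rows.append((seg_start_s + t, float(amps[j]), color, bad))
    return pd.DataFrame(rows, columns=["time_s", "theta_amp_uv", "color_step", "artifact"])
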