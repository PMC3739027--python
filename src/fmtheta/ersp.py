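"""Individual theta determination via event-related spectral perturbation.

The individual frontal-midline theta frequency is the 4-8 Hz peak of the
ERSP -- the time-frequency power change relative to the pre-stimulus
baseline, averaged over epochs -- computed separately for the four task
conditions and then averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import UnprofiledSubjectError
from .synthetic import TaskEpochs


@dataclass
class ERSPResult:
    """Event-related spectral perturbation on a frequency x time grid (dB)."""

    freqs: np.ndarray           # Hz, strictly increasing
    times: np.ndarray           # s relative to stimulus (window centers)
    values: np.ndarray          # (n_freqs, n_times), dB re pre-stimulus baseline
    condition: str = ""


def compute_ersp(epochs: np.ndarray, sampling_rate_hz: float, epoch_times: np.ndarray,
                 baseline_interval: tuple[float, float] = (-1.0, 0.0),
                 window_s: float = 1.0, overlap: float = 0.9, nfft: int = 2048,
                 fmin: float = 2.0, fmax: float = 12.0,
                 condition: str = "") -> ERSPResult:
    """Short-time-FFT ERSP of a set of single-channel epochs.

    Power is estimated with a sliding Hamming-tapered FFT (zero-padded to
    ``nfft`` for a fine frequency grid), averaged over epochs, and expressed
    in dB relative to the mean power of the pre-stimulus baseline interval,
    per frequency.
    """
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    if epochs.size == 0 or epochs.shape[0] < 1:
        raise ValueError("need at least one epoch")
    lo, hi = baseline_interval
    if hi > 0:
        raise ValueError("baseline interval must precede the stimulus (end <= 0 s)")

    nperseg = int(round(window_s * sampling_rate_hz))
    noverlap = int(round(overlap * nperseg))
    freqs, t_rel, sxx = signal.spectrogram(
        epochs, fs=sampling_rate_hz, window=signal.get_window("hamming", nperseg),
        nperseg=nperseg, noverlap=noverlap, nfft=max(nfft, nperseg),
        mode="psd", axis=-1)
    times = epoch_times[0] + t_rel                 # window centers, stimulus-relative
    power = sxx.mean(axis=0)                       # average over epochs

    keep = (freqs >= fmin) & (freqs <= fmax)
    freqs, power = freqs[keep], power[keep]

    base_cols = (times >= lo) & (times <= hi)
    if not base_cols.any():
        raise ValueError("no spectrogram window falls inside the baseline interval")
    baseline = power[:, base_cols].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = 10.0 * np.log10(power / baseline[:, None])
    return ERSPResult(freqs=freqs, times=times, values=values, condition=condition)


def detect_theta_peak(ersp: ERSPResult, band: tuple[float, float] = (4.0, 8.0),
                      min_prominence_db: float = 1.0) -> float | None:
    """Frequency of the maximal time-averaged post-stimulus perturbation.

    The perturbation is averaged over post-stimulus times, local maxima are
    located on the full frequency grid, and the largest one inside ``band``
    is returned -- the lowest frequency on ties.  Returns ``None`` (no-peak)
    if no local maximum reaches ``min_prominence_db``.
    """
    if band[0] < ersp.freqs[0] or band[1] > ersp.freqs[-1]:
        raise ValueError(f"frequency grid does not cover the band {band}")
    post = ersp.times > 0
    if not post.any():
        raise ValueError("ERSP contains no post-stimulus time points")
    curve = ersp.values[:, post].mean(axis=1)
    if not np.all(np.isfinite(curve)):
        return None
    peaks, _ = signal.find_peaks(curve, prominence=min_prominence_db)
    in_band = peaks[(ersp.freqs[peaks] >= band[0]) & (ersp.freqs[peaks] <= band[1])]
    if in_band.size == 0:
        return None
    best = in_band[np.argmax(curve[in_band])]      # argmax -> first (lowest) on ties
    return float(ersp.freqs[best])


def individual_theta(peaks) -> float:
    """Arithmetic mean of the four task-condition peak frequencies."""
    peaks = list(peaks)
    if any(p is None for p in peaks):
        raise UnprofiledSubjectError("at least one condition yielded no theta peak")
    return float(np.mean([float(p) for p in peaks]))


def profile_individual_theta(task_epochs: TaskEpochs,
                             band: tuple[float, float] = (4.0, 8.0),
                             min_prominence_db: float = 1.0,
                             window_s: float = 1.0, overlap: float = 0.9,
                             ) -> tuple[float, dict[str, float | None]]:
    """End-to-end profiling: ERSP peak per condition, averaged.

    Blink-contaminated epochs are excluded before the ERSP is computed.
    Returns the individual theta frequency and the per-condition peaks;
    raises :class:`UnprofiledSubjectError` if any condition has no peak.
    """
    peaks: dict[str, float | None] = {}
    for cond, block in task_epochs.epochs.items():
        clean = block[~task_epochs.contaminated[cond]]
        if clean.shape[0] == 0:
            peaks[cond] = None
            continue
        ersp = compute_ersp(clean, task_epochs.sampling_rate_hz, task_epochs.times,
                            window_s=window_s, overlap=overlap, condition=cond)
        peaks[cond] = detect_theta_peak(ersp, band=band,
                                        min_prominence_db=min_prominence_db)
    return individual_theta(peaks.values()), peaks
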