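"""Configuration objects for the generator and the end-to-end study run.

All tunable parameters of the pipeline live here so that a run can be
described by a single structured text (YAML) file and reproduced exactly
from it plus a root seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError

#: The seven recorded electrodes, in canonical order.
CHANNELS = ("Fz", "FC1", "FCz", "FC2", "Cz", "Fp1", "Fp2")

#: The eight five-minute segments of one training session, in order.
SEGMENT_LABELS = (
    "start_baseline",
    "block_1", "block_2", "block_3", "block_4", "block_5", "block_6",
    "end_baseline",
)

#: Task-battery conditions used for individual theta profiling.
CONDITIONS = ("inhibition", "conflict", "updating", "switching")


def _default_weights() -> dict[str, float]:
    # Signed coupling of latent responsiveness to the three predictive
    # morphometry measures: right MCC gray-matter volume (+), left cingulate
    # bundle white-matter volume (+), right cingulate bundle white-matter
    # concentration (-).
    return {
        "gm_vol_mcc_r": 0.5,
        "wm_vol_cb_l": 0.5,
        "wm_conc_cb_r": -0.5,
    }


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    Amplitudes are in microvolt; the amplitude law for training block ``b``
    (1-6) of session ``s`` (1-8) is

        A(b, s) = baseline_amp * (1 + rho * (within_session_gain * b
                                             + across_session_gain * (s - 1)))

    clamped at zero, while baseline segments carry the un-gained baseline
    amplitude.  ``rho`` is the latent responsiveness, coupled to morphometry
    z-scores through ``morphometry_weights``.
    """

    n_subjects: int = 19
    seed: int = 0
    sampling_rate_hz: float = 250.0
    segment_duration_s: float = 300.0

    theta_peak_range_hz: tuple[float, float] = (4.0, 8.0)
    baseline_amp_mean_uv: float = 2.0
    baseline_amp_sd_uv: float = 0.4
    within_session_gain: float = 0.05   # per block, scaled by rho
    across_session_gain: float = 0.05   # per session, scaled by rho

    noise_sd_uv: float = 5.0            # 1/f^alpha background, per channel
    noise_alpha: float = 1.0

    blink_rate_hz: float = 0.1
    blink_amp_mean_uv: float = 150.0
    blink_amp_cv: float = 0.2
    blink_duration_s: float = 0.4

    responsiveness_mean: float = 1.0
    responsiveness_noise_sd: float = 0.5
    morphometry_weights: dict[str, float] = field(default_factory=_default_weights)
    cingulate_coupling: float = 0.6     # corr(z left-CB volume, z right-CB concentration)
    morphometry_noise_sd: float = 0.1

    # Task-epoch generator (theta profiling stage)
    burst_freq_offsets_hz: tuple[float, float, float, float] = (-0.3, -0.1, 0.1, 0.3)
    burst_amp_uv: float = 5.0
    epoch_pre_s: float = 1.0
    epoch_post_s: float = 2.0

    def validate(self) -> None:
        lo, hi = self.theta_peak_range_hz
        if not (4.0 <= lo <= hi <= 8.0):
            raise ConfigurationError(
                f"theta_peak_range_hz must lie within [4, 8], got {self.theta_peak_range_hz}"
            )
        for name in ("baseline_amp_sd_uv", "noise_sd_uv", "morphometry_noise_sd",
                     "responsiveness_noise_sd", "blink_amp_cv"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.baseline_amp_mean_uv <= 0:
            raise ConfigurationError("baseline_amp_mean_uv must be > 0")
        if self.blink_rate_hz < 0:
            raise ConfigurationError("blink_rate_hz must be >= 0")
        if self.sampling_rate_hz <= 0 or self.segment_duration_s <= 0:
            raise ConfigurationError("sampling rate and segment duration must be > 0")
        if not -1.0 <= self.cingulate_coupling <= 1.0:
            raise ConfigurationError("cingulate_coupling must be a correlation in [-1, 1]")
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")


@dataclass
class StudyConfig:
    """Everything needed to reproduce one end-to-end study run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    seed: int = 0

    # theta profiling
    n_epochs_per_condition: int = 60
    profiling_channel: str = "FCz"
    ersp_window_s: float = 1.0
    ersp_overlap: float = 0.9
    peak_prominence_db: float = 1.0

    # neurofeedback loop
    feedback_channel: str = "FCz"
    band_halfwidth_hz: float = 1.0
    window_s: float = 2.0
    step_s: float = 0.2
    update_s: float = 0.25
    eog_threshold_quantile: float = 0.99
    artifact_halfwidth_hz: float = 1.0
    calibration_duration_s: float = 60.0

    # learning indices
    l1_reference: str = "first_session"   # or "own_start"
    l2_blocks_only: bool = True

    # stepwise regression
    entry_p: float = 0.05
    removal_p: float = 0.10

    out_dir: str | None = None

    def validate(self) -> None:
        self.generator.validate()
        if self.l1_reference not in ("first_session", "own_start"):
            raise ConfigurationError("l1_reference must be 'first_session' or 'own_start'")
        if not 0 < self.entry_p <= self.removal_p < 1:
            raise ConfigurationError("require 0 < entry_p <= removal_p < 1")
        if not 0 < self.eog_threshold_quantile <= 1:
            raise ConfigurationError("eog_threshold_quantile must be in (0, 1]")
        for name in ("window_s", "step_s", "update_s", "band_halfwidth_hz"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return list(obj)
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def save_config(config: StudyConfig, path: str | Path) -> None:
    """Serialize a study configuration to YAML (lossless round trip)."""
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=False)


def _tuplify(cls, data: dict) -> dict:
    out = dict(data)
    for f in dataclasses.fields(cls):
        if f.name in out and isinstance(out[f.name], list):
            ftype = str(f.type)
            if ftype.startswith("tuple"):
                out[f.name] = tuple(out[f.name])
    return out


def load_config(path: str | Path) -> StudyConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    gen = GeneratorConfig(**_tuplify(GeneratorConfig, data.pop("generator", {})))
    config = StudyConfig(generator=gen, **_tuplify(StudyConfig, data))
    config.validate()
    return config
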