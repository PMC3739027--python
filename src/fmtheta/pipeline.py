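"""End-to-end study pipeline: simulate -> profile -> train x8 -> indices ->
correlate -> regress.

The entry point is :func:`run_study`, which consumes a :class:`StudyConfig`
and returns (and optionally writes) the full set of cohort outputs: subject
profiles, the morphometry table, per-session records, learning curves, the
repeated-measures ANOVAs, the early-vs-final success correlation, and the
four stepwise structure-function regressions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .config import SEGMENT_LABELS, GeneratorConfig, StudyConfig, save_config
from .ersp import profile_individual_theta
from .feedback import SessionRecord, calibrate_eog, run_session
from .indices import LearningCurves, compute_curves
from .rois import gm_columns, wm_columns
from .stats import (AnovaResult, CorrelationResult, RegressionResult,
                    pearson_one_tailed, rm_anova_oneway, stepwise_regression)
from .synthetic import (SubjectProfile, generate_calibration_recording,
                        generate_cohort_profiles, generate_morphometry_table,
                        generate_session_eeg, generate_task_epochs)

log = logging.getLogger("fmtheta")


@dataclass
class SubjectOutcome:
    profile: SubjectProfile
    individual_theta_hz: float
    sessions: list[SessionRecord]
    curves: LearningCurves


@dataclass
class StudyResult:
    config: StudyConfig
    profiles: list[SubjectProfile]
    morphometry: pd.DataFrame
    subjects: dict[str, SubjectOutcome]
    curves_long: pd.DataFrame
    anova_block: AnovaResult
    anova_session: AnovaResult
    early_final: CorrelationResult
    regressions: dict[str, RegressionResult]

    @property
    def success(self) -> pd.DataFrame:
        rows = {sid: (o.curves.success_L1, o.curves.early_success_L2,
                      o.curves.final_success_L2, o.profile.responsiveness)
                for sid, o in self.subjects.items()}
        return pd.DataFrame.from_dict(
            rows, orient="index",
            columns=["success_L1", "early_success_L2", "final_success_L2",
                     "responsiveness"]).rename_axis("subject_id")

    def l1_matrix(self) -> np.ndarray:
        return np.vstack([o.curves.L1 for o in self.subjects.values()])

    def l2_matrix(self) -> np.ndarray:
        return np.vstack([o.curves.L2 for o in self.subjects.values()])


def run_subject(profile: SubjectProfile, config: StudyConfig,
                seed) -> SubjectOutcome:
    """Profile, calibrate and train one subject through all 8 sessions."""
    gen = config.generator
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    seeds = [np.random.default_rng(child) for child in ss.spawn(10)]

    epochs = generate_task_epochs(profile, config.n_epochs_per_condition, seeds[0], gen)
    theta_hz, _ = profile_individual_theta(
        epochs, min_prominence_db=config.peak_prominence_db,
        window_s=config.ersp_window_s, overlap=config.ersp_overlap)
    profile.theta_band = (theta_hz - config.band_halfwidth_hz,
                          theta_hz + config.band_halfwidth_hz)

    calibration = generate_calibration_recording(
        profile, seeds[1], gen, duration_s=config.calibration_duration_s)
    profile.artifact_band = calibrate_eog(
        calibration, threshold_quantile=config.eog_threshold_quantile,
        halfwidth_hz=config.artifact_halfwidth_hz,
        window_s=config.window_s, step_s=config.step_s)

    sessions = []
    for s in range(1, 9):
        eeg = generate_session_eeg(profile, s, seeds[1 + s], gen)
        record, _ = run_session(
            profile, eeg, profile.artifact_band, session_index=s,
            feedback_channel=config.feedback_channel,
            window_s=config.window_s, step_s=config.step_s, update_s=config.update_s)
        sessions.append(record)

    curves = compute_curves(sessions, config.l1_reference, config.l2_blocks_only)
    return SubjectOutcome(profile, theta_hz, sessions, curves)


def cohort_statistics(result_subjects: dict[str, SubjectOutcome],
                      morphometry: pd.DataFrame, config: StudyConfig):
    """The study's inference block over a finished cohort."""
    l1 = np.vstack([o.curves.L1 for o in result_subjects.values()])
    l2 = np.vstack([o.curves.L2 for o in result_subjects.values()])
    anova_block = rm_anova_oneway(l1)
    anova_session = rm_anova_oneway(l2)

    early = np.array([o.curves.early_success_L2 for o in result_subjects.values()])
    final = np.array([o.curves.final_success_L2 for o in result_subjects.values()])
    early_final = pearson_one_tailed(early, final)

    success_l1 = np.array([o.curves.success_L1 for o in result_subjects.values()])
    success_l2 = final
    order = list(result_subjects.keys())
    X = morphometry.loc[order]
    regressions = {
        "L1_gm": stepwise_regression(X[gm_columns()], success_l1,
                                     config.entry_p, config.removal_p),
        "L1_wm": stepwise_regression(X[wm_columns()], success_l1,
                                     config.entry_p, config.removal_p),
        "L2_gm": stepwise_regression(X[gm_columns()], success_l2,
                                     config.entry_p, config.removal_p),
        "L2_wm": stepwise_regression(X[wm_columns()], success_l2,
                                     config.entry_p, config.removal_p),
    }
    return anova_block, anova_session, early_final, regressions


def run_study(config: StudyConfig) -> StudyResult:
    """Execute the full study pipeline for one synthetic cohort."""
    config.validate()
    gen: GeneratorConfig = config.generator
    root = np.random.SeedSequence(config.seed)
    cohort_seed, morph_seed, *subject_seeds = root.spawn(2 + gen.n_subjects)

    profiles = generate_cohort_profiles(gen, cohort_seed)
    morphometry = generate_morphometry_table(profiles, gen, np.random.default_rng(morph_seed))

    subjects: dict[str, SubjectOutcome] = {}
    for profile, seed in zip(profiles, subject_seeds):
        try:
            subjects[profile.subject_id] = run_subject(profile, config, seed)
        except Exception as exc:
            raise RuntimeError(
                f"pipeline failed for subject {profile.subject_id}: {exc}") from exc
        log.info("subject %s: theta=%.2f Hz, success_L1=%.3f uV",
                 profile.subject_id, subjects[profile.subject_id].individual_theta_hz,
                 subjects[profile.subject_id].curves.success_L1)

    anova_block, anova_session, early_final, regressions = cohort_statistics(
        subjects, morphometry, config)

    rows = []
    for sid, outcome in subjects.items():
        for pos, label in enumerate(SEGMENT_LABELS):
            rows.append((sid, "L1", label, outcome.curves.L1[pos]))
        for s in range(8):
            rows.append((sid, "L2", f"session_{s + 1}", outcome.curves.L2[s]))
    curves_long = pd.DataFrame(rows, columns=["subject_id", "index_type",
                                              "position", "value_uv"])

    result = StudyResult(config=config, profiles=profiles, morphometry=morphometry,
                         subjects=subjects, curves_long=curves_long,
                         anova_block=anova_block, anova_session=anova_session,
                         early_final=early_final, regressions=regressions)
    if config.out_dir:
        write_outputs(result, Path(config.out_dir))
    return result


def _stats_payload(result: StudyResult) -> dict:
    return {
        "anova_block": dataclasses.asdict(result.anova_block),
        "anova_session": dataclasses.asdict(result.anova_session),
        "early_final_correlation": dataclasses.asdict(result.early_final),
        "regressions": {name: dataclasses.asdict(reg)
                        for name, reg in result.regressions.items()},
    }


def write_outputs(result: StudyResult, out_dir: Path) -> None:
    """Persist all cohort outputs plus the resolved configuration."""
    out_dir.mkdir(parents=True, exist_ok=True)
    fio.write_profiles(result.profiles, out_dir / "profiles.json")
    fio.write_roi_table(result.morphometry, out_dir / "morphometry.tsv")
    fio.write_sessions({sid: o.sessions for sid, o in result.subjects.items()},
                       out_dir / "sessions.json")
    result.curves_long.to_csv(out_dir / "curves.tsv", sep="\t", index=False)
    result.success.to_csv(out_dir / "success.tsv", sep="\t")
    (out_dir / "stats.json").write_text(json.dumps(_stats_payload(result), indent=1))
    save_config(result.config, out_dir / "config_resolved.yaml")
    _write_run_log(result.config, out_dir / "run_log.txt")


def _write_run_log(config: StudyConfig, path: Path) -> None:
    import scipy

    lines = [
        f"seed: {config.seed}",
        f"numpy: {np.__version__}", f"scipy: {scipy.__version__}",
        f"pandas: {pd.__version__}",
        "resolved config: see config_resolved.yaml",
    ]
    path.write_text("\n".join(lines) + "\n")
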