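"""Step 3 — run the eight-session neurofeedback protocol per subject.

For each subject: an EOG calibration fixes the individualized artifact band,
then each session's EEG is pushed through the online chain (sliding 2-s
Hamming FFT every 200 ms, artifact-window rejection, baseline-referenced
color mapping), yielding the per-segment mean theta amplitudes.
"""

import warnings

import numpy as np

import fmtheta as fm
from fmtheta import io as fio

from common import RESULTS, study_config, subject_seeds

config = study_config()
profiles = fio.read_profiles(RESULTS / "profiles_profiled.json")

records: dict[str, list] = {}
n_rejected = n_total = 0
with warnings.catch_warnings():
    warnings.simplefilter("ignore")            # low-quality segment warnings
    for profile, seed in zip(profiles, subject_seeds(config)):
        streams = [np.random.default_rng(s) for s in seed.spawn(10)]
        calibration = fm.generate_calibration_recording(
            profile, streams[1], config.generator,
            duration_s=config.calibration_duration_s)
        profile.artifact_band = fm.calibrate_eog(
            calibration, threshold_quantile=config.eog_threshold_quantile)
        sessions = []
        for s in range(1, 9):
            eeg = fm.generate_session_eeg(profile, s, streams[1 + s], config.generator)
            record, _ = fm.run_session(profile, eeg, profile.artifact_band,
                                       session_index=s)
            sessions.append(record)
            n_rejected += record.n_windows_rejected.sum()
            n_total += (record.n_windows_used + record.n_windows_rejected).sum()
        records[profile.subject_id] = sessions

fio.write_sessions(records, RESULTS / "sessions.json")
fio.write_profiles(profiles, RESULTS / "profiles_trained.json")
print(f"trained {len(records)} subjects x 8 sessions; "
      f"{100 * n_rejected / n_total:.1f}% of windows rejected as eye artifacts")
print(f"wrote {RESULTS / 'sessions.json'}")
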