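"""Shared setup for the numbered analysis drivers.

The drivers run a 40-subject synthetic cohort through the full protocol.
Segments are shortened from the protocol's 300 s to 20 s so the whole
analysis runs on a laptop in minutes; the amplitude law and all downstream
statistics are independent of segment duration (it only sets the number of
2-s windows averaged per segment).
"""

from pathlib import Path

import fmtheta as fm

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 7


def study_config(n_subjects: int = 40, seed: int = SEED) -> fm.StudyConfig:
    return fm.StudyConfig(
        generator=fm.GeneratorConfig(segment_duration_s=20.0, n_subjects=n_subjects),
        seed=seed)


def subject_seeds(config: fm.StudyConfig):
    """The same per-subject seed streams run_study would use."""
    import numpy as np

    root = np.random.SeedSequence(config.seed)
    _, _, *seeds = root.spawn(2 + config.generator.n_subjects)
    return seeds
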