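"""Learning indices quantifying neurofeedback training success.

Two indices, both in microvolt:

* L1 (within-session dynamics): for each of the 8 segments, the mean over
  sessions of the segment amplitude minus the reference start-baseline
  amplitude.  By default the reference is session 1's start baseline
  (constant across sessions); per-session own baselines are available as an
  option.
* L2 (across-session maintenance): per session, the mean amplitude over
  training blocks 1-6 minus the same quantity for session 1; L2 of session 1
  is therefore 0 by construction.

Scalar success summaries: ``success_L1`` (mean L1 over the six blocks),
``early_success_L2`` (session 2) and ``final_success_L2`` (session 8).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SEGMENT_LABELS
from .feedback import SessionRecord

N_SESSIONS = 8
_BLOCK_COLS = slice(1, 7)       # block_1 .. block_6 within SEGMENT_LABELS


@dataclass
class LearningCurves:
    """Per-subject learning curves and scalar success summaries."""

    L1: np.ndarray              # 8 values, one per segment
    L2: np.ndarray              # 8 values, one per session
    segment_labels: tuple[str, ...] = SEGMENT_LABELS

    @property
    def success_L1(self) -> float:
        return float(self.L1[_BLOCK_COLS].mean())

    @property
    def early_success_L2(self) -> float:
        return float(self.L2[1])

    @property
    def final_success_L2(self) -> float:
        return float(self.L2[7])


def _amplitude_matrix(sessions: list[SessionRecord]) -> np.ndarray:
    """Sessions x segments amplitude matrix, validated and ordered."""
    ordered = sorted(sessions, key=lambda s: s.session_index)
    if [s.session_index for s in ordered] != list(range(1, N_SESSIONS + 1)):
        raise ValueError(
            f"need sessions 1..{N_SESSIONS}, got {[s.session_index for s in sessions]}")
    amp = np.vstack([s.segment_amp_uv for s in ordered])
    if not np.all(np.isfinite(amp)):
        s_idx, seg_idx = np.argwhere(~np.isfinite(amp))[0]
        raise ValueError(
            f"missing amplitude in session {s_idx + 1}, segment "
            f"{SEGMENT_LABELS[seg_idx]}")
    return amp


def compute_L1(sessions: list[SessionRecord],
               reference: str = "first_session") -> np.ndarray:
    """Within-session learning index: 8 segment values in uV."""
    amp = _amplitude_matrix(sessions)
    if reference == "first_session":
        ref = np.full(N_SESSIONS, amp[0, 0])
    elif reference == "own_start":
        ref = amp[:, 0]
    else:
        raise ValueError("reference must be 'first_session' or 'own_start'")
    return (amp - ref[:, None]).mean(axis=0)


def compute_L2(sessions: list[SessionRecord],
               blocks_only: bool = True) -> np.ndarray:
    """Across-session learning index: 8 session values in uV."""
    amp = _amplitude_matrix(sessions)
    summary = amp[:, _BLOCK_COLS].mean(axis=1) if blocks_only else amp.mean(axis=1)
    return summary - summary[0]


def compute_curves(sessions: list[SessionRecord], l1_reference: str = "first_session",
                   l2_blocks_only: bool = True) -> LearningCurves:
    return LearningCurves(L1=compute_L1(sessions, l1_reference),
                          L2=compute_L2(sessions, l2_blocks_only))


def success_scores(curves: LearningCurves) -> tuple[float, float, float]:
    """(success_L1, early_success_L2, final_success_L2)."""
    return curves.success_L1, curves.early_success_L2, curves.final_success_L2
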