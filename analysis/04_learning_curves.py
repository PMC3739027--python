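"""Step 4 — learning indices and training-effect ANOVAs.

L1 (within-session dynamics, referenced to session 1's start baseline) and
L2 (across-session change of the block mean) are computed per subject, then
tested with one-way repeated-measures ANOVAs over the factor block (8 levels)
and session (8 levels), mirroring the study's inference.
"""

import dataclasses
import json

import numpy as np
import pandas as pd

import fmtheta as fm
from fmtheta import io as fio

from common import RESULTS

records = fio.read_sessions(RESULTS / "sessions.json")
curves = {sid: fm.compute_curves(sessions) for sid, sessions in records.items()}

rows = []
for sid, c in curves.items():
    for label, value in zip(c.segment_labels, c.L1):
        rows.append((sid, "L1", label, value))
    for s, value in enumerate(c.L2, start=1):
        rows.append((sid, "L2", f"session_{s}", value))
pd.DataFrame(rows, columns=["subject_id", "index_type", "position",
                            "value_uv"]).to_csv(RESULTS / "curves.tsv",
                                                sep="\t", index=False)

success = pd.DataFrame(
    {sid: (c.success_L1, c.early_success_L2, c.final_success_L2)
     for sid, c in curves.items()},
    index=["success_L1", "early_success_L2", "final_success_L2"],
).T.rename_axis("subject_id")
success.to_csv(RESULTS / "success.tsv", sep="\t")

l1 = np.vstack([c.L1 for c in curves.values()])
l2 = np.vstack([c.L2 for c in curves.values()])
anova_block = fm.rm_anova_oneway(l1)
anova_session = fm.rm_anova_oneway(l2)
(RESULTS / "anova.json").write_text(json.dumps(
    {"block": dataclasses.asdict(anova_block),
     "session": dataclasses.asdict(anova_session)}, indent=1))

print("mean L1 (uV):", np.round(l1.mean(0), 3).tolist())
print("mean L2 (uV):", np.round(l2.mean(0), 3).tolist())
print(f"ANOVA block:   F({anova_block.df1}, {anova_block.df2}) = "
      f"{anova_block.F:.2f}, p = {anova_block.p:.2e}")
print(f"ANOVA session: F({anova_session.df1}, {anova_session.df2}) = "
      f"{anova_session.F:.2f}, p = {anova_session.p:.2e}")
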