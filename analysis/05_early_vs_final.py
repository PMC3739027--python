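"""Step 5 — does early training success predict the final outcome?

One-tailed Pearson correlation between the L2 change at session 2 (early
success) and at session 8 (final success), preceded by Kolmogorov-Smirnov
normality checks of both variables.
"""

import dataclasses
import json

import pandas as pd

import fmtheta as fm

from common import RESULTS

success = pd.read_csv(RESULTS / "success.tsv", sep="\t", index_col=0)
result = fm.pearson_one_tailed(success["early_success_L2"].to_numpy(),
                               success["final_success_L2"].to_numpy())
(RESULTS / "early_vs_final.json").write_text(
    json.dumps(dataclasses.asdict(result), indent=1))

print(f"KS normality p (early, final): {result.ks_p[0]:.3f}, {result.ks_p[1]:.3f}")
print(f"early vs final training success: r = {result.r:.3f}, "
      f"t({result.df}) = {result.t:.2f}, one-tailed p = {result.p_one_tailed:.2e}")
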