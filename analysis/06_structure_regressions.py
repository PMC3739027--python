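"""Step 6 — predict training success from regional brain morphometry.

Four stepwise multiple regressions (criterion L1 or L2-based success; gray-
or white-matter predictors, volume and concentration in one model), with
standardized betas, adjusted R-squared and the model F test.
"""

import dataclasses
import json

import pandas as pd

import fmtheta as fm
from fmtheta import io as fio
from fmtheta.rois import gm_columns, wm_columns

from common import RESULTS

roi = fio.read_roi_table(RESULTS / "morphometry.tsv")
success = pd.read_csv(RESULTS / "success.tsv", sep="\t", index_col=0)
order = success.index
models = {
    "L1_gm": (gm_columns(), "success_L1"),
    "L1_wm": (wm_columns(), "success_L1"),
    "L2_gm": (gm_columns(), "final_success_L2"),
    "L2_wm": (wm_columns(), "final_success_L2"),
}

results = {}
for name, (cols, criterion) in models.items():
    res = fm.stepwise_regression(roi.loc[order, cols],
                                 success[criterion].to_numpy())
    results[name] = dataclasses.asdict(res)
    if res.selected:
        betas = ", ".join(f"{k}: {v:+.2f}" for k, v in res.beta_std.items())
        print(f"{name}: F({res.df1}, {res.df2}) = {res.F:.2f}, "
              f"adj R^2 = {res.adj_r2:.3f}, beta_std {{{betas}}}")
    else:
        print(f"{name}: no predictor met the entry criterion (n.s.)")

(RESULTS / "regressions.json").write_text(json.dumps(results, indent=1))
print(f"wrote {RESULTS / 'regressions.json'}")
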