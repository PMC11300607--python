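#!/usr/bin/env python
"""Summarise the hypoxia-conditioned movement analysis of the pipeline run.

Prints the per-category district rank-difference quantiles (eastward
displacement under hypoxic initial conditions) and the mixed-model
estimates of the four logger-matched movement metrics.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1] / "results" / "run"

q = pd.read_csv(ROOT / "rank_diff_quantiles.csv")
print("district rank-difference quantiles by initial DO condition:")
print(q.to_string(index=False))

est = pd.read_csv(ROOT / "estimates.csv")
print("\nmixed-model category contrasts (normoxic - hypoxic):")
for r in est.itertuples():
    star = "*" if r.significant else " "
    print(f"  {r.metric:<12} hypoxic={r.mean_hypoxic:7.3f}  "
          f"normoxic={r.mean_normoxic:7.3f}  diff={r.difference:7.3f} "
          f"[{r.ci_low:.3f}, {r.ci_high:.3f}]{star}")
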