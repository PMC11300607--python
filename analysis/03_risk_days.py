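#!/usr/bin/env python
"""Examine the risk-days surface and the published catch percentiles.

Reports the top time-area risk cells of the pipeline run and, separately,
ranks the published mean-catch matrix (2019-2022 demersal gears) to show
the November western-district endpoint at the 100th percentile.
"""

from pathlib import Path

import pandas as pd

import riskdays as rd

ROOT = Path(__file__).resolve().parents[1] / "results"

risk = pd.read_csv(ROOT / "run" / "risk_days.csv")
top = risk.sort_values("risk_days", ascending=False).head(5)
print("top risk-days cells (synthetic study):")
for r in top.itertuples():
    print(f"  month {r.month:>2}  {r.smu_id:<8} mean_days={r.mean_days:6.2f} "
          f"percentile={r.percentile:.2f}  risk_days={r.risk_days:6.2f}")

refuge = risk[(risk["month"] == 9) & (risk["smu_id"] == "4 NY/PA")]
if len(refuge):
    r = refuge.iloc[0]
    print(f"September eastern refuge: mean_days={r['mean_days']:.2f}, "
          f"risk_days={r['risk_days']:.2f}")

ranked = rd.percentile_ranks(rd.published_mean_catch())
ranked.to_csv(ROOT / "published_catch_percentiles.csv", index=False)
cell = ranked.set_index(["month", "smu_id"]).loc[(11, "1 OH")]
n = int((ranked["mean_catch_lb"] > 0).sum())
print(f"published catch matrix: {n} nonzero cells; "
      f"November '1 OH' = {cell['mean_catch_lb']:.0f} lb "
      f"-> percent rank {100 * cell['percentile']:.0f}%")
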