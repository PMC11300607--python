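#!/usr/bin/env python
"""Generate the default synthetic study bundle.

Writes the full input bundle (detections, receivers, tags, SMU polygons,
catch, daily DO) plus ground-truth tracks/occupancy to results/bundle/.
Seeded and deterministic; downstream scripts read these files.
"""

from pathlib import Path

import riskdays as rd

OUT = Path(__file__).resolve().parents[1] / "results" / "bundle"

config = rd.ScenarioConfig(seed=1)
bundle = rd.simulate_scenario(config)
paths = rd.write_bundle(bundle, OUT)

print(f"scenario seed={config.seed}: {config.n_fish} fish, {config.n_months} months")
print(f"receivers: {len(bundle.receivers)} "
      f"({int(bundle.receivers['has_logger'].sum())} with DO loggers)")
print(f"detections: {len(bundle.detections)}")
print(f"catch records: {len(bundle.catch)} "
      f"(years {config.catch_years[0]}-{config.catch_years[1]})")
print(f"wrote {len(paths)} files to {OUT}")
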