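# riskdays

Time-area exploitation risk for acoustically tagged migratory fish.

Migratory fish that cross management and jurisdictional boundaries meet
abruptly different fisheries along the way, so their risk of capture is a
moving target in both space and time. `riskdays` implements a complete,
tested pipeline for quantifying that risk from passive acoustic telemetry:
the motivating system is Lake Whitefish (*Coregonus clupeaformis*) in a
large seasonally stratified lake divided into spatial management units
(SMUs) — four west-to-east districts crossed with national/state
jurisdictions — where fish spawn in the west in November, summer in the
central basin, and shift east when bottom hypoxia develops under
stratification.

The pipeline:

1. **QC** (`io_qc`) — read detections/receivers/tags/SMU polygons, flag
   false detections with the minimum-lag criterion (a detection is valid
   iff another detection of the same tag on the same receiver falls within
   a configurable window, default 3600 s), censor tag fates (tags never
   detected, or with a valid-detection span under 35 days, are excluded),
   and assign receivers to SMUs by point-in-polygon.
2. **Residency** (`residency`) — attribute every day between a tag's first
   and last valid detection to month × SMU cells. The gap between
   consecutive detections in different SMUs is split evenly at its
   temporal midpoint, then partitioned across calendar-month boundaries,
   so allocated days sum exactly to the detection span. Cells are averaged
   over the fish at large each month and normalised to proportions; a
   Gaussian random-intercept trend of ordinal SMU code on month (weighted
   by detections, tags as random effects) summarises the migration wave.
3. **Catch risk** (`catch_risk`) — build the month × SMU mean commercial
   catch matrix (per-year month sums averaged across years), convert the
   nonzero cells to cumulative rank percentiles — percentile(c) =
   (# nonzero cells ≤ c)/(# nonzero cells), zeros excluded — and form
   **risk days = mean residency days × catch percentile**, the pipeline's
   exploitation-risk proxy. Zero-catch cells are refuges: zero risk no
   matter the residency.
4. **Hypoxia response** (`hypoxia_movement`, `stats_models`) — extract
   between-SMU transitions censored to < 21 days during the stratified
   window (June–October), code each by district rank difference
   (destination − origin ordinal; + = eastward, 0 = latitudinal) and by
   the dissolved-oxygen category of the origin SMU on departure day
   (hypoxic < 2 mg/L), compare the rank-difference distributions by
   quantiles, and fit Gaussian random-intercept (tag) models comparing
   four logger-matched movement metrics between DO categories.
5. **Synthetic study** (`synthetic_data`) — a seeded agent-based generator
   (8-SMU lake, receiver grid, seasonal migration kernel, central-basin
   summer hypoxia with configurable avoidance strength, bursty detection
   process with ±0.9 m depth-sensor noise, Poisson-lognormal catch around
   the published mean-catch profile) with full ground truth, so every
   stage has a recovery test against known truth.

## Worked example

The numbered scripts under `analysis/` run the study end to end:

```sh
python analysis/01_simulate_study.py   # writes results/bundle/
python analysis/02_run_pipeline.py     # writes results/run/
python analysis/03_risk_days.py
python analysis/04_hypoxia_response.py
```

On the default 50-fish, 12-month scenario (seed 1) this prints:

```
99810 detections read, 80836 valid after QC
tags: 45 retained, 5 excluded
residency records: 1761; censored transitions: 880

top risk-days cells (synthetic study):
  month 11  1 OH     mean_days= 24.11 percentile=1.00  risk_days= 24.11
  month  3  2 ON     mean_days=  7.88 percentile=0.90  risk_days=  7.08
  ...
September eastern refuge: mean_days=5.40, risk_days=0.27
published catch matrix: 59 nonzero cells; November '1 OH' = 31265 lb -> percent rank 100%

district rank-difference quantiles by initial DO condition:
initial_condition   n  min  q25  median  q75  max
          hypoxic 105   -1    1       1    1    2
         normoxic 775   -2   -1       0    1    2
```

Reading: the November spawning aggregation in the south-western SMU
("1 OH") coincides with the 100th-percentile trap-net catch, making it the
dominant risk cell (24 risk days); the eastern district in September holds
fish but almost no catch — a refuge; and transitions that start in hypoxic
water are displaced east (median rank difference +1) while normoxic
starts show no longitudinal bias (median 0). The logger-matched mixed
models show the same response at fine scale: fish under hypoxic initial
conditions changed receivers on 67% of successive day pairs versus 42%
under normoxia, and gained dissolved oxygen when they moved.

A command-line interface mirrors the scripts:
`riskdays simulate|qc|residency|risk|hypoxia|run --help`.

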