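# Methods

This note documents the models and procedures implemented in `riskdays`,
the parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical decisions a maintainer should know
about.

## Detection QC

**False-detection filter (minimum lag).** Acoustic receivers occasionally
log spurious code detections from signal collisions and ambient noise;
these are overwhelmingly isolated in time. A detection is flagged valid
iff another detection of the same tag on the same receiver lies within
`min_lag_max_s` of it. The window defaults to 3600 s, the conventional
one-hour setting for this filter family; it is configurable. Flags are a
pure function of the (tag, receiver, timestamp) triples, so the filter is
idempotent, and flagged rows are retained rather than dropped.

**Tag fates.** A tag's at-large span is the interval between its first and
last *valid* detections (the filter therefore runs first). Tags never
detected, or with spans under `min_days` (default 35 d), are excluded as
presumed mortalities or failures; a non-blank `fate_override` in the tag
table (e.g. "harvested") excludes a tag unconditionally — no automatic
harvest detection is attempted. Every tag appears exactly once in the
fate table.

**SMU assignment.** Receivers are assigned to spatial management units by
point-in-polygon (`shapely.covers`, boundary-inclusive). A receiver on a
shared boundary goes to the SMU with the smaller district ordinal, ties
broken by lexicographic `smu_id` — deterministic and logged. All
timestamps are normalised to UTC and calendar months are evaluated in UTC.

## Residency allocation

Between consecutive detections of a tag, time must be attributed to SMUs
without observing the fish. The rule: the interval is split at its
temporal midpoint; the first half accrues to the origin SMU, the second
to the destination (the whole interval when both ends share an SMU), and
each accrued sub-interval is then partitioned across calendar-month
boundaries. Implementing the "even split" as a *temporal* midpoint (rather
than halving the total gap duration after the fact) keeps SMU attribution
and month partitioning mutually consistent; the two readings coincide
whenever no month boundary crosses the gap. The construction conserves
time exactly: per tag, allocated days sum to the detection span (verified
to 1e-6 d). Arithmetic is done on integer nanoseconds; the midpoint uses
integer halving, so conservation is exact by construction. Gaps are split
regardless of length here — the 21-day censor belongs to the transition
analysis only.

Monthly summaries average per-tag-year cell totals over the (tag, year)
pairs at large during any part of the month — a tag at large but absent
from an SMU contributes a zero to that cell — and are normalised so each
month's proportions sum to 1. When a tag spans multiple years, averaging
is over tag-year pairs (not pooled within tag); the choice matters little
at the simulated scale but is fixed and documented here.

The descriptive seasonal trend fits ordinal SMU code (1..n, west to east)
on month as a continuous covariate with a Gaussian random intercept per
tag. Weighting "by total detections" is implemented by fitting on
per-detection rows — each detection is one observation, which is exactly
frequency weighting (`weighted=False` collapses to one row per
tag × month × SMU cell). The reported 95% band is the fixed-effects Wald
band. A boundary or singular mixed fit falls back to an OLS fixed-effects
fit, flagged in the output.

## Catch percentiles and risk days

Catch (pounds, demersal gears) is summed per month within each year and
averaged across the configured year range, with absent year × cell
combinations counting as zero. Among the n nonzero cells of the resulting
month × SMU matrix, the cumulative rank percentile of cell c is
(# nonzero cells with value ≤ value(c)) / n; zero cells carry a null
percentile. Ties share the maximal ("≤"-counted) rank, so an all-equal
matrix degenerates to 1.0 and the maximum cell is always 1.0. Percentiles
are fractions in (0, 1] internally (keeping the risk-days product in day
units) and rendered as integer percent in reports. Scale invariance holds
by construction.

**Risk days** = mean residency days × percentile, per month × SMU cell;
null percentile (zero catch) or zero residency gives zero. The statistic
is a relative exploitation-risk proxy, not an absolute capture
probability: it assumes catch quantity proxies fishing pressure and that
catchability is comparable across the gears pooled into the matrix.

The packaged table `data/lake_whitefish_mean_catch_2019_2022.csv` is the
published 2019–2022 mean monthly demersal-gear catch of Lake Whitefish by
SMU (Lake Erie Committee binational catch reporting). Its 59 nonzero
cells peak at 31,265 lb in November in "1 OH"; ranking the table puts that
cell at the 100th percentile. The interior percentiles printed alongside
the published table are *not* reproducible from the 59 printed means
under any single rank convention (they were evidently computed on a finer,
unpublished matrix), so only the maximum-cell endpoint and the monotone
ordering are treated as checkable.

## Hypoxia-conditioned movement

Bottom dissolved oxygen below 2.0 mg/L defines hypoxia (strict
inequality; 2.0 is normoxic; missing readings are "unknown"). During the
stratified window (June–October by default), consecutive valid detections
of a tag in different SMUs with a gap strictly under 21 days become
transitions; longer gaps say little about a response to departure
conditions. Each transition is coded by district rank difference
(destination − origin ordinal; latitudinal moves within a district are 0)
and by the DO category of the origin SMU on the departure date.
Rank-difference distributions are compared by quantiles per category;
"unknown" transitions are excluded from contrasts but counted.

The fine-scale analysis matches depth-sensing detections to DO loggers on
the receivers themselves at tag-day resolution: the day's first detection
is its representative (the published analysis does not state which
detection anchored its match; first-of-day is fixed here and documented).
Four metrics result: receiver-bottom-minus-tag depth difference (negative
values — tags apparently below the bottom — are retained as-is; they are
known detection-at-a-distance and ±0.9 m sensor-accuracy artifacts),
change in tag depth and change in logger DO across successive tag-days on
*different* logger receivers (category from the earlier receiver), and a
0/1 moved indicator per successive day pair. "Proportion of days moved"
is defined at tag-day resolution to match the metric's name.

## Category mixed models

Each metric is modelled as value = μ_category + b_tag + ε with
b_tag ~ N(0, σ²_tag), fitted by REML (statsmodels MixedLM) in a
cell-means parameterisation. The 0/1 moved metric is fitted on the same
Gaussian contract (a linear probability model), matching the descriptive
treatment of proportions. The difference is normoxic − hypoxic by fixed
convention. Confidence intervals use the large-sample normal (Wald)
approximation; the fitting backend supports neither Kenward–Roger nor
Satterthwaite small-sample df, so the output records
`df_method="normal"`. At the simulated sizes (tens of tags) the normal
approximation is adequate: the coverage experiment (200 replicates of 50
tags × 10 obs/category, true difference 2.0, tag and residual sd 1.0)
lands inside the 93–97% band.

Degenerate inputs (zero total variance) return the raw means with a
[0, 0] difference interval. A boundary fit — estimated tag variance
indistinguishable from zero — is refit as plain OLS and flagged: the
MixedLM optimizer can return corrupt fixed effects on the variance
boundary while reporting convergence, and with σ²_tag = 0 the
fixed-effects model is the correct reduction anyway.

## Synthetic study generator

The generator emulates the study system's phenomenology, not its
hydrodynamics: a rectangular lake (≈ 364 × 177 km at the chosen
latitudes) split into four west-to-east districts × north/south
jurisdictions = 8 SMUs; a receiver grid at 10 km spacing (648 receivers),
with DO loggers on every central-basin (districts 2–3) receiver; district
mean bottom depths of 7.4 / 18.5 / 20.0 / 24.4 m west to east with smooth
positional undulation.

**Movement.** Fish move at most one district per day. From January
through May the monthly kernel targets the central basin; November
targets district 1 (with a southward side pull, producing the
south-western spawning aggregation); December re-disperses east. The
summer window (June–October) is an *unbiased* random walk
(p = 0.15/2 east, 0.15/2 west per day): the eastward summer shift in the
emulated system is produced entirely by the avoidance term — when a
fish's current SMU is hypoxic that day, its eastward step probability is
multiplied by (1 + avoidance_strength), default 5. This symmetry is
deliberate: a built-in eastward summer drift would confound the
hypoxic/normoxic contrast through unequal origin-district composition,
making the avoidance-off control uninterpretable.

**DO field.** Central-basin SMU bottom DO follows a sin² drawdown from a
base of 8.5 mg/L to 1.0 mg/L at peak (July–September window) scaled by
`severity`; outer districts never leave normoxia. Logger readings are the
SMU value plus N(0, 0.3) noise.

**Detections.** The fish is snapped to one receiver of its SMU
(re-stationing with p = 0.2/day and on every SMU change); with ~1 km
detection range against 10 km spacing, only that receiver hears it.
Detections arrive in encounter bursts as on real arrays: ≥ 1 burst per
day (mean 4), a burst logs on average 3 transmissions 120 s apart, and
each is retained with probability `detection_p_per_transmission`
(default 0.5, ≈ 6 detections/fish-day — the same order as the motivating
data set). The burst structure is what makes the minimum-lag filter
meaningful on synthetic data: thinned singleton bursts are flagged, dense
bursts survive. Recorded depth adds N(0, 0.9 m) sensor noise to the true
demersal depth (district bottom − 1 m ± 0.5 m). Ten percent of tags fall
silent within the first 5–25 days to exercise the fate censor; tag
models/battery lives follow the three release-site groups of the
motivating study.

**Catch.** Yearly draws for 2019–2022 are Poisson with a lognormal
(σ = 0.5, mean-1) multiplicative intensity around the published
mean-catch profile, so the November district-1-south cell has the largest
expected value by construction while year-to-year noise is realistic.

**What the generator does not emulate** — and hence what passing recovery
tests do and do not show: continuous 2-D movement (space is SMU-level),
temperature-dependent habitat choice, detection-range variation with
conditions, receiver outages, clock drift, multi-year tracks, and the
river corridor / ninth-jurisdiction geometry of the real system. Recovery
results demonstrate the pipeline's correctness under known truth, not the
field estimates' accuracy.

## Problem sizes and runtimes

The default scenario is 50 fish × 12 months (≈ 100k detections), chosen
so a full pipeline run takes ~2 s. The test suite's experiments use: 50
random tracks for conservation and oracle equivalence; 100 random
matrices for percentile properties; one 50-fish scenario at detection
probability 1 for residency recovery (tolerance 1 day/month/SMU; observed
max error ≈ 0.1); 200 fish per arm for the avoidance on/off contrast; 200
replicates for mixed-model coverage; and 100 seeded default scenarios for
the top-risk-cell frequency check (November "1 OH" must top ≥ 95). The
heavier checks complete in about a minute total.

## Known limitations

- Risk days inherit every caveat of catch-as-effort: no gear
  standardisation, no effort data, retrospective only.
- The residency rule attributes gap time to the two bounding SMUs only;
  a fish transiting a third SMU between detections is invisible.
- The transition analysis conditions on origin-SMU DO on the departure
  date; within-SMU DO heterogeneity below the SMU scale is not modelled.
- Wald intervals slightly undercover at very small tag counts; with ≥ 2
  but < ~10 tags, treat the mixed-model CIs as descriptive.
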