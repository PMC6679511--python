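# Methods

This note documents the statistical models implemented in `homesense`, the
parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical conventions adopted
where the mathematics alone does not fix a choice.

## Event preprocessing

Raw input is a CSV of timestamped sensor events (UTC instants; presence
sensors emit `on`/`off`, momentary sensors emit `detect`). All calendar
logic — day boundaries, time bins, night windows — runs on the subject's
local clock, configurable per pipeline (`timezone`, default UTC). Bins are
half-open local-time intervals; on a DST transition the day trace keeps the
true number of bins of the local day (46 or 50 half-hour bins instead of
48) rather than forcing a fixed length, so no phantom activations appear.

**Sessionization** merges `on`/`off` pairs of one presence sensor into rest
intervals: gaps shorter than `gap_merge` (default 15 min) are bridged, and
merged intervals shorter than `min_rest_duration` (default 10 min) are
discarded as incidental presences (sitting on the bed to dress, say) rather
than rest. Both defaults are conventions of this package, chosen so that a
brief nighttime exit does not split a sleep episode while a walk-by
pressure blip does not count as a nap; both are configurable. Malformed
sequences are handled leniently because packet loss is a fact of wireless
deployments: a repeated `on` extends the open interval, an orphan `off` is
dropped with a logged warning, and a dangling `on` at end-of-stream closes
at the last observed event and is marked `truncated`.

**Rest-end confirmation** fuses other sensors: an interval's end is
`confirmed` when a PIR or contact event fires within `confirm_window`
(default 10 min) afterwards, evidence that the subject actually got up
rather than the pad losing contact.

**Visit counting** clusters toilet detections separated by less than
`visit_gap` (default 5 min) into single visits; a visit belongs to the
local date of its first detection. Days inside the covered range with no
visits count zero — absence of events is data here, not missingness. The
optional night tally uses a half-open local window, default 00:00–06:00 (a
convention; no standard definition exists).

**Day-trace binning** marks bin j active iff the summed active time inside
the bin reaches `tmin` (default 5 of 30 min). The threshold filters
walk-bys while catching genuine naps; it is configurable and must not
exceed the bin width. Binning is invariant to event order and to splitting
an interval at interior points. A rest spanning midnight contributes to
both days' traces; any per-day *duration* report would need an attribution
rule, but binning needs none.

**Transmission quality.** Sensors buffer readings locally and transmit
hourly bursts; a missed burst delays data (retransmitted next period), and
only an outage exceeding the roughly one-day local buffer loses data
("severe"). Day-level percentages are reported conservatively: the
ideal-day share is *floored* at one decimal and the severe share *ceiled*
at two decimals, so reliability is never overstated and failures never
understated. (Computed exactly with rational arithmetic; e.g. 8231/8970 →
91.7%, 17/8970 → 0.19%.)

## Rolling Poisson regression

Daily counts in a trailing window of W = 30 days are modeled as independent
Poisson with log-link mean over four factors (bias; linear ramp scaled to
[0, 1]; intermediate indicator of days W−A−I+1…W−A; abrupt indicator of the
last A days), A = 5 and I = 10 by default. I is a package convention —
long enough to absorb a recently passed step, short enough to leave ≥ 15
clean baseline days. The linear covariate's [0, 1] scaling makes its
coefficient the log fold-change across the whole window, so all effects are
reported on one multiplicative scale, 100(e^β − 1) percent relative to
baseline.

Fitting is maximum likelihood via IRLS (statsmodels GLM); convergence is
taken from the fitter and reported honestly. Missing days are dropped
pairwise from the likelihood, never imputed — the setting is unsupervised
and there is no ground truth to impute from. In the rolling loop, windows
containing missing days are skipped by default (`min_usable = W`);
passing a smaller `min_usable` enables fits on partially observed windows.
Non-identifiable factors — an indicator never active in the window, or
active only on zero-count days, where the MLE diverges — are excluded
before fitting and reported, as is residual collinearity.

**Factor selection.** "Keep only significant factors" is implemented as a
single screen: fit the full model, drop every non-bias factor with Wald
p ≥ α (default 0.05) at once, refit with the survivors. Under a
constant-rate null this retains each factor at rate ≈ α — the screen is
calibrated, which matters because retention is exactly what triggers
caregiver alerts. Classical backward elimination (drop the single worst
factor, refit, repeat) is also provided (`method="backward"`); it is
slightly anti-conservative (measured ≈ 6–6.5% false retention per factor at
α = 5%) because factors are retested after collinear companions leave. The
same collinearity explains a power asymmetry of the screen: the linear +
intermediate columns can nearly reproduce a last-A-days step, so a genuine
abrupt change at a low baseline rate may need a few days inside the abrupt
span before its full-model p-value clears α. Alerts are per-day flags;
persistence rules are left to reporting, and re-fitting each day means an
absorbed anomaly adjusts subsequent predictions instead of re-triggering.

**Unexplained days.** The last day's count is compared with the equal-tailed
integer interval [lo, hi] where lo is the smallest k with CDF(k) ≥
(1−level)/2 and hi the smallest k with CDF(k) ≥ 1−(1−level)/2; the interval
always carries at least `level` (default 95%) probability mass, so the
false-flag rate is at most 1−level (conservative, because the Poisson is
discrete; measured ≈ 2–3% at rate 4). By default the last day is inside the
fitted window ("the last W counts are modeled") and scored in-sample;
`holdout_last=True` excludes it from the likelihood and scores it
out-of-sample.

**Cosine similarity** between count series uses the convention
sim(0, 0) = 1 and sim(0, x≠0) = 0 — identical emptiness is maximal
agreement. The cosine is undefined at zero norm, so some convention is
required; this one is used consistently in clustering as well.

## Sensor profiles

Each 30-min bin is Bernoulli(p) across days, assumed independent between
days and (for novelty scoring) between bins; p̂ = n_pos/N is the MLE.
Intervals are Wilson score by default — they behave well near p̂ ∈ {0, 1}
at small N and produce the expected asymmetric bands; Clopper–Pearson
(`ci="beta"`) is available where guaranteed-coverage (conservative)
intervals are preferred. The 30-min width is the sleep-analysis trade-off
between temporal resolution and estimate noise.

**Comparison.** Each bin contributes a 2×2 table (active/inactive days in
group A vs. B), tested by Pearson chi-square without continuity correction,
or Fisher's exact test when any expected cell is < 5 (the exact test also
handles degenerate empty-margin tables, returning p = 1). Raw p-values are
Holm–Bonferroni-adjusted across all bins of the day, controlling the
family-wise error rate at α.

**Clustering.** Binary day traces are clustered agglomeratively (average
linkage by default, complete available) under cosine distance with the
zero-vector convention above. For each candidate k in 2…k_max (default 8),
clusters with fewer than n_SAM = 5 member days are invalid; the selected k
maximizes the silhouette of the *full* partition averaged over
valid-cluster members. Undersized clusters thus do not count toward the
score but still act as neighbors — the alternative (recomputing silhouette
after removing them) monotonically rewards peeling single noisy days into
singletons and drives k to k_max. Ties break toward fewer clusters; if no
k yields two valid clusters (e.g. all traces identical) the result
degenerates to a single cluster with silhouette reported as undefined.
Cluster ids are ordered by size (0 = largest); undersized-cluster days are
labeled −1.

**Novelty.** NS(x) = −Σ_j [x_j log θ′_j + (1−x_j) log(1−θ′_j)] with the
reference profile clipped into [ε, 1−ε]. Clipping is required because the
likelihood is infinite when an estimated probability of exactly 0 or 1
disagrees with a realization; ε defaults to max(1/(2N), 0.005) — half the
resolution of an N-day estimate, floored for very long references — and is
configurable. The default reference is the largest cluster's profile; any
cluster or an explicit reference period can be chosen. Days with NS ≥
Q75 + 1.5·IQR (linear-interpolation percentiles, at least 4 scores
required) are outliers; the inlier rule is strict (NS < threshold), so in
the degenerate all-equal-scores case everything is flagged —
`require_positive_iqr=True` suppresses flagging there instead.

## Synthetic data generator

The generator is deliberately the exact inverse of the analysis models, so
parameter recovery is well-posed: day traces are drawn from a weighted
mixture of per-bin Bernoulli "modes", daily counts from independent
Poissons whose log-mean adds a baseline, a linear ramp (log fold-change
over the period), an abrupt step and per-day outlier multipliers, and
events are expanded from traces/counts so that preprocessing recovers them
exactly (bit-exact round trips under the stated fill/tmin contract).
Transmission faults tag events with the burst that carried them: a missed
day delays one scheduled burst by one period, a severe day (always a subset
of missed) drops the day's payload. All operations take explicit seeds;
identical seeds give byte-identical event files.

Default study conditions used by the tests and the acceptance script:

* counts: baseline 4 visits/day (typical toilet-usage scale); power
  demonstrations of the abrupt screen use baseline 20/day, where a ×2 step
  is detectable within the 5-day abrupt span;
* routines: night-only (21:30–07:00 active at 0.97, background 0.01 per
  bin) vs. night + afternoon rest (additionally 13:30–16:30). This is the
  "well-separated" margin: between-mode cosine distance ≈ 0.13, about twice
  the typical within-mode noise distance, at which cluster recovery is
  exact for essentially all seeds (measured 195/200); at smaller
  separations recovery degrades gracefully, typically by single anomalous
  days peeling into undersized clusters — an inherent property of
  agglomerative clustering combined with the minimum-cluster-size rule;
* deviant days: drawn from a daytime-long-presence mode (08:00–18:00 at
  0.9), disjoint from both routines, so novelty scores separate cleanly;
* simulation sizes: 2000 windows for null calibration, 500 replicates for
  effect recovery, 2016 datasets for interval coverage, 20+20/45 days for
  clustering and novelty — sizes at which Monte-Carlo bands are a fraction
  of the effects being checked.

What the generator does **not** emulate: multi-person occupancy confusion,
temporally drifting or dilating routines (modes are stationary), sensor
dropout within a day, correlated bins, overdispersed counts, or radio/power
behavior. Passing tests therefore demonstrate correctness of the
statistical machinery under its own model assumptions, not robustness to
every real-world violation of them; the explicit handling of malformed
event sequences and missing days covers the most common violations only.

## Pipeline and report

The `report` command validates every stage parameter up front (pydantic),
runs preprocessing → trends → profiles → clustering → novelty → quality,
and emits a JSON report (schema published via the pydantic model, version
1.0) plus a human-readable text rendering. The report carries only derived
summaries — never raw event payloads — and echoes all parameters for
provenance. Only fully observed local days (midnight-to-midnight inside
the event span) are scored for novelty, since a censored partial day would
look spuriously deviant. Runs are deterministic given the configuration;
any stage error aborts with a message naming the stage. Logging goes to
stderr with stage-tagged lines.

## Known limitations

* Wald-based screening at W = 30 relies on asymptotics; at very low
  baseline rates (≪ 1 count/day) p-values become conservative and power is
  limited.
* The abrupt/intermediate/linear design is intentionally collinear;
  coefficients of jointly retained factors can individually look extreme
  while their combination fits well (the report shows per-factor percents,
  which should be read jointly).
* Novelty scoring assumes bin independence; strongly autocorrelated
  presence (long continuous rests) makes NS differences steeper than a
  calibrated likelihood would be. The IQR threshold is a robust heuristic,
  not a significance level.
* Counts are modeled as Poisson; overdispersion (negative binomial) is out
  of scope, as are forecasting, Bayesian proportion tests and
  Isolation-Forest/LOF-style novelty thresholds.
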