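# homesense

Behavioral analytics for IoT home-monitoring sensor streams, aimed at
ambient-assisted-living deployments where simple in-home sensors (bed and
chair occupancy pads, a toilet presence sensor, PIR motion detectors,
magnetic contacts) continuously log the daily routines of an older adult —
for example someone recovering from a stroke — and a care manager needs
concise, statistically grounded synthesis instead of raw event streams.

Because behavior varies from person to person and no annotations are
available, every analysis is unsupervised and personalized: changes are
detected relative to the subject's own learned habits.

## What it computes

**Rolling Poisson trend detection** (count behaviors, e.g. daily toilet
visits). Each day, the trailing window of W = 30 daily counts $y_i$ is
modeled as independent Poisson with log-linear mean

$$\mathbb{E}[Y_i \mid x_i; \beta] = \mu_i = e^{x_i^\top \beta},$$

where the covariates are a baseline (bias), a linear ramp scaled to $[0,1]$
over the window (long-term drift; its coefficient is the log fold-change
across the window), an *abrupt* indicator of the last A = 5 days, and an
*intermediate* indicator of the I = 10 days before that (which absorbs a
past step without inflating the baseline). Only factors significant at
$\alpha = 0.05$ (Wald test on the full model) are retained and refit; a
retained abrupt or linear factor raises an **alert**, reported as a
multiplicative percent change $100(e^\beta - 1)$. The last day's count is
checked against the central 95% region of its fitted Poisson distribution;
counts outside it are labeled **unexplained**.

**Sensor Profiles** (presence behaviors, e.g. bed rests). The day is split
into 30-minute bins; bin $j$ of day $i$ is a Bernoulli realization
$X_j^{(i)} = 1$ iff the sensor was active at least $t_{\min} = 5$ minutes in
that bin. The profile is the per-bin MLE $\hat p_j = n_{POS}/N$ with Wilson
95% intervals. On top of it:

* **profile comparison** — per-bin two-proportion tests (chi-square, or
  Fisher's exact for sparse tables) with Holm–Bonferroni family-wise error
  control across bins;
* **multi-modal routine discovery** — agglomerative clustering of binary
  day traces under cosine distance; the number of clusters maximizes the
  mean silhouette over clusters with at least $n_{SAM} = 5$ member days;
* **novelty detection** — the Novelty Score of a day is its negative
  log-likelihood under a reference profile $\theta$,
  $NS = -\sum_j \log p(x_j^{(i)}; \theta_j)$, with days above the Tukey
  threshold $Q_{75} + 1.5\,\mathrm{IQR}$ flagged **deviant**.

A seeded simulator generates event streams with known ground truth (routine
modes, trends, outliers, deviant days, transmission faults) so every stage
is testable end to end, and an event-stream preprocessor handles
sessionization, visit counting, day-trace binning and transmission-quality
reporting.

## Worked example

Generate a 90-day synthetic pilot (visit-rate doubling at day 75, three
deviant bed days) and run the full pipeline:

```bash
homesense simulate --days 90 --seed 11 --abrupt-day 75 \
    --abrupt-log-effect 0.693 --n-deviant 3 --out pilot
printf 'events_csv: pilot/events.csv\nsubject: pilot-07\noutput_dir: out\n' > cfg.yaml
homesense report --config cfg.yaml
```

which prints:

```
Behavior report for pilot-07
Period: 2024-01-01 .. 2024-03-31

Data quality:
  91/91 ideal days (100.0%), 0 severe transmission failures (0.0%)

Toilet usage (61 analysis days):
  alert 2024-02-09: abrupt -75.4%, linear +655.8%
  alert 2024-02-16: linear -55.1%
  alert 2024-03-16: abrupt +48.4%
  alert 2024-03-17: abrupt +59.6%
  alert 2024-03-21: linear +172.4%
  alert 2024-03-22: linear +166.1%
  alert 2024-03-29: abrupt +136.5%
  unexplained days: 2024-02-05

Bed rests (90 days, 242 rest intervals):
  2 routine cluster(s), silhouette 0.4426
  novelty threshold 29.74; deviant days: 2024-01-16, 2024-01-22, 2024-02-03, 2024-03-27
```

The injected rate doubling (day 75 = 2024-03-15) is picked up as alerts
with a positive abrupt effect on 03-16/03-17 (+48%, +60%, converging toward
the true +100% as the step fills the 5-day abrupt span), and all three
injected deviant bed days (01-16, 01-22, 03-27) exceed the novelty
threshold; 02-03 is a chance false positive of the novelty rule, and the
early-February alerts are false positives of the per-day trend screen —
both illustrate why flags are synthesized for a human reviewer rather than
acted on automatically. A machine-readable `out/report.json` (with a
published schema) accompanies the text.

Library use mirrors the CLI: `simulate.sample_day_traces` /
`simulate.simulate_daily_counts` generate data, `events.*` preprocess,
`trends.rolling_analysis`, `profiles.cluster_day_traces`,
`profiles.novelty_scores` analyze, `pipeline.run_pipeline` ties it together.

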