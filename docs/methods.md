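# Methods

## The task and its reduction

A session presents 50 images: 25 first showings and 25 repeats. Within
each of the 5 categories of 5 images, three images are shown twice, one
three times, and one only once; the order is pseudo-random with no more
than four consecutive first showings or repeats, and every repeat
follows a previous showing of the same image. A key press with a
recorded latency of 200–2999 ms counts as a response; latencies below
200 ms, the 3000 ms timeout code, and absent presses count as
non-responses. Crossing response/non-response with repeat/first-showing
yields HIT, Miss, False Alarm, and Correct Rejection, with the
identities HITs + Misses = 25 and CRs + FAs = 25 enforced by
construction. A session's RT is the arithmetic mean of its HIT
latencies, reported in seconds at millisecond resolution (half-up).

Absent latencies are stored as explicit nulls, never 0 or 3000: the
timeout is a recorded value in the scoring scheme and must remain
distinguishable from "no press".

## The RevEx model

Per-session mean RTs are modelled by the reverse-exponential law

    -ln CD(t) = a · exp(-b · t),

with CD(t) the fraction of sessions at or below t ("fraction faster").
Algebraically this is the Gumbel (maximum) distribution with location
μ = ln(a)/b and scale β = 1/b; the package works in the (a, b)
parameterization the model is reported in, and the test suite holds the
closed forms against scipy's `gumbel_r` as an independent oracle.
Useful derived quantities: mode ln(a)/b, median (ln a − ln ln 2)/b, and
the halving time ln(2)/b — the RT shift that halves −ln CD, about
104 ms at the published calibration, which is the model's "halving the
processing resources slows the response by ~100 ms" reading.

Two orientation conventions coexist deliberately. CD and `cdf` are
fraction-faster; the normative table's RT column and
`survival_percentile` are fraction-slower, 1 − exp(−a·e^(−bt)). Both
are explicit in the API to prevent sign drift.

### Fitting

`fit_revex` reproduces the spreadsheet exponential-trendline procedure
the calibration was originally obtained with, rather than a maximum-
likelihood Gumbel fit:

1. sort the sample of session means; set aside round(trim·n) values
   from each tail (default trim 0.5%), which restricts the evaluated
   range, intersected with the fit window [0.6, 1.6] s;
2. evaluate the empirical fraction-faster CD of the full sample on a
   millisecond grid over that range (right-closed counting, matching
   per-millisecond cumulative tabulation);
3. exclude grid points with CD = 0 or CD = 1 (y = −ln CD is undefined
   there; the count is reported), and regress ln(−ln CD) on t by
   ordinary least squares.

The slope gives −b, the intercept back-transforms to a, and the
reported R² is that of the log-linear regression — the convention under
which the published fit explains essentially all the variance. A fit
needs at least 100 sample values inside the window. `RevExFitter`
wraps the same procedure as a scikit-learn density-style estimator.

Numerical notes: the grid epsilon (1e-9 s) guards float equality
between millisecond-rounded session means and grid points; sampling is
by inverse transform through the exact quantile function; quantile
probabilities are validated to (0, 1).

## Quality filters

The validity filter drops sessions with fewer than 30/50 correct,
fewer than 5 HITs or 5 Correct Rejections, a missing mean HIT RT, or a
mean HIT RT below 0.5 s or above 2.0 s. The analysis-subset filter,
applied before correlation analyses, further drops sessions with fewer
than 10 HITs, fewer than 15 Correct Rejections, fewer than 35 correct,
or RT outside [0.6, 1.4] s. Both RT bounds are strict removal bounds
("less than" / "more than" read literally), so a session at exactly the
bound survives. Removal accounting is set-based: a session is removed
once, with every failed criterion recorded, so per-reason tallies may
sum to more than the total removed — the original study's removal
arithmetic implies overlapping removal sets, and deduplicated
accounting is the reproducible choice. First-test selection keeps each
user's earliest timestamp, ties broken by stable input order (no
published rule exists for ties).

## The synthetic cohort generator

The generator emulates the statistical structure the population
analyses assume; its defaults are the study conditions, not tuning
knobs.

* **Latent mean RT.** Drawn exactly from RevEx(a = 263.94, b = 6.682)
  by inverse transform. Fast guessers (see below) draw from the law
  truncated below 0.6 s and everyone else from the law truncated
  above; because the default fast-guesser share equals the law's own
  sub-0.6 s mass (0.0083), the mixture marginal is exactly RevEx.
* **Strategy archetypes** (default mix): balanced 0.7617,
  over-responder 0.08, under-responder 0.15, fast-guesser 0.0083.
  Over-responders draw an elevated false-alarm propensity
  (Beta(6, 9), mean 0.4 — Correct Rejections collapse, HITs stable);
  under-responders lose HITs with stable CRs; fast guessers respond
  indiscriminately (p_fa ~ Beta(6, 4)) at sub-0.6 s speed — the only
  regime showing a speed–accuracy trade-off. Balanced and
  under-responding subjects share the baseline p_fa ~ Beta(2, 18)
  (mean 0.1, i.e. about 22–23 Correct Rejections). Moving p_hit and
  p_fa on separate, independently sampled axes is what makes HIT and
  CR counts uncorrelated across the cohort.
* **Two-regime miss model.** Conditional on RT, balanced and
  over-responding subjects keep high HIT counts at any speed (expected
  misses rise only from 1 to 4.5 across 0.65–1.4 s), while
  under-responders carry the steep linear coupling: expected misses =
  (rt − 0.837)/0.0308, clipped to [0, 15]. Large miss counts therefore
  arise almost exclusively among slow under-responders, which is what
  lets the population show simultaneously (i) a high average HIT count
  at every RT, (ii) a steep ~31 ms-per-miss slope when RT is averaged
  within HIT strata (the classic regression-dilution asymmetry), and
  (iii) a validity filter that is nearly neutral in RT, so the
  filtered cohort's RT percentile column still tracks the RevEx
  formula. The anchors 0.837 s (RT at 25 HITs) and
  0.0308 s/miss = (1.299 − 0.837)/15 come from the published curve
  endpoints. A ceiling of p_hit = 0.97 reflects that even ideal
  subjects miss occasionally.
* **Trial noise.** HIT (and False Alarm) latencies are drawn from a
  normal distribution truncated symmetrically at ±3 sd around the
  latent mean (default sd 0.1 s), clipped into the response window, so
  the session mean is an unbiased estimate of the latent mean. The
  default is deliberately modest: only session means are analysed, and
  a larger trial-level spread would only blur the session-mean
  distribution relative to the latent law (real trial-level RT
  variability is larger).
* **Sequences.** Constraint satisfaction is by rejection sampling with
  a retry budget (default 10,000): a random 25/25 arrangement is
  rejected on run length, a random first-showing order is rejected by
  a prefix-feasibility check (each repeat slot needs a pending repeat
  among already-shown images), and repeats are then assigned uniformly
  among eligible images. Uniformity over all admissible orders is not
  claimed. The minimum lag between a showing and its repeat is
  configurable (default 1, i.e. only "strictly later" is enforced; the
  exact deployed lag rule is unpublished and lag effects are out of
  scope); a minimum lag above the run limit is rejected as infeasible.
  For population-scale score analyses the cohort can share one
  generated sequence (`simulate_cohort_scores` default): scores are
  invariant to presentation order, so this changes no analysed
  statistic.

### What the generator does not emulate

Practice effects across repeat tests, category-level confusability,
lag/spacing effects, demographic covariates, and intra-individual RT
variability structure. Passing tests therefore show that the pipeline
correctly recovers the modelled population structure — not that real
populations have exactly this structure.

## Population analyses

Percentile tables follow the normative conventions: count columns are
"fraction strictly below the threshold", the RT column "fraction
strictly slower". Individual lookups interpolate linearly between
tabulated thresholds and flag values clamped to the table ends. The
embedded reference table (`crtlab/data/reference_percentiles.csv`)
transcribes the published normative percentiles for 282,140 valid
first tests; its RT column agrees with the closed-form survival
percentile to ≤0.05 points at every row, and the package treats the
formula as authoritative. Conditional curves default to millisecond RT
bins (coarsenable); strata with fewer than 5 observations are flagged
sparse rather than dropped. Correlation reports give squared Pearson
correlations and apply the analysis-subset filter by default
(`subset_policy=None` disables); zero-variance inputs are reported as
undefined rather than NaN.

## Problem sizes and tolerances

Cohort-scale properties (HIT–CR independence r² < 0.01,
Kolmogorov–Smirnov agreement of latent mean RTs with the RevEx law at
the 1% critical value, the 30.8 ms-per-miss slope within 20%, the
filtered RT percentile column within 1 point) are checked at
n = 20,000 subjects; parameter recovery of the fit (b within 2%, a
within 10%, R² ≥ 0.999) at n = 100,000 sampled means; sequence
constraints by brute-force validation over 1,000 seeds. The noiseless
plug-in inversion of the fit is checked at quantile positions
(i − 0.5)/n with n = 200,000, where recovery is limited by the O(1/n)
discretization of the empirical CDF rather than by the regression.

## Known limitations

* The generator's two-regime miss model is the simplest structure that
  reproduces the published marginal and conditional relations; the
  real mixture of strategies is surely richer.
* The analysis-subset removal counts of the original study are not
  exactly reproducible from its printed figures (the removal sets
  overlap); this package reports deduplicated removals only.
* Whether a response at exactly 2,999 versus 3,000 ms is handled
  uniformly across deployment platforms is taken exactly as the
  scoring rule states; no further boundary information is available.
* The model median (0.889 s at the published calibration) sits between
  the two published descriptive medians (0.890 and 0.900 s); the
  package reports model and empirical medians separately and does not
  reconcile them.
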