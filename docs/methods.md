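# Methods

## Model and estimators

The network survival estimator treats each respondent's interview as a
window onto their personal network. Writing *w_i* for the design weight
of respondent *i* (treated as an inverse inclusion probability after
denormalization), the three ingredients for a demographic group α are

- the weighted total of reports about deaths in α,
  `y_hat = sum_i y_{i,Dα} w_i`, summed over *all* respondents — reports
  count toward the decedent's group, not the respondent's;
- the group's average personal network size
  `dbar_hat = [sum_{i in α} sum_j y_{i,Aj} w_i / sum_j N_Aj] * N_F / N_Fα`,
  calibrated against known populations of sizes `N_Aj`;
- the exposure `N_hat = sum_{i in α} w_i`, valid when the sampling frame
  is complete for α.

The death count is `D_hat = y_hat / dbar_hat` and the rate
`M_hat = D_hat / N_hat`. With the group size inside `dbar_hat` estimated
from the same weights (the default), the exposure cancels algebraically:
`M_hat = y_hat * sum_j N_Aj / (y_known,α * N_F)`. The implementation
satisfies this identity to machine precision, and the rate is then
invariant to any common rescaling of the weights.

Using the respondents' network size for the visibility of deaths assumes
(1) decedents had networks as large on average as their group's
survivors, and (2) reporting is complete (no omissions) and precise (no
false positives). Neither assumption is observable from the survey data,
so the package never "corrects" estimates silently; instead the
sensitivity module carries the exact decomposition
`D_α = (y/dbar) * (1/δ) * (η/τ)` with

- δ — mean network connections to the frame among the group's decedents,
  divided by the same mean among its living members;
- τ — true-positive reports about the group's deaths divided by the
  group's total decedent visibility;
- η — true-positive reports divided by all reports naming a death in the
  group.

These operational definitions are the unique ones under which the
decomposition is an exact identity on any realised population-and-reports
pair, which the simulator verifies directly (see below). Grids over δ and
the ratio η/τ (default {0.5, 1, 1.5} each) show how structural and
reporting violations move the estimates — including the regimes where
they cancel (δ and η/τ moving together) or compound (moving apart).

## Tunable parameters

| Parameter | Default | Meaning |
| --- | --- | --- |
| age bands | 15-24 … 55-64, 65+ | ten-year adult bands; fully configurable strings like `"15-24,…,65+"` |
| `n_falpha` | `"estimate"` | group size in the degree estimator; external totals accepted |
| recall window | 12 months | reports window; rates are annualized if changed |
| bootstrap `B`, level | 200 replicates, 95% | percentile intervals; replicates exposed for diagnostics |
| sibling pooling window | 84 months | the conventional length needed for stable direct sibling estimates |
| grid values | {0.5, 1, 1.5}² | δ × (η/τ) sensitivity grid |

Reports missing the decedent's sex or age are excluded from sex- and
age-specific numerators but kept in all-adult totals; exclusions are
logged, never silent. Respondents missing any known-population item are
dropped from degree estimation (and logged), since a partially answered
battery biases the calibration downward.

## Survey designs and uncertainty

Weights are denormalized so they sum to an external frame-population
total before any estimation; when arms of a survey experiment are
analysed separately, each arm is denormalized to the same frame total.
Uncertainty uses the Rao–Wu rescaled bootstrap: within each stratum of
`n_h` sampled PSUs, `n_h − 1` PSUs are drawn with replacement and every
weight is multiplied by `(n_h/(n_h−1)) · r_hi` (`r_hi` = times the PSU
was drawn). Resampling `n_h − 1` units makes the replicate variance of a
total match the textbook with-replacement first-stage variance estimator;
the small finite-population correction is deliberately omitted, the
standard design-based convention when first-stage fractions are small.
PSUs, not households, are the resampled unit. Strata with a single PSU
raise an error rather than being silently collapsed. Percentile rather
than normal-theory intervals are reported, matching how replicate
distributions are usually displayed.

## Life-table aggregation

Age-band rates are treated as piecewise-constant hazards:
`q_band = 1 − exp(−width · M)`, composed multiplicatively, with partial
bands pro-rated by width. This is the minimal convention — it needs no
separate assumption about the timing of deaths within bands and is
exactly invariant to subdividing a band — so 45q15 from this package may
differ slightly from published figures computed with nax-style life-table
columns.

## Sibling comparator

Sibling histories are processed at month resolution (century month
codes). Windows and age bands are half-open `[lo, hi)`; deaths are placed
at the middle of the death month, which fixes every boundary case and
makes a brute-force month-by-month tally an exact oracle, since band
boundaries in years always fall on month edges. Exposure splits exactly
at band crossings and truncates at the death instant; deaths are
assigned to the band of age at death; rates are weighted deaths over
weighted person-years. The respondent's own exposure is excluded by
default (their survival is guaranteed by selection), with a flag for
sensitivity checks; no sibship-size selection adjustment is applied.
Records with impossible dates or missing survival status are skipped and
logged.

## The synthetic-data generator

The simulator realises the population model the estimator assumes, so
every estimand has computable truth: members carry sex, age (from a
young-adult age pyramid), and a gamma expected degree (shape 2, mean 100
by default — a weak-tie, acquaintance-style network; the resulting
reporting volume is several tenths of a death per interview at the
default mortality schedule). Ties form independently with probability
`d_i d_j / sum(d)`, the one random-graph family in which all truths have
closed forms. Deaths follow configurable sex- and age-specific rates over
a 12-month window (defaults in the range of a high-mortality sub-Saharan
schedule, giving 45q15 near 0.22/0.29); decedents' ties are frozen at
death, and a multiplier on decedents' expected degrees manipulates δ
directly. Reporting applies a false-negative probability per decedent
neighbour and a false-positive intensity per living neighbour; known-
population membership (about 7% of the population across eight groups of
realistic relative sizes) is assigned independently of degree. Samples
are stratified two-stage cluster draws with exact design weights; the
default design (10 strata × 4 of 20 PSUs × 60 respondents) yields 2,400
respondents, the scale of one arm of a national survey experiment.

Two generation paths exist. The full-graph path realises every tie and
supports census estimation and the exact (δ, τ, η) identity; it is meant
for populations up to a few tens of thousands. The survey-level path
exploits tie independence to realise only the respondent-by-special-
member tie matrix (specials = decedents and known-population members),
which reproduces the sampled-data distribution at any population size and
makes replication studies cheap; overlaps between respondents and special
members are ignored there (O(1/N) effects). For coverage studies the
truth file reports, besides realised deaths and survivors, the census
value of the estimand conditional on the realised degrees — the finite-
population quantity a design-based interval targets. Intervals cannot be
expected to cover the underlying hazard parameters themselves: with only
a few dozen deaths per band, the binomial death realisation and the
decedents' degree draw move the census estimand by more than the design
noise, and no survey-side interval can absorb population-level
randomness.

What the simulator does not emulate: network clustering and homophily
beyond degree, age- or degree-correlated known-population membership,
respondent recall heaping, and multi-year dynamics. Passing tests
therefore certify the estimators under the method's own assumptions (and
controlled violations of the three factors), not robustness to real-world
reporting behaviour.

## Numerical and design choices

- Half-open integer age bands everywhere; bands must be contiguous and
  disjoint.
- Zero degree or zero exposure raise named errors instead of returning
  infinities; a zero reported-death total returns a zero count and rate.
- Bootstrap replicates on which a statistic is undefined are dropped;
  more than half failing raises an instability error.
- All randomness flows through `numpy.random.Generator` seeded from a
  single integer; identical inputs, configuration and seeds give
  byte-identical outputs.
- Problem sizes used by the validation suite — 100 random scenarios for
  the identity check, 6-member frames for exhaustive sample enumeration,
  200 replicated surveys of 2,400 respondents with 200 bootstrap
  replicates for recovery and coverage, B = 2,000 for the variance
  comparison — were chosen so each check's Monte Carlo error is several
  times smaller than the property it verifies.

## Known limitations

- The no-false-positives assumption is untestable from survey data alone;
  only the sensitivity grid speaks to it.
- Known-population sizes are taken as exact; errors in them scale all
  rates by the corresponding factor.
- The frame must be complete for every estimated group; alternative
  exposure sources for incomplete frames are not implemented.
- The sibling estimator implements the direct method only — no indirect
  variants, no pooling across surveys, and no sibship-selection
  adjustment.
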