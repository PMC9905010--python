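# Methods

## Model overview

Trend Impact Analysis combines a deterministic trend extrapolation with a
stochastic event layer. The forecast for year `t` under a scenario `S`
(a set of drivers) is

    forecast_q(t) = clip( baseline(t) + Q_q[ Σ_{e∈S} Δ_e(t) ], 0, 100 )

where `baseline(t)` is the fitted trend, `Δ_e(t)` is event `e`'s simulated
impact trajectory, and `Q_q` is the empirical percentile (q = 2.5, 50, 97.5)
over Monte-Carlo repetitions. The method assumes events are *independent*
(no cross-impact adjustment between drivers), that an event's elicited
impact is additive in prevalence percentage points, and that the baseline
trend would continue unchanged in the absence of events.

## Baseline trend

Prevalence (%) is regressed on Gregorian calendar year by unweighted OLS.
Calendar years are used directly as the regressor because the observations
are unevenly spaced (2008, 2010, 2013, 2016, 2017, 2018) and equal-index
spacing would change the fit. Survey sample sizes are carried as metadata
but not used as weights: the series mixes surveys of ~5,000 with registries
of ~340,000 subjects, and weighting would let three registry years dominate
a six-point fit.

Three functional forms are available — linear, quadratic (with the squared
term centred for conditioning), and log-linear (log prevalence on year,
back-transformed). `compare_models` ranks them by adjusted R², ties broken
toward fewer parameters. Diagnostics are computed on the prevalence scale
for every form so the ranking is comparable; for linear and quadratic this
coincides with the usual OLS R². On the packaged series the linear form
gives R² = 0.8002 and adjusted R² = 0.7502; the derivation of the adjusted
value uses `1 − (1 − R²)(n − 1)/(n − k − 1)` with k slope terms.

Predictions are clipped to [0, 100] at output (prevalence is a percentage);
clipping is logged and never occurs within the study horizon. The fitted
2031 baseline is 29.33 % unrounded. Published summaries of this kind of
analysis often quote a slightly lower value (29.10) obtainable by rounding
the fitted coefficients before extrapolating; the package always
extrapolates with full-precision coefficients and treats ±0.35 pp as the
agreement band for that endpoint.

Baseline parameter uncertainty is deliberately *not* propagated into the
forecast bands: the method's confidence interval is defined as the
event-impact percentiles added to the point baseline, so with no drivers
the band has zero width.

## Delphi screening and aggregation

Round-1 retention: an event survives iff its mean Likert intensity is
**≥ 3** (the rule "scored less than 3 is excluded" makes the boundary value
pass) and at most half of its respondents flagged it as already acting on
the trend. The "already affected" exclusion has no published quantitative
rule; a simple majority of flags was chosen as the least arbitrary
operationalisation. Retention is monotone in the cutoff by construction.

Round-2 aggregation: per event and year, the occurrence probability is the
expert mean divided by 100 and the impact is the signed expert mean in
percentage points, taken as directly elicited (no Likert-to-percent
rescaling). Missing individual responses are dropped from the mean
(available-case) and logged. A driver whose mean impacts change sign across
years is rejected by default — each driver is conceptually a force in one
direction — but `allow_mixed_sign=True` accepts such profiles, classifying
by the sign of the total impact and zeroing contradicting years.

## Monte-Carlo engine

Per event, repetition, and horizon year (in order): draw `r ~ U(0,1)`; the
event fires when `r < p_{e,t}` (the `standard` rule). On firing, the
onset-year impact `I_{e,onset}` is added to that year and every later year,
and the event draws no further in that repetition (`single_occurrence`).
Two documented variants exist behind flags, neither default:

- `occurrence_rule="literal"` fires when `r > p`, reproducing a published
  wording of the comparison. This inverts the elicitation — high-probability
  events would almost never fire — so the standard rule, under which larger
  elicited probabilities produce larger expected deviations, is the default.
- `impact_profile="per_year"` accumulates each post-onset year's own impact
  instead of persisting the onset value; `single_occurrence=False` lets the
  event fire repeatedly, stacking impacts. (No Gordon-style ramp from first
  impact to steady state is implemented.)

The per-event trajectories are summed within repetitions into an
`n_reps × n_years` matrix; column percentiles use linear interpolation
between order statistics (`numpy.percentile` default), an arbitrary but
standard choice the source method leaves unspecified. The median (not the
mean) of the impact distribution adjusts the central forecast.

Every event owns a dedicated random substream seeded by
`SeedSequence([seed, sha256(event_id)])`. Consequences: results are
reproducible bit-for-bit given a seed and invariant to driver ordering, and
scenario subsets (negative-only / positive-only / combined) reuse identical
draws, making cross-scenario orderings exact per repetition — adding an
all-negative driver can never raise any repetition's total impact.

The engine keeps a literal year-by-year implementation
(`simulate_event_rep`) alongside the vectorised one used in production;
tests assert they agree draw for draw, and a brute-force enumeration of
occurrence patterns over short horizons provides an exact distributional
oracle.

## Synthetic data generator

The elicited panel values behind the motivating study are unpublished, so
the generator emulates the panel's *structure*: 14 round-1 experts of whom
9 continue to round 2, 15 candidate events, horizon 2021–2031, with
screening retaining exactly 2 positive and 5 negative drivers. Retained
events have intensity centres 7–8.5 and excluded ones 1.0 (or an
already-affected flag rate of 0.97), so the mean-over-panel rule decides
with a margin of many standard errors at any seed — the pattern is
calibrated analytically, not searched for. Negative impact centres
(−0.9 … −1.4 pp, probabilities 0.5–0.75) outweigh the positive ones
(+0.7, +0.9 pp), reproducing the qualitative scenario ordering
negative < combined < baseline < positive.

Noise families: Likert intensities are normal draws rounded to integers and
clipped to 0–10; occurrence probabilities are beta-distributed with the
requested mean and standard deviation (a spread incompatible with the mean
is capped and logged); impacts are normal with the direction-consistent
sign enforced by clipping at zero. Prevalence series are linear trends plus
i.i.d. Gaussian noise, clipped to [0, 100].

What the generator does **not** emulate: correlated expert opinion, panel
attrition that depends on the events, time-varying elicitation uncertainty,
non-additive or saturating impacts, and autocorrelated deviations of the
observed series from trend. Tests passing on synthetic panels therefore
demonstrate the correctness of the computational pipeline and its
statistical calibration under the stated model — not the realism of any
particular elicitation.

## Problem sizes and numerics

Simulations default to 10,000 repetitions over an 11-year horizon; the
engine is vectorised, so a three-scenario run completes in well under a
second. Parameter-recovery checks use 500 replicate series and 3
Monte-Carlo standard errors as the agreement band; distributional checks
against the enumeration oracle use 20,000 repetitions and 3 binomial
standard errors per CDF atom. Seed-sensitivity is assessed with
order-statistic brackets (ranks `n·q ± 3√(n·q(1−q))`), which are
distribution-free and robust to the impact distribution's discreteness.

## Known limitations

- Events are simulated independently; real drivers (e.g. a tax and a school
  program) may interact. Cross-impact analysis is out of scope.
- The baseline is a single regression extrapolation with no autocorrelation
  or changepoint modelling; with six observations little more is estimable.
- Impact persistence is a step function from onset; gradual ramp-up is not
  modelled.
- The forecast band reflects only event uncertainty, not baseline
  coefficient uncertainty or elicitation sampling error.
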