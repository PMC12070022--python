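# Methods

## Preprocessing

Event records (participant, channel, start, end; ISO-8601 timestamps with
explicit UTC offsets) are binned on a local wall-clock hourly grid. Per
channel, overlapping events are unioned before the per-hour activity
fraction is computed (union length / 3600 s), so fractions never exceed 1
and events spanning hour boundaries contribute to every hour they overlap.
Binarization marks an hour active when its fraction is strictly positive
*and* at least the threshold; threshold 0 (the default) is the "any
activity" rule, 0.05 and 0.10 are the sensitivity variants. Raising the
threshold is monotone: it can only remove active hours.

Availability is inferred from passive sampling frequency, which does not
depend on the participant actively using the phone: an hour with at least
one record of any kind (Wi-Fi scan, location fix, or activity) is
overall-available; an hour with at least one location fix is GPS-available.
GPS channels are not model inputs — only the availability signal uses them.
Hours that are not overall-available have all five channels marked missing
simultaneously; nothing is imputed.

The first calendar day of each participant's data is discarded (behaviour
on the onboarding day is atypical), so every series starts at a local
midnight and `hour_of_day[t] = t mod 24`. A series must span at least one
full day or preprocessing refuses it. Timestamps are reduced to their own
local wall-clock time; on daylight-saving transitions the repeated hour
merges into its first occurrence and the skipped hour simply contains no
records, so it is flagged unavailable — local wall-clock structure is what
the hour covariate models, so this is the behaviour we want.

## The hidden Markov model

States emit the five binary channels as independent Bernoulli draws
(φ: N×5). Transitions follow a per-origin multinomial logistic link on the
one-hot hour of day (24 columns, no intercept; destination state 1 is the
zero-fixed reference), giving each hour its own transition matrix. The
starting distribution π is free. Missing observations contribute nothing to
the emission term (missing-at-random is assumed); a fully missing hour is
carried through the transition structure only, so the likelihood stays
finite under arbitrary block missingness.

**EM.** The E-step is a scaled forward–backward pass. Sequences are padded
to a common length and processed as a batch; padding is all-missing, which
is exactly transparent to the recursion (the emission factor is 1 and
row-stochastic transitions preserve the scaling), and padded steps are
masked out of all sufficient statistics. The M-step updates are closed
form: π from the mean first-hour posterior, φ from posterior-weighted means
of the observed channel values, and — because the one-hot hour design makes
the expected multinomial-logistic log-likelihood separate by hour — the
transition coefficients are `β_mnh = log(W_hmn / W_hm1)` with `W` the
expected transition counts per hour. This is the exact maximizer of the
M-step objective, so no inner Newton iterations are needed; a count
smoothing of 1e-8 guards hours an origin state never visits. φ is clipped
to [1e-6, 1−1e-6] to keep the likelihood finite. Convergence is declared
when the relative log-likelihood improvement drops below 1e-6 (max 500
iterations); the trace is retained and must be nondecreasing.

**Initialisation and restarts.** π starts uniform with Dirichlet jitter, φ
at the channel means plus state-specific offsets (linspace −0.2…0.2 plus
N(0, 0.05) noise), β at zero. Ten random restarts by default; the best
final log-likelihood wins. After fitting, states are relabelled by
ascending phone-usage emission probability so state 1 is always the
socially inactive state; the β tensor is re-referenced accordingly.

**Model selection and decoding.** BIC = −2L + k·log(n) with
k = (N−1) + N·C + N(N−1)·P free parameters and n the number of non-missing
timepoints (timepoints, not participants, were chosen as the BIC sample
size — the likelihood factorises over them). Decoding uses the Viterbi
algorithm with ties broken toward the lowest state index; at missing hours
the emission term is absent, so decoding is transition-driven there.
Decoding never refits the model.

## Phenotype and model comparison

The socially active state is the one with maximal communication-app
emission probability (phone usage breaks ties; an exact tie after both is
an error — the states are not interpretable). Total dwell time drops
missing hours *after* decoding and reports the active percentage of the
observed hours only. When two models' decodings are compared (e.g. an
HC-trained vs a clinical-group-trained model), states are first matched by
minimising the total L1 distance between emission rows (exhaustive over N!,
N ≤ 4); accuracy, sensitivity and specificity are computed over jointly
observed hours with active = positive. An empty reference class yields an
explicit null metric, never a silent 1.

## Cohort analyses

Training/validation split: HCs with ≥90% overall availability train the
model, minus a seeded random subset (default 15) retained in validation;
all SZ/AD/SCC participants and low-availability HCs are validation.

OLS models (statsmodels) use treatment coding against HC and two-sided t
tests; rank-deficient designs are rejected with the collinear terms named.
The group model is a multinomial logit (HC reference) with Wald z tests,
OR = exp(coef) and Wald 95% CIs; with two categories it coincides with the
binomial logit, which the tests verify. Age-matching filters compute their
cutoffs from the data (HCs above the oldest SZ, below the youngest AD/SCC
are dropped), never from constants.

Multiplicity adjustment defaults to `min(1, m·p)` per family because that
closed form reproduces the published adjusted values exactly (e.g.
.08 × 6 = .48); standard Benjamini–Hochberg is available as
`benjamini_hochberg`. The family sizes (6 for the full SFS model, 3 for the
group logistic, …) are configuration, not inference. Display conventions
(2 decimals, `<.001`, `>.99`) apply only at report time; raw p values are
retained internally.

## Synthetic-data generator

The generator emulates the structure the analysis assumes, not any
particular real dataset:

- **Latent dynamics.** 2-state model, π = (0.74, 0.26) (series start at
  midnight, mostly asleep). The transition score into the active state
  follows a raised-cosine diurnal profile peaked at 15:00 (from the
  inactive state: −3.2 night to −0.6 mid-afternoon; active-state
  persistence: −0.8 to 1.6), giving HC dwell times around 30–40%.
- **Emissions.** Inactive φ = (0.05, 0.03, 0.01, 0.01, 0.15); active
  φ = (0.55, 0.75, 0.10, 0.12, 0.95) — a silent state and a
  communication-heavy state.
- **Group effects** act on the into-active transition score (HC 0,
  SZ −0.1, AD −0.9, SCC −0.35) plus a per-participant N(0, 0.3) random
  effect: occupancy, the target phenotype, is controlled by transitions,
  not emissions.
- **Events.** Each active channel-hour becomes one interval with duration
  fraction ~ Beta(1.5, 5) placed uniformly in the hour; overall phone usage
  is the union of the other channels' intervals plus its own, so it is a
  superset. Under Beta(1.5, 5), 8.9% of active hours fall below a 5%
  threshold and 22.4% below 10% (Beta CDF), so the 0% and 5% rules agree on
  >90% of active hours while 10% diverges — the qualitative sensitivity
  structure the thresholds are meant to probe.
- **Availability.** Wi-Fi scans at 6/h and location fixes at 1.5/h
  (Poisson); per-participant availability targets ~ Beta(7, 1) (mean 0.875,
  about half the participants above 0.9); missing hours arrive in
  geometric-length blocks (mean 12 h) with all records in those hours
  removed, so availability is genuinely inferred from sampling absence.
- **Cohort and clinical scores.** Default 42 collection days plus a partial
  onboarding day that preprocessing trims; group sizes default to
  validation-set proportions of the source cohort scaled to a desk-size
  study (40/6/8/16). SFS is linear in *true* dwell, age, group and
  group×dwell with the published point estimates as default coefficients
  (dwell 0.1193, age 0.0269, SZ −20.5052, AD 4.4857, AD×dwell −0.3201,
  noise SD 10; SCC terms 0 — SFS was not administered to that group, and
  the score-administration pattern by group is reproduced). Loneliness,
  MMSE and PANSS use plausible stand-in coefficients with weak or null
  dwell effects. Group labels can also be drawn from a logistic model on
  dwell for slope-recovery studies.

What the generator does **not** emulate: real marginal activity
distributions (app-specific usage mixtures, weekday/weekend structure),
non-random missingness (e.g. phone off exactly when inactive), device
effects, or population age–dwell confounding. Passing tests therefore show
that the estimators recover the truth under the model's own assumptions at
realistic scales — not that those assumptions hold in any particular real
cohort.

## Problem sizes and numerical choices

The recovery benchmarks run at 300 sequences × 500 h (starting-probability
recovery), 100 × 1000 h (emission recovery, tolerance ±0.02), n = 2000
(OLS slope) and n = 20000 (logistic slope); the end-to-end study uses 60
participants × 42 days — sizes at which the Monte-Carlo error of each
estimate is comfortably inside its check tolerance. Oracle-equivalence
suites enumerate all N^T paths for T ≤ 8, N ≤ 3 at tolerance 1e-9.
Tie-breaks (Viterbi: lowest state index; state matching: first minimal
permutation) are deterministic. All randomness flows from explicit seeds;
the pipeline derives stage seeds from one master seed via
`SeedSequence.spawn` in a fixed order.

## Known limitations

- Emission families are Bernoulli only; continuous or zero-inflated
  emissions are out of scope.
- No covariates over starting probabilities, and one shared transition
  model per fit (no per-group or per-participant transition parameters).
- The multinomial logit uses Wald inference; profile-likelihood intervals
  are not implemented. Published CIs constructed by other means can differ
  in the last digits.
- Hour-of-day is the only transition covariate; day-of-week and trend
  effects are not modelled.
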