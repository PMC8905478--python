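# Methods

## The intervention model

`gdmtext` models an automated two-way SMS program supporting self-monitoring
of blood glucose (SMBG) in gestational diabetes. The design draws on two
Health Belief Model constructs: reminders are a *cue to action* (an external
stimulus prompting the check), while positive feedback and motivational
texts target *self-efficacy* (confidence in one's ability to keep
monitoring). The program is an adjunct to clinical care, not a monitoring
service: a disclaimer sent at enrollment states that no clinician watches
the account in real time, and every out-of-range or critical reply directs
the participant to her care team rather than offering clinical advice.

### Scheduling

Four reminders per day are anchored to mealtimes reported during SMS
onboarding: breakfast−30 min (fasting), breakfast+60, lunch+60 and
dinner+60 min (postprandial). Messages begin no earlier than 24 hours after
enrollment. A participant's schedule is generated over the half-open window
`[start, start + program_days)` where `start = enrolled_at + 24 h`; because
every slot recurs daily and the window is a whole number of days, each slot
fires exactly `program_days` times regardless of how the window aligns with
the clock. Partial first calendar days are therefore possible, but the
total prompt count is exact: 10 participants × 14 days × 4 slots = 560.
Weekly educational and motivational messages share one day/time preference
per participant; mealtimes are fixed for the program duration. A single
naive local clock per participant at minute resolution is used throughout —
the program's rules are clock-time rules, so time-zone arithmetic would add
nothing but failure modes.

### Glucose classification

Integer mg/dL values (decimals round half-up, SMS replies being effectively
integers) partition into four tiers per context:

| tier | fasting | postprandial |
| --- | --- | --- |
| critical_low | ≤60 | ≤60 |
| in_range | 61–94 | 61–139 |
| out_of_range | 95–199 | 140–199 |
| critical_high | ≥200 | ≥200 |

Two boundary decisions were genuinely open. A value of exactly 60 mg/dL sits
between "low below 60" and desired ranges starting at 61; it is assigned to
critical_low, the conservative choice for patient safety. Values between the
plausibility floor (20 mg/dL) and 60 are treated uniformly as critical_low
with no separate "mildly low" band — the published program distinguishes no
such band. The non-critical out_of_range band is the set difference between
the critical cutoffs and the desired ranges. Values outside the plausibility
window 20–600 mg/dL are rejected as implausible (the engine then sends a
clarification prompt instead of feedback). All eight bounds can be
overridden from a YAML config; the table above is the default.

### Conversation handling

The engine is a pure state machine driven by an external clock (`tick`),
which makes every behavior — including the full simulator replay — exactly
reproducible. Decisions the deployed program's description leaves open were
resolved as follows:

* **Reply linkage.** A glucose value is attributed to the most recent
  unanswered reminder within a 3-hour window (configurable); its slot fixes
  the fasting/postprandial context. Orphan values fall back to time of day:
  before the reported breakfast time → fasting, otherwise postprandial.
  This makes classification total over all inbound values.
* **Unrecognized texts** draw at most one clarification prompt per pending
  reminder, preventing reply loops.
* **STOP** is honored from any pre-terminal state, including onboarding: a
  single acknowledgment is sent, all future events are cancelled, and no
  further outbound message is ever produced.
* **Rotation** of the four in-range replies is strict per-participant
  round-robin ("rotating" admits several readings; round-robin is the
  deterministic, testable one). Educational and motivational messages rotate
  the same way so consecutive weeks differ.

## Adherence analytics

Adherence is checks performed over checks recommended by the clinician,
capped at 100%. The cap is applied **per calendar day** before aggregation:
six checks on a 4-recommended day credit 4, so a binge day cannot mask
missed days. An aggregate-level cap (period totals only) is selectable via
`cap="aggregate"` since the published definition does not fix the level.
Readings within 5 minutes of each other (failed strips, immediate retests)
collapse into one check event; clustering is chained over the participant's
full timeline and each cluster is dated by its first reading.

The pre period is the 7 days before enrollment; the during period is
`program_days` days starting the day after enrollment (messages start after
the 24-h delay). Participants with no pre-period device data are excluded
from the statistical comparison — they were not yet self-monitoring — but
still receive a during-period summary.

### The rank-sum test

The pre/during comparison uses the two-sample Wilcoxon rank-sum test, kept
unpaired as named even though pre and during are measurements on the same
women; a paired signed-rank variant is available behind `paired=True` for
sensitivity analysis. The implementation switches by sample:

* both groups ≤10 observations and the pooled sample tie-free → **exact**
  enumeration of the rank-sum null distribution via a subset-sum
  dynamic-programming recurrence; two-sided p = min(1, 2·min(P(W≤w),
  P(W≥w)));
* otherwise → normal approximation with tie-corrected variance and a 0.5
  continuity correction.

The exact path is verified in the test suite against a brute-force
permutation oracle over every rank configuration with up to 6 observations
per group, and cross-checked against `scipy.stats.mannwhitneyu`
(`method="exact"`) on random draws; the asymptotic path stays within 0.05
of the exact p for tie-free samples up to n=10. Type-I error at n=9 vs 10
over 1,000 null replicates is calibrated to the nominal 0.05. Shapiro–Wilk
p-values are reported per group (None when a group has fewer than 3 values
or zero range, where the statistic is undefined). Significance is declared
below P=.05.

## The synthetic cohort

The simulator emulates the pilot study's conditions: 10 participants, 14
program days, a 7-day pre-enrollment baseline, a 93% per-slot check
probability and a 67.9% reply rate, with 4 recommended checks per day.

* **Checks** are independent Bernoulli draws per reminder slot. The pre
  period uses the same mechanism (optionally with its own probability
  `pre_check_prob`) at the would-be slot times.
* **Reply semantics.** `reply_prob` is the *marginal* probability that a
  prompt receives a texted value. Internally a performed check is texted
  with probability `min(1, reply_prob / check_prob)`, which guarantees that
  every texted value corresponds to a real device record while making the
  planted marginal rate recoverable from the engine's response-rate metric.
  A consequence: the marginal reply rate can never exceed the check rate.
* **Timing.** A check happens a truncated-normal delay after its reminder
  (mean 10 min, sd 8 min, floor 1 min) — patients respond to the prompt, so
  readings follow it; symmetric jitter around the slot would put a large
  fraction of replies before the reminder they answer and break linkage.
  The texted value follows the reading by 1–5 min.
* **Glucose values** are drawn from context-dependent normals — fasting
  N(85, 8), postprandial N(115, 18) mg/dL — with a 1% critical-low and 2%
  critical-high tail mixture, truncated to 20–600 and rounded to integers.
  These are invented but physiologically sensible defaults for diet- and
  insulin-managed GDM; all are configurable.
* **Enrollment** defaults to 05:00 local time, before the earliest possible
  fasting slot, so the 24-hour quiet period ends before the next day's
  first slot and every participant accrues exactly `program_days` complete
  4-reminder days. Mealtimes vary deterministically across participants
  (breakfast 06:45–08:44).
* **Reproducibility.** Each participant draws from an independent substream
  seeded by `(seed, participant_index)`, so enlarging the cohort appends
  participants without reshuffling existing ones; all outputs are
  byte-identical across runs at a fixed seed.

What the simulator does **not** model: physiological glucose dynamics or
autocorrelation, any effect of the messages on glucose values or on
subsequent checking behavior, day-to-day mealtime variation,
continuous-glucose-monitor streams, and message-content comprehension.
Passing pipeline tests therefore demonstrate that the engine and analytics
measure planted behavioral rates correctly — not that the intervention
changes real-world behavior, which is a clinical question outside this
package's scope.

## Problem sizes and numerical choices

The validation suite uses the study-scale cohort (10×14 days) for volume
and recovery checks, 9×7 days for the baseline-week scenario, 1,000 null
replicates for type-I calibration, and 100 replicates of a 20-participant
cohort with a 0.5→0.95 planted adherence jump for the power check (observed
rejection ≥90%). Exact-test enumeration is exercised exhaustively up to 6
observations per group and by random sampling up to 10. Reported adherence
percentages round half-up to integers while raw fractions are retained for
statistics; response rates are reported as percent to one decimal.

## Known limitations

* The individual-level device data behind the published pre/during medians
  (93% vs 97%) are not available, so that specific comparison cannot be
  recomputed; the pipeline instead demonstrates recovery of planted rates.
* Spanish is supported as a language tag throughout, but the shipped
  catalog contains English bodies only; requesting a missing language
  raises a catalog-gap error rather than silently falling back (the engine
  falls back to English only when rendering for an enrolled participant).
* The out-of-range (non-critical) feedback wording, the onboarding
  questions, the STOP acknowledgment and three of the four in-range replies
  are program-faithful stand-ins, not deployed texts.
* Re-sending unanswered reminders, "ate meal" keywords, weekday/weekend
  mealtimes and glucose-history graphs are deliberately absent: they were
  user suggestions, not part of the tested program.
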