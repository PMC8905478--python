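# gdmtext

Two-way SMS self-monitoring support for gestational diabetes mellitus
(GDM), implemented as a fully testable engine with no SMS gateway and no
patient data.

Women with GDM are asked to check blood glucose four times a day — fasting
and one hour after each meal — and adherence to that schedule drives
clinical decisions. `gdmtext` implements the automated texting program that
supports this behavior:

* **Reminders** — four per day, anchored to reported mealtimes: 30 minutes
  before breakfast (fasting check) and one hour after breakfast, lunch and
  dinner (postprandial checks), starting 24 hours after enrollment.
* **Two-way feedback** — texted glucose values are parsed, linked back to
  the reminder they answer, and classified by context: desired ranges are
  61–94 mg/dL fasting and 61–139 mg/dL postprandial; values ≤60 mg/dL or
  ≥200 mg/dL are critical in either context. In-range values get one of
  four rotating encouragements (strict per-participant round-robin);
  out-of-range and critical values get a reply asking the participant to
  contact her care team, with a single fixed reply per critical tier.
* **Weekly educational and motivational messages** at the participant's
  chosen day and time.
* **Opt-out** — texting `STOP` (any case) cancels all future messages after
  a single acknowledgment.
* **Adherence analytics** — self-monitoring adherence is the number of
  checks performed divided by the number recommended, capped at 100%
  (checking more than recommended still counts as full adherence; the cap
  is applied per day by default). Repeat fingersticks within 5 minutes
  collapse to one check. The pre-enrollment week is compared with the
  program fortnight using the Wilcoxon rank-sum test — exact when both
  groups have ≤10 tie-free values, a tie-corrected normal approximation
  otherwise — with Shapiro–Wilk normality checks, medians and 25th–75th
  IQRs, and a P<.05 significance threshold.
* **Synthetic cohort simulator** — per-slot Bernoulli check behavior,
  probabilistic replying, and context-dependent glucose distributions with
  critical tails, reproducible from a single seed, so the entire pipeline
  can be exercised and validated end to end.

The conversation engine is a pure state machine: time only advances through
an explicit `tick`, so replaying the same roster and inbound stream yields
a byte-identical JSON-lines message log.

## Worked example

Simulate the default cohort (10 participants, 14 program days, 93% per-slot
check probability, 67.9% reply probability) and analyze it:

```console
$ gdmtext simulate --out demo --seed 1
participants: 10
reminder prompts sent: 560
response rate: 67.3%
outputs written to demo/

$ gdmtext analyze --device demo/device_export.csv --roster demo/roster.yaml --out demo/report
pre: 257/280 recommended checks (92%)
during: 513/560 recommended checks (92%)
median adherence pre 93% (IQR 93%-93%) vs during 92% (IQR 88%-95%)
rank-sum P=1.00 (normal_approx)
report written to demo/report/
```

Reading the numbers: 10 participants × 14 days × 4 reminders is exactly 560
reply-requesting prompts. With seed 1 the realized reply rate is 67.3% —
the empirical draw around the planted 67.9% marginal reply probability.
Adherence during the program (513 of 560 recommended checks, 92%) is the
realized draw around the planted 93% check probability, and because pre and
during behavior were generated from the same probability, the rank-sum test
correctly finds no difference (P=1.00).

The same machinery is available as a library:

```python
from gdmtext import classify, Context
classify(140, Context.POSTPRANDIAL).tier   # <Tier.OUT_OF_RANGE>
classify(85, Context.FASTING).tier         # <Tier.IN_RANGE>
```

`gdmtext catalog-validate [PATH]` checks a message catalog's invariants
(all categories covered; exactly 4 rotating in-range replies and exactly
one reply per critical tier).

## Layout

| module | what it does |
| --- | --- |
| `gdmtext.catalog` | message templates, rotation groups, YAML round-trip |
| `gdmtext.scheduler` | participants, mealtime-anchored timetables, roster I/O |
| `gdmtext.glucose` | threshold classification and tier→category mapping |
| `gdmtext.engine` | the two-way conversation state machine and message log |
| `gdmtext.adherence` | capped adherence, dedup, rank-sum comparison, reports |
| `gdmtext.simulate` | seeded synthetic cohorts with known ground truth |
| `gdmtext.cli` | `gdmtext simulate / analyze / catalog-validate` |

See `docs/methods.md` for the behavioral model, parameter defaults and
design decisions.
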