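# Methods

## Scope and model

`oacost` implements a societal micro-costing comparison of two first-line
care models for knee and hip osteoarthritis in Sweden: face-to-face,
group-based education and supervised exercise at a clinic ("BOA"), and
digital delivery of the same guideline care through an app with asynchronous
physiotherapist contact ("Joint Academy"). The unit of analysis is a
12-week **episode of care**; the episode length is fixed for both models to
keep them comparable, even though digital care is open-ended in practice.

Costing follows the standard identification → quantification → valuation
workflow. Every resource is assigned to one of three societal domains —
health system (A), patient (B), other sectors (C) — and one of seven
categories (contacts, administration, technical support, training,
transportation, direct fees, emissions). The engine emits one cost item per
populated (domain, category) cell and aggregates them into a per-domain
breakdown whose grand total is, by construction, exactly the sum of the
three subtotals.

## Valuation rules

Time is valued by the human-capital method:

- **Provider time**: gross physiotherapist hourly wage × (1 + social fee
  rate). The default social fee rate is the legally mandatory minimum of
  31.42 %; a 50.1 % convention also circulates and can be selected in the
  valuation config. On-site staff time in facility-based care carries a
  further 10 % facility (rent) surcharge.
- **Patient care-contact time**: full gross population wage, net of social
  fees. (An alternative reading values all patient time as leisure; the
  full-wage rule for care contacts is the only one consistent with the
  magnitude of the published patient contact lines, and the leisure rule is
  applied to travel time only.)
- **Patient travel time**: 30 % of the gross population wage (the standard
  leisure-time reference value).
- **Group sessions**: the provider-side session cost is divided by the
  average number of participants to obtain the unit cost; the undivided
  payer-perspective figure remains available via
  `allocate_group_session`'s input.
- **Training**: one-off provider training hours are valued at the gross
  wage × 1.5 (senior-led instruction) plus social fees, then amortized over
  the episodes a trained provider delivers.
- **Technical support**: an annual stand-by budget divided by the annual
  patient count; for the face-to-face model, support is assumed to be half
  of the digital model's per-patient figure (no data exist for it).
- **Direct fees**: every patient is assumed to reach the national annual
  user-fee ceiling of 1 100 SEK.
- **Emissions**: clinic travel is assigned 0.014 t CO2 per face-to-face
  episode, monetized at an emission-rights price (see below). Digital care
  has no travel and no emissions.

All arithmetic is carried at full double precision. Whole-SEK rounding
(half away from zero) is applied only when rendering reports; published
sub-items therefore sum to published subtotals only to ±1 SEK, which the
report writer reproduces by rounding lines and subtotals independently.

Duration ranges in the digital protocol ("5–8 minutes") are resolved by a
configurable midpoint policy; the default arithmetic midpoint (6.5 min)
reproduces the documented 143-minute episode total
(3 × 15 + 15 × 6.5 = 142.5 → 143 half-up).

## Calibration of the bundled configs

The unrounded micro-data behind the published unit-cost table (its complete
supplementary version) are not publicly available. Reproducing the printed
line items bottom-up is therefore a **calibration, not a derivation**: the
bundled `boa.yaml`, `ja.yaml` and `valuation.yaml` fix the published
protocol quantities (28 one-hour face-to-face contacts; 18 digital contacts
totalling 142.5 minutes; 2 h vs one-day training; the 31.42 % / 30 % / 10 %
/ 1 100 SEK valuation parameters) and calibrate the unpublished ones so the
engine reproduces the printed table line by line:

| parameter | value | status |
|---|---|---|
| physiotherapist gross wage | 190 SEK/h | calibrated, Statistics-Sweden scale |
| population gross wage | 196.56 SEK/h | calibrated, Statistics-Sweden scale |
| average group size (BOA) | 12.43 | calibrated to the 619 SEK contacts line |
| round trip to clinic | 52.514 min × 28 visits | calibrated to the 1 445 SEK line |
| admin hours (BOA sys/pat) | 2.0048 / 6.127 h | calibrated to 651 / 1 204 SEK |
| admin hours (JA sys/pat) | 1.6432 / 0.9897 h | calibrated to 610 / 195 SEK |
| training amortization | 100.2 (BOA), 68.1 (JA) episodes/provider | calibrated to 30 / 11 SEK |
| support budget | 284 000 SEK / 1 421 patients, halved for BOA | calibrated within the admin lines |
| effective CO2 price | 4 200 SEK/t | calibrated to the 59 SEK emissions line |

Two published lines — the digital model's system and patient contact costs
(145 and 716 SEK) — cannot be reproduced from the published 143-minute
schedule at any plausible gross wage (143 min of physiotherapist time at
~190 SEK/h with fees is ≈ 590 SEK, not 145). The bundled digital config
therefore carries two explicit line-level scale factors
(`system.contacts: 0.24417`, `patient.contacts: 1.5334`) that absorb
whatever valuation the unavailable supplementary table applied. They
default to 1.0, so the pure bottom-up costing is always available by
removing them.

Three published figures are irreconcilable with the other published inputs
and are carried as flagged metadata (`PUBLISHED_UNRECONCILED`), never
computed: the program totals of "117 million" and "4.1 million" SEK
(cohort × printed unit cost gives 100 433 115 and 3 944 696 SEK), and the
total emission value of 555 747 SEK (133 t × 220 USD/t at the stated
exchange rate gives 286 862.75 SEK, implying an unpublished effective price
near 4 180 SEK/t). The published total-hours cells ("56", "139,2") have an
unclear unit and are not reproduced either.

## Cost-effectiveness

Effects are mean pain on the 0–10 numeric rating scale over the 12-week
episode: 5.7 → 3.2 under digital care (a 44 % reduction) and 5.2 → 4.1
face-to-face (21 %). The ICER divides the incremental cost by the
difference of **post-treatment scores** (3.2 − 4.1 = −0.9), the published
convention; dividing by the difference of within-arm changes
(−2.5 vs −1.1) is available via `measure="change"`. The reported integer
ICER is truncated toward zero — (2 776 − 10 611)/(3.2 − 4.1) = 8 705.55…,
reported as 8 705 — matching how the published figure was derived.
Dominance is classified on the cost-effectiveness plane with pain as a
negative outcome; ties are classified weakly (equal effect, lower cost →
dominant).

The deterministic (tornado) and probabilistic sensitivity analyses are
analytic extensions beyond the published point estimates. PSA defaults:
gamma distributions for costs (mean/sd parameterization), normal truncated
to [0, 10] for pain scores. The CEAC reports the probability that the pain
improvement, valued at a willingness-to-pay per point, exceeds the
incremental cost.

## Budget impact

The substitution scenario asks what is saved when a fraction *s* of the
9 465 face-to-face patients (2018) instead receive digital care. Two
arithmetics ship because the published scenario table does not follow the
natural formula:

- `standard`: savings = s × N_boa × (c_boa − c_ja); linear in all three.
- `as_printed`: the published rows satisfy remaining = (1 − s) × N_boa ×
  c_ja with remaining + savings constant at N_boa × c_boa. This mode
  reproduces each published row to within 0.01 % (the printed unit costs
  are whole-SEK rounded) without asserting an interpretation of that
  column.

The 60 % adherence footnote has no visible effect on the published rows;
it is exposed as an off-by-default multiplier on savings.

## Synthetic cohorts

The generator emulates the individually tailored nature of both programs:
session counts are binomially thinned by the stated participation rates
(60 % for exercise sessions, 44 % for the co-patient lecture), durations
jitter symmetrically (truncated normal, ±20 % bounds, mean preserved),
wages are lognormal around the context wage (cv 0.30), travel times are
truncated normal (sd 15 min), and pain scores are normal truncated to
[0, 10] (sd 2.0 by default). **None of these dispersions is an empirical
estimate** — the source analysis is mean-based — so they are conventions,
chosen once at realistic magnitudes and labelled as such. All randomness
derives from one integer-seeded `numpy` generator; nothing touches global
state.

What passing tests show: the generator is centred on the deterministic
pipeline (zero-variance cohorts reproduce it bit-for-bit through to the
ICER; jittered cohort means converge at the Monte-Carlo rate), and the
costing engine is internally consistent. What they do not show: anything
about real patient-level variation, selection between arms (patients
self-select their care model), or real-world adherence — none of which the
synthetic model attempts to capture.

Problem sizes used in the test suite were chosen to keep Monte-Carlo error
well below the 3-standard-error acceptance bands: 10 000 episodes for
cost-recovery checks, 50 000 draws for effect-mean recovery, 10 000 PSA
draws.

## Numerical choices

- Conservation (total = Σ subtotals) holds exactly because the total is
  computed as the sum of the subtotals in a fixed order.
- The bottom-up mean of a constant (zero-variance) cohort is returned as
  the constant itself rather than `sum/n`, avoiding a one-ulp rounding
  artifact.
- Degenerate inputs raise `ValidationError` (negative times or money, group
  size < 1, zero amortization denominators, substitution rates outside
  [0, 1], inconsistent emission decompositions beyond 1 %).
- Config validation errors name the file and field.

## Known limitations

- Line-level calibration (above) means the bundled configs reproduce the
  published table by construction where its inputs are unpublished; only
  the quantities listed as "published" are independent evidence.
- No QALY modelling: quality-of-life instruments are mentioned in the
  source setting but never analyzed, so the effect unit is the pain NRS.
- No willingness-to-pay threshold is adjudicated.
- Surgery-avoidance savings, multi-year projections, discounting and uptake
  dynamics are out of scope.
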