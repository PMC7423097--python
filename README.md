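# oacost

Societal costing and cost-effectiveness analysis of first-line osteoarthritis
(OA) care: a digital treatment platform (app-based exercise therapy with
asynchronous physiotherapist support, "Joint Academy") compared with the
established face-to-face, group-based program ("BOA") used across Sweden.

The package is aimed at health economists and health-services researchers who
want the full analysis pipeline — episode micro-costing, travel and CO2
accounting, incremental cost-effectiveness, and substitution-scenario budget
impact — as tested, reusable code with every parameter in auditable config
files, plus a synthetic-cohort generator so each stage can be validated
without any patient data.

## The model

The unit of analysis is a 12-week episode of care, costed from a societal
perspective across three domains: health system (A), patient (B), and other
sectors (C, here CO2 emissions of clinic travel). Time is valued by the
human-capital method: provider hours at the gross physiotherapist wage *w_p*
times (1 + social fees *f*), with a 10 % facility surcharge for on-site care;
patient care time at the gross population wage *w*; patient travel time at
the leisure value 0.3 *w*. Group-session costs are divided by the average
group size *g*; one-off training is amortized over the episodes a trained
provider delivers; all patients pay the annual user-fee ceiling (1 100 SEK).

Cost-effectiveness on the 0–10 pain numeric rating scale uses

    ICER = (C_JA − C_BOA) / (E_JA − E_BOA)

with post-treatment pain scores entered directly and the reported integer
truncated toward zero. Budget impact for substituting a fraction *s* of the
face-to-face cohort is `s · N_BOA · (c_BOA − c_JA)` (standard mode), with an
`as_printed` mode that reproduces the published scenario table's arithmetic.
See `docs/methods.md` for the valuation rules, the calibration of the bundled
configs, and the synthetic-data conventions.

## Worked example

```python
import oacost as oc

ctx = oc.load_valuation_context(oc.bundled_path("valuation"))
boa = oc.load_care_model(oc.bundled_path("boa"))
ja  = oc.load_care_model(oc.bundled_path("ja"))
print(oc.render_breakdown_report([oc.cost_model(boa, ctx), oc.cost_model(ja, ctx)]))
```

```
                                BOA  Joint Academy  Difference
Contacts/Visits/Sessions        619            145         474
Administration                  651            610          41
Training of physiotherapists     30             11          19
A: Sub-total                   1299            766         533
Contacts/Visits                5504            716        4788
Administration                 1204            195        1009
Transportation                 1445           <NA>        <NA>
Direct costs                   1100           1100           0
B: Sub-total                   9253           2010        7243
CO2 emissions                    59           <NA>        <NA>
C: Sub-total                     59              0          59
Total                         10611           2776        7835
```

One face-to-face episode costs 10 611 SEK to society, a digital episode
2 776 SEK — a difference of 7 835 SEK, most of it on the patient side (time
in sessions, travel), since digital care removes clinic visits entirely
(hence also the missing transport and emission lines).

The same pipeline is available from the shell:

```sh
$ oacost icer --cost-a 2776 --cost-b 10611 --effect-a 3.2 --effect-b 4.1
{"delta_cost": -7835.0, "delta_effect": -0.8999999999999995, "icer_sek_per_point": 8705, "quadrant": "dominant"}
```

Digital care is cheaper *and* reduces pain more (5.7 → 3.2, i.e. 44 %,
versus 5.2 → 4.1, i.e. 21 %), so it dominates; the ratio of 8 705 SEK per
pain point is the cost per unit of effect had the deltas been traded off.

```sh
$ oacost scenario --mode as_printed
 substitution_rate  remaining_cost    savings  savings_percent       mode
              0.25      19706130.0 80726985.0        80.378852 as_printed
              0.50      13137420.0 87295695.0        86.919235 as_printed
              0.75       6568710.0 93864405.0        93.459617 as_printed
```

Switching half of the 9 465 face-to-face patients to digital care saves
roughly 87 million SEK per year under the published table's arithmetic
(`--mode standard` gives the natural formula instead). Other subcommands:
`cost` (single-model breakdown), `emissions` (cohort CO2 and its value),
`simulate` (synthetic cohort CSV; `--seed` required), `report` (the
comparison table above, to file).

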