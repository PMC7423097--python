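# Digital first-line OA care (Joint Academy): app-delivered exercises with
# asynchronous physiotherapist contact; no clinic travel.  The protocol is the
# published 12-week schedule: three 15-minute telephone contacts plus fifteen
# 5-8-minute platform contacts (18 activities, ~143 physiotherapist minutes).
# The two line_scales entries are calibration anchors: the published contact
# cost lines cannot be reproduced from this schedule at any plausible gross
# wage, because the unrounded valuation behind the published table is not
# public; with the scales set to 1 the engine yields the pure bottom-up
# costing.  See docs/methods.md.
name: Joint Academy
episode_weeks: 12
facility_based: false
contacts:
  - label: Start-up meeting
    mode: telephone
    duration_minutes: 15
    occurrences: 1
  - label: Weekly follow-up
    mode: platform
    duration_range: {low: 5, high: 8}
    occurrences: 12
  - label: 6-week follow-up meeting
    mode: telephone
    duration_minutes: 15
    occurrences: 1
  - label: Monthly follow-up session
    mode: platform
    duration_range: {low: 5, high: 8}
    occurrences: 3
  - label: 3-month follow-up
    mode: telephone
    duration_minutes: 15
    occurrences: 1
admin:
  system_hours: 1.6432    # reading patient reports, preparing responses
  patient_hours: 0.9897   # onboarding and self-reporting time
training:
  hours_per_provider: 2.0      # online courses plus certification exam
  episodes_per_provider: 68.1  # amortization denominator (calibrated)
support:
  annual_budget: 284000   # stand-by technical support, annual budget
  annual_patients: 1421   # 2018 digital-care cohort
  halved: false
transport:
  mode: none              # care at home: no travel, no emissions
line_scales:
  system.contacts: 0.24417
  patient.contacts: 1.5334
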