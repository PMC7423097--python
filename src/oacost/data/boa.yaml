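# Face-to-face first-line OA care (BOA): group-based lectures and supervised
# exercise at a clinic over a 12-week episode.  Quantities that are not public
# (average group size, admin hours, training amortization, travel minutes,
# effective CO2 price) are calibrated so the engine reproduces the published
# unit-cost table line by line; see docs/methods.md.
name: BOA
episode_weeks: 12
facility_based: true
contacts:
  - label: OA information lecture
    mode: in_person
    duration_minutes: 60
    occurrences: 3
    group_size: 12.43
    on_site: true
    once_per_episode: true          # counted once regardless of episode length
  - label: Co-patient experience lecture
    mode: in_person
    duration_minutes: 60
    occurrences: 1
    group_size: 12.43
    on_site: true
    once_per_episode: true
    participation_key: co_patient   # 44% of patients attend
  - label: Group exercise session
    mode: in_person
    duration_minutes: 60
    occurrences: 24                 # twice weekly over 12 weeks
    group_size: 12.43
    on_site: true
    participation_key: exercise     # 60% of patients attend
admin:
  system_hours: 2.0048    # session preparation, equipment, booking (per episode)
  patient_hours: 6.127    # patient-side preparation and follow-up
training:
  hours_per_provider: 8.0       # one-day qualification course
  episodes_per_provider: 100.2  # amortization denominator (calibrated)
support:
  annual_budget: 284000   # digital model's support budget...
  annual_patients: 1421
  halved: true            # ...assumed half of it applies here, per patient
transport:
  mode: car
  round_trip_minutes: 52.514  # average round trip to a clinic (calibrated)
  visits_per_episode: 28
  emission_tons_per_episode: 0.014
  emission_price_sek_per_ton: 4200.0  # effective price behind the published line
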