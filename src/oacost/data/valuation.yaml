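# Swedish valuation context, reference year 2018 (all money in SEK).
# Wages are calibrated Statistics-Sweden-scale gross hourly rates; the
# published unit-cost table's unrounded inputs are not public, so the exact
# values were calibrated to reproduce its printed lines (see docs/methods.md).
provider_gross_hourly_wage: 190.0     # physiotherapist, SEK/h
population_gross_hourly_wage: 196.56  # general population, SEK/h
social_fee_rate: 0.3142               # legally mandatory minimum employer fees
leisure_fraction: 0.30                # patient leisure time vs gross wage
facility_surcharge: 0.10              # rent surcharge on on-site staff time
user_fee_ceiling: 1100.0              # annual out-of-pocket cap, SEK/year
training_wage_multiplier: 1.5         # senior-staff-led training valuation
fx_usd_per_100_sek: 10.2
fx_eur_per_100_sek: 9.43
reference_year: 2018
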