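# National indicator system: 20 indicators across the three subsystems
# (elderly population, healthcare resource demand, healthcare resource supply).
# reference_weight is the published average entropy weight for each indicator,
# kept as metadata for cross-checking; it is never used in computation.
- indicator_id: pop_ge60
  label: Number of persons aged >=60 years
  subsystem: elderly_population
  polarity: positive
  unit: 10,000 people
  reference_weight: 0.1154
- indicator_id: pop_ge65
  label: Number of persons aged >=65 years
  subsystem: elderly_population
  polarity: positive
  unit: 10,000 people
  reference_weight: 0.1605
- indicator_id: density_ge60
  label: Density of older persons aged >=60 years
  subsystem: elderly_population
  polarity: positive
  unit: people/km^2
  reference_weight: 0.1153
- indicator_id: density_ge65
  label: Density of older persons aged >=65 years
  subsystem: elderly_population
  polarity: positive
  unit: people/km^2
  reference_weight: 0.1605
- indicator_id: prop_ge60
  label: Proportion of population aged >=60 years
  subsystem: elderly_population
  polarity: positive
  unit: "%"
  reference_weight: 0.1125
- indicator_id: prop_ge65
  label: Proportion of population aged >=65 years
  subsystem: elderly_population
  polarity: positive
  unit: "%"
  reference_weight: 0.1623
- indicator_id: dep_ratio_ge65
  label: Dependency ratio of the elderly population aged 65 and over
  subsystem: elderly_population
  polarity: positive
  unit: "%"
  reference_weight: 0.1734
- indicator_id: bed_occupancy
  label: Hospital bed occupancy rate
  subsystem: demand
  polarity: positive
  unit: "%"
  reference_weight: 0.1649
- indicator_id: daily_visits_per_doctor
  label: Daily visits per doctor
  subsystem: demand
  polarity: positive
  unit: person-time
  reference_weight: 0.1249
- indicator_id: daily_inpatients_per_doctor
  label: Daily inpatients per doctor
  subsystem: demand
  polarity: positive
  unit: day
  reference_weight: 0.1485
- indicator_id: visits_per_capita
  label: Number of visits per inhabitant per year
  subsystem: demand
  polarity: positive
  unit: time
  reference_weight: 0.1279
- indicator_id: total_expenditure
  label: Total medical expenditures
  subsystem: demand
  polarity: negative
  unit: hundred million RMB
  reference_weight: 0.0575
- indicator_id: per_capita_cost
  label: Per capita medical costs
  subsystem: demand
  polarity: negative
  unit: RMB
  reference_weight: 0.0562
- indicator_id: oop_share
  label: Percentage of out-of-pocket medical expenses
  subsystem: demand
  polarity: negative
  unit: "%"
  reference_weight: 0.3201
- indicator_id: n_hospitals
  label: Number of hospitals
  subsystem: supply
  polarity: positive
  unit: piece
  reference_weight: 0.1355
- indicator_id: hospital_beds
  label: Number of hospital beds
  subsystem: supply
  polarity: positive
  unit: 10,000 beds
  reference_weight: 0.1271
- indicator_id: hospital_technicians
  label: Number of hospital health technicians
  subsystem: supply
  polarity: positive
  unit: 10,000 people
  reference_weight: 0.1333
- indicator_id: primary_institutions
  label: Number of primary health care institutions
  subsystem: supply
  polarity: positive
  unit: piece
  reference_weight: 0.2287
- indicator_id: primary_beds
  label: Number of beds in primary health care
  subsystem: supply
  polarity: positive
  unit: 10,000 beds
  reference_weight: 0.1704
- indicator_id: primary_technicians
  label: Number of primary health care technicians
  subsystem: supply
  polarity: positive
  unit: 10,000 people
  reference_weight: 0.2049
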