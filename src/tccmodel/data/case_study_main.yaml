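# Canadian residential-care case study: main parameter set.
# Effect-side inputs for the toileting & containment care (T&CC) cohort model:
# initial distributions, group/care-stage/skin-health transition tables,
# age-band mortality, adverse-event rates, utilities and task time/staffing.
# Currency context for the companion economics fixture: CAD, price year 2020.
meta:
  scenario: canadian_residential_care
  currency: CAD
  price_year: 2020

settings:
  cycle_length_years: 0.16666666666666666   # 2-month cycle
  discount_rate: 0.05                        # annual, costs and effects
  start_age: 86.0
  max_cycles: 240
  included_groups: [G2, G3, G4, G5, G6]      # care-dependent residential population
  survival_epsilon: 1.0e-6

# Initial cohort distributions. The care-stage split is assumed identical for
# every included group; skin health is a per-cycle mixture so its initial
# distribution is informational only.
initial_distributions:
  group: {G2: 0.21, G3: 0.46, G4: 0.19, G5: 0.09, G6: 0.05}
  care_stage: {CS1: 0.16, CS2: 0.47, CS3: 0.37}
  skin_health: {SHL1: 0.89, SHL2: 0.07, SHL3: 0.02, SHL4: 0.02, SHL5: 0.01}

# Per-cycle group (care-need profile) transitions. Deterioration only:
# no probability mass may flow to a lower-indexed group.
group_transition:
  G2: {G2: 0.935, G3: 0.063, G4: 0.002}
  G3: {G3: 0.914, G4: 0.064, G5: 0.022}
  G4: {G4: 0.393, G5: 0.585, G6: 0.022}
  G5: {G5: 0.978, G6: 0.022}
  G6: {G6: 1.000}

# Stay/worsen probabilities for residents who change group, used when
# settings.group_change_cs_rule is "shift": the care stage stays (10%) or
# worsens one step (90%), CS3 absorbing. Under the default "trial" rule,
# group-movers follow the strategy's care-stage matrix like everyone else,
# which is the convention consistent with the published cohort movement.
cs_shift_on_group_change: {stay: 0.10, worsen: 0.90}

# Probability of death per 2-month cycle by age band, weighted for sex.
# Group classes share rows: G1 alone, G4 alone, and G2/G3/G5/G6 together.
mortality:
  age_bands: [65, 75, 85, 95]   # band edges; last band is open-ended
  G1:
    mean:    [0.069, 0.064, 0.069, 0.087]
    ci_low:  [0.066, 0.063, 0.068, 0.082]
    ci_high: [0.071, 0.066, 0.071, 0.092]
  G4:
    mean:    [0.036, 0.048, 0.068, 0.102]
    ci_low:  [0.033, 0.047, 0.067, 0.094]
    ci_high: [0.038, 0.050, 0.070, 0.109]
  other:
    mean:    [0.055, 0.056, 0.069, 0.092]
    ci_low:  [0.054, 0.055, 0.068, 0.088]
    ci_high: [0.057, 0.057, 0.070, 0.097]

# Care-stage transition probabilities per cycle (trial-derived). Rows are
# printed rounded; the loader renormalizes each row to sum to one.
cs_transition:
  conventional:
    CS1: {CS1: 0.38, CS2: 0.63, CS3: 0.00}
    CS2: {CS1: 0.10, CS2: 0.45, CS3: 0.45}
    CS3: {CS1: 0.06, CS2: 0.50, CS3: 0.44}
  dht:
    CS1: {CS1: 0.25, CS2: 0.75, CS3: 0.00}
    CS2: {CS1: 0.23, CS2: 0.68, CS3: 0.09}
    CS3: {CS1: 0.06, CS2: 0.35, CS3: 0.59}

# Per-cycle skin-health assignment probabilities given care stage (SHL1..SHL5).
shl_given_cs:
  conventional:
    CS1: [1.000, 0.000, 0.000, 0.000, 0.000]
    CS2: [0.972, 0.018, 0.004, 0.004, 0.003]
    CS3: [0.875, 0.075, 0.016, 0.016, 0.013]
  dht:
    CS1: [1.000, 0.000, 0.000, 0.000, 0.000]
    CS2: [0.972, 0.018, 0.004, 0.004, 0.003]
    CS3: [1.000, 0.000, 0.000, 0.000, 0.000]

# Adverse care-consequence probabilities per cycle. Fractures are assumed
# impossible for the immobile groups G5-G6.
event_rates:
  conventional:
    fracture_g2_g4: 0.0027
    fracture_g5_g6: 0.0000
    uti: 0.0577
    constipation: 0.0894
    pu1: 0.2940
    pu2: 0.0680
    pu3: 0.0074
    pu4: 0.0154
  dht:
    fracture_g2_g4: 0.0026
    fracture_g5_g6: 0.0000
    uti: 0.0543
    constipation: 0.0787
    pu1: 0.2917
    pu2: 0.0675
    pu3: 0.0073
    pu4: 0.0153

# Baseline utility per group (CS1/SHL1 reference) and decrement magnitudes.
# Decrements are stored as non-negative magnitudes and subtracted.
utilities:
  baseline: {G1: 0.80, G2: 0.70, G3: 0.64, G4: 0.54, G5: 0.30, G6: 0.30}
  cs_decrement: {CS1: 0.000, CS2: 0.014, CS3: 0.030}
  shl_decrement: {SHL1: 0.000, SHL2: 0.033, SHL3: 0.033, SHL4: 0.035, SHL5: 0.037}
  event_decrement:
    fracture: 0.121
    uti: 0.090
    constipation: 0.030
    pu1: 0.000
    pu2: 0.037
    pu3: 0.037
    pu4: 0.037

# Average minutes per continence-care task per staff member, and staff count
# required per task, by group.
care_tasks:
  minutes:
    product_check:        {G2: 3.20, G3: 4.10, G4: 4.10, G5: 4.10, G6: 4.10}
    product_change:       {G2: 6.60, G3: 10.20, G4: 10.20, G5: 10.20, G6: 10.20}
    toileting_assistance: {G2: 9.50, G3: 11.70, G4: 11.70, G5: 11.70, G6: 11.70}
    leakage_change:       {G2: 7.40, G3: 9.10, G4: 9.10, G5: 9.10, G6: 9.10}
    shl5_treatment:       {G2: 1.00, G3: 1.00, G4: 1.00, G5: 1.00, G6: 1.00}
  staff:
    product_check:        {G2: 1.00, G3: 1.00, G4: 1.00, G5: 1.00, G6: 1.00}
    product_change:       {G2: 1.30, G3: 1.30, G4: 1.30, G5: 1.30, G6: 2.00}
    toileting_assistance: {G2: 1.30, G3: 1.30, G4: 1.30, G5: 1.30, G6: 2.00}
    leakage_change:       {G2: 1.30, G3: 1.30, G4: 1.30, G5: 1.30, G6: 2.00}
    shl5_treatment:       {G2: 1.00, G3: 1.00, G4: 1.00, G5: 1.00, G6: 1.00}

# Care-stage classification cut-offs on total 24-hour absorbency
# (Rothwell units, ISO 11948-1), per resident size class.
care_stage_absorbency_cutoffs:
  average: [3800, 5700]
  large: [4500, 6750]
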