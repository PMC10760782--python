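# SYNTHETIC economics fixture (unit costs and resource-use frequencies).
#
# The cost side of the Canadian case study depends on unit-cost and task-
# frequency tables that are not part of the bundled effect-side parameter set.
# This file supplies a complete, internally consistent set of SYNTHETIC
# placeholder values in the right units so that the cost pipeline is fully
# runnable and testable. Every value below is flagged `placeholder`; cost
# results obtained with this file characterise the model mechanics, not the
# published Canadian case study.
meta:
  synthetic: true
  currency: CAD
  price_year: 2020
  placeholder: true

labour:
  wage_formal_per_min: 0.55      # CAD per staff-minute, placeholder
  wage_informal_per_min: 0.29    # CAD per minute of informal care, placeholder
  informal_share: 0.0            # residential setting: all care is formal

# Task occurrences per resident per day, by strategy and care stage.
# Applied uniformly across groups G2-G6 (group differences enter through
# task minutes and staffing, which are group-specific).
task_frequencies_per_day:
  conventional:
    CS1: {product_check: 3.0, product_change: 2.0, toileting_assistance: 4.0, leakage_change: 0.20}
    CS2: {product_check: 3.0, product_change: 3.0, toileting_assistance: 2.5, leakage_change: 0.30}
    CS3: {product_check: 4.0, product_change: 4.0, toileting_assistance: 0.5, leakage_change: 0.40}
  dht:
    CS1: {product_check: 2.0, product_change: 1.8, toileting_assistance: 4.5, leakage_change: 0.15}
    CS2: {product_check: 2.5, product_change: 2.6, toileting_assistance: 3.0, leakage_change: 0.20}
    CS3: {product_check: 3.0, product_change: 3.5, toileting_assistance: 0.8, leakage_change: 0.30}

# Absorbent products: acquisition price (CAD/piece), laboratory absorbency
# (Rothwell units/piece) and dry weight (kg/piece), with mean daily usage
# counts per care stage and strategy.
products:
  types:
    pad_day:     {price: 0.85, absorbency: 1400, dry_weight_kg: 0.075}
    brief_heavy: {price: 1.60, absorbency: 2800, dry_weight_kg: 0.130}
  daily_counts:
    conventional:
      CS1: {pad_day: 2.0, brief_heavy: 0.3}
      CS2: {pad_day: 2.2, brief_heavy: 1.2}
      CS3: {pad_day: 1.5, brief_heavy: 2.8}
    dht:
      CS1: {pad_day: 1.8, brief_heavy: 0.2}
      CS2: {pad_day: 2.0, brief_heavy: 0.9}
      CS3: {pad_day: 1.4, brief_heavy: 2.4}

# Perineal hygiene consumable cost per application; the hygiene regime runs
# with every product change. The person-centred arm uses better products.
hygiene_cost_per_application: {conventional: 0.05, dht: 0.12}

disposal_tariff_per_kg: 0.25     # CAD per kg of dry product waste, placeholder

# Cost per adverse-event occurrence (CAD), placeholder magnitudes.
event_costs:
  fracture: 12000.0
  uti: 320.0
  constipation: 180.0
  pu1: 150.0
  pu2: 1200.0
  pu3: 4500.0
  pu4: 9000.0

# Technology acquisition (sensor hardware, software, assessment briefs),
# expressed per person-year; zero for conventional care.
technology_cost_per_person_year: {conventional: 0.0, dht: 250.0}

# Severe-dermatitis (SHL5) topical treatment: applied at every product change
# for a 7-day episode, one extra staff-minute per application.
shl5_treatment:
  minutes_per_application: 1.0
  duration_days: 7.0
  unit_cost_per_application: 0.80
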