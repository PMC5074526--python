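# Default invasiveness ranking schema: 21 criteria in four attribute
# groups (ecological impact 40, invasive characteristics 25, dispersal
# ability 25, feasibility of control 10; total 100 points).
#
# Each criterion lists its answer levels and the points they award;
# "unknown" in a scorecard excludes the criterion from scoring.  The
# point allocation is editable: scoring normalises by the answered
# maximum, so any rebalancing that keeps the group structure is valid.
name: invasiveness-ranking-default
criteria:
  # ---- ecological impact (40) ----
  - id: imp_ecosystem
    group: ecological impact
    prompt: Impact on ecosystem processes (hydrology, fire regime, nutrient cycling)
    max_points: 10
    levels: {severe: 10, major: 7, moderate: 3, negligible: 0}
  - id: imp_community
    group: ecological impact
    prompt: Impact on native plant community structure and composition
    max_points: 10
    levels: {severe: 10, major: 7, moderate: 3, negligible: 0}
  - id: imp_trophic
    group: ecological impact
    prompt: Impact on higher trophic levels (pollinators, herbivores, fauna habitat)
    max_points: 10
    levels: {severe: 10, major: 7, moderate: 3, negligible: 0}
  - id: imp_disturbance
    group: ecological impact
    prompt: Alteration of natural disturbance regimes
    max_points: 10
    levels: {severe: 10, major: 7, moderate: 3, negligible: 0}
  # ---- invasive characteristics (25) ----
  - id: inv_life_history
    group: invasive characteristics
    prompt: Invasive life-history traits (short generation time, rapid growth)
    max_points: 4
    levels: {strong: 4, some: 2, none: 0}
  - id: inv_reproduction
    group: invasive characteristics
    prompt: Reproductive output (seed production, vegetative spread)
    max_points: 4
    levels: {prolific: 4, moderate: 2, low: 0}
  - id: inv_stress_tolerance
    group: invasive characteristics
    prompt: Tolerance of environmental stress (drought, cold, salinity)
    max_points: 4
    levels: {broad: 4, intermediate: 2, narrow: 0}
  - id: inv_climate_breadth
    group: invasive characteristics
    prompt: Breadth of climates occupied in the current range
    max_points: 4
    levels: {broad: 4, intermediate: 2, narrow: 0}
  - id: inv_competitive
    group: invasive characteristics
    prompt: Competitive ability against established vegetation
    max_points: 3
    levels: {strong: 3, moderate: 2, weak: 0}
  - id: inv_allelopathy
    group: invasive characteristics
    prompt: Allelopathy or other chemical interference
    max_points: 3
    levels: {documented: 3, suspected: 1, none: 0}
  - id: inv_soil_alteration
    group: invasive characteristics
    prompt: Alteration of soil properties (e.g. nitrogen fixation, salt accumulation)
    max_points: 3
    levels: {documented: 3, suspected: 1, none: 0}
  # ---- dispersal ability (25) ----
  - id: dsp_long_distance
    group: dispersal ability
    prompt: Potential for long-distance natural dispersal (wind, water, birds)
    max_points: 5
    levels: {high: 5, moderate: 3, low: 0}
  - id: dsp_human
    group: dispersal ability
    prompt: Potential for human-mediated dispersal (trade, vehicles, horticulture)
    max_points: 5
    levels: {high: 5, moderate: 3, low: 0}
  - id: dsp_propagule_pressure
    group: dispersal ability
    prompt: Propagule pressure from nearby invaded jurisdictions
    max_points: 5
    levels: {high: 5, moderate: 3, low: 0}
  - id: dsp_seed_longevity
    group: dispersal ability
    prompt: Seed-bank longevity
    max_points: 5
    levels: {persistent: 5, intermediate: 3, transient: 0}
  - id: dsp_range_expansion
    group: dispersal ability
    prompt: Documented rate of range expansion elsewhere
    max_points: 5
    levels: {rapid: 5, moderate: 3, slow: 0}
  # ---- feasibility of control (10) ----
  - id: ctl_detection
    group: feasibility of control
    prompt: Difficulty of detection at low abundance
    max_points: 2
    levels: {hard: 2, moderate: 1, easy: 0}
  - id: ctl_eradication
    group: feasibility of control
    prompt: Difficulty of eradication once established
    max_points: 2
    levels: {hard: 2, moderate: 1, easy: 0}
  - id: ctl_regrowth
    group: feasibility of control
    prompt: Regrowth or reinvasion after treatment
    max_points: 2
    levels: {likely: 2, possible: 1, unlikely: 0}
  - id: ctl_nontarget
    group: feasibility of control
    prompt: Risk of non-target damage from available control methods
    max_points: 2
    levels: {high: 2, moderate: 1, low: 0}
  - id: ctl_cost
    group: feasibility of control
    prompt: Cost and effort of sustained control
    max_points: 2
    levels: {high: 2, moderate: 1, low: 0}
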