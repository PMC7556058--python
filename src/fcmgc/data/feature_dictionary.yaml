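# Feature dictionary for the 27 gastric-cancer risk factors.
#
# Levels are listed in ascending-activation order: the encoding maps them to
# equally spaced values {0, 1/(k-1), ..., 1}. For factors whose causal edge
# into the GC concept is negative (protective factors such as vegetable or
# fruit consumption), ascending activation means ascending *intensity* of
# the factor, not ascending risk — the edge sign carries the direction.
#
# Counts are the published per-level patient frequencies of the 560-record
# study cohort; they define the marginal distributions the synthetic cohort
# generator draws from. Counts are kept exactly as published even where the
# source table is internally inconsistent: the baking-dish levels cover only
# 421 of 560 records (the residual 139 are assigned to an explicit "other"
# level) and the BMI counts sum to 558, not 560 (marginals are normalized by
# their own total, so the two unaccounted records simply carry no mass).
# The published risk-score margin (high/moderate/low counts) is kept for
# reference; synthetic labels come from the ground-truth map, not from this
# margin.
cohort_size: 560
risk_score_counts:
  high: 300
  medium: 186
  low: 74
features:
  - id: C1
    name: sex
    category: personal
    levels: [female, male]
    counts: [304, 256]
  - id: C2
    name: blood_group
    category: personal
    levels: [O, B, AB, A]
    counts: [279, 78, 80, 123]
  - id: C3
    name: bmi
    category: personal
    levels: [under_18.5, 18.5_to_24.9, 25_to_29.9, over_30]
    counts: [293, 120, 76, 69]
  - id: C4
    name: age
    category: personal
    levels: [under_40, 41_to_60, over_60]
    counts: [20, 210, 330]
  - id: C5
    name: physical_activity
    category: personal
    levels: [light, medium, high]
    counts: [156, 236, 168]
  - id: C6
    name: alcohol_consumption
    category: personal
    levels: ["no", "yes"]
    counts: [475, 85]
  - id: C7
    name: chemical_exposure
    category: personal
    levels: ["no", "yes"]
    counts: [506, 54]
  - id: C8
    name: smoking
    category: personal
    levels: ["no", "yes"]
    counts: [362, 198]
  - id: C9
    name: salt_consumption
    category: diet_food
    levels: [none, low, high]
    counts: [10, 175, 375]
  - id: C10
    name: vegetable_consumption
    category: diet_food
    levels: [monthly, weekly, daily]
    counts: [320, 214, 26]
  - id: C11
    name: smoked_food
    category: diet_food
    levels: [none, monthly, weekly, daily]
    counts: [5, 406, 149, 0]
  - id: C12
    name: milk_consumption
    category: diet_food
    levels: ["no", "yes"]
    counts: [346, 214]
  - id: C13
    name: fast_food
    category: diet_food
    levels: [none, monthly, weekly]
    counts: [4, 241, 315]
  - id: C14
    name: fried_food
    category: diet_food
    levels: [none, monthly, weekly]
    counts: [0, 369, 191]
  - id: C15
    name: fruit_consumption
    category: diet_food
    levels: [none, monthly, weekly]
    counts: [6, 369, 185]
  - id: C16
    name: food_storage_container
    category: diet_food
    levels: [chinaware, steel, copper, aluminum, plastic]
    counts: [2, 9, 32, 216, 301]
  - id: C17
    name: baking_dish
    category: diet_food
    levels: [teflon, other, copper, aluminum]
    counts: [390, 139, 21, 10]
  - id: C18
    name: allergy_history
    category: systemic_condition
    levels: ["no", "yes"]
    counts: [471, 89]
  - id: C19
    name: family_history_of_cancer
    category: systemic_condition
    levels: ["no", "yes"]
    counts: [349, 211]
  - id: C20
    name: family_history_of_gc
    category: systemic_condition
    levels: ["no", "yes"]
    counts: [437, 123]
  - id: C21
    name: cardiovascular_history
    category: systemic_condition
    levels: ["no", "yes"]
    counts: [375, 185]
  - id: C22
    name: general_health_status
    category: systemic_condition
    levels: [good, so_so, poor]
    counts: [79, 190, 291]
  - id: C23
    name: gastric_reflux_history
    category: stomach_condition
    levels: ["no", "yes"]
    counts: [326, 234]
  - id: C24
    name: stomach_surgery_history
    category: stomach_condition
    levels: ["no", "yes"]
    counts: [512, 48]
  - id: C25
    name: stomach_infection_history
    category: stomach_condition
    levels: ["no", "yes"]
    counts: [384, 176]
  - id: C26
    name: mucosa_status
    category: stomach_condition
    levels: [normal, swollen, red, sore]
    counts: [94, 126, 157, 183]
  - id: C27
    name: gastric_inflammation_history
    category: stomach_condition
    levels: ["no", "yes"]
    counts: [397, 163]
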