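# Default nutritional constraints applied by the diet optimiser.
#
# Values follow widely used population intake goals (total fat, saturated
# fat and free sugars as shares of dietary energy; fibre and sodium in
# absolute grams per day; a 400 g/day floor on combined fruit and
# vegetables).  They are defaults, editable per analysis, not a normative
# claim about any specific guideline edition.
#
# percent_energy bounds are percentages of total dietary energy; because
# total energy is held at its baseline value during optimisation they are
# linear in the consumption vector.  energy_per_g converts grams of the
# nutrient to kcal (Atwater factors).
energy_nutrient: energy
energy_equality: true
liquid_proportion_equality: true
fruit_veg_min_g: 400.0
nutrients:
  fat:
    upper: 30.0
    percent_energy: true
    energy_per_g: 9.0
  saturated_fat:
    upper: 10.0
    percent_energy: true
    energy_per_g: 9.0
  free_sugars:
    upper: 10.0
    percent_energy: true
    energy_per_g: 4.0
  fibre:
    lower: 25.0
  sodium:
    upper: 2.0
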