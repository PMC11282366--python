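# Default trait-by-environment rule table for ordered terrestriality grades.
#
# Grades follow the habitat associations of the two-pathway framework:
#   grade 0  fully marine
#   grade 1  lower intertidal (direct) / estuaries (indirect)
#   grade 2  upper intertidal (direct) / freshwater (indirect)
#   grade 3  beaches (direct) / riverbanks (indirect)
#   grade 4-5  coastal forests and jungles, incl. tree climbing
#
# This shipped table is an editable approximation assembled from habitat
# associations summarised in the natural-history literature; users with
# their own codings should supply a file with the same structure.

vocabulary:
  adult_habitat:
    - marine subtidal
    - marine reef
    - deep sea
    - hydrothermal vent
    - lower intertidal
    - estuary
    - mangrove
    - upper intertidal
    - freshwater
    - beach
    - riverbank
    - coastal forest
    - jungle
  osmoregulatory_status: [osmoconformer, weak regulator, strong regulator, unknown]
  larval_development: [planktonic marine, abbreviated, direct, unknown]
  respiratory_structure: [gills, gills and lung, branchiostegal lung, unknown]
  water_wicking_setae: [present, absent, unknown]
  burrow_type: [none, simple, deep, inland, unknown]
  diurnal_activity: [nocturnal, diurnal, both, unknown]

habitat_rules:
  - {habitat: marine subtidal,   grade: 0, pathway: none}
  - {habitat: marine reef,       grade: 0, pathway: none}
  - {habitat: deep sea,          grade: 0, pathway: none}
  - {habitat: hydrothermal vent, grade: 0, pathway: none}
  - {habitat: lower intertidal,  grade: 1, pathway: direct}
  - {habitat: estuary,           grade: 1, pathway: indirect}
  - {habitat: mangrove,          grade: 1, pathway: direct}
  - {habitat: upper intertidal,  grade: 2, pathway: direct}
  - {habitat: freshwater,        grade: 2, pathway: indirect}
  - {habitat: beach,             grade: 3, pathway: direct}
  - {habitat: riverbank,         grade: 3, pathway: indirect}
  - {habitat: coastal forest,    grade: 4, pathway: direct}
  - {habitat: jungle,            grade: 4, pathway: direct}

# Within the 4-5 band, full independence markers promote grade 4 -> 5.
upgrade_to_5:
  respiratory_structure: [branchiostegal lung]
  water_wicking_setae: [present]
  burrow_type: [inland]
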