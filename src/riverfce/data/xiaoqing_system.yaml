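# Multifunctional-river indicator system for the Xiaoqing River main stem:
# four criterion-layer functions (A1-A4), twelve sub-criterion functions
# (B1-B12) and twenty-two indicators (C1-C22), each with five grade
# intervals I (excellent) .. V (poor) in the indicator's own units.
#
# Interval notation: "[a, b)" etc.; "> v" / ">= v" for unbounded extreme
# grades; "= v" for a single-point grade; a two-element list gives the two
# branches of a bidirectional (best-in-central-band) indicator.
hierarchy:
  criteria:
    A1: [B1, B2, B3]      # environmental function
    A2: [B4, B5, B6]      # ecological function
    A3: [B7, B8, B9]      # social function
    A4: [B10, B11, B12]   # economic function
  subcriteria:
    B1: [C1, C2]          # hydrological function
    B2: [C3, C4, C5]      # water quality purification
    B3: [C6]              # self-repair / regulation
    B4: [C7, C8, C9]      # biological habitat
    B5: [C10, C11]        # river corridor
    B6: [C12]             # soil and water conservation
    B7: [C13, C14]        # flood control and transportation
    B8: [C15, C16]        # water supply
    B9: [C17]             # recreation
    B10: [C18, C19]       # economic benefit
    B11: [C20]            # aquaculture benefit
    B12: [C21, C22]       # tourist industry benefit

indicators:
  - id: C1
    name: Monthly average flow rate of change
    unit: "%"
    direction: negative
    criterion: A1
    subcriterion: B1
    grades: {I: "[0, 0.2]", II: "(0.2, 0.4]", III: "(0.4, 0.6]", IV: "(0.6, 0.8]", V: "> 0.8"}
  - id: C2
    name: Degree of ecological flow satisfaction
    unit: "%"
    direction: positive
    criterion: A1
    subcriterion: B1
    grades: {I: "[98, 100]", II: "[90, 98)", III: "[80, 90)", IV: "[60, 80)", V: "[0, 60)"}
  - id: C3
    name: Rate of drinking water source water quality standards
    unit: "%"
    direction: positive
    criterion: A1
    subcriterion: B2
    grades: {I: "[90, 100]", II: "[80, 90)", III: "[70, 80)", IV: "[60, 70)", V: "[0, 60)"}
  - id: C4
    name: Surface water quality (single-factor class score)
    unit: "-"
    direction: categorical
    criterion: A1
    subcriterion: B2
    grades: {I: "= 5", II: "= 4", III: "= 3", IV: "= 2", V: "= 1"}
  - id: C5
    name: Substrate contamination index
    unit: "-"
    direction: negative
    criterion: A1
    subcriterion: B2
    grades: {I: "[0, 1)", II: "[1, 2)", III: "[2, 3)", IV: "[3, 5)", V: ">= 5"}
  - id: C6
    name: Self-purification capacity of water bodies (dissolved oxygen)
    unit: mg/L
    direction: positive
    criterion: A1
    subcriterion: B3
    grades: {I: "> 7.5", II: "(5, 7.5]", III: "(3, 5]", IV: "(2, 3]", V: "[0, 2]"}
  - id: C7
    name: Phytoplankton diversity index
    unit: "-"
    direction: positive
    criterion: A2
    subcriterion: B4
    grades: {I: "> 3", II: "(2, 3]", III: "(1, 2]", IV: "(0, 1]", V: "= 0"}
  - id: C8
    name: Zooplankton diversity index
    unit: "-"
    direction: positive
    criterion: A2
    subcriterion: B4
    grades: {I: "> 3", II: "(2, 3]", III: "(1, 2]", IV: "(0, 1]", V: "= 0"}
  - id: C9
    name: Benthic macroinvertebrate diversity index
    unit: "-"
    direction: positive
    criterion: A2
    subcriterion: B4
    grades: {I: "> 3", II: "(2, 3]", III: "(1, 2]", IV: "(0, 1]", V: "= 0"}
  - id: C10
    name: River vertical connection index
    unit: pcs/100 km
    direction: negative
    criterion: A2
    subcriterion: B5
    grades: {I: "[0, 0.3)", II: "[0.3, 0.5)", III: "[0.5, 0.8)", IV: "[0.8, 1.2)", V: ">= 1.2"}
  - id: C11
    name: Landscape fragmentation
    unit: "%"
    direction: negative
    criterion: A2
    subcriterion: B5
    grades: {I: "[0, 30]", II: "(30, 60]", III: "(60, 80]", IV: "(80, 90]", V: "(90, 100]"}
  - id: C12
    name: Suspended sand transportation modulus
    unit: t/km^2
    direction: negative
    criterion: A2
    subcriterion: B6
    grades: {I: "[0, 50]", II: "(50, 100]", III: "(100, 200]", IV: "(200, 500]", V: "> 500"}
  - id: C13
    name: Attainment rate of flood control engineering measures
    unit: "%"
    direction: positive
    criterion: A3
    subcriterion: B7
    grades: {I: "[95, 100]", II: "[85, 95)", III: "[70, 85)", IV: "[50, 70)", V: "[0, 50)"}
  - id: C14
    name: Percentage of navigable river sections
    unit: "%"
    direction: positive
    criterion: A3
    subcriterion: B7
    grades: {I: "[90, 100]", II: "[80, 90)", III: "[60, 80)", IV: "[30, 60)", V: "[0, 30)"}
  - id: C15
    name: Modulus of groundwater resources
    unit: million m^3/km^2
    direction: positive
    criterion: A3
    subcriterion: B8
    grades: {I: "> 50", II: "(30, 50]", III: "(20, 30]", IV: "(10, 20]", V: "[0, 10]"}
  - id: C16
    name: Utilization rate of water resources
    unit: "%"
    direction: bidirectional
    criterion: A3
    subcriterion: B8
    grades:
      I: "[25, 30]"
      II: ["[20, 25)", "(30, 40]"]
      III: ["[10, 20)", "(40, 50]"]
      IV: ["[5, 10)", "(50, 60]"]
      V: ["[0, 5)", "(60, 100]"]
  - id: C17
    name: Degree of human activity demand satisfaction
    unit: "%"
    direction: positive
    criterion: A3
    subcriterion: B9
    grades: {I: "[90, 100]", II: "[80, 90)", III: "[60, 80)", IV: "[30, 60)", V: "[0, 30)"}
  - id: C18
    name: Per capita GDP
    unit: "10^4 CNY"
    direction: positive
    criterion: A4
    subcriterion: B10
    grades: {I: "> 15", II: "(12, 15]", III: "(10, 12]", IV: "(5, 10]", V: "[0, 5]"}
  - id: C19
    name: Water consumption per 10^4 CNY GDP
    unit: m^3
    direction: negative
    criterion: A4
    subcriterion: B10
    grades: {I: "[0, 15)", II: "[15, 25)", III: "[25, 45)", IV: "[45, 80)", V: ">= 80"}
  - id: C20
    name: Fish production capacity
    unit: "-"
    direction: positive
    criterion: A4
    subcriterion: B11
    grades: {I: "[90, 100]", II: "[80, 90)", III: "[60, 80)", IV: "[30, 60)", V: "[0, 30)"}
  - id: C21
    name: Average tourist flow index
    unit: "-"
    direction: positive
    criterion: A4
    subcriterion: B12
    grades: {I: "> 3", II: "(2, 3]", III: "(1, 2]", IV: "(0, 1]", V: "= 0"}
  - id: C22
    name: Visibility of scenic area
    unit: "%"
    direction: positive
    criterion: A4
    subcriterion: B12
    grades: {I: "[90, 100]", II: "[80, 90)", III: "[60, 80)", IV: "[30, 60)", V: "[0, 30)"}
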