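# Printed phase-comparison fixtures: published 2x2 counts with the p-values
# and matched odds-ratio confidence intervals printed alongside them.
# Orientation (which group is row 1) follows the direction each comparison
# was reported in, which is not uniform across the published tables; it is
# data, not code.  `printed_p` is a string to preserve "<" bounds and the
# printed rounding.  `p_convention` records the two-sided convention under
# which the printed p-value reproduces (all but one reproduce under the
# matched minlike ordering; the fluids comparison reproduces only under the
# doubled-one-sided convention, evidently computed with different software).
comparisons:
  - id: fluids_given
    description: received any fluid therapy, observation vs intervention
    group1: observation
    group2: intervention
    events1: 714
    total1: 978
    events2: 874
    total2: 1123
    printed_p: "0.012"
    p_convention: doubled
    printed_ci: [0.63, 0.94]
  - id: hospitalization
    description: admitted >24 h, intervention vs observation
    group1: intervention
    group2: observation
    events1: 548
    total1: 1123
    events2: 578
    total2: 978
    printed_p: "<0.001"
    printed_ci: [0.55, 0.79]
  - id: severe_aki_followup_mortality_hospitalized
    description: >-
      follow-up mortality among hospitalized severe (stage 2-3) AKI,
      observation vs intervention
    group1: observation
    group2: intervention
    events1: 27
    total1: 135
    events2: 21
    total2: 178
    printed_p: "0.057"
    printed_ci: [0.98, 3.52]
  - id: de_novo_ckd_overall
    description: de novo CKD during follow-up, observation vs intervention
    group1: observation
    group2: intervention
    events1: 37
    total1: 186
    events2: 42
    total2: 298
    printed_p: "0.101"
    printed_ci: [0.91, 2.47]
  - id: de_novo_ckd_6mo
    description: de novo CKD at 6 months, observation vs intervention
    group1: observation
    group2: intervention
    events1: 21
    total1: 96
    events2: 16
    total2: 134
    printed_p: "0.047"
  - id: stage2_overall_mortality
    description: overall mortality in stage-2 AKI, observation vs intervention
    group1: observation
    group2: intervention
    events1: 11
    total1: 46
    events2: 9
    total2: 92
    printed_p: "0.039"
  - id: in_hospital_mortality
    description: in-hospital mortality, observation vs intervention
    group1: observation
    group2: intervention
    events1: 38
    total1: 578
    events2: 67
    total2: 548
    printed_p: "0.001"
  - id: ckd_among_admitted
    description: CKD share of admissions, observation vs intervention
    group1: observation
    group2: intervention
    events1: 34
    total1: 578
    events2: 15
    total2: 548
    printed_p: "0.012"
  - id: stage3_share_of_aki
    description: stage-3 share among AKI, observation vs intervention
    group1: observation
    group2: intervention
    events1: 103
    total1: 240
    events2: 135
    total2: 388
    printed_p: "0.043"
  - id: nkd_among_admitted
    description: NKD share of admissions, observation vs intervention
    group1: observation
    group2: intervention
    events1: 125
    total1: 578
    events2: 83
    total2: 548
    printed_p: "0.006"
  - id: akd_vs_aki_in_hospital_mortality
    description: in-hospital mortality, AKD (no AKI) vs AKI at 7 days
    group1: AKD
    group2: AKI
    events1: 59
    total1: 351
    events2: 19
    total2: 518
    printed_p: "<0.001"
    printed_ci: [3.10, 9.38]
  - id: hospitalized_vs_non_mortality
    description: 6-month mortality, hospitalized vs non-hospitalized
    group1: hospitalized
    group2: non_hospitalized
    events1: 217
    total1: 1126
    events2: 56
    total2: 975
    printed_p: "<0.001"
    printed_ci: [2.88, 5.34]
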