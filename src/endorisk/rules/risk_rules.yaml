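# Prognostic risk-group rule tables, version 1.
#
# Each system is an ordered rule list evaluated top-down; the first rule
# whose conditions all hold fires.  Ordering encodes precedence
# (advanced -> high -> high-intermediate -> intermediate -> low), which makes
# overlap resolution explicit.  Conditions match on a derived feature
# vector:
#   stage:    IA | IB | II | III | IVA | IVB
#   histo:    endometrioid | non_endometrioid
#   grade:    low | high
#   lvsi:     absent | focal | substantial      (three-tier)
#   lvsi_binary: negative | positive            (focal|substantial -> positive)
#   invaded:  "true" | "false"                  (any myometrial invasion)
#   depth:    none | lt50 | ge50
#   residual: "true" | "false"
#   subgroup: POLE | MMRd | p53abn | NSMP | unknown
version: 1
systems:
  esmo2016:
    # Clinicopathologic-only system; LVSI is binarized (focal counts as
    # positive), depth of invasion is the recorded field, and non-endometrioid
    # histotypes are high risk at any early stage.
    - id: esmo2016.advanced_residual
      class: advanced_metastatic
      when: {stage: [III], residual: ["true"]}
    - id: esmo2016.advanced_stage_iv
      class: advanced_metastatic
      when: {stage: [IVA, IVB]}
    - id: esmo2016.high_non_endometrioid
      class: high
      when: {histo: [non_endometrioid]}
    - id: esmo2016.high_stage_ii_iii
      class: high
      when: {stage: [II, III]}
    - id: esmo2016.high_g3_deep
      class: high
      when: {stage: [IA, IB], grade: [high], depth: [ge50]}
    - id: esmo2016.high_intermediate_g3_superficial
      class: high_intermediate
      when: {stage: [IA, IB], grade: [high]}
    - id: esmo2016.high_intermediate_lvsi
      class: high_intermediate
      when: {stage: [IA, IB], grade: [low], lvsi_binary: [positive]}
    - id: esmo2016.intermediate_deep
      class: intermediate
      when: {stage: [IA, IB], grade: [low], depth: [ge50], lvsi_binary: [negative]}
    - id: esmo2016.low
      class: low
      when: {stage: [IA, IB], grade: [low], depth: [none, lt50], lvsi_binary: [negative]}

  esgo2020_unknown:
    # 2020 guidelines without molecular data.  Focal LVSI is grouped with
    # absent; only substantial LVSI raises the class.
    - id: esgo2020u.advanced_residual
      class: advanced_metastatic
      when: {stage: [III, IVA], residual: ["true"]}
    - id: esgo2020u.metastatic_ivb
      class: advanced_metastatic
      when: {stage: [IVB]}
    - id: esgo2020u.high_stage_iii_iva
      class: high
      when: {stage: [III, IVA]}
    - id: esgo2020u.high_non_endometrioid_invasive
      class: high
      when: {stage: [IA, IB, II], histo: [non_endometrioid], invaded: ["true"]}
    - id: esgo2020u.high_intermediate_stage_ii
      class: high_intermediate
      when: {stage: [II]}
    - id: esgo2020u.high_intermediate_substantial_lvsi
      class: high_intermediate
      when: {stage: [IA, IB], histo: [endometrioid], lvsi: [substantial]}
    - id: esgo2020u.high_intermediate_ib_high_grade
      class: high_intermediate
      when: {stage: [IB], histo: [endometrioid], grade: [high]}
    - id: esgo2020u.intermediate_non_endometrioid_no_invasion
      class: intermediate
      when: {stage: [IA, IB], histo: [non_endometrioid], invaded: ["false"]}
    - id: esgo2020u.intermediate_ib_low_grade
      class: intermediate
      when: {stage: [IB], histo: [endometrioid], grade: [low]}
    - id: esgo2020u.intermediate_ia_high_grade
      class: intermediate
      when: {stage: [IA], histo: [endometrioid], grade: [high]}
    - id: esgo2020u.low
      class: low
      when: {stage: [IA], histo: [endometrioid], grade: [low]}

  esgo2020_known:
    # 2020 guidelines with the molecular subgroup integrated.  Advanced-stage
    # (III/IV) disease is high risk or worse regardless of subgroup; in
    # stage I-II a POLE-mutant tumor is down-staged to low risk (including
    # high-grade and stage II tumors) and p53abn with myometrial invasion is
    # up-staged to high risk.  MMRd and NSMP follow the clinicopathologic
    # rules.
    - id: esgo2020k.advanced_residual
      class: advanced_metastatic
      when: {stage: [III, IVA], residual: ["true"]}
    - id: esgo2020k.metastatic_ivb
      class: advanced_metastatic
      when: {stage: [IVB]}
    - id: esgo2020k.high_stage_iii_iva
      class: high
      when: {stage: [III, IVA]}
    - id: esgo2020k.low_pole_early_stage
      class: low
      when: {stage: [IA, IB, II], subgroup: [POLE]}
    - id: esgo2020k.high_p53abn_invasive
      class: high
      when: {stage: [IA, IB, II], subgroup: [p53abn], invaded: ["true"]}
    - id: esgo2020k.high_non_endometrioid_invasive
      class: high
      when: {stage: [IA, IB, II], histo: [non_endometrioid], invaded: ["true"]}
    - id: esgo2020k.intermediate_p53abn_no_invasion
      class: intermediate
      when: {stage: [IA, IB, II], subgroup: [p53abn], invaded: ["false"]}
    - id: esgo2020k.intermediate_non_endometrioid_no_invasion
      class: intermediate
      when: {stage: [IA, IB], histo: [non_endometrioid], invaded: ["false"]}
    - id: esgo2020k.high_intermediate_stage_ii
      class: high_intermediate
      when: {stage: [II]}
    - id: esgo2020k.high_intermediate_substantial_lvsi
      class: high_intermediate
      when: {stage: [IA, IB], histo: [endometrioid], lvsi: [substantial]}
    - id: esgo2020k.high_intermediate_ib_high_grade
      class: high_intermediate
      when: {stage: [IB], histo: [endometrioid], grade: [high]}
    - id: esgo2020k.intermediate_ib_low_grade
      class: intermediate
      when: {stage: [IB], histo: [endometrioid], grade: [low]}
    - id: esgo2020k.intermediate_ia_high_grade
      class: intermediate
      when: {stage: [IA], histo: [endometrioid], grade: [high]}
    - id: esgo2020k.low
      class: low
      when: {stage: [IA], histo: [endometrioid], grade: [low]}
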