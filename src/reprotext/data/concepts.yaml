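# Concept inventory for Chinese reproductive outpatient notes.
#
# rule:
#   quantity     keyword + numeric quantity + optional unit
#   categorical  keyword + qualitative token
#   date         calendar date (year/month/day), used to time repeated tests
#
# timed concepts are followed over occasions as (date, value) series; the
# others keep the first occurring value only.
#
# plausible_range bounds are the postprocessing sanity window (editable);
# gap is the keyword-to-value matching style (tight: optional separator
# only; loose: a short non-numeric filler such as 厚度/卵泡数 may intervene).

concepts:
  - name: menarche_age
    field: menstrual_history
    keywords: ["初潮"]
    rule: quantity
    timed: false
    gap: loose
    units: ["岁"]
    plausible_range: [8, 20]
  - name: menstrual_cycle
    field: menstrual_history
    keywords: ["月经周期", "/"]
    rule: quantity
    timed: false
    gap: loose
    units: ["天"]
    plausible_range: [10, 365]
  - name: menstruation_amount
    field: menstrual_history
    keywords: ["量"]
    rule: categorical
    timed: false
    gap: tight
    categories: ["偏少", "偏多", "少", "中", "多"]
    plausible_range: null
  - name: exam_date
    field: hormone_test
    keywords: ["年", "月", "日"]
    rule: date
    timed: false
    gap: tight
    plausible_range: null
  - name: fsh
    field: hormone_test
    keywords: ["FSH"]
    rule: quantity
    timed: true
    gap: tight
    units: ["mIU/ml", "mIU/mL", "IU/L", "U/L"]
    plausible_range: [0, 200]
  - name: lh
    field: hormone_test
    keywords: ["LH"]
    rule: quantity
    timed: true
    gap: tight
    units: ["mIU/ml", "mIU/mL", "IU/L", "U/L"]
    plausible_range: [0, 200]
  - name: e2
    field: hormone_test
    keywords: ["E2", "E"]
    rule: quantity
    timed: true
    gap: tight
    units: ["pg/ml", "pg/mL", "pmol/L"]
    plausible_range: [0, 10000]
  - name: p
    field: hormone_test
    keywords: ["PRGE", "PRG", "P"]
    rule: quantity
    timed: true
    gap: tight
    units: ["ng/ml", "ng/mL", "nmol/L"]
    plausible_range: [0, 300]
  - name: prl
    field: hormone_test
    keywords: ["PRL"]
    rule: quantity
    timed: true
    gap: tight
    units: ["ng/ml", "ng/mL", "mIU/L"]
    plausible_range: [0, 10000]
  - name: t
    field: hormone_test
    keywords: ["TEST", "T"]
    rule: quantity
    timed: true
    gap: tight
    units: ["ng/ml", "ng/mL", "nmol/L"]
    plausible_range: [0, 100]
  - name: amh
    field: hormone_test
    keywords: ["AMH", "抗苗勒管激素", "抗苗勒氏激素"]
    rule: quantity
    timed: true
    gap: tight
    units: ["ng/ml", "ng/mL", "pmol/L"]
    plausible_range: [0, 30]
  - name: endometrial_thickness
    field: ultrasound
    keywords: ["内膜厚", "内膜", "En"]
    rule: quantity
    timed: true
    gap: loose
    units: ["mm"]
    plausible_range: [1, 30]
  - name: uterine_position
    field: ultrasound
    keywords: ["子宫", "UT"]
    rule: categorical
    timed: false
    gap: tight
    categories: ["水平位", "前位", "后位", "中位", "前倾", "后倾"]
    plausible_range: null
  - name: afc_left
    field: ultrasound
    keywords: ["左侧卵巢", "左卵巢", "左侧附件", "左附件", "Lov"]
    rule: quantity
    timed: true
    gap: loose
    units: ["个", "枚"]
    plausible_range: [0, 60]
  - name: afc_right
    field: ultrasound
    keywords: ["右侧卵巢", "右卵巢", "右侧附件", "右附件", "Rov"]
    rule: quantity
    timed: true
    gap: loose
    units: ["个", "枚"]
    plausible_range: [0, 60]
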