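# Default 12-question thyroid cancer extraction schema: staging (T, N, TNM)
# and recurrence-risk fields. Conditional items (q5, q12) apply only when
# their trigger question is answered "yes"; otherwise their canonical
# answer is not_applicable.
questions:
  - question_id: q1
    text: "What is the size of the primary tumor?"
    answer_type: size_cm
    group: T
  - question_id: q2
    text: "Does the tumor extend beyond the capsule of the thyroid?"
    answer_type: boolean
    group: T
  - question_id: q3
    text: "Where is the primary cancer located (right thyroid lobe, left thyroid lobe, or isthmus)?"
    answer_type: location
    group: T
  - question_id: q4
    text: "Were any cervical lymph nodes present?"
    answer_type: boolean
    group: N
  - question_id: q5
    text: "If cervical lymph nodes are present, how many lymph nodes were positive for malignancy?"
    answer_type: count
    group: N
    depends_on: [q4, true]
  - question_id: q6
    text: "What is the final pathology TNM stage of the thyroid cancer?"
    answer_type: tnm_stage
    group: TNM
  - question_id: q7
    text: "Is vascular invasion present?"
    answer_type: boolean
    group: recurrence_risk
  - question_id: q8
    text: "Is lymphatic invasion present?"
    answer_type: boolean
    group: recurrence_risk
  - question_id: q9
    text: "What was the histology of the primary cancer?"
    answer_type: histology
    group: recurrence_risk
  - question_id: q10
    text: "Was there a variant of thyroid cancer such as tall cell, hobnail variant, or columnar cell variant present, indicative of a more aggressive histology?"
    answer_type: variant
    group: recurrence_risk
  - question_id: q11
    text: "Was there a second thyroid cancer present?"
    answer_type: boolean
    group: recurrence_risk
  - question_id: q12
    text: "If there was a second thyroid cancer present, what was the histology?"
    answer_type: histology
    group: recurrence_risk
    depends_on: [q11, true]
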