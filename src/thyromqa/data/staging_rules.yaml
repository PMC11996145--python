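# Simplified AJCC 8th-edition T/N thresholds and ATA 2015 recurrence-risk
# features for differentiated thyroid carcinoma, as used by the 12-question
# extraction schema. Deliberately omits T4, the N1a/N1b split, M staging and
# microscopic-ETE nuance; the synthetic generator never emits such cases.
version: ajcc8-ata2015-simplified-1
t_category:
  # size thresholds in cm; upper bounds are inclusive
  t1a_max_cm: 1.0
  t1b_max_cm: 2.0
  t2_max_cm: 4.0
  # gross extrathyroidal extension into strap muscles overrides size
  gross_ete_category: T3b
n_category:
  n1_min_positive: 1
recurrence_risk:
  high_features: [gross_ete]
  intermediate_features: [vascular_invasion, aggressive_variant, nodal_disease]
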