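# Child and Adolescent Trauma Screen-2 (CATS-2), 20-item PTSD symptom
# section (0-to-3 Likert); unidimensional.  The source questionnaire labels
# symptom items 16-35 (following a 15-item trauma-exposure checklist that is
# out of scope here) and presents a few items with lettered response
# variants (24a-d, 25a-b, 30a-b) that collapse to one score each; the
# bundled spec therefore carries 20 items with ids 16..35.
name: cats2
title: Child and Adolescent Trauma Screen-2 (symptom section)
rater: self
age_range: [7, 18]
n_categories: 4
items: [16, 17, 18, 19, 20, 21, 22, 23, 24, 25, 26, 27, 28, 29, 30, 31,
        32, 33, 34, 35]
subscales:
  unidimensional: [16, 17, 18, 19, 20, 21, 22, 23, 24, 25, 26, 27, 28, 29,
                   30, 31, 32, 33, 34, 35]
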