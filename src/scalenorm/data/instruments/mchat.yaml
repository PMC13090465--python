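# Modified Checklist for Autism in Toddlers - Revised (MCHAT-R/F).
# 20 yes/no items; unidimensional.
name: mchat
title: Modified Checklist for Autism in Toddlers - Revised
rater: caregiver
age_range: [1, 3]
n_categories: 2
items: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20]
subscales:
  unidimensional: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16,
                   17, 18, 19, 20]
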