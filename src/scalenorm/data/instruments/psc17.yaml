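# Pediatric Symptom Checklist, 17-item shortened version.
# 0-to-2 Likert items; three-factor structure.
name: psc17
title: Pediatric Symptom Checklist - 17
rater: caregiver
age_range: [6, 18]
n_categories: 3
items: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17]
subscales:
  externalizing: [4, 5, 8, 10, 12, 14, 16]
  internalizing: [2, 6, 9, 11, 15]
  attention: [1, 3, 7, 13, 17]
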