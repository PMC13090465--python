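# Swanson, Nolan and Pelham Scale (SNAP-IV), 26 items.
# 0-to-3 Likert items; four-factor structure with hyperactivity and
# impulsivity split into separate subscales.
name: snap4
title: Swanson, Nolan and Pelham Scale (SNAP-IV)
rater: caregiver
age_range: [6, 18]
n_categories: 4
items: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18,
        19, 20, 21, 22, 23, 24, 25, 26]
subscales:
  inattention: [1, 2, 3, 4, 5, 6, 7, 8, 9]
  hyperactivity: [10, 11, 12, 13, 14]
  impulsivity: [15, 16, 17, 18]
  oppositional: [19, 20, 21, 22, 23, 24, 25, 26]
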