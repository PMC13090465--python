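# Revised Children's Anxiety and Depression Scale, 25-item short version.
# 0-to-3 Likert items; two-factor structure (anxiety / depression).
name: rcads25
title: Revised Children's Anxiety and Depression Scale - 25
rater: self
age_range: [8, 18]
n_categories: 4
items: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18,
        19, 20, 21, 22, 23, 24, 25]
subscales:
  anxiety: [2, 3, 5, 6, 7, 9, 11, 12, 14, 17, 18, 20, 22, 23, 25]
  depression: [1, 4, 8, 10, 13, 15, 16, 19, 21, 24]
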