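# Child Autism Spectrum Test (CAST), 28-item two-factor version
# (16 social-contact + 12 inflexible/repetitive items).  Item ids keep the
# original 37-item numbering used by the distributor.
name: cast
title: Child Autism Spectrum Test
rater: caregiver
age_range: [3, 6]
n_categories: 2
items: [1, 2, 5, 7, 8, 9, 10, 11, 13, 15, 16, 17, 18, 20, 21, 23, 24, 25,
        27, 28, 29, 30, 31, 32, 34, 35, 36, 37]
subscales:
  social_contact: [1, 2, 5, 8, 10, 11, 13, 15, 16, 17, 21, 23, 24, 27, 31, 35]
  inflexible_repetitive: [7, 9, 18, 20, 25, 28, 29, 30, 32, 34, 36, 37]
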