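# scalenorm

Psychometric validation and local norming for ordinal mental-health
screening questionnaires, built around item response theory.

`scalenorm` is for researchers and clinical-measurement teams who need to
(1) check whether a screening instrument's subscales behave as
unidimensional, locally independent, monotone scales in a new population,
and (2) turn raw summed scores into interpretable normative metrics
(Z-scores, T-scores, percentiles, severity bands) for that population.
It ships structural definitions for six widely used child/adolescent
instruments — PSC-17, RCADS-25, SNAP-IV, MCHAT-R/F, CAST, and the CATS-2
symptom scale — and a synthetic-cohort generator so the entire pipeline is
testable without any data download.

## The model

Each subscale is calibrated with a unidimensional **graded response model
(GRM)**.  For item *j* with ordered categories *k = 0..K−1*, discrimination
*a<sub>j</sub>* and ordered thresholds *b<sub>j1</sub> < … <
b<sub>j,K−1</sub>*, the boundary curves are logistic in the latent trait θ:

    P(X_j >= k | θ) = 1 / (1 + exp(−a_j (θ − b_jk)))

and category probabilities are differences of adjacent boundaries.  Binary
items are the K = 2 special case (two-parameter logistic).  The **graded
rating scale model (GRSM)** variant constrains all items to one shared step
vector plus a per-item location.  Calibration is marginal maximum
likelihood (EM over a fixed quadrature grid, N(0,1) latent prior); scoring
is EAP (posterior mean of θ).

On top of the calibration the package computes:

- limited-information global fit: **M2** on univariate + bivariate margins,
  with RMSEA, CFI, TLI against an independence baseline, and SRMR;
- **residual correlations** (marginal or Q3) for local independence;
- nonparametric **Loevinger scalability** (H, H_i) and rest-score
  **monotonicity** checks with criticality scores;
- reliability (**Cronbach's α**, **McDonald's ω<sub>t</sub>**);
- a COSMIN-style rubric that converts these statistics into per-subscale
  pass/fail verdicts;
- **normative tables** linking each crude summed score to E[θ | S = s]
  (Lord–Wingersky recursion), then to per-group Z, T = 50 + 10·Z,
  percentiles, and PROMIS severity bands (minimal < 55, mild 55–59,
  moderate 60–69, severe ≥ 70).

## Worked example

Generate a synthetic school-age screening cohort (1,356 caregivers,
age × gender strata) and validate the PSC-17 on it:

```bash
scalenorm simulate --preset psc17-like --out sim
scalenorm validate --instrument psc17 --responses sim/responses.csv --out report
```

which prints

```
wrote 1356 x 17 responses to sim
psc17/externalizing: supported
psc17/internalizing: supported
psc17/attention: supported
```

`report/report.json` holds the full statistics.  For the internalizing
subscale this run gives α = 0.75, ω<sub>t</sub> = 0.86, RMSEA = 0.00,
CFI = TLI = 1.00, SRMR = 0.014 — every rubric criterion passes, so the
subscale's status is `supported`.  `report/norms_internalizing.csv` maps
every attainable crude score (0–10 for five 0–2 items) to norms per group;
for boys aged 10–13:

```
 crude     Z     T  percentile     band
     0 -2.35 26.52        1.59  minimal
     5 -0.60 44.00       26.36  minimal
     9  0.75 57.47       74.77     mild
    10  1.38 63.82       91.14 moderate
```

Read: a boy in this group summing 9 sits at T ≈ 57 (mild band, ~75th
percentile of the reference group).  T is anchored so that 50 is the
reference-group mean and 10 points is one reference SD; bands are
interpretive conventions, not clinical cutoffs.  `report/report.html`
renders the same content as a color-coded table.

Weak instruments are caught the same way: the `mchat-like` preset, which
emulates a community toddler sample with eight poorly discriminating
items, yields `not supported` with `monotonicity` as the failing
criterion.

To validate real data, provide a CSV with one column per item id plus
`age_group` and `gender` columns (responses coded from 0; use `--origin`
at ingest for 1-based codings), and either a bundled instrument name or
your own YAML spec.

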