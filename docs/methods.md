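# Methods

This note records the statistical model, the estimation and diagnostic
choices, what the synthetic cohorts do and do not emulate, and the design
decisions taken where more than one defensible option existed.

## Measurement model

Each subscale is treated as a unidimensional graded response model (GRM).
With latent trait θ and, for item *j* with K ordered categories,
discrimination a_j > 0 and strictly increasing thresholds b_j1 < … <
b_j,K−1, the boundary probabilities are logistic,

    P(X_j ≥ k | θ) = σ(a_j (θ − b_jk)),  σ(z) = 1/(1+e^(−z)),

with P(X ≥ 0) = 1 and P(X ≥ K) = 0; category probabilities are
differences of adjacent boundaries.  The logistic metric carries **no**
1.702 scaling constant; that constant enters exactly once, when
discriminations are converted to normal-ogive factor loadings
(λ_j = a*_j / √(1 + a*_j²), a*_j = a_j / 1.702).  K = 2 reduces the model
to the two-parameter logistic, and the binary instruments (MCHAT-R/F,
CAST) run through the identical code path.

The graded rating scale model (GRSM) constrains all items of a subscale to
a shared step vector t (centred at zero for identification) and a per-item
location d_j, with b_jk = d_j + t_k.  It requires equal category counts
across items and is the default nowhere; callers opt in per subscale.

## Estimation

Calibration is marginal maximum likelihood with a fixed N(0,1) latent
prior (this fixes the trait scale; no post-hoc rescaling).  The latent
integral uses 61 equally spaced nodes on [−6, 6] with normal-density
weights renormalized to sum to one; both the node count and the bound are
configurable.  For a trapezoid-type rule on a Gaussian-decaying integrand
this grid is accurate far beyond the needs of the statistics built on it
(EAP scores from the default grid agree with a 10⁴-point dense integrator
to ~5·10⁻⁹ on binary items; the test tolerance is 10⁻⁶).

EM details:

- E-step over persons (pattern collapsing would change nothing but speed);
  expected category-by-node counts per item.
- M-step per item by bounded quasi-Newton (L-BFGS-B) with analytic
  gradients on an order-preserving parameterization: log a, b_1, and log
  threshold gaps, with box bounds (a ≤ ~30) so degenerate items — e.g. a
  duplicated pair, whose ML discrimination diverges — stop at a finite
  boundary instead of overflowing.  For the GRSM the M-step is joint
  across items (shared steps) with numeric gradients.
- Start values: a = 1 and thresholds from inverse-normal cumulative
  category frequencies — deterministic, so identical inputs give
  byte-identical outputs.
- Convergence: absolute log-likelihood change < 1e−5 (default), max 500
  iterations; non-convergence is flagged, never silent.  The marginal
  log-likelihood is checked to be nondecreasing at every iteration and a
  material decrease raises an error.
- An item with fewer than two observed categories aborts calibration with
  the item named.  Category counts are taken from the observed data, so a
  never-observed top category is simply not parameterized.

## Item and global fit

**M2.**  Global fit uses the limited-information statistic on univariate
and bivariate margins (one entry per item-category with k ≥ 1, and per
category pair for each item pair).  With e = p − π(η̂), Ξ the asymptotic
covariance of the sample margins under the model (computed exactly via
joint probabilities of up to four items at the quadrature nodes), and
Δ = ∂π/∂η the Jacobian with respect to the free item parameters (central
differences), the statistic is n·e′C₂e with the usual orthogonal-complement
weight C₂; df = #margins − #free parameters.  A tiny ridge (1e−10)
stabilizes near-collinear margins.  Null simulations at n = 2,000 give
mean M2 ≈ df and a 5% rejection rate at α = 0.05.

**Baseline and indices.**  CFI and TLI need an independence baseline: the
model with each item's marginal category distribution free (ML =
observed proportions) and all inter-item association removed — run through
the same M2 machinery with a single-node "grid".  RMSEA =
√(max(0, (M2−df)/(df(n−1)))); CFI and TLI use the standard noncentrality
forms, capped at 1.  SRMR is the RMS difference between observed and
model-implied inter-item Pearson correlations.

**Infit.**  Item infit is the information-weighted mean-square residual
Σ(x−E)²/ΣW.  The default integrates numerator and denominator over each
person's trait posterior, which keeps the statistic centred at 1 for any
subscale length.  Evaluating both at the EAP point estimate (available as
`method="point"`) is the convention many Rasch tools print, but it is
biased low on short subscales — around 0.65–0.9 on five items under the
generating model — because the point estimate is fitted to the same
responses it is compared against.

**Residual correlations.**  The default is the difference between
observed and model-implied inter-item correlations ("marginal"), which is
O(n^−1/2) under local independence.  Yen's Q3 (residuals against the EAP
score) is available behind a flag; note its built-in negative bias of
about −1/(p−1) on short subscales, and that it is the better detector for
near-duplicated item pairs, whose dependence maximum likelihood otherwise
absorbs into the discriminations.

**Scalability and monotonicity.**  Loevinger's H_ij is the ratio of the
observed inter-item covariance to the maximum covariance attainable under
the fixed marginals (covariance of the two sorted columns); H_i and H
aggregate numerators and denominators.  Zero-variance items are skipped
with a warning.  Manifest monotonicity groups persons by rest score
(adjacent scores merged until each group reaches `minsize`, default
max(n/10, 50) for n ≥ 500, else max(n/5, 10)) and records every drop of an
item-step probability exceeding `minvi` = 0.03 across ordered group pairs.
Each item's criticality score is

    crit = round(10 · Σ_v z_v · d_v / minvi),

where d_v is the drop and z_v its pooled binomial z-statistic.  The
formula is this package's own (the conventional bands come from an
unpublished lineage of implementations); it is deterministic and scaled so
a single borderline drop lands well under 40, while a reversed item scores
in the hundreds.  Only band membership (< 40 negligible, 40–90 borderline,
> 90 serious) should be interpreted, never the digit.

## Evaluation rubric

Per subscale: (1) unidimensionality — at least two of {RMSEA ≤ 0.06, with
(0.06, 0.08] still counting but labelled "acceptable"; SRMR ≤ 0.08; TLI
and CFI jointly ≥ 0.95}; (2) local independence — all |r| < 0.2 OR third
quartile < 0.37, offending pairs always listed; (3) monotonicity — every
H_i > 0.3 (strict) and no violation with crit > 90; the "adequate looking
graphs" escape is a manual override flag, never automatic; (4) global fit
— criterion 1 passed AND all item infits in [0.5, 1.5].  Reliability is
rated positive/good/excellent strictly above 0.7/0.8/0.9.  "Supported"
requires all four structural criteria plus at least positive reliability;
the reliability gate is configurable because structural validity and
internal consistency are sometimes reported separately.  Missing
components yield "incomplete", never a silent pass.

Treating TLI/CFI as one joint member keeps the unidimensionality menu at
exactly three entries, which is the reading under which the published
two-of-three wording reproduces the known failure pattern of the autism
screeners (RMSEA 0.06 acceptable, all else failing → 1 of 3 → fail).

Note on α vs ω_t: ω_t is computed from the normal-ogive loadings, i.e. on
the latent-response metric, while α uses raw categorized scores; for
ordinal items α is therefore attenuated a few hundredths below ω_t even
under exact tau-equivalence of the latent model.

## Normative references

Within each norm group (age band × gender; genders pooled with a warning
when a cell is below the minimum size, default 30), person-level Z scores
standardize the EAP trait against the group mean and SD, and T = 50 + 10Z.
Crude summed scores are linked model-based: the Lord–Wingersky recursion
gives P(S = s | θ) at each node, hence P(S = s) and E[θ | S = s] under the
prior; each attainable sum maps to θ(s) → Z → T.  This linking is defined
for sums unobserved in the sample and is monotone because E[θ | S = s] is
nondecreasing in s.  Percentiles are mid-probability empirical
percentiles, 100·(P(S < s) + P(S = s)/2), of the group's observed sums.
An empirical linking (averaging observed T within each sum) exists behind
the model-based default for comparison.

Severity bands follow the PROMIS convention on the raw T: minimal < 55,
mild [55, 60), moderate [60, 70), severe ≥ 70.  Displayed scores are
truncated into each band's nominal display range (floor 20, ceiling 80 in
the extreme bands; unit slope inside every band) so that band membership
is never changed by display rescaling and raw values are always retained
in machine output.  Bands are interpretive conventions, not clinically
calibrated cutoffs, and this package deliberately computes no diagnostic
thresholds.

## Synthetic cohorts

The generator draws a standard-normal trait per stratum (optional mean
shifts), then samples each response from its GRM category distribution via
a single uniform draw compared against the boundary curves — so responses
are monotonically coupled to the trait.  A root seed expands into
independent substreams (one for the trait, one per item), so extending a
design never perturbs earlier draws.  There is no item-level missingness,
matching the electronically administered surveys this pipeline targets.

Presets emulate the cohorts of the motivating nationwide survey: strata
and sizes follow its published margins (e.g. 1,356 caregivers of 6–18
year olds for the PSC-17; 137 adolescents for the self-report CATS-2; 200
toddlers for the MCHAT-R/F).  Generic item parameters are drawn with
discriminations in [0.8, 2.5] and thresholds in [−2.5, 2.5]; the presets
for instruments the survey found well-behaved narrow discriminations to
[1.3, 2.5], which reproduces the scalability band (H_i ≈ 0.4–0.6) and
loading range those instruments showed, while the autism-screener presets
plant weakly discriminating items (a ≈ 0.2–0.4, shifted thresholds) to
reproduce their community-sample failure mode.  Each subscale's trait is
drawn independently — the generator does not model cross-subscale trait
correlations, rater effects, acquiescence or recruitment bias, so passing
pipeline tests on these fixtures demonstrates correctness of the
statistical machinery, not realism of any particular instrument's
item-level behaviour in the field.  Fixture sample sizes in tests (mostly
n = 2,000, twenty replicate seeds for the recovery and null-calibration
batteries; n = 5,000 where a single cohort must pin down item-level
statistics) were chosen so Monte-Carlo error is small relative to the
asserted tolerances.

## Known limitations

- No multidimensional, bifactor, or hierarchical models; alternative
  factor structures are compared by rerunning the pipeline per partition.
- No measurement invariance / DIF testing across groups.
- Polychoric-based reliability variants are out of scope; α uses Pearson
  covariances on raw scores.
- The M2 implementation recomputes the exact margin covariance under the
  fitted model; for very long subscales (≫ 25 polytomous items) this is
  the pipeline's dominant cost.
- Norm groups with few members produce tables flagged "unstable"; the
  package warns rather than refuses, since pooling decisions are
  substantive.
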