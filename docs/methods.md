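# Methods

## Setting

Each subject contributes a pair of serum 25-hydroxyvitamin D measurements in
ng/mL — one by chemiluminescence immunoassay (CLIA), one by liquid
chromatography–tandem mass spectrometry (LC-MS/MS) — plus age (years) and
sex. The analysis object is the inter-method difference
`d = lcms − clia`, recomputed on load and never trusted from input files.

## Agreement battery

**Intraclass correlation.** A one-way random-effects layout: subjects are
groups, the two methods are the `k = 2` repeated measures of one quantity.
`MSB = k·Σ(x̄ᵢ − x̄)²/(n−1)`, `MSW = ΣΣ(xᵢⱼ − x̄ᵢ)²/(n(k−1))`, and
`ICC = (MSB − MSW)/(MSB + (k−1)·MSW)`. This one-way form treats any
systematic method offset as within-subject disagreement, which is the
conservative choice for method comparison. Rules of thumb: < 0.40 poor,
\> 0.75 excellent.

**Bland–Altman.** Mean and sample SD (n−1 denominator throughout the
package) of the differences; limits of agreement `mean ± 1.96·SD`. The
1.96 is a fixed constant of the classic formula, not a quantile lookup; the
Wilson interval's z *is* a quantile, because its level is configurable.

**Threshold agreement.** At a clinical cutoff t (20 ng/mL deficiency,
30 ng/mL insufficiency), a value exactly equal to t classifies as
"sufficient" (≥ t) for both methods. Agreement rate is the concordant
fraction; Cohen's κ corrects it for chance using the row×column marginal
products; the discordant proportion gets a Wilson score interval, which is
well-behaved at small counts and at the 0 and 1 boundaries (where its
bounds are exactly 0 and 1; the implementation clamps the closed form's
round-off). Degenerate marginals (all subjects on one side for both
methods) make κ undefined; it is returned as NaN with a warning rather than
raising, so batch runs on extreme synthetic draws survive. The
multi-threshold reclassification summary counts subjects discordant at
*any* threshold (a union, not a sum — one subject can be discordant at
both).

**Comparison regression.** Plain OLS of the reference on the candidate with
intercept; 95% coefficient intervals from the t distribution with n−2
degrees of freedom. Deming or Passing–Bablok alternatives are deliberately
out of scope. All p-values in the package are two-sided.

## Fuzzy inference system

**Why fuzzy.** The residual difference may vary smoothly with demographics
without sharp boundaries ("women in their thirties", "high concentrations").
A Takagi–Sugeno system generated from clusters represents such graded
patterns as a small set of interpretable IF–THEN rules.

**Construction.**

1. The joint matrix `[clia, lcms, sex_code, age, diff]` is min–max scaled
   to [0,1] per dimension. Years and ng/mL are incommensurate; without
   scaling, Euclidean distance would be dominated by one axis. The
   transform is stored in the model for inversion; a zero-range dimension
   (e.g. a single-sex cohort) maps to a constant.
2. Fuzzy C-means minimizes `J_m = Σᵢ Σⱼ μᵢⱼ^m ‖xᵢ − cⱼ‖²` by alternating
   the closed-form membership and center updates. Defaults follow common
   biomedical practice: N = 3 clusters, fuzzifier m = 2. Initialization is
   a seeded random membership matrix (rows normalized); 5 restarts keep the
   best objective to guard against local minima. Convergence is declared on
   an objective change below 1e-6 (the objective, not membership movement,
   is what the model optimizes). A point coincident with a center receives
   full membership there, split evenly over coincident centers. The
   membership update normalizes squared distances by each point's nearest
   center before exponentiating, so small fuzzifiers cannot overflow.
3. Each cluster becomes one rule. Antecedents are Gaussian membership
   functions per input (scaled space): center = cluster-center projection,
   sigma = membership-weighted standard deviation of that input, floored at
   0.05 of the unit range so a tight cluster cannot produce a spike that
   numerically kills firing strengths. Rules are labelled low/medium/high
   by ranking cluster centers per input (stable sort, ties broken by
   cluster index).
4. Consequents are first-order (linear in the scaled inputs) by default,
   fitted in one global least-squares problem over all rules weighted by
   normalized firing strengths. The system is solved by minimum-norm
   (pseudo-inverse) least squares: rank deficiency is *generic* here — a
   cluster that fires almost only on one sex makes its sex column coincide
   with its constant column, because sex is binary — and the minimum-norm
   solution still minimizes the residual. A constant-consequent (zero-order)
   variant is available via `build_fis(..., linear=False)`. A non-finite
   solution (never observed in practice) falls back to constant consequents
   with a warning.
5. Inference: a query's firing strength per rule is the product of its
   Gaussian memberships, computed in the log domain and normalized
   softmax-style, so a query far from every rule still yields valid convex
   weights instead of 0/0. The prediction is the firing-weighted convex
   combination of rule consequent outputs (ng/mL).

**Summaries.** Rule weights are mean raw firing strengths over a dataset,
normalized to sum to 1 — a measure of how much of the data each rule
covers. (This definition is recorded in the report so alternatives can be
compared; "weight of a rule" has no single canonical definition.) Rule
surfaces evaluate the normalized output `(y − min d)/(max d − min d)` over
a 2-D grid spanning the observed ranges of two inputs with the others
fixed; out-of-range outputs clamp to [0,1] with a warning. Age profiles
evaluate the system along age at fixed sex with both assay inputs pinned to
their consistency locus (both reading 20 ng/mL), isolating the demographic
contribution.

**Sex encoding.** Sex enters numeric matrices through a configurable
male/female code pair (default 0/1). Predictions are invariant to the
choice on fitted data, which the tests verify by swapping the codes.

## A structural caveat on demographic profiles

Because the output is *arithmetically determined* by two of the inputs
(`d = lcms − clia` exactly), the conditional expectation of the output
given all four inputs carries **no demographic information**: any
residual-minimizing first-order system learns the identity
`d = in₂ − in₁` (training RMSE ~1e-14) and therefore predicts exactly
0 ng/mL at the consistency locus for every age and sex — demographic age
profiles from the first-order system are flat. The zero-order variant
cannot express the identity, but its three clusters organize along the
dominant concentration axis, and it carries a systematic sex offset even on
effect-free data (the binary sex codes sit asymmetrically around cluster
sex-centers near the cohort's female proportion). Consequently a
demographic effect injected into the generator is recoverable by the
relative-risk verification stage (which looks at the differences directly)
but **not** by the fitted system's age profile; age-profile structure
reported from models of this architecture on such data should be regarded
as a numerical artifact of the fit, not a finding. This is a property of
the modelling setup — using both assay results as inputs while predicting
their difference — and no parameter choice inside this package removes it.

## Verification stage

Differences are dichotomized at a threshold (the cohort mean by default;
the boundary value is "high"). The experimental group is women aged 30–40,
both bounds inclusive; everyone else is control. Relative risk
`RR = (a/(a+b))/(c/(c+d))` with the log-RR normal 95% CI
`exp(ln RR ± 1.96·√(1/a − 1/(a+b) + 1/c − 1/(c+d)))` — the standard
epidemiological default; simulation in the test suite confirms ~95%
coverage at moderate counts. A zero high-count in the control group flags
an infinite RR with undefined CI; an optional Haldane–Anscombe 0.5
continuity correction is available behind a flag.

## Synthetic cohort generator

Emulates the cohort-level statistics of a two-assay comparison study:

| parameter | default | meaning |
|---|---|---|
| n | 138 | cohort size |
| female_prop | 0.565 | Bernoulli sex draw |
| age_mean, age_sd | 40.75, 15.59 y | truncated normal on [18, 90] |
| clia_mean, clia_sd | 20.71, 9.22 ng/mL | truncated normal on [3, 56] |
| slope, intercept | 1.161, −2.009 | reference = slope·clia + intercept |
| resid_sd | 3.4 ng/mL | normal residual; puts R² near 0.91 |
| effect_delta | 0 (effect preset: 2.5) | added to lcms for women aged 30–40 |

Truncated normals are **moment-matched**: the latent location/scale are
solved (2-D root find on the truncated moments) so the *realized* mean and
SD equal the configured targets — naive truncation at 3 ng/mL would
inflate the CLIA mean by ~0.6 ng/mL. The verification-cohort generator
draws exact stratum sizes, with experimental ages following the population
age law conditioned on the 30–40 window. `lcms` is floored at 0.

What the generator does *not* emulate: assay-specific mechanisms
(antibody cross-reactivity, D₂/D₃ fractions, binding-protein interference),
non-normal residuals, heteroscedasticity across the concentration range,
and age–concentration correlation. Passing tests therefore demonstrate the
pipeline's statistical correctness under a clean additive model, not its
behavior on real sera.

## Problem sizes and seeds

All randomness flows from integer seeds (numpy `default_rng`); model
reports embed the training seed. The test suite uses cohorts of 138–600
for pipeline properties, n = 2000–10000 for law-of-large-numbers and
regression-recovery checks, 100 replicates of n = 500 for CI coverage of
the generator's slope/intercept, and 20-seed batches of n = 600 for the
effect-recovery and null-calibration experiments — sizes at which the
targeted effects are comfortably resolvable while the whole suite stays
fast. Fuzzy clustering cross-checks use a 30-point 2-D fixture against an
independent loop-based implementation kept in the test tree.

## Known limitations

- The one-way ICC form is the only one implemented; two-way
  consistency/agreement variants are out of scope.
- Cross-classification supports two categories per threshold; ordinal
  multi-band classification (deficient/insufficient/sufficient as one
  3×3 table) is composed from per-threshold 2×2 tables instead.
- The demographic-profile caveat above: first-order profiles are
  structurally flat; zero-order profiles carry an encoding-geometry bias.
- The relative-risk stage is unadjusted; confounders (BMI, hormonal
  status, diet) are not modelled.
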