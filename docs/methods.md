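# Methods

## Model and scope

We consider N items classified into C ≥ 3 ordered categories by R ≥ 2
raters, summarized either as an N×C rater-count table (cell R_ic = raters
putting item i in category c) or, for exactly two raters, a C×C
cross-classification. Observed weighted agreement A_w is the average
weight w(c, c~) over all item × rater-pair combinations, with the
distance-power weights w = 1 − (|c−c~|/(C−1))^γ. The coefficient class is

    I_w = (A_w − E_w) / (1 − E_w),     E_w = Σ_{c,c~} w(c,c~) p_c q_c~,

where the chance proportions (p, q) select the member: p = q = 1/C
(S-coefficient), rater-specific margins (Cohen), pooled margins at R = 2
(Scott), pooled frequencies Σ_i R_ic/(NR) (Fleiss), or the posterior-mean
style (1 + Σ_i R_ic)/(C + NR) (uniform prior). Krippendorff's alpha,
Gwet's AC2 and the all-rater multivariate weighted kappa fall outside the
class and outside this package, as do missing-data designs (all raters
rate all items) and standard errors.

Both A_w and E_w are functions of the *distance profiles* alone:
O_(l) and E_(l), the observed and chance fractions of rater-pair cases
exactly l categories apart (l = 1..C−1), plus the diagonal masses. All
downstream analysis operates on the pair (O, E); that is why a published
profile table is accepted as input on equal footing with raw data.

## Derivatives and decomposition

Writing T(γ) = Σ_s s^γ E_(s),

    D1(γ) = Σ_{m=2..C−1} Σ_{l<m} ln(m/l) · (l^γ E_l / T)(m^γ E_m / T)
            · (O_l/E_l − O_m/E_m),

and each second-derivative component is its D1 component times the
multiplier [Σ_s ln(lm/s²) s^γ E_(s)] / T. Components are enumerated with
the larger distance m outer, l inner, and their sums reproduce the totals
exactly (they are the totals). Both formulas are validated in the test
suite against central finite differences of the independently computed
coefficient (step 1e−5 for D1 at relative tolerance 1e−6; step 1e−4 for
D2), and the coefficient itself is computed by two algebraically
independent routes (the profile form and the definitional
(A_w − E_w)/(1 − E_w) form) that must agree to 1e−12.

For C = 3 only the pair (1, 2) exists, so I_w is monotone in γ with
direction sign(O₁/E₁ − O₂/E₂), D2 = ln2 · (E₁ − 2^γ E₂)/(E₁ + 2^γ E₂) · D1
exactly, and |D1| peaks at γ* = ln(E₁/E₂)/ln 2. γ* may be negative
(bottom-heavy chance profiles from bimodal marginals); the summary value
D1(γ*) is evaluated at γ* directly — the decomposition is well defined for
any real γ because every distance is ≥ 1. No closed-form peak exists for
C > 3; `curvature_sign_scan` brackets extrema of D1 numerically on a γ
grid and is labelled a heuristic extension.

## Parameters, units, defaults

* **γ** (dimensionless, ≥ 0 in the public API; default 1): identity 0,
  radical .5, linear 1, quadratic 2. γ = 0 is an exact special case
  (identity weight matrix), not a numerical limit.
* **Chance model** (default `fleiss`): `cohen` requires a
  rater-distinguished pair table and is refused on rater-count input
  rather than guessing a split; `scott` is the R = 2 restriction of
  `fleiss` and shares its code path.
* **Label cutoffs**: degree moderate |D1| < .05, high .05 ≤ |D1| < .10,
  very high |D1| ≥ .10; change minor |D2/D1| < .10 (strict, overriding the
  sign), else intensifying/weakening by sign. Brackets are half-open
  exactly as listed.
* **Report rounding**: 3 decimals, half away from zero, applied only in
  the display layer; all arithmetic is double precision throughout.

## Numerical and degenerate-input choices

* Chance proportions must be strictly positive; an unused category raises
  a validation error instead of silent smoothing (smoothing would change
  published values). `drop_empty_categories` is the explicit opt-in, and
  it renumbers the ordinal positions, i.e. changes the distances.
* The curvature ratio is a tagged `None` (not an exception) when
  |D1| < 1e−14; the recovery heuristic then drops its quadratic term.
* Ties in strict inequality conditions (exact equality) are reported with
  a tie flag and `holds = False` for both directions, since D1 = 0 there.
* Proportion tables must sum to 1 within 1e−9; count tables must be exact
  integers. Profile partitions (Σ O_(l) + diagonal = 1) are validated at
  1e−9 to admit published 3-decimal tables.
* Category-distance sums use l ≥ 1 everywhere, so 0^0 never arises.

## Recovery at unreported weighting schemes

The triple (I_w(γ), D1(γ), D2(γ)/D1(γ)) is sufficient for the quadratic
approximation I_w(γ+Δ) ≈ I_w + D1(Δ + ½(D2/D1)Δ²). Its remainder is third
order: the test suite verifies the error shrinks ≈8× when Δ halves
(Δ ∈ {.1, .05, .025}) on random profiles. On the embedded worked examples
the recovery is accurate to a few units in the third decimal over Δ = ±1.

## Synthetic data generator

`generate_ratings` draws, per item, a category distribution from a
Dirichlet with parameters `marginal_concentration / agreement_strength`,
then R multinomial rater choices. Larger `agreement_strength` collapses
item distributions onto single categories — near-perfect agreement with
marginal frequencies still following the normalized concentration —
while small values make all items share the common marginal, i.e.
chance-level agreement; unimodal concentrations over the ordered
categories concentrate disagreements near the diagonal. Defaults
(N = 100, C = 5, R = 2, flat concentration, strength 1, seed 0) give a
mid-range table typical of the moderate-agreement literature datasets.
Randomness is numpy `default_rng` (PCG64), fully determined by the seed,
and the generator identifier is logged by the CLI.

What the generator does *not* emulate: rater-specific bias (its raters
are exchangeable, so it cannot produce Cohen-vs-Scott divergence by
itself), missing ratings, and serial or learning effects between items.
Passing tests on generated data therefore demonstrate the algebraic and
analytic properties of the estimators, not robustness to those real-data
features.

## Problem sizes used in the checks

The worked examples are desk-scale (a 3×3 proportion table standing for
100 items, and a published 5-category profile). Property checks use 100
random two-rater tables (C = 3..6) × 5 chance models × 5 γ values for the
dual-route identity, 100 random three-category profiles for the monotone
direction law and the multiplier identity, and 20-profile batches for the
finite-difference and invariance checks; the full suite runs in a few
seconds on one CPU.

## Known limitations

* The derivative theory is specific to the power family; arbitrary
  user-supplied weight matrices are out of scope.
* No inference: D1/D2 describe deterministic sensitivity of the point
  estimate, and the package provides no sampling variances for them.
* Vanishing susceptibility (D1 → 0 as γ → ∞) sets in slowly when C is
  large, at rate ≈ ((C−2)/(C−1))^γ.
* For C > 3 the γ–I_w relationship may be non-monotonic; report D1 at the
  γ actually used, and use the sign-scan utility to locate reversals.
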