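# Methods

## Scope and models

`exactanova` implements classical sums-of-squares inference for two
settings in which popular statistical software is known to disagree:

1. **Unbalanced two-way fixed-effects ANOVA.**  The model is
   `y_ijk = μ + α_i + β_j + γ_ij + e_ijk`, `e_ijk ~ N(0, σe²)`, with
   `n_ij ≥ 1` observations in every cell and possibly unequal cell counts.
   The package computes type 1 (sequential), type 2 (partially adjusted)
   and type 3 (unweighted marginal means) tests, plus the contrast-dependent
   construction that several R routines present *as* type 3.

2. **Balanced randomized complete block (RCB) and split-plot designs**
   analysed with a mixed model (`y_ij = μ + α_i + b_j + e_ij`, respectively
   `y_ijk = μ + α_i + b_j + (ab)_ij + τ_k + (ατ)_ik + e_ijk`, with
   `b_j ~ N(0, σB²)`, `(ab)_ij ~ N(0, σAB²)`).  Here the exact F-test of the
   (main-plot) treatment effect is `MS_A/MS_E` (RCB) or `MS_A/MS_AB`
   (split-plot) on `(a−1, (a−1)(b−1))` df, independent of any variance
   component estimates.  The package also *emulates* what mixed-model
   software reports when a variance estimate is bounded at zero, and
   measures the Type I error consequences by simulation.

## Fixed tests: one quadratic-form engine

Every tested hypothesis is a contrast among the cell means,
`H0: W μ = 0`, and every test statistic is

    SS = (W m)' (W D W')⁻¹ (W m),   F = SS / k / σ̂e²,

with `m` the observed cell means, `D = diag(1/n_ij)`, `k = rank(W)`, and
`σ̂e²` the residual mean square of the full interaction model.  Because the
least-squares coefficients of any sub-model are an exact linear map of the
saturated cell means, this quadratic form reproduces the classical
reduction-in-sums-of-squares values identically; the tests verify this
against nested-fit RSS differences and against `statsmodels.anova_lm`.

The families differ only in `W`:

* **type 1, first term**: frequency-weighted marginal means, level `i`
  weighting cell `(i,j)` by `n_ij/n_i·`;
* **type 1, later terms / type 2**: the coefficient rows of the model
  containing the adjusting terms, mapped onto the cell means (the map
  `S_term (X'X)⁻¹ X' X_cell`);
* **type 3 (correct)**: equal weights `1/b` per cell — Yates's weighted
  squares of means, computed in the cell-means parametrization and hence
  provably independent of any contrast coding;
* **type 3 "as implemented"**: the hypothesis `L β = 0` with `L` selecting
  the term's own columns of the *coded* design.  Under sum-to-zero coding
  this equals the correct type 3.  Under first- (or last-) level reference
  coding the main-effect test collapses to a comparison *at the reference
  level of the other factor*; on the shipped weight-gain dataset this moves
  the "sex" p-value from 0.49 (correct) to 0.037 or 0.005.

A note on balance: the as-implemented construction under reference codings
tests its conditional hypothesis *even on balanced data* (verified against
R's `car::Anova` directly), so the balanced-data equivalence of all test
families holds across codings only for types 1/2/3-correct, for the
as-implemented variant under sum coding, and for the highest-order
(interaction) term under every coding.

Rank-deficient designs are handled with a rank-revealing Moore–Penrose
pseudo-inverse (singular values below `1e−9` of the largest treated as
zero).  Any reflexive g-inverse yields the same estimable functions; the
pseudo-inverse is used because its reflexivity and symmetry are easy to
verify numerically.  Estimability of a user-supplied `L` is checked row by
row via `L (X'X)⁻(X'X) = L` (relative tolerance `1e−6`).  p-values are
always upper-tail.  A numerator quadratic form below `1e−12` is reported at
its true small value with a logged warning rather than truncated to zero
(some software prints `F = 0, p = 1` in this situation; that defect is
documented, not reproduced).

Hypothesis weights reported to the user are normalized so the weights on
the first factor level's cells sum to one (the customary fractional form);
rows whose first-level weights cancel are scaled to make the first nonzero
entry positive.

## Balanced mixed designs: strata, pooling, strategies

For the balanced layouts the stratum sums of squares `(SS_s, df_s)` are
sufficient.  Expected mean squares: RCB `E[MS_B] = σe² + aσB²`,
`E[MS_E] = σe²`; split-plot `E[MS_AB] = σe² + cσAB²`,
`E[MS_B] = σe² + cσAB² + acσB²`, `E[MS_E] = σe²`.

* **Unbounded estimates** equate mean squares to expectations; they
  coincide with unconstrained REML here and may be negative.
* **Bounded estimates** reproduce non-negativity-constrained REML in
  closed form: each face of the constraint set has an explicit maximizer
  (flooring a component merges the strata whose expected mean squares
  become equal, pooling their SS), and the feasible candidate with the
  largest restricted likelihood is returned.  The tests check this against
  a numerically maximized constrained restricted likelihood to `1e−6` on
  hundreds of random datasets.
* **Boundary detection** is closed-form — unbounded innermost estimate
  `≤ 0`, i.e. `MS_B ≤ MS_E` (RCB) or `MS_AB ≤ MS_E` (split-plot) — with
  zero counting as boundary.  This removes optimizer-convergence ambiguity
  but need not coincide exactly with the boundary declaration of any
  particular REML optimizer on tiny layouts (see Limitations).

Strategy emulation for the treatment test:

| strategy      | denominator MS            | denominator df                      |
|---------------|---------------------------|-------------------------------------|
| `exact`/`nobound` | MS_E (RCB) / MS_AB (split-plot) | `(a−1)(b−1)`                  |
| `sas_default` | pooled MS at boundary     | `a(b−1)` (RCB) / `(ac−1)(b−1)` (sp) |
| `r_lmer`      | pooled MS at boundary     | `(a−1)(b−1)` always                 |

Away from the boundary all four coincide.  The pooled mean square is
`(SS_B + SS_E)/(df_B + df_E)` (RCB) or `(SS_AB + SS_E)/(df_AB + df_E)`
(split-plot) and always lies between the mean squares it pools.  The
Kenward–Roger adjustment itself is **not** implemented; on these balanced
designs its reported behaviour reduces to the df rules above, and the
emulation makes no claim beyond them.  With fixed block effects the same
arithmetic applies with σB² absent from the estimable components.

`wald_F` assembles `V = ZGZ' + σe²I` from supplied components and computes
`F = (Lβ̂)'(LĈL')⁻¹(Lβ̂)/k` with `Ĉ = (X'V⁻¹X)⁻`; on these balanced designs
it equals the mean-square ratios above (tested to `1e−8`), which is the
algebraic reason the strategy table can be computed from strata alone.

## Simulation engine

The Type I error study generates data under the global null (all fixed
effects zero) with the block variance σB² ∈ {0.1,…,0.9} (RCB; σe² = 1) or
the whole-plot variance σAB² ∈ {0.1,…,0.9} (split-plot; σb² = σe² = 1),
200 000 replicates per case by default, significance level 0.05, over the
six layouts per model encoded in the shipped `config/table_grid.yaml`.
These generator defaults *are* the study conditions; they are not tuning
knobs.

Because each stratum SS is an independent scaled chi-square under the
model (`SS_s ~ λ_s χ²(df_s)`), the default engine draws strata directly
from that law; a full data-generation route exists and the tests confirm
the two routes agree.  All randomness flows through
`numpy.random.default_rng([master_seed, case_index])`, one substream per
case, so per-case results do not depend on which other cases run;
replicates within a case are generated vectorized from that single stream
(per-replicate substreams would buy nothing here and cost vectorization).

The boundary probability has the closed form
`P(F(df_B, df_E) ≤ σe²/(σe² + aσB²))` (RCB; split-plot analogous), used as
an oracle for the Monte-Carlo estimate.  Reported frequencies carry the
Monte-Carlo standard error `sqrt(p̂(1−p̂)/n)`; at 200 000 replicates this
is ≈ 0.0005 at p = 0.05.

What the generator does *not* emulate: non-normal random effects,
unbalanced or missing data, REML optimizer quirks, and the interior
behaviour of the Kenward–Roger adjustment.  Agreement of the emulated
strategies with the published grid therefore validates the df rules, not
the software internals.

## Numerical and design choices

* Factor levels are strings, ordered by first appearance; "first level"
  and "last level" coding semantics are defined against that order.
* Term order for the two-way model is A, B, A×B with A the factor the user
  names first.
* Zero residual df (one observation per cell) is detected by exact integer
  comparison; the fit succeeds with the error variance flagged
  unavailable, and tests requiring it raise.
* Rejection in the simulation uses `p < α` strictly; ties at exactly α
  have probability zero.
* Test sizes: property tests use dozens of random small tables; the
  REML-oracle comparison uses 100 random datasets per layout (RCB 2×4,
  split-plot 3×2×4); the Q-Q study uses 10 000 replicates; grid cells in
  the acceptance suite use the full 200 000.

## Known limitations

* The `sas_default` emulation reproduces the published grid closely except
  in the `{a=3, b=2}` split-plot layout, where the actual software's
  near-boundary Kenward–Roger behaviour deviates from the pooled-df rule
  (the published `nobound` column deviates from the exact test there for
  the same reason).  The emulation reports its own computed value rather
  than guessing at unpublished internals.
* The closed-form boundary rule can differ from an iterative REML
  optimizer's boundary declaration on very small layouts (e.g. 2×2), so
  boundary probabilities there are trusted only against the closed-form
  oracle, not against published optimizer-based estimates.
* Type 4 (empty-cell) tests, covariates, three-way and higher designs,
  unbalanced mixed models, Satterthwaite df and the full Kenward–Roger
  algorithm are out of scope.
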