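# exactanova

Exact sums-of-squares ANOVA for small designed experiments — and a faithful
emulation of the ways popular statistical software departs from it.

Two practical problems motivate the package:

1. **"Type 3" tests in unbalanced two-way ANOVA are contrast-dependent in
   some software.**  The correct type 3 test compares *unweighted* marginal
   means, `H0: μ̄_1· = … = μ̄_a·` with `μ̄_i· = (1/b) Σ_j μ_ij`, and cannot
   depend on how factor levels are coded.  Several widely used R routines
   instead test the term's own coefficients in the coded parametrization;
   under the default reference coding that silently becomes a comparison
   *at the reference level of the other factor*.  On the same 15
   observations this moves the test of sex from F = 0.52 (p = 0.49) to
   F = 5.96 (p = 0.037) or F = 13.68 (p = 0.005), depending only on the
   contrast option.

2. **Mixed-model F-tests in balanced block designs differ between packages
   when a variance component is estimated as zero.**  For a balanced RCB or
   split-plot experiment the exact test `F = MS_A/MS_E` (or `MS_A/MS_AB`)
   on `(a−1, (a−1)(b−1))` df needs no variance components at all.
   Mixed-model software computes a Wald-type F instead; when the bounded
   REML estimate of the block (or whole-plot) variance hits zero, the
   denominator becomes a pooled mean square and different packages attach
   different denominator df — inflating or deflating the Type I error.
   `exactanova` computes the exact test, the closed-form bounded/unbounded
   variance components, the per-package strategy emulations, and a
   Monte-Carlo engine that measures each strategy's Type I error.

For whom: statisticians and methods-minded analysts of designed
experiments (agronomy, animal science, lab biology) who need to know *which
hypothesis their software actually tested*, and teachers who want the
discrepancies reproducible on one small dataset.

## Worked example

The built-in `table1` dataset is an unbalanced two-factorial weight-gain
experiment (15 animals; sex × three diets, 1–3 animals per cell):

```python
from exactanova import TwoWayAnova, make_fixture

res = TwoWayAnova(make_fixture("table1"), scheme="treatment").fit()
print(res.summary())
```

prints (abridged):

```
Two-way fixed-effects ANOVA
  response: gain   factors: Sex x Diet   n = 15
  contrast scheme: treatment
  residual SS = 24.6667 on 9 df   sigma2_hat = 2.7407

Type 1 tests
               SS       F  df_num  df_den      p
Sex       30.0444 10.9622       1       9 0.0091
...
Type 2 tests
Sex       10.4348  3.8073       1       9 0.0828
...
Type 3 tests (unweighted marginal means)
Sex        1.4118  0.5151       1       9 0.4911
...
Type 3impl tests [treatment]
Sex       16.3333  5.9595       1       9 0.0373
```

Four different answers for "does sex matter": the sequential test (sex
ignoring diet, F = 10.96) reflects the unequal cell counts; the adjusted
test gives F = 3.81; the correct type 3 comparison of unweighted marginal
means gives F = 0.52 (p = 0.49); and the coefficient-drop construction
under reference coding (`3impl`) gives F = 5.96 — it is actually testing
females vs males *on the first diet only*, as its cell-mean weights show:

```python
res.hypothesis_weights("3impl", "Sex")   # [[ 1, 0, 0, -1, 0, 0 ]]
```

For a balanced blocked design:

```python
from exactanova import BlockAnova
res = BlockAnova(make_fixture("rcb_boundary", seed=1), design="rcb").fit()
res.varcomps(bounded=False)   # sigma_b2 < 0: boundary case
for s in ("exact", "sas_default", "r_lmer"):
    t = res.test(s)
    print(s, round(t.F, 2), t.df_den, round(t.pvalue, 3))
```

Here `exact` keeps df = (a−1)(b−1) = 3, the pooled-denominator strategies
share a larger F, and the `sas_default` rule switches to a(b−1) = 6 df —
the same dataset can be "significant" under one convention and not under
another.

A command-line interface mirrors the library
(`exactanova anova|mixed|simulate|fixtures`, see `--help`).

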