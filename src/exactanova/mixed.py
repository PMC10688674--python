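"""Exact F-tests and software-strategy emulation for balanced randomized
complete block (RCB) and split-plot experiments.

For these balanced designs the ANOVA decomposition into strata (treatment,
block, whole-plot error, residual ...) carries all the information: the
expected mean square of each random stratum is a known linear function of
the variance components, moment (ANOVA) estimators coincide with
unconstrained REML, and the treatment test

    RCB:        F = MS_A / MS_E      on (a-1, (a-1)(b-1)) df
    split-plot: F = MS_A / MS_AB     on (a-1, (a-1)(b-1)) df

is *exactly* F-distributed regardless of the variance-component estimates.

Mixed-model software instead computes a Wald-type F from estimated variance
components.  When the whole-plot (or block) variance estimate is bounded at
zero, the denominator silently becomes a pooled mean square, and different
packages attach different denominator df to it.  ``strategy_test`` emulates
the four behaviours compared here:

* ``exact`` / ``nobound`` — the sums-of-squares test above (allowing a
  negative variance estimate reproduces it);
* ``sas_default`` — bounded fit; at the boundary the denominator df become
  a(b-1) (RCB) or (ac-1)(b-1) (split-plot), as if the random term were
  dropped from the model;
* ``r_lmer`` — bounded fit (same F as ``sas_default``) but the denominator
  df stay at the exact-test value (a-1)(b-1).

The Kenward–Roger machinery itself is not implemented; on these balanced
designs its reported behaviour reduces to the df rules above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import ExperimentTable, TableError
from .design import pinv_rank
from .fixed import TestResult

__all__ = [
    "RCBLayout",
    "SplitPlotLayout",
    "Stratum",
    "StratumTable",
    "VarComps",
    "MixedTestResult",
    "STRATEGIES",
    "strata_rcb",
    "strata_splitplot",
    "varcomp_unbounded",
    "varcomp_bounded",
    "exact_F_main",
    "strategy_test",
    "wald_F",
    "reml_minus2loglik",
    "BlockAnova",
    "BlockAnovaResults",
]

STRATEGIES = ("exact", "nobound", "sas_default", "r_lmer")


@dataclass(frozen=True)
class RCBLayout:
    """Randomized complete block layout: ``a`` treatments x ``b`` blocks,
    one observation per (treatment, block)."""

    a: int
    b: int

    def __post_init__(self):
        if self.a < 2 or self.b < 2:
            raise ValueError("RCB layout needs a >= 2 treatments and b >= 2 blocks")


@dataclass(frozen=True)
class SplitPlotLayout:
    """Split-plot layout: ``a`` main-plot treatments x ``b`` blocks x ``c``
    subplot treatments, one observation per (i, j, k) cell.  Block effects
    may be modelled as random (default) or fixed."""

    a: int
    b: int
    c: int
    block_effects: str = "random"

    def __post_init__(self):
        if self.a < 2 or self.b < 2 or self.c < 2:
            raise ValueError("split-plot layout needs a, b, c >= 2")
        if self.block_effects not in ("random", "fixed"):
            raise ValueError("block_effects must be 'random' or 'fixed'")


@dataclass
class Stratum:
    """One ANOVA stratum: sum of squares, df, and the coefficients of
    (sigma_e2, sigma_ab2, sigma_b2) in its expected mean square."""

    name: str
    ss: float
    df: int
    ems: dict[str, float] = field(default_factory=dict)

    @property
    def ms(self) -> float:
        return self.ss / self.df


@dataclass
class StratumTable:
    """Per-stratum sums of squares for a balanced blocked design."""

    layout: RCBLayout | SplitPlotLayout
    strata: dict[str, Stratum]

    def __getitem__(self, name: str) -> Stratum:
        return self.strata[name]

    def __contains__(self, name: str) -> bool:
        return name in self.strata

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"stratum": s.name, "SS": s.ss, "df": s.df, "MS": s.ms, **{f"E[MS]:{k}": v for k, v in s.ems.items()}}
            for s in self.strata.values()
        ]
        return pd.DataFrame(rows).set_index("stratum")

    @classmethod
    def from_mean_squares(cls, layout, mean_squares: dict[str, float]) -> "StratumTable":
        """Build a stratum table from mean squares alone (e.g. values
        printed in a report); SS = MS * df."""
        template = _strata_template(layout)
        required = {"A", *_random_strata(layout)}
        strata = {}
        for name, (df, ems) in template.items():
            if name not in mean_squares:
                if name not in required:   # fixed / subplot strata are optional here
                    continue
                raise ValueError(f"mean square for stratum {name!r} required")
            strata[name] = Stratum(name, mean_squares[name] * df, df, ems)
        return cls(layout=layout, strata=strata)


def _strata_template(layout) -> dict[str, tuple[int, dict[str, float]]]:
    if isinstance(layout, RCBLayout):
        a, b = layout.a, layout.b
        return {
            "A": (a - 1, {"sigma_e2": 1.0}),
            "B": (b - 1, {"sigma_e2": 1.0, "sigma_b2": a}),
            "E": ((a - 1) * (b - 1), {"sigma_e2": 1.0}),
        }
    a, b, c = layout.a, layout.b, layout.c
    whole = {"sigma_e2": 1.0, "sigma_ab2": c}
    tmpl = {
        "A": (a - 1, dict(whole)),
        "B": (b - 1, {"sigma_e2": 1.0, "sigma_ab2": c, "sigma_b2": a * c}),
        "AB": ((a - 1) * (b - 1), dict(whole)),
        "C": (c - 1, {"sigma_e2": 1.0}),
        "AC": ((a - 1) * (c - 1), {"sigma_e2": 1.0}),
        "E": (a * (b - 1) * (c - 1), {"sigma_e2": 1.0}),
    }
    if layout.block_effects == "fixed":
        tmpl["B"] = (b - 1, {"sigma_e2": 1.0, "sigma_ab2": c})
    return tmpl


def _grid_rcb(table: ExperimentTable, layout: RCBLayout) -> np.ndarray:
    """Arrange observations into an (a, b) array; error on duplicated or
    missing cells."""
    treat, block = table.factors
    if len(table.levels[treat]) != layout.a or len(table.levels[block]) != layout.b:
        raise TableError(
            f"table has {len(table.levels[treat])} treatment and "
            f"{len(table.levels[block])} block levels; layout says ({layout.a}, {layout.b})"
        )
    counts = table.cell_counts(treat, block)
    if not np.all(counts == 1):
        raise TableError("RCB requires exactly one observation per (treatment, block) cell")
    y = np.full((layout.a, layout.b), np.nan)
    y[table.level_index(treat).to_numpy(), table.level_index(block).to_numpy()] = table.y
    return y


def strata_rcb(table: ExperimentTable, layout: RCBLayout) -> StratumTable:
    """ANOVA decomposition of an RCB experiment into treatment (A), block
    (B) and residual (E) strata.  The three SS add up to the total
    corrected SS."""
    y = _grid_rcb(table, layout)
    return strata_rcb_from_grid(y, layout)


def strata_rcb_from_grid(y: np.ndarray, layout: RCBLayout) -> StratumTable:
    a, b = layout.a, layout.b
    g = y.mean()
    yi = y.mean(axis=1)
    yj = y.mean(axis=0)
    ss_a = b * float(((yi - g) ** 2).sum())
    ss_b = a * float(((yj - g) ** 2).sum())
    ss_e = float(((y - yi[:, None] - yj[None, :] + g) ** 2).sum())
    tmpl = _strata_template(layout)
    vals = {"A": ss_a, "B": ss_b, "E": ss_e}
    return StratumTable(layout, {n: Stratum(n, vals[n], *_df_ems(tmpl, n)) for n in vals})


def _df_ems(tmpl, name):
    df, ems = tmpl[name]
    return df, ems


def strata_splitplot(table: ExperimentTable, layout: SplitPlotLayout) -> StratumTable:
    """ANOVA decomposition of a split-plot experiment into six strata:
    main-plot treatment (A), blocks (B), whole-plot error (AB), subplot
    treatment (C), interaction (AC) and residual (E)."""
    main, block, sub = table.factors
    dims = (len(table.levels[main]), len(table.levels[block]), len(table.levels[sub]))
    if dims != (layout.a, layout.b, layout.c):
        raise TableError(f"table levels {dims} do not match layout ({layout.a}, {layout.b}, {layout.c})")
    idx = (
        table.level_index(main).to_numpy() * layout.b * layout.c
        + table.level_index(block).to_numpy() * layout.c
        + table.level_index(sub).to_numpy()
    )
    if len(np.unique(idx)) != layout.a * layout.b * layout.c or table.n != layout.a * layout.b * layout.c:
        raise TableError("split-plot requires exactly one observation per (i, j, k) cell")
    y = np.empty(layout.a * layout.b * layout.c)
    y[idx] = table.y
    return strata_splitplot_from_grid(y.reshape(layout.a, layout.b, layout.c), layout)


def strata_splitplot_from_grid(y: np.ndarray, layout: SplitPlotLayout) -> StratumTable:
    a, b, c = layout.a, layout.b, layout.c
    g = y.mean()
    yi = y.mean(axis=(1, 2))
    yj = y.mean(axis=(0, 2))
    yk = y.mean(axis=(0, 1))
    yij = y.mean(axis=2)
    yik = y.mean(axis=1)
    ss_a = b * c * float(((yi - g) ** 2).sum())
    ss_b = a * c * float(((yj - g) ** 2).sum())
    ss_ab = c * float(((yij - yi[:, None] - yj[None, :] + g) ** 2).sum())
    ss_c = a * b * float(((yk - g) ** 2).sum())
    ss_ac = b * float(((yik - yi[:, None] - yk[None, :] + g) ** 2).sum())
    # residual: y_ijk - ybar_ij. - ybar_i.k + ybar_i..
    resid = y - yij[:, :, None] - yik[:, None, :] + yi[:, None, None]
    ss_e = float((resid ** 2).sum())
    tmpl = _strata_template(layout)
    vals = {"A": ss_a, "B": ss_b, "AB": ss_ab, "C": ss_c, "AC": ss_ac, "E": ss_e}
    return StratumTable(layout, {n: Stratum(n, vals[n], *_df_ems(tmpl, n)) for n in vals})


# ----------------------------------------------------------------------
# Variance components
# ----------------------------------------------------------------------

@dataclass
class VarComps:
    """Variance-component estimates.  With ``bounded=False`` these are the
    moment/unconstrained-REML estimators and may be negative (except the
    residual); with ``bounded=True`` every component is >= 0 and
    ``at_boundary`` names the components floored at zero."""

    sigma_e2: float
    sigma_b2: float | None = None
    sigma_ab2: float | None = None
    bounded: bool = False
    at_boundary: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        out = {"sigma_e2": self.sigma_e2}
        if self.sigma_b2 is not None:
            out["sigma_b2"] = self.sigma_b2
        if self.sigma_ab2 is not None:
            out["sigma_ab2"] = self.sigma_ab2
        return out


def varcomp_unbounded(strata: StratumTable, layout) -> VarComps:
    """Moment (ANOVA) estimators from the stratum mean squares; identical
    to unconstrained REML for these balanced designs.  Negative values are
    returned as-is."""
    if isinstance(layout, RCBLayout):
        ms_b, ms_e = strata["B"].ms, strata["E"].ms
        return VarComps(sigma_e2=ms_e, sigma_b2=(ms_b - ms_e) / layout.a)
    c, ac = layout.c, layout.a * layout.c
    ms_ab, ms_e = strata["AB"].ms, strata["E"].ms
    sigma_ab2 = (ms_ab - ms_e) / c
    if layout.block_effects == "fixed":
        return VarComps(sigma_e2=ms_e, sigma_ab2=sigma_ab2)
    ms_b = strata["B"].ms
    return VarComps(sigma_e2=ms_e, sigma_ab2=sigma_ab2, sigma_b2=(ms_b - ms_ab) / ac)


def reml_minus2loglik(strata: StratumTable, layout, comps: dict[str, float]) -> float:
    """-2 x restricted log-likelihood (up to a constant) evaluated from the
    random strata: sum over strata of df*log(lambda) + SS/lambda, with
    lambda the stratum's expected mean square at ``comps``."""
    random_strata = _random_strata(layout)
    out = 0.0
    for name in random_strata:
        s = strata[name]
        lam = sum(coef * comps.get(key, 0.0) for key, coef in s.ems.items())
        if lam <= 0:
            return math.inf
        out += s.df * math.log(lam) + s.ss / lam
    return out


def _random_strata(layout) -> tuple[str, ...]:
    if isinstance(layout, RCBLayout):
        return ("B", "E")
    if layout.block_effects == "fixed":
        return ("AB", "E")
    return ("B", "AB", "E")


def varcomp_bounded(strata: StratumTable, layout) -> VarComps:
    """Non-negative variance-component estimates, reproducing bounded REML
    for these balanced designs.

    Every face of the non-negativity constraint set has a closed-form
    maximizer (flooring a component at zero merges the strata whose
    expected mean squares become equal, i.e. pools their sums of squares);
    the feasible candidate with the largest restricted likelihood is
    returned.  With all moment estimates positive this is simply the
    unbounded solution.
    """
    unb = varcomp_unbounded(strata, layout)
    if isinstance(layout, RCBLayout):
        if unb.sigma_b2 > 0:
            return VarComps(sigma_e2=unb.sigma_e2, sigma_b2=unb.sigma_b2, bounded=True)
        sb, se = strata["B"], strata["E"]
        pooled = (sb.ss + se.ss) / (sb.df + se.df)
        return VarComps(sigma_e2=pooled, sigma_b2=0.0, bounded=True, at_boundary=("sigma_b2",))

    if layout.block_effects == "fixed":
        if unb.sigma_ab2 > 0:
            return VarComps(sigma_e2=unb.sigma_e2, sigma_ab2=unb.sigma_ab2, bounded=True)
        sab, se = strata["AB"], strata["E"]
        pooled = (sab.ss + se.ss) / (sab.df + se.df)
        return VarComps(sigma_e2=pooled, sigma_ab2=0.0, bounded=True, at_boundary=("sigma_ab2",))

    # random blocks, two non-residual components: enumerate KKT candidates
    sb, sab, se = strata["B"], strata["AB"], strata["E"]
    ac, c = layout.a * layout.c, layout.c
    candidates: list[tuple[dict, tuple[str, ...]]] = []
    if unb.sigma_ab2 >= 0 and unb.sigma_b2 >= 0:
        candidates.append(({"sigma_e2": unb.sigma_e2, "sigma_ab2": unb.sigma_ab2,
                            "sigma_b2": unb.sigma_b2}, ()))
    # sigma_ab2 = 0: AB and E strata share lambda = sigma_e2
    se_pool = (sab.ss + se.ss) / (sab.df + se.df)
    sb2 = (sb.ms - se_pool) / ac
    if sb2 >= 0:
        candidates.append(({"sigma_e2": se_pool, "sigma_ab2": 0.0, "sigma_b2": sb2},
                           ("sigma_ab2",)))
    # sigma_b2 = 0: B and AB strata share lambda = sigma_e2 + c*sigma_ab2
    ms_pool = (sb.ss + sab.ss) / (sb.df + sab.df)
    ab2 = (ms_pool - se.ms) / c
    if ab2 >= 0:
        candidates.append(({"sigma_e2": se.ms, "sigma_ab2": ab2, "sigma_b2": 0.0},
                           ("sigma_b2",)))
    # both zero: all three strata pooled
    tot = (sb.ss + sab.ss + se.ss) / (sb.df + sab.df + se.df)
    candidates.append(({"sigma_e2": tot, "sigma_ab2": 0.0, "sigma_b2": 0.0},
                       ("sigma_ab2", "sigma_b2")))

    best, boundary = min(
        candidates, key=lambda cand: reml_minus2loglik(strata, layout, cand[0])
    )
    return VarComps(sigma_e2=best["sigma_e2"], sigma_ab2=best["sigma_ab2"],
                    sigma_b2=best["sigma_b2"], bounded=True, at_boundary=boundary)


# ----------------------------------------------------------------------
# Tests
# ----------------------------------------------------------------------

@dataclass
class MixedTestResult(TestResult):
    """F-test of the (main-plot) treatment effect, labelled with the
    strategy that produced its denominator and df."""

    strategy: str = "exact"
    varcomps: VarComps | None = None
    at_boundary: bool = False


def _mixed_result(F, df_num, df_den, strategy, varcomps=None, at_boundary=False, term="A"):
    p = float(stats.f.sf(F, df_num, df_den)) if np.isfinite(F) else math.nan
    return MixedTestResult(
        term=term, test_type=f"mixed:{strategy}", F=float(F), df_num=df_num,
        df_den=df_den, pvalue=p, strategy=strategy, varcomps=varcomps,
        at_boundary=at_boundary,
    )


def _denominator_stratum(layout) -> str:
    return "E" if isinstance(layout, RCBLayout) else "AB"


def exact_F_main(strata: StratumTable, layout) -> MixedTestResult:
    """The exact sums-of-squares F-test of the (main-plot) treatment
    effect: MS_A/MS_E for RCB, MS_A/MS_AB for split-plot, both on
    (a-1, (a-1)(b-1)) df.  Independent of variance-component estimates."""
    den = strata[_denominator_stratum(layout)]
    num = strata["A"]
    if den.ss <= 0:
        res = _mixed_result(math.inf if num.ss > 0 else math.nan, num.df, den.df, "exact")
        res.pvalue = math.nan
        return res
    return _mixed_result(num.ms / den.ms, num.df, den.df, "exact")


def _pooled_denominator(strata: StratumTable, layout) -> tuple[float, int]:
    """Bounded-fit denominator at the boundary: pooled mean square of the
    merged strata and the denominator df the 'as if dropped' model has."""
    if isinstance(layout, RCBLayout):
        sb, se = strata["B"], strata["E"]
        pooled = (sb.ss + se.ss) / (sb.df + se.df)
        return pooled, layout.a * (layout.b - 1)
    sab, se = strata["AB"], strata["E"]
    pooled = (sab.ss + se.ss) / (sab.df + se.df)
    return pooled, (layout.a * layout.c - 1) * (layout.b - 1)


def _innermost_negative(strata: StratumTable, layout) -> bool:
    """Boundary indicator: unbounded estimate of the innermost non-residual
    component (block for RCB, whole-plot for split-plot) is <= 0,
    equivalently MS of that stratum <= MS_E."""
    vc = varcomp_unbounded(strata, layout)
    inner = vc.sigma_b2 if isinstance(layout, RCBLayout) else vc.sigma_ab2
    return inner <= 0


def strategy_test(strata: StratumTable, layout, strategy: str) -> MixedTestResult:
    """Emulate one of the four software strategies for the treatment test.

    ``exact`` and ``nobound`` return :func:`exact_F_main`.  ``sas_default``
    and ``r_lmer`` use the bounded fit: away from the boundary they equal
    the exact test; at the boundary both use F = MS_A / pooled MS, with
    denominator df a(b-1) (RCB) or (ac-1)(b-1) (split-plot) for
    ``sas_default`` and the exact value (a-1)(b-1) for ``r_lmer``.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    exact = exact_F_main(strata, layout)
    if strategy in ("exact", "nobound"):
        res = _mixed_result(exact.F, exact.df_num, exact.df_den, strategy,
                            varcomps=varcomp_unbounded(strata, layout))
        res.pvalue = exact.pvalue
        return res
    vc = varcomp_bounded(strata, layout)
    boundary = _innermost_negative(strata, layout)
    if not boundary:
        return _mixed_result(exact.F, exact.df_num, exact.df_den, strategy, varcomps=vc)
    pooled_ms, sas_df = _pooled_denominator(strata, layout)
    F = strata["A"].ms / pooled_ms
    df_den = sas_df if strategy == "sas_default" else exact.df_den
    return _mixed_result(F, exact.df_num, df_den, strategy, varcomps=vc, at_boundary=True)


# ----------------------------------------------------------------------
# Wald-type F from an assembled covariance matrix
# ----------------------------------------------------------------------

def _mixed_design(table: ExperimentTable, layout):
    """Cell-mean fixed design X, random-effect incidence blocks Z, and the
    treatment-mean contrast L for the layouts handled here."""
    if isinstance(layout, RCBLayout):
        treat, block = table.factors
        _grid_rcb(table, layout)  # validates
        it = table.level_index(treat).to_numpy()
        ib = table.level_index(block).to_numpy()
        X = np.zeros((table.n, layout.a))
        X[np.arange(table.n), it] = 1.0
        Zb = np.zeros((table.n, layout.b))
        Zb[np.arange(table.n), ib] = 1.0
        L = np.zeros((layout.a - 1, layout.a))
        L[:, 0] = 1.0
        L[np.arange(layout.a - 1), np.arange(1, layout.a)] = -1.0
        return X, {"sigma_b2": Zb}, L
    main, block, sub = table.factors
    im = table.level_index(main).to_numpy()
    ib = table.level_index(block).to_numpy()
    isub = table.level_index(sub).to_numpy()
    X = np.zeros((table.n, layout.a * layout.c))
    X[np.arange(table.n), im * layout.c + isub] = 1.0
    Zb = np.zeros((table.n, layout.b))
    Zb[np.arange(table.n), ib] = 1.0
    Zab = np.zeros((table.n, layout.a * layout.b))
    Zab[np.arange(table.n), im * layout.b + ib] = 1.0
    # contrast of main-plot marginal means mu_i. = mean_k mu_ik
    L = np.zeros((layout.a - 1, layout.a * layout.c))
    for i in range(layout.a - 1):
        L[i, 0:layout.c] = 1.0 / layout.c
        L[i, (i + 1) * layout.c:(i + 2) * layout.c] = -1.0 / layout.c
    Z = {"sigma_ab2": Zab}
    if layout.block_effects == "random":
        Z["sigma_b2"] = Zb
    return X, Z, L


def wald_F(table: ExperimentTable, layout, comps: VarComps,
           L: np.ndarray | None = None) -> MixedTestResult:
    """Wald-type F-statistic from the assembled marginal covariance
    V = Z G Z' + sigma_e2 I at the supplied variance components.

    Computes ``F = (L b)' (L C L')^{-1} (L b) / k`` with the generalized
    least squares ``b`` and ``C = (X' V^{-1} X)^-``.  The denominator df
    are *not* chosen here (that is a strategy decision); the result
    carries df_den = NaN and no p-value.  Raises if V is not positive
    definite, naming the offending component.
    """
    X, Zblocks, L_default = _mixed_design(table, layout)
    if L is None:
        L = L_default
    L = np.atleast_2d(np.asarray(L, dtype=float))
    V = np.eye(table.n) * comps.sigma_e2
    comps_dict = comps.as_dict()
    for key, Z in Zblocks.items():
        V += comps_dict.get(key, 0.0) * (Z @ Z.T)
    try:
        cho = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        neg = [k for k, v in comps_dict.items() if v is not None and v < 0]
        raise ValueError(
            "assembled V is not positive definite"
            + (f" (negative component(s): {neg})" if neg else "")
        ) from None
    Vinv_X = np.linalg.solve(cho.T, np.linalg.solve(cho, X))
    C, _ = pinv_rank(X.T @ Vinv_X)
    beta = C @ (Vinv_X.T @ table.y)
    M = L @ C @ L.T
    Minv, k = pinv_rank(M)
    F = float((L @ beta) @ Minv @ (L @ beta)) / k
    res = _mixed_result(F, k, math.nan, "wald", varcomps=comps)
    res.pvalue = math.nan
    return res


# ----------------------------------------------------------------------
# Model / Results front end
# ----------------------------------------------------------------------

class BlockAnova:
    """Balanced blocked-design ANOVA (RCB or split-plot) with mixed-model
    strategy emulation.

    Parameters
    ----------
    table : ExperimentTable
        Factors must be registered as ``(treatment, block)`` for an RCB
        design or ``(main_plot, block, subplot)`` for a split-plot design.
    design : {"rcb", "splitplot"}
    fixed_blocks : bool
        Treat block effects as fixed (split-plot only); the block variance
        then drops out of the estimable components.

    Examples
    --------
    >>> from exactanova import make_fixture, BlockAnova
    >>> res = BlockAnova(make_fixture("rcb_boundary", seed=1), design="rcb").fit()
    >>> res.test("exact").df_den, res.test("sas_default").df_den
    (3, 6)
    """

    def __init__(self, table: ExperimentTable, design: str = "rcb", fixed_blocks: bool = False):
        self.table = table
        if design == "rcb":
            if len(table.factors) != 2:
                raise TableError("rcb design requires factors (treatment, block)")
            if fixed_blocks:
                raise ValueError("fixed blocks make the RCB model purely fixed-effects; not handled here")
            treat, block = table.factors
            self.layout = RCBLayout(a=len(table.levels[treat]), b=len(table.levels[block]))
        elif design == "splitplot":
            if len(table.factors) != 3:
                raise TableError("splitplot design requires factors (main_plot, block, subplot)")
            m, bl, s = table.factors
            self.layout = SplitPlotLayout(
                a=len(table.levels[m]), b=len(table.levels[bl]), c=len(table.levels[s]),
                block_effects="fixed" if fixed_blocks else "random",
            )
        else:
            raise ValueError("design must be 'rcb' or 'splitplot'")
        self.design = design

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, response: str, *, design: str,
                       treatment: str, block: str, subplot: str | None = None,
                       fixed_blocks: bool = False) -> "BlockAnova":
        factors = (treatment, block) if design == "rcb" else (treatment, block, subplot)
        table = ExperimentTable.from_dataframe(frame, response, factors)
        return cls(table, design=design, fixed_blocks=fixed_blocks)

    def fit(self) -> "BlockAnovaResults":
        strata = (strata_rcb if self.design == "rcb" else strata_splitplot)(self.table, self.layout)
        return BlockAnovaResults(self, strata)


class BlockAnovaResults:
    """Stratum table, variance components and strategy tests of a fitted
    balanced blocked design."""

    def __init__(self, model: BlockAnova, strata: StratumTable):
        self.model = model
        self.strata = strata

    @property
    def layout(self):
        return self.model.layout

    def varcomps(self, bounded: bool = True) -> VarComps:
        f = varcomp_bounded if bounded else varcomp_unbounded
        return f(self.strata, self.layout)

    def test(self, strategy: str = "exact") -> MixedTestResult:
        return strategy_test(self.strata, self.layout, strategy)

    def tests(self, strategies=STRATEGIES) -> list[MixedTestResult]:
        return [self.test(s) for s in strategies]

    def summary(self) -> str:
        lines = [
            f"Balanced {self.model.design} ANOVA, layout {self.layout}",
            "",
            self.strata.to_frame().to_string(float_format=lambda v: f"{v:.4f}"),
            "",
        ]
        for bounded in (False, True):
            vc = self.varcomps(bounded=bounded)
            tag = "bounded" if bounded else "unbounded"
            comps = ", ".join(f"{k}={v:.4f}" for k, v in vc.as_dict().items())
            extra = f"  (at boundary: {', '.join(vc.at_boundary)})" if vc.at_boundary else ""
            lines.append(f"variance components ({tag}): {comps}{extra}")
        lines.append("")
        rows = [
            {"strategy": r.strategy, "F": r.F, "ndf": r.df_num, "ddf": r.df_den,
             "p": r.pvalue, "boundary": r.at_boundary}
            for r in self.tests()
        ]
        lines.append(pd.DataFrame(rows).set_index("strategy").to_string(float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)
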