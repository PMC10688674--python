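"""Type 1, 2 and 3 tests for the unbalanced two-way model.

All hypotheses tested here are contrasts among the cell means mu_ij.  Each
test family differs only in *which* weights it places on the cells:

* type 1 (sequential): the first factor is tested ignoring the second, with
  cell means weighted by the observed cell frequencies; subsequent terms
  are adjusted for the terms already entered.
* type 2: each main effect is adjusted for the other main effect but not
  for the interaction.
* type 3 (correct): equal (unweighted) marginal means — Yates's method of
  weighted squares of means, computed on the cell-means parametrization so
  the result cannot depend on any contrast coding.
* "type 3 as implemented": the construction used by several popular R
  routines — test the term's own coefficients in the coded parametrization.
  Under sum-to-zero coding this coincides with the correct type 3; under
  first/last-level reference coding it instead tests equality of the two
  sexes *at the reference diet*, a conditional hypothesis.

Every test statistic is the quadratic form
``SS = (W m)' (W D W')^{-1} (W m)`` with ``m`` the observed cell means and
``D = diag(1/n_ij)``, divided by its rank and by the full-model error
variance; this is algebraically identical to the classical
reduction-in-sums-of-squares computations (the unit tests verify that
against nested fits and against statsmodels).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import ExperimentTable
from .design import (
    ContrastScheme,
    DesignError,
    DesignMatrices,
    FixedFit,
    build_design,
    fit_ols,
    pinv_rank,
)

__all__ = [
    "HypothesisSpec",
    "TestResult",
    "EstimabilityError",
    "general_F",
    "type1_tests",
    "type2_tests",
    "type3_correct",
    "type3_as_implemented",
    "hypothesis_weights",
    "TwoWayAnova",
    "TwoWayAnovaResults",
]

logger = logging.getLogger(__name__)

#: numerator quadratic forms below this trigger the "F computed as 0" warning
ZERO_NUMERATOR_TOL = 1e-12


class EstimabilityError(ValueError):
    """A hypothesis row lies outside the row space of the design."""


@dataclass
class HypothesisSpec:
    """A linear hypothesis H0: L beta = 0, optionally with the equivalent
    weight representation on the a*b cell means.

    ``L`` lives in the parametrization of the design it was built for
    (coded columns); ``cell_weights`` has one column per (i,j) cell in
    registered row-major order.  Either may be None.
    """

    L: np.ndarray | None = None
    cell_weights: np.ndarray | None = None
    label: str = ""

    def __post_init__(self):
        if self.L is None and self.cell_weights is None:
            raise ValueError("HypothesisSpec needs L and/or cell_weights")
        if self.L is not None:
            self.L = np.atleast_2d(np.asarray(self.L, dtype=float))
        if self.cell_weights is not None:
            self.cell_weights = np.atleast_2d(np.asarray(self.cell_weights, dtype=float))

    @property
    def k(self) -> int:
        M = self.L if self.L is not None else self.cell_weights
        return int(np.linalg.matrix_rank(M))


@dataclass
class TestResult:
    """One F-test: statistic, degrees of freedom, upper-tail p-value."""

    term: str
    test_type: str                 # "1", "2", "3", "3impl", strategy names
    F: float
    df_num: int
    df_den: float
    pvalue: float
    ss: float | None = None
    scheme: str | None = None
    hypothesis: HypothesisSpec | None = field(default=None, repr=False)

    def as_dict(self) -> dict:
        return {
            "term": self.term, "type": self.test_type, "SS": self.ss,
            "F": self.F, "df_num": self.df_num, "df_den": self.df_den,
            "p": self.pvalue, "scheme": self.scheme,
        }


def _check_rows_nonzero(M: np.ndarray, what: str) -> None:
    norms = np.linalg.norm(M, axis=1)
    if np.any(norms <= ZERO_NUMERATOR_TOL):
        row = int(np.argmin(norms))
        raise ValueError(f"{what} row {row} is (numerically) zero: rank-deficient hypothesis")


def general_F(L, fit: FixedFit, label: str = "") -> TestResult:
    """F-test of H0: L beta = 0 against the fit's error variance.

    ``F = (L b)' (L (X'X)^- L')^{-1} (L b) / k / sigma2_hat`` with
    ``k = rank(L)``; p is the upper-tail F(k, df_resid) probability.
    Raises :class:`EstimabilityError` naming the first offending row if a
    row of L is not estimable.
    """
    spec = L if isinstance(L, HypothesisSpec) else HypothesisSpec(L=L, label=label)
    if spec.L is None:
        raise ValueError("general_F needs a coded-parametrization L")
    if fit.sigma2 is None:
        raise ValueError("error variance unavailable (zero residual df); cannot test")
    Lm = spec.L
    _check_rows_nonzero(Lm, "L")
    X = fit.X
    xtx = X.T @ X
    # estimability: L (X'X)^- (X'X) = L for any reflexive g-inverse
    back = Lm @ fit.ginv @ xtx
    err = np.linalg.norm(back - Lm, axis=1) / np.maximum(np.linalg.norm(Lm, axis=1), 1.0)
    bad = np.flatnonzero(err > 1e-6)
    if bad.size:
        raise EstimabilityError(f"hypothesis row {int(bad[0])} is not estimable (relative error {err[bad[0]]:.2e})")
    M = Lm @ fit.ginv @ Lm.T
    Minv, k = pinv_rank(M)
    if k < Lm.shape[0]:
        raise ValueError(f"L (X'X)^- L' is singular: rank {k} < {Lm.shape[0]} rows; drop redundant rows")
    v = Lm @ fit.beta
    ss = float(v @ Minv @ v)
    if ss < ZERO_NUMERATOR_TOL:
        logger.warning("numerator quadratic form is numerically zero (%.3e); F reported as the true small value", ss)
    F = ss / k / fit.sigma2
    return TestResult(
        term=spec.label or label or "L", test_type="general", F=F, df_num=k,
        df_den=fit.df_resid, pvalue=float(stats.f.sf(F, k, fit.df_resid)),
        ss=ss, hypothesis=spec,
    )


# ----------------------------------------------------------------------
# Cell-mean quadratic-form engine
# ----------------------------------------------------------------------

def cell_quadratic(W: np.ndarray, fit: FixedFit) -> tuple[float, int]:
    """Numerator SS and rank for the hypothesis W mu = 0 on cell means."""
    W = np.atleast_2d(np.asarray(W, dtype=float))
    _check_rows_nonzero(W, "weight matrix")
    D = np.diag(1.0 / fit.cell_counts)
    M = W @ D @ W.T
    Minv, k = pinv_rank(M)
    if k < W.shape[0]:
        raise ValueError(f"weight rows are linearly dependent: rank {k} < {W.shape[0]}")
    v = W @ fit.cell_means
    ss = float(v @ Minv @ v)
    if ss < ZERO_NUMERATOR_TOL:
        logger.warning("numerator quadratic form is numerically zero (%.3e)", ss)
    return ss, k


def _cell_test(W: np.ndarray, fit: FixedFit, term: str, test_type: str,
               scheme: str | None = None) -> TestResult:
    if fit.sigma2 is None:
        raise ValueError("error variance unavailable (zero residual df); cannot test")
    ss, k = cell_quadratic(W, fit)
    F = ss / k / fit.sigma2
    return TestResult(
        term=term, test_type=test_type, F=F, df_num=k, df_den=fit.df_resid,
        pvalue=float(stats.f.sf(F, k, fit.df_resid)), ss=ss, scheme=scheme,
        hypothesis=HypothesisSpec(cell_weights=W, label=term),
    )


# -- weight constructions ----------------------------------------------

def _weights_sequential_first(counts: np.ndarray, first_axis: int) -> np.ndarray:
    """Frequency-weighted marginal-mean contrasts for the factor tested
    ignoring the other (the sequential hypothesis for the first term):
    level i carries weights n_ij / n_i. on its cells."""
    if first_axis == 1:
        counts = counts.T
    a, b = counts.shape
    prop = counts / counts.sum(axis=1, keepdims=True)
    rows = []
    for i in range(a - 1):
        w = np.zeros((a, b))
        w[i] = prop[i]
        w[i + 1] = -prop[i + 1]
        rows.append(w if first_axis == 0 else w.T)
    return np.vstack([r.reshape(1, -1) for r in rows])


def _weights_adjusted_main(table: ExperimentTable, term: str) -> np.ndarray:
    """Weights of the hypothesis tested by the main effect adjusted for the
    other main effect (interaction excluded): the coefficient rows of the
    additive model, expressed as a linear map of the cell means."""
    design = build_design(table, terms=table.factors, scheme=ContrastScheme.SUM_TO_ZERO)
    X = design.X_coded
    xtx_inv, rank = pinv_rank(X.T @ X)
    if rank < X.shape[1]:  # cannot happen with all cells filled
        raise DesignError("additive design is rank deficient")
    proj = xtx_inv @ X.T @ design.X_cell          # beta_additive = proj @ cell_means
    return proj[design.term_columns(term), :]


def _weights_unweighted_main(a: int, b: int, axis: int) -> np.ndarray:
    """Equal-weight marginal-mean contrasts (the correct type 3 hypothesis)."""
    m, other = (a, b) if axis == 0 else (b, a)
    rows = []
    for i in range(m - 1):
        w = np.zeros((a, b))
        sl = (i, slice(None)) if axis == 0 else (slice(None), i)
        sl2 = (i + 1, slice(None)) if axis == 0 else (slice(None), i + 1)
        w[sl] = 1.0 / other
        w[sl2] = -1.0 / other
        rows.append(w.reshape(1, -1))
    return np.vstack(rows)


def _weights_interaction(a: int, b: int) -> np.ndarray:
    """A basis of the interaction space (last levels as reference)."""
    rows = []
    for i in range(a - 1):
        for j in range(b - 1):
            w = np.zeros((a, b))
            w[i, j] = 1.0
            w[i, b - 1] = -1.0
            w[a - 1, j] = -1.0
            w[a - 1, b - 1] = 1.0
            rows.append(w.reshape(1, -1))
    return np.vstack(rows)


def _full_fit(table: ExperimentTable, scheme=ContrastScheme.SUM_TO_ZERO) -> FixedFit:
    return fit_ols(build_design(table, scheme=scheme))


def _axis_of(table: ExperimentTable, factor: str) -> int:
    try:
        return table.factors.index(factor)
    except ValueError:
        raise DesignError(f"factor {factor!r} not in table factors {table.factors}") from None


def type1_tests(table: ExperimentTable, order=None,
                scheme: ContrastScheme = ContrastScheme.SUM_TO_ZERO) -> list[TestResult]:
    """Sequential (added-in-order) tests for both main effects and the
    interaction, each against the full-model error variance.

    The result depends on which factor is named first in ``order``; the
    contrast scheme does not affect the values (it is accepted for
    interface symmetry).  The term sums of squares plus the residual SS
    add up to the total corrected SS.
    """
    fa, fb = table.factors
    order = tuple(order) if order is not None else (fa, fb)
    if set(order) != {fa, fb}:
        raise DesignError(f"order {order!r} must name both factors {table.factors} exactly once")
    first, second = order
    fit = _full_fit(table)
    counts = table.cell_counts(fa, fb)
    scheme = ContrastScheme.from_name(scheme)
    a, b = counts.shape

    W_first = _weights_sequential_first(counts, _axis_of(table, first))
    W_second = _weights_adjusted_main(table, second)
    W_int = _weights_interaction(a, b)
    sch = scheme.value
    return [
        _cell_test(W_first, fit, first, "1", sch),
        _cell_test(W_second, fit, second, "1", sch),
        _cell_test(W_int, fit, f"{fa}:{fb}", "1", sch),
    ]


def type2_tests(table: ExperimentTable,
                scheme: ContrastScheme = ContrastScheme.SUM_TO_ZERO) -> list[TestResult]:
    """Each main effect adjusted for the other main effect (interaction
    excluded); independent of term order and of contrast scheme."""
    fa, fb = table.factors
    fit = _full_fit(table)
    a, b = (len(table.levels[fa]), len(table.levels[fb]))
    sch = ContrastScheme.from_name(scheme).value
    return [
        _cell_test(_weights_adjusted_main(table, fa), fit, fa, "2", sch),
        _cell_test(_weights_adjusted_main(table, fb), fit, fb, "2", sch),
        _cell_test(_weights_interaction(a, b), fit, f"{fa}:{fb}", "2", sch),
    ]


def type3_correct(table: ExperimentTable) -> list[TestResult]:
    """Correct type 3 tests: equal unweighted marginal means for each main
    effect (Yates's weighted squares of means), computed on the cell-means
    parametrization and therefore free of any contrast choice."""
    fa, fb = table.factors
    fit = _full_fit(table)
    a, b = (len(table.levels[fa]), len(table.levels[fb]))
    return [
        _cell_test(_weights_unweighted_main(a, b, 0), fit, fa, "3"),
        _cell_test(_weights_unweighted_main(a, b, 1), fit, fb, "3"),
        _cell_test(_weights_interaction(a, b), fit, f"{fa}:{fb}", "3"),
    ]


def type3_as_implemented(table: ExperimentTable,
                         scheme: ContrastScheme = ContrastScheme.SUM_TO_ZERO) -> list[TestResult]:
    """The contrast-dependent construction used by popular R routines:
    test the term's own coefficients in the coded parametrization.

    Under SUM_TO_ZERO this equals :func:`type3_correct`.  Under
    FIRST_LEVEL_REFERENCE the "sex" test degenerates to a comparison of
    the two sexes at the first level of the other factor; under
    LAST_LEVEL_REFERENCE, at the last level.
    """
    scheme = ContrastScheme.from_name(scheme)
    design = build_design(table, scheme=scheme)
    fit = fit_ols(design)
    out = []
    for term in design.terms:
        idx = design.term_columns(term)
        L = np.zeros((idx.size, design.X_coded.shape[1]))
        L[np.arange(idx.size), idx] = 1.0
        res = general_F(HypothesisSpec(L=L, label=term), fit)
        res.test_type = "3impl"
        res.scheme = scheme.value
        out.append(res)
    return out


ALL_TEST_TYPES = ("1", "2", "3", "3impl")


def hypothesis_weights(spec: HypothesisSpec, design: DesignMatrices) -> np.ndarray:
    """Re-express H0: L beta = 0 as weights on the a*b cell means.

    Since E[Y] = X_cell mu, every estimable L beta equals
    ``L (X'X)^- X' X_cell mu``; the resulting rows are normalized so the
    weights over the first factor level's cells sum to 1 where that sum is
    nonzero (matching the customary fractional presentation), and so the
    first nonzero weight in each row is positive otherwise.
    """
    if spec.cell_weights is not None:
        W = spec.cell_weights.copy()
    else:
        X = design.X_coded
        ginv, _ = pinv_rank(X.T @ X)
        back = spec.L @ ginv @ (X.T @ X)
        err = np.linalg.norm(back - spec.L, axis=1) / np.maximum(np.linalg.norm(spec.L, axis=1), 1.0)
        bad = np.flatnonzero(err > 1e-6)
        if bad.size:
            raise EstimabilityError(f"hypothesis row {int(bad[0])} is not estimable")
        W = spec.L @ ginv @ (X.T @ design.X_cell)

    b = len(design.table.levels[design.factors[1]])
    for r in range(W.shape[0]):
        first_level_sum = W[r, :b].sum()
        if abs(first_level_sum) > 1e-10:
            W[r] /= first_level_sum
        else:
            nz = np.flatnonzero(np.abs(W[r]) > 1e-12)
            if nz.size:
                W[r] /= abs(W[r, nz[0]]) * np.sign(W[r, nz[0]])
    W[np.abs(W) < 1e-12] = 0.0
    return W


# ----------------------------------------------------------------------
# Model / Results front end
# ----------------------------------------------------------------------

class TwoWayAnova:
    """Two-way fixed-effects ANOVA model for possibly unbalanced data.

    Parameters
    ----------
    table : ExperimentTable
        Two registered factors plus a numeric response; every (i,j) cell
        must contain at least one observation.
    scheme : ContrastScheme or str
        Coding used for the coded design (affects only the
        "as-implemented" type 3 tests).

    Examples
    --------
    >>> from exactanova import make_fixture, TwoWayAnova
    >>> res = TwoWayAnova(make_fixture("table1")).fit()
    >>> round(res.anova_table(1).loc["Sex", "F"], 4)
    10.9622
    """

    def __init__(self, table: ExperimentTable, scheme=ContrastScheme.SUM_TO_ZERO):
        if len(table.factors) != 2:
            raise DesignError("TwoWayAnova requires exactly two factors")
        self.table = table
        self.scheme = ContrastScheme.from_name(scheme)
        self.design = build_design(table, scheme=self.scheme)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, response: str, factors,
                       scheme=ContrastScheme.SUM_TO_ZERO) -> "TwoWayAnova":
        return cls(ExperimentTable.from_dataframe(frame, response, tuple(factors)), scheme)

    def fit(self) -> "TwoWayAnovaResults":
        return TwoWayAnovaResults(self, fit_ols(self.design))


class TwoWayAnovaResults:
    """Fitted two-way ANOVA: estimates, error variance and the four test
    families."""

    def __init__(self, model: TwoWayAnova, fit: FixedFit):
        self.model = model
        self.fit = fit

    @property
    def sigma2(self) -> float | None:
        return self.fit.sigma2

    @property
    def df_resid(self) -> int:
        return self.fit.df_resid

    @property
    def rss(self) -> float:
        return self.fit.rss

    def cell_means(self) -> pd.DataFrame:
        fa, fb = self.model.table.factors
        t = self.model.table
        return pd.DataFrame(
            np.asarray(self.fit.cell_means).reshape(len(t.levels[fa]), len(t.levels[fb])),
            index=pd.Index(t.levels[fa], name=fa),
            columns=pd.Index(t.levels[fb], name=fb),
        )

    def tests(self, test_type: str, order=None) -> list[TestResult]:
        table, scheme = self.model.table, self.model.scheme
        if test_type == "1":
            return type1_tests(table, order=order, scheme=scheme)
        if test_type == "2":
            return type2_tests(table, scheme=scheme)
        if test_type == "3":
            return type3_correct(table)
        if test_type == "3impl":
            return type3_as_implemented(table, scheme=scheme)
        raise ValueError(f"unknown test type {test_type!r}; choose from {ALL_TEST_TYPES}")

    def anova_table(self, test_type="3", order=None) -> pd.DataFrame:
        rows = [r.as_dict() for r in self.tests(str(test_type), order=order)]
        return pd.DataFrame(rows).set_index("term")

    def hypothesis_weights(self, test_type: str, term: str | None = None, order=None) -> np.ndarray:
        term = term or self.model.table.factors[0]
        for res in self.tests(str(test_type), order=order):
            if res.term == term:
                return hypothesis_weights(res.hypothesis, self.model.design)
        raise ValueError(f"no test of term {term!r}")

    def summary(self) -> str:
        t = self.model.table
        lines = [
            "Two-way fixed-effects ANOVA",
            f"  response: {t.response}   factors: {t.factors[0]} x {t.factors[1]}"
            f"   n = {t.n}",
            f"  contrast scheme: {self.model.scheme.value}",
            f"  residual SS = {self.rss:.4f} on {self.df_resid} df"
            + (f"   sigma2_hat = {self.sigma2:.4f}" if self.sigma2 is not None else "   (saturated)"),
            "",
        ]
        for typ in ("1", "2", "3", "3impl"):
            df = self.anova_table(typ)
            lines.append(f"Type {typ} tests" + ("" if typ in ("1", "2") else f" [{self.model.scheme.value}]" if typ == "3impl" else " (unweighted marginal means)"))
            lines.append(
                df[["SS", "F", "df_num", "df_den", "p"]]
                .to_string(float_format=lambda v: f"{v:.4f}")
            )
            lines.append("")
        return "\n".join(lines)
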