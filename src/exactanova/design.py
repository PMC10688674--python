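"""Contrast coding, design matrices and generalized-inverse least squares.

The two-way interaction model ``y_ijk = mu + alpha_i + beta_j + gamma_ij +
e_ijk`` is overparameterized in its indicator form; it is handled here both
through a full-column-rank *coded* design (intercept + contrast columns)
and through the *cell-means* design (one indicator per (i,j) cell).  The
two spans are identical, so fitted values, residual sums of squares and all
estimable functions agree between them — only the meaning of individual
coefficients depends on the coding.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .data import ExperimentTable, TableError

__all__ = [
    "ContrastScheme",
    "coding_matrix",
    "DesignMatrices",
    "DesignError",
    "build_design",
    "FixedFit",
    "fit_ols",
]

#: relative singular-value cutoff for the rank-revealing pseudo-inverse
RANK_RTOL = 1e-9


class DesignError(ValueError):
    """Raised for invalid factor/term configurations."""


class ContrastScheme(enum.Enum):
    """How an m-level factor maps to its m x (m-1) coding matrix.

    FIRST_LEVEL_REFERENCE sets the first level's parameters to zero
    (R's ``contr.treatment``); LAST_LEVEL_REFERENCE sets the last level's
    (R's ``contr.SAS``); SUM_TO_ZERO sigma-restricts each factor's
    parameters to sum to zero (``contr.sum``).
    """

    FIRST_LEVEL_REFERENCE = "treatment"
    LAST_LEVEL_REFERENCE = "saslast"
    SUM_TO_ZERO = "sum"

    @classmethod
    def from_name(cls, name) -> "ContrastScheme":
        if isinstance(name, cls):
            return name
        for scheme in cls:
            if name in (scheme.name, scheme.value):
                return scheme
        raise DesignError(f"unknown contrast scheme {name!r}")


def coding_matrix(m: int, scheme: ContrastScheme) -> np.ndarray:
    """Return the m x (m-1) level-coding matrix for an m-level factor."""
    if m < 2:
        raise DesignError("a factor needs at least 2 levels to be coded")
    scheme = ContrastScheme.from_name(scheme)
    if scheme is ContrastScheme.FIRST_LEVEL_REFERENCE:
        return np.vstack([np.zeros((1, m - 1)), np.eye(m - 1)])
    if scheme is ContrastScheme.LAST_LEVEL_REFERENCE:
        return np.vstack([np.eye(m - 1), np.zeros((1, m - 1))])
    return np.vstack([np.eye(m - 1), -np.ones((1, m - 1))])  # SUM_TO_ZERO


@dataclass
class DesignMatrices:
    """Coded and cell-means design matrices for a two-way layout.

    ``columns`` maps each coded column to its term ("(Intercept)", factor
    name, or "A:B") and the level combination it codes.
    """

    table: ExperimentTable
    factors: tuple[str, str]
    scheme: ContrastScheme
    terms: tuple[str, ...]
    X_coded: np.ndarray
    X_cell: np.ndarray
    columns: list[tuple[str, str]]          # (term, label) per coded column
    cells: list[tuple[str, str]]            # (level_a, level_b) per cell column

    def term_columns(self, term: str) -> np.ndarray:
        idx = [i for i, (t, _) in enumerate(self.columns) if t == term]
        if not idx:
            raise DesignError(f"term {term!r} not in design (terms: {self.terms})")
        return np.asarray(idx)


def _interaction_name(fa: str, fb: str) -> str:
    return f"{fa}:{fb}"


def build_design(
    table: ExperimentTable,
    terms=None,
    scheme: ContrastScheme = ContrastScheme.SUM_TO_ZERO,
) -> DesignMatrices:
    """Build coded and cell-means design matrices for a two-way model.

    ``terms`` is the ordered term list; by default ``(A, B, A:B)`` with A
    the factor registered first.  Sub-models (e.g. ``("Sex",)`` or
    ``("Sex", "Diet")``) are supported for sequential fitting.
    """
    scheme = ContrastScheme.from_name(scheme)
    if len(table.factors) != 2:
        raise DesignError(f"two-way design requires exactly 2 factors, got {table.factors}")
    fa, fb = table.factors
    if terms is None:
        terms = (fa, fb, _interaction_name(fa, fb))
    terms = tuple(terms)
    known = {fa, fb, _interaction_name(fa, fb), _interaction_name(fb, fa)}
    for t in terms:
        if t not in known:
            raise DesignError(f"unknown term {t!r}; factors are {table.factors}")
    for f in (fa, fb):
        if len(table.levels[f]) < 2:
            raise DesignError(f"factor {f!r} has a single level; no contrast columns exist")
    table.require_no_empty_cells(fa, fb)

    ia = table.level_index(fa).to_numpy()
    ib = table.level_index(fb).to_numpy()
    a, b = len(table.levels[fa]), len(table.levels[fb])
    Ca = coding_matrix(a, scheme)
    Cb = coding_matrix(b, scheme)

    cols = [np.ones(table.n)]
    names: list[tuple[str, str]] = [("(Intercept)", "1")]
    for term in terms:
        if term == fa:
            for j in range(a - 1):
                cols.append(Ca[ia, j])
                names.append((fa, table.levels[fa][j if scheme is not ContrastScheme.FIRST_LEVEL_REFERENCE else j + 1]))
        elif term == fb:
            for j in range(b - 1):
                cols.append(Cb[ib, j])
                names.append((fb, table.levels[fb][j if scheme is not ContrastScheme.FIRST_LEVEL_REFERENCE else j + 1]))
        else:  # interaction
            for p in range(a - 1):
                for q in range(b - 1):
                    cols.append(Ca[ia, p] * Cb[ib, q])
                    names.append((_interaction_name(fa, fb), f"{p},{q}"))
    X_coded = np.column_stack(cols)

    cells = table.cells(fa, fb)
    cell_idx = ia * b + ib
    X_cell = np.zeros((table.n, a * b))
    X_cell[np.arange(table.n), cell_idx] = 1.0

    return DesignMatrices(
        table=table, factors=(fa, fb), scheme=scheme, terms=terms,
        X_coded=X_coded, X_cell=X_cell, columns=names, cells=cells,
    )


@dataclass
class FixedFit:
    """Generalized-inverse least-squares solution of a fixed-effects model.

    Holds the solution vector, the reflexive g-inverse of X'X used to
    obtain it, the residual sum of squares and df, the error-variance
    estimate (``None`` when the residual df is zero), and the fitted cell
    means of the saturated layout.
    """

    design: DesignMatrices
    X: np.ndarray                 # the model matrix actually solved
    beta: np.ndarray
    ginv: np.ndarray              # (X'X)^- , reflexive
    rank: int
    rss: float
    df_resid: int
    sigma2: float | None
    cell_means: np.ndarray        # shape (a*b,), registered cell order
    cell_counts: np.ndarray       # shape (a*b,)

    @property
    def fitted(self) -> np.ndarray:
        return self.X @ self.beta

    @property
    def residuals(self) -> np.ndarray:
        return self.design.table.y - self.fitted


def pinv_rank(M: np.ndarray, rtol: float = RANK_RTOL) -> tuple[np.ndarray, int]:
    """Rank-revealing Moore–Penrose pseudo-inverse via SVD.

    Singular values below ``rtol`` times the largest are treated as zero.
    The Moore–Penrose inverse is in particular a reflexive g-inverse, so
    estimable functions do not depend on this choice.
    """
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    if s.size == 0 or s[0] == 0.0:
        return np.zeros_like(M.T), 0
    keep = s > rtol * s[0]
    s_inv = np.where(keep, 1.0 / np.where(keep, s, 1.0), 0.0)
    return (Vt.T * s_inv) @ U.T, int(keep.sum())


def fit_ols(design: DesignMatrices, table: ExperimentTable | None = None) -> FixedFit:
    """Least-squares fit via the generalized inverse of X'X.

    beta = (X'X)^- X'Y.  Works for rank-deficient designs; for the coded
    full-rank design the g-inverse is the ordinary inverse.  When the
    residual df is zero (saturated model, one observation per cell) the fit
    succeeds but the error variance is flagged unavailable.
    """
    if table is None:
        table = design.table
    if table is not design.table and len(table.frame) != len(design.table.frame):
        raise DesignError("design was built from a different table")
    X = design.X_coded
    y = table.y
    xtx = X.T @ X
    ginv, rank = pinv_rank(xtx)
    beta = ginv @ (X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df_resid = table.n - rank
    sigma2 = rss / df_resid if df_resid > 0 else None

    counts = design.X_cell.sum(axis=0)
    with np.errstate(invalid="ignore"):
        cell_means = (design.X_cell.T @ y) / counts
    return FixedFit(
        design=design, X=X, beta=beta, ginv=ginv, rank=rank, rss=rss,
        df_resid=df_resid, sigma2=sigma2,
        cell_means=cell_means, cell_counts=counts,
    )


def fit_cell_means(design: DesignMatrices) -> FixedFit:
    """Saturated fit in the cell-means parametrization (used as the
    contrast-free route for correct type 3 tests and weight extraction)."""
    X = design.X_cell
    y = design.table.y
    xtx = X.T @ X
    ginv, rank = pinv_rank(xtx)
    beta = ginv @ (X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df_resid = design.table.n - rank
    counts = X.sum(axis=0)
    return FixedFit(
        design=design, X=X, beta=beta, ginv=ginv, rank=rank, rss=rss,
        df_resid=df_resid, sigma2=rss / df_resid if df_resid > 0 else None,
        cell_means=beta.copy(), cell_counts=counts,
    )
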