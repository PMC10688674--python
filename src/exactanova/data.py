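"""Long-format experiment tables, CSV input, and built-in fixtures.

An :class:`ExperimentTable` holds one row per observation: string-valued
factor columns plus a numeric response.  Factor levels are ordered by first
appearance unless an explicit order is supplied; contrast semantics
("first level", "last level") are defined against this order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExperimentTable",
    "TableError",
    "read_table",
    "make_fixture",
    "FIXTURE_NAMES",
]


class TableError(ValueError):
    """Raised for malformed or inconsistent experiment tables."""


@dataclass
class ExperimentTable:
    """Long-format observations: factor-level assignments plus a response.

    Parameters
    ----------
    frame : pandas.DataFrame
        One row per observation.  Factor columns are coerced to strings
        ("1" is the diet *label*, not the number 1).
    response : str
        Name of the numeric response column.
    factors : tuple of str
        Registered factor columns, in the order they were declared.
    levels : dict
        Ordered level list per factor (first-appearance order by default).
    """

    frame: pd.DataFrame
    response: str
    factors: tuple[str, ...]
    levels: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.factors = tuple(self.factors)
        missing = [c for c in (*self.factors, self.response) if c not in self.frame.columns]
        if missing:
            raise TableError(f"column(s) not present in data: {missing}")
        frame = self.frame.copy()
        y = pd.to_numeric(frame[self.response], errors="coerce")
        if y.isna().any():
            bad = int(np.flatnonzero(y.isna().to_numpy())[0])
            raise TableError(
                f"response column {self.response!r} is missing or non-numeric at row {bad}"
            )
        yv = y.to_numpy(dtype=float)
        if not np.all(np.isfinite(yv)):
            raise TableError(f"response column {self.response!r} contains non-finite values")
        frame[self.response] = yv
        for f in self.factors:
            frame[f] = frame[f].astype(str)
            observed = list(dict.fromkeys(frame[f].tolist()))
            if f in self.levels:
                unknown = set(observed) - set(self.levels[f])
                if unknown:
                    raise TableError(f"factor {f!r} has levels {sorted(unknown)} outside the declared order")
            else:
                self.levels[f] = observed
        if len(frame) == 0:
            raise TableError("empty table")
        self.frame = frame.reset_index(drop=True)

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        response: str,
        factors: tuple[str, ...] | list[str],
        levels: dict[str, list[str]] | None = None,
    ) -> "ExperimentTable":
        return cls(frame=frame, response=response, factors=tuple(factors), levels=dict(levels or {}))

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def y(self) -> np.ndarray:
        return self.frame[self.response].to_numpy(dtype=float)

    def level_index(self, factor: str) -> pd.Series:
        """Integer level codes (0-based, in registered level order)."""
        lut = {lev: i for i, lev in enumerate(self.levels[factor])}
        return self.frame[factor].map(lut)

    # -- two-way helpers ------------------------------------------------
    def cells(self, fa: str, fb: str) -> list[tuple[str, str]]:
        """All (level_a, level_b) cells in row-major registered order."""
        return [(la, lb) for la in self.levels[fa] for lb in self.levels[fb]]

    def cell_counts(self, fa: str, fb: str) -> np.ndarray:
        a, b = len(self.levels[fa]), len(self.levels[fb])
        counts = np.zeros((a, b), dtype=int)
        ia = self.level_index(fa).to_numpy()
        ib = self.level_index(fb).to_numpy()
        np.add.at(counts, (ia, ib), 1)
        return counts

    def cell_means(self, fa: str, fb: str) -> np.ndarray:
        a, b = len(self.levels[fa]), len(self.levels[fb])
        tot = np.zeros((a, b))
        ia = self.level_index(fa).to_numpy()
        ib = self.level_index(fb).to_numpy()
        np.add.at(tot, (ia, ib), self.y)
        counts = self.cell_counts(fa, fb)
        with np.errstate(invalid="ignore"):
            return tot / counts

    def require_no_empty_cells(self, fa: str, fb: str) -> None:
        counts = self.cell_counts(fa, fb)
        if (counts == 0).any():
            i, j = map(int, np.argwhere(counts == 0)[0])
            raise TableError(
                f"empty cell ({self.levels[fa][i]}, {self.levels[fb][j]}): "
                "two-way tests here require n_ij >= 1 in every cell"
            )


def read_table(path, response_col: str, factor_cols) -> ExperimentTable:
    """Read a long-format CSV (header row, comma separated, UTF-8).

    Raises :class:`TableError` with a distinct message for a missing
    column, a non-numeric/missing response, or an empty file.
    """
    try:
        frame = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise TableError(f"empty file: {path}") from exc
    if len(frame) == 0:
        raise TableError(f"file has a header but no rows: {path}")
    for col in (*factor_cols, response_col):
        if col not in frame.columns:
            raise TableError(f"column {col!r} not found in {path} (header: {list(frame.columns)})")
    return ExperimentTable.from_dataframe(frame, response=response_col, factors=tuple(factor_cols))


# ----------------------------------------------------------------------
# Built-in fixtures
# ----------------------------------------------------------------------

# Unbalanced two-factorial weight-gain experiment: 15 animals, each on one
# of three diets, weight gain recorded; sex is the factor of interest.
_TABLE1 = {
    ("Female", "1"): [10],
    ("Female", "2"): [19, 21],
    ("Female", "3"): [23, 22, 25],
    ("Male", "1"): [13, 17, 14],
    ("Male", "2"): [18, 20, 17],
    ("Male", "3"): [17, 18, 20],
}

FIXTURE_NAMES = ("table1", "rcb_boundary", "splitplot_boundary", "balanced_2x2")


def _table1() -> ExperimentTable:
    rows = [(s, d, y) for (s, d), ys in _TABLE1.items() for y in ys]
    frame = pd.DataFrame(rows, columns=["Sex", "Diet", "gain"])
    return ExperimentTable.from_dataframe(frame, response="gain", factors=("Sex", "Diet"))


def _balanced_2x2(seed: int) -> ExperimentTable:
    rng = np.random.default_rng(seed)
    rows = []
    for la in ("a1", "a2"):
        for lb in ("b1", "b2"):
            for _ in range(3):
                rows.append((la, lb, rng.normal()))
    frame = pd.DataFrame(rows, columns=["A", "B", "y"])
    return ExperimentTable.from_dataframe(frame, response="y", factors=("A", "B"))


def _rcb_boundary(seed: int) -> ExperimentTable:
    """Synthetic RCB dataset (a=2, b=4) with a negative unbounded block
    variance estimate, found by rejection sampling from the seeded stream."""
    from .simulate import gen_rcb
    from .mixed import RCBLayout, strata_rcb, varcomp_unbounded

    layout = RCBLayout(a=2, b=4)
    rng = np.random.default_rng([seed, 101])
    for _ in range(1000):
        table = gen_rcb(layout, sigma_b2=0.1, sigma_e2=1.0, rng=rng)
        vc = varcomp_unbounded(strata_rcb(table, layout), layout)
        if vc.sigma_b2 < 0:
            return table
    raise RuntimeError("rejection sampling failed to find a boundary RCB dataset")


def _splitplot_boundary(seed: int) -> ExperimentTable:
    """Synthetic split-plot dataset (a=3, b=2, c=12) with a negative
    unbounded whole-plot variance estimate."""
    from .simulate import gen_splitplot
    from .mixed import SplitPlotLayout, strata_splitplot, varcomp_unbounded

    layout = SplitPlotLayout(a=3, b=2, c=12)
    rng = np.random.default_rng([seed, 202])
    for _ in range(1000):
        table = gen_splitplot(layout, sigma_b2=1.0, sigma_ab2=0.1, sigma_e2=1.0, rng=rng)
        vc = varcomp_unbounded(strata_splitplot(table, layout), layout)
        if vc.sigma_ab2 < 0:
            return table
    raise RuntimeError("rejection sampling failed to find a boundary split-plot dataset")


def make_fixture(name: str, seed: int = 0) -> ExperimentTable:
    """Return a named built-in dataset.

    ``table1`` is the printed unbalanced weight-gain experiment;
    ``rcb_boundary`` / ``splitplot_boundary`` are seeded synthetic datasets
    guaranteed to have a negative unbounded variance estimate (for
    exercising strategy divergence); ``balanced_2x2`` is a balanced layout
    on which all fixed-test types coincide.
    """
    if name == "table1":
        return _table1()
    if name == "balanced_2x2":
        return _balanced_2x2(seed)
    if name == "rcb_boundary":
        return _rcb_boundary(seed)
    if name == "splitplot_boundary":
        return _splitplot_boundary(seed)
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
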