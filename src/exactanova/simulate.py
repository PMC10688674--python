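"""Monte-Carlo engine: Type I error rates of the test strategies, boundary
probabilities, and p-value uniformity, for balanced RCB and split-plot
designs simulated under the null hypothesis (all fixed effects zero).

Two generation routes are provided.  The ``data`` route draws every
observation (block effects, whole-plot effects, residuals all normal) and
runs the ANOVA decomposition; the default ``strata`` route draws the
stratum sums of squares directly from their exact sampling distribution —
under the null each stratum SS is an independent scaled chi-square,
``SS_s ~ lambda_s * chi2(df_s)`` with ``lambda_s`` the stratum's expected
mean square.  The two routes sample the same distribution; the data route
serves as a cross-check of the closed form.

All reported frequencies carry their Monte-Carlo standard error
``sqrt(p(1-p)/n)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .data import ExperimentTable
from .mixed import RCBLayout, SplitPlotLayout, STRATEGIES

__all__ = [
    "SimulationSpec",
    "SimulationResult",
    "gen_rcb",
    "gen_splitplot",
    "sample_strata",
    "type1_error_study",
    "boundary_prob",
    "boundary_prob_exact",
    "pvalue_quantiles",
    "run_grid",
    "default_grid",
]


@dataclass(frozen=True)
class SimulationSpec:
    """One simulation case: model, layout, generating variances, replicate
    count, significance level, strategies and master seed."""

    model: str                       # "rcb" | "splitplot"
    a: int
    b: int
    c: int | None = None
    sigma_b2: float = 1.0
    sigma_ab2: float = 0.0
    sigma_e2: float = 1.0
    reps: int = 200_000
    alpha: float = 0.05
    strategies: tuple[str, ...] = STRATEGIES
    seed: int = 0
    blocks: str = "random"
    method: str = "strata"           # "strata" | "data"

    def __post_init__(self):
        if self.model not in ("rcb", "splitplot"):
            raise ValueError("model must be 'rcb' or 'splitplot'")
        if self.model == "splitplot" and not self.c:
            raise ValueError("split-plot spec needs c")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for name, v in (("sigma_b2", self.sigma_b2), ("sigma_ab2", self.sigma_ab2),
                        ("sigma_e2", self.sigma_e2)):
            if v < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def layout(self):
        if self.model == "rcb":
            return RCBLayout(self.a, self.b)
        return SplitPlotLayout(self.a, self.b, self.c, block_effects=self.blocks)


@dataclass
class SimulationResult:
    """Per-strategy rejection frequencies with Monte-Carlo standard errors
    plus the boundary frequency of the case."""

    spec: SimulationSpec
    rejection: dict[str, float]
    mc_se: dict[str, float]
    boundary_freq: float
    pvalues: dict[str, np.ndarray] | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"strategy": s, "rejection": self.rejection[s], "mc_se": self.mc_se[s],
             "boundary_freq": self.boundary_freq}
            for s in self.rejection
        ]
        return pd.DataFrame(rows).set_index("strategy")


# ----------------------------------------------------------------------
# Single-dataset generators
# ----------------------------------------------------------------------

def gen_rcb(layout: RCBLayout, sigma_b2: float, sigma_e2: float,
            rng: np.random.Generator) -> ExperimentTable:
    """One RCB dataset under the null: y_ij = b_j + e_ij with
    b_j ~ N(0, sigma_b2), e_ij ~ N(0, sigma_e2), all fixed effects zero."""
    y = (rng.normal(0.0, np.sqrt(sigma_b2), (1, layout.b))
         + rng.normal(0.0, np.sqrt(sigma_e2), (layout.a, layout.b)))
    rows = [
        (f"t{i+1}", f"b{j+1}", y[i, j])
        for i in range(layout.a) for j in range(layout.b)
    ]
    frame = pd.DataFrame(rows, columns=["treatment", "block", "y"])
    return ExperimentTable.from_dataframe(frame, response="y", factors=("treatment", "block"))


def gen_splitplot(layout: SplitPlotLayout, sigma_b2: float, sigma_ab2: float,
                  sigma_e2: float, rng: np.random.Generator) -> ExperimentTable:
    """One split-plot dataset under the null:
    y_ijk = b_j + (ab)_ij + e_ijk.  Block effects are generated the same
    way for fixed-block studies (the generating design still has block
    heterogeneity; "fixed" only changes the analysis model)."""
    a, b, c = layout.a, layout.b, layout.c
    y = (rng.normal(0.0, np.sqrt(sigma_b2), (1, b, 1))
         + rng.normal(0.0, np.sqrt(sigma_ab2), (a, b, 1))
         + rng.normal(0.0, np.sqrt(sigma_e2), (a, b, c)))
    rows = [
        (f"m{i+1}", f"b{j+1}", f"s{k+1}", y[i, j, k])
        for i in range(a) for j in range(b) for k in range(c)
    ]
    frame = pd.DataFrame(rows, columns=["main", "block", "sub", "y"])
    return ExperimentTable.from_dataframe(frame, response="y", factors=("main", "block", "sub"))


# ----------------------------------------------------------------------
# Vectorized stratum sampling
# ----------------------------------------------------------------------

def _ems(spec: SimulationSpec) -> dict[str, float]:
    """Expected mean squares of the strata relevant to the treatment test."""
    if spec.model == "rcb":
        return {"A": spec.sigma_e2, "den": spec.sigma_e2,
                "pool": spec.sigma_e2 + spec.a * spec.sigma_b2}
    lam_w = spec.sigma_e2 + spec.c * spec.sigma_ab2
    return {"A": lam_w, "den": lam_w, "pool": spec.sigma_e2}


def _dfs(spec: SimulationSpec) -> dict[str, int]:
    a, b = spec.a, spec.b
    if spec.model == "rcb":
        # denominator stratum E; the stratum pooled with it at boundary is B
        return {"A": a - 1, "den": (a - 1) * (b - 1), "pool": b - 1,
                "sas": a * (b - 1)}
    c = spec.c
    # denominator stratum AB; pooled with the residual stratum E at boundary
    return {"A": a - 1, "den": (a - 1) * (b - 1), "pool": a * (b - 1) * (c - 1),
            "sas": (a * c - 1) * (b - 1)}


def sample_strata(spec: SimulationSpec, rng: np.random.Generator,
                  reps: int | None = None) -> dict[str, np.ndarray]:
    """Sums of squares of the treatment stratum (A), the exact-test
    denominator stratum (E for RCB, AB for split-plot) and the stratum
    pooled with it at the boundary (B for RCB, E for split-plot), for
    ``reps`` replicates.

    ``method='strata'`` draws each SS from its scaled-chi-square law;
    ``method='data'`` generates full data arrays and decomposes them.
    """
    reps = reps or spec.reps
    dfs, ems = _dfs(spec), _ems(spec)
    if spec.method == "strata":
        return {
            "A": ems["A"] * rng.chisquare(dfs["A"], reps),
            "den": ems["den"] * rng.chisquare(dfs["den"], reps),
            "pool": ems["pool"] * rng.chisquare(dfs["pool"], reps),
        }
    if spec.method != "data":
        raise ValueError("method must be 'strata' or 'data'")
    out = {k: np.empty(reps) for k in ("A", "den", "pool")}
    chunk = max(1, int(2e6 // (spec.a * spec.b * (spec.c or 1))))
    for start in range(0, reps, chunk):
        n = min(chunk, reps - start)
        sl = slice(start, start + n)
        if spec.model == "rcb":
            y = (rng.normal(0, np.sqrt(spec.sigma_b2), (n, 1, spec.b))
                 + rng.normal(0, np.sqrt(spec.sigma_e2), (n, spec.a, spec.b)))
            g = y.mean(axis=(1, 2), keepdims=True)
            yi = y.mean(axis=2, keepdims=True)
            yj = y.mean(axis=1, keepdims=True)
            out["A"][sl] = spec.b * ((yi - g) ** 2).sum(axis=(1, 2))
            out["pool"][sl] = spec.a * ((yj - g) ** 2).sum(axis=(1, 2))
            out["den"][sl] = ((y - yi - yj + g) ** 2).sum(axis=(1, 2))
        else:
            a, b, c = spec.a, spec.b, spec.c
            y = (rng.normal(0, np.sqrt(spec.sigma_b2), (n, 1, b, 1))
                 + rng.normal(0, np.sqrt(spec.sigma_ab2), (n, a, b, 1))
                 + rng.normal(0, np.sqrt(spec.sigma_e2), (n, a, b, c)))
            g = y.mean(axis=(1, 2, 3), keepdims=True)
            yi = y.mean(axis=(2, 3), keepdims=True)
            yj = y.mean(axis=(1, 3), keepdims=True)
            yij = y.mean(axis=3, keepdims=True)
            yik = y.mean(axis=2, keepdims=True)
            out["A"][sl] = b * c * ((yi - g) ** 2).sum(axis=(1, 2, 3))
            out["den"][sl] = c * ((yij - yi - yj + g) ** 2).sum(axis=(1, 2, 3))
            out["pool"][sl] = ((y - yij - yik + yi) ** 2).sum(axis=(1, 2, 3))
    return out


def _strategy_pvalues(spec: SimulationSpec, ss: dict[str, np.ndarray],
                      strategy: str) -> np.ndarray:
    """Per-replicate p-values of one strategy from the stratum SS arrays."""
    dfs = _dfs(spec)
    ms_a = ss["A"] / dfs["A"]
    ms_den = ss["den"] / dfs["den"]
    F_exact = ms_a / ms_den
    if strategy in ("exact", "nobound"):
        return stats.f.sf(F_exact, dfs["A"], dfs["den"])
    boundary = _boundary_mask(spec, ss)
    pooled = (ss["den"] + ss["pool"]) / (dfs["den"] + dfs["pool"])
    F_bd = ms_a / pooled
    ddf_bd = dfs["sas"] if strategy == "sas_default" else dfs["den"]
    p = stats.f.sf(F_exact, dfs["A"], dfs["den"])
    p_bd = stats.f.sf(F_bd, dfs["A"], ddf_bd)
    return np.where(boundary, p_bd, p)


def _boundary_mask(spec: SimulationSpec, ss: dict[str, np.ndarray]) -> np.ndarray:
    """Non-positive unbounded innermost variance estimate, per replicate."""
    dfs = _dfs(spec)
    ms_den = ss["den"] / dfs["den"]
    ms_pool = ss["pool"] / dfs["pool"]
    if spec.model == "rcb":
        return ms_pool <= ms_den      # MS_B <= MS_E
    return ms_den <= ms_pool          # MS_AB <= MS_E


def _case_rng(spec: SimulationSpec, case_index: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(spec.seed) & 0x7FFFFFFF, case_index])


def type1_error_study(spec: SimulationSpec, case_index: int = 0,
                      keep_pvalues: bool = False) -> SimulationResult:
    """Estimate the Type I error frequency of each strategy at the spec's
    significance level, together with the boundary frequency."""
    rng = _case_rng(spec, case_index)
    ss = sample_strata(spec, rng)
    rejection, mc_se, pvals = {}, {}, {}
    for strat in spec.strategies:
        p = _strategy_pvalues(spec, ss, strat)
        rej = float(np.mean(p < spec.alpha))
        rejection[strat] = rej
        mc_se[strat] = float(np.sqrt(rej * (1 - rej) / spec.reps))
        if keep_pvalues:
            pvals[strat] = np.sort(p)
    return SimulationResult(
        spec=spec, rejection=rejection, mc_se=mc_se,
        boundary_freq=float(np.mean(_boundary_mask(spec, ss))),
        pvalues=pvals if keep_pvalues else None,
    )


def boundary_prob(spec: SimulationSpec, case_index: int = 0) -> SimulationResult:
    """Monte-Carlo frequency of a non-positive unbounded innermost variance
    estimate."""
    rng = _case_rng(spec, case_index)
    ss = sample_strata(spec, rng)
    freq = float(np.mean(_boundary_mask(spec, ss)))
    return SimulationResult(
        spec=spec, rejection={}, mc_se={"boundary": float(np.sqrt(freq * (1 - freq) / spec.reps))},
        boundary_freq=freq,
    )


def boundary_prob_exact(spec: SimulationSpec) -> float:
    """Closed-form boundary probability from the central-F distribution.

    The innermost unbounded estimate is non-positive iff the ratio of the
    two stratum mean squares falls below the ratio of their expected mean
    squares, a central F event:
    RCB, P(MS_B <= MS_E) = P(F(b-1, (a-1)(b-1)) <= sigma_e2 / (sigma_e2 + a sigma_b2));
    split-plot analogously with the AB and E strata.
    """
    dfs = _dfs(spec)
    if spec.model == "rcb":
        ratio = spec.sigma_e2 / (spec.sigma_e2 + spec.a * spec.sigma_b2)
        return float(stats.f.cdf(ratio, dfs["pool"], dfs["den"]))
    ratio = spec.sigma_e2 / (spec.sigma_e2 + spec.c * spec.sigma_ab2)
    return float(stats.f.cdf(ratio, dfs["den"], dfs["pool"]))


def pvalue_quantiles(spec: SimulationSpec, strategy: str = "exact",
                     case_index: int = 0) -> pd.DataFrame:
    """Sorted p-values paired with uniform quantiles, for Q-Q plotting.

    Columns: ``empirical`` (order statistics of the simulated p-values)
    and ``uniform`` (the corresponding U(0,1) plotting positions
    (i - 0.5)/n).
    """
    res = type1_error_study(replace(spec, strategies=(strategy,)), case_index,
                            keep_pvalues=True)
    p = res.pvalues[strategy]
    n = len(p)
    return pd.DataFrame({"empirical": p, "uniform": (np.arange(1, n + 1) - 0.5) / n})


# ----------------------------------------------------------------------
# Grid runner
# ----------------------------------------------------------------------

def default_grid() -> dict:
    """The shipped 30 + 30 case grid (five block/whole-plot variances per
    layout, six layouts per model)."""
    import importlib.resources as res

    import yaml

    with res.files("exactanova").joinpath("config/table_grid.yaml").open() as fh:
        return yaml.safe_load(fh)


def grid_cases(config: dict, reps: int | None = None, seed: int = 0,
               strategies=STRATEGIES) -> list[SimulationSpec]:
    cases = []
    for model_cfg in config["models"]:
        model = model_cfg["model"]
        for layout in model_cfg["layouts"]:
            for var in model_cfg["variances"]:
                kw = dict(model=model, a=layout["a"], b=layout["b"],
                          c=layout.get("c"), reps=reps or model_cfg.get("reps", 200_000),
                          alpha=model_cfg.get("alpha", 0.05), seed=seed,
                          strategies=tuple(strategies))
                if model == "rcb":
                    kw.update(sigma_b2=var, sigma_e2=model_cfg.get("sigma_e2", 1.0))
                else:
                    kw.update(sigma_ab2=var, sigma_b2=model_cfg.get("sigma_b2", 1.0),
                              sigma_e2=model_cfg.get("sigma_e2", 1.0))
                cases.append(SimulationSpec(**kw))
    return cases


def run_grid(config: dict | None = None, reps: int | None = None, seed: int = 0,
             strategies=STRATEGIES) -> pd.DataFrame:
    """Run the Type I error study over a case grid; one output row per
    case, one column per strategy, plus the boundary-frequency column
    (mirroring the layout of the published comparison tables)."""
    config = config or default_grid()
    rows = []
    for idx, spec in enumerate(grid_cases(config, reps=reps, seed=seed, strategies=strategies)):
        res = type1_error_study(spec, case_index=idx)
        row = {"model": spec.model, "a": spec.a, "b": spec.b}
        if spec.model == "splitplot":
            row["c"] = spec.c
            row["sigma_ab2"] = spec.sigma_ab2
        else:
            row["sigma_b2"] = spec.sigma_b2
        row.update({s: res.rejection[s] for s in spec.strategies})
        row["pr_boundary"] = res.boundary_freq
        rows.append(row)
    return pd.DataFrame(rows)
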