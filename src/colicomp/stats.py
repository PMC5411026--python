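"""Linear models with type-I (sequential) ANOVA and eta-squared effect sizes.

The run tables relate the final C fraction F_C to the externally tuned
division-of-labor variable (MitC dose in experiments, switching rate s_C in
simulations), the number of viable edge clusters N_C,Edge, and the spatial
initial-condition metrics (N_C0, R_C0, D_C0) or the initial-condition label
IC.  Terms enter the sequential decomposition in the design order: the
externally tuned variable first, N_C,Edge second, spatial details last.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "LinearModelResult",
    "sequential_anova",
    "fit_nc_edge_model",
    "fit_fc_model_experimental",
    "fit_fc_model_simulation",
    "outcome_distribution",
    "fc_variance_over_time",
]

_SS_REL_TOL = 1e-8


@dataclass
class AnovaResult:
    """Sequential (type I) ANOVA table with eta-squared effect sizes."""

    table: pd.DataFrame
    ss_total: float

    def __post_init__(self) -> None:
        ss = self.table["sum_sq"].sum()
        if self.ss_total > 0 and abs(ss - self.ss_total) > _SS_REL_TOL * self.ss_total:
            raise AssertionError("sequential SS do not decompose the total SS")

    def eta_squared(self) -> pd.Series:
        return self.table["eta_sq"].drop("Residual")

    def summary(self) -> str:
        lines = ["Sequential (type I) ANOVA",
                 f"total SS = {self.ss_total:.6g}", ""]
        lines.append(self.table.to_string(float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


@dataclass
class LinearModelResult:
    """OLS fit plus its sequential ANOVA decomposition."""

    params: pd.Series
    bse: pd.Series
    anova: AnovaResult
    ols_result: object = field(repr=False, default=None)

    def summary(self) -> str:
        coefs = pd.DataFrame({"coef": self.params, "std err": self.bse})
        return coefs.to_string(float_format=lambda v: f"{v:.4g}") + "\n\n" + self.anova.summary()


def _zscore(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant column")
    return (x - x.mean()) / sd


def _cat_block(values: pd.Series | np.ndarray, name: str) -> tuple[np.ndarray, list[str]]:
    """Treatment-contrast dummies (lowest level is the reference)."""
    v = pd.Series(values)
    levels = sorted(v.unique().tolist())
    if len(levels) < 2:
        raise ValueError(f"categorical predictor {name!r} has a single level")
    cols = [np.asarray(v == lv, dtype=float) for lv in levels[1:]]
    return np.column_stack(cols), [f"{name}[{lv}]" for lv in levels[1:]]


def _interaction(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """All column products of two design blocks."""
    a = np.atleast_2d(a.T).T
    b = np.atleast_2d(b.T).T
    return (a[:, :, None] * b[:, None, :]).reshape(len(a), -1)


def sequential_anova(y: np.ndarray, terms: list[tuple[str, np.ndarray]]) -> AnovaResult:
    """Type-I ANOVA by nested-model residual sums of squares.

    SS of the k-th term is RSS(terms 1..k-1) - RSS(terms 1..k), fitted by
    OLS with an intercept; eta^2 is SS_term / SS_total.  The order of terms
    matters whenever predictors are correlated.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    ss_total = float(((y - y.mean()) ** 2).sum())
    X = np.ones((n, 1))
    rss_prev = ss_total
    rank_prev = 1
    rows = []
    for name, block in terms:
        block = np.atleast_2d(np.asarray(block, dtype=float).T).T
        X = np.column_stack([X, block])
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(((y - X @ beta) ** 2).sum())
        df = rank - rank_prev
        rows.append((name, df, max(rss_prev - rss, 0.0)))
        rss_prev, rank_prev = rss, rank
    df_resid = n - rank_prev
    if df_resid < 0:
        raise ValueError("more parameters than observations")
    mse = rss_prev / df_resid if df_resid > 0 else np.nan
    recs = {}
    for name, df, ss in rows:
        if df > 0 and df_resid > 0 and mse > 0:
            f = (ss / df) / mse
            p = float(sps.f.sf(f, df, df_resid))
        else:
            f, p = np.nan, np.nan
        recs[name] = {"df": df, "sum_sq": ss,
                      "eta_sq": ss / ss_total if ss_total > 0 else np.nan,
                      "F": f, "PR(>F)": p}
    recs["Residual"] = {"df": df_resid, "sum_sq": rss_prev,
                        "eta_sq": rss_prev / ss_total if ss_total > 0 else np.nan,
                        "F": np.nan, "PR(>F)": np.nan}
    table = pd.DataFrame(recs).T
    table["df"] = table["df"].astype(int)
    return AnovaResult(table=table, ss_total=ss_total)


def fit_nc_edge_model(table: pd.DataFrame, dose_col: str = "MitC") -> LinearModelResult:
    """Linear model for the edge-cluster count:
    N_C,Edge = b0 + b1*N_C0 + b2*R_C0 + b3*D_C0 + b4*MitC, all predictors
    z-standardized (the dose treated numerically here, as printed).
    """
    if len(table) < 20:
        raise ValueError("need at least 20 rows")
    names = ["N_C0", "R_C0_um", "D_C0_um", dose_col]
    missing = [c for c in names if c not in table.columns]
    if missing:
        raise ValueError(f"missing predictors: {missing}")
    y = np.asarray(table["N_C_Edge"], dtype=float)
    blocks = [(n, _zscore(table[n].to_numpy())) for n in names]
    X = sm.add_constant(np.column_stack([b for _, b in blocks]))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design")
    res = sm.OLS(y, X).fit()
    labels = ["const"] + names
    return LinearModelResult(
        params=pd.Series(res.params, index=labels),
        bse=pd.Series(res.bse, index=labels),
        anova=sequential_anova(y, blocks),
        ols_result=res,
    )


def _fc_model(table: pd.DataFrame, response: str, main_terms: list[tuple[str, str]],
              interaction_order: list[tuple[str, str]]) -> LinearModelResult:
    y = np.asarray(table[response], dtype=float)
    blocks: dict[str, np.ndarray] = {}
    terms: list[tuple[str, np.ndarray]] = []
    for name, kind in main_terms:
        if kind == "categorical":
            block, _ = _cat_block(table[name], name)
        else:
            block = np.asarray(table[name], dtype=float)[:, None]
        blocks[name] = block
        terms.append((name, block))
    for a, b in interaction_order:
        terms.append((f"{a}:{b}", _interaction(blocks[a], blocks[b])))
    X = np.ones((len(y), 1))
    for _, blk in terms:
        X = np.column_stack([X, blk])
    res = sm.OLS(y, X).fit()
    return LinearModelResult(
        params=pd.Series(res.params),
        bse=pd.Series(res.bse),
        anova=sequential_anova(y, terms),
        ols_result=res,
    )


def fit_fc_model_experimental(table: pd.DataFrame, dose_col: str = "MitC") -> LinearModelResult:
    """Full main-effects + pairwise-interaction model for F_C (experimental form).

    The dose is categorical; N_C,Edge, N_C0, D_C0, R_C0 are continuous.
    Sequential term order: dose, N_C,Edge, N_C0, D_C0, R_C0, then the
    pairwise interactions in the printed order.
    """
    for lv, cnt in pd.Series(table[dose_col]).value_counts().items():
        if cnt == 0:
            raise ValueError(f"empty categorical level {lv!r}")
    main = [(dose_col, "categorical"), ("N_C_Edge", "continuous"), ("N_C0", "continuous"),
            ("D_C0_um", "continuous"), ("R_C0_um", "continuous")]
    inter = [(dose_col, "N_C_Edge"), (dose_col, "N_C0"), (dose_col, "D_C0_um"),
             (dose_col, "R_C0_um"),
             ("N_C_Edge", "N_C0"), ("N_C_Edge", "D_C0_um"), ("N_C_Edge", "R_C0_um"),
             ("N_C0", "D_C0_um"), ("N_C0", "R_C0_um"), ("D_C0_um", "R_C0_um")]
    return _fc_model(table, "F_C", main, inter)


def fit_fc_model_simulation(table: pd.DataFrame) -> LinearModelResult:
    """Three-factor model for simulated F_C:
    F_C ~ s_C + N_C,Edge + IC + s_C:N_C,Edge + s_C:IC + N_C,Edge:IC,
    all three variables categorical, sequential in that order.
    """
    main = [("s_C", "categorical"), ("N_C_Edge", "categorical"), ("IC", "categorical")]
    inter = [("s_C", "N_C_Edge"), ("s_C", "IC"), ("N_C_Edge", "IC")]
    return _fc_model(table, "F_C", main, inter)


def outcome_distribution(outcomes, n_boot: int = 0, seed: int | None = None,
                         alpha: float = 0.05) -> pd.DataFrame:
    """Counts and proportions of the four outcome classes.

    With ``n_boot`` > 0, percentile bootstrap confidence intervals for the
    proportions are added.
    """
    from .metrics import Outcome

    labels = [getattr(o, "value", o) for o in outcomes]
    if len(labels) == 0:
        raise ValueError("empty outcome list")
    classes = [o.value for o in Outcome]
    counts = pd.Series(labels).value_counts().reindex(classes, fill_value=0)
    out = pd.DataFrame({"count": counts, "proportion": counts / len(labels)})
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        arr = np.asarray(labels)
        props = np.empty((n_boot, len(classes)))
        for b in range(n_boot):
            resampled = arr[rng.integers(0, len(arr), len(arr))]
            props[b] = [(resampled == c).mean() for c in classes]
        out["ci_low"] = np.quantile(props, alpha / 2, axis=0)
        out["ci_high"] = np.quantile(props, 1 - alpha / 2, axis=0)
    return out


def fc_variance_over_time(replicates) -> float:
    """Across-replicate variance of the colonized-area C fraction, time-averaged.

    ``replicates`` is a sequence of Trajectories on a common recording grid,
    or a 2-D array (replicates x time points).  Population variance
    (divide by n) at each recorded time, averaged over the time course.
    """
    from .simulator import Trajectory

    if len(replicates) < 2:
        raise ValueError("need at least 2 replicates")
    if isinstance(replicates[0], Trajectory):
        t0 = replicates[0].times
        for tr in replicates[1:]:
            if len(tr.times) != len(t0) or not np.allclose(tr.times, t0):
                raise ValueError("replicates are not on a common time grid")
        mat = np.vstack([tr.colonized_c_fraction() for tr in replicates])
    else:
        mat = np.asarray(replicates, dtype=float)
        if mat.ndim != 2:
            raise ValueError("expected a 2-D array of fractions")
    return float(mat.var(axis=0, ddof=0).mean())
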