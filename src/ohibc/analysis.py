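"""Score-trend tables and lagged management-sensitivity regressions.

Two analyses sit on top of the assessed score tables:

* ``score_trend`` — OLS of a goal's score (0-100 scale) on calendar year,
  giving points-per-year slopes with R-squared and p-values, per region
  and for the study-area rollup.

* the management-sensitivity regressions — a causal chain is posited in
  which regulatory action boosts regulatory resilience r_reg, effective
  regulation reduces ecological pressures p_ecol after a lag, and reduced
  pressures improve status after a further lag.  Each link is tested with
  a fixed-effects (region + year) least-squares panel regression of a
  proportional-change response on the lagged components:

      (p_ecol,t+lam - p_ecol,t)/p_ecol,t = a + b1 r_reg,t + b3 r_soc,t
      (x_t+lam - x_t)/x_t               = a + b p_t

  with lag lam in 1..6 years.  Ecological resilience is excluded from the
  first model (near-constant over the study window; including it makes
  the design singular) and social pressures from the response (collinear
  with social resilience).  Candidate (lag, component-subset) models are
  compared by leave-one-out cross-validation RMSE; the LOOCV RMSE is
  computed with the exact PRESS identity for least squares.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrendRow",
    "RegressionResult",
    "score_trend",
    "score_trend_table",
    "build_panel",
    "pressure_response_model",
    "status_response_model",
    "loocv_model_select",
    "loocv_rmse_literal",
    "significance_code",
]

PANEL_COLUMNS = [
    "region_id", "year", "goal",
    "p_ecol", "p_soc", "r_reg", "r_ecol", "r_soc", "status",
]
PRESSURE_COMPONENTS = ("r_reg", "r_soc")
LAG_RANGE = range(1, 7)


@dataclass(frozen=True)
class TrendRow:
    """One score-on-year regression (slope in points per year)."""

    scope: str
    goal: str
    slope: float
    r2: float
    p_value: float
    n_years: int


@dataclass
class RegressionResult:
    """One fitted sensitivity model.

    ``params``/``bse``/``pvalues`` cover the intercept and the included
    substantive components (region/year fixed-effect coefficients are
    fitted but not reported).
    """

    goal: str
    lag: int
    response: str  # "pressure_change" | "status_change"
    included_components: tuple[str, ...]
    params: dict[str, float]
    bse: dict[str, float]
    pvalues: dict[str, float]
    adj_r2: float
    loocv_rmse: float
    n_obs: int
    n_params: int
    dropped_zero_denominator: int = 0

    def summary_row(self) -> dict:
        row = {
            "goal": self.goal, "lag": self.lag, "response": self.response,
            "n_obs": self.n_obs, "adj_r2": self.adj_r2,
            "loocv_rmse": self.loocv_rmse,
        }
        for name in ("intercept", *self.included_components):
            if name in self.params:
                row[name] = self.params[name]
                row[f"{name}_p"] = self.pvalues[name]
                row[f"{name}_sig"] = significance_code(self.pvalues[name])
        return row


def significance_code(p: float) -> str:
    if math.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "."
    return ""


# ---------------------------------------------------------------------------
# Trend tables


def score_trend(score_series: Mapping[int, float] | pd.Series,
                scope: str = "study-area", goal: str = "Index") -> TrendRow:
    """OLS of score (0-100) on calendar year; slope in points/year."""
    if isinstance(score_series, pd.Series):
        score_series = dict(zip(score_series.index, score_series.values))
    pts = sorted(
        (int(y), float(v)) for y, v in score_series.items() if not math.isnan(float(v))
    )
    if len(pts) < 3:
        raise ValueError("score_trend needs >= 3 years of scores")
    years = np.array([y for y, _ in pts], dtype=float)
    vals = np.array([v for _, v in pts], dtype=float)
    if np.allclose(vals, vals[0]):
        return TrendRow(scope, goal, 0.0, 0.0, 1.0, len(pts))
    fit = stats.linregress(years, vals)
    return TrendRow(
        scope=scope, goal=goal, slope=float(fit.slope),
        r2=float(fit.rvalue**2), p_value=float(fit.pvalue), n_years=len(pts),
    )


def score_trend_table(
    scores: pd.DataFrame, study_region_id: str = "BC", scale: float = 100.0
) -> pd.DataFrame:
    """Per-scope, per-goal trend rows from a long score table (0-1 scale,
    ``score`` dimension); slopes are reported on the 0-100 scale."""
    sub = scores[scores["dimension"] == "score"]
    rows = []
    for (rid, goal), grp in sub.groupby(["region_id", "goal"]):
        series = {
            int(y): float(v) * scale
            for y, v in zip(grp["year"], grp["value"])
            if not math.isnan(float(v))
        }
        if len(series) < 3:
            continue
        scope = "study-area" if rid == study_region_id else str(rid)
        t = score_trend(series, scope=scope, goal=str(goal))
        rows.append(
            {"scope": t.scope, "goal": t.goal, "slope": t.slope,
             "r2": t.r2, "p_value": t.p_value, "sig": significance_code(t.p_value),
             "n_years": t.n_years}
        )
    return pd.DataFrame(
        rows, columns=["scope", "goal", "slope", "r2", "p_value", "sig", "n_years"]
    ).sort_values(["scope", "goal"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Panel assembly


def build_panel(
    score_table: pd.DataFrame, components: pd.DataFrame | None = None
) -> pd.DataFrame:
    """One record per (region, year, goal) bundling status with the
    pressure/resilience components.

    ``score_table`` may already be a components panel (as produced by
    ``run_assessment``); alternatively pass a long score table plus a
    separate components table to join on (region_id, year, goal).
    Records missing p_ecol are dropped (warned); duplicate keys raise.
    """
    if components is None:
        panel = score_table.copy()
    else:
        status = score_table[score_table["dimension"] == "status"].rename(
            columns={"value": "status"}
        )[["region_id", "year", "goal", "status"]]
        panel = components.merge(status, on=["region_id", "year", "goal"], how="inner")
        if len(panel) < len(components):
            missing = len(components) - len(panel)
            raise ValueError(
                f"build_panel: {missing} component records lack a matching status key"
            )
    missing_cols = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing_cols:
        raise ValueError(f"build_panel: missing columns {missing_cols}")
    dup = panel.duplicated(["region_id", "year", "goal"])
    if dup.any():
        r = panel.loc[dup.idxmax()]
        raise ValueError(
            f"build_panel: duplicate key ({r['region_id']}, {int(r['year'])}, {r['goal']})"
        )
    keep = panel["p_ecol"].notna()
    if (~keep).any():
        import warnings

        warnings.warn(
            f"build_panel: dropping {(~keep).sum()} records with missing p_ecol",
            stacklevel=2,
        )
    return panel.loc[keep, PANEL_COLUMNS].sort_values(
        ["goal", "region_id", "year"]
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Fixed-effects least squares with exact LOOCV


def _design(
    df: pd.DataFrame, regressors: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Intercept + substantive regressors + region/year indicator sets
    (one reference level each)."""
    y = df["_response"].to_numpy(dtype=float)
    cols: list[np.ndarray] = [np.ones(len(df))]
    names = ["intercept"]
    for reg in regressors:
        cols.append(df[reg].to_numpy(dtype=float))
        names.append(reg)
    for fe in ("region_id", "year"):
        levels = sorted(df[fe].unique())
        for lev in levels[1:]:  # first level is the reference
            cols.append((df[fe] == lev).to_numpy(dtype=float))
            names.append(f"{fe}[{lev}]")
    X = np.column_stack(cols)
    return X, y, names


def _fit_ols(X: np.ndarray, y: np.ndarray):
    """Least squares via statsmodels, with the LOOCV RMSE computed from
    the exact PRESS identity (residual over 1 - leverage)."""
    import statsmodels.api as sm

    n, k = X.shape
    if n <= k:
        raise ValueError(f"fewer observations ({n}) than parameters ({k})")
    with np.errstate(divide="ignore", invalid="ignore"):
        res = sm.OLS(y, X).fit()
        beta = np.asarray(res.params, dtype=float)
        bse = np.asarray(res.bse, dtype=float)
        pvals = np.asarray(res.pvalues, dtype=float)
        adj_r2 = float(res.rsquared_adj)  # nan for a constant response
    resid = np.asarray(res.resid, dtype=float)
    h = np.einsum(
        "ij,jk,ik->i", X, np.asarray(res.normalized_cov_params, dtype=float), X
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        press_resid = resid / (1.0 - h)
    loocv = float(np.sqrt(np.mean(press_resid**2)))
    return beta, bse, pvals, adj_r2, loocv


def loocv_rmse_literal(X: np.ndarray, y: np.ndarray) -> float:
    """Literal leave-one-out loop: refit without each observation and
    predict it.  Independent oracle for the PRESS shortcut."""
    n = len(y)
    errs = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        beta, *_ = np.linalg.lstsq(X[mask], y[mask], rcond=None)
        errs[i] = y[i] - X[i] @ beta
    return float(np.sqrt(np.mean(errs**2)))


def _proportional_change(
    panel: pd.DataFrame, column: str, lag: int
) -> tuple[pd.DataFrame, int]:
    """Response (v_{t+lag} - v_t)/v_t within each region; zero-denominator
    observations are dropped (counted)."""
    frames = []
    dropped = 0
    for rid, sub in panel.groupby("region_id"):
        sub = sub.sort_values("year").set_index("year")
        for t in sub.index:
            if t + lag not in sub.index:
                continue
            v0 = float(sub.at[t, column])
            v1 = float(sub.at[t + lag, column])
            if math.isnan(v0) or math.isnan(v1):
                continue
            if v0 == 0.0:
                dropped += 1
                continue
            row = sub.loc[t].to_dict()
            row.update(region_id=rid, year=int(t), _response=(v1 - v0) / v0)
            frames.append(row)
    return pd.DataFrame(frames), dropped


def _fit_panel_model(
    df: pd.DataFrame,
    regressors: Sequence[str],
    goal: str,
    lag: int,
    response: str,
    components_label: tuple[str, ...],
    dropped: int,
) -> RegressionResult:
    if regressors:
        df = df.dropna(subset=list(regressors))
        if df.empty:
            raise ValueError(
                f"goal {goal!r}: no observations with {list(regressors)} present"
            )
    X, y, names = _design(df, regressors)
    beta, bse, pvals, adj_r2, loocv = _fit_ols(X, y)
    keep = ["intercept", *regressors]
    idx = {name: i for i, name in enumerate(names)}
    return RegressionResult(
        goal=goal,
        lag=lag,
        response=response,
        included_components=tuple(components_label),
        params={k: float(beta[idx[k]]) for k in keep},
        bse={k: float(bse[idx[k]]) for k in keep},
        pvalues={k: float(pvals[idx[k]]) for k in keep},
        adj_r2=float(adj_r2),
        loocv_rmse=float(loocv),
        n_obs=len(y),
        n_params=X.shape[1],
        dropped_zero_denominator=dropped,
    )


def pressure_response_model(
    panel: pd.DataFrame,
    goal: str,
    lag: int,
    components: Iterable[str] = PRESSURE_COMPONENTS,
) -> RegressionResult:
    """Proportional change in ecological pressures at t+lag regressed on
    resilience components at t, with region and year fixed effects."""
    if lag not in LAG_RANGE:
        raise ValueError(f"lag must be in 1..6, got {lag}")
    comps = tuple(components)
    bad = set(comps) - set(PRESSURE_COMPONENTS)
    if bad:
        raise ValueError(f"unknown resilience components: {sorted(bad)}")
    sub = panel[panel["goal"] == goal]
    if sub.empty:
        raise ValueError(f"no panel records for goal {goal!r}")
    df, dropped = _proportional_change(sub, "p_ecol", lag)
    if df.empty:
        raise ValueError(f"goal {goal!r}, lag {lag}: no usable observations")
    return _fit_panel_model(
        df, list(comps), goal, lag, "pressure_change", comps, dropped
    )


def status_response_model(
    panel: pd.DataFrame,
    goal: str,
    lag: int,
    pressure_set: str = "ecol",
) -> RegressionResult:
    """Proportional change in status at t+lag regressed on pressures at t
    (ecological only, or ecological + social), with fixed effects."""
    if lag not in LAG_RANGE:
        raise ValueError(f"lag must be in 1..6, got {lag}")
    if pressure_set not in {"ecol", "ecol+soc"}:
        raise ValueError("pressure_set must be 'ecol' or 'ecol+soc'")
    sub = panel[panel["goal"] == goal].copy()
    if sub.empty:
        raise ValueError(f"no panel records for goal {goal!r}")
    if pressure_set == "ecol":
        sub["pressure"] = sub["p_ecol"]
    else:
        sub["pressure"] = sub["p_ecol"] + sub["p_soc"].fillna(0.0)
    df, dropped = _proportional_change(sub, "status", lag)
    if df.empty:
        raise ValueError(f"goal {goal!r}, lag {lag}: no usable observations")
    if np.allclose(df["_response"], 0.0):
        # Constant status: intercept-only fit.
        return _fit_panel_model(df, [], goal, lag, "status_change", (pressure_set,), dropped)
    return _fit_panel_model(
        df, ["pressure"], goal, lag, "status_change", (pressure_set,), dropped
    )


def loocv_model_select(
    panel: pd.DataFrame,
    goal: str,
    lags: Iterable[int] = LAG_RANGE,
    candidate_component_subsets: Iterable[tuple[str, ...]] | None = None,
    response: str = "pressure_change",
) -> RegressionResult:
    """Fit every (lag, component-subset) candidate and return the one with
    the smallest LOOCV RMSE; ties break to fewer parameters, then smaller
    lag.  The intercept-only model is always a candidate."""
    if candidate_component_subsets is None:
        subsets: list[tuple[str, ...]] = []
        if response == "pressure_change":
            for k in range(len(PRESSURE_COMPONENTS) + 1):
                subsets.extend(itertools.combinations(PRESSURE_COMPONENTS, k))
        else:
            subsets = [("ecol",), ("ecol+soc",)]
    else:
        subsets = [tuple(s) for s in candidate_component_subsets]
    results: list[RegressionResult] = []
    for lag in lags:
        for comps in subsets:
            try:
                if response == "pressure_change":
                    res = pressure_response_model(panel, goal, lag, comps)
                else:
                    res = status_response_model(panel, goal, lag, comps[0])
            except (ValueError, np.linalg.LinAlgError):
                continue
            results.append(res)
    if not results:
        raise ValueError(f"goal {goal!r}: no valid candidate model")
    results.sort(key=lambda r: (r.loocv_rmse, r.n_params, r.lag))
    return results[0]


def sensitivity_tables(
    panel: pd.DataFrame, goals: Iterable[str] | None = None
) -> dict[str, pd.DataFrame]:
    """Best pressure-response model per goal plus the two status-response
    variants at their best lag, shaped like the published summary tables."""
    goals = sorted(panel["goal"].unique()) if goals is None else list(goals)
    press_rows, stat_all_rows, stat_ecol_rows = [], [], []
    for g in goals:
        try:
            press_rows.append(loocv_model_select(panel, g).summary_row())
        except ValueError:
            pass
        for rows, pset in ((stat_all_rows, "ecol+soc"), (stat_ecol_rows, "ecol")):
            try:
                best = loocv_model_select(
                    panel, g, candidate_component_subsets=[(pset,)],
                    response="status_change",
                )
                rows.append(best.summary_row())
            except ValueError:
                pass
    return {
        "pressure_vs_resilience": pd.DataFrame(press_rows),
        "status_vs_all_pressures": pd.DataFrame(stat_all_rows),
        "status_vs_ecol_pressures": pd.DataFrame(stat_ecol_rows),
    }
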