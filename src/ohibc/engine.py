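"""Pressure/resilience aggregation and index assembly.

The assessment scores each goal g in each region from five quantities:

* status x (current benefit over its reference point, 0-1),
* trend T (proportional change in status over the previous five years),
* pressures p (0-1 aggregate of stressors weighted by goal sensitivity),
* resilience r (0-1 aggregate of regulatory, ecological-integrity and
  social factors), capped so that r <= p — once a pressure is adequately
  addressed, further resilience must not inflate future status,
* likely future status  x_F = (1/(1+delta)) (1 + beta T + (1-beta)(r-p)) x,
  clipped to [0, 1].

The goal score is I = (x + x_F)/2; a region's index is the omega-weighted
mean over its scored goals; study-area scores are means over participating
regions weighted by marine area.  Missing statuses propagate to missing
scores and every aggregation renormalizes over what is present — nothing
is imputed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .goals import MISSING, goal_trend, is_missing
from .layers import EngineConfig, LayerTable, Region

__all__ = [
    "StudyBundle",
    "Prepared",
    "AssessmentResult",
    "aggregate_pressures",
    "aggregate_resilience",
    "cap_resilience",
    "likely_future_status",
    "goal_score",
    "combine_subgoals",
    "region_index",
    "study_area_score",
    "run_assessment",
    "scores_to_report",
]

DIMENSIONS = ("status", "trend", "pressures", "resilience", "future", "score")
MATRIX_COLUMNS = ["goal", "layer_id", "weight", "category"]
PRESSURE_CATEGORIES = ("ecological", "social")
RESILIENCE_CATEGORIES = ("regulatory", "ecological", "social")


@dataclass
class StudyBundle:
    """Validated inputs for one assessment run."""

    regions: Sequence[Region]
    layers: Mapping[str, LayerTable]
    pressure_matrix: pd.DataFrame
    resilience_matrix: pd.DataFrame
    stocks: pd.DataFrame | None = None
    salmon: pd.DataFrame | None = None
    escapement: pd.DataFrame | None = None
    species_risk: pd.DataFrame | None = None
    iconic_risk: pd.DataFrame | None = None

    def region_ids(self) -> list[str]:
        return [r.region_id for r in self.regions]


class Prepared:
    """Gapfilled layer lookup over the study grid plus a lookback margin
    (rolling no-net-loss baselines need the five years before the first
    assessment year; LOCF/NOCB supplies them when data are truncated)."""

    def __init__(self, bundle: StudyBundle, config: EngineConfig, lookback: int = 5):
        first, last = config.study_years
        self.years = config.years
        grid = list(range(first - lookback, last + 1))
        self._filled: dict[tuple[str, str], dict[int, float]] = {}
        for lid, table in bundle.layers.items():
            for rid in table.regions():
                series = table.series(rid)
                if series:
                    self._filled[(lid, rid)] = table.gapfilled(rid, grid)

    def value(self, layer_id: str, region_id: str, year: int) -> float:
        return self._filled.get((layer_id, region_id), {}).get(year, MISSING)

    def series(self, layer_id: str, region_id: str) -> dict[int, float]:
        return dict(self._filled.get((layer_id, region_id), {}))

    def has(self, layer_id: str, region_id: str) -> bool:
        return (layer_id, region_id) in self._filled


# A status builder maps a prepared bundle to {(region_id, year): status}
# for one status-bearing goal (leaf of the goal tree).
StatusBuilder = Callable[[StudyBundle, Prepared, EngineConfig], dict[tuple[str, int], float]]


def _check_matrix(matrix: pd.DataFrame, categories: Sequence[str], kind: str) -> pd.DataFrame:
    missing = [c for c in MATRIX_COLUMNS if c not in matrix.columns]
    if missing:
        raise ValueError(f"{kind} matrix: missing columns {missing}")
    if (matrix["weight"] < 0).any():
        raise ValueError(f"{kind} matrix: weights must be >= 0")
    bad = set(matrix["category"]) - set(categories)
    if bad:
        raise ValueError(f"{kind} matrix: unknown categories {sorted(bad)}")
    per_layer = matrix.groupby("layer_id")["category"].nunique()
    if (per_layer > 1).any():
        off = per_layer[per_layer > 1].index.tolist()
        raise ValueError(f"{kind} matrix: layers with multiple categories: {off}")
    return matrix


def _entries_by_category(
    matrix: pd.DataFrame, goal: str, categories: Sequence[str]
) -> dict[str, list[tuple[str, float]]]:
    sub = matrix[(matrix["goal"] == goal) & (matrix["weight"] > 0)]
    return {
        cat: [
            (str(r.layer_id), float(r.weight))
            for r in sub[sub["category"] == cat].itertuples()
        ]
        for cat in categories
    }


def _category_means(
    layer_values: Mapping[str, float],
    entries: Mapping[str, list[tuple[str, float]]],
    kind: str,
) -> dict[str, float]:
    out: dict[str, float] = {}
    for cat, pairs in entries.items():
        num = den = 0.0
        for lid, w in pairs:
            v = layer_values.get(lid, MISSING)
            if is_missing(v):
                continue
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{kind} layer {lid!r} value {v} outside [0, 1]")
            num += w * v
            den += w
        if den > 0:
            out[cat] = num / den
    return out


def aggregate_pressures(
    layer_values: Mapping[str, float],
    matrix: pd.DataFrame,
    goal: str,
) -> tuple[float, float, float]:
    """Weight-weighted mean of the goal's pressure layers by category.

    ``layer_values`` maps pressure layer_id to its [0, 1] value for one
    region-year.  Returns (p_ecol, p_soc, p) where p is the mean of the
    categories that are present; a goal bound to no pressure layer gets
    p = 0 with a warning.
    """
    entries = _entries_by_category(matrix, goal, PRESSURE_CATEGORIES)
    cats = _category_means(layer_values, entries, "pressure")
    if not cats:
        warnings.warn(f"goal {goal!r}: no pressure layers bound; p = 0", stacklevel=2)
        return (MISSING, MISSING, 0.0)
    p_ecol = cats.get("ecological", MISSING)
    p_soc = cats.get("social", MISSING)
    p = float(np.mean(list(cats.values())))
    return (p_ecol, p_soc, p)


def aggregate_resilience(
    layer_values: Mapping[str, float],
    matrix: pd.DataFrame,
    goal: str,
) -> tuple[float, float, float, float]:
    """Weighted category means for regulatory / ecological / social
    resilience; r is the unweighted mean of the present categories."""
    entries = _entries_by_category(matrix, goal, RESILIENCE_CATEGORIES)
    cats = _category_means(layer_values, entries, "resilience")
    if not cats:
        warnings.warn(f"goal {goal!r}: no resilience layers bound; r = 0", stacklevel=2)
        return (MISSING, MISSING, MISSING, 0.0)
    r = float(np.mean(list(cats.values())))
    return (
        cats.get("regulatory", MISSING),
        cats.get("ecological", MISSING),
        cats.get("social", MISSING),
        r,
    )


def cap_resilience(r: float, p: float) -> float:
    """Cap resilience so that (r - p) <= 0."""
    return min(r, p)


def likely_future_status(
    x: float, T: float, p: float, r_capped: float, config: EngineConfig
) -> float:
    """Status projected five years ahead, clipped to [0, 1]."""
    if is_missing(x) or is_missing(T):
        return MISSING
    xf = (
        (1.0 / (1.0 + config.delta))
        * (1.0 + config.beta * T + (1.0 - config.beta) * (r_capped - p))
        * x
    )
    return float(min(max(xf, 0.0), 1.0))


def goal_score(x: float, x_future: float) -> float:
    """Goal score: the average of current and likely future status."""
    if is_missing(x) or is_missing(x_future):
        return MISSING
    return (x + x_future) / 2.0


def _renorm_mean(values: Sequence[float], weights: Sequence[float]) -> float:
    pairs = [(v, w) for v, w in zip(values, weights) if not is_missing(v) and w > 0]
    if not pairs:
        return MISSING
    v = np.array([p[0] for p in pairs])
    w = np.array([p[1] for p in pairs])
    return float(np.average(v, weights=w))


def combine_subgoals(
    subgoal_scores: Mapping[str, float], weights: Mapping[str, float] | None = None
) -> float:
    """Weighted mean over non-missing subgoals, weights renormalized."""
    keys = list(subgoal_scores)
    w = [1.0 if weights is None else float(weights.get(k, 1.0)) for k in keys]
    return _renorm_mean([subgoal_scores[k] for k in keys], w)


def region_index(
    goal_scores: Mapping[str, float], goal_weights: Mapping[str, float] | None = None
) -> float:
    """omega-weighted mean over the region's scored goals."""
    keys = list(goal_scores)
    w = [1.0 if goal_weights is None else float(goal_weights.get(k, 1.0)) for k in keys]
    return _renorm_mean([goal_scores[k] for k in keys], w)


def study_area_score(
    region_values: Mapping[str, float], regions: Sequence[Region]
) -> float:
    """Marine-area-weighted mean over participating regions, renormalized
    over regions with a value."""
    participating = {r.region_id: r.area_km2 for r in regions if r.in_study_aggregate}
    vals = [region_values.get(rid, MISSING) for rid in participating]
    wts = list(participating.values())
    return _renorm_mean(vals, wts)


# ---------------------------------------------------------------------------
# Orchestration


@dataclass
class AssessmentResult:
    """Long-format score table plus the per-goal component panel used by
    the management-sensitivity analysis."""

    scores: pd.DataFrame  # region_id, year, goal, dimension, value (0-1 scale)
    panel: pd.DataFrame  # region_id, year, goal, p_ecol, p_soc, r_reg, r_ecol, r_soc, status
    config: EngineConfig = field(default_factory=EngineConfig)


def run_assessment(
    bundle: StudyBundle,
    models: Mapping[str, StatusBuilder],
    tree: Mapping[str, Sequence[str]],
    config: EngineConfig = EngineConfig(),
) -> AssessmentResult:
    """Score every (region, year, goal): status, trend, pressures,
    resilience (capped), likely future status and score; then roll up
    subgoals, region indices and study-area scores.

    ``models`` maps each status-bearing goal (a leaf of ``tree``) to its
    status builder; ``tree`` maps top-level goals to their subgoal lists
    (empty list = the goal itself bears status).  Deterministic: identical
    inputs give identical outputs.
    """
    leaves = [g for g, subs in tree.items() if not subs] + [
        s for subs in tree.values() for s in subs
    ]
    missing_models = [g for g in leaves if g not in models]
    if missing_models:
        raise ValueError(f"no status model bound for goals: {missing_models}")
    pm = _check_matrix(bundle.pressure_matrix, PRESSURE_CATEGORIES, "pressure")
    rm = _check_matrix(bundle.resilience_matrix, RESILIENCE_CATEGORIES, "resilience")
    for kind, matrix in (("pressure", pm), ("resilience", rm)):
        unbound = set(matrix["layer_id"]) - set(bundle.layers)
        if unbound:
            raise ValueError(f"{kind} matrix references absent layers: {sorted(unbound)}")

    prepared = Prepared(bundle, config)
    years = config.years
    rids = bundle.region_ids()
    window = config.trend_window

    status: dict[str, dict[tuple[str, int], float]] = {
        g: dict(models[g](bundle, prepared, config)) for g in leaves
    }
    p_entries = {g: _entries_by_category(pm, g, PRESSURE_CATEGORIES) for g in leaves}
    r_entries = {g: _entries_by_category(rm, g, RESILIENCE_CATEGORIES) for g in leaves}

    rows: list[tuple] = []
    panel_rows: list[dict] = []
    leaf_scores: dict[tuple[str, str, int], float] = {}

    for g in leaves:
        for rid in rids:
            series = {y: status[g].get((rid, y), MISSING) for y in years}
            for y in years:
                x = series[y]
                pts = sum(
                    1
                    for yy in range(y - window + 1, y + 1)
                    if yy in series and not is_missing(series[yy])
                )
                if is_missing(x):
                    T = MISSING
                elif pts >= 2:
                    T = goal_trend(series, y, window=window, clip=config.trend_clip)
                else:
                    T = 0.0  # degenerate early-window case; documented
                pvals = {
                    lid: prepared.value(lid, rid, y)
                    for pairs in p_entries[g].values()
                    for lid, _ in pairs
                }
                rvals = {
                    lid: prepared.value(lid, rid, y)
                    for pairs in r_entries[g].values()
                    for lid, _ in pairs
                }
                pcats = _category_means(pvals, p_entries[g], "pressure")
                p_ecol = pcats.get("ecological", MISSING)
                p_soc = pcats.get("social", MISSING)
                p = float(np.mean(list(pcats.values()))) if pcats else 0.0
                rcats = _category_means(rvals, r_entries[g], "resilience")
                r_reg = rcats.get("regulatory", MISSING)
                r_ecol = rcats.get("ecological", MISSING)
                r_soc = rcats.get("social", MISSING)
                r = float(np.mean(list(rcats.values()))) if rcats else 0.0
                r_capped = cap_resilience(r, p)
                xf = likely_future_status(x, T, p, r_capped, config)
                score = goal_score(x, xf)
                leaf_scores[(g, rid, y)] = score
                for dim, v in zip(
                    DIMENSIONS, (x, T, p, r_capped, xf, score)
                ):
                    rows.append((rid, y, g, dim, v))
                panel_rows.append(
                    {
                        "region_id": rid, "year": y, "goal": g,
                        "p_ecol": p_ecol, "p_soc": p_soc,
                        "r_reg": r_reg, "r_ecol": r_ecol, "r_soc": r_soc,
                        "status": x,
                    }
                )

    # Parent goals: renormalized unweighted mean of subgoal scores.
    top_scores: dict[tuple[str, str, int], float] = {}
    for goal, subs in tree.items():
        for rid in rids:
            for y in years:
                if subs:
                    v = combine_subgoals({s: leaf_scores[(s, rid, y)] for s in subs})
                    rows.append((rid, y, goal, "score", v))
                else:
                    v = leaf_scores[(goal, rid, y)]
                top_scores[(goal, rid, y)] = v

    # Region indices.
    index_scores: dict[tuple[str, int], float] = {}
    for rid in rids:
        for y in years:
            v = region_index(
                {g: top_scores[(g, rid, y)] for g in tree}, config.goal_weights
            )
            index_scores[(rid, y)] = v
            rows.append((rid, y, "Index", "score", v))

    # Study-area rollups (goals, subgoals and the Index).
    sid = config.study_region_id
    for y in years:
        for g in leaves:
            rows.append(
                (sid, y, g, "score",
                 study_area_score({rid: leaf_scores[(g, rid, y)] for rid in rids},
                                  bundle.regions))
            )
        for goal, subs in tree.items():
            if subs:
                rows.append(
                    (sid, y, goal, "score",
                     study_area_score({rid: top_scores[(goal, rid, y)] for rid in rids},
                                      bundle.regions))
                )
        rows.append(
            (sid, y, "Index", "score",
             study_area_score({rid: index_scores[(rid, y)] for rid in rids},
                              bundle.regions))
        )

    scores = pd.DataFrame(
        rows, columns=["region_id", "year", "goal", "dimension", "value"]
    ).sort_values(["goal", "region_id", "year", "dimension"]).reset_index(drop=True)
    panel = pd.DataFrame(panel_rows).sort_values(
        ["goal", "region_id", "year"]
    ).reset_index(drop=True)
    _assert_invariants(scores)
    return AssessmentResult(scores=scores, panel=panel, config=config)


def _assert_invariants(scores: pd.DataFrame) -> None:
    """Hard internal checks on the assembled table."""
    sub = scores[scores["dimension"].isin(["status", "future", "score", "pressures", "resilience"])]
    vals = sub["value"].dropna()
    if ((vals < -1e-12) | (vals > 1 + 1e-12)).any():
        raise AssertionError("score table contains values outside [0, 1]")
    wide = scores.pivot_table(
        index=["region_id", "year", "goal"], columns="dimension", values="value"
    )
    if {"pressures", "resilience"} <= set(wide.columns):
        both = wide.dropna(subset=["pressures", "resilience"])
        if ((both["resilience"] - both["pressures"]) > 1e-12).any():
            raise AssertionError("resilience cap violated: r > p in output")


def scores_to_report(scores: pd.DataFrame, raw: bool = False) -> pd.DataFrame:
    """Reporting view: status/future/score dimensions on the 0-100 integer
    scale (trend stays on [-1, 1]; pressures/resilience on [0, 1])."""
    out = scores.copy()
    if raw:
        return out
    mask = out["dimension"].isin(["status", "future", "score"])
    out.loc[mask, "value"] = (out.loc[mask, "value"] * 100).round(0)
    return out
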