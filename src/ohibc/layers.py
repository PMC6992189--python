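"""Regions, data layers, delimited-text IO and time-series gapfilling.

Everything the assessment consumes arrives as "data layers": long-format
tables of (layer_id, region_id, year, value).  Real-world layers are rarely
complete — census-style data are periodic (every 5 or 10 years) and many
series are truncated (start after the first assessment year or end before
the last).  Two simple, transparent gapfilling procedures bring every layer
onto the full assessment grid:

* linear interpolation between available data years (periodic series), and
* last-observation-carried-forward / next-observation-carried-back
  extension beyond the observed span (truncated series).

Missing is a first-class value (NaN) distinct from zero everywhere; nothing
in this module silently zero-fills.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Region",
    "LayerTable",
    "EngineConfig",
    "LayerError",
    "read_regions",
    "write_regions",
    "read_layer_table",
    "read_layer_bundle",
    "write_layer_bundle",
    "interpolate_periodic",
    "extend_series",
    "gapfill_series",
    "validate_layers",
]

LAYER_COLUMNS = ["layer_id", "region_id", "year", "value", "units"]
REGION_COLUMNS = ["region_id", "name", "area_km2", "inhabited", "in_study_aggregate"]


class LayerError(ValueError):
    """Malformed or inconsistent layer input."""


@dataclass(frozen=True)
class Region:
    """One assessment region.

    ``area_km2`` is the marine area used to weight regional scores into the
    study-area rollup; ``in_study_aggregate`` marks whether the region
    participates in that rollup (a study may assess more regions than it
    aggregates, e.g. a sparsely populated overlap region kept separate).
    """

    region_id: str
    name: str
    area_km2: float
    inhabited: bool = True
    in_study_aggregate: bool = True

    def __post_init__(self) -> None:
        if not self.region_id:
            raise ValueError("region_id must be non-empty")
        if not (self.area_km2 > 0):
            raise ValueError(f"region {self.region_id!r}: area_km2 must be > 0")


@dataclass(frozen=True)
class EngineConfig:
    """Parameters of the index equations.

    beta
        Relative weight of recent trend versus (resilience - pressures) in
        likely future status; 0.67 means trend counts twice as much.
    delta
        Discount rate on future status (0 = future valued equally).
    trend_window
        Years in the trend regression window (the window *ends* at the
        assessment year).
    trend_clip
        Symmetric bound on the proportional trend.
    goal_weights
        Per-goal weights omega_g for the region index (default: all 1).
    study_years
        Inclusive (first, last) assessment years.
    status_cap
        Cap statuses at 1 (exceeding a reference never scores above 100).
    study_region_id
        Identifier used for study-area rollup rows in output tables.
    """

    beta: float = 0.67
    delta: float = 0.0
    trend_window: int = 5
    trend_clip: float = 1.0
    goal_weights: Mapping[str, float] = field(default_factory=dict)
    study_years: tuple[int, int] = (2001, 2016)
    status_cap: bool = True
    study_region_id: str = "BC"

    def __post_init__(self) -> None:
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError(f"beta must be in [0, 1], got {self.beta}")
        if self.delta < 0:
            raise ValueError(f"delta must be >= 0, got {self.delta}")
        if self.trend_window < 2:
            raise ValueError("trend_window must be >= 2")
        if any(w < 0 for w in self.goal_weights.values()):
            raise ValueError("goal weights must be >= 0")
        if self.study_years[0] > self.study_years[1]:
            raise ValueError("study_years must be (first, last) with first <= last")

    @property
    def years(self) -> list[int]:
        return list(range(self.study_years[0], self.study_years[1] + 1))


class LayerTable:
    """A single data layer: at most one value per (region, year).

    Wraps a pandas DataFrame with columns region_id, year, value (plus a
    layer-wide ``units`` string).  Values may be NaN (missing); non-missing
    values must be finite.
    """

    def __init__(self, layer_id: str, frame: pd.DataFrame, units: str = ""):
        if not layer_id:
            raise LayerError("layer_id must be non-empty")
        frame = frame.loc[:, ["region_id", "year", "value"]].copy()
        frame["region_id"] = frame["region_id"].astype(str)
        try:
            frame["year"] = frame["year"].astype(int)
        except (TypeError, ValueError) as exc:
            raise LayerError(f"layer {layer_id!r}: malformed year: {exc}") from exc
        frame["value"] = pd.to_numeric(frame["value"], errors="coerce").astype(float)
        dup = frame.duplicated(["region_id", "year"])
        if dup.any():
            r = frame.loc[dup.idxmax()]
            raise LayerError(
                f"layer {layer_id!r}: duplicate record for "
                f"({r['region_id']}, {int(r['year'])})"
            )
        bad = frame["value"].notna() & ~np.isfinite(frame["value"])
        if bad.any():
            raise LayerError(f"layer {layer_id!r}: non-finite value present")
        self.layer_id = layer_id
        self.units = units
        self._frame = frame.sort_values(["region_id", "year"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self._frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LayerTable):
            return NotImplemented
        return (
            self.layer_id == other.layer_id
            and self.units == other.units
            and self._frame.equals(other._frame)
        )

    def to_frame(self) -> pd.DataFrame:
        out = self._frame.copy()
        out.insert(0, "layer_id", self.layer_id)
        out["units"] = self.units
        return out

    def regions(self) -> list[str]:
        return sorted(self._frame["region_id"].unique())

    def series(self, region_id: str) -> dict[int, float]:
        """Observed (non-missing) values for one region, keyed by year."""
        sub = self._frame[self._frame["region_id"] == region_id]
        return {
            int(y): float(v)
            for y, v in zip(sub["year"], sub["value"])
            if not math.isnan(v)
        }

    def gapfilled(self, region_id: str, years: Sequence[int]) -> dict[int, float]:
        """Interpolate within, then extend beyond, the observed span."""
        return gapfill_series(self.series(region_id), years)


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no"}:
        return False
    raise ValueError(f"cannot parse boolean flag from {x!r}")


def read_regions(path: str | Path) -> list[Region]:
    df = pd.read_csv(path)
    missing = [c for c in REGION_COLUMNS if c not in df.columns]
    if missing:
        raise LayerError(f"region file {path}: missing columns {missing}")
    regions = [
        Region(
            region_id=str(r.region_id),
            name=str(r.name),
            area_km2=float(r.area_km2),
            inhabited=_parse_bool(r.inhabited),
            in_study_aggregate=_parse_bool(r.in_study_aggregate),
        )
        for r in df.itertuples()
    ]
    ids = [r.region_id for r in regions]
    if len(set(ids)) != len(ids):
        raise LayerError(f"region file {path}: duplicate region_id")
    return regions


def write_regions(regions: Iterable[Region], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "region_id": r.region_id,
                "name": r.name,
                "area_km2": r.area_km2,
                "inhabited": r.inhabited,
                "in_study_aggregate": r.in_study_aggregate,
            }
            for r in regions
        ]
    ).to_csv(path, index=False)


def _read_layer_frame(path: str | Path) -> pd.DataFrame:
    # round_trip parsing: a written bundle must reload to identical floats
    df = pd.read_csv(
        path, dtype={"layer_id": str, "region_id": str}, float_precision="round_trip"
    )
    missing = [c for c in ("layer_id", "region_id", "year", "value") if c not in df.columns]
    if missing:
        raise LayerError(f"layer file {path}: missing columns {missing}")
    if "units" not in df.columns:
        df["units"] = ""
    df["units"] = df["units"].fillna("")
    years = pd.to_numeric(df["year"], errors="coerce")
    bad = years.isna() | (years != years.round())
    if bad.any():
        # +2: header line plus 1-based indexing
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise LayerError(f"layer file {path}: malformed year at line {line}")
    df["year"] = years.astype(int)
    return df


def read_layer_table(path: str | Path, expected_units: str | None = None) -> LayerTable:
    """Read a CSV holding exactly one layer."""
    df = _read_layer_frame(path)
    ids = df["layer_id"].unique()
    if len(ids) != 1:
        raise LayerError(f"layer file {path}: expected one layer, found {sorted(ids)}")
    units = str(df["units"].iloc[0]) if len(df) else ""
    if expected_units is not None and units != expected_units:
        raise LayerError(
            f"layer file {path}: units {units!r} != expected {expected_units!r}"
        )
    return LayerTable(str(ids[0]), df, units=units)


def read_layer_bundle(path: str | Path) -> dict[str, LayerTable]:
    """Read a CSV holding many layers into a dict keyed by layer_id."""
    df = _read_layer_frame(path)
    out: dict[str, LayerTable] = {}
    for lid, sub in df.groupby("layer_id", sort=True):
        units = str(sub["units"].iloc[0])
        out[str(lid)] = LayerTable(str(lid), sub, units=units)
    return out


def write_layer_bundle(layers: Mapping[str, LayerTable] | Iterable[LayerTable],
                       path: str | Path) -> None:
    if isinstance(layers, Mapping):
        layers = layers.values()
    frames = [t.to_frame() for t in layers]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Gapfilling


def _observed(series: Mapping[int, float]) -> list[tuple[int, float]]:
    obs = sorted(
        (int(y), float(v)) for y, v in series.items() if not math.isnan(float(v))
    )
    return obs


def interpolate_periodic(
    series: Mapping[int, float], target_years: Iterable[int]
) -> dict[int, float]:
    """Fill interior target years by linear interpolation between data years.

    Observed values are never modified; years outside the observed span are
    left for :func:`extend_series`.
    """
    obs = _observed(series)
    if not obs:
        raise LayerError("interpolate_periodic: empty series")
    out = dict(obs)
    xs = np.array([y for y, _ in obs], dtype=float)
    vs = np.array([v for _, v in obs], dtype=float)
    for y in target_years:
        y = int(y)
        if xs[0] <= y <= xs[-1] and y not in out:
            out[y] = float(np.interp(y, xs, vs))
    return dict(sorted(out.items()))


def extend_series(
    series: Mapping[int, float], target_years: Iterable[int]
) -> dict[int, float]:
    """LOCF/NOCB extension: carry the last observation forward beyond the
    observed span and the first observation back before it."""
    obs = _observed(series)
    if not obs:
        raise LayerError("extend_series: empty series")
    out = dict(series)
    first_y, first_v = obs[0]
    last_y, last_v = obs[-1]
    for y in target_years:
        y = int(y)
        if y < first_y:
            out[y] = first_v
        elif y > last_y:
            out[y] = last_v
    return dict(sorted(out.items()))


def gapfill_series(
    series: Mapping[int, float], target_years: Iterable[int]
) -> dict[int, float]:
    """Interpolate within the observed span, then extend beyond it."""
    years = [int(y) for y in target_years]
    return extend_series(interpolate_periodic(series, years), years)


# ---------------------------------------------------------------------------
# Validation


def validate_layers(
    tables: Mapping[str, LayerTable],
    regions: Sequence[Region],
    config: EngineConfig,
    bounded_layers: Iterable[str] = (),
) -> pd.DataFrame:
    """Report (never raise) per-layer problems.

    Returns a DataFrame with columns layer_id, region_id, year, issue.
    Issues: unknown region ids, values outside [0, 1] for layers declared
    bounded, and (region, year) cells still missing after gapfilling.
    """
    known = {r.region_id for r in regions}
    bounded = set(bounded_layers)
    rows: list[dict] = []
    years = config.years
    for lid, table in sorted(tables.items()):
        frame = table.to_frame()
        for r in frame.itertuples():
            if r.region_id not in known:
                rows.append(
                    {"layer_id": lid, "region_id": r.region_id, "year": int(r.year),
                     "issue": "unknown_region"}
                )
            if lid in bounded and not math.isnan(r.value) and not (0.0 <= r.value <= 1.0):
                rows.append(
                    {"layer_id": lid, "region_id": r.region_id, "year": int(r.year),
                     "issue": "out_of_range"}
                )
        for rid in sorted(known & set(table.regions())):
            if not table.series(rid):
                for y in years:
                    rows.append(
                        {"layer_id": lid, "region_id": rid, "year": y,
                         "issue": "missing_after_gapfill"}
                    )
                continue
            filled = table.gapfilled(rid, years)
            for y in years:
                if y not in filled or math.isnan(filled[y]):
                    rows.append(
                        {"layer_id": lid, "region_id": rid, "year": y,
                         "issue": "missing_after_gapfill"}
                    )
    return pd.DataFrame(rows, columns=["layer_id", "region_id", "year", "issue"])


def with_goal_weights(config: EngineConfig, weights: Mapping[str, float]) -> EngineConfig:
    return replace(config, goal_weights=dict(weights))
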