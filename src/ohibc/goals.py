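"""Status and trend operations for the eight assessment goals.

Each operation maps prepared inputs to a status on [0, 1] (reported 0-100
downstream) or NaN when a goal genuinely cannot be scored for a region
(e.g. no aquaculture tenures, or all catch from unassessed stocks).
Statuses measure current benefit delivery against a reference point:
ratios against MSY-based stock targets, "no net loss" rolling baselines,
policy targets (30% protection), historic habitat extents, or zero
contamination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MISSING",
    "HcrParams",
    "StockRecord",
    "RiskRecord",
    "DEFAULT_RISK_WEIGHTS",
    "status_ratio",
    "no_net_loss_status",
    "livelihoods_status",
    "stock_score_hcr",
    "unassessed_penalty",
    "fisheries_status",
    "aquaculture_status",
    "salmon_status",
    "fn_access_components",
    "fn_access_status",
    "lsp_status",
    "species_status",
    "habitat_status",
    "pressure_condition_component",
    "clean_waters_status",
    "goal_trend",
]

MISSING = float("nan")


def is_missing(x: float | None) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def _present(values: Iterable[float | None]) -> list[float]:
    return [float(v) for v in values if not is_missing(v)]


# ---------------------------------------------------------------------------
# Generic status forms


def status_ratio(x: float, x_ref: float, cap: bool = True) -> float:
    """Current benefit over its reference point, optionally capped at 1."""
    if x_ref <= 0:
        raise ValueError(f"reference must be > 0, got {x_ref}")
    if x < 0:
        raise ValueError(f"current benefit must be >= 0, got {x}")
    s = x / x_ref
    return min(s, 1.0) if cap else s


def no_net_loss_status(value_t: float, history: Sequence[float]) -> float:
    """Status against the mean of the prior five (gapfilled) years.

    A series that starts in the assessment year scores 1 automatically:
    next-observation-carried-back makes every prior-year value equal the
    current one, so the baseline equals the observation.
    """
    if is_missing(value_t):
        return MISSING
    hist = _present(history)
    if not hist:
        return MISSING
    baseline = float(np.mean(hist))
    if baseline <= 0:
        if value_t > 0:
            raise ValueError("no-net-loss baseline <= 0 with positive current value")
        return MISSING
    return min(value_t / baseline, 1.0)


def livelihoods_status(
    employment_rate_t: float,
    employment_history: Sequence[float],
    wage_t: float,
    wage_history: Sequence[float],
) -> float:
    """Mean of the employment-rate and wage no-net-loss components.

    A component whose series is entirely missing is dropped and the mean
    renormalizes over what remains; both missing gives missing.
    """
    comps = []
    if not is_missing(employment_rate_t) and _present(employment_history):
        comps.append(no_net_loss_status(employment_rate_t, employment_history))
    if not is_missing(wage_t) and _present(wage_history):
        comps.append(no_net_loss_status(wage_t, wage_history))
    comps = _present(comps)
    return float(np.mean(comps)) if comps else MISSING


# ---------------------------------------------------------------------------
# Wild-capture fisheries: harvest-control-rule stock scoring


@dataclass(frozen=True)
class HcrParams:
    """Harvest-control-rule scoring curve.

    The biomass score is 0 at ``b_lo`` (collapse), rises linearly to 1 at
    ``b_ok_lo``, stays 1 on the plateau [b_ok_lo, b_ok_hi] around the
    B/B_MSY = 1 target, then declines linearly to ``underexploit_floor``
    at ``b_hi`` and beyond — penalizing both overexploitation and
    underexploitation.  When F/F_MSY is available, the score is multiplied
    by a fishing-mortality factor: 1 inside [0, ``f_band_hi``], declining
    linearly to 0 at 2 * f_band_hi.  ``gamma`` is the unassessed-catch
    penalty exponent.
    """

    b_lo: float = 0.05
    b_ok_lo: float = 0.8
    b_ok_hi: float = 1.5
    b_hi: float = 3.0
    underexploit_floor: float = 0.25
    f_band_hi: float = 1.2
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.b_lo < self.b_ok_lo <= self.b_ok_hi < self.b_hi):
            raise ValueError("HCR breakpoints must satisfy 0 <= b_lo < b_ok_lo <= b_ok_hi < b_hi")
        if not (0.0 <= self.underexploit_floor <= 1.0):
            raise ValueError("underexploit_floor must be in [0, 1]")
        if self.f_band_hi <= 0:
            raise ValueError("f_band_hi must be > 0")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


@dataclass(frozen=True)
class StockRecord:
    """Per-stock catch and assessment metrics for one region-year."""

    stock_id: str
    region_id: str
    year: int
    catch: float
    bbmsy: float = MISSING
    ffmsy: float = MISSING
    assessed: bool = False
    exempt: bool = False

    def __post_init__(self) -> None:
        if self.catch < 0:
            raise ValueError(f"stock {self.stock_id}: catch must be >= 0")
        if self.assessed and is_missing(self.bbmsy):
            raise ValueError(f"stock {self.stock_id}: assessed stock needs B/B_MSY")


def stock_score_hcr(
    bbmsy: float, ffmsy: float = MISSING, params: HcrParams = HcrParams()
) -> float:
    """Score one assessed stock on [0, 1] against the harvest control rule."""
    p = params
    if is_missing(bbmsy):
        raise ValueError("stock_score_hcr requires B/B_MSY (assessed stock)")
    if bbmsy < 0 or (not is_missing(ffmsy) and ffmsy < 0):
        raise ValueError("stock metrics must be >= 0")
    b = float(bbmsy)
    if b <= p.b_lo:
        score = 0.0
    elif b < p.b_ok_lo:
        score = (b - p.b_lo) / (p.b_ok_lo - p.b_lo)
    elif b <= p.b_ok_hi:
        score = 1.0
    elif b < p.b_hi:
        score = 1.0 + (p.underexploit_floor - 1.0) * (b - p.b_ok_hi) / (p.b_hi - p.b_ok_hi)
    else:
        score = p.underexploit_floor
    if not is_missing(ffmsy):
        f = float(ffmsy)
        if f <= p.f_band_hi:
            factor = 1.0
        elif f < 2.0 * p.f_band_hi:
            factor = 2.0 - f / p.f_band_hi
        else:
            factor = 0.0
        score *= factor
    return float(min(max(score, 0.0), 1.0))


def unassessed_penalty(assessed_catch_fraction: float, gamma: float = 1.0) -> float:
    """Penalty multiplier for catch taken from unassessed stocks."""
    if not (0.0 <= assessed_catch_fraction <= 1.0):
        raise ValueError("assessed catch fraction must be in [0, 1]")
    return float(assessed_catch_fraction**gamma)


def fisheries_status(
    stocks: Iterable[StockRecord], params: HcrParams = HcrParams()
) -> float:
    """Catch-weighted mean stock score times the unassessed-stock penalty.

    Exempt stocks (sustainably managed without an MSY reference) are
    excluded from both the score and the penalty; missing when no assessed
    stock contributes catch.
    """
    assessed = [s for s in stocks if not s.exempt and s.assessed]
    unassessed = [s for s in stocks if not s.exempt and not s.assessed]
    w = sum(s.catch for s in assessed)
    if w <= 0:
        return MISSING
    mean_score = (
        sum(s.catch * stock_score_hcr(s.bbmsy, s.ffmsy, params) for s in assessed) / w
    )
    total = w + sum(s.catch for s in unassessed)
    penalty = unassessed_penalty(w / total, params.gamma)
    return float(mean_score * penalty)


def aquaculture_status(
    production: float, reference_production: float, has_tenures: bool = True
) -> float:
    """Production against the tenure-based potential; regions without active
    tenures are not scored."""
    if not has_tenures:
        return MISSING
    if reference_production <= 0:
        raise ValueError("aquaculture reference must be > 0 where tenures exist")
    if is_missing(production):
        return MISSING
    return min(production / reference_production, 1.0)


def salmon_status(indicator_stocks: Iterable[tuple[float, float]]) -> float:
    """Study-wide salmon score from (catch, target) indicator pairs.

    Per-stock score is symmetric around the catch target (overshoot is
    treated as unsustainable like undershoot): max(0, 1 - |c - t| / t).
    """
    scores = []
    for catch, target in indicator_stocks:
        if target <= 0:
            raise ValueError("salmon catch target must be > 0")
        scores.append(max(0.0, 1.0 - abs(catch - target) / target))
    if not scores:
        return MISSING
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# First Nations resource access


def fn_access_components(
    herring_index_series: Mapping[int, float],
    herring_reference: float,
    year: int,
    closure_fraction: float,
    escapement_ratios: Iterable[float],
    license_fraction: float,
    population_fraction: float,
    population_floor: float = 0.15,
) -> dict[str, float]:
    """Four access components: herring spawn, shellfish, salmon, licenses.

    herring: 3-year running mean of the spawn index over the reference.
    shellfish: 1 minus the area-weighted closed fraction of the year.
    salmon: mean over indicator stocks of min(escapement/target, 1).
    licenses: license share over max(population share, floor), capped at 1.
    """
    if herring_reference <= 0:
        raise ValueError("herring reference index must be > 0")
    window = _present(herring_index_series.get(y, MISSING) for y in (year - 2, year - 1, year))
    herring = min(float(np.mean(window)) / herring_reference, 1.0) if window else MISSING
    if is_missing(closure_fraction):
        shellfish = MISSING
    else:
        if not (0.0 <= closure_fraction <= 1.0):
            raise ValueError("closure fraction must be in [0, 1]")
        shellfish = 1.0 - closure_fraction
    ratios = _present(escapement_ratios)
    salmon = float(np.mean([min(r, 1.0) for r in ratios])) if ratios else MISSING
    if is_missing(license_fraction) or is_missing(population_fraction):
        licenses = MISSING
    else:
        licenses = min(license_fraction / max(population_fraction, population_floor), 1.0)
    return {
        "herring": herring,
        "shellfish": shellfish,
        "salmon": salmon,
        "licenses": licenses,
    }


def fn_access_status(components: Mapping[str, float]) -> float:
    """Unweighted mean of the present components (renormalized)."""
    vals = _present(components.values())
    return float(np.mean(vals)) if vals else MISSING


# ---------------------------------------------------------------------------
# Sense of place, biodiversity, habitats, clean waters


def lsp_status(
    marine_protected_fraction: float,
    land_protected_fraction: float,
    target: float = 0.30,
) -> float:
    """Protected-area coverage against the target (default 30%), averaged
    over the coastal-marine and coastal-watershed zones."""
    if target <= 0:
        raise ValueError("protection target must be > 0")
    zones = [marine_protected_fraction, land_protected_fraction]
    return float(np.mean([min(f / target, 1.0) for f in zones]))


DEFAULT_RISK_WEIGHTS: dict[str, float] = {
    "LC": 0.0, "NT": 0.2, "VU": 0.4, "EN": 0.6, "CR": 0.8, "EX": 1.0,
}


@dataclass(frozen=True)
class RiskRecord:
    """Species extinction-risk record; ``category`` is an IUCN-style code or
    a numeric risk weight in [0, 1].  National (COSEWIC) assessments
    supersede global (IUCN) ones for the same species."""

    species_id: str
    region_id: str
    category: str | float
    source: str = "IUCN"
    area_weight: float = 1.0

    def risk(self, weights: Mapping[str, float] = DEFAULT_RISK_WEIGHTS) -> float:
        if isinstance(self.category, (int, float)):
            w = float(self.category)
            if not (0.0 <= w <= 1.0):
                raise ValueError(f"numeric risk weight must be in [0, 1], got {w}")
            return w
        try:
            return float(weights[str(self.category)])
        except KeyError:
            raise ValueError(f"unknown risk category {self.category!r}") from None


def species_status(
    records: Iterable[RiskRecord],
    risk_weights: Mapping[str, float] = DEFAULT_RISK_WEIGHTS,
) -> float:
    """1 minus the area-weighted mean extinction risk of assessed species."""
    chosen: dict[str, RiskRecord] = {}
    for rec in records:
        prev = chosen.get(rec.species_id)
        if prev is None or (rec.source == "COSEWIC" and prev.source != "COSEWIC"):
            chosen[rec.species_id] = rec
    if not chosen:
        return MISSING
    w = np.array([r.area_weight for r in chosen.values()], dtype=float)
    if (w <= 0).any():
        raise ValueError("area_weight must be > 0")
    risk = np.array([r.risk(risk_weights) for r in chosen.values()], dtype=float)
    return float(1.0 - np.average(risk, weights=w))


def habitat_status(
    current_extents: Mapping[str, float],
    reference_extents: Mapping[str, float],
    service_weights: Mapping[str, float],
) -> float:
    """Service-weighted habitat extent against reference extents, capped at 1.

    status = min(sum_h w_h * C_h / sum_h w_h * R_h, 1).
    """
    habs = [h for h, w in service_weights.items() if w > 0]
    if not habs:
        raise ValueError("habitat_status: all service weights are zero")
    num = 0.0
    den = 0.0
    for h in habs:
        w = float(service_weights[h])
        ref = float(reference_extents[h])
        if ref <= 0:
            raise ValueError(f"habitat {h!r}: reference extent must be > 0")
        cur = float(current_extents[h])
        if is_missing(cur):
            return MISSING
        num += w * cur
        den += w * ref
    return min(num / den, 1.0)


def pressure_condition_component(intensity: float) -> float:
    """Condition of a habitat scored as 1 minus a rescaled pressure
    intensity (e.g. trawl effort on soft-bottom habitat)."""
    if not (0.0 <= intensity <= 1.0):
        raise ValueError(f"pressure intensity must be in [0, 1], got {intensity}")
    return 1.0 - intensity


def clean_waters_status(
    c_nutrient: float, c_chemical: float, c_pathogen: float, c_debris: float
) -> float:
    """Geometric mean of the four contamination components (1 = pristine).

    A poor score in any one component drags the whole goal down; a zero
    annihilates it.  Missing any component gives missing — the goal is not
    renormalized over a subset.
    """
    comps = [c_nutrient, c_chemical, c_pathogen, c_debris]
    if any(is_missing(c) for c in comps):
        return MISSING
    if any(c < 0 or c > 1 for c in comps):
        raise ValueError("clean-waters components must be in [0, 1]")
    return float(np.prod(comps) ** 0.25)


# ---------------------------------------------------------------------------
# Trend


def goal_trend(
    status_series: Mapping[int, float],
    year_t: int,
    window: int = 5,
    clip: float = 1.0,
) -> float:
    """Proportional change in status over the window ending at ``year_t``.

    OLS slope of status on year over the window, times the window length,
    divided by the status at the window start; clipped symmetrically.
    A zero window-start status gives a trend of 0 (degenerate baseline).
    """
    pts = sorted(
        (y, float(v))
        for y, v in status_series.items()
        if year_t - window + 1 <= y <= year_t and not is_missing(v)
    )
    if len(pts) < 2:
        raise ValueError("goal_trend needs >= 2 status values in the window")
    years = np.array([y for y, _ in pts], dtype=float)
    vals = np.array([v for _, v in pts], dtype=float)
    slope = float(np.polyfit(years, vals, 1)[0])
    start = vals[0]
    if start == 0.0:
        return 0.0
    t = slope * window / start
    return float(min(max(t, -clip), clip))
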