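"""Default goal registry: the eight-goal British Columbia goal set.

Maps each status-bearing goal (a leaf of the goal tree) to a status
builder over prepared layers.  Layer bindings and every model parameter
(HCR breakpoints, risk weights, the 30% protection target, the herring
reference index, habitat service weights) are configurable; the defaults
below name the layers the synthetic study generator emits.

Goal keys::

    HAB  Habitat Services        CS carbon storage, CP coastal protection
    FP   Food Provision          FIS wild-capture fisheries, MAR aquaculture,
                                 SAL wild-capture salmon
    FNA  First Nations Resource Access Opportunities
    LIV  Coastal Livelihoods     LIV_FN First Nations, LIV_NFN non-First Nations
    TR   Tourism & Recreation
    SP   Sense of Place          LSP lasting special places, ICO iconic species
    BD   Biodiversity            SPP species, HABS habitats
    CW   Clean Waters
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from . import goals as G
from .engine import Prepared, StatusBuilder, StudyBundle
from .goals import MISSING, HcrParams, RiskRecord, StockRecord, is_missing
from .layers import EngineConfig

__all__ = ["GOAL_TREE", "GoalParams", "DEFAULT_BINDINGS", "default_models", "leaf_goals"]

GOAL_TREE: dict[str, list[str]] = {
    "HAB": ["CS", "CP"],
    "FP": ["FIS", "MAR", "SAL"],
    "FNA": [],
    "LIV": ["LIV_FN", "LIV_NFN"],
    "TR": [],
    "SP": ["LSP", "ICO"],
    "BD": ["SPP", "HABS"],
    "CW": [],
}

NNL_WINDOW = 5  # "mean of prior five year period" baselines

DEFAULT_BINDINGS: dict[str, dict] = {
    "TR": {"visits": "tr_visits"},
    "LIV_FN": {"employment": "liv_emp_fn", "wages": "liv_wage_fn"},
    "LIV_NFN": {"employment": "liv_emp_nfn", "wages": "liv_wage_nfn"},
    "MAR": {"production": "mar_production", "reference": "mar_reference"},
    "FNA": {
        "herring_index": "fna_herring_index",
        "closure": "fna_closure_frac",
        "license": "fna_license_frac",
        "population": "fna_pop_frac",
    },
    "LSP": {"marine": "lsp_marine_frac", "land": "lsp_land_frac"},
    "CW": {
        "nutrient": "cw_nutrient",
        "chemical": "cw_chemical",
        "pathogen": "cw_pathogen",
        "debris": "cw_debris",
    },
    "CS": {
        "habitats": {
            "salt_marsh": {"current": "hab_sm_extent", "reference": "hab_sm_ref", "weight": 2.0},
            "coastal_forest": {"current": "hab_cf_extent", "reference": "hab_cf_ref", "weight": 1.0},
        }
    },
    "CP": {
        "habitats": {
            "salt_marsh": {"current": "hab_sm_extent", "reference": "hab_sm_ref", "weight": 1.0},
            "coastal_forest": {"current": "hab_cf_extent", "reference": "hab_cf_ref", "weight": 2.0},
        }
    },
    "HABS": {
        "habitats": {
            "salt_marsh": {"current": "hab_sm_extent", "reference": "hab_sm_ref", "weight": 1.0},
        },
        "pressure_layers": ["hab_trawl_soft", "hab_trawl_ebsa"],
    },
}


@dataclass
class GoalParams:
    """Tunable parameters of the goal models."""

    hcr: HcrParams = field(default_factory=HcrParams)
    lsp_target: float = 0.30
    herring_reference: float = 1.0
    fn_population_floor: float = 0.15
    risk_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(G.DEFAULT_RISK_WEIGHTS)
    )
    bindings: dict[str, dict] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_BINDINGS)
    )

    def binding(self, goal: str) -> dict:
        return self.bindings.get(goal, DEFAULT_BINDINGS.get(goal, {}))


def leaf_goals(tree: Mapping[str, list[str]] = GOAL_TREE) -> list[str]:
    return [g for g, subs in tree.items() if not subs] + [
        s for subs in tree.values() for s in subs
    ]


def _nnl_history(series: Mapping[int, float], year: int) -> list[float]:
    return [series.get(year - k, MISSING) for k in range(NNL_WINDOW, 0, -1)]


def _grid(bundle: StudyBundle, config: EngineConfig):
    for rid in bundle.region_ids():
        for y in config.years:
            yield rid, y


def _tourism_builder(params: GoalParams) -> StatusBuilder:
    layer = params.binding("TR")["visits"]

    def build(bundle, prepared, config):
        out = {}
        for rid, y in _grid(bundle, config):
            if not prepared.has(layer, rid):
                out[(rid, y)] = MISSING
                continue
            s = prepared.series(layer, rid)
            out[(rid, y)] = G.no_net_loss_status(s.get(y, MISSING), _nnl_history(s, y))
        return out

    return build


def _livelihoods_builder(goal: str, params: GoalParams) -> StatusBuilder:
    b = params.binding(goal)
    emp_layer, wage_layer = b["employment"], b["wages"]

    def build(bundle, prepared, config):
        out = {}
        for rid, y in _grid(bundle, config):
            emp = prepared.series(emp_layer, rid) if prepared.has(emp_layer, rid) else {}
            wage = prepared.series(wage_layer, rid) if prepared.has(wage_layer, rid) else {}
            out[(rid, y)] = G.livelihoods_status(
                emp.get(y, MISSING), _nnl_history(emp, y),
                wage.get(y, MISSING), _nnl_history(wage, y),
            )
        return out

    return build


def _aquaculture_builder(params: GoalParams) -> StatusBuilder:
    b = params.binding("MAR")
    prod_layer, ref_layer = b["production"], b["reference"]

    def build(bundle, prepared, config):
        out = {}
        for rid, y in _grid(bundle, config):
            has_tenures = prepared.has(ref_layer, rid)
            ref = prepared.value(ref_layer, rid, y) if has_tenures else MISSING
            prod = prepared.value(prod_layer, rid, y)
            if has_tenures and is_missing(ref):
                out[(rid, y)] = MISSING
            else:
                out[(rid, y)] = G.aquaculture_status(prod, ref if has_tenures else 1.0,
                                                     has_tenures=has_tenures)
        return out

    return build


def _fisheries_builder(params: GoalParams) -> StatusBuilder:
    def build(bundle, prepared, config):
        out = {(rid, y): MISSING for rid, y in _grid(bundle, config)}
        if bundle.stocks is None or bundle.stocks.empty:
            return out
        df = bundle.stocks
        for (rid, y), sub in df.groupby(["region_id", "year"]):
            if (str(rid), int(y)) not in out:
                continue
            records = [
                StockRecord(
                    stock_id=str(r.stock_id), region_id=str(rid), year=int(y),
                    catch=float(r.catch_t),
                    bbmsy=float(r.bbmsy) if not pd.isna(r.bbmsy) else MISSING,
                    ffmsy=float(r.ffmsy) if not pd.isna(r.ffmsy) else MISSING,
                    assessed=bool(r.assessed), exempt=bool(r.exempt),
                )
                for r in sub.itertuples()
            ]
            out[(str(rid), int(y))] = G.fisheries_status(records, params.hcr)
        return out

    return build


def _salmon_builder(params: GoalParams) -> StatusBuilder:
    def build(bundle, prepared, config):
        out = {(rid, y): MISSING for rid, y in _grid(bundle, config)}
        if bundle.salmon is None or bundle.salmon.empty:
            return out
        for y, sub in bundle.salmon.groupby("year"):
            y = int(y)
            if y not in config.years:
                continue
            s = G.salmon_status(list(zip(sub["catch"], sub["target"])))
            for rid in bundle.region_ids():
                out[(rid, y)] = s
        return out

    return build


def _fn_access_builder(params: GoalParams) -> StatusBuilder:
    b = params.binding("FNA")

    def build(bundle, prepared, config):
        esc: dict[int, list[float]] = {}
        if bundle.escapement is not None and not bundle.escapement.empty:
            for y, sub in bundle.escapement.groupby("year"):
                esc[int(y)] = [float(v) for v in sub["escapement_ratio"]]
        out = {}
        for rid, y in _grid(bundle, config):
            herring = prepared.series(b["herring_index"], rid)
            comps = G.fn_access_components(
                herring_index_series=herring,
                herring_reference=params.herring_reference,
                year=y,
                closure_fraction=prepared.value(b["closure"], rid, y),
                escapement_ratios=esc.get(y, []),
                license_fraction=prepared.value(b["license"], rid, y),
                population_fraction=prepared.value(b["population"], rid, y),
                population_floor=params.fn_population_floor,
            )
            out[(rid, y)] = G.fn_access_status(comps)
        return out

    return build


def _lsp_builder(params: GoalParams) -> StatusBuilder:
    b = params.binding("LSP")

    def build(bundle, prepared, config):
        out = {}
        for rid, y in _grid(bundle, config):
            marine = prepared.value(b["marine"], rid, y)
            land = prepared.value(b["land"], rid, y)
            if is_missing(marine) or is_missing(land):
                out[(rid, y)] = MISSING
            else:
                out[(rid, y)] = G.lsp_status(marine, land, params.lsp_target)
        return out

    return build


def _parse_category(raw) -> str | float:
    try:
        return float(raw)
    except (TypeError, ValueError):
        return str(raw)


def _species_builder(source_attr: str, params: GoalParams) -> StatusBuilder:
    def build(bundle, prepared, config):
        df = getattr(bundle, source_attr)
        by_region: dict[str, float] = {}
        if df is not None and not df.empty:
            for rid, sub in df.groupby("region_id"):
                records = [
                    RiskRecord(
                        species_id=str(r.species_id), region_id=str(rid),
                        category=_parse_category(r.category),
                        source=str(r.source), area_weight=float(r.area_weight),
                    )
                    for r in sub.itertuples()
                ]
                by_region[str(rid)] = G.species_status(records, params.risk_weights)
        return {
            (rid, y): by_region.get(rid, MISSING) for rid, y in _grid(bundle, config)
        }

    return build


def _habitat_extent_status(
    prepared: Prepared, habitats: Mapping[str, Mapping], rid: str, y: int
) -> float:
    current, reference, weights = {}, {}, {}
    for name, spec in habitats.items():
        current[name] = prepared.value(spec["current"], rid, y)
        reference[name] = prepared.value(spec["reference"], rid, y)
        weights[name] = float(spec["weight"])
    if any(is_missing(v) for v in current.values()) or any(
        is_missing(v) for v in reference.values()
    ):
        return MISSING
    return G.habitat_status(current, reference, weights)


def _habitat_services_builder(goal: str, params: GoalParams) -> StatusBuilder:
    habitats = params.binding(goal)["habitats"]

    def build(bundle, prepared, config):
        return {
            (rid, y): _habitat_extent_status(prepared, habitats, rid, y)
            for rid, y in _grid(bundle, config)
        }

    return build


def _bd_habitats_builder(params: GoalParams) -> StatusBuilder:
    b = params.binding("HABS")
    habitats = b["habitats"]
    pressure_layers = list(b.get("pressure_layers", []))

    def build(bundle, prepared, config):
        out = {}
        for rid, y in _grid(bundle, config):
            comps = [_habitat_extent_status(prepared, habitats, rid, y)]
            for lid in pressure_layers:
                v = prepared.value(lid, rid, y)
                comps.append(
                    MISSING if is_missing(v) else G.pressure_condition_component(v)
                )
            present = [c for c in comps if not is_missing(c)]
            out[(rid, y)] = sum(present) / len(present) if present else MISSING
        return out

    return build


def _clean_waters_builder(params: GoalParams) -> StatusBuilder:
    b = params.binding("CW")

    def build(bundle, prepared, config):
        return {
            (rid, y): G.clean_waters_status(
                prepared.value(b["nutrient"], rid, y),
                prepared.value(b["chemical"], rid, y),
                prepared.value(b["pathogen"], rid, y),
                prepared.value(b["debris"], rid, y),
            )
            for rid, y in _grid(bundle, config)
        }

    return build


def default_models(params: GoalParams | None = None) -> dict[str, StatusBuilder]:
    """Status builders for every leaf of :data:`GOAL_TREE`."""
    p = params or GoalParams()
    return {
        "CS": _habitat_services_builder("CS", p),
        "CP": _habitat_services_builder("CP", p),
        "FIS": _fisheries_builder(p),
        "MAR": _aquaculture_builder(p),
        "SAL": _salmon_builder(p),
        "FNA": _fn_access_builder(p),
        "LIV_FN": _livelihoods_builder("LIV_FN", p),
        "LIV_NFN": _livelihoods_builder("LIV_NFN", p),
        "TR": _tourism_builder(p),
        "LSP": _lsp_builder(p),
        "ICO": _species_builder("iconic_risk", p),
        "SPP": _species_builder("species_risk", p),
        "HABS": _bd_habitats_builder(p),
        "CW": _clean_waters_builder(p),
    }
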