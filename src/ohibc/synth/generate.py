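"""Seeded synthetic study bundles emulating the shape of the BC study.

The default spec mirrors the study structure: 8 regions (one excluded
from the study-area aggregate), assessment years 2001-2016, a mix of
annual, periodic (5- and 10-year) and truncated layers (visitation data
beginning 2007, census-like series every 5 years, land-use habitat
extents observed 1990/2000/2010, a static marine-debris layer), stochastic
stock sets with one region whose catch is entirely unassessed, study-wide
salmon indicator stocks, species risk tables, and pressure/resilience
weight matrices covering every goal.  A single master seed is split
deterministically per layer, so identical (spec, seed) pairs give
byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..engine import StudyBundle
from ..goals import MISSING
from ..layers import EngineConfig, LayerTable, Region, write_layer_bundle, write_regions
from ..models import GoalParams
from .expected import expected_scores

__all__ = ["LayerSpec", "SyntheticSpec", "generate_study", "write_study"]


@dataclass(frozen=True)
class LayerSpec:
    """Generative settings for one data layer.

    value(region i, year t) = baseline * (1 + region_spread * s_i)
                              + trend * (t - first observed year) + noise
    with s_i a deterministic per-region offset in [-1, 1]; sampled every
    ``period`` years within [first_year, last_year]; optionally clipped
    to [0, 1] after noise (bounded layers).
    """

    layer_id: str
    baseline: float
    trend: float = 0.0
    noise_sd: float = 0.0
    period: int = 1
    first_year: int | None = None
    last_year: int | None = None
    bounded01: bool = False
    region_spread: float = 0.0
    units: str = ""
    regions: tuple[str, ...] | None = None  # None = all regions

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError(f"layer {self.layer_id}: noise_sd must be >= 0")
        if self.period < 1:
            raise ValueError(f"layer {self.layer_id}: period must be >= 1")


DEFAULT_REGION_NAMES = [
    ("r1", "North Coast"),
    ("r2", "Haida Gwaii"),
    ("r3", "Central Coast"),
    ("r4", "North Vancouver Island"),
    ("r5", "West Vancouver Island"),
    ("r6", "Strait of Georgia"),
    ("r7", "Aristazabal Island"),
    ("r8", "Offshore"),  # assessed but excluded from the study aggregate
]


def _default_layers() -> list[LayerSpec]:
    return [
        # Goal inputs -----------------------------------------------------
        LayerSpec("tr_visits", 50_000, 800, 1500, first_year=2007,
                  region_spread=0.3, units="visits"),
        LayerSpec("liv_emp_fn", 0.52, 0.003, 0.01, period=5, first_year=2001,
                  bounded01=True, region_spread=0.08),
        LayerSpec("liv_emp_nfn", 0.62, 0.003, 0.01, period=5, first_year=2001,
                  bounded01=True, region_spread=0.08),
        LayerSpec("liv_wage_fn", 22.0, 0.15, 0.3, period=5, first_year=2001,
                  region_spread=0.1, units="CAD/h"),
        LayerSpec("liv_wage_nfn", 28.0, 0.20, 0.3, period=5, first_year=2001,
                  region_spread=0.1, units="CAD/h"),
        # Aquaculture: no tenures in r2 (Haida-Gwaii-like) or the excluded
        # region, exercising the missing-subgoal renormalization.
        LayerSpec("mar_production", 8_000, 60, 200, region_spread=0.4,
                  units="t", regions=("r1", "r3", "r4", "r5", "r6", "r7")),
        LayerSpec("mar_reference", 10_000, 0, 0, first_year=2001, last_year=2001,
                  region_spread=0.4, units="t",
                  regions=("r1", "r3", "r4", "r5", "r6", "r7")),
        LayerSpec("fna_herring_index", 1.05, 0.005, 0.05, region_spread=0.1),
        LayerSpec("fna_closure_frac", 0.15, -0.002, 0.02, bounded01=True,
                  region_spread=0.3),
        LayerSpec("fna_license_frac", 0.12, 0.004, 0.005, bounded01=True,
                  region_spread=0.2),
        LayerSpec("fna_pop_frac", 0.25, 0.0, 0.0, period=5, first_year=2001,
                  bounded01=True, region_spread=0.2),
        LayerSpec("lsp_marine_frac", 0.08, 0.010, 0.002, bounded01=True,
                  region_spread=0.3),
        LayerSpec("lsp_land_frac", 0.12, 0.008, 0.002, bounded01=True,
                  region_spread=0.3),
        # Land-use-like habitat extents: decadal, truncated at 2010.
        LayerSpec("hab_sm_extent", 1_000, -0.6, 2.0, period=10, first_year=1990,
                  last_year=2010, region_spread=0.5, units="km2"),
        LayerSpec("hab_cf_extent", 5_000, -2.0, 8.0, period=10, first_year=1990,
                  last_year=2010, region_spread=0.5, units="km2"),
        LayerSpec("hab_sm_ref", 1_000, 0, 0, first_year=1990, last_year=1990,
                  region_spread=0.5, units="km2"),
        LayerSpec("hab_cf_ref", 5_000, 0, 0, first_year=1990, last_year=1990,
                  region_spread=0.5, units="km2"),
        LayerSpec("hab_trawl_soft", 0.20, -0.008, 0.01, bounded01=True,
                  region_spread=0.4),
        LayerSpec("hab_trawl_ebsa", 0.10, -0.004, 0.005, bounded01=True,
                  region_spread=0.4),
        LayerSpec("cw_nutrient", 0.85, 0.002, 0.02, bounded01=True, region_spread=0.1),
        LayerSpec("cw_chemical", 0.70, 0.000, 0.02, bounded01=True, region_spread=0.15),
        LayerSpec("cw_pathogen", 0.90, 0.001, 0.01, bounded01=True, region_spread=0.05),
        LayerSpec("cw_debris", 0.75, 0.0, 0.0, first_year=2014, last_year=2014,
                  bounded01=True, region_spread=0.2),
        # Pressure layers -------------------------------------------------
        LayerSpec("prs_chemical", 0.35, 0.004, 0.02, bounded01=True, region_spread=0.2),
        LayerSpec("prs_nutrient", 0.25, -0.003, 0.02, bounded01=True, region_spread=0.2),
        LayerSpec("prs_sst", 0.40, 0.008, 0.03, bounded01=True, region_spread=0.1),
        LayerSpec("prs_fishing", 0.45, -0.008, 0.02, bounded01=True, region_spread=0.2),
        LayerSpec("prs_habitat", 0.30, -0.004, 0.02, bounded01=True, region_spread=0.2),
        LayerSpec("prs_social", 0.30, -0.004, 0.02, bounded01=True, region_spread=0.2),
        # Resilience layers ----------------------------------------------
        LayerSpec("res_mpa", 0.30, 0.015, 0.01, bounded01=True, region_spread=0.2),
        LayerSpec("res_fishing_reg", 0.50, 0.010, 0.01, bounded01=True),
        LayerSpec("res_aqua_reg", 0.55, 0.010, 0.01, bounded01=True),
        LayerSpec("res_species_cond", 0.85, 0.0, 0.0, bounded01=True,
                  region_spread=0.05),
        LayerSpec("res_cwb", 0.60, 0.004, 0.01, period=5, first_year=2001,
                  bounded01=True, region_spread=0.15),
    ]


# Which pressure layers drive which goals (ecological unless noted).
PRESSURE_BINDINGS: dict[str, list[tuple[str, float, str]]] = {
    "CS": [("prs_habitat", 3.0, "ecological"), ("prs_sst", 1.0, "ecological"),
           ("prs_social", 1.0, "social")],
    "CP": [("prs_habitat", 3.0, "ecological"), ("prs_sst", 1.0, "ecological"),
           ("prs_social", 1.0, "social")],
    "FIS": [("prs_fishing", 3.0, "ecological"), ("prs_sst", 1.0, "ecological")],
    "MAR": [("prs_chemical", 2.0, "ecological"), ("prs_nutrient", 1.0, "ecological")],
    "SAL": [("prs_fishing", 2.0, "ecological"), ("prs_sst", 2.0, "ecological")],
    "FNA": [("prs_fishing", 2.0, "ecological"), ("prs_chemical", 1.0, "ecological"),
            ("prs_social", 2.0, "social")],
    "LIV_FN": [("prs_social", 3.0, "social"), ("prs_fishing", 1.0, "ecological")],
    "LIV_NFN": [("prs_social", 3.0, "social"), ("prs_fishing", 1.0, "ecological")],
    "TR": [("prs_chemical", 1.0, "ecological"), ("prs_social", 1.0, "social")],
    "LSP": [("prs_habitat", 2.0, "ecological"), ("prs_social", 1.0, "social")],
    "ICO": [("prs_fishing", 1.0, "ecological"), ("prs_sst", 2.0, "ecological")],
    "SPP": [("prs_fishing", 1.0, "ecological"), ("prs_sst", 2.0, "ecological")],
    "HABS": [("prs_habitat", 3.0, "ecological"), ("prs_fishing", 1.0, "ecological")],
    "CW": [("prs_chemical", 3.0, "ecological"), ("prs_nutrient", 2.0, "ecological")],
}

RESILIENCE_BINDINGS: dict[str, list[tuple[str, float, str]]] = {
    "CS": [("res_mpa", 2.0, "regulatory"), ("res_species_cond", 1.0, "ecological"),
           ("res_cwb", 1.0, "social")],
    "CP": [("res_mpa", 2.0, "regulatory"), ("res_species_cond", 1.0, "ecological"),
           ("res_cwb", 1.0, "social")],
    "FIS": [("res_fishing_reg", 3.0, "regulatory"), ("res_species_cond", 1.0, "ecological"),
            ("res_cwb", 1.0, "social")],
    "MAR": [("res_aqua_reg", 3.0, "regulatory"), ("res_cwb", 1.0, "social")],
    "SAL": [("res_fishing_reg", 2.0, "regulatory"), ("res_species_cond", 1.0, "ecological")],
    "FNA": [("res_fishing_reg", 1.0, "regulatory"), ("res_mpa", 1.0, "regulatory"),
            ("res_cwb", 2.0, "social")],
    "LIV_FN": [("res_cwb", 1.0, "social")],
    "LIV_NFN": [("res_cwb", 1.0, "social")],
    "TR": [("res_mpa", 1.0, "regulatory"), ("res_cwb", 1.0, "social")],
    "LSP": [("res_mpa", 3.0, "regulatory"), ("res_cwb", 1.0, "social")],
    "ICO": [("res_mpa", 1.0, "regulatory"), ("res_species_cond", 2.0, "ecological")],
    "SPP": [("res_mpa", 1.0, "regulatory"), ("res_species_cond", 2.0, "ecological")],
    "HABS": [("res_mpa", 2.0, "regulatory"), ("res_fishing_reg", 1.0, "regulatory"),
             ("res_species_cond", 1.0, "ecological")],
    "CW": [("res_mpa", 1.0, "regulatory"), ("res_cwb", 1.0, "social")],
}

RISK_CATEGORIES = ["LC", "LC", "LC", "LC", "LC", "NT", "NT", "VU", "EN", "CR"]


def _perfect_layers() -> list[LayerSpec]:
    """Flat, noise-free layers with every goal input at its reference and
    every pressure at zero — the analytic all-scores-1 study."""
    return [
        LayerSpec("tr_visits", 50_000, 0, 0, first_year=2007, units="visits"),
        LayerSpec("liv_emp_fn", 0.60, 0, 0, bounded01=True),
        LayerSpec("liv_emp_nfn", 0.60, 0, 0, bounded01=True),
        LayerSpec("liv_wage_fn", 25.0, 0, 0, units="CAD/h"),
        LayerSpec("liv_wage_nfn", 25.0, 0, 0, units="CAD/h"),
        LayerSpec("mar_production", 10_000, 0, 0, units="t"),
        LayerSpec("mar_reference", 10_000, 0, 0, first_year=2001, last_year=2001,
                  units="t"),
        LayerSpec("fna_herring_index", 1.0, 0, 0),
        LayerSpec("fna_closure_frac", 0.0, 0, 0, bounded01=True),
        LayerSpec("fna_license_frac", 0.30, 0, 0, bounded01=True),
        LayerSpec("fna_pop_frac", 0.20, 0, 0, bounded01=True),
        LayerSpec("lsp_marine_frac", 0.50, 0, 0, bounded01=True),
        LayerSpec("lsp_land_frac", 0.50, 0, 0, bounded01=True),
        LayerSpec("hab_sm_extent", 1_000, 0, 0, period=10, first_year=1990,
                  last_year=2010, units="km2"),
        LayerSpec("hab_cf_extent", 5_000, 0, 0, period=10, first_year=1990,
                  last_year=2010, units="km2"),
        LayerSpec("hab_sm_ref", 1_000, 0, 0, first_year=1990, last_year=1990,
                  units="km2"),
        LayerSpec("hab_cf_ref", 5_000, 0, 0, first_year=1990, last_year=1990,
                  units="km2"),
        LayerSpec("hab_trawl_soft", 0.0, 0, 0, bounded01=True),
        LayerSpec("hab_trawl_ebsa", 0.0, 0, 0, bounded01=True),
        LayerSpec("cw_nutrient", 1.0, 0, 0, bounded01=True),
        LayerSpec("cw_chemical", 1.0, 0, 0, bounded01=True),
        LayerSpec("cw_pathogen", 1.0, 0, 0, bounded01=True),
        LayerSpec("cw_debris", 1.0, 0, 0, first_year=2014, last_year=2014,
                  bounded01=True),
        LayerSpec("prs_chemical", 0.0, 0, 0, bounded01=True),
        LayerSpec("prs_nutrient", 0.0, 0, 0, bounded01=True),
        LayerSpec("prs_sst", 0.0, 0, 0, bounded01=True),
        LayerSpec("prs_fishing", 0.0, 0, 0, bounded01=True),
        LayerSpec("prs_habitat", 0.0, 0, 0, bounded01=True),
        LayerSpec("prs_social", 0.0, 0, 0, bounded01=True),
        LayerSpec("res_mpa", 0.0, 0, 0, bounded01=True),
        LayerSpec("res_fishing_reg", 0.0, 0, 0, bounded01=True),
        LayerSpec("res_aqua_reg", 0.0, 0, 0, bounded01=True),
        LayerSpec("res_species_cond", 0.0, 0, 0, bounded01=True),
        LayerSpec("res_cwb", 0.0, 0, 0, bounded01=True),
    ]


@dataclass
class SyntheticSpec:
    """Full description of a synthetic study."""

    n_regions: int = 8
    years: tuple[int, int] = (2001, 2016)
    layer_specs: list[LayerSpec] = field(default_factory=_default_layers)
    noise_scale: float = 1.0  # global multiplier on every layer's noise_sd
    n_assessed_stocks: int = 3
    n_unassessed_stocks: int = 2
    unassessed_region: str | None = "r6"  # all catch unassessed (no FIS score)
    n_salmon_stocks: int = 4
    n_species: int = 24
    n_iconic: int = 10
    herring_reference: float = 1.0
    perfect: bool = False  # every input at reference, zero pressures
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        first, last = self.years
        if last - first + 1 < 5:
            raise ValueError("years span must cover at least the trend window")
        if self.perfect:
            self.layer_specs = _perfect_layers()
            self.noise_scale = 0.0
            self.n_unassessed_stocks = 0
            self.unassessed_region = None


def _region_list(spec: SyntheticSpec) -> list[Region]:
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    areas = rng.uniform(5_000, 60_000, size=spec.n_regions)
    regions = []
    for i in range(spec.n_regions):
        rid, name = (
            DEFAULT_REGION_NAMES[i]
            if i < len(DEFAULT_REGION_NAMES)
            else (f"r{i + 1}", f"Region {i + 1}")
        )
        regions.append(
            Region(
                region_id=rid, name=name, area_km2=float(round(areas[i], 1)),
                inhabited=(rid != "r7"),
                in_study_aggregate=(i < min(spec.n_regions, 7)),
            )
        )
    return regions


def _layer_table(
    spec: SyntheticSpec, ls: LayerSpec, regions: list[Region], child_seed
) -> LayerTable:
    rng = np.random.default_rng(child_seed)
    first, last = spec.years
    y0 = ls.first_year if ls.first_year is not None else first
    y1 = ls.last_year if ls.last_year is not None else last
    years = list(range(y0, y1 + 1, ls.period))
    rids = [r.region_id for r in regions]
    if ls.regions is not None:
        rids = [r for r in rids if r in ls.regions]
    n = len(rids)
    offsets = (
        np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(1)
    )  # deterministic per-region spread
    rows = []
    for i, rid in enumerate(rids):
        base = ls.baseline * (1.0 + ls.region_spread * offsets[i])
        for y in years:
            v = base + ls.trend * (y - y0)
            if ls.noise_sd > 0:
                v += rng.normal(0.0, ls.noise_sd * spec.noise_scale)
            if ls.bounded01:
                v = min(max(v, 0.0), 1.0)
            rows.append({"region_id": rid, "year": y, "value": float(v)})
    return LayerTable(ls.layer_id, pd.DataFrame(rows), units=ls.units)


def _stock_table(spec: SyntheticSpec, regions: list[Region], child_seed) -> pd.DataFrame:
    rng = np.random.default_rng(child_seed)
    first, last = spec.years
    rows = []
    for r in regions:
        all_unassessed = r.region_id == spec.unassessed_region
        n_a = 0 if all_unassessed else spec.n_assessed_stocks
        n_u = spec.n_unassessed_stocks + (spec.n_assessed_stocks if all_unassessed else 0)
        base_b = rng.uniform(0.8, 1.3, size=max(n_a, 1))
        base_f = rng.uniform(0.6, 1.1, size=max(n_a, 1))
        base_c = rng.uniform(100, 400, size=n_a + n_u) if n_a + n_u else []
        for y in range(first, last + 1):
            for j in range(n_a):
                if spec.perfect:
                    bb, ff = 1.0, 1.0
                else:
                    bb = float(np.clip(base_b[j] + rng.normal(0, 0.08), 0.05, 3.5))
                    ff = float(np.clip(base_f[j] + rng.normal(0, 0.08), 0.0, 2.5))
                rows.append(
                    {
                        "stock_id": f"{r.region_id}_a{j}", "region_id": r.region_id,
                        "year": y,
                        "catch_t": float(base_c[j] * rng.uniform(0.8, 1.2)),
                        "bbmsy": bb, "ffmsy": ff,
                        "assessed": True, "exempt": False,
                    }
                )
            for j in range(n_u):
                rows.append(
                    {
                        "stock_id": f"{r.region_id}_u{j}", "region_id": r.region_id,
                        "year": y,
                        "catch_t": float(base_c[n_a + j] * rng.uniform(0.8, 1.2)),
                        "bbmsy": MISSING, "ffmsy": MISSING,
                        "assessed": False, "exempt": False,
                    }
                )
            # one exempt stock per region (herring-like): never scored,
            # never penalized
            rows.append(
                {
                    "stock_id": f"{r.region_id}_x", "region_id": r.region_id,
                    "year": y, "catch_t": float(rng.uniform(50, 150)),
                    "bbmsy": MISSING, "ffmsy": MISSING,
                    "assessed": False, "exempt": True,
                }
            )
    return pd.DataFrame(rows)


def _salmon_tables(spec: SyntheticSpec, child_seed) -> tuple[pd.DataFrame, pd.DataFrame]:
    rng = np.random.default_rng(child_seed)
    first, last = spec.years
    targets = rng.uniform(800, 3_000, size=spec.n_salmon_stocks)
    catch_rows, esc_rows = [], []
    for y in range(first, last + 1):
        for j in range(spec.n_salmon_stocks):
            catch_rows.append(
                {
                    "stock_id": f"sal{j}", "year": y,
                    "catch": float(targets[j])
                    if spec.perfect
                    else float(targets[j] * rng.uniform(0.75, 1.25)),
                    "target": float(targets[j]),
                }
            )
            esc_rows.append(
                {
                    "stock_id": f"sal{j}", "year": y,
                    "escapement_ratio": 1.0
                    if spec.perfect
                    else float(np.clip(rng.normal(0.95, 0.12), 0.0, 2.0)),
                }
            )
    return pd.DataFrame(catch_rows), pd.DataFrame(esc_rows)


def _risk_table(
    n_species: int, regions: list[Region], child_seed, prefix: str,
    perfect: bool = False,
) -> pd.DataFrame:
    rng = np.random.default_rng(child_seed)
    rows = []
    cats = [
        "LC" if perfect else RISK_CATEGORIES[rng.integers(len(RISK_CATEGORIES))]
        for _ in range(n_species)
    ]
    for r in regions:
        for j in range(n_species):
            rows.append(
                {
                    "species_id": f"{prefix}{j}", "region_id": r.region_id,
                    "category": cats[j], "source": "COSEWIC" if j % 3 else "IUCN",
                    "area_weight": float(rng.uniform(0.4, 1.0)),
                }
            )
            if j % 5 == 0:  # duplicate IUCN record a step riskier, superseded
                rows.append(
                    {
                        "species_id": f"{prefix}{j}", "region_id": r.region_id,
                        "category": "VU", "source": "IUCN",
                        "area_weight": float(rng.uniform(0.4, 1.0)),
                    }
                )
    return pd.DataFrame(rows)


def _matrix(bindings: dict[str, list[tuple[str, float, str]]]) -> pd.DataFrame:
    rows = [
        {"goal": g, "layer_id": lid, "weight": w, "category": cat}
        for g, entries in bindings.items()
        for lid, w, cat in entries
    ]
    return pd.DataFrame(rows, columns=["goal", "layer_id", "weight", "category"])


def generate_study(
    spec: SyntheticSpec | None = None,
) -> tuple[StudyBundle, GoalParams, EngineConfig, pd.DataFrame]:
    """Generate a complete, validated input set plus independently
    computed expected stage values.

    Returns (bundle, goal_params, engine_config, expected) where
    ``expected`` is a long table of stage values (statuses, trend, p, r,
    future, score, rollups) computed by a direct plain-loop transcription
    of the scoring equations — an independent code path from the engine.
    """
    spec = spec or SyntheticSpec()
    regions = _region_list(spec)
    ss = np.random.SeedSequence([spec.seed, 1])
    specs = sorted(spec.layer_specs, key=lambda ls: ls.layer_id)
    children = ss.spawn(len(specs) + 4)
    layers = {
        ls.layer_id: _layer_table(spec, ls, regions, child)
        for ls, child in zip(specs, children[: len(specs)])
    }
    stocks = _stock_table(spec, regions, children[-4])
    salmon, escapement = _salmon_tables(spec, children[-3])
    species_risk = _risk_table(spec.n_species, regions, children[-2], "sp", spec.perfect)
    iconic_risk = _risk_table(spec.n_iconic, regions, children[-1], "ico", spec.perfect)
    bundle = StudyBundle(
        regions=regions,
        layers=layers,
        pressure_matrix=_matrix(PRESSURE_BINDINGS),
        resilience_matrix=_matrix(RESILIENCE_BINDINGS),
        stocks=stocks,
        salmon=salmon,
        escapement=escapement,
        species_risk=species_risk,
        iconic_risk=iconic_risk,
    )
    params = GoalParams(herring_reference=spec.herring_reference)
    config = EngineConfig(study_years=spec.years)
    expected = expected_scores(bundle, params, config)
    return bundle, params, config, expected


def write_study(
    out_dir: str | Path,
    spec: SyntheticSpec | None = None,
) -> tuple[StudyBundle, GoalParams, EngineConfig, pd.DataFrame]:
    """Generate a study and write the full input bundle plus
    ``expected_scores.csv`` and a ready-to-run ``config.yaml``."""
    from ..config import write_config

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = spec or SyntheticSpec()
    bundle, params, config, expected = generate_study(spec)
    write_regions(bundle.regions, out / "regions.csv")
    write_layer_bundle(bundle.layers, out / "layers.csv")
    bundle.stocks.to_csv(out / "stocks.csv", index=False)
    bundle.salmon.to_csv(out / "salmon.csv", index=False)
    bundle.escapement.to_csv(out / "escapement.csv", index=False)
    bundle.species_risk.to_csv(out / "species_risk.csv", index=False)
    bundle.iconic_risk.to_csv(out / "iconic_risk.csv", index=False)
    bundle.pressure_matrix.to_csv(out / "pressure_matrix.csv", index=False)
    bundle.resilience_matrix.to_csv(out / "resilience_matrix.csv", index=False)
    expected.to_csv(out / "expected_scores.csv", index=False)
    write_config(out / "config.yaml", params, config)
    return bundle, params, config, expected
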