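"""YAML configuration: engine parameters, goal-model parameters, layer
bindings and input file names, with every default overridable and unknown
keys rejected (fail fast — a typo must not silently fall back)."""

from __future__ import annotations

import copy
import dataclasses
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .engine import StudyBundle
from .goals import HcrParams
from .layers import EngineConfig, read_layer_bundle, read_regions
from .models import DEFAULT_BINDINGS, GoalParams, leaf_goals

__all__ = ["ConfigError", "load_config", "write_config", "load_bundle", "DEFAULT_FILES"]

DEFAULT_FILES: dict[str, str] = {
    "regions": "regions.csv",
    "layers": "layers.csv",
    "stocks": "stocks.csv",
    "salmon": "salmon.csv",
    "escapement": "escapement.csv",
    "species_risk": "species_risk.csv",
    "iconic_risk": "iconic_risk.csv",
    "pressure_matrix": "pressure_matrix.csv",
    "resilience_matrix": "resilience_matrix.csv",
}

_ENGINE_KEYS = {
    "beta", "delta", "trend_window", "trend_clip", "goal_weights",
    "study_years", "status_cap", "study_region_id",
}
_GOAL_KEYS = {
    "hcr", "lsp_target", "herring_reference", "fn_population_floor",
    "risk_weights", "bindings",
}
_HCR_KEYS = {f.name for f in dataclasses.fields(HcrParams)}


class ConfigError(ValueError):
    """Invalid configuration document."""


def _reject_unknown(section: Mapping[str, Any], allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)}")


def load_config(path: str | Path) -> tuple[GoalParams, EngineConfig, dict[str, str]]:
    """Parse and validate a configuration file.

    Returns (goal_params, engine_config, files) with every unspecified
    value at its documented default.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _reject_unknown(doc, {"engine", "goal_params", "files"}, str(path))

    eng = dict(doc.get("engine") or {})
    _reject_unknown(eng, _ENGINE_KEYS, "engine")
    if "study_years" in eng:
        eng["study_years"] = tuple(int(y) for y in eng["study_years"])
    try:
        config = EngineConfig(**eng)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"engine: {exc}") from exc

    gp = dict(doc.get("goal_params") or {})
    _reject_unknown(gp, _GOAL_KEYS, "goal_params")
    hcr_doc = dict(gp.pop("hcr", {}) or {})
    _reject_unknown(hcr_doc, _HCR_KEYS, "goal_params.hcr")
    try:
        hcr = HcrParams(**hcr_doc)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"goal_params.hcr: {exc}") from exc
    bindings = copy.deepcopy(DEFAULT_BINDINGS)
    for goal, b in (gp.pop("bindings", {}) or {}).items():
        if goal not in bindings:
            raise ConfigError(f"bindings: unknown goal {goal!r}")
        merged = dict(bindings[goal])
        merged.update(b or {})
        bindings[goal] = merged
    try:
        params = GoalParams(hcr=hcr, bindings=bindings, **gp)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"goal_params: {exc}") from exc
    for goal in leaf_goals():
        required = set(DEFAULT_BINDINGS.get(goal, {}))
        got = set(params.binding(goal))
        if required - got:
            raise ConfigError(
                f"goal {goal!r}: missing layer bindings {sorted(required - got)}"
            )

    files = dict(DEFAULT_FILES)
    extra = dict(doc.get("files") or {})
    _reject_unknown(extra, set(DEFAULT_FILES), "files")
    files.update({k: str(v) for k, v in extra.items()})
    return params, config, files


def write_config(
    path: str | Path,
    params: GoalParams,
    config: EngineConfig,
    files: Mapping[str, str] | None = None,
) -> None:
    doc = {
        "engine": {
            "beta": config.beta,
            "delta": config.delta,
            "trend_window": config.trend_window,
            "trend_clip": config.trend_clip,
            "goal_weights": dict(config.goal_weights),
            "study_years": list(config.study_years),
            "status_cap": config.status_cap,
            "study_region_id": config.study_region_id,
        },
        "goal_params": {
            "hcr": dataclasses.asdict(params.hcr),
            "lsp_target": params.lsp_target,
            "herring_reference": params.herring_reference,
            "fn_population_floor": params.fn_population_floor,
            "risk_weights": dict(params.risk_weights),
            "bindings": params.bindings,
        },
        "files": dict(files or DEFAULT_FILES),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_bundle(config_path: str | Path) -> tuple[StudyBundle, GoalParams, EngineConfig]:
    """Load the full input bundle named by a configuration file; file
    paths are resolved relative to the configuration's directory."""
    config_path = Path(config_path)
    params, config, files = load_config(config_path)
    base = config_path.parent

    def p(key: str) -> Path:
        return base / files[key]

    for key in ("regions", "layers", "pressure_matrix", "resilience_matrix"):
        if not p(key).exists():
            raise ConfigError(f"required input file missing: {p(key)}")

    def opt_csv(key: str) -> pd.DataFrame | None:
        return pd.read_csv(p(key)) if p(key).exists() else None

    bundle = StudyBundle(
        regions=read_regions(p("regions")),
        layers=read_layer_bundle(p("layers")),
        pressure_matrix=pd.read_csv(p("pressure_matrix")),
        resilience_matrix=pd.read_csv(p("resilience_matrix")),
        stocks=opt_csv("stocks"),
        salmon=opt_csv("salmon"),
        escapement=opt_csv("escapement"),
        species_risk=opt_csv("species_risk"),
        iconic_risk=opt_csv("iconic_risk"),
    )
    return bundle, params, config
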