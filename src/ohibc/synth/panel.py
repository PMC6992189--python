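"""Regression panels with known coefficients for recovery testing.

Builds a goal panel in which the proportional-change response (pressure
or status) equals a linear predictor in the resilience/pressure
components plus region and year fixed effects plus Gaussian noise, by
propagating the responded-to series forward along lag-``lag`` chains.
The generating effects use the same reference-level convention as the
fitted design (first region and first base year pinned to zero), so
noise-free fits recover the truth exactly.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from ..analysis import PANEL_COLUMNS

__all__ = ["generate_panel"]


def generate_panel(
    alpha: float,
    slopes: Mapping[str, float],
    lag: int = 1,
    noise_sd: float = 0.01,
    n_regions: int = 8,
    years: tuple[int, int] = (2001, 2016),
    seed: int = 0,
    goal: str = "FIS",
    response: str = "pressure_change",
    region_effect_sd: float = 0.02,
    year_effect_sd: float = 0.02,
    on_degenerate: str = "error",
) -> tuple[pd.DataFrame, dict]:
    """Panel whose proportional-change response follows a known model.

    ``slopes`` keys: for ``response="pressure_change"`` any of
    {"r_reg", "r_soc"}; for ``response="status_change"`` use {"pressure"}
    (the regressor is p_ecol).  Returns (panel, truth) where truth records
    alpha, slopes, lag and the realized fixed effects.  Trajectories are
    kept bounded away from 0; hitting the floor raises (or regenerates a
    deterministic variant when ``on_degenerate="regenerate"``).
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if response not in {"pressure_change", "status_change"}:
        raise ValueError(f"unknown response {response!r}")
    bad = set(slopes) - ({"r_reg", "r_soc"} if response == "pressure_change" else {"pressure"})
    if bad:
        raise ValueError(f"unknown slope components: {sorted(bad)}")

    first, last = years
    yrs = list(range(first, last + 1))
    rng = np.random.default_rng(seed)
    rids = [f"r{i + 1}" for i in range(n_regions)]

    u = rng.normal(0.0, region_effect_sd, size=n_regions)
    u[0] = 0.0  # reference region
    v = rng.normal(0.0, year_effect_sd, size=len(yrs))
    v[0] = 0.0  # reference base year

    # Component series: region-specific bases with independent annual
    # wiggle so the components are identifiable alongside the year effects.
    def component(base_lo: float, base_hi: float, wiggle: float) -> np.ndarray:
        base = rng.uniform(base_lo, base_hi, size=n_regions)
        vals = base[:, None] + rng.normal(0.0, wiggle, size=(n_regions, len(yrs)))
        return np.clip(vals, 0.05, 0.95)

    r_reg = component(0.3, 0.7, 0.08)
    r_soc = component(0.4, 0.8, 0.08)
    r_ecol = np.full((n_regions, len(yrs)), 0.8)
    p_soc = component(0.2, 0.4, 0.05)

    if response == "pressure_change":
        regressors = {"r_reg": r_reg, "r_soc": r_soc}
        driven_base = rng.uniform(0.45, 0.65, size=n_regions)
    else:
        p_ecol_series = component(0.3, 0.6, 0.06)
        regressors = {"pressure": p_ecol_series}
        driven_base = rng.uniform(0.6, 0.85, size=n_regions)

    driven = np.empty((n_regions, len(yrs)))
    driven[:, :lag] = driven_base[:, None] * np.linspace(1.0, 0.98, lag)[None, :]
    eps = rng.normal(0.0, noise_sd, size=(n_regions, len(yrs)))
    for ti in range(len(yrs) - lag):
        resp = alpha + u[:, None].squeeze(1) + v[ti] + eps[:, ti]
        for name, series in regressors.items():
            resp = resp + slopes.get(name, 0.0) * series[:, ti]
        driven[:, ti + lag] = driven[:, ti] * (1.0 + resp)
    if (driven <= 0.01).any() or (driven > 1.0).any():
        if on_degenerate == "regenerate":
            return generate_panel(
                alpha, slopes, lag, noise_sd, n_regions, years, seed + 10_000,
                goal, response, region_effect_sd, year_effect_sd, on_degenerate,
            )
        raise ValueError("generated trajectory left (0.01, 1]; adjust truth or seed")

    if response == "pressure_change":
        p_ecol = driven
        status = np.clip(
            0.7 + rng.normal(0.0, 0.02, size=(n_regions, len(yrs))), 0.0, 1.0
        )
    else:
        p_ecol = regressors["pressure"]
        status = driven

    rows = []
    for i, rid in enumerate(rids):
        for ti, y in enumerate(yrs):
            rows.append(
                {
                    "region_id": rid, "year": y, "goal": goal,
                    "p_ecol": float(p_ecol[i, ti]), "p_soc": float(p_soc[i, ti]),
                    "r_reg": float(r_reg[i, ti]), "r_ecol": float(r_ecol[i, ti]),
                    "r_soc": float(r_soc[i, ti]), "status": float(status[i, ti]),
                }
            )
    panel = pd.DataFrame(rows, columns=PANEL_COLUMNS)
    truth = {
        "alpha": alpha,
        "slopes": dict(slopes),
        "lag": lag,
        "noise_sd": noise_sd,
        "response": response,
        "region_effects": {rid: float(u[i]) for i, rid in enumerate(rids)},
        "year_effects": {y: float(v[ti]) for ti, y in enumerate(yrs)},
    }
    return panel, truth
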