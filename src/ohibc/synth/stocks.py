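"""Constructed stock sets that hit prescribed harvest-control-rule scores.

Inverts the rising limb of the HCR biomass curve so each assessed stock's
B/B_MSY maps to a chosen score under the given parameters, and draws
catches so the assessed share of total catch equals a prescribed
fraction — making the fisheries status analytically predictable.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from ..goals import MISSING, HcrParams

__all__ = ["generate_stock_set", "bbmsy_for_score"]

STOCK_COLUMNS = [
    "stock_id", "region_id", "year", "catch_t", "bbmsy", "ffmsy", "assessed", "exempt",
]


def bbmsy_for_score(score: float, params: HcrParams = HcrParams()) -> float:
    """A B/B_MSY value scoring ``score`` under the curve (no F factor).

    Uses the rising (overexploitation) limb, where every score in [0, 1]
    is reachable; score 1 maps to the plateau target B/B_MSY = 1.
    """
    if not (0.0 <= score <= 1.0):
        raise ValueError(f"target stock score must be in [0, 1], got {score}")
    if score == 1.0:
        return 1.0
    if score == 0.0:
        return params.b_lo
    return params.b_lo + score * (params.b_ok_lo - params.b_lo)


def generate_stock_set(
    n_assessed: int,
    n_unassessed: int,
    score_targets: Sequence[float],
    seed: int,
    assessed_catch_fraction: float | None = None,
    region_id: str = "r1",
    year: int = 2001,
    params: HcrParams = HcrParams(),
) -> pd.DataFrame:
    """StockRecord table for one region-year with prescribed scores.

    ``score_targets`` gives the HCR score of each assessed stock; when
    unassessed stocks are present, ``assessed_catch_fraction`` fixes the
    assessed share of total catch (the penalty base).
    """
    if n_assessed < 0 or n_unassessed < 0:
        raise ValueError("stock counts must be >= 0")
    if len(score_targets) != n_assessed:
        raise ValueError("score_targets must have one entry per assessed stock")
    rng = np.random.default_rng(seed)
    rows = []
    assessed_catch = rng.uniform(50.0, 150.0, size=n_assessed)
    for i, s in enumerate(score_targets):
        rows.append(
            {
                "stock_id": f"stk_a{i}", "region_id": region_id, "year": year,
                "catch_t": float(assessed_catch[i]),
                "bbmsy": bbmsy_for_score(float(s), params),
                "ffmsy": MISSING, "assessed": True, "exempt": False,
            }
        )
    if n_unassessed:
        if n_assessed:
            if assessed_catch_fraction is None:
                assessed_catch_fraction = 0.5
            if not (0.0 < assessed_catch_fraction <= 1.0):
                raise ValueError("assessed_catch_fraction must be in (0, 1]")
            total_un = float(assessed_catch.sum()) * (
                1.0 - assessed_catch_fraction
            ) / assessed_catch_fraction
            shares = rng.dirichlet(np.ones(n_unassessed)) * total_un
        else:
            shares = rng.uniform(50.0, 150.0, size=n_unassessed)
        for i, c in enumerate(shares):
            rows.append(
                {
                    "stock_id": f"stk_u{i}", "region_id": region_id, "year": year,
                    "catch_t": float(c), "bbmsy": MISSING, "ffmsy": MISSING,
                    "assessed": False, "exempt": False,
                }
            )
    return pd.DataFrame(rows, columns=STOCK_COLUMNS)
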