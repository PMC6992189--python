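"""Independent transcription of the scoring equations for oracle tests.

Computes the expected stage values (status, trend, pressures, resilience,
likely future status, score, and all rollups) for a synthetic bundle with
deliberately plain code — dictionary loops and closed-form arithmetic,
sharing nothing with the engine, goal-model or aggregation modules.
Engine-versus-expectations agreement is therefore a genuine dual-route
check, not a tautology.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

NAN = float("nan")
LOOKBACK = 5


def _isnan(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def _fill(series: dict[int, float], years: list[int]) -> dict[int, float]:
    obs = sorted((y, v) for y, v in series.items() if not _isnan(v))
    if not obs:
        return {}
    xs = [y for y, _ in obs]
    vs = [v for _, v in obs]
    out = dict(obs)
    for y in years:
        if y in out:
            continue
        if y < xs[0]:
            out[y] = vs[0]
        elif y > xs[-1]:
            out[y] = vs[-1]
        else:
            j = max(i for i, x in enumerate(xs) if x <= y)
            x0, x1 = xs[j], xs[j + 1]
            out[y] = vs[j] + (vs[j + 1] - vs[j]) * (y - x0) / (x1 - x0)
    return out


def _slope(pairs: list[tuple[int, float]]) -> float:
    ys = [float(p[0]) for p in pairs]
    vs = [float(p[1]) for p in pairs]
    my, mv = sum(ys) / len(ys), sum(vs) / len(vs)
    num = sum((y - my) * (v - mv) for y, v in zip(ys, vs))
    den = sum((y - my) ** 2 for y in ys)
    return num / den


def _mean(vals) -> float:
    vals = [v for v in vals if not _isnan(v)]
    return sum(vals) / len(vals) if vals else NAN


def _wmean(pairs) -> float:
    pairs = [(v, w) for v, w in pairs if not _isnan(v) and w > 0]
    if not pairs:
        return NAN
    tot = sum(w for _, w in pairs)
    return sum(v * w for v, w in pairs) / tot


def expected_scores(bundle, params, config) -> pd.DataFrame:
    """Long (region_id, year, goal, dimension, value) table of expected
    values for the default goal set, computed independently of the engine."""
    first, last = config.study_years
    years = list(range(first, last + 1))
    grid = list(range(first - LOOKBACK, last + 1))
    rids = [r.region_id for r in bundle.regions]
    areas = {r.region_id: r.area_km2 for r in bundle.regions if r.in_study_aggregate}

    filled: dict[tuple[str, str], dict[int, float]] = {}
    for lid, table in bundle.layers.items():
        frame = table.to_frame()
        for rid in rids:
            sub = frame[frame["region_id"] == rid]
            series = {
                int(y): float(v)
                for y, v in zip(sub["year"], sub["value"])
                if not _isnan(v)
            }
            if series:
                filled[(lid, rid)] = _fill(series, grid)

    def val(lid, rid, y):
        return filled.get((lid, rid), {}).get(y, NAN)

    def nnl(lid, rid, y):
        s = filled.get((lid, rid), {})
        if y not in s:
            return NAN
        hist = [s[y - k] for k in range(1, 6) if (y - k) in s]
        if not hist:
            return NAN
        base = sum(hist) / len(hist)
        if base <= 0:
            return NAN
        return min(s[y] / base, 1.0)

    hcr = params.hcr

    def stock_score(b, f):
        if b <= hcr.b_lo:
            s = 0.0
        elif b < hcr.b_ok_lo:
            s = (b - hcr.b_lo) / (hcr.b_ok_lo - hcr.b_lo)
        elif b <= hcr.b_ok_hi:
            s = 1.0
        elif b < hcr.b_hi:
            s = 1.0 + (hcr.underexploit_floor - 1.0) * (b - hcr.b_ok_hi) / (
                hcr.b_hi - hcr.b_ok_hi
            )
        else:
            s = hcr.underexploit_floor
        if not _isnan(f):
            if f <= hcr.f_band_hi:
                fac = 1.0
            elif f < 2 * hcr.f_band_hi:
                fac = 2.0 - f / hcr.f_band_hi
            else:
                fac = 0.0
            s *= fac
        return min(max(s, 0.0), 1.0)

    # ----- leaf statuses --------------------------------------------------
    status: dict[str, dict[tuple[str, int], float]] = {}

    def hab_extent(goal, rid, y):
        habs = params.binding(goal)["habitats"]
        num = den = 0.0
        for spec in habs.values():
            w = float(spec["weight"])
            if w <= 0:
                continue
            c = val(spec["current"], rid, y)
            r = val(spec["reference"], rid, y)
            if _isnan(c) or _isnan(r):
                return NAN
            num += w * c
            den += w * r
        return min(num / den, 1.0)

    for goal in ("CS", "CP"):
        status[goal] = {(rid, y): hab_extent(goal, rid, y) for rid in rids for y in years}

    b = params.binding("HABS")
    status["HABS"] = {}
    for rid in rids:
        for y in years:
            comps = [hab_extent("HABS", rid, y)]
            for lid in b.get("pressure_layers", []):
                v = val(lid, rid, y)
                comps.append(NAN if _isnan(v) else 1.0 - v)
            status["HABS"][(rid, y)] = _mean(comps)

    status["FIS"] = {(rid, y): NAN for rid in rids for y in years}
    if bundle.stocks is not None:
        for (rid, y), sub in bundle.stocks.groupby(["region_id", "year"]):
            rid, y = str(rid), int(y)
            if rid not in rids or y not in years:
                continue
            rows = sub[~sub["exempt"].astype(bool)]
            a = rows[rows["assessed"].astype(bool)]
            u = rows[~rows["assessed"].astype(bool)]
            wa = float(a["catch_t"].sum())
            if wa <= 0:
                continue
            mean_s = (
                sum(
                    c * stock_score(bb, ff if not pd.isna(ff) else NAN)
                    for c, bb, ff in zip(a["catch_t"], a["bbmsy"], a["ffmsy"])
                )
                / wa
            )
            frac = wa / (wa + float(u["catch_t"].sum()))
            status["FIS"][(rid, y)] = mean_s * frac**hcr.gamma

    bm = params.binding("MAR")
    status["MAR"] = {}
    for rid in rids:
        for y in years:
            ref = val(bm["reference"], rid, y)
            prod = val(bm["production"], rid, y)
            status["MAR"][(rid, y)] = (
                NAN if (_isnan(ref) or _isnan(prod)) else min(prod / ref, 1.0)
            )

    status["SAL"] = {(rid, y): NAN for rid in rids for y in years}
    if bundle.salmon is not None:
        for y, sub in bundle.salmon.groupby("year"):
            y = int(y)
            if y not in years:
                continue
            s = _mean(
                [
                    max(0.0, 1.0 - abs(c - t) / t)
                    for c, t in zip(sub["catch"], sub["target"])
                ]
            )
            for rid in rids:
                status["SAL"][(rid, y)] = s

    bf = params.binding("FNA")
    esc = {}
    if bundle.escapement is not None:
        for y, sub in bundle.escapement.groupby("year"):
            esc[int(y)] = [float(v) for v in sub["escapement_ratio"]]
    status["FNA"] = {}
    for rid in rids:
        hseries = filled.get((bf["herring_index"], rid), {})
        for y in years:
            win = [hseries[k] for k in (y - 2, y - 1, y) if k in hseries]
            herring = (
                min((sum(win) / len(win)) / params.herring_reference, 1.0)
                if win
                else NAN
            )
            cl = val(bf["closure"], rid, y)
            shellfish = NAN if _isnan(cl) else 1.0 - cl
            ratios = esc.get(y, [])
            sal = _mean([min(r, 1.0) for r in ratios]) if ratios else NAN
            lic = val(bf["license"], rid, y)
            pop = val(bf["population"], rid, y)
            licenses = (
                NAN
                if (_isnan(lic) or _isnan(pop))
                else min(lic / max(pop, params.fn_population_floor), 1.0)
            )
            status["FNA"][(rid, y)] = _mean([herring, shellfish, sal, licenses])

    for goal in ("LIV_FN", "LIV_NFN"):
        bl = params.binding(goal)
        status[goal] = {}
        for rid in rids:
            for y in years:
                comps = [nnl(bl["employment"], rid, y), nnl(bl["wages"], rid, y)]
                status[goal][(rid, y)] = _mean(comps)

    bt = params.binding("TR")
    status["TR"] = {(rid, y): nnl(bt["visits"], rid, y) for rid in rids for y in years}

    bl = params.binding("LSP")
    status["LSP"] = {}
    for rid in rids:
        for y in years:
            m = val(bl["marine"], rid, y)
            t = val(bl["land"], rid, y)
            status["LSP"][(rid, y)] = (
                NAN
                if (_isnan(m) or _isnan(t))
                else (min(m / params.lsp_target, 1.0) + min(t / params.lsp_target, 1.0)) / 2.0
            )

    for goal, df in (("SPP", bundle.species_risk), ("ICO", bundle.iconic_risk)):
        per_region = {}
        if df is not None and not df.empty:
            for rid, sub in df.groupby("region_id"):
                chosen = {}
                for r in sub.itertuples():
                    prev = chosen.get(r.species_id)
                    if prev is None or (r.source == "COSEWIC" and prev.source != "COSEWIC"):
                        chosen[r.species_id] = r
                num = den = 0.0
                for r in chosen.values():
                    try:
                        w = float(r.category)
                    except (TypeError, ValueError):
                        w = params.risk_weights[str(r.category)]
                    num += r.area_weight * w
                    den += r.area_weight
                per_region[str(rid)] = 1.0 - num / den
        status[goal] = {
            (rid, y): per_region.get(rid, NAN) for rid in rids for y in years
        }

    bc = params.binding("CW")
    status["CW"] = {}
    for rid in rids:
        for y in years:
            comps = [val(bc[k], rid, y) for k in ("nutrient", "chemical", "pathogen", "debris")]
            if any(_isnan(c) for c in comps):
                status["CW"][(rid, y)] = NAN
            else:
                status["CW"][(rid, y)] = (
                    comps[0] * comps[1] * comps[2] * comps[3]
                ) ** 0.25

    # ----- pressures / resilience / future / score ------------------------
    pm = bundle.pressure_matrix
    rm = bundle.resilience_matrix
    tree = {
        "HAB": ["CS", "CP"], "FP": ["FIS", "MAR", "SAL"], "FNA": [],
        "LIV": ["LIV_FN", "LIV_NFN"], "TR": [], "SP": ["LSP", "ICO"],
        "BD": ["SPP", "HABS"], "CW": [],
    }
    leaves = [g for g, s in tree.items() if not s] + [x for s in tree.values() for x in s]
    window = config.trend_window

    rows = []
    leaf_score: dict[tuple[str, str, int], float] = {}
    for g in leaves:
        psub = pm[(pm["goal"] == g) & (pm["weight"] > 0)]
        rsub = rm[(rm["goal"] == g) & (rm["weight"] > 0)]
        for rid in rids:
            series = {y: status[g][(rid, y)] for y in years}
            for y in years:
                x = series[y]
                pts = [
                    (yy, series[yy])
                    for yy in range(y - window + 1, y + 1)
                    if yy in series and not _isnan(series[yy])
                ]
                if _isnan(x):
                    T = NAN
                elif len(pts) >= 2:
                    start = pts[0][1]
                    T = 0.0 if start == 0 else _slope(pts) * window / start
                    T = min(max(T, -config.trend_clip), config.trend_clip)
                else:
                    T = 0.0
                cat_p = {}
                for cat in ("ecological", "social"):
                    e = psub[psub["category"] == cat]
                    cat_p[cat] = _wmean(
                        [(val(r.layer_id, rid, y), r.weight) for r in e.itertuples()]
                    )
                present = [v for v in cat_p.values() if not _isnan(v)]
                p = _mean(present) if present else 0.0
                cat_r = {}
                for cat in ("regulatory", "ecological", "social"):
                    e = rsub[rsub["category"] == cat]
                    cat_r[cat] = _wmean(
                        [(val(r.layer_id, rid, y), r.weight) for r in e.itertuples()]
                    )
                present_r = [v for v in cat_r.values() if not _isnan(v)]
                r = _mean(present_r) if present_r else 0.0
                r_cap = min(r, p)
                if _isnan(x) or _isnan(T):
                    xf = NAN
                else:
                    xf = (
                        (1.0 / (1.0 + config.delta))
                        * (1.0 + config.beta * T + (1.0 - config.beta) * (r_cap - p))
                        * x
                    )
                    xf = min(max(xf, 0.0), 1.0)
                sc = NAN if (_isnan(x) or _isnan(xf)) else (x + xf) / 2.0
                leaf_score[(g, rid, y)] = sc
                for dim, v in (
                    ("status", x), ("trend", T), ("pressures", p),
                    ("resilience", r_cap), ("future", xf), ("score", sc),
                ):
                    rows.append((rid, y, g, dim, v))

    top: dict[tuple[str, str, int], float] = {}
    for goal, subs in tree.items():
        for rid in rids:
            for y in years:
                if subs:
                    v = _mean([leaf_score[(s, rid, y)] for s in subs])
                    rows.append((rid, y, goal, "score", v))
                else:
                    v = leaf_score[(goal, rid, y)]
                top[(goal, rid, y)] = v

    omega = dict(config.goal_weights)
    index: dict[tuple[str, int], float] = {}
    for rid in rids:
        for y in years:
            index[(rid, y)] = _wmean(
                [(top[(g, rid, y)], omega.get(g, 1.0)) for g in tree]
            )
            rows.append((rid, y, "Index", "score", index[(rid, y)]))

    sid = config.study_region_id
    for y in years:
        for g in leaves:
            rows.append(
                (sid, y, g, "score",
                 _wmean([(leaf_score[(g, rid, y)], areas[rid]) for rid in areas]))
            )
        for goal, subs in tree.items():
            if subs:
                rows.append(
                    (sid, y, goal, "score",
                     _wmean([(top[(goal, rid, y)], areas[rid]) for rid in areas]))
                )
        rows.append(
            (sid, y, "Index", "score",
             _wmean([(index[(rid, y)], areas[rid]) for rid in areas]))
        )

    return pd.DataFrame(
        rows, columns=["region_id", "year", "goal", "dimension", "value"]
    ).sort_values(["goal", "region_id", "year", "dimension"]).reset_index(drop=True)
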