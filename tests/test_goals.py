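"""Goal-model status operations: examples, bounds and monotonicity."""

import math

import numpy as np
import pytest

from ohibc.goals import (
    MISSING,
    HcrParams,
    RiskRecord,
    StockRecord,
    aquaculture_status,
    clean_waters_status,
    fisheries_status,
    fn_access_components,
    fn_access_status,
    goal_trend,
    habitat_status,
    livelihoods_status,
    lsp_status,
    no_net_loss_status,
    pressure_condition_component,
    salmon_status,
    species_status,
    status_ratio,
    stock_score_hcr,
    unassessed_penalty,
)


class TestStatusRatio:
    @pytest.mark.parametrize("x, ref, expected", [(50, 100, 0.5), (120, 100, 1.0), (0, 100, 0.0)])
    def test_ratio_with_cap(self, x, ref, expected):
        assert status_ratio(x, ref) == pytest.approx(expected)

    def test_uncapped_can_exceed_one(self):
        assert status_ratio(120, 100, cap=False) == pytest.approx(1.2)

    def test_nonpositive_reference_is_error(self):
        with pytest.raises(ValueError):
            status_ratio(1.0, 0.0)


class TestNoNetLoss:
    def test_first_year_of_truncated_series_scores_one(self):
        # NOCB extension makes the prior five years equal the current value.
        assert no_net_loss_status(42.0, [42.0] * 5) == 1.0

    @pytest.mark.parametrize("v, expected", [(90.0, 0.9), (110.0, 1.0), (100.0, 1.0)])
    def test_against_prior_five_year_mean(self, v, expected):
        assert no_net_loss_status(v, [100.0] * 5) == pytest.approx(expected)

    def test_degenerate_zero_baseline_is_error(self):
        with pytest.raises(ValueError):
            no_net_loss_status(5.0, [0.0] * 5)

    def test_monotone_in_current_value(self):
        hist = [80.0, 90, 100, 110, 120]
        vals = [no_net_loss_status(v, hist) for v in np.linspace(0, 200, 25)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert all(0 <= v <= 1 for v in vals)


class TestLivelihoods:
    def test_both_components_at_their_means(self):
        assert livelihoods_status(0.6, [0.6] * 5, 25.0, [25.0] * 5) == 1.0

    def test_mean_of_components(self):
        # employment 0.8, wages 1.0
        assert livelihoods_status(0.48, [0.6] * 5, 26.0, [25.0] * 5) == pytest.approx(0.9)

    def test_missing_wage_series_renormalizes_to_employment(self):
        got = livelihoods_status(0.48, [0.6] * 5, MISSING, [])
        assert got == pytest.approx(0.8)  # hand average over the one component

    def test_both_missing_gives_missing(self):
        assert math.isnan(livelihoods_status(MISSING, [], MISSING, []))


class TestHarvestControlRule:
    @pytest.mark.parametrize(
        "bbmsy, ffmsy, expected",
        [
            (1.0, 1.0, 1.0),  # the reference target
            (0.05, MISSING, 0.0),  # collapse breakpoint
            (0.425, MISSING, 0.5),  # midpoint of the rising limb
            (0.8, MISSING, 1.0),
            (1.5, MISSING, 1.0),
            (3.0, MISSING, 0.25),  # underexploitation floor
            (5.0, MISSING, 0.25),
            (1.0, 1.2, 1.0),  # F inside the tolerance band
            (1.0, 1.8, 0.5),  # halfway down the F penalty
            (1.0, 2.4, 0.0),
        ],
    )
    def test_default_curve_values(self, bbmsy, ffmsy, expected):
        assert stock_score_hcr(bbmsy, ffmsy) == pytest.approx(expected)

    def test_plateau_is_exactly_one(self):
        for b in np.linspace(0.8, 1.5, 50):
            assert stock_score_hcr(b) == 1.0

    def test_curve_is_continuous_on_dense_grid(self):
        grid = np.linspace(0.0, 4.0, 4001)
        vals = np.array([stock_score_hcr(b) for b in grid])
        assert np.abs(np.diff(vals)).max() < 2e-3  # max slope 4/3 per unit B
        assert ((vals >= 0) & (vals <= 1)).all()

    def test_missing_bbmsy_and_negatives_rejected(self):
        with pytest.raises(ValueError):
            stock_score_hcr(MISSING)
        with pytest.raises(ValueError):
            stock_score_hcr(-0.1)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            HcrParams(b_lo=0.9, b_ok_lo=0.8)


class TestFisheries:
    def _stock(self, sid, catch, bbmsy=MISSING, assessed=False, exempt=False):
        return StockRecord(sid, "r1", 2001, catch, bbmsy=bbmsy, assessed=assessed,
                           exempt=exempt)

    @pytest.mark.parametrize("frac, gamma, expected", [(1, 1, 1), (0, 1, 0), (0.5, 1, 0.5), (0.25, 0.5, 0.5)])
    def test_unassessed_penalty(self, frac, gamma, expected):
        assert unassessed_penalty(frac, gamma) == pytest.approx(expected)

    def test_penalty_rejects_out_of_range_fraction(self):
        with pytest.raises(ValueError):
            unassessed_penalty(1.2)

    def test_single_perfect_stock(self):
        s = [self._stock("a", 100, bbmsy=1.0, assessed=True)]
        assert fisheries_status(s) == 1.0

    def test_catch_weighted_mean(self):
        s = [
            self._stock("a", 75, bbmsy=1.0, assessed=True),  # score 1.0
            self._stock("b", 25, bbmsy=0.425, assessed=True),  # score 0.5
        ]
        assert fisheries_status(s) == pytest.approx(0.875)

    def test_unassessed_catch_applies_penalty(self):
        s = [
            self._stock("a", 50, bbmsy=1.0, assessed=True),
            self._stock("b", 50),  # unassessed, same catch
        ]
        assert fisheries_status(s) == pytest.approx(0.5)

    def test_exempt_stocks_neither_scored_nor_penalized(self):
        s = [
            self._stock("a", 50, bbmsy=1.0, assessed=True),
            self._stock("x", 500, exempt=True),
        ]
        assert fisheries_status(s) == 1.0

    def test_all_catch_unassessed_gives_missing(self):
        assert math.isnan(fisheries_status([self._stock("b", 100)]))

    def test_equal_scores_with_all_assessed_returns_that_score(self):
        s = [self._stock(f"s{i}", 10 * (i + 1), bbmsy=0.425, assessed=True) for i in range(4)]
        assert fisheries_status(s) == pytest.approx(0.5)


class TestAquacultureAndSalmon:
    @pytest.mark.parametrize("prod, ref, expected", [(100, 100, 1.0), (200, 100, 1.0), (50, 100, 0.5)])
    def test_production_against_potential(self, prod, ref, expected):
        assert aquaculture_status(prod, ref) == pytest.approx(expected)

    def test_no_tenures_means_no_score(self):
        assert math.isnan(aquaculture_status(0.0, 1.0, has_tenures=False))

    def test_bad_reference_with_tenures_is_error(self):
        with pytest.raises(ValueError):
            aquaculture_status(10.0, 0.0)

    @pytest.mark.parametrize(
        "pairs, expected",
        [
            ([(100, 100), (50, 50)], 1.0),  # all stocks at target
            ([(0, 100)], 0.0),
            ([(150, 100)], 0.5),  # symmetric overshoot penalty
            ([(100, 100), (150, 100)], 0.75),
        ],
    )
    def test_salmon_indicator_scores(self, pairs, expected):
        assert salmon_status(pairs) == pytest.approx(expected)

    def test_no_indicator_stocks_gives_missing(self):
        assert math.isnan(salmon_status([]))


class TestFirstNationsAccess:
    def test_component_examples(self):
        comps = fn_access_components(
            herring_index_series={2004: 1.0, 2005: 1.0, 2006: 1.0},
            herring_reference=1.0,
            year=2006,
            closure_fraction=0.0,
            escapement_ratios=[1.2, 0.8],
            license_fraction=0.10,
            population_fraction=0.20,
        )
        assert comps["herring"] == pytest.approx(1.0)
        assert comps["shellfish"] == pytest.approx(1.0)
        assert comps["salmon"] == pytest.approx(0.9)  # mean(min(1.2,1), 0.8)
        assert comps["licenses"] == pytest.approx(0.5)  # 0.10 / 0.20
        assert fn_access_status(comps) == pytest.approx((1 + 1 + 0.9 + 0.5) / 4)

    def test_population_floor_applies(self):
        comps = fn_access_components({}, 1.0, 2001, 0.0, [], 0.12, 0.05)
        assert comps["licenses"] == pytest.approx(0.12 / 0.15)

    def test_missing_components_renormalize(self):
        comps = {"herring": MISSING, "shellfish": 0.8, "salmon": MISSING, "licenses": 0.6}
        assert fn_access_status(comps) == pytest.approx(0.7)

    def test_bad_herring_reference_is_error(self):
        with pytest.raises(ValueError):
            fn_access_components({}, 0.0, 2001, 0.0, [], 0.1, 0.1)


class TestPlacesSpeciesHabitats:
    @pytest.mark.parametrize(
        "m, l, expected", [(0.30, 0.30, 1.0), (0.15, 0.30, 0.75), (0.60, 0.00, 0.5)]
    )
    def test_protected_area_against_30pct_target(self, m, l, expected):
        assert lsp_status(m, l) == pytest.approx(expected)

    def test_species_all_least_concern_scores_one(self):
        recs = [RiskRecord(f"s{i}", "r1", "LC") for i in range(5)]
        assert species_status(recs) == 1.0

    def test_species_all_extinct_scores_zero(self):
        recs = [RiskRecord(f"s{i}", "r1", "EX") for i in range(5)]
        assert species_status(recs) == 0.0

    def test_species_half_lc_half_en(self):
        recs = [RiskRecord("a", "r1", "LC"), RiskRecord("b", "r1", "EN")]
        assert species_status(recs) == pytest.approx(0.7)  # 1 - mean(0, 0.6)

    def test_cosewic_supersedes_iucn(self):
        recs = [
            RiskRecord("a", "r1", "EN", source="IUCN"),
            RiskRecord("a", "r1", "LC", source="COSEWIC"),
        ]
        assert species_status(recs) == 1.0

    def test_species_monotone_in_risk(self):
        lo = species_status([RiskRecord("a", "r1", "NT")])
        hi = species_status([RiskRecord("a", "r1", "CR")])
        assert lo > hi

    def test_habitat_extent_examples(self):
        assert habitat_status({"a": 10.0}, {"a": 10.0}, {"a": 1.0}) == 1.0
        # two habitats, equal weight and reference, one halved
        got = habitat_status({"a": 10.0, "b": 5.0}, {"a": 10.0, "b": 10.0},
                             {"a": 1.0, "b": 1.0})
        assert got == pytest.approx(0.75)

    def test_habitat_all_zero_weights_is_error(self):
        with pytest.raises(ValueError):
            habitat_status({"a": 1.0}, {"a": 1.0}, {"a": 0.0})

    @pytest.mark.parametrize("x, expected", [(0.0, 1.0), (1.0, 0.0), (0.5, 0.5)])
    def test_trawl_pressure_condition(self, x, expected):
        assert pressure_condition_component(x) == pytest.approx(expected)


class TestCleanWaters:
    def test_geometric_mean_examples(self):
        assert clean_waters_status(1, 1, 1, 1) == 1.0
        assert clean_waters_status(0.9, 0.8, 0.7, 0.0) == 0.0
        assert clean_waters_status(0.9, 0.8, 0.7, 0.6) == pytest.approx(0.3024**0.25)

    def test_missing_component_gives_missing(self):
        assert math.isnan(clean_waters_status(0.9, MISSING, 0.7, 0.6))

    def test_geometric_below_arithmetic_mean(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            c = rng.uniform(0.01, 1.0, 4)
            gm = clean_waters_status(*c)
            assert gm <= np.mean(c) + 1e-12
        assert clean_waters_status(0.4, 0.4, 0.4, 0.4) == pytest.approx(0.4)

    def test_monotone_in_every_component(self):
        base = clean_waters_status(0.5, 0.5, 0.5, 0.5)
        for i in range(4):
            c = [0.5] * 4
            c[i] = 0.9
            assert clean_waters_status(*c) > base


class TestGoalTrend:
    def test_flat_series_has_zero_trend(self):
        s = {y: 0.6 for y in range(2001, 2006)}
        assert goal_trend(s, 2005) == pytest.approx(0.0)

    def test_linear_rise_proportional_change(self):
        s = {2001 + i: 0.50 + 0.05 * i for i in range(5)}
        # slope 0.05/yr x 5 yr / 0.50 start
        assert goal_trend(s, 2005) == pytest.approx(0.5)

    def test_steep_decline_clips_at_minus_one(self):
        s = {2001 + i: max(1.0 - 0.4 * i, 0.01) for i in range(5)}
        assert goal_trend(s, 2005) == -1.0

    def test_scale_invariance(self):
        s = {2001 + i: 0.2 + 0.03 * i for i in range(5)}
        t1 = goal_trend(s, 2005)
        t2 = goal_trend({y: 3.7 * v for y, v in s.items()}, 2005)
        assert t1 == pytest.approx(t2)

    def test_fewer_than_two_points_is_error(self):
        with pytest.raises(ValueError):
            goal_trend({2005: 0.5}, 2005)

    def test_zero_start_gives_zero_trend(self):
        s = {2001: 0.0, 2002: 0.1, 2003: 0.2}
        assert goal_trend(s, 2003) == 0.0
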