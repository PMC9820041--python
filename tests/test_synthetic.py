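"""Synthetic scenario generator: planted truth must be recoverable."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from activitygrid import (ScenarioConfig, bin_points_to_cells,
                          change_table, classify_table, generate_attributes,
                          generate_intensity, generate_pois,
                          generate_scenario, plant_labels, window_sum,
                          WindowPolicy)
from activitygrid.change import PERIODS
from activitygrid.taxonomy import CategoryTaxonomy


def _gdp_only_effects(coef=-12.0):
    return {p: {"intercept": -20.0, "gdp": coef} for p in PERIODS}


class TestDeterminism:
    def test_regeneration_is_bit_identical(self):
        cfg = ScenarioConfig(n_rows=6, n_cols=6, seed=123)
        a, b = generate_scenario(cfg), generate_scenario(cfg)
        pd.testing.assert_frame_equal(a.pois, b.pois)
        pd.testing.assert_frame_equal(a.intensity, b.intensity)
        pd.testing.assert_frame_equal(a.truth.attributes,
                                      b.truth.attributes)
        pd.testing.assert_series_equal(a.truth.labels, b.truth.labels)

    def test_stages_reseed_independently(self):
        # regenerating POIs alone matches the full-scenario POIs
        cfg = ScenarioConfig(n_rows=6, n_cols=6, seed=77)
        full = generate_scenario(cfg)
        truth = plant_labels(cfg)
        pois, _ = generate_pois(cfg, truth)
        pd.testing.assert_frame_equal(pois, full.pois)


class TestGeneratePois:
    def test_full_dominance_draws_only_planted_class(self):
        tax = CategoryTaxonomy()
        cfg = ScenarioConfig(n_rows=5, n_cols=5, seed=2, dominance=1.0,
                             pois_per_cell=100.0,
                             label_mix={"residential": 1.0})
        pois, truth = generate_pois(cfg)
        assert set(pois["category"]) <= set(tax.classes["residential"])

    def test_mixed_profile_cells_stay_below_dominance(self):
        # equal expected shares: classified shares each < 50% almost always
        cfg = ScenarioConfig(n_rows=25, n_cols=40, seed=1,
                             pois_per_cell=100.0,
                             label_mix={"mixed": 1.0})
        pois, truth = generate_pois(cfg)
        counts, _ = bin_points_to_cells(pois, cfg.grid)
        out = classify_table(counts)
        shares = out[["C_res", "C_work", "C_ent"]].to_numpy()
        frac_all_below = ((shares < 50.0).all(axis=1)).mean()
        assert frac_all_below >= 0.99

    def test_unknown_category_in_weights_rejected(self):
        with pytest.raises(ValueError, match="unknown categories"):
            generate_pois(ScenarioConfig(
                n_rows=2, n_cols=2,
                category_weights={"Bowling alley": 1.0}))

    def test_zero_poi_request_rejected(self):
        with pytest.raises(ValueError, match="zero total POIs"):
            ScenarioConfig(pois_per_cell=0.0)

    def test_national_class_totals_positive(self, small_scenario):
        tax = CategoryTaxonomy()
        by_cat = small_scenario.pois["category"].value_counts()
        for cls, cats in tax.classes.items():
            assert sum(by_cat.get(c, 0) for c in cats) > 0


class TestGenerateIntensity:
    def _truth_with_rates(self, cfg, rates):
        truth = plant_labels(cfg)
        n = cfg.grid.n_cells
        truth.change_rates = pd.DataFrame(
            {p: np.full(n, r) for p, r in zip(PERIODS, rates)},
            index=truth.labels.index)
        return truth

    def test_zero_rates_zero_noise_reproduce_baseline_sums(self):
        cfg = ScenarioConfig(n_rows=4, n_cols=4, seed=5, noise_sd=0.0)
        truth = self._truth_with_rates(cfg, (0.0, 0.0, 0.0))
        intensity = generate_intensity(cfg, truth)
        policy = WindowPolicy()
        for cid in range(cfg.grid.n_cells):
            label = truth.labels[cid]
            days = intensity[intensity["cell_id"] == cid]
            bins = days.filter(like="bin_").to_numpy()
            sums = window_sum(bins, policy, label)
            np.testing.assert_allclose(sums, sums[0])

    def test_planted_minus_25_scales_window_sum_to_three_quarters(self):
        cfg = ScenarioConfig(n_rows=3, n_cols=3, seed=5, noise_sd=0.0)
        truth = self._truth_with_rates(cfg, (-25.0, 0.0, 0.0))
        intensity = generate_intensity(cfg, truth)
        policy = WindowPolicy()
        cid = 0
        label = truth.labels[cid]
        days = intensity[intensity["cell_id"] == cid]
        bins = days.filter(like="bin_").to_numpy()
        sums = window_sum(bins, policy, label)
        assert np.isclose(sums[1], 0.75 * sums[0])

    def test_all_bins_nonnegative(self, small_scenario):
        bins = small_scenario.intensity.filter(like="bin_").to_numpy()
        assert (bins >= 0).all()

    def test_rate_below_minus_100_rejected(self):
        cfg = ScenarioConfig(n_rows=3, n_cols=3, seed=5)
        truth = self._truth_with_rates(cfg, (-150.0, 0.0, 0.0))
        with pytest.raises(ValueError, match="-100"):
            generate_intensity(cfg, truth)

    def test_noise_sd_controls_realized_rate_spread(self):
        cfg = ScenarioConfig(n_rows=25, n_cols=40, seed=7, noise_sd=0.05)
        scenario = generate_scenario(cfg)
        changes = change_table(scenario.intensity, scenario.truth.labels)
        dev = (changes["period1"]
               - scenario.truth.change_rates["period1"]) / 100.0
        assert 0.05 * 0.8 <= dev.std() <= 0.05 * 1.2


class TestGenerateAttributes:
    def test_gdp_only_effect_is_rank_monotone(self):
        cfg = ScenarioConfig(n_rows=10, n_cols=10, seed=3,
                             effect_spec=_gdp_only_effects(), noise_sd=0.0)
        truth = generate_attributes(cfg, plant_labels(cfg))
        rho = stats.spearmanr(truth.attributes["gdp"],
                              truth.change_rates["period1"]).statistic
        assert abs(rho) >= 0.9

    def test_zero_effects_give_constant_rates(self):
        cfg = ScenarioConfig(n_rows=5, n_cols=5, seed=3,
                             effect_spec={p: {"intercept": -10.0}
                                          for p in PERIODS})
        truth = generate_attributes(cfg, plant_labels(cfg))
        assert (truth.change_rates.nunique() == 1).all()
        assert (truth.change_rates.iloc[0] == -10.0).all()

    def test_attribute_types_and_ranges(self, small_scenario):
        attrs = small_scenario.truth.attributes
        assert set(attrs["urban_rural"].unique()) <= {0, 1}
        assert set(attrs["admin_level"].unique()) <= {1, 2, 3, 4}
        cont = ["gdp", "population_density", "built_up_area",
                "bus_stop_density", "junction_density", "cumulative_cases"]
        assert (attrs[cont] >= 0).all().all()

    def test_unknown_effect_attribute_rejected(self):
        cfg = ScenarioConfig(n_rows=3, n_cols=3,
                             effect_spec={"period1": {"night_lights": 1.0}})
        with pytest.raises(ValueError, match="unknown"):
            generate_attributes(cfg, plant_labels(cfg))

    def test_cases_constant_within_city(self, small_scenario):
        attrs = small_scenario.truth.attributes
        assert (attrs.groupby("city_id")["cumulative_cases"]
                .nunique() == 1).all()


class TestPlantedRecovery:
    def test_labels_recovered_at_moderate_dominance(self):
        cfg = ScenarioConfig(n_rows=25, n_cols=40, seed=19, dominance=0.6)
        s = generate_scenario(cfg)
        counts, _ = bin_points_to_cells(s.pois, s.grid)
        got = classify_table(counts)["label"]
        pure = s.truth.labels.isin(
            ["residential", "working", "entertainment"])
        rate = (got[pure] == s.truth.labels[pure]).mean()
        assert rate >= 0.95

    def test_realized_rates_converge_to_planted_as_noise_vanishes(self):
        devs = []
        for sd in (0.1, 0.01, 0.001):
            cfg = ScenarioConfig(n_rows=8, n_cols=8, seed=13, noise_sd=sd)
            s = generate_scenario(cfg)
            changes = change_table(s.intensity, s.truth.labels)
            devs.append((changes["period2"]
                         - s.truth.change_rates["period2"]).abs().mean())
        assert devs[0] > devs[1] > devs[2]
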