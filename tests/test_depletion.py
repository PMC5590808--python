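"""Consumption-extrapolation depletion arithmetic and the life-history
vulnerability rules."""

import math

import pytest
from hypothesis import given, settings, strategies as st

import shellforage as sf
from shellforage.depletion import round_half_up
from shellforage.domain import ValidationError


def profile(island=sf.Island.KORAM, shoreline=1551.0, users=26, strip=3.0):
    return sf.IslandProfile(island, users, shoreline, strip)


class TestForagingGeometry:
    def test_area_is_shoreline_times_strip(self):
        assert sf.foraging_area(profile(shoreline=1551.0)) == 4653.0
        assert sf.foraging_area(profile(shoreline=653.0)) == 1959.0
        assert sf.foraging_area(profile(shoreline=0.0)) == 0.0

    def test_shoreline_per_user_rounds_half_up(self):
        assert sf.shoreline_per_user(profile(shoreline=653.0, users=4)) == 163.3
        assert sf.shoreline_per_user(profile(shoreline=1551.0, users=28)) == 55.4
        assert sf.shoreline_per_user(profile(shoreline=500.0, users=1)) == 500.0

    @given(scale=st.floats(0.1, 10.0))
    @settings(max_examples=30, deadline=None)
    def test_area_homogeneous_in_shoreline(self, scale):
        base = sf.foraging_area(profile(shoreline=100.0))
        assert sf.foraging_area(profile(shoreline=100.0 * scale)) == (
            pytest.approx(base * scale)
        )


class TestStandingPopulation:
    def test_observed_densities_scale_to_standing_stock(self, observed_transects):
        koram = [p for p in observed_transects if p.island is sf.Island.KORAM]
        nomsao = [p for p in observed_transects if p.island is sf.Island.NOMSAO]
        # 181/14 -> 12.93 /m2; 12.93 x 4653 -> 60163
        assert sf.transect_density(koram, sf.Taxon.P_SULCATUS) == 12.93
        assert sf.standing_population(koram, sf.Taxon.P_SULCATUS, 4653.0) == 60163
        # 568/14 -> 40.57 /m2; 40.57 x 1959 -> 79477
        assert sf.standing_population(nomsao, sf.Taxon.P_SULCATUS, 1959.0) == 79477

    def test_zero_counts_give_zero_population(self):
        plots = [
            sf.SnailTransectPlot(sf.Island.KORAM, i + 1, {sf.Taxon.P_SULCATUS: 0})
            for i in range(14)
        ]
        assert sf.standing_population(plots, sf.Taxon.P_SULCATUS, 4653.0) == 0

    def test_no_plots_rejected(self):
        with pytest.raises(ValidationError):
            sf.standing_population([], sf.Taxon.P_SULCATUS, 100.0)


class TestAnnualConsumption:
    def test_daily_total_basis(self, scenario):
        _, rates = scenario
        annual = sf.annual_consumption(rates, 26, "daily_total")
        assert annual == pytest.approx(46.5 * 26 * 365)
        rounded = sf.annual_consumption(rates, 26, "daily_total",
                                        report_rounding="nearest_thousand")
        assert rounded == 441000.0

    def test_hourly_periwinkle_basis(self, scenario):
        _, rates = scenario
        assert sf.annual_consumption(rates, 4, "hourly_periwinkle") == 9344.0
        assert sf.annual_consumption(rates, 0, "hourly_periwinkle") == 0.0

    def test_unknown_basis_rejected(self, scenario):
        _, rates = scenario
        with pytest.raises(ValueError):
            sf.annual_consumption(rates, 4, "weekly")

    @given(users=st.integers(0, 100))
    @settings(max_examples=30, deadline=None)
    def test_linear_in_users(self, users, scenario):
        _, rates = scenario
        per_user = sf.annual_consumption(rates, 1, "hourly_periwinkle")
        assert sf.annual_consumption(rates, users, "hourly_periwinkle") == (
            pytest.approx(per_user * users)
        )


class TestDepletionAssessment:
    def test_ratio_times_standing_equals_annual(self):
        est = sf.depletion_assessment(60163, 60736.0)
        assert est.depletion_ratio * est.standing_population == pytest.approx(
            est.annual_consumption
        )
        assert est.depleted_within_year
        assert est.years_to_depletion == pytest.approx(1 / est.depletion_ratio)

    def test_sparse_island_ratio_is_about_a_tenth(self):
        est = sf.depletion_assessment(79477, 9344.0)
        assert est.depletion_ratio == pytest.approx(0.1176, abs=1e-3)
        assert not est.depleted_within_year

    def test_degenerate_cases_encoded_as_infinities(self):
        assert sf.depletion_assessment(1000, 0.0).years_to_depletion == math.inf
        assert sf.depletion_assessment(0, 5.0).depletion_ratio == math.inf

    def test_full_island_pipeline(self, scenario, observed_transects):
        profiles, rates = scenario
        est = sf.island_depletion(
            profiles[sf.Island.KORAM], rates, observed_transects
        )
        assert est.foraging_area_m2 == 4653.0
        assert est.standing_population == 60163
        assert est.annual_consumption == pytest.approx(60736.0)
        assert est.depletion_ratio > 1.0


class TestUndersizeFraction:
    def test_direct_count(self):
        sizes = [
            sf.SizeRecord(sf.Island.KORAM, sf.Taxon.P_SULCATUS, float(v), 5.0)
            for v in (1, 2, 3, 4)
        ]
        frac, n = sf.undersize_fraction(sizes, 2.5)
        assert (frac, n) == (0.5, 4)

    def test_zero_threshold_gives_zero_fraction(self):
        sizes = [sf.SizeRecord(sf.Island.KORAM, sf.Taxon.P_SULCATUS, 3.0, 2.0)]
        assert sf.undersize_fraction(sizes, 0.0) == (0.0, 1)

    def test_none_undersized_when_all_above_threshold(self):
        """All measured individuals at or above reproductive size -> 0%."""
        sizes = [
            sf.SizeRecord(sf.Island.NOMSAO, sf.Taxon.P_SULCATUS, 17.44 + i, 5.0)
            for i in range(100)
        ]
        frac, n = sf.undersize_fraction(sizes, 17.44)
        assert (frac, n) == (0.0, 100)

    @given(t1=st.floats(0.0, 10.0), t2=st.floats(0.0, 10.0))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_threshold(self, t1, t2):
        sizes = [
            sf.SizeRecord(sf.Island.KORAM, sf.Taxon.P_SULCATUS, float(v))
            for v in (1, 2, 5, 7, 9)
        ]
        lo, hi = sorted((t1, t2))
        assert sf.undersize_fraction(sizes, lo)[0] <= (
            sf.undersize_fraction(sizes, hi)[0]
        )


class TestVulnerability:
    def test_rock_oyster_predictions(self):
        va = sf.assess_vulnerability(sf.ROCK_OYSTER_PROFILE)
        assert va.predictions == {
            "aggregation": "slow_recovery",
            "size_at_maturity": "slow_recovery",
            "reproductive_output": "fast_recovery",
            "larval_mode": "fast_recovery",
        }
        assert va.summary == "mixed"

    def test_periwinkle_predictions(self):
        va = sf.assess_vulnerability(sf.PERIWINKLE_PROFILE)
        assert va.predictions == {
            "aggregation": "slow_recovery",
            "size_at_maturity": "fast_recovery",
            "reproductive_output": "slow_recovery",
            "larval_mode": "fast_recovery",
        }
        assert va.summary == "mixed"

    def test_all_fast_profile_is_resilient(self):
        lh = sf.LifeHistoryProfile(
            sf.Taxon.C_BIFASCIATUS, "low", "small", "high", "planktonic"
        )
        assert sf.assess_vulnerability(lh).summary == "resilient"

    def test_all_slow_profile_is_vulnerable(self):
        lh = sf.LifeHistoryProfile(
            sf.Taxon.C_BIFASCIATUS, "high", "large", "low", "attached"
        )
        assert sf.assess_vulnerability(lh).summary == "vulnerable"


class TestGroupArithmetic:
    def test_tool_user_percentage(self):
        assert sf.tool_user_percentage(25, 36) == 69.4
        assert sf.tool_user_percentage(3, 14) == 21.4

    def test_population_density(self):
        assert sf.population_density_per_km2(9, 0.10) == 90.0
        assert sf.population_density_per_km2(64, 0.45) == 142.0

    def test_half_up_rounding_convention(self):
        assert round_half_up(163.25, 1) == 163.3
        assert round_half_up(12.925, 2) == 12.93
        assert round_half_up(0.5) == 1.0
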