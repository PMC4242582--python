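"""Wintering-cost model: allometry, heat loss, distances, migration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from limosa import datasets
from limosa.energetics import (
    BREEDING_SITE,
    FEMALE,
    MALE,
    ClimateConditions,
    EnergeticsConfig,
    HeatLossCoefficients,
    Site,
    basal_metabolic_rate,
    cost_table,
    great_circle_distance,
    maintenance_cost,
    migration_cost,
    standardized_heat_loss,
    wintering_cost,
)

COEFFS = HeatLossCoefficients()


class TestBasalMetabolicRate:
    @pytest.mark.parametrize(
        "mass, expected",
        [(0.270, 1.9481154960792921), (0.323, 2.2200315967445374)],
    )
    def test_allometric_values(self, mass, expected):
        # frozen from 5.06 * BM**0.729 evaluated by hand
        assert basal_metabolic_rate(mass) == pytest.approx(expected, rel=1e-12)

    def test_mass_specific_rate_declines_with_mass(self):
        assert (
            basal_metabolic_rate(0.323) / 0.323 < basal_metabolic_rate(0.270) / 0.270
        )

    @given(st.floats(min_value=0.1, max_value=0.99))
    @settings(max_examples=50, derandomize=True)
    def test_monotone_but_sublinear(self, mass):
        bigger = mass + 0.01
        assert basal_metabolic_rate(bigger) > basal_metabolic_rate(mass)
        assert (
            basal_metabolic_rate(bigger) / bigger < basal_metabolic_rate(mass) / mass
        )

    def test_rejects_nonpositive_mass(self):
        with pytest.raises(ValueError):
            basal_metabolic_rate(0.0)


class TestStandardizedHeatLoss:
    def test_zero_at_thermoneutral_still_air(self):
        climate = ClimateConditions(41.0, 0.0, 0.0)
        assert standardized_heat_loss(FEMALE, COEFFS, climate) == 0.0

    def test_worked_value_female_freezing(self):
        # 0.1111*41 + 0.2*sqrt(6) - 0.01*50, each term checked by hand
        climate = ClimateConditions(0.0, 6.0, 50.0)
        assert standardized_heat_loss(FEMALE, COEFFS, climate) == pytest.approx(
            4.544997948556636, rel=1e-12
        )

    def test_monotonicities(self):
        ref = ClimateConditions(0.0, 6.0, 50.0)
        h = standardized_heat_loss(FEMALE, COEFFS, ref)
        assert h > standardized_heat_loss(FEMALE, COEFFS, ClimateConditions(7.0, 6.0, 50.0))
        assert h <= standardized_heat_loss(FEMALE, COEFFS, ClimateConditions(0.0, 9.0, 50.0))
        assert h >= standardized_heat_loss(FEMALE, COEFFS, ClimateConditions(0.0, 6.0, 80.0))

    def test_never_negative(self):
        warm = ClimateConditions(40.9, 0.0, 500.0)
        assert standardized_heat_loss(MALE, COEFFS, warm) == 0.0

    def test_scales_with_conductance(self):
        climate = ClimateConditions(0.0, 0.0, 0.0)
        h_m = standardized_heat_loss(MALE, COEFFS, climate)
        h_f = standardized_heat_loss(FEMALE, COEFFS, climate)
        assert h_f / h_m == pytest.approx(
            FEMALE.thermal_conductance / MALE.thermal_conductance, rel=1e-12
        )


class TestMaintenance:
    def test_additivity_and_thermoneutral_limit(self):
        assert maintenance_cost(2.0, 3.0) == 5.0
        assert maintenance_cost(2.0, 0.0) == 2.0

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            maintenance_cost(-1.0, 0.0)


class TestGreatCircle:
    def test_zero_iff_identical(self):
        assert great_circle_distance(55.0, 8.0, 55.0, 8.0) == 0.0
        assert great_circle_distance(55.0, 8.0, 55.0, 8.1) > 0.0

    def test_sylt_to_breeding_grounds(self):
        lat, lon = datasets.SITE_COORDS["Sylt-Romo Wadden Sea"]
        d = great_circle_distance(lat, lon, *BREEDING_SITE)
        assert d == pytest.approx(1861.6, abs=0.5)

    def test_antipodal_maximum(self):
        d = great_circle_distance(0.0, 0.0, 0.0, 180.0)
        assert d == pytest.approx(np.pi * 6371.0, rel=1e-9)

    def test_symmetric(self, rng):
        a = rng.uniform([-90, -180], [90, 180], size=(20, 2))
        b = rng.uniform([-90, -180], [90, 180], size=(20, 2))
        d1 = great_circle_distance(a[:, 0], a[:, 1], b[:, 0], b[:, 1])
        d2 = great_circle_distance(b[:, 0], b[:, 1], a[:, 0], a[:, 1])
        np.testing.assert_allclose(d1, d2, rtol=1e-12)

    def test_agrees_with_law_of_cosines_oracle(self, rng):
        a = rng.uniform([-85, -180], [85, 180], size=(1000, 2))
        b = rng.uniform([-85, -180], [85, 180], size=(1000, 2))
        d_hav = great_circle_distance(a[:, 0], a[:, 1], b[:, 0], b[:, 1])
        p1, p2 = np.radians(a[:, 0]), np.radians(b[:, 0])
        dlam = np.radians(b[:, 1] - a[:, 1])
        cosang = np.sin(p1) * np.sin(p2) + np.cos(p1) * np.cos(p2) * np.cos(dlam)
        d_slc = 6371.0 * np.arccos(np.clip(cosang, -1.0, 1.0))
        np.testing.assert_allclose(d_hav, d_slc, rtol=1e-6, atol=1e-6)

    def test_rejects_bad_coordinates(self):
        with pytest.raises(ValueError):
            great_circle_distance(91.0, 0.0, 0.0, 0.0)


class TestMigration:
    def test_round_trip_worked_values(self):
        assert migration_cost(1940.0, FEMALE) == pytest.approx(3466.13, abs=0.01)
        assert migration_cost(1940.0, MALE) == pytest.approx(2845.33, abs=0.01)

    def test_linear_in_distance_and_zero_at_origin(self):
        assert migration_cost(0.0, MALE) == 0.0
        assert migration_cost(2000.0, MALE) == pytest.approx(
            2 * migration_cost(1000.0, MALE), rel=1e-12
        )

    def test_female_exceeds_male_at_equal_distance(self):
        assert migration_cost(1000.0, FEMALE) > migration_cost(1000.0, MALE)

    def test_rejects_negative_distance(self):
        with pytest.raises(ValueError):
            migration_cost(-1.0, MALE)


class TestWinteringCost:
    def test_breakdown_consistency(self):
        site = Site("x", ClimateConditions(0.0, 6.0, 50.0), distance_km=1940.0)
        b = wintering_cost(site, FEMALE)
        assert b.maintenance == pytest.approx(b.bmr + b.heat_loss)
        assert b.maintenance >= b.bmr
        cfg = EnergeticsConfig()
        assert b.seasonal_total == pytest.approx(
            b.maintenance * cfg.winter_duration * 86.4 + b.migration
        )

    def test_distance_override_beats_coordinates(self):
        site = Site("x", ClimateConditions(0.0, 6.0, 50.0), lat=55.0, lon=8.0,
                    distance_km=1940.0)
        assert wintering_cost(site, MALE).one_way_distance == 1940.0

    def test_requires_coordinates_or_override(self):
        site = Site("x", ClimateConditions(0.0, 6.0, 50.0))
        with pytest.raises(ValueError):
            wintering_cost(site, MALE)

    def test_published_sites_female_dearer_and_monotone_in_temperature(self):
        costs = cost_table(datasets.site_table())
        wide = costs.pivot(index="site", columns="sex", values="seasonal_total_kj")
        assert (wide["female"] > wide["male"]).all()
        # hold distance fixed: colder site always dearer
        tab = datasets.site_table().sort_values("t_air_c")
        tab["distance_km_override"] = 2000.0
        c = cost_table(tab)
        for sex in ("male", "female"):
            totals = (
                c[c.sex == sex]
                .set_index("site")
                .loc[tab["site"], "seasonal_total_kj"]
                .to_numpy()
            )
            assert np.all(np.diff(totals) < 0)

    def test_migration_is_minor_share_of_seasonal_cost(self):
        costs = cost_table(datasets.site_table())
        share = costs["migration_kj"] / (costs["seasonal_total_kj"] - costs["migration_kj"])
        assert (share > 0.005).all() and (share < 0.10).all()
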