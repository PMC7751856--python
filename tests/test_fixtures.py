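"""Synthetic city generation, the emulated survey sample, and the
calibration of group fixtures to the published aggregates."""
import dataclasses

import numpy as np
import pytest

from foodtravel.env_model import ZONES, load_environment
from foodtravel.errors import CalibrationError, RecipeError
from foodtravel.fixtures import (
    CalibrationTargets,
    CityRecipe,
    build_group_fixtures,
    emulate_survey_sample,
    generate_synthetic_city,
    load_groups,
    save_groups,
    trip_count_pmf,
)
from foodtravel.population import GROUP_ORDER, GROUP_SAMPLE_SIZES


class TestCityRecipe:
    def test_one_store_per_zone(self, tmp_path):
        recipe = CityRecipe(
            store_counts={
                "neighborhood": {"convenience": 1},
                "city": {"dollar": 1},
                "suburbs": {"chain_supermarket": 1},
            }
        )
        paths = generate_synthetic_city(recipe, seed=0, out_dir=tmp_path)
        env = load_environment(
            paths["houses"], paths["stores"], paths["roads"], paths["zones"]
        )
        assert sorted(s.zone for s in env.stores) == sorted(ZONES)

    def test_default_recipe_round_trips_cleanly(self, study):
        # build_study loads the generated files through the validated loader
        assert len(study.env.houses) == CityRecipe().n_tracts * CityRecipe().houses_per_tract
        assert len(study.respondents) == 188

    def test_store_zone_histogram_matches_recipe(self, study):
        recipe = study.recipe
        for zone in ZONES:
            expected = sum(recipe.store_counts.get(zone, {}).values())
            assert sum(1 for s in study.env.stores if s.zone == zone) == expected

    def test_store_type_histogram_matches_recipe(self, study):
        recipe = study.recipe
        for zone in ZONES:
            for t, c in recipe.store_counts.get(zone, {}).items():
                got = sum(
                    1 for s in study.env.stores if s.zone == zone and s.store_type == t
                )
                assert got == c

    def test_infeasible_store_counts_rejected(self, tmp_path):
        recipe = CityRecipe(
            store_counts={"suburbs": {"chain_supermarket": 500}}
        )
        with pytest.raises(RecipeError, match="suburbs"):
            generate_synthetic_city(recipe, seed=0, out_dir=tmp_path)

    def test_city_generation_deterministic(self, tmp_path):
        a = generate_synthetic_city(CityRecipe(), seed=1, out_dir=tmp_path / "a")
        b = generate_synthetic_city(CityRecipe(), seed=1, out_dir=tmp_path / "b")
        assert a["stores"].read_text() == b["stores"].read_text()
        assert a["houses"].read_text() == b["houses"].read_text()
        assert a["tracts"].read_text() == b["tracts"].read_text()


class TestSurveySample:
    def test_group_sizes_match_published_table(self, study):
        sizes = study.respondents.groupby("group").size().to_dict()
        assert sizes == GROUP_SAMPLE_SIZES
        assert len(study.respondents) == 188

    def test_low_income_household_size(self, study):
        sub = study.respondents[study.respondents["group"].str.startswith("Co")]
        assert len(sub) == 91
        # persons = 1 + Poisson(1.2)
        assert abs(sub["persons"].mean() - 2.20) <= 3 * np.sqrt(1.2 / len(sub))

    def test_respondents_stratify_into_their_group(self, study):
        from foodtravel.population import stratify_respondent

        for _, row in study.respondents.iterrows():
            assert stratify_respondent(row["age"], row["income"]) == row["group"]

    def test_sample_deterministic(self, study):
        again = emulate_survey_sample(
            study.targets, study.env.stores, seed=np.random.SeedSequence(42).spawn(2)[1]
        )
        assert again.equals(study.respondents)


class TestCalibration:
    def test_pinned_zone_shares_exact(self, study):
        g = study.groups["CoLwInYg"].zone_shares
        assert g["neighborhood"] == pytest.approx(0.25, abs=1e-6)
        assert g["city"] == pytest.approx(0.57, abs=1e-6)
        assert g["suburbs"] == pytest.approx(0.18, abs=1e-6)
        m = study.groups["MeInYg"].zone_shares
        assert m["neighborhood"] == pytest.approx(0.11, abs=1e-6)
        assert m["suburbs"] == pytest.approx(0.52, abs=1e-6)

    def test_population_share_solves_to_target(self, study):
        pop = study.targets.expected_population_zone_shares()
        assert pop["neighborhood"] == pytest.approx(0.23, abs=1e-9)
        assert pop["suburbs"] > 1 / 3  # "more than one-third in the suburbs"

    def test_all_fixture_pmfs_normalized(self, study):
        for g in study.groups.values():
            assert sum(g.trip_count_distribution.values()) == pytest.approx(1.0)
            assert sum(g.store_pool.values()) == pytest.approx(1.0)
            assert sum(g.zone_shares.values()) == pytest.approx(1.0)
            assert sum(g.noncar_mode_distribution.values()) == pytest.approx(1.0)
            for row in g.noncar_mode_by_distance:
                assert sum(row.values()) == pytest.approx(1.0)

    def test_trip_pmf_hits_requested_mean(self):
        for mean in (3.0, 5.5, 8.5):
            pmf = trip_count_pmf(mean)
            assert np.arange(len(pmf)) @ pmf == pytest.approx(mean, abs=1e-3)

    def test_missing_zone_in_pool_is_calibration_error(self, study):
        resp = study.respondents.copy()
        nbhd = {s.id for s in study.env.stores if s.zone == "neighborhood"}
        city_store = sorted(s.id for s in study.env.stores if s.zone == "city")[0]

        # strip every neighborhood store out of the reported pools
        resp["stores"] = resp["stores"].map(
            lambda r: ";".join(s for s in r.split(";") if s not in nbhd) or city_store
        )
        with pytest.raises(CalibrationError, match="neighborhood"):
            build_group_fixtures(resp, study.env, study.od, study.targets)

    def test_groups_json_round_trip(self, study, tmp_path):
        path = tmp_path / "groups.json"
        save_groups(study.groups, path)
        back = load_groups(path)
        for name, g in study.groups.items():
            b = back[name]
            assert b.name == g.name and b.sample_size == g.sample_size
            assert b.store_pool == pytest.approx(g.store_pool)
            assert b.zone_shares == pytest.approx(g.zone_shares)
            assert b.trip_count_distribution == pytest.approx(g.trip_count_distribution)
            assert b.noncar_mode_distribution == pytest.approx(g.noncar_mode_distribution)
            for r1, r2 in zip(b.noncar_mode_by_distance, g.noncar_mode_by_distance):
                assert r1 == pytest.approx(r2)
            assert b.zone_shares_unconsidered == pytest.approx(g.zone_shares_unconsidered)

    def test_targets_yaml_round_trip(self, study, tmp_path):
        path = tmp_path / "targets.yaml"
        study.targets.to_yaml(path)
        back = CalibrationTargets.from_yaml(path)
        assert back.group_zone_shares == study.targets.group_zone_shares
        assert back.no_car_share == study.targets.no_car_share

    def test_calibration_is_projection_for_feasible_group(self, study):
        """A pool already confined to a zone with target share 1 keeps its
        weights (up to normalization)."""
        targets = dataclasses.replace(
            study.targets,
            group_zone_shares={
                g: (
                    {"neighborhood": 1.0, "city": 0.0, "suburbs": 0.0}
                    if g == "CoLwInYg"
                    else d
                )
                for g, d in study.targets.group_zone_shares.items()
            },
        )
        nbhd = {s.id for s in study.env.stores if s.zone == "neighborhood"}
        resp = study.respondents.copy()
        some_nbhd_store = sorted(nbhd)[0]

        def to_nbhd(r):
            kept = [s for s in r.split(";") if s in nbhd]
            return ";".join(kept) if kept else some_nbhd_store

        resp.loc[resp["group"] == "CoLwInYg", "stores"] = resp.loc[
            resp["group"] == "CoLwInYg", "stores"
        ].map(to_nbhd)
        groups = build_group_fixtures(resp, study.env, study.od, targets)
        pool = groups["CoLwInYg"].store_pool
        assert set(pool) <= nbhd
        assert groups["CoLwInYg"].zone_shares["neighborhood"] == 1.0
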