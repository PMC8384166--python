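import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rdscentral import (
    AttributeSpec,
    CohortConfig,
    ConfigurationError,
    plant_signal,
    simulate_attributes,
    simulate_cohort,
    simulate_forest,
)


def point_mass(k, coupon_max=6):
    dist = [0.0] * (coupon_max + 1)
    dist[k] = 1.0
    return tuple(dist)


def forest_config(**kwargs):
    defaults = dict(n_cities=1, seeds_per_city=5, max_waves=3, rng_seed=0)
    defaults.update(kwargs)
    return CohortConfig(**defaults)


class TestConfigValidation:
    def test_distribution_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            forest_config(recruit_count_dist=(0.5, 0.4, 0, 0, 0, 0, 0))

    def test_distribution_length_must_match_coupon_max(self):
        with pytest.raises(ConfigurationError):
            forest_config(coupon_max=3, recruit_count_dist=point_mass(0))

    def test_binary_prevalence_bounds(self):
        with pytest.raises(ConfigurationError):
            AttributeSpec("bad", "binary", 1.5)

    def test_unknown_kind(self):
        with pytest.raises(ConfigurationError):
            AttributeSpec("bad", "mystery", 0.5)

    def test_planted_needs_rate(self):
        with pytest.raises(ConfigurationError):
            AttributeSpec("p", "binary", 0.1, planted=True)


class TestSimulateForest:
    def test_point_mass_zero_gives_isolated_seeds(self):
        config = forest_config(n_cities=2, recruit_count_dist=point_mass(0))
        forest = simulate_forest(config)
        assert forest.n_nodes() == 10
        assert forest.n_edges() == 0
        assert forest.n_components() == 10

    def test_point_mass_six_one_wave_gives_seven_node_star(self):
        config = forest_config(
            seeds_per_city=1, max_waves=1, recruit_count_dist=point_mass(6)
        )
        forest = simulate_forest(config)
        g = forest.graph("city1")
        assert g.number_of_nodes() == 7
        assert max(dict(g.degree).values()) == 6  # the seed holds all 6 edges

    def test_acyclic_and_degree_capped(self, default_cohort):
        forest = default_cohort.forest
        assert forest.is_forest()
        for city in forest.cities:
            assert max(dict(forest.graph(city).degree).values()) <= 7

    def test_deterministic_given_seed(self):
        config = forest_config(seeds_per_city=20, rng_seed=42)
        a, b = simulate_forest(config), simulate_forest(config)
        for city in a.cities:
            assert set(a.graph(city).edges) == set(b.graph(city).edges)

    def test_majority_of_components_size_1_or_2_under_defaults(self):
        forest = simulate_forest(CohortConfig(rng_seed=3))
        sizes = [len(c) for city in forest.cities for c in forest.components(city)]
        assert sum(s <= 2 for s in sizes) / len(sizes) > 0.5

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        weights=st.lists(
            st.floats(0.0, 1.0, allow_nan=False), min_size=7, max_size=7
        ).filter(lambda w: sum(w) > 0),
        seed=st.integers(0, 2**20),
    )
    def test_tree_identity_holds_for_any_distribution(self, weights, seed):
        dist = tuple(np.asarray(weights) / np.sum(weights))
        config = forest_config(recruit_count_dist=dist, rng_seed=seed, max_waves=4)
        forest = simulate_forest(config)
        assert forest.is_forest()
        for city in forest.cities:
            degrees = dict(forest.graph(city).degree).values()
            assert max(degrees, default=0) <= config.coupon_max + 1


class TestSimulateAttributes:
    def test_prevalence_zero_gives_all_no(self):
        config = forest_config(
            seeds_per_city=50,
            recruit_count_dist=point_mass(0),
            attribute_specs=[AttributeSpec("never", "binary", 0.0)],
            missing_rate=0.0,
        )
        table = simulate_attributes(simulate_forest(config), config)
        assert (table["never"] == 0.0).all()

    def test_missing_rate_zero_gives_no_missingness(self):
        config = CohortConfig(n_cities=1, seeds_per_city=20, missing_rate=0.0, rng_seed=1)
        table = simulate_attributes(simulate_forest(config), config)
        assert not table.drop(columns=["recruiter_id"]).isna().any().any()

    def test_sample_prevalence_concentrates(self):
        config = forest_config(
            seeds_per_city=2000,
            recruit_count_dist=point_mass(0),
            attribute_specs=[AttributeSpec("coin", "binary", 0.5)],
            missing_rate=0.0,
            rng_seed=5,
        )
        table = simulate_attributes(simulate_forest(config), config)
        assert abs(table["coin"].mean() - 0.5) < 3 * np.sqrt(0.25 / 2000)

    def test_byte_identical_tables_for_same_seed(self):
        config = CohortConfig(n_cities=2, seeds_per_city=40, rng_seed=99)
        a, b = simulate_cohort(config).table, simulate_cohort(config).table
        pd.testing.assert_frame_equal(a, b)
        assert a.to_csv() == b.to_csv()


class TestPlantSignal:
    @pytest.fixture()
    def planted_spec(self):
        return AttributeSpec(
            "marker", "binary", 0.05, planted=True, planted_central_rate=1.0
        )

    def test_planting_leaves_topology_unchanged(self, small_cohort, planted_spec):
        before = {
            city: set(small_cohort.forest.graph(city).edges)
            for city in small_cohort.forest.cities
        }
        planted = plant_signal(small_cohort, "betweenness", planted_spec)
        for city, edges in before.items():
            assert set(planted.forest.graph(city).edges) == edges
        assert "marker" in planted.truth

    def test_rate_one_low_prevalence_gives_full_deviant_count(
        self, small_cohort, planted_spec
    ):
        # prevalence 0.05 < 0.2, so every planted 1 deviates; rate 1.0 means
        # every central node carries the attribute -> deviant count = |c|
        from rdscentral import central_nodes, compute_baseline, one_hot_encode
        from rdscentral import filter_features, score_attributes

        planted = plant_signal(small_cohort, "betweenness", planted_spec)
        features = one_hot_encode(filter_features(planted.table, 0.5))
        city = planted.forest.cities[0]
        central = central_nodes(planted.forest, city, "betweenness")
        baseline = compute_baseline(features, city)
        records = {
            r.attribute: r
            for r in score_attributes(central, features, baseline)
        }
        assert records["marker"].deviant_count == central.set_size == 15

    def test_non_planted_spec_rejected(self, small_cohort):
        spec = AttributeSpec("x", "binary", 0.1)
        with pytest.raises(ConfigurationError):
            plant_signal(small_cohort, "betweenness", spec)

    def test_explicit_node_override(self, small_cohort, planted_spec):
        nodes = list(small_cohort.table["respondent_id"][:10])
        planted = plant_signal(small_cohort, "closeness", planted_spec, nodes=nodes)
        values = planted.table.set_index("respondent_id").loc[nodes, "marker"]
        assert (values == 1.0).all()
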