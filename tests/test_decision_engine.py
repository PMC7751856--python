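"""The weekly shopping decision process: trip counts, type filter, the two
decision orderings, and the simulation driver."""
import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from foodtravel.decision_engine import (
    SimulationConfig,
    decide_store_type_filter,
    draw_trip_count,
    run_simulation,
    select_mode_first,
    select_store_first,
    simulate_week,
)
from foodtravel.env_model import (
    Environment,
    House,
    RoadNetwork,
    Store,
    ZonePartition,
    build_od_matrix,
)
from foodtravel.population import HouseholdAgent

import networkx as nx
from shapely.geometry import box


def line_env(store_specs, house_x=0.0):
    """Houses/stores on a line; all stores in the neighborhood zone unless
    placed beyond x=20 (city ends at 20)."""
    xs = sorted({house_x} | {x for x, _ in store_specs})
    g = nx.Graph()
    for i, x in enumerate(xs):
        g.add_node(i, pos=(x, 0.0))
    for a, b in zip(range(len(xs) - 1), range(1, len(xs))):
        g.add_edge(a, b, length=xs[b] - xs[a])
    net = RoadNetwork(g)
    zones = ZonePartition(box(-1, -1, 10, 1), box(-2, -2, 20, 2))
    houses = [House("H0", house_x, 0.0, "T0")]
    stores = [
        Store(f"S{i}", x, 0.0, stype, zone=zones.classify(x, 0.0))
        for i, (x, stype) in enumerate(store_specs)
    ]
    env = Environment(net, houses, stores, zones, snap_radius=0.01)
    od = build_od_matrix(net, houses, stores, snap_radius=0.01)
    return env, od


def make_group(study, **overrides):
    """Variant of the packaged young-core-poor group with the type-zone
    coupling stripped (unit tests exercise the uncoupled law)."""
    g = study.groups["CoLwInYg"]
    overrides.setdefault("zone_shares_by_type", None)
    overrides.setdefault("zone_shares_unconsidered", None)
    return dataclasses.replace(g, **overrides)


@pytest.fixture()
def walk_setup(study):
    """Two equal-weight neighborhood stores at 1 and 4 miles."""
    env, od = line_env([(1.0, "convenience"), (4.0, "convenience")])
    group = make_group(
        study,
        store_pool={"S0": 0.5, "S1": 0.5},
        zone_shares={"neighborhood": 1.0, "city": 0.0, "suburbs": 0.0},
    )
    agent = HouseholdAgent(0, "CoLwInYg", house_id="H0", has_car=False)
    return env, od, group, agent


class TestDrawTripCount:
    def test_degenerate_distribution(self, study):
        group = make_group(study, trip_count_distribution={5: 1.0})
        rng = np.random.default_rng(0)
        assert all(draw_trip_count(group, rng) == 5 for _ in range(20))

    def test_draws_match_pmf(self, study):
        """Empirical frequencies match the fixture pmf (chi-square, a=0.01)."""
        group = study.groups["CoLwInYg"]
        rng = np.random.default_rng(1)
        draws = [draw_trip_count(group, rng) for _ in range(10_000)]
        pmf = group.trip_count_distribution
        support = sorted(pmf)
        observed = np.array([draws.count(k) for k in support])
        expected = np.array([pmf[k] * 10_000 for k in support])
        keep = expected >= 5
        _, p = chisquare(
            observed[keep], expected[keep] * observed[keep].sum() / expected[keep].sum()
        )
        assert p > 0.01

    def test_mixture_mean_is_five_trips_per_week(self, study):
        """Sample-weighted draws across all groups average ~5 trips/week."""
        rng = np.random.default_rng(2)
        names = list(study.groups)
        weights = np.array([study.groups[g].sample_size for g in names], dtype=float)
        weights /= weights.sum()
        draws = []
        for g in rng.choice(names, size=10_000, p=weights):
            draws.append(draw_trip_count(study.groups[g], rng))
        draws = np.array(draws)
        assert abs(draws.mean() - 5.0) <= 3 * draws.std() / np.sqrt(len(draws))


class TestTypeFilter:
    def test_never_considering_returns_full_pool(self, study):
        group = make_group(study, type_consideration_prob=0.0)
        pool = {"S0": 0.5, "S1": 0.5}
        types = {"S0": "convenience", "S1": "dollar"}
        rng = np.random.default_rng(0)
        for _ in range(10):
            assert decide_store_type_filter(group, pool, types, rng) == pool

    def test_single_type_pool_is_identity(self, study):
        group = make_group(
            study,
            type_consideration_prob=1.0,
            store_type_weights={"convenience": 1.0},
        )
        pool = {"S0": 0.25, "S1": 0.75}
        types = {"S0": "convenience", "S1": "convenience"}
        rng = np.random.default_rng(0)
        assert decide_store_type_filter(group, pool, types, rng) == pool

    def test_restriction_renormalizes(self, study):
        group = make_group(
            study,
            type_consideration_prob=1.0,
            store_type_weights={"convenience": 1.0},
        )
        pool = {"S0": 0.2, "S1": 0.2, "S2": 0.6}
        types = {"S0": "convenience", "S1": "convenience", "S2": "dollar"}
        rng = np.random.default_rng(0)
        out = decide_store_type_filter(group, pool, types, rng)
        assert set(out) == {"S0", "S1"}
        assert sum(out.values()) == pytest.approx(1.0)

    def test_empty_restriction_falls_back(self, study):
        group = make_group(
            study,
            type_consideration_prob=1.0,
            store_type_weights={"chain_supermarket": 1.0},
        )
        pool = {"S0": 1.0}
        types = {"S0": "convenience"}
        rng = np.random.default_rng(0)
        assert decide_store_type_filter(group, pool, types, rng) == pool


class TestModeFirst:
    def test_car_owner_always_drives(self, walk_setup):
        env, od, group, _ = walk_setup
        agent = HouseholdAgent(0, "CoLwInYg", house_id="H0", has_car=True)
        rng = np.random.default_rng(0)
        cfg = SimulationConfig(weeks=1)
        pool = group.store_pool
        for _ in range(50):
            mode, _store = select_mode_first(agent, group, pool, od, cfg, rng)
            assert mode == "car"

    def test_single_store_pool(self, walk_setup):
        env, od, group, agent = walk_setup
        rng = np.random.default_rng(0)
        cfg = SimulationConfig(weeks=1)
        for _ in range(20):
            _mode, store = select_mode_first(agent, group, {"S0": 1.0}, od, cfg, rng)
            assert store == "S0"

    def test_walk_distance_decay_ratio(self, walk_setup):
        """Equal-weight stores at 1 and 4 mi with lambda_walk=3: the near
        store wins with probability e^(-1/3)/(e^(-1/3)+e^(-4/3)) ~= 0.731."""
        env, od, group, agent = walk_setup
        group = dataclasses.replace(
            group, noncar_mode_distribution={"walk": 1.0}
        )
        cfg = SimulationConfig(weeks=1, lambda_walk=3.0)
        rng = np.random.default_rng(3)
        n = 10_000
        near = 0
        for _ in range(n):
            mode, store = select_mode_first(agent, group, group.store_pool, od, cfg, rng)
            assert mode == "walk"
            near += store == "S0"
        expected = np.exp(-1 / 3) / (np.exp(-1 / 3) + np.exp(-4 / 3))
        assert abs(near / n - expected) <= 3 * np.sqrt(expected * (1 - expected) / n)


class TestStoreFirst:
    def test_car_owner_always_drives(self, walk_setup):
        env, od, group, _ = walk_setup
        agent = HouseholdAgent(0, "CoLwInYg", house_id="H0", has_car=True)
        rng = np.random.default_rng(0)
        cfg = SimulationConfig(weeks=1)
        for _ in range(50):
            _store, mode = select_store_first(agent, group, group.store_pool, od, cfg, rng)
            assert mode == "car"

    def test_pool_weights_respected(self, walk_setup):
        env, od, group, agent = walk_setup
        pool = {"S0": 0.75, "S1": 0.25}
        cfg = SimulationConfig(weeks=1)
        rng = np.random.default_rng(4)
        n = 10_000
        hits = sum(
            select_store_first(agent, group, pool, od, cfg, rng)[0] == "S0"
            for _ in range(n)
        )
        assert abs(hits / n - 0.75) <= 3 * np.sqrt(0.75 * 0.25 / n)

    def test_motorized_exclusive_beyond_six_miles(self, study):
        """With a binned table fully motorized beyond 6 mi, a carless trip to
        a store 8 mi out must go by bus or taxi."""
        env, od = line_env([(8.0, "convenience")])
        group = make_group(
            study,
            store_pool={"S0": 1.0},
            noncar_mode_by_distance=[
                {"walk": 0.5, "bike": 0.5} if b < 6 else {"bus": 0.9, "taxi": 0.1}
                for b in range(11)
            ],
        )
        agent = HouseholdAgent(0, "CoLwInYg", house_id="H0", has_car=False)
        cfg = SimulationConfig(weeks=1)
        rng = np.random.default_rng(5)
        for _ in range(100):
            _store, mode = select_store_first(agent, group, group.store_pool, od, cfg, rng)
            assert mode in {"bus", "taxi"}


class TestSimulateWeek:
    def _setup(self, study, trip_pmf):
        env, od = line_env([(1.0, "convenience"), (4.0, "dollar")])
        group = make_group(
            study,
            store_pool={"S0": 0.5, "S1": 0.5},
            zone_shares={"neighborhood": 1.0, "city": 0.0, "suburbs": 0.0},
            trip_count_distribution=trip_pmf,
        )
        groups = {"CoLwInYg": group}
        agent = HouseholdAgent(0, "CoLwInYg", house_id="H0", has_car=True)
        return env, od, groups, agent

    def test_zero_draw_gives_empty_week(self, study):
        env, od, groups, agent = self._setup(study, {0: 1.0})
        rng = np.random.default_rng(0)
        assert simulate_week(agent, env, od, SimulationConfig(weeks=1), rng, groups) == []

    def test_record_count_equals_draw(self, study):
        env, od, groups, agent = self._setup(study, {3: 1.0})
        rng = np.random.default_rng(0)
        records = simulate_week(agent, env, od, SimulationConfig(weeks=1), rng, groups)
        assert len(records) == 3
        for r in records:
            assert r.distance == od.distance("H0", r.store_id)
            assert r.zone == "neighborhood"
            assert r.mode == "car" and r.motorized

    def test_determinism(self, study):
        env, od, groups, agent = self._setup(study, {2: 0.5, 4: 0.5})
        cfg = SimulationConfig(weeks=1)
        a = simulate_week(agent, env, od, cfg, np.random.default_rng(11), groups)
        b = simulate_week(agent, env, od, cfg, np.random.default_rng(11), groups)
        assert a == b


class TestRunSimulation:
    def _bundle(self, study, n_agents=3, has_car=True, trip_pmf=None):
        env, od = line_env([(1.0, "convenience"), (4.0, "dollar")])
        group = make_group(
            study,
            store_pool={"S0": 0.5, "S1": 0.5},
            zone_shares={"neighborhood": 1.0, "city": 0.0, "suburbs": 0.0},
            trip_count_distribution=trip_pmf or {2: 1.0},
        )
        groups = {"CoLwInYg": group}
        agents = [
            HouseholdAgent(i, "CoLwInYg", house_id="H0", has_car=has_car)
            for i in range(n_agents)
        ]
        return env, od, groups, agents

    def test_fixed_trip_count_conservation(self, study):
        env, od, groups, agents = self._bundle(study, n_agents=1)
        log = run_simulation(agents, env, od, SimulationConfig(weeks=1, seed=0), groups)
        assert len(log) == 2

    def test_seed_determinism(self, study):
        env, od, groups, agents = self._bundle(study, trip_pmf={1: 0.3, 3: 0.7})
        cfg = SimulationConfig(weeks=4, seed=5)
        a = run_simulation(agents, env, od, cfg, groups)
        b = run_simulation(agents, env, od, cfg, groups)
        pd.testing.assert_frame_equal(a, b)

    def test_agent_order_invariance(self, study):
        env, od, groups, agents = self._bundle(
            study, n_agents=5, has_car=False, trip_pmf={1: 0.5, 2: 0.5}
        )
        cfg = SimulationConfig(weeks=3, seed=7)
        a = run_simulation(agents, env, od, cfg, groups)
        b = run_simulation(list(reversed(agents)), env, od, cfg, groups)
        a_sorted = a.sort_values(["agent_id", "week"]).reset_index(drop=True)
        b_sorted = b.sort_values(["agent_id", "week"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a_sorted, b_sorted)

    def test_vectorized_engine_matches_scalar_law(self, study):
        """The batched driver and the per-trip reference implementation draw
        from the same store/mode law (chi-square on frequencies)."""
        env, od = line_env(
            [(1.0, "convenience"), (4.0, "dollar"), (8.0, "independent_supermarket")]
        )
        group = make_group(
            study,
            store_pool={"S0": 0.2, "S1": 0.3, "S2": 0.5},
            zone_shares={"neighborhood": 1.0, "city": 0.0, "suburbs": 0.0},
            trip_count_distribution={1: 1.0},
        )
        groups = {"CoLwInYg": group}
        agent = HouseholdAgent(0, "CoLwInYg", house_id="H0", has_car=False)
        cfg = SimulationConfig(weeks=4000, seed=13)
        log = run_simulation([agent], env, od, cfg, groups)

        rng = np.random.default_rng(14)
        scalar = []
        for w in range(4000):
            scalar.extend(
                simulate_week(agent, env, od, SimulationConfig(weeks=1, seed=0), rng,
                              groups, week=w)
            )
        vec_counts = log["store_id"].value_counts()
        sca = pd.Series([r.store_id for r in scalar]).value_counts()
        stores = sorted(set(vec_counts.index) | set(sca.index))
        obs = np.array([vec_counts.get(s, 0) for s in stores])
        exp = np.array([sca.get(s, 0) for s in stores], dtype=float)
        exp = exp * obs.sum() / exp.sum()
        _, p = chisquare(obs, exp)
        assert p > 0.001
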