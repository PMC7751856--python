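"""Weekly grocery-shopping decision process and trip-log generation.

Every week a household agent draws a number of shopping trips from its
group's empirical trip-count distribution. Each trip:

1. decides, with the group's type-consideration probability, whether to fix
   the store type first (store type is a proxy for what groceries to buy);
   if so the type is drawn from the group's type weights;
2. draws the shopping zone (neighborhood / city / suburbs): conditional on
   the considered type when one was fixed (chain-supermarket groceries pull
   the trip to the suburbs, quick formats keep it nearby), otherwise from
   the complementary habitual distribution — the two are calibrated so the
   per-trip zone marginal equals the group's published zone shares. The
   store pool is restricted to the zone (and to the considered type where
   the zone offers it);
3. routes through one of two decision orderings: *mode first* (pick the
   travel mode, then a store — walkers and cyclists discount far stores by
   an exponential distance decay) or *store first* (pick the store from the
   pool weights, then a mode from a distance-binned table).

Agents with a car always drive — a hard behavioral rule, not a probability.
Carless agents choose among bus, taxi, walking and cycling. Trips are
memoryless across weeks, and each agent owns an independent RNG stream
derived from the simulation seed, so results do not depend on agent
iteration order.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .env_model import Environment, ODMatrix, ZONES
from .errors import ConfigurationError
from .population import AgentGroup, HouseholdAgent, MODES, MOTORIZED

#: default half-open distance bin edges (miles); last bin is open-ended
DEFAULT_DISTANCE_BINS = tuple(float(i) for i in range(11))


@dataclass
class SimulationConfig:
    weeks: int = 52
    seed: int = 0
    lambda_walk: float = 3.0  # miles; e-folding of walk store choice
    lambda_bike: float = 6.0
    distance_bins: tuple = DEFAULT_DISTANCE_BINS
    # global overrides for the sensitivity analysis; None = use group values
    mode_first_prob: float | None = None
    type_consideration_prob: float | None = None

    def __post_init__(self) -> None:
        if self.weeks < 1:
            raise ConfigurationError("weeks must be >= 1")
        if self.lambda_walk <= 0 or self.lambda_bike <= 0:
            raise ConfigurationError("distance-decay lambdas must be positive")

    def decay_lambda(self, mode: str) -> float:
        if mode == "walk":
            return self.lambda_walk
        if mode == "bike":
            return self.lambda_bike
        return np.inf

    def bin_index(self, distance: float) -> int:
        edges = np.asarray(self.distance_bins)
        return int(np.clip(np.searchsorted(edges, distance, side="right") - 1,
                           0, len(edges) - 1))


@dataclass
class TripRecord:
    agent_id: int
    week: int
    store_id: str
    mode: str
    motorized: bool
    distance: float
    zone: str


# ---------------------------------------------------------------------------
# scalar operations (the readable per-trip contract; unit-test surface)
# ---------------------------------------------------------------------------

def draw_trip_count(group: AgentGroup, rng: np.random.Generator) -> int:
    """Number of shopping trips this week, from the group's categorical pmf."""
    counts = list(group.trip_count_distribution)
    probs = list(group.trip_count_distribution.values())
    return int(rng.choice(counts, p=probs))


def decide_store_type_filter(
    group: AgentGroup,
    pool: dict[str, float],
    store_types: dict[str, str],
    rng: np.random.Generator,
) -> dict[str, float]:
    """Optionally restrict a store pool to one store type.

    With probability ``type_consideration_prob`` a type is drawn from the
    group's type weights and the pool restricted (weights renormalized); an
    empty restriction falls back to the full pool.
    """
    if not pool:
        raise ConfigurationError("store pool is empty")
    p = group.type_consideration_prob
    if rng.random() >= p:
        return dict(pool)
    types = list(group.store_type_weights)
    t = str(rng.choice(types, p=list(group.store_type_weights.values())))
    restricted = {s: w for s, w in pool.items() if store_types[s] == t}
    if not restricted:
        return dict(pool)
    total = sum(restricted.values())
    return {s: w / total for s, w in restricted.items()}


def _sample_store(
    pool: dict[str, float],
    od_row_lookup,
    lam: float,
    rng: np.random.Generator,
) -> str:
    ids = list(pool)
    w = np.array([pool[s] for s in ids], dtype=float)
    if np.isfinite(lam):
        d = np.array([od_row_lookup(s) for s in ids])
        w = w * np.exp(-d / lam)
    w = w / w.sum()
    return str(rng.choice(ids, p=w))


def select_mode_first(
    agent: HouseholdAgent,
    group: AgentGroup,
    pool: dict[str, float],
    od: ODMatrix,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[str, str]:
    """Pick the travel mode, then the store.

    Car owners drive, always. Carless agents draw a mode from the group's
    marginal non-car distribution. Walkers/cyclists then choose a store with
    weight ∝ pool weight × exp(−d/λ_mode); motorized modes apply no decay.
    """
    if agent.has_car:
        mode = "car"
    else:
        mode = str(
            rng.choice(
                list(group.noncar_mode_distribution),
                p=list(group.noncar_mode_distribution.values()),
            )
        )
    store = _sample_store(
        pool, lambda s: od.distance(agent.house_id, s), cfg.decay_lambda(mode), rng
    )
    return mode, store


def select_store_first(
    agent: HouseholdAgent,
    group: AgentGroup,
    pool: dict[str, float],
    od: ODMatrix,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[str, str]:
    """Pick the store from the pool weights, then the mode.

    Carless agents draw the mode from the group's distance-binned non-car
    table evaluated at the network distance to the chosen store; distances
    beyond the last edge use the open-ended tail bin.
    """
    store = _sample_store(pool, None, np.inf, rng)
    if agent.has_car:
        return store, "car"
    d = od.distance(agent.house_id, store)
    row = group.noncar_mode_by_distance[
        min(cfg.bin_index(d), len(group.noncar_mode_by_distance) - 1)
    ]
    mode = str(rng.choice(list(row), p=list(row.values())))
    return store, mode


def simulate_week(
    agent: HouseholdAgent,
    env: Environment,
    od: ODMatrix,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    groups: dict[str, AgentGroup],
    week: int = 0,
) -> list[TripRecord]:
    """One agent-week of the decision process; emits one record per trip."""
    group = groups[agent.group]
    store_types = {s.id: s.store_type for s in env.stores}
    store_zone = {s.id: s.zone for s in env.stores}
    zone_pools = _zone_pools(group, store_zone)
    p_mf = cfg.mode_first_prob if cfg.mode_first_prob is not None else group.mode_first_prob
    p_type = (
        cfg.type_consideration_prob
        if cfg.type_consideration_prob is not None
        else group.type_consideration_prob
    )

    n = draw_trip_count(group, rng)
    records = []
    for _ in range(n):
        if rng.random() < p_type:
            t = str(
                rng.choice(
                    list(group.store_type_weights),
                    p=list(group.store_type_weights.values()),
                )
            )
            zdist = group.zone_dist_for_type(t)
            zone = str(rng.choice(list(zdist), p=list(zdist.values())))
            restricted = {
                s: w for s, w in zone_pools[zone].items() if store_types[s] == t
            }
            pool = restricted or dict(zone_pools[zone])
        else:
            zdist = group.zone_dist_unconsidered()
            zone = str(rng.choice(list(zdist), p=list(zdist.values())))
            pool = dict(zone_pools[zone])
        total = sum(pool.values())
        pool = {s: w / total for s, w in pool.items()}
        if rng.random() < p_mf:
            mode, store = select_mode_first(agent, group, pool, od, cfg, rng)
        else:
            store, mode = select_store_first(agent, group, pool, od, cfg, rng)
        records.append(
            TripRecord(
                agent_id=agent.id,
                week=week,
                store_id=store,
                mode=mode,
                motorized=MOTORIZED[mode],
                distance=od.distance(agent.house_id, store),
                zone=store_zone[store],
            )
        )
    return records


def _zone_pools(group: AgentGroup, store_zone: dict[str, str]) -> dict[str, dict]:
    pools: dict[str, dict] = {z: {} for z in ZONES}
    for s, w in group.store_pool.items():
        pools[store_zone[s]][s] = w
    for z, share in group.zone_shares.items():
        if share > 0 and not pools[z]:
            raise ConfigurationError(
                f"group {group.name}: zone {z} has share {share} but no stores in pool"
            )
    return pools


# ---------------------------------------------------------------------------
# vectorized engine (identical decision law, batched per agent)
# ---------------------------------------------------------------------------


class _GroupRuntime:
    """Per-group arrays resolved against the OD store columns."""

    def __init__(self, group: AgentGroup, env: Environment, od: ODMatrix,
                 cfg: SimulationConfig):
        self.group = group
        self.p_type = (
            group.type_consideration_prob
            if cfg.type_consideration_prob is None
            else cfg.type_consideration_prob
        )
        self.p_mode_first = (
            group.mode_first_prob if cfg.mode_first_prob is None else cfg.mode_first_prob
        )
        stores_by_id = env.stores_by_id
        ids = list(group.store_pool)
        self.cols = np.array([od.store_col_index(s) for s in ids])
        self.weights = np.array([group.store_pool[s] for s in ids])
        zone_arr = np.array([ZONES.index(stores_by_id[s].zone) for s in ids])
        from .env_model import STORE_TYPES

        type_arr = np.array([STORE_TYPES.index(stores_by_id[s].store_type) for s in ids])

        # zone laws: unconditional (habitual) and conditional on the type
        zb = group.zone_dist_unconsidered()
        self.zone_unconsidered_cum = np.cumsum([zb.get(z, 0.0) for z in ZONES])
        # member indices per (zone, type) and per zone
        self.members: dict[tuple[int, int], np.ndarray] = {}
        for zi, zname in enumerate(ZONES):
            in_zone = np.nonzero(zone_arr == zi)[0]
            if group.zone_shares.get(zname, 0.0) > 0 and in_zone.size == 0:
                raise ConfigurationError(
                    f"group {group.name}: zone {zname} has positive share "
                    "but no stores in pool"
                )
            self.members[(zi, -1)] = in_zone
            for ti in range(len(STORE_TYPES)):
                sub = in_zone[type_arr[in_zone] == ti]
                if sub.size:
                    self.members[(zi, ti)] = sub

        self.type_names = list(group.store_type_weights)
        self.type_indices = np.array(
            [STORE_TYPES.index(t) for t in self.type_names]
        )
        self.type_cum = np.cumsum(list(group.store_type_weights.values()))
        # per considered type (aligned with type_names): zone law cumsum
        self.zone_by_type_cum = [
            np.cumsum([group.zone_dist_for_type(t).get(z, 0.0) for z in ZONES])
            for t in self.type_names
        ]

        self.noncar_names = list(group.noncar_mode_distribution)
        self.noncar_cum = np.cumsum(list(group.noncar_mode_distribution.values()))
        self.noncar_decay = np.array(
            [cfg.decay_lambda(m) for m in self.noncar_names]
        )
        # binned table rows -> cumulative over NONCAR_MODES order
        self.bin_modes = []
        for row in group.noncar_mode_by_distance:
            names = list(row)
            self.bin_modes.append((names, np.cumsum(list(row.values()))))

        self.trip_counts = np.array(list(group.trip_count_distribution))
        self.trip_cum = np.cumsum(list(group.trip_count_distribution.values()))


def _categorical(cum: np.ndarray, n: int, rng) -> np.ndarray:
    return np.searchsorted(cum, rng.random(n) * cum[-1], side="right").clip(0, len(cum) - 1)


def _simulate_agent(
    agent: HouseholdAgent,
    rt: _GroupRuntime,
    od_row: np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator,
):
    n_per_week = rt.trip_counts[_categorical(rt.trip_cum, cfg.weeks, rng)]
    total = int(n_per_week.sum())
    if total == 0:
        return None
    weeks = np.repeat(np.arange(cfg.weeks, dtype=np.int32), n_per_week)

    # type decision first; the zone law is conditional on a considered type
    consider = rng.random(total) < rt.p_type
    type_local = np.full(total, -1)  # index into rt.type_names
    k = int(consider.sum())
    if k:
        type_local[consider] = _categorical(rt.type_cum, k, rng)
    zone_idx = np.empty(total, dtype=int)
    un = np.nonzero(type_local < 0)[0]
    zone_idx[un] = _categorical(rt.zone_unconsidered_cum, un.size, rng)
    for tl in np.unique(type_local[type_local >= 0]):
        members = np.nonzero(type_local == tl)[0]
        zone_idx[members] = _categorical(
            rt.zone_by_type_cum[int(tl)], members.size, rng
        )
    type_req = np.where(type_local >= 0, rt.type_indices[type_local], -1)
    # fall back to the zone pool when the requested type is absent there
    for i in np.nonzero(type_req >= 0)[0]:
        if (zone_idx[i], type_req[i]) not in rt.members:
            type_req[i] = -1

    mode_first = rng.random(total) < rt.p_mode_first
    mode_idx = np.full(total, MODES.index("car"))
    lam = np.full(total, np.inf)
    if not agent.has_car:
        mf = np.nonzero(mode_first)[0]
        if mf.size:
            picks = _categorical(rt.noncar_cum, mf.size, rng)
            mode_idx[mf] = [MODES.index(rt.noncar_names[p]) for p in picks]
            lam[mf] = rt.noncar_decay[picks]

    # store choice grouped by (zone, type, decay-lambda)
    store_local = np.empty(total, dtype=int)
    decay_key = np.where(np.isfinite(lam), lam, -1.0)
    keys = np.stack([zone_idx, type_req, decay_key], axis=1)
    order = np.lexsort((decay_key, type_req, zone_idx))
    sorted_keys = keys[order]
    boundaries = np.nonzero(
        np.any(np.diff(sorted_keys, axis=0) != 0, axis=1)
    )[0] + 1
    for chunk in np.split(order, boundaries):
        zi, ti, dk = keys[chunk[0]]
        sub = rt.members[(int(zi), int(ti))]
        w = rt.weights[sub]
        if dk >= 0:
            w = w * np.exp(-od_row[rt.cols[sub]] / dk)
        cum = np.cumsum(w)
        store_local[chunk] = sub[_categorical(cum, chunk.size, rng)]

    store_cols = rt.cols[store_local]
    dist = od_row[store_cols]

    if not agent.has_car:
        sf = np.nonzero(~mode_first)[0]
        if sf.size:
            edges = np.asarray(cfg.distance_bins)
            bins = np.clip(
                np.searchsorted(edges, dist[sf], side="right") - 1,
                0,
                len(rt.bin_modes) - 1,
            )
            for b in np.unique(bins):
                names, cum = rt.bin_modes[int(b)]
                members = sf[bins == b]
                picks = _categorical(cum, members.size, rng)
                mode_idx[members] = [MODES.index(names[p]) for p in picks]

    return weeks, store_cols, mode_idx, zone_idx, dist


def run_simulation(
    agents: list[HouseholdAgent],
    env: Environment,
    od: ODMatrix,
    cfg: SimulationConfig,
    groups: dict[str, AgentGroup],
) -> pd.DataFrame:
    """Simulate all agents over ``cfg.weeks`` weeks and return the trip log.

    Each agent's RNG stream is spawned from ``(cfg.seed, agent.id)``, so the
    log is invariant to the order in which agents are simulated.
    """
    runtimes = {name: _GroupRuntime(g, env, od, cfg) for name, g in groups.items()}
    store_ids = np.asarray(od.store_ids)
    store_type = np.asarray([env.stores_by_id[s].store_type for s in od.store_ids])

    parts = {k: [] for k in
             ("agent_id", "group", "week", "store_col", "mode", "zone", "distance")}
    house_row_cache: dict[str, np.ndarray] = {}
    for agent in agents:
        rt = runtimes[agent.group]
        row = house_row_cache.get(agent.house_id)
        if row is None:
            row = od.house_row(agent.house_id)
            house_row_cache[agent.house_id] = row
        rng = np.random.default_rng(
            np.random.SeedSequence(cfg.seed, spawn_key=(int(agent.id),))
        )
        out = _simulate_agent(agent, rt, row, cfg, rng)
        if out is None:
            continue
        weeks, store_cols, mode_idx, zone_idx, dist = out
        n = len(weeks)
        parts["agent_id"].append(np.full(n, agent.id, dtype=np.int64))
        parts["group"].append(np.full(n, agent.group, dtype=object))
        parts["week"].append(weeks)
        parts["store_col"].append(store_cols)
        parts["mode"].append(mode_idx)
        parts["zone"].append(zone_idx)
        parts["distance"].append(dist)

    if not parts["agent_id"]:
        return _empty_log()
    mode_arr = np.concatenate(parts["mode"])
    zone_arr = np.concatenate(parts["zone"])
    store_cols = np.concatenate(parts["store_col"])
    log = pd.DataFrame(
        {
            "agent_id": np.concatenate(parts["agent_id"]),
            "group": pd.Categorical(np.concatenate(parts["group"])),
            "week": np.concatenate(parts["week"]),
            "store_id": pd.Categorical(store_ids[store_cols]),
            "store_type": pd.Categorical(store_type[store_cols]),
            "zone": pd.Categorical(
                np.asarray(ZONES, dtype=object)[zone_arr], categories=list(ZONES)
            ),
            "mode": pd.Categorical(
                np.asarray(MODES, dtype=object)[mode_arr], categories=list(MODES)
            ),
            "motorized": np.isin(mode_arr,
                                 [MODES.index(m) for m in MODES if MOTORIZED[m]]),
            "distance_miles": np.concatenate(parts["distance"]),
        }
    )
    return log


def _empty_log() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "agent_id": pd.Series(dtype=np.int64),
            "group": pd.Categorical([]),
            "week": pd.Series(dtype=np.int32),
            "store_id": pd.Categorical([]),
            "store_type": pd.Categorical([]),
            "zone": pd.Categorical([], categories=list(ZONES)),
            "mode": pd.Categorical([], categories=list(MODES)),
            "motorized": pd.Series(dtype=bool),
            "distance_miles": pd.Series(dtype=float),
        }
    )


def write_trip_log(log: pd.DataFrame, path) -> None:
    """Trip log as CSV: agent_id, group, week, store_id, store_type, zone,
    mode, motorized, distance_miles."""
    log.to_csv(path, index=False)
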