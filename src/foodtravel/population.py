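"""Agent groups, sample-based Monte Carlo upscaling, and agent placement.

The survey population is stratified into eight income × age groups. The
income rows are [0, 20k), [20k, 50k), [50k, ∞) USD/yr and the age columns
18–44, 45–64, 65+ (both closed); the two highest-income older cells are
merged into a single group. Upscaling expands the 188-respondent sample to
the full household population: per census tract, group labels are drawn
multinomially from the tract's group mix, and each synthetic household
resamples one respondent record (with replacement) from its group.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, PlacementError
from .env_model import House, STORE_TYPES

#: canonical group order; sample sizes sum to 188
GROUP_ORDER = (
    "CoLwInYg",
    "CoLwInMiAg",
    "CoLwInOld",
    "LwInYg",
    "LwInMiAg",
    "LwInOld",
    "MeInYg",
    "MeInMiAgOld",
)

GROUP_SAMPLE_SIZES = {
    "CoLwInYg": 33,
    "CoLwInMiAg": 43,
    "CoLwInOld": 15,
    "LwInYg": 23,
    "LwInMiAg": 28,
    "LwInOld": 11,
    "MeInYg": 13,
    "MeInMiAgOld": 22,
}

INCOME_STRATA = ("<20k", "20k-49.99k", ">=50k")
AGE_STRATA = ("18-44", "45-64", "65+")

GROUP_INCOME = {
    "CoLwInYg": "<20k",
    "CoLwInMiAg": "<20k",
    "CoLwInOld": "<20k",
    "LwInYg": "20k-49.99k",
    "LwInMiAg": "20k-49.99k",
    "LwInOld": "20k-49.99k",
    "MeInYg": ">=50k",
    "MeInMiAgOld": ">=50k",
}

GROUP_AGE = {
    "CoLwInYg": "18-44",
    "CoLwInMiAg": "45-64",
    "CoLwInOld": "65+",
    "LwInYg": "18-44",
    "LwInMiAg": "45-64",
    "LwInOld": "65+",
    "MeInYg": "18-44",
    "MeInMiAgOld": "45-64/65+",
}

MODES = ("car", "bus", "taxi", "walk", "bike")
NONCAR_MODES = ("bus", "taxi", "walk", "bike")
MOTORIZED = {"car": True, "bus": True, "taxi": True, "walk": False, "bike": False}


def stratify_respondent(age: float, income: float) -> str:
    """Map (age in years, household income in USD/yr) to its group name."""
    if age < 18:
        raise ValueError("survey respondents must be 18 years or older")
    if income < 0:
        raise ValueError("income must be nonnegative")
    if income < 20_000:
        row = 0
    elif income < 50_000:
        row = 1
    else:
        row = 2
    col = 0 if age <= 44 else (1 if age <= 64 else 2)
    table = [
        ["CoLwInYg", "CoLwInMiAg", "CoLwInOld"],
        ["LwInYg", "LwInMiAg", "LwInOld"],
        ["MeInYg", "MeInMiAgOld", "MeInMiAgOld"],
    ]
    return table[row][col]


def _normalized(weights: dict, what: str) -> dict:
    vals = np.array(list(weights.values()), dtype=float)
    if (vals < 0).any() or vals.sum() <= 0:
        raise ConfigurationError(f"{what}: weights must be nonnegative, positive sum")
    return {k: float(v / vals.sum()) for k, v in weights.items()}


@dataclass
class AgentGroup:
    """One income × age stratum and its empirical probability distributions."""

    name: str
    income_stratum: str
    age_stratum: str
    sample_size: int
    car_ownership_prob: float
    trip_count_distribution: dict[int, float]
    type_consideration_prob: float
    mode_first_prob: float
    store_type_weights: dict[str, float]
    store_pool: dict[str, float]
    #: calibrated per-trip zone marginal {neighborhood, city, suburbs}
    zone_shares: dict[str, float]
    #: marginal mode distribution for carless agents (mode-first branch)
    noncar_mode_distribution: dict[str, float]
    #: per-distance-bin mode distribution for carless agents (store-first
    #: branch); rows align with SimulationConfig.distance_bins
    noncar_mode_by_distance: list[dict[str, float]]
    household_size_mean: float
    #: zone distribution conditional on the considered store type, and the
    #: complementary distribution for trips that skip the type decision;
    #: their type_consideration_prob-mixture equals zone_shares. When None,
    #: zone_shares is used unconditionally (uncoupled zone and type).
    zone_shares_by_type: dict[str, dict[str, float]] | None = None
    zone_shares_unconsidered: dict[str, float] | None = None

    def zone_dist_for_type(self, store_type: str) -> dict[str, float]:
        if self.zone_shares_by_type is None:
            return self.zone_shares
        return self.zone_shares_by_type[store_type]

    def zone_dist_unconsidered(self) -> dict[str, float]:
        if self.zone_shares_unconsidered is None:
            return self.zone_shares
        return self.zone_shares_unconsidered

    def __post_init__(self) -> None:
        for p, what in [
            (self.car_ownership_prob, "car_ownership_prob"),
            (self.type_consideration_prob, "type_consideration_prob"),
            (self.mode_first_prob, "mode_first_prob"),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{self.name}: {what} must lie in [0, 1]")
        if not self.store_pool:
            raise ConfigurationError(f"{self.name}: store pool must be nonempty")
        self.trip_count_distribution = {
            int(k): v
            for k, v in _normalized(self.trip_count_distribution, "trip counts").items()
        }
        if any(k < 0 for k in self.trip_count_distribution):
            raise ConfigurationError(f"{self.name}: negative trip count")
        self.store_type_weights = _normalized(self.store_type_weights, "type weights")
        for t in self.store_type_weights:
            if t not in STORE_TYPES:
                raise ConfigurationError(f"{self.name}: unknown store type {t!r}")
        self.store_pool = _normalized(self.store_pool, "store pool")
        self.zone_shares = _normalized(self.zone_shares, "zone shares")
        self.noncar_mode_distribution = _normalized(
            self.noncar_mode_distribution, "noncar modes"
        )
        self.noncar_mode_by_distance = [
            _normalized(row, "binned noncar modes") for row in self.noncar_mode_by_distance
        ]
        if (self.zone_shares_by_type is None) != (self.zone_shares_unconsidered is None):
            raise ConfigurationError(
                f"{self.name}: zone_shares_by_type and zone_shares_unconsidered "
                "must be given together"
            )
        if self.zone_shares_by_type is not None:
            self.zone_shares_by_type = {
                t: _normalized(d, f"zone|{t}") for t, d in self.zone_shares_by_type.items()
            }
            for t in self.store_type_weights:
                if t not in self.zone_shares_by_type:
                    raise ConfigurationError(
                        f"{self.name}: no zone distribution for considered type {t!r}"
                    )
            self.zone_shares_unconsidered = _normalized(
                self.zone_shares_unconsidered, "unconsidered zones"
            )

    def zone_marginal(self, type_consideration_prob: float | None = None) -> dict:
        """Per-trip zone law implied by the type-conditional distributions.

        Equals ``zone_shares`` by construction at the group's own
        consideration probability; shifts when that probability is varied
        (e.g. in the sensitivity analysis)."""
        p = (
            self.type_consideration_prob
            if type_consideration_prob is None
            else type_consideration_prob
        )
        out = {}
        for z in self.zone_shares:
            considered = sum(
                w * self.zone_dist_for_type(t).get(z, 0.0)
                for t, w in self.store_type_weights.items()
            )
            out[z] = p * considered + (1 - p) * self.zone_dist_unconsidered().get(z, 0.0)
        return out

    @property
    def mean_trips_per_week(self) -> float:
        return float(
            sum(k * p for k, p in self.trip_count_distribution.items())
        )


@dataclass
class TractProfile:
    tract_id: str
    household_count: int
    group_mix: dict[str, float]

    def __post_init__(self) -> None:
        if self.household_count <= 0:
            raise ConfigurationError(f"tract {self.tract_id}: household_count <= 0")
        self.group_mix = _normalized(self.group_mix, f"tract {self.tract_id} mix")


@dataclass
class HouseholdAgent:
    id: int
    group: str
    respondent_id: str | None = None
    house_id: str | None = None
    tract_id: str | None = None
    has_car: bool | None = None
    persons: int | None = None


def load_tracts(path) -> list[TractProfile]:
    """Read tracts.csv: tract_id, household_count, one share column per group."""
    df = pd.read_csv(path)
    tracts = []
    for _, row in df.iterrows():
        mix = {g: float(row[g]) for g in GROUP_ORDER}
        tracts.append(
            TractProfile(str(row["tract_id"]), int(row["household_count"]), mix)
        )
    return tracts


def upscale_population(
    respondents: pd.DataFrame,
    tracts: list[TractProfile],
    seed,
) -> list[HouseholdAgent]:
    """Sample-based Monte Carlo proportional upscaling of the survey sample.

    For each tract, ``household_count`` agents are drawn by (i) a multinomial
    draw of group labels from the tract's group mix and (ii) resampling one
    respondent record per label, with replacement, within the group.
    Fully reproducible given ``seed``.
    """
    rng = _as_rng(seed)
    by_group = {
        g: respondents.index[respondents["group"] == g].to_numpy()
        for g in GROUP_ORDER
    }
    agents: list[HouseholdAgent] = []
    next_id = 0
    for tract in tracts:
        names = [g for g in GROUP_ORDER if tract.group_mix.get(g, 0.0) > 0]
        probs = np.array([tract.group_mix[g] for g in names])
        for g in names:
            if len(by_group[g]) == 0:
                raise ConfigurationError(
                    f"tract {tract.tract_id}: mix puts mass on empty group {g}"
                )
        counts = rng.multinomial(tract.household_count, probs / probs.sum())
        for g, n in zip(names, counts):
            if n == 0:
                continue
            picks = rng.choice(by_group[g], size=n, replace=True)
            for r in picks:
                agents.append(
                    HouseholdAgent(
                        id=next_id,
                        group=g,
                        respondent_id=str(respondents.loc[r, "respondent_id"]),
                        tract_id=tract.tract_id,
                    )
                )
                next_id += 1
    return agents


def instantiate_agents(
    agents: list[HouseholdAgent],
    houses_by_tract: dict[str, list[House]],
    groups: dict[str, AgentGroup],
    seed,
) -> list[HouseholdAgent]:
    """Place agents in houses of their tract and draw car access and size.

    Houses are drawn uniformly within the tract (several agents may share a
    house). Car access is Bernoulli with the group's ownership probability;
    household size is 1 + Poisson(mean − 1), matching the stratum mean.
    """
    rng = _as_rng(seed)
    for agent in agents:
        pool = houses_by_tract.get(agent.tract_id, [])
        if not pool:
            raise PlacementError(
                f"tract {agent.tract_id} holds agents but has no houses"
            )
        house = pool[int(rng.integers(len(pool)))]
        agent.house_id = house.id
        g = groups[agent.group]
        agent.has_car = bool(rng.random() < g.car_ownership_prob)
        agent.persons = 1 + int(rng.poisson(max(g.household_size_mean - 1.0, 0.0)))
    return agents


def agents_frame(agents: list[HouseholdAgent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "agent_id": [a.id for a in agents],
            "group": pd.Categorical([a.group for a in agents], categories=GROUP_ORDER),
            "respondent_id": [a.respondent_id for a in agents],
            "tract_id": [a.tract_id for a in agents],
            "house_id": [a.house_id for a in agents],
            "has_car": [a.has_car for a in agents],
            "persons": [a.persons for a in agents],
        }
    )


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
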