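"""Synthetic study conditions: city, survey sample, calibrated group fixtures.

The survey microdata and the real GIS extracts behind the study are not
deposited, so this module builds a stand-in study area and sample whose
*aggregates* are calibrated to the published numbers:

* a three-zone city — a ~9.6 sq mi neighborhood of 23 census tracts nested
  in a 12 × 12 mi city, with suburbs along arterial corridors running
  northeast, stores concentrated on the arterials and national-chain
  supermarkets only in the suburbs (the 2008 condition the study captures);
* a 188-row respondent sample with the published stratum sizes
  (33, 43, 15, 23, 28, 11, 13, 22 across the eight income × age groups);
* per-group probability fixtures (car ownership, trip counts, modes, store
  pools, zone shares) whose simulated aggregates reproduce the published
  zone shares, car-ownership shares, trip frequencies and non-motorized
  travel bands.

Everything is generated programmatically and seed-deterministic; all
synthetic stand-ins are labelled as such.
"""
from __future__ import annotations

import json
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .decision_engine import DEFAULT_DISTANCE_BINS
from .env_model import (
    Environment,
    ODMatrix,
    STORE_TYPES,
    ZONES,
    build_od_matrix,
    load_environment,
)
from .errors import CalibrationError, ConfigurationError, RecipeError
from .population import (
    AgentGroup,
    GROUP_AGE,
    GROUP_INCOME,
    GROUP_ORDER,
    GROUP_SAMPLE_SIZES,
    TractProfile,
    load_tracts,
)

# ---------------------------------------------------------------------------
# study conditions: the published aggregates the fixtures are calibrated to
# ---------------------------------------------------------------------------

#: per-trip shopping-zone shares (neighborhood, city, suburbs). The two
#: pinned groups carry the published splits (25/57/18 and 11/37/52); the
#: remaining six are plausible interpolations, rescaled at build time so the
#: trip-weighted population neighborhood share is exactly 23%.
ZONE_SHARE_BASE = {
    "CoLwInYg": (0.25, 0.57, 0.18),
    "CoLwInMiAg": (0.28, 0.47, 0.25),
    "CoLwInOld": (0.30, 0.45, 0.25),
    "LwInYg": (0.20, 0.40, 0.40),
    "LwInMiAg": (0.22, 0.40, 0.38),
    "LwInOld": (0.25, 0.40, 0.35),
    "MeInYg": (0.11, 0.37, 0.52),
    "MeInMiAgOld": (0.15, 0.33, 0.52),
}
PINNED_GROUPS = ("CoLwInYg", "MeInYg")
POPULATION_NEIGHBORHOOD_SHARE = 0.23

#: share of households without vehicle access. Car owners always drive, so a
#: group's non-motorized trip share is bounded by its no-car share; the young
#: core-poor value is set high enough to support their published 40-50%
#: non-motorized band, while the top stratum stays at the published ~10% and
#: the whole population above 30%.
NO_CAR_SHARE = {
    "CoLwInYg": 0.58,
    "CoLwInMiAg": 0.42,
    "CoLwInOld": 0.30,
    "LwInYg": 0.32,
    "LwInMiAg": 0.25,
    "LwInOld": 0.20,
    "MeInYg": 0.10,
    "MeInMiAgOld": 0.10,
}

#: weekly trip-count means; the sample-weighted mixture mean is ~5.0
#: trips/week, the young shop most (the medium-income young by far), the old
#: least.
TRIP_MEAN = {
    "CoLwInYg": 5.5,
    "CoLwInMiAg": 5.0,
    "CoLwInOld": 3.0,
    "LwInYg": 5.5,
    "LwInMiAg": 5.0,
    "LwInOld": 3.0,
    "MeInYg": 8.5,
    "MeInMiAgOld": 4.0,
}

#: mean persons supported by the household income, per income stratum
HOUSEHOLD_SIZE_MEAN = {"<20k": 2.20, "20k-49.99k": 2.37, ">=50k": 2.56}

#: marginal non-car mode split (walk, bike, bus, taxi) for the mode-first
#: branch; the young lean on walking/cycling, the old on the bus.
NONCAR_MODE_MARGINAL = {
    "CoLwInYg": (0.62, 0.26, 0.10, 0.02),
    "CoLwInMiAg": (0.45, 0.20, 0.32, 0.03),
    "CoLwInOld": (0.28, 0.12, 0.55, 0.05),
    "LwInYg": (0.50, 0.25, 0.23, 0.02),
    "LwInMiAg": (0.40, 0.18, 0.39, 0.03),
    "LwInOld": (0.25, 0.12, 0.58, 0.05),
    "MeInYg": (0.60, 0.25, 0.13, 0.02),
    "MeInMiAgOld": (0.30, 0.15, 0.50, 0.05),
}

#: probability that a carless store-first trip is motorized, per 1-mile
#: distance bin [0,1), ..., [9,10), [10,inf). Motorized share rises with
#: distance; the low-income young go fully motorized at 6 miles and beyond,
#: the medium-income young level off below 1 (some walk/cycle past 8 miles).
MOTORIZED_PROB_CURVE = {
    "CoLwInYg": (0.02, 0.04, 0.06, 0.10, 0.14, 0.20, 0.28, 0.38, 0.48, 0.58, 0.72),
    "CoLwInMiAg": (0.05, 0.08, 0.12, 0.20, 0.30, 0.45, 0.60, 0.72, 0.82, 0.90, 0.95),
    "CoLwInOld": (0.30, 0.40, 0.50, 0.60, 0.70, 0.80, 0.88, 0.93, 0.96, 0.98, 1.0),
    "LwInYg": (0.05, 0.10, 0.20, 0.35, 0.50, 0.75, 1.0, 1.0, 1.0, 1.0, 1.0),
    "LwInMiAg": (0.20, 0.30, 0.40, 0.55, 0.65, 0.78, 0.88, 0.94, 0.97, 0.99, 1.0),
    "LwInOld": (0.35, 0.45, 0.55, 0.65, 0.75, 0.85, 0.92, 0.96, 0.98, 0.99, 1.0),
    "MeInYg": (0.40, 0.45, 0.50, 0.55, 0.60, 0.65, 0.70, 0.75, 0.80, 0.85, 0.85),
    "MeInMiAgOld": (0.40, 0.50, 0.60, 0.70, 0.80, 0.88, 0.93, 0.96, 0.98, 0.99, 1.0),
}

#: store-type weights used when a trip explicitly considers the store type
#: (type is a proxy for what groceries to buy, so full-line supermarkets
#: dominate); deliberately more supermarket-heavy than the habitual store
#: pools, which include quick convenience/dollar visits.
TYPE_CONSIDERATION_WEIGHTS = {
    "chain_supermarket": 0.15,
    "independent_supermarket": 0.55,
    "convenience": 0.12,
    "dollar": 0.10,
    "other": 0.08,
}

#: where a trip lands once a store type has been decided: chain supermarkets
#: exist only in the suburbs, quick formats mostly nearby. Deciding what
#: groceries to buy therefore largely decides how far the household travels
#: — the dominant driver of distance variability.
ZONE_BY_TYPE = {
    "chain_supermarket": {"neighborhood": 0.0, "city": 0.0, "suburbs": 1.0},
    "independent_supermarket": {"neighborhood": 0.15, "city": 0.55, "suburbs": 0.30},
    "convenience": {"neighborhood": 0.55, "city": 0.40, "suburbs": 0.05},
    "dollar": {"neighborhood": 0.45, "city": 0.45, "suburbs": 0.10},
    "other": {"neighborhood": 0.25, "city": 0.50, "suburbs": 0.25},
}

#: relative report propensity by store type when respondents list the stores
#: they habitually visit (habitual pools mix quick trips with supermarket
#: runs, so they are less supermarket-heavy than the deliberate type choice)
REPORT_ATTRACTIVENESS = {
    "chain_supermarket": 3.0,
    "independent_supermarket": 1.2,
    "convenience": 1.5,
    "dollar": 1.2,
    "other": 0.8,
}

#: published non-motorized trip-share bands used in validation: (low, high,
#: max distance in miles or None for all trips)
NONMOTORIZED_BANDS = {
    "CoLwInYg": (0.40, 0.50, None),
    "CoLwInMiAg": (0.20, 0.40, 5.0),
    "CoLwInOld": (0.00, 0.20, None),
    "LwInYg": (0.00, 0.25, None),
    "LwInMiAg": (0.00, 0.20, None),
    "LwInOld": (0.00, 0.20, None),
    "MeInYg": (0.00, 0.20, None),
    "MeInMiAgOld": (0.00, 0.20, None),
}

TYPE_CONSIDERATION_PROB = 0.5
MODE_FIRST_PROB = 0.5
STORES_PER_RESPONDENT = 6
TRIP_PMF_SUPPORT = 26  # trip counts 0..25 (truncation bias < 1e-4 at mean 8.5)


@dataclass
class CalibrationTargets:
    """Published aggregates the group fixtures must reproduce in output."""

    group_zone_shares: dict[str, dict[str, float]]
    population_neighborhood_share: float
    no_car_share: dict[str, float]
    trip_mean: dict[str, float]
    household_size_mean: dict[str, float]
    nonmotorized_bands: dict[str, tuple]

    def __post_init__(self) -> None:
        for g, shares in self.group_zone_shares.items():
            vals = np.array(list(shares.values()))
            if (vals < 0).any() or abs(vals.sum() - 1.0) > 1e-9:
                raise ConfigurationError(f"{g}: zone shares must sum to 1")

    @classmethod
    def default(cls) -> "CalibrationTargets":
        shares = _solve_population_share(
            ZONE_SHARE_BASE, TRIP_MEAN, GROUP_SAMPLE_SIZES,
            POPULATION_NEIGHBORHOOD_SHARE, PINNED_GROUPS,
        )
        return cls(
            group_zone_shares=shares,
            population_neighborhood_share=POPULATION_NEIGHBORHOOD_SHARE,
            no_car_share=dict(NO_CAR_SHARE),
            trip_mean=dict(TRIP_MEAN),
            household_size_mean=dict(HOUSEHOLD_SIZE_MEAN),
            nonmotorized_bands=dict(NONMOTORIZED_BANDS),
        )

    def expected_population_zone_shares(self) -> dict[str, float]:
        """Trip-weighted zone shares over the eight groups (analytic)."""
        w = np.array([GROUP_SAMPLE_SIZES[g] * self.trip_mean[g] for g in GROUP_ORDER])
        w = w / w.sum()
        out = {}
        for z in ZONES:
            out[z] = float(
                sum(wi * self.group_zone_shares[g][z] for wi, g in zip(w, GROUP_ORDER))
            )
        return out

    def to_yaml(self, path) -> None:
        payload = {
            "group_zone_shares": {
                g: {z: float(v) for z, v in d.items()}
                for g, d in self.group_zone_shares.items()
            },
            "population_neighborhood_share": self.population_neighborhood_share,
            "no_car_share": {k: float(v) for k, v in self.no_car_share.items()},
            "trip_mean": {k: float(v) for k, v in self.trip_mean.items()},
            "household_size_mean": {
                k: float(v) for k, v in self.household_size_mean.items()
            },
            "nonmotorized_bands": {
                k: list(v) for k, v in self.nonmotorized_bands.items()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CalibrationTargets":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        payload["nonmotorized_bands"] = {
            k: tuple(v) for k, v in payload["nonmotorized_bands"].items()
        }
        return cls(**payload)


def _solve_population_share(base, trip_mean, sizes, pop_target, pinned):
    """Rescale free groups' neighborhood shares (city absorbs the shift) so
    the expected trip-weighted population neighborhood share hits the target."""
    w = {g: sizes[g] * trip_mean[g] for g in GROUP_ORDER}
    total = sum(w.values())
    pinned_mass = sum(w[g] * base[g][0] for g in pinned)
    free_mass = sum(w[g] * base[g][0] for g in GROUP_ORDER if g not in pinned)
    needed = pop_target * total - pinned_mass
    if free_mass <= 0 or needed <= 0:
        raise CalibrationError("population neighborhood share target infeasible")
    factor = needed / free_mass
    shares = {}
    for g in GROUP_ORDER:
        n, c, s = base[g]
        if g not in pinned:
            n2 = n * factor
            c2 = 1.0 - n2 - s
            if c2 <= 0 or n2 >= 1:
                raise CalibrationError(f"{g}: rescaled zone shares infeasible")
            n, c = n2, c2
        shares[g] = {"neighborhood": n, "city": c, "suburbs": s}
    return shares


# ---------------------------------------------------------------------------
# synthetic city
# ---------------------------------------------------------------------------

@dataclass
class CityRecipe:
    """Geometry and store layout of the synthetic three-zone city (miles)."""

    city_extent: float = 12.0  # city = [0, extent]^2
    neighborhood_origin: tuple = (2.0, 2.0)
    neighborhood_side: float = 3.1  # 9.61 sq mi, "just under 10"
    city_grid_spacing: float = 1.0
    neighborhood_grid_points: int = 21  # ~0.155 mi spacing
    #: suburb arterial corridors: (axis, fixed coord, start, stop) with nodes
    #: every mile; 'h' runs east at fixed y, 'v' runs north at fixed x
    corridors: tuple = (
        ("h", 8.0, 13.0, 20.0),
        ("h", 4.0, 13.0, 19.0),
        ("v", 8.0, 13.0, 18.0),
    )
    #: city arterial lines (within the city, stores sit on these)
    city_arterials: tuple = (("h", 4.0), ("h", 8.0), ("v", 8.0))
    store_counts: dict = field(
        default_factory=lambda: {
            "neighborhood": {
                "independent_supermarket": 3,
                "convenience": 6,
                "dollar": 3,
                "other": 2,
            },
            "city": {
                "independent_supermarket": 8,
                "convenience": 8,
                "dollar": 5,
                "other": 4,
            },
            "suburbs": {
                "chain_supermarket": 8,
                "independent_supermarket": 4,
                "convenience": 3,
                "dollar": 2,
                "other": 2,
            },
        }
    )
    n_tracts: int = 23
    houses_per_tract: int = 130
    total_households: int = 14_536  # "a little over 14.5k"

    def __post_init__(self) -> None:
        if self.neighborhood_side <= 0 or self.city_extent <= 0:
            raise RecipeError("extents must be positive")
        x0, y0 = self.neighborhood_origin
        if (
            x0 < 0
            or y0 < 0
            or x0 + self.neighborhood_side >= self.city_extent
            or y0 + self.neighborhood_side >= self.city_extent
        ):
            raise RecipeError("neighborhood must sit strictly inside the city")
        for zone, counts in self.store_counts.items():
            for t, c in counts.items():
                if t not in STORE_TYPES or c < 0:
                    raise RecipeError(f"bad store count {zone}/{t}")


def _grid_coords(recipe: CityRecipe) -> np.ndarray:
    city = np.arange(0.0, recipe.city_extent + 1e-9, recipe.city_grid_spacing)
    x0, _ = recipe.neighborhood_origin
    nbhd = np.linspace(x0, x0 + recipe.neighborhood_side, recipe.neighborhood_grid_points)
    return np.unique(np.round(np.concatenate([city, nbhd]), 9))


def _corridor_nodes(recipe: CityRecipe) -> list[tuple[float, float]]:
    nodes = []
    for axis, fixed, start, stop in recipe.corridors:
        for c in np.arange(start, stop + 1e-9, 1.0):
            nodes.append((c, fixed) if axis == "h" else (fixed, c))
    return nodes


def _tract_cell(recipe: CityRecipe, idx: int) -> tuple:
    """Rectangle of tract ``idx`` in a 6 x 4 grid over the neighborhood; the
    last two cells are merged so 24 cells give 23 tracts."""
    ncol, nrow = 6, 4
    x0, y0 = recipe.neighborhood_origin
    w = recipe.neighborhood_side / ncol
    h = recipe.neighborhood_side / nrow
    cells = [idx] if idx < recipe.n_tracts - 1 else [recipe.n_tracts - 1, recipe.n_tracts]
    rects = []
    for c in cells:
        col, row = c % ncol, c // ncol
        rects.append((x0 + col * w, y0 + row * h, x0 + (col + 1) * w, y0 + (row + 1) * h))
    return rects


def generate_synthetic_city(recipe: CityRecipe, seed, out_dir) -> dict[str, Path]:
    """Write houses/stores/roads/zones GeoJSON and tracts.csv for the recipe.

    The road network is a non-uniform grid over the city (fine inside the
    neighborhood so every house snaps within the default radius) plus
    mile-spaced suburb corridors; stores sit exactly on network nodes, with
    zone-stratified counts and chain supermarkets pushed to the far ends of
    the corridors.
    """
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    coords = _grid_coords(recipe)
    x0, y0 = recipe.neighborhood_origin
    x1 = x0 + recipe.neighborhood_side
    y1 = y0 + recipe.neighborhood_side

    # --- roads: one LineString per grid row/column + corridors
    road_features = []
    for y in coords:
        road_features.append(_line([(x, y) for x in coords]))
    for x in coords:
        road_features.append(_line([(x, y) for y in coords]))
    for axis, fixed, start, stop in recipe.corridors:
        pts = [
            (c, fixed) if axis == "h" else (fixed, c)
            for c in np.concatenate(
                [[start - 1.0], np.arange(start, stop + 1e-9, 1.0)]
            )
        ]
        road_features.append(_line(pts))

    # --- candidate store nodes per zone
    nbhd_nodes = [
        (x, y) for x in coords for y in coords if x0 <= x <= x1 and y0 <= y <= y1
    ]
    city_nodes = []
    for axis, fixed in recipe.city_arterials:
        for c in coords:
            p = (c, fixed) if axis == "h" else (fixed, c)
            inside_nbhd = x0 <= p[0] <= x1 and y0 <= p[1] <= y1
            if not inside_nbhd and p not in city_nodes:
                city_nodes.append(p)
    suburb_nodes = _corridor_nodes(recipe)

    center = ((x0 + x1) / 2.0, (y0 + y1) / 2.0)

    def manhattan(p):
        return abs(p[0] - center[0]) + abs(p[1] - center[1])

    store_features = []
    sid = 0
    for zone, candidates in (
        ("neighborhood", nbhd_nodes),
        ("city", city_nodes),
        ("suburbs", suburb_nodes),
    ):
        counts = recipe.store_counts.get(zone, {})
        n_needed = sum(counts.values())
        if n_needed > len(candidates):
            raise RecipeError(
                f"{zone}: {n_needed} stores requested but only "
                f"{len(candidates)} corridor nodes available"
            )
        picked = [candidates[i] for i in
                  rng.choice(len(candidates), size=n_needed, replace=False)]
        # supermarkets toward the far end of the zone, quick formats nearby
        picked.sort(key=manhattan)
        order = [
            t
            for t in (
                "convenience",
                "dollar",
                "other",
                "independent_supermarket",
                "chain_supermarket",
            )
            for _ in range(counts.get(t, 0))
        ]
        for p, t in zip(picked, order):
            store_features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": list(p)},
                    "properties": {"id": f"S{sid:03d}", "store_type": t},
                }
            )
            sid += 1

    # --- houses, uniform within their tract cell
    house_features = []
    hid = 0
    for t in range(recipe.n_tracts):
        rects = _tract_cell(recipe, t)
        areas = np.array([(r[2] - r[0]) * (r[3] - r[1]) for r in rects])
        for _ in range(recipe.houses_per_tract):
            r = rects[int(rng.choice(len(rects), p=areas / areas.sum()))]
            hx = rng.uniform(r[0], r[2])
            hy = rng.uniform(r[1], r[3])
            house_features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [hx, hy]},
                    "properties": {"id": f"H{hid:04d}", "tract_id": f"T{t:02d}"},
                }
            )
            hid += 1

    zone_features = [
        {
            "type": "Feature",
            "geometry": _box(x0, y0, x1, y1),
            "properties": {"level": "neighborhood"},
        },
        {
            "type": "Feature",
            "geometry": _box(0.0, 0.0, recipe.city_extent, recipe.city_extent),
            "properties": {"level": "city"},
        },
    ]

    paths = {}
    for name, feats in (
        ("houses", house_features),
        ("stores", store_features),
        ("roads", road_features),
        ("zones", zone_features),
    ):
        p = out / f"{name}.geojson"
        with open(p, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)
        paths[name] = p

    # --- tract profiles: household counts and group mixes
    hh = rng.multinomial(
        recipe.total_households,
        rng.dirichlet(np.full(recipe.n_tracts, 50.0)),
    )
    hh = np.maximum(hh, 1)
    alpha = np.array([GROUP_SAMPLE_SIZES[g] for g in GROUP_ORDER], dtype=float)
    rows = []
    for t in range(recipe.n_tracts):
        mix = rng.dirichlet(alpha)
        rows.append(
            {"tract_id": f"T{t:02d}", "household_count": int(hh[t]),
             **{g: mix[i] for i, g in enumerate(GROUP_ORDER)}}
        )
    tracts = out / "tracts.csv"
    pd.DataFrame(rows).to_csv(tracts, index=False)
    paths["tracts"] = tracts
    return paths


def _line(points) -> dict:
    return {
        "type": "Feature",
        "geometry": {
            "type": "LineString",
            "coordinates": [[float(x), float(y)] for x, y in points],
        },
        "properties": {},
    }


def _box(x0, y0, x1, y1) -> dict:
    return {
        "type": "Polygon",
        "coordinates": [[[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]],
    }


# ---------------------------------------------------------------------------
# synthetic survey sample
# ---------------------------------------------------------------------------

_AGE_RANGE = {"18-44": (18, 44), "45-64": (45, 64), "65+": (65, 85), "45-64/65+": (45, 85)}
_INCOME_RANGE = {"<20k": (6_000, 19_999), "20k-49.99k": (20_000, 49_999), ">=50k": (50_000, 120_000)}


def emulate_survey_sample(
    targets: CalibrationTargets, stores, seed
) -> pd.DataFrame:
    """Synthetic 188-row respondent sample with the published stratum sizes.

    Attributes are drawn from the calibration targets; each respondent
    reports the handful of stores they habitually visit, drawn zone-first
    from the group's zone shares and within zone by store-type report
    propensity. Columns: respondent_id, group, age, income, has_car,
    persons, trips_per_week, stores (';'-joined ids).
    """
    rng = np.random.default_rng(seed)
    by_zone: dict[str, list] = {z: [] for z in ZONES}
    for s in stores:
        by_zone[s.zone].append(s)
    rows = []
    rid = 0
    for g in GROUP_ORDER:
        alo, ahi = _AGE_RANGE[GROUP_AGE[g]]
        ilo, ihi = _INCOME_RANGE[GROUP_INCOME[g]]
        zshare = targets.group_zone_shares[g]
        pmf = trip_count_pmf(targets.trip_mean[g])
        for _ in range(GROUP_SAMPLE_SIZES[g]):
            zones = rng.choice(
                ZONES, size=STORES_PER_RESPONDENT, p=[zshare[z] for z in ZONES]
            )
            reported = []
            for z in zones:
                cand = by_zone[z]
                w = np.array([REPORT_ATTRACTIVENESS[s.store_type] for s in cand])
                reported.append(cand[int(rng.choice(len(cand), p=w / w.sum()))].id)
            rows.append(
                {
                    "respondent_id": f"R{rid:03d}",
                    "group": g,
                    "age": int(rng.integers(alo, ahi + 1)),
                    "income": int(rng.integers(ilo, ihi + 1)),
                    "has_car": bool(rng.random() >= targets.no_car_share[g]),
                    "persons": 1
                    + int(
                        rng.poisson(
                            targets.household_size_mean[GROUP_INCOME[g]] - 1.0
                        )
                    ),
                    "trips_per_week": int(
                        rng.choice(np.arange(len(pmf)), p=pmf)
                    ),
                    "stores": ";".join(reported),
                }
            )
            rid += 1
    return pd.DataFrame(rows)


def trip_count_pmf(mean: float, support: int = TRIP_PMF_SUPPORT) -> np.ndarray:
    """Poisson pmf with the given mean, renormalized on 0..support-1."""
    from scipy.stats import poisson

    p = poisson.pmf(np.arange(support), mean)
    return p / p.sum()


# ---------------------------------------------------------------------------
# calibrated group fixtures
# ---------------------------------------------------------------------------

def build_group_fixtures(
    respondents: pd.DataFrame,
    env: Environment,
    od: ODMatrix,
    targets: CalibrationTargets,
    n_distance_bins: int = len(DEFAULT_DISTANCE_BINS),
) -> dict[str, AgentGroup]:
    """Derive per-group fixtures from the respondent sample and targets.

    Store pools (which stores, with what within-zone weight) come from the
    respondents' reports; the per-trip zone distribution, car ownership,
    trip-count pmf and mode tables come from the calibration targets, so the
    simulated aggregates reproduce the published numbers in expectation. A
    group whose pool misses a zone carrying positive target share raises a
    calibration error.
    """
    stores_by_id = env.stores_by_id
    groups = {}
    for g in GROUP_ORDER:
        sub = respondents[respondents["group"] == g]
        if len(sub) == 0:
            raise CalibrationError(f"group {g}: no respondents")
        pool: dict[str, float] = {}
        for reports in sub["stores"]:
            for sid in str(reports).split(";"):
                pool[sid] = pool.get(sid, 0.0) + 1.0
        zshare = targets.group_zone_shares[g]
        pooled_zones = {stores_by_id[s].zone for s in pool}
        for z, share in zshare.items():
            if share > 0 and z not in pooled_zones:
                raise CalibrationError(
                    f"group {g}: target zone share {share:.2f} for {z!r} "
                    "but no reported store in that zone"
                )
        pmf = trip_count_pmf(targets.trip_mean[g])
        curve = MOTORIZED_PROB_CURVE[g]
        if len(curve) != n_distance_bins:
            raise ConfigurationError(
                f"group {g}: motorized curve has {len(curve)} bins, "
                f"expected {n_distance_bins}"
            )
        binned = [_bin_mode_row(m, b) for b, m in enumerate(curve)]
        walk, bike, bus, taxi = NONCAR_MODE_MARGINAL[g]
        zone_by_type, zone_unconsidered = _solve_zone_coupling(
            zshare, TYPE_CONSIDERATION_WEIGHTS, ZONE_BY_TYPE, TYPE_CONSIDERATION_PROB
        )
        groups[g] = AgentGroup(
            name=g,
            income_stratum=GROUP_INCOME[g],
            age_stratum=GROUP_AGE[g],
            sample_size=GROUP_SAMPLE_SIZES[g],
            car_ownership_prob=1.0 - targets.no_car_share[g],
            trip_count_distribution={i: float(p) for i, p in enumerate(pmf)},
            type_consideration_prob=TYPE_CONSIDERATION_PROB,
            mode_first_prob=MODE_FIRST_PROB,
            store_type_weights=dict(TYPE_CONSIDERATION_WEIGHTS),
            store_pool=pool,
            zone_shares={z: zshare[z] for z in ZONES},
            noncar_mode_distribution={
                "walk": walk, "bike": bike, "bus": bus, "taxi": taxi
            },
            noncar_mode_by_distance=binned,
            household_size_mean=targets.household_size_mean[GROUP_INCOME[g]],
            zone_shares_by_type=zone_by_type,
            zone_shares_unconsidered=zone_unconsidered,
        )
    return groups


def _solve_zone_coupling(target, type_weights, zone_by_type, p_consider):
    """Per-group type-conditional zone laws plus the complementary habitual
    law, constrained so their mixture equals the target zone marginal.

    Each type's zone law is restricted to the target's support and, when the
    implied considered mixture overshoots a zone's target, shrunk toward the
    target just enough that the habitual law stays a proper distribution
    (full coupling is retained whenever feasible)."""
    supported = {z: target.get(z, 0.0) > 0 for z in ZONES}
    cond = {}
    for t, w in type_weights.items():
        raw = {z: zone_by_type[t].get(z, 0.0) * supported[z] for z in ZONES}
        s = sum(raw.values())
        cond[t] = {z: v / s for z, v in raw.items()} if s > 0 else dict(target)
    mix = {
        z: sum(w * cond[t][z] for t, w in type_weights.items()) for z in ZONES
    }
    alpha = 1.0
    if 0 < p_consider < 1:
        for z in ZONES:
            if mix[z] > target.get(z, 0.0) + 1e-12:
                alpha = min(
                    alpha,
                    (1 - p_consider)
                    * target.get(z, 0.0)
                    / (p_consider * (mix[z] - target.get(z, 0.0))),
                )
    alpha = max(0.0, min(1.0, alpha))
    cond = {
        t: {z: alpha * d[z] + (1 - alpha) * target.get(z, 0.0) for z in ZONES}
        for t, d in cond.items()
    }
    if p_consider >= 1.0:
        return cond, dict(target)
    habitual = {}
    for z in ZONES:
        considered = sum(w * cond[t][z] for t, w in type_weights.items())
        habitual[z] = max(
            (target.get(z, 0.0) - p_consider * considered) / (1.0 - p_consider), 0.0
        )
    total = sum(habitual.values())
    if abs(total - 1.0) > 1e-6:
        raise CalibrationError("zone coupling solve left an improper habitual law")
    return cond, habitual


def _bin_mode_row(motorized_prob: float, bin_index: float) -> dict[str, float]:
    """Mode split for one distance bin: motorized mass to bus/taxi, the rest
    to walk/bike with walking fading out as distance grows."""
    m = float(motorized_prob)
    mid = bin_index + 0.5
    walk_frac = max(0.15, 1.0 - mid / 8.0)
    nm = 1.0 - m
    row = {
        "bus": m * 0.88,
        "taxi": m * 0.12,
        "walk": nm * walk_frac,
        "bike": nm * (1.0 - walk_frac),
    }
    return {k: v for k, v in row.items() if v > 0} or {"bus": 1.0}


def save_groups(groups: dict[str, AgentGroup], path) -> None:
    payload = {}
    for g, grp in groups.items():
        d = dict(grp.__dict__)
        d["trip_count_distribution"] = {
            str(k): v for k, v in grp.trip_count_distribution.items()
        }
        payload[g] = d
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_groups(path) -> dict[str, AgentGroup]:
    with open(path) as fh:
        payload = json.load(fh)
    out = {}
    for g, d in payload.items():
        d["trip_count_distribution"] = {
            int(k): v for k, v in d["trip_count_distribution"].items()
        }
        out[g] = AgentGroup(**d)
    return out


# ---------------------------------------------------------------------------
# the packaged study bundle
# ---------------------------------------------------------------------------

#: fixture seed of the packaged synthetic study
PACKAGED_FIXTURE_SEED = 42


@dataclass
class StudyBundle:
    recipe: CityRecipe
    targets: CalibrationTargets
    env: Environment
    od: ODMatrix
    groups: dict[str, AgentGroup]
    respondents: pd.DataFrame
    tracts: list[TractProfile]


def build_study(
    seed: int = PACKAGED_FIXTURE_SEED,
    out_dir=None,
    recipe: CityRecipe | None = None,
    targets: CalibrationTargets | None = None,
) -> StudyBundle:
    """Generate the packaged synthetic study end to end.

    Writes the environment files (to ``out_dir`` or a temporary directory),
    loads them back through the validated loader, builds the OD matrix, the
    respondent sample and the calibrated group fixtures.
    """
    recipe = recipe or CityRecipe()
    targets = targets or CalibrationTargets.default()
    ss = np.random.SeedSequence(seed)
    city_seed, survey_seed = ss.spawn(2)

    def _build(dirname):
        paths = generate_synthetic_city(recipe, city_seed, dirname)
        env = load_environment(
            paths["houses"], paths["stores"], paths["roads"], paths["zones"]
        )
        tracts = load_tracts(paths["tracts"])
        targets.to_yaml(Path(dirname) / "calibration_targets.yaml")
        od = build_od_matrix(env.network, env.houses, env.stores)
        respondents = emulate_survey_sample(targets, env.stores, survey_seed)
        respondents.to_csv(Path(dirname) / "respondents.csv", index=False)
        groups = build_group_fixtures(respondents, env, od, targets)
        save_groups(groups, Path(dirname) / "groups.json")
        return StudyBundle(recipe, targets, env, od, groups, respondents, tracts)

    if out_dir is not None:
        return _build(out_dir)
    with tempfile.TemporaryDirectory() as tmp:
        return _build(tmp)
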