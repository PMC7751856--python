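"""Shared fixtures: the packaged synthetic study and one full-scale run.

The full 52-week simulation of the upscaled population is expensive (~30 s),
so it is built once per session and shared by the behavioral-constraint,
calibration-closure and acceptance tests.
"""
import json

import numpy as np
import pytest
from hypothesis import settings

from foodtravel import build_study, simulate_study
from foodtravel.population import agents_frame

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

#: population/simulation seed used by the deterministic test run
RUN_SEED = 42
WEEKS = 52


@pytest.fixture(scope="session")
def study():
    return build_study()


@pytest.fixture(scope="session")
def full_run(study):
    agents, log = simulate_study(study, seed=RUN_SEED, weeks=WEEKS)
    return {
        "agents": agents,
        "agents_df": agents_frame(agents),
        "log": log,
        "weeks": WEEKS,
    }


def write_minimal_city(tmp_path, store_props=None):
    """Smallest valid environment: 1 house, 1 store, 2-node network, nested
    square zones."""
    store_props = (
        {"id": "S0", "store_type": "convenience"} if store_props is None else store_props
    )
    files = {}
    collections = {
        "houses": [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [1.0, 1.0]},
                "properties": {"id": "H0", "tract_id": "T0"},
            }
        ],
        "stores": [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [2.0, 1.0]},
                "properties": store_props,
            }
        ],
        "roads": [
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [[1.0, 1.0], [2.0, 1.0]],
                },
                "properties": {},
            }
        ],
        "zones": [
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[[0, 0], [4, 0], [4, 4], [0, 4], [0, 0]]],
                },
                "properties": {"level": "neighborhood"},
            },
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [[[-2, -2], [8, -2], [8, 8], [-2, 8], [-2, -2]]],
                },
                "properties": {"level": "city"},
            },
        ],
    }
    for name, feats in collections.items():
        p = tmp_path / f"{name}.geojson"
        p.write_text(json.dumps({"type": "FeatureCollection", "features": feats}))
        files[name] = p
    return files


def three_sigma_binomial(p: float, n: int) -> float:
    return 3.0 * np.sqrt(max(p * (1.0 - p), 1e-12) / n)
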