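"""End-to-end convenience pipeline: fixtures → population → trip log."""
from __future__ import annotations

import numpy as np
import pandas as pd

from .decision_engine import SimulationConfig, run_simulation
from .fixtures import StudyBundle
from .population import (
    HouseholdAgent,
    agents_frame,  # noqa: F401  (re-exported convenience)
    instantiate_agents,
    upscale_population,
)


def build_population(bundle: StudyBundle, seed: int) -> list[HouseholdAgent]:
    """Upscale the respondent sample and place agents in houses."""
    ss = np.random.SeedSequence(seed)
    up_seed, place_seed = [np.random.default_rng(c) for c in ss.spawn(2)]
    agents = upscale_population(bundle.respondents, bundle.tracts, up_seed)
    return instantiate_agents(
        agents, bundle.env.houses_by_tract, bundle.groups, place_seed
    )


def simulate_study(
    bundle: StudyBundle,
    seed: int,
    weeks: int = 52,
    agents: list[HouseholdAgent] | None = None,
    cfg: SimulationConfig | None = None,
) -> tuple[list[HouseholdAgent], pd.DataFrame]:
    """Build (or reuse) the upscaled population and run the weekly simulation.

    The population draws and the trip draws use independent streams derived
    from ``seed``.
    """
    if agents is None:
        agents = build_population(bundle, seed)
    if cfg is None:
        sim_seed = int(
            np.random.SeedSequence(seed, spawn_key=(7,)).generate_state(1)[0] % (2**31)
        )
        cfg = SimulationConfig(weeks=weeks, seed=sim_seed)
    log = run_simulation(agents, bundle.env, bundle.od, cfg, bundle.groups)
    return agents, log


__all__ = ["build_population", "simulate_study", "agents_frame"]
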