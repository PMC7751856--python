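"""Variance-based global sensitivity analysis (Sobol' indices).

A reusable Saltelli-sampling / Jansen-estimator engine, plus the harness
that runs it on the simulator: the uncertain decision parameters (the
mode-first vs store-first split, the probability of considering a store
type, and the walk/bike distance-decay scales) are varied jointly and their
first-order (S1) and total-order (ST) contributions to the variance of the
median distance traveled are estimated.

Sampling uses a scrambled Sobol' sequence in 2k dimensions split into the
classic A / B / AB_i / BA_i cross-sampling blocks; indices use the Jansen
(1999) estimators, with the mirrored BA block averaged in for S1. For a
deterministic model Σ S1 ≤ 1 and ST_i ≥ S1_i up to estimator noise.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .errors import AlignmentError, ConfigurationError


@dataclass
class SAProblem:
    """Named parameters with uniform ranges."""

    names: list[str]
    bounds: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.bounds):
            raise ConfigurationError("names and bounds must align")
        for n, (lo, hi) in zip(self.names, self.bounds):
            if not hi > lo:
                raise ConfigurationError(f"parameter {n}: empty range [{lo}, {hi}]")

    @property
    def k(self) -> int:
        return len(self.names)


#: the simulator's uncertain decision parameters
DEFAULT_PROBLEM = SAProblem(
    names=["mode_first_prob", "type_consideration_prob", "lambda_walk", "lambda_bike"],
    bounds=[(0.0, 1.0), (0.0, 1.0), (1.0, 5.0), (2.0, 10.0)],
)


@dataclass
class SAResult:
    problem: SAProblem
    S1: np.ndarray
    ST: np.ndarray
    S1_conf: np.ndarray  # (k, 2) percentile bootstrap CI
    ST_conf: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.problem.names,
                "S1": self.S1,
                "S1_lo": self.S1_conf[:, 0],
                "S1_hi": self.S1_conf[:, 1],
                "ST": self.ST,
                "ST_lo": self.ST_conf[:, 0],
                "ST_hi": self.ST_conf[:, 1],
            }
        )


def saltelli_sample(problem: SAProblem, N: int, seed) -> np.ndarray:
    """Cross-sampling design matrix with N(2k + 2) rows.

    Row layout: N rows of A, N rows of B, then N rows of AB_i for each
    parameter i (A with column i from B), then N rows of BA_i. Deterministic
    given the seed; a power-of-two N keeps the Sobol' sequence balanced.
    """
    if N < 1:
        raise ConfigurationError("N must be a positive integer")
    k = problem.k
    eng = qmc.Sobol(d=2 * k, scramble=True, seed=np.random.default_rng(seed))
    base = eng.random(N)
    lo = np.array([b[0] for b in problem.bounds])
    hi = np.array([b[1] for b in problem.bounds])
    A = lo + base[:, :k] * (hi - lo)
    B = lo + base[:, k:] * (hi - lo)
    blocks = [A, B]
    for i in range(k):
        AB = A.copy()
        AB[:, i] = B[:, i]
        blocks.append(AB)
    for i in range(k):
        BA = B.copy()
        BA[:, i] = A[:, i]
        blocks.append(BA)
    return np.vstack(blocks)


def _split_blocks(Y: np.ndarray, k: int):
    N = len(Y) // (2 * k + 2)
    if N * (2 * k + 2) != len(Y):
        raise AlignmentError(
            f"output length {len(Y)} is not N(2k+2) for k={k} parameters"
        )
    yA = Y[:N]
    yB = Y[N : 2 * N]
    yAB = [Y[(2 + i) * N : (3 + i) * N] for i in range(k)]
    yBA = [Y[(2 + k + i) * N : (3 + k + i) * N] for i in range(k)]
    return yA, yB, yAB, yBA


def _jansen(yA, yB, yAB, yBA):
    """Jansen estimators of S1 and ST, averaging the two mirrored halves."""
    y_all = np.concatenate([yA, yB])
    V = y_all.var(ddof=0)
    if V == 0:
        k = len(yAB)
        return np.zeros(k), np.zeros(k)
    S1, ST = [], []
    for ab, ba in zip(yAB, yBA):
        v1 = V - 0.5 * np.mean((yB - ab) ** 2)
        v1_m = V - 0.5 * np.mean((yA - ba) ** 2)
        vt = 0.5 * np.mean((yA - ab) ** 2)
        vt_m = 0.5 * np.mean((yB - ba) ** 2)
        S1.append(0.5 * (v1 + v1_m) / V)
        ST.append(0.5 * (vt + vt_m) / V)
    return np.array(S1), np.array(ST)


def sobol_indices(
    Y: np.ndarray,
    problem: SAProblem,
    n_bootstrap: int = 200,
    conf_level: float = 0.95,
    seed: int = 0,
) -> SAResult:
    """First- and total-order Sobol' indices from design-aligned outputs.

    ``Y`` must align row-for-row with :func:`saltelli_sample`. Confidence
    intervals are percentile bootstrap over resampled base-sample indices.
    """
    Y = np.asarray(Y, dtype=float)
    if not np.isfinite(Y).all():
        raise AlignmentError("model outputs must be finite")
    yA, yB, yAB, yBA = _split_blocks(Y, problem.k)
    S1, ST = _jansen(yA, yB, yAB, yBA)

    rng = np.random.default_rng(seed)
    N = len(yA)
    s1_bs = np.empty((n_bootstrap, problem.k))
    st_bs = np.empty((n_bootstrap, problem.k))
    for b in range(n_bootstrap):
        idx = rng.integers(0, N, size=N)
        s1_bs[b], st_bs[b] = _jansen(
            yA[idx], yB[idx], [ab[idx] for ab in yAB], [ba[idx] for ba in yBA]
        )
    alpha = 100 * (1 - conf_level) / 2
    S1_conf = np.percentile(s1_bs, [alpha, 100 - alpha], axis=0).T
    ST_conf = np.percentile(st_bs, [alpha, 100 - alpha], axis=0).T
    return SAResult(problem, S1, ST, S1_conf, ST_conf)


@dataclass
class ModelSAConfig:
    """Reduced-scale settings for the simulator sensitivity analysis.

    Sobol' indices are variance ratios and robust to population scale, so
    the default runs a subsample of agents for a handful of weeks with
    common random numbers across design points.
    """

    N: int = 64
    n_agents: int = 200
    weeks: int = 8
    replicates: int = 2
    seed: int = 0


def run_model_sa(
    problem: SAProblem,
    bundle,
    agents,
    sa_cfg: ModelSAConfig | None = None,
) -> SAResult:
    """Sobol' analysis of the median distance traveled.

    Each design point overrides the decision parameters globally, re-runs
    the simulation on a fixed agent subsample with the same replicate seeds
    (common random numbers), and averages the pooled median trip distance
    over replicates.
    """
    from .analytics import median_trip_distance
    from .decision_engine import SimulationConfig, run_simulation

    sa_cfg = sa_cfg or ModelSAConfig()
    design = saltelli_sample(problem, sa_cfg.N, sa_cfg.seed)
    pick_rng = np.random.default_rng(np.random.SeedSequence(sa_cfg.seed, spawn_key=(1,)))
    if sa_cfg.n_agents and sa_cfg.n_agents < len(agents):
        sub = [agents[i] for i in
               pick_rng.choice(len(agents), size=sa_cfg.n_agents, replace=False)]
    else:
        sub = list(agents)
    rep_seeds = [int(s) for s in
                 np.random.SeedSequence(sa_cfg.seed, spawn_key=(2,)).generate_state(
                     sa_cfg.replicates
                 ) % (2**31)]

    Y = np.empty(len(design))
    for r, row in enumerate(design):
        params = dict(zip(problem.names, row))
        medians = []
        for s in rep_seeds:
            cfg = SimulationConfig(
                weeks=sa_cfg.weeks,
                seed=s,
                lambda_walk=params.get("lambda_walk", 3.0),
                lambda_bike=params.get("lambda_bike", 6.0),
                mode_first_prob=params.get("mode_first_prob"),
                type_consideration_prob=params.get("type_consideration_prob"),
            )
            log = run_simulation(sub, bundle.env, bundle.od, cfg, bundle.groups)
            medians.append(median_trip_distance(log, by=None))
        Y[r] = float(np.mean(medians))
    return sobol_indices(Y, problem, seed=sa_cfg.seed)
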