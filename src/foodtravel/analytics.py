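"""Reductions of trip logs: mode-by-distance profiles, zone summaries,
store-visit maps, and the median trip distance (the sensitivity-analysis
output)."""
from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import JoinError
from .env_model import ZONES


def mode_share_by_distance(log: pd.DataFrame, bins) -> pd.DataFrame:
    """Per group and distance bin, the share of trips that are non-motorized.

    ``bins`` are strictly increasing edges of half-open intervals
    [lo, hi); trips at or beyond the last edge fall in an open-ended tail.
    Empty bins are absent from the result, not zero rows.
    Columns: group, bin_lo, bin_hi, trips, nonmotorized_share.
    """
    edges = np.asarray(bins, dtype=float)
    if len(edges) < 2 or (np.diff(edges) <= 0).any():
        raise ValueError("bins must be strictly increasing with >= 2 edges")
    idx = np.clip(
        np.searchsorted(edges, log["distance_miles"].to_numpy(), side="right") - 1,
        0,
        len(edges) - 1,
    )
    df = log.assign(_bin=idx)
    rows = []
    for (g, b), sub in df.groupby(["group", "_bin"], observed=True):
        lo = edges[b]
        hi = edges[b + 1] if b + 1 < len(edges) else np.inf
        rows.append(
            {
                "group": g,
                "bin_lo": lo,
                "bin_hi": hi,
                "trips": len(sub),
                "nonmotorized_share": float((~sub["motorized"]).mean()),
            }
        )
    return pd.DataFrame(rows)


def zone_trip_summary(log: pd.DataFrame, agents: pd.DataFrame, weeks: int) -> dict:
    """Weekly per-household trip rates by zone and population zone shares.

    Returns ``{"per_group": DataFrame(group, zone, trips, rate_per_week),
    "population_zone_shares": {zone: share}}``. Every log record must join
    to an agent.
    """
    known = set(agents["agent_id"])
    if not set(log["agent_id"].unique()).issubset(known):
        raise JoinError("trip log contains records with unknown agent ids")
    group_sizes = agents.groupby("group", observed=True).size()
    counts = (
        log.groupby(["group", "zone"], observed=True)
        .size()
        .rename("trips")
        .reset_index()
    )
    counts["rate_per_week"] = [
        t / (group_sizes[g] * weeks) for g, t in zip(counts["group"], counts["trips"])
    ]
    shares = log["zone"].value_counts(normalize=True)
    return {
        "per_group": counts,
        "population_zone_shares": {z: float(shares.get(z, 0.0)) for z in ZONES},
    }


def store_visit_map(log: pd.DataFrame, stores, weeks: int) -> pd.DataFrame:
    """Weekly visit rate and motorized share per (group, store).

    Visit rates are normalized by the global maximum across all groups, so
    the largest circle on the map is 1.0 regardless of group. Columns:
    group, store_id, visits_per_week, normalized_rate, motorized_share.
    """
    known = {s.id for s in stores}
    if not set(log["store_id"].unique()).issubset(known):
        raise JoinError("trip log references unknown stores")
    agg = (
        log.groupby(["group", "store_id"], observed=True)
        .agg(trips=("motorized", "size"), motorized_share=("motorized", "mean"))
        .reset_index()
    )
    agg["visits_per_week"] = agg["trips"] / weeks
    agg["normalized_rate"] = agg["visits_per_week"] / agg["visits_per_week"].max()
    return agg.drop(columns="trips")


def median_trip_distance(
    log: pd.DataFrame, by: str | None = "group", per_agent_week: bool = False
):
    """Median distance traveled, per trip (default) or per agent-week total.

    Even-length samples use the midpoint convention (numpy's median).
    Returns a float when ``by`` is None, else a ``{group: miles}`` dict with
    empty groups absent.
    """
    if per_agent_week:
        values = log.groupby(["agent_id", "week"], observed=True)[
            "distance_miles"
        ].sum()
        frame = values.reset_index().merge(
            log[["agent_id", "group"]].drop_duplicates(), on="agent_id"
        )
        col = "distance_miles"
    else:
        frame = log
        col = "distance_miles"
    if by is None:
        if len(frame) == 0:
            raise ValueError("empty trip log")
        return float(np.median(frame[col]))
    out = {}
    for g, sub in frame.groupby(by, observed=True):
        if len(sub):
            out[g] = float(np.median(sub[col]))
    return out
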