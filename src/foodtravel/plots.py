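"""Optional plotting hooks mirroring the study's output surfaces.

Plots are a convenience for inspection, not an analysis surface; all
figures accept an existing Axes to compose into panels.
"""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402


def plot_mode_share_by_distance(profile: pd.DataFrame, group: str, ax=None):
    """Bar chart of trips per distance bin, split motorized/non-motorized."""
    ax = ax or plt.subplots()[1]
    sub = profile[profile["group"] == group].sort_values("bin_lo")
    nm = sub["trips"] * sub["nonmotorized_share"]
    ax.bar(sub["bin_lo"], sub["trips"] - nm, width=0.9, align="edge",
           label="motorized", color="#88aadd")
    ax.bar(sub["bin_lo"], nm, bottom=sub["trips"] - nm, width=0.9, align="edge",
           label="non-motorized", color="#dd8899")
    ax.set_xlabel("distance to store (miles)")
    ax.set_ylabel("trips")
    ax.set_title(group)
    ax.legend()
    return ax


def plot_store_visit_map(visit_map: pd.DataFrame, stores, group: str, ax=None):
    """Store bubbles sized by normalized visit rate, colored by motorized share."""
    ax = ax or plt.subplots()[1]
    pos = {s.id: (s.x, s.y) for s in stores}
    sub = visit_map[visit_map["group"] == group]
    xs = [pos[s][0] for s in sub["store_id"]]
    ys = [pos[s][1] for s in sub["store_id"]]
    sc = ax.scatter(xs, ys, s=600 * sub["normalized_rate"],
                    c=sub["motorized_share"], cmap="coolwarm", vmin=0, vmax=1,
                    alpha=0.8, edgecolor="k", linewidth=0.3)
    plt.colorbar(sc, ax=ax, label="motorized share")
    ax.set_title(group)
    ax.set_aspect("equal")
    return ax


def plot_zone_trip_rates(summary: dict, ax=None):
    """Grouped bars: weekly per-household trips by shopping zone and group."""
    ax = ax or plt.subplots()[1]
    piv = summary["per_group"].pivot(index="group", columns="zone",
                                     values="rate_per_week")
    piv.plot.bar(ax=ax)
    ax.set_ylabel("shopping trips / week / household")
    return ax
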