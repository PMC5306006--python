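"""Static figures: colony maps colored by resource flow, and survival curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .colony import ColonyMap, FlowTable

_FLOW_COLORS = {
    "zero": "#f8e3c9", "low": "#f5c98a", "medium": "#ef9b3f",
    "high": "#b85c1e", "one": "#7a3a0d",
}


def plot_colony_map(cmap: ColonyMap, flow: FlowTable | None = None, ax=None):
    """Nests as circles (colored by flow band when a FlowTable is given),
    trees as triangles, internest trails gray and foraging trails green."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for t in cmap.trails.values():
        a, b = cmap.nodes[t.endpoint_a], cmap.nodes[t.endpoint_b]
        color = "0.5" if t.kind == "internest" else "forestgreen"
        ax.plot([a.x, b.x], [a.y, b.y], color=color, lw=1, zorder=1)
    for n in cmap.trees.values():
        ax.scatter(n.x, n.y, marker="^", color="forestgreen", s=60, zorder=2)
    for nid, n in cmap.nests.items():
        color = _FLOW_COLORS[flow.category[nid]] if flow else "#ef9b3f"
        ax.scatter(n.x, n.y, marker="o", color=color, edgecolor="k", s=90, zorder=3)
    ax.set_title(f"{cmap.colony_id} @ {cmap.timepoint}")
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m)")
    ax.set_aspect("equal")
    return ax


def plot_survival_curves(curves, labels=None, ax=None):
    """Step plot of one or more SurvivalCurve objects."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for i, curve in enumerate(curves):
        label = labels[i] if labels else ", ".join(
            f"{k}={v}" for k, v in curve.profile.items()
        )
        ax.step(curve.times, curve.survival, where="post", label=label or None)
    ax.set_xlabel("mapping intervals since entry")
    ax.set_ylabel("S(t)")
    ax.set_ylim(0, 1.02)
    if labels or any(c.profile for c in curves):
        ax.legend()
    return ax
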