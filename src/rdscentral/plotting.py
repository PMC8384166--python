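"""Plain component rendering with per-measure highlight colors.

High-betweenness nodes are drawn red, high-closeness green, high-eigenvector
purple, and the component's seed yellow (the seed color takes precedence even
when the seed is also selected).  Layout is deterministic given a seed.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx

MEASURE_COLORS = {
    "betweenness": "red",
    "closeness": "green",
    "eigenvector": "purple",
}
SEED_COLOR = "yellow"
BASE_COLOR = "lightgray"


def plot_component(
    forest,
    city: str,
    component_id: str,
    highlights: Mapping[str, Sequence[str]] | None = None,
    path=None,
    layout_seed: int = 0,
):
    """Render one component; returns the matplotlib figure.

    ``component_id`` is the smallest respondent id in the component.
    ``highlights`` maps measure name to the node ids to color; every
    highlighted node must belong to the component.
    """
    g = forest.graph(city)
    if component_id not in g:
        raise ValueError(f"node {component_id!r} not in city {city!r}")
    comp = forest.component_of(city, component_id)
    highlights = highlights or {}
    colors = {}
    for measure, nodes in highlights.items():
        if measure not in MEASURE_COLORS:
            raise ValueError(f"unknown measure {measure!r}")
        for node in nodes:
            if node not in comp:
                raise ValueError(f"highlight node {node!r} not in component")
            colors[node] = MEASURE_COLORS[measure]
    sub = g.subgraph(comp)
    for node in sub:
        if sub.nodes[node].get("seed"):
            colors[node] = SEED_COLOR
    node_list = sorted(sub)
    node_colors = [colors.get(n, BASE_COLOR) for n in node_list]
    pos = nx.spring_layout(sub, seed=layout_seed)
    fig, ax = plt.subplots(figsize=(8, 8))
    nx.draw_networkx(
        sub,
        pos=pos,
        nodelist=node_list,
        node_color=node_colors,
        with_labels=False,
        node_size=60,
        edge_color="gray",
        ax=ax,
    )
    ax.set_axis_off()
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
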