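"""All-pairs mutual conditional entropy, heatmaps and association networks.

An items×items MCE matrix summarises which questionnaire items mutually
convey information: low MCE means strong mutual predictability. The network
view links items whose association weight 1 − MCE exceeds a strict threshold
(0.2 by default), with edge thickness proportional to that weight; all item
nodes are retained, including isolated ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .data_io import ResponseTable, crosstab
from .entropy import mutual_conditional_entropy
from .errors import DegenerateDistributionError, ValidationError

__all__ = [
    "MCEMatrix",
    "EntropyNetwork",
    "mce_matrix",
    "build_network",
    "heatmap_matrix",
    "plot_heatmap",
    "plot_network",
]

DEFAULT_THRESHOLD = 0.2


@dataclass
class MCEMatrix:
    """Symmetric items×items matrix of mutual conditional entropies.

    ``values`` holds NaN where the statistic is undefined (a constant item);
    ``defined`` is the companion mask. The diagonal is identically 0 (an
    item predicts itself perfectly) and ``n_pair`` records the per-pair
    subject count under pairwise deletion.
    """

    items: tuple[str, ...]
    values: np.ndarray
    defined: np.ndarray
    n_pair: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.items), columns=list(self.items))

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index_label="item")
        return path


@dataclass
class EntropyNetwork:
    """Thresholded undirected item graph with edge weight 1 − MCE."""

    graph: nx.Graph
    threshold: float

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, dict]]:
        return list(self.graph.edges(data=True))

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "mce": d["mce"], "weight": d["weight"], "n_pair": d["n_pair"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "mce", "weight", "n_pair"])

    def to_edge_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.edge_list().to_csv(path, index=False)
        return path

    def to_graphml(self, path: str | Path) -> Path:
        path = Path(path)
        nx.write_graphml(self.graph, path)
        return path


def mce_matrix(table: ResponseTable, items: Optional[Sequence[str]] = None) -> MCEMatrix:
    """Pairwise MCE over the given items (all declared items by default).

    Each unordered pair is computed once from its own maximal subject set
    under pairwise deletion; degenerate items (constant responses) yield NaN
    cells flagged undefined rather than zeros.
    """
    ids = tuple(items) if items is not None else table.item_ids
    if len(ids) < 2:
        raise ValidationError("MCE matrix needs at least two items")
    k = len(ids)
    values = np.zeros((k, k))
    defined = np.ones((k, k), dtype=bool)
    n_pair = np.zeros((k, k), dtype=np.int64)
    for i in range(k):
        n_pair[i, i] = int((~table.is_missing(ids[i])).sum())
    for i in range(k):
        for j in range(i + 1, k):
            try:
                ct = crosstab(table, ids[i], ids[j])
                m = mutual_conditional_entropy(ct)
                n = ct.total
            except (DegenerateDistributionError, ValidationError):
                m, n = np.nan, 0
            values[i, j] = values[j, i] = m
            n_pair[i, j] = n_pair[j, i] = n
            defined[i, j] = defined[j, i] = not np.isnan(m)
    return MCEMatrix(items=ids, values=values, defined=defined, n_pair=n_pair)


def build_network(m: MCEMatrix, threshold: float = DEFAULT_THRESHOLD) -> EntropyNetwork:
    """Keep edge (i, j) iff 1 − MCE(i, j) > threshold (strictly).

    Undefined cells produce no edge; every item remains a node. Raising the
    threshold can only remove edges.
    """
    if not 0 <= threshold < 1:
        raise ValidationError(f"threshold must be in [0, 1), got {threshold}")
    g = nx.Graph(threshold=threshold)
    g.add_nodes_from(m.items)
    k = len(m.items)
    for i in range(k):
        for j in range(i + 1, k):
            if not m.defined[i, j]:
                continue
            w = 1.0 - m.values[i, j]
            if w > threshold:
                g.add_edge(
                    m.items[i],
                    m.items[j],
                    weight=float(w),
                    mce=float(m.values[i, j]),
                    n_pair=int(m.n_pair[i, j]),
                )
    return EntropyNetwork(graph=g, threshold=threshold)


def heatmap_matrix(m: MCEMatrix) -> pd.DataFrame:
    """Value grid for rendering: items in declared order, undefined cells NaN."""
    return m.to_frame()


def plot_heatmap(m: MCEMatrix, out: str | Path, title: str = "Mutual conditional entropy"):
    """Render the MCE heatmap to SVG and PNG; returns the written paths."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    import seaborn as sns

    grid = heatmap_matrix(m)
    fig, ax = plt.subplots(figsize=(0.8 * len(m.items) + 2, 0.8 * len(m.items) + 1.5))
    sns.heatmap(
        grid,
        mask=~m.defined,
        vmin=0.0,
        vmax=1.0,
        cmap="viridis_r",
        annot=len(m.items) <= 12,
        fmt=".2f",
        square=True,
        cbar_kws={"label": "MCE (lower = stronger association)"},
        ax=ax,
    )
    ax.set_title(title)
    paths = _save_both(fig, out)
    plt.close(fig)
    return paths


def plot_network(net: EntropyNetwork, out: str | Path, layout_seed: int = 0):
    """Draw the association network (force-directed layout, fixed seed).

    Edge thickness is proportional to the weight 1 − MCE. The layout is
    presentation-only and carries no semantics.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    g = net.graph
    pos = nx.spring_layout(g, seed=layout_seed)
    fig, ax = plt.subplots(figsize=(6, 6))
    widths = [8 * d["weight"] for _, _, d in g.edges(data=True)]
    nx.draw_networkx_nodes(g, pos, node_color="#cfe2f3", edgecolors="black", ax=ax)
    nx.draw_networkx_labels(g, pos, ax=ax)
    nx.draw_networkx_edges(g, pos, width=widths, ax=ax)
    ax.set_title(f"Item association network (1 − MCE > {net.threshold:g})")
    ax.set_axis_off()
    paths = _save_both(fig, out)
    plt.close(fig)
    return paths


def _save_both(fig, out: str | Path) -> list[Path]:
    out = Path(out)
    paths = []
    for suffix in (".svg", ".png"):
        p = out.with_suffix(suffix)
        fig.savefig(p, bbox_inches="tight", dpi=150)
        paths.append(p)
    return paths
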