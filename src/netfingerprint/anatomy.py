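"""Anatomy of selected networks.

Summarizes an edge mask against an atlas annotation: per-node degrees and
the complete set of highest-degree nodes, counts of edges within and
between the ten canonical macroscale networks (medial frontal,
fronto-parietal, default mode, motor/sensory, three visual, salience,
subcortical, cerebellum/brainstem), and the fraction of all possible
connections a mask occupies.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cpm import EdgeMask
from .errors import DataError, ParameterError
from .synth import CANONICAL_NETWORKS

__all__ = [
    "AtlasInfo",
    "node_degrees",
    "summarize_by_network",
    "edge_fraction",
    "read_atlas",
    "plot_network_matrix",
]


@dataclass
class AtlasInfo:
    """Node annotation: macro-region, canonical network, hemisphere."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"macro_region", "network"}
        if not required <= set(self.table.columns):
            raise DataError(f"atlas table needs columns {sorted(required)}")
        if self.table.index.has_duplicates:
            dupes = self.table.index[self.table.index.duplicated()].tolist()
            raise DataError(f"duplicate node ids in atlas: {dupes}")
        unknown = sorted(set(self.table["network"]) - set(CANONICAL_NETWORKS))
        if unknown:
            raise DataError(
                f"unknown canonical network label(s) {unknown}; "
                f"expected one of {list(CANONICAL_NETWORKS)}"
            )

    @property
    def n_nodes(self) -> int:
        return len(self.table)

    def network_of(self, node: int) -> str:
        try:
            return self.table.loc[node, "network"]
        except KeyError:
            raise DataError(f"node {node} is not labeled in the atlas") from None


def read_atlas(path: str | Path) -> AtlasInfo:
    """Load a node annotation table (``atlas.tsv`` format, node-indexed)."""
    return AtlasInfo(pd.read_csv(path, sep="\t", index_col=0))


def node_degrees(
    mask: EdgeMask, n_nodes: int | None = None
) -> tuple[pd.DataFrame, dict[str, tuple[int, ...]]]:
    """Per-node incident edge counts per polarity, plus the top-degree sets.

    Returns ``(degrees, hubs)``: a node-indexed DataFrame with columns
    ``positive``, ``negative``, ``total`` and, per polarity, the complete
    argmax set of nodes (ties reported together; empty when the mask has
    no edges of that polarity).
    """
    nodes = {i for e in mask.positive | mask.negative for i in e}
    if n_nodes is None:
        n_nodes = (max(nodes) + 1) if nodes else 0
    elif nodes and max(nodes) >= n_nodes:
        raise ParameterError(
            f"mask references node {max(nodes)} but n_nodes={n_nodes}"
        )
    deg = pd.DataFrame(
        0, index=pd.RangeIndex(n_nodes, name="node"), columns=["positive", "negative"]
    )
    for col, edges in (("positive", mask.positive), ("negative", mask.negative)):
        for i, j in edges:
            deg.loc[i, col] += 1
            deg.loc[j, col] += 1
    deg["total"] = deg["positive"] + deg["negative"]

    hubs: dict[str, tuple[int, ...]] = {}
    for col in ("positive", "negative", "total"):
        top = deg[col].max() if len(deg) else 0
        hubs[col] = tuple(deg.index[deg[col] == top]) if top > 0 else ()
    return deg, hubs


def summarize_by_network(
    mask: EdgeMask, atlas: AtlasInfo
) -> dict[str, pd.DataFrame]:
    """Count mask edges within and between the ten canonical networks.

    Returns 10 x 10 symmetric count matrices keyed ``"positive"``,
    ``"negative"`` and ``"sum"``; within-network edges sit on the diagonal,
    and the upper triangle (diagonal included) of each matrix sums to the
    number of mask edges of that polarity.
    """
    nets = list(CANONICAL_NETWORKS)
    idx = {name: i for i, name in enumerate(nets)}
    out = {}
    for polarity, edges in (("positive", mask.positive), ("negative", mask.negative)):
        counts = np.zeros((len(nets), len(nets)), dtype=int)
        for i, j in edges:
            a, b = idx[atlas.network_of(i)], idx[atlas.network_of(j)]
            counts[a, b] += 1
            if a != b:
                counts[b, a] += 1
        out[polarity] = pd.DataFrame(counts, index=nets, columns=nets)
    out["sum"] = out["positive"] + out["negative"]
    return out


def edge_fraction(n_edges: int, n_nodes: int) -> float:
    """Percent of all unordered node pairs that a mask occupies.

    With a 268-node atlas there are 268*267/2 = 35,778 possible edges, so a
    39-edge network occupies about 0.109% of all possible connections.
    """
    if n_nodes < 2:
        raise ParameterError(f"n_nodes must be at least 2, got {n_nodes}")
    total = n_nodes * (n_nodes - 1) // 2
    if not 0 <= n_edges <= total:
        raise ParameterError(
            f"n_edges={n_edges} outside [0, {total}] for {n_nodes} nodes"
        )
    return 100.0 * n_edges / total


def plot_network_matrix(matrix: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """Write a heat map of a canonical-network count matrix."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(matrix.to_numpy(), cmap="viridis")
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=45)
    ax.set_yticks(range(len(matrix.index)), matrix.index)
    for (i, j), v in np.ndenumerate(matrix.to_numpy()):
        if v:
            ax.text(j, i, str(v), ha="center", va="center", color="w", fontsize=7)
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="edges")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
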