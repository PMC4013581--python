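"""Correlated-segment networks from a cross-correlation matrix.

Coarse-grains a residue-level DCCM to the segment level: an *edge* exists
between residues i ∈ A and j ∈ B when |C(i,j)| ≥ c, and the weight of the
segment pair (A, B) is the number of such residue edges — so drawn line
widths proportional to the weight reproduce the "width ∝ sum of
connecting edges" convention for these diagrams.  The absolute value is
used because strong anticorrelation is communication too; signed
sub-networks can be requested.

Paths through the network (e.g. β1 → β5-αC loop → β6/4/5 → β7/8) are
found by hop count, with ties broken toward the strongest bottleneck
edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .structure_io import SegmentTable
from .trajectory_analysis import DCCM

__all__ = ["SegmentNetwork", "build_segment_network", "path_exists"]


@dataclass(frozen=True)
class NetworkEdge:
    seg_a: str
    seg_b: str
    n_edges: int          # residue pairs with |C| >= threshold
    mean_abs_c: float     # mean |C| over all intersegment residue pairs


@dataclass
class SegmentNetwork:
    """Segment-level correlation network.

    ``nodes`` maps segment name → residue count; ``edges`` is symmetric
    (stored once per unordered pair, both orders queryable).
    """

    nodes: dict[str, int]
    edges: list[NetworkEdge]
    threshold: float
    signed: str = "abs"    # "abs" | "positive" | "negative"

    def edge(self, a: str, b: str) -> NetworkEdge | None:
        for e in self.edges:
            if {e.seg_a, e.seg_b} == {a, b}:
                return e
        return None

    def weight(self, a: str, b: str) -> int:
        e = self.edge(a, b)
        return 0 if e is None else e.n_edges

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for name, size in self.nodes.items():
            g.add_node(name, n_residues=size)
        for e in self.edges:
            g.add_edge(e.seg_a, e.seg_b, weight=e.n_edges,
                       mean_abs_c=e.mean_abs_c)
        return g

    def to_rows(self):
        return [(e.seg_a, e.seg_b, e.n_edges, round(e.mean_abs_c, 6))
                for e in self.edges]

    def to_dot(self) -> str:
        """DOT export; pen widths scale with edge count."""
        wmax = max((e.n_edges for e in self.edges), default=1)
        lines = ["graph segments {"]
        for name in self.nodes:
            lines.append(f'  "{name}";')
        for e in self.edges:
            pw = 1.0 + 4.0 * e.n_edges / wmax
            lines.append(
                f'  "{e.seg_a}" -- "{e.seg_b}" '
                f'[penwidth={pw:.2f}, label="{e.n_edges}"];'
            )
        lines.append("}")
        return "\n".join(lines)


def build_segment_network(
    dccm: DCCM,
    segments: SegmentTable,
    threshold: float = 0.5,
    signed: str = "abs",
) -> SegmentNetwork:
    """Build the segment network at a correlation threshold.

    ``signed``: "abs" thresholds |C| (default); "positive"/"negative"
    keep only the corresponding sign.  Raising the threshold can only
    remove edges.  Composite segments (sheet groups) whose residues all
    appear in the DCCM are supported; a segment not covered by the DCCM
    is an error.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    if signed not in ("abs", "positive", "negative"):
        raise ValueError(f"unknown signed mode {signed!r}")

    res_to_row = {int(r): k for k, r in enumerate(dccm.residues)}
    seg_rows: dict[str, np.ndarray] = {}
    for seg in segments:
        rows = []
        for r in sorted(seg.residues()):
            if r not in res_to_row:
                raise ValueError(
                    f"segment {seg.name!r} residue {r} not covered by the DCCM"
                )
            rows.append(res_to_row[r])
        seg_rows[seg.name] = np.array(rows, dtype=int)

    names = list(seg_rows)
    edges: list[NetworkEdge] = []
    for a_i in range(len(names)):
        for b_i in range(a_i + 1, len(names)):
            a, b = names[a_i], names[b_i]
            ra, rb = seg_rows[a], seg_rows[b]
            # exclude residues shared between overlapping segments
            block = dccm.matrix[np.ix_(ra, rb)].copy()
            shared = np.isin(ra, rb)
            if shared.any():
                for k in np.flatnonzero(shared):
                    block[k, rb == ra[k]] = np.nan
            vals = block[np.isfinite(block)]
            if vals.size == 0:
                continue
            if signed == "abs":
                scores = np.abs(vals)
            elif signed == "positive":
                scores = np.where(vals > 0, vals, 0.0)
            else:
                scores = np.where(vals < 0, -vals, 0.0)
            n_edges = int(np.sum(scores >= threshold))
            if n_edges > 0:
                edges.append(NetworkEdge(
                    seg_a=a, seg_b=b, n_edges=n_edges,
                    mean_abs_c=float(np.mean(np.abs(vals))),
                ))

    nodes = {seg.name: len(seg.residues()) for seg in segments}
    return SegmentNetwork(nodes=nodes, edges=edges, threshold=threshold,
                          signed=signed)


def path_exists(
    network: SegmentNetwork,
    source: str,
    sink: str,
) -> list[str] | None:
    """Shortest communication path between two segments, or ``None``.

    Shortest by hop count; among equally short paths the one with the
    larger minimum edge weight wins, then the lexicographically smallest.
    """
    for node in (source, sink):
        if node not in network.nodes:
            raise KeyError(f"unknown segment {node!r}")
    g = network.to_graph()
    if source == sink:
        return [source]
    try:
        paths = list(nx.all_shortest_paths(g, source, sink))
    except nx.NetworkXNoPath:
        return None
    except nx.NodeNotFound:
        return None

    def score(path):
        min_w = min(
            g.edges[u, v]["weight"] for u, v in zip(path[:-1], path[1:])
        )
        return (-min_w, tuple(path))

    return min(paths, key=score)
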