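"""Node-centrality baselines: NC, PeC and degree.

NC sums the edge clustering coefficient (ECC) over a node's incident
edges; PeC additionally weights each incident edge by the (clamped)
co-expression of its endpoints; degree is the classic
centrality-lethality baseline.  All three rank proteins directly by a
node score, in contrast to the edge-ranking route.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .measures import pearson_correlation, triangle_count


@dataclass
class NodeScoreTable:
    """Protein -> score mapping plus the method that produced it."""

    scores: dict[str, float]
    method: str

    def __getitem__(self, protein: str) -> float:
        return self.scores[protein]

    def __len__(self) -> int:
        return len(self.scores)


def ecc(net: nx.Graph, edge: tuple[str, str]) -> float:
    """Edge clustering coefficient: z(u,v) / min(deg u - 1, deg v - 1).

    The triangle count of the edge normalized by the maximum number of
    triangles it could belong to; defined as 0 when either endpoint has
    degree 1 (denominator <= 0).
    """
    u, v = edge
    if not net.has_edge(u, v):
        raise ValueError(f"edge {edge!r} not in network")
    denom = min(net.degree(u) - 1, net.degree(v) - 1)
    if denom <= 0:
        return 0.0
    return triangle_count(net, edge) / denom


def nc_scores(net: nx.Graph) -> NodeScoreTable:
    """NC(i) = sum of ECC over i's incident edges."""
    scores = {n: 0.0 for n in net.nodes}
    for u, v in net.edges:
        e = ecc(net, (u, v))
        scores[u] += e
        scores[v] += e
    return NodeScoreTable(scores, "nc")


def pec_scores(net: nx.Graph, expr: pd.DataFrame) -> NodeScoreTable:
    """PeC(i) = sum over neighbours j of ECC(i,j) x max(0, PCC(i,j)).

    Missing correlations (gene absent, short or constant profile)
    contribute 0, as does negative co-expression — the same clamp used
    in the edge-weight product, so the two methods are comparable.
    """
    scores = {n: 0.0 for n in net.nodes}
    for u, v in net.edges:
        r = pearson_correlation(expr, u, v)
        r = 0.0 if (r != r or r < 0) else r  # NaN or negative -> 0
        contrib = ecc(net, (u, v)) * r
        scores[u] += contrib
        scores[v] += contrib
    return NodeScoreTable(scores, "pec")


def degree_scores(net: nx.Graph) -> NodeScoreTable:
    return NodeScoreTable({n: float(d) for n, d in net.degree()}, "degree")


def rank_nodes(scores: NodeScoreTable) -> list[str]:
    """Proteins by descending score, ties broken lexicographically."""
    return [p for p, _ in sorted(scores.scores.items(), key=lambda kv: (-kv[1], kv[0]))]
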