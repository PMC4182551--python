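"""Edge weighting, edge ranking and the edge-derived protein list.

The edge weight is the plain product of the enabled per-pair measures
(GO similarity x co-expression x triangle count by default).  A product,
rather than a normalized sum, keeps each measure on its native scale and
makes any single zero/missing measure veto the edge.  Edges are sorted
by descending weight and the ranked protein list is read off the edge
ranking: walking edges from the strongest down, each endpoint is emitted
the first time it appears, so proteins touching many strong edges
surface early.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .network import canonical_edge

#: canonical λ-flag order, matching the measure-table columns.
LAMBDA_ORDER = ("GE", "PCC", "NTE", "PP")


@dataclass(frozen=True)
class EdgeWeightConfig:
    """Which measures enter the edge-weight product, and the open policies.

    ``enabled`` holds the λ flags: the subset of {GE, PCC, NTE, PP} whose
    product forms the weight (default GE·PCC·NTE — the combination that
    performed best in the measure-ablation study; PP adds nothing).
    ``negative_pcc_policy`` resolves the sign ambiguity of a product with
    a negative correlation: ``clamp-to-zero`` (default; negative
    co-expression is no evidence of joint essentiality) or
    ``absolute-value``.  ``tie_policy`` orders equal-weight edges:
    ``lexicographic`` on canonical (u, v) (default, platform-stable) or
    ``input-order`` (stable sort of the table as given).
    """

    enabled: tuple[str, ...] = ("GE", "PCC", "NTE")
    tie_policy: str = "lexicographic"
    negative_pcc_policy: str = "clamp-to-zero"

    def __post_init__(self) -> None:
        bad = set(self.enabled) - set(LAMBDA_ORDER)
        if bad:
            raise ValueError(f"unknown measures in config: {sorted(bad)}")
        if not self.enabled:
            raise ValueError("at least one measure must be enabled")
        if self.tie_policy not in ("lexicographic", "input-order"):
            raise ValueError(f"unknown tie policy: {self.tie_policy!r}")
        if self.negative_pcc_policy not in ("clamp-to-zero", "absolute-value"):
            raise ValueError(f"unknown negative-PCC policy: {self.negative_pcc_policy!r}")

    def label(self) -> str:
        return "*".join(m for m in LAMBDA_ORDER if m in self.enabled)


def all_lambda_combinations() -> list[tuple[str, ...]]:
    """All 15 non-empty subsets of {GE, PCC, NTE, PP}, in canonical order."""
    out = []
    for mask in range(1, 16):
        out.append(tuple(m for i, m in enumerate(LAMBDA_ORDER) if mask >> i & 1))
    return out


def edge_weight(row, config: EdgeWeightConfig) -> float:
    """Weight of one measure-table row: product of the enabled measures.

    A missing (NaN) or zero enabled measure yields weight 0; negative PCC
    is clamped or folded per the configured policy.
    """
    w = 1.0
    for m in config.enabled:
        x = row[m]
        if x is None or (isinstance(x, float) and math.isnan(x)):
            return 0.0
        x = float(x)
        if m == "PCC" and x < 0:
            x = 0.0 if config.negative_pcc_policy == "clamp-to-zero" else -x
        w *= x
    return max(w, 0.0)


@dataclass
class RankedEdgeList:
    """Edges in non-increasing weight order, with the config that produced it."""

    edges: list[tuple[str, str]]
    weights: list[float]
    config: EdgeWeightConfig = field(default_factory=EdgeWeightConfig)

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(zip(self.edges, self.weights))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": range(1, len(self.edges) + 1),
                "u": [e[0] for e in self.edges],
                "v": [e[1] for e in self.edges],
                "weight": self.weights,
            }
        )


def rank_edges(table: pd.DataFrame, config: EdgeWeightConfig | None = None) -> RankedEdgeList:
    """Rank the edges of a measure table by descending weight.

    The sort is stable; equal weights fall back to the configured tie
    policy.  Measures the config enables must be columns of ``table``.
    """
    config = config or EdgeWeightConfig()
    if table.empty:
        raise ValueError("measure table is empty")
    missing = set(config.enabled) - set(table.columns)
    if missing:
        raise ValueError(f"measure table lacks enabled columns: {sorted(missing)}")
    records = []
    for i, row in enumerate(table.itertuples(index=False)):
        rowd = row._asdict()
        e = canonical_edge(str(rowd["u"]), str(rowd["v"]))
        records.append((e, edge_weight(rowd, config), i))
    if config.tie_policy == "lexicographic":
        records.sort(key=lambda r: (-r[1], r[0]))
    else:
        records.sort(key=lambda r: (-r[1], r[2]))
    return RankedEdgeList(
        edges=[r[0] for r in records], weights=[r[1] for r in records], config=config
    )


def proteins_from_edges(ranked: RankedEdgeList) -> list[str]:
    """Derive the ranked protein list from a ranked edge list.

    Walk edges from highest weight down; each edge contributes its two
    endpoints, in within-edge canonical order, skipping proteins already
    emitted.  The result is duplicate-free and covers every protein
    incident to at least one ranked edge.
    """
    if not ranked.edges:
        raise ValueError("ranked edge list is empty")
    seen: set[str] = set()
    out: list[str] = []
    for u, v in ranked.edges:
        for p in (u, v):
            if p not in seen:
                seen.add(p)
                out.append(p)
    return out


def top_k(proteins: list[str], k: int) -> list[str]:
    """First min(k, len) proteins of a ranked list."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return proteins[:k]


def extract_modules(
    net: nx.Graph,
    ranked: RankedEdgeList,
    top_e: int,
    min_module_size: int = 2,
) -> list[set[str]]:
    """Connected components of the subgraph induced by the top ``top_e`` edges.

    These sub-networks of only high-ranking interactions are the candidate
    modules (protein complexes / pathway cores).  Components smaller than
    ``min_module_size`` nodes are dropped; the rest are returned largest
    first (ties broken by sorted node content for determinism).
    """
    if top_e < 1:
        raise ValueError("top_e must be >= 1")
    if top_e > len(ranked.edges):
        raise ValueError(f"top_e={top_e} exceeds the {len(ranked.edges)} ranked edges")
    sub = nx.Graph()
    sub.add_edges_from(ranked.edges[:top_e])
    comps = [set(c) for c in nx.connected_components(sub) if len(c) >= min_module_size]
    return sorted(comps, key=lambda c: (-len(c), tuple(sorted(c))))
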