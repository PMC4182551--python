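"""Edge-deletion robustness protocol.

The original network is degraded in 10 cumulative steps by deleting X
edges per step, chosen from the top, the bottom, or uniformly at random
in the ORIGINAL ranked edge list (the ranking is not redone between
steps; what is re-done on every perturbed network is the scoring
itself).  Topology-dependent quantities — triangle counts, ECC, degree —
are recomputed on each perturbed graph, while pair-intrinsic measures
(GO similarity, co-expression) are kept from the unperturbed table.
Nodes isolated by deletion stay in the network; they simply can no
longer appear in an edge-derived protein list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from . import baselines
from .evaluation import EvaluationCurve, precision_recall
from .measures import triangle_count
from .network import EssentialityLabels
from .ranking import EdgeWeightConfig, RankedEdgeList, proteins_from_edges, rank_edges

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PerturbationPlan:
    """How to degrade the network: mode, edges per step, steps, seed.

    ``mode`` is ``top`` (delete the strongest-ranked edges first),
    ``bottom`` (the weakest first) or ``random`` (uniform without
    replacement, seeded).  ``x`` edges are removed at each of ``steps``
    cumulative steps.
    """

    mode: str
    x: int
    steps: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("top", "bottom", "random"):
            raise ValueError(f"unknown perturbation mode: {self.mode!r}")
        if self.x < 1 or self.steps < 1:
            raise ValueError("x and steps must be >= 1")
        if self.mode == "random" and self.seed is None:
            raise ValueError("random mode requires a seed")


def deletion_schedule(ranked: RankedEdgeList, plan: PerturbationPlan) -> list[tuple[str, str]]:
    """The x*steps edges to delete, in deletion order."""
    total = plan.x * plan.steps
    if total > len(ranked.edges):
        raise ValueError(
            f"plan deletes {total} edges but the ranking has only {len(ranked.edges)}"
        )
    if plan.mode == "top":
        return list(ranked.edges[:total])
    if plan.mode == "bottom":
        return list(ranked.edges[::-1][:total])
    rng = np.random.default_rng(plan.seed)
    idx = rng.choice(len(ranked.edges), size=total, replace=False)
    return [ranked.edges[i] for i in idx]


def perturb_series(
    net: nx.Graph, ranked: RankedEdgeList, plan: PerturbationPlan
) -> list[nx.Graph]:
    """Return steps+1 networks: the original, then one per cumulative step.

    Step t lacks exactly the first t*x edges of the deletion schedule.
    """
    schedule = deletion_schedule(ranked, plan)
    series = [net.copy()]
    current = net.copy()
    for t in range(plan.steps):
        for u, v in schedule[t * plan.x : (t + 1) * plan.x]:
            if current.has_edge(u, v):
                current.remove_edge(u, v)
        series.append(current.copy())
    return series


def _ew_rank_perturbed(
    g: nx.Graph, base_table: pd.DataFrame, config: EdgeWeightConfig
) -> RankedEdgeList:
    """Re-rank a perturbed graph: keep GE/PCC per pair, recount NTE."""
    keep = base_table.apply(lambda r: g.has_edge(r["u"], r["v"]), axis=1)
    table = base_table.loc[keep].copy()
    if "NTE" in table.columns:
        table["NTE"] = [
            triangle_count(g, (r.u, r.v)) for r in table.itertuples(index=False)
        ]
    return rank_edges(table, config)


def robustness_run(
    net: nx.Graph,
    base_table: pd.DataFrame,
    labels: EssentialityLabels,
    plan: PerturbationPlan,
    method: str = "ew",
    config: EdgeWeightConfig | None = None,
    expr: pd.DataFrame | None = None,
    P: int | None = None,
) -> list[EvaluationCurve]:
    """Evaluate one method across the perturbation series.

    For every perturbed network the chosen scorer is re-applied from
    scratch (EW re-ranks edges with fresh triangle counts; NC/PeC re-score
    nodes on the perturbed topology) and the resulting ranked protein
    list is turned into a precision-recall curve.  ``P`` is held fixed
    across steps (default: resolved on the unperturbed list) so curves
    are comparable.  An emptied network truncates the series with a
    warning.
    """
    if method not in ("ew", "nc", "pec"):
        raise ValueError(f"unknown method: {method!r}")
    if method == "pec" and expr is None:
        raise ValueError("pec requires an expression matrix")
    config = config or EdgeWeightConfig()
    ranked0 = rank_edges(base_table, config)
    series = perturb_series(net, ranked0, plan)
    curves: list[EvaluationCurve] = []
    for step, g in enumerate(series):
        if g.number_of_edges() == 0:
            logger.warning("perturbation step %d emptied the network; truncating", step)
            break
        if method == "ew":
            proteins = proteins_from_edges(_ew_rank_perturbed(g, base_table, config))
        elif method == "nc":
            proteins = baselines.rank_nodes(baselines.nc_scores(g))
        else:
            proteins = baselines.rank_nodes(baselines.pec_scores(g, expr))
        if step == 0 and P is None:
            P = max(1, sum(1 for p in proteins if labels.is_essential(p)))
        curves.append(precision_recall(proteins, labels, P=P))
    return curves
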