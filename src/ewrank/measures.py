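"""Per-edge measures: GO similarity (GE), co-expression (PCC), triangle
count (NTE) and Jukes-Cantor sequence distance (PP).

Each measure scores how strongly the two endpoint proteins of an
interaction are related — functionally (GE), transcriptionally (PCC),
topologically (NTE) or evolutionarily (PP).  ``build_measure_table``
assembles one row per network edge; missing values (a gene absent from
the expression matrix, an unannotated protein, a saturated alignment)
are stored as NaN and propagate to the weighting stage rather than being
imputed.
"""

from __future__ import annotations

import math
from functools import lru_cache
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .network import AnnotationSet, canonical_edge

MEASURES = ("GE", "PCC", "NTE", "PP")

#: Wang-style semantic contribution factors per DAG relation.
WANG_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


def triangle_count(net: nx.Graph, edge: tuple[str, str]) -> int:
    """Number of triangles the edge belongs to: ``|N(u) ∩ N(v)|``.

    Counts the common neighbours of the two endpoints (the endpoints
    themselves cannot be common neighbours in a simple graph).
    """
    u, v = edge
    if not net.has_edge(u, v):
        raise ValueError(f"edge {edge!r} not in network")
    return len(set(net[u]) & set(net[v]))


def pearson_correlation(expr: pd.DataFrame, u: str, v: str) -> float:
    """Pearson correlation of two genes' expression profiles.

    Computed over the samples where both genes have finite values.
    Returns NaN (missing) if either gene is absent from the matrix,
    fewer than 3 common samples exist, or either profile is constant.
    """
    if u not in expr.index or v not in expr.index:
        return math.nan
    x = expr.loc[u].to_numpy(dtype=float)
    y = expr.loc[v].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan
    return float(stats.pearsonr(x, y).statistic)


def _wang_svalues(dag: nx.DiGraph, term: str) -> dict[str, float]:
    """Semantic contribution of each ancestor of ``term`` (Wang method).

    S(term)=1; walking child->parent links multiplies by 0.8 (is_a) or
    0.6 (part_of); an ancestor reachable by several paths keeps the
    maximal contribution.
    """
    s = {term: 1.0}
    queue = [term]
    while queue:
        t = queue.pop()
        for parent in dag.successors(t):
            w = WANG_WEIGHTS.get(dag[t][parent].get("relation", "is_a"), 0.8)
            cand = s[t] * w
            if cand > s.get(parent, 0.0):
                s[parent] = cand
                queue.append(parent)
    return s


def _wang_term_sim(dag: nx.DiGraph, a: str, b: str) -> float:
    sa, sb = _wang_svalues(dag, a), _wang_svalues(dag, b)
    shared = set(sa) & set(sb)
    denom = sum(sa.values()) + sum(sb.values())
    return sum(sa[t] + sb[t] for t in shared) / denom


def go_similarity(annots: AnnotationSet, u: str, v: str, method: str = "jaccard") -> float:
    """Annotation similarity of two proteins in [0, 1], or NaN if either
    protein is unannotated.

    ``jaccard``: term-set overlap |T(u)∩T(v)| / |T(u)∪T(v)|.
    ``dag-bma``: best-match-average of pairwise Wang-style DAG term
    similarities, which credits distinct but ontologically close terms.
    """
    tu, tv = annots.annotated(u), annots.annotated(v)
    if not tu or not tv:
        return math.nan
    known = set(annots.ontology.nodes)
    for t in (tu | tv) - known:
        raise ValueError(f"annotated term {t!r} not in ontology")
    if method == "jaccard":
        return len(tu & tv) / len(tu | tv)
    if method == "dag-bma":
        dag = annots.ontology
        sims = {(a, b): _wang_term_sim(dag, a, b) for a in tu for b in tv}
        best_u = [max(sims[(a, b)] for b in tv) for a in tu]
        best_v = [max(sims[(a, b)] for a in tu) for b in tv]
        return (sum(best_u) + sum(best_v)) / (len(tu) + len(tv))
    raise ValueError(f"unknown GO similarity method: {method!r}")


# -- Jukes-Cantor protein distance ------------------------------------------
# 20 amino-acid states: d = -(19/20) ln(1 - (20/19) p), saturated at p >= 19/20.

_JC_STATES = 20.0
_JC_FRAC = (_JC_STATES - 1.0) / _JC_STATES  # 19/20


@lru_cache(maxsize=1)
def _aligner():
    from Bio import Align
    from Bio.Align import substitution_matrices

    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -10.0
    al.extend_gap_score = -0.5
    return al


def jukes_cantor_distance(seq_u: str, seq_v: str) -> float:
    """Jukes-Cantor corrected distance between two protein sequences.

    A global pairwise alignment (BLOSUM62, affine gaps) is computed; the
    mismatch proportion *p* is taken over aligned non-gap columns only, and
    corrected for multiple substitutions over 20 amino-acid states.
    Returns NaN when the correction saturates (p >= 19/20).
    """
    if not seq_u or not seq_v:
        raise ValueError("empty sequence")
    aln = _aligner().align(seq_u, seq_v)[0]
    a, b = str(aln[0]), str(aln[1])
    pairs = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
    if not pairs:
        return math.nan
    p = sum(x != y for x, y in pairs) / len(pairs)
    if p >= _JC_FRAC:
        return math.nan
    return -_JC_FRAC * math.log(1.0 - p / _JC_FRAC)


def jukes_cantor_from_p(p: float) -> float:
    """Distance from a precomputed mismatch proportion (alignment-free entry)."""
    if p >= _JC_FRAC:
        return math.nan
    return -_JC_FRAC * math.log(1.0 - p / _JC_FRAC)


def build_measure_table(
    net: nx.Graph,
    expr: pd.DataFrame | None = None,
    annots: AnnotationSet | None = None,
    seqs: dict[str, str] | None = None,
    enabled: tuple[str, ...] = ("GE", "PCC", "NTE"),
    go_method: str = "jaccard",
) -> pd.DataFrame:
    """Assemble the per-edge measure table (one row per edge).

    Columns: ``u``, ``v`` (canonical order u < v) plus one column per
    enabled measure; disabled measures are simply absent.  Each enabled
    measure must have its input supplied (``expr`` for PCC, ``annots``
    for GE, ``seqs`` for PP; NTE needs only the network).
    """
    enabled = tuple(enabled)
    unknown = set(enabled) - set(MEASURES)
    if unknown:
        raise ValueError(f"unknown measures: {sorted(unknown)}")
    needs = {"PCC": expr, "GE": annots, "PP": seqs}
    for m, inp in needs.items():
        if m in enabled and inp is None:
            raise ValueError(f"measure {m} enabled but its input was not supplied")

    rows = []
    for u, v in sorted(canonical_edge(u, v) for u, v in net.edges):
        row: dict[str, object] = {"u": u, "v": v}
        if "GE" in enabled:
            row["GE"] = go_similarity(annots, u, v, method=go_method)
        if "PCC" in enabled:
            row["PCC"] = pearson_correlation(expr, u, v)
        if "NTE" in enabled:
            row["NTE"] = triangle_count(net, (u, v))
        if "PP" in enabled:
            su, sv = seqs.get(u), seqs.get(v)
            row["PP"] = jukes_cantor_distance(su, sv) if su and sv else math.nan
        rows.append(row)
    cols = ["u", "v"] + [m for m in MEASURES if m in enabled]
    table = pd.DataFrame(rows, columns=cols)
    if "NTE" in enabled:
        table["NTE"] = table["NTE"].astype(int)
    return table


def read_measure_table(path: str | Path) -> pd.DataFrame:
    """Read a precomputed per-edge measure table (TSV with header
    ``u v GE PCC NTE [PP]``), canonicalizing endpoint order.

    This is the entry point for externally computed tables where the
    measures were derived from sources not shipped with the interaction
    map (curated GO similarity, microarray co-expression, ...).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"u", "v", "GE", "PCC", "NTE"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    nte = df["NTE"]
    if not np.all(np.isfinite(nte)) or np.any(nte < 0) or np.any(nte != nte.astype(int)):
        raise ValueError(f"{path}: NTE must be non-negative integers")
    df["NTE"] = nte.astype(int)
    swap = df["u"] > df["v"]
    df.loc[swap, ["u", "v"]] = df.loc[swap, ["v", "u"]].to_numpy()
    dup = df.duplicated(subset=["u", "v"], keep=False)
    if dup.any():
        pairs = df.loc[dup, ["u", "v"]].drop_duplicates().itertuples(index=False)
        raise ValueError(f"{path}: duplicated edge rows: {[tuple(p) for p in pairs]}")
    return df.sort_values(["u", "v"], ignore_index=True)


def write_measure_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a measure table as TSV at full float precision (bit round-trip)."""
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")
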