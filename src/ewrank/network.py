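"""Reading, validating and cleaning PPI networks and companion data.

A PPI network is an undirected simple :class:`networkx.Graph` whose nodes
are opaque protein-identifier strings.  Identifiers are case-sensitive and
no mapping between accession namespaces is attempted: callers must
pre-harmonize ids across the interaction, label, expression, annotation
and sequence files.  Self-loops and duplicate (or reversed-duplicate)
interaction records are dropped at read time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet
import pandas as pd
from Bio import SeqIO
from Bio.UniProt.GOA import gafiterator

logger = logging.getLogger(__name__)

ESSENTIAL = "essential"
NONESSENTIAL = "nonessential"
UNKNOWN = "unknown"
STATUSES = frozenset({ESSENTIAL, NONESSENTIAL, UNKNOWN})

#: status tokens accepted in label files, mapped to canonical statuses.
#: ``conditional`` is resolved by the ``conditional_as_essential`` flag.
_STATUS_ALIASES = {
    "essential": ESSENTIAL,
    "e": ESSENTIAL,
    "nonessential": NONESSENTIAL,
    "non-essential": NONESSENTIAL,
    "n": NONESSENTIAL,
    "unknown": UNKNOWN,
    "u": UNKNOWN,
}


class ParseError(ValueError):
    """Raised when an input file does not parse under its declared dialect."""


def canonical_edge(u: str, v: str) -> tuple[str, str]:
    """Return the endpoints of an undirected edge in canonical (sorted) order."""
    return (u, v) if u <= v else (v, u)


@dataclass
class EssentialityLabels:
    """Protein -> {essential, nonessential, unknown} mapping.

    Proteins absent from the underlying table are reported as ``unknown``
    (knock-out catalogues do not cover every protein in an interaction map).
    """

    statuses: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {s for s in self.statuses.values() if s not in STATUSES}
        if bad:
            raise ValueError(f"invalid status values: {sorted(bad)}")

    def status(self, protein: str) -> str:
        return self.statuses.get(protein, UNKNOWN)

    def is_essential(self, protein: str) -> bool:
        return self.status(protein) == ESSENTIAL

    def counts(self) -> dict[str, int]:
        out = {ESSENTIAL: 0, NONESSENTIAL: 0, UNKNOWN: 0}
        for s in self.statuses.values():
            out[s] += 1
        return out

    def __len__(self) -> int:
        return len(self.statuses)


@dataclass
class AnnotationSet:
    """Per-protein ontology term sets plus the term DAG they live in.

    ``ontology`` is a directed graph with child->parent edges carrying a
    ``relation`` attribute (``is_a`` or ``part_of``).  Every annotated term
    must exist in the DAG and the DAG must be acyclic.
    """

    terms: dict[str, set[str]]
    ontology: nx.DiGraph

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.ontology):
            raise ValueError("ontology graph contains a cycle")
        known = set(self.ontology.nodes)
        for protein, ts in self.terms.items():
            missing = ts - known
            if missing:
                raise ValueError(
                    f"protein {protein!r} annotated with unknown terms: {sorted(missing)}"
                )

    def annotated(self, protein: str) -> set[str]:
        return self.terms.get(protein, set())


def read_edge_list(path: str | Path, format: str = "two-column") -> nx.Graph:
    """Read an undirected PPI edge list.

    Parameters
    ----------
    path
        Two-column whitespace/tab-delimited file (``A B`` per line) or a
        SIF file (``A interaction-type B [C ...]``, one source per line).
    format
        ``"two-column"`` or ``"sif"``.

    Self-loops are dropped and duplicate / reversed-duplicate edges are
    collapsed; the numbers dropped are logged.  Lines starting with ``#``
    are comments.
    """
    path = Path(path)
    if format not in ("two-column", "sif"):
        raise ValueError(f"unknown edge-list format: {format!r}")
    net = nx.Graph()
    n_self, n_dup, n_lines = 0, 0, 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            n_lines += 1
            if format == "two-column":
                if len(fields) < 2:
                    raise ParseError(f"{path}:{lineno}: expected two columns, got {line!r}")
                pairs = [(fields[0], fields[1])]
            else:  # SIF: source, relation, targets...
                if len(fields) < 3:
                    raise ParseError(f"{path}:{lineno}: SIF line needs source, type, target(s)")
                pairs = [(fields[0], t) for t in fields[2:]]
            for u, v in pairs:
                if u == v:
                    n_self += 1
                    continue
                if net.has_edge(u, v):
                    n_dup += 1
                    continue
                net.add_edge(u, v)
    if n_lines == 0:
        raise ParseError(f"{path}: no interaction records found")
    logger.info(
        "read %s: %d nodes, %d edges (%d self-loops dropped, %d duplicates collapsed)",
        path, net.number_of_nodes(), net.number_of_edges(), n_self, n_dup,
    )
    return net


def filter_small_components(net: nx.Graph, min_size: int = 5) -> nx.Graph:
    """Keep only connected components with at least ``min_size`` nodes.

    The default of 5 removes single-pair interactions and small unconnected
    fragments, which carry no triangle signal.  Idempotent; never adds
    nodes or edges.  May return an empty graph.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    keep: set[str] = set()
    for comp in nx.connected_components(net):
        if len(comp) >= min_size:
            keep |= comp
    out = net.subgraph(keep).copy()
    logger.info(
        "component filter (min %d): kept %d/%d nodes, %d/%d edges",
        min_size, out.number_of_nodes(), net.number_of_nodes(),
        out.number_of_edges(), net.number_of_edges(),
    )
    return out


def read_labels(path: str | Path, conditional_as_essential: bool = True) -> EssentialityLabels:
    """Read a TSV of ``protein_id<TAB>status`` essentiality labels.

    ``conditional`` records map to essential by default (conditionally
    essential genes are lethal in at least one tested environment); with
    the flag off they become unknown.
    """
    path = Path(path)
    statuses: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected protein_id and status")
            protein, token = fields[0], fields[1].lower()
            if protein == "protein_id":  # header row
                continue
            if token == "conditional":
                status = ESSENTIAL if conditional_as_essential else UNKNOWN
            elif token in _STATUS_ALIASES:
                status = _STATUS_ALIASES[token]
            else:
                raise ParseError(f"{path}:{lineno}: unrecognized status token {token!r}")
            statuses[protein] = status
    labels = EssentialityLabels(statuses)
    logger.info("read %s: %s", path, labels.counts())
    return labels


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression matrix (TSV, header row of sample ids).

    Duplicate gene rows are an error (ambiguous profiles); at least 3
    samples are required for any downstream correlation to be defined.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    dupes = df.index[df.index.duplicated()].unique().tolist()
    if dupes:
        raise ParseError(f"{path}: duplicate gene rows: {dupes}")
    return df.astype(float)


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_annotations(obo_path: str | Path, gaf_path: str | Path) -> AnnotationSet:
    """Read a GO-style ontology (OBO 1.2) plus protein annotations (GAF 2.x).

    Proteins in the GAF annotated with terms missing from the ontology are
    an error; proteins absent from the GAF simply have no annotations.
    The returned DAG keeps child->parent ``is_a``/``part_of`` links only.
    """
    onto_multi = obonet.read_obo(str(obo_path))
    dag = nx.DiGraph()
    dag.add_nodes_from(onto_multi.nodes)
    for child, parent, key in onto_multi.edges(keys=True):
        if key in ("is_a", "part_of"):
            dag.add_edge(child, parent, relation=key)
    terms: dict[str, set[str]] = {}
    with open(gaf_path) as fh:
        for rec in gafiterator(fh):
            terms.setdefault(rec["DB_Object_ID"], set()).add(rec["GO_ID"])
    return AnnotationSet(terms=terms, ontology=dag)


def read_sequences(fasta_path: str | Path) -> dict[str, str]:
    """Read protein sequences from FASTA; ids are headers up to first whitespace."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
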