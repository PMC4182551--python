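"""Synthetic benchmark bundles: a PPI-like network with a planted
essential core, plus matching expression, annotation, label and sequence
data.

The generator emulates the structure the edge-ranking method exploits:
essential proteins interconnect densely (a planted-partition /
stochastic-block-model graph with p_core >> p_cross >= p_periphery),
co-express (core genes share a latent expression factor), and share
function (core proteins draw ontology terms from a common pool).  Labels
mark the core essential and the periphery nonessential, with a fraction
masked to unknown as in real knock-out catalogues.  Everything derives
from a single seed, so bundles are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .network import (
    ESSENTIAL,
    NONESSENTIAL,
    UNKNOWN,
    AnnotationSet,
    EssentialityLabels,
    read_annotations,
    read_edge_list,
    read_expression,
    read_labels,
    read_sequences,
)

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class FixtureParams:
    """Generator knobs.

    Edge probabilities follow the planted-partition premise
    (p_core > p_cross >= p_periphery); ``core_correlation`` is the target
    mean Pearson correlation between two core genes' expression profiles;
    ``core_term_overlap`` the fraction of a core protein's annotations
    drawn from the shared core term pool; ``unknown_fraction`` of labels
    are masked to unknown.  ``n_modules`` splits the core into several
    planted blocks (each with its own latent expression factor) to
    exercise module extraction.
    """

    n_core: int = 30
    n_periphery: int = 120
    p_core: float = 0.5
    p_periphery: float = 0.02
    p_cross: float = 0.03
    expr_samples: int = 36
    core_correlation: float = 0.8
    annot_terms: int = 40
    core_term_overlap: float = 0.7
    unknown_fraction: float = 0.09
    n_modules: int = 1
    seed: int = 7

    def __post_init__(self) -> None:
        for p in (self.p_core, self.p_periphery, self.p_cross,
                  self.core_correlation, self.core_term_overlap, self.unknown_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities/fractions must lie in [0, 1]")
        if self.n_core >= 1 and self.p_core <= self.p_cross:
            raise ValueError("p_core must exceed p_cross (planted core must be denser)")
        if self.n_core + self.n_periphery < 10:
            raise ValueError("need at least 10 proteins in total")
        if self.n_modules < 1:
            raise ValueError("n_modules must be >= 1")


@dataclass
class FixtureBundle:
    """All the objects one analysis run consumes, over one id universe."""

    net: nx.Graph
    labels: EssentialityLabels
    expr: pd.DataFrame
    annots: AnnotationSet
    seqs: dict[str, str]
    core: set[str]
    params: FixtureParams | None = field(default=None, compare=False)


def _block_sizes(params: FixtureParams) -> list[int]:
    base, extra = divmod(params.n_core, params.n_modules)
    cores = [base + (1 if i < extra else 0) for i in range(params.n_modules)]
    return [c for c in cores if c > 0] + [params.n_periphery]


def generate_fixture(params: FixtureParams | None = None) -> FixtureBundle:
    """Generate a complete bundle from a single seed.

    The graph is a stochastic block model over ``n_modules`` core blocks
    and one periphery block; protein ids are assigned by a seeded shuffle
    so identifier order carries no information about the planted labels.
    """
    params = params or FixtureParams()
    if params.n_core < 1:
        raise ValueError("empty core: n_core must be >= 1")
    rng = np.random.default_rng(params.seed)

    sizes = _block_sizes(params)
    n_core_blocks = len(sizes) - 1
    n = sum(sizes)
    probs = [
        [
            params.p_core if (i == j and i < n_core_blocks)
            else params.p_periphery if (i == j)
            else params.p_cross
            for j in range(len(sizes))
        ]
        for i in range(len(sizes))
    ]
    g_int = nx.stochastic_block_model(sizes, probs, seed=int(rng.integers(2**31)))

    ids = [f"G{i:04d}" for i in range(1, n + 1)]
    rng.shuffle(ids)
    mapping = dict(enumerate(ids))
    net = nx.Graph()
    net.add_nodes_from(ids)
    net.add_edges_from((mapping[u], mapping[v]) for u, v in g_int.edges)

    block_of = {}  # protein -> core-block index, or -1 for periphery
    offset = 0
    for b, size in enumerate(sizes):
        for i in range(offset, offset + size):
            block_of[mapping[i]] = b if b < n_core_blocks else -1
        offset += size
    core = {p for p, b in block_of.items() if b >= 0}

    # expression: one latent factor per core block; noise sd chosen so the
    # expected pairwise within-block correlation 1/(1+sd^2) hits the target
    samples = [f"S{j:02d}" for j in range(1, params.expr_samples + 1)]
    r = params.core_correlation
    sd = math.sqrt(1.0 / r - 1.0) if r > 0 else math.inf
    latents = rng.normal(size=(n_core_blocks, params.expr_samples))
    profiles = {}
    for p in ids:
        b = block_of[p]
        if b >= 0 and math.isfinite(sd):
            profiles[p] = latents[b] + rng.normal(scale=sd, size=params.expr_samples)
        else:
            profiles[p] = rng.normal(size=params.expr_samples)
    expr = pd.DataFrame.from_dict(profiles, orient="index", columns=samples).loc[
        sorted(ids)
    ]
    expr.index.name = "gene"

    # ontology: root -> branch terms -> leaf terms (mixed is_a / part_of)
    n_leaves = max(params.annot_terms, 4)
    n_branches = max(2, n_leaves // 8)
    dag = nx.DiGraph()
    root = "T:0000"
    dag.add_node(root)
    branches = [f"T:B{i:02d}" for i in range(n_branches)]
    for b in branches:
        dag.add_edge(b, root, relation="is_a")
    leaves = [f"T:{i:04d}" for i in range(1, n_leaves + 1)]
    for i, t in enumerate(leaves):
        rel = "is_a" if i % 3 else "part_of"
        dag.add_edge(t, branches[i % n_branches], relation=rel)
    core_pool = leaves[: max(2, n_leaves // 3)]
    terms: dict[str, set[str]] = {}
    for p in ids:
        k = int(rng.integers(3, 7))
        if block_of[p] >= 0:
            k_core = int(round(k * params.core_term_overlap))
            chosen = set(rng.choice(core_pool, size=min(k_core, len(core_pool)),
                                    replace=False))
            chosen |= set(rng.choice(leaves, size=k - len(chosen), replace=True))
        elif rng.random() < 0.9:  # leave ~10% of the periphery unannotated
            chosen = set(rng.choice(leaves, size=min(k, 3), replace=False))
        else:
            chosen = set()
        if chosen:
            terms[p] = chosen
    annots = AnnotationSet(terms=terms, ontology=dag)

    # sequences: each core block diverges ~5% from a block ancestor;
    # periphery sequences are independent draws
    seq_len = 120
    ancestors = [
        "".join(rng.choice(list(_AA), size=seq_len)) for _ in range(n_core_blocks)
    ]
    seqs = {}
    for p in ids:
        b = block_of[p]
        if b >= 0:
            s = list(ancestors[b])
            for i in rng.choice(seq_len, size=max(1, seq_len // 20), replace=False):
                s[i] = rng.choice(list(_AA))
            seqs[p] = "".join(s)
        else:
            seqs[p] = "".join(rng.choice(list(_AA), size=seq_len))

    statuses = {p: (ESSENTIAL if p in core else NONESSENTIAL) for p in ids}
    n_mask = int(round(params.unknown_fraction * n))
    for p in rng.choice(sorted(ids), size=n_mask, replace=False):
        statuses[p] = UNKNOWN
    labels = EssentialityLabels(statuses)

    return FixtureBundle(net=net, labels=labels, expr=expr, annots=annots,
                         seqs=seqs, core=core, params=params)


PRESETS = {
    "default": FixtureParams(),
    "multimodule": FixtureParams(n_core=40, n_modules=3),
    # no planted structure at all: one uniform random block, no signal
    "null": FixtureParams(n_core=1, n_periphery=149, p_core=0.05,
                          p_cross=0.03, p_periphery=0.03,
                          core_correlation=0.0, core_term_overlap=0.0),
}


def preset(name: str, seed: int | None = None) -> FixtureParams:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    p = PRESETS[name]
    return replace(p, seed=seed) if seed is not None else p


# -- serialization -----------------------------------------------------------

FILES = {
    "edges": "edges.tsv",
    "labels": "labels.tsv",
    "expr": "expression.tsv",
    "obo": "ontology.obo",
    "gaf": "annotations.gaf",
    "fasta": "sequences.fasta",
    "core": "core.txt",
}


def write_fixture(bundle: FixtureBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle in the exact dialects the readers accept.

    Emits a two-column edge list, a protein/status TSV, an expression TSV,
    OBO 1.2 + GAF 2.1 annotation files, a FASTA and the ground-truth core
    list; ``read_fixture`` of the result round-trips the bundle.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: outdir / v for k, v in FILES.items()}

    with open(paths["edges"], "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in bundle.net.edges):
            fh.write(f"{u}\t{v}\n")
        for node in sorted(n for n in bundle.net.nodes if bundle.net.degree(n) == 0):
            fh.write(f"# isolated: {node}\n")

    with open(paths["labels"], "w") as fh:
        fh.write("protein_id\tstatus\n")
        for p in sorted(bundle.labels.statuses):
            fh.write(f"{p}\t{bundle.labels.statuses[p]}\n")

    bundle.expr.to_csv(paths["expr"], sep="\t", index_label="gene")

    dag = bundle.annots.ontology
    with open(paths["obo"], "w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic\n")
        for term in sorted(dag.nodes):
            fh.write(f"\n[Term]\nid: {term}\nname: synthetic term {term}\n")
            for parent in sorted(dag.successors(term)):
                rel = dag[term][parent].get("relation", "is_a")
                if rel == "is_a":
                    fh.write(f"is_a: {parent}\n")
                else:
                    fh.write(f"relationship: part_of {parent}\n")

    with open(paths["gaf"], "w") as fh:
        fh.write("!gaf-version: 2.1\n")
        for p in sorted(bundle.annots.terms):
            for t in sorted(bundle.annots.terms[p]):
                cols = ["SYN", p, p, "", t, "SYN:0001", "IEA", "", "P",
                        "", "", "protein", "taxon:0", "20140930", "SYN", "", ""]
                fh.write("\t".join(cols) + "\n")

    with open(paths["fasta"], "w") as fh:
        for p in sorted(bundle.seqs):
            fh.write(f">{p}\n{bundle.seqs[p]}\n")

    with open(paths["core"], "w") as fh:
        for p in sorted(bundle.core):
            fh.write(p + "\n")

    return paths


def read_fixture(outdir: str | Path) -> FixtureBundle:
    """Read a written bundle back through the standard readers."""
    outdir = Path(outdir)
    paths = {k: outdir / v for k, v in FILES.items()}
    net = read_edge_list(paths["edges"])
    for line in open(paths["edges"]):
        if line.startswith("# isolated:"):
            net.add_node(line.split(":", 1)[1].strip())
    core = {line.strip() for line in open(paths["core"]) if line.strip()}
    return FixtureBundle(
        net=net,
        labels=read_labels(paths["labels"]),
        expr=read_expression(paths["expr"]),
        annots=read_annotations(paths["obo"], paths["gaf"]),
        seqs=read_sequences(paths["fasta"]),
        core=core,
    )
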