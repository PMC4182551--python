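# ewrank

Essential proteins are those a cell cannot survive without; in a
protein–protein interaction (PPI) network they tend to interact densely
with *each other*, to co-express, and to share function.  `ewrank`
predicts essential proteins by ranking the network's **edges** rather
than its nodes: each interaction (u, v) receives a weight

```
W(u,v) = GE(u,v)^λ1 · PCC(u,v)^λ2 · NTE(u,v)^λ3 · PP(u,v)^λ4 ,   λi ∈ {0,1}
```

the plain product of the enabled per-pair measures —

* **GE** — GO-annotation functional similarity of the two proteins
  (Jaccard overlap of term sets by default, or a Wang-style
  best-match-average over the ontology DAG),
* **PCC** — Pearson correlation of their gene-expression profiles
  (negative correlations clamped to zero by default),
* **NTE** — the number of triangles the edge belongs to,
  |N(u) ∩ N(v)|,
* **PP** — Jukes–Cantor-corrected pairwise sequence distance
  (available but disabled by default: it adds nothing to accuracy).

Edges are sorted by descending weight and the ranked protein list is
read off the edge ranking: walking from the strongest edge down, each
endpoint is emitted the first time it appears.  The top *k* of that list
are the essential-protein candidates.  The package also provides the
standard node-centrality baselines (NC — summed edge clustering
coefficient; PeC — ECC × co-expression; degree), precision–recall and
Jackknife evaluation against essentiality labels, an edge-deletion
robustness protocol, extraction of top-edge network modules, and a fully
synthetic benchmark generator so everything is testable without any
downloads.

It is written for computational/systems biologists who have a PPI edge
list (two-column or SIF), a knock-out–derived essentiality table
(essential / nonessential / conditional / unknown), and optionally an
expression matrix, GO annotations (OBO + GAF) and protein FASTA.

## Worked example

```python
import ewrank
from ewrank.fixtures import FixtureParams, generate_fixture

bundle = generate_fixture(FixtureParams(seed=7))   # 150 proteins, 30 planted essentials
table = ewrank.build_measure_table(bundle.net, expr=bundle.expr, annots=bundle.annots)
ranked = ewrank.rank_edges(table)                  # GE·PCC·NTE weights
proteins = ewrank.proteins_from_edges(ranked)

print("strongest edge:", ranked.edges[0], f"weight={ranked.weights[0]:.3f}")
print("top 5 proteins:", proteins[:5])
curve = ewrank.precision_recall(proteins, bundle.labels)
print(f"precision@50 = {curve.at(50)['precision']:.3f}, recall@50 = {curve.at(50)['recall']:.3f}")
recovered = sum(p in bundle.core for p in proteins[:len(bundle.core)])
print(f"planted core recovered in top-30: {recovered}/{len(bundle.core)}")
```

prints

```
strongest edge: ('G0091', 'G0097') weight=3.832
top 5 proteins: ['G0091', 'G0097', 'G0122', 'G0056', 'G0065']
precision@50 = 0.600, recall@50 = 1.000
planted core recovered in top-30: 30/30
```

All 30 planted essential proteins occupy the first 30 rank positions
(the remaining top-50 slots are filled by periphery proteins, hence
precision 0.600 at k = 50 while recall already reaches 1.0 — every
essential protein labelled as such in this bundle sits inside the
top 50).  The strongest edge joins two core proteins: high triangle
count, high co-expression, shared annotations.

The same pipeline from the shell:

```sh
ewrank fixture --preset default --seed 7 --out fx/
ewrank rank --edges fx/edges.tsv --expr fx/expression.tsv \
            --obo fx/ontology.obo --gaf fx/annotations.gaf \
            --labels fx/labels.tsv --out run/
ewrank baseline --method nc --edges fx/edges.tsv --out nc.tsv
```

Every ranked output carries a header comment with the tool version and a
hash of the resolved configuration (λ flags, tie policy, clamping
policy), so reported counts are traceable to the choices that produced
them.

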