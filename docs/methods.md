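# Methods

## The edge-weight model

The working hypothesis is that protein essentiality is carried by
*interactions*: essential proteins form densely interconnected,
co-expressed, functionally coherent neighbourhoods, so the interactions
inside such neighbourhoods are the signal worth ranking.  Each edge
(u, v) of an undirected simple PPI graph receives

W(u,v) = Π over enabled measures m of m(u,v),

a plain product rather than a normalized sum.  The measures live on
different scales (a correlation in [−1,1], a similarity in [0,1], a
triangle count in ℕ) and differ across species; a product is invariant
to those scales in the only way that matters for a ranking — multiplying
any one measure by a positive constant across all edges leaves the edge
order unchanged — and it makes any single zero measure veto the edge,
which matches the conjunctive hypothesis (a strong edge must be strong
topologically *and* biologically).  The default measure set is
GE·PCC·NTE; the sequence-distance measure PP is implemented but disabled
by default because it contributes no ranking signal when combined with
the others.

The protein ranking is read off the edge ranking: edges are visited in
descending weight, each edge emits its two endpoints in canonical
order, and a protein is emitted only on first appearance.  Proteins
touching many strong edges therefore surface early; proteins incident to
no edge never appear and consumers must treat them as ranked last.

### Measures

* **NTE** — |N(u) ∩ N(v)|, the number of triangles through the edge.
  Exact, integer, recomputed whenever topology changes.
* **PCC** — Pearson correlation over samples where both genes are
  finite; missing (NaN) if a gene is absent, fewer than 3 common samples
  exist, or a profile is constant.  Negative values are clamped to zero
  at weighting time by default (negative co-expression is not evidence
  of joint essentiality); an absolute-value policy is available and
  recorded in the config.
* **GE** — default is the Jaccard overlap of the two proteins' term
  sets: parameter-free, monotone in shared annotation, and independent
  of ontology topology.  A DAG-aware alternative (`dag-bma`) propagates
  per-term semantic contributions through is_a (0.8) and part_of (0.6)
  parent links, scores term pairs by shared-ancestor contribution, and
  aggregates by best-match average; it credits distinct but
  ontologically close terms at the cost of two tuning constants.  The
  method used is carried in the measure-table provenance.
* **PP** — mismatch proportion p over the aligned non-gap columns of a
  global pairwise alignment (BLOSUM62, gap open −10, extend −0.5),
  corrected for multiple substitutions over a 20-letter alphabet:
  d = −(19/20)·ln(1 − (20/19)p), missing when saturated (p ≥ 19/20).
  Stored as a distance; disabled by default.

Missing measure values propagate to the weighting stage and produce
weight 0 there — never silent imputation, and never row exclusion, so
every edge keeps a rank position.

### Ties and determinism

Equal-weight edges (common: every zero-weight edge ties) are ordered
lexicographically on canonical (u, v) by default, which is reproducible
across platforms and runs; an input-order policy exists for replaying
externally supplied tables.  All outputs embed a hash of the resolved
configuration.

## Baselines

NC(i) = Σ_j ECC(i,j) with ECC = NTE / min(deg u − 1, deg v − 1)
(0 when the denominator is ≤ 0); PeC(i) = Σ_j ECC(i,j)·max(0, PCC(i,j));
degree centrality.  The exact published variants of NC and PeC are
defined in their source works, not re-printed alongside the edge-weight
method; the forms implemented here are the ECC-sum and
ECC×co-expression-sum readings, tagged on every score table so outputs
are traceable.  PeC deliberately reuses the same negative-correlation
clamp as the edge weights so the two methods differ only in how they
aggregate.

## Evaluation

At each cutoff n of a ranked list, TP(n) counts essential proteins,
FP(n) nonessential ones; unknown-status proteins occupy rank positions
but enter neither count, so TP + FP ≤ n.  Precision = TP/(TP+FP)
(defined as 0 on an all-unknown prefix), recall = TP/P.  P defaults to
the number of essential-labelled proteins present in the evaluated
list, so a perfect ranking reaches recall 1.0; an explicit organism-wide
P can be passed instead.  The Jackknife curve is the cumulative TP(n)
against n, with the random-selection reference slope P/N.

## Perturbation protocol

Robustness is probed by deleting X edges per step for `steps` cumulative
steps, chosen from the top, the bottom, or uniformly at random (seeded,
without replacement) of the *original* ranked edge list — the deletion
schedule is fixed once, not re-derived per step.  On every perturbed
network the scorer is re-applied from scratch: triangle counts, ECC and
degree are topology-dependent and recomputed, while GE and PCC are
pair-intrinsic and kept from the unperturbed table.  Nodes isolated by
deletion stay in the graph (they can no longer be ranked by edges, which
is itself part of the signal).  P is held fixed across steps so curves
are comparable.

A subtlety follows from recomputation: deleting a weak edge that closes
a triangle with a strong edge lowers that strong edge's NTE, which can
swap adjacent same-tier proteins in the ranked *sequence* without
altering which proteins are predicted.  The package therefore treats
"the prediction at cutoff k" as the **set** of the first k proteins when
assessing whether a perturbation changed the prediction.  On the default
synthetic bundle (k = 30, the planted-core size), deleting 20 weakest
edges per step for 10 steps — about 42% of all edges — never changes the
predicted set, while deleting 30 strongest edges per step changes it
within 3 steps.  The bottom/top step sizes are asymmetric by design,
mirroring the protocol this analysis follows, where an order of
magnitude more edges are removed per step from the bottom than from the
top.

## Synthetic benchmark generator

`generate_fixture` emulates exactly the structure the method assumes,
with a stochastic block model: one (or several) dense core blocks of
essential proteins (edge probability p_core = 0.5 within), a sparse
periphery (p_periphery = 0.02), and sparse core–periphery mixing
(p_cross = 0.03).  Defaults: 30 core + 120 periphery proteins.  Core
genes' expression is one latent N(0,1) profile per block plus
independent noise with sd chosen as √(1/r − 1) so the expected pairwise
within-block correlation equals the target r = 0.8 over 36 samples (36
matches a typical time-course compendium); periphery profiles are
independent.  Core proteins draw ~70% of their 3–6 ontology terms from
a shared pool in a small three-level DAG (mixed is_a/part_of links);
about 10% of periphery proteins are left unannotated to exercise the
missing-value path.  Core sequences diverge ~5% from a per-block
ancestor; periphery sequences are independent.  Labels mark core
essential and periphery nonessential, then 9% of all labels are masked
to unknown, matching the share of uncatalogued proteins in a typical
curated map.  Protein identifiers are assigned by a seeded shuffle so
lexicographic tie-breaking carries no information about the planted
truth.  All draws flow from one integer seed; equal seeds give
bit-identical bundles.

What the generator does **not** emulate: heavy-tailed degree
distributions, experimental false-positive/false-negative interaction
noise, correlated annotation bias (well-studied proteins having more
terms), or realistic expression noise spectra.  Passing tests on these
bundles therefore demonstrates correctness of the machinery and
recoverability of a planted signal under idealized conditions — not
expected accuracy on real interactome data.  The planted core is also
denser relative to the network than real essential sub-networks, which
makes the set-level prediction *more* robust to top-edge deletion than a
real map would be; the robustness checks account for this by deleting a
larger edge fraction than a full-size study needs.

## Problem sizes and numerical choices

Tests and the acceptance script run on bundles of 150 proteins
(~480 edges), 100-seed replication for the parameter-recovery rate, and
random-graph oracle checks up to n = 50; these sizes give stable
statistics while keeping a full run in tens of seconds.  Float
comparisons in tests use relative tolerances of 1e-6 or better; measure
tables are written at 17 significant digits so read∘write is
bit-faithful.  Degenerate inputs are handled explicitly: empty networks
yield empty tables, an all-zero-weight ranking falls back to pure
lexicographic order, saturated sequence distances and short/constant
expression profiles are missing values, and star-graph ECC denominators
of zero score 0.

## Known limitations

* Identifier harmonization across input files is the caller's job; no
  accession mapping is attempted, and proteins absent from a source are
  treated as missing rather than matched fuzzily.
* The published variants of NC/PeC may differ in detail from the
  readings implemented here; comparisons against printed baseline
  numbers should account for that.
* GO namespaces are pooled, not split per aspect.
* Reproducing published organism-scale counts requires the original
  per-edge supplementary tables, which are third-party data and not
  redistributed.
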