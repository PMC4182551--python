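"""Reproduction of published top-k essential counts from precomputed
per-edge measure tables.

Some PPI studies distribute, alongside the interaction map, a per-edge
table of GO similarity, co-expression and triangle counts plus a
per-protein essentiality table.  Given those two files this module
re-derives the ranked protein list (GE x PCC x NTE weights) and counts
essential proteins among the top k, for direct comparison with printed
values.  The tables themselves are not shipped with this package; point
the functions at local copies (convert spreadsheets to TSV first).
"""

from __future__ import annotations

from pathlib import Path

from .evaluation import top_k_true_positives
from .measures import read_measure_table
from .network import read_labels
from .ranking import EdgeWeightConfig, proteins_from_edges, rank_edges

#: published top-k essential-protein counts for the two benchmark maps
PUBLISHED_COUNTS = {
    "yeast": {100: 83, 200: 158, 600: 374},
    "ecoli": {100: 57, 200: 109, 400: 172, 600: 221},
}


def reproduce_counts(
    measures_path: str | Path,
    labels_path: str | Path,
    ks: tuple[int, ...],
    tie_policy: str = "lexicographic",
) -> dict[int, int]:
    """Top-k essential counts from a measure table + label table.

    Weights are the GE x PCC x NTE product (negative co-expression
    clamped to zero); tie order among equal weights is configurable
    because published rankings rarely state it.
    """
    table = read_measure_table(measures_path)
    labels = read_labels(labels_path)
    config = EdgeWeightConfig(enabled=("GE", "PCC", "NTE"), tie_policy=tie_policy)
    proteins = proteins_from_edges(rank_edges(table, config))
    return {k: top_k_true_positives(proteins, labels, k) for k in ks}
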