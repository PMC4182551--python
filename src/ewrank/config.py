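"""Run configuration and the end-to-end pipeline.

A run is described by a flat YAML file (or CLI flags overriding it).
The resolved config is validated before any computation, hashed, and the
hash embedded as a header comment in every ranked output, so published
counts stay traceable to the tie-break and clamp policies that produced
them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__, measures, ranking
from .evaluation import compare_methods, jackknife, precision_recall
from .network import (
    filter_small_components,
    read_annotations,
    read_edge_list,
    read_expression,
    read_labels,
    read_sequences,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Fully resolved parameters for one pipeline run."""

    edges: str | None = None
    edge_format: str = "two-column"
    measures_table: str | None = None
    expr: str | None = None
    obo: str | None = None
    gaf: str | None = None
    fasta: str | None = None
    labels: str | None = None
    lambdas: tuple[str, ...] = ("GE", "PCC", "NTE")
    tie_policy: str = "lexicographic"
    negative_pcc_policy: str = "clamp-to-zero"
    go_method: str = "jaccard"
    min_component_size: int = 5
    conditional_as_essential: bool = True
    ks: tuple[int, ...] = (50, 100, 200, 300, 400, 500, 600)
    perturb_mode: str | None = None
    perturb_x: int = 100
    perturb_steps: int = 10
    seed: int = 7
    out: str = "ewrank-out"

    def __post_init__(self) -> None:
        self.lambdas = tuple(self.lambdas)
        self.ks = tuple(int(k) for k in self.ks)
        # constructing the weight config validates λ/tie/clamp choices
        self.weight_config()
        if self.min_component_size < 1:
            raise ValueError("min_component_size must be >= 1")
        if self.measures_table is None:
            if self.edges is None:
                raise ValueError("either edges or measures_table must be given")
            needs = {"GE": ("obo", "gaf"), "PCC": ("expr",), "PP": ("fasta",)}
            for lam, attrs in needs.items():
                if lam in self.lambdas:
                    for a in attrs:
                        if getattr(self, a) is None:
                            raise ValueError(
                                f"lambda {lam} enabled but --{a} input is missing"
                            )

    def weight_config(self) -> ranking.EdgeWeightConfig:
        return ranking.EdgeWeightConfig(
            enabled=self.lambdas,
            tie_policy=self.tie_policy,
            negative_pcc_policy=self.negative_pcc_policy,
        )

    def digest(self) -> str:
        # the output directory does not influence results; keep it out of
        # the provenance hash so reruns into different dirs match
        payload = {k: v for k, v in dataclasses.asdict(self).items() if k != "out"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus flag overrides.

    Flags win over file values.  Unknown keys are an error (a silently
    ignored typo would change results without a trace).
    """
    values: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(values) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**values)


def _provenance_header(config: RunConfig) -> str:
    return (
        f"# ewrank {__version__} config={config.digest()} "
        f"lambdas={','.join(config.lambdas)} tie={config.tie_policy} "
        f"pcc={config.negative_pcc_policy}\n"
    )


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute read -> filter -> measures -> rank -> evaluate end-to-end.

    Returns the paths of every file written.  Deterministic given the
    config and seed.
    """
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    try:
        if config.measures_table is not None:
            table = measures.read_measure_table(config.measures_table)
        else:
            net = read_edge_list(config.edges, format=config.edge_format)
            net = filter_small_components(net, config.min_component_size)
            expr = read_expression(config.expr) if config.expr else None
            annots = (
                read_annotations(config.obo, config.gaf) if config.obo else None
            )
            seqs = read_sequences(config.fasta) if config.fasta else None
            table = measures.build_measure_table(
                net, expr=expr, annots=annots, seqs=seqs,
                enabled=config.lambdas, go_method=config.go_method,
            )
    except Exception as exc:
        raise RuntimeError(f"[measures] {exc}") from exc

    try:
        ranked = ranking.rank_edges(table, config.weight_config())
        proteins = ranking.proteins_from_edges(ranked)
    except Exception as exc:
        raise RuntimeError(f"[ranking] {exc}") from exc

    header = _provenance_header(config)
    edges_path = outdir / "ranked_edges.tsv"
    with open(edges_path, "w") as fh:
        fh.write(header)
        ranked.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.17g")
    written["ranked_edges"] = edges_path

    proteins_path = outdir / "ranked_proteins.tsv"
    with open(proteins_path, "w") as fh:
        fh.write(header)
        fh.write("rank\tprotein\n")
        for i, p in enumerate(proteins, start=1):
            fh.write(f"{i}\t{p}\n")
    written["ranked_proteins"] = proteins_path

    if config.labels:
        try:
            labels = read_labels(
                config.labels, conditional_as_essential=config.conditional_as_essential
            )
            ks = tuple(k for k in config.ks if k <= len(proteins)) or (len(proteins),)
            counts = compare_methods({"ew": proteins}, labels, ks=ks)
            pr = precision_recall(proteins, labels)
            jk = jackknife(proteins, labels)
        except Exception as exc:
            raise RuntimeError(f"[evaluation] {exc}") from exc
        counts_path = outdir / "topk_counts.tsv"
        with open(counts_path, "w") as fh:
            fh.write(header)
            counts.to_csv(fh, sep="\t")
        written["topk_counts"] = counts_path
        for name, curve in (("pr_curve", pr), ("jackknife_curve", jk)):
            p = outdir / f"{name}.tsv"
            with open(p, "w") as fh:
                fh.write(header)
                curve.frame.to_csv(fh, sep="\t", index=False)
            written[name] = p

    logger.info("pipeline wrote %d files to %s", len(written), outdir)
    return written
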