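"""Integration of predicted miRNA targets with literature-derived disease
genes, and the end-to-end pipeline runner.

The integrative step is a case-normalized set intersection: genes that are
both consensus-predicted targets of the miRNA *and* significantly
disease-associated in the literature.  The overlap is then annotated with
the pathways in which it is significantly enriched.

:func:`run_pipeline` wires every stage together on synthetic inputs with
planted ground truth: corpus simulation -> co-citation mining -> consensus
target voting -> overlap -> pathway enrichment -> network hub analysis,
plus an expression meta-analysis on simulated studies.  The whole run is
deterministic under the config seed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import io as mio
from .consensus import consensus_targets, support_histogram
from .enrichment import EnrichmentResult, GeneSetCollection, enrich
from .meta import effects_from_studies, forest_table, pool_random_effects
from .mining import filter_significant, rank_genes
from .network import build_network, connectivity, hub_test
from .synthetic import (CorpusSimConfig, MetaSimConfig, PredictorSimConfig,
                        simulate_corpus, simulate_genesets_and_edges,
                        simulate_meta_studies, simulate_predictions)

logger = logging.getLogger(__name__)

__all__ = ["OverlapReport", "PipelineConfig", "overlap", "annotate_overlap",
           "run_pipeline"]


@dataclass(frozen=True)
class OverlapReport:
    """Genes supported by both evidence streams, with pathway annotation."""

    overlap_genes: tuple[str, ...]
    n_targets: int
    n_disease_genes: int
    per_gene_pathways: dict[str, tuple[str, ...]] = field(default_factory=dict)
    significant_pathways: tuple[EnrichmentResult, ...] = ()

    @property
    def n_overlap(self) -> int:
        return len(self.overlap_genes)


def _normalize(genes: Iterable[str], aliases: Mapping[str, str] | None) -> set[str]:
    table = {k.strip().upper(): v.strip().upper() for k, v in (aliases or {}).items()}
    out = set()
    for g in genes:
        sym = str(g).strip().upper()
        out.add(table.get(sym, sym))
    return out


def overlap(targets: Iterable[str], disease_genes: Iterable[str],
            aliases: Mapping[str, str] | None = None) -> OverlapReport:
    """Case-normalized intersection of target and disease-gene sets.

    ``aliases`` maps alternate spellings to canonical symbols (e.g.
    ``{"BCL-2": "BCL2"}``); matching is exact after upper-casing,
    whitespace stripping and alias replacement.  Commutative in its two
    set arguments.
    """
    t = _normalize(targets, aliases)
    d = _normalize(disease_genes, aliases)
    if not t or not d:
        raise ValueError("both input gene sets must be non-empty")
    return OverlapReport(
        overlap_genes=tuple(sorted(t & d)),
        n_targets=len(t),
        n_disease_genes=len(d),
    )


def annotate_overlap(report: OverlapReport,
                     enrichment_results: Sequence[EnrichmentResult],
                     alpha: float = 0.05) -> OverlapReport:
    """Attach significant pathways and a per-gene pathway map to the overlap.

    Only sets with p < alpha annotate; a gene in no significant set gets an
    empty pathway tuple.
    """
    significant = tuple(r for r in enrichment_results if r.p < alpha)
    per_gene = {}
    for gene in report.overlap_genes:
        per_gene[gene] = tuple(sorted(r.set_name for r in significant
                                      if gene in r.overlap_genes))
    return OverlapReport(
        overlap_genes=report.overlap_genes,
        n_targets=report.n_targets,
        n_disease_genes=report.n_disease_genes,
        per_gene_pathways=per_gene,
        significant_pathways=significant,
    )


@dataclass(frozen=True)
class PipelineConfig:
    """Study conditions for the default synthetic end-to-end run.

    120 genes; 20 are disease-associated in the literature, 20 are true
    miRNA targets, and the 10 genes in both groups are the planted
    integrative signal the pipeline should recover.
    """

    seed: int = 0
    n_genes: int = 120
    n_disease_genes: int = 20
    n_true_targets: int = 20
    n_planted_overlap: int = 10
    mining_alpha: float = 0.01
    consensus_threshold: int = 4
    enrichment_alpha: float = 0.05
    n_gene_sets: int = 10
    set_size_range: tuple[int, int] = (5, 20)
    n_edges: int = 150

    def __post_init__(self) -> None:
        if self.n_planted_overlap > min(self.n_disease_genes, self.n_true_targets):
            raise ValueError("planted overlap larger than its parent sets")
        if self.n_disease_genes + self.n_true_targets - self.n_planted_overlap > self.n_genes:
            raise ValueError("disease genes and targets exceed the gene universe")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(f"G{i + 1:03d}" for i in range(self.n_genes))

    @property
    def disease_genes(self) -> tuple[str, ...]:
        return self.genes[: self.n_disease_genes]

    @property
    def true_targets(self) -> tuple[str, ...]:
        start = self.n_disease_genes - self.n_planted_overlap
        return self.genes[start: start + self.n_true_targets]

    @property
    def planted_overlap(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.disease_genes) & set(self.true_targets)))


def run_pipeline(config: PipelineConfig = PipelineConfig(),
                 outdir: str | Path | None = None) -> dict:
    """Run every stage on synthetic inputs and return one JSON-able bundle.

    Per-stage sub-seeds are derived deterministically from ``config.seed``,
    so reruns with the same config produce identical bundles.  With
    ``outdir`` set, per-stage TSVs plus a ``bundle.json`` are written
    there.  Stage timings and record counts go to the logger.
    """
    import numpy as np

    sub = [int(s.generate_state(1)[0] >> 1)  # keep sub-seeds below 2**31
           for s in np.random.SeedSequence(config.seed).spawn(4)]
    genes = config.genes
    bundle: dict = {"config": {
        "seed": config.seed, "n_genes": config.n_genes,
        "n_disease_genes": config.n_disease_genes,
        "n_true_targets": config.n_true_targets,
        "n_planted_overlap": config.n_planted_overlap,
        "mining_alpha": config.mining_alpha,
        "consensus_threshold": config.consensus_threshold,
        "enrichment_alpha": config.enrichment_alpha,
    }}

    def _stage(name):
        logger.info("stage %s ...", name)
        return time.perf_counter()

    # 1. expression meta-analysis on simulated studies
    t0 = _stage("meta")
    meta_cfg = MetaSimConfig(seed=sub[0])
    studies = simulate_meta_studies(meta_cfg)
    effects = effects_from_studies(studies)
    pooled = pool_random_effects(effects)
    bundle["meta"] = {"pooled": pooled.as_dict(),
                      "forest": forest_table(effects, pooled)}
    logger.info("stage meta: %d studies in %.2fs", len(studies), time.perf_counter() - t0)

    # 2. literature mining
    t0 = _stage("mining")
    corpus_cfg = CorpusSimConfig(genes=genes, enriched_genes=config.disease_genes,
                                 seed=sub[1])
    mentions, _ = simulate_corpus(corpus_cfg)
    cocite = rank_genes(mentions, genes=genes)
    disease_called = filter_significant(cocite, alpha=config.mining_alpha)
    bundle["mining"] = {
        "n_docs": corpus_cfg.n_docs,
        "n_genes_scored": len(cocite),
        "disease_genes_called": sorted(disease_called),
    }
    logger.info("stage mining: %d/%d genes called in %.2fs",
                len(disease_called), len(cocite), time.perf_counter() - t0)

    # 3. consensus target calling
    t0 = _stage("consensus")
    pred_cfg = PredictorSimConfig(genes=genes, true_targets=config.true_targets,
                                  seed=sub[2])
    matrix = simulate_predictions(pred_cfg)
    consensus = consensus_targets(matrix, threshold=config.consensus_threshold)
    bundle["consensus"] = {
        "threshold": consensus.threshold,
        "members": {g: consensus.members[g] for g in sorted(consensus.members)},
        "support_histogram": [int(c) for c in support_histogram(matrix)],
    }
    logger.info("stage consensus: %d targets in %.2fs", len(consensus),
                time.perf_counter() - t0)

    # 4. integrative overlap + enrichment annotation
    t0 = _stage("integration")
    core = overlap(consensus.members, disease_called)
    sets, edges = simulate_genesets_and_edges(
        genes, n_sets=config.n_gene_sets, set_size_range=config.set_size_range,
        n_edges=config.n_edges, seed=sub[3])
    collection = GeneSetCollection.from_sets(sets, universe=genes)
    enr = enrich(core.overlap_genes, collection, alpha=config.enrichment_alpha) \
        if core.overlap_genes else []
    report = annotate_overlap(core, enr, alpha=config.enrichment_alpha)
    planted = set(config.planted_overlap)
    recovered = planted & set(report.overlap_genes)
    bundle["integration"] = {
        "n_targets": report.n_targets,
        "n_disease_genes": report.n_disease_genes,
        "overlap_genes": list(report.overlap_genes),
        "n_overlap": report.n_overlap,
        "planted_overlap": list(config.planted_overlap),
        "planted_recall": (len(recovered) / len(planted)) if planted else 1.0,
        "per_gene_pathways": {g: list(p) for g, p in report.per_gene_pathways.items()},
        "significant_pathways": [
            {"term": r.set_name, "count": r.overlap_count, "p_value": r.p,
             "genes": list(r.overlap_genes)}
            for r in report.significant_pathways
        ],
    }
    logger.info("stage integration: overlap %d in %.2fs", report.n_overlap,
                time.perf_counter() - t0)

    # 5. network analysis on the simulated interactions
    t0 = _stage("network")
    graph = build_network(edges)
    degrees = connectivity(graph)
    hubs = hub_test(degrees) if len(degrees) >= 2 else []
    bundle["network"] = {
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "top_hubs": [
            {"node": h.node, "degree": h.degree, "z": h.z, "p": h.p}
            for h in hubs[:10]
        ],
    }
    logger.info("stage network: %d nodes, %d edges in %.2fs",
                graph.number_of_nodes(), graph.number_of_edges(),
                time.perf_counter() - t0)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mio.write_studies_tsv(studies, outdir / "studies.tsv")
        mio.write_forest_tsv(bundle["meta"]["forest"], outdir / "forest.tsv")
        mio.write_mentions_tsv(mentions, outdir / "mentions.tsv")
        mio.write_cocitation_tsv(cocite, outdir / "cocitation.tsv")
        mio.write_predictions_tsv(matrix, outdir / "predictions.tsv")
        mio.write_gmt(sets, outdir / "gene_sets.gmt")
        mio.write_edges_tsv(edges, outdir / "edges.tsv")
        if enr:
            mio.write_enrichment_tsv(enr, outdir / "enrichment.tsv")
        if hubs:
            mio.write_hub_tsv(hubs, outdir / "hubs.tsv")
        mio.write_json(bundle, outdir / "bundle.json")
    return bundle
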