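"""Synthetic inputs with known ground truth for every pipeline stage.

Five generators emulate the five external inputs the pipeline consumes:

* two-group expression studies with a true standardized mean difference
  ``delta`` and between-study SD ``tau`` (random-effects world);
* a document corpus with controlled gene-disease co-mention enrichment;
* a gene x tool boolean prediction matrix with separate hit rates for true
  targets and non-targets;
* random gene-set collections;
* random typed interaction edge lists.

All generators are deterministic under their config seed; per-study /
per-document randomness comes from sub-streams spawned from a single
:class:`numpy.random.SeedSequence`, so callers never manage seeds.

Study-level data are simulated at the observation level and then
summarized, so the per-study SDs carry realistic sampling noise and the
small-sample bias that Hedges' correction addresses is actually exercised.
Controls are shifted *up* by the study's true effect, matching the
convention that a gene down-regulated in the disease group has a positive
SMD (control minus case).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .consensus import DEFAULT_TOOLS, PredictionMatrix
from .meta import GroupSummary, StudyRecord
from .network import EdgeRecord

__all__ = [
    "MetaSimConfig",
    "CorpusSimConfig",
    "PredictorSimConfig",
    "simulate_meta_studies",
    "simulate_corpus",
    "simulate_predictions",
    "simulate_genesets_and_edges",
]


def _check_range(name: str, rng: tuple[int, int], low: int = 2) -> None:
    lo, hi = rng
    if lo > hi:
        raise ValueError(f"{name} is empty: {rng}")
    if lo < low:
        raise ValueError(f"{name} lower bound must be >= {low} (got {lo})")


@dataclass(frozen=True)
class MetaSimConfig:
    """Conditions for simulating a set of two-group expression studies.

    Defaults mirror a typical miRNA-expression meta-analysis: 11 studies,
    a true SMD of 0.63, per-arm sizes spanning the 4-96 range seen in GEO
    series, and a between-study SD calibrated so the expected I-squared
    sits near 40%.
    """

    n_studies: int = 11
    delta: float = 0.63
    tau: float = 0.23
    n_case_range: tuple[int, int] = (4, 96)
    n_control_range: tuple[int, int] = (4, 96)
    within_sd: float = 1.0
    stratum: str = "tissue"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.within_sd <= 0:
            raise ValueError("within_sd must be > 0")
        _check_range("n_case_range", self.n_case_range)
        _check_range("n_control_range", self.n_control_range)


@dataclass(frozen=True)
class CorpusSimConfig:
    """Conditions for simulating a literature corpus with planted
    gene-disease co-mention enrichment.

    ``enriched_genes`` have their odds of being mentioned in a
    disease-relevant document multiplied by ``enrichment_odds``; all other
    gene-document mentions are independent of the disease flag (null).
    """

    n_docs: int = 2000
    genes: tuple[str, ...] = ()
    disease_doc_rate: float = 0.3
    gene_doc_rate: float = 0.02
    enriched_genes: tuple[str, ...] = ()
    enrichment_odds: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("gene list must be non-empty")
        for rate in (self.disease_doc_rate, self.gene_doc_rate):
            if not (0 <= rate <= 1):
                raise ValueError(f"rates must be in [0, 1], got {rate}")
        if not set(self.enriched_genes) <= set(self.genes):
            raise ValueError("enriched_genes must be a subset of genes")
        if self.enrichment_odds < 1:
            raise ValueError("enrichment_odds must be >= 1")


@dataclass(frozen=True)
class PredictorSimConfig:
    """Conditions for simulating a multi-tool target-prediction matrix."""

    genes: tuple[str, ...] = ()
    n_tools: int = 11
    true_targets: tuple[str, ...] = ()
    hit_rate_true: float = 0.8
    hit_rate_false: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("gene list must be non-empty")
        if self.n_tools < 1:
            raise ValueError("n_tools must be >= 1")
        if not set(self.true_targets) <= set(self.genes):
            raise ValueError("true_targets must be a subset of genes")
        if not (0 <= self.hit_rate_false < self.hit_rate_true <= 1):
            raise ValueError("need 0 <= hit_rate_false < hit_rate_true <= 1")


def simulate_meta_studies(config: MetaSimConfig) -> list[StudyRecord]:
    """Draw two-group studies under a random-effects model.

    For study i, a true effect delta_i ~ Normal(delta, tau^2) is drawn;
    case observations are Normal(0, within_sd^2) and control observations
    Normal(delta_i * within_sd, within_sd^2).  Group n, sample mean and
    sample SD (ddof=1) are returned per study.
    """
    streams = np.random.SeedSequence(config.seed).spawn(config.n_studies)
    studies = []
    for i, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        n_case = int(rng.integers(config.n_case_range[0], config.n_case_range[1] + 1))
        n_control = int(rng.integers(config.n_control_range[0], config.n_control_range[1] + 1))
        delta_i = rng.normal(config.delta, config.tau)
        case_obs = rng.normal(0.0, config.within_sd, size=n_case)
        control_obs = rng.normal(delta_i * config.within_sd, config.within_sd, size=n_control)
        studies.append(
            StudyRecord(
                study_id=f"SIM{i + 1:03d}",
                case=GroupSummary(n=n_case, mean=float(case_obs.mean()),
                                  sd=float(case_obs.std(ddof=1))),
                control=GroupSummary(n=n_control, mean=float(control_obs.mean()),
                                     sd=float(control_obs.std(ddof=1))),
                stratum=config.stratum,
            )
        )
    return studies


def simulate_corpus(config: CorpusSimConfig) -> tuple[pd.DataFrame, int]:
    """Draw a document-gene mention table and the corpus size N.

    Each document is disease-relevant with probability
    ``disease_doc_rate``.  Gene g is mentioned with probability
    ``gene_doc_rate`` except that for enriched genes in disease documents
    the mention *odds* are multiplied by ``enrichment_odds``.
    """
    base = config.gene_doc_rate
    if base >= 1.0:
        p_enriched = 1.0
    else:
        odds = config.enrichment_odds * base / (1.0 - base)
        p_enriched = odds / (1.0 + odds)
    enriched = set(config.enriched_genes)

    root, *doc_streams = np.random.SeedSequence(config.seed).spawn(config.n_docs + 1)
    flag_rng = np.random.default_rng(root)
    flags = flag_rng.random(config.n_docs) < config.disease_doc_rate

    rows = []
    for i, (flag, stream) in enumerate(zip(flags, doc_streams)):
        rng = np.random.default_rng(stream)
        u = rng.random(len(config.genes))
        mentioned = []
        for g, x in zip(config.genes, u):
            p = p_enriched if (flag and g in enriched) else base
            if x < p:
                mentioned.append(g)
        rows.append((f"DOC{i + 1:05d}", bool(flag), ";".join(mentioned)))
    table = pd.DataFrame(rows, columns=["doc_id", "disease_flag", "genes"])
    return table, config.n_docs


def simulate_predictions(config: PredictorSimConfig) -> PredictionMatrix:
    """Draw a boolean gene x tool support grid with per-cell Bernoulli hits."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    truth = np.array([g in set(config.true_targets) for g in config.genes])
    rates = np.where(truth, config.hit_rate_true, config.hit_rate_false)
    grid = rng.random((len(config.genes), config.n_tools)) < rates[:, None]
    tools = tuple(
        DEFAULT_TOOLS[i] if i < len(DEFAULT_TOOLS) else f"tool{i + 1}"
        for i in range(config.n_tools)
    )
    return PredictionMatrix(genes=tuple(config.genes), tools=tools, support=grid)


def simulate_genesets_and_edges(
    genes: Sequence[str],
    n_sets: int = 10,
    set_size_range: tuple[int, int] = (5, 20),
    n_edges: int = 100,
    seed: int = 0,
) -> tuple[dict[str, tuple[str, ...]], list[EdgeRecord]]:
    """Random gene-set collection plus a random typed edge list.

    Sets have no duplicate members; edges avoid self-loops and carry an
    interaction type and a polarity label drawn uniformly.
    """
    if not genes:
        raise ValueError("gene list must be non-empty")
    lo, hi = set_size_range
    if lo < 1 or lo > hi:
        raise ValueError(f"invalid set_size_range {set_size_range}")
    if hi > len(genes):
        raise ValueError("set size exceeds gene count")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    genes = list(genes)

    sets = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        sets[f"SET{i + 1:03d}"] = tuple(sorted(str(m) for m in members))

    types = sorted({"enzyme_enzyme", "protein_protein", "gene_expression"})
    polarities = sorted({"association", "inhibition", "activation"})
    edges = []
    for _ in range(n_edges):
        u, v = rng.choice(genes, size=2, replace=False)
        edges.append(
            EdgeRecord(
                source=str(u),
                target=str(v),
                interaction_type=types[int(rng.integers(len(types)))],
                polarity=polarities[int(rng.integers(len(polarities)))],
            )
        )
    return sets, edges
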