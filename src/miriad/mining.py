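"""Literature co-citation scoring of gene-disease association.

Given a corpus of N documents, of which n mention the disease and m mention
a given gene, the chance that the gene and the disease co-occur in k or more
documents under random assortment is the hypergeometric upper tail

    p = 1 - sum_{i=0}^{k-1} C(m, i) C(N-m, n-i) / C(N, n) = P[X >= k].

Evaluation goes through the survival function of
:class:`scipy.stats.hypergeom` (log-gamma space), not literal factorials,
so realistic corpus sizes do not overflow.  Co-occurrence is counted at the
document level: a gene counts once per document no matter how many times it
is mentioned.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import false_discovery_control, hypergeom

__all__ = [
    "CorpusCounts",
    "CocitationResult",
    "tag_mentions",
    "cocitation_pvalue",
    "rank_genes",
    "filter_significant",
]


@dataclass(frozen=True)
class CorpusCounts:
    """Document counts for one gene: corpus size N, disease docs n, gene docs
    m, co-mention docs k."""

    N: int
    n: int
    m: int
    k: int

    def __post_init__(self) -> None:
        if not (0 <= self.n <= self.N and 0 <= self.m <= self.N):
            raise ValueError(f"need 0 <= n, m <= N; got n={self.n}, m={self.m}, N={self.N}")
        if not (0 <= self.k <= min(self.m, self.n)):
            raise ValueError(f"need 0 <= k <= min(m, n); got k={self.k}, m={self.m}, n={self.n}")


@dataclass(frozen=True)
class CocitationResult:
    gene: str
    counts: CorpusCounts
    p: float

    @property
    def frequency(self) -> int:
        """Co-mention count k, the ranking frequency."""
        return self.counts.k


def cocitation_pvalue(k: int, n: int, m: int, N: int) -> float:
    """Upper-tail hypergeometric probability P[X >= k] of co-citation.

    Parameters follow the counting convention above: ``N`` total documents,
    ``n`` disease documents, ``m`` gene documents, ``k`` co-mentions.
    ``k = 0`` returns exactly 1 (empty sum).
    """
    CorpusCounts(N=N, n=n, m=m, k=k)  # validates
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, m, n))


def tag_mentions(documents: Mapping[str, str], lexicon: Iterable[str]) -> dict[str, set[str]]:
    """Case-insensitive dictionary matcher on word boundaries.

    Returns, per document id, the set of lexicon symbols (upper-cased) whose
    whole-word form appears in the text.  This is deliberately simple
    plumbing for building mention tables from raw text; it does no synonym
    or conjunction resolution.
    """
    lex = sorted({g.strip().upper() for g in lexicon if g.strip()})
    if not lex:
        raise ValueError("lexicon must be non-empty")
    pattern = re.compile(
        r"\b(" + "|".join(re.escape(g) for g in lex) + r")\b", re.IGNORECASE
    )
    out: dict[str, set[str]] = {}
    for doc_id, text in documents.items():
        out[doc_id] = {match.group(1).upper() for match in pattern.finditer(text or "")}
    return out


def _mention_sets(table: pd.DataFrame) -> list[tuple[bool, set[str]]]:
    rows = []
    for flag, genes in zip(table["disease_flag"], table["genes"]):
        if isinstance(genes, str):
            gene_set = {g.strip().upper() for g in genes.split(";") if g.strip()}
        else:
            gene_set = {str(g).upper() for g in genes}
        rows.append((bool(flag), gene_set))
    return rows


def rank_genes(table: pd.DataFrame, genes: Sequence[str] | None = None) -> list[CocitationResult]:
    """Score every gene in a mention table against the disease flag.

    ``table`` needs columns ``doc_id``, ``disease_flag`` (bool/0-1) and
    ``genes`` (semicolon-joined string or an iterable of symbols per row).
    ``genes`` restricts/extends the scored universe (default: every symbol
    seen in the table).  Results are sorted by ascending p, ties broken by
    descending co-mention count k, then symbol.
    """
    if len(table) == 0:
        raise ValueError("mention table is empty")
    rows = _mention_sets(table)
    N = len(rows)
    n = sum(1 for flag, _ in rows if flag)
    if genes is None:
        universe = sorted(set().union(*(g for _, g in rows)) or set())
    else:
        universe = sorted({g.strip().upper() for g in genes})

    results = []
    for gene in universe:
        m = sum(1 for _, gs in rows if gene in gs)
        k = sum(1 for flag, gs in rows if flag and gene in gs)
        results.append(
            CocitationResult(gene=gene, counts=CorpusCounts(N=N, n=n, m=m, k=k),
                             p=cocitation_pvalue(k, n, m, N))
        )
    results.sort(key=lambda r: (r.p, -r.counts.k, r.gene))
    return results


def filter_significant(results: Sequence[CocitationResult], alpha: float,
                       method: str = "raw") -> list[str]:
    """Genes with p < alpha, in stable (input) order.

    ``method="bh"`` applies Benjamini-Hochberg adjustment before
    thresholding; the default leaves the raw co-citation p-values
    uncorrected.
    """
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if method == "raw":
        pvals = [r.p for r in results]
    elif method == "bh":
        pvals = list(false_discovery_control([r.p for r in results], method="bh")) if results else []
    else:
        raise ValueError(f"unknown method {method!r}")
    if alpha == 1.0:  # alpha=1 disables filtering even for discrete p = 1
        return [r.gene for r in results]
    return [r.gene for r, p in zip(results, pvals) if p < alpha]


def results_frame(results: Sequence[CocitationResult]) -> pd.DataFrame:
    """Tabular view (gene, k, m, n, N, p) of co-citation results."""
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "k": [r.counts.k for r in results],
            "m": [r.counts.m for r in results],
            "n": [r.counts.n for r in results],
            "N": [r.counts.N for r in results],
            "p": [r.p for r in results],
        }
    )
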