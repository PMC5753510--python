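"""Hypergeometric gene-set / pathway over-representation analysis.

For a query of n genes drawn from a universe of N, the chance that k or more
fall into a set of size K under random sampling is the hypergeometric upper
tail P[X >= k] -- identical to a one-sided Fisher exact test on the 2x2
table (k, n-k, K-k, N-n-K+k).

The universe defaults to the union of all collection members.  Query genes
outside the universe are dropped (with a warning) rather than inflating the
query size, and duplicates are ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy.stats import false_discovery_control, hypergeom

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "enrich",
    "categorize_go",
    "GO_NAMESPACES",
]

CATEGORIES = ("pathway", "GO_biological_process", "GO_cellular_component",
              "GO_molecular_function")
GO_NAMESPACES = CATEGORIES[1:]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets with a per-set category and a background universe."""

    sets: dict[str, frozenset[str]]
    categories: dict[str, str]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            if not members <= self.universe:
                raise ValueError(f"gene set {name!r} has members outside the universe")
        for name, cat in self.categories.items():
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r} for set {name!r}")

    @classmethod
    def from_sets(cls, sets: Mapping[str, Iterable[str]],
                  categories: Mapping[str, str] | str = "pathway",
                  universe: Iterable[str] | None = None) -> "GeneSetCollection":
        """Normalize symbols to upper case and derive the universe if absent."""
        norm = {name: frozenset(str(g).strip().upper() for g in members)
                for name, members in sets.items()}
        if isinstance(categories, str):
            cats = {name: categories for name in norm}
        else:
            cats = dict(categories)
        if universe is None:
            uni: frozenset[str] = frozenset().union(*norm.values()) if norm else frozenset()
        else:
            uni = frozenset(str(g).strip().upper() for g in universe)
        return cls(sets=norm, categories=cats, universe=uni)


@dataclass(frozen=True)
class EnrichmentResult:
    """Overlap of the query with one gene set and its tail probability."""

    set_name: str
    category: str
    overlap_count: int      # k
    set_size: int           # K
    query_size: int         # n (after universe restriction)
    universe_size: int      # N
    p: float
    overlap_genes: tuple[str, ...]
    significant: bool


def enrich(query: Iterable[str], collection: GeneSetCollection,
           alpha: float = 0.05, method: str = "raw") -> list[EnrichmentResult]:
    """Score every set in the collection against the query.

    Returns results sorted by ascending p (ties by name).  ``method="bh"``
    applies Benjamini-Hochberg before the ``alpha`` flag; the default uses
    raw p-values.
    """
    q_all = {str(g).strip().upper() for g in query}
    q = q_all & collection.universe
    dropped = q_all - collection.universe
    if dropped:
        logger.warning("dropping %d query genes outside the universe: %s",
                       len(dropped), sorted(dropped)[:10])
    if not q:
        raise ValueError("query has no genes in the universe")

    N = len(collection.universe)
    n = len(q)
    results = []
    for name, members in collection.sets.items():
        overlap = q & members
        k, K = len(overlap), len(members)
        p = float(hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        results.append((name, K, k, tuple(sorted(overlap)), p))
    results.sort(key=lambda r: (r[4], r[0]))

    pvals = [r[4] for r in results]
    if method == "bh":
        flags = [p < alpha for p in false_discovery_control(pvals, method="bh")]
    elif method == "raw":
        flags = [p < alpha for p in pvals]
    else:
        raise ValueError(f"unknown method {method!r}")

    return [
        EnrichmentResult(
            set_name=name,
            category=collection.categories.get(name, "pathway"),
            overlap_count=k,
            set_size=K,
            query_size=n,
            universe_size=N,
            p=p,
            overlap_genes=overlap,
            significant=flag,
        )
        for (name, K, k, overlap, p), flag in zip(results, flags)
    ]


def categorize_go(genes: Iterable[str],
                  annotation: Mapping[str, Sequence[str]]) -> dict[str, set[str]]:
    """Group genes by GO namespace from a symbol -> ["namespace:term", ...] map.

    A gene annotated in several namespaces appears in each; genes with no
    annotation are returned under ``"unannotated"``.
    """
    groups: dict[str, set[str]] = {ns: set() for ns in GO_NAMESPACES}
    groups["unannotated"] = set()
    for gene in {str(g).strip().upper() for g in genes}:
        terms = annotation.get(gene, ())
        hit = False
        for term in terms:
            ns = term.split(":", 1)[0]
            if ns in groups:
                groups[ns].add(gene)
                hit = True
        if not hit:
            groups["unannotated"].add(gene)
    return groups
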