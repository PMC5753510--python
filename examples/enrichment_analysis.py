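"""Hypergeometric pathway enrichment of a query gene list.

Builds a small pathway collection in which one set ("CELL_CYCLE") is
heavily represented in the query, scores every set, and prints the
Table-style output (term, count, p, member genes).
"""

from miriad import GeneSetCollection, enrich

universe = [f"U{i:03d}" for i in range(200)]
collection = GeneSetCollection.from_sets(
    {
        "CELL_CYCLE": universe[:15],
        "FOCAL_ADHESION": universe[15:35],
        "RANDOM_SET": universe[100:120],
    },
    universe=universe,
)

query = universe[:10] + universe[150:155]  # 10 of 15 cell-cycle genes + noise
results = enrich(query, collection, alpha=0.05)

print(f"query n={results[0].query_size}, universe N={results[0].universe_size}")
print(f"{'term':16s} {'count':>5s} {'p':>10s}  genes")
for r in results:
    flag = "*" if r.significant else " "
    print(f"{r.set_name:16s} {r.overlap_count:5d} {r.p:10.2e}{flag} "
          f"{';'.join(r.overlap_genes[:4])}...")
# p is the hypergeometric upper tail P[X >= k]: the chance a random query
# of this size hits the set at least k times.  * marks p < 0.05.
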