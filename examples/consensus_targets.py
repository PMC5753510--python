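"""Call consensus miRNA targets from an 11-tool prediction matrix.

True targets are hit by each tool with probability 0.8, non-targets with
0.1; a gene predicted by at least 4 of the 11 tools is called a consensus
target.
"""

from miriad import (PredictorSimConfig, consensus_targets,
                    simulate_predictions, support_histogram)

genes = tuple(f"G{i:02d}" for i in range(30))
matrix = simulate_predictions(PredictorSimConfig(
    genes=genes, true_targets=genes[:6], hit_rate_true=0.8,
    hit_rate_false=0.1, seed=5))

hist = support_histogram(matrix)
print("support level -> gene count:",
      {lvl: int(c) for lvl, c in enumerate(hist) if c})

result = consensus_targets(matrix, threshold=4)
print(f"\nconsensus targets (>= 4 of {len(matrix.tools)} tools):")
for gene, count in sorted(result.members.items()):
    marker = "*" if gene in genes[:6] else " "
    print(f"  {gene} ({count} tools) {marker}")
print("* = planted true target; the vote separates them from background noise")
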