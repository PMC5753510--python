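# miriad

Integrative analysis of a microRNA's role in disease, built from five
composable statistical engines plus a synthetic-data generator with known
ground truth. The motivating use case is the common study design around a
single dysregulated miRNA (e.g. miR-34a in hepatocellular carcinoma): pool
its expression effect across public microarray datasets, mine the
literature for disease-associated genes, call consensus targets across
prediction tools, intersect the two gene lists, and characterize the
overlap with pathway enrichment and network hub analysis.

## What it computes

**Random-effects meta-analysis.** Each study contributes Hedges'
standardized mean difference g = J·(x̄₂ − x̄₁)/s_p with the small-sample
correction J = 1 − 3/(4·df − 1) and variance
v = (n₁+n₂)/(n₁n₂) + g²/(2(n₁+n₂)). Studies are pooled with
DerSimonian–Laird weights w* = 1/(v + τ̂²), where
τ̂² = max(0, (Q − df)/C) from Cochran's Q; heterogeneity is reported as
I² = max(0, (Q − df)/Q)·100 with a chi-square p-value. The sign convention
is control − case, so a gene down-regulated in disease has positive SMD.
Two decision rules are reported side by side: the conventional
zero-crossing normal test, and a unit-interval stability rule that also
requires the 95% CI to exclude +1 and −1 (closed interval). Leave-one-out
sensitivity analysis and per-stratum subgroup pooling are included.

**Literature co-citation mining.** With N documents total, n mentioning
the disease, m mentioning a gene and k mentioning both, the association
score is the hypergeometric upper tail
p = P[X ≥ k] = 1 − Σᵢ₌₀^{k−1} C(m,i)C(N−m,n−i)/C(N,n), evaluated in
log-gamma space so realistic corpus sizes never overflow.

**Consensus target calling.** A gene × tool boolean prediction matrix is
reduced by support voting: a gene is a consensus target when at least a
threshold number of tools (default 4 of 11) predict it.

**Gene-set enrichment.** The same hypergeometric upper tail applied to
query/set overlaps against a background universe — identical to a
one-sided Fisher exact test — plus GO-namespace categorization.

**Network hub analysis.** Typed interaction edge lists (enzyme–enzyme,
protein–protein, gene expression, co-citation; polarity association /
inhibition / activation) merge into an undirected simple graph; each
node's degree is standardized against the empirical degree distribution
(z = (k − mean)/SD) with a one-sided upper-tail p.

**Integration.** Case-normalized, alias-aware intersection of consensus
targets and literature disease genes, annotated with the significantly
enriched pathways per overlap gene.

## Worked example

```bash
python examples/full_pipeline.py
```

prints (seed 0):

```
meta-analysis: SMD 0.55 [0.36, 0.74], I2 43%
literature mining: 20 disease genes called from 2000 documents
consensus voting: 22 targets at threshold 4
integrative overlap: 10 genes (planted 10, recall 1.00)
network: 109 nodes; top hub G109 (degree 8)
```

The synthetic run plants 20 disease-associated genes and 20 true miRNA
targets with 10 genes in both groups; the integrative overlap recovers
all 10 (recall 1.00). The pooled SMD estimates the simulated true effect
0.63 from 11 noisy studies, and I² ≈ 43% reflects the calibrated
between-study heterogeneity. Other examples (`examples/*.py`) exercise
each engine on its own; the same stages are scriptable through the thin
CLI (`miriad simulate|meta|cocite|consensus|enrich|network|integrate|run-all`).

## Layout

- `src/miriad/meta.py` — effect sizes, pooling, heterogeneity, decisions
- `src/miriad/mining.py` — mention tagging and the co-citation statistic
- `src/miriad/consensus.py` — prediction matrices and support voting
- `src/miriad/enrichment.py` — gene-set collections, enrichment, GO groups
- `src/miriad/network.py` — typed graphs, connectivity, hub z-test, GraphML
- `src/miriad/integrate.py` — overlap, annotation, pipeline runner
- `src/miriad/synthetic.py` — ground-truth generators for all five inputs
- `src/miriad/io.py` — TSV/GMT/JSON readers and writers
- `docs/methods.md` — model assumptions, parameter choices, limitations
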