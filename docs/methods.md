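# Methods

## Meta-analysis model

Per-study effects are Hedges' g: the between-group mean difference divided
by the pooled SD, shrunk by J = 1 − 3/(4·df − 1) to remove small-sample
bias, with the usual large-sample variance
v = (n₁+n₂)/(n₁n₂) + g²/(2(n₁+n₂)). This is the conventional
"standardized mean difference" of mainstream meta-analysis software, which
is the appropriate reading when source studies report only group n, mean
and SD on platform-arbitrary expression scales.

Pooling is DerSimonian–Laird: fixed weights w = 1/v give Cochran's
Q = Σw(g − ḡ)², the moment estimator τ̂² = max(0, (Q − df)/C) with
C = Σw − Σw²/Σw, and random weights w* = 1/(v + τ̂²). Confidence
intervals use normal quantiles (no Knapp–Hartung adjustment), matching the
defaults of the standard desktop tools for this analysis. Known
consequence: with K ≈ 11 studies and moderate heterogeneity the 95% CI
undercovers slightly (about 92–93% in our own simulations), which is a
property of the estimator, not a defect of the implementation.

Degenerate cases: a single study pools to itself with Q = 0, df = 0 and
p_het defined as 1; I² is floored at 0 when Q ≤ df; τ̂² is floored at 0.
A pooled SD of zero with unequal means raises an error rather than
returning an infinite effect.

### Decision rules

Two calls are reported side by side:

* the conventional two-sided normal test of SMD = 0;
* a **unit-interval stability rule**: the 95% CI must exclude both +1 and
  −1, with the closed-interval convention that touching a boundary counts
  as overlap (`significance_rule`).

`PooledResult.significance_flag` combines the two — the CI must exclude 0
*and* both unit values. The combination is deliberate: a stability screen
alone would "accept" a null effect whose narrow CI sits around zero, which
is not what any analyst means by significant. The heterogeneity flag is
raised when p_het < 0.05 or I² > 50%.

The vascular-invasion-type situation — conventionally significant
(p ≈ 0.03) yet failing the unit-rule because the CI covers −1 — is exactly
why both calls are exposed; downstream code can choose either.

## Co-citation statistic

Document-level co-occurrence only: a gene counts once per document. The
upper tail P[X ≥ k] is computed via `scipy.stats.hypergeom.sf`, i.e. in
log-gamma space; a literal factorial evaluation overflows for realistic
corpus sizes (N in the tens of thousands). Exactness is guarded by tests
against an independent integer-arithmetic oracle (`math.comb` sums) over
every valid (k, n, m, N) with N ≤ 40, and against exhaustive enumeration
of all C(10,5) disease-document assignments at one small configuration.
k = 0 returns exactly 1 (empty-sum convention). Because the statistic is
discrete, null p-values are stochastically *larger* than uniform
(conservative); the test suite checks the calibration in that direction.

No multiple-testing correction is applied by default — the ranking
p-values are reported raw, as is conventional for this screening step —
but Benjamini–Hochberg is available via `method="bh"`. The significance
cut-off `alpha` is a required analysis choice, not a package default with
scientific standing; `alpha = 1` disables filtering entirely (including
genes whose discrete p equals 1). Genes are ranked by ascending p with
ties broken by descending co-mention count k, then symbol; both k and m
are reported so either frequency convention can be read off.

The bundled mention tagger is deliberately plain: case-insensitive
whole-word dictionary matching. It exists so raw-text fixtures work and is
not a substitute for named-entity recognition; synonym and conjunction
resolution are out of scope.

## Consensus voting

A gene is a consensus target when its row sum over tools reaches the
threshold (default 4, configurable). Monotonicity in the threshold and
equivalence to brute-force row filtering are property-tested. The eleven
default tool names cover the commonly used prediction servers; running the
tools themselves is out of scope — their outputs arrive as a 0/1 TSV.

## Enrichment

Hypergeometric upper tail on |query ∩ set| against a universe that
defaults to the union of all collection members (overridable — published
analyses rarely state their background, and the choice matters). Query
genes outside the universe are dropped with a warning instead of being
counted in n: counting them would silently inflate significance.
Duplicates and ordering are immaterial. Raw p by default, BH behind a
flag. GO categorization is a flat namespace grouping; graph propagation /
ancestor closure is out of scope.

## Network hub test

The "z-test" for hubs is interpreted as standardization of a node's degree
against the network's own empirical degree distribution (sample SD,
ddof = 1), with a one-sided upper-tail normal p. A permutation null would
be an alternative reading; the text sources for this style of analysis
never define the test, so the simplest self-contained interpretation was
chosen and is stated here openly. Regular graphs (zero degree variance)
take a degenerate path: all z = 0, p = 0.5, flag set. The graph is
undirected and simple; polarity and interaction type survive as edge
annotations (pipe-joined in GraphML, tuples in memory), and self-loops are
dropped with a warning.

## Synthetic-data generators

The generators define the study conditions under which the engines are
validated:

* **Studies** (`MetaSimConfig`): K = 11 studies, true SMD δ = 0.63,
  per-arm sizes uniform on 4–96 (the span seen in the motivating public
  datasets), unit within-study SD, between-study SD τ = 0.23. τ was
  calibrated once so the expected I² is ≈ 40%, matching the moderate
  heterogeneity regime of interest. Observations are simulated at the
  individual level and then summarized, so SD sampling noise and
  small-sample bias are real; controls are shifted up by the study's true
  effect (down-regulation in disease ⇒ positive SMD).
* **Corpus** (`CorpusSimConfig`): 2000 documents, disease rate 0.3, gene
  mention rate 0.02; enriched genes have their mention *odds* in disease
  documents multiplied by 20. These values give high but not trivial
  detection power at α = 0.01.
* **Predictions** (`PredictorSimConfig`): 11 tools, hit rate 0.8 for true
  targets vs 0.1 for non-targets — consistent with the threshold-4 vote
  retaining >99.8% of true targets (binomial tail) while passing ≈2% of
  noise.
* **Gene sets and edges**: uniform random sets (duplicate-free) and
  uniformly typed/polarized edges.

Determinism: every generator draws from sub-streams spawned from one
`numpy.random.SeedSequence`, so a config (including its seed) fully
determines the output, file-byte-for-file-byte.

What the generators do **not** emulate: probe-level microarray structure,
normalization artifacts, correlated gene mentions, citation bursts,
tool-specific prediction biases, or scale-free network topology. Passing
tests therefore demonstrate correctness of the statistics and the
plumbing under a clean generative model, not robustness to the messiness
of real public data.

## Pipeline

`run_pipeline` executes meta-analysis, mining, consensus, overlap +
enrichment, and network analysis on one synthetic world (120 genes, 20
disease genes, 20 targets, 10 planted in both). Stage sub-seeds derive
from the config seed; the JSON bundle contains no timestamps, so reruns
are byte-identical. Stage timings go to the logger, not the bundle. The
planted-overlap recall reported in the bundle is the fraction of the 10
ground-truth genes present in the recovered intersection.

Symbol matching in the integrative overlap is exact after upper-casing
and whitespace stripping, with an optional user-supplied alias table for
style clashes like Bcl-2 vs BCL2; no automatic synonym resolution is
attempted.

## Numerical and testing choices

Sizes were chosen to keep the default suite and the acceptance script
fast while leaving Monte-Carlo margins comfortable: 200 replicate
meta-analyses for coverage/bias, the full N ≤ 40 lattice (≈260k tuples)
for the co-citation oracle, 500 random instances for the Fisher
equivalence, 100 random matrices for voting monotonicity. Oracle
tolerances (1e-12 for co-citation, 1e-10 for enrichment) sit orders of
magnitude above the observed worst-case disagreement (~3e-16) but well
below any scientifically meaningful difference.

## Known limitations

* DL + normal-quantile CIs undercover slightly at small K (see above);
  Knapp–Hartung or REML variants are deliberately not offered to keep
  parity with the standard desktop workflow this package mirrors.
* The co-citation statistic inherits all biases of literature mention
  counts (publication bias, gene-name ambiguity); it measures association
  of *mentions*, not biology.
* Enrichment results depend strongly on the background universe, which
  callers should set explicitly when they have one.
* The hub test assumes an approximately normal degree distribution; on
  heavy-tailed real interactomes the one-sided p is a ranking device
  rather than a calibrated error rate.
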