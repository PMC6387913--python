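# Methods

## Problem and data model

Histone modifications act combinatorially: the presence of one mark shifts
the odds of others, and the joint pattern around a cassette exon differs
between exons that are included in and excluded from the mature transcript.
The package analyses this as a purely discrete problem. Its input is a binary
matrix per condition — rows are exons (or the ~180 bp intronic windows
immediately preceding/succeeding them), columns are the 38 CD4⁺ T-cell
histone marks (20 methylations, 18 acetylations, `histone_bn.catalog`),
entries are presence calls in {0, 1}. Six such matrices form a full study:
{included, excluded} × {exon, preceding intron, succeeding intron}. Upstream
signal processing (peak calling, binarisation, exon classification) is out of
scope; the matrices are the interface.

## Pairwise correlation

Association between two marks is the Pearson coefficient of their binary
columns, which equals the phi coefficient of the 2×2 contingency table:

    phi = (n11·n00 − n10·n01) / sqrt(n1.·n0.·n.1·n.0)

Constant columns make phi undefined; the package returns NaN and records the
column, rather than substituting 0, because a fabricated zero would be
indistinguishable from measured independence. No significance testing is
attached — downstream use is sign and magnitude only (edge colouring,
heatmaps). Heatmaps order marks either by catalog or by average-linkage
hierarchical clustering on the (1 − r) distance; undefined rows sort last.

## Structure learning

Dependencies among marks are modelled as a Bayesian network: a DAG whose
edges encode direct statistical dependence. Learning maximises a decomposable
score over structures:

* **BDeu** (default): the log marginal likelihood of each child's CPT under a
  Dirichlet prior with hyperparameter ess/(q·r) per cell, where r = 2 states,
  q = 2^|parents| parent configurations, and ess = 1 (equivalent sample
  size). ess = 1 is the common weak-prior default; larger values smooth CPTs
  toward uniform and admit denser graphs.
* **BIC**: maximised log likelihood minus (log n)/2 · q per node, used where
  an asymptotically consistent penalty is wanted (e.g. the null-calibration
  analyses).

Search is greedy hill climbing over single-edge moves (add, delete, reverse)
from the empty graph, accepting the best admissible move until none improves
the score by more than 1e-9 (below the float noise of count-based scores).
Admissibility enforces acyclicity and an in-degree cap of `max_parents = 4`,
which keeps the 2^q CPT cells populated at n ≈ 10⁴ and matches the sparse
networks the consensus protocol produces. Ties between moves are broken by a
fixed total order (operation type, then lexicographic endpoint names), so a
run is reproducible bit for bit across platforms.

Plain greedy search from the empty graph lands in a local optimum on a few
percent of small datasets — typically one surplus edge whose removal only
pays off after a second re-orientation move. The learner therefore restarts
from `n_restarts = 4` random DAGs by default; every restart topology is
derived from the config seed, so determinism is unaffected, and the
best-scoring result across starts is returned. Measured on one hundred
4-variable datasets (n = 500), the default learner attains the exhaustive
optimum in ≥ 95 cases; with the single-start search it is ≈ 90.

For p ≤ 5 variables, `exhaustive_search` scores every labeled DAG
(1, 3, 25, 543, 29 281 for p = 1..5) and returns the global optimum; it
exists purely as the exact oracle for testing the heuristic.

## Consensus protocol

Single learned networks are unstable: resampling the data flips weak edges.
The robustness protocol partitions the samples uniformly at random into ten
folds, learns one "fundamental" network on each leave-one-fold-out subset
(90% of the data), and retains an edge only if it appears in at least seven
of the ten fundamental networks.

Edge identity for the 7-of-10 count is the **skeleton pair**: score-equivalent
DAGs can represent the same dependence with either orientation, so counting
directed edges would undercount stable dependencies. Direction is then
resolved by majority among the networks containing the pair; exact ties go to
the lexicographically smaller node as parent and are flagged. Both the
skeleton count and the per-direction counts are reported, so a
strict-directed reading of the rule can be recovered from the output.
Majority orientations of different pairs need not be jointly acyclic; any
resulting cycle is repaired by re-orienting the lowest-stability edge on the
cycle (dropping it if re-orientation would cycle again), and every repair is
flagged. Retained edges are annotated with the sign of the phi coefficient
computed on the **full** dataset (not per fold), matching how the final
networks are coloured from the dataset-level correlations.

A config option (`n_rounds > 1`) repeats the whole ten-fold round with fresh
fold seeds and applies the same retention fraction (7/10) to the pooled
networks. This implements the alternative reading of "repeated ten times";
the default is the single round that yields exactly ten fundamental networks.

## Post-analysis

* **Combinatorial patterns** are operationalised as connected components
  (≥ 2 marks) of the consensus skeleton; isolated marks are listed
  separately. This pairs naturally with sparse networks, where edge and
  pattern counts of the same order (e.g. ~20 edges, ~10 components over 38
  nodes) are the expected output shape.
* **Marks directly tied to splicing** come from an explicit operationalised
  mode: append a binary outcome column (1 = included, 0 = excluded) to the
  class-combined matrix of a region, run the full consensus protocol over
  the 39 nodes, and report the marks adjacent to the outcome node. The
  per-class 38-node networks are produced separately; both outputs are
  always emitted.
* **Network differencing** is skeleton-level set algebra (A-only, B-only,
  shared) plus sign agreement on shared edges.

## Synthetic data

The generator exists so every stage is testable with a known answer key.

* `build_planted_dag(n_nodes, n_edges, max_parents, effect_strength, seed)`
  draws a uniform random topological order, picks exactly `n_edges` edges
  under the in-degree cap, and parameterises children with a noisy-OR-like
  rule: P(child = 1) = effect_strength if at least one parent is on, else
  1 − effect_strength; roots are Bernoulli(0.5). One knob (effect strength)
  controls detectability. The benchmark conditions are 38 nodes, 20 edges,
  effect 0.9, n = 10⁴ — a mark-panel-sized problem with unambiguous planted
  dependencies.
* `histone_preset` mimics the qualitative correlation geography of the real
  matrices: a latent binary "activity" state (sampled, not returned) raises
  31 marks from a 0.15 baseline to 0.45 when on — producing the broad
  positive-correlation block and a ≈ 0.3 marginal presence rate — and
  represses H3K9me3 (0.55 when inactive, 0.12 when active), producing its
  negative row. H2BK5me1 additionally drives its six cluster partners
  (H3K4me1, H3K4me2, H3K79me1, H3K9me1, H4K20me1, H4K91ac) with effect 0.85.
  The 0.3 base rate is an invented, documented default: the source data are
  described only qualitatively. The latent-variable construction keeps the
  planted DAG sparse instead of wiring 37 explicit edges.
* One integer seed feeds two derived streams (structure vs sampling), so
  tests can vary data while fixing topology.

What the preset does **not** emulate: linkage between the three regions of
one exon (regions are analysed separately), spatial/genomic autocorrelation,
class-imbalanced sample sizes, and any continuous signal structure. Passing
tests therefore demonstrate correctness of the machinery and recoverability
under the planted model, not that the biological conclusions reproduce.

## Seeding and determinism

The pipeline takes one master seed; folds, synthetic sampling, and restart
topologies consume derived substreams (`SeedSequence([master, stage, index])`,
truncated below 2³¹). A pipeline run writes a manifest with the config, a
hash of the analysis settings (excluding the output path), and a SHA-256
checksum of every output file; rerunning with the same config reproduces
every checksum, including PNG heatmaps (fixed Agg backend, volatile metadata
stripped).

## Numerical and degenerate-input choices

* Scores are computed from contingency counts via `bincount` on bit-packed
  parent configurations; local scores are cached by (child, parent set).
* Convergence tolerance 1e-9 on log-score improvement; score comparisons in
  tests use the same tolerance.
* Zero counts contribute 0 to the BIC log likelihood; BDeu handles them
  through the Gamma terms.
* All-zero rows (an exon with no mark present) warn but are accepted —
  upstream processing usually removes them, but every operation is defined
  on them. Constant columns propagate as undefined correlations and sign
  "undefined" on consensus edges (as does an exactly zero phi).
* `make_folds` requires n ≥ k and produces fold sizes differing by at most
  one.

## Problem sizes

Defaults throughout are the study conditions: n = 10⁴ samples, 38 marks,
20 planted edges, effect 0.9, ten folds, threshold 7, five replicate seeds
for averaged metrics, one hundred 4-variable datasets (n = 500) for the
oracle-parity benchmark. The acceptance script runs all of these end to end.

## Known limitations

* Greedy search with restarts is exact only empirically; no optimality
  guarantee beyond the measured ≥ 95% parity at 4 variables.
* The consensus direction rule (majority + lexicographic ties + cycle
  repair) is a pragmatic invention; direction on near-tied pairs should not
  be over-interpreted, which is why ties and repairs are flagged.
* BDeu scores are sensitive to ess in well-known ways; only ess = 1 is
  exercised by the benchmarks.
* The outcome-node mode measures adjacency in a learned DAG, not causal
  effect; with class-specific dependency structure, many marks can be
  legitimately adjacent to the outcome.
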