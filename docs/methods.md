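# Methods

## The model

The pipeline treats a multi-compound herbal preparation as a small
bipartite pharmacology system: compounds are screened for plausible oral
activity, their protein targets are assembled from interaction-database
exports, and the target set is then interrogated three ways — gene-set
over-representation, tissue-expression localization, and intersection
with disease differential-expression signatures. Nothing in the pipeline
models mechanism; every stage is a deterministic set-level computation,
which is why each one can be verified against enumeration oracles or
planted ground truth.

## ADME screen

A compound is active when OB ≥ 15 % and Caco-2 ≥ −0.4 and DL ≥ 0.18, all
three inclusive. Inclusive (≥) is the default because boundary values
should count as meeting a threshold stated with "≥"; a flag switches to
strict (>) comparison. Drug-likeness is the Tanimoto similarity
F(A,B) = A·B/(|A|²+|B|²−A·B) of descriptor vectors; the function is
provided (symmetric, F(A,A)=1, bounded in [0,1] for componentwise
nonnegative inputs), but the packaged compound table's DL values are
consumed as given — the reference "average drug" descriptor vector is
not public, and stored DL values can be negative (the table contains
−2.18), so no [0,1] bound is asserted on stored values. The rescue list
is configuration, not code: it ships as the 14 packaged compounds that
fail the default thresholds, and any rescue id absent from the input is
an error, because a silently ignored typo would alter the retained set.

## Target catalog

Edge tables from different sources are unioned; duplicate
(compound, target) pairs collapse to one edge carrying the union of
source tags. Merging is idempotent and order-invariant. Edges whose
accession is missing from the target table are kept but reported in a
warning list — an interaction observed under an unresolvable accession is
evidence, not noise. Downstream gene-level stages key on gene symbols
(uppercased at ingest, exact string match thereafter) because expression
and DE inputs are symbol-keyed. The headline ratio
(unique targets)/(screened compounds) is reported to one decimal.

## Networks and centrality

Graphs are undirected and unweighted — the inputs carry neither direction
nor affinity. Betweenness uses Brandes' algorithm (networkx) with
endpoints excluded; normalized values divide by (N−1)(N−2)/2 where N is
the order of the whole graph, the convention of common network viewers,
applied unchanged to disconnected graphs so values stay comparable
across exports. Graphs with N < 3 get all-zero normalized betweenness.
Rankings break ties lexicographically by node id so output is
deterministic.

## Over-representation

P(X ≥ k) is the upper hypergeometric tail (scipy's stable survival
function); the EASE variant, which retests with k − 1, is opt-in rather
than default because it is one tool's convention, not part of the test
itself. Benjamini–Hochberg is the literal step-up definition
q_(i) = min_{j≥i} p_(j)·m/j capped at 1 and is cross-checked in the
tests against both a quadratic-time literal implementation and
statsmodels. The universe defaults to the union of all collection
members when none is supplied; query genes outside the universe are
dropped with a count. Raw p-values drive the p < 0.01 cutoff and
adjusted values are reported alongside, so either convention can be
read off the output.

## Organ localization

For each gene the mean is taken over *all* tissues in the matrix (e.g.
all 84 atlas tissues) and a call is made wherever expression strictly
exceeds that mean; counting then restricts to the 17-tissue immunity
panel, which is a configuration list, not an inference. Strict ">" means
a constant gene is called nowhere and no gene can be called in every
tissue of the full matrix. A single-tissue matrix is rejected (each
value equals its own mean; the call is undefined). Probe-level input is
collapsed to genes by max (default; conservative for presence calls) or
mean.

## Differential expression

Per gene, the pooled two-sample variance s² with d = n₁+n₂−2 degrees of
freedom is shrunk to s̃² = (d₀s₀² + d·s²)/(d₀+d); the moderated
t = Δmean/(s̃·√(1/n₁+1/n₂)) gets d₀+d degrees of freedom. At d₀ = 0 this
is exactly the ordinary pooled t (asserted to 1e−10 in the tests); as
d₀ → ∞ the posterior variance pins to s₀². The prior is fitted by method
of moments on log s² under the scaled-F model s² ~ s₀²·F(d, d₀):
Var[log s²] − trigamma(d/2) = trigamma(d₀/2), inverted by Newton, with
the mean matched through the digamma shift. When the observed
log-variance spread is smaller than trigamma(d/2) no finite d₀ fits and
the estimator falls back to (d₀ = 4, s₀² = mean variance); d₀ is capped
at 100 — beyond that the moderated and fully-pooled statistics are
indistinguishable at these sample sizes. "Highly expressed in the
disease group" is read as a positive-direction filter before top-N
ranking by ascending p (ties by |t| then symbol); a both-directions mode
exists for comparison with tools whose top tables mix directions.

## Synthetic data

The generators are the test harness's ground truth and are deliberately
constructive rather than statistical: the compound generator *forces*
each value to the intended side of its threshold after drawing from
plausible ranges (log-normal OB, normal(0.5, 0.8) Caco-2,
uniform[−0.5, 0.95] DL), so pass counts are exact and never flake;
failing compounds violate a random nonempty subset of the three axes so
exclusion reports exercise every combination. Interaction degrees follow
a geometric law (mean 13 by default, echoing a heavy-tailed
polypharmacology profile over ~182 targets); 30 % of edges are
duplicated into a second source file to exercise cross-source merging.
Expression baselines are log-normal (log-mean 5, σ = 0.5) with planted
cells multiplied by a boost factor (8× in the tests, at which planted
call recovery is exact for the fixed seeds); two-group matrices are
N(0,1) with planted genes shifted +3σ in the disease group, at which the
20 planted genes fill the top-20 exactly. What the generators do *not*
emulate: array-platform intensity distributions, probe-level noise,
correlated genes, batch effects, or realistic herb chemistry — so
passing tests demonstrate algorithmic correctness and exact bookkeeping,
not robustness to real-data pathologies.

## Problem sizes and determinism

Test and driver simulations use 200-gene × 20-tissue atlases, 200-gene ×
20-sample two-group matrices, 2000-gene DE runs in the drivers, and
≤ 8-node graphs for the exhaustive betweenness oracle (200 random
cases) — sizes at which enumeration oracles are exact and the whole
suite runs in seconds. All generators are pure functions of their
arguments including the seed; the pipeline run report contains no
timestamps, so identical config + seed reproduces it byte for byte.

## Known limitations

- The packaged tables are transcriptions of printed tables, stored
  verbatim (including one obsolete UniProt accession, P62158 for CALM1);
  no identifier updating is performed, by design — provenance over
  currency.
- Live database retrieval is out of scope, so numbers that depend on a
  specific database snapshot (real edge counts, real degree leaders,
  real enrichment term counts) are not reproduced here; the machinery
  that would compute them is what the oracle suite verifies.
- The organ-localization rule is a threshold call, not a statistical
  test; it inherits the strong baseline-dependence shown by the
  synthetic drivers (a right-skewed baseline yields many chance calls).
- The moderated-t implementation covers the ordinary empirical-Bayes
  case only; variance-trend and robust variants are not implemented.
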