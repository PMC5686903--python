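# Methods

## The model

AP-ISA searches a gene-expression matrix E of size m × n (m samples in rows,
n genes in columns, log-scale values) for *biclusters*: pairs of a sample
subset and a gene subset whose sub-matrix shows coherently elevated
expression.  Samples and genes may belong to several biclusters.  The method
composes two classical pieces:

1. **Affinity propagation (AP)** over the samples supplies a global
   partition into K clusters (K = the number of subtypes expected, e.g. 5
   for breast cancer).  AP exchanges responsibility/availability messages
   over a similarity matrix — here the negative squared Euclidean distance
   between sample rows — and represents each cluster by an exemplar sample.
2. **The iterative signature algorithm (ISA)** refines sparse binary sample
   vectors ("seeds") to fixed points.  One iteration scores every gene as
   the mean of the row-normalised matrix E_C over the selected samples,
   keeps genes whose score z-exceeds t_G, then scores every sample as the
   mean of the column-normalised matrix E_G over the kept genes and keeps
   samples whose score z-exceeds t_C.  A (sample set, gene set) pair that
   reproduces itself is a transcription module, i.e. a bicluster.

The coupling: 10,000 random sparsity-2 seeds are generated; a seed is kept
only if its whole support lies in a single AP cluster, and kept seeds are
grouped by that cluster.  100 seeds are then drawn with largest-remainder
quotas proportional to AP cluster size, so rare subtypes stay represented,
and each group receives its own gene threshold — larger groups smaller
t_G, so their modules can grow — before every seed is iterated to a fixed
point.  Identical fixed points merge (their *basin count* is the number of
seeds that reached them); near-duplicates are removed by a Jaccard-graph
diversity selection.

## Score normalisation and thresholds

Scores are averages over the selected rows/columns (not raw matrix-vector
products), which makes thresholds comparable across seed sizes.  Thresholds
are in standard-deviation units of the score vector and one-sided by default
(over-expression); a two-sided option exists.  Standard deviations use the
sample (n−1) convention everywhere.

A useful identity governs the operating regime.  When a score vector is
essentially bimodal — members of a group of prevalence p at one level,
everything else at another — the standardised score of the members is

    z_in ≈ sqrt((1 − p) / p),

independent of the effect size.  Hence a sample threshold t_C can only keep
a group with prevalence p < 1/(1 + t_C²): t_C = 1.6 caps recoverable groups
at ~28% prevalence, which would exclude the majority subtype.  The default
is therefore **t_C = 1.0** (groups up to ~50% prevalence selectable, with
comfortable margin up to ~40%).  The same identity on the gene axis, with q
the planted gene fraction, means the top of the t_G range (default
[1.0, 2.0], mapped onto groups by size rank) is safe while q ≲ 0.2.  The
historical configuration t_G = (1, 1.4, 0.9, 1.4, 2), t_C = 1.6 can be
reproduced verbatim through `t_g_overrides`/`t_c`.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 5 | requested AP cluster count (expected subtypes) |
| `n_seeds` | 10,000 | random seeds generated |
| `sparsity` | 2 | samples per seed; smallest value for which the same-cluster rule is non-trivial |
| `total_selected` | 100 | seeds iterated, apportioned by cluster size |
| `t_range` | (1.0, 2.0) | gene thresholds, mapped largest-group→low by size rank (ties share midpoints) |
| `t_c` | 1.0 | sample threshold, constant across groups (see identity above) |
| `max_iter`, `min_stable` | 100, 2 | ISA iteration budget; convergence = exact support equality for `min_stable` consecutive iterations |
| `dedup_jaccard` | 0.8 | overlap above which two fixed points are considered duplicates |
| `damping` | 0.5 | AP message damping |

Convergence by exact support equality is the strictest reproducible choice;
"approximately equal" criteria would need an arbitrary metric.  Seeds whose
modules vanish (either axis empties) or never stabilise are dropped but
counted in provenance.

## Finding K with affinity propagation

AP has no native cluster-count parameter; K is reached by bisection on the
shared preference placed on the similarity diagonal, exploiting that the
emergent cluster count is non-decreasing in the preference.  The bracket
starts at the min/max off-diagonal similarity and expands geometrically in
both directions — small K routinely requires preferences *below* the
minimum similarity.  If the probe budget (30) is exhausted the closest K is
returned flagged, and the pipeline aborts rather than guess.

After the messages converge, the exemplar set is finished with a
best-improvement add/drop/swap local search on AP's net-similarity
objective (exemplars pay the preference; every other sample attaches to its
most similar exemplar).  Message passing alone can settle in slightly
sub-optimal configurations; the polish removes that gap and, on problems
with m ≤ 40 where it costs microseconds, restarts from every singleton
configuration as well, which in testing makes the returned configuration
match an exhaustive search over exemplar subsets.  A seeded symmetric-
breaking noise of relative scale 1e-12 is added to the similarities to
avoid degenerate oscillation; it is far below any meaningful similarity
difference.

## Diversity selection

"Keep the diverse biclusters" is operationalised as follows: fixed points
are nodes of a graph with an edge wherever the Jaccard index of their
tagged sample∪gene membership sets exceeds `dedup_jaccard`; within each
connected component the record with the largest basin count survives
(ties: more samples, then lexicographically smaller id) and inherits the
component's total basin count.  Two survivors can in principle overlap
above the cut if they were connected only through a dropped intermediate;
direct pairs are below it.

## The effective number of biclusters

For bicluster entry sets U_1, …, U_K (U_k = the set of (sample, gene) cells
of bicluster k),

    F(U_1, …, U_K) = Σ_k (1/|U_k|) Σ_{x∈U_k} 1/N(x),

with N(x) the number of biclusters containing entry x.  F lies in [1, K],
equals K exactly iff the sets are pairwise disjoint, and equals r whenever
the collection splits into r disjoint groups of identical biclusters.
F/K (the "ratio") measures non-redundant structure per reported bicluster.
|U_k| counts matrix *entries*, not samples: overlap in samples alone does
not reduce F unless gene sets overlap too.

## Subtype capture and methylation profiling

A capture table counts, per bicluster, the samples carrying each reference
label (e.g. PAM50 calls); a bicluster *matches* a subtype when its most
frequent label reaches `min_fraction` (default 0.5) of its samples, and can
match at most one.  Methylation is summarised per sample as the mean CpG
beta value within each of six region categories (TSS200, TSS1500, 5'UTR,
1st exon, gene body, 3'UTR — the first four forming the promoter region),
optionally restricted to a bicluster's samples.  Missing betas are excluded
pairwise; a category with no contributing CpG is reported missing, never 0.
No hypo-/hypermethylation calls are made — only means are reported.

## Synthetic data: what it emulates and what it does not

`planted_expression` draws iid Normal(0, sd²) background and adds Δ·sd to
each planted (sample, gene) cell.  Defaults: m = 200 samples, n = 500
genes, five latent groups at prevalences (0.30, 0.15, 0.35, 0.15, 0.05) —
the unequal-subtype structure the method targets — each with a disjoint
60-gene block at Δ = 3.  `planted_methylation` draws betas from
Beta(μν, (1−μ)ν) with per-group, per-region means μ and concentration
ν = 50, CpGs assigned round-robin to the six categories.

The generators deliberately omit correlated noise, batch effects, heavy
tails, overlapping gene programs and realistic marginals; additive
mean-shift blocks keep every recovery statement analytically checkable.
Passing the planted-recovery suite therefore demonstrates correctness of
the machinery under the model's own assumptions, not performance on real
tumour cohorts.

## Numerical choices and degenerate inputs

- Constant rows/columns cannot be z-normalised and are rejected by name.
- A constant score vector thresholds to the empty set with a warning.
- Duplicate identifiers, non-numeric cells and (by default) missing values
  are load-time errors; per-gene mean imputation is opt-in.
- All randomness flows through explicit integer seeds (`numpy` Generator);
  identical inputs and seeds reproduce bicluster sets byte-for-byte.
- Problem sizes in the test and acceptance runs (m = 200, n = 500, ten
  pipeline replicates; 100 oracle trials at m ≤ 10) are chosen so the full
  planted design stays at desk scale while every statistical bound retains
  a wide margin.

## Known limitations

- On pure-noise data at permissive thresholds (t ≈ 2) ISA converges to tiny
  spurious fixed points (a handful of samples) rather than vanishing; no
  robustness filtering of such modules is implemented, so null inputs can
  yield many trivial biclusters.  Planted-signal recovery is unaffected.
- Groups with prevalence ≳ 1/(1 + t_C²) cannot be captured whole (see the
  bimodal identity); the default t_C = 1.0 pushes this bound to 50% but a
  dominant group beyond that would be truncated.
- The Jaccard-graph diversity rule resolves ambiguity deterministically but
  is one of several defensible readings of "keep the diverse biclusters".
- AP's K-search assumes cluster count is monotone in the shared preference;
  non-converged probes can locally violate this, in which case the closest
  achieved K is reported and flagged.
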