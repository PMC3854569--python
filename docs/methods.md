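# Methods

## Model

A regulatory module couples a gene set *M = {g₁ … gₙ}* with a binary
decision tree over transcription-factor activity states.  TF activity is
taken to be readable from the TF's own expression (regulators are
themselves transcriptionally regulated), discretized per TF into
{−1, 0, +1} by z-scores computed against the TF's own mean and standard
deviation across the conditions in the active matrix: +1 where z ≥ z_hi,
−1 where z ≤ z_lo, 0 otherwise; a constant profile is all-normal.  The
defaults z_hi = +1.0 and z_lo = −1.0 flag roughly the top and bottom
~16% of conditions for a Gaussian profile; both are configurable.

Internal tree nodes ask one of two query types per TF — "state = +1?"
(high) or "state = −1?" (low) — matching a three-state discretization in
which "normal" is never queried directly.  The leaves partition the
conditions; within leaf *k* the pooled log-expression of all module genes
over the leaf's conditions is modeled as *N(μₖ, σₖ)* with maximum-likelihood
parameters (mean, population standard deviation).  Expression values enter
on the natural-log scale after RPKM-style normalization
(count / (gene length in KB) / (library size in millions)); a pseudocount
of 1.0 precedes the log because zero counts are ubiquitous in RNA-Seq.  The
natural-log base is a free choice: any fixed base rescales all likelihood
comparisons uniformly.

## Inference

Starting from K-means clusters (Lloyd iterations, Euclidean distance on
log-expression rows, 10 restarts keeping best inertia, convergence
tolerance 1e-6, seeded), the fit alternates:

1. **Tree construction.**  For each module, every feasible (TF, high/low)
   query is scored by the summed log-density of all gene × condition values
   under the two sides' pooled Gaussians; the best query is accepted if it
   beats the unsplit leaf by more than `epsilon_gain` and recursion
   continues on each side.  Exact ties go to the lexicographically smaller
   (tf_id, query_state).  Splitting stops at `max_depth`, when a side would
   drop below `min_leaf_conditions`, or when no query improves the leaf.
   No TF repeats on a root-to-leaf path, and a TF that is itself a target
   gene of the module is excluded from that module's own candidate list
   (self-explanation guard; can be disabled).
2. **Gene reassignment.**  Each gene moves to the tree maximizing the sum
   of leaf log-densities of its profile; ties go to the lowest module
   index; emptied modules are dropped (not reseeded).

Greedy tree rebuilding alone is not guaranteed monotone: a fresh greedy
tree can score below the previous topology refit on the module's new gene
set (greedy's root choice is locally optimal but the recursion may not
recover a better deep structure).  The tree step therefore evaluates both
the fresh greedy tree and the previous topology with leaf parameters refit
on the current genes, and keeps the better.  Per-leaf ML refitting never
scores below the stale parameters, so every half-step is a true coordinate
ascent, the total log-likelihood trace is non-decreasing by construction
(asserted on every run), and—with deterministic tie-breaks—the assignment
sequence cannot cycle; it reaches a fixed point, in practice within a
handful of iterations (cap: `max_iter` = 50).

### Parameters

| parameter | default | units / meaning |
|---|---|---|
| z_hi, z_lo | +1.0, −1.0 | per-TF z-score cutoffs for high/low states |
| sigma_floor | 0.01 | log-units; lower bound on leaf σ (degenerate-leaf guard) |
| min_leaf_conditions | 2 | minimum conditions on each side of a split |
| epsilon_gain | 1e-6 | log-likelihood units; split acceptance margin |
| max_depth | 3 | query levels per tree (published trees show ≤ 3) |
| max_iter | 50 | outer iteration cap |
| DEG threshold | 0.05 | adjusted p (0.001 when emulating the DEGseq path) |
| enrichment cutoff | 0.01 | raw hypergeometric p |
| upstream length | 500 | bp before the start codon |

## Choosing K

For each K in the scan range, the curve records the mean within-cluster
pairwise Pearson correlation (size-1 clusters contribute 1.0; exact
zero-variance rows contribute 0 and are flagged) and the mean cluster size
n/K.  The automatic choice is the kneedle criterion: the K whose
normalized avg_corr lies farthest above the chord joining the curve's
endpoints — the corner where correlation gains flatten into the plateau.
A maximum-second-difference rule was considered and rejected: on idealized
module-structured data it ties exactly between K*−1 and K* (the rise into
the last pre-plateau point equals the flattening at the plateau corner),
so sampling noise resolves it to K*−1 about half the time, while the chord
criterion selects the plateau corner K* robustly.  Flat curves
(structureless data) fall back to the smallest K with a warning; a scan
window narrower than 3 returns its midpoint with a warning.  The chosen K
is always overridable.

## Differential-expression filter

Negative-binomial DE machinery is intentionally out of scope: adjusted
p-values from edgeR/DEGseq are imported from TSV.  For self-contained runs
a stand-in test is provided: each gene's pooled count in group A out of its
pooled total is tested two-sided against the library-size proportion with
an exact binomial test (genes with zero total count get p = 1), followed by
Benjamini–Hochberg adjustment and an inclusive (≤) threshold.  The
stand-in pools replicate-free groups and is Poisson-consistent with the
synthetic count generator; it is a stand-in, not an edgeR reimplementation.
Multi-comparison designs combine per-comparison selections by intersection
("common responders") or union.

## Module evaluation

The per-condition score log p_j = Σᵢ[−(x_ij−μₖ)²/(2σₖ²) − ln σₖ] drops the
constant −½·ln 2π per term; the leaf k is the one containing condition j.
The null model draws `n_reps` (default 1000) same-size gene sets from a
universe (default: all genes of the active matrix), **refits** each leaf's
(μ, σ) on the drawn genes over the fixed condition partition, and records
the mean score over conditions — a proper "random genes, same topology"
null; keeping the fitted module's parameters instead would conflate gene
identity with parameter mismatch.

Stability under non-DE TF injection compares two runs' predicted relations
as co-membership pair sets — gene–gene (same module), TF–TF (co-regulating
a module's tree), TF–target — restricted to the genes/TFs present in both
runs, scoring each set Rand-style: (pairs predicted together in both runs +
pairs in neither) / all candidate pairs.  Fraction 0 compares the baseline
with an identical rerun and is exactly 1 by determinism.

Threshold robustness fits networks on the DEG sets of a strict and a loose
adjusted-p cutoff (with BH these are nested) and reports, per strict
module, the best-Jaccard loose module and the containment |S∩L|/|S|.

## Annotation

GO enrichment is the one-sided hypergeometric upper tail
P(X ≥ k | N, K_bg, n) per GO term present in the module, against a
background defaulting to all annotated genes of the active matrix; raw
p-values are reported (matching published practice) with an optional BH
flag.  Upstream windows follow GFF3 1-based inclusive coordinates: forward
genes take [max(1, s−L), s−1], reverse genes the reverse complement of
[e+1, e+L], truncated at contig ends.  The nodulin motif scan counts all
overlapping exact occurrences of AAAGAT and CTCTT per record
(case-normalized; ambiguity codes never match; optional reverse-complement
scan).

## Synthetic data

The generator plants the exact structure the model assumes.  TF rows get
three-tier profiles (≈¼ high / ½ normal / ¼ low per condition, both tails
forced non-empty, small jitter); their truth states are obtained by running
the actual discretizer on the generated rows, so states and rows can never
disagree.  Per module a random full binary query tree of the requested
depth is drawn whose every leaf keeps ≥ 2 conditions; leaf means follow the
left-to-right leaf order in steps of `leaf_mean_separation` (randomized
offset and sign), so adjacent leaves differ by at least the separation and
the root split carries the widest gap — the regime in which greedy search
is expected to recover the hierarchy.  Member genes sample
N(leaf mean, leaf_sigma).  Background genes are structureless constitutive
profiles: a per-gene level drawn uniformly over the planted dynamic range
plus i.i.d. noise.  (A single shared mid-range Gaussian population was
rejected: it forms one tight K-means cluster that a single module swallows
wholesale, which says nothing about the inference.)  Decoy TFs
(`n_decoy_tfs`) are TF-like rows that regulate nothing — the non-DE TF pool
for injection experiments.  TF rows participate in the matrix as genes so
the member-TF exclusion path is exercised.  Defaults — 5 modules × 30
genes, 30 background genes, 20 conditions, 12 TFs, separation 4.0, leaf σ
0.5 (separation/σ = 8), depth 2 — and regeneration from stored parameters
is bit-identical.

Counts are Poisson with rates proportional to exp(log-expression), columns
scaled to a target library size; selected genes get a group-A rate shift
(scalar or per-gene) and form the DE truth set.  Over-dispersion can be
added by post-processing the rate matrix before drawing.

### What passing on synthetic data does and does not show

The generator realizes the model's own assumptions: Gaussian leaves,
perfectly readable TF states, no batch effects, no dispersion beyond
Poisson, and condition-independent noise.  Recovery there demonstrates the
estimator's correctness and its self-consistency (oracle-equivalent split
search, monotone convergence, calibrated null separation), not performance
on real transcriptomes, where TF activity is often post-transcriptional,
leaves are heavy-tailed, and replicate structure matters.  Regulator
*identity* is unidentifiable whenever two TFs share a state pattern on the
relevant conditions — any method can only recover the induced condition
hierarchy — so tree-recovery is measured on `condition_hierarchy()`, the
nested unordered partition of conditions, with fitting depth matched to the
planted depth (an intentionally matched-capacity harness; with a deeper
budget the ML objective will subdivide leaves whenever noise permits a
marginal gain).  Recovery Rand indices are computed over planted module
genes only: background and TF rows have no ground-truth module.  Harness
fits use K = planted modules + 3 so background/constitutive genes can
occupy their own clusters instead of being forced into planted ones.

## Problem sizes in the shipped harnesses

The test-suite and `scripts/acceptance.py` use deliberately compact
instances chosen to exercise every code path on a single CPU: 50 random
split-oracle instances (≤ 3 TFs × ≤ 8 conditions × ≤ 6 genes), 20
convergence datasets (3 modules × 8 genes, 16 conditions, mixed depth and
noise), 10 recovery seeds at generator defaults, 20 null-separation
replicates at 200 null draws each, 5 stability seeds (8 regulator + 20
decoy TFs, fractions 0/5/10/50%), and one threshold-robustness instance
whose per-module shift ladder (log-spaced factors 1.15→6.0 at library
200k) spreads the stand-in test's p-values across both cutoffs so the
strict DEG set retains a subset of each well-powered module.

## Known limitations

* The stand-in DE test ignores replicate-level dispersion; imported
  edgeR/DEGseq tables are the intended path for real data.
* Library-size renormalization makes strong rate shifts visible in *other*
  genes' proportions (composition effect) — inherent to proportion-based
  testing, visible in the synthetic count fixtures too.
* Leaf Gaussians pool all module genes; per-gene leaf variance is not
  modeled.
* The likelihood is maximized, not integrated: no structure priors or
  Bayesian model averaging.
* Discretization uses the full active matrix per TF; stage-specific runs
  that should discretize against a reference condition set must subset the
  matrix first.
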