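# Methods

## Model and assumptions

A pathway is reduced to its set of gene symbols; topology, small
molecules and directionality are ignored. This makes pathway
similarity a set-overlap problem (Jaccard coefficient) and pathway
consolidation a graph-clustering problem. The reduction assumes the
inputs are already symbolised consistently across sources — the
package offers only optional upper-casing (`read_gmt(normalize=True)`),
no identifier mapping.

SuperPaths are connected components under the union of absorption,
identity, core (*T₂*) and best-neighbor (*T₁*) edges (see README for
definitions). Connected components make the construction independent
of input order and of the orientation of best-edge proposals; we rely
on `networkx` for component extraction and verify the partition
against a plain union-find oracle in the tests.

### Interpretation choices in the clustering rules

Several details of the rule set are underdetermined; the package's
readings, chosen for determinism and order independence:

- A small pathway links to **all** qualifying larger partners, not
  one; a single-partner rule would need an arbitrary tie-break.
- "Larger" requires `|genes(l)| ≥ |genes(s)|` in addition to the
  `< 200` cap; absorption adds edges only — the small pathway stays a
  member and contributes to support counts.
- Identity means exact gene-set equality (equivalently *J* = 1).
  Identical copies are joined directly and are never nearest-neighbor
  candidates.
- Best-edge search runs for every pathway, including those already in
  a core: their best edges land inside their component or genuinely
  extend it.
- Hub degree counts absorption and identity edges as well as
  core/best edges (they are real co-membership evidence;
  `aux_edges_in_hub_degree=False` disables this). Hub ties go to the
  larger gene set, then to the smallest pathway id.
- Cluster ids derive from the smallest member id (`SP_<id>`), so
  output is stable under permutation.

## The threshold objective

The uniqueness and informativeness scores are implemented as

- `U(s) = log10( (1/|G_s|) · Σ_{g∈G_s} 1/N_sp(g) )`, where `N_sp(g)`
  counts SuperPaths (post-clustering, not source pathways) whose gene
  union contains `g`;
- `I(g) = log10( (1/|S_g|) · Σ_{s∈S_g} 1/|G_s| )` over the SuperPaths
  containing `g`;

with **unweighted** means over SuperPaths and genes respectively for
`U_S` and `I_S`. The printed source formulas for these scores are
typographically ambiguous; this reading is fixed by the scores'
required limiting behaviour, which the tests assert: `U_S = 0` iff no
gene is shared between clusters, a single 10-gene cluster gives
`I(g) = −1`, and merging two clusters never lowers `U_S` nor raises
`I_S` (the antagonism that makes `U_S + I_S` a usable trade-off).
Counting `N_sp` against SuperPaths rather than input pathways is what
makes `U_S` rise as redundancy is consolidated.

The grid search scores every admissible `t1 ≤ t2` pair (default step
0.1 on (0, 1]); the diagonal `t1 = t2` is pure single-linkage
clustering. Ties in the argmax are broken to the smallest `(t1, t2)`,
which on cleanly separated corpora (where many cutoffs give identical
partitions) reports the left edge of the optimal plateau.

## Dilution resampling

For each candidate `t2`, the full-data co-cluster pair set is fixed;
each replicate revisits a uniform pathway subsample (default dilutions
0.75 and 0.9, 100 replicates; 25 in the fast tests), reclusters, and
reports the fraction of full-data pairs — restricted to sampled
pathways — still co-clustered. Replicates whose restriction is empty
are skipped and counted. Per-replicate ratios are averaged (not
pooled across replicates); the spread is the sample (n−1) standard
deviation. The same subsample sequence is replayed for every `t2`
(one seeded generator per `t2`), making the comparison across cutoffs
paired. Recovery is identically 1 at dilution 1.0 and for corpora
whose clusters are exact-duplicate groups, which the tests use as
calibration points.

## Evaluation statistics

- **Novel pairs**: gene pairs inside some SuperPath union but no
  single pathway. Controls are pseudo-SuperPaths: per real SuperPath,
  a uniform sample (without replacement) of the same number of genes
  from the annotated universe, with each member pathway's size
  mirrored by resampling within the pseudo-set so the same novel-pair
  extraction applies.
- **KS contrast**: the control is downsampled without replacement to
  the test-set size, then a one-sided two-sample Kolmogorov–Smirnov
  test (`alternative="less"` on the test sample's CDF, i.e. test
  stochastically greater) is applied. Per-bin test/control count
  ratios use width-10 bins with a pseudo-count of one observation for
  empty control bins so finite fold ratios can be reported.
- **ORA**: upper-tail hypergeometric `P(X ≥ overlap)` — the classical
  one-sided Fisher/over-representation test; the enrichment delta for
  a SuperPath is `−log10 p(union)` minus the constituents' mean
  `−log10 p`. The two-member cohort filter (exactly two members,
  pairwise `J < 0.6`) selects the dissimilar pairs where the contrast
  is informative.
- **Concordance**: all unordered pathway pairs classified at
  name-similarity ≥ 0.5 and gene-Jaccard ≥ 0.5. Name similarity is
  the Jaccard of stemmed token sets; the stemmer is the classic
  Porter algorithm (implemented in `_stem.py`), and the default
  stopword list is deliberately minimal (articles, prepositions,
  connectives) — domain words like "pathway" and "signaling" are
  kept because dropping them is a corpus-dependent choice; both list
  and cutoffs are configurable. Because the stopword list and
  stemmer conventions of the original analysis are not recoverable,
  concordance values on real corpora are comparable only
  qualitatively.

## Synthetic study conditions

The generator plants disjoint base modules (default 10 modules of
20–60 genes in a 2000-gene universe) released as 2–4 variants over 4
pseudo-sources. A variant keeps each module gene with probability
`keep_rate` (default 0.8) and gains `Binomial(module size, noise_rate)`
background genes (default rate 0.05); 10 unrelated noise pathways are
mixed in. With these defaults within-module Jaccard concentrates
around 0.55–0.75 and cross-module Jaccard stays near 0, so planted
recovery at the grid optimum is essentially exact (adjusted Rand ≥
0.9 is the acceptance bar).

`n_bridge_pathways` (default 0) adds composite pathways equal to the
full union of two modules whose size ratio lies in [1.1, 1.45] — the
way hierarchical sources publish parent pathways. The composite's
similarity to its larger module (≈ 0.8r/(r+1)) exceeds that to the
smaller (≈ 0.8/(r+1) ≈ 0.33–0.38), so its best edge stays within one
module while low upper cutoffs chain both modules through it: the
unstable-chaining regime that gives the dilution scan an interior
optimum over `t2`, as on real corpora.

Pair evidence is drawn lazily per gene pair from a hash-seeded
stream: publication counts are negative-binomial (dispersion 0.5,
mean `background_rate`, default 2) to mimic heavy-tailed publication
counts, multiplied by `signal_multiplier` for within-module pairs;
PPI scores are Beta(1.2·multiplier, 8). Lazy dense evaluation makes
the `multiplier = 1` null exact — every pair is identically
distributed — which the false-positive-rate test requires; evidence
read from TSV tables instead uses the sparse absent-pair-scores-0
convention. Query sets mix module genes (probability
`from_module_fraction`, default 0.8) with background genes.

What the synthetic corpus does *not* emulate: hierarchical source
structure beyond two-module composites, source-specific curation and
size biases, gene-symbol noise, and the heavy right tail of real
pathway sizes. Passing the planted-recovery tests therefore shows the
algorithm and its threshold selection behave correctly when modules
exist and are separable — not that any particular real corpus is this
separable.

## Problem sizes and numerics

Test corpora use 10–14 modules' worth of pathways (≈ 35–45 sets);
stability runs use 25 replicates over seven `t2` values and two
dilutions; evidence contrasts use 500 test pairs; the
false-positive-rate check uses 50 evidence seeds. These sizes give
stable behaviour at interactive runtimes while exercising every code
path at the same rates as larger corpora.

Degenerate inputs are handled explicitly: Jaccard and containment
reject empty sets (rather than adopting a 0/0 convention), empty name
token sets score 0, genes with no pathway annotation are excluded
from `I_S`, stability replicates with no restricted pairs contribute
no observation, and the source-size standard deviation uses the
population formula by default (`ddof` configurable). Pathways are
never deduplicated at load; identity handling belongs to the
clustering stage.

## Known limitations

- All-pairs name concordance is quadratic in corpus size; fine to a
  few thousand pathways, slow beyond.
- The similarity graph stores edges at `j_min = t1`; exploratory
  graphs at lower thresholds must be built explicitly
  (`pairwise_graph(collection, j_min=0.05)`).
- Absorption pairs are found by scanning small×large candidates
  directly, quadratic in the number of sub-200-gene pathways.
- `grid_search` reclusters from scratch per grid point; no
  incremental reuse across thresholds.
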