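# Methods

## Ontology model

An ontology is reduced to a directed acyclic graph whose nodes are classes
and whose edges run from a child class to each parent via a configurable
relation set, `{is_a, part_of}` by default (`is_a`-only is a flag; other
OBO relations are ignored).  Obsolete classes are parsed and counted but
excluded from edges, closures, sampling universes and the IC normalization
constant.  Multi-rooted ontologies such as GO are treated as independent
weakly connected components: each component has its own root(s) and its own
class count *N*, which keeps IC(root) = 0 within every namespace.  Classes
from different components share no ancestor and score 0 under every
measure; no virtual global root is introduced.

Depth is the length of the *shortest* parent-edge path to any root
(`longest=True` is available but is not the default or the tested
contract).  Descendant counts treat multi-path descendants once.

## Information content

The default intrinsic IC is the descendant-counting (Seco-style) form

    IC(c) = 1 − log(desc(c) + 1) / log(N),   p(c) = (desc(c) + 1) / N,

computed per component; a single-class component has IC 0 by convention.
IC is monotone non-increasing from leaves (IC 1) to roots (IC 0), which the
test suite asserts on random DAGs.  A normalized Sánchez-style
leaves-over-subsumers variant is provided behind the same interface for
sensitivity checks; all shipped analyses use Seco.

## Similarity measures

Pairwise measures (Resnik, Lin, Jiang–Conrath, Schlicker) are defined on
class pairs through the most informative common ancestor (MICA) and mixed
into entity scores by Average, Best Match Average
(BMA = ½·(mean of row maxima + mean of column maxima)) or Max over the
matrix of the two entities' *direct* classes.  Groupwise measures (simGIC,
UI, NTO) operate on the *extended* — ancestor-closed — sets.  Numerical
conventions that the literature leaves open, fixed here once:

* Jiang–Conrath distance d = IC(a) + IC(b) − 2·IC(MICA) is mapped to a
  similarity as 1/(1 + d), bounded in (0, 1].
* Schlicker's relevance factor uses the topological p(MICA), since no
  annotation corpus exists in the intrinsic setting.
* NTO is computed on extended sets (direct-set mode available).
* Lin returns 0 when IC(a) + IC(b) = 0 (two roots).
* MICA ties on IC break to the lexicographically smallest class id;
  equal-IC classes within a component necessarily share p, so Schlicker is
  unaffected by the tie order.

Full similarity matrices are evaluated by a vectorized engine: a
term-by-term MICA table is built by writing each ontology class's IC into
the block of term pairs it subsumes in increasing-IC order (the last write
is the maximum), and groupwise scores come from boolean
incidence-matrix products.  The scalar single-pair implementations remain
the reference; tests assert elementwise agreement between the two paths.

## Synthetic data

`generate_random_dag` draws, for each class, 1..max_parents parents
uniformly among all earlier classes.  That model is kept (and tested) as
the generic random-DAG fixture, but it is a poor stand-in for GO at small
scale: uniform attachment concentrates ancestry in a few early hubs, and at
2000 classes a term's mean ancestor closure reaches ~2–3 % of the whole
ontology (GO's is of order 0.03 %), so set-overlap measures saturate
after a handful of annotations.

`generate_layered_dag` is therefore the generator behind the shipped
studies.  Classes fill depth strata of geometrically growing capacity
(branching 3 by default); each class takes one uniform parent from the
stratum above and, with probability 0.2, a second parent from that same
stratum — mirroring how secondary parents in GO sit at a similar depth as
the primary one.  Closures then stay compact (mean ≈ 11 classes at 2000
nodes, ≈ 0.5 % of the ontology) and the depth strata are exact, which also
gives the depth-controlled corpora well-populated groups.

Corpora: `annotate_by_size` draws, per entity, the requested number of
distinct classes uniformly from all non-obsolete classes (all components
pooled; a namespace filter would be a restriction of the universe).
Sampling is without replacement within an entity so that the nominal size
is the effective size.  `annotate_by_depth` samples from a single depth
stratum; strata thinner than the per-entity size fall back to sampling
with replacement plus deduplication and flag it in provenance.  The
annotation size of depth-controlled entities defaults to 10 (the design
leaves it open; 10 is in the typical range of curated per-gene GO
annotation counts).  `shuffle_annotations` replaces every entity's classes
by a fresh uniform draw of the same cardinality — the size-preserving null
used throughout.

Interaction networks: `random_interactions` samples endpoint pairs with
probability proportional to `size^γ · LogNormal(0, σ)`.  γ = σ = 0 gives a
uniform network (degree independent of annotation size).  The confounded
study condition uses γ = 0.7, σ = 1.0 over a corpus spanning sizes 1..55:
the lognormal term reproduces the heavy-tailed hub structure of curated
interactomes, and the pair was calibrated once so that the realized
annotation-size/degree Pearson correlation lands near the ≈ 0.34 reported
for yeast.  Without the hub term, a near-Poisson degree distribution at the
same Pearson correlation concentrates far fewer interactions on
highly-annotated entities and the randomized-annotation AUC barely leaves
0.5 — the hub structure, not the correlation coefficient alone, carries
the bias.

What the generators deliberately do **not** emulate: co-annotation
structure (real genes' annotations cluster in related branches), evidence
codes, per-gene annotation-size distributions of any particular organism,
and community structure in interaction networks.  Passing tests therefore
demonstrate measure-intrinsic size sensitivity and the degree/annotation
confounder mechanism, not organism-level effect sizes.

## Bias profiles and statistics

For a similarity matrix over a grouped corpus:

* **size/depth profile** — each entity's mean similarity to all *other*
  entities (self-similarities are always excluded, since they would
  inflate small-group means), summarized per group by mean, population
  variance and count;
* **difference profile** — raw similarities of the n(n−1)/2 unordered
  pairs, binned by |size_i − size_j|, summarized the same way.  The
  variance column is the variance of per-entity means for grouped
  profiles and of raw pair values for difference bins; both
  interpretations of "variance in similarity" are defensible and the
  per-group tables expose the underlying n.

Sensitivity is the Spearman and Pearson correlation between group keys and
group means (and, separately, group variances), computed over the group
summary points (20 or 55 sizes, not the raw half-million pairs), matching
how the published coefficients are defined.  Coefficients are undefined
(and raised as errors) for fewer than 3 points or constant inputs.
Classification uses the Pearson r of the size profile with strict
thresholds at ±0.5; the published rule's negative branch is read as
r < −0.5.

## ROC evaluation

All unordered non-self entity pairs are ranked by similarity; known
interactions (restricted to the matrix universe) are positives, every
other pair a negative — the closed-world convention, with no negative
subsampling.  The AUC is the rank-sum (Mann–Whitney) statistic with half
credit for ties, which is exact under the heavy score ties NTO and UI
produce and equals the trapezoidal area of the ROC curve; curve points are
thinned to ≤ 2000 for output.  Significance of AUC > 0.5 is assessed by a
seeded label permutation (positives re-drawn uniformly among pairs,
add-one-smoothed p-value; 200 permutations by default in the pipeline).  A
Wilcoxon-type test over per-entity AUCs is deliberately not the default:
its pairing is ambiguous, whereas the permutation null is exactly the
hypothesis being tested.

## Study conditions and scale

The shipped desk-scale studies (shared by the acceptance script and the
acceptance tests) use: a 2000-class layered DAG; sizes 1..20 with 20
entities per size for the sensitivity profiles; sizes 1..55 with 6
entities per size, 3000 interaction edges for the confounder experiment.
These sizes keep a full run under a minute on one core while leaving the
qualitative pattern stable across seeds.  The full-ontology design
(GO/HPO, sizes 1..55, 100 entities per size) runs through
`scripts/replicate_tables.py` against a downloaded OBO release.

## Known limitations

* Intrinsic IC only; corpus-derived (annotation-frequency) IC variants are
  out of scope, so quantitative coefficients on real corpora may differ
  from extrinsic-IC implementations.
* The uniform-attachment DAG remains available but saturates groupwise
  measures at small ontology sizes; profile coefficients measured on it
  are noisier than on the layered generator (see above).
* Depth profiles on small synthetic ontologies cover far fewer strata than
  GO's 17 levels.
* Gene–disease evaluation is supported as the same two-corpus machinery
  over a user-supplied merged ontology; building such cross-species
  ontologies is out of scope.
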