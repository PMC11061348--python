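# Methods

## Problem setting

A full ER agonist pathway model integrates many high-throughput assays into
a single activity score (an AUC in [0, 1]; ≥ 0.1 is called active).  A
reduced model uses a small assay subset — here the canonical 4-assay case:
a cell-free receptor-binding assay, a protein-dimerization assay, a
transactivation reporter assay, and a cell-proliferation assay — and is
evaluated against the full model treated as reference truth.  Because the
reduced battery lacks the full model's interference ("pseudoreceptor") and
antagonist pathways, its characteristic failure is the false positive:
antagonists and borderline weak actives score above threshold.  The
analysis localizes those failures in structural space (clusters) and
quantifies how far cheap triage rules go in removing them.

## Clustering

Fingerprints are binary substructure indicator vectors (729 features by
default).  Dissimilarity is the Tanimoto distance 1 − c/(a + b − c) with
c shared on-bits and a, b per-vector on-bit counts; it equals the Jaccard
distance on bit vectors and is computed through `scipy.spatial.distance`.
Degenerate all-zero fingerprints are defined to be at distance 0 from each
other and 1 from everything else, and are warned about rather than
rejected: such rows usually indicate an upstream featurization failure.

Ward agglomeration comes in two dialects whose merge heights differ:

* `ward_d2`: Ward's minimum-variance objective on squared dissimilarities
  (scipy's `linkage(method="ward")`, R's `ward.D2`).  Default, because it
  is the variant consistent with Ward's objective when the input is a
  distance matrix.
* `ward_d`: the Lance–Williams Ward update applied to raw dissimilarities
  (R's historical `ward.D`).  Implemented through the exact identity
  ward_d(d) = ward_d2(√d)², which preserves merge order and maps heights
  back to the raw-dissimilarity scale.

Both dialects are verified in the test suite against merge heights and
cut partitions computed independently with R's `stats::hclust`/`cutree`.
The tree is cut at an **absolute** height (no percentile cutting); a
chemical pair shares a cluster iff its cophenetic merge height is at or
below the cut.  Cluster ids are relabelled 1..K by first member appearance
in the input order, so ids are deterministic for a fixed ordering while
the partition itself is order-invariant (a property test permutes the
input and compares partitions as sets of sets).  Merge ties are resolved
by the linkage implementation's scan order; with real-valued noisy
fingerprints exact ties are rare, and the tie rule is documented as
implementation-defined.

Cut-height choice is data analysis, not a constant of the method: the size
profile (`cluster_size_profile`) reports singleton and doubleton counts,
which are the diagnostics used to balance "no singleton clusters" against
"no absurdly merged clusters".  For the synthetic generator's default
universe the dendrogram shows a wide gap — within-block merges complete
below height ≈ 0.7 and between-block merges start above ≈ 3.7 — and the
default cut of 2.0 sits in that gap.

## KNN mapping

Tested chemicals not in the universe receive the majority cluster of their
k nearest universe chemicals under Tanimoto distance.  k is selected by
hold-out accuracy: the labelled universe is split uniformly at random
(80% train / 20% test, seeded), each candidate k ∈ {1…5} predicts the
held-out labels, and the most accurate k wins with ties going to the
smallest k.  The split is deliberately not stratified by cluster, so
singleton clusters can be absent from training and cap attainable
accuracy — matching how the protocol behaves on real inventories; the
selection result records every candidate's accuracy.

Determinism requires explicit tie rules, since binary fingerprints
produce many exactly-equal distances:

1. neighbour distance ties break by lexicographically lowest training
   chemical id;
2. majority-vote ties break to the cluster of the single nearest
   neighbour.

The KNN is implemented directly over the distance matrix rather than via
`sklearn.neighbors`, because these tie rules are part of the contract.
A self-consistency check is built into the pipeline: every tested chemical
that is also a universe member must map back to its own cluster.

## Scoring and concordance

The subset score is Σ wᵢ·AUCᵢ / Σ wᵢ over the model's assays.  Weights are
normalized by default so the score stays on the AUC scale and the 0.1
threshold keeps its meaning; `normalize_weights: false` gives the raw
weighted sum for exact replication against externally produced outputs.
CI scores apply the same functional to the lower/upper 95% CI input
matrices (no resampling), which preserves lo ≤ med ≤ hi by monotonicity.
The activity call is closed at the threshold (AUC ≥ 0.1 is active).
A chemical missing any of the model's assay values is excluded from
scoring and listed, never imputed.

Per-cluster statistics use the standard definitions (sensitivity
tp/(tp+fn), specificity tn/(tn+fp), accuracy, balanced accuracy as the
mean of sensitivity and specificity, PPV, NPV, prevalence).  Ratios with
zero denominators are **NA**, never 0 or 1, and an NA component makes
balanced accuracy NA rather than silently halving the information; NA
values are excluded from cross-cluster averages.  Clusters below a size
floor (`min_cluster_n`, default 2) are reported separately, and a
conservation test asserts that floored-out chemicals plus per-cluster
counts reproduce the global confusion counts exactly.  The prevalence
partition is reported both with and without the size floor, since
summaries of "all-negative clusters" are sensitive to whether singleton
clusters are included.

## Triage and prioritization

False positives get the first matching category, in this order:

1. **antagonist_flagged** — reference antagonist designation; expected
   false positives of an agonist-only battery.
2. **below_tp_quartile** — subset AUC strictly below the q-quantile
   (default 0.25, linear-interpolation definition) of the true positives'
   subset AUCs.  Strict `<` means a chemical exactly at the quartile is
   not down-weighted.  The quantile definition is config-relevant because
   reproducing a published quartile value depends on it.
3. **low_assay_count** — active (assay AUC strictly greater than the
   activity floor, default 0) in fewer than `min_active_assays` (default
   3) of the model's assays.
4. **residual_high_priority** — the false positives that no cheap rule
   removes.

The order mirrors the narrative of the triage cascade as successive set
subtractions from the FP pool; first-match assignment reproduces it, and a
test constructs an overlap case to guard against accidental reordering.
CI-overlap with the threshold (closed intervals; full-model CI used only
when supplied) is reported per false positive as an uncertainty marker,
not as a removal rule.

Prioritization ranks subset-positive chemicals by (meets the
assay-support minimum, subset AUC descending, chemical id), computes
per-cluster positive fractions, and lists negative chemicals in clusters
containing at least one positive as "cluster-rescued" screening
candidates — structural neighbourhood evidence standing in for the
chemical's own weak signal.

## Synthetic data generator

The generator provides ground truth for every stage; its defaults are the
package's study conditions.

**Universe.**  10 clusters × 20 chemicals, 729 bits.  Each cluster owns a
40-bit mask (masks sampled disjointly when the feature space allows);
members switch mask bits on with probability 0.9 and background bits with
probability 0.02.  This yields within-cluster Tanimoto distances around
0.5 and between-cluster distances near 1.0 — strong but not degenerate
separation, so clustering is exercised rather than trivialized.  Tested
chemicals are half the universe plus 60 extras drawn from the same cluster
profiles (so the KNN stage has genuine queries with known generating
clusters).

**Assay archetypes** (mixture over tested chemicals: inactive 0.62,
strong agonist 0.10, weak agonist 0.08, antagonist-like 0.04, borderline
0.16 — tracking a mostly-inactive screening inventory with a ~10%
false-positive rate and a small antagonist share):

| archetype        | binding | dimer. | transact. | prolif. | full-model base |
|------------------|--------:|-------:|----------:|--------:|----------------:|
| strong_agonist   |    0.55 |   0.50 |      0.60 |    0.50 |            0.50 |
| weak_agonist     |    0    |   0.14 |      0.22 |    0.12 |            0.16 |
| antagonist_like  |    0.55 |   0.45 |      0    |    0    |            0.03 |
| inactive         |    0    |   0    |      0    |    0    |            0    |
| borderline       |    0    |   0    |      0.22 |    0.18 |            0.05 |

The antagonist-like profile is active only in the binding/dimerization
assays that agonist and antagonist pathways share — the structural reason
a 4-assay agonist battery false-flags antagonists — and carries the
antagonist flag.  The borderline profile's subset mean is exactly 0.1, so
under noise it straddles the call threshold with an overlapping CI.  The
weak agonist's full-model base is 0.16 (≈2 noise SDs above threshold)
rather than something closer to 0.1, so the archetype genuinely plants
true positives instead of flickering between reference calls.

Noise is truncated-normal (SD 0.05, clipped to [0, 1]) applied only to
assays with a non-zero archetype mean: an assay with no underlying
response reports exactly 0, keeping active-assay counts faithful to the
archetype.  CI bounds are med ∓ the noise SD, clipped and order-correct.
With zero noise the whole pipeline is exactly enumerable — planted
partition, confusion counts, and triage category counts are reproduced
bit-for-bit, and the tests assert this.

What the generator does **not** emulate: correlation between structural
cluster and assay archetype (archetypes are drawn independently of
cluster, so the synthetic prevalence partition is flatter than real
inventories, where activity concentrates in a few chemical classes);
heavy-tailed cluster-size distributions; missing assay values; and any
relationship between fingerprint bits and mechanism.  Passing tests
demonstrate the pipeline's correctness and the triage rules' behaviour
under the planted archetype mixture, not field performance on a real
inventory.

## Numerical choices and problem sizes

* Quantiles: linear interpolation (`numpy.quantile` default).
* Threshold comparisons: call active iff AUC ≥ threshold; assay-activity
  counting strictly greater than the floor; quartile rule strictly less.
* Zero-denominator ratios: NA, excluded from averages.
* Seeds: every stochastic step requires an explicit seed; the pipeline
  derives independent child seeds from the config seed via
  `numpy.random.SeedSequence`, and reruns are byte-identical.
* Default problem sizes (universe 200, tested 160; filter-efficiency
  checks on 600 archetype draws; three seeds for stochastic bands) keep a
  full run in seconds while leaving enough counts for stable fractions.

## Known limitations

* Cut-height and dialect sensitivity: cluster counts at a fixed height
  differ between `ward_d` and `ward_d2`; any reported cluster count must
  name the dialect and height.
* The antagonist flag is an input (from the reference pathway model); no
  antagonist model is fit here, and the triage treats the flag as ground
  truth.
* Balanced accuracy on small clusters is dominated by single chemicals
  (a 10-chemical cluster with one inactive member has specificity 0 or 1
  only); the per-cluster report should be read alongside cluster sizes.
* Real fingerprint generation from structures (SMILES → substructure
  bits) is out of scope; fingerprints are consumed as a ready matrix.
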