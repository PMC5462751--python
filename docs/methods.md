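# Methods

## Model and assumptions

The scorer is a hyper-ensemble: *n* probabilistic random forests, each
trained on a balanced resample of the data, whose probability-of-deleterious
outputs are averaged. The design rests on three assumptions that hold for
variant-prioritization feature spaces:

- positives are scarce but locally coherent, so synthetic positives made by
  linear interpolation between Euclidean-near positives (SMOTE) are
  realistic — this fails for categorical or strongly non-convex feature
  manifolds, which is why the generator used for testing is a Gaussian
  mixture, where segments between neighbours stay on-distribution;
- negatives are abundant and redundant, so partitioning them across base
  learners loses little information per learner while the union keeps
  coverage high and makes the learners diverse;
- averaging probabilities across diverse, individually accurate ensembles
  is more robust than any single learner (the hyper-ensemble step).

Training set per partition: all positives, plus *f* synthetics per
positive, plus min(*m*(*f*+1)|P|, |Nᵢ|) negatives drawn without replacement
from partition *Nᵢ*. When the partition cannot supply *n*ₑₓ negatives the
whole partition is used and a warning is emitted; sampling with replacement
would bias trees toward duplicated negatives.

## Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| n | negative partitions = base forests | 10 | coverage/diversity trade-off at desk scale; more helps slowly |
| f | synthetics per positive | 2 | triples the effective positive count without flooding the space |
| m | negatives per positive+synthetic | 3 | exploits more negatives per learner while staying near-balanced |
| k | SMOTE neighbours | 5 | standard SMOTE locality; clamped to \|P\|−1 for tiny P |
| n_trees | trees per forest | 10 | the committee of n forests supplies the ensemble size; 10×10 trees total |
| max_features | per-split feature sample | sqrt(d) | standard random-forest default |
| separation (generator) | centroid distance, units of within-class SD | 2.5 | learnable but imperfect signal; 0 = exact null, ≥4 ≈ ceiling |

Interpolation weight λ is uniform on the unit interval and endpoint draws
(exact duplicates) are allowed; each of the *f* repetitions redraws both
the neighbour and λ. Neighbour ties at equal distance break by ascending
row index, making every SMOTE run fully reproducible. A positive set of
size 1 cannot be interpolated: the point is duplicated *f* times with a
warning, preserving the *f*·|P| cardinality contract.

## Seed policy

One master seed feeds a `numpy` `SeedSequence`; the partition shuffle and,
per partition, the SMOTE draws, the negative subsample and the tree growth
each get independent spawned streams. Results are therefore identical
whether base learners are trained serially or in parallel, and every CV
fold derives its own sub-seed from the master seed and fold id, so fold
order is immaterial and reruns are byte-identical down to the output files
(fixed `%.10g` float formatting).

## Cross-validation schemes

Random folds leak in genomics: physically close variants share features.
Three schemes keep genomic units atomic:

- **Cytoband-aware**: bands with ≥1 positive are assigned greedily
  (descending positive count, to the currently positive-lightest fold, ties
  by band name), bounding the fold-total spread by the largest band's
  positive count; empty bands are assigned uniformly at random; every
  variant inherits its band's fold. Only positives are balanced; negative
  counts per fold are left to chance.
- **Topologically-aware**: negatives are kept only within ±window bp of a
  positive (closed interval, same chromosome) or inside a TAD containing a
  positive; overlapping windows are merged and each merged window /
  positive-bearing TAD is one fold, so metrics rank each positive against
  its matched negatives. A locus inside several overlapping candidate
  regions joins the fold of its nearest positive. Positives with no matched
  negative are retained with a warning.
- **Progressive subsampling**: negatives sorted by genome order
  (chromosomes 1..22, X, Y, MT, then position) and picked every
  s = ⌊|N|/target⌋-th, so density falls while first-to-last coverage is
  preserved — the instrument for imbalance sweeps at 1:1 … 1:1000.

Out-of-fold scores are pooled (not per-fold averaged) before computing
metrics. Every CV run records per-fold train/test index sets, and an audit
rejects any overlap or double-scoring; the audit is itself tested with a
deliberately planted leak.

## Metrics

AUPRC uses non-interpolated average precision (mean of precision at each
positive's rank under a stable descending sort); linear interpolation of
the PR curve would overestimate. AUROC is the exact Mann–Whitney
probability with half credit for ties. F-score is F1. Sensitivity-vs-
quantile reports the fraction of positives inside the top ⌈q·T⌉ of the
ranking. With zero predicted positives, precision is reported as 1.0 and
flagged rather than dropped, keeping threshold sweeps rectangular.

## Feature transforms

For chromatin-effect probability pairs, `diff` = |P(ref) − P(alt)| and
`logfold` = |logit P(ref) − logit P(alt)| (natural log; the base is
irrelevant after standardization). Probabilities are clipped at 1e-6 from
both ends so logits stay finite. Column order is fixed (all diffs, all
logfolds, then conservation columns) so serialized matrices reproduce
byte-for-byte. Standardization is global (population variance), matching
how such feature sets are normalized before analysis; fitted means/scales
are returned for reuse on new variants, and a train-only workflow is
available by standardizing the training matrix and applying its parameters.
Constant columns map to zero with scale 1, keeping the transform
invertible.

## What the generator emulates — and what it does not

The generator reproduces the *structure* of the real problems: extreme
imbalance, sub-clustered positives (so SMOTE locality matters), genomic
coordinates with band-atomic fold validity by construction, and
chromatin-probability pairs with a controllable effect fraction. It does
not emulate real linkage structure, feature correlation across chromatin
marks, annotation sparsity, or ancestry-dependent allele frequencies.
Passing tests therefore demonstrate the algorithmic contracts and the
relative imbalance-robustness of the method, not absolute performance on
real cohorts.

Positive sub-clusters have unit within-cluster SD, equal to the negative
class, so zero separation yields exactly identically distributed classes —
a true null under which cross-validated AUROC sits at chance (verified
within ±0.05 over 5 seeds). The cost of that choice is that no finite
separation makes the task trivially easy: at separation 4 and 1:10 the
cross-validated AUPRC plateaus around 0.74 (AUROC ≈ 0.95) with the default
10-tree forests, which the test suite freezes as the strong-signal
reference point.

## Problem sizes used in the shipped experiments

The acceptance script and the imbalance-trend test use 40 positives,
d = 10, 3 sub-clusters, separation 2.5, negatives grown 1:1 → 1:1000 by
genomic thinning from a single 40,000-negative cohort, 5-fold cytoband CV,
and default learning parameters; trend claims are counted over 10 master
seeds, script quantities averaged over 5 replicate cohorts. These sizes
reproduce the qualitative imbalance behaviour while keeping a full run in
the minutes range on one CPU.

## Known limitations

- The method has many coupled learning parameters (n, f, m, k, forest
  settings); defaults are sensible for hundreds of positives but are not
  auto-tuned.
- Hy scores are committee means, not calibrated probabilities.
- SMOTE assumes continuous features; one-hot or ordinal columns would be
  interpolated as if continuous.
- The matched-negative builder loads interval tables into memory; it is
  meant for 10³–10⁵ regions, not whole-genome base-pair resolution.
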