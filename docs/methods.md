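# Methods

## Problem setting

A phosphorylation-site predictor decides, for each serine, threonine or
tyrosine in a protein, whether the surrounding sequence context resembles
the contexts of experimentally verified phosphosites.  The unit of analysis
is the 25-residue window from offset −12 to +12 around the candidate
residue.  Windows that run past a terminus are completed with a reserved
pad symbol `-`; the pad is not one of the 20 amino acids and is excluded
from every count, denominator and distance position, so the 400-pair CKSAAP
space and the AF simplex are unaffected by truncation.  Non-standard
residue codes (B, J, O, U, Z, `*`) are collapsed to the wildcard `X`, which
is treated like a pad in all encodings.  User-facing coordinates are
1-based inclusive; internals are 0-based.

## Dataset construction

Positives are annotated sites; negatives are annotated negative sites or,
when none are given, every unannotated S/T/Y in the supplied proteins.
"Redundancy" removal is exact 25-mer identity within a class, keeping the
first occurrence in (protein, position) order; identical windows appearing
in both classes are kept and logged as conflicts, since deleting either
would silently change the class priors.  An optional accessibility table
restricts negatives to solvent-inaccessible residues (buried residues
cannot be reached by kinases, so they are the most trustworthy negatives);
negatives without a flag are dropped and counted.

Splitting holds out a per-class fraction (default 1/3) as an independent
test set, then downsamples whichever training class is in excess of the
requested (+):(−) ratio; positives are never upsampled.  The split unit is
the site; a protein-level split (`by_protein`) is available for users who
consider same-protein sites a leakage channel.

## Encodings

* **AF** (20 dims): residue frequency over the non-pad, non-wildcard
  characters of the window.  Values are rationals with denominator ≤ 25.
* **CKSAAP** (400·(k_max+1) dims, k_max = 5 → 2400): for spacing k, every
  position pair (i, i+k+1) whose members are both standard residues
  contributes to `N_total,k`; the feature is `N_ab,k / N_total,k`.  The
  candidate residue itself participates in the counts — nothing about the
  method requires excluding it, and the center-adjacent pairs carry real
  signal (e.g. the S-P pair of proline-directed kinases).
* **KNN** (7 dims): the similarity matrix is BLOSUM62 over the standard 20
  residues, min-max scaled to [0, 1] (an affine map, so similarity order is
  preserved and the extremes are exactly 0 and 1).  The distance between
  aligned windows is one minus the mean similarity over positions where
  both windows have standard residues.  For each fraction f of the
  reference-set sizes, k = max(1, round-half-away(f·n)); the feature is
  (mean of the k nearest negative distances) / (mean of the k nearest
  positive distances), so larger values mean the query sits closer to the
  positive class.  Neighbor ties break by reference order (stable sort).
  A query that duplicates reference windows can make the positive mean 0;
  the ratio is then set to a configured cap (default 100, far above the
  O(1) scale of real ratios) and logged, or to 1 when both means are 0.
  During training and cross-validation the query is removed from its own
  reference class by (protein, position) key (`exclude_self`), preventing
  self-match leakage; at prediction time novel queries need no exclusion.

Combined schemes concatenate blocks in the fixed order AF, CKSAAP, KNN.
Feature identifiers (`AF:R`, `CK:SP:k0`, `KNN:f0.01`) make saved layouts
auditable.

## Relief-F selection

The combined schemes are reduced to fixed target dimensions (AF-KNN 27,
i.e. no reduction; AF-CKSAAP 952; CKSAAP-KNN 939) by two-class relief-F:
for each instance, the k = 10 nearest same-class and other-class neighbors
(Euclidean distance on range-scaled features) update each feature's weight
by mean miss-difference minus mean hit-difference.  Constant features have
zero range, contribute no difference and keep weight exactly 0.  The top-d
features by weight are retained in layout order, ties broken by layout
position, so selection is a deterministic function of the weights.  The
retained dimensions are configuration defaults, not thresholds on the
weights: they pin the dimensionality of each combined scheme while leaving
the ranking entirely data-driven.  Selection is fitted on training folds
only and frozen for held-out data; fitting it once globally would leak
test-fold label structure into the selected features, so no global mode is
offered.

## Classifiers and pipeline

The pipeline is encode → min-max scale (parameters from training data) →
relief-F top-d (combined schemes) → fit.  Scaling is applied for every
family: the RBF kernel and neighbor distances need comparable feature
scales, while tree splits are invariant under any strictly monotone
per-feature map, so the trees are unaffected.

* **SVM** (flagship): RBF kernel, defaults C = 1, γ = 1/d with d the
  retained dimension.  `tune=True` runs an inner stratified 3-fold grid
  search (C ∈ {0.1, 1, 10, 100}, γ ∈ {4^j/d, j = −2…2}) selected by MCC.
  The decision score is the signed margin.
* **RF**: 100 trees, floor(√d) candidate features per split; score = the
  fraction of trees voting positive.
* **DT**: Gini criterion, fully grown; score = positive proportion of the
  reached leaf.  Encoded vectors are complete by construction, so no
  missing-value handling exists anywhere in the pipeline.
* **KNNC**: k = 5; score = positive-neighbor fraction.

Labels are positive iff score ≥ threshold, ties positive.  The default
threshold is family-dependent — 0 for the SVM margin, 0.5 for the [0, 1]
vote/proportion scores — because a single 0 default would label every
fragment positive for the latter three families.  The threshold is
user-adjustable everywhere (`threshold` argument, `--threshold` flag).

Models persist as a single schema-versioned joblib archive containing the
fitted classifier, encoding/selection/classifier specs, scaler parameters,
retained feature identifiers, the KNN reference fragments when the scheme
needs them, and the training keys used by the holdout-overlap guard.

## Evaluation

Sn, Sp, ACC and MCC follow the standard confusion-matrix definitions, with
MCC = 0 by convention when its denominator vanishes (logged).  ROC curves
are built from continuous decision scores with a threshold at every
distinct score (tied scores form one operating point) and AUC by the
trapezoidal rule, which equals the tie-corrected rank-sum statistic.
Cross-validation is stratified 10-fold with shuffling; every fitted
component, including KNN references, is confined to the training folds.
Fold confusion counts are pooled (micro-averaged) for the headline metrics
— at unbalanced ratios some folds have too few positives for a stable
per-fold MCC — and per-fold metrics are also reported.  Independent
evaluation refuses any test fragment whose (protein, position) key appears
in the model's training set, and reports per-residue (S/T/Y) breakdowns
alongside the pooled numbers.

## Synthetic data

The generator emulates the statistical structure the encodings are built
to detect, not rice biology.  Negatives are i.i.d. windows from a
background composition (default uniform over the 20 residues) with the
center drawn from an S/T/Y distribution whose default (0.85, 0.12, 0.03)
approximates the observed abundance of phospho-S/T/Y substrates in rice.
Positives additionally receive positional motifs (residue written at an
offset with a given probability) and pair motifs (rejection tilt: a
candidate with c copies of the pair is accepted with probability
min(1, m^(c−2)), which enriches the pair by ≈ m when the background pair
probability is small; the achieved enrichment is logged and infeasible
multipliers are rejected up front with the achievable bound).  The standard
strong-signal conditions — P at +1 with probability 0.95, R at −3 and K at
+3 with probability 0.8, S-P pair at k = 0 enriched 3× — imitate
proline-directed plus basophilic kinase preferences and were fixed once as
the package's benchmark conditions.

What passing synthetic benchmarks does *not* show: real phosphosite signal
is weaker, kinase-family-structured and correlated with disorder and
composition biases that the i.i.d. background lacks; absolute metric values
on synthetic data therefore say nothing about accuracy on real proteomes,
only that each pipeline stage recovers the kind of signal it is designed
for.  One consequence observed on the standard conditions: the planted
motifs are near-deterministic single-position features, which axis-aligned
tree ensembles exploit optimally, so the random forest can edge out the
tuned SVM there even though SVMs dominate on real phosphosite data with
diffuse signal.

The protein generator embeds the windows into background proteins at
non-overlapping recorded positions (optionally truncated at the N-terminus
to exercise pad handling), producing FASTA + site tables that drive the
whole pipeline end-to-end.

## Benchmark problem sizes

The shipped benchmark (tests and `scripts/acceptance.py`) uses 500 + 500
fragments, 10-fold cross-validation, and five seeds for the null check —
large enough that CV MCC on strong signal stabilizes to ±0.02 across seeds
while the full run stays at minutes on a single core.  Unit tests use 60 to
250 fragments per class.

## Known limitations

* The KNN encoding is O(n²) in dataset size per cross-validation fold;
  at the shipped sizes this is seconds, but it is the binding cost for
  datasets in the tens of thousands.
* Negatives drawn from unannotated residues are inevitably contaminated
  with unobserved true sites; the accessibility filter mitigates but cannot
  remove this.
* Hard-margin reproduction of any particular external SVM's decision
  values is not attempted; solver tolerance alone perturbs scores at the
  1e-3 level.
* No kinase-family-specific models, probability calibration, PSSM/one-hot/
  physicochemical encodings, or alternative selectors (mRMR, lasso).
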