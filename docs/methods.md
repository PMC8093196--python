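# Methods

## Problem and model

The package scores pairs of sequence-aligning genomic regions from two
species for evidence of conservation at the functional-genomics level.
The supervised framing: positives are aligning pairs derived from a
pairwise genome alignment; negatives are the same regions randomly
re-paired so that neither member aligns to the other. The classifier sees
only per-species functional-genomics annotations — never sequence or the
alignment itself — so any separation it achieves reflects cross-species
dependence of functional annotations at aligning loci.

The classifier is an ensemble of pseudo-Siamese networks: two
species-specific branches (shared structure, distinct weights) feed a
combining subnetwork that emits a probability. The ensemble mean is the
score. Key modeling commitments:

* **Negatives as derangements.** Mismatch negatives are a permutation of
  the positive B-regions over the A-regions with all true alignment
  partners forbidden (random shuffles with bounded retries, residual
  collisions fixed by pairwise swaps). This matches every feature's
  marginal distribution between classes exactly — asserted in tests — and
  is what guarantees a purely marginal model (logistic regression) scores
  at chance. One negative per positive; class imbalance is expressed by
  the 50× negative loss weight, not by example counts. A genome-background
  variant samples both members uniformly instead.
* **50× negative weighting.** Weighted binary cross-entropy with weight 1
  for positives and `w_neg = 50` for negatives. This makes high scores
  demanding: most aligning windows score low, and the random-expectation
  AUPRC of the weighted precision-recall curve is 1/(1+50) = 1/51 ≈ 0.02.
  Validation AUROC for early stopping is computed unweighted.
* **Chromosome-disjoint splits.** Train, validation and test roles are
  per-species chromosome sets, pairwise disjoint; a pair enters a role
  only if *both* its chromosomes belong to it. The default scheme trains
  on alternating odd chromosomes, validates on the remaining odds, tests
  on evens; `chrX`-style chromosomes are excluded from fitting but covered
  by prediction. Genome-wide scores come from two complementary ensembles
  (odd-trained / even-trained), each scoring only pairs whose chromosomes
  it never saw.
* **First-base featurization.** Annotations are read at the first base of
  each ≤ 50-bp region and represent the whole region (a per-base mode
  exists for base-resolution scoring). Peak overlap uses half-open BED
  semantics; segmentation gaps encode all-zero one-hots rather than
  erroring; the species-wide signal min/max is computed once over all
  signal tracks jointly, persisted with the schema, and out-of-range
  prediction-time values clip to [0, 1].

## Network and optimization

The architecture text leaves optimizer, activation and initialization
open; the package fixes them as ReLU activations, He-uniform
initialization, inverted dropout after every hidden layer, and Adam, all
recorded in the model artifact. The loss is computed in logit space
(softplus form), so no probability clamping is needed during training; the
standalone per-example loss helper clamps at 1e-12. Training stops when
validation AUROC fails to improve for 3 consecutive epochs (the
best-epoch weights are kept), at 100 epochs, or at a per-member wall-time
cap. Member k of an ensemble derives its subset-sampling and
initialization seed from `config.seed + k`; identical seeds reproduce
identical weights on fixed hardware.

Predictions are evaluated in fixed-size zero-padded chunks of 512 rows.
BLAS selects kernels by matrix shape, so variable batch sizes can change
the last ulp of a dot product; fixed-shape chunks make every score
bit-identical regardless of how predictions are batched, which the
neighborhood-max invariant (W = 0 equals the plain score exactly) relies
on.

Default desk-scale profile: K = 10 members, up to 2×10⁴ examples per
class per member, 10 hyper-parameter candidates; branch/final widths
(32,)/(32,), batch 64, learning rate 3e-3, dropout 0.1. The paper-scale
profile (K = 100, 10⁶ per class per member, 100 candidates) is retained as
`TrainingConfig.paper_profile()`. The shipped hyper-parameter search space
is a documented default, not a claim about any particular published space.

## Baselines

Logistic regression and a random-forest ensemble consume concatenated
(A, B) vectors under the same subset/weighting protocol (grid search over
regularization strength for the former, random search over forest
hyper-parameters for the latter; both via scikit-learn). The
single-species baseline is a fully connected network on species-A features
with its own labels — does this region align at all — and rejects datasets
carrying species-B features.

## Scoring variants

The neighborhood-max score re-pairs an A-region with 50-bp B-windows
stepped at 50-bp increments from the aligning B-region's first base out to
a symmetric width W (W not a multiple of the step truncates the outermost
window; windows crossing a chromosome end are dropped). W = 0 reproduces
the plain score exactly, and the result is non-decreasing in W by
construction. Text outputs (bedGraph on genome A plus a paired-coordinate
TSV) print scores at 6 decimal places and never merge adjacent equal-score
windows.

## Evaluation statistics

Weighted AUROC/AUPRC use scikit-learn with per-example weights and are
cross-checked in tests against an exhaustive weighted pairwise-comparison
oracle (ties one half) and a step-curve average-precision oracle. The
weighted Jaccard similarity over tissue-group activity fractions,
Σ min(h_i, m_i)/Σ max(h_i, m_i), raises a flagged exclusion on a zero
denominator rather than returning a value. Chromatin-state frequency
correlations report undefined states as missing, not zero. Variant
enrichment uses equal-width score bins against a uniform background over
all scored regions, a one-sided exact binomial tail per bin, and no
multiple-testing correction (raw thresholds are the caller's choice).
Mann-Whitney comparisons use the exact distribution for small groups and
the tie-corrected normal approximation otherwise. The windowed-mean filter
drops windows with *strictly less than* half their bases annotated, so
exactly-half windows are retained.

## Synthetic data

The generator emulates a two-species compendium with a latent-activity
model: each 200-bp segment carries a categorical state (quiescent /
enhancer-like / promoter-like, background probabilities 0.55/0.25/0.20)
and a Beta-distributed intensity in [0, 1]. Within aligned blocks, runs of
species-B bases mapping into one species-A segment inherit that segment's
state and (slightly perturbed) intensity with probability ρ — the planted
concordance — and draw independently otherwise. Observed tracks are
emissions: peak tracks threshold intensity × a state-class affinity with
assay-noise flips (rate 0.1), so at zero noise peaks are a pure function
of the latent; segmentations map the latent state to one of five labels
with noise; signal is 10× intensity plus Gaussian noise. Aligned species-A
segments get a mild (1.5×) bias toward active states, which gives the
single-species baseline a learnable signal and supports a planted variant
enrichment (4× rate in active aligned segments).

Defaults — 4 chromosomes × 1 Mb per species, 2000 alignment records of
200–800 matched columns with ~1% gap columns on a syntenic layout
(chromosome i aligns to chromosome i, mirroring mammalian large-scale
synteny and keeping every chromosome-parity split populated), 6 peak
tracks over 3 tissue groups, 2 epigenomes × 5 states, 1 signal track per
species — generate in about 2 s and yield ≈ 26,000 positive windows. A
`concordance_audit` estimates ρ from the latent truth, correcting raw
cross-species agreement for chance via the empirical state marginals; it
recovers planted values within ±0.03 at these sizes.

What the generator does *not* model: realistic sequence evolution,
assay-specific noise structure, correlated experiments, chromatin-state
transition structure, or copy-number/duplication geometry. Passing tests
therefore demonstrate that the pipeline recovers planted cross-species
dependence under controlled conditions — not performance on real
compendia, whose headline numbers depend on data volumes (thousands of
tracks, millions of pairs) far beyond a test fixture.

## Numerical and design choices

* Coordinates are 0-based half-open internally; axt's 1-based inclusive
  headers and reverse-complement minus-strand query coordinates are
  converted on read (query chromosome sizes are required for the latter;
  the conversion is an involution, tested by round trip).
* Best-partner resolution keeps the highest-scoring block among
  A-overlapping candidates; ties break by (score, lower B chromosome,
  lower B start) for determinism.
* Negatives are generated within each split role separately, so marginal
  matching holds exactly inside every role.
* Equal-width binning puts the maximum score in the top bin; percentile
  binning resolves ties by stable rank and requires k distinct scores.
* Positional lookup uses sorted-array bisection per chromosome (merged
  intervals for peaks; non-overlap enforced for segmentations/signal).

## Known limitations

Training is CPU-only and single-threaded by design; the paper-scale
profile is supported but slow. The score is only defined where the
alignment is; scoring arbitrary non-aligning pairs is deliberately limited
to the neighborhood operation, since unrestricted application degrades
specificity. Hyper-parameter search defaults are small; serious use should
widen them. The logistic/forest baselines inherit scikit-learn's threading
defaults (pinned to one job for reproducibility).
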