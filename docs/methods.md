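# Methods

## Series model

Each assemblage (one butchered carcass, or one archaeological site) is
summarised as a numeric series over the four major long bones.  Every bone
is divided into `n_bins` equal segments along its proximo-distal axis;
cut-mark positions — fractions of bone length in [0, 1] measured from the
proximal end — are assigned to half-open bins `[i/n, (i+1)/n)`, with
position 1.0 joining the last bin.  The per-bone vectors are concatenated
in the fixed order humerus, radius, femur, tibia (forelimb before hindlimb,
stylopod before zeugopod).  Elements digitised distal-end-first (the tibia,
in the scanning convention of the source data) are flagged in their
`BoneTemplate` and reversed at ingestion, so index 0 of every block is
always proximal.

`n_bins` defaults to 30 (series length 120).  The reference classifier
configurations imply a series length of at least 119 (a BOSS window of 119,
WEASEL window sweeps up to 110); 120 is the smallest round length
consistent with both, and the value is configurable throughout.  Missing
elements contribute zero blocks rather than an error: differential
preservation of long-bone portions is a real feature of archaeofaunal
assemblages.

Two representations are derived from the same counts: **raw** (per-bin
counts; carries overall mark intensity, which is higher under bulk
defleshing of complete carcasses) and **relative** (per-bin percentage of
the assemblage total, summing to 100; carries anatomical patterning only).
An all-zero assemblage has no defined patterning, so its relative transform
is an explicit error rather than a NaN vector.

## Synthetic generator

The generator emulates the structure that distinguishes the two butchery
scenarios, not any particular experimental assemblage:

* **Exclusive zones** — proximal half of the humerus, proximal half and
  distal quarter of the femur.  These portions carry flesh only on a
  complete carcass; secondary-access series are identically zero there by
  construction, which is the feature that makes the two classes formally
  separable.
* **Shared zones** — proximal and distal metadiaphyses of all four bones
  (bins [n/6, n/3) and [2n/3, 5n/6), minus any overlap with the exclusive
  bands).  Both classes mark them; class P at a higher rate
  (`rate_shared_primary = 3.0` vs `rate_shared_secondary = 1.5` expected
  marks per bin), reflecting more extensive meat removal.
* Mid-shafts are quiet in both classes.

Counts are independent Poisson draws per bin — the simplest count law
consistent with rate-based clustering; overdispersion is deliberately not
modelled, to keep the null simple.  `rate_exclusive_primary = 3.0` by
default; setting it to 0 with equal shared rates yields the negative
control in which the two classes are distributionally identical and every
classifier must fall to chance.  An optional per-element dropout
probability (default 0) zeroes whole bones, emulating preservation bias.
Default sample size is 40 carcasses per class.  All sampling flows through
an explicit `numpy` generator seeded from the configuration; identical
configurations produce bitwise-identical datasets.

What the generator does **not** emulate: correlated mark placement within
a butchery stroke, inter-carcass size effects, taxon differences,
carnivore ravaging sequences, mark morphology.  Passing tests therefore
demonstrate that the pipeline recovers the zone/intensity structure when it
is present — not that real experimental assemblages are this clean.

## Augmentation

**Within-class combination** sums k (default 2) distinct same-class
carcasses into each new case, drawing constituents without replacement so a
sample is never combined with itself.  Summation is the natural operation
for count series: totals add exactly, and raw/relative duality is
preserved.  Constituent ids are recorded as provenance; labels are never
mixed.

**GAN** — one generator/discriminator pair per class, fully-connected
(latent dim 16, two hidden layers of 64, ReLU / leaky-ReLU 0.2, sigmoid
outputs), binary cross-entropy loss, Adam (lr 1e-3), implemented directly
on numpy with manual backpropagation so that training is exactly
reproducible from a seed.  Training series are scaled to [0, 1] by per-bin
maxima; generated outputs are clipped to be nonnegative and un-scaled by
the same maxima.  A consequence worth noting: bins that are identically
zero in the training class (the exclusive zones of class S) have zero
scale, so generated secondary carcasses can never place marks there — the
augmentation cannot corrupt the class-defining feature.  Raw-mode outputs
are left real-valued (classifiers consume real vectors; rounding would add
unmodelled noise); relative-mode outputs are renormalised to sum to 100.

Because the generator's classes are clean Poisson profiles, the GAN's
samples regress toward the class prototypes rather than widening
within-class variance.  Classifiers trained on GAN-augmented sets
consequently score as well as — occasionally one test sample better than —
those trained on combination-augmented sets on this synthetic data.  The
degradation observed on real experimental data (where an adversarially
learned latent space broadens genuinely heterogeneous classes) is therefore
*not* reproduced here, and the directional test documenting that signature
is expected to fail for BOSS VS; see the test suite.  This is a property of
the clean simulation, not of the augmentation code.

## Classifier families

All symbolic transforms are implemented in the package; generic model fits
behind them (logistic regression, linear SVM, random forest, MLP) use
scikit-learn.

* **1-NN DTW** — unconstrained dynamic time warping with squared local
  cost (numba-compiled DP).  Probability is the vote fraction of the
  predicted label (always 1.00 at k=1); vote ties break by smaller summed
  distance, then fixed class order.
* **SAX-VSM** — sliding windows (default length L/4, the window length
  being otherwise unspecified in the reference configuration), z-normalised
  per window, PAA to 6 segments, Gaussian-breakpoint alphabet of 2;
  numerosity reduction; per-class bags weighted by tf-idf; cosine
  similarity.  Per-window z-normalisation makes verdicts invariant to
  rescaling the query.
* **BOSS** — windows of length 119, z-normalised, DFT with the mean
  coefficient dropped, first 4 coefficients discretised by per-coefficient
  quantile edges (MCB) learned on training windows; numerosity-reduced
  bags compared by the asymmetric BOSS distance (1-NN) or fed to a linear
  SVM.  The alphabet defaults to 2: with a single long window each bag
  holds at most two words, and a finer alphabet makes novel query words —
  which tie against the entire training set — common.
* **BOSS VS** — SFA words at word sizes {2, 3, 4} (alphabet 2), class-merged
  bags, tf-idf class vectors, cosine; majority over word sizes, ties to P.
  The window length is selected by leave-one-out accuracy on the training
  set over a grid of series-length fractions (L/6 … 3L/4), as in the
  algorithm's published formulation.
* **WEASEL** — for every window length in 5…110 (raw) or 5…80 (relative),
  non-z-normalised windows, equi-depth MCB, unigrams and bigrams (words one
  window-length apart) tagged by window size; χ² scores against the labels
  on training counts, top decile retained; liblinear logistic regression on
  the sparse counts.
* **MTF** — amplitudes quantile-binned into 6 states (5–7 supported), the
  row-normalised first-order transition matrix projected back onto all
  time-point pairs, block-averaged to a 12×12 image (`image_size = 0.1`);
  flattened pixels classified by logistic regression or a 100-tree random
  forest, which report a class probability.

### tf-idf weighting

Two weightings are implemented for the vector-space families.  The strict
form (tf × log(n_classes/df)) zeroes every word that occurs in all class
corpora.  At the reference configurations the entire vocabulary is at most
16–64 words and both classes use all of them, so strict idf zeroes *every*
weight and pins the classifier at chance; BOSS VS and SAX-VSM therefore
default to the smoothed sublinear form (1 + log tf) × log(1 + n_classes/df)
of the published BOSS-VS formulation, with the strict form retained as an
option.

### Numerical conventions

Z-normalisation of a zero-variance vector returns zeros (SAX then emits the
degenerate all-lowest-symbol word).  A PAA segment value exactly on a
breakpoint takes the lower symbol; an MCB coefficient exactly on an edge
takes the upper bin.  MTF transition-matrix rows with no observed outgoing
transition become self-loops (absorbing states), keeping the matrix
row-stochastic without spreading probability to unvisited states; a
constant series yields an all-ones field and a strictly increasing series a
{0, 1} field.  Every label tie anywhere in the package resolves to the
fixed class order (P before S): determinism over hidden randomness.

## Ensembles

Five MLP base learners (two hidden layers; widths (64,32), (48,24),
(32,16), (64,16), (32,32); lbfgs, max 500 iterations; seeds derived from
the ensemble seed) are trained on the relative series.  Stacking is
out-of-fold: a stratified 5-fold split produces base probabilities never
seen by the bases' own training, on which a small MLP meta-learner (one
hidden layer of 16) is trained; per-base out-of-fold accuracy and F1 are
reported.  The majority mode takes the hard argmax vote of the bases; its
probability is the mean base probability of the winning class — a soft
score that explains reported values that are not multiples of 1/5.  Even
splits break by higher mean probability, then fixed class order.  F1 is
computed from confusion counts with class P positive.

## Pipeline

`split` is stratified and seeded.  `run_all` fits every family on both
representations, scores the held-out set, and classifies query assemblages
with models refitted on the full reference set (train + test): held-out
accuracy validates the framework, but unknowns are compared against all
available reference evidence.  A family that raises during fitting is
reported as `"N.C."` (no convergence) without affecting other cells.
`dendrogram` performs agglomerative average-linkage clustering (Euclidean
distance by default; the reference figure names only
"similarity/dissimilarity distances") and cuts the tree into 25 flat
groups, serialising it as Newick via scikit-bio.

## Problem sizes

The test suite and the acceptance script run the full analysis at 40
carcasses per class (the separable fixture), 16 per class × 20 seeds for
the negative control, and 5 seeds for the augmentation comparison; the DTW
oracle is checked exhaustively for all series up to length 3 over the
alphabet {0, 1, 2} and on 1 500 random longer pairs.  These sizes keep a
complete run in the low minutes on one CPU while leaving every check
statistically meaningful at its stated tolerance.

## Known limitations

* The generator's Poisson independence assumption makes classes cleaner
  than real butchery data; accuracy figures on synthetic fixtures are
  upper bounds, not estimates of archaeological performance.
* The GAN is a minimal fully-connected pair; it demonstrates the
  augmentation mechanics and its contracts, not state-of-the-art sample
  diversity (see Augmentation above).
* Only the four major long bones are modelled; metapodials and axial
  elements are out of scope, as is mark morphology (cut vs tooth vs
  trampling) and any 3D surface information beyond the longitudinal
  coordinate.
* Epiphyseal vs shaft-only binning and absolute-length differences between
  elements are abstracted away: bins are relative to each bone's own
  length.
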