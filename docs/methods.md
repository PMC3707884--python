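# Methods

## Problem and model

`orfsvm` frames coding-potential assessment as binary classification of
nucleotide sequences. The positive class is "reads like a verified
protein-coding ORF", the negative class "reads like intergenic sequence".
The discriminant is a linear SVM over frame-aware composition statistics;
linearity is deliberate: with thousands of training sequences and a
4682-dimensional representation, a linear kernel is both sufficient and the
only option that keeps the per-dimension weights interpretable.

### Feature encoding

All six encoders read the frame beginning at the first base of the stored
sequence. For negatives (intergenic runs) this frame is arbitrary, which is
the point: the classifier learns that genuine ORFs carry in-frame structure
that arbitrary frames of background sequence lack. Trailing 1–2 bases past
the last full codon are ignored; codons containing any character outside
{A, C, G, T} are dropped from every numerator *and* denominator, so
ambiguity codes shrink the effective sample rather than distorting
frequencies.

The blocks and their normalisation groups:

1. **Positional mono-nucleotide** (12): base frequency at codon positions
   1–3; one group of 4 per position.
2. **Positional di-nucleotide** (48): pairs at positions (1,2) and (2,3)
   within a codon and the cross-codon pair (3, next 1); one group of 16
   each. The cross-codon group does not wrap from the last codon to the
   first.
3. **Mono-codon** (64) over non-overlapping in-frame codons.
4. **Di-codon** (4096) over adjacent codon pairs.
5. **Mono-amino-acid** (21): codons translated by the standard genetic
   code with the three stop codons collapsed onto a 21st symbol `*`, so
   termination usage is counted rather than discarded.
6. **Di-amino-acid** (441) over adjacent residue pairs.

Blocks 4 and 6 slide their two-codon window by one codon (n−1 overlapping
windows), matching the first-order-Markov reading of dicodon usage; a
non-overlapping step (every other codon pair) is available via the
`step=6` switch on the encoders and `dicodon_step` in `RunConfig`. Each
group sums to exactly 1 or is exactly all-zero when it has no countable
window (e.g. cross-codon groups of a single-codon input). Internal stop
codons are counted, not rejected — intergenic negatives necessarily contain
them — and the terminal stop of a real ORF is included in all counts.

Ordering is frozen (`FEATURE_ORDER_VERSION`): blocks by measurement id;
nucleotide k-mers lexicographic over A<C<G<T; amino acids alphabetical by
one-letter code with `*` last. Persisted models record the version tag and
refuse to load under a different ordering.

### Scaling

Per-dimension min–max scaling to [0, 1], fit on training vectors only and
applied unchanged to test vectors (values outside the training range are
not clipped). Dimensions constant in training map to 0 for any input: a
constant feature carries no information and must not explode under a zero
range. Inside cross-validation the scaler is re-fit on each fold's training
part by default (no information leakage); `refit_scaler=False` reproduces
the cheaper fit-once-globally variant.

### Classifier

`sklearn.svm.LinearSVC` (liblinear) with hinge loss in the dual, tolerance
1e-4, capped at 20000 iterations, fixed `random_state`, and class weights
{+1: 1, −1: w_ratio} so the effective costs are C and C·w_ratio. The
direction of w_ratio (negatives over positives) reflects that specificity
is the fragile side of this problem: negatives crowd the margin, so
up-weighting them trades sensitivity for specificity. Defaults
C = 2^−3.5, w_ratio = 2^0.6, the tuned operating point; the grid-search
helper covers log2 C ∈ [−8, 4] (step 0.5) and log2 w_ratio ∈ [−2, 2]
(step 0.2) and breaks ties toward the smaller C, then the smaller
|log2 w_ratio| — the least-regularised-against, simplest model.

Accuracy is defined as (Sn + Sp)/2, the balanced mean, not the pooled
fraction correct; with a 4835-vs-3515-style imbalance the pooled fraction
would overweight the majority class. Cross-validation reports per-fold
Sn/Sp, their means and sample standard deviations (over folds), pooled
confusion counts, and the identities of positives misclassified in their
held-out fold. Fold partitions are stratified and seeded; when k exceeds
the minority-class count (up to leave-one-out) a plain shuffled partition
is used, re-drawn (bounded, seeded) if a training split ever loses a class.

### Dataset construction

External coordinates are 1-based inclusive; conversion to half-open
arithmetic happens only at extraction. Minus-strand ORFs are emitted 5'→3'
on the coding strand. Intergenic negatives are the maximal runs covered by
no annotated ORF of any category, with both strands collapsed onto one
coordinate track, kept only when strictly longer than the threshold
(default 300 bp — short runs carry too little composition signal and the
strict inequality follows the conventional cutoff). Annotation rows with
an unrecognised category are skipped with a logged count and belong to
neither class. The overlap report pairs each candidate ORF with the
reference ORF it overlaps most (≥ 1 bp, same chromosome, either strand)
and summarises the antisense fraction among overlapping candidates —
spurious annotations tend to sit antisense to real genes.

### Retrospective snapshot protocol

Given an ordered series of annotation snapshots: for each adjacent pair,
train only on the older snapshot (its verified ORFs vs its intergenic
runs, full six-feature selection, tuned defaults), predict the older
snapshot's unresolved ORFs, and intersect the predicted-coding set with the
ORFs that are annotated in both snapshots and moved to verified in the
newer one. Coverage = 100 × (hits / newly-verified); the pooled series
value is Σ hits / Σ new. Matching is by systematic name; renames are out of
scope. `n_predicted` counts predicted-coding among *all* of the older test
ORFs, not only those surviving to the newer snapshot.

## Synthetic data

The generator emulates exactly the statistical contrast the features
detect. Coding sequences are ATG + i.i.d. sense codons from a usage table +
one stop codon: never an internal in-frame stop, always a codon-multiple
length. Non-coding sequences are i.i.d. bases at a configurable GC
fraction, lengths not rounded to codon multiples (so the truncation rule is
exercised) and above 300 bp by default, mirroring the negative-set rule.

Signal levels:

* **strong** — heavily tilted codon table (third-position A/T preference,
  G-leading bonus) against a uniform background; near-separable, used for
  pipeline-integrity checks (CV should exceed 99%).
* **yeast_like** — the packaged table `data/yeast_like_codons.yaml`:
  a composition background exponentially tilted toward third-position A/T
  with a G-leading bonus, giving table GC ≈ 0.40 against background
  GC 0.36. The values are illustrative defaults constructed from this
  parametric family, not measured codon usage.
* **null** — both classes drawn from one frame-free base model; only the
  labels differ, so any classifier should sit near 50%. The null
  deliberately drops the ORF scaffold (start/stop, stop-free body):
  a scaffolded "null" would still be separable, because the absence of
  internal in-frame stops is itself one of the strongest genuine coding
  signals — essentially every background sequence longer than ~300 bp
  contains in-frame stops.

For calibration-style tests there is additionally `gc_contrast_benchmark`:
two frame-free base models differing only in GC (defaults 0.40 vs 0.36,
lengths 1800–2400 bp). Its Bayes-optimal rule is the exact base-composition
likelihood ratio, giving a computable error floor (≈ 97% accuracy at the
defaults); the test suite checks that cross-validated SVM accuracy on the
positional-base block lands within 3 points of that floor.

What passing these tests does *not* show: real intergenic DNA is not
i.i.d. (promoters, ncRNAs, repeats), real genes have introns, biased
lengths and correlated codon choice, and real annotations contain errors.
The synthetic results validate the machinery and its statistical behaviour,
not genome-specific accuracy figures, which require a real genome and
annotation as input.

## Numerical and design choices

* Solver determinism: fixed input order + fixed `random_state` makes
  training and CV bit-reproducible for a given seed.
* Model persistence is plain-text JSON (weights, bias, C, w_ratio, scaler
  min/max, selection, ordering tag); reloading reproduces decision scores
  to 1e-10 (double round-trip is exact).
* Sequences shorter than one codon are flagged `unscorable` in prediction
  output rather than dropped, and raise a clear error in direct encoding.
* Degenerate inputs: single-codon sequences produce exactly-zero pair
  blocks; empty intergenic results and empty prediction inputs are valid;
  a training set with one class is an error, not a warning.
* Problem sizes in the shipped tests and the acceptance script (benchmarks
  of 1000–2000 sequences per class, loci with dozens of planted ORFs) were
  chosen as the smallest sets at which the measured quantities are stable
  across seeds.

## Known limitations

* Single reading frame per sequence; no frame search, no intron models.
* Binary linear classification only: no probability calibration, no
  nonlinear kernels, no multi-class evidence categories.
* Annotation parsing covers GFF3 rows carrying an `orf_classification`
  attribute and the seven-column tab dialect; the wider feature-file
  vocabulary of annotation databases is out of scope.
* Snapshot matching is by systematic name; renamed or re-coordinated ORFs
  between snapshots are not tracked.
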