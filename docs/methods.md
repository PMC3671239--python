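# Methods

## Problem and model

`phavip` classifies phage protein sequences as virion (structural,
particle-bound; class 1) or nonvirion (class 0). The model is deliberately
simple and interpretable: composition features, a filter feature selector,
and a naive Bayes decision rule.

### Sequence representation

A sequence of length L over the 20 standard residues is encoded as 420
frequencies: 20 amino-acid frequencies `count(r)/L` and 400 overlapping
dipeptide frequencies `count(xy)/(L−1)`. The dipeptide denominator is the
number of overlapping windows, which makes the block sum to exactly 1;
sequences of length 1 are rejected at encode time rather than given an
all-zero dipeptide block, so the sum-to-one invariant can never be silently
violated. Dipeptides are read N→C, so KE and EK are distinct features (the
shipped benchmark subset contains both directions of several pairs, which
is why directionality matters). The canonical feature order is
alphabetical — A…Y, then AA…YY row-major; no downstream computation depends
on the order because features are always addressed by name.

Sequences containing any letter outside the 20-residue alphabet are
rejected, not just the ambiguity codes B/X/Z: the 420-feature space is
simply undefined for other symbols (J, O, U, gaps, stops). Input policies:
`strict` raises on the first invalid record, `skip` drops and logs each
one, and `mask-reject` additionally refuses soft-masked (lowercase)
residues where the default dialect tolerance would uppercase them.
Redundancy pruning (CD-HIT-style clustering) is a curation step outside
this package; the dataset manifest carries a `redundancy_pruned` provenance
flag only.

### Feature selection

CFS scores a subset S (|S| = k) by
`Merit(S) = k·r̄_cf / sqrt(k + k(k−1)·r̄_ff)`, where `r̄_cf` is the mean
feature–class association and `r̄_ff` the mean pairwise feature–feature
association over distinct pairs. At k = 1 the denominator is 1 and the
merit is just `r_cf`, an explicit convention that avoids 0/0.

Associations are symmetrical uncertainty, `2·I(x;y)/(H(x)+H(y))` with
base-2 logs and SU = 0 when both variables are constant, computed on
features discretized by the recursive Fayyad–Irani MDL criterion (cuts are
midpoints between adjacent distinct values; a split is accepted only when
its information gain exceeds the MDL threshold, so label-independent
features collapse to a single bin and get SU = 0). Absolute Pearson
correlation is available as an alternative association for continuous
work; symmetrical uncertainty is the default.

Search is forward best-first with backtracking: a priority queue of
unexpanded subsets keyed by merit, each expansion evaluating all
single-feature additions, stopping after `stale_limit` consecutive
expansions that fail to improve the global best. The default patience is
5; `math.inf` disables early stopping and runs until the queue is
exhausted. Ties in the queue and among candidates are broken by canonical
feature order, so the search is fully deterministic — two runs on the same
matrix produce identical traces. On problems with at most 12 features the
search (with patience ≥ the feature count) empirically attains the
exhaustive-search merit maximum; this is checked in the test suite, not
guaranteed by the algorithm.

Selection is run inside stratified k-fold cross-validation (k = 10 by
default): one subset per training fold, a consensus of features chosen in
at least ⌈k/2⌉ folds, and held-out naive Bayes accuracy per fold. The
selector itself is fold-agnostic and pure.

### Classifier

Per class and feature a Gaussian is fitted by maximum likelihood; priors
are the training class frequencies (not uniform). The decision statistic
is the log posterior ratio (natural logs); class 1 is called when the score
is ≥ θ, inclusive at the boundary. The log base only rescales θ, so the
choice is documentation, not substance.

Standard deviations are floored at `sigma_min` (default 1e-6; composition
features live in [0, 1]) to keep log ratios finite when a feature is
constant within a class. The floor has a practical consequence worth
knowing: a dipeptide absent from every training row of one class gets
σ = 1e-6 there, and a held-out sequence containing even one occurrence of
it (frequency ≈ 1/L) then contributes a z-score of order 10³–10⁴. With few
training rows per class this divergence dominates the score and degrades
small-sample leave-one-out performance on the full 420-feature space;
around a hundred sequences per class the effect disappears because rare
dipeptides are observed in both classes. Feature selection, which removes
such features, is the principled mitigation.

θ defaults to 0 (maximum a posteriori). `tune_threshold` evaluates the
midpoints between consecutive distinct training scores plus below-min and
above-max sentinels, maximizing accuracy or Youden's J; ties go to the
smallest candidate, making tuning deterministic.

Models persist as a single JSON document (schema version, feature names,
priors, per-class μ/σ, θ, `sigma_min`, provenance checksum), keys sorted
so diffs are reproducible; the save→load round trip is bit-exact.

### Evaluation

Sn, Sp and Acc are kept unrounded internally and rounded half-up to two
decimals only in displays. The jackknife pools all n held-out predictions
into one confusion matrix (micro-averaging) — the convention under which a
published 99/208-benchmark operating point (75/99 positives and 168/208
negatives correct) reproduces Sn 75.76 %, Sp 80.77 %, Acc 79.15 % exactly.
The ROC is built from the continuous log-ratio scores (never from hard
predictions), tied scores collapse to a single point, and the trapezoidal
area equals the Mann–Whitney estimate with ties counted half; both routes
are computed and asserted equal in the tests, with scikit-learn's
`roc_auc_score` as a third, independent cross-check.

## Synthetic data

The generator emulates the statistical shape of a curated two-class
benchmark, not phage biology: class 0 sequences are i.i.d. draws from a
base composition; class 1 sequences are drawn from a shifted composition
in which mass δ is added to a chosen residue set proportionally to their
base frequencies and removed from the rest proportionally to theirs. The
expected per-residue frequency difference is therefore known in closed
form, which is what the recovery tests check against. An optional
first-order Markov term multiplies transitions that form chosen dipeptides
by (1 + γ) with row renormalization, adding dipeptide signal beyond the
marginal shift.

Defaults, chosen once: 100 sequences per class, lengths uniform on 50–300
residues (typical phage protein scale), uniform base composition 1/20
(a neutral background that keeps the configured shift analytically
transparent), δ = 0.15 on {K, E} — mirroring the K/E dominance of the
benchmark-selected subset, so the selection-recovery test is a structural
analogue of the real selection result — and γ = 0. All sampling is a pure
function of the config including its seed; identical configs give
byte-identical FASTA output.

What the generator does *not* emulate: real length and composition
distributions of phage proteomes, homology/redundancy structure between
sequences, domain architecture or any order signal beyond first-order
Markov coupling. Passing recovery tests therefore demonstrates that the
pipeline detects compositional class signal of a known size under clean
conditions; it says nothing about accuracy on real, redundant, fragmentary
protein data.

## Problem sizes used in the checks

The packaged checks run the pipeline at 100 sequences per class (lengths
50–300): at δ = 0.3 on {K, E} the jackknife exceeds 90 % accuracy and 0.95
auROC, at δ = 0 the auROC sits within 0.45–0.55, and best-first selection
recovers a K/E-bearing feature in at least 4 of 5 seeds. Exhaustive-search
equivalence is verified on problems of up to 12 features, where full
enumeration is cheap. The ROC chance-level calibration uses 2000 scores
per class.

## Known limitations

- The Gaussian density is an assumption, not a fit diagnostic; composition
  features are bounded and often zero-inflated, and a kernel-density or
  discretized variant is explicitly out of scope.
- The σ floor interacts badly with class-absent features at small n (see
  above); prefer selected subsets when training sets are small.
- CFS with best-first search is a heuristic: no optimality guarantee exists
  beyond the small-problem empirical checks.
- The consensus-of-folds subset depends on the fold seed; the shipped
  `PUBLISHED_38` constant decouples downstream use from that randomness.
- Multiclass problems, PseAAC-style order-correlation encodings, gapped
  dipeptides and wrapper/embedded selection are out of scope.
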