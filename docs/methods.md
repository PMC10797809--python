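# Methods

## Evidence model

The package works on a frame of discernment Θ = {A₁, …, A_φ}: an exhaustive
set of φ ≥ 2 mutually exclusive hypotheses (in the motivating application,
seven fundus-disease labels). A basic probability assignment (BPA) is a mass
function m with m(A) ∈ [0, 1] and Σ m(A) = 1. All mass functions here are
**Bayesian** — mass lives only on singleton hypotheses. This is a deliberate
restriction: the BPAs of interest are classifier softmax outputs, which never
assign mass to composite subsets, and every worked example the package
reproduces is singleton-only. The 2^Θ power-set machinery (belief/plausibility
intervals, composite focal elements) is out of scope, as are alternative
combination rules (Yager, Murphy, PCR); the rule dispatch is a plain mapping
that could be extended, but no alternative rule ships.

### Dempster's rule and the conflict factor

For l independent sources the combined mass of hypothesis A is

    (m₁ ⊕ … ⊕ m_l)(A) = Π_s m_s(A) / (1 − k),
    k = 1 − Σ_A Π_s m_s(A),

where k ∈ [0, 1] is the conflict factor and (1 − k) the normalization
coefficient. For singleton BPAs the agreement sum runs over single labels —
the only non-empty intersections are "all sources name the same hypothesis".
When k = 1 the denominator vanishes and the rule is undefined (the
complete-conflict paradox); the implementation raises a dedicated
`CompleteConflictError` when the agreement mass is ≤ 1e-12 (exact-zero
products in floating point make a strict equality test meaningless).

Three more classical failure modes ship as packaged fixtures alongside the
complete-conflict case: the **0-trust** paradox (one source assigns a
hypothesis mass 0 and vetoes it regardless of the other sources — the
one-vote veto), the **1-trust** paradox (a hypothesis that every source
considers weak receives fused mass 1), and the **high-conflict** paradox
(strong majority support is overturned). All four BPA sets are shipped as
CSV data files and exposed by `paradox_fixtures()`.

### Softmax remapping (the "idset" rule)

The remapped rule pushes each BPA through an exponential normalization
before combining:

    m′(A_α) = exp(m(A_α)) / Σ_i exp(m(A_i)).

exp is strictly increasing and strictly positive, so the remap (i) preserves
the ranking of hypotheses within each source, ties included; (ii) maps every
mass into [1/(1+(φ−1)e), e/(e+φ−1)] ⊂ (0, 1), shrinking the distance between
BPAs; and (iii) guarantees a strictly positive agreement mass, hence k < 1
and a rule that can never hit the zero-denominator failure or the one-vote
veto. The base is e exactly — the transform is parameter-free and no
temperature is applied anywhere in the reproduction paths.

The remap is applied **exactly once per source**: raw inputs are remapped,
the remapped masses are combined classically, and the fused output is not
remapped again. `softmax_remap` refuses an already-remapped mass so the
transform cannot be iterated by accident; `combine_idset` accepts
pre-remapped sources and uses them as-is.

A consequence worth knowing: since Π_s exp(m_s(A)) = exp(Σ_s m_s(A)), the
fused mass under this rule depends on the sources only through the column
sums of raw mass — hypotheses with equal column sums fuse to exactly equal
masses. The 0-trust fixture is such a case (columns F and G both sum to 1.5),
so its fused F and G are mathematically tied at 0.38365…; reference tables
that fuse 3-d.p.-rounded intermediates instead print a small spurious gap
(0.385 vs 0.382). The implementation keeps full double precision and resolves
the tie by the documented rule below, which still yields the decision F.

### Numerical choices

- Mass validation tolerance: |Σm − 1| ≤ 1e-6 by default (CSV round-tripping
  of softmax outputs), with opt-in renormalization by the sum.
- Complete-conflict detection: agreement mass ≤ 1e-12.
- Products are taken by direct multiplication, not in log space — with a
  handful of sources and at most a few hundred hypotheses the products stay
  far above underflow; as a guard the unnormalized products are rescaled by
  their maximum before the final normalization.
- Argmax tie-break: among masses within 1e-12 of the maximum, the lowest
  frame index wins and a warning is logged. Ties are real (see above), the
  policy is explicit, and callers who care about margins get the full fused
  vector.

## Decision-level classifier fusion

`fuse_predictions` (and the scikit-learn estimator `EvidenceFusionClassifier`
wrapping the same arithmetic) treats each classifier's per-sample class
probability vector directly as a BPA and fuses row i of every source, for
any number of sources ≥ 2. No per-model calibration is applied before
fusion — the softmax outputs are the mass functions, and the remap (under
the idset rule) is the rule's own preprocessing. Batch fusion is vectorized;
a test asserts row-for-row equality with the scalar core path. Under the
classical rule a sample can hit complete conflict: such rows get a NaN mass
vector, a `None` decision and an entry in the failure report, and the batch
continues — the estimator interface, which must return a label per sample,
raises instead. The idset rule cannot fail by construction.

## Evaluation metrics

Per-class rates are one-vs-rest from the confusion matrix: precision
TP/(TP+FP), recall TP/(TP+FN), specificity TN/(TN+FP), F1 the harmonic mean
of precision and recall. Headline numbers are macro averages (unweighted over
classes); per-class values are always emitted so any other aggregation can be
recomputed. A rate with a zero denominator is *undefined*: reported as None,
excluded from the macro average, and logged — substituting 0 would silently
deflate macros. Agreement is unweighted Cohen's kappa, (p_o − p_e)/(1 − p_e)
with p_e from the row×column marginals (the class labels are nominal, so no
weighting scheme applies); kappa is undefined when p_e = 1. Ranking quality
is one-vs-rest ROC AUC via the Mann–Whitney rank statistic with mid-ranks for
ties (identical to trapezoidal ROC integration), macro-averaged over classes
present in the truth; absent classes are skipped with a warning. All of these
are implemented directly and cross-checked in the test suite against
scikit-learn on random label sets to 1e-9.

Confidence intervals, where requested, are percentile bootstrap (resampling
samples with replacement, 2000 replicates by default, seeded). This is
generic uncertainty plumbing, offered because published tables often carry
95% CIs whose construction is unstated; it is one reasonable choice, not a
reproduction of any specific published interval.

## Synthetic prediction generator

`gen_predictions` emulates the statistical setting of two (or more) imperfect
classifiers over a class frame, without any network: truth is drawn from
class priors (default: the training-split proportions of the seven-class
fundus corpus, N dominating at ~54%), each source predicts the true class
with its target accuracy (errors uniform over the wrong classes), and the
emitted probability row puts mass p on the predicted class with the
remaining 1 − p spread by a symmetric Dirichlet(1) draw over the other
classes.

Sharpness is governed by one concentration parameter c, with p = c/(c+1) for
correct predictions and p = (c/2)/((c/2)+1) for wrong ones (defaults 0.8 and
2/3 at c = 4). The halved concentration on errors encodes the
confidence–correctness correlation that real softmax ensembles exhibit and
that makes decision fusion work: when two sources disagree, the correct one
is, on average, the more confident, so the fused argmax recovers the truth
more often than either source alone. A fully symmetric emitter (same p for
correct and wrong rows) was considered and rejected: in a disagreement it
makes the correct and the wrong source statistically indistinguishable, the
fused decision degenerates to a coin flip, and fusion provably cannot beat
the better source on average — which would contradict the very effect the
generator exists to exercise. Requiring c > 2 keeps both p values above 1/2,
so the row argmax always equals the intended prediction and realized
accuracy tracks the target to within binomial noise; c → ∞ gives one-hot
rows.

`error_mode="shared"` makes all sources err on the same samples *and* name
the same wrong class: disagreement never occurs, so fusion has nothing to
resolve. This is the negative control establishing that the fusion gain
comes from disagreement resolution, not from averaging noise.

What the generator does **not** model: inter-class visual similarity (errors
are uniform over wrong classes, whereas real fundus confusions are
structured), miscalibration, per-class accuracy differences, and partial
error correlation between the two extremes. Passing the fusion-gain tests
therefore shows the mechanism works under the stated statistical conditions,
not that any particular accuracy level would be reached on real images.

Study conditions used by the seeded simulation tests: two sources at target
accuracy 0.85, independent errors, n = 500 samples per replicate, 50
replicates, default priors and concentration. The fused-beats-both criterion
is checked at the ≥95%-of-replicates level; the shared-error control at a
mean-gain threshold of 0.005 (the generator's sharing construction actually
gives identically zero gain).

## Image augmentation

The six-fold expansion of an RGB image is [original, random rotation,
horizontal mirror, vertical mirror, RBG channel swap, BGR channel swap] —
the only composition of the listed transforms consistent with a 6× dataset
count (5258 inputs → 31,548 outputs in the motivating corpus). Images are
first resized to a square target (default 512×512×3) by direct bilinear
rescale without cropping. Channel permutations move whole planes, so each
per-plane histogram is preserved bitwise — brightness and contrast change,
structure does not; mirrors and permutations are bitwise involutions.
Rotation draws its angle uniformly from [−180°, 180°) from a seeded
generator, resamples bilinearly and fills exposed corners with black; angle
range, fill and interpolation are configurable defaults since the protocol
leaves them open. `train_test_split_files` provides the seeded 8:2 split of
the augmented pool used by the motivating protocol, and warns that splitting
*after* augmentation leaks variants of one source image across the
train/test boundary; split before augmenting unless fidelity to that
protocol is the point.

## Problem sizes in the test suite

The property suites run 1000 random frames (φ ≤ 5, l ≤ 5) against an
independent enumeration oracle; the fusion-gain simulation runs 50 seeded
replicates at n = 500 plus 50 shared-error controls; augmentation tests use
50 synthetic 24×24 images and verify the 6× counter arithmetically for the
full-corpus size. The whole suite completes in well under a minute on one
CPU.

## Known limitations

- Singleton-only masses: no composite focal elements, belief/plausibility,
  or discounting/reliability weights.
- The remapped rule compresses evidence toward uniformity (all remapped
  masses lie in a narrow positive band), so fused margins are small even
  when raw evidence is decisive; decisions are unaffected but the fused
  masses should not be read as calibrated probabilities.
- Published headline results on real fundus datasets (accuracies, AUCs,
  kappa on ODIR-5K / DRD) require training deep networks on the source
  images and are not reproduced here; the package reproduces the evidence-
  theory worked examples exactly and demonstrates the fusion mechanism on
  synthetic sources.
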