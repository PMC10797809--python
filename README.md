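# dsfusion

Dempster–Shafer evidence combination with softmax-remapped conflict handling,
for decision-level fusion of multi-classifier outputs (e.g. two CNNs
diagnosing fundus images), plus the evaluation metrics and image-augmentation
pipeline that go with that workflow.

## The problem

Dempster's rule combines l independent basic probability assignments
(BPAs) m₁ … m_l over a frame of hypotheses Θ = {A₁, …, A_φ} by

    (m₁ ⊕ … ⊕ m_l)(A) = Π_s m_s(A) / (1 − k),      k = 1 − Σ_A Π_s m_s(A),

where k is the conflict factor. The rule is a natural way to fuse the
softmax outputs of several classifiers into one decision — but it fails when
k → 1. Four classical paradoxes (complete conflict, 0-trust, 1-trust, high
conflict) make it either undefined (zero denominator) or confidently wrong
(a single zero mass vetoes a hypothesis no matter how strongly the other
sources support it).

The remapped rule implemented here fixes this by pushing every BPA through
an exponential normalization before combining:

    m′(A_α) = exp(m(A_α)) / Σ_i exp(m(A_i)).

The softmax preserves each source's ranking of hypotheses, shrinks the
distance between BPAs, and makes every mass strictly positive — so k < 1
always, the rule never becomes undefined, and the one-vote veto disappears.
The package reproduces all four paradox worked examples exactly and ships
them as fixtures.

## What's in the box

- `dsfusion.core` — frames, mass functions, validation, Dempster's rule,
  conflict factor, BPA CSV I/O.
- `dsfusion.idset` — the softmax remap and the remapped combination rule.
- `dsfusion.fusion` — per-sample fusion of classifier probability matrices:
  `fuse_predictions` (batch-robust, collects per-sample classical failures)
  and `EvidenceFusionClassifier`, a scikit-learn estimator over horizontally
  stacked per-source probability blocks.
- `dsfusion.metrics` — one-vs-rest precision/recall/specificity/F1, accuracy,
  Cohen's kappa, one-vs-rest ROC AUC, percentile-bootstrap CIs.
- `dsfusion.augment` — the 6× augmentation scheme: resize to 512×512×3,
  random rotation, horizontal/vertical mirroring, RGB→RBG and RGB→BGR
  channel permutation.
- `dsfusion.synthetic` — the packaged paradox fixtures and a seeded
  generator of multi-classifier softmax outputs with controllable accuracy
  and error correlation.
- `dsfusion` CLI — `combine`, `paradoxes`, `fuse-predictions`, `evaluate`,
  `simulate`, `augment`.

## Worked example

The four paradox fixtures under both rules:

```
$ dsfusion paradoxes

complete_conflict  (frame: F, G, H)
  m1: 1  0  0
  m2: 0  1  0
  m3: 0.8  0.1  0.1
  m4: 0.8  0.1  0.1
  k (raw) = 1
  classical: FAILS (complete conflict, k = 1)
  k (remapped) = 0.958897
  idset:     0.7478  0.1844  0.0678   decision=F

zero_trust  (frame: F, G, H)
  m1: 0.5  0.2  0.3
  m2: 0.5  0.2  0.3
  m3: 0  0.9  0.1
  m4: 0.5  0.2  0.3
  k (raw) = 0.9901
  classical: 0.0000  0.7273  0.2727   decision=G
  k (remapped) = 0.965947
  idset:     0.3837  0.3837  0.2327   decision=F
```

Reading the first block: three of four sources strongly support F, but one
source gives F mass zero, so classical combination is undefined (k = 1).
After the remap all masses are positive, k drops below 1, and the fused
decision is F with mass 0.748 — the verdict the evidence supports. In the
0-trust block the classical rule's one-vote veto forces m(F) = 0 and decides
G; the remapped rule restores F. (Fused F and G tie exactly there — the
fused mass under the remapped rule depends only on each hypothesis's raw
column sum, and both columns sum to 1.5; ties break to the lowest frame
index, with a logged warning.)

The same machinery in Python, fusing two synthetic classifiers:

```python
>>> import numpy as np
>>> from dsfusion import GeneratorSpec, gen_predictions, fuse_predictions
>>> truth, (m1, m2) = gen_predictions(
...     GeneratorSpec(n_samples=200, accuracies=(0.85, 0.85), seed=7))
>>> fused = fuse_predictions([m1, m2], rule="idset")
>>> def acc(m):
...     pred = np.asarray(m.frame.labels, object)[m.rows.argmax(1)]
...     return (pred == truth).mean()
>>> acc(m1), acc(m2), fused.accuracy(truth)
(np.float64(0.88), np.float64(0.84), 0.985)
```

Both simulated classifiers sit near their 0.85 accuracy target; fusing their
probability vectors with the remapped rule resolves most of their
disagreements in favour of the truth (0.985). The gain disappears, by
design, when the sources share their errors — see
`docs/methods.md` for the generator's model and the negative control.

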