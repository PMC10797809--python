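"""Packaged paradox fixtures and seeded generators for fusion experiments.

Two kinds of test material live here:

* the four classical failure cases of Dempster's rule — complete-conflict,
  0-trust, 1-trust and high-conflict — shipped as CSV fixtures and returned
  as ready-made mass functions by :func:`paradox_fixtures`;
* a seeded generator of multi-classifier softmax outputs over a frame of
  disease labels, with controllable per-source accuracy, error correlation
  and sharpness, used to study when decision fusion helps.

The generator draws a true class per sample from the class priors, decides
per source whether the prediction is correct (Bernoulli at the source's
accuracy target; errors uniform over the wrong classes), and emits a
probability vector putting mass p on the predicted class with the remainder
spread by a symmetric Dirichlet draw over the other classes. Sharpness is
governed by a single ``concentration`` c through p = c/(c+1) for correct
predictions and p = (c/2)/(c/2+1) for incorrect ones: wrong predictions are
emitted at half confidence. The confidence–correctness link is what real
softmax ensembles exhibit and is the mechanism by which fusing two
disagreeing sources recovers the truth; a fully symmetric generator would
make the correct and the wrong source statistically indistinguishable in a
disagreement and fusion could never beat the individual sources on average.
Both p values stay above 1/2 for the default c, so the emitted argmax always
equals the intended prediction and realized accuracy tracks the target to
within binomial noise.

With ``error_mode="shared"`` all sources err on the same samples *and* name
the same wrong class — the negative control: disagreement never occurs, so
fusion has nothing to resolve and yields no gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

from .core import Frame, MassFunction, read_bpa_csv
from .fusion import PredictionMatrix

__all__ = [
    "PARADOX_NAMES",
    "DEFAULT_LABELS",
    "DEFAULT_PRIORS",
    "GeneratorSpec",
    "paradox_fixtures",
    "gen_predictions",
    "gen_images",
]

#: Fixture names in presentation order.
PARADOX_NAMES = ("complete_conflict", "zero_trust", "one_trust", "high_conflict")

#: The seven fundus-disease labels: normal, diabetic retinopathy, glaucoma,
#: cataract, age-related macular degeneration, hypertensive retinopathy,
#: pathological myopia.
DEFAULT_LABELS = ("N", "D", "G", "C", "AMD", "H", "M")

#: Default class priors: the training-set class counts of the 7-label fundus
#: corpus the package's defaults emulate, normalized.
_TRAIN_COUNTS = np.array([13588, 6665, 1046, 1260, 1138, 497, 1142], dtype=float)
DEFAULT_PRIORS = tuple(_TRAIN_COUNTS / _TRAIN_COUNTS.sum())


def paradox_fixtures() -> dict[str, list[MassFunction]]:
    """The four packaged paradox BPA sets, keyed by :data:`PARADOX_NAMES`.

    complete_conflict, zero_trust, one_trust: 4 sources over (F, G, H);
    high_conflict: 5 sources over (F, G, H, I, J).
    """
    out: dict[str, list[MassFunction]] = {}
    for name in PARADOX_NAMES:
        ref = resources.files("dsfusion.data").joinpath(f"{name}.csv")
        with resources.as_file(ref) as path:
            out[name] = read_bpa_csv(path)
    return out


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one synthetic multi-classifier run.

    Parameters
    ----------
    n_samples : int
        Number of samples to draw.
    accuracies : sequence of float
        One per source, each in (1/φ, 1]: the probability a source predicts
        the true class.
    class_priors : sequence of float
        Probability of each frame label; must sum to 1. Defaults to the
        7-class fundus training proportions.
    labels : sequence of str
        Frame labels; length must match the priors.
    error_mode : {"independent", "shared"}
        Whether sources err independently or on the same samples (with the
        same wrong label — the no-disagreement negative control).
    concentration : float
        Sharpness c of the emitted softmax vectors; predicted-class mass is
        c/(c+1) when correct and (c/2)/(c/2+1) when wrong. Default 4.0
        (masses 0.8 and 2/3). Must exceed 2 so both stay above 1/2.
    seed : int
        Fixes all randomness end-to-end.
    """

    n_samples: int
    accuracies: tuple[float, ...] = (0.85, 0.85)
    class_priors: tuple[float, ...] = DEFAULT_PRIORS
    labels: tuple[str, ...] = DEFAULT_LABELS
    error_mode: str = "independent"
    concentration: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "accuracies", tuple(float(a) for a in self.accuracies))
        object.__setattr__(self, "class_priors", tuple(float(p) for p in self.class_priors))
        object.__setattr__(self, "labels", tuple(str(lab) for lab in self.labels))
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if len(self.labels) != len(self.class_priors):
            raise ValueError("labels and class_priors lengths differ")
        phi = len(self.labels)
        if abs(sum(self.class_priors) - 1.0) > 1e-9 or min(self.class_priors) < 0:
            raise ValueError("class_priors must be a probability vector")
        if len(self.accuracies) < 1:
            raise ValueError("need at least one source accuracy")
        for a in self.accuracies:
            if not (1.0 / phi < a <= 1.0):
                raise ValueError(f"accuracy {a} outside (1/{phi}, 1]")
        if self.error_mode not in ("independent", "shared"):
            raise ValueError(f"unknown error_mode {self.error_mode!r}")
        if self.concentration <= 2.0:
            raise ValueError("concentration must exceed 2 (argmax guarantee)")

    @property
    def frame(self) -> Frame:
        return Frame(self.labels)


def _emit_rows(
    rng: np.random.Generator,
    predicted: np.ndarray,
    correct: np.ndarray,
    phi: int,
    concentration: float,
) -> np.ndarray:
    """Probability rows with mass p on the predicted class, rest Dirichlet."""
    n = predicted.size
    c_eff = np.where(correct, concentration, concentration / 2.0)
    p = c_eff / (c_eff + 1.0)
    rest = rng.dirichlet(np.ones(phi - 1), size=n) * (1.0 - p)[:, None]
    rows = np.empty((n, phi))
    for i in range(n):
        j = predicted[i]
        rows[i, j] = p[i]
        rows[i, np.arange(phi) != j] = rest[i]
    return rows


def gen_predictions(
    spec: GeneratorSpec,
) -> tuple[np.ndarray, list[PredictionMatrix]]:
    """Draw truth labels and one prediction matrix per source.

    Returns ``(truth, matrices)`` where ``truth`` is an array of label
    strings and each matrix's rows are valid mass functions whose argmax is
    the source's predicted class. Identical spec (same seed) reproduces the
    output bitwise.
    """
    rng = np.random.default_rng(spec.seed)
    phi = len(spec.labels)
    labels = np.asarray(spec.labels, dtype=object)
    truth_idx = rng.choice(phi, size=spec.n_samples, p=spec.class_priors)

    shared_err = rng.random(spec.n_samples)  # used only in shared mode
    shared_wrong = rng.integers(0, phi - 1, size=spec.n_samples)

    matrices = []
    ids = tuple(f"s{i:05d}" for i in range(spec.n_samples))
    for s, acc in enumerate(spec.accuracies):
        if spec.error_mode == "shared":
            correct = shared_err < acc
            wrong_off = shared_wrong
        else:
            correct = rng.random(spec.n_samples) < acc
            wrong_off = rng.integers(0, phi - 1, size=spec.n_samples)
        # error labels uniform over the phi-1 wrong classes
        wrong = (truth_idx + 1 + wrong_off) % phi
        predicted = np.where(correct, truth_idx, wrong)
        rows = _emit_rows(rng, predicted, correct, phi, spec.concentration)
        matrices.append(
            PredictionMatrix(
                frame=spec.frame,
                rows=rows,
                sample_ids=ids,
                source_name=f"source{s + 1}",
            )
        )
    return labels[truth_idx], matrices


def gen_images(
    n: int, size: int = 64, seed: int = 0
) -> list["np.ndarray"]:
    """Synthetic RGB test images: smooth random gradients plus a bright disc.

    Cheap stand-ins for fundus photographs (a dark field with a bright
    circular structure), adequate for exercising resize/rotate/mirror/
    channel-permutation plumbing. Returns uint8 arrays of shape
    (size, size, 3).
    """
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size]
    images = []
    for _ in range(n):
        base = np.empty((size, size, 3))
        for ch, lo in zip(range(3), (60.0, 20.0, 5.0)):
            gx, gy = rng.uniform(-1, 1, 2)
            base[:, :, ch] = lo + 40 * (gx * xx + gy * yy) / size + rng.uniform(0, 30)
        cx, cy = rng.uniform(0.25 * size, 0.75 * size, 2)
        r = rng.uniform(0.08, 0.2) * size
        disc = ((xx - cx) ** 2 + (yy - cy) ** 2) < r**2
        base[disc] += np.array([150.0, 110.0, 40.0])
        base += rng.normal(0, 3, base.shape)
        images.append(np.clip(base, 0, 255).astype(np.uint8))
    return images
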