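"""Hypothesis frames, mass functions, and Dempster's rule of combination.

The frame of discernment Θ = {A₁, …, A_φ} is an exhaustive set of mutually
exclusive hypotheses (here: disease labels). A basic probability assignment
(BPA, or *mass function*) m assigns non-negative belief mass to hypotheses
with Σ m(A) = 1. All mass functions in this package are *Bayesian* (singleton
mass only): the BPAs of interest are classifier softmax outputs, which never
place mass on composite subsets, so the full 2^Θ power-set machinery is
deliberately not implemented.

Dempster's rule combines l independent mass functions by

    (m₁ ⊕ … ⊕ m_l)(A) = Π_s m_s(A) / (1 − k),

where the conflict factor

    k = 1 − Σ_A Π_s m_s(A)

is the total product mass falling on incompatible hypothesis combinations and
(1 − k) is the normalization coefficient. For singleton BPAs the agreement
term reduces to all sources naming the same label. When k = 1 (complete
conflict) the denominator vanishes and the rule fails; see
:mod:`dsfusion.idset` for the remapped rule that cannot fail this way.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: |Σm − 1| tolerance accepted when validating a mass vector (CSV round-trips
#: of softmax outputs rarely sum to 1 exactly).
DEFAULT_SUM_TOLERANCE = 1e-6

#: Agreement mass at or below this threshold is treated as complete conflict
#: (k = 1): exact-zero products in floating point.
COMPLETE_CONFLICT_EPS = 1e-12


class MassValidityError(ValueError):
    """A mass vector entry lies outside [0, 1]."""


class MassNormalizationError(ValueError):
    """A mass vector does not sum to 1 within tolerance."""


class FrameMismatchError(ValueError):
    """Mass functions defined on different frames cannot be combined."""


class CompleteConflictError(ArithmeticError):
    """Dempster's rule failed: k = 1, the normalization denominator is zero.

    This is the complete-conflict paradox — some hypothesis is assigned mass
    zero by at least one source in every agreement term. The ID-SET rule
    (:func:`dsfusion.idset.combine_idset`) is immune to it.
    """


@dataclass(frozen=True)
class Frame:
    """Ordered frame of discernment: the φ mutually exclusive hypotheses."""

    labels: tuple[str, ...]

    def __init__(self, labels: Iterable[str]):
        labels = tuple(str(lab) for lab in labels)
        if len(labels) < 2:
            raise ValueError(f"a frame needs at least 2 hypotheses, got {len(labels)}")
        if len(set(labels)) != len(labels):
            raise ValueError("frame labels must be unique")
        if any(not lab for lab in labels):
            raise ValueError("frame labels must be non-empty strings")
        object.__setattr__(self, "labels", labels)

    @property
    def size(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"label {label!r} not in frame {self.labels}") from None

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.labels)


@dataclass(frozen=True)
class MassFunction:
    """A Bayesian BPA: one non-negative mass per frame label, summing to 1."""

    frame: Frame
    masses: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "masses", np.asarray(self.masses, dtype=float).reshape(-1)
        )
        if self.masses.shape != (self.frame.size,):
            raise ValueError(
                f"mass vector length {self.masses.size} != frame size {self.frame.size}"
            )
        self.masses.setflags(write=False)

    def __getitem__(self, label: str) -> float:
        return float(self.masses[self.frame.index(label)])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.frame.labels, map(float, self.masses)))


@dataclass(frozen=True)
class FusionResult:
    """Outcome of combining l sources: fused masses, conflict k, decision."""

    frame: Frame
    masses: np.ndarray
    k: float
    rule: str
    decision: str
    n_sources: int
    failed: bool = field(default=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "masses", np.asarray(self.masses, dtype=float).reshape(-1)
        )
        self.masses.setflags(write=False)

    def __getitem__(self, label: str) -> float:
        return float(self.masses[self.frame.index(label)])

    def to_json(self) -> str:
        return json.dumps(
            {
                "labels": list(self.frame.labels),
                "masses": [float(m) for m in self.masses],
                "k": float(self.k),
                "rule": self.rule,
                "decision": self.decision,
                "n_sources": self.n_sources,
            }
        )


def validate_mass(
    masses: Sequence[float] | np.ndarray,
    frame: Frame,
    tolerance: float = DEFAULT_SUM_TOLERANCE,
    renormalize: bool = False,
) -> MassFunction:
    """Validate a raw vector as a BPA on ``frame``.

    Every entry must lie in [0, 1] and the sum must be within ``tolerance``
    of 1. With ``renormalize=True`` a vector passing both checks is divided
    by its sum so it sums to 1 exactly.

    Raises
    ------
    MassValidityError
        if any entry is negative or exceeds 1 (the offending index is named).
    MassNormalizationError
        if the sum is outside tolerance (the sum is reported).
    """
    vec = np.asarray(masses, dtype=float).reshape(-1)
    if vec.shape != (frame.size,):
        raise ValueError(
            f"mass vector length {vec.size} does not match frame size {frame.size}"
        )
    bad = np.flatnonzero((vec < 0.0) | (vec > 1.0))
    if bad.size:
        i = int(bad[0])
        raise MassValidityError(
            f"mass[{i}] = {vec[i]!r} for label {frame.labels[i]!r} is outside [0, 1]"
        )
    total = float(vec.sum())
    if abs(total - 1.0) > tolerance:
        raise MassNormalizationError(
            f"masses sum to {total!r}, outside tolerance {tolerance} of 1"
        )
    if renormalize and total != 0.0:
        vec = vec / total
    return MassFunction(frame, vec)


def _common_frame(sources: Sequence[MassFunction]) -> Frame:
    if len(sources) < 2:
        raise ValueError(f"need at least 2 sources to combine, got {len(sources)}")
    frame = sources[0].frame
    for i, src in enumerate(sources[1:], start=2):
        if src.frame != frame:
            raise FrameMismatchError(
                f"source {i} is on frame {src.frame.labels}, expected {frame.labels}"
            )
    return frame


def _agreement(sources: Sequence[MassFunction]) -> np.ndarray:
    """Per-label unnormalized agreement mass Π_s m_s(A)."""
    stack = np.vstack([src.masses for src in sources])
    return np.prod(stack, axis=0)


def conflict_factor(sources: Sequence[MassFunction]) -> float:
    """Conflict factor k = 1 − Σ_A Π_s m_s(A) for singleton BPAs.

    k ∈ [0, 1]: 0 means the sources agree perfectly on a point mass, 1 means
    every hypothesis is vetoed by at least one source.
    """
    _common_frame(sources)
    k = 1.0 - float(_agreement(sources).sum())
    # guard float round-off at the boundaries
    return min(1.0, max(0.0, k))


def _decide(frame: Frame, masses: np.ndarray) -> str:
    # ties (exact or within float round-off) break to the lowest frame index
    ties = np.flatnonzero(masses >= masses.max() - 1e-12)
    top = int(ties[0])
    if ties.size > 1:
        logger.warning(
            "fused masses tie at %r among labels %s; lowest frame index %r wins",
            float(masses[top]),
            [frame.labels[int(i)] for i in ties],
            frame.labels[top],
        )
    return frame.labels[top]


def combine_classical(sources: Sequence[MassFunction]) -> FusionResult:
    """Combine ≥2 singleton BPAs with Dempster's rule.

    Fused mass of each label A is Π_s m_s(A) / (1 − k). Products are taken by
    direct multiplication (source counts here are small); an underflow guard
    rescales the unnormalized products by their maximum before normalizing.

    Raises
    ------
    CompleteConflictError
        if k = 1 within machine tolerance: the complete-conflict paradox, the
        normalization denominator (1 − k) is zero.
    FrameMismatchError
        if the sources live on different frames.
    """
    frame = _common_frame(sources)
    prod = _agreement(sources)
    agreement = float(prod.sum())
    if agreement <= COMPLETE_CONFLICT_EPS:
        raise CompleteConflictError(
            "complete-conflict paradox: conflict factor k = 1, the Dempster "
            "normalization denominator (1 - k) is zero; no hypothesis is "
            "supported by every source. Use the idset rule instead."
        )
    k = 1.0 - agreement
    # underflow guard: normalize by the max first, then by the sum
    scaled = prod / prod.max()
    fused = scaled / scaled.sum()
    return FusionResult(
        frame=frame,
        masses=fused,
        k=k,
        rule="classical",
        decision=_decide(frame, fused),
        n_sources=len(sources),
    )


def read_bpa_csv(
    path,
    tolerance: float = DEFAULT_SUM_TOLERANCE,
    renormalize: bool = False,
) -> list[MassFunction]:
    """Read evidence sources from CSV: header = frame labels, one row per BPA."""
    import pandas as pd

    df = pd.read_csv(path, float_precision="round_trip")
    frame = Frame(df.columns)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            out.append(validate_mass(row, frame, tolerance, renormalize))
        except (MassValidityError, MassNormalizationError) as exc:
            raise type(exc)(f"row {i}: {exc}") from exc
    return out


def write_bpa_csv(path, sources: Sequence[MassFunction]) -> None:
    import pandas as pd

    frame = _common_frame(sources) if len(sources) > 1 else sources[0].frame
    df = pd.DataFrame([s.masses for s in sources], columns=list(frame.labels))
    df.to_csv(path, index=False, float_format="%.17g")
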