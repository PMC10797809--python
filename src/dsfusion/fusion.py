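"""Decision-level fusion of classifier probability outputs.

Each classifier emits a per-sample class-probability vector (a softmax
output); that vector is treated directly as a Bayesian BPA on the frame of
class labels and the vectors of ≥2 classifiers are fused per sample with
either the classical Dempster rule or the softmax-remapped (ID-SET) rule.
The remap, where used, is the rule's own preprocessing — the raw network
outputs are the m₁, m₂ mass functions.

The estimator :class:`EvidenceFusionClassifier` packages the same operation
in scikit-learn form (the per-source probability matrices are horizontally
stacked into one feature matrix); :func:`fuse_predictions` is the functional
surface over named :class:`PredictionMatrix` objects and is batch-robust:
classical-rule failures on individual samples are collected into a failure
report instead of aborting the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .core import (
    COMPLETE_CONFLICT_EPS,
    DEFAULT_SUM_TOLERANCE,
    CompleteConflictError,
    Frame,
    MassFunction,
    MassNormalizationError,
    MassValidityError,
    validate_mass,
)

__all__ = [
    "PredictionMatrix",
    "FusedPredictions",
    "PredictionParseError",
    "AlignmentError",
    "EvidenceFusionClassifier",
    "fuse_predictions",
    "read_predictions",
    "write_predictions",
    "write_fused",
]

SAMPLE_ID_COLUMN = "sample_id"


class PredictionParseError(ValueError):
    """A prediction CSV row or column failed validation."""


class AlignmentError(ValueError):
    """Prediction matrices entering one fusion disagree on frame or samples."""


@dataclass(frozen=True)
class PredictionMatrix:
    """Per-sample class-probability rows from one classifier."""

    frame: Frame
    rows: np.ndarray
    sample_ids: tuple[str, ...]
    source_name: str = ""

    def __post_init__(self) -> None:
        rows = np.asarray(self.rows, dtype=float)
        if rows.ndim != 2 or rows.shape[1] != self.frame.size:
            raise ValueError(
                f"rows must be (n_samples, {self.frame.size}), got {rows.shape}"
            )
        if len(self.sample_ids) != rows.shape[0]:
            raise ValueError("sample_ids length does not match number of rows")
        object.__setattr__(self, "rows", rows)
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        rows.setflags(write=False)

    @property
    def n_samples(self) -> int:
        return self.rows.shape[0]

    def mass(self, i: int) -> MassFunction:
        """Row ``i`` as a MassFunction (validated on construction)."""
        return MassFunction(self.frame, self.rows[i])


@dataclass(frozen=True)
class FusedPredictions:
    """Per-sample fused masses, conflicts and decisions for one batch."""

    frame: Frame
    sample_ids: tuple[str, ...]
    decisions: tuple[str | None, ...]
    fused_masses: np.ndarray
    conflicts: np.ndarray
    rule: str
    failures: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    @property
    def n_failures(self) -> int:
        return len(self.failures)

    def accuracy(self, truth: Sequence[str]) -> float:
        """Fraction of samples whose fused decision equals the true label."""
        truth = [str(t) for t in truth]
        if len(truth) != len(self.sample_ids):
            raise ValueError("truth length does not match number of samples")
        hits = sum(d == t for d, t in zip(self.decisions, truth))
        return hits / len(truth)


def _check_alignment(matrices: Sequence[PredictionMatrix]) -> None:
    if len(matrices) < 2:
        raise ValueError(f"need at least 2 prediction matrices, got {len(matrices)}")
    ref = matrices[0]
    for m in matrices[1:]:
        if m.frame != ref.frame:
            raise AlignmentError(
                f"source {m.source_name!r} frame {m.frame.labels} != {ref.frame.labels}"
            )
        if m.sample_ids != ref.sample_ids:
            raise AlignmentError(
                f"source {m.source_name!r} sample ids differ from {ref.source_name!r}"
            )


def _argmax_low(row: np.ndarray) -> int:
    """Index of the maximum, breaking float-round-off ties to the lowest."""
    return int(np.flatnonzero(row >= row.max() - 1e-12)[0])


def _fuse_rows(stack: np.ndarray, rule: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-row fusion of ``stack`` (n_sources, n_samples, φ).

    Returns (fused, k, failed) where failed marks rows with agreement mass
    ≤ the complete-conflict threshold under the classical rule. Equivalent,
    row by row, to the scalar combine functions in core/idset (tested).
    """
    if rule == "idset":
        e = np.exp(stack)
        stack = e / e.sum(axis=2, keepdims=True)
    prod = np.prod(stack, axis=0)  # (n_samples, φ)
    agreement = prod.sum(axis=1)
    failed = agreement <= COMPLETE_CONFLICT_EPS
    k = 1.0 - agreement
    fused = np.full_like(prod, np.nan)
    ok = ~failed
    fused[ok] = prod[ok] / agreement[ok, None]
    return fused, k, failed


def fuse_predictions(
    matrices: Sequence[PredictionMatrix], rule: str = "idset"
) -> FusedPredictions:
    """Fuse aligned prediction matrices sample by sample.

    Row i of the result is the combination of row i of every matrix under
    ``rule`` ∈ {"classical", "idset"}. The ID-SET rule never fails; under the
    classical rule, samples hitting the complete-conflict paradox get a NaN
    mass row, a ``None`` decision, and an entry in ``failures`` — the batch
    is never aborted.
    """
    if rule not in ("classical", "idset"):
        raise ValueError(f"unknown rule {rule!r}; expected 'classical' or 'idset'")
    _check_alignment(matrices)
    stack = np.stack([m.rows for m in matrices])
    fused, k, failed = _fuse_rows(stack, rule)
    frame = matrices[0].frame
    ids = matrices[0].sample_ids
    decisions: list[str | None] = []
    failures: list[tuple[str, str]] = []
    for i in range(fused.shape[0]):
        if failed[i]:
            decisions.append(None)
            failures.append(
                (ids[i], "complete conflict: k = 1, classical rule undefined")
            )
        else:
            decisions.append(frame.labels[_argmax_low(fused[i])])
    return FusedPredictions(
        frame=frame,
        sample_ids=ids,
        decisions=tuple(decisions),
        fused_masses=fused,
        conflicts=k,
        rule=rule,
        failures=tuple(failures),
    )


class EvidenceFusionClassifier(ClassifierMixin, BaseEstimator):
    """Combine the softmax outputs of several classifiers by evidence fusion.

    The feature matrix X stacks the per-source class-probability blocks
    horizontally: with ``n_sources`` sources over φ classes, X has shape
    (n_samples, n_sources·φ) and columns ``[src0·φ…, src1·φ…, …]`` — the
    layout produced by ``np.hstack`` on the individual probability matrices.

    Parameters
    ----------
    rule : {"idset", "classical"}
        Fusion rule. "idset" softmax-remaps each source's row before the
        Dempster product and can never hit the k = 1 failure; "classical"
        raises :class:`CompleteConflictError` if any row conflicts totally.
    n_sources : int
        Number of stacked probability blocks in X.
    classes : sequence of label names, optional
        Frame labels, in column order. Defaults to stringified indices.
    tolerance : float
        |Σ − 1| tolerance for validating each probability block row.

    Attributes
    ----------
    classes_ : ndarray of shape (n_classes,)
        Frame labels.
    frame_ : Frame
        The frame of discernment shared by all sources.
    n_features_in_ : int
    """

    def __init__(
        self,
        rule: str = "idset",
        n_sources: int = 2,
        classes: Sequence[str] | None = None,
        tolerance: float = DEFAULT_SUM_TOLERANCE,
    ):
        self.rule = rule
        self.n_sources = n_sources
        self.classes = classes
        self.tolerance = tolerance

    def _split(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError(f"X must be 2-D, got shape {X.shape}")
        if X.shape[1] % self.n_sources:
            raise ValueError(
                f"n_features {X.shape[1]} is not divisible by n_sources {self.n_sources}"
            )
        phi = X.shape[1] // self.n_sources
        if phi < 2:
            raise ValueError("each source block needs at least 2 class columns")
        return np.stack(np.hsplit(X, self.n_sources))  # (n_sources, n, φ)

    def fit(self, X, y=None):
        """Validate the stacked probability blocks and fix the frame."""
        if self.rule not in ("classical", "idset"):
            raise ValueError(f"unknown rule {self.rule!r}")
        stack = self._split(X)
        phi = stack.shape[2]
        if self.classes is not None:
            if len(self.classes) != phi:
                raise ValueError(
                    f"classes has {len(self.classes)} labels but blocks have {phi} columns"
                )
            labels = tuple(str(c) for c in self.classes)
        else:
            labels = tuple(str(i) for i in range(phi))
        sums = stack.sum(axis=2)
        if (stack < 0).any() or (stack > 1).any():
            raise MassValidityError("probability entries must lie in [0, 1]")
        if np.abs(sums - 1.0).max() > self.tolerance:
            raise MassNormalizationError(
                "each source block row must sum to 1 within tolerance"
            )
        self.frame_ = Frame(labels)
        self.classes_ = np.asarray(labels, dtype=object)
        self.n_features_in_ = int(np.asarray(X).shape[1])
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Fused mass vectors, one row per sample (rows sum to 1)."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "frame_")
        stack = self._split(X)
        fused, _, failed = _fuse_rows(stack, self.rule)
        if failed.any():
            raise CompleteConflictError(
                f"classical rule undefined (k = 1) on {int(failed.sum())} sample(s); "
                "use rule='idset' or the batch-tolerant fuse_predictions()"
            )
        return fused

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        # first index within round-off of the row max: lowest-index tie-break
        near_max = proba >= proba.max(axis=1, keepdims=True) - 1e-12
        return self.classes_[near_max.argmax(axis=1)]

    def conflict(self, X) -> np.ndarray:
        """Per-sample conflict factor k under the configured rule."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "frame_")
        _, k, _ = _fuse_rows(self._split(X), self.rule)
        return k


def read_predictions(
    path,
    source_name: str = "",
    tolerance: float = DEFAULT_SUM_TOLERANCE,
    renormalize: bool = False,
) -> PredictionMatrix:
    """Read one classifier's predictions from CSV.

    Layout: a ``sample_id`` column plus one probability column per class
    label. Every row must validate as a mass function on the frame defined
    by the probability columns.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if SAMPLE_ID_COLUMN not in df.columns:
        raise PredictionParseError(f"{path}: missing required column '{SAMPLE_ID_COLUMN}'")
    labels = [c for c in df.columns if c != SAMPLE_ID_COLUMN]
    frame = Frame(labels)
    probs = df[labels]
    if not all(np.issubdtype(dt, np.number) for dt in probs.dtypes):
        bad = [c for c, dt in probs.dtypes.items() if not np.issubdtype(dt, np.number)]
        raise PredictionParseError(f"{path}: non-numeric cells in column(s) {bad}")
    rows = probs.to_numpy(dtype=float)
    out = np.empty_like(rows)
    for i in range(rows.shape[0]):
        try:
            out[i] = validate_mass(rows[i], frame, tolerance, renormalize).masses
        except (MassValidityError, MassNormalizationError) as exc:
            raise PredictionParseError(f"{path}: row {i + 1}: {exc}") from exc
    return PredictionMatrix(
        frame=frame,
        rows=out,
        sample_ids=tuple(df[SAMPLE_ID_COLUMN].astype(str)),
        source_name=source_name or str(path),
    )


def write_predictions(path, matrix: PredictionMatrix) -> None:
    """Write a PredictionMatrix to CSV; round-trips to 17 significant digits."""
    df = pd.DataFrame(matrix.rows, columns=list(matrix.frame.labels))
    df.insert(0, SAMPLE_ID_COLUMN, list(matrix.sample_ids))
    df.to_csv(path, index=False, float_format="%.17g")


def write_fused(path, fused: FusedPredictions) -> None:
    """Write fused results: sample_id, decision, k, one mass column per class."""
    df = pd.DataFrame(fused.fused_masses, columns=list(fused.frame.labels))
    df.insert(0, "k", fused.conflicts)
    df.insert(0, "decision", [d if d is not None else "" for d in fused.decisions])
    df.insert(0, SAMPLE_ID_COLUMN, list(fused.sample_ids))
    df.to_csv(path, index=False, float_format="%.17g")
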