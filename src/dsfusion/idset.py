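"""Softmax-remapped Dempster combination (ID-SET).

Dempster's rule fails when the conflict factor k → 1, which happens whenever
some source assigns a hypothesis mass 0 (the one-vote veto) or the BPAs are
far apart. The remapped rule first pushes every BPA through an exponential
normalization

    m'(A_α) = exp(m(A_α)) / Σ_i exp(m(A_i)),

i.e. a softmax of the raw masses. exp is strictly increasing and strictly
positive, so the remap preserves the ranking of hypotheses, shrinks the
distance between BPAs, and guarantees every remapped mass is strictly
positive — hence the post-remap agreement mass is positive, k < 1, and the
combination can never hit the zero-denominator failure. The remapped sources
are then combined with the classical rule; the remap is applied exactly once
per source and the fused output is not remapped again.

A useful identity: since Π_s exp(m_s(A)) = exp(Σ_s m_s(A)), the fused mass
under this rule is proportional to exp of the *sum* of the raw masses of A
across sources — hypotheses with equal raw-mass column sums fuse to exactly
equal masses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import (
    Frame,
    FusionResult,
    MassFunction,
    _common_frame,
    _decide,
    combine_classical,
)

__all__ = ["RemappedMass", "softmax_remap", "combine_idset"]


@dataclass(frozen=True)
class RemappedMass(MassFunction):
    """A softmax-remapped BPA. Strictly positive, provenance kept."""

    raw: MassFunction = None  # type: ignore[assignment]


def softmax_remap(m: MassFunction) -> RemappedMass:
    """Exponentially normalize one BPA: m'(A) = exp(m(A)) / Σ exp(m(A_i)).

    The result is strictly positive, sums to 1, and preserves the ranking of
    the raw masses (ties stay ties). Each entry lies in
    [1/(1+(φ−1)e), e/(e+φ−1)] because raw masses lie in [0, 1].

    Remapping is a one-shot preprocessing step: passing an already-remapped
    mass is rejected so the transform cannot be iterated by accident.
    """
    if isinstance(m, RemappedMass):
        raise TypeError("mass is already remapped; the softmax remap is applied once")
    e = np.exp(m.masses)
    return RemappedMass(frame=m.frame, masses=e / e.sum(), raw=m)


def combine_idset(sources: Sequence[MassFunction]) -> FusionResult:
    """Remap every source once, then combine with Dempster's rule.

    Accepts raw mass functions (remapped here) or already-remapped masses
    (used as-is, never remapped twice). All remapped masses are strictly
    positive, so the agreement mass is positive and this rule never raises
    the complete-conflict error. The reported k is the post-remap conflict.
    """
    frame = _common_frame(sources)
    remapped = [
        s if isinstance(s, RemappedMass) else softmax_remap(s) for s in sources
    ]
    result = combine_classical(remapped)
    return FusionResult(
        frame=frame,
        masses=result.masses,
        k=result.k,
        rule="idset",
        decision=_decide(frame, result.masses),
        n_sources=len(sources),
    )
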