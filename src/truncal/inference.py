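"""Clonality calling and correctness scoring over repeated sampling.

A mutation is called *putatively clonal* when it is detected — at
within-sample frequency ``>= epsilon`` — in every sample taken.  Against
the simulator's ground truth, a sampling repetition is *correct* iff no
sub-clonal mutation was misclassified as clonal, i.e. the putative set is
a subset of the truly clonal set.  Missed truncal mutations (false
negatives) do not make a repetition incorrect: a false positive would
steer therapy at a target absent from part of the tumour, a false
negative merely shortens the candidate list.  A strict mode requiring
putative == truncal exactly is available for sensitivity analyses.

``proportion_correct`` repeats a sampling protocol many times (one
master seed spawning per-repetition child seeds, so repetitions are
independent and individually replayable) and reports the fraction of
correct classifications; ``rotational_proportion_correct`` scores every
rotation of an edge pattern instead, which is deterministic given the
tumour.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from typing import FrozenSet, List, Optional, Sequence, Set

from .clones import clonal_structure, genotype, ground_truth_clonal
from .growth import TumourState
from .sampling import (
    BiopsySample,
    PatternSpec,
    rotation_sweep,
    sample_bulk,
    sample_edge_random,
    sample_pooled,
    sample_single_cells,
)

__all__ = [
    "InferenceResult",
    "ProtocolResult",
    "SamplingProtocol",
    "detected",
    "call_clonal",
    "score",
    "proportion_correct",
    "rotational_proportion_correct",
]


@dataclass(frozen=True)
class InferenceResult:
    """Putative clonal set of one repetition and its correctness."""

    putative_clonal: FrozenSet[int]
    correct: bool
    epsilon: float
    n_samples: int


@dataclass(frozen=True)
class ProtocolResult:
    """Aggregated correctness of a sampling protocol on one tumour."""

    proportion_correct: float
    repetitions: int
    protocol: str
    f_of_tumour: float
    flags: Optional[Sequence[bool]] = None

    @property
    def se(self) -> float:
        """Binomial standard error of the proportion."""
        p = self.proportion_correct
        return math.sqrt(max(p * (1.0 - p), 0.0) / self.repetitions)


@dataclass(frozen=True)
class SamplingProtocol:
    """Descriptor of a repeatable sampling protocol.

    ``kind`` is one of ``single_cell``, ``bulk``, ``pooled`` or
    ``edge_random``; ``size_fraction`` applies to the multi-cell kinds.
    """

    kind: str
    n: int
    size_fraction: float = 0.01
    epsilon: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("single_cell", "bulk", "pooled", "edge_random"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (0.0 <= self.epsilon <= 1.0):
            raise ValueError("epsilon must lie in [0, 1]")

    def draw(self, state: TumourState, rng) -> List[BiopsySample]:
        if self.kind == "single_cell":
            return sample_single_cells(state, self.n, rng)
        if self.kind == "bulk":
            return sample_bulk(state, self.n, self.size_fraction, rng)
        if self.kind == "pooled":
            return sample_pooled(state, self.n, self.size_fraction, rng)
        return sample_edge_random(state, self.n, rng)

    def describe(self) -> str:
        if self.kind in ("single_cell", "edge_random"):
            return f"{self.kind}(n={self.n}, eps={self.epsilon})"
        return (
            f"{self.kind}(n={self.n}, s={self.size_fraction}, eps={self.epsilon})"
        )


def detected(sample: BiopsySample, epsilon: float) -> Set[int]:
    """Mutations detected in a sample: within-sample frequency >= epsilon.

    The threshold is inclusive; at ``epsilon=0`` every present mutation
    is detected, and single-cell samples (all frequencies 1) are
    threshold-invariant for any ``epsilon <= 1``.
    """
    if not (0.0 <= epsilon <= 1.0):
        raise ValueError("epsilon must lie in [0, 1]")
    if epsilon == 0.0:
        return set(sample.freq_in_sample)
    return {m for m, fr in sample.freq_in_sample.items() if fr >= epsilon}


def call_clonal(samples: Sequence[BiopsySample], epsilon: float) -> Set[int]:
    """Putative clonal set: mutations detected in every sample."""
    if not samples:
        raise ValueError("cannot call clonality from zero samples")
    putative = detected(samples[0], epsilon)
    for sample in samples[1:]:
        putative &= detected(sample, epsilon)
    return putative


def score(
    putative: Set[int], state: TumourState, *, strict: bool = False,
    founder_only: bool = False,
) -> bool:
    """True iff no sub-clonal mutation was misclassified as clonal.

    Default scoring is asymmetric — ``putative`` must be a subset of the
    truly clonal set; ``strict=True`` additionally requires every truly
    clonal mutation to be recovered.
    """
    truth = ground_truth_clonal(state, founder_only=founder_only)
    if strict:
        return putative == truth
    return putative <= truth


def proportion_correct(
    state: TumourState,
    protocol: SamplingProtocol,
    repetitions: int,
    seed: int,
    *,
    keep_flags: bool = False,
    strict: bool = False,
) -> ProtocolResult:
    """Fraction of correct classifications over repeated sampling.

    Each repetition draws fresh samples with its own child seed, calls
    the putative clonal set at the protocol's ``epsilon`` and scores it
    against ground truth.  Reproducible from ``seed``.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    truth = ground_truth_clonal(state)
    for cell_id in state.extant:  # warm the genotype cache once
        genotype(cell_id, state)
    master = random.Random(seed)
    child_seeds = [master.randrange(2 ** 31) for _ in range(repetitions)]
    flags: List[bool] = []
    for rep, child in enumerate(child_seeds):
        try:
            samples = protocol.draw(state, random.Random(child))
        except Exception as exc:
            raise RuntimeError(f"sampling failed at repetition {rep}") from exc
        putative = call_clonal(samples, protocol.epsilon)
        ok = putative == truth if strict else putative <= truth
        flags.append(ok)
    structure = clonal_structure(state)
    return ProtocolResult(
        proportion_correct=sum(flags) / repetitions,
        repetitions=repetitions,
        protocol=protocol.describe(),
        f_of_tumour=structure.f_largest,
        flags=tuple(flags) if keep_flags else None,
    )


def rotational_proportion_correct(
    state: TumourState,
    spec: PatternSpec,
    n_steps: int = 64,
    epsilon: float = 0.0,
) -> ProtocolResult:
    """Correct fraction over all rotations of an equidistant edge pattern.

    Every rotation of the template is one repetition; the result is a
    deterministic function of the tumour (no sampling randomness).
    """
    truth = ground_truth_clonal(state)
    sweeps = rotation_sweep(state, spec, n_steps)
    flags = [call_clonal(samples, epsilon) <= truth for samples in sweeps]
    structure = clonal_structure(state)
    return ProtocolResult(
        proportion_correct=sum(flags) / len(flags),
        repetitions=len(flags),
        protocol=f"pattern(points={spec.n_points}, steps={n_steps}, eps={epsilon})",
        f_of_tumour=structure.f_largest,
        flags=tuple(flags),
    )
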