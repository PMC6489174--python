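"""Closed-form sampling theory for truncal-mutation classification.

For deciding whether a mutation is truncal (carried by every cancer cell)
from multi-region samples, the only part of the tumour phylogeny that
matters is the set of *first-tier branches*: sub-clones that split
directly off the ancestral population.  A classification is wrong exactly
when all samples land inside one single first-tier branch, because that
branch's founding mutation then appears in every sample.

With a *balancing factor* ``f`` — the proportion of the tumour taken by
the first (largest) first-tier branch — and branching mutations arriving
at equidistant intervals, the k-th first-tier branch holds a fraction
``f * (1-f)**(k-1)`` of all cells.  The probability that ``n`` random
samples do not all fall into one branch then has a closed form in three
variants:

* single bifurcation:          ``p = 1 - f**n``
* ``M`` first-tier branches:   ``p = 1 - f**n * sum_{i<M} (1-f)**(n*i)``
* many branches (geometric
  limit, ``M -> inf``):        ``p = (1 - f**n - (1-f)**n) / (1 - (1-f)**n)``

This module implements the three probabilities, the planner for the
number of samples needed to reach a target confidence, the expected
sample count for equidistant (pattern) sampling, and an estimator of
``f`` from the coincidence frequencies of sample-subset intersections,
plus a Monte-Carlo oracle used to verify the finite-``M`` formula.
"""

from __future__ import annotations

import itertools
import math
import random
from dataclasses import dataclass, field
from typing import AbstractSet, Dict, Iterable, Sequence, Union

import numpy as np
from scipy import optimize

__all__ = [
    "AnalyticQuery",
    "CoincidenceProfile",
    "FEstimate",
    "OracleResult",
    "p_single_bifurcation",
    "p_finite_branches",
    "p_truncal",
    "samples_needed",
    "equidistant_pattern_n",
    "coincidence_profile",
    "expected_coincidence",
    "estimate_f",
    "monte_carlo_oracle",
]

# f-estimation search: dense grid over (0, 1) followed by bounded local
# refinement; _F_LOWER doubles as the value reported for degenerate fits.
_GRID_SIZE = 1000
_F_LOWER = 1e-4
_SEARCH_CAP = 1_000_000  # hard cap for samples_needed


def _as_f(f: float, *, name: str = "f") -> float:
    f = float(f)
    if math.isnan(f) or not (0.0 <= f <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {f!r}")
    return f


def _as_n(n: int, *, name: str = "n") -> int:
    if isinstance(n, bool) or int(n) != n or int(n) < 1:
        raise ValueError(f"{name} must be a positive integer, got {n!r}")
    return int(n)


@dataclass(frozen=True)
class AnalyticQuery:
    """A (f, n, M) triple: balancing factor, sample count, branch count.

    ``M`` may be ``math.inf`` (or the string ``"inf"``) for the
    geometric-limit model with effectively unbounded first-tier branches.
    """

    f: float
    n: int
    M: Union[int, float] = math.inf

    def __post_init__(self) -> None:
        object.__setattr__(self, "f", _as_f(self.f))
        object.__setattr__(self, "n", _as_n(self.n))
        M = self.M
        if isinstance(M, str):
            if M.lower() not in ("inf", "infinite", "infinity"):
                raise ValueError(f"M must be a positive integer or 'inf', got {M!r}")
            M = math.inf
        if M != math.inf:
            M = _as_n(M, name="M")
        object.__setattr__(self, "M", M)


def p_single_bifurcation(f: float, n: int) -> float:
    """Probability of correct truncal classification, single-bifurcation tree.

    With one first-tier branch of size ``f``, classification fails only
    when all ``n`` samples come from that branch: ``p = 1 - f**n``.
    """
    f = _as_f(f)
    n = _as_n(n)
    return 1.0 - f ** n


def p_finite_branches(f: float, n: int, M: Union[int, float]) -> float:
    """Probability of correct classification with ``M`` first-tier branches.

    Branch k holds a fraction ``f*(1-f)**(k-1)`` of the tumour; failure is
    the event that all ``n`` samples fall in one single branch, so

        ``p = 1 - f**n * sum_{i=0}^{M-1} (1-f)**(n*i)``.

    ``M=1`` reduces to :func:`p_single_bifurcation`; ``M="inf"`` gives the
    geometric limit :func:`p_truncal`.  The boundaries ``f=0`` and ``f=1``
    evaluate naturally to 1 and 0 (with the convention ``0**0 = 1``).
    """
    query = AnalyticQuery(f, n, M)
    if query.M == math.inf:
        return p_truncal(query.f, query.n)
    f, n, M = query.f, query.n, int(query.M)
    if f == 0.0:
        return 1.0
    # (1-f)**(n*i) summed over i < M; stable direct evaluation.
    ratio = (1.0 - f) ** n
    if ratio == 1.0:  # f == 0 handled above; unreachable, kept for safety
        series = float(M)
    else:
        series = (1.0 - ratio ** M) / (1.0 - ratio)
    return 1.0 - f ** n * series


def p_truncal(f: float, n: int) -> float:
    """Probability of correct truncal classification, many-branch limit.

    Geometric-series limit of :func:`p_finite_branches` as the number of
    first-tier branches grows:

        ``p = (1 - f**n - (1-f)**n) / (1 - (1-f)**n)``.

    Boundary conventions (analytic limits, the formula is 0/0 there):
    ``f=0`` maps to 0 for ``n=1`` and 1 for ``n>=2``; ``f=1`` maps to 0.
    For any ``f`` in (0, 1) a single sample can never reveal a branching,
    so ``n=1`` maps to 0.
    """
    f = _as_f(f)
    n = _as_n(n)
    if f == 0.0:
        return 0.0 if n == 1 else 1.0
    if f == 1.0:
        return 0.0
    q = (1.0 - f) ** n
    return (1.0 - f ** n - q) / (1.0 - q)


def samples_needed(f: float, p_target: float) -> int:
    """Smallest ``n`` with ``p_truncal(f, n) > p_target`` (strict).

    The bound is strict because the confidence statements this planner
    reproduces are of the form "greater than 98%".
    """
    f = _as_f(f)
    if not (0.0 < f < 1.0):
        raise ValueError(f"samples_needed requires 0 < f < 1, got {f!r}")
    p_target = float(p_target)
    if not (0.0 < p_target < 1.0):
        raise ValueError(f"p_target must lie in (0, 1), got {p_target!r}")
    for n in range(1, _SEARCH_CAP + 1):
        if p_truncal(f, n) > p_target:
            return n
    raise RuntimeError(f"no n <= {_SEARCH_CAP} reaches p_target={p_target}")


def equidistant_pattern_n(f: float) -> int:
    """Samples needed on average by an equidistant pattern: ``ceil(1/(1-f))``.

    Samples placed at equal spacing around the tumour guarantee that, on
    average, one of ``n = 1/(1-f)`` samples misses the largest sub-clone.
    A 1e-9 tolerance absorbs floating-point excess so that e.g. ``f=0.9``
    yields 10 rather than ceil(10.000000000000002) = 11.
    """
    f = _as_f(f)
    if f == 1.0:
        raise ValueError("f=1 requires infinitely many samples")
    return max(1, math.ceil(1.0 / (1.0 - f) - 1e-9))


@dataclass(frozen=True)
class CoincidenceProfile:
    """Observed subset-coincidence frequencies from ``n_total`` samples.

    ``ratios[i]`` is the fraction of size-``i`` subsets of the samples
    whose putative clonal set (intersection of detected mutations) equals
    the putative clonal set of all ``n_total`` samples.  Under the
    geometric-limit model this fraction estimates
    ``p_truncal(f, i) / p_truncal(f, n_total)``.
    """

    n_total: int
    ratios: Dict[int, float]

    def __post_init__(self) -> None:
        _as_n(self.n_total, name="n_total")
        keys = sorted(self.ratios)
        if keys and keys != list(range(keys[0], keys[-1] + 1)):
            raise ValueError(f"subset sizes must be contiguous, got {keys}")
        for i, r in self.ratios.items():
            if not (2 <= i <= self.n_total - 1):
                raise ValueError(f"subset size {i} outside 2..{self.n_total - 1}")
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"ratio for i={i} outside [0, 1]: {r}")


def coincidence_profile(
    samples: Sequence[AbstractSet[int]],
    *,
    max_exact: int = 12,
    n_subsets: int = 2000,
    seed: int = 0,
) -> CoincidenceProfile:
    """Subset-coincidence frequencies of detected-mutation sets.

    For each subset size ``i`` in ``2..n-1``, the fraction of the
    ``C(n, i)`` sample subsets whose intersection equals the intersection
    of all ``n`` sets.  All subsets are enumerated exactly for
    ``n <= max_exact``; above that, ``n_subsets`` subsets per size are
    drawn uniformly with the given seed.
    """
    sets = [frozenset(s) for s in samples]
    n = len(sets)
    if n < 3:
        raise ValueError(f"need at least 3 samples, got {n}")
    grand = frozenset.intersection(*sets)
    ratios: Dict[int, float] = {}
    rng = random.Random(seed)
    for i in range(2, n):
        if n <= max_exact:
            subsets: Iterable[Sequence[int]] = itertools.combinations(range(n), i)
            total = math.comb(n, i)
        else:
            subsets = [rng.sample(range(n), i) for _ in range(n_subsets)]
            total = n_subsets
        hits = 0
        for idx in subsets:
            inter = sets[idx[0]]
            for j in idx[1:]:
                inter = inter & sets[j]
                if len(inter) == len(grand):
                    break  # intersections only shrink and contain `grand`
            if inter == grand:
                hits += 1
        ratios[i] = hits / total
    return CoincidenceProfile(n_total=n, ratios=ratios)


def expected_coincidence(f: float, n_total: int) -> CoincidenceProfile:
    """Noise-free coincidence profile predicted by the geometric-limit model."""
    f = _as_f(f)
    n_total = _as_n(n_total, name="n_total")
    if n_total < 3:
        raise ValueError("n_total must be at least 3")
    pn = p_truncal(f, n_total)
    ratios = {i: p_truncal(f, i) / pn for i in range(2, n_total)}
    return CoincidenceProfile(n_total=n_total, ratios=ratios)


@dataclass(frozen=True)
class FEstimate:
    """Result of fitting the balancing factor to a coincidence profile."""

    f_hat: float
    residual: float
    degenerate: bool = False


def _ratio_sse(obs: np.ndarray, i_vals: np.ndarray, n_total: int, f: np.ndarray) -> np.ndarray:
    """Sum of squared differences between observed and predicted ratios.

    Vectorised over an array of candidate ``f`` in (0, 1).
    """
    f = np.atleast_1d(np.asarray(f, dtype=float))
    one_minus = 1.0 - f
    q_i = one_minus[:, None] ** i_vals
    p_i = (1.0 - f[:, None] ** i_vals - q_i) / (1.0 - q_i)
    q_n = one_minus ** n_total
    p_n = (1.0 - f ** n_total - q_n) / (1.0 - q_n)
    pred = p_i / p_n[:, None]
    return ((pred - obs) ** 2).sum(axis=1)


def estimate_f(profile: CoincidenceProfile) -> FEstimate:
    """Least-squares estimate of the balancing factor ``f``.

    Minimises the squared distance between the observed subset-coincidence
    ratios and ``p_truncal(f, i) / p_truncal(f, n_total)`` over ``f`` in
    (0, 1), via a 1000-point grid followed by bounded scalar refinement on
    the bracketing interval.  Deterministic for fixed input.

    When every observed ratio equals 1 no discordance was seen and ``f``
    is not identifiable (any sufficiently small ``f`` fits); the lower
    search boundary is returned with ``degenerate=True``.
    """
    if profile.n_total < 3:
        raise ValueError("f estimation needs n_total >= 3")
    if not profile.ratios:
        raise ValueError("empty coincidence profile")
    i_vals = np.array(sorted(profile.ratios), dtype=float)
    obs = np.array([profile.ratios[int(i)] for i in i_vals], dtype=float)
    if np.all(obs >= 1.0 - 1e-12):
        return FEstimate(f_hat=_F_LOWER, residual=float(((obs - 1.0) ** 2).sum()),
                         degenerate=True)
    grid = np.linspace(_F_LOWER, 1.0 - _F_LOWER, _GRID_SIZE)
    sse = _ratio_sse(obs, i_vals, profile.n_total, grid)
    k = int(np.argmin(sse))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, _GRID_SIZE - 1)]
    res = optimize.minimize_scalar(
        lambda f: float(_ratio_sse(obs, i_vals, profile.n_total, f)[0]),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    if res.fun <= sse[k]:
        return FEstimate(f_hat=float(res.x), residual=float(res.fun))
    return FEstimate(f_hat=float(grid[k]), residual=float(sse[k]))


@dataclass(frozen=True)
class OracleResult:
    """Monte-Carlo estimate of a classification probability."""

    estimate: float
    se: float
    reps: int


def monte_carlo_oracle(f: float, n: int, M: int, reps: int, seed: int) -> OracleResult:
    """Simulation oracle for :func:`p_finite_branches`.

    Draws ``n`` samples per repetition from the categorical distribution
    over the ``M`` first-tier branches (masses ``f*(1-f)**k``) and the
    ancestral remainder (mass ``(1-f)**M``).  A repetition fails iff all
    ``n`` samples land in one single first-tier branch; samples all in the
    ancestral remainder count as success, since the remainder carries no
    sub-clonal first-tier mutation to misclassify.  Returns the success
    fraction with its binomial standard error.
    """
    query = AnalyticQuery(f, n, M)
    if query.M == math.inf:
        raise ValueError("the oracle needs a finite branch count M")
    f, n, M = query.f, query.n, int(query.M)
    reps = _as_n(reps, name="reps")
    masses = f * (1.0 - f) ** np.arange(M, dtype=float)
    remainder = (1.0 - f) ** M
    total = masses.sum() + remainder
    if abs(total - 1.0) > 1e-12:
        raise RuntimeError(f"branch masses sum to {total!r}, not 1")
    cdf = np.cumsum(np.append(masses, remainder))
    cdf[-1] = 1.0
    rng = np.random.default_rng(seed)
    draws = np.searchsorted(cdf, rng.random((reps, n)), side="right")
    failures = np.logical_and(
        (draws == draws[:, :1]).all(axis=1), draws[:, 0] < M
    ).sum()
    p = 1.0 - failures / reps
    se = math.sqrt(max(p * (1.0 - p), 0.0) / reps)
    return OracleResult(estimate=float(p), se=float(se), reps=reps)
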