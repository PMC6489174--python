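"""Config-driven computational experiments on simulated tumours.

Each runner grows a batch of tumours and evaluates one question as a
tidy table, a pure function of ``(config, master_seed)``:

* :func:`run_single_cell_validation` — random single-cell sampling at
  several sample numbers, against the closed-form prediction
  ``p_truncal(f_largest, n)``;
* :func:`run_epsilon_sweep` — pooled two-sample biopsies of a well-mixed
  tumour over a detection-threshold sweep, locating the threshold at
  which classification becomes reliably correct (it tracks the largest
  sub-clone fraction);
* :func:`run_bulk_grid` — contiguous bulk biopsies of structured tumours
  over a (sample number x threshold) grid, with paired single-cell
  references;
* :func:`run_pattern_comparison` — rotational equidistant edge patterns
  versus random (and edge-random control) single-cell sampling.

The default scale (30 tumours of 5 000 cells, 1 000 sampling repetitions)
keeps a full run in minutes while preserving every ordering property of
interest; ``ExperimentConfig.full_scale()`` switches to 20 000-cell
tumours with 10 000 repetitions.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .analytic import p_truncal
from .clones import clonal_structure, genotype, ground_truth_clonal
from .growth import GrowthParams, TumourState, grow
from .inference import (
    PatternSpec,
    SamplingProtocol,
    call_clonal,
    proportion_correct,
    rotational_proportion_correct,
)

__all__ = [
    "ExperimentConfig",
    "grow_batch",
    "run_single_cell_validation",
    "run_epsilon_sweep",
    "run_bulk_grid",
    "run_pattern_comparison",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Shared knobs of the experiment runners.

    Every run is fully determined by ``(config, master seed)``: tumour
    seeds, per-repetition sampling seeds and subset draws all descend
    from the master seed.
    """

    n_tumours: int = 30
    n_target: int = 5_000
    mu: float = 0.5
    d: float = 0.1
    neighborhood: str = "moore8"
    repetitions: int = 1_000
    sample_numbers: Tuple[int, ...] = (2, 5, 10)
    size_fraction: float = 0.01
    epsilons: Tuple[float, ...] = (0.0, 0.3, 0.8)
    pattern_points: int = 4
    rotation_steps: int = 64

    @classmethod
    def full_scale(cls, **overrides) -> "ExperimentConfig":
        """Full-scale conditions: 20 000-cell tumours, 10 000 repetitions."""
        base = cls(n_target=20_000, repetitions=10_000)
        return replace(base, **overrides)


def _spawn_seeds(master_seed: int, count: int) -> List[int]:
    rng = random.Random(master_seed)
    return [rng.randrange(2 ** 31) for _ in range(count)]


def grow_batch(
    config: ExperimentConfig, seed: int, mode: str = "structured"
) -> List[TumourState]:
    """Grow ``config.n_tumours`` independent tumours.

    The stochastic growth makes the largest-sub-clone fraction ``f``
    emergent, so a batch spans a broad range of ``f`` by itself; no
    tumour is discarded.
    """
    states = []
    for tumour_seed in _spawn_seeds(seed, config.n_tumours):
        params = GrowthParams(
            mu=config.mu,
            d=config.d,
            n_target=config.n_target,
            mode=mode,
            neighborhood=config.neighborhood,
            seed=tumour_seed,
        )
        states.append(grow(params))
    return states


def run_single_cell_validation(
    config: ExperimentConfig, seed: int
) -> pd.DataFrame:
    """Random single-cell sampling versus the closed-form prediction.

    One row per tumour x sample number: the measured proportion of
    correct classifications over ``config.repetitions`` draws, its
    binomial standard error under the theoretical proportion
    ``p_truncal(f_largest, n)``, and that prediction itself.
    """
    states = grow_batch(config, seed, mode="structured")
    sub_seeds = _spawn_seeds(seed + 1, len(states) * len(config.sample_numbers))
    rows = []
    for t, state in enumerate(states):
        f = clonal_structure(state).f_largest
        for j, n in enumerate(config.sample_numbers):
            protocol = SamplingProtocol(kind="single_cell", n=n)
            result = proportion_correct(
                state,
                protocol,
                config.repetitions,
                sub_seeds[t * len(config.sample_numbers) + j],
            )
            p_theory = p_truncal(f, n)
            rows.append(
                {
                    "tumour": t,
                    "tumour_seed": state.params.seed,
                    "f_largest": f,
                    "n": n,
                    "proportion_correct": result.proportion_correct,
                    "p_theory": p_theory,
                    "se_theory": math.sqrt(
                        p_theory * (1.0 - p_theory) / config.repetitions
                    ),
                    "repetitions": config.repetitions,
                }
            )
    return pd.DataFrame(rows)


def _hypergeometric_sd(f: float, sample_size: int, population: int) -> float:
    """SD of the within-sample frequency of a mutation at population
    frequency ``f`` in a without-replacement sample."""
    if sample_size >= population:
        return 0.0
    fpc = (population - sample_size) / (population - 1)
    return math.sqrt(f * (1.0 - f) / sample_size * fpc)


def run_epsilon_sweep(
    config: ExperimentConfig,
    seed: int,
    epsilons: Optional[Sequence[float]] = None,
    n_samples: int = 2,
) -> pd.DataFrame:
    """Detection-threshold sweep on well-mixed tumours (pooled biopsies).

    For each tumour, ``n_samples`` pooled samples of
    ``config.size_fraction`` of the cells are scored over an epsilon
    grid (default 0, 0.1, ..., 1) plus one per-tumour *boundary*
    threshold ``f_largest + 3 x hypergeometric SD`` (capped at 1), the
    point above which even the largest sub-clone's within-sample
    frequency almost never reaches the threshold.
    """
    grid = (
        [round(e, 10) for e in np.linspace(0.0, 1.0, 11)]
        if epsilons is None
        else list(epsilons)
    )
    states = grow_batch(config, seed, mode="well_mixed")
    sub_seeds = _spawn_seeds(seed + 1, len(states))
    rows = []
    for t, state in enumerate(states):
        f = clonal_structure(state).f_largest
        sample_size = math.ceil(config.size_fraction * state.n_extant)
        boundary = min(
            1.0, f + 3.0 * _hypergeometric_sd(f, sample_size, state.n_extant)
        )
        eps_values = [(e, False) for e in grid] + [(boundary, True)]
        shared = _multi_epsilon_proportions(
            state,
            SamplingProtocol(
                kind="pooled", n=n_samples, size_fraction=config.size_fraction
            ),
            [e for e, _ in eps_values],
            config.repetitions,
            sub_seeds[t],
        )
        for (eps, is_boundary), p in zip(eps_values, shared):
            rows.append(
                {
                    "tumour": t,
                    "tumour_seed": state.params.seed,
                    "f_largest": f,
                    "n": n_samples,
                    "epsilon": eps,
                    "is_boundary": is_boundary,
                    "proportion_correct": p,
                    "repetitions": config.repetitions,
                }
            )
    return pd.DataFrame(rows)


def _multi_epsilon_proportions(
    state: TumourState,
    protocol: SamplingProtocol,
    epsilons: Sequence[float],
    repetitions: int,
    seed: int,
) -> List[float]:
    """Correct fractions at several thresholds from the *same* samples.

    Pairs the epsilon values repetition-by-repetition, eliminating
    sampling noise from threshold comparisons.
    """
    truth = ground_truth_clonal(state)
    for cell_id in state.extant:
        genotype(cell_id, state)
    master = random.Random(seed)
    correct = [0] * len(epsilons)
    for _ in range(repetitions):
        samples = protocol.draw(state, random.Random(master.randrange(2 ** 31)))
        for k, eps in enumerate(epsilons):
            if call_clonal(samples, eps) <= truth:
                correct[k] += 1
    return [c / repetitions for c in correct]


def run_bulk_grid(config: ExperimentConfig, seed: int) -> pd.DataFrame:
    """Bulk biopsies of structured tumours across (n, epsilon).

    For each tumour and each sample number, bulk biopsies (connected
    patches of ``config.size_fraction`` of the cells) are scored at every
    threshold in ``config.epsilons`` on the same draws, alongside a
    single-cell reference at the same ``n`` with a paired seed.
    """
    states = grow_batch(config, seed, mode="structured")
    rows = []
    for t, state in enumerate(states):
        f = clonal_structure(state).f_largest
        pair_seeds = _spawn_seeds(
            seed + 1 + t, len(config.sample_numbers)
        )
        for j, n in enumerate(config.sample_numbers):
            bulk = _multi_epsilon_proportions(
                state,
                SamplingProtocol(
                    kind="bulk", n=n, size_fraction=config.size_fraction
                ),
                config.epsilons,
                config.repetitions,
                pair_seeds[j],
            )
            single = proportion_correct(
                state,
                SamplingProtocol(kind="single_cell", n=n),
                config.repetitions,
                pair_seeds[j],
            )
            base = {
                "tumour": t,
                "tumour_seed": state.params.seed,
                "f_largest": f,
                "n": n,
                "repetitions": config.repetitions,
                "p_theory": p_truncal(f, n),
            }
            for eps, p in zip(config.epsilons, bulk):
                rows.append(
                    {**base, "protocol": "bulk", "epsilon": eps,
                     "proportion_correct": p}
                )
            rows.append(
                {**base, "protocol": "single_cell", "epsilon": 0.0,
                 "proportion_correct": single.proportion_correct}
            )
    return pd.DataFrame(rows)


def run_pattern_comparison(config: ExperimentConfig, seed: int) -> pd.DataFrame:
    """Rotational edge-pattern sampling versus random single cells.

    One row per tumour with three accuracies at ``n = pattern_points``
    samples: the deterministic rotation sweep of the equidistant edge
    pattern, plain random single-cell sampling, and random single cells
    restricted to the tumour edge (control for edge-specific effects).
    """
    states = grow_batch(config, seed, mode="structured")
    sub_seeds = _spawn_seeds(seed + 1, 2 * len(states))
    spec = PatternSpec(n_points=config.pattern_points)
    rows = []
    for t, state in enumerate(states):
        f = clonal_structure(state).f_largest
        pattern = rotational_proportion_correct(
            state, spec, n_steps=config.rotation_steps
        )
        rand = proportion_correct(
            state,
            SamplingProtocol(kind="single_cell", n=config.pattern_points),
            config.repetitions,
            sub_seeds[2 * t],
        )
        edge_rand = proportion_correct(
            state,
            SamplingProtocol(kind="edge_random", n=config.pattern_points),
            config.repetitions,
            sub_seeds[2 * t + 1],
        )
        rows.append(
            {
                "tumour": t,
                "tumour_seed": state.params.seed,
                "f_largest": f,
                "n": config.pattern_points,
                "pattern_accuracy": pattern.proportion_correct,
                "pattern_repetitions": pattern.repetitions,
                "random_accuracy": rand.proportion_correct,
                "edge_random_accuracy": edge_rand.proportion_correct,
                "repetitions": config.repetitions,
                "equidistant_n": 1.0 / (1.0 - f) if f < 1.0 else math.inf,
            }
        )
    return pd.DataFrame(rows)
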