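"""Biopsy sampling protocols on a grown tumour.

Four ways of drawing samples, mirroring how multi-region tumour material
can be collected:

* random single cells (``sample_single_cells``);
* contiguous bulk biopsies — a connected patch of cells grown by
  breadth-first expansion from a random seed cell (``sample_bulk``,
  structured tumours);
* pooled samples — random cells without spatial cohesion
  (``sample_pooled``, the natural biopsy of a well-mixed tumour);
* pattern samples — single cells at equidistant angles on the tumour
  edge, plus a stepwise rotation sweep of the template
  (``pattern_samples`` / ``rotation_sweep``, structured tumours).

Each sample carries its member cells and the within-sample frequency of
every mutation, which downstream inference thresholds at ``epsilon``.
"""

from __future__ import annotations

import math
import random
from collections import Counter, deque
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import numpy as np

from .clones import genotype
from .growth import _OFFSETS, TumourState

__all__ = [
    "BiopsySample",
    "PatternSpec",
    "sample_single_cells",
    "sample_bulk",
    "sample_pooled",
    "sample_edge_random",
    "edge_cells",
    "pattern_samples",
    "rotation_sweep",
]


@dataclass(frozen=True)
class BiopsySample:
    """A set of sampled cells with within-sample mutation frequencies."""

    cell_ids: FrozenSet[int]
    freq_in_sample: Dict[int, float]
    anchor: Optional[Tuple[int, int]] = None
    protocol_tag: str = "single_cell"
    truncated: bool = False  # bulk biopsy hit a component boundary


@dataclass(frozen=True)
class PatternSpec:
    """Equidistant edge-sampling template.

    ``n_points`` single-cell samples at target angles
    ``rotation_offset + 2*pi*k/n_points`` around the tumour centroid.
    """

    n_points: int = 4
    rotation_offset: float = 0.0
    placement: str = "edge-equidistant"

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")


def _as_rng(rng) -> random.Random:
    return rng if isinstance(rng, random.Random) else random.Random(rng)


def _freq_over(cells: Sequence[int], state: TumourState) -> Dict[int, float]:
    counts: Counter = Counter()
    for cell_id in cells:
        counts.update(genotype(cell_id, state))
    size = len(cells)
    return {m: c / size for m, c in counts.items()}


def _single_cell_sample(cell_id: int, state: TumourState, tag: str) -> BiopsySample:
    rec = state.record(cell_id)
    return BiopsySample(
        cell_ids=frozenset({cell_id}),
        freq_in_sample=dict.fromkeys(genotype(cell_id, state), 1.0),
        anchor=rec.position,
        protocol_tag=tag,
    )


def sample_single_cells(state: TumourState, n: int, rng) -> List[BiopsySample]:
    """``n`` distinct extant cells drawn uniformly without replacement."""
    rng = _as_rng(rng)
    if n > state.n_extant:
        raise ValueError(f"cannot draw {n} cells from {state.n_extant} extant")
    cells = rng.sample(sorted(state.extant), n)
    return [_single_cell_sample(c, state, "single_cell") for c in cells]


def _target_size(state: TumourState, size_fraction: float) -> int:
    size = math.ceil(size_fraction * state.n_extant)
    if size < 1:
        raise ValueError(f"size_fraction {size_fraction} gives an empty sample")
    return size


def sample_bulk(
    state: TumourState, n: int, size_fraction: float, rng
) -> List[BiopsySample]:
    """``n`` contiguous biopsies of ``ceil(size_fraction * N)`` cells each.

    Each biopsy grows by breadth-first expansion over occupied neighbour
    sites from a uniformly drawn seed cell, with randomised neighbour
    visiting order, so it is a connected patch of exactly the target size
    (smaller, with ``truncated=True``, only if the seed's connected
    component is smaller).  Biopsies are drawn independently and may
    overlap.
    """
    if state.occupancy is None:
        raise ValueError("bulk biopsies require a structured tumour")
    rng = _as_rng(rng)
    size = _target_size(state, size_fraction)
    offsets = list(_OFFSETS[state.params.neighborhood])
    occupancy = state.occupancy
    extant_sorted = sorted(state.extant)
    samples = []
    for _ in range(n):
        seed_cell = extant_sorted[rng.randrange(len(extant_sorted))]
        members: List[int] = [seed_cell]
        seen: Set[int] = {seed_cell}
        queue = deque([state.records[seed_cell].position])
        while queue and len(members) < size:
            x, y = queue.popleft()
            rng.shuffle(offsets)
            for dx, dy in offsets:
                neighbour = occupancy.get((x + dx, y + dy))
                if neighbour is not None and neighbour not in seen:
                    seen.add(neighbour)
                    members.append(neighbour)
                    queue.append((x + dx, y + dy))
                    if len(members) >= size:
                        break
        samples.append(
            BiopsySample(
                cell_ids=frozenset(members),
                freq_in_sample=_freq_over(members, state),
                anchor=state.records[seed_cell].position,
                protocol_tag="bulk",
                truncated=len(members) < size,
            )
        )
    return samples


def sample_pooled(
    state: TumourState, n: int, size_fraction: float, rng
) -> List[BiopsySample]:
    """``n`` pooled samples of random cells (no spatial cohesion).

    The natural biopsy of a well-mixed tumour; allowed on structured
    states as a control.  Cells are drawn uniformly without replacement
    within each sample; samples are independent of one another.
    """
    rng = _as_rng(rng)
    size = _target_size(state, size_fraction)
    if size > state.n_extant:
        raise ValueError(f"sample size {size} exceeds population {state.n_extant}")
    extant_sorted = sorted(state.extant)
    samples = []
    for _ in range(n):
        members = rng.sample(extant_sorted, size)
        samples.append(
            BiopsySample(
                cell_ids=frozenset(members),
                freq_in_sample=_freq_over(members, state),
                anchor=None,
                protocol_tag="pooled",
            )
        )
    return samples


def edge_cells(state: TumourState) -> Set[int]:
    """Extant cells with at least one empty neighbouring lattice site."""
    if state.occupancy is None:
        raise ValueError("edge detection requires a structured tumour")
    offsets = _OFFSETS[state.params.neighborhood]
    occupancy = state.occupancy
    edge = set()
    for cell_id in state.extant:
        x, y = state.records[cell_id].position
        for dx, dy in offsets:
            if (x + dx, y + dy) not in occupancy:
                edge.add(cell_id)
                break
    return edge


def sample_edge_random(state: TumourState, n: int, rng) -> List[BiopsySample]:
    """``n`` distinct single cells drawn uniformly from the tumour edge.

    Control protocol for pattern sampling: same cell population (the
    edge), no geometric constraint between the samples.
    """
    rng = _as_rng(rng)
    edge = sorted(edge_cells(state))
    if n > len(edge):
        raise ValueError(f"cannot draw {n} cells from {len(edge)} edge cells")
    cells = rng.sample(edge, n)
    return [_single_cell_sample(c, state, "edge_random") for c in cells]


def _edge_geometry(state: TumourState) -> dict:
    """Edge-cell ids, polar angles and radii about the extant centroid.

    Cached on the state; states are treated as immutable after growth.
    """
    if state.edge_cache is None:
        positions = np.array(
            [state.records[c].position for c in sorted(state.extant)], dtype=float
        )
        centroid = positions.mean(axis=0)
        edge = np.array(sorted(edge_cells(state)), dtype=int)
        edge_pos = np.array(
            [state.records[int(c)].position for c in edge], dtype=float
        )
        rel = edge_pos - centroid
        state.edge_cache = {
            "ids": edge,
            "angles": np.arctan2(rel[:, 1], rel[:, 0]),
            "radii": np.hypot(rel[:, 0], rel[:, 1]),
        }
    return state.edge_cache


def pattern_samples(state: TumourState, spec: PatternSpec) -> List[BiopsySample]:
    """Single-cell samples at equidistant angles on the tumour edge.

    For each target angle ``rotation_offset + 2*pi*k/n_points`` the edge
    cell with the nearest polar angle about the extant-cell centroid is
    selected (ties broken by larger radius, then lower cell id).  The
    returned samples are distinct: an already-selected cell is skipped in
    favour of the next-nearest candidate.
    """
    geo = _edge_geometry(state)
    ids, angles, radii = geo["ids"], geo["angles"], geo["radii"]
    if len(ids) < spec.n_points:
        raise ValueError(
            f"{len(ids)} edge cells cannot host a {spec.n_points}-point pattern"
        )
    chosen: List[int] = []
    taken = np.zeros(len(ids), dtype=bool)
    for k in range(spec.n_points):
        theta = spec.rotation_offset + 2.0 * math.pi * k / spec.n_points
        diff = np.abs((angles - theta + math.pi) % (2.0 * math.pi) - math.pi)
        order = np.lexsort((ids, -radii, np.round(diff, 12)))
        for idx in order:
            if not taken[idx]:
                taken[idx] = True
                chosen.append(int(ids[idx]))
                break
    return [_single_cell_sample(c, state, "pattern") for c in chosen]


def rotation_sweep(
    state: TumourState, spec: PatternSpec, n_steps: int = 64
) -> List[List[BiopsySample]]:
    """Pattern samples at ``n_steps`` rotations spanning one angular period.

    Offsets ``j * (2*pi/n_points) / n_steps`` for ``j = 0..n_steps-1``;
    by symmetry of the template one period covers the full circumference.
    Consecutive offsets that select identical cells are retained —
    repetition counts follow offsets, not uniqueness.  Deterministic.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    period = 2.0 * math.pi / spec.n_points
    sweeps = []
    for j in range(n_steps):
        rotated = PatternSpec(
            n_points=spec.n_points,
            rotation_offset=spec.rotation_offset + j * period / n_steps,
            placement=spec.placement,
        )
        sweeps.append(pattern_samples(state, rotated))
    return sweeps
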