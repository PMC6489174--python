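"""Sampling protocols: sizes, connectivity, edge geometry, patterns."""

import math
import random
from collections import deque

import pytest

from truncal.clones import clonal_structure, genotype
from truncal.growth import neighbors
from truncal.sampling import (
    PatternSpec,
    edge_cells,
    pattern_samples,
    rotation_sweep,
    sample_bulk,
    sample_edge_random,
    sample_pooled,
    sample_single_cells,
)

from conftest import build_state


def test_single_cells_distinct_and_certain(small_structured):
    samples = sample_single_cells(small_structured, 5, random.Random(1))
    assert len(samples) == 5
    ids = {next(iter(s.cell_ids)) for s in samples}
    assert len(ids) == 5
    for s in samples:
        assert set(s.freq_in_sample.values()) == {1.0}


def test_single_cells_exhaustive_union_is_all_mutations(small_structured):
    samples = sample_single_cells(
        small_structured, small_structured.n_extant, random.Random(2)
    )
    union = set().union(*(s.freq_in_sample for s in samples))
    assert union == set(clonal_structure(small_structured).freq)


def test_single_cells_overdraw_rejected(small_structured):
    with pytest.raises(ValueError):
        sample_single_cells(small_structured, small_structured.n_extant + 1, 1)


def test_bulk_biopsies_have_exact_size_and_connectivity(small_structured):
    state = small_structured
    samples = sample_bulk(state, 3, 0.05, random.Random(3))
    target = math.ceil(0.05 * state.n_extant)
    for s in samples:
        assert len(s.cell_ids) == target
        assert not s.truncated
        # connectivity under the state's neighbourhood
        positions = {state.records[c].position for c in s.cell_ids}
        start = next(iter(positions))
        seen = {start}
        queue = deque([start])
        while queue:
            pos = queue.popleft()
            for nbr in neighbors(pos, state.params.neighborhood):
                if nbr in positions and nbr not in seen:
                    seen.add(nbr)
                    queue.append(nbr)
        assert seen == positions


def test_bulk_whole_tumour_recovers_population_frequencies(small_structured):
    (sample,) = sample_bulk(small_structured, 1, 1.0, random.Random(4))
    assert sample.cell_ids == frozenset(small_structured.extant)
    cs = clonal_structure(small_structured)
    assert sample.freq_in_sample == pytest.approx(cs.freq)


def test_bulk_frequencies_are_integer_counts(small_structured):
    (sample,) = sample_bulk(small_structured, 1, 0.03, random.Random(5))
    size = len(sample.cell_ids)
    for fr in sample.freq_in_sample.values():
        assert (fr * size) == pytest.approx(round(fr * size), abs=1e-9)


def test_bulk_requires_structure(small_well_mixed):
    with pytest.raises(ValueError):
        sample_bulk(small_well_mixed, 1, 0.05, 1)


def test_pooled_sample_size_and_mean_frequency(small_well_mixed):
    state = small_well_mixed
    samples = sample_pooled(state, 40, 0.1, random.Random(6))
    size = math.ceil(0.1 * state.n_extant)
    assert all(len(s.cell_ids) == size for s in samples)
    cs = clonal_structure(state)
    mut = max(cs.freq, key=lambda m: cs.freq[m] if m != 0 else 0)
    mean = sum(s.freq_in_sample.get(mut, 0.0) for s in samples) / len(samples)
    # hypergeometric mean is the population frequency
    sd = math.sqrt(cs.freq[mut] * (1 - cs.freq[mut]) / size / len(samples))
    assert abs(mean - cs.freq[mut]) < 4 * sd + 1e-9


def test_pooled_full_fraction_is_exact(small_well_mixed):
    (sample,) = sample_pooled(small_well_mixed, 1, 1.0, random.Random(7))
    assert sample.freq_in_sample == pytest.approx(
        clonal_structure(small_well_mixed).freq
    )


def test_pooled_oversize_rejected(small_well_mixed):
    with pytest.raises(ValueError):
        sample_pooled(small_well_mixed, 1, 1.5, 1)


def test_edge_of_full_block_is_perimeter():
    cells = [(None, 0, (0, 0), True)]
    cells += [(0, None, (x, y), True) for x in range(3) for y in range(3)
              if (x, y) != (0, 0)]
    state = build_state(cells)
    edge = edge_cells(state)
    centre = state.occupancy[(1, 1)]
    assert centre not in edge
    assert len(edge) == 8


def test_edge_of_single_cell_and_filament():
    lone = build_state([(None, 0, (0, 0), True)])
    assert edge_cells(lone) == {0}
    filament = build_state(
        [(None, 0, (0, 0), True)] + [(0, None, (i, 0), True) for i in range(1, 10)]
    )
    assert edge_cells(filament) == set(filament.extant)


def test_pattern_on_disk_is_equidistant_and_peripheral(plain_disk):
    samples = pattern_samples(plain_disk, PatternSpec(n_points=4))
    assert len({s.cell_ids for s in samples}) == 4
    angles = sorted(math.atan2(y, x) % (2 * math.pi) for s in samples
                    for (x, y) in [s.anchor])
    gaps = [b - a for a, b in zip(angles, angles[1:])]
    gaps.append(2 * math.pi - sum(gaps))
    for gap in gaps:
        assert gap == pytest.approx(math.pi / 2, abs=0.2)
    for s in samples:
        x, y = s.anchor
        assert math.hypot(x, y) >= 9.0  # maximal radius up to rasterisation


def test_pattern_offset_periodicity(plain_disk):
    base = pattern_samples(plain_disk, PatternSpec(n_points=4, rotation_offset=0.3))
    shifted = pattern_samples(
        plain_disk, PatternSpec(n_points=4, rotation_offset=0.3 + math.pi / 2)
    )
    assert {s.cell_ids for s in base} == {s.cell_ids for s in shifted}


def test_single_point_pattern_takes_nearest_edge_cell(plain_disk):
    (sample,) = pattern_samples(plain_disk, PatternSpec(n_points=1))
    x, y = sample.anchor
    assert abs(math.atan2(y, x)) < 0.15
    assert x >= 9


def test_pattern_needs_enough_edge_cells():
    lone = build_state([(None, 0, (0, 0), True)])
    with pytest.raises(ValueError):
        pattern_samples(lone, PatternSpec(n_points=4))


def test_rotation_sweep_single_step_is_base_pattern(plain_disk):
    spec = PatternSpec(n_points=4)
    (only,) = rotation_sweep(plain_disk, spec, n_steps=1)
    base = pattern_samples(plain_disk, spec)
    assert [s.cell_ids for s in only] == [s.cell_ids for s in base]


def test_rotation_sweep_covers_extreme_edge_cells(plain_disk):
    sweeps = rotation_sweep(plain_disk, PatternSpec(n_points=4), n_steps=32)
    assert len(sweeps) == 32
    union = {c for samples in sweeps for s in samples for c in s.cell_ids}
    for pos in [(10, 0), (0, 10), (-10, 0), (0, -10)]:
        assert plain_disk.occupancy[pos] in union
    assert len(union) >= 32


def test_rotation_sweep_requires_steps(plain_disk):
    with pytest.raises(ValueError):
        rotation_sweep(plain_disk, PatternSpec(n_points=4), n_steps=0)


def test_edge_random_draws_from_edge_only(small_structured):
    samples = sample_edge_random(small_structured, 4, random.Random(8))
    edge = edge_cells(small_structured)
    assert all(next(iter(s.cell_ids)) in edge for s in samples)


def test_detected_set_matches_member_genotypes(small_structured):
    (sample,) = sample_bulk(small_structured, 1, 0.05, random.Random(9))
    carried = set().union(
        *(genotype(c, small_structured) for c in sample.cell_ids)
    )
    assert set(sample.freq_in_sample) == carried
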