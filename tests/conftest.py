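import math

import pytest
from hypothesis import settings

from truncal.growth import CellRecord, GrowthParams, TumourState, grow

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


def build_state(cells, mode="structured", mu=0.5, d=0.1):
    """Hand-built tumour state from (parent_id, new_mutation_id, position, alive).

    Cell ids are assigned sequentially; the first entry must be the
    founder (parent None, mutation 0).
    """
    records = [
        CellRecord(i, parent, mut, pos, alive)
        for i, (parent, mut, pos, alive) in enumerate(cells)
    ]
    extant = {r.cell_id for r in records if r.alive}
    occupancy = (
        {r.position: r.cell_id for r in records if r.alive}
        if mode == "structured"
        else None
    )
    params = GrowthParams(
        mu=mu, d=d, n_target=max(2, len(extant)), mode=mode, seed=0
    )
    return TumourState(
        records=records, extant=extant, occupancy=occupancy, params=params
    )


@pytest.fixture
def four_cell_state():
    """Genotypes {0}, {0}, {0,1}, {0,1,2}: one first-tier branch of size 1/2."""
    return build_state(
        [
            (None, 0, (0, 0), True),
            (0, None, (0, 1), True),
            (0, 1, (1, 0), True),
            (2, 2, (1, 1), True),
        ]
    )


@pytest.fixture
def drift_fixed_state():
    """Same lineage, but every cell lacking mutation 1 has died: {0,1} fixed."""
    return build_state(
        [
            (None, 0, (0, 0), False),
            (0, None, (0, 1), False),
            (0, 1, (1, 0), True),
            (2, 2, (1, 1), True),
        ]
    )


@pytest.fixture
def two_branch_state():
    """Two first-tier branches (mutations 1 and 2) plus the founder."""
    return build_state(
        [
            (None, 0, (0, 0), True),
            (0, 1, (-1, 0), True),
            (0, 2, (1, 0), True),
            (1, 3, (-2, 0), True),
            (2, 4, (2, 0), True),
        ]
    )


def disk_state(radius, assign=None):
    """Rasterised disk of cells; ``assign(x, y)`` may map positions to a
    first-tier branch (1=left-ish, 2=right-ish) for symmetry tests."""
    cells = [(None, 0, (0, 0), True)]
    roots = {}
    coords = [
        (x, y)
        for x in range(-radius, radius + 1)
        for y in range(-radius, radius + 1)
        if 0 < x * x + y * y <= radius * radius
    ]
    if assign is None:
        cells.extend((0, None, pos, True) for pos in coords)
    else:
        # branch roots first so members can point at them
        for branch, pos in ((1, (-1, 0)), (2, (1, 0))):
            roots[branch] = len(cells)
            cells.append((0, branch, pos, True))
        for pos in coords:
            if pos in ((-1, 0), (1, 0)):
                continue
            cells.append((roots[assign(*pos)], None, pos, True))
    return build_state(cells)


@pytest.fixture
def plain_disk():
    return disk_state(10)


@pytest.fixture
def half_plane_disk():
    """Disk split into two half-plane first-tier clones around the founder."""
    return disk_state(6, assign=lambda x, y: 1 if (x < 0 or (x == 0 and y > 0)) else 2)


@pytest.fixture(scope="session")
def small_structured():
    return grow(GrowthParams(mu=0.5, d=0.1, n_target=400, seed=42))


@pytest.fixture(scope="session")
def small_well_mixed():
    return grow(
        GrowthParams(mu=0.5, d=0.1, n_target=400, mode="well_mixed", seed=43)
    )


def smoothed_se(p, reps):
    """Binomial SE with add-one smoothing (non-zero at p in {0, 1})."""
    pt = (p * reps + 1.0) / (reps + 2.0)
    return math.sqrt(pt * (1.0 - pt) / reps)
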