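"""Stochastic tumour growth with neutral mutation accumulation.

Tumour cells occupy nodes of an unbounded two-dimensional integer
lattice (structured mode) or an unstructured pool (well-mixed mode).
Growth starts from a single founder cell carrying the founding truncal
mutation (id 0) and proceeds in discrete steps:

1. one cell able to divide is chosen uniformly at random — in structured
   mode a cell divides only into an adjacent empty lattice site, so cells
   walled in by neighbours are excluded from the draw (peripheral growth
   emerges); in well-mixed mode every cell can divide;
2. the daughter is placed on a uniformly chosen empty neighbouring site
   (structured) or simply added to the pool (well-mixed);
3. with probability ``mu`` the daughter acquires one fresh, never-seen
   mutation (infinite-allele assumption: each mutation arises exactly
   once and is lost only through cell death);
4. with probability ``d`` one uniformly chosen extant cell — the newborn
   daughter included — dies and frees its site.

All mutations are neutral.  The full lineage (parent id, birth mutation,
position) is recorded so the mutational profile of any cell can be
reconstructed afterwards.  Runs are bit-reproducible from the seed.
"""

from __future__ import annotations

import gzip
import json
import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

__all__ = [
    "MOORE8",
    "VONNEUMANN4",
    "GrowthParams",
    "CellRecord",
    "TumourState",
    "neighbors",
    "grow",
    "to_newick",
    "state_to_json",
    "state_from_json",
    "save_state",
    "load_state",
]

Coord = Tuple[int, int]

# Deterministic neighbour orders (row-major scan around the origin).
MOORE8: Tuple[Coord, ...] = (
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
)
VONNEUMANN4: Tuple[Coord, ...] = ((-1, 0), (0, -1), (0, 1), (1, 0))

_OFFSETS = {"moore8": MOORE8, "vonneumann4": VONNEUMANN4}


def neighbors(position: Coord, neighborhood: str = "moore8") -> List[Coord]:
    """Lattice sites adjacent to ``position`` (Moore or von Neumann)."""
    try:
        offsets = _OFFSETS[neighborhood]
    except KeyError:
        raise ValueError(f"unknown neighborhood {neighborhood!r}") from None
    x, y = position
    return [(x + dx, y + dy) for dx, dy in offsets]


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of a single growth run.

    mu
        Probability per division that the daughter acquires one new
        mutation.  Default 0.5: with realistic per-exome mutation rates a
        new detectable mutation arises in roughly every other division,
        producing early branching and broad intratumour heterogeneity.
    d
        Probability, per division, that one random extant cell dies
        afterwards.  Default 0.1, a non-aggressive tumour.
    n_target
        Extant population size at which growth stops (e.g. 20 000 cells
        so that a 1% biopsy holds 200 cells).
    mode
        ``"structured"`` (lattice) or ``"well_mixed"`` (no geometry).
    neighborhood
        ``"moore8"`` (default) or ``"vonneumann4"``; structured mode only.
    """

    mu: float = 0.5
    d: float = 0.1
    n_target: int = 20_000
    mode: str = "structured"
    neighborhood: str = "moore8"
    seed: int = 0
    max_steps: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.mu <= 1.0):
            raise ValueError(f"mu must lie in [0, 1], got {self.mu}")
        if not (0.0 <= self.d < 1.0):
            raise ValueError(f"d must lie in [0, 1), got {self.d}")
        if self.n_target < 2:
            raise ValueError(f"n_target must be >= 2, got {self.n_target}")
        if self.mode not in ("structured", "well_mixed"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.neighborhood not in _OFFSETS:
            raise ValueError(f"unknown neighborhood {self.neighborhood!r}")

    @property
    def effective_max_steps(self) -> int:
        # E[steps] ~ n_target / (1 - d); the default cap is far above that.
        if self.max_steps is not None:
            return self.max_steps
        return max(100_000, 100 * self.n_target)


@dataclass
class CellRecord:
    """One row of the append-only lineage table.

    ``new_mutation_id`` is the single novel mutation (if any) acquired at
    this cell's birth; the founder carries the truncal founder mutation 0.
    ``position`` is ``None`` in well-mixed mode.
    """

    __slots__ = ("cell_id", "parent_id", "new_mutation_id", "position", "alive")

    cell_id: int
    parent_id: Optional[int]
    new_mutation_id: Optional[int]
    position: Optional[Coord]
    alive: bool


@dataclass
class TumourState:
    """A grown tumour: lineage table plus the extant population.

    ``records`` is append-only and indexed by ``cell_id``; ``extant`` is
    the set of currently alive cells; ``occupancy`` maps lattice
    coordinates to alive cell ids (structured mode only).  States are
    treated as immutable after growth — downstream modules cache derived
    quantities (genotypes, edge geometry) on the private fields below.
    """

    records: List[CellRecord]
    extant: Set[int]
    occupancy: Optional[Dict[Coord, int]]
    params: GrowthParams
    steps_executed: int = 0
    births: int = 0
    deaths: int = 0
    # Caches populated lazily by the clones / sampling modules.
    genotype_cache: Dict[int, frozenset] = field(
        default_factory=dict, repr=False, compare=False
    )
    edge_cache: Optional[dict] = field(default=None, repr=False, compare=False)

    @property
    def n_extant(self) -> int:
        return len(self.extant)

    def record(self, cell_id: int) -> CellRecord:
        try:
            rec = self.records[cell_id]
        except IndexError:
            raise KeyError(f"unknown cell id {cell_id}") from None
        return rec


def grow(params: GrowthParams) -> TumourState:
    """Run the growth process until ``n_target`` cells are extant.

    Raises ``RuntimeError`` if the step cap is exceeded (or, defensively,
    on extinction — the death step is skipped while only one cell is
    alive, so a tumour cannot actually die out).
    """
    rng = random.Random(params.seed)
    structured = params.mode == "structured"
    offsets = _OFFSETS[params.neighborhood]
    mu, d = params.mu, params.d
    max_steps = params.effective_max_steps

    founder = CellRecord(0, None, 0, (0, 0) if structured else None, True)
    records: List[CellRecord] = [founder]
    alive: List[int] = [0]  # swap-remove list for O(1) uniform deletion
    alive_index: Dict[int, int] = {0: 0}
    occupancy: Optional[Dict[Coord, int]] = {(0, 0): 0} if structured else None
    next_mutation = 1
    steps = births = deaths = 0

    while len(alive) < params.n_target:
        if not alive:
            raise RuntimeError("tumour went extinct")
        steps += 1
        if steps > max_steps:
            raise RuntimeError(
                f"max_steps={max_steps} exceeded at population {len(alive)}"
            )

        if structured:
            # Uniform draw among cells with >= 1 empty neighbouring site
            # (rejection sampling; equivalent per committed division).
            while True:
                parent_id = alive[rng.randrange(len(alive))]
                px, py = records[parent_id].position
                empties = [
                    pos
                    for dx, dy in offsets
                    if (pos := (px + dx, py + dy)) not in occupancy
                ]
                if empties:
                    break
            position = empties[rng.randrange(len(empties))]
        else:
            parent_id = alive[rng.randrange(len(alive))]
            position = None

        if rng.random() < mu:
            mutation: Optional[int] = next_mutation
            next_mutation += 1
        else:
            mutation = None
        child_id = len(records)
        records.append(CellRecord(child_id, parent_id, mutation, position, True))
        alive_index[child_id] = len(alive)
        alive.append(child_id)
        if structured:
            occupancy[position] = child_id
        births += 1

        # Random death of one extant cell (daughter included); skipped at
        # population 1 so a nascent tumour cannot go extinct.
        if d > 0.0 and len(alive) > 1 and rng.random() < d:
            victim_pos = rng.randrange(len(alive))
            victim = alive[victim_pos]
            last = alive.pop()
            if victim_pos < len(alive):
                alive[victim_pos] = last
                alive_index[last] = victim_pos
            del alive_index[victim]
            rec = records[victim]
            rec.alive = False
            if structured:
                del occupancy[rec.position]
            deaths += 1

    return TumourState(
        records=records,
        extant=set(alive),
        occupancy=occupancy,
        params=params,
        steps_executed=steps,
        births=births,
        deaths=deaths,
    )


# ---------------------------------------------------------------------------
# Serialisation (documented JSON schema) and Newick export — plumbing.


def state_to_json(state: TumourState) -> dict:
    """JSON-serialisable dict for a state.

    Schema: ``{"params": {...}, "steps_executed": int, "births": int,
    "deaths": int, "records": [[cell_id, parent_id, new_mutation_id,
    x, y, alive], ...]}`` with ``x``/``y`` null in well-mixed mode.
    """
    rows = []
    for r in state.records:
        x, y = r.position if r.position is not None else (None, None)
        rows.append([r.cell_id, r.parent_id, r.new_mutation_id, x, y, int(r.alive)])
    p = state.params
    return {
        "params": {
            "mu": p.mu,
            "d": p.d,
            "n_target": p.n_target,
            "mode": p.mode,
            "neighborhood": p.neighborhood,
            "seed": p.seed,
            "max_steps": p.max_steps,
        },
        "steps_executed": state.steps_executed,
        "births": state.births,
        "deaths": state.deaths,
        "records": rows,
    }


def state_from_json(payload: dict) -> TumourState:
    """Inverse of :func:`state_to_json`."""
    params = GrowthParams(**payload["params"])
    records: List[CellRecord] = []
    extant: Set[int] = set()
    occupancy: Optional[Dict[Coord, int]] = (
        {} if params.mode == "structured" else None
    )
    for cell_id, parent_id, mut, x, y, alive in payload["records"]:
        position = (x, y) if x is not None else None
        records.append(CellRecord(cell_id, parent_id, mut, position, bool(alive)))
        if alive:
            extant.add(cell_id)
            if occupancy is not None:
                occupancy[position] = cell_id
    return TumourState(
        records=records,
        extant=extant,
        occupancy=occupancy,
        params=params,
        steps_executed=payload.get("steps_executed", 0),
        births=payload.get("births", 0),
        deaths=payload.get("deaths", 0),
    )


def save_state(state: TumourState, path: str) -> None:
    """Write a state as JSON (gzipped if the path ends in ``.gz``)."""
    payload = json.dumps(state_to_json(state))
    if path.endswith(".gz"):
        with gzip.open(path, "wt") as fh:
            fh.write(payload)
    else:
        with open(path, "w") as fh:
            fh.write(payload)


def load_state(path: str) -> TumourState:
    """Read a state written by :func:`save_state`."""
    if path.endswith(".gz"):
        with gzip.open(path, "rt") as fh:
            return state_from_json(json.load(fh))
    with open(path) as fh:
        return state_from_json(json.load(fh))


def to_newick(state: TumourState) -> str:
    """Cell-lineage tree in Newick format.

    Every recorded cell is a node labelled ``c<cell_id>``; a cell that
    acquired a mutation at birth is labelled ``c<id>|m<mutation_id>``.
    Internal nodes are ancestors, leaves are cells without offspring.
    """
    import dendropy

    tree = dendropy.Tree()
    nodes: Dict[int, dendropy.Node] = {}
    for rec in state.records:
        node = dendropy.Node()
        label = f"c{rec.cell_id}"
        if rec.new_mutation_id is not None:
            label += f"|m{rec.new_mutation_id}"
        node.label = label
        nodes[rec.cell_id] = node
        if rec.parent_id is None:
            tree.seed_node = node
        else:
            nodes[rec.parent_id].add_child(node)
    for leaf in tree.leaf_node_iter():  # leaves are serialised via taxa
        leaf.taxon = tree.taxon_namespace.new_taxon(label=leaf.label)
    return tree.as_string(schema="newick", suppress_rooting=True)
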