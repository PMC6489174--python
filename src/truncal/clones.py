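"""Clone structure reconstruction from a grown tumour.

Reconstructs per-cell genotypes from the lineage table and summarises the
population: per-mutation frequencies among extant cells, the truncal set
(mutations at frequency 1), the decomposition into first-tier branches —
sub-clones that diverged directly from the ancestral population, each
defined by the first non-truncal mutation on a cell's root-to-cell
lineage path — and the balancing factor ``f``.

"Truly clonal" is defined operationally as present in every extant cell
at observation time: a mutation fixed later by drift is indistinguishable
from a founder mutation in any sampling scheme.  The founder-only
alternative is available via ``ground_truth_clonal(..., founder_only=True)``.
First-tier branches are recomputed relative to this final truncal set, so
drift-fixed mutations never define a branch.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Tuple

from .growth import TumourState

__all__ = [
    "ClonalStructure",
    "genotype",
    "mutation_counts",
    "clonal_structure",
    "ground_truth_clonal",
]


def genotype(cell_id: int, state: TumourState) -> FrozenSet[int]:
    """Mutational profile of a cell: all mutations on its lineage path.

    Union of ``new_mutation_id`` along the parent chain up to the
    founder; always contains the founder mutation 0.  Results are
    memoised on the state, so reconstructing every extant genotype costs
    one chain walk per cell overall.
    """
    cache = state.genotype_cache
    got = cache.get(cell_id)
    if got is not None:
        return got
    chain: List[int] = []
    cur: Optional[int] = cell_id
    while cur is not None and cur not in cache:
        chain.append(cur)
        cur = state.record(cur).parent_id
    base = cache[cur] if cur is not None else frozenset()
    for cid in reversed(chain):
        mut = state.records[cid].new_mutation_id
        base = base | {mut} if mut is not None else base
        cache[cid] = base
    return cache[cell_id]


def mutation_counts(state: TumourState) -> Counter:
    """Carrier counts of every segregating mutation over extant cells."""
    counts: Counter = Counter()
    for cell_id in state.extant:
        counts.update(genotype(cell_id, state))
    return counts


@dataclass(frozen=True)
class ClonalStructure:
    """Population-level clone summary of a tumour.

    ``freq`` maps each segregating mutation to its frequency among extant
    cells; ``truncal`` holds the mutations at frequency 1; ``first_tier``
    lists ``(branch_root_mutation_id, size_fraction)`` sorted by
    descending size; ``ancestral_fraction`` is the share of extant cells
    whose genotype is exactly the truncal set.  ``f_largest`` is the
    highest frequency among non-truncal mutations (the balancing factor
    used throughout); ``f_first_tier`` the largest first-tier branch
    fraction.  Since every member of a branch carries its root mutation
    and no nested mutation can exceed its branch, the two coincide
    whenever any branch exists.
    """

    freq: Dict[int, float]
    truncal: FrozenSet[int]
    first_tier: Tuple[Tuple[int, float], ...]
    f_largest: float
    f_first_tier: float
    ancestral_fraction: float


def ground_truth_clonal(state: TumourState, founder_only: bool = False) -> FrozenSet[int]:
    """Mutations truly clonal in the tumour.

    Default: mutations carried by every extant cell (equal to the
    intersection of all extant genotypes; always contains 0).  With
    ``founder_only=True``, only the founder's own mutations count, i.e.
    drift-fixed mutations are excluded.
    """
    if not state.extant:
        raise ValueError("state has no extant cells")
    if founder_only:
        return frozenset({0})
    n = state.n_extant
    counts = mutation_counts(state)
    return frozenset(m for m, c in counts.items() if c == n)


def clonal_structure(state: TumourState) -> ClonalStructure:
    """Compute frequencies, truncal set, first-tier branches and ``f``."""
    if not state.extant:
        raise ValueError("state has no extant cells")
    n = state.n_extant
    counts = mutation_counts(state)
    freq = {m: c / n for m, c in counts.items()}
    truncal = frozenset(m for m, c in counts.items() if c == n)

    # Branch assignment: first non-truncal mutation on the root-to-cell
    # path, inherited from the parent once determined (None = ancestral).
    branch_of: Dict[int, Optional[int]] = {}
    records = state.records
    for cell_id in state.extant:
        chain: List[int] = []
        cur: Optional[int] = cell_id
        while cur is not None and cur not in branch_of:
            chain.append(cur)
            cur = records[cur].parent_id
        current: Optional[int] = branch_of[cur] if cur is not None else None
        for cid in reversed(chain):
            if current is None:
                mut = records[cid].new_mutation_id
                if mut is not None and mut not in truncal:
                    current = mut
            branch_of[cid] = current

    branch_counts: Counter = Counter(
        branch_of[cell_id] for cell_id in state.extant
    )
    ancestral = branch_counts.pop(None, 0)
    first_tier = tuple(
        sorted(
            ((m, c / n) for m, c in branch_counts.items()),
            key=lambda item: (-item[1], item[0]),
        )
    )
    f_largest = max(
        (fr for m, fr in freq.items() if m not in truncal), default=0.0
    )
    f_first_tier = first_tier[0][1] if first_tier else 0.0
    return ClonalStructure(
        freq=freq,
        truncal=truncal,
        first_tier=first_tier,
        f_largest=f_largest,
        f_first_tier=f_first_tier,
        ancestral_fraction=ancestral / n,
    )
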