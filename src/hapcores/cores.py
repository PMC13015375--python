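"""Block cores via a rank-aware 2-D sweep line.

Within a connected component of the block-overlap graph, the *block core* is
the largest subset of blocks whose multi-way intersection is non-empty: they
share at least one common haplotype and a common interval of positive
length.  It is reported as the tuple (B*, H*, S*, E*) with H* the common
haplotype set, S* = max s_i and E* = min e_i over the members.

The sweep processes one start and one end event per block along the site
axis (x); at every end event the active blocks are projected onto the PBWT
rank axis (y) at the ending site, where each block occupies a small number
of contiguous rank runs (exactly one at its own end site).  A 1-D sweep
over the run boundaries finds the deepest rank — the rank covered by the
most blocks — and the blocks covering it form a candidate core.  Because
every covering block contains the witness haplotype at that rank, each
candidate's multi-way intersection is provably non-empty, and every optimal
subset is discovered at the end event of its earliest-ending member; the
deepest candidate over all end events is therefore a true block core.

A minimum core length L restricts the blocks considered at an end event e
to those spanning at least L back from e (the persistence filter A_L(e)),
which guarantees E* - S* >= L for every returned core.
"""
from __future__ import annotations

import dataclasses
import warnings

from .blocks import Block, BlockSet
from .overlap import Component, build_overlap_graph, connected_components
from .panel import HaplotypePanel, interval_length
from .pbwt import PBWTIndex


@dataclasses.dataclass
class RankIntervalSet:
    """A block's haplotypes as disjoint inclusive rank runs at one site."""

    block_id: int
    site: int
    runs: list[tuple[int, int]]  # sorted, disjoint [lo, hi] inclusive


@dataclasses.dataclass(frozen=True)
class Core:
    """Block core (B*, H*, S*, E*); size 0 encodes 'no qualifying core'."""

    member_blocks: frozenset[int]
    H_star: frozenset[int]
    S_star: int | None
    E_star: int | None

    @property
    def size(self) -> int:
        return len(self.member_blocks)

    @classmethod
    def empty(cls) -> "Core":
        return cls(frozenset(), frozenset(), None, None)


@dataclasses.dataclass
class SweepStats:
    """Instrumentation counters for the complexity contract."""

    events: int = 0
    end_events: int = 0
    max_active: int = 0
    max_runs: int = 0


def project_ranks(block: Block, site: int, index: PBWTIndex) -> RankIntervalSet:
    """Project a block's haplotypes onto PBWT ranks at ``site``.

    Returns the maximal runs of consecutive ranks.  Within [block.s,
    block.e] the relative PBWT order of the block's haplotypes is invariant
    and at site == block.e the members form exactly one run (adjacency);
    projection outside the block interval is permitted but flagged.
    """
    if not (block.s <= site <= block.e):
        warnings.warn(
            f"projecting block {block.id} at site {site} outside "
            f"[{block.s}, {block.e}]",
            stacklevel=2,
        )
    r = index.rank_arrays[site]
    ranks = sorted(int(r[h]) for h in block.H)
    runs: list[tuple[int, int]] = []
    lo = hi = ranks[0]
    for v in ranks[1:]:
        if v == hi + 1:
            hi = v
        else:
            runs.append((lo, hi))
            lo = hi = v
    runs.append((lo, hi))
    return RankIntervalSet(block_id=block.id, site=site, runs=runs)


def _elementary_candidates(interval_sets: list[RankIntervalSet]):
    """Covering block-id sets of the elementary rank intervals.

    Run endpoints split the rank axis into elementary intervals; for each
    one with positive coverage the covering id set is returned (de-duplicated
    keeping the smallest witness rank) as (depth, witness_rank, ids).
    """
    bounds = sorted({b for iv in interval_sets for (lo, hi) in iv.runs for b in (lo, hi + 1)})
    seen: dict[frozenset[int], tuple[int, int]] = {}
    for a, b in zip(bounds, bounds[1:]):
        covering = frozenset(
            iv.block_id
            for iv in interval_sets
            if any(lo <= a and b <= hi + 1 for (lo, hi) in iv.runs)
        )
        if covering and covering not in seen:
            seen[covering] = (len(covering), a)
    return [(depth, rank, ids) for ids, (depth, rank) in seen.items()]


def max_depth_point(interval_sets: list[RankIntervalSet]):
    """Maximum number of blocks covering a single rank.

    Returns (depth, witness_rank, covering_block_ids); (0, None, frozenset())
    on empty input.  Ties on depth are broken by the smallest rank.
    """
    cands = _elementary_candidates(interval_sets)
    if not cands:
        return 0, None, frozenset()
    depth, rank, ids = max(cands, key=lambda t: (t[0], -t[1]))
    return depth, rank, ids


def _block_map(blocks: BlockSet) -> dict[int, Block]:
    return blocks.by_id()


def _sweep_component(
    component: Component,
    blocks: BlockSet,
    index: PBWTIndex,
    min_core_length: float | None,
    unit: str,
    min_core_width: int,
    panel: HaplotypePanel | None,
    stats: SweepStats | None,
) -> Core:
    bmap = _block_map(blocks)
    members = [bmap[i] for i in component.block_ids]
    # end (kind 0) before start (kind 1) at equal positions: a block [s, p)
    # is never co-active with one starting at p (half-open intervals)
    events = sorted(
        [(b.s, 1, b.id) for b in members] + [(b.e, 0, b.id) for b in members]
    )
    active: set[int] = set()
    best: Core = Core.empty()
    best_key = None  # (size,) — earliest event wins ties, so strict improvement only
    for pos, kind, bid in events:
        if stats is not None:
            stats.events += 1
        if kind == 1:
            active.add(bid)
            if stats is not None:
                stats.max_active = max(stats.max_active, len(active))
            continue
        # end event of block bid at site pos
        if stats is not None:
            stats.end_events += 1
        if min_core_length is None:
            considered = list(active)
        else:
            considered = [
                i
                for i in active
                if interval_length(panel, (bmap[i].s, pos), unit) >= min_core_length
            ]
        if considered:
            sets = [project_ranks(bmap[i], pos, index) for i in considered]
            if stats is not None:
                stats.max_runs = max(stats.max_runs, sum(len(s.runs) for s in sets))
            cands = _elementary_candidates(sets)
            cands.sort(key=lambda t: (-t[0], t[1]))
            # deepest candidate whose explicit haplotype intersection is wide
            # enough; among equal-depth valid candidates at this event prefer
            # the lexicographically smallest id tuple
            chosen = None
            chosen_depth = None
            for depth, _rank, ids in cands:
                if chosen is not None and depth < chosen_depth:
                    break
                H = frozenset.intersection(*(bmap[i].H for i in ids))
                if len(H) < min_core_width:
                    continue
                key = tuple(sorted(ids))
                if chosen is None or key < tuple(sorted(chosen[0])):
                    chosen = (ids, H)
                    chosen_depth = depth
            if chosen is not None:
                ids, H = chosen
                S = max(bmap[i].s for i in ids)
                E = min(bmap[i].e for i in ids)
                if len(ids) > best.size:
                    best = Core(member_blocks=ids, H_star=H, S_star=S, E_star=E)
        active.discard(bid)
    return best


def find_block_core(
    component: Component,
    blocks: BlockSet,
    index: PBWTIndex,
    min_core_length: float | None = None,
    unit: str = "sites",
    min_core_width: int = 1,
    panel: HaplotypePanel | None = None,
    with_stats: bool = False,
):
    """Maximum-cardinality block subset with non-empty multi-way intersection.

    Returns the block core of ``component`` (a ``Core``; size 0 when no
    candidate meets ``min_core_width``/``min_core_length``).  Ties between
    equal-size cores go to the candidate at the earliest end event, then to
    the lexicographically smallest sorted block-id tuple.  With
    ``with_stats=True`` returns (core, SweepStats).
    """
    if min_core_width < 1:
        raise ValueError("min_core_width must be >= 1")
    stats = SweepStats()
    core = _sweep_component(
        component, blocks, index, min_core_length, unit, min_core_width, panel, stats
    )
    if with_stats:
        return core, stats
    return core


def find_all_cores(
    blocks: BlockSet,
    index: PBWTIndex,
    L_overlap: float,
    W_overlap: int = 1,
    min_core_length: float | None = None,
    min_core_width: int = 1,
    panel: HaplotypePanel | None = None,
    overlap_unit: str = "sites",
    core_unit: str = "sites",
) -> list[tuple[Component, Core]]:
    """Overlap graph -> connected components -> one block core per component."""
    graph = build_overlap_graph(blocks, L_overlap, W_overlap, panel, overlap_unit)
    comps = connected_components(graph)
    out = []
    for comp in comps:
        core = find_block_core(
            comp, blocks, index, min_core_length, core_unit, min_core_width, panel
        )
        out.append((comp, core))
    return out
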