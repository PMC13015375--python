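"""Local cores (maximal cliques) and the local core graph.

A *local core* is an inclusion-maximal subset of blocks with non-empty
multi-way intersection: no further block can be added without emptying the
common haplotype set or interval (or violating the minimum core length).
A component may contain many local cores; the block core (the maximum one)
is always among them.

Enumeration reuses the 2-D sweep: at every end event the active,
length-filtered blocks are projected onto PBWT ranks, and *every*
elementary rank interval's covering block set becomes a candidate (not only
the deepest point, since maximal cliques of all sizes are wanted).
Candidates are pooled globally across events, keyed by their frozen id
sets; a final size-descending pass keeps a candidate only when it is not a
subset of an already-kept one.  Every candidate has a witness haplotype
shared by all its blocks, hence is valid, and every inclusion-maximal valid
subset surfaces at the end event of its earliest-ending member, so on a
component the kept family equals the family of inclusion-maximal valid
subsets.
"""
from __future__ import annotations

import dataclasses
import statistics

from .blocks import BlockSet
from .cores import Core, _elementary_candidates, project_ranks
from .overlap import Component, build_overlap_graph, connected_components
from .panel import HaplotypePanel, interval_length
from .pbwt import PBWTIndex


@dataclasses.dataclass(frozen=True)
class LocalCore:
    member_blocks: frozenset[int]
    H_star: frozenset[int]
    S_star: int
    E_star: int
    maximal: bool = True

    @property
    def size(self) -> int:
        return len(self.member_blocks)

    def sort_key(self):
        return (-self.size, self.S_star, tuple(sorted(self.member_blocks)))


def enumerate_local_cores(
    component: Component,
    blocks: BlockSet,
    index: PBWTIndex,
    min_core_length: float | None = None,
    unit: str = "sites",
    panel: HaplotypePanel | None = None,
) -> list[LocalCore]:
    """All local cores of a component, sorted by (size desc, S*, id tuple)."""
    bmap = blocks.by_id()
    members = [bmap[i] for i in component.block_ids]
    events = sorted(
        [(b.s, 1, b.id) for b in members] + [(b.e, 0, b.id) for b in members]
    )
    active: set[int] = set()
    pool: set[frozenset[int]] = set()
    for pos, kind, bid in events:
        if kind == 1:
            active.add(bid)
            continue
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
            for _depth, _rank, ids in _elementary_candidates(sets):
                pool.add(ids)
        active.discard(bid)

    # size-descending subset filter: keep a candidate iff it is not contained
    # in any kept (necessarily maximal) candidate
    kept: list[frozenset[int]] = []
    for cand in sorted(pool, key=lambda c: (-len(c), tuple(sorted(c)))):
        if not any(cand <= k for k in kept):
            kept.append(cand)

    cores = []
    for ids in kept:
        H = frozenset.intersection(*(bmap[i].H for i in ids))
        S = max(bmap[i].s for i in ids)
        E = min(bmap[i].e for i in ids)
        cores.append(LocalCore(member_blocks=ids, H_star=H, S_star=S, E_star=E))
    cores.sort(key=LocalCore.sort_key)
    return cores


def find_all_local_cores(
    blocks: BlockSet,
    index: PBWTIndex,
    L_overlap: float,
    W_overlap: int = 1,
    min_core_length: float | None = None,
    panel: HaplotypePanel | None = None,
    overlap_unit: str = "sites",
    core_unit: str = "sites",
) -> list[tuple[Component, list[LocalCore]]]:
    """Local cores of every connected component of the overlap graph."""
    graph = build_overlap_graph(blocks, L_overlap, W_overlap, panel, overlap_unit)
    return [
        (
            comp,
            enumerate_local_cores(comp, blocks, index, min_core_length, core_unit, panel),
        )
        for comp in connected_components(graph)
    ]


# ---------------------------------------------------------------------------
# local core graph


@dataclasses.dataclass
class CoreGraphEdge:
    core_i: int
    core_j: int
    shared_blocks: int
    iou_w: float
    iou_l: float


@dataclasses.dataclass
class CoreGraph:
    """Local cores as nodes; edges connect cores sharing >= 1 block.

    Per-edge intersection-over-union redundancy measures: iou_w over the
    cores' haplotype sets, iou_l over their intervals.  Per-node robustness
    summaries median(W)/max(W) and median(L)/max(L) over member blocks are
    available when the producing block set is supplied.
    """

    cores: list[LocalCore | Core]
    edges: list[CoreGraphEdge]
    node_metrics: list[dict[str, float]] | None = None


def _interval_iou(s1: int, e1: int, s2: int, e2: int) -> float:
    inter = min(e1, e2) - max(s1, s2)
    if inter <= 0:
        return 0.0
    union = (e1 - s1) + (e2 - s2) - inter
    return inter / union


def build_core_graph(
    cores: list[LocalCore],
    blocks: BlockSet | None = None,
) -> CoreGraph:
    edges = []
    for i in range(len(cores)):
        for j in range(i + 1, len(cores)):
            shared = cores[i].member_blocks & cores[j].member_blocks
            if not shared:
                continue
            hu = cores[i].H_star | cores[j].H_star
            iou_w = len(cores[i].H_star & cores[j].H_star) / len(hu) if hu else 0.0
            iou_l = _interval_iou(
                cores[i].S_star, cores[i].E_star, cores[j].S_star, cores[j].E_star
            )
            edges.append(
                CoreGraphEdge(
                    core_i=i,
                    core_j=j,
                    shared_blocks=len(shared),
                    iou_w=iou_w,
                    iou_l=iou_l,
                )
            )
    node_metrics = None
    if blocks is not None:
        bmap = blocks.by_id()
        node_metrics = []
        for core in cores:
            widths = [bmap[i].width for i in sorted(core.member_blocks)]
            lengths = [bmap[i].length_sites for i in sorted(core.member_blocks)]
            node_metrics.append(
                {
                    "median_w_over_max_w": statistics.median(widths) / max(widths),
                    "median_l_over_max_l": statistics.median(lengths) / max(lengths),
                }
            )
    return CoreGraph(cores=list(cores), edges=edges, node_metrics=node_metrics)
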