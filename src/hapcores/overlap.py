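"""The (L,W)-block-overlap graph and its connected components.

Two blocks overlap when their interval intersection [max(s1,s2), min(e1,e2))
has length >= L_overlap (in the chosen unit) and their haplotype sets share
at least W_overlap members.  Blocks are nodes; overlaps are edges.
"""
from __future__ import annotations

import dataclasses

import networkx as nx

from .blocks import Block, BlockSet
from .panel import HaplotypePanel, interval_length


@dataclasses.dataclass
class OverlapGraph:
    n_blocks: int
    adjacency: list[list[int]]  # sorted neighbor lists, symmetric, no self-loops
    L: float
    unit: str
    W: int

    def edges(self):
        for i, nbrs in enumerate(self.adjacency):
            for j in nbrs:
                if i < j:
                    yield (i, j)

    @property
    def n_edges(self) -> int:
        return sum(len(nbrs) for nbrs in self.adjacency) // 2


@dataclasses.dataclass
class Component:
    """Connected component: sorted block ids."""

    block_ids: list[int]

    def __len__(self) -> int:
        return len(self.block_ids)


def block_intersection(b1: Block, b2: Block) -> tuple[frozenset[int], int, int]:
    """(H1 ∩ H2, max(s1, s2), min(e1, e2)).

    The intersection is non-empty iff the haplotype set is non-empty and the
    interval has positive length (half-open semantics: touching intervals do
    not overlap).
    """
    return (b1.H & b2.H, max(b1.s, b2.s), min(b1.e, b2.e))


def is_lw_overlap(
    b1: Block,
    b2: Block,
    L: float,
    W: int = 1,
    panel: HaplotypePanel | None = None,
    unit: str = "sites",
) -> bool:
    """True iff the interval intersection is >= L and |H1 ∩ H2| >= W."""
    H, s, e = block_intersection(b1, b2)
    if len(H) < W or e <= s:
        return False
    return interval_length(panel, (s, e), unit) >= L


def build_overlap_graph(
    blocks: BlockSet,
    L: float,
    W: int = 1,
    panel: HaplotypePanel | None = None,
    unit: str = "sites",
    method: str = "sweep",
) -> OverlapGraph:
    """Build the (L, W)-overlap graph over a canonically sorted block set.

    With method='sweep', candidate pairs are generated by an interval sweep
    on the x-axis (only pairs whose [s, e) intervals positively intersect are
    tested); method='naive' tests all pairs and serves as the oracle.
    """
    n = len(blocks)
    adj: list[set[int]] = [set() for _ in range(n)]

    def add_if_overlap(i: int, j: int) -> None:
        if is_lw_overlap(blocks[i], blocks[j], L, W, panel, unit):
            adj[i].add(j)
            adj[j].add(i)

    if method == "naive":
        for i in range(n):
            for j in range(i + 1, n):
                add_if_overlap(i, j)
    elif method == "sweep":
        order = sorted(range(n), key=lambda i: (blocks[i].s, blocks[i].e, i))
        active: list[int] = []
        for i in order:
            s_i = blocks[i].s
            active = [j for j in active if blocks[j].e > s_i]
            for j in active:
                add_if_overlap(i, j)
            active.append(i)
    else:
        raise ValueError(f"unknown method {method!r}")
    return OverlapGraph(
        n_blocks=n,
        adjacency=[sorted(nbrs) for nbrs in adj],
        L=L,
        unit=unit,
        W=W,
    )


def connected_components(graph: OverlapGraph) -> list[Component]:
    """Connected components, sorted by smallest member id."""
    g = nx.Graph()
    g.add_nodes_from(range(graph.n_blocks))
    g.add_edges_from(graph.edges())
    comps = [Component(block_ids=sorted(c)) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: c.block_ids[0])
    return comps
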