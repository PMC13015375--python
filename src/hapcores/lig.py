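"""Local IBD graphs (LIG) and the block <-> persistent-clique correspondence.

At a site k, the local IBD graph G_k connects haplotype pairs that share an
IBD segment covering k; restricting to segments of length >= L gives
G_k(L).  A set of >= W haplotypes that are pairwise connected at k is a
W-clique; a clique that holds over a run of >= L consecutive sites is an
L-persistent W-clique, and such persistent cliques are exactly (L, W)-
haplotype blocks when IBD is taken as exact sequence identity.  This module
provides that verification lens plus the per-site IBD-rate summary track.

Interval semantics: a segment [s, e) covers site k iff s <= k < e
(half-open throughout, consistent with the rest of the package).
"""
from __future__ import annotations

import dataclasses
import itertools
from collections import defaultdict

import numpy as np

from .blocks import BlockSet, enumerate_candidates, find_width_maximal_blocks
from .panel import HaplotypePanel, interval_length
from .pbwt import PBWTIndex, build_pbwt


@dataclasses.dataclass(frozen=True)
class IBDSegment:
    """Pairwise shared segment over half-open [s, e); hap_i < hap_j."""

    hap_i: int
    hap_j: int
    s: int
    e: int

    def __post_init__(self) -> None:
        if self.hap_i == self.hap_j:
            raise ValueError("an IBD segment needs two distinct haplotypes")
        if self.e <= self.s:
            raise ValueError(f"empty segment interval [{self.s}, {self.e})")

    @property
    def pair(self) -> tuple[int, int]:
        return (min(self.hap_i, self.hap_j), max(self.hap_i, self.hap_j))


@dataclasses.dataclass
class LocalIBDGraph:
    site: int
    edges: set[tuple[int, int]]  # ordered pairs (i < j)
    L: float | None = None

    def has_edge(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in self.edges


def _segment_length(seg: IBDSegment, panel, unit: str) -> float:
    return interval_length(panel, (seg.s, seg.e), unit)


def build_lig(
    segments: list[IBDSegment],
    k: int,
    L: float | None = None,
    unit: str = "sites",
    panel: HaplotypePanel | None = None,
) -> LocalIBDGraph:
    """G_k(L): edges for pairs with a segment of length >= L covering site k."""
    edges = set()
    for seg in segments:
        if seg.s <= k < seg.e and (
            L is None or _segment_length(seg, panel, unit) >= L
        ):
            edges.add(seg.pair)
    return LocalIBDGraph(site=k, edges=edges, L=L)


def _merge_pair_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals; overlapping or touching runs merge."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def blocks_to_segments(blocks: BlockSet) -> list[IBDSegment]:
    """Expand blocks into pairwise segments, merging per-pair interval unions."""
    per_pair: dict[tuple[int, int], list[tuple[int, int]]] = defaultdict(list)
    for b in blocks:
        for i, j in itertools.combinations(b.members, 2):
            per_pair[(i, j)].append((b.s, b.e))
    out = []
    for (i, j), ivs in sorted(per_pair.items()):
        for s, e in _merge_pair_intervals(ivs):
            out.append(IBDSegment(hap_i=i, hap_j=j, s=s, e=e))
    return out


def pairwise_match_segments(panel: HaplotypePanel, min_sites: int = 1) -> list[IBDSegment]:
    """Maximal exact-agreement runs >= min_sites for every haplotype pair.

    These play the role of IBD segments when identity by state over the
    panel is taken as the sharing criterion (small panels only: O(M^2 N)).
    """
    X = panel.alleles
    M, N = panel.M, panel.N
    out = []
    for i in range(M):
        for j in range(i + 1, M):
            eq = X[i] == X[j]
            k = 0
            while k < N:
                if eq[k]:
                    start = k
                    while k < N and eq[k]:
                        k += 1
                    if k - start >= min_sites:
                        out.append(IBDSegment(hap_i=i, hap_j=j, s=start, e=k))
                else:
                    k += 1
    return out


def ibd_rate_track(
    segments: list[IBDSegment],
    n_haps: int,
    n_sites: int,
    L: float | None = None,
    unit: str = "sites",
    panel: HaplotypePanel | None = None,
) -> np.ndarray:
    """Fraction of haplotype pairs with a qualifying segment at each site.

    Piecewise constant between segment endpoints; per-pair interval unions
    are merged first so overlapping segments are not double counted.
    """
    per_pair: dict[tuple[int, int], list[tuple[int, int]]] = defaultdict(list)
    for seg in segments:
        if L is None or _segment_length(seg, panel, unit) >= L:
            per_pair[seg.pair].append((seg.s, seg.e))
    diff = np.zeros(n_sites + 1, dtype=np.int64)
    for ivs in per_pair.values():
        for s, e in _merge_pair_intervals(ivs):
            diff[s] += 1
            diff[min(e, n_sites)] -= 1
    counts = np.cumsum(diff[:-1])
    n_pairs = n_haps * (n_haps - 1) // 2
    return counts / n_pairs if n_pairs else counts.astype(float)


# ---------------------------------------------------------------------------
# block <-> persistent-clique verification


@dataclasses.dataclass
class EquivalenceReport:
    n_blocks: int
    n_persistent_cliques: int
    counterexamples_blocks: list  # (block_id, site, pair) triples
    counterexamples_cliques: list  # (clique, interval) pairs
    segment_provenance: str = "pairwise exact matches of the panel"

    @property
    def blocks_are_cliques(self) -> bool:
        return not self.counterexamples_blocks

    @property
    def cliques_are_blocks(self) -> bool:
        return not self.counterexamples_cliques

    @property
    def passed(self) -> bool:
        return self.blocks_are_cliques and self.cliques_are_blocks


def _persistent_cliques(panel: HaplotypePanel, segments, L: int, W: int):
    """L-persistent W-cliques scanned from the per-site LIG sequence.

    Maximal cliques are read off each G_k(L) (via networkx); a clique's
    persistence range is the run of consecutive sites over which all its
    pairs stay connected, and only ranges of >= L sites qualify.
    """
    import networkx as nx

    pair_cover: dict[tuple[int, int], list[tuple[int, int]]] = defaultdict(list)
    for seg in segments:
        if seg.e - seg.s >= L:
            pair_cover[seg.pair].append((seg.s, seg.e))
    for pair in pair_cover:
        pair_cover[pair] = _merge_pair_intervals(pair_cover[pair])

    found: dict[frozenset[int], set[tuple[int, int]]] = defaultdict(set)
    for k in range(panel.N):
        g = nx.Graph()
        for pair, ivs in pair_cover.items():
            if any(s <= k < e for s, e in ivs):
                g.add_edge(*pair)
        for clique in nx.find_cliques(g):
            if len(clique) < W:
                continue
            cset = frozenset(clique)
            # persistence range containing k: intersect per-pair coverage
            lo, hi = 0, panel.N
            ok = True
            for i, j in itertools.combinations(sorted(cset), 2):
                cover = pair_cover.get((i, j), [])
                containing = [iv for iv in cover if iv[0] <= k < iv[1]]
                if not containing:
                    ok = False
                    break
                lo = max(lo, containing[0][0])
                hi = min(hi, containing[0][1])
            if ok and hi - lo >= L:
                found[cset].add((lo, hi))
    return found


def verify_block_clique_equivalence(
    panel: HaplotypePanel,
    blocks: BlockSet | None = None,
    L: int = 2,
    W: int = 2,
    index: PBWTIndex | None = None,
) -> EquivalenceReport:
    """Check both directions of the block / persistent-clique correspondence.

    (a) every (L, W)-block's haplotype set is a W-clique in G_k(L) at every
        site k of its interval;
    (b) every L-persistent W-clique scanned from the LIG sequence is
        contained in some row-/interval-maximal (L, W)-block candidate
        (containment of both the haplotype set and the persistence range).

    Direction (b) is checked against the candidate family *before* the
    width-maximality filter: a persistent clique's full range can exceed
    every width-maximal block's interval when a wider block on a
    sub-interval supersedes a narrower, longer one.
    """
    if index is None:
        index = build_pbwt(panel)
    if blocks is None:
        blocks = find_width_maximal_blocks(panel, index, L=L, unit="sites", W=W)
    segments = pairwise_match_segments(panel, min_sites=1)

    # direction (a): per-site pairwise edges within every block
    bad_blocks = []
    ligs = {k: build_lig(segments, k, L=L, unit="sites") for k in range(panel.N)}
    for b in blocks:
        for k in range(b.s, b.e):
            g = ligs[k]
            for i, j in itertools.combinations(b.members, 2):
                if not g.has_edge(i, j):
                    bad_blocks.append((b.id, k, (i, j)))

    # direction (b): persistent cliques contained in (L, W)-block candidates
    candidates = [
        (H, s, e)
        for (H, s, e) in enumerate_candidates(panel, index)
        if e - s >= L and len(H) >= W
    ]
    cliques = _persistent_cliques(panel, segments, L=L, W=W)
    bad_cliques = []
    for cset, ranges in cliques.items():
        for lo, hi in ranges:
            contained = any(
                cset <= H and s <= lo and hi <= e for (H, s, e) in candidates
            )
            if not contained:
                bad_cliques.append((tuple(sorted(cset)), (lo, hi)))
    n_cliques = sum(len(r) for r in cliques.values())
    return EquivalenceReport(
        n_blocks=len(blocks),
        n_persistent_cliques=n_cliques,
        counterexamples_blocks=bad_blocks,
        counterexamples_cliques=bad_cliques,
    )


# ---------------------------------------------------------------------------
# segment TSV input / output


def write_segments(segments: list[IBDSegment], path) -> None:
    with open(path, "w") as fh:
        fh.write("#hap_i\thap_j\tstart_site\tend_site\n")
        for seg in segments:
            i, j = seg.pair
            fh.write(f"{i}\t{j}\t{seg.s}\t{seg.e}\n")


def read_segments(path) -> list[IBDSegment]:
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            i, j, s, e = (int(v) for v in fields[:4])
            out.append(IBDSegment(hap_i=i, hap_j=j, s=s, e=e))
    return out
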