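"""Width-maximal (L,W)-haplotype blocks.

A haplotype block is a tuple B = (H, s, e): a set H of >= 2 haplotypes all
carrying an identical subsequence over the half-open site interval [s, e).
A block qualifies as an (L, W)-block when its length is >= L (in the chosen
unit) and its width |H| is >= W.

The enumeration works with three maximality notions, formalized as:

(ii)  row-maximal      — H contains *every* haplotype matching the shared
                         subsequence on [s, e);
(iii) interval-maximal — extending to s-1 or e (where in range) breaks the
                         all-equal property of H;
(iv)  width-maximal    — no block (H', s', e') satisfying (i)-(iii) exists
                         with H a strict subset of H' and [s', e') contained
                         in [s, e): the haplotype set cannot be enlarged
                         without the qualifying interval dropping below L.

Two independent enumerators are provided: a PBWT/divergence-based finder
(single pass over sites, linear-time candidate generation) and a brute-force
enumerator over all intervals that serves as its correctness oracle.
"""
from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .panel import HaplotypePanel, interval_length
from .pbwt import PBWTIndex


@dataclasses.dataclass(frozen=True)
class Block:
    """Haplotype block (H, s, e); ``members`` is H as a sorted tuple."""

    id: int
    H: frozenset[int]
    s: int
    e: int

    def __post_init__(self) -> None:
        if self.e <= self.s:
            raise ValueError(f"block {self.id}: empty interval [{self.s}, {self.e})")
        if len(self.H) < 2:
            raise ValueError(f"block {self.id}: needs at least 2 haplotypes")

    @property
    def members(self) -> tuple[int, ...]:
        return tuple(sorted(self.H))

    @property
    def width(self) -> int:
        return len(self.H)

    @property
    def length_sites(self) -> int:
        return self.e - self.s

    def sort_key(self):
        return (self.s, self.e, self.members)


@dataclasses.dataclass
class BlockSet:
    """Canonically sorted list of blocks with the thresholds that produced it.

    Blocks are sorted by (s, e, members) with dense ids 0..len-1.
    """

    blocks: list[Block]
    L: float | None = None
    unit: str = "sites"
    W: int | None = None

    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self):
        return iter(self.blocks)

    def __getitem__(self, i: int) -> Block:
        return self.blocks[i]

    def by_id(self) -> dict[int, Block]:
        return {b.id: b for b in self.blocks}


def _canonical(blocks, L=None, unit="sites", W=None) -> BlockSet:
    """Sort, de-duplicate on (H, s, e), and assign dense ids."""
    uniq = {(b.H, b.s, b.e) for b in blocks}
    ordered = sorted(uniq, key=lambda t: (t[1], t[2], tuple(sorted(t[0]))))
    out = [Block(id=i, H=H, s=s, e=e) for i, (H, s, e) in enumerate(ordered)]
    return BlockSet(blocks=out, L=L, unit=unit, W=W)


# ---------------------------------------------------------------------------
# PBWT-based enumeration


def _site_candidates(panel: HaplotypePanel, index: PBWTIndex, e: int):
    """Yield every row- and interval-maximal block candidate ending at e.

    Candidates are the nodes of the laminar family induced by the divergence
    array at site e: a maximal rank run [lo, hi] in a_e whose internal
    divergence maximum is s, bounded by strictly larger divergences.  The run
    is exactly the set of haplotypes matching over [s, e) (row-maximal), s is
    the leftmost extension (interval-maximal on the left), and the candidate
    is kept only when the run does not remain all-equal at column e
    (interval-maximal on the right; at e = N this holds vacuously).
    """
    M, N = panel.M, panel.N
    a = index.prefix_arrays[e]
    d = index.divergence_arrays[e]
    X = panel.alleles
    stack = [(0, M - 1)]
    while stack:
        lo, hi = stack.pop()
        if hi - lo < 1:
            continue
        seg = d[lo + 1 : hi + 1]
        s = int(seg.max())
        if s < e:
            col_ok = True
            if e < N:
                col = X[a[lo : hi + 1], e]
                col_ok = bool((col != col[0]).any())
            if col_ok:
                yield frozenset(int(h) for h in a[lo : hi + 1]), s, e
        # children: sub-runs between positions where d == s (their internal
        # maxima are strictly smaller, so each is its own candidate class)
        prev = lo
        for off in np.flatnonzero(seg == s):
            j = lo + 1 + int(off)
            stack.append((prev, j - 1))
            prev = j
        stack.append((prev, hi))


def enumerate_candidates(panel: HaplotypePanel, index: PBWTIndex):
    """All row- and interval-maximal block candidates (|H| >= 2), any length."""
    for e in range(1, panel.N + 1):
        yield from _site_candidates(panel, index, e)


def _width_maximal_filter(cands, L, unit, W, panel):
    """Apply (i) then (iv): dominators are candidates meeting (i)-(iii)."""
    qualified = [
        (H, s, e)
        for (H, s, e) in cands
        if len(H) >= W and interval_length(panel, (s, e), unit) >= L
    ]
    out = []
    for H, s, e in qualified:
        dominated = any(
            H < H2 and s <= s2 and e2 <= e for (H2, s2, e2) in qualified
        )
        if not dominated:
            out.append((H, s, e))
    return out


def find_width_maximal_blocks(
    panel: HaplotypePanel,
    index: PBWTIndex,
    L: float,
    unit: str = "sites",
    W: int = 2,
    width_maximal: bool = True,
) -> BlockSet:
    """Enumerate all width-maximal (L, W)-blocks of the panel via the PBWT.

    Parameters
    ----------
    L : float
        Minimum block length in ``unit`` (sites, bp, or cm).  bp/cm lengths
        span from site s to site e-1 and are evaluated per candidate, so the
        threshold behaves correctly under uneven marker density.
    W : int
        Minimum block width (>= 2).
    width_maximal : bool
        When False, skip the width-maximality filter (iv) and return every
        row-/interval-maximal (L, W)-block candidate.
    """
    if W < 2:
        raise ValueError("W must be >= 2")
    if L <= 0:
        raise ValueError("L must be positive")
    cands = list(enumerate_candidates(panel, index))
    if width_maximal:
        kept = _width_maximal_filter(cands, L, unit, W, panel)
    else:
        kept = [
            (H, s, e)
            for (H, s, e) in cands
            if len(H) >= W and interval_length(panel, (s, e), unit) >= L
        ]
    blocks = [Block(id=0, H=H, s=s, e=e) for (H, s, e) in kept]
    return _canonical(blocks, L=L, unit=unit, W=W)


# ---------------------------------------------------------------------------
# brute-force oracle


def enumerate_blocks_bruteforce(panel: HaplotypePanel, L: int, W: int = 2) -> BlockSet:
    """Exhaustive width-maximal (L, W)-block enumerator (L in sites).

    For every interval [s, e) with e - s >= L, rows are grouped by their
    subsequence; groups of size >= W that are interval-maximal are collected
    and the width-maximality filter is applied.  Intended for small panels
    (M*N up to ~1e4) as the independent oracle for the PBWT-based finder.
    """
    X = panel.alleles
    M, N = panel.M, panel.N
    cands = []
    for s in range(N):
        for e in range(s + max(int(L), 1), N + 1):
            groups: dict[bytes, list[int]] = {}
            for h in range(M):
                groups.setdefault(X[h, s:e].tobytes(), []).append(h)
            for H in groups.values():
                if len(H) < 2:
                    continue
                left_max = s == 0 or np.unique(X[H, s - 1]).size > 1
                right_max = e == N or np.unique(X[H, e]).size > 1
                if left_max and right_max:
                    cands.append((frozenset(H), s, e))
    kept = _width_maximal_filter(cands, L, "sites", W, panel)
    blocks = [Block(id=0, H=H, s=s, e=e) for (H, s, e) in kept]
    return _canonical(blocks, L=L, unit="sites", W=W)


# ---------------------------------------------------------------------------
# TSV input / output


class BlockRecordError(ValueError):
    """Invalid block record in a TSV file (reported with its line number)."""


_HEADER = "#block_id\tstart_site\tend_site\thaplotypes"


def write_blocks(blocks: BlockSet, path, panel: HaplotypePanel | None = None) -> None:
    """Write blocks as TSV; bp/cM bounds added when a panel is supplied.

    End coordinates refer to site e-1 (the last covered site).
    """
    header = _HEADER
    if panel is not None:
        header += "\tstart_bp\tend_bp"
        if panel.site_cm is not None:
            header += "\tstart_cm\tend_cm"
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for b in blocks:
            fields = [str(b.id), str(b.s), str(b.e), ",".join(map(str, b.members))]
            if panel is not None:
                fields += [str(int(panel.site_bp[b.s])), str(int(panel.site_bp[b.e - 1]))]
                if panel.site_cm is not None:
                    fields += [
                        format(panel.site_cm[b.s], "g"),
                        format(panel.site_cm[b.e - 1], "g"),
                    ]
            fh.write("\t".join(fields) + "\n")


def read_blocks(path) -> BlockSet:
    """Read a block TSV; records are validated and re-sorted canonically."""
    blocks = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 4:
                raise BlockRecordError(f"{path}:{lineno}: expected >= 4 columns")
            try:
                bid, s, e = int(fields[0]), int(fields[1]), int(fields[2])
                haps = [int(v) for v in fields[3].split(",") if v != ""]
            except ValueError as exc:
                raise BlockRecordError(f"{path}:{lineno}: {exc}") from exc
            H = frozenset(haps)
            if len(H) < len(haps):
                warnings.warn(
                    f"{path}:{lineno}: duplicate haplotype indices collapsed",
                    stacklevel=2,
                )
            if e <= s:
                raise BlockRecordError(f"{path}:{lineno}: empty interval [{s}, {e})")
            if len(H) < 2:
                raise BlockRecordError(f"{path}:{lineno}: fewer than 2 haplotypes")
            blocks.append(Block(id=bid, H=H, s=s, e=e))
    return _canonical(blocks)
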