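"""Positional Burrows-Wheeler transform (PBWT) index.

The PBWT orders the haplotypes at every site k by the lexicographic order
of their *reversed prefixes* x[k-1], x[k-2], ..., x[0].  Haplotypes that
agree on a suffix window ending at k thereby become adjacent, which is the
structural property every downstream algorithm in this package exploits.

We keep, for k = 0..N:

* the positional prefix array a_k (``prefix_arrays[k]``) — the permutation
  placing haplotypes in reversed-prefix order;
* its inverse r_k (``rank_arrays[k]``) — the rank of each haplotype;
* the divergence array d_k — d_k[j] is the smallest s such that haplotypes
  a_k[j-1] and a_k[j] match over [s, k) (d_k[0] = k by convention).

a_0 is the identity permutation and ties are broken stably throughout (the
0s-before-1s partition preserves prior order), so identical reversed
prefixes appear in original row order and all outputs are deterministic.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .panel import HaplotypePanel


@dataclasses.dataclass
class PBWTIndex:
    prefix_arrays: np.ndarray     # (N+1, M) int32, a_k
    rank_arrays: np.ndarray       # (N+1, M) int32, r_k with r_k[a_k[j]] = j
    divergence_arrays: np.ndarray  # (N+1, M) int32, d_k
    M: int
    N: int


def build_pbwt(panel: HaplotypePanel) -> PBWTIndex:
    """Single left-to-right pass building all N+1 prefix/rank/divergence arrays.

    a_{k+1} is obtained from a_k by the stable partition of column k values
    (0s before 1s); total work is proportional to M*N.
    """
    M, N = panel.M, panel.N
    X = panel.alleles
    ppa = np.empty((N + 1, M), dtype=np.int32)
    rank = np.empty((N + 1, M), dtype=np.int32)
    div = np.empty((N + 1, M), dtype=np.int32)

    a = list(range(M))
    d = [0] * M
    for k in range(N + 1):
        ppa[k] = a
        div[k] = d
        rank[k, a] = np.arange(M, dtype=np.int32)
        if k == N:
            break
        col = X[:, k]
        a0: list[int] = []
        a1: list[int] = []
        d0: list[int] = []
        d1: list[int] = []
        p = q = k + 1
        for j in range(M):
            h = a[j]
            dj = d[j]
            if dj > p:
                p = dj
            if dj > q:
                q = dj
            if col[h] == 0:
                a0.append(h)
                d0.append(p)
                p = 0
            else:
                a1.append(h)
                d1.append(q)
                q = 0
        a = a0 + a1
        d = d0 + d1
    return PBWTIndex(prefix_arrays=ppa, rank_arrays=rank, divergence_arrays=div, M=M, N=N)


def rank_at(index: PBWTIndex, site: int, hap: int) -> int:
    """Rank of haplotype ``hap`` in reversed-prefix order at ``site`` (0..N)."""
    if not 0 <= site <= index.N:
        raise IndexError(f"site {site} out of range 0..{index.N}")
    if not 0 <= hap < index.M:
        raise IndexError(f"haplotype {hap} out of range 0..{index.M - 1}")
    return int(index.rank_arrays[site, hap])
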