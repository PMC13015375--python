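"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's algorithmic machinery (PBWT passes,
sweep lines, divergence trees): prefix arrays come from an explicit sort,
cores from exhaustive subset enumeration, depths from per-rank counting.
"""
from __future__ import annotations

import itertools

import numpy as np


def pbwt_sort_oracle(alleles: np.ndarray, k: int) -> list[int]:
    """Prefix array at site k via stable sort of reversed-prefix tuples."""
    M = alleles.shape[0]
    return sorted(range(M), key=lambda h: tuple(alleles[h, :k][::-1]))


def _length(panel, s, e, unit):
    if unit == "sites":
        return e - s
    if unit == "bp":
        return float(panel.site_bp[e - 1] - panel.site_bp[s])
    if unit == "cm":
        return float(panel.site_cm[e - 1] - panel.site_cm[s])
    raise ValueError(unit)


def subset_valid(blocks, ids, min_core_length=None, unit="sites",
                 min_core_width=1, panel=None):
    """Non-empty multi-way haplotype and interval intersection (+ thresholds)."""
    members = [b for b in blocks if b.id in ids]
    H = frozenset.intersection(*(b.H for b in members))
    if len(H) < min_core_width or not H:
        return False
    S = max(b.s for b in members)
    E = min(b.e for b in members)
    if E <= S:
        return False
    if min_core_length is not None and _length(panel, S, E, unit) < min_core_length:
        return False
    return True


def max_core_oracle(blocks, component_ids, min_core_length=None, unit="sites",
                    min_core_width=1, panel=None):
    """(max size, list of optimal subsets) over all non-empty subsets."""
    ids = sorted(component_ids)
    best = 0
    witnesses = []
    for r in range(1, len(ids) + 1):
        for comb in itertools.combinations(ids, r):
            if subset_valid(blocks, set(comb), min_core_length, unit,
                            min_core_width, panel):
                if r > best:
                    best = r
                    witnesses = [frozenset(comb)]
                elif r == best:
                    witnesses.append(frozenset(comb))
    return best, witnesses


def maximal_valid_subsets(blocks, component_ids, min_core_length=None,
                          unit="sites", panel=None):
    """All inclusion-maximal valid subsets (the local-core family)."""
    ids = sorted(component_ids)
    valid = [
        frozenset(comb)
        for r in range(1, len(ids) + 1)
        for comb in itertools.combinations(ids, r)
        if subset_valid(blocks, set(comb), min_core_length, unit, 1, panel)
    ]
    return {
        v for v in valid if not any(v < w for w in valid)
    }


def depth_oracle(interval_sets, M: int):
    """Max coverage depth by counting per rank 0..M-1."""
    best_depth, best_rank = 0, None
    for r in range(M):
        d = sum(
            1
            for iv in interval_sets
            if any(lo <= r <= hi for (lo, hi) in iv.runs)
        )
        if d > best_depth:
            best_depth, best_rank = d, r
    return best_depth, best_rank


def rank_runs_oracle(ranks):
    """Sort ranks and split where the gap exceeds 1."""
    ranks = sorted(ranks)
    runs = []
    lo = hi = ranks[0]
    for v in ranks[1:]:
        if v == hi + 1:
            hi = v
        else:
            runs.append((lo, hi))
            lo = hi = v
    runs.append((lo, hi))
    return runs
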