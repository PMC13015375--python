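from __future__ import annotations

import numpy as np
import pytest

from hapcores import HaplotypePanel, build_pbwt, make_micro_instance
from hapcores.blocks import _canonical
from hapcores.synth import Plant, PlantSpec, generate_panel


@pytest.fixture(scope="session")
def micro_instance():
    """Worked 4-block instance: panel, canonical blocks, PBWT index."""
    return make_micro_instance()


def random_panel(seed: int, max_m: int = 16, max_n: int = 24) -> HaplotypePanel:
    """Small random panel; duplicate rows are injected so ties and shared
    blocks actually occur."""
    rng = np.random.default_rng(seed)
    M = int(rng.integers(2, max_m + 1))
    N = int(rng.integers(2, max_n + 1))
    alleles = rng.integers(0, 2, size=(M, N), dtype=np.uint8)
    # copy a few rows (possibly partially) to create matches
    for _ in range(int(rng.integers(0, max(2, M // 3) + 1))):
        src, dst = rng.integers(0, M, size=2)
        if src == dst:
            continue
        s = int(rng.integers(0, N))
        e = int(rng.integers(s + 1, N + 1))
        alleles[dst, s:e] = alleles[src, s:e]
    return HaplotypePanel(alleles=alleles, site_bp=100 * (np.arange(N) + 1))


def random_block_instance(seed: int, max_blocks: int = 12, M: int = 24, N: int = 40):
    """Random planted-block instance: (panel, BlockSet, index).

    All plants copy windows of one shared base haplotype, so overlapping
    plants are automatically consistent; the planted (H, s, e) tuples are
    the instance's block list, as consumed by the core sweep.
    """
    rng = np.random.default_rng(seed)
    base = rng.integers(0, 2, size=N, dtype=np.uint8)
    B = int(rng.integers(1, max_blocks + 1))
    plants = []
    for _ in range(B):
        w = int(rng.integers(2, 7))
        haps = tuple(int(h) for h in rng.choice(M, size=w, replace=False))
        s = int(rng.integers(0, N - 1))
        e = int(rng.integers(s + 2, min(s + 2 + 20, N) + 1))
        plants.append(Plant(haps=haps, s=s, e=e, sequence=tuple(base[s:e])))
    spec = PlantSpec(M=M, N=N, plants=plants, seed=int(seed) % (2**31))
    panel, truth = generate_panel(spec)
    blocks = _canonical(truth)
    return panel, blocks, build_pbwt(panel)
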