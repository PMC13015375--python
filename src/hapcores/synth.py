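"""Deterministic synthetic haplotype panels with planted blocks.

The generator emulates the one structural feature the rest of the package
consumes: subsets of haplotypes carrying an identical subsequence over a
controlled interval, embedded in independent Bernoulli background alleles
with optional flip noise outside the planted cells.  It makes no attempt at
population-genetic realism (no coalescent, no recombination map, no
mutation model) — structure, not fidelity.

One global integer seed drives an independent counter-based stream per
plant (numpy SeedSequence keyed on (seed, stream)), so adding a plant never
perturbs the randomness of earlier plants or of the background.

Planted truth is recorded as a list of blocks.  Width-maximal detection may
legitimately *extend* a plant when background alleles match by chance, so
truth is a containment claim (each plant lies inside some detected block),
not an equality claim; fixtures that need equality place disagreeing guard
columns around each plant.
"""
from __future__ import annotations

import dataclasses

import numpy as np

from .blocks import Block, BlockSet, _canonical
from .panel import HaplotypePanel
from .pbwt import PBWTIndex, build_pbwt


class PlantError(ValueError):
    """Inconsistent or out-of-bounds plant specification."""


@dataclasses.dataclass(frozen=True)
class Plant:
    """A planted identical segment: haplotypes ``haps`` share ``sequence``
    over [s, e).  sequence=None draws it from the plant's own RNG stream."""

    haps: tuple[int, ...]
    s: int
    e: int
    sequence: tuple[int, ...] | None = None


@dataclasses.dataclass
class PlantSpec:
    M: int
    N: int
    plants: list[Plant] = dataclasses.field(default_factory=list)
    background: float = 0.5
    noise_rate: float = 0.0
    seed: int = 0


def _plant_sequences(spec: PlantSpec) -> list[np.ndarray]:
    seqs = []
    for idx, plant in enumerate(spec.plants):
        if plant.sequence is not None:
            seq = np.asarray(plant.sequence, dtype=np.uint8)
            if seq.shape != (plant.e - plant.s,):
                raise PlantError(
                    f"plant {idx}: sequence length {seq.size} != interval "
                    f"length {plant.e - plant.s}"
                )
            if not np.isin(seq, (0, 1)).all():
                raise PlantError(f"plant {idx}: sequence must be binary")
        else:
            rng = np.random.default_rng([spec.seed, 2 + idx])
            seq = rng.integers(0, 2, size=plant.e - plant.s, dtype=np.uint8)
        seqs.append(seq)
    return seqs


def generate_panel(spec: PlantSpec) -> tuple[HaplotypePanel, list[Block]]:
    """Materialize a PlantSpec; returns (panel, planted truth blocks).

    Raises PlantError when two plants prescribe conflicting alleles for the
    same haplotype cell.  Reproducible: the same spec yields a bit-identical
    panel.
    """
    if spec.M < 1 or spec.N < 1:
        raise PlantError("panel dimensions must be positive")
    for idx, plant in enumerate(spec.plants):
        if not (0 <= plant.s < plant.e <= spec.N):
            raise PlantError(f"plant {idx}: interval outside the panel")
        if len(set(plant.haps)) < 2:
            raise PlantError(f"plant {idx}: needs >= 2 distinct haplotypes")
        if any(not 0 <= h < spec.M for h in plant.haps):
            raise PlantError(f"plant {idx}: haplotype index outside the panel")

    bg_rng = np.random.default_rng([spec.seed, 0])
    alleles = (bg_rng.random((spec.M, spec.N)) < spec.background).astype(np.uint8)
    planted = np.zeros((spec.M, spec.N), dtype=bool)
    seqs = _plant_sequences(spec)
    for idx, (plant, seq) in enumerate(zip(spec.plants, seqs)):
        for h in plant.haps:
            window = alleles[h, plant.s : plant.e]
            already = planted[h, plant.s : plant.e]
            if np.any(already & (window != seq)):
                raise PlantError(
                    f"plant {idx}: conflicts with an earlier plant on "
                    f"haplotype {h}"
                )
            window[:] = seq
            planted[h, plant.s : plant.e] = True
    if spec.noise_rate > 0:
        noise_rng = np.random.default_rng([spec.seed, 1])
        flip = (noise_rng.random((spec.M, spec.N)) < spec.noise_rate) & ~planted
        alleles[flip] ^= 1

    site_bp = 1000 * (np.arange(spec.N, dtype=np.int64) + 1)
    panel = HaplotypePanel(alleles=alleles, site_bp=site_bp)
    truth = [
        Block(id=i, H=frozenset(p.haps), s=p.s, e=p.e)
        for i, p in enumerate(spec.plants)
    ]
    return panel, truth


# ---------------------------------------------------------------------------
# worked micro-instance and schematic fixtures


def make_micro_instance(seed: int = 7) -> tuple[HaplotypePanel, BlockSet, PBWTIndex]:
    """The worked 4-block instance used throughout the tests and docs.

    Blocks (on a 7 x 14 panel, canonical id order):
        B0 = ({1,2,3}, 0, 10)   B1 = ({1,5},   0, 14)
        B2 = ({2,3,4}, 2, 12)   B3 = ({3,4,5}, 4, 14)
    Exhaustive enumeration over all 15 non-empty subsets shows the unique
    block core is {B0, B2, B3} with H* = {3} on [4, 10), and the local cores
    are exactly {B0,B2,B3}, {B0,B1}, {B1,B3}.
    """
    rng = np.random.default_rng([seed, 99])
    base = rng.integers(0, 2, size=14, dtype=np.uint8)
    plants = [
        Plant(haps=(1, 2, 3), s=0, e=10, sequence=tuple(base[0:10])),
        Plant(haps=(2, 3, 4), s=2, e=12, sequence=tuple(base[2:12])),
        Plant(haps=(3, 4, 5), s=4, e=14, sequence=tuple(base[4:14])),
        Plant(haps=(1, 5), s=0, e=14, sequence=tuple(base[0:14])),
    ]
    spec = PlantSpec(M=7, N=14, plants=plants, seed=seed)
    panel, truth = generate_panel(spec)
    blocks = _canonical(truth, L=2, unit="sites", W=2)
    return panel, blocks, build_pbwt(panel)


@dataclasses.dataclass
class SchematicFixture:
    """A canned panel + block list with its expected structural counts."""

    name: str
    panel: HaplotypePanel
    blocks: BlockSet
    index: PBWTIndex
    expected: dict


def _two_components(seed: int) -> SchematicFixture:
    rng = np.random.default_rng([seed, 99])
    base = rng.integers(0, 2, size=14, dtype=np.uint8)
    base2 = rng.integers(0, 2, size=14, dtype=np.uint8)
    plants = [
        Plant(haps=(1, 2, 3), s=0, e=10, sequence=tuple(base[0:10])),
        Plant(haps=(2, 3, 4), s=2, e=12, sequence=tuple(base[2:12])),
        Plant(haps=(3, 4, 5), s=4, e=14, sequence=tuple(base[4:14])),
        Plant(haps=(1, 5), s=0, e=14, sequence=tuple(base[0:14])),
        Plant(haps=(8, 9), s=16, e=30, sequence=tuple(base2)),
        Plant(haps=(8, 9, 10), s=18, e=28, sequence=tuple(base2[2:12])),
    ]
    spec = PlantSpec(M=12, N=30, plants=plants, seed=seed)
    panel, truth = generate_panel(spec)
    blocks = _canonical(truth, L=2, unit="sites", W=2)
    return SchematicFixture(
        name="two_components",
        panel=panel,
        blocks=blocks,
        index=build_pbwt(panel),
        expected={
            "n_components": 2,
            "core_sizes": [3, 2],
            "overlap_L": 2,
            "overlap_W": 1,
        },
    )


def _six_local_cores(seed: int) -> SchematicFixture:
    rng = np.random.default_rng([seed, 99])
    base = rng.integers(0, 2, size=14, dtype=np.uint8)
    base3 = rng.integers(0, 2, size=10, dtype=np.uint8)
    plants = [
        Plant(haps=(1, 2, 3), s=0, e=10, sequence=tuple(base[0:10])),
        Plant(haps=(2, 3, 4), s=2, e=12, sequence=tuple(base[2:12])),
        Plant(haps=(3, 4, 5), s=4, e=14, sequence=tuple(base[4:14])),
        Plant(haps=(1, 5), s=0, e=14, sequence=tuple(base[0:14])),
        Plant(haps=(10, 11), s=16, e=26, sequence=tuple(base3)),
        Plant(haps=(11, 12), s=16, e=26, sequence=tuple(base3)),
        Plant(haps=(10, 12), s=16, e=26, sequence=tuple(base3)),
    ]
    spec = PlantSpec(M=14, N=30, plants=plants, seed=seed)
    panel, truth = generate_panel(spec)
    blocks = _canonical(truth, L=2, unit="sites", W=2)
    return SchematicFixture(
        name="six_local_cores",
        panel=panel,
        blocks=blocks,
        index=build_pbwt(panel),
        expected={
            "n_components": 2,
            "n_local_cores": 6,
            "component_core_sizes": [3, 2],
            "overlap_L": 2,
            "overlap_W": 1,
        },
    )


def _interrupted_adjacency() -> SchematicFixture:
    # 5 haplotypes x 5 sites; block ({0,1}, 1, 5): rows 0 and 1 share sites
    # 1..4 but differ at site 0, and rows 2,3 sort between them at the
    # interior site 3 (two rank runs) while being adjacent at the end site.
    rows = [
        [0, 1, 0, 1, 0],
        [1, 1, 0, 1, 0],
        [0, 1, 0, 0, 1],
        [0, 1, 0, 0, 1],
        [1, 0, 1, 0, 1],
    ]
    alleles = np.array(rows, dtype=np.uint8)
    panel = HaplotypePanel(
        alleles=alleles, site_bp=1000 * (np.arange(5, dtype=np.int64) + 1)
    )
    block = Block(id=0, H=frozenset({0, 1}), s=1, e=5)
    blocks = BlockSet(blocks=[block], L=4, unit="sites", W=2)
    return SchematicFixture(
        name="interrupted_adjacency",
        panel=panel,
        blocks=blocks,
        index=build_pbwt(panel),
        expected={"interior_site": 3, "interior_runs": 2, "end_runs": 1},
    )


def make_schematic_fixtures(seed: int = 7) -> dict[str, SchematicFixture]:
    """Three canned fixtures exercising the structural situations the
    algorithms are built around: two overlap-graph components with cores of
    size 3 and 2; two components carrying six local cores in total; and a
    block whose members are interrupted by other haplotypes at an interior
    site (multiple rank runs) yet adjacent at their end site."""
    return {
        "two_components": _two_components(seed),
        "six_local_cores": _six_local_cores(seed),
        "interrupted_adjacency": _interrupted_adjacency(),
    }
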