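# hapcores

Detection and analysis of **haplotype block cores** in phased panels:
genomic segments where many haplotype blocks — multi-way shared segments —
pile up on a common interval and a common set of carriers. Layered block
overlap of this kind is informative about recent relatedness and signals of
selection, and gives a compact, less redundant view of local IBD sharing
than per-site IBD graphs. The package is aimed at population-genetics
practitioners working with phased biallelic panels (VCF or a plain 0/1
matrix format) at cohort-to-desk scale.

## What it computes

Given a panel `X ∈ {0,1}^{M×N}` and thresholds:

1. **Width-maximal (L, W)-blocks** `B = (H, s, e)` — sets of `|H| ≥ W`
   haplotypes identical over `[s, e)` with length ≥ L, whose haplotype set
   cannot be enlarged without the qualifying interval dropping below L.
   Enumeration uses the positional Burrows–Wheeler transform (PBWT):
   haplotypes sorted by reversed-prefix order at every site, with
   divergence arrays exposing all maximal agreement classes in a single
   left-to-right pass.
2. The **(L, W)-overlap graph**: edges between blocks with
   `min(e1,e2) − max(s1,s2) ≥ L_overlap` and `|H1 ∩ H2| ≥ W_overlap`,
   split into connected components.
3. Per component, the **block core** — the largest block subset with a
   non-empty multi-way intersection — reported as
   `(ℬ*, H* = ∩H_i, S* = max s_i, E* = min e_i)`, found by a 2-D sweep
   line: block start/end events along the genome, and a depth sweep over
   PBWT rank runs at each end event. An optional minimum core length L
   keeps only blocks spanning ≥ L back from each end event, so every
   reported core persists over at least L.
4. **Local cores** — all inclusion-maximal such subsets (maximal cliques)
   — plus a **core graph** with intersection-over-union redundancy
   measures, and **local IBD graph** utilities (per-site sharing graphs,
   IBD-rate tracks, block/persistent-clique verification).

See `docs/methods.md` for the formal definitions, the sweep's correctness
argument, and numerical choices.

## Worked example

The worked micro-instance ships with the package: four blocks on a 7×14
panel,

```
B0: H={1, 2, 3} [0,10)
B1: H={1, 5}    [0,14)
B2: H={2, 3, 4} [2,12)
B3: H={3, 4, 5} [4,14)
```

```python
from hapcores import (make_micro_instance, find_block_core,
                      enumerate_local_cores)
from hapcores.overlap import Component

panel, blocks, index = make_micro_instance()
comp = Component(block_ids=[b.id for b in blocks])

core = find_block_core(comp, blocks, index)
print(f"core: blocks={sorted(core.member_blocks)} H*={set(core.H_star)} "
      f"interval=[{core.S_star},{core.E_star})")
for lc in enumerate_local_cores(comp, blocks, index):
    print(f"local core: blocks={sorted(lc.member_blocks)} "
          f"H*={set(lc.H_star)} interval=[{lc.S_star},{lc.E_star})")
```

prints

```
core: blocks=[0, 2, 3] H*={3} interval=[4,10)
local core: blocks=[0, 2, 3] H*={3} interval=[4,10)
local core: blocks=[0, 1] H*={1} interval=[0,10)
local core: blocks=[1, 3] H*={5} interval=[4,14)
```

Reading: the deepest pile-up is the three staggered blocks B0, B2, B3 —
haplotype 3 carries all three, and their intervals share `[4, 10)` — so the
block core has size 3. B1 overlaps B0 (through haplotype 1) and B3
(through haplotype 5) but no single haplotype is shared by all four blocks,
so those pairs are *maximal* cliques (local cores), not the maximum.
Exhaustive enumeration over all 15 subsets confirms both the core and the
local-core family.

## Command line

```
hapcores find-blocks --panel panel.vcf --min-length 2 --unit cm --min-width 50 --out blocks.tsv
hapcores components  --blocks blocks.tsv --min-overlap-length 1 --out components.tsv
hapcores cores       --panel panel.vcf --min-block-length 2 --unit cm --out results/
hapcores local-cores --panel panel.matrix --min-core-length 1.5 --unit cm --out results/
hapcores synth       --spec plantspec.yaml --out panel.matrix --truth truth.tsv
hapcores run         --config config.yaml
```

All TSV outputs carry one `#`-prefixed header line. Physical/genetic
length of `[s, e)` is measured from site `s` to site `e−1` (the last
covered site). Re-running any command on the same inputs produces
byte-identical outputs.

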