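# Methods

## The model

A phased haplotype panel is a binary matrix `X ∈ {0,1}^{M×N}` (rows =
haplotypes, columns = variant sites), with per-site physical positions (bp)
and, optionally, genetic positions (cM) interpolated from a recombination
map. Site indices are 0-based and every interval is half-open `[s, e)`,
covering sites `s .. e−1`. The bp/cM length of `[s, e)` is measured from
site `s` to site `e−1`: site `e` lies outside the interval, so counting to
it would credit a match with distance it does not span.

A **haplotype block** `B = (H, s, e)` is a set `H` of ≥ 2 haplotypes all
carrying an identical subsequence over `[s, e)`; an *(L, W)-block*
additionally has length ≥ L (in sites, bp, or cM) and width `|H| ≥ W`.
The package enumerates **width-maximal** (L, W)-blocks: blocks whose
haplotype set cannot be enlarged without the qualifying interval dropping
below L. Since a one-sentence definition leaves edge cases open, the
enumeration is built on an explicit formalization:

* **(ii) row-maximal** — `H` contains every haplotype matching the shared
  subsequence on `[s, e)`;
* **(iii) interval-maximal** — extending to `s−1` or `e` (where in range)
  breaks the all-equal property of `H`;
* **(iv) width-maximal** — no block `(H′, s′, e′)` satisfying (i)–(iii)
  exists with `H ⊊ H′` and `[s′, e′) ⊆ [s, e)`.

Under (iv) a long, narrow block is *superseded* by a strictly wider block on
a qualifying sub-interval. This is a deliberate, documented choice — other
formalizations of the same phrase are conceivable — and both enumerators
(PBWT-based and brute-force) implement exactly this semantics, so the
equivalence tests pin the formalization, not just the code.

**Overlap graph.** Two blocks *(L, W)-overlap* when
`min(e1,e2) − max(s1,s2) ≥ L` (interval intersection length, evaluated in
the configured unit) and `|H1 ∩ H2| ≥ W`. Blocks are nodes, overlaps are
edges; analysis proceeds per connected component. The overlap thresholds
`(L_overlap, W_overlap)` are independent of the block-definition thresholds
`(L_block, W_block)`.

**Block core.** Within a component, a subset `𝒞` of blocks is *valid* when
its multi-way intersection is non-empty: `H* = ∩ H_i ≠ ∅` and
`E* − S* > 0` with `S* = max s_i`, `E* = min e_i`. The block core is a
maximum-cardinality valid subset, reported as `(ℬ*, H*, S*, E*)`. A
**local core** is an inclusion-maximal valid subset; the block core is
always among the local cores. Note the deliberate semantics: validity is
*multi-way* intersection, not pairwise overlap. For `W_overlap > 1` a
pairwise clique in the overlap graph need not have a non-empty multi-way
haplotype intersection; this package's cores are always witnessed by an
actual shared haplotype.

## PBWT machinery

The positional Burrows–Wheeler transform orders haplotypes at each site `k`
by the lexicographic order of their reversed prefixes
`x[k−1], x[k−2], …, x[0]`. Construction is Durbin's single left-to-right
pass: `a_0` is the identity permutation and `a_{k+1}` is the stable
0s-before-1s partition of `a_k` on column `k`, with the companion divergence
array `d_k[j]` = the smallest `s` such that `a_k[j−1]` and `a_k[j]` agree on
`[s, k)`. Stable ties mean identical reversed prefixes stay in original row
order, making every downstream output deterministic. All N+1 prefix, rank
(inverse prefix) and divergence arrays are kept addressable; at desk scale
(`M·N` up to ~10⁷) this is cheap, and nothing in the API forbids a future
checkpoint-and-recompute backend.

Block candidates satisfying (ii)+(iii) are read off the divergence arrays:
at each site `e`, the maximal rank runs bounded by strictly larger
divergences — the nodes of the laminar family induced by `d_e` — are exactly
the row-maximal agreement classes with their leftmost interval extension
`s = max` internal divergence; a candidate is kept when the class is not
all-equal at column `e`. Filter (i) and the domination filter (iv) are then
applied; (iv) is a quadratic scan over qualified candidates, which is
adequate at the scales this package targets.

## The core sweep

Events (one start, one end per block) are sorted by position with **end
events before start events at equal positions**, so a block `[s, p)` is
never co-active with a block starting at `p` — the ordering consistent with
half-open intervals. At the end event of block `b` at site `e`, the active
blocks (restricted to `𝒜_L(e) = {b′ : length([s_{b′}, e)) ≥ L}` when a
minimum core length `L` is set) are projected onto PBWT ranks at `e`. Each
block's members occupy a few contiguous rank runs (exactly one run at its
own end site when the block is row-maximal in the panel; externally supplied
blocks whose `H` is a strict subset of the agreement class may split). The
elementary intervals between run boundaries each define a covering block
set; the deepest one is the candidate core at this event.

Correctness of the deepest-point rule (for minimum core width 1): every
covering block at a rank contains the witness haplotype `a_e[r]`, so every
candidate is valid; conversely an optimal subset 𝒞 is fully active at the
end event of its earliest-ending member, where any common haplotype's rank
is covered by all of 𝒞 — the deepest candidate there is at least as large
and itself valid. The sweep therefore returns a true maximum, which the
test suite additionally verifies against exhaustive subset enumeration on
hundreds of random instances.

With `min_core_width > 1` the deepest candidate's explicit `H*` may be too
small even though a smaller, wider-intersection candidate exists; the
implementation then falls back to the next-deepest distinct candidate at
the event. This fallback is a heuristic — exactness is only claimed and
tested for width 1 (the definition's `H* ≠ ∅`).

Tie-breaks are fixed for reproducibility: among equal-size cores, the
earliest end event wins, then the lexicographically smallest sorted
block-id tuple. Instrumentation counters (events processed, maximum active
set, maximum run count) expose the `O(B log B + B·a·i log i)` cost profile
without asserting wall-clock time.

**Local cores** reuse the same sweep but pool *every* elementary interval's
covering set across all end events (keyed by frozen id set), then keep a
candidate iff it is not a subset of an already-kept candidate, scanning by
size descending. Pooling globally rather than filtering per event
guarantees cross-event maximality; the argument above shows every
inclusion-maximal valid subset surfaces as a candidate and every kept
candidate is valid, so the kept family *equals* the brute-force family of
inclusion-maximal valid subsets — an equality the tests check directly on
random instances.

## Local IBD graphs

At site `k`, the local IBD graph `G_k(L)` connects haplotype pairs with a
shared segment of length ≥ L covering `k`. Segment membership here is
`s_ij ≤ k < e_ij` — half-open, consistent with the rest of the package,
and a deliberate deviation from formulations that close the interval at
`e`. A set of ≥ W pairwise-connected haplotypes is a W-clique; one that
persists over ≥ L consecutive sites is an L-persistent W-clique, which is
precisely an (L, W)-block when sharing is exact sequence identity.
`verify_block_clique_equivalence` checks both directions on a panel:
blocks are cliques site-by-site, and scanned persistent cliques are
contained in row-/interval-maximal (L, W)-block candidates. The second
direction deliberately uses the candidate family *before* the
width-maximality filter: a persistent clique's full range can exceed every
width-maximal block's interval when a wider block on a sub-interval
supersedes a narrower, longer one — containment in the pre-(iv) family is
the statement that is actually true.

Pairs connected by several overlapping (or touching) segments are merged by
interval union before rate computation, so the per-site IBD rate — the
fraction of haplotype pairs with a qualifying segment — never double counts
a pair.

## Synthetic data

The generator plants identical segments (haplotype subset × interval ×
shared sequence) into Bernoulli(0.5) background alleles, with optional flip
noise applied only outside planted cells. Each plant draws from its own
RNG stream keyed on (seed, plant index), so appending a plant never
perturbs earlier randomness, and the same spec is bit-reproducible.
Overlapping plants prescribing conflicting alleles for a shared haplotype
are rejected.

What it emulates: the block/overlap/core combinatorics the algorithms
consume. What it does not: coalescent genealogies, recombination maps,
mutation processes, genotyping error models, or realistic allele-frequency
spectra. Passing tests therefore demonstrate algorithmic correctness on
controlled structure, not detection power on real cohorts.

Planted truth is a *containment* claim — width-maximal detection may extend
a plant whenever background happens to agree — so tests assert each plant
lies inside some detected block; equality is only asserted on fixtures
engineered with disagreeing guard columns. Note also that an externally
specified block list (as in the worked micro-instance) need not be
row-maximal in any realizing panel: forcing `{1,5}` and `{1,2,3}` and
`{3,4,5}` to share one donor sequence over overlapping windows makes
haplotypes 1, 3, 5 globally identical, which is why the end-site
single-run property is stated for agreement classes rather than arbitrary
haplotype subsets.

Three canned schematic fixtures pin structural behaviors: two overlap
components with cores of sizes 3 and 2; two components carrying six local
cores whose per-component maxima coincide with the block cores; and a
5×5 panel whose block projects to two rank runs at an interior site but one
run at its end site (members interrupted mid-match, adjacent at the end).

## Problem sizes and numerical choices

The default test run uses panels up to 16×24 (PBWT sort equivalence, 50
seeds), 12×20 (block-finder equivalence, 100 seeds × L ∈ {2,3}), planted
instances of ≤ 12 blocks on 24×40 panels (core optimality, 300 seeds;
exhaustive subset oracles are exponential in block count, so 12 blocks =
4095 subsets is the practical ceiling), and ≤ 10 blocks for local-core
family equality. The acceptance study generates an 80×300 panel with six
clusters of four staggered plants (sliding 6-haplotype windows over a
shared donor sequence, 18-site intervals, 1% background flip noise) and
runs the full pipeline at `L_block = 10` sites, `W_block = 3`,
`L_overlap = 4` sites, `W_overlap = 1`. These sizes were chosen so each
oracle comparison remains exhaustive and the whole suite completes in
seconds while still exercising every code path.

Other fixed choices: thresholds given in bp/cM are evaluated per candidate
through the coordinate arrays (variable windows), not converted to a fixed
site count, so they behave correctly under uneven marker density; genetic
map interpolation is linear with clamped extrapolation beyond the map
range; `|H| ≥ 2` is enforced for all blocks regardless of configured W;
empty components return an empty core (size 0) rather than raising.

## Known limitations

* Core exactness for `min_core_width > 1` is heuristic (see above).
* The width-maximality filter and the local-core subset filter are
  quadratic in candidate count; biobank-scale panels would need the
  streaming/memory-mapped engineering that is explicitly out of scope here.
* Maximal-clique counts can grow super-polynomially in adversarial block
  arrangements; the sweep's candidate pooling is output-sensitive but makes
  no worst-case output-polynomial guarantee.
* IBD segments derived from the panel are identity-by-state exact matches;
  no attempt is made to model true descent, genotyping error, or phasing
  error.
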