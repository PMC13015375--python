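"""Rank projection, depth sweep, and block-core optimality vs brute force."""
from __future__ import annotations

import numpy as np
import pytest

from hapcores import (
    build_overlap_graph,
    connected_components,
    find_all_cores,
    find_block_core,
    make_schematic_fixtures,
    max_depth_point,
    project_ranks,
)
from hapcores.blocks import Block, _canonical
from hapcores.cores import RankIntervalSet
from hapcores.overlap import Component

from ._oracles import depth_oracle, max_core_oracle, rank_runs_oracle, subset_valid
from .conftest import random_block_instance


class TestProjectRanks:
    def test_single_run_at_end_site_for_row_maximal_blocks(self, micro_instance):
        """End-site adjacency holds for row-maximal haplotype sets.

        Externally supplied blocks need not be row-maximal (the micro
        instance's ({1,5}, 0, 14) is interrupted by haplotype 3, which
        carries the same sequence), so the single-run property is asserted
        on each block's full agreement class."""
        panel, blocks, idx = micro_instance
        for b in blocks:
            h0 = next(iter(b.H))
            cls = frozenset(
                int(h)
                for h in range(panel.M)
                if (panel.alleles[h, b.s : b.e] == panel.alleles[h0, b.s : b.e]).all()
            )
            full = Block(id=b.id, H=cls, s=b.s, e=b.e)
            assert len(project_ranks(full, b.e, idx).runs) == 1

    def test_interrupted_interior_projection(self):
        fx = make_schematic_fixtures()["interrupted_adjacency"]
        block = fx.blocks[0]
        interior = project_ranks(block, fx.expected["interior_site"], fx.index)
        assert len(interior.runs) == fx.expected["interior_runs"]
        end = project_ranks(block, block.e, fx.index)
        assert len(end.runs) == fx.expected["end_runs"]

    def test_projection_outside_interval_is_flagged(self, micro_instance):
        _, blocks, idx = micro_instance
        b = blocks[3]  # starts at s=4
        with pytest.warns(UserWarning):
            project_ranks(b, 0, idx)

    @pytest.mark.parametrize("seed", range(20))
    def test_runs_match_naive_partition(self, seed):
        """Runs reproduce the sorted-rank consecutive partition exactly."""
        panel, blocks, idx = random_block_instance(seed, max_blocks=6)
        rng = np.random.default_rng(1000 + seed)
        for _ in range(5):
            b = blocks[int(rng.integers(0, len(blocks)))]
            site = int(rng.integers(b.s, b.e + 1))
            proj = project_ranks(b, site, idx)
            ranks = [int(idx.rank_arrays[site][h]) for h in b.H]
            assert proj.runs == rank_runs_oracle(ranks)
            # runs cover exactly H
            covered = {
                int(idx.prefix_arrays[site][r])
                for lo, hi in proj.runs
                for r in range(lo, hi + 1)
            }
            assert covered == set(b.H)


class TestMaxDepthPoint:
    def run_set(self, bid, runs):
        return RankIntervalSet(block_id=bid, site=0, runs=runs)

    def test_empty_input(self):
        assert max_depth_point([]) == (0, None, frozenset())

    def test_single_block(self):
        depth, rank, ids = max_depth_point([self.run_set(5, [(2, 4)])])
        assert (depth, rank, ids) == (1, 2, frozenset({5}))

    def test_two_overlapping_runs(self):
        depth, rank, ids = max_depth_point(
            [self.run_set(0, [(0, 4)]), self.run_set(1, [(3, 7)])]
        )
        assert (depth, rank, ids) == (2, 3, frozenset({0, 1}))

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_per_rank_counting(self, seed):
        rng = np.random.default_rng(seed)
        M = 20
        sets = []
        for bid in range(int(rng.integers(1, 8))):
            k = int(rng.integers(1, 4))
            points = sorted(rng.choice(M, size=2 * k, replace=False))
            runs = [(int(points[2 * i]), int(points[2 * i + 1])) for i in range(k)]
            sets.append(self.run_set(bid, runs))
        depth, rank, ids = max_depth_point(sets)
        o_depth, o_rank = depth_oracle(sets, M)
        assert depth == o_depth
        assert rank == o_rank
        assert len(ids) == depth


class TestFindBlockCore:
    def test_singleton_component(self):
        blocks = _canonical([Block(id=0, H=frozenset({0, 1}), s=2, e=9)])
        panel, bset, idx = random_block_instance(0, max_blocks=1)
        comp = Component(block_ids=[bset[0].id])
        core = find_block_core(comp, bset, idx)
        b = bset[0]
        assert core.member_blocks == {b.id}
        assert core.H_star == b.H
        assert (core.S_star, core.E_star) == (b.s, b.e)

    def test_micro_instance_core(self, micro_instance):
        _, blocks, idx = micro_instance
        comp = Component(block_ids=[b.id for b in blocks])
        core = find_block_core(comp, blocks, idx)
        by_key = {b.sort_key(): b.id for b in blocks}
        expect_members = {
            by_key[(0, 10, (1, 2, 3))],
            by_key[(2, 12, (2, 3, 4))],
            by_key[(4, 14, (3, 4, 5))],
        }
        assert core.member_blocks == expect_members
        assert core.H_star == frozenset({3})
        assert (core.S_star, core.E_star) == (4, 10)

    def test_empty_result_when_width_unreachable(self, micro_instance):
        _, blocks, idx = micro_instance
        comp = Component(block_ids=[b.id for b in blocks])
        core = find_block_core(comp, blocks, idx, min_core_width=10)
        assert core.size == 0

    @pytest.mark.parametrize("seed", range(60))
    def test_core_size_equals_exhaustive_maximum(self, seed):
        panel, blocks, idx = random_block_instance(seed)
        graph = build_overlap_graph(blocks, L=1, W=1)
        for comp in connected_components(graph):
            core = find_block_core(comp, blocks, idx)
            best, _ = max_core_oracle(blocks, comp.block_ids)
            assert core.size == best
            assert subset_valid(blocks, core.member_blocks)

    @pytest.mark.parametrize("seed", range(20))
    def test_optimal_subsets_surface_at_end_events(self, seed):
        """Every oracle-optimal subset's E* is a member's end site, and all
        members are active there (start <= E*-1 < end)."""
        panel, blocks, idx = random_block_instance(seed, max_blocks=8)
        graph = build_overlap_graph(blocks, L=1, W=1)
        bmap = blocks.by_id()
        for comp in connected_components(graph):
            _, witnesses = max_core_oracle(blocks, comp.block_ids)
            for witness in witnesses:
                E = min(bmap[i].e for i in witness)
                assert any(bmap[i].e == E for i in witness)
                for i in witness:
                    assert bmap[i].s < E <= bmap[i].e

    @pytest.mark.parametrize("seed", range(30))
    def test_length_constrained_core_matches_oracle(self, seed):
        panel, blocks, idx = random_block_instance(seed)
        graph = build_overlap_graph(blocks, L=1, W=1)
        for comp in connected_components(graph):
            core = find_block_core(comp, blocks, idx, min_core_length=4)
            best, _ = max_core_oracle(blocks, comp.block_ids, min_core_length=4)
            assert core.size == best
            if core.size:
                assert core.E_star - core.S_star >= 4
                assert subset_valid(blocks, core.member_blocks, min_core_length=4)

    def test_event_count_instrumentation(self, micro_instance):
        _, blocks, idx = micro_instance
        comp = Component(block_ids=[b.id for b in blocks])
        core, stats = find_block_core(comp, blocks, idx, with_stats=True)
        assert stats.events == 2 * len(blocks)
        assert stats.end_events == len(blocks)
        assert stats.max_active <= len(blocks)


class TestFindAllCores:
    def test_empty_block_set(self):
        bset = _canonical([])
        panel, _, idx = random_block_instance(0, max_blocks=1)
        assert find_all_cores(bset, idx, L_overlap=1) == []

    def test_two_component_schematic_cores(self):
        fx = make_schematic_fixtures()["two_components"]
        res = find_all_cores(
            fx.blocks,
            fx.index,
            L_overlap=fx.expected["overlap_L"],
            W_overlap=fx.expected["overlap_W"],
        )
        assert sorted((core.size for _, core in res), reverse=True) == fx.expected[
            "core_sizes"
        ]

    def test_identical_blocks_form_one_full_core(self):
        # n blocks sharing haplotypes and interval pairwise-distinct by one hap
        raw = [
            Block(id=i, H=frozenset({0, 1, 2, 10 + i}), s=0, e=8) for i in range(5)
        ]
        blocks = _canonical(raw)
        panel, _, idx = random_block_instance(3)
        res = find_all_cores(blocks, idx, L_overlap=1)
        assert len(res) == 1
        _, core = res[0]
        assert core.size == 5
        assert core.H_star == frozenset({0, 1, 2})
        assert (core.S_star, core.E_star) == (0, 8)
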