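"""Panel IO, genetic-map interpolation, and PBWT index correctness."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from hapcores import (
    HaplotypePanel,
    attach_genetic_map,
    build_pbwt,
    interval_length,
    rank_at,
    read_panel,
)
from hapcores.panel import (
    CoordinateError,
    PanelFormatError,
    PhaseError,
    SiteInterval,
    write_matrix,
)

from ._oracles import pbwt_sort_oracle
from .conftest import random_panel

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=100000>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def write_vcf(path, samples, records):
    with open(path, "w") as fh:
        fh.write(VCF_HEADER.format(samples="\t".join(samples)))
        for pos, ref, alt, gts in records:
            fh.write(
                f"1\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


class TestMatrixFormat:
    def test_roundtrip_and_transcription(self, tmp_path):
        p = tmp_path / "panel.matrix"
        p.write_text("#BP 100 200 300\n010\n110\n")
        panel = read_panel(p, format="matrix")
        assert (panel.M, panel.N) == (2, 3)
        assert panel.alleles[1].tolist() == [1, 1, 0]
        assert panel.site_bp.tolist() == [100, 200, 300]
        out = tmp_path / "roundtrip.matrix"
        write_matrix(panel, out)
        again = read_panel(out, format="matrix")
        assert np.array_equal(again.alleles, panel.alleles)
        assert again.site_bp.tolist() == panel.site_bp.tolist()

    def test_missing_bp_header_rejected(self, tmp_path):
        p = tmp_path / "bad.matrix"
        p.write_text("010\n110\n")
        with pytest.raises(PanelFormatError):
            read_panel(p, format="matrix")

    def test_non_binary_rejected(self, tmp_path):
        p = tmp_path / "bad.matrix"
        p.write_text("#BP 1 2 3\n012\n")
        with pytest.raises(PanelFormatError):
            read_panel(p, format="matrix")


class TestVcf:
    def test_phased_split_into_two_rows(self, tmp_path):
        p = tmp_path / "one.vcf"
        write_vcf(p, ["S1"], [(50, "A", "G", ["0|1"])])
        panel = read_panel(p, format="vcf")
        assert (panel.M, panel.N) == (2, 1)
        assert panel.alleles.tolist() == [[0], [1]]
        assert panel.sample_ids == ["S1_0", "S1_1"]

    def test_unphased_rejected(self, tmp_path):
        p = tmp_path / "unphased.vcf"
        write_vcf(p, ["S1"], [(50, "A", "G", ["0/1"])])
        with pytest.raises(PhaseError):
            read_panel(p, format="vcf")

    def test_multiallelic_rejected(self, tmp_path):
        p = tmp_path / "multi.vcf"
        write_vcf(p, ["S1"], [(50, "A", "G,T", ["0|1"])])
        with pytest.raises(PanelFormatError):
            read_panel(p, format="vcf")


class TestGeneticMap:
    @pytest.mark.parametrize(
        "gmap, bp, expected_cm",
        [
            ([(0, 0.0), (1000, 1.0)], [500], [0.5]),
            ([(0, 0.0), (1000, 1.0)], [2000], [1.0]),  # clamped extrapolation
            ([(0, 0.0), (100, 0.1), (200, 0.4)], [150], [0.25]),
        ],
    )
    def test_interpolation(self, gmap, bp, expected_cm):
        panel = HaplotypePanel(
            alleles=np.zeros((1, len(bp)), dtype=np.uint8), site_bp=bp
        )
        out = attach_genetic_map(panel, gmap)
        assert out.site_cm == pytest.approx(expected_cm)

    def test_empty_and_decreasing_maps_rejected(self):
        panel = HaplotypePanel(alleles=np.zeros((1, 1), dtype=np.uint8), site_bp=[5])
        with pytest.raises(CoordinateError):
            attach_genetic_map(panel, np.empty((0, 2)))
        with pytest.raises(CoordinateError):
            attach_genetic_map(panel, [(0, 1.0), (10, 0.5)])


class TestIntervalLength:
    def setup_method(self):
        self.panel = HaplotypePanel(
            alleles=np.zeros((1, 4), dtype=np.uint8),
            site_bp=[0, 10, 20, 30],
            site_cm=[0.0, 0.5, 1.5, 1.5],
        )

    def test_units(self):
        assert interval_length(None, (2, 8), "sites") == 6
        assert interval_length(self.panel, (0, 4), "bp") == 30
        assert interval_length(self.panel, (1, 3), "cm") == 1.0

    def test_cm_without_map_is_an_error(self):
        panel = HaplotypePanel(alleles=np.zeros((1, 2), dtype=np.uint8), site_bp=[1, 2])
        with pytest.raises(ValueError):
            interval_length(panel, (0, 2), "cm")

    def test_invalid_interval(self):
        with pytest.raises(ValueError):
            SiteInterval(3, 3)
        with pytest.raises(ValueError):
            interval_length(None, (5, 2), "sites")


class TestPbwt:
    def test_singleton_panel(self):
        panel = HaplotypePanel(
            alleles=np.array([[0, 1, 0]], dtype=np.uint8), site_bp=[1, 2, 3]
        )
        idx = build_pbwt(panel)
        assert all(idx.prefix_arrays[k].tolist() == [0] for k in range(4))

    def test_three_hap_example(self):
        panel = HaplotypePanel(
            alleles=np.array([[0, 0], [1, 0], [0, 1]], dtype=np.uint8),
            site_bp=[1, 2],
        )
        idx = build_pbwt(panel)
        assert idx.prefix_arrays[0].tolist() == [0, 1, 2]
        assert idx.prefix_arrays[1].tolist() == [0, 2, 1]
        assert idx.prefix_arrays[2].tolist() == [0, 1, 2]
        assert rank_at(idx, 1, 2) == 1

    def test_rank_identity_at_zero_and_roundtrip(self):
        panel = random_panel(11)
        idx = build_pbwt(panel)
        for h in range(panel.M):
            assert rank_at(idx, 0, h) == h
        for k in range(panel.N + 1):
            a = idx.prefix_arrays[k]
            for h in range(panel.M):
                assert a[rank_at(idx, k, h)] == h

    def test_bounds_errors(self):
        panel = random_panel(3)
        idx = build_pbwt(panel)
        with pytest.raises(IndexError):
            rank_at(idx, panel.N + 1, 0)
        with pytest.raises(IndexError):
            rank_at(idx, 0, panel.M)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_reversed_prefix_sort(self, seed):
        panel = random_panel(seed)
        idx = build_pbwt(panel)
        for k in range(panel.N + 1):
            assert idx.prefix_arrays[k].tolist() == pbwt_sort_oracle(panel.alleles, k)

    @pytest.mark.parametrize("seed", range(6))
    def test_prefix_adjacency(self, seed):
        """Haplotypes identical over [0, k) occupy consecutive ranks."""
        panel = random_panel(seed, max_m=10, max_n=12)
        idx = build_pbwt(panel)
        for k in range(panel.N + 1):
            a = idx.prefix_arrays[k]
            keys = [tuple(panel.alleles[h, :k]) for h in a]
            # equal keys must be contiguous in the array
            seen = set()
            prev = None
            for key in keys:
                if key != prev:
                    assert key not in seen
                    seen.add(key)
                prev = key

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        alleles=arrays(
            np.uint8,
            st.tuples(st.integers(1, 8), st.integers(1, 10)),
            elements=st.integers(0, 1),
        )
    )
    def test_divergence_is_exact_match_start(self, alleles):
        """d_k[j] is the smallest s with a_k[j-1] and a_k[j] equal on [s, k)."""
        panel = HaplotypePanel(
            alleles=alleles, site_bp=np.arange(alleles.shape[1]) + 1
        )
        idx = build_pbwt(panel)
        for k in range(panel.N + 1):
            a = idx.prefix_arrays[k]
            d = idx.divergence_arrays[k]
            for j in range(1, panel.M):
                x, y = panel.alleles[a[j - 1]], panel.alleles[a[j]]
                s = k
                while s > 0 and x[s - 1] == y[s - 1]:
                    s -= 1
                assert d[j] == s


def test_panel_invariant_violations():
    with pytest.raises(PanelFormatError):
        HaplotypePanel(alleles=np.array([[0, 2]]), site_bp=[1, 2])
    with pytest.raises(CoordinateError):
        HaplotypePanel(alleles=np.zeros((1, 2), dtype=np.uint8), site_bp=[5, 5])
    with pytest.raises(PanelFormatError):
        HaplotypePanel(
            alleles=np.zeros((2, 1), dtype=np.uint8),
            site_bp=[1],
            sample_ids=["a", "a"],
        )
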