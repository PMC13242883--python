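"""Variant calling, window divergence ratios, GC landscape and
outlier-region delimitation."""

import numpy as np
import pytest

from bathypan import divergence as dv
from bathypan import simgenome as sg
from bathypan.validation import align_chromosome, reciprocal_overlap
from conftest import random_dna


def _snp(pos, chrom="chr", strain="s"):
    return dv.SnpRecord(chrom, pos, "A", "C", strain)


class TestCallVariants:
    def test_identical_sequences_yield_nothing(self, rng):
        seq = random_dna(rng, 5_000)
        blocks, _ = align_chromosome(seq, seq, "c")
        snps, svs = dv.call_variants(blocks, {"c": seq}, {"c": seq}, "s")
        assert snps == [] and svs == []

    def test_known_snps_recovered(self, rng):
        seq = random_dna(rng, 20_000)
        arr = bytearray(seq.encode())
        subs = {2_000: "A", 7_500: "C", 13_000: "G"}
        comp = {"A": "C", "C": "G", "G": "T", "T": "A"}
        truth = {}
        for p in subs:
            ref_b = chr(arr[p])
            arr[p] = ord(comp[ref_b])
            truth[p] = (ref_b, comp[ref_b])
        qry = arr.decode()
        blocks, _ = align_chromosome(seq, qry, "c")
        snps, _svs = dv.call_variants(blocks, {"c": seq}, {"c": qry}, "s")
        got = {s.position: (s.ref_base, s.alt_base) for s in snps}
        assert got == truth

    def test_deletion_between_blocks(self, rng):
        seq = random_dna(rng, 30_000)
        qry = seq[:10_000] + seq[14_000:]
        blocks, _ = align_chromosome(seq, qry, "c")
        _snps, svs = dv.call_variants(blocks, {"c": seq}, {"c": qry}, "s")
        dels = [s for s in svs if s.type == "DEL"]
        assert any(reciprocal_overlap((10_000, 14_000),
                                      (d.ref_start, d.ref_end)) >= 0.95
                   for d in dels)

    def test_inversion_record_from_block_label(self, rng):
        seq = random_dna(rng, 60_000)
        qry = seq[:20_000] + sg.revcomp(seq[20_000:40_000]) + seq[40_000:]
        blocks, _ = align_chromosome(seq, qry, "c")
        _snps, svs = dv.call_variants(blocks, {"c": seq}, {"c": qry}, "s")
        invs = [s for s in svs if s.type == "INV"]
        assert len(invs) == 1
        assert reciprocal_overlap((20_000, 40_000),
                                  (invs[0].ref_start, invs[0].ref_end)) >= 0.95


class TestWindowDivergence:
    def test_uniform_rate_gives_mean_ratio_one(self):
        rng = np.random.default_rng(5)
        chrom_len = 1_000_000  # 50 windows at step = window
        pos = rng.integers(0, chrom_len, size=5_000)
        windows = dv.window_divergence([_snp(int(p)) for p in pos],
                                       {"chr": chrom_len}, window=20_000,
                                       step=20_000, aligned_bp=chrom_len)
        assert len(windows) == 50
        mean_ratio = np.mean([w.ratio for w in windows])
        assert abs(mean_ratio - 1.0) <= 0.1

    def test_no_variants_all_zero(self):
        windows = dv.window_divergence([], {"chr": 100_000},
                                       genome_wide_density=0.01)
        assert all(w.ratio == 0 and w.n_variants == 0 for w in windows)

    def test_counts_conserved_at_step_equals_window(self):
        rng = np.random.default_rng(6)
        pos = rng.integers(0, 333_333, size=777)
        windows = dv.window_divergence([_snp(int(p)) for p in pos],
                                       {"chr": 333_333}, window=20_000,
                                       step=20_000, aligned_bp=333_333)
        assert sum(w.n_variants for w in windows) == 777
        assert windows[-1].end == 333_333  # partial final window kept

    def test_sv_counted_once_at_midpoint(self):
        sv = dv.SvRecord("DEL", "chr", 19_000, 23_000, 0, 0, "s")
        windows = dv.window_divergence([sv], {"chr": 60_000}, window=20_000,
                                       step=20_000, aligned_bp=60_000)
        assert [w.n_variants for w in windows] == [0, 1, 0]

    def test_invalid_window_raises(self):
        with pytest.raises(ValueError):
            dv.window_divergence([], {"chr": 1000}, window=0)


class TestDetectReducedPolymorphism:
    def test_no_low_windows_empty(self):
        ws = [dv.WindowStat("c", i * 10, i * 10 + 10, 1, 0.1, 1.2)
              for i in range(10)]
        assert dv.detect_reduced_polymorphism(ws) == []

    def test_worked_run_example(self):
        ratios = [1.2, 0.4, 0.5, 0.3, 1.1]
        ws = [dv.WindowStat("c", i * 10, i * 10 + 10, 0, 0.0, r)
              for i, r in enumerate(ratios)]
        out = dv.detect_reduced_polymorphism(ws, min_consecutive=3)
        assert out == [("c", 10, 40)]

    def test_short_runs_suppressed(self):
        ratios = [0.5, 0.5, 1.2, 0.5, 0.5]
        ws = [dv.WindowStat("c", i * 10, i * 10 + 10, 0, 0.0, r)
              for i, r in enumerate(ratios)]
        assert dv.detect_reduced_polymorphism(ws, min_consecutive=3) == []


class TestGcProfile:
    def test_all_g(self):
        assert all(v == 1.0 for _w, v in dv.gc_profile("G" * 500, 100, 100))

    def test_alternating(self):
        assert all(v == 0.5 for _w, v in dv.gc_profile("ACGT" * 250, 100, 100))

    def test_outlier_region_gc(self, small_cfg, boc_pair):
        ancestor = boc_pair[0]
        chrom = ancestor.seq(small_cfg.boc_chrom)
        region = chrom[len(chrom) - small_cfg.boc_region_len_A:]
        vals = [v for _w, v in dv.gc_profile(region, 20_000, 20_000)]
        assert 0.38 <= np.mean(vals) <= 0.42


class TestDelimitOutlierRegion:
    def test_flat_gc_full_synteny_none(self, rng):
        seq = random_dna(rng, 400_000)
        gc = dv.gc_profile(seq)
        assert dv.delimit_outlier_region(gc, [], chrom_len=len(seq)) is None

    def test_gc_only_evidence(self):
        rng = np.random.default_rng(8)
        normal = sg.random_seq(rng, 900_000, 0.48)
        low = sg.random_seq(rng, 100_000, 0.40)
        seq = normal + low
        gc = dv.gc_profile(seq)
        region = dv.delimit_outlier_region(gc, None, chrom_len=len(seq))
        assert region is not None
        assert reciprocal_overlap(region, (900_000, 1_000_000)) >= 0.8

    def test_boc_pair_recovery(self, small_cfg, boc_pair, boc_alignment):
        _anc, hapl_a, _b, truth = boc_pair
        _blocks, nonsyn = boc_alignment
        chrom_seq = hapl_a.seq(small_cfg.boc_chrom)
        gc = dv.gc_profile(chrom_seq)
        region = dv.delimit_outlier_region(gc, nonsyn,
                                           chrom_len=len(chrom_seq))
        _c, s, e = truth.regions["boc_outlier"]["haplA"]
        assert region is not None
        assert reciprocal_overlap(region, (s, e)) >= 0.9


class TestCodingDensity:
    def _gene(self, s, e, chrom="c"):
        return sg.GeneModel(f"g{s}", chrom, s, e, "+")

    def test_single_gene_fraction(self):
        assert dv.coding_density([self._gene(0, 460)], (0, 1000)) == 0.46

    def test_union_not_sum(self):
        genes = [self._gene(0, 500), self._gene(250, 750)]
        assert dv.coding_density(genes, (0, 1000)) == 0.75

    def test_no_genes(self):
        assert dv.coding_density([], (0, 1000)) == 0.0

    def test_out_of_range(self):
        with pytest.raises(dv.RangeError):
            dv.coding_density([], (500, 100))
        with pytest.raises(dv.RangeError):
            dv.coding_density([], (0, 2000), chrom_len=1000)

    def test_monotone_under_added_genes(self, rng):
        genes = []
        last = 0.0
        for _ in range(20):
            s = int(rng.integers(0, 900))
            genes.append(self._gene(s, s + int(rng.integers(10, 100))))
            cur = dv.coding_density(genes, (0, 1000))
            assert cur >= last
            last = cur
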