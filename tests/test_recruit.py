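"""Read recruitment: indexing, mapping, complexity labels, the four
filters, abundance and ratio statistics."""

import warnings

import numpy as np
import pytest

from bathypan import recruit as rc
from bathypan import simgenome as sg
from bathypan.simgenome import ConfigError
from conftest import random_dna


class TestIndex:
    def test_position_count(self):
        idx = rc.index_references([("t1", "ACGT" * 250)], k=21)
        assert idx.n_positions == 1000 - 21 + 1

    def test_identical_references_list_both(self, rng):
        seq = random_dna(rng, 200)
        idx = rc.index_references([("a", seq), ("b", seq)], k=21)
        kv = rc._kmer_ints(seq[:21], 21)
        lo, hi = idx.lookup_range(kv)
        tis, _pos = idx.entries(int(lo[0]), int(hi[0]))
        assert sorted(tis.tolist()) == [0, 1]

    def test_short_reference_warns_empty(self):
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            idx = rc.index_references([("t", "ACGT")], k=21)
        assert idx.n_positions == 0 and len(w) == 1

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ConfigError):
            rc.index_references([("t", "A" * 30), ("t", "C" * 30)])


class TestMapRead:
    def test_exact_substring(self, rng):
        ref = random_dna(rng, 2000)
        idx = rc.index_references([("t", ref)])
        m = rc.map_read(("r", ref[500:600]), idx)
        assert m.identity == 1.0 and m.aligned_fraction == 1.0
        assert m.unique and m.target_pos == 500 and m.strand == "+"

    def test_reverse_strand_read(self, rng):
        ref = random_dna(rng, 2000)
        idx = rc.index_references([("t", ref)])
        m = rc.map_read(("r", sg.revcomp(ref[300:400])), idx)
        assert m is not None and m.strand == "-" and m.target_pos == 300

    def test_random_read_unmapped(self, rng):
        ref = random_dna(rng, 2000)
        idx = rc.index_references([("t", ref)])
        assert rc.map_read(("r", random_dna(rng, 100)), idx) is None

    def test_two_identical_targets_not_unique(self, rng):
        ref = random_dna(rng, 2000)
        idx = rc.index_references([("a", ref), ("b", ref)])
        m = rc.map_read(("r", ref[100:200]), idx)
        assert m is not None and not m.unique

    def test_tied_reads_spread_over_targets(self, rng):
        ref = random_dna(rng, 4000)
        idx = rc.index_references([("a", ref), ("b", ref)])
        hits = [rc.map_read((f"r{i}", ref[i * 30 : i * 30 + 100]), idx)
                for i in range(50)]
        targets = {m.target_id for m in hits}
        assert targets == {"a", "b"}


class TestComplexity:
    def test_homopolymer_low(self):
        assert rc.read_complexity("A" * 150)[0] == 1.0

    def test_dimer_repeat_low(self):
        assert rc.read_complexity("AC" * 75)[0] == 1.0

    def test_uniform_random_high_complexity(self, rng):
        lows = [rc.read_complexity(random_dna(rng, 150))[0]
                for _ in range(1000)]
        assert np.mean([l > 0 for l in lows]) < 0.05

    def test_empty_read_rejected(self):
        with pytest.raises(ValueError):
            rc.read_complexity("")


class TestFilters:
    def _r(self, read_id="r", **kw):
        base = dict(read_id=read_id, target_id="t", target_pos=0, strand="+",
                    identity=1.0, aligned_fraction=1.0, unique=True,
                    low_complexity_frac=0.0, high_complexity_frac=1.0,
                    read_len=100)
        base.update(kw)
        return rc.MappingResult(**base)

    @pytest.mark.parametrize("kw,kept", [
        (dict(identity=0.94), False),
        (dict(aligned_fraction=0.79, identity=0.99), False),
        (dict(low_complexity_frac=0.80), False),
        (dict(high_complexity_frac=0.25), False),
        (dict(), True),
    ])
    def test_threshold_rules(self, kw, kept):
        assert bool(rc.apply_filters([self._r(**kw)])) is kept

    def test_positional_duplicates_removed(self):
        a = self._r("r1", target_pos=5)
        b = self._r("r2", target_pos=5)
        c = self._r("r3", target_pos=6)
        out = rc.apply_filters([b, a, c])
        assert [r.read_id for r in out] == ["r1", "r3"]  # first by read id

    def test_filter_idempotence(self, rng):
        results = [self._r(f"r{i}", target_pos=int(rng.integers(0, 50)),
                           identity=float(rng.uniform(0.9, 1.0)))
                   for i in range(100)]
        once = rc.apply_filters(results)
        assert rc.apply_filters(once) == once


class TestAbundance:
    def _r(self, i, target="t"):
        return rc.MappingResult(f"r{i}", target, i, "+", 1.0, 1.0, True,
                                0.0, 1.0, 100)

    def test_fraction_of_sequenced(self):
        filtered = [self._r(i) for i in range(500)]
        assert rc.relative_abundance(filtered, 100_000) == {"t": 0.005}

    def test_zero_mapped(self):
        assert rc.relative_abundance([], 1000) == {}

    def test_additivity_bound(self, rng):
        filtered = [self._r(i, target=f"t{int(rng.integers(3))}")
                    for i in range(200)]
        ab = rc.relative_abundance(filtered, 400)
        assert sum(ab.values()) <= 1.0

    def test_mixture_recovery_with_filters(self, rng):
        # 4% of reads from the indexed genome at 0.5% error: the filtered
        # abundance stays within a binomial band minus small filter loss
        target = sg.GenomeAssembly("tgt", [("c1", random_dna(rng, 150_000))])
        other = sg.GenomeAssembly("oth", [("c1", random_dna(rng, 150_000))])
        reads, _t = sg.simulate_reads([(target, 0.04), (other, 0.96)],
                                      25_000, 100, 0.005, seed=17)
        idx = rc.index_references([("tgt", target.chromosomes[0][1])])
        filtered = rc.apply_filters(rc.map_reads(reads, idx))
        ab = rc.relative_abundance(filtered, len(reads))["tgt"]
        assert 0.035 <= ab <= 0.041


class TestHaplotypeRatio:
    def test_single_origin_ratio(self, rng):
        region_a = random_dna(rng, 40_000)
        region_b = random_dna(rng, 40_000)
        asm = sg.GenomeAssembly("A", [("boc", region_a)])
        reads, _ = sg.simulate_reads([(asm, 1.0)], 3_000, 100, 0.002, seed=3)
        hr = rc.haplotype_ratio(reads, ("A", region_a), ("B", region_b))
        assert hr.ratio_a >= 0.99

    def test_undefined_when_nothing_maps(self, rng):
        reads = [sg.SimRead(f"r{i}", random_dna(rng, 100)) for i in range(50)]
        hr = rc.haplotype_ratio(reads, ("A", random_dna(rng, 30_000)),
                                ("B", random_dna(rng, 30_000)))
        assert hr.undefined and hr.ratio_a is None


class TestCrossMappingSpecificity:
    def test_identical_references_zero_specificity(self, rng):
        ref = random_dna(rng, 60_000)
        asm = sg.GenomeAssembly("x", [("c", ref)])
        reads, _ = sg.simulate_reads([(asm, 1.0)], 2_000, 100, 0.0, seed=5)
        spec = rc.cross_mapping_specificity(reads, [("a", ref), ("b", ref)])
        assert spec.get("a", 0.0) == 0.0 and spec.get("b", 0.0) == 0.0

    def test_disjoint_references_full_specificity(self, rng):
        ref_a, ref_b = random_dna(rng, 60_000), random_dna(rng, 60_000)
        mix = [(sg.GenomeAssembly("A", [("c", ref_a)]), 0.5),
               (sg.GenomeAssembly("B", [("c", ref_b)]), 0.5)]
        reads, _ = sg.simulate_reads(mix, 2_000, 100, 0.0, seed=6)
        spec = rc.cross_mapping_specificity(reads, [("a", ref_a),
                                                    ("b", ref_b)])
        assert spec["a"] == 1.0 and spec["b"] == 1.0

    def test_sister_references_low_specificity(self, rng):
        # ~92% shared identical sequence; reads 90/10 by strain: the rarer
        # reference recruits mostly shared reads, few of them specific
        shared_len, spec_len = 55_000, 5_000
        shared = random_dna(rng, shared_len)
        ref_a = shared + random_dna(rng, spec_len)
        ref_b = shared + random_dna(rng, spec_len)
        mix = [(sg.GenomeAssembly("A", [("c", ref_a)]), 0.9),
               (sg.GenomeAssembly("B", [("c", ref_b)]), 0.1)]
        reads, _ = sg.simulate_reads(mix, 20_000, 100, 0.002, seed=7)
        spec = rc.cross_mapping_specificity(reads, [("a", ref_a),
                                                    ("b", ref_b)])
        assert spec["b"] <= 0.15
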