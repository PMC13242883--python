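"""Maximal-exact-match discovery, chaining, filtering and classification."""

import edlib
import pytest

from bathypan import anchor_align as aa
from bathypan.validation import _brute_mems
from conftest import random_dna


class TestFindMems:
    def test_worked_example_forward(self):
        got = {(a.ref_pos, a.qry_pos, a.length)
               for a in aa.find_mems("ACGTACGT", "TACGTA", 4,
                                     both_strands=False)}
        assert got == {(0, 1, 5), (3, 0, 5)}

    def test_self_match_full_length(self):
        seq = "ACGTTGCAGG"
        anchors = aa.find_mems(seq, seq, 5)
        assert any(a.ref_pos == 0 and a.qry_pos == 0 and a.length == len(seq)
                   and a.strand == "+" for a in anchors)

    def test_revcomp_identity(self):
        anchors = aa.find_mems("AAAA", "TTTT", 4)
        assert [(a.ref_pos, a.qry_pos, a.length, a.strand)
                for a in anchors] == [(0, 0, 4, "-")]

    def test_empty_sequences(self):
        assert aa.find_mems("", "ACGT", 4) == []
        assert aa.find_mems("ACGT", "", 4) == []

    @pytest.mark.parametrize("trial", range(40))
    def test_matches_brute_force(self, rng, trial):
        n, m = int(rng.integers(10, 400)), int(rng.integers(10, 400))
        ref, qry = random_dna(rng, n), random_dna(rng, m)
        if trial % 2 and n > 60:
            s = int(rng.integers(0, n - 40))
            seg = ref[s : s + 30]
            qry = qry[: m // 2] + (aa.revcomp(seg) if trial % 4 else seg) \
                + qry[m // 2:]
        k = int(rng.integers(5, 12))
        got = {(a.ref_pos, a.qry_pos, a.length, a.strand)
               for a in aa.find_mems(ref, qry, k)}
        assert got == _brute_mems(ref, qry, k)


class TestChainAndExtend:
    def test_single_anchor_identity_one(self, rng):
        seq = random_dna(rng, 400)
        blocks = aa.chain_and_extend(aa.find_mems(seq, seq, 20), seq, seq)
        assert len(blocks) == 1
        b = blocks[0]
        assert b.identity == 1.0 and b.n_mismatch == 0 and b.n_gapcols == 0
        assert (b.ref_start, b.ref_end) == (0, 400)

    def test_substituted_gap_identity_bookkeeping(self, rng):
        # two 300-bp exact anchors around a 10-bp fully substituted gap;
        # an AC-repeat replaced by a GT-repeat shares no base under any
        # alignment shift, so the optimal edit path is 10 substitutions
        # (verified against edlib as the oracle)
        flank_l, flank_r = random_dna(rng, 300), random_dna(rng, 300)
        ref = flank_l + "AC" * 5 + flank_r
        qry = flank_l + "GT" * 5 + flank_r
        assert edlib.align("GT" * 5, "AC" * 5,
                           mode="NW")["editDistance"] == 10
        blocks = aa.chain_and_extend(aa.find_mems(ref, qry, 20), ref, qry)
        assert len(blocks) == 1
        b = blocks[0]
        assert b.n_mismatch == 10 and b.n_gapcols == 0
        assert b.identity == pytest.approx(600 / 610)

    def test_minus_strand_blocks_forward_coords(self, rng):
        seq = random_dna(rng, 500)
        qry = aa.revcomp(seq)
        anchors = aa.find_mems(seq, qry, 20)
        assert all(a.strand == "-" for a in anchors)
        blocks = aa.chain_and_extend(anchors, seq, qry)
        assert blocks and all(b.strand == "-" for b in blocks)
        b = blocks[0]
        assert 0 <= b.qry_start < b.qry_end <= len(qry)

    def test_out_of_bounds_anchor_rejected(self):
        with pytest.raises(aa.IntegrityError):
            aa.chain_and_extend([aa.Anchor(0, 0, 50)], "ACGT", "ACGT")


class TestFilterBlocks:
    def _blk(self, identity, length):
        n_err = round((1 - identity) * length)
        return aa.AlignmentBlock("r", 0, length, "q", 0, length, "+", length,
                                 (length - n_err) / length, n_err, 0)

    @pytest.mark.parametrize("identity,length,kept", [
        (0.99, 99, False),   # too short (strict >100)
        (0.90, 5000, False), # identity not strictly above 0.90
        (0.95, 101, True),
    ])
    def test_strict_thresholds(self, identity, length, kept):
        out = aa.filter_blocks([self._blk(identity, length)])
        assert bool(out) is kept

    def test_relaxing_thresholds_is_monotone(self, rng):
        blocks = [self._blk(float(rng.uniform(0.85, 1.0)),
                            int(rng.integers(50, 400))) for _ in range(200)]
        base = len(aa.filter_blocks(blocks))
        assert len(aa.filter_blocks(blocks, min_identity=0.85)) >= base
        assert len(aa.filter_blocks(blocks, min_length=50)) >= base


class TestClassifyBlocks:
    def test_collinear_all_syn_no_nonsyntenic(self, rng):
        seq = random_dna(rng, 2000)
        blocks = aa.chain_and_extend(aa.find_mems(seq, seq, 20), seq, seq)
        blocks, nonsyn = aa.classify_blocks(blocks, ref_len=len(seq))
        assert all(b.class_label == "SYN" for b in blocks)
        assert nonsyn == []

    def test_tandem_duplication_labelled_dup(self, rng):
        seq = random_dna(rng, 3000)
        qry = seq[:1500] + seq[1000:1500] + seq[1500:]  # tandem copy
        blocks, _ = (lambda b: aa.classify_blocks(
            aa.filter_blocks(b), ref_len=len(seq)))(
            aa.chain_and_extend(aa.find_mems(seq, qry, 20), seq, qry))
        labels = {b.class_label for b in blocks}
        assert "DUP" in labels
        dup = [b for b in blocks if b.class_label == "DUP"]
        assert any(abs(b.ref_start - 1000) < 30 and abs(b.ref_end - 1500) < 30
                   for b in dup)

    def test_syn_blocks_non_overlapping(self, boc_alignment):
        blocks, _ = boc_alignment
        syn = sorted((b for b in blocks if b.class_label == "SYN"),
                     key=lambda b: b.ref_start)
        for prev, nxt in zip(syn, syn[1:]):
            assert prev.ref_end <= nxt.ref_start
        by_qry = sorted(syn, key=lambda b: b.qry_start)
        for prev, nxt in zip(by_qry, by_qry[1:]):
            assert prev.qry_end <= nxt.qry_start

    def test_identity_recomputes_from_counts(self, boc_alignment):
        blocks, _ = boc_alignment
        for b in blocks:
            recomputed = (b.aligned_length - b.n_mismatch - b.n_gapcols) \
                / b.aligned_length
            assert b.identity == recomputed

    def test_inversion_labelled_inv(self, rng):
        seq = random_dna(rng, 5000)
        qry = seq[:2000] + aa.revcomp(seq[2000:3000]) + seq[3000:]
        blocks, _ = (lambda b: aa.classify_blocks(
            aa.filter_blocks(b), ref_len=len(seq)))(
            aa.chain_and_extend(aa.find_mems(seq, qry, 20), seq, qry))
        inv = [b for b in blocks if b.class_label == "INV"]
        assert any(abs(b.ref_start - 2000) < 30 and abs(b.ref_end - 3000) < 30
                   for b in inv)


class TestSharedSequenceCatalog:
    def test_identical_socs(self, rng):
        soc = random_dna(rng, 100_000)
        records, frac = aa.shared_sequence_catalog(
            [("s1", soc), ("s2", soc)])
        assert len(records) == 1
        assert records[0].length == 100_000
        assert frac == {"s1": 1.0, "s2": 1.0}

    def test_unrelated_socs_share_nothing(self, rng):
        records, frac = aa.shared_sequence_catalog(
            [("s1", random_dna(rng, 50_000)), ("s2", random_dna(rng, 50_000))])
        assert records == []
        assert frac == {"s1": 0.0, "s2": 0.0}

    def test_designed_shared_blocks_total(self, rng):
        shared = [random_dna(rng, n) for n in (5_000, 10_000, 20_000)]
        private = [random_dna(rng, n) for n in (12_000, 9_000, 15_000, 8_000)]
        soc_a = private[0] + shared[0] + private[1] + shared[1] + shared[2]
        soc_b = shared[2] + private[2] + shared[0] + private[3] + shared[1]
        records, frac = aa.shared_sequence_catalog(
            [("a", soc_a), ("b", soc_b)])
        total = sum(r.length for r in records)
        assert abs(total - 35_000) <= 1_000

    def test_symmetry_of_shared_totals(self, rng):
        shared = random_dna(rng, 15_000)
        soc_a = random_dna(rng, 10_000) + shared + random_dna(rng, 8_000)
        soc_b = shared + random_dna(rng, 20_000)
        r_ab, _ = aa.shared_sequence_catalog([("a", soc_a), ("b", soc_b)])
        r_ba, _ = aa.shared_sequence_catalog([("b", soc_b), ("a", soc_a)])
        t_ab = sum(r.length for r in r_ab)
        t_ba = sum(r.length for r in r_ba)
        assert abs(t_ab - t_ba) <= 0.01 * max(t_ab, t_ba)

    def test_requires_two_sequences(self):
        with pytest.raises(ValueError):
            aa.shared_sequence_catalog([("s1", "ACGT" * 100)])
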