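"""Synthetic genome generator: composition targets, truth replay,
haplotype derivation, strain evolution and read mixtures."""

import numpy as np
import pytest

from bathypan import fileio
from bathypan import simgenome as sg
from bathypan.simgenome import ConfigError, SimulationError


def _tiny_cfg(**kw):
    base = dict(seed=7, n_chromosomes=3,
                chrom_lengths=[250_000, 650_000, 140_000],
                boc_chrom="chr02", soc_chrom="chr03", snp_rate=0.002)
    base.update(kw)
    return sg.SimConfig(**base)


class TestConfig:
    def test_region_must_fit_chromosome(self):
        cfg = _tiny_cfg(chrom_lengths=[250_000, 300_000, 140_000],
                        boc_region_len_A=2_000_000)
        with pytest.raises(ConfigError):
            cfg.validate()

    def test_boc_and_soc_must_differ(self):
        with pytest.raises(ConfigError):
            _tiny_cfg(soc_chrom="chr02").validate()

    def test_rates_in_unit_interval(self):
        with pytest.raises(ConfigError):
            _tiny_cfg(snp_rate=1.5).validate()

    def test_outlier_gc_below_genome_gc(self):
        with pytest.raises(ConfigError):
            _tiny_cfg(outlier_gc=0.60).validate()

    def test_default_lengths_cover_19_chromosomes(self):
        cfg = sg.SimConfig(seed=3)
        lengths = cfg.resolved_chrom_lengths()
        assert len(lengths) == 19
        assert abs(sum(lengths) - cfg.total_genome_size) < 0.1 * cfg.total_genome_size


class TestBuildAncestor:
    def test_composition_targets(self, small_cfg, boc_pair):
        ancestor = boc_pair[0]
        chrom = ancestor.seq(small_cfg.boc_chrom)
        ostart = len(chrom) - small_cfg.boc_region_len_A
        assert abs(sg.gc_fraction(chrom[ostart:]) - small_cfg.outlier_gc) < 0.02
        assert abs(sg.gc_fraction(chrom[:ostart]) - small_cfg.genome_gc) < 0.02
        from bathypan.divergence import coding_density
        genes = ancestor.genes_on(small_cfg.boc_chrom)
        assert abs(coding_density(genes, (ostart, len(chrom)))
                   - small_cfg.gene_density_outlier) < 0.05
        assert abs(coding_density(genes, (0, ostart))
                   - small_cfg.gene_density_normal) < 0.05

    def test_emitted_files_byte_identical_across_runs(self, tmp_path):
        cfg = _tiny_cfg()
        payloads = []
        for run in range(2):
            asm, _ = sg.build_ancestor(cfg)
            fa, gff = tmp_path / f"a{run}.fa", tmp_path / f"a{run}.gff3"
            fileio.write_fasta(fa, asm.chromosomes)
            fileio.write_gff3(gff, asm)
            payloads.append(fa.read_bytes() + gff.read_bytes())
        assert payloads[0] == payloads[1]

    def test_gene_models_valid(self, boc_pair):
        boc_pair[0].validate()


class TestDeriveBocHaplotypes:
    def test_zero_events_is_identity(self, small_cfg, boc_pair):
        hapl_a, hapl_b, _ = sg.derive_boc_haplotypes(boc_pair[0], small_cfg,
                                                     events=[])
        assert hapl_a.chromosomes == hapl_b.chromosomes

    def test_event_replay_reconstructs_haplb(self, small_cfg, boc_pair):
        _anc, hapl_a, hapl_b, truth = boc_pair
        chrom = small_cfg.boc_chrom
        _c, s, e = truth.regions["boc_outlier"]["haplA"]
        out_a = hapl_a.seq(chrom)[s:]
        assert sg.replay_boc_events(out_a, truth.events) == hapl_b.seq(chrom)[s:]

    def test_haplb_outlier_length_near_target(self, small_cfg, boc_pair):
        truth = boc_pair[3]
        _c, s, e = truth.regions["boc_outlier"]["haplB"]
        assert abs((e - s) - small_cfg.boc_region_len_B) < 0.02 * \
            small_cfg.boc_region_len_B

    def test_flanks_untouched(self, small_cfg, boc_pair):
        _anc, hapl_a, hapl_b, truth = boc_pair
        chrom = small_cfg.boc_chrom
        _c, s, _e = truth.regions["boc_outlier"]["haplA"]
        assert hapl_a.seq(chrom)[:s] == hapl_b.seq(chrom)[:s]

    def test_shared_divergent_core_genes(self, small_cfg, boc_pair):
        _anc, hapl_a, hapl_b, truth = boc_pair
        chrom = small_cfg.boc_chrom
        _c, s, _e = truth.regions["boc_outlier"]["haplA"]
        a_ids = {g.gene_id for g in hapl_a.genes_on(chrom) if g.start >= s}
        b_ids = {g.gene_id for g in hapl_b.genes_on(chrom) if g.start >= s}
        assert len(a_ids & b_ids) >= 3  # retained-segment genes survive


class TestEvolveStrain:
    def test_identity_without_mutations(self, boc_pair):
        anc = boc_pair[0]
        cfg = _tiny_cfg()
        child, truth = sg.evolve_strain(anc, cfg, seed=1, snp_rate=0.0,
                                        sv_counts={})
        assert child.chromosomes == anc.chromosomes
        assert truth.snps == [] and truth.svs == []

    def test_poisson_snp_count(self):
        cfg = sg.SimConfig(seed=9, n_chromosomes=2,
                           chrom_lengths=[1_000_000, 300_000],
                           boc_chrom="chr01", soc_chrom="chr02",
                           boc_region_len_A=300_000, snp_rate=0.005)
        anc, _ = sg.build_ancestor(cfg)
        _child, truth = sg.evolve_strain(anc, cfg, seed=2, sv_counts={})
        n = sum(1 for s in truth.snps if s[0] == "chr01")
        assert abs(n - 5_000) < 3 * 70.7

    def test_deletion_length_bookkeeping(self, boc_pair):
        seq = boc_pair[0].seq("chr01")
        child_seq, _map, rows = sg.apply_sv_ops(seq, [("DEL", 50_000, 60_000)])
        assert len(child_seq) == len(seq) - 10_000
        assert rows == [("DEL", 50_000, 60_000, 50_000, 50_000)]

    def test_truth_replay_reproduces_child(self, boc_pair):
        anc = boc_pair[0]
        cfg = _tiny_cfg()
        child, truth = sg.evolve_strain(anc, cfg, seed=3)
        replay = sg.replay_evolution(anc, truth)
        assert [s for _n, s in replay.chromosomes] == \
            [s for _n, s in child.chromosomes]

    def test_unplaceable_sv_raises(self):
        cfg = sg.SimConfig(seed=5, n_chromosomes=2,
                           chrom_lengths=[60_000, 50_000],
                           boc_chrom="chr01", soc_chrom="chr02",
                           boc_region_len_A=20_000,
                           sv_counts={"INV": 60},
                           sv_len_ranges={"INV": (20_000, 40_000)})
        anc, _ = sg.build_ancestor(cfg)
        with pytest.raises(SimulationError):
            sg.evolve_strain(anc, cfg, seed=1)

    def test_genes_remain_consistent_after_svs(self, boc_pair):
        anc = boc_pair[0]
        cfg = _tiny_cfg()
        child, _ = sg.evolve_strain(anc, cfg, seed=4)
        child.validate()
        from bathypan.anchor_align import revcomp
        seqs = dict(child.chromosomes)
        for g in child.genes[:50]:
            expected = seqs[g.chrom][g.start:g.end]
            if g.strand == "-":
                expected = revcomp(expected)
            assert g.cds_seq == expected


class TestPopulationAndSoc:
    def test_single_block_pool_gives_identical_socs(self):
        cfg = _tiny_cfg(soc_pool_size=1, soc_core_len=30_000,
                        soc_len_range=(30_000, 80_000))
        strains, _ = sg.assemble_population(cfg, (3, 0), seed=2)
        socs = {s.seq(cfg.soc_chrom) for s in strains}
        assert len(socs) == 1

    def test_designed_core_families_in_all_strains(self):
        cfg = _tiny_cfg()
        strains, truth = sg.assemble_population(
            cfg, (4, 0), seed=3, cluster_spec=sg.ClusterSpec(5, 0, 0))
        for fam, carriers in truth.cluster_design.items():
            assert sorted(carriers) == sorted(s.strain_id for s in strains)
            for s in strains:
                assert any(g.gene_id == f"{fam}|{s.strain_id}"
                           for g in s.genes)

    def test_soc_lengths_within_range(self):
        cfg = _tiny_cfg()
        strains, _ = sg.assemble_population(cfg, (2, 2), seed=4)
        lo, hi = cfg.soc_len_range
        for s in strains:
            assert lo <= len(s.seq(cfg.soc_chrom)) <= hi

    def test_soc_out_of_range_raises(self):
        cfg = _tiny_cfg(soc_core_len=300_000)
        with pytest.raises(ConfigError):
            sg.assemble_population(cfg, (2, 0), seed=1)

    def test_truth_records_block_carriers(self):
        cfg = _tiny_cfg()
        strains, truth = sg.assemble_population(cfg, (2, 2), seed=5)
        seqs = {s.strain_id: s.seq(cfg.soc_chrom) for s in strains}
        assert truth.soc_blocks
        for _bid, rows in truth.soc_blocks:
            lengths = {e - s for _sid, s, e, _o in rows}
            assert len(lengths) == 1  # one block, one length everywhere
            for sid, s, e, _o in rows:
                assert 0 <= s < e <= len(seqs[sid])


class TestSimulateReads:
    def test_single_genome_origins(self, boc_pair):
        anc = boc_pair[0]
        reads, truth = sg.simulate_reads([(anc, 1.0)], 500, 100, 0.0, seed=1)
        assert len(reads) == 500
        assert all(o[1] == anc.strain_id for o in truth.mixture_origins)

    def test_error_free_reads_are_substrings(self, boc_pair):
        anc = boc_pair[0]
        reads, truth = sg.simulate_reads([(anc, 1.0)], 200, 80, 0.0, seed=2)
        seqs = dict(anc.chromosomes)
        from bathypan.anchor_align import revcomp
        for r, (_rid, _s, chrom, pos, strand) in zip(reads,
                                                     truth.mixture_origins):
            raw = seqs[chrom][pos:pos + 80]
            assert r.seq == (raw if strand == "+" else revcomp(raw))

    def test_weighted_mixture_proportions(self, boc_pair):
        anc = boc_pair[0]
        other = sg.GenomeAssembly("twin", list(anc.chromosomes), [])
        reads, truth = sg.simulate_reads([(anc, 0.7), (other, 0.3)],
                                         50_000, 100, 0.0, seed=3)
        frac = np.mean([o[1] == anc.strain_id for o in truth.mixture_origins])
        assert abs(frac - 0.7) <= 3 * np.sqrt(0.21 / 50_000)

    def test_read_longer_than_chromosome_raises(self, boc_pair):
        with pytest.raises(SimulationError):
            sg.simulate_reads([(boc_pair[0], 1.0)], 10, 200_000, 0.0, seed=1)

    def test_invalid_weights(self, boc_pair):
        with pytest.raises(ConfigError):
            sg.simulate_reads([(boc_pair[0], -1.0)], 10, 100, 0.0, seed=1)
        with pytest.raises(ConfigError):
            sg.simulate_reads([(boc_pair[0], 0.0)], 10, 100, 0.0, seed=1)
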