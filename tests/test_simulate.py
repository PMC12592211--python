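"""The synthetic study system: construction invariants, determinism, and
agreement with closed-form expectations."""

import math

import numpy as np
import pytest

from uvsdr import kmer, simulate
from uvsdr.ancestral import TreeIndex, transition_matrix
from uvsdr.core_io import HET, HOM_REF
from uvsdr.kmer import KmerConfig
from uvsdr.simulate import SimulationConfig


class TestGenomePair:
    def test_zero_length_sdr_gives_identical_genomes(self):
        cfg = SimulationConfig(seed=3, n_autosomes=1, autosome_len=50_000,
                               uv_len=50_000, sdr_start=0, sdr_len=0,
                               n_gametologues=0, n_sex_specific=0,
                               n_autosomal_genes=4, n_par_genes=0)
        male, female, *_ = simulate.simulate_genome_pair(cfg)
        assert male.records == female.records

    def test_autosomes_and_pars_identical_between_sexes(self, tiny_genomes,
                                                        tiny_sim_cfg):
        male, female, _, _, truth = tiny_genomes
        cfg = tiny_sim_cfg
        for chrom in male:
            if chrom != simulate.UV_CHROM:
                assert male[chrom] == female[chrom]
        sdr = cfg.sdr_interval
        assert male[simulate.UV_CHROM][:sdr.start] == \
            female[simulate.UV_CHROM][:sdr.start]
        assert male[simulate.UV_CHROM][sdr.end:] == \
            female[simulate.UV_CHROM][sdr.end:]

    def test_sdr_haplotypes_share_few_single_copy_kmers(self, tiny_genomes,
                                                        tiny_sim_cfg):
        male, female, *_ = tiny_genomes
        sdr = tiny_sim_cfg.sdr_interval
        m_sdr = male[simulate.UV_CHROM][sdr.start:sdr.end]
        f_sdr = female[simulate.UV_CHROM][sdr.start:sdr.end]
        from uvsdr.core_io import SequenceSet

        sc = kmer.genome_single_copy_kmers(SequenceSet({"m": m_sdr}),
                                           KmerConfig())
        f_kmers = kmer.count_read_kmers([f_sdr], KmerConfig(min_count=1))
        shared = f_kmers.contains_codes(sc.codes["m"]).mean()
        assert shared < 0.05

    def test_kmer_collision_rate_matches_expectation(self, tiny_genomes,
                                                     tiny_sim_cfg):
        """Chance sharing of unique male-SDR background 15-mers with female
        k-mers is near L_female / 4^15 per k-mer (random collisions only,
        so gametologue CDS intervals are excluded and single-copy status is
        genome-wide, removing shared TE motifs)."""
        male, female, ann_m, *_ = tiny_genomes
        sdr = tiny_sim_cfg.sdr_interval
        sc = kmer.genome_single_copy_kmers(male, KmerConfig())
        pos = sc.positions[simulate.UV_CHROM]
        codes = sc.codes[simulate.UV_CHROM]
        in_sdr = (pos >= sdr.start) & (pos < sdr.end)
        for f in ann_m.by_type("gene"):
            iv = f.interval
            if iv.chrom == simulate.UV_CHROM:
                in_sdr &= ~((pos >= iv.start - 14) & (pos < iv.end))
        f_all = kmer.count_read_kmers(
            list(female.records.values()), KmerConfig(min_count=1))
        shared = float(f_all.contains_codes(codes[in_sdr]).mean())
        expected = female.total_length() / 4 ** 15  # ~0.06% here
        n = int(in_sdr.sum())
        slack = 4 * math.sqrt(expected * (1 - expected) / n)
        assert shared < 5 * expected + slack + 1e-3

    def test_true_pairs_lie_inside_both_sdr_beds(self, tiny_genomes):
        male, female, ann_m, ann_f, truth = tiny_genomes
        for m_gene, f_gene, _ks in truth.true_pairs:
            fm = ann_m.get(m_gene)
            ff = ann_f.get(f_gene)
            assert any(iv.contains(fm.interval)
                       for iv in truth.sdr_bed["male"])
            assert any(iv.contains(ff.interval)
                       for iv in truth.sdr_bed["female"])

    def test_identical_config_and_seed_byte_identical(self, tiny_sim_cfg):
        a = simulate.simulate_genome_pair(tiny_sim_cfg)
        b = simulate.simulate_genome_pair(tiny_sim_cfg)
        assert a[0].records == b[0].records
        assert a[1].records == b[1].records
        assert list(a[2]) == list(b[2])

    def test_sdr_outside_chromosome_rejected(self):
        with pytest.raises(ValueError, match="SDR interval"):
            SimulationConfig(uv_len=1000, sdr_start=800, sdr_len=500)


class TestReads:
    def _genome(self, seed=0, n=100_000):
        rng = np.random.default_rng(seed)
        from uvsdr.core_io import SequenceSet

        return SequenceSet({"c": "".join(rng.choice(list("ACGT"), size=n))})

    def test_total_bases_match_depth(self):
        genome = self._genome()
        reads, _ = simulate.simulate_reads(genome, 10.0, 100, 0.0, 1)
        assert abs(reads.total_bases() - 1_000_000) <= 100

    def test_zero_depth_zero_reads(self):
        reads, _ = simulate.simulate_reads(self._genome(), 0.0, 100, 0.0, 1)
        assert reads.n_reads == 0

    def test_same_seed_identical_fastq(self, tmp_path):
        genome = self._genome(n=5_000)
        a, _ = simulate.simulate_reads(genome, 2.0, 50, 0.01, 9)
        b, _ = simulate.simulate_reads(genome, 2.0, 50, 0.01, 9)
        pa, pb = tmp_path / "a.fastq", tmp_path / "b.fastq"
        a.to_fastq(pa)
        b.to_fastq(pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_error_rate_realized(self):
        genome = self._genome(n=20_000)
        clean, _ = simulate.simulate_reads(genome, 5.0, 100, 0.0, 3)
        noisy, _ = simulate.simulate_reads(genome, 5.0, 100, 0.01, 3)
        mismatch = (clean.codes != noisy.codes).mean()
        assert 0.005 < mismatch < 0.015

    def test_per_base_depth_truth_consistent(self):
        genome = self._genome(n=10_000)
        reads, truth = simulate.simulate_reads(genome, 8.0, 100, 0.0, 4)
        total = truth["c"].sum()
        assert total == reads.total_bases()

    def test_read_longer_than_sequence_rejected(self):
        with pytest.raises(ValueError, match="read_len"):
            simulate.simulate_reads(self._genome(n=50), 1.0, 100, 0.0, 1)


class TestPopulationGenotypes:
    def test_sexlinked_sites_fully_het_in_males(self):
        cfg = SimulationConfig(seed=2, n_sites=1200, n_sexlinked_sites=25)
        gt = simulate.simulate_population_genotypes(cfg)
        males = gt.sex_columns("male")
        females = gt.sex_columns("female")
        sex_scaffold = f"scaffold_{cfg.n_scaffolds}"
        mask = (gt.sites["chrom"] == sex_scaffold).to_numpy()
        linked = gt.genotypes[mask][:cfg.n_sexlinked_sites]
        assert (linked[:, males] == HET).all()
        assert (linked[:, females] == HOM_REF).all()

    def test_no_linkage_equal_heterozygosity_in_expectation(self):
        cfg = SimulationConfig(seed=8, n_sites=4000, n_sexlinked_sites=0)
        gt = simulate.simulate_population_genotypes(cfg)
        males = gt.sex_columns("male")
        females = gt.sex_columns("female")
        h_m = (gt.genotypes[:, males] == HET).mean()
        h_f = (gt.genotypes[:, females] == HET).mean()
        # both estimate the configured het within binomial error
        se = math.sqrt(cfg.autosomal_het * (1 - cfg.autosomal_het)
                       / (cfg.n_sites * cfg.n_individuals))
        assert abs(h_m - cfg.autosomal_het) < 5 * se
        assert abs(h_m - h_f) < 7 * se

    def test_same_seed_reproducible(self):
        cfg = SimulationConfig(seed=4, n_sites=600)
        a = simulate.simulate_population_genotypes(cfg)
        b = simulate.simulate_population_genotypes(cfg)
        assert (a.genotypes == b.genotypes).all()


class TestFamilyEvolution:
    def test_zero_loss_from_present_root_keeps_all_tips(self):
        tree = simulate.default_species_tree()
        # loss = 0 makes presence absorbing; stationary root = all present
        matrix, _ = simulate.simulate_family_evolution(
            tree, gain=2.0, loss=0.0, gamma_shape=1.0, n_families=100,
            seed=0)
        assert (matrix.to_numpy() == 1).all()

    def test_zero_gain_gives_all_absent(self):
        tree = simulate.default_species_tree()
        matrix, _ = simulate.simulate_family_evolution(
            tree, gain=0.0, loss=1.5, gamma_shape=1.0, n_families=100,
            seed=0)
        assert (matrix.to_numpy() == 0).all()

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError, match="stationary"):
            simulate.simulate_family_evolution(
                simulate.default_species_tree(), 0.0, 0.0, 1.0, 10, 0)

    def test_tip_presence_matches_transition_formula(self):
        """Across many families (no rate variation), tip presence frequency
        matches stationary-root chain marginals: P(present) = pi1 at every
        node."""
        tree = simulate.default_species_tree()
        g, l, n = 0.6, 1.2, 6000
        matrix, _ = simulate.simulate_family_evolution(
            tree, g, l, gamma_shape=None, n_families=n, seed=13,
            n_categories=1)
        pi1 = g / (g + l)
        se = math.sqrt(pi1 * (1 - pi1) / n)
        for tip in matrix.columns:
            assert abs(matrix[tip].mean() - pi1) < 4 * se

    def test_node_truth_consistent_with_tips(self):
        tree = simulate.default_species_tree()
        index = TreeIndex(tree)
        matrix, node_truth = simulate.simulate_family_evolution(
            index, 0.5, 1.0, 1.0, 50, seed=1)
        for f in range(50):
            for tip in matrix.columns:
                assert node_truth[(f"fam{f}", tip)] == matrix[tip].iloc[f]


class TestHomologyTable:
    def test_oldest_stratum_gene_has_qualifying_hit_there(self):
        hits, true_ages, ladder = simulate.simulate_homology_table(
            150, 5, seed=2)
        for gene, age in true_ages.items():
            if age == 1:
                sub = hits[(hits["gene"] == gene)
                           & (hits["evalue"] <= 1e-5)
                           & hits["taxon"].str.startswith("taxon_r1")]
                assert len(sub) >= 1

    def test_focal_age_gene_has_no_qualifying_external_hit(self):
        hits, true_ages, ladder = simulate.simulate_homology_table(
            150, 5, seed=2)
        focal = ladder.focal_taxa()
        for gene, age in true_ages.items():
            if age == ladder.n_strata:
                sub = hits[(hits["gene"] == gene)
                           & (hits["evalue"] <= 1e-5)
                           & ~hits["taxon"].isin(focal)]
                assert len(sub) == 0

    def test_proportions_respected(self):
        props = (0.7, 0.2, 0.1)
        _, true_ages, _ = simulate.simulate_homology_table(
            2000, 3, stratum_proportions=props, seed=3)
        counts = np.bincount(list(true_ages.values()), minlength=4)[1:]
        assert np.allclose(counts / 2000, props, atol=0.05)
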