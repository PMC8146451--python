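"""Tests for the introgression-bulk generator: parent construction, meiosis
and selection, bulk haplotype arithmetic, read sampling and F2 populations."""

import numpy as np
import pandas as pd
import pytest

from introbsa import synthetic_data as sd


class TestBuildParents:
    def test_variant_counts_follow_binomial(self):
        parents = sd.build_parents(9, [("chr1", 1_000_000)], 1e-3, seed=1)
        assert len(parents.recurrents) == 9
        mean, sd_ = 1_000_000 * 1e-3, np.sqrt(1_000_000 * 1e-3 * (1 - 1e-3))
        for p in parents.recurrents:
            assert abs(len(p.variants) - mean) < 4 * sd_

    def test_zero_rate_gives_reference_identical_parents(self):
        parents = sd.build_parents(3, [("chr1", 20_000)], 0.0, seed=2)
        for p in parents.recurrents:
            assert p.variants == []
        # the donor still carries its one designated causal mutation
        assert [v.label for v in parents.donor.variants] == ["causal"]

    def test_donor_variants_are_ems_transitions(self):
        parents = sd.build_parents(2, [("chr1", 50_000)], 1e-3, seed=3)
        for v in parents.donor.variants:
            assert (v.ref, v.alt) in {("G", "A"), ("C", "T")}

    def test_causal_matches_reference_base(self):
        parents = sd.build_parents(2, [("chr1", 50_000)], 1e-3, seed=4)
        c = parents.causal
        assert parents.reference[c.chrom][c.pos - 1] == c.ref

    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ValueError):
            sd.build_parents(2, [("chr1", 0)], 1e-3, seed=5)

    def test_out_of_range_snp_rate_rejected(self):
        with pytest.raises(ValueError):
            sd.build_parents(2, [("chr1", 10_000)], 0.5, seed=6)


class TestSimulateLineage:
    CHROMS = [("chr1", 100_000), ("chr2", 100_000)]

    def _parents(self, seed=0):
        return sd.build_parents(1, self.CHROMS, 0.0, seed=seed)

    def test_selection_forces_causal_homozygosity(self):
        p = self._parents()
        for seed in range(5):
            ln = sd.simulate_lineage(
                p.donor, p.recurrents[0], 2, 4, p.causal, seed=seed
            )
            assert ln.is_causal_homozygous()

    def test_causal_outside_genome_rejected(self):
        p = self._parents()
        bad = sd.VariantSite("chr1", 10_000_000, "G", "A")
        with pytest.raises(ValueError):
            sd.simulate_lineage(p.donor, p.recurrents[0], 1, 1, bad, seed=0)

    def test_unlinked_donor_fraction_after_three_backcrosses(self):
        # chr2 is unlinked to the selected causal site on chr1: the expected
        # donor fraction after BC3 is (1/2)^4 = 0.0625
        p = self._parents()
        rng = np.random.default_rng(7)
        fracs = [
            sd.simulate_lineage(
                p.donor, p.recurrents[0], 3, 2, p.causal, seed=rng
            ).donor_fraction("chr2")
            for _ in range(500)
        ]
        assert abs(np.mean(fracs) - 0.0625) < 0.01

    def test_unlinked_donor_fraction_without_backcrossing(self):
        # selfing an F1 without backcrossing keeps the Mendelian 1/2
        # expectation away from the selected locus
        p = self._parents()
        rng = np.random.default_rng(8)
        fracs = [
            sd.simulate_lineage(
                p.donor, p.recurrents[0], 0, 2, p.causal, seed=rng
            ).donor_fraction("chr2")
            for _ in range(300)
        ]
        assert abs(np.mean(fracs) - 0.5) < 0.05

    def test_donor_fraction_decays_with_distance_from_causal(self):
        # selection drags linked donor segments along; the retained donor
        # fraction must fall off with distance in expectation
        length = 200_000
        p = sd.build_parents(1, [("chr1", length)], 0.0, seed=9)
        causal_pos = p.causal.pos  # near the chromosome middle
        rng = np.random.default_rng(10)
        edges = np.array([0, 25_000, 50_000, 75_000, 100_000])
        distances = (edges[:-1] + edges[1:]) // 2
        probe = [
            causal_pos + d if causal_pos + d <= length else causal_pos - d
            for d in distances
        ]
        hits = np.zeros(len(probe))
        n_reps = 250
        for _ in range(n_reps):
            ln = sd.simulate_lineage(p.donor, p.recurrents[0], 2, 2,
                                     p.causal, seed=rng)
            for k, pos in enumerate(probe):
                o = ln.origin_at("chr1", int(pos))
                hits[k] += sum(o) / 2
        frac = hits / n_reps
        assert frac[0] > frac[-1]
        assert all(b <= a + 0.03 for a, b in zip(frac, frac[1:]))


class TestBulks:
    def _experiment(self):
        return sd.simulate_bulk_experiment(
            seed=11, chromosomes=(("chr1", 60_000), ("chr2", 60_000)),
            snp_rate=3e-4,
        )

    def test_causal_frequency_one_in_mutant_bulk(self):
        exp = self._experiment()
        c = exp.causal
        track = exp.mutant_track
        row = track[(track.chrom == c.chrom) & (track.pos == c.pos)]
        assert row.freq.tolist() == [1.0]

    def test_parent_private_snvs_at_one_ninth_in_normal_bulk(self):
        exp = self._experiment()
        nonzero = exp.normal_track.query("freq > 0")
        assert not nonzero.empty
        assert (np.isclose(nonzero.freq, 1 / 9)).mean() > 0.99

    def test_bulk_frequency_equals_haplotype_enumeration(self):
        # oracle: walk all 18 haplotypes per position and count carriers
        exp = self._experiment()
        genomes = {g.id: g for g in [exp.parents.donor, *exp.parents.recurrents]}
        track = exp.mutant_track
        check = track.sample(n=50, random_state=0)
        for row in check.itertuples(index=False):
            key = (row.chrom, row.pos, row.ref, row.alt)
            carriers = 0
            for ln in exp.lineages:
                for origin in ln.origin_at(row.chrom, row.pos):
                    parent_id = ln.donor_id if origin == sd.DONOR else ln.recurrent_id
                    if key in genomes[parent_id].carries():
                        carriers += 1
            assert carriers / 18 == row.freq

    def test_inconsistent_chromosome_sets_rejected(self):
        exp = self._experiment()
        genomes = {g.id: g for g in [exp.parents.donor, *exp.parents.recurrents]}
        catalog = sd.variant_catalog(genomes.values())
        broken = exp.lineages[0]
        hap0 = {"chrX": broken.haplotypes[0]["chr1"]}
        bad = sd.Lineage(
            "bad", broken.donor_id, broken.recurrent_id, 1, 1,
            (hap0, hap0), broken.causal,
        )
        with pytest.raises(ValueError, match="chromosome sets"):
            sd.assemble_bulk([exp.lineages[0], bad], genomes, catalog)

    def test_empty_bulk_rejected(self):
        with pytest.raises(ValueError):
            sd.assemble_bulk([], {}, pd.DataFrame())

    def test_mixed_allele_bulk_exact_fractions(self):
        counts, alleles = sd.mixed_allele_bulk(seed=12)
        assert len(alleles) == 3
        # distinct positions, exact lineage-fraction frequencies 5/9, 3/9, 1/9
        assert len({a.pos for a in alleles}) == 3


class TestSampleReadCounts:
    def _track(self, freqs):
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.arange(1, len(freqs) + 1) * 10,
                "ref": "G",
                "alt": "A",
                "freq": freqs,
            }
        )

    def test_fixed_allele_zero_error_gives_all_alt(self):
        t = self._track(np.ones(200))
        counts = sd.sample_read_counts({"b": t}, mean_depth=30, seed=1)
        assert (counts.df["b_ref"] == 0).all()
        assert (counts.df["b_alt"] == counts.depth("b")).all()

    def test_intermediate_frequency_mean(self):
        t = self._track(np.full(10_000, 0.5))
        counts = sd.sample_read_counts({"b": t}, mean_depth=50, seed=2)
        frac = counts.df["b_alt"] / counts.depth("b")
        se = frac.std() / np.sqrt(len(frac))
        assert abs(frac.mean() - 0.5) < 3 * se

    def test_same_seed_reproduces_table(self):
        t = self._track(np.linspace(0, 1, 100))
        a = sd.sample_read_counts({"b": t}, mean_depth=20, seed=3)
        b = sd.sample_read_counts({"b": t}, mean_depth=20, seed=3)
        assert a.df.equals(b.df)

    def test_invalid_parameters_rejected(self):
        t = self._track([0.5])
        with pytest.raises(ValueError):
            sd.sample_read_counts({"b": t}, mean_depth=0, seed=1)
        with pytest.raises(ValueError):
            sd.sample_read_counts({"b": t}, mean_depth=10, error_rate=0.5, seed=1)


class TestSimulateF2:
    def test_genotype_ratio_near_1_2_1(self):
        pop = sd.simulate_f2(285, seed=5)
        counts = pd.Series([x.genotype for x in pop]).value_counts()
        for geno, p in [("mut/mut", 0.25), ("WT/mut", 0.5), ("WT/WT", 0.25)]:
            sd_ = np.sqrt(285 * p * (1 - p))
            assert abs(counts.get(geno, 0) - 285 * p) < 4 * sd_

    def test_phenotype_is_recessive(self):
        pop = sd.simulate_f2(500, seed=6)
        for x in pop:
            assert (x.phenotype == "brown") == (x.genotype == "mut/mut")

    def test_reproducible_under_seed(self):
        a = sd.simulate_f2(4, seed=7)
        b = sd.simulate_f2(4, seed=7)
        assert [x.genotype for x in a] == [x.genotype for x in b]


class TestFixtureSet:
    def test_round_trips_and_format_invariants(self, tmp_path):
        from introbsa import io as iom

        paths = sd.write_fixture_set(tmp_path, seed=3)
        ref = iom.read_fasta(paths["reference"])
        assert {k: len(v) for k, v in ref.items()} == {"chr1": 100_000, "chr2": 100_000}

        genes = iom.read_gff3(paths["genes"])
        for g in genes:
            for s, e in g.cds:
                assert 1 <= s <= e <= len(ref[g.chrom])

        tsv = iom.read_counts_tsv(paths["counts_tsv"])
        vcf = iom.read_counts_vcf(paths["counts_vcf"])
        a = tsv.df.sort_values(["chrom", "pos"]).reset_index(drop=True)
        b = vcf.df[a.columns].sort_values(["chrom", "pos"]).reset_index(drop=True)
        assert a.equals(b)
        # VCF written position-sorted within chromosome
        with open(paths["counts_vcf"]) as fh:
            body = [l.split("\t") for l in fh if not l.startswith("#")]
        for prev, cur in zip(body, body[1:]):
            if prev[0] == cur[0]:
                assert int(prev[1]) <= int(cur[1])

        panel = iom.read_panel_vcf(paths["panel"])
        assert len(panel) == 5
        f2 = iom.read_f2_tsv(paths["f2"])
        assert len(f2) == 60
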