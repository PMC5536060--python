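"""Unit and property tests for the F2 cross simulator."""

import numpy as np
import pytest
from scipy import stats

import bulkseg as bs
from bulkseg.cross import simulate_gametes, single_branch_mask, highly_branched_mask

import oracles


@pytest.fixture(scope="module")
def two_marker_genome():
    return bs.GenomeModel(
        chromosomes=[("c1", 20_000_000)],
        recombination_rate=2.0,
        snp_positions={"c1": np.array([5_000_000, 15_000_000])},
    )


class TestGenome:
    def test_tomato_defaults(self):
        g = bs.GenomeModel.tomato(seed=3)
        assert g.n_snps == 15_640
        assert len(g.chromosomes) == 12
        fa = g.locus("FA")
        assert fa.chrom == "chr03"
        # planted loci are themselves markers
        assert fa.pos in g.snp_positions["chr03"]
        assert g.locus("S").pos in g.snp_positions["chr02"]

    def test_positions_strictly_increasing_within_bounds(self):
        g = bs.GenomeModel.tomato(n_snps=2_000, seed=5)
        for name, length in g.chromosomes:
            pos = g.snp_positions[name]
            assert np.all(np.diff(pos) > 0)
            assert pos[0] >= 1 and pos[-1] <= length

    def test_invalid_genomes_rejected(self):
        with pytest.raises(ValueError):
            bs.GenomeModel(chromosomes=[("c1", 0)])
        with pytest.raises(ValueError):
            bs.GenomeModel(
                chromosomes=[("c1", 100)],
                snp_positions={"c1": np.array([5, 5, 9])},
            )
        with pytest.raises(ValueError):
            bs.GenomeModel(
                chromosomes=[("c1", 100)],
                snp_positions={"c1": np.array([50, 200])},
            )


class TestGametes:
    def test_no_recombination_gives_intact_haplotypes(self):
        g = bs.GenomeModel(
            chromosomes=[("c1", 1_000_000)],
            recombination_rate=0.0,
            snp_positions={"c1": np.array([1, 250_000, 999_999])},
        )
        gam = simulate_gametes(g, 500, np.random.default_rng(0))["c1"]
        assert np.all(gam.min(axis=1) == gam.max(axis=1))

    def test_haldane_recombination_fraction(self, two_marker_genome):
        # 10 Mb apart at 2 cM/Mb: r = (1 - exp(-2 * 0.1)) / 2
        gam = simulate_gametes(two_marker_genome, 200_000, np.random.default_rng(1))["c1"]
        r_obs = float((gam[:, 0] != gam[:, 1]).mean())
        r_exp = (1 - np.exp(-0.4)) / 2
        se = np.sqrt(r_exp * (1 - r_exp) / 200_000)
        assert abs(r_obs - r_exp) < 3 * se

    def test_dosage_autocorrelation_decays_with_distance(self):
        pos = np.arange(1, 9) * 7_000_000
        g = bs.GenomeModel(
            chromosomes=[("c1", 60_000_000)],
            recombination_rate=2.0,
            snp_positions={"c1": pos},
        )
        gam = simulate_gametes(g, 30_000, np.random.default_rng(3))["c1"].astype(float)
        corrs = [np.corrcoef(gam[:, 0], gam[:, j])[0, 1] for j in range(1, 8)]
        rho = stats.spearmanr(np.arange(1, 8), corrs).statistic
        assert rho < -0.95  # monotone decay with map distance


class TestSimulateF2:
    def test_mendelian_dosage_mean(self, mini_genome):
        pop = bs.simulate_f2(mini_genome, 10_000, seed=4)
        means = pop.dosage.mean(axis=0)
        se = np.sqrt(0.5 / 10_000)  # var(dosage) = 1/2
        assert np.all(np.abs(means - 1.0) < 4 * se + 0.02)
        # genome-wide pooled allele frequency approaches 1/2
        assert abs(pop.dosage.mean() / 2 - 0.5) < 0.01

    def test_single_marker_one_two_one(self, mini_genome):
        pop = bs.simulate_f2(mini_genome, 10_000, seed=5)
        d = pop.causal_dosage("FA")
        counts = np.bincount(d, minlength=3)
        res = bs.chi_square_gof(counts, (1, 2, 1))
        assert res.p_value > 1e-4

    def test_rejects_bad_input(self, mini_genome):
        with pytest.raises(ValueError):
            bs.simulate_f2(mini_genome, 0)
        empty = bs.GenomeModel(chromosomes=[("c1", 100)])
        with pytest.raises(ValueError):
            bs.simulate_f2(empty, 5)

    def test_seed_reproducibility(self, mini_genome):
        a = bs.simulate_f2(mini_genome, 50, seed=42)
        b = bs.simulate_f2(mini_genome, 50, seed=42)
        assert np.array_equal(a.dosage, b.dosage)


class TestPhenotypes:
    def test_noiseless_limits(self, mini_genome):
        pop = bs.simulate_f2(mini_genome, 400, seed=6)
        model = bs.PhenotypeModel(
            class_means={"F_S_": 0.0, "F_ss": 1.2, "ffS_": 2.0, "ffss": 5.0},
            class_sd=0.0,
        )
        bs.assign_phenotypes(pop, model, seed=7)
        classes = pop.genotype_classes()
        assert np.all(pop.bn[classes == "ffss"] == 32)  # 2**5
        assert np.all(pop.bn[classes == "F_S_"] == 1)
        assert np.all(pop.bn_median == np.median(pop.bn, axis=1))

    def test_highly_branched_fraction_matches_exact_oracle(self, mini_genome):
        # frozen via exact integration of the phenotype model: the
        # highly-branched probability is 0.0625 (the 15:1 class share)
        means = {"F_S_": 0.3, "F_ss": 1.2, "ffS_": 2.0, "ffss": 5.0}
        p_exact = oracles.exact_p_highly_branched(means, 0.7)
        assert abs(p_exact - 1 / 16) < 2e-4
        pop = bs.simulate_f2(mini_genome, 8000, seed=8)
        bs.assign_phenotypes(pop, bs.PhenotypeModel(class_means=means), seed=9)
        p_obs = float((pop.bn_median > 16).mean())
        se = np.sqrt(p_exact * (1 - p_exact) / 8000)
        assert abs(p_obs - p_exact) < 4 * se

    def test_requires_causal_genotypes(self):
        g = bs.GenomeModel(
            chromosomes=[("c9", 1_000_000)],
            snp_positions={"c9": np.array([10, 20])},
        )
        pop = bs.simulate_f2(g, 5, seed=1)
        with pytest.raises(KeyError):
            bs.assign_phenotypes(pop, seed=2)

    def test_bn_are_integers_at_least_one(self, phenotyped_population):
        assert phenotyped_population.bn.dtype.kind == "i"
        assert phenotyped_population.bn.min() >= 1


class TestBulks:
    def test_noiseless_hb_equals_ffss(self, mini_genome):
        pop = bs.simulate_f2(mini_genome, 600, seed=10)
        model = bs.PhenotypeModel(class_sd=0.0)
        bs.assign_phenotypes(pop, model, seed=11)
        hb = set(np.flatnonzero(highly_branched_mask(pop)))
        ffss = set(np.flatnonzero(pop.genotype_classes() == "ffss"))
        assert hb == ffss

    def test_requested_sizes_returned_disjoint(self, phenotyped_population):
        sb, hb = bs.select_bulks(phenotyped_population, 60, 11, seed=13)
        assert len(sb) == 60 and len(hb) == 11
        assert not set(sb) & set(hb)
        assert np.all(phenotyped_population.bn_median[sb] == 1)
        assert np.all(phenotyped_population.bn_median[hb] > 16)

    def test_shortfall_reports_deficit(self, mini_genome):
        pop = bs.simulate_f2(mini_genome, 30, seed=14)
        bs.assign_phenotypes(pop, seed=15)
        n_hb = int(highly_branched_mask(pop).sum())
        with pytest.raises(bs.BulkSelectionError, match=str(n_hb)):
            bs.select_bulks(pop, 1, n_hb + 1, seed=16)

    def test_single_branch_rule(self, phenotyped_population):
        sel = single_branch_mask(phenotyped_population)
        assert np.all(phenotyped_population.pct_single[sel] >= 0.7)


class TestBulkReads:
    def test_error_free_fixed_bulks(self, mini_genome):
        pop = bs.simulate_f2(mini_genome, 200, seed=17)
        bs.assign_phenotypes(pop, seed=18)
        cfg = bs.ReadSimConfig(error_rate=0.0)
        # force dosage to the two pure states
        pop.dosage[:50] = 0
        pop.dosage[50:100] = 2
        counts = bs.simulate_bulk_reads(pop, np.arange(50), np.arange(50, 100), cfg, seed=19)
        assert (counts["sb_alt"] == 0).all()  # bulk of dosage 0: no alt reads
        assert (counts["hb_ref"] == 0).all()  # bulk of dosage 2: no ref reads

    def test_het_bulk_mean_index_half(self, mini_genome):
        pop = bs.simulate_f2(mini_genome, 100, seed=20)
        pop.dosage[:] = 1  # f = 0.5 everywhere
        bs.assign_phenotypes(pop, seed=21)
        counts = bs.simulate_bulk_reads(
            pop, np.arange(50), np.arange(50, 100), bs.ReadSimConfig(), seed=22
        )
        idx = bs.compute_snp_indices(counts)
        mean_idx = idx["sb_index"].mean()
        n = idx["sb_index"].notna().sum()
        se = np.sqrt(0.25 / 12 / n) * 1.2  # binomial at poisson depth ~12
        assert abs(mean_idx - 0.5) < 4 * se

    def test_depth_is_ref_plus_alt(self, mini_genome):
        pop = bs.simulate_f2(mini_genome, 80, seed=23)
        bs.assign_phenotypes(pop, seed=24)
        cfg = bs.ReadSimConfig(depth_model="fixed")
        counts = bs.simulate_bulk_reads(pop, np.arange(40), np.arange(40, 80), cfg, seed=25)
        assert ((counts["sb_ref"] + counts["sb_alt"]) == 12).all()
        assert counts[["sb_ref", "sb_alt", "hb_ref", "hb_alt"]].min().min() >= 0

    def test_empty_bulk_rejected(self, phenotyped_population):
        with pytest.raises(ValueError):
            bs.simulate_bulk_reads(phenotyped_population, [], [1], seed=1)


class TestStudy:
    def test_study_reproducible_and_feasible(self, mini_genome):
        a = bs.simulate_study(genome=mini_genome, seed=30)
        b = bs.simulate_study(genome=mini_genome, seed=30)
        assert a.counts.equals(b.counts)
        assert np.array_equal(a.sb_ids, b.sb_ids)
        assert len(a.sb_ids) == 60 and len(a.hb_ids) == 11

    def test_hb_bulk_fixed_at_fa_locus(self, mini_genome):
        # HB plants are (almost surely) ffss: no PI-type allele at FA
        study = bs.simulate_study(genome=mini_genome, seed=31)
        d = study.population.causal_dosage("FA")[study.hb_ids]
        assert d.max() == 0
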