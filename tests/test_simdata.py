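"""Unit and property tests for the population simulator."""

import numpy as np
import pytest

from herdimpute import (GenomeMap, MISSING, Pedigree, PedigreeRecord,
                        SnpPanel, TraitSpec, apply_genotyping, gene_drop,
                        simulate_founder_haplotypes, simulate_pedigree,
                        simulate_phenotypes)
from conftest import make_population


class TestGenomeMap:
    def test_uniform_map_is_one_cm_per_mb(self):
        gmap = GenomeMap.uniform(2, 10, spacing_bp=100_000)
        assert gmap.n_markers == 20
        np.testing.assert_allclose(gmap.cm, gmap.bp / 1e6)

    def test_rejects_unsorted_positions(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            GenomeMap(np.array(["1", "1"]), np.array(["a", "b"]),
                      np.array([200, 100]), np.array([0.2, 0.1]))

    def test_rejects_duplicate_ids(self):
        with pytest.raises(ValueError, match="unique"):
            GenomeMap(np.array(["1", "1"]), np.array(["a", "a"]),
                      np.array([100, 200]), np.array([0.1, 0.2]))


class TestSimulatePedigree:
    def test_single_generation_is_all_founders(self):
        ped = simulate_pedigree(10, 1, seed=3)
        assert len(ped) == 10
        assert ped.is_founder.all()

    def test_fixed_seed_reproduces_pedigree(self):
        a = simulate_pedigree(12, 3, {"sires_per_generation": 2}, seed=7)
        b = simulate_pedigree(12, 3, {"sires_per_generation": 2}, seed=7)
        assert [r.__dict__ for r in a] == [r.__dict__ for r in b]

    def test_sires_limited_to_designated_males_per_generation(self):
        ped = simulate_pedigree(10, 3, {"sires_per_generation": 2}, seed=5)
        by_year = ped.birth_year
        for year in np.unique(by_year)[1:]:
            cohort = np.flatnonzero(by_year == year)
            sires = {ped.records[i].sire_id for i in cohort}
            assert len(sires) <= 2
            # all sires come from the immediately previous generation
            for s in sires:
                assert ped.records[ped.index[s]].birth_year == year - 1

    def test_topological_order_and_parent_sexes(self):
        ped = simulate_pedigree(20, 4, seed=1)
        for i, r in enumerate(ped):
            if ped.sire_idx[i] >= 0:
                assert ped.sire_idx[i] < i
                assert ped.records[ped.sire_idx[i]].sex == "M"
            if ped.dam_idx[i] >= 0:
                assert ped.records[ped.dam_idx[i]].sex == "F"

    def test_birth_year_increases_by_generation(self):
        ped = simulate_pedigree(10, 3, seed=0)
        for i in range(len(ped)):
            s = ped.sire_idx[i]
            if s >= 0:
                assert ped.records[i].birth_year == \
                    ped.records[s].birth_year + 1

    @pytest.mark.parametrize("nf,ng", [(1, 2), (5, 0)])
    def test_invalid_counts_rejected(self, nf, ng):
        with pytest.raises(ValueError):
            simulate_pedigree(nf, ng)

    def test_pedigree_rejects_wrong_parent_sex(self):
        recs = [PedigreeRecord("a", "0", "0", "F", 2000),
                PedigreeRecord("b", "a", "0", "M", 2001)]
        with pytest.raises(ValueError, match="sex"):
            Pedigree(recs)


class TestFounderHaplotypes:
    def test_zero_switch_rate_copies_pool_haplotypes_exactly(self):
        gmap = GenomeMap.uniform(1, 50)
        pool, founders = simulate_founder_haplotypes(
            gmap, None, n_ancestral=5, mosaic_switch_rate=0.0,
            n_founders=20, seed=2)
        flat = founders.reshape(-1, gmap.n_markers)
        for h in flat:
            assert any((h == p).all() for p in pool.haplotypes)

    def test_realized_maf_near_fixed_spectrum(self):
        gmap = GenomeMap.uniform(1, 200)
        _, founders = simulate_founder_haplotypes(
            gmap, {"dist": "fixed", "value": 0.5}, n_ancestral=40,
            mosaic_switch_rate=1.0, n_founders=1000, seed=4)
        freq = founders.reshape(-1, gmap.n_markers).mean(axis=0)
        # binomial bound across pool draw + mosaic sampling
        assert abs(freq.mean() - 0.5) < 0.02

    def test_ld_decays_with_genetic_distance(self):
        gmap = GenomeMap.uniform(1, 200, spacing_bp=100_000)  # 0.1 cM apart
        _, founders = simulate_founder_haplotypes(
            gmap, None, n_ancestral=20, mosaic_switch_rate=1.0,
            n_founders=1000, seed=9)
        h = founders.reshape(-1, gmap.n_markers).astype(float)

        def mean_r2(lag):
            r2 = []
            for j in range(0, gmap.n_markers - lag, 7):
                a, b = h[:, j], h[:, j + lag]
                if a.std() == 0 or b.std() == 0:
                    continue
                r2.append(np.corrcoef(a, b)[0, 1] ** 2)
            return np.mean(r2)

        assert mean_r2(1) > mean_r2(50)  # 0.1 cM vs 5 cM apart

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            GenomeMap(np.array([]), np.array([]), np.array([]), np.array([]))


class TestGeneDrop:
    def test_zero_length_chromosome_transmits_intact_haplotype(self):
        gmap = GenomeMap(np.array(["1"] * 5), np.array(list("abcde")),
                         np.arange(1, 6), np.zeros(5))
        ped = simulate_pedigree(4, 2, {"sires_per_generation": 1}, seed=0)
        nf = int(ped.is_founder.sum())
        rng = np.random.default_rng(0)
        founders = rng.integers(0, 2, size=(nf, 2, 5)).astype(np.uint8)
        pop = gene_drop(ped, founders, gmap, seed=1)
        for i in np.flatnonzero(~ped.is_founder):
            for hap, parent in ((0, ped.sire_idx[i]), (1, ped.dam_idx[i])):
                h = pop.haplotypes[i, hap]
                assert (h == pop.haplotypes[parent, 0]).all() or \
                    (h == pop.haplotypes[parent, 1]).all()

    def test_mean_crossover_count_matches_map_length(self):
        # 100 cM chromosome: crossovers per meiosis ~ Poisson(1)
        gmap = GenomeMap(np.array(["1"] * 2), np.array(["a", "b"]),
                         np.array([1, 100_000_001]), np.array([0.0, 100.0]))
        ped_recs = [PedigreeRecord("s", "0", "0", "M", 2000),
                    PedigreeRecord("d", "0", "0", "F", 2000)]
        ped_recs += [PedigreeRecord(f"o{i}", "s", "d", "M", 2001)
                     for i in range(5000)]
        ped = Pedigree(ped_recs)
        founders = np.zeros((2, 2, 2), dtype=np.uint8)
        pop = gene_drop(ped, founders, gmap, seed=3, record_crossovers=True)
        counts = [n for (_, _, _, n) in pop.crossover_log]
        n_meioses = len(counts)
        assert n_meioses == 10_000
        se = np.sqrt(1.0 / n_meioses)  # Poisson(1) variance = 1
        assert abs(np.mean(counts) - 1.0) < 3 * se

    def test_offspring_haplotype_is_legal_parental_mosaic(self):
        pop = make_population(n_founders=10, n_generations=2,
                              markers_per_chrom=50, seed=21)
        ped = pop.pedigree
        for i in np.flatnonzero(~ped.is_founder):
            for hap, parent in ((0, ped.sire_idx[i]), (1, ped.dam_idx[i])):
                h = pop.haplotypes[i, hap]
                p = pop.haplotypes[parent]
                # every allele matches at least one parental haplotype
                assert ((h == p[0]) | (h == p[1])).all()

    def test_mendelian_consistency_all_trios(self, small_population):
        pop = small_population
        g = pop.genotypes
        ped = pop.pedigree
        for i in np.flatnonzero(~ped.is_founder):
            s, d = ped.sire_idx[i], ped.dam_idx[i]
            lo = (g[s] == 2).astype(int) + (g[d] == 2).astype(int)
            hi = 2 - (g[s] == 0).astype(int) - (g[d] == 0).astype(int)
            assert ((g[i] >= lo) & (g[i] <= hi)).all()

    def test_missing_founder_haplotypes_rejected(self):
        ped = simulate_pedigree(10, 1, seed=0)
        gmap = GenomeMap.uniform(1, 10)
        with pytest.raises(ValueError, match="founders"):
            gene_drop(ped, np.zeros((3, 2, 10), dtype=np.uint8), gmap)


class TestPhenotypes:
    def test_tiny_heritability_gives_negligible_tbv(self, small_population):
        trait = TraitSpec("t", 1e-6, 20)
        phen = simulate_phenotypes(small_population, trait, seed=0)
        assert phen.tbv.var() < 1e-5
        # DTD is then (tiny) pure noise: identical to its residual part
        np.testing.assert_allclose(phen.dtd, phen.tbv + phen.residual)

    def test_high_reliability_makes_dtd_track_tbv(self):
        pop = make_population(n_founders=100, n_generations=4,
                              markers_per_chrom=80, seed=31)
        trait = TraitSpec("t", 0.5, 40)
        phen = simulate_phenotypes(pop, trait,
                                   reliability_range=(0.989, 0.99), seed=1)
        assert np.corrcoef(phen.tbv, phen.dtd)[0, 1] > 0.99

    def test_fixed_seed_reproduces_phenotypes(self, small_population):
        trait = TraitSpec("t", 0.25, 30)
        a = simulate_phenotypes(small_population, trait, seed=5)
        b = simulate_phenotypes(small_population, trait, seed=5)
        np.testing.assert_array_equal(a.dtd, b.dtd)
        np.testing.assert_array_equal(a.reliability, b.reliability)

    def test_dtd_regression_on_tbv_has_unit_slope(self):
        pop = make_population(n_founders=200, n_generations=5,
                              markers_per_chrom=80, seed=41)
        trait = TraitSpec("t", 0.4, 50)
        phen = simulate_phenotypes(pop, trait, seed=2)
        slope = np.cov(phen.dtd, phen.tbv)[0, 1] / phen.tbv.var()
        n = len(phen.dtd)
        # residuals independent of TBV -> slope 1 within Monte-Carlo error
        se = phen.residual.std() / (phen.tbv.std() * np.sqrt(n))
        assert abs(slope - 1.0) < 4 * se

    def test_invalid_heritability_rejected(self):
        with pytest.raises(ValueError, match="heritability"):
            TraitSpec("t", 1.5, 10)

    def test_reliabilities_clamped_inside_unit_interval(self, small_population):
        phen = simulate_phenotypes(small_population, TraitSpec("t", 0.25, 10),
                                   reliability_range=(0.0, 1.0), seed=3)
        assert (phen.reliability >= 0.01).all()
        assert (phen.reliability <= 0.99).all()


class TestApplyGenotyping:
    def test_clean_assay_equals_truth(self, small_population):
        pop = small_population
        panel = np.arange(pop.gmap.n_markers)
        g = apply_genotyping(pop, panel, 0.0, 0.0, seed=0)
        np.testing.assert_array_equal(g, pop.genotypes)

    def test_missing_fraction_matches_rate(self, small_population):
        g = apply_genotyping(small_population,
                             np.arange(small_population.gmap.n_markers),
                             missing_rate=0.5, seed=1)
        frac = (g == MISSING).mean()
        n = g.size
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_full_error_rate_never_matches_truth(self, small_population):
        pop = small_population
        panel = np.arange(pop.gmap.n_markers)
        g = apply_genotyping(pop, panel, 0.0, 1.0, seed=2)
        assert (g != pop.genotypes).all()

    def test_invalid_rate_rejected(self, small_population):
        with pytest.raises(ValueError, match="missing_rate"):
            apply_genotyping(small_population, np.arange(3), -0.1, 0.0)

    def test_panel_subset_selects_columns(self, small_population):
        pop = small_population
        panel = SnpPanel.from_indices(pop.gmap, "p", np.array([0, 5, 9]))
        g = apply_genotyping(pop, panel, 0.0, 0.0, seed=0)
        np.testing.assert_array_equal(g, pop.genotypes[:, [0, 5, 9]])
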