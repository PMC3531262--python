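"""Tests for the diploid haplotype-copying imputer."""

import numpy as np
import pytest

from herdimpute import (HaplotypeCopyingImputer, HmmConfig, MISSING,
                        ReferencePanel, best_guess, dosage, emission_matrix,
                        impute_diploid, impute_tiered, sampling_baseline,
                        transition_rates)
from herdimpute._kernels import diploid_forward_backward
from conftest import brute_force_posteriors, make_population


class TestTransitionRates:
    def test_zero_distance_gives_floor(self):
        rho = transition_rates(np.array([0.0]), K=10, ne=100)
        assert rho[0] == pytest.approx(1e-8)

    def test_infinite_distance_gives_one(self):
        rho = transition_rates(np.array([np.inf]), K=10, ne=100)
        assert rho[0] == 1.0

    def test_closed_form_value(self):
        # Ne=100, K=100, c=0.01 M: rho = 1 - exp(-0.04)
        rho = transition_rates(np.array([0.01]), K=100, ne=100)
        assert rho[0] == pytest.approx(1.0 - np.exp(-0.04), abs=1e-12)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            transition_rates(np.array([-0.1]), K=5)

    def test_small_k_rejected(self):
        with pytest.raises(ValueError, match="K"):
            transition_rates(np.array([0.1]), K=1)


class TestEmissionChannel:
    def test_rows_are_distributions(self):
        e = emission_matrix(0.02)
        np.testing.assert_allclose(e.sum(axis=1), 1.0)

    def test_zero_error_is_identity(self):
        np.testing.assert_allclose(emission_matrix(0.0), np.eye(3))


class TestBestGuessAndDosage:
    @pytest.mark.parametrize("triple,expected", [
        ((0.1, 0.2, 0.7), 2),
        ((0.5, 0.5, 0.0), 0),     # tie -> lower B-allele count
        ((0.0, 1.0, 0.0), 1),
    ])
    def test_best_guess(self, triple, expected):
        assert best_guess(np.array(triple)) == expected

    @pytest.mark.parametrize("triple,expected", [
        ((0.4, 0.2, 0.4), 1.0),
        ((0.0, 0.0, 1.0), 2.0),
        ((1 / 3, 1 / 3, 1 / 3), 1.0),
    ])
    def test_dosage_formula(self, triple, expected):
        assert dosage(np.array(triple)) == pytest.approx(expected)

    def test_unnormalised_triple_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            best_guess(np.array([0.5, 0.5, 0.5]))
        with pytest.raises(ValueError, match="sum to 1"):
            dosage(np.array([0.2, 0.2, 0.2]))


class TestDiploidHmm:
    def test_worked_three_marker_instance_matches_enumeration(self):
        # h1=000, h2=111; typed het at markers 1 and 3, marker 2 masked
        H = np.array([[0, 0, 0], [1, 1, 1]], dtype=np.uint8)
        gt = np.array([1, MISSING, 1], dtype=np.int8)
        rho = transition_rates(np.array([0.01, 0.01]), K=2, ne=100)
        emis = emission_matrix(0.01)
        fstore = np.empty((3, 2, 2))
        gp, _ = diploid_forward_backward(gt, H, rho, emis, fstore)
        expected = brute_force_posteriors(gt, H, rho, emis)
        np.testing.assert_allclose(gp, expected, atol=1e-10)
        # the two flanking hets make the het posterior dominate in between
        assert gp[1, 1] > 0.5

    def test_posteriors_normalised_everywhere(self):
        pop = make_population(n_founders=20, n_generations=2,
                              markers_per_chrom=40, seed=3)
        ref = pop.haplotypes[:10].reshape(20, -1)
        test = pop.genotypes[10:14].astype(np.int8)
        test[:, ::3] = MISSING
        res = impute_diploid(test, ref, HmmConfig(),
                             genetic_pos_cm=pop.gmap.cm,
                             chrom=pop.gmap.chrom)
        np.testing.assert_allclose(res.posteriors.sum(axis=-1), 1.0,
                                   atol=1e-8)
        np.testing.assert_array_equal(res.best_guess,
                                      np.argmax(res.posteriors, axis=-1))
        np.testing.assert_allclose(
            res.dosage,
            res.posteriors[..., 1] + 2 * res.posteriors[..., 2])

    def test_perfect_template_copying_recovers_truth(self):
        rng = np.random.default_rng(5)
        L = 120
        H = rng.integers(0, 2, size=(8, L)).astype(np.uint8)
        # test animal's haplotypes are exact reference copies
        truth = H[2] + H[5]
        gt = truth.astype(np.int8).copy()
        gt[::4] = MISSING  # dense typed scaffold, 25% masked
        imp = HaplotypeCopyingImputer(error_rate=0.001, spacing_cm=0.05)
        imp.fit(H)
        bg = imp.predict(gt)[0]
        np.testing.assert_array_equal(bg, truth)

    def test_unfitted_predict_rejected(self):
        with pytest.raises(ValueError, match="not fitted"):
            HaplotypeCopyingImputer().predict(np.zeros(5, dtype=np.int8))

    def test_marker_mismatch_rejected(self):
        imp = HaplotypeCopyingImputer().fit(
            np.zeros((2, 10), dtype=np.uint8))
        with pytest.raises(ValueError, match="markers"):
            imp.predict(np.zeros(7, dtype=np.int8))

    def test_reference_with_single_haplotype_rejected(self):
        with pytest.raises(ValueError, match="K>=2"):
            HaplotypeCopyingImputer().fit(np.zeros((1, 5), dtype=np.uint8))
        with pytest.raises(ValueError, match="K=2"):
            ReferencePanel(np.zeros((1, 5), dtype=np.uint8),
                           np.array(list("abcde")))

    def test_oracle_equivalence_on_random_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            K = int(rng.integers(2, 4))
            L = int(rng.integers(2, 5))
            H = rng.integers(0, 2, size=(K, L)).astype(np.uint8)
            gt = rng.integers(-1, 3, size=L).astype(np.int8)
            rho = transition_rates(rng.uniform(0, 0.05, size=L - 1), K)
            emis = emission_matrix(rng.uniform(0, 0.05))
            fstore = np.empty((L, K, K))
            gp, _ = diploid_forward_backward(gt, H, rho, emis, fstore)
            np.testing.assert_allclose(
                gp, brute_force_posteriors(gt, H, rho, emis), atol=1e-10)

    def test_long_chromosome_has_no_underflow(self):
        rng = np.random.default_rng(23)
        L, K = 10_000, 24
        H = rng.integers(0, 2, size=(K, L)).astype(np.uint8)
        gt = (H[0] + H[1]).astype(np.int8)
        gt[rng.random(L) < 0.3] = MISSING
        imp = HaplotypeCopyingImputer(spacing_cm=0.01).fit(H)
        p = imp.predict_proba(gt)
        assert np.isfinite(p).all()
        np.testing.assert_allclose(p.sum(axis=-1), 1.0, atol=1e-8)

    def test_reference_cap_subsamples_by_allele_sharing(self):
        rng = np.random.default_rng(29)
        L = 60
        H = rng.integers(0, 2, size=(30, L)).astype(np.uint8)
        gt = (H[3] + H[4]).astype(np.int8)
        imp = HaplotypeCopyingImputer(max_reference_haplotypes=8).fit(H)
        sub = imp._select_reference(gt)
        assert sub.shape == (8, L)
        # the two template haplotypes score highest and must be retained
        assert any((sub == H[3]).all(axis=1))
        assert any((sub == H[4]).all(axis=1))


class TestTiered:
    def _setup(self, seed):
        pop = make_population(n_founders=60, n_generations=3,
                              markers_per_chrom=80, seed=seed)
        n = pop.n_animals
        L = pop.gmap.n_markers
        rng = np.random.default_rng(seed + 100)
        perm = rng.permutation(n)
        top, mid, test = perm[:8], perm[8:58], perm[58:78]
        top_h = pop.haplotypes[top].reshape(-1, L)
        med_cols = np.zeros(L, dtype=bool)
        med_cols[::3] = True
        low_cols = np.zeros(L, dtype=bool)
        low_cols[::12] = True
        mid_g = pop.genotypes[mid].astype(np.int8)
        mid_g[:, ~med_cols] = MISSING
        test_g = pop.genotypes[test].astype(np.int8)
        test_g[:, ~low_cols] = MISSING
        truth = pop.genotypes[test]
        masked = ~low_cols
        return pop, top_h, mid_g, test_g, truth, masked

    def test_empty_mid_tier_equals_two_tier(self):
        pop, top_h, _, test_g, _, _ = self._setup(1)
        cfg = HmmConfig()
        kw = dict(genetic_pos_cm=pop.gmap.cm, chrom=pop.gmap.chrom)
        two = impute_diploid(test_g, top_h, cfg, **kw)
        three = impute_tiered(test_g, np.empty((0, test_g.shape[1])), top_h,
                              cfg, **kw)
        np.testing.assert_allclose(two.posteriors, three.posteriors)

    def test_nesting_violation_rejected(self):
        pop, top_h, mid_g, test_g, _, _ = self._setup(2)
        bad_mid = mid_g.copy()
        bad_mid[:, :] = MISSING
        bad_mid[:, 1] = 1  # mid typed set no longer contains the low panel
        with pytest.raises(ValueError, match="nesting"):
            impute_tiered(test_g, bad_mid, top_h,
                          genetic_pos_cm=pop.gmap.cm, chrom=pop.gmap.chrom)

    def test_middle_tier_reduces_error_with_small_top_reference(self):
        from herdimpute import allelic_error_rate
        gaps = []
        for seed in range(5):
            pop, top_h, mid_g, test_g, truth, masked = self._setup(seed)
            cfg = HmmConfig(max_reference_haplotypes=150)
            kw = dict(genetic_pos_cm=pop.gmap.cm, chrom=pop.gmap.chrom)
            two = impute_diploid(test_g, top_h, cfg, **kw)
            three = impute_tiered(test_g, mid_g, top_h, cfg, **kw)
            e2 = allelic_error_rate(truth[:, masked],
                                    two.best_guess[:, masked])
            e3 = allelic_error_rate(truth[:, masked],
                                    three.best_guess[:, masked])
            gaps.append(e2 - e3)
        assert np.mean(gaps) > 0


class TestSamplingBaseline:
    def test_extreme_frequencies_are_deterministic(self):
        masked = np.ones((5, 4), dtype=bool)
        g0 = sampling_baseline(masked, np.zeros(4), seed=0)
        np.testing.assert_array_equal(g0, 0)
        g1 = sampling_baseline(masked, np.ones(4), seed=0)
        np.testing.assert_array_equal(g1, 2)

    def test_unmasked_entries_stay_missing(self):
        masked = np.zeros((3, 3), dtype=bool)
        masked[0, 0] = True
        g = sampling_baseline(masked, np.full(3, 0.5), seed=1)
        assert (g[~masked] == MISSING).all()

    def test_invalid_frequency_rejected(self):
        with pytest.raises(ValueError, match="frequencies"):
            sampling_baseline(np.ones((2, 2), dtype=bool),
                              np.array([0.5, 1.5]))

    def test_seed_determinism(self):
        masked = np.ones((10, 10), dtype=bool)
        p = np.full(10, 0.3)
        np.testing.assert_array_equal(sampling_baseline(masked, p, 7),
                                      sampling_baseline(masked, p, 7))
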