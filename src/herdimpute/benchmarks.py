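"""Canned benchmark designs for qualitative-reproduction studies.

These functions wire the simulator, panel builder, imputer, evaluator and
predictor into the standard study designs: the typed-density x
reference-size sweep, the 2-tier vs 3-tier comparison, the genomic
prediction comparison (true vs imputed vs low-density genotypes), and the
kinship-stratified error analysis. Problem sizes default to a desk scale
chosen so each sweep completes in minutes on one core while preserving the
qualitative structure of chip-scale data (panel density ratios, half-sib
family structure, LD decay); docs/methods.md discusses what this scale
does and does not show.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluation import (DEFAULT_KINSHIP_BINS, error_report, mask_genotypes,
                         pedigree_kinship, stratify_error_by_kinship)
from .imputation import HmmConfig, impute_diploid, impute_tiered, \
    sampling_baseline
from .panels import panel_maf, thin_indices
from .prediction import SnpBlup, cross_validate_lambda, dgv_accuracy
from .simdata import MISSING, TraitSpec, simulate_phenotypes
from .pipeline import stage_seed


def _population(seed, n_founders, n_generations, n_chrom, markers_per_chrom,
                sires_per_generation=4, offspring_per_generation=None):
    from .simdata import (GenomeMap, gene_drop, simulate_founder_haplotypes,
                          simulate_pedigree)
    gmap = GenomeMap.uniform(n_chrom, markers_per_chrom)
    ped = simulate_pedigree(
        n_founders, n_generations,
        {"sires_per_generation": sires_per_generation,
         "offspring_per_generation":
             offspring_per_generation or n_founders},
        seed=stage_seed(seed, "pedigree"))
    _, founders = simulate_founder_haplotypes(
        gmap, None, n_founders=int(np.sum(ped.is_founder)),
        seed=stage_seed(seed, "founders"))
    return gene_drop(ped, founders, gmap, seed=stage_seed(seed, "genedrop"))


def _thin_panel(pop, fraction):
    g = pop.genotypes
    maf = panel_maf(g)
    target = max(2, int(round(fraction * pop.gmap.n_markers)))
    return thin_indices(pop.gmap.bp, maf, target, pop.gmap.chrom)


def density_reference_sweep(seed: int,
                            density_fractions=(0.10, 0.25, 0.60),
                            reference_fractions=(0.05, 0.20, 0.50),
                            n_founders=75, n_generations=3,
                            n_chrom=2, markers_per_chrom=150,
                            n_test=50, hmm: HmmConfig | None = None
                            ) -> pd.DataFrame:
    """Allelic error as a function of typed-panel density and reference
    size, with the frequency-sampling baseline in every cell.

    A fixed held-out test cohort is imputed against nested references of
    increasing size, at each typed density (thinned panels whose fractions
    echo the 3K/7K/35K-of-50K chip ratios). Returns one row per
    (density, reference) cell.
    """
    hmm = hmm or HmmConfig(max_reference_haplotypes=100)
    pop = _population(seed, n_founders, n_generations, n_chrom,
                      markers_per_chrom)
    rng = np.random.default_rng(stage_seed(seed, "sweep-split"))
    n = pop.n_animals
    perm = rng.permutation(n)
    test_idx = perm[:n_test]
    ref_pool = perm[n_test:]
    truth = pop.genotypes[test_idx].astype(np.int8)
    rows = []
    for rf in reference_fractions:
        n_ref = max(2, int(round(rf * len(ref_pool))))
        ref_idx = ref_pool[:n_ref]  # nested references
        ref_h = pop.haplotypes[ref_idx].reshape(-1, pop.gmap.n_markers)
        freq = ref_h.mean(axis=0)
        for df in density_fractions:
            typed = _thin_panel(pop, df)
            masked_g, store = mask_genotypes(truth, typed)
            res = impute_diploid(masked_g, ref_h, hmm,
                                 genetic_pos_cm=pop.gmap.cm,
                                 chrom=pop.gmap.chrom)
            rep = error_report(res.best_guess, store)
            base = sampling_baseline(store.masked, freq,
                                     stage_seed(seed, f"base{rf}:{df}"))
            brep = error_report(np.where(store.masked, base, store.truth),
                                store)
            rows.append({"density_fraction": df, "n_typed": len(typed),
                         "reference_fraction": rf, "n_reference": n_ref,
                         "allelic_error": rep.allelic_error,
                         "genotypic_error": rep.genotypic_error,
                         "baseline_allelic_error": brep.allelic_error,
                         "n_genotypes": rep.n_genotypes})
    return pd.DataFrame(rows)


def tiered_comparison(seed: int, n_top: int = 8, n_mid: int = 120,
                      n_test: int = 30, n_founders: int = 80,
                      n_generations: int = 3, n_chrom: int = 2,
                      markers_per_chrom: int = 120,
                      medium_step: int = 4, low_step: int = 16,
                      hmm: HmmConfig | None = None) -> dict:
    """2-tier vs 3-tier imputation errors for one seed.

    Top tier: ``n_top`` animals with full (phased) high-density
    haplotypes. Middle tier: ``n_mid`` animals typed on every
    ``medium_step``-th marker. Test: ``n_test`` animals typed on every
    ``low_step``-th marker. Returns the allelic error of the plain 2-tier
    run and of the 3-tier run with the middle tier appended as
    pseudo-reference.
    """
    hmm = hmm or HmmConfig(max_reference_haplotypes=150)
    pop = _population(seed, n_founders, n_generations, n_chrom,
                      markers_per_chrom)
    L = pop.gmap.n_markers
    rng = np.random.default_rng(stage_seed(seed, "tier-split"))
    perm = rng.permutation(pop.n_animals)
    top, mid, test = (perm[:n_top], perm[n_top:n_top + n_mid],
                      perm[n_top + n_mid:n_top + n_mid + n_test])
    top_h = pop.haplotypes[top].reshape(-1, L)
    med_cols = np.zeros(L, dtype=bool)
    med_cols[::medium_step] = True
    low_cols = np.zeros(L, dtype=bool)
    low_cols[::low_step] = True
    mid_g = pop.genotypes[mid].astype(np.int8)
    mid_g[:, ~med_cols] = MISSING
    test_g = pop.genotypes[test].astype(np.int8)
    test_g[:, ~low_cols] = MISSING
    truth = pop.genotypes[test].astype(np.int8)
    store_mask = np.broadcast_to(~low_cols, truth.shape)
    from .evaluation import MaskedTruth
    store = MaskedTruth(np.array(store_mask), truth)
    kw = dict(genetic_pos_cm=pop.gmap.cm, chrom=pop.gmap.chrom)
    two = impute_diploid(test_g, top_h, hmm, **kw)
    three = impute_tiered(test_g, mid_g, top_h, hmm, **kw)
    return {
        "two_tier_allelic_error":
            error_report(two.best_guess, store).allelic_error,
        "three_tier_allelic_error":
            error_report(three.best_guess, store).allelic_error,
        "n_top": n_top, "n_mid": n_mid, "n_test": n_test,
        "n_masked": store.n_masked,
    }


def prediction_comparison(seed: int, n_founders: int = 80,
                          n_generations: int = 4, n_chrom: int = 2,
                          markers_per_chrom: int = 300,
                          heritability: float = 0.25, n_causal: int = 100,
                          low_fraction: float = 0.15,
                          n_validation: int = 80,
                          hmm: HmmConfig | None = None) -> dict:
    """DGV accuracy from true high-density genotypes vs imputed genotypes
    (best-guess and dosage) vs the low-density subset alone.

    SNP effects are trained on the training animals' true genotypes with a
    cross-validated lambda; validation animals are imputed from the low
    panel using the training animals as reference.
    """
    hmm = hmm or HmmConfig(max_reference_haplotypes=120)
    pop = _population(seed, n_founders, n_generations, n_chrom,
                      markers_per_chrom)
    trait = TraitSpec("trait", heritability, n_causal)
    phen = simulate_phenotypes(pop, trait, reliability_range=(0.5, 0.9),
                               seed=stage_seed(seed, "phenotypes"))
    rng = np.random.default_rng(stage_seed(seed, "pred-split"))
    perm = rng.permutation(pop.n_animals)
    val_idx, train_idx = perm[:n_validation], perm[n_validation:]
    typed = _thin_panel(pop, low_fraction)
    truth = pop.genotypes.astype(np.int8)
    masked_val, _ = mask_genotypes(truth[val_idx], typed)
    ref_h = pop.haplotypes[train_idx].reshape(-1, pop.gmap.n_markers)
    res = impute_diploid(masked_val, ref_h, hmm,
                         genetic_pos_cm=pop.gmap.cm, chrom=pop.gmap.chrom)
    X_train = truth[train_idx].astype(float)
    dtd_tr, rel_tr = phen.dtd[train_idx], phen.reliability[train_idx]
    from .prediction import default_lambda_grid
    lam, _ = cross_validate_lambda(
        X_train, dtd_tr, rel_tr,
        grid=default_lambda_grid(X_train.shape[1], heritability, 6),
        n_folds=4, seed=stage_seed(seed, "cv"), heritability=heritability)
    model = SnpBlup(lam=lam).fit(X_train, dtd_tr, rel_tr)
    dtd_val = phen.dtd[val_idx]
    lam_low = lam * len(typed) / pop.gmap.n_markers
    low_model = SnpBlup(lam=lam_low).fit(X_train[:, typed], dtd_tr, rel_tr)
    return {
        "lambda": lam,
        "accuracy_true": dgv_accuracy(
            model.predict(truth[val_idx].astype(float)), dtd_val),
        "accuracy_imputed": dgv_accuracy(
            model.predict(res.best_guess.astype(float)), dtd_val),
        "accuracy_dosage": dgv_accuracy(model.predict(res.dosage), dtd_val),
        "accuracy_low_density": dgv_accuracy(
            low_model.predict(truth[val_idx][:, typed].astype(float)),
            dtd_val),
        "n_train": len(train_idx), "n_validation": len(val_idx),
        "n_snps": pop.gmap.n_markers,
    }


def kinship_stratified_errors(seed: int, n_founders: int = 120,
                              n_generations: int = 3,
                              sires_per_generation: int = 10,
                              markers_per_chrom: int = 150,
                              n_reference: int = 30, n_test: int = 70,
                              low_fraction: float = 0.10,
                              hmm: HmmConfig | None = None
                              ) -> pd.DataFrame:
    """Per-test-animal allelic error with max-kinship-to-reference, for
    binning into the standard kinship intervals.

    The reference is a small random draw from the earlier generations and
    the test cohort comes from the final generation, so test animals span
    near-unrelated to parent-in-reference.
    """
    hmm = hmm or HmmConfig(max_reference_haplotypes=80)
    pop = _population(seed, n_founders, n_generations, 1,
                      markers_per_chrom,
                      sires_per_generation=sires_per_generation)
    ped = pop.pedigree
    last = ped.birth_year.max()
    rng = np.random.default_rng(stage_seed(seed, "kin-split"))
    earlier = np.flatnonzero(ped.birth_year < last)
    final = np.flatnonzero(ped.birth_year == last)
    ref_idx = np.sort(rng.choice(earlier, size=n_reference, replace=False))
    test_idx = np.sort(rng.choice(final, size=min(n_test, len(final)),
                                  replace=False))
    typed = _thin_panel(pop, low_fraction)
    truth = pop.genotypes[test_idx].astype(np.int8)
    masked_g, store = mask_genotypes(truth, typed)
    ref_h = pop.haplotypes[ref_idx].reshape(-1, pop.gmap.n_markers)
    res = impute_diploid(masked_g, ref_h, hmm,
                         genetic_pos_cm=pop.gmap.cm, chrom=pop.gmap.chrom)
    rep = error_report(res.best_guess, store)
    kin = pedigree_kinship(ped)
    from .evaluation import max_kinship_to_reference
    return pd.DataFrame({
        "animal": test_idx,
        "allelic_error": rep.per_animal["allelic_error"].to_numpy(),
        "max_kinship": max_kinship_to_reference(kin, ref_idx, test_idx),
    })


def bin_kinship_errors(frames, bins=DEFAULT_KINSHIP_BINS) -> pd.DataFrame:
    """Pool per-animal kinship/error frames (e.g. across seeds) into the
    standard kinship bins."""
    df = pd.concat(frames, ignore_index=True)
    edges = np.asarray(bins)
    which = np.clip(np.searchsorted(edges, df["max_kinship"], side="left")
                    - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = which == b
        rows.append({"bin_low": edges[b], "bin_high": edges[b + 1],
                     "n_animals": int(sel.sum()),
                     "mean_allelic_error":
                         float(df.loc[sel, "allelic_error"].mean())
                         if sel.any() else np.nan})
    return pd.DataFrame(rows)
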