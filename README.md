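# herdimpute

Genotype-imputation benchmarking for livestock genomic selection, built
around the workflow used in dairy cattle breeding: a small cohort is
genotyped on a high-density SNP chip, the bulk of the population on a
cheap low-density chip, and the missing genotypes are predicted
(*imputed*) from shared haplotypes before being fed into genomic
prediction.

Everything runs on simulated data, so every imputed genotype can be scored
against known truth. The package provides:

- **`simdata`** — a pedigreed population simulator: multi-generation
  pedigrees with overlapping sire half-sib families, founder haplotypes
  with tunable LD (mosaics of a small ancestral pool), gene dropping under
  the Haldane crossover model, daughter-trait-deviation (DTD) phenotypes
  with per-animal reliabilities, and a chip-assay view with missingness
  and genotyping error.
- **`panels`** — marker QC (MAF > 0.01, call rate > 0.9, HWE P > 1e-4,
  Mendelian-inconsistency masking) and chip-like panel construction by
  iterative thinning: repeatedly drop the lower-MAF member of the closest
  adjacent marker pair.
- **`imputation`** — a diploid Li–Stephens haplotype-copying HMM
  (`HaplotypeCopyingImputer`, a scikit-learn-style estimator). The hidden
  state is an ordered pair of reference haplotypes; per-interval switch
  probability is `rho_j = 1 − exp(−4·Ne·c_j/K)` with `Ne = 100` by
  default; genotypes are emitted through a per-allele error channel.
  Forward–backward gives a posterior triple `(p_AA, p_AB, p_BB)` at every
  locus, from which best-guess genotypes (argmax) and B-allele dosages
  (`p_AB + 2·p_BB`) follow. Includes 2-tier and 3-tier (pseudo-reference
  augmentation) designs and a frequency-sampling baseline.
- **`evaluation`** — reference/test scenario construction, masking,
  allelic and genotypic error rates, pedigree kinship (tabular method) and
  relatedness-stratified error analysis.
- **`prediction`** — reliability-weighted SNP-BLUP (`SnpBlup`): solves

  ```
  [ 1'R⁻¹1     1'R⁻¹X      ] [μ̂]   [1'R⁻¹y]
  [ X'R⁻¹1    X'R⁻¹X + λI  ] [ĝ] = [X'R⁻¹y]
  ```

  with `y = 2·DTD`, `R_ii = 1/rel_i − 1`, λ by seeded cross-validation;
  DGV = `μ̂ + Xĝ`, accuracy = Pearson r(DGV, DTD) in a validation cohort.
- **`pipeline` / CLI** — YAML-configured end-to-end runs with per-stage
  seeds, VCF/TSV artifacts and a checksummed manifest.

## Worked example

Simulate a 225-animal population on a 300-marker genome, thin a 30-marker
low-density panel, impute the masked genotypes of half the animals from
the other half, and score the result:

```python
import numpy as np
from herdimpute import (GenomeMap, HmmConfig, allelic_error_rate,
                        gene_drop, impute_diploid, mask_genotypes,
                        error_report, sampling_baseline,
                        simulate_founder_haplotypes, simulate_pedigree,
                        thin_indices, panel_maf)

gmap = GenomeMap.uniform(n_chromosomes=2, markers_per_chromosome=150)
ped = simulate_pedigree(n_founders=75, n_generations=3,
                        mating_design={"sires_per_generation": 4}, seed=7)
_, founders = simulate_founder_haplotypes(gmap, None, n_founders=75, seed=8)
pop = gene_drop(ped, founders, gmap, seed=9)

low = thin_indices(gmap.bp, panel_maf(pop.genotypes), 30, gmap.chrom)

ref, test = np.arange(0, 225, 2), np.arange(1, 225, 2)
ref_haps = pop.haplotypes[ref].reshape(-1, gmap.n_markers)
masked, store = mask_genotypes(pop.genotypes[test].astype(np.int8), low)

res = impute_diploid(masked, ref_haps, HmmConfig(ne=100),
                     genetic_pos_cm=gmap.cm, chrom=gmap.chrom)
rep = error_report(res.best_guess, store)
base = sampling_baseline(store.masked, ref_haps.mean(axis=0), seed=10)
base_err = allelic_error_rate(store.truth[store.masked], base[store.masked])
print(f"masked genotypes scored : {rep.n_genotypes}")
print(f"HMM allelic error       : {rep.allelic_error:.2f}%")
print(f"HMM genotypic error     : {rep.genotypic_error:.2f}%")
print(f"sampling baseline error : {base_err:.2f}%")
```

Output:

```
masked genotypes scored : 30240
HMM allelic error       : 7.57%
HMM genotypic error     : 14.18%
sampling baseline error : 24.56%
```

Reading: of the 30,240 masked genotypes, 14.2% of best-guess genotypes
are wrong, but only 7.6% of *alleles* — most miscalls miss a single
allele. Copying haplotypes from the 50% reference panel is more than
three times more accurate than drawing genotypes from reference allele
frequencies. A full configured run (panels, scenarios, kinship
stratification, prediction) is one command:

```sh
herdimpute run --seed 1 --outdir out
```

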