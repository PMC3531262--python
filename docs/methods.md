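# Methods

This note documents the models, the defaults and why they were chosen,
the numerical decisions, and what the synthetic benchmarks can and cannot
show.

## Population simulator

**Pedigree.** Generations are discrete; each non-founder generation is
sired by a small number of designated males from the previous generation
(default 4 per generation), producing the overlapping half-sib families
typical of dairy breeding where a few elite sires dominate. Dams are
drawn with replacement from the previous generation's females (a
simplification: real cows calve once a year, so very large full-sib
families are rarer than here). Birth year increments by one per
generation, so cohort splits ("bulls born before year Y in the
reference") are expressible. Pedigrees are topologically ordered by
construction, which the `Pedigree` container also validates (and which
rules out ancestry cycles).

**Genome map.** Uniform marker grids with the standard cattle
approximation of 1 cM per Mb; a map file with explicit genetic positions
can be supplied instead. Default marker spacing is 50 kb (0.05 cM).

**Founder LD.** Founder haplotypes are recombinant mosaics of a small
pool of `H` ancestral haplotypes (default `H = 20`), switching template
as a Poisson process with 1 expected switch per cM. Limited ancestral
diversity plus a finite switch rate produces LD that decays with genetic
distance — the feature the copying HMM exploits — with two dials
(`H`, switch rate) instead of a coalescent simulation. Marker allele
frequencies are drawn from a configurable spectrum (default uniform on
[0.05, 0.5]).

**Gene dropping.** Haldane model: crossovers per chromosome are
Poisson(genetic length in Morgans) with positions uniform on the cM
scale, no interference, random start phase. Offspring genotypes are
Mendelian-consistent by construction; the assay layer then adds
missingness and genotyping error (an erroneous call is replaced by one of
the other two codes uniformly), which is what the QC filters exercise.

**Phenotypes.** A trait is `n_causal` markers with normal (or gamma)
effects; the true breeding value (TBV) is the causal genotype score,
standardised to variance h². DTD (daughter trait deviation) phenotypes
are `DTD_i = TBV_i + e_i` with `Var(e_i) = Var(TBV)·(1 − rel_i)/rel_i`,
which makes `rel_i` exactly the squared correlation between `DTD_i` and
`TBV_i` — the usual meaning of the reliability of a progeny-based proof.
Reliabilities are drawn uniformly from a configurable range and clamped
to [0.01, 0.99] so the SNP-BLUP residual weights `1/rel − 1` stay finite
and positive. The benchmark traits use h² = 0.25 (production-trait
scale); h² = 0.04 (fertility scale) is supported and exercised in the
simulator's range checks.

## Panel QC and thinning

QC order matters and is fixed: Mendelian-inconsistent offspring genotypes
are set missing first, then MAF, call rate and HWE are computed on the
cleaned matrix. The HWE test is a 1-df chi-square goodness of fit on
observed genotype counts (the conventional marker-QC test; the threshold
is a P-value, so any asymptotically equivalent test would filter nearly
identically). A marker passes only if it is strictly above all three
thresholds (defaults MAF > 0.01, call rate > 0.9, HWE P > 1e-4).
Filtering is idempotent: statistics recomputed on a filtered matrix
cannot newly fail.

Thinning is iterative: find the globally smallest adjacent interval
(pairs form within chromosomes only), drop the lower-MAF member,
recompute. Two details are underdetermined by the verbal rule and fixed
here for determinism: distances are physical (bp), ties between equal
smallest intervals resolve to the earliest (chromosome, left position),
and an equal-MAF pair drops its right member. The implementation uses a
lazily invalidated heap over a doubly-linked survivor list (O(n log n));
the test suite checks it against a literal O(n²) re-scan of the rule.
A target below one marker per chromosome is rejected: the
within-chromosome pair rule can never remove a chromosome's last marker.

## The imputation model

The imputer is a generic diploid Li–Stephens copying HMM — deliberately
*not* a re-implementation of any specific imputation program. Hidden
state: an ordered pair of the K phased reference haplotypes. Transitions
are independent per haplotype: with probability
`rho_j = 1 − exp(−4·Ne·c_j/K)` the template is re-drawn uniformly across
an interval of `c_j` Morgans (`Ne` defaults to 100, the effective
population size commonly reported for Holstein-Friesians). Because the
K²-state transition kernel factorises, one forward or backward step costs
O(K²) via row/column sums, so a whole animal is O(L·K²).

Emission: each copied allele is observed incorrectly with probability ε
(default 0.005, typical chip-error scale), giving a 3×3
genotype-given-allele-sum channel; untyped or missing loci are
uninformative. Genotype posteriors at a locus marginalise the state
posterior through the same channel. Best guess is the posterior argmax
with ties resolved toward the lower B-allele count; dosage is
`p_AB + 2·p_BB`.

Numerics: forward variables are renormalised at every locus, so there is
no underflow regardless of chromosome length (exercised at L = 10,000).
Chromosome boundaries are handled as intervals with `rho = 1`, which is
exactly an independent restart, so whole genomes run in one pass and
equal per-chromosome runs. Forward matrices are stored per locus for the
backward sweep (float32 storage beyond ~6·10⁷ states·loci to bound
memory). The per-interval switch probability is floored at 1e-8 so
zero-length intervals stay connected. The core recursions are
numba-compiled.

**Reference cap.** Cost is quadratic in K, so a per-animal cap (default
400 haplotypes) subsamples the reference when it is larger, keeping the
haplotypes with the highest expected allele-sharing with the animal's
typed genotypes.

**Unphased input.** Test genotypes are handled directly by the
ordered-pair HMM; no pre-phasing. The reference must be phased (true
phase in simulation; a pre-phased VCF for real data — statistical phasing
of references is out of scope).

**Tiered imputation.** The 3-tier design (low-density test, mid-density
cohort, small high-density top panel) is implemented stage-wise: the mid
cohort is imputed to high density against the top panel; its pseudo-
phased haplotypes (per-locus max-posterior state path, reconciled with
the observed genotypes at typed loci) are appended to the reference; the
test cohort is then imputed against the enlarged panel. How a specific
external tool merges two reference panels "in the same run" is
unpublished detail; the stage-wise construction is this package's design
and is validated by reproducing the qualitative pattern — the middle tier
helps most when the top tier is small, and the gain fades as the top tier
grows.

**Baseline.** The sampling baseline draws each masked genotype as two
independent alleles at the reference frequency (a Hardy–Weinberg draw).
At truth and reference frequency 0.5 its expected allelic error is
exactly 37.5% (E|g − g'|/2 for independent Binomial(2, ½) pairs), which
the test suite verifies by Monte Carlo.

## Error statistics and relatedness

Allelic error counts `|B-count(truth) − B-count(imputed)|` alleles wrong
per genotype (0, 1 or 2), over twice the number of imputed genotypes,
×100; genotypic error is the fraction of mismatched best-guess genotypes
×100. Hence allelic ≤ genotypic ≤ 2·allelic always. Masked entries whose
truth is itself missing (simulated assay dropouts) are excluded from all
denominators. Best-guess genotypes are what gets scored; dosages are
evaluated only through prediction accuracy.

Pedigree kinship uses the recursive tabular method
(`f(i,j) = ½(f(s_i,j) + f(d_i,j))`, `f(i,i) = ½(1 + f(s_i,d_i))`,
unknown parents contribute 0), checked against single-locus gene-dropping
IBD estimates. Test animals are stratified by their maximum kinship to
any reference animal into the standard bins 0–0.01 / 0.01–0.1 / 0.1–0.2
/ 0.2–0.4, and by whether their sire is in the reference. "Key ancestor"
reference rules pick the animals with the most pedigree descendants.

## Genomic prediction

Weighted SNP-BLUP on the 2×DTD scale with residual weights
`R_ii = 1/rel_i − 1` and ridge penalty λ on all SNP effects jointly.
Genotype columns are intentionally *not* centred or scaled — the raw
0/1/2 (or dosage) coding is used and the general mean absorbs the offset.
The system is solved in the SNP dimension (Cholesky on the (p+1)-block
normal equations) when p < n, otherwise through the exact dual identity
`μ̂ = (1'M⁻¹y)/(1'M⁻¹1)`, `ĝ = X'M⁻¹(y − 1μ̂)` with
`M = XX' + λR`; both routes must satisfy the block system to 1e-8
relative residual or the solver raises.

λ is chosen by k-fold cross-validation (default 5 folds, seeded shuffle)
maximising mean held-out Pearson correlation between DGV and DTD, on a
10-point log grid spanning four orders of magnitude around the heuristic
centre `N_SNP·(1 − h²)/h²`. λ is trait-specific. Validation accuracy
uses raw DTD — Pearson r is scale-invariant, so the 2× factor is
immaterial there. Under pure-noise phenotypes the held-out correlation
is mean-zero for *every* λ (independent validation noise cannot
correlate with any prediction), so CV cannot systematically prefer heavy
shrinkage there; the grid selection is only meaningful when signal
exists, and the tests exercise exactly that regime.

## Benchmark designs and scale

The four canned designs in `herdimpute.benchmarks` (used by the test
suite and `scripts/acceptance.py`) run at a desk scale chosen so the full
suite completes in minutes on one core:

- **Density × reference sweep:** 225 animals, 2×150 markers; typed
  panels at 10/25/60% density (echoing 3K/7K/35K-of-50K ratios); nested
  references at 5/20/50%; 50 held-out test animals; K capped at 100.
- **Tiered:** 80 founders, 2×120 markers; top tier 8 animals (60 for the
  large-top condition), middle tier 120 animals at every-4th-marker
  density, 30 test animals at every-16th.
- **Prediction:** 320 animals (80 validation), 2×300 markers, 100 causal
  markers, h² = 0.25, reliabilities 0.5–0.9, low panel at 15% density.
- **Kinship stratification:** 360 animals in 3 generations with 10 sires
  per generation, single 150-marker chromosome, 30-animal reference from
  the earlier generations, 70 final-generation test animals.

These sizes sit below the simulator's nominal default scale (2,000
animals, 5 chromosomes × 2,000 markers, mimicking 800K:50K:7K:3K density
ratios at roughly 1/75 scale), which remains the configuration default
for standalone runs.

**What the synthetic scale shows and does not show.** The generator
reproduces the *structural* features the method depends on — LD decaying
with genetic distance, haplotypes shared through a complex pedigree,
nested panel densities, reliability-weighted phenotypes — so directional
findings (error falls with panel density, reference size and
relatedness; the HMM dominates frequency sampling; a middle tier rescues
a small top tier; imputed genotypes nearly match true genotypes for
prediction) are meaningful. Absolute error rates and accuracies are not
comparable to chip-scale cattle data: the simulated genome is short, the
ancestral haplotype pool is small, marker density per cM is low, and
population size is hundreds rather than thousands. Error rates here are
correspondingly higher than the sub-1% figures achievable when imputing
between dense commercial chips with thousands of reference animals.

## Known limitations

- No coalescent/mutation/selection machinery; founder LD is
  phenomenological (mosaic model).
- Autosomes only; no X-chromosome inheritance.
- Dams are sampled with replacement within a generation.
- The tiered pseudo-reference inherits stage-1 imputation errors; with a
  very small top tier those errors are correlated across pseudo-
  haplotypes, which bounds the achievable 3-tier gain.
- Statistical phasing of unphased reference panels is out of scope, as
  are cluster-based haplotype models and pedigree/linkage-based
  imputation.
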