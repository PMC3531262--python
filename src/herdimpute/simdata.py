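"""Synthetic pedigreed-population generator for imputation benchmarking.

Produces the data structures the rest of the pipeline consumes: a
multi-generation pedigree with overlapping sire half-sib families, a genome
map, founder haplotypes with tunable linkage disequilibrium (ancestral-mosaic
model), gene-dropped genotypes with known phase, daughter-trait-deviation
(DTD) phenotypes with per-animal reliabilities, and a chip-assay view of the
true genotypes with configurable missingness and genotyping error.

All randomness flows through ``numpy.random.default_rng(seed)``; every
operation is a pure function of its inputs and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Missing-genotype code used throughout the package (VCF "./.").
MISSING: int = -1

UNKNOWN_PARENT = "0"


# ---------------------------------------------------------------------------
# Genome map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeMap:
    """Ordered biallelic marker map: chromosome, id, physical (bp) and
    genetic (cM) position per marker.

    Markers must be grouped by chromosome, with bp strictly increasing and
    cM non-decreasing within each chromosome. Marker ids are unique
    genome-wide.
    """

    chrom: np.ndarray
    marker_id: np.ndarray
    bp: np.ndarray
    cm: np.ndarray

    def __post_init__(self):
        chrom = np.asarray(self.chrom)
        mid = np.asarray(self.marker_id)
        bp = np.asarray(self.bp, dtype=np.int64)
        cm = np.asarray(self.cm, dtype=np.float64)
        n = len(chrom)
        if not (len(mid) == len(bp) == len(cm) == n):
            raise ValueError("map arrays must have equal length")
        if n == 0:
            raise ValueError("empty genome map")
        if len(np.unique(mid)) != n:
            raise ValueError("marker ids must be unique genome-wide")
        # chromosomes must be contiguous blocks
        seen = []
        for c in chrom:
            if not seen or seen[-1] != c:
                if c in seen:
                    raise ValueError("chromosome blocks must be contiguous")
                seen.append(c)
        for c in seen:
            sl = chrom == c
            if np.any(np.diff(bp[sl]) <= 0):
                raise ValueError(f"bp not strictly increasing on chrom {c}")
            if np.any(np.diff(cm[sl]) < 0):
                raise ValueError(f"cM not non-decreasing on chrom {c}")
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "marker_id", mid)
        object.__setattr__(self, "bp", bp)
        object.__setattr__(self, "cm", cm)

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    @property
    def chromosomes(self) -> list:
        out = []
        for c in self.chrom:
            if not out or out[-1] != c:
                out.append(c)
        return out

    def chrom_slice(self, c) -> slice:
        idx = np.flatnonzero(self.chrom == c)
        if idx.size == 0:
            raise KeyError(f"no such chromosome: {c}")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def subset(self, indices: np.ndarray) -> "GenomeMap":
        indices = np.asarray(indices)
        return GenomeMap(self.chrom[indices], self.marker_id[indices],
                         self.bp[indices], self.cm[indices])

    @classmethod
    def uniform(cls, n_chromosomes: int, markers_per_chromosome: int,
                spacing_bp: int = 50_000) -> "GenomeMap":
        """Evenly spaced map with the standard cattle approximation of
        1 cM per Mb (so genetic length scales with physical length)."""
        chroms, mids, bps, cms = [], [], [], []
        for c in range(1, n_chromosomes + 1):
            for j in range(markers_per_chromosome):
                pos = (j + 1) * spacing_bp
                chroms.append(str(c))
                mids.append(f"snp{c}_{j + 1}")
                bps.append(pos)
                cms.append(pos / 1e6)  # 1 cM/Mb
        return cls(np.array(chroms), np.array(mids),
                   np.array(bps, dtype=np.int64), np.array(cms))


# ---------------------------------------------------------------------------
# Pedigree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PedigreeRecord:
    animal_id: str
    sire_id: str  # UNKNOWN_PARENT if unknown
    dam_id: str
    sex: str  # 'M' or 'F'
    birth_year: int


class Pedigree:
    """Topologically ordered pedigree with fast integer parent lookups.

    ``sire_idx``/``dam_idx`` are row indices into the pedigree itself, -1 for
    unknown parents. Construction validates topological order (parents before
    offspring, which also rules out ancestry cycles) and parent sexes.
    """

    def __init__(self, records: Sequence[PedigreeRecord]):
        self.records = list(records)
        ids = [r.animal_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate animal ids in pedigree")
        self.index = {a: i for i, a in enumerate(ids)}
        n = len(ids)
        self.sire_idx = np.full(n, -1, dtype=np.int64)
        self.dam_idx = np.full(n, -1, dtype=np.int64)
        for i, r in enumerate(self.records):
            for which, pid in (("sire", r.sire_id), ("dam", r.dam_id)):
                if pid == UNKNOWN_PARENT:
                    continue
                if pid not in self.index:
                    raise ValueError(f"unknown {which} id {pid!r} for animal "
                                     f"{r.animal_id!r} (not declared '0')")
                j = self.index[pid]
                if j >= i:
                    raise ValueError(
                        f"pedigree not topologically ordered: {which} "
                        f"{pid!r} appears at/after offspring {r.animal_id!r}")
                want = "M" if which == "sire" else "F"
                if self.records[j].sex != want:
                    raise ValueError(f"{which} {pid!r} has sex "
                                     f"{self.records[j].sex!r}, expected {want!r}")
                (self.sire_idx if which == "sire" else self.dam_idx)[i] = j

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def animal_ids(self) -> list:
        return [r.animal_id for r in self.records]

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire_idx < 0) & (self.dam_idx < 0)

    @property
    def founder_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_founder)

    @property
    def birth_year(self) -> np.ndarray:
        return np.array([r.birth_year for r in self.records])

    @property
    def sex(self) -> np.ndarray:
        return np.array([r.sex for r in self.records])


def simulate_pedigree(n_founders: int, n_generations: int,
                      mating_design: dict | None = None,
                      seed: int = 0) -> Pedigree:
    """Simulate a multi-generation pedigree with sire half-sib families.

    Each non-founder generation is sired by a small number of designated
    males drawn from the previous generation (mimicking the heavy use of a
    few elite sires in dairy breeding), and birth year increases by one per
    generation so birth-year cohort splits are expressible.

    ``mating_design`` keys (all optional):
      ``sires_per_generation`` (default 4), ``offspring_per_generation``
      (default ``n_founders``), ``female_fraction`` (default 0.5),
      ``base_year`` (default 2000, the founders' birth year).
    """
    if n_founders < 2:
        raise ValueError("n_founders must be >= 2")
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    design = dict(mating_design or {})
    n_sires = int(design.pop("sires_per_generation", 4))
    n_off = int(design.pop("offspring_per_generation", n_founders))
    female_frac = float(design.pop("female_fraction", 0.5))
    base_year = int(design.pop("base_year", 2000))
    if design:
        raise ValueError(f"unknown mating_design keys: {sorted(design)}")
    if n_sires < 1 or n_off < 1:
        raise ValueError("sires_per_generation and offspring_per_generation "
                         "must be >= 1")

    rng = np.random.default_rng(seed)

    def assign_sexes(n: int) -> np.ndarray:
        # guarantee both sexes whenever n >= 2
        n_f = int(round(n * female_frac))
        n_f = min(max(n_f, 1 if n >= 2 else 0), n - 1 if n >= 2 else n)
        sexes = np.array(["F"] * n_f + ["M"] * (n - n_f))
        rng.shuffle(sexes)
        return sexes

    records: list[PedigreeRecord] = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"A{counter:05d}"

    founders = []
    for sex in assign_sexes(n_founders):
        r = PedigreeRecord(new_id(), UNKNOWN_PARENT, UNKNOWN_PARENT,
                           str(sex), base_year)
        records.append(r)
        founders.append(r)

    prev = founders
    for g in range(1, n_generations):
        males = [r for r in prev if r.sex == "M"]
        females = [r for r in prev if r.sex == "F"]
        if not males or not females:
            raise ValueError("previous generation lacks one sex; increase "
                             "generation size")
        sires = list(rng.choice(len(males), size=min(n_sires, len(males)),
                                replace=False))
        sires = [males[i] for i in sires]
        cur = []
        sexes = assign_sexes(n_off)
        for k in range(n_off):
            sire = sires[int(rng.integers(len(sires)))]
            dam = females[int(rng.integers(len(females)))]
            r = PedigreeRecord(new_id(), sire.animal_id, dam.animal_id,
                               str(sexes[k]), base_year + g)
            records.append(r)
            cur.append(r)
        prev = cur
    return Pedigree(records)


# ---------------------------------------------------------------------------
# Founder haplotypes: ancestral-mosaic LD model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HaplotypePool:
    """Small pool of ancestral haplotypes from which founder haplotypes are
    built as recombinant mosaics; limited pool size is what creates LD."""

    haplotypes: np.ndarray          # (n_ancestral, n_markers) uint8
    allele_freq: np.ndarray         # spectrum draw per marker
    maf_spectrum: dict = field(default_factory=dict)

    def __post_init__(self):
        h = np.asarray(self.haplotypes, dtype=np.uint8)
        if h.ndim != 2 or not np.isin(h, [0, 1]).all():
            raise ValueError("pool haplotypes must be a binary 2-D matrix")
        object.__setattr__(self, "haplotypes", h)


def _draw_frequencies(rng: np.random.Generator, n: int,
                      spectrum: dict) -> np.ndarray:
    dist = spectrum.get("dist", "uniform")
    if dist == "uniform":
        lo = float(spectrum.get("low", 0.05))
        hi = float(spectrum.get("high", 0.5))
        return rng.uniform(lo, hi, size=n)
    if dist == "fixed":
        return np.full(n, float(spectrum.get("value", 0.5)))
    if dist == "beta":
        return rng.beta(float(spectrum["a"]), float(spectrum["b"]), size=n)
    raise ValueError(f"unknown MAF spectrum dist {dist!r}")


def simulate_founder_haplotypes(gmap: GenomeMap, maf_spectrum: dict | None,
                                n_ancestral: int = 20,
                                mosaic_switch_rate: float = 1.0,
                                n_founders: int = 100,
                                seed: int = 0) -> tuple[HaplotypePool, np.ndarray]:
    """Build founder haplotypes as mosaics of a small ancestral pool.

    Per marker, an allele frequency is drawn from ``maf_spectrum`` and the
    pool's alleles are Bernoulli draws at that frequency. Each founder
    haplotype then copies along the chromosome from one pool haplotype,
    switching to a uniformly chosen pool haplotype as a Poisson process with
    ``mosaic_switch_rate`` expected switches per cM. LD decays with genetic
    distance at a rate controlled by the switch rate and pool size.

    Returns the pool and a ``(n_founders, 2, n_markers)`` haplotype array.
    """
    if n_ancestral < 2:
        raise ValueError("n_ancestral must be >= 2")
    if mosaic_switch_rate < 0:
        raise ValueError("mosaic_switch_rate must be >= 0")
    spectrum = dict(maf_spectrum or {"dist": "uniform", "low": 0.05, "high": 0.5})
    rng = np.random.default_rng(seed)
    L = gmap.n_markers
    freq = _draw_frequencies(rng, L, spectrum)
    pool = (rng.random((n_ancestral, L)) < freq).astype(np.uint8)

    n_haps = 2 * n_founders
    # per-interval switch probability (Poisson process on the cM scale);
    # chromosome starts always re-draw the source
    switch = np.zeros((n_haps, L), dtype=bool)
    switch[:, 0] = True
    for c in gmap.chromosomes:
        sl = gmap.chrom_slice(c)
        d_cm = np.diff(gmap.cm[sl])
        p_sw = 1.0 - np.exp(-mosaic_switch_rate * d_cm)
        switch[:, sl.start] = True
        if len(d_cm):
            switch[:, sl.start + 1:sl.stop] = rng.random(
                (n_haps, len(d_cm))) < p_sw
    draws = rng.integers(0, n_ancestral, size=(n_haps, L))
    pos = np.where(switch, np.arange(L)[None, :], 0)
    last_switch = np.maximum.accumulate(pos, axis=1)
    sources = np.take_along_axis(draws, last_switch, axis=1)
    founder = pool[sources, np.arange(L)[None, :]]
    founder = founder.reshape(n_founders, 2, L).astype(np.uint8)
    return HaplotypePool(pool, freq, spectrum), founder


# ---------------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------------

@dataclass
class SimulatedPopulation:
    """Phase-known diploid population aligned to a genome map.

    ``haplotypes[i, 0]`` is the paternal and ``haplotypes[i, 1]`` the
    maternal haplotype of animal ``i`` (pedigree row order).
    """

    haplotypes: np.ndarray  # (n_animals, 2, n_markers) uint8
    gmap: GenomeMap
    pedigree: Pedigree
    phase_known: bool = True
    crossover_log: list | None = None

    @property
    def n_animals(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def genotypes(self) -> np.ndarray:
        """True B-allele counts, shape (n_animals, n_markers)."""
        return self.haplotypes.sum(axis=1, dtype=np.int8)

    @property
    def animal_ids(self) -> list:
        return self.pedigree.animal_ids


def _meiosis(parent_haps: np.ndarray, gmap: GenomeMap,
             rng: np.random.Generator,
             log: list | None, parent_idx: int) -> np.ndarray:
    """One gamete from a parent's haplotype pair under the Haldane model:
    crossover count per chromosome ~ Poisson(genetic length in Morgans),
    positions uniform on the cM scale, no interference."""
    L = gmap.n_markers
    gamete = np.empty(L, dtype=np.uint8)
    for c in gmap.chromosomes:
        sl = gmap.chrom_slice(c)
        cm = gmap.cm[sl]
        length_m = (cm[-1] - cm[0]) / 100.0
        n_x = rng.poisson(length_m) if length_m > 0 else 0
        start = int(rng.integers(2))
        if n_x:
            xpos = np.sort(rng.uniform(cm[0], cm[-1], size=n_x))
            src = (start + np.searchsorted(xpos, cm, side="right")) % 2
        else:
            src = np.full(len(cm), start)
        gamete[sl] = parent_haps[src, np.arange(sl.start, sl.stop)]
        if log is not None:
            log.append((parent_idx, c, start, int(n_x)))
    return gamete


def gene_drop(pedigree: Pedigree, founder_haplotypes: np.ndarray,
              gmap: GenomeMap, seed: int = 0,
              record_crossovers: bool = False) -> SimulatedPopulation:
    """Drop founder haplotypes through the pedigree with recombination.

    ``founder_haplotypes`` has shape (n_founders, 2, n_markers) and is
    assigned to founders in pedigree order. Every transmitted gamete is a
    legal recombinant of the parent's pair, so genotypes are Mendelian-
    consistent by construction.
    """
    founders = pedigree.founder_indices
    fh = np.asarray(founder_haplotypes, dtype=np.uint8)
    if fh.ndim != 3 or fh.shape[1] != 2:
        raise ValueError("founder_haplotypes must have shape (n, 2, L)")
    if fh.shape[0] < len(founders):
        raise ValueError(f"need haplotypes for {len(founders)} founders, "
                         f"got {fh.shape[0]}")
    if fh.shape[2] != gmap.n_markers:
        raise ValueError("founder haplotypes do not match map length")
    rng = np.random.default_rng(seed)
    n = len(pedigree)
    L = gmap.n_markers
    haps = np.zeros((n, 2, L), dtype=np.uint8)
    haps[founders] = fh[: len(founders)]
    log: list | None = [] if record_crossovers else None
    for i in range(n):
        s, d = pedigree.sire_idx[i], pedigree.dam_idx[i]
        if s < 0 and d < 0:
            continue
        if s < 0 or d < 0:
            raise ValueError(f"animal {pedigree.records[i].animal_id!r} has "
                             "exactly one known parent; gene drop requires "
                             "both or neither")
        haps[i, 0] = _meiosis(haps[s], gmap, rng, log, int(s))
        haps[i, 1] = _meiosis(haps[d], gmap, rng, log, int(d))
    return SimulatedPopulation(haps, gmap, pedigree, True, log)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraitSpec:
    """A quantitative trait: heritability, number of causal markers, and the
    causal-effect distribution ('normal' or 'gamma')."""

    name: str
    heritability: float
    n_causal: int
    effect_dist: str = "normal"

    def __post_init__(self):
        if not 0.0 < self.heritability < 1.0:
            raise ValueError("heritability must be in (0, 1)")
        if self.n_causal < 1:
            raise ValueError("n_causal must be >= 1")


@dataclass(frozen=True)
class PhenotypeRecord:
    animal_id: str
    trait: str
    dtd: float
    reliability: float


@dataclass
class PhenotypeSet:
    """DTD phenotypes plus the simulation truth needed for calibration
    checks (true breeding values, residuals, causal architecture)."""

    trait: TraitSpec
    animal_ids: list
    dtd: np.ndarray
    reliability: np.ndarray
    tbv: np.ndarray
    residual: np.ndarray
    causal_indices: np.ndarray
    causal_effects: np.ndarray

    @property
    def records(self) -> list[PhenotypeRecord]:
        return [PhenotypeRecord(a, self.trait.name, float(y), float(r))
                for a, y, r in zip(self.animal_ids, self.dtd, self.reliability)]


def simulate_phenotypes(population: SimulatedPopulation, trait: TraitSpec,
                        reliability_range: tuple[float, float] = (0.3, 0.9),
                        seed: int = 0) -> PhenotypeSet:
    """Simulate daughter trait deviations (DTD) with per-animal reliability.

    True breeding value TBV = causal genotypes x effects, standardised to
    variance h^2 (nominal phenotypic variance 1). DTD_i = TBV_i + e_i with
    Var(e_i) = Var(TBV) * (1 - rel_i) / rel_i, which makes rel_i the squared
    correlation between DTD_i and TBV_i — the usual meaning of the
    reliability of a progeny-based proof. Reliabilities are drawn uniformly
    from ``reliability_range`` and clamped to [0.01, 0.99] so downstream
    residual weights (1/rel - 1) stay finite.
    """
    rng = np.random.default_rng(seed)
    h2 = trait.heritability
    G = population.genotypes.astype(np.float64)
    L = G.shape[1]
    if trait.n_causal > L:
        raise ValueError("more causal markers than markers in the map")
    causal = np.sort(rng.choice(L, size=trait.n_causal, replace=False))
    if trait.effect_dist == "normal":
        eff = rng.normal(size=trait.n_causal)
    elif trait.effect_dist == "gamma":
        eff = rng.gamma(0.4, 1.66, size=trait.n_causal) * \
            rng.choice([-1, 1], size=trait.n_causal)
    else:
        raise ValueError(f"unknown effect_dist {trait.effect_dist!r}")
    raw = G[:, causal] @ eff
    sd = raw.std()
    if sd == 0:
        raise ValueError("causal genotypes are monomorphic; no genetic "
                         "variance can be simulated")
    scale = np.sqrt(h2) / sd
    tbv = (raw - raw.mean()) * scale
    eff = eff * scale
    lo, hi = reliability_range
    rel = np.clip(rng.uniform(lo, hi, size=len(tbv)), 0.01, 0.99)
    var_g = h2
    resid = rng.normal(size=len(tbv)) * np.sqrt(var_g * (1.0 - rel) / rel)
    dtd = tbv + resid
    return PhenotypeSet(trait, population.animal_ids, dtd, rel, tbv, resid,
                        causal, eff)


# ---------------------------------------------------------------------------
# Chip assay view
# ---------------------------------------------------------------------------

def apply_genotyping(population: SimulatedPopulation, panel,
                     missing_rate: float = 0.0, error_rate: float = 0.0,
                     seed: int = 0) -> np.ndarray:
    """Observe true genotypes through a chip assay on ``panel`` markers.

    ``panel`` is a SnpPanel or an integer index array into the map. Each
    entry is independently set missing with ``missing_rate`` and, if not
    missing, replaced by one of the two other genotype codes with
    ``error_rate``. Returns an int8 matrix coded 0/1/2 with ``MISSING`` for
    dropped calls; the population's truth is left untouched.
    """
    for rate, name in ((missing_rate, "missing_rate"), (error_rate, "error_rate")):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    idx = np.asarray(getattr(panel, "indices", panel))
    rng = np.random.default_rng(seed)
    g = population.genotypes[:, idx].astype(np.int8)
    if error_rate > 0:
        err = rng.random(g.shape) < error_rate
        bump = rng.integers(1, 3, size=g.shape).astype(np.int8)
        g = np.where(err, (g + bump) % 3, g).astype(np.int8)
    if missing_rate > 0:
        miss = rng.random(g.shape) < missing_rate
        g[miss] = MISSING
    return g
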