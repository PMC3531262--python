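"""Imputation scenario construction and accuracy evaluation.

A :class:`Scenario` describes how a genotyped population is split into a
reference set (kept at high density) and a test set (reduced to a typed
panel with everything else masked), mirroring the reference/test designs
used to benchmark imputation in dairy cattle: random bull fractions,
key-ancestor references, sex splits, and birth-year cohort splits.

Accuracy statistics: the allelic error rate (incorrectly predicted alleles
over all imputed alleles, x100; per genotype the allele mismatch is the
absolute B-allele count difference, 0/1/2) and the genotypic error rate
(mismatched best-guess genotypes, x100). Allelic error is always between
half the genotypic error and the genotypic error itself.

Relatedness analyses: pedigree kinship (recursive/tabular method), per-test-
animal maximum kinship to the reference binned into the standard intervals
0-0.01 / 0.01-0.1 / 0.1-0.2 / 0.2-0.4, and a with-sire/without-sire
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simdata import MISSING, Pedigree

DEFAULT_KINSHIP_BINS = (0.0, 0.01, 0.1, 0.2, 0.4)


# ---------------------------------------------------------------------------
# Scenario construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SelectionRule:
    """Predicate + sampling rule for choosing animals.

    ``fraction``/``count`` select at random (seeded) among animals matching
    the predicates; ``key_ancestors`` instead takes the ``count`` animals
    with the most pedigree descendants.
    """

    fraction: float | None = None
    count: int | None = None
    sex: str | None = None
    birth_year_min: int | None = None
    birth_year_max: int | None = None
    key_ancestors: bool = False

    def candidates(self, pedigree: Pedigree) -> np.ndarray:
        keep = np.ones(len(pedigree), dtype=bool)
        if self.sex is not None:
            keep &= pedigree.sex == self.sex
        by = pedigree.birth_year
        if self.birth_year_min is not None:
            keep &= by >= self.birth_year_min
        if self.birth_year_max is not None:
            keep &= by <= self.birth_year_max
        return np.flatnonzero(keep)


@dataclass(frozen=True)
class Scenario:
    """A reference/test split plus a typed-panel/masking recipe.

    ``typed_panel`` names the panel the test animals are genotyped on;
    ``mask`` is either ``{"type": "complement"}`` (mask everything off the
    typed panel) or ``{"type": "every_nth", "n": N, "animal_fraction": f}``
    (mask every Nth marker in a fraction of the test animals).
    """

    name: str
    reference: SelectionRule
    test: SelectionRule | None = None
    typed_panel: str | None = None
    mask: dict = field(default_factory=lambda: {"type": "complement"})


def split_reference_test(pedigree: Pedigree, scenario: Scenario,
                         seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Resolve a scenario into disjoint (reference, test) animal index sets.

    Reference animals are sampled (seeded) from the rule's candidates, or
    taken as the top descendants-count animals for key-ancestor rules. The
    test set is the scenario's test rule minus the reference, or the
    complement of the reference when no test rule is given.
    """
    rng = np.random.default_rng(seed)
    rule = scenario.reference
    cand = rule.candidates(pedigree)
    if cand.size == 0:
        raise ValueError(f"scenario {scenario.name!r}: no animals satisfy "
                         "the reference predicates")
    if rule.key_ancestors:
        if rule.count is None:
            raise ValueError("key_ancestors rule requires a count")
        counts = descendant_counts(pedigree)[cand]
        order = cand[np.argsort(-counts, kind="stable")]
        ref = np.sort(order[: rule.count])
    elif rule.count is not None:
        if rule.count > cand.size:
            raise ValueError(f"scenario {scenario.name!r}: requested "
                             f"{rule.count} reference animals, only "
                             f"{cand.size} candidates")
        ref = np.sort(rng.choice(cand, size=rule.count, replace=False))
    elif rule.fraction is not None:
        k = int(round(rule.fraction * cand.size))
        if k == 0:
            raise ValueError(f"scenario {scenario.name!r}: reference "
                             "fraction selects no animals")
        ref = np.sort(rng.choice(cand, size=k, replace=False))
    else:
        ref = cand
    in_ref = np.zeros(len(pedigree), dtype=bool)
    in_ref[ref] = True
    if scenario.test is not None:
        tcand = scenario.test.candidates(pedigree)
        test = tcand[~in_ref[tcand]]
    else:
        test = np.flatnonzero(~in_ref)
    if test.size == 0:
        raise ValueError(f"scenario {scenario.name!r}: empty test set")
    return ref, test


def descendant_counts(pedigree: Pedigree) -> np.ndarray:
    """Number of pedigree descendants per animal."""
    n = len(pedigree)
    # ancestors-of relation, built top-down; descendant count is its
    # column-sum transpose
    counts = np.zeros(n, dtype=np.int64)
    anc: list[set] = [set() for _ in range(n)]
    for i in range(n):
        s, d = pedigree.sire_idx[i], pedigree.dam_idx[i]
        acc = set()
        for p in (s, d):
            if p >= 0:
                acc.add(int(p))
                acc |= anc[p]
        anc[i] = acc
        for a in acc:
            counts[a] += 1
    return counts


# ---------------------------------------------------------------------------
# Masking
# ---------------------------------------------------------------------------

@dataclass
class MaskedTruth:
    """Bookkeeping for masked genotypes: boolean mask of masked entries and
    the pre-masking truth matrix."""

    masked: np.ndarray   # bool (n_animals, n_markers)
    truth: np.ndarray    # int8, original genotypes

    @property
    def n_masked(self) -> int:
        return int(self.masked.sum())


def mask_genotypes(genotypes: np.ndarray, typed,
                   animal_fraction: float = 1.0,
                   seed: int = 0) -> tuple[np.ndarray, MaskedTruth]:
    """Reduce full-panel test genotypes to a typed subset.

    ``typed`` is either an array of typed column indices (e.g. a low-density
    panel mapped onto the full panel) or a tuple ``("every_nth", N)`` which
    masks every Nth marker (columns N-1, 2N-1, ...) and keeps the rest.
    With ``animal_fraction < 1`` the masking applies to a random (seeded)
    subset of animals only, as in masking every 10th marker in half the
    genotyped cows.
    """
    g = np.asarray(genotypes, dtype=np.int8)
    n, L = g.shape
    if isinstance(typed, tuple) and len(typed) == 2 and typed[0] == "every_nth":
        step = int(typed[1])
        if step < 2:
            raise ValueError("every_nth rule requires n >= 2")
        masked_cols = np.zeros(L, dtype=bool)
        masked_cols[step - 1::step] = True
    else:
        idx = np.asarray(getattr(typed, "indices", typed), dtype=np.int64)
        if idx.size == 0:
            raise ValueError("typed panel is empty")
        if idx.min() < 0 or idx.max() >= L:
            raise ValueError("typed panel indices outside the full panel")
        masked_cols = np.ones(L, dtype=bool)
        masked_cols[idx] = False
    rows = np.ones(n, dtype=bool)
    if animal_fraction < 1.0:
        rng = np.random.default_rng(seed)
        k = int(round(animal_fraction * n))
        rows[:] = False
        rows[rng.choice(n, size=k, replace=False)] = True
    masked = rows[:, None] & masked_cols[None, :]
    out = g.copy()
    out[masked] = MISSING
    return out, MaskedTruth(masked, g.copy())


# ---------------------------------------------------------------------------
# Error statistics
# ---------------------------------------------------------------------------

def _check_pair(truth, imputed):
    t = np.asarray(truth)
    m = np.asarray(imputed)
    if t.shape != m.shape:
        raise ValueError("truth and imputed shapes differ")
    if np.any(t == MISSING) or np.any(m == MISSING):
        raise ValueError("error rates are defined on non-missing genotypes; "
                         "restrict to the masked set with known truth first")
    return t.astype(np.int64), m.astype(np.int64)


def allelic_error_rate(truth, imputed) -> float:
    """100 x incorrectly predicted alleles / total imputed alleles. The
    per-genotype allele mismatch is |B-count(truth) - B-count(imputed)|."""
    t, m = _check_pair(truth, imputed)
    return 100.0 * np.abs(t - m).sum() / (2.0 * t.size)


def genotypic_error_rate(truth, imputed) -> float:
    """100 x fraction of genotypes whose best-guess differs from truth."""
    t, m = _check_pair(truth, imputed)
    return 100.0 * np.count_nonzero(t != m) / t.size


@dataclass
class ErrorReport:
    """Overall and stratified imputation error rates for one scenario."""

    allelic_error: float
    genotypic_error: float
    n_genotypes: int
    per_animal: pd.DataFrame
    per_marker: pd.DataFrame
    per_chromosome: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"stratum": "overall",
                              "allelic_error": self.allelic_error,
                              "genotypic_error": self.genotypic_error,
                              "n_genotypes": self.n_genotypes}])


def error_report(result_best_guess: np.ndarray, store: MaskedTruth,
                 animal_ids=None, chrom=None) -> ErrorReport:
    """Score imputed best-guess genotypes against the masked truth.

    Masked entries whose truth is itself missing (simulated assay dropouts)
    are excluded from all denominators.
    """
    bg = np.asarray(result_best_guess, dtype=np.int64)
    truth = store.truth.astype(np.int64)
    scored = store.masked & (store.truth != MISSING)
    if not scored.any():
        raise ValueError("no masked genotypes with known truth to score")
    diff = np.where(scored, np.abs(truth - bg), 0)
    mism = np.where(scored, truth != bg, False)
    n_per_animal = scored.sum(axis=1)
    n_per_marker = scored.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pa = pd.DataFrame({
            "animal": (animal_ids if animal_ids is not None
                       else np.arange(bg.shape[0])),
            "n_genotypes": n_per_animal,
            "allelic_error": 100.0 * diff.sum(axis=1) /
            (2.0 * np.maximum(n_per_animal, 1)),
            "genotypic_error": 100.0 * mism.sum(axis=1) /
            np.maximum(n_per_animal, 1),
        })
        pm = pd.DataFrame({
            "marker": np.arange(bg.shape[1]),
            "n_genotypes": n_per_marker,
            "allelic_error": 100.0 * diff.sum(axis=0) /
            (2.0 * np.maximum(n_per_marker, 1)),
            "genotypic_error": 100.0 * mism.sum(axis=0) /
            np.maximum(n_per_marker, 1),
        })
    pc = None
    if chrom is not None:
        chrom = np.asarray(chrom)
        pm["chrom"] = chrom
        grp = pm[n_per_marker > 0].groupby("chrom", sort=False)
        pc = grp.apply(lambda d: pd.Series({
            "n_genotypes": d["n_genotypes"].sum(),
            "allelic_error": np.average(d["allelic_error"],
                                        weights=d["n_genotypes"]),
            "genotypic_error": np.average(d["genotypic_error"],
                                          weights=d["n_genotypes"]),
        }), include_groups=False).reset_index()
    n = int(scored.sum())
    return ErrorReport(
        allelic_error=100.0 * diff.sum() / (2.0 * n),
        genotypic_error=100.0 * mism.sum() / n,
        n_genotypes=n, per_animal=pa, per_marker=pm, per_chromosome=pc)


# ---------------------------------------------------------------------------
# Pedigree kinship
# ---------------------------------------------------------------------------

def pedigree_kinship(pedigree: Pedigree) -> np.ndarray:
    """Kinship coefficients by the recursive (tabular) method.

    f(i, j) = 0.5*(f(sire_i, j) + f(dam_i, j)) for i later than j, with
    unknown parents contributing 0, and f(i, i) = 0.5*(1 + f(sire_i,
    dam_i)). Requires (and the Pedigree class guarantees) topological
    order, which excludes ancestry cycles.
    """
    n = len(pedigree)
    f = np.zeros((n, n))
    s, d = pedigree.sire_idx, pedigree.dam_idx
    for i in range(n):
        fs = f[s[i], :i] if s[i] >= 0 else 0.0
        fd = f[d[i], :i] if d[i] >= 0 else 0.0
        if i:
            row = 0.5 * (fs + fd) if (s[i] >= 0 or d[i] >= 0) else np.zeros(i)
            f[i, :i] = row
            f[:i, i] = row
        fsd = f[s[i], d[i]] if (s[i] >= 0 and d[i] >= 0) else 0.0
        f[i, i] = 0.5 * (1.0 + fsd)
    return f


def max_kinship_to_reference(kinship: np.ndarray, reference_idx,
                             test_idx) -> np.ndarray:
    """Highest kinship of each test animal with any reference animal."""
    k = np.asarray(kinship)
    return k[np.ix_(np.asarray(test_idx), np.asarray(reference_idx))].max(axis=1)


def stratify_error_by_kinship(per_animal_error: np.ndarray,
                              kinship: np.ndarray, reference_idx, test_idx,
                              bins=DEFAULT_KINSHIP_BINS) -> pd.DataFrame:
    """Mean allelic error of test animals binned by their maximum pedigree
    kinship to the reference set. Default bins are the standard intervals
    0-0.01, 0.01-0.1, 0.1-0.2 and 0.2-0.4; empty bins are reported with
    count 0 and no mean."""
    err = np.asarray(per_animal_error, dtype=np.float64)
    test_idx = np.asarray(test_idx)
    if len(err) != len(test_idx):
        raise ValueError("per_animal_error must align with test_idx")
    maxk = max_kinship_to_reference(kinship, reference_idx, test_idx)
    edges = np.asarray(bins, dtype=np.float64)
    if maxk.max() > edges[-1] + 1e-12 or maxk.min() < edges[0] - 1e-12:
        raise ValueError("kinship values fall outside the bin range; widen "
                         "the bins")
    # first bin is closed on the left so kinship 0 is included
    which = np.clip(np.searchsorted(edges, maxk, side="left") - 1, 0,
                    len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = which == b
        rows.append({
            "bin_low": edges[b], "bin_high": edges[b + 1],
            "n_animals": int(sel.sum()),
            "mean_allelic_error": float(err[sel].mean()) if sel.any()
            else np.nan,
        })
    return pd.DataFrame(rows)


def sire_in_reference_comparison(per_animal_error: np.ndarray,
                                 pedigree: Pedigree, reference_idx,
                                 test_idx) -> pd.DataFrame:
    """Mean allelic error of test animals whose sire is in the reference
    set versus those whose sire is not (unknown sires count as absent)."""
    err = np.asarray(per_animal_error, dtype=np.float64)
    test_idx = np.asarray(test_idx)
    in_ref = np.zeros(len(pedigree), dtype=bool)
    in_ref[np.asarray(reference_idx)] = True
    sires = pedigree.sire_idx[test_idx]
    with_sire = (sires >= 0) & in_ref[np.clip(sires, 0, None)]
    rows = []
    for label, sel in (("sire_in_reference", with_sire),
                       ("sire_not_in_reference", ~with_sire)):
        rows.append({
            "group": label, "n_animals": int(sel.sum()),
            "mean_allelic_error": float(err[sel].mean()) if sel.any()
            else np.nan,
        })
    return pd.DataFrame(rows)
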