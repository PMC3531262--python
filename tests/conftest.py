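"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the implementation code paths they
check: brute-force path enumeration for the HMM, a dense generic linear
solve for the mixed-model equations, a naive re-scan for panel thinning,
and single-locus gene-dropping for kinship.
"""

from itertools import product

import numpy as np
import pytest

from herdimpute import (GenomeMap, gene_drop, simulate_founder_haplotypes,
                        simulate_pedigree)


# ---------------------------------------------------------------------------
# Population builder
# ---------------------------------------------------------------------------

def make_population(n_founders=40, n_generations=3, n_chrom=2,
                    markers_per_chrom=100, sires_per_generation=4,
                    offspring_per_generation=None, seed=0,
                    mosaic_switch_rate=1.0, n_ancestral=20):
    gmap = GenomeMap.uniform(n_chrom, markers_per_chrom)
    ped = simulate_pedigree(
        n_founders, n_generations,
        {"sires_per_generation": sires_per_generation,
         "offspring_per_generation": offspring_per_generation or n_founders},
        seed=seed)
    _, founders = simulate_founder_haplotypes(
        gmap, None, n_ancestral=n_ancestral,
        mosaic_switch_rate=mosaic_switch_rate,
        n_founders=int(np.sum(ped.is_founder)), seed=seed + 1)
    return gene_drop(ped, founders, gmap, seed=seed + 2)


@pytest.fixture(scope="session")
def small_population():
    """120-animal, 2x100-marker population reused across read-only tests."""
    return make_population(n_founders=40, n_generations=3, seed=11)


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def brute_force_posteriors(gt, H, rho, emis):
    """Genotype posteriors by exhaustive enumeration of all K^(2L) ordered
    reference-pair state paths of the copying model."""
    K, L = H.shape
    gp = np.zeros((L, 3))
    states = list(product(range(K), repeat=2))

    def trans(r, a, b):
        return (1 - r) * (a == b) + r / K

    total = 0.0
    for path in product(states, repeat=L):
        p = 1.0 / (K * K)
        for l in range(1, L):
            r = rho[l - 1]
            p *= trans(r, path[l - 1][0], path[l][0]) * \
                trans(r, path[l - 1][1], path[l][1])
        for l in range(L):
            if gt[l] >= 0:
                s = H[path[l][0], l] + H[path[l][1], l]
                p *= emis[s, gt[l]]
        total += p
        for l in range(L):
            s = H[path[l][0], l] + H[path[l][1], l]
            gp[l] += p * emis[s]
    return gp / total


def dense_mme_solve(y, X, rel, lam):
    """Generic dense solve of the full (1 + N_SNP) weighted ridge system."""
    w = np.clip(rel, 0.01, 0.99)
    w = w / (1.0 - w)
    n, p = X.shape
    Z = np.column_stack([np.ones(n), X])
    C = Z.T @ (Z * w[:, None])
    C[1:, 1:] += lam * np.eye(p)
    sol = np.linalg.solve(C, Z.T @ (w * y))
    return sol[0], sol[1:]


def naive_thin(bp, maf, target, chrom=None):
    """Literal re-scan implementation of the thinning rule: repeatedly find
    the globally smallest within-chromosome adjacent interval (ties: first
    chromosome, smallest left position) and remove the lower-MAF member
    (ties: the right member)."""
    bp = list(map(int, bp))
    maf = list(map(float, maf))
    n = len(bp)
    chrom = list(chrom) if chrom is not None else [0] * n
    order = []
    for c in chrom:
        if c not in order:
            order.append(c)
    crank = [order.index(c) for c in chrom]
    alive = list(range(n))
    while len(alive) > target:
        best = None
        for a, b in zip(alive[:-1], alive[1:]):
            if crank[a] != crank[b]:
                continue
            key = (bp[b] - bp[a], crank[a], bp[a])
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        drop = b if maf[b] <= maf[a] else a
        alive.remove(drop)
    return np.array(alive)


def gene_drop_kinship(pedigree, n_replicates=100_000, seed=0):
    """Monte-Carlo kinship: drop uniquely labelled founder alleles through
    the pedigree (single locus, no recombination) and count identity by
    descent between randomly drawn allele pairs."""
    rng = np.random.default_rng(seed)
    n = len(pedigree)
    lab = np.zeros((n_replicates, n, 2), dtype=np.int64)
    for i in range(n):
        s, d = pedigree.sire_idx[i], pedigree.dam_idx[i]
        if s < 0 and d < 0:
            lab[:, i, 0] = 2 * i
            lab[:, i, 1] = 2 * i + 1
        else:
            pick_s = rng.integers(2, size=n_replicates)
            pick_d = rng.integers(2, size=n_replicates)
            lab[:, i, 0] = lab[np.arange(n_replicates), s, pick_s]
            lab[:, i, 1] = lab[np.arange(n_replicates), d, pick_d]
    f_hat = np.zeros((n, n))
    f_se = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            m = np.zeros(n_replicates)
            for a in range(2):
                for b in range(2):
                    m += lab[:, i, a] == lab[:, j, b]
            m /= 4.0
            f_hat[i, j] = f_hat[j, i] = m.mean()
            f_se[i, j] = f_se[j, i] = m.std() / np.sqrt(n_replicates)
    return f_hat, f_se
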