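"""Population-based genotype imputation with a diploid haplotype-copying HMM.

The model is the classic Li-Stephens copying process: each of a test
animal's two chromosomes is an imperfect mosaic of the K phased reference
haplotypes. Along the genome each copied haplotype switches template with
probability ``rho_j = 1 - exp(-4*Ne*c_j/K)`` per interval of genetic length
``c_j`` Morgans (Ne is the effective population size, default 100 as is
typical for Holstein-Friesian cattle). At typed loci the unphased genotype
is emitted through a per-allele error channel with rate ``epsilon``;
untyped or missing loci are uninformative. Forward-backward over the K^2
ordered-pair states yields a posterior probability triple (p_AA, p_AB,
p_BB) at every locus, from which best-guess genotypes (posterior argmax)
and B-allele dosages (p_AB + 2*p_BB) follow.

This is a generic copying HMM, not a reimplementation of any particular
imputation program: those tools add phasing heuristics and haplotype
clustering that are out of scope here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from ._kernels import diploid_forward_backward
from .simdata import MISSING

__all__ = [
    "HmmConfig", "ReferencePanel", "ImputationResult",
    "HaplotypeCopyingImputer", "transition_rates", "emission_matrix",
    "best_guess", "dosage", "impute_diploid", "impute_tiered",
    "sampling_baseline",
]


@dataclass(frozen=True)
class HmmConfig:
    """Copying-model parameters: effective population size ``ne`` (scales
    switch rates), per-allele emission error ``error_rate``, a floor on the
    per-interval switch probability, and a cap on reference haplotypes used
    per animal (cost is O(L*K^2))."""

    ne: int = 100
    error_rate: float = 0.005
    min_switch: float = 1e-8
    max_reference_haplotypes: int = 400

    def __post_init__(self):
        if self.ne <= 0:
            raise ValueError("ne must be positive")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if self.max_reference_haplotypes < 2:
            raise ValueError("max_reference_haplotypes must be >= 2")


@dataclass(frozen=True)
class ReferencePanel:
    """Phased reference haplotypes (K x L binary matrix) with marker ids."""

    haplotypes: np.ndarray
    marker_ids: np.ndarray

    def __post_init__(self):
        h = np.asarray(self.haplotypes, dtype=np.uint8)
        if h.ndim != 2:
            raise ValueError("haplotypes must be 2-D (K x L)")
        if h.shape[0] < 2:
            raise ValueError("reference needs at least K=2 haplotypes")
        if not np.isin(h, [0, 1]).all():
            raise ValueError("haplotypes must be binary")
        ids = np.asarray(self.marker_ids)
        if len(ids) != h.shape[1]:
            raise ValueError("marker_ids must match haplotype columns")
        object.__setattr__(self, "haplotypes", h)
        object.__setattr__(self, "marker_ids", ids)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]


@dataclass
class ImputationResult:
    """Per-locus genotype posteriors, best-guess genotypes (posterior
    argmax, ties toward the lower B-allele count) and B-allele dosages."""

    posteriors: np.ndarray       # (n_animals, L, 3)
    best_guess: np.ndarray       # (n_animals, L) int8
    dosage: np.ndarray           # (n_animals, L) float64
    marker_ids: np.ndarray | None = None


def transition_rates(c: np.ndarray, K: int, ne: int = 100,
                     min_switch: float = 1e-8) -> np.ndarray:
    """Per-interval switch probabilities rho_j = 1 - exp(-4*Ne*c_j/K).

    ``c`` is genetic interval length in Morgans (``inf`` allowed, e.g. at
    chromosome boundaries, giving rho = 1 i.e. an independent restart).
    Results are floored at ``min_switch``.
    """
    c = np.asarray(c, dtype=np.float64)
    if np.any(c < 0):
        raise ValueError("genetic distances must be non-negative")
    if K < 2:
        raise ValueError("K must be >= 2")
    rho = -np.expm1(-4.0 * ne * c / K)
    return np.clip(rho, min_switch, 1.0)


def emission_matrix(error_rate: float) -> np.ndarray:
    """P(observed genotype g | copied allele sum s) under independent
    per-allele flips with probability ``error_rate``. Rows index s=0,1,2;
    columns index g."""
    e = float(error_rate)
    q = 1.0 - e
    return np.array([
        [q * q, 2 * q * e, e * e],
        [q * e, q * q + e * e, q * e],
        [e * e, 2 * q * e, q * q],
    ])


def _validate_triples(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=np.float64)
    if p.shape[-1] != 3:
        raise ValueError("posterior triples must have last dimension 3")
    if np.any(p < -1e-12):
        raise ValueError("posterior probabilities must be non-negative")
    if np.any(np.abs(p.sum(axis=-1) - 1.0) > 1e-6):
        raise ValueError("posterior triples must sum to 1")
    return p


def best_guess(posterior: np.ndarray) -> np.ndarray:
    """Most likely genotype per triple; ties resolve toward the lower
    B-allele count (argmax of (p_AA, p_AB, p_BB) takes the first max)."""
    p = _validate_triples(posterior)
    return np.argmax(p, axis=-1).astype(np.int8)


def dosage(posterior: np.ndarray) -> np.ndarray:
    """Expected B-allele count p_AB + 2*p_BB per triple."""
    p = _validate_triples(posterior)
    return p[..., 1] + 2.0 * p[..., 2]


class HaplotypeCopyingImputer(BaseEstimator):
    """Diploid Li-Stephens-style genotype imputer.

    Fit on a phased reference haplotype matrix, then predict genotype
    posteriors for unphased test genotype rows (0/1/2 with -1 at
    untyped/missing loci, columns aligned to the reference markers).

    Parameters
    ----------
    ne : effective population size scaling switch rates (default 100).
    error_rate : per-allele emission error probability (default 0.005).
    min_switch : floor on the per-interval switch probability.
    max_reference_haplotypes : per-animal cap on reference haplotypes; when
        the reference exceeds it, the haplotypes closest to the animal by
        allele-sharing at its typed loci are used.
    spacing_cm : genetic spacing assumed when ``fit`` is not given explicit
        genetic positions (uniform grid, default 0.05 cM per interval).
    """

    def __init__(self, ne: int = 100, error_rate: float = 0.005,
                 min_switch: float = 1e-8,
                 max_reference_haplotypes: int = 400,
                 spacing_cm: float = 0.05):
        self.ne = ne
        self.error_rate = error_rate
        self.min_switch = min_switch
        self.max_reference_haplotypes = max_reference_haplotypes
        self.spacing_cm = spacing_cm

    # ------------------------------------------------------------------
    def fit(self, X, y=None, *, genetic_pos_cm=None, chrom=None,
            marker_ids=None):
        """Store the phased reference panel.

        X : (K, L) binary haplotype matrix (or a ReferencePanel).
        genetic_pos_cm : optional per-marker genetic position in cM.
        chrom : optional per-marker chromosome labels; intervals across a
            chromosome boundary become independent restarts.
        """
        HmmConfig(self.ne, self.error_rate, self.min_switch,
                  max(self.max_reference_haplotypes, 2))
        if isinstance(X, ReferencePanel):
            marker_ids = X.marker_ids
            X = X.haplotypes
        H = np.asarray(X, dtype=np.uint8)
        if H.ndim != 2 or H.shape[0] < 2:
            raise ValueError("reference must be a (K>=2, L) matrix")
        if not np.isin(H, [0, 1]).all():
            raise ValueError("reference haplotypes must be binary")
        L = H.shape[1]
        if genetic_pos_cm is None:
            genetic_pos_cm = np.arange(L) * float(self.spacing_cm)
        pos = np.asarray(genetic_pos_cm, dtype=np.float64)
        if len(pos) != L:
            raise ValueError("genetic positions must match marker count")
        c = np.diff(pos) / 100.0  # cM -> Morgans
        if chrom is not None:
            chrom = np.asarray(chrom)
            if len(chrom) != L:
                raise ValueError("chrom must match marker count")
            c[chrom[:-1] != chrom[1:]] = np.inf
        if np.any(c < 0):
            raise ValueError("genetic positions must be non-decreasing "
                             "within chromosomes")
        self.reference_ = H
        self.intervals_morgans_ = c
        self.marker_ids_ = (np.asarray(marker_ids) if marker_ids is not None
                            else None)
        self.n_markers_ = L
        return self

    # ------------------------------------------------------------------
    def _check_test(self, G) -> np.ndarray:
        if not hasattr(self, "reference_"):
            raise ValueError("imputer is not fitted; call fit first")
        G = np.asarray(G)
        if G.ndim == 1:
            G = G[None, :]
        if G.shape[1] != self.n_markers_:
            raise ValueError(
                f"test genotypes have {G.shape[1]} markers; reference has "
                f"{self.n_markers_} (typed loci must be a subset of the "
                "reference markers, aligned on the reference grid)")
        G = G.astype(np.int8)
        if not np.isin(G, [MISSING, 0, 1, 2]).all():
            raise ValueError("test genotype codes must be 0/1/2 or -1")
        return G

    def _select_reference(self, g: np.ndarray) -> np.ndarray:
        """Subsample reference haplotypes for one animal when K exceeds the
        cap: keep those sharing the most alleles with the animal's typed
        genotypes (expected-agreement score)."""
        H = self.reference_
        K = H.shape[0]
        cap = int(self.max_reference_haplotypes)
        if K <= cap:
            return H
        typed = g != MISSING
        if not typed.any():
            return H[:cap]
        gt = g[typed].astype(np.float64) / 2.0
        ht = H[:, typed].astype(np.float64)
        score = ht @ gt + (1.0 - ht) @ (1.0 - gt)
        order = np.argsort(-score, kind="stable")[:cap]
        return H[np.sort(order)]

    def predict_proba(self, G) -> np.ndarray:
        """Genotype posterior triples, shape (n_animals, L, 3)."""
        G = self._check_test(G)
        emis = emission_matrix(self.error_rate)
        n, L = G.shape
        out = np.empty((n, L, 3))
        for a in range(n):
            H = self._select_reference(G[a])
            K = H.shape[0]
            rho = transition_rates(self.intervals_morgans_, K, self.ne,
                                   self.min_switch)
            dtype = np.float64 if L * K * K <= 60_000_000 else np.float32
            fstore = np.empty((L, K, K), dtype=dtype)
            gp, _ = diploid_forward_backward(G[a], H, rho, emis, fstore)
            out[a] = gp
        return out

    def predict(self, G) -> np.ndarray:
        """Best-guess genotypes (posterior argmax), shape (n_animals, L)."""
        return best_guess(self.predict_proba(G))

    def predict_dosage(self, G) -> np.ndarray:
        return dosage(self.predict_proba(G))

    def impute(self, G) -> ImputationResult:
        """Full result: posteriors, best-guess and dosage in one pass."""
        p = self.predict_proba(G)
        return ImputationResult(p, best_guess(p), dosage(p),
                                self.marker_ids_)

    def predict_haplotypes(self, G) -> np.ndarray:
        """Pseudo-phased haplotypes from the per-locus max-posterior state
        path, reconciled with the observed genotype at typed loci (observed
        homozygotes force both alleles; observed heterozygotes keep the
        copied phase when consistent, else default to 0|1).

        Shape (n_animals, 2, L). Used to build pseudo-reference haplotypes
        in the tiered framework.
        """
        G = self._check_test(G)
        emis = emission_matrix(self.error_rate)
        n, L = G.shape
        out = np.empty((n, 2, L), dtype=np.uint8)
        for a in range(n):
            H = self._select_reference(G[a])
            K = H.shape[0]
            rho = transition_rates(self.intervals_morgans_, K, self.ne,
                                   self.min_switch)
            dtype = np.float64 if L * K * K <= 60_000_000 else np.float32
            fstore = np.empty((L, K, K), dtype=dtype)
            _, path = diploid_forward_backward(G[a], H, rho, emis, fstore)
            cols = np.arange(L)
            h0 = H[path[:, 0], cols]
            h1 = H[path[:, 1], cols]
            g = G[a]
            hom = (g == 0) | (g == 2)
            h0 = np.where(hom, (g // 2).clip(0, 1).astype(np.uint8), h0)
            h1 = np.where(hom, (g // 2).clip(0, 1).astype(np.uint8), h1)
            het_bad = (g == 1) & (h0 + h1 != 1)
            h0 = np.where(het_bad, 0, h0).astype(np.uint8)
            h1 = np.where(het_bad, 1, h1).astype(np.uint8)
            out[a, 0] = h0
            out[a, 1] = h1
        return out


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def _make_imputer(config: HmmConfig | None,
                  genetic_pos_cm, chrom) -> HaplotypeCopyingImputer:
    cfg = config or HmmConfig()
    imp = HaplotypeCopyingImputer(
        ne=cfg.ne, error_rate=cfg.error_rate, min_switch=cfg.min_switch,
        max_reference_haplotypes=cfg.max_reference_haplotypes)
    imp._fit_kwargs = dict(genetic_pos_cm=genetic_pos_cm, chrom=chrom)
    return imp


def impute_diploid(test_genotypes: np.ndarray, reference,
                   config: HmmConfig | None = None,
                   genetic_pos_cm=None, chrom=None) -> ImputationResult:
    """Impute test animals against a phased reference panel (2-tier run).

    ``test_genotypes`` is (n, L) coded 0/1/2 with -1 at untyped/missing
    loci, columns aligned to the reference markers.
    """
    imp = _make_imputer(config, genetic_pos_cm, chrom)
    imp.fit(reference, **imp._fit_kwargs)
    return imp.impute(test_genotypes)


def impute_tiered(test_genotypes: np.ndarray, mid_reference: np.ndarray,
                  top_reference, config: HmmConfig | None = None,
                  genetic_pos_cm=None, chrom=None) -> ImputationResult:
    """3-tier imputation: a medium-density cohort is first imputed to high
    density against the (small) top-tier reference, its pseudo-phased
    haplotypes are appended to the reference, and the low-density test
    animals are then imputed against the enlarged panel.

    ``mid_reference`` rows are genotypes on the full high-density grid with
    -1 outside the medium panel; an empty mid tier degenerates to a plain
    2-tier run. Typed loci of the test set must be a subset of the mid
    tier's typed loci (panel nesting low <= medium <= high).
    """
    imp = _make_imputer(config, genetic_pos_cm, chrom)
    imp.fit(top_reference, **imp._fit_kwargs)
    mid = np.asarray(mid_reference)
    if mid.size == 0:
        return imp.impute(test_genotypes)
    test = np.asarray(test_genotypes)
    typed_test = (test != MISSING).any(axis=0)
    typed_mid = (mid != MISSING).any(axis=0)
    if np.any(typed_test & ~typed_mid):
        raise ValueError("panel nesting violated: test typed loci must be a "
                         "subset of the mid-tier typed loci")
    pseudo = imp.predict_haplotypes(mid)
    augmented = np.vstack([imp.reference_,
                           pseudo.reshape(-1, pseudo.shape[2])])
    imp.fit(augmented, **imp._fit_kwargs)
    return imp.impute(test_genotypes)


def sampling_baseline(masked: np.ndarray, ref_freq: np.ndarray,
                      seed: int = 0) -> np.ndarray:
    """Naive baseline: draw each masked genotype as two independent alleles
    at the reference B-allele frequency (a Hardy-Weinberg draw). Entries
    not masked are returned as missing.
    """
    masked = np.asarray(masked, dtype=bool)
    p = np.asarray(ref_freq, dtype=np.float64)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequencies must be in [0, 1]")
    if masked.ndim != 2 or len(p) != masked.shape[1]:
        raise ValueError("ref_freq must align with masked columns")
    rng = np.random.default_rng(seed)
    draws = rng.binomial(2, np.broadcast_to(p, masked.shape)).astype(np.int8)
    return np.where(masked, draws, np.int8(MISSING))
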