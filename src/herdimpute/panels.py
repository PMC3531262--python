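"""SNP panel construction: QC filtering, even-spacing thinning, intersection.

A :class:`SnpPanel` is an ordered marker subset of a genome map, standing in
for a commercial chip (3K/7K/50K/800K roles). Low-density panels are derived
from denser ones by iterative thinning: repeatedly find the closest adjacent
marker pair (within chromosomes) and drop the lower-MAF member, until the
target count is reached.

QC mirrors common chip pipelines: Mendelian-inconsistent genotypes are set
missing first (offspring call), then markers are filtered on MAF, call rate
and a Hardy-Weinberg chi-square test computed on the cleaned matrix.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simdata import MISSING, GenomeMap, Pedigree


@dataclass(frozen=True)
class SnpPanel:
    """Named ordered marker subset of a genome map."""

    name: str
    indices: np.ndarray          # positions in the parent map, sorted
    marker_ids: np.ndarray

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=np.int64)
        ids = np.asarray(self.marker_ids)
        if len(idx) != len(ids):
            raise ValueError("indices and marker_ids length mismatch")
        if len(idx) and np.any(np.diff(idx) <= 0):
            raise ValueError("panel indices must be strictly increasing "
                             "(map order)")
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "marker_ids", ids)

    def __len__(self) -> int:
        return len(self.indices)

    @classmethod
    def from_indices(cls, gmap: GenomeMap, name: str,
                     indices: np.ndarray) -> "SnpPanel":
        idx = np.unique(np.asarray(indices, dtype=np.int64))
        if len(idx) and (idx[0] < 0 or idx[-1] >= gmap.n_markers):
            raise ValueError("panel indices outside map")
        return cls(name, idx, gmap.marker_id[idx])

    @classmethod
    def from_ids(cls, gmap: GenomeMap, name: str, ids) -> "SnpPanel":
        lookup = {m: i for i, m in enumerate(gmap.marker_id)}
        missing = [m for m in ids if m not in lookup]
        if missing:
            raise ValueError(f"marker ids not in map: {missing[:5]}")
        return cls.from_indices(gmap, name, np.array([lookup[m] for m in ids]))

    @classmethod
    def full(cls, gmap: GenomeMap, name: str = "full") -> "SnpPanel":
        return cls(name, np.arange(gmap.n_markers), gmap.marker_id.copy())


@dataclass(frozen=True)
class QcThresholds:
    """Marker QC thresholds; a marker passes if it is strictly above all
    three (MAF > maf_min, call rate > call_rate_min, HWE P > hwe_p_min)."""

    maf_min: float = 0.01
    call_rate_min: float = 0.9
    hwe_p_min: float = 1e-4

    def __post_init__(self):
        for v, name in ((self.maf_min, "maf_min"),
                        (self.call_rate_min, "call_rate_min"),
                        (self.hwe_p_min, "hwe_p_min")):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class QcResult:
    kept: np.ndarray             # surviving column indices into the input
    report: pd.DataFrame
    genotypes: np.ndarray        # cleaned matrix restricted to kept markers
    mendel_masked: int = 0


def mendel_mask(genotypes: np.ndarray, pedigree: Pedigree) -> np.ndarray:
    """Return a copy with Mendelian-inconsistent offspring genotypes set
    missing.

    A genotype (B-allele count) is inconsistent if it falls outside the range
    of allele sums its non-missing parents can transmit: a parent coded 0
    transmits a 0 allele, 2 transmits a 1 allele, 1 transmits either, and a
    missing parent genotype is unconstrained.
    """
    g = np.asarray(genotypes, dtype=np.int8).copy()
    if g.shape[0] != len(pedigree):
        raise ValueError("genotype rows must align with pedigree order")

    def contrib(parent_idx):
        n_mk = g.shape[1]
        lo = np.zeros((g.shape[0], n_mk), dtype=np.int8)
        hi = np.ones((g.shape[0], n_mk), dtype=np.int8)
        has = parent_idx >= 0
        pg = g[np.clip(parent_idx, 0, None)]
        known = has[:, None] & (pg != MISSING)
        lo[known & (pg == 2)] = 1
        hi[known & (pg == 0)] = 0
        return lo, hi

    lo_s, hi_s = contrib(pedigree.sire_idx)
    lo_d, hi_d = contrib(pedigree.dam_idx)
    bad = (g != MISSING) & ((g < lo_s + lo_d) | (g > hi_s + hi_d))
    g[bad] = MISSING
    return g


def hwe_pvalues(genotypes: np.ndarray) -> np.ndarray:
    """Per-marker Hardy-Weinberg chi-square goodness-of-fit P (1 df),
    computed on non-missing genotypes. Monomorphic markers get P = 1."""
    g = np.asarray(genotypes)
    obs = np.stack([(g == k).sum(axis=0) for k in (0, 1, 2)]).astype(float)
    n = obs.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = (2 * obs[0] + obs[1]) / (2 * n)
        exp = np.stack([n * p**2, 2 * n * p * (1 - p), n * (1 - p)**2])
        chi2 = np.where(exp > 0, (obs - exp)**2 / np.where(exp > 0, exp, 1.0),
                        0.0).sum(axis=0)
    pval = stats.chi2.sf(chi2, df=1)
    pval[n == 0] = np.nan
    pval[(p == 0) | (p == 1)] = 1.0
    return pval


def qc_filter(genotypes: np.ndarray,
              thresholds: QcThresholds | None = None,
              pedigree: Pedigree | None = None,
              marker_ids=None) -> QcResult:
    """Filter markers on MAF, call rate and HWE after Mendelian masking.

    Statistics are computed on the Mendelian-masked matrix over all animals
    in the dataset. The report lists per-marker MAF, call rate, HWE P, the
    number of genotypes masked for Mendelian inconsistency, and the failure
    reasons of dropped markers.
    """
    g = np.asarray(genotypes, dtype=np.int8)
    if g.size == 0:
        raise ValueError("empty genotype matrix")
    if not np.isin(g, [MISSING, 0, 1, 2]).all():
        raise ValueError("genotype codes must be 0/1/2 or missing (-1)")
    thresholds = thresholds or QcThresholds()
    n_mk = g.shape[1]
    if marker_ids is None:
        marker_ids = np.array([f"m{j}" for j in range(n_mk)])

    if pedigree is not None:
        cleaned = mendel_mask(g, pedigree)
        masked_per_marker = ((cleaned == MISSING) & (g != MISSING)).sum(axis=0)
    else:
        cleaned = g.copy()
        masked_per_marker = np.zeros(n_mk, dtype=int)

    nonmiss = cleaned != MISSING
    n_called = nonmiss.sum(axis=0)
    call_rate = n_called / g.shape[0]
    with np.errstate(invalid="ignore"):
        p = np.where(n_called > 0,
                     cleaned.clip(min=0).sum(axis=0) / (2 * np.maximum(n_called, 1)),
                     np.nan)
    maf = np.minimum(p, 1 - p)
    hwe_p = hwe_pvalues(np.where(nonmiss, cleaned, MISSING))

    fail_maf = ~(maf > thresholds.maf_min)
    fail_cr = ~(call_rate > thresholds.call_rate_min)
    fail_hwe = ~(hwe_p > thresholds.hwe_p_min)
    keep = ~(fail_maf | fail_cr | fail_hwe)

    reasons = []
    for j in range(n_mk):
        r = []
        if fail_maf[j]:
            r.append("maf")
        if fail_cr[j]:
            r.append("call_rate")
        if fail_hwe[j]:
            r.append("hwe")
        reasons.append(";".join(r))
    report = pd.DataFrame({
        "marker_id": marker_ids,
        "maf": maf,
        "call_rate": call_rate,
        "hwe_p": hwe_p,
        "mendel_masked_count": masked_per_marker,
        "status": np.where(keep, "pass", "fail"),
        "reason": reasons,
    })
    kept = np.flatnonzero(keep)
    return QcResult(kept, report, cleaned[:, kept],
                    int(masked_per_marker.sum()))


# ---------------------------------------------------------------------------
# Iterative even-spacing thinning
# ---------------------------------------------------------------------------

def thin_indices(bp: np.ndarray, maf: np.ndarray, target_count: int,
                 chrom: np.ndarray | None = None) -> np.ndarray:
    """Iteratively thin markers to ``target_count`` for even spacing.

    Each iteration finds the globally smallest adjacent interval (pairs are
    formed within chromosomes only) and removes the lower-MAF member of that
    pair. Ties: among equal smallest intervals, the pair on the earliest
    chromosome with the smallest left position wins; within a pair with
    equal MAF, the right member is removed. Returns the indices of surviving
    markers, in input order.
    """
    bp = np.asarray(bp, dtype=np.int64)
    maf = np.asarray(maf, dtype=np.float64)
    n = len(bp)
    if target_count <= 0:
        raise ValueError("target_count must be positive")
    if target_count > n:
        raise ValueError("target_count exceeds number of markers")
    if len(maf) != n:
        raise ValueError("bp and maf length mismatch")
    if chrom is None:
        chrom = np.zeros(n, dtype=np.int64)
    # rank chromosomes by order of appearance so ties resolve deterministically
    order, rank = [], {}
    for c in chrom:
        if c not in rank:
            rank[c] = len(order)
            order.append(c)
    crank = np.array([rank[c] for c in chrom])
    for c in order:
        sel = crank == rank[c]
        if np.any(np.diff(bp[sel]) <= 0):
            raise ValueError("positions must be strictly increasing within "
                             "chromosome")

    # doubly-linked list over surviving markers within each chromosome,
    # plus a lazily invalidated heap of adjacent gaps
    nxt = np.full(n, -1, dtype=np.int64)
    prv = np.full(n, -1, dtype=np.int64)
    heap: list[tuple] = []
    for c in order:
        idx = np.flatnonzero(crank == rank[c])
        for a, b in zip(idx[:-1], idx[1:]):
            nxt[a], prv[b] = b, a
            heapq.heappush(heap, (int(bp[b] - bp[a]), rank[c], int(bp[a]),
                                  int(a), int(b)))
    if target_count < len(order):
        raise ValueError("target_count below one marker per chromosome; "
                         "the within-chromosome pair rule cannot remove a "
                         "chromosome's last marker")
    alive = np.ones(n, dtype=bool)
    n_alive = n
    while n_alive > target_count:
        gap, cr, lpos, a, b = heapq.heappop(heap)
        if not (alive[a] and alive[b] and nxt[a] == b):
            continue  # stale entry
        drop = b if maf[b] <= maf[a] else a
        alive[drop] = False
        n_alive -= 1
        left, right = prv[drop], nxt[drop]
        if left >= 0:
            nxt[left] = right
        if right >= 0:
            prv[right] = left
        if left >= 0 and right >= 0:
            heapq.heappush(heap, (int(bp[right] - bp[left]), int(crank[drop]),
                                  int(bp[left]), int(left), int(right)))
    return np.flatnonzero(alive)


def thin_evenly(gmap: GenomeMap, maf: np.ndarray, target_count: int,
                source: SnpPanel | None = None,
                name: str | None = None) -> SnpPanel:
    """Thin a panel (default: the full map) to ``target_count`` markers by
    the iterative smallest-interval / lower-MAF rule. ``maf`` is per marker
    of the source panel."""
    src = source or SnpPanel.full(gmap)
    maf = np.asarray(maf, dtype=np.float64)
    if len(maf) != len(src):
        raise ValueError("maf must align with the source panel")
    keep_local = thin_indices(gmap.bp[src.indices], maf, target_count,
                              gmap.chrom[src.indices])
    idx = src.indices[keep_local]
    return SnpPanel(name or f"{src.name}_thin{target_count}", idx,
                    gmap.marker_id[idx])


def intersect_panels(panel_a: SnpPanel, panel_b: SnpPanel,
                     name: str | None = None) -> SnpPanel:
    """Markers present on both panels, in map order. An empty intersection
    is allowed but warned about."""
    common = np.intersect1d(panel_a.indices, panel_b.indices)
    if len(common) == 0:
        warnings.warn(f"panels {panel_a.name!r} and {panel_b.name!r} share "
                      "no markers", stacklevel=2)
    mask = np.isin(panel_a.indices, common)
    return SnpPanel(name or f"{panel_a.name}&{panel_b.name}",
                    panel_a.indices[mask], panel_a.marker_ids[mask])


def panel_maf(genotypes: np.ndarray) -> np.ndarray:
    """Observed MAF per column of a 0/1/2/missing matrix."""
    g = np.asarray(genotypes)
    nonmiss = g != MISSING
    n = np.maximum(nonmiss.sum(axis=0), 1)
    p = np.where(nonmiss, g, 0).sum(axis=0) / (2 * n)
    return np.minimum(p, 1 - p)
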