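"""Numba kernels for the diploid haplotype-copying HMM.

The hidden state at each marker is an ordered pair (a, b) of reference
haplotypes. Per-haplotype transitions are independent with switch
probability rho per interval (a switch re-draws the haplotype uniformly, so
T(a -> a') = (1-rho)*[a == a'] + rho/K), which lets the K^2-state transition
be applied in O(K^2) via row/column sums instead of O(K^4).

Forward variables are rescaled to sum to one at every locus, so the
recursion cannot underflow regardless of chromosome length.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _apply_transition(F, rho, K, out):
    a = 1.0 - rho
    b = rho / K
    tot = 0.0
    rowsum = np.zeros(K)
    colsum = np.zeros(K)
    for i in range(K):
        for j in range(K):
            v = F[i, j]
            rowsum[i] += v
            colsum[j] += v
            tot += v
    aa = a * a
    ab = a * b
    bb = b * b * tot
    for i in range(K):
        ri = ab * rowsum[i]
        for j in range(K):
            out[i, j] = aa * F[i, j] + ri + ab * colsum[j] + bb


@njit(cache=True)
def _emit_and_norm(F, H, l, g, emis, K):
    """Multiply F elementwise by the genotype emission at locus l (no-op for
    missing g) and normalise to sum 1. Returns the pre-normalisation sum."""
    s = 0.0
    if g >= 0:
        for i in range(K):
            hi = H[i, l]
            for j in range(K):
                F[i, j] *= emis[hi + H[j, l], g]
                s += F[i, j]
    else:
        for i in range(K):
            for j in range(K):
                s += F[i, j]
    if s > 0.0:
        inv = 1.0 / s
        for i in range(K):
            for j in range(K):
                F[i, j] *= inv
    return s


@njit(cache=True)
def diploid_forward_backward(gt, H, rho, emis, fstore):
    """Posterior genotype probabilities and max-posterior state path.

    Parameters
    ----------
    gt : (L,) int8, observed genotypes, -1 for missing/untyped
    H : (K, L) uint8, phased reference haplotypes
    rho : (L-1,) float64, per-interval switch probability
    emis : (3, 3) float64, emis[s, g] = P(observe g | copied allele sum s)
    fstore : (L, K, K) float array, scratch for scaled forward matrices
             (float32 acceptable; recursion runs in float64)

    Returns
    -------
    gp : (L, 3) float64 genotype posteriors (rows sum to 1)
    path : (L, 2) int32 per-locus argmax ordered state
    """
    K, L = H.shape
    gp = np.zeros((L, 3))
    path = np.zeros((L, 2), dtype=np.int32)

    F = np.full((K, K), 1.0 / (K * K))
    _emit_and_norm(F, H, 0, gt[0], emis, K)
    for i in range(K):
        for j in range(K):
            fstore[0, i, j] = F[i, j]
    tmp = np.zeros((K, K))
    for l in range(1, L):
        _apply_transition(F, rho[l - 1], K, tmp)
        for i in range(K):
            for j in range(K):
                F[i, j] = tmp[i, j]
        _emit_and_norm(F, H, l, gt[l], emis, K)
        for i in range(K):
            for j in range(K):
                fstore[l, i, j] = F[i, j]

    B = np.ones((K, K))
    post = np.zeros((K, K))
    for l in range(L - 1, -1, -1):
        # posterior at l: fstore[l] (includes emission at l) times B
        # (excludes emission at l)
        s = 0.0
        for i in range(K):
            for j in range(K):
                post[i, j] = fstore[l, i, j] * B[i, j]
                s += post[i, j]
        inv = 1.0 / s
        best = -1.0
        bi = 0
        bj = 0
        p0 = 0.0
        p1 = 0.0
        p2 = 0.0
        for i in range(K):
            hi = H[i, l]
            for j in range(K):
                p = post[i, j] * inv
                st = hi + H[j, l]
                p0 += p * emis[st, 0]
                p1 += p * emis[st, 1]
                p2 += p * emis[st, 2]
                if p > best:
                    best = p
                    bi = i
                    bj = j
        tot = p0 + p1 + p2
        gp[l, 0] = p0 / tot
        gp[l, 1] = p1 / tot
        gp[l, 2] = p2 / tot
        path[l, 0] = bi
        path[l, 1] = bj
        if l > 0:
            # fold emission at l into B, then pull through the transition
            g = gt[l]
            if g >= 0:
                for i in range(K):
                    hi = H[i, l]
                    for j in range(K):
                        B[i, j] *= emis[hi + H[j, l], g]
            _apply_transition(B, rho[l - 1], K, tmp)
            s = 0.0
            for i in range(K):
                for j in range(K):
                    B[i, j] = tmp[i, j]
                    s += B[i, j]
            inv = 1.0 / s
            for i in range(K):
                for j in range(K):
                    B[i, j] *= inv
    return gp, path
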