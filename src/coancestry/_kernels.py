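"""Numba kernels for the copying-model HMM.

The hidden state at site ``l`` is the donor haplotype being copied.  All
recurrences use scaled linear-space forward-backward: the forward vector is
renormalised at every site and the log-likelihood accumulated from the
normalisers, so no underflow occurs and the backward pass reuses the same
scale factors.

Conventions (pinned; see docs/methods.md):

* uniform initial distribution over the ``k`` donors;
* between adjacent sites at genetic distance ``g`` Morgans, a recombination
  occurs with probability ``1 - exp(-rho * g)`` and the donor is then drawn
  uniformly (possibly the same donor again: a recombination always starts a
  new chunk);
* symmetric miscopy emission: probability ``1 - mu`` of observing the donor
  allele, ``mu`` of the other allele.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def forward_backward_regions(match, nu, mu, half_span, region_of, n_regions):
    """Expected painting summaries for one recipient haplotype.

    Parameters
    ----------
    match : uint8 (L, k)
        1 where donor allele equals the recipient allele.
    nu : float64 (L-1,)
        No-recombination probability per inter-site interval.
    mu : float64
        Per-site miscopy probability.
    half_span : float64 (L,)
        Genetic length (Morgans) attributed to each site (half the flanking
        intervals); used for expected donated lengths.
    region_of : int64 (L,)
        Region index per site; chunk-count contributions (the initial site
        and every expected recombination) accrue to the region of the site
        where the chunk begins, so region matrices sum exactly to the total.
    n_regions : int64

    Returns
    -------
    chunks : float64 (n_regions, k)
        Expected chunk counts per region per donor haplotype.
    lengths, muts : float64 (k,)
        Expected donated genetic length and mismatches per donor haplotype.
    rec : float64 (L-1,)
        Posterior expected number of recombination events per interval.
    loglik : float64
    gamma : float64 (L, k)
        Site-wise posterior over donors (rows sum to 1).
    """
    L, k = match.shape
    f = np.empty((L, k))
    logc = np.empty(L)

    # forward
    s = 0.0
    for d in range(k):
        e = (1.0 - mu) if match[0, d] else mu
        f[0, d] = e / k
        s += f[0, d]
    for d in range(k):
        f[0, d] /= s
    logc[0] = np.log(s)
    for l in range(1, L):
        v = nu[l - 1]
        w = (1.0 - v) / k
        s = 0.0
        for d in range(k):
            e = (1.0 - mu) if match[l, d] else mu
            f[l, d] = e * (v * f[l - 1, d] + w)
            s += f[l, d]
        for d in range(k):
            f[l, d] /= s
        logc[l] = np.log(s)
    loglik = logc.sum()

    # backward with on-the-fly accumulation
    chunks = np.zeros((n_regions, k))
    lengths = np.zeros(k)
    muts = np.zeros(k)
    rec = np.zeros(max(L - 1, 1))
    gamma = np.empty((L, k))
    b = np.ones(k)
    for d in range(k):
        g = f[L - 1, d]
        gamma[L - 1, d] = g
        lengths[d] += g * half_span[L - 1]
        if not match[L - 1, d]:
            muts[d] += g
    for l in range(L - 1, 0, -1):
        # interval between sites l-1 and l
        v = nu[l - 1]
        w = (1.0 - v) / k
        cl = np.exp(logc[l])
        r = region_of[l]
        eb_sum = 0.0
        for d in range(k):
            e = (1.0 - mu) if match[l, d] else mu
            eb = e * b[d]
            # P(recombination in this interval AND donor d at site l | data)
            pr = w * eb / cl
            chunks[r, d] += pr
            rec[l - 1] += pr
            eb_sum += eb
        for d in range(k):
            e = (1.0 - mu) if match[l, d] else mu
            b[d] = (v * e * b[d] + w * eb_sum) / cl
        for d in range(k):
            g = f[l - 1, d] * b[d]
            gamma[l - 1, d] = g
            lengths[d] += g * half_span[l - 1]
            if not match[l - 1, d]:
                muts[d] += g
    r0 = region_of[0]
    for d in range(k):
        chunks[r0, d] += gamma[0, d]
    return chunks, lengths, muts, rec, loglik, gamma


@njit(cache=True)
def sample_path(match, nu, mu, seed):
    """Backward-sample one painting from the forward lattice.

    Returns the donor path (length ``L``) and a 0/1 array marking sites that
    begin a new chunk (site 0 always does; recombination choosing the same
    donor again still begins a new chunk).
    """
    np.random.seed(seed)
    L, k = match.shape
    f = np.empty((L, k))
    s = 0.0
    for d in range(k):
        e = (1.0 - mu) if match[0, d] else mu
        f[0, d] = e / k
        s += f[0, d]
    for d in range(k):
        f[0, d] /= s
    for l in range(1, L):
        v = nu[l - 1]
        w = (1.0 - v) / k
        s = 0.0
        for d in range(k):
            e = (1.0 - mu) if match[l, d] else mu
            f[l, d] = e * (v * f[l - 1, d] + w)
            s += f[l, d]
        for d in range(k):
            f[l, d] /= s

    path = np.empty(L, dtype=np.int64)
    newchunk = np.zeros(L, dtype=np.int8)
    newchunk[0] = 1
    # sample last state from the filtered distribution
    u = np.random.random()
    acc = 0.0
    d = k - 1
    for j in range(k):
        acc += f[L - 1, j]
        if u <= acc:
            d = j
            break
    path[L - 1] = d
    for l in range(L - 1, 0, -1):
        v = nu[l - 1]
        w = (1.0 - v) / k
        d = path[l]
        # P(no recomb, stay on d) vs P(recomb, redraw from f[l-1])
        stay = v * f[l - 1, d]
        total = stay + w  # sum_d' f[l-1,d'] = 1
        if np.random.random() * total <= stay:
            path[l - 1] = d
        else:
            newchunk[l] = 1
            u = np.random.random()
            acc = 0.0
            d2 = k - 1
            for j in range(k):
                acc += f[l - 1, j]
                if u <= acc:
                    d2 = j
                    break
            path[l - 1] = d2
    return path, newchunk
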