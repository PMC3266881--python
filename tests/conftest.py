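import itertools

import numpy as np
import pytest

from coancestry import GeneticMap, HaplotypePanel
from coancestry.cluster import Partition


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_panel(rng):
    """8 haplotypes (4 diploids), 20 sites."""
    alleles = rng.integers(0, 2, size=(8, 20))
    return HaplotypePanel(alleles, np.arange(1, 21) * 1000)


@pytest.fixture
def uniform_map():
    return GeneticMap.uniform(1.0)


def all_partitions(n):
    """Every set partition of range(n), via restricted growth strings."""
    def rec(prefix, maxlbl):
        if len(prefix) == n:
            yield Partition(prefix)
            return
        for lbl in range(maxlbl + 2):
            yield from rec(prefix + [lbl], max(maxlbl, lbl))
    yield from rec([0], 0)


def enumerate_paintings(match, nu, mu, half):
    """Brute-force expected painting summaries for one recipient.

    Enumerates every donor path together with every recombination
    indicator pattern consistent with it (a recombination may reselect the
    same donor, still opening a new chunk), weights by path probability and
    emission, and accumulates expected chunk counts, donated lengths and
    mismatches per donor haplotype.
    """
    L, k = match.shape
    emis = np.where(match, 1 - mu, mu)
    chunks = np.zeros(k)
    lengths = np.zeros(k)
    muts = np.zeros(k)
    rec_events = 0.0
    tot = 0.0
    for path in itertools.product(range(k), repeat=L):
        free = [l for l in range(1, L) if path[l] == path[l - 1]]
        for bits in itertools.product((0, 1), repeat=len(free)):
            r = [None] + [1] * (L - 1)
            for f_l, b in zip(free, bits):
                r[f_l] = b
            p = 1.0 / k * emis[0, path[0]]
            for l in range(1, L):
                p *= ((1 - nu[l - 1]) / k) if r[l] else nu[l - 1]
                p *= emis[l, path[l]]
            tot += p
            chunks[path[0]] += p
            for l in range(1, L):
                if r[l]:
                    chunks[path[l]] += p
                    rec_events += p
            for l in range(L):
                lengths[path[l]] += p * half[l]
                if not match[l, path[l]]:
                    muts[path[l]] += p
    return (chunks / tot, lengths / tot, muts / tot, rec_events / tot,
            np.log(tot))
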