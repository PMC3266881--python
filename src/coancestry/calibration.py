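"""Estimation of the chunk normalizer ``c``.

The clustering likelihood treats the rescaled counts ``X/c`` as multinomial
draws; ``c`` is the "effective number of independent chunks" correcting for
(a) dependence between chunks and (b) the smoothing introduced by using
expected rather than sampled chunk counts.  It is estimated by variance
matching: split the genome into regions large enough to be approximately
independent, and choose ``c`` so the mean observed between-region variance
of the contributions equals the variance the rescaled multinomial model
predicts.

For truly unlinked markers the variance match has a closed form
(:func:`c_unlinked_theoretical`); the empirical estimator should agree with
it, which is exercised by the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import GeneticMap, HaplotypePanel
from .painting import (
    PaintingParams,
    build_coancestry,
    singleton_filter_genotypes,
    unlinked_coancestry,
)

__all__ = [
    "RegionContributions",
    "split_regions",
    "estimate_c",
    "c_unlinked_theoretical",
]


@dataclass
class RegionContributions:
    """Per-region coancestry matrices that sum to the full matrix."""

    matrices: list

    def __post_init__(self) -> None:
        if len(self.matrices) < 2:
            raise ValueError("need at least 2 regions to estimate c")
        shapes = {m.shape for m in self.matrices}
        if len(shapes) != 1:
            raise ValueError("region matrices must share a shape")

    @property
    def total(self) -> np.ndarray:
        return np.sum(self.matrices, axis=0)

    @property
    def n_regions(self) -> int:
        return len(self.matrices)


def _region_edges_cm(panel: HaplotypePanel, gmap: GeneticMap | None,
                     region_length_cm: float, min_sites: int) -> np.ndarray:
    gmap = gmap or GeneticMap.uniform(1.0)
    cum = gmap.cumulative_morgans(panel.positions.astype(float))
    cum = cum - cum[0]
    width = region_length_cm / 100.0  # Morgans
    region = np.minimum((cum / width).astype(np.int64), max(
        int(np.ceil((cum[-1] - 1e-12) / width)) - 1, 0))
    # merge regions holding fewer than min_sites sites into their left
    # neighbour (or right neighbour for a leading short region)
    ids, counts = np.unique(region, return_counts=True)
    remap = {}
    new = 0
    for idx, (rid, cnt) in enumerate(zip(ids, counts)):
        if cnt < min_sites and new > 0:
            warnings.warn(f"region {rid} has {cnt} sites; merged into neighbour")
            remap[rid] = new - 1
        else:
            if cnt < min_sites:
                warnings.warn(f"region {rid} has {cnt} sites; merged into neighbour")
                remap[rid] = new  # leading short region joins the next one
            else:
                remap[rid] = new
                new += 1
    region = np.array([remap[r] for r in region], dtype=np.int64)
    region = np.maximum.accumulate(region)  # keep contiguous, non-decreasing
    # edges: first site index of each region after the first
    edges = np.flatnonzero(np.diff(region) > 0) + 1
    return edges


def split_regions(
    panels,
    maps=None,
    params: PaintingParams | None = None,
    region_length_cm: float = 5.0,
    region_sites: int | None = None,
    min_sites: int = 2,
) -> RegionContributions:
    """Region-wise contributions to the coancestry matrix.

    Linked mode: regions are windows of ``region_length_cm`` genetic map
    length (independence between regions is recombinational, so the default
    is map-based); the chunk-count contributions are accumulated per region
    within a single forward-backward pass, so they sum exactly to the
    whole-data matrix.  Regions with fewer than ``min_sites`` sites are
    merged into a neighbour with a warning.

    Unlinked mode: sites (after the singleton filter) are split into
    contiguous blocks of ``region_sites`` markers and the analytic matrix
    computed per block.
    """
    params = params or PaintingParams()
    if isinstance(panels, HaplotypePanel):
        panels = [panels]
    if maps is None or isinstance(maps, GeneticMap):
        maps = [maps] * len(panels)
    if params.unlinked:
        if region_sites is None:
            raise ValueError("unlinked mode needs region_sites")
        ploidy = panels[0].ploidy
        G = np.concatenate([p.genotypes() for p in panels], axis=1)
        G = G[:, singleton_filter_genotypes(G, ploidy)]
        mats = []
        for start in range(0, G.shape[1], region_sites):
            block = G[:, start : start + region_sites]
            if block.shape[1] < min_sites and mats:
                warnings.warn("short trailing block merged into neighbour")
                prev = np.arange(start - region_sites, start)
                block = G[:, np.concatenate([prev, np.arange(start, G.shape[1])])]
                mats[-1] = unlinked_coancestry(
                    block, theta=params.theta, symmetrize=True, ploidy=ploidy
                )
                break
            # singletons already filtered globally; keep mu consistent by
            # computing emission weights from the global panel size
            mats.append(_unlinked_block(block, params, ploidy))
        return RegionContributions(mats)
    edges = [
        _region_edges_cm(p, m, region_length_cm, min_sites)
        for p, m in zip(panels, maps)
    ]
    res = build_coancestry(panels, maps, params, region_edges=edges)
    return RegionContributions(res.region_X)


def _unlinked_block(G_block, params, ploidy):
    # blocks inherit the global singleton filter; per-block singletons are
    # retained deliberately so the blocks sum to the full matrix
    try:
        return unlinked_coancestry(G_block, theta=params.theta,
                                   symmetrize=True, ploidy=ploidy)
    except ValueError:
        return np.zeros((G_block.shape[0],) * 2)


def estimate_c(contribs: RegionContributions | list) -> float:
    """Variance-matching estimate of the chunk normalizer.

    Under the rescaled multinomial model, region ``r``'s count toward pair
    ``(i, j)`` has variance ``c * tbar_i * q_ij (1 - q_ij)`` where ``tbar_i``
    is recipient ``i``'s mean chunks per region and ``q_ij`` its overall
    donor proportions.  The observed and predicted variances are matched on
    the symmetric pair sums ``X_ij + X_ji`` rather than single entries: a
    shared haplotype tract is counted once in each direction, so the two
    directed counts are positively correlated while the multinomial model
    treats rows independently — matching pair sums charges that duplication
    to ``c`` (the correlation is near 1 for unlinked sites, smaller for
    linked chunks).  ``c`` is the ratio of the mean observed pair-sum
    variance over unordered pairs to the mean prediction at ``c = 1``;
    for independent multinomial rows it is unbiased for the generating
    ``c``.
    """
    if not isinstance(contribs, RegionContributions):
        contribs = RegionContributions(list(contribs))
    A = np.stack(contribs.matrices)  # (R, N, N)
    R, N, _ = A.shape
    upper = np.triu(np.ones((N, N), dtype=bool), k=1)
    pair = A + A.transpose(0, 2, 1)
    s2 = pair.var(axis=0, ddof=1)
    total = A.sum(axis=0)
    row = total.sum(axis=1, keepdims=True)
    if (row == 0).any():
        raise ValueError("a recipient has zero total chunks")
    q = total / row
    tbar = row[:, 0] / R
    pred = tbar[:, None] * q * (1.0 - q)
    pred_pair = pred + pred.T
    obs = float(s2[upper].mean())
    if obs <= 0:
        raise ValueError("zero observed between-region variance; degenerate input")
    return obs / float(pred_pair[upper].mean())


def c_unlinked_theoretical(n_ind: int, ploidy: int = 2) -> float:
    """Closed-form variance-match normalizer for truly unlinked markers.

    Each unlinked site donates, from each recipient haplotype, a posterior
    weight to every other individual that is (to leading order in the panel
    size) ``sum_a g_i^a g_j^a / n_a``, whose variance under binomial
    genotype sampling is ``ploidy^2 / n^2`` *independently of the allele
    frequency* while its mean is ``ploidy^2 / n``.  The same quantity is
    donated in both directions — every single-site chunk appears once in
    ``X_ij`` and once (to leading order identically) in ``X_ji`` — so the
    pair-sum variance is four times the per-entry variance.  Matching it
    against the two-entry multinomial prediction
    ``2 c * ploidy * L * q (1 - q)`` at ``q = 1/(N-1)`` gives::

        c = 2 * ploidy * (N - 1)^2 / ((ploidy * N)^2 * (N - 2))

    about ``1/N`` for large diploid samples: expectation-smoothing makes
    the unlinked matrix far less variable than one multinomial draw per
    site, so the effective number of independent chunks is much larger than
    the site count.  Derivation in docs/methods.md.
    """
    N = int(n_ind)
    if N < 3:
        raise ValueError("need at least 3 individuals")
    n = ploidy * N
    return 2.0 * ploidy * (N - 1) ** 2 / (n * n * (N - 2))
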