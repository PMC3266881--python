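"""Chromosome painting under the Li & Stephens copying model.

Each haplotype in the sample is reconstructed ("painted") as a mosaic of
chunks copied from the haplotypes of all *other* individuals.  The expected
number of chunks each donor individual contributes to each recipient
individual, accumulated over recipient haplotypes and chromosomes, is the
coancestry matrix ``X``; expected donated genetic lengths ``Y`` and expected
mismatch (mutation) counts ``M`` are accumulated from the same posteriors.

The recombination scaling ``rho`` (switch rate per Morgan) can be fitted by
EM; the miscopy probability is fixed from Watterson's estimator by default.
The infinite-recombination limit, where every site is its own chunk, has a
closed form (:func:`unlinked_coancestry`) that never requires phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from . import _kernels
from .io import GeneticMap, HaplotypePanel

__all__ = [
    "PaintingParams",
    "PaintingResult",
    "watterson_theta",
    "paint_haplotype",
    "sample_painting",
    "em_fit_rho",
    "build_coancestry",
    "unlinked_coancestry",
    "ChromosomePainter",
]


def watterson_theta(n_haps: int) -> float:
    """Per-site miscopy probability from Watterson's estimator.

    With ``n`` haplotypes, the population mutation rate is estimated as
    ``theta = 1 / sum_{m=1}^{n-1} 1/m`` and the probability that a copied
    site carries the non-donor allele is ``theta / (2 (n + theta))``.
    Strictly decreasing in ``n``.
    """
    n = int(n_haps)
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    theta = 1.0 / np.sum(1.0 / np.arange(1, n))
    return float(theta / (2.0 * (n + theta)))


@dataclass
class PaintingParams:
    """Scaling parameters of the copying model.

    rho
        Global recombination scaling: switch rate per Morgan (the
        per-interval recombination probability is ``1 - exp(-rho g)``).
        Shared by all individuals.
    theta
        Per-site miscopy probability in (0, 1/2); ``None`` fixes it from
        Watterson's estimator at the donor-panel size.
    n_em_iters
        EM iterations used by the fitting entry points (0 = keep ``rho``).
    unlinked
        Treat every marker as its own chunk (infinite recombination).
    em_update_theta
        Also re-estimate the miscopy probability inside EM.
    """

    rho: float = 4000.0
    theta: float | None = None
    n_em_iters: int = 0
    unlinked: bool = False
    em_update_theta: bool = False

    def __post_init__(self) -> None:
        if not self.unlinked and not self.rho > 0:
            raise ValueError("rho must be positive (or use unlinked=True)")
        if self.theta is not None and not 0 < self.theta < 0.5:
            raise ValueError("theta (miscopy probability) must be in (0, 1/2)")

    def miscopy(self, n_donors: int) -> float:
        return self.theta if self.theta is not None else watterson_theta(n_donors)


@dataclass
class PaintingResult:
    """Coancestry summaries, recipient individuals by donor individuals."""

    X: np.ndarray  # expected chunk counts
    Y: np.ndarray | None = None  # expected donated length (Morgans)
    M: np.ndarray | None = None  # expected mismatches in donated chunks
    loglik: float | None = None
    rho: float | None = None
    theta: float | None = None
    em_history: list | None = None
    site_posteriors: dict | None = None  # recipient hap -> (L, N) table
    region_X: list | None = None  # per-region chunk-count matrices
    labels: list | None = None

    @property
    def total_chunks(self) -> np.ndarray:
        return self.X.sum(axis=1)

    def summary(self) -> str:
        n = self.X.shape[0]
        lines = [
            "Chromosome painting summary",
            f"  individuals:            {n}",
            f"  mean chunks/recipient:  {self.total_chunks.mean():.3f}",
        ]
        if self.rho is not None:
            lines.append(f"  rho (switches/Morgan):  {self.rho:.6g}")
        if self.theta is not None:
            lines.append(f"  miscopy probability:    {self.theta:.6g}")
        if self.loglik is not None:
            lines.append(f"  log-likelihood:         {self.loglik:.6g}")
        return "\n".join(lines)


def _donor_setup(panel: HaplotypePanel, recipient: int):
    i = int(panel.hap_to_ind[recipient])
    donors = np.flatnonzero(panel.hap_to_ind != i)
    if donors.size == 0:
        raise ValueError("empty donor set")
    return i, donors


def _intervals(panel: HaplotypePanel, gmap: GeneticMap | None):
    if gmap is None:
        gmap = GeneticMap.uniform(1.0)
    g = gmap.intersite_morgans(panel.positions)
    half = np.zeros(panel.n_sites)
    if panel.n_sites > 1:
        half[:-1] += g / 2.0
        half[1:] += g / 2.0
    return g, half


def _paint_one(panel, recipient, donors, nu, mu, half, region_of, n_regions):
    match = np.ascontiguousarray(
        (panel.alleles[donors] == panel.alleles[recipient]).T.astype(np.uint8)
    )
    return _kernels.forward_backward_regions(
        match, nu, mu, half, region_of, n_regions
    )


def paint_haplotype(
    recipient: int,
    panel: HaplotypePanel,
    gmap: GeneticMap | None,
    params: PaintingParams,
    return_site_posteriors: bool = False,
):
    """Paint one recipient haplotype; aggregate donors to individuals.

    Returns a dict with per-donor-individual expected ``chunks``,
    ``lengths``, ``muts``, the ``loglik``, and optionally the ``(L, N)``
    site-posterior table.
    """
    i, donors = _donor_setup(panel, recipient)
    g, half = _intervals(panel, gmap)
    mu = params.miscopy(donors.size)
    nu = np.exp(-params.rho * g) if not params.unlinked else np.zeros_like(g)
    region_of = np.zeros(panel.n_sites, dtype=np.int64)
    chunks, lengths, muts, rec, loglik, gamma = _paint_one(
        panel, recipient, donors, nu, mu, half, region_of, 1
    )
    N = panel.n_ind
    out = {
        "chunks": _agg(chunks[0], donors, panel, N),
        "lengths": _agg(lengths, donors, panel, N),
        "muts": _agg(muts, donors, panel, N),
        "loglik": float(loglik),
        "expected_switches": float(rec.sum()),
        "recipient_ind": i,
    }
    if return_site_posteriors:
        post = np.zeros((panel.n_sites, N))
        np.add.at(post.T, panel.hap_to_ind[donors], gamma.T)
        out["site_posteriors"] = post
    return out


def _agg(per_hap: np.ndarray, donors: np.ndarray, panel: HaplotypePanel, N: int):
    out = np.zeros(N)
    np.add.at(out, panel.hap_to_ind[donors], per_hap)
    return out


def sample_painting(
    recipient: int,
    panel: HaplotypePanel,
    gmap: GeneticMap | None,
    params: PaintingParams,
    seed: int,
):
    """Sample one explicit painting: ``(start, end, donor_hap)`` segments.

    Segments are site-index ranges (inclusive start, exclusive end) tiling
    ``[0, L)``; a recombination that re-selects the same donor still starts
    a new segment.  Deterministic for a fixed seed.
    """
    _, donors = _donor_setup(panel, recipient)
    g, _ = _intervals(panel, gmap)
    mu = params.miscopy(donors.size)
    nu = np.exp(-params.rho * g) if not params.unlinked else np.zeros_like(g)
    match = np.ascontiguousarray(
        (panel.alleles[donors] == panel.alleles[recipient]).T.astype(np.uint8)
    )
    path, newchunk = _kernels.sample_path(match, nu, mu, int(seed) & 0x7FFFFFFF)
    starts = np.flatnonzero(newchunk)
    ends = np.append(starts[1:], panel.n_sites)
    return [(int(s), int(e), int(donors[path[s]])) for s, e in zip(starts, ends)]


def _paint_panel(panel, gmap, rho, theta, unlinked, region_edges=None,
                 save_site_posteriors=False):
    """Paint every haplotype of one panel; accumulate individual matrices."""
    N = panel.n_ind
    g, half = _intervals(panel, gmap)
    nu = np.exp(-rho * g) if not unlinked else np.zeros_like(g)
    region_of = np.zeros(panel.n_sites, dtype=np.int64)
    n_regions = 1
    if region_edges is not None:
        region_of = np.searchsorted(np.asarray(region_edges), np.arange(panel.n_sites),
                                    side="right").astype(np.int64)
        n_regions = int(region_of.max()) + 1
    X = np.zeros((n_regions, N, N))
    Y = np.zeros((N, N))
    M = np.zeros((N, N))
    rec_tot = np.zeros(max(panel.n_sites - 1, 1))
    mut_tot = 0.0
    loglik = 0.0
    posts = {} if save_site_posteriors else None
    mu = theta
    for h in range(panel.n_haps):
        i, donors = _donor_setup(panel, h)
        if mu is None:
            mu = watterson_theta(donors.size)
        chunks, lengths, muts, rec, ll, gamma = _paint_one(
            panel, h, donors, nu, mu, half, region_of, n_regions
        )
        d_ind = panel.hap_to_ind[donors]
        np.add.at(X[:, i, :].T, d_ind, chunks.T)
        np.add.at(Y[i], d_ind, lengths)
        np.add.at(M[i], d_ind, muts)
        rec_tot[: rec.size] += rec
        mut_tot += muts.sum()
        loglik += ll
        if save_site_posteriors:
            post = np.zeros((panel.n_sites, N))
            np.add.at(post.T, d_ind, gamma.T)
            posts[h] = post
    return X, Y, M, rec_tot, mut_tot, loglik, posts, mu


def _as_pairs(panels, maps):
    if isinstance(panels, HaplotypePanel):
        panels = [panels]
    if maps is None:
        maps = [None] * len(panels)
    elif isinstance(maps, GeneticMap):
        maps = [maps]
    if len(maps) != len(panels):
        raise ValueError("need one genetic map per panel")
    first = panels[0]
    for p in panels[1:]:
        if p.n_ind != first.n_ind or p.ploidy != first.ploidy:
            raise ValueError("individual sets differ across chromosomes")
    return panels, maps


def build_coancestry(
    panels,
    maps=None,
    params: PaintingParams | None = None,
    region_edges=None,
    save_site_posteriors: bool = False,
) -> PaintingResult:
    """Full coancestry matrices, summed over haplotypes and chromosomes.

    ``region_edges`` (per panel: increasing site indices splitting the sites
    into regions) additionally returns per-region chunk-count matrices from
    the same forward-backward pass, so the region matrices sum exactly to
    ``X``.
    """
    params = params or PaintingParams()
    panels, maps = _as_pairs(panels, maps)
    if params.unlinked:
        X = unlinked_coancestry(panels, theta=params.theta, symmetrize=True)
        return PaintingResult(X=X, theta=params.theta, labels=panels[0].labels)
    N = panels[0].n_ind
    X = np.zeros((N, N))
    Y = np.zeros((N, N))
    M = np.zeros((N, N))
    loglik = 0.0
    region_X = [] if region_edges is not None else None
    posts = {} if save_site_posteriors else None
    theta_used = None
    for c, (panel, gmap) in enumerate(zip(panels, maps)):
        edges = region_edges[c] if region_edges is not None else None
        Xc, Yc, Mc, _, _, ll, pc, mu = _paint_panel(
            panel, gmap, params.rho, params.theta, params.unlinked,
            region_edges=edges, save_site_posteriors=save_site_posteriors,
        )
        X += Xc.sum(axis=0)
        Y += Yc
        M += Mc
        loglik += ll
        theta_used = mu
        if region_X is not None:
            region_X.extend(list(Xc))
        if save_site_posteriors:
            posts[c] = pc
    return PaintingResult(
        X=X, Y=Y, M=M, loglik=loglik, rho=params.rho, theta=theta_used,
        site_posteriors=posts, region_X=region_X, labels=panels[0].labels,
    )


def em_fit_rho(panels, maps=None, params: PaintingParams | None = None):
    """Fit the recombination scaling by EM.

    Each iteration computes the posterior expected number of recombination
    events per inter-site interval (E-step, from forward-backward over every
    recipient haplotype and chromosome) and maximises the expected
    complete-data log-likelihood over ``rho`` (M-step).  Returns
    ``(rho, history, theta)`` where history rows are ``(rho, loglik)`` per
    iteration; the observed-data log-likelihood is non-decreasing.
    """
    params = params or PaintingParams()
    if params.unlinked:
        raise ValueError("EM for rho requires linked mode")
    if params.n_em_iters < 1:
        raise ValueError("n_em_iters must be >= 1")
    panels, maps = _as_pairs(panels, maps)
    g_all = np.concatenate(
        [_intervals(p, m)[0] for p, m in zip(panels, maps)]
    )
    H = sum(p.n_haps for p in panels) / len(panels)  # recipients per interval
    rho = params.rho
    theta = params.theta
    history = []
    for _ in range(params.n_em_iters):
        rec = []
        loglik = 0.0
        mut_tot = 0.0
        n_site_obs = 0
        for panel, gmap in zip(panels, maps):
            _, _, _, rc, mt, ll, _, _ = _paint_panel(
                panel, gmap, rho, theta, False
            )
            rec.append(rc)
            loglik += ll
            mut_tot += mt
            n_site_obs += panel.n_haps * panel.n_sites
        R = np.concatenate(rec)
        history.append((rho, loglik))
        rho = _mstep_rho(R, g_all, H, rho)
        if params.em_update_theta:
            theta = min(max(mut_tot / n_site_obs, 1e-9), 0.499)
    return rho, history, theta


def _mstep_rho(R: np.ndarray, g: np.ndarray, H: float, rho0: float) -> float:
    """Maximise sum_l R_l log(1-e^{-rho g_l}) - (H - R_l) rho g_l over rho."""
    good = g > 0
    R, g = R[good], g[good]
    if R.size == 0 or R.sum() <= 0:
        import warnings

        warnings.warn("no recombination signal; rho left unchanged")
        return rho0

    def score(log_rho):
        rg = np.exp(log_rho) * g
        rg = np.clip(rg, 1e-300, 700.0)
        em = np.exp(-rg)
        # d/drho of Q, times rho (monotone sign-equivalent in log-rho);
        # 1 - e^{-rg} via expm1 for small rg
        return float(np.sum(R * rg * em / -np.expm1(-rg) - (H - R) * rg))

    lo, hi = -30.0, 30.0
    if score(lo) <= 0:  # pathological: no signal at any rate
        return float(np.exp(lo))
    if score(hi) >= 0:
        return float(np.exp(hi))
    return float(np.exp(brentq(score, lo, hi, xtol=1e-10)))


def singleton_filter_genotypes(G: np.ndarray, ploidy: int) -> np.ndarray:
    carriers1 = (G > 0).sum(axis=0)
    carriers0 = (G < ploidy).sum(axis=0)
    return (carriers1 > 1) & (carriers0 > 1)


def unlinked_coancestry(
    data,
    theta: float | None = None,
    symmetrize: bool = True,
    ploidy: int = 2,
) -> np.ndarray:
    """Analytic coancestry matrix in the infinite-recombination limit.

    Every site is a one-marker chunk: the posterior weight a recipient
    haplotype places on a donor haplotype is the match emission for
    allele-sharing donors and the miscopy emission otherwise, normalised
    over the donor set (all haplotypes of other individuals).  The
    computation needs only genotypes, never phase.  Sites whose minor allele
    is carried by a single individual are uninformative and dropped; a panel
    with only such sites is rejected.

    By default the donor/recipient-averaged matrix ``(X + X^T)/2`` is
    returned, which is symmetric to machine precision and is what all
    downstream inference consumes; ``symmetrize=False`` returns the raw
    recipient-by-donor matrix, which is the exact ``rho -> inf`` limit of
    the linked painting.
    """
    if isinstance(data, HaplotypePanel):
        data = [data]
    if isinstance(data, (list, tuple)) and isinstance(data[0], HaplotypePanel):
        ploidy = data[0].ploidy
        G = np.concatenate([p.genotypes() for p in data], axis=1)
    else:
        G = np.asarray(data, dtype=np.int64)
    N, L = G.shape
    keep = singleton_filter_genotypes(G, ploidy)
    if not keep.any():
        raise ValueError("all sites are singletons; no donor information")
    G = G[:, keep].astype(np.float64)
    n = N * ploidy
    k = n - ploidy  # donors per recipient haplotype
    mu = theta if theta is not None else watterson_theta(k)

    G1 = G  # allele-1 dosage, (N, L)
    G0 = ploidy - G
    n1 = G1.sum(axis=0)  # (L,)
    # matching donors for a recipient haplotype of individual i with allele a
    m1 = n1[None, :] - G1
    m0 = (n - n1)[None, :] - G0
    Z1 = m1 * (1.0 - mu) + (k - m1) * mu
    Z0 = m0 * (1.0 - mu) + (k - m0) * mu
    A1 = G1 / Z1
    A0 = G0 / Z0
    # weight from i to j at one site: sum_a G_i^a [mu*ploidy + (1-2mu) G_j^a] / Z_a(i)
    X = (1.0 - 2.0 * mu) * (A1 @ G1.T + A0 @ G0.T)
    X += mu * ploidy * (A1 + A0).sum(axis=1)[:, None]
    np.fill_diagonal(X, 0.0)
    if symmetrize:
        X = (X + X.T) / 2.0
    return X


class ChromosomePainter:
    """Model object: painting one or more chromosomes of a sample.

    Parameters
    ----------
    panels, maps
        One :class:`HaplotypePanel` (and optional :class:`GeneticMap`) per
        chromosome, all over the same individuals.
    params
        Copying-model parameters; ``n_em_iters > 0`` fits ``rho`` by EM
        before the final painting.

    ``fit()`` returns a :class:`PaintingResult`.
    """

    def __init__(self, panels, maps=None, params: PaintingParams | None = None):
        self.panels, self.maps = _as_pairs(panels, maps)
        self.params = params or PaintingParams()

    def fit(self, region_edges=None, save_site_posteriors=False) -> PaintingResult:
        params = self.params
        history = None
        if not params.unlinked and params.n_em_iters > 0:
            rho, history, theta = em_fit_rho(self.panels, self.maps, params)
            params = replace(params, rho=rho, theta=theta, n_em_iters=0)
        res = build_coancestry(
            self.panels, self.maps, params,
            region_edges=region_edges,
            save_site_posteriors=save_site_posteriors,
        )
        res.em_history = history
        return res
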