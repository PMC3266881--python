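import numpy as np
import pytest
from fractions import Fraction

from coancestry import (
    GeneticMap,
    HaplotypePanel,
    PaintingParams,
    build_coancestry,
    em_fit_rho,
    paint_haplotype,
    sample_painting,
    unlinked_coancestry,
    watterson_theta,
)
from coancestry.painting import _intervals

from conftest import enumerate_paintings


def _random_instance(rng, n_ind_other, L):
    H = 2 * (n_ind_other + 1)
    alleles = rng.integers(0, 2, size=(H, L))
    positions = np.sort(rng.choice(np.arange(1, 10**6), L, replace=False))
    return HaplotypePanel(alleles, positions)


class TestWatterson:
    def test_two_haplotypes_single_harmonic_term(self):
        # theta = 1 / H_1 = 1; miscopy = theta / (2 (n + theta)) = 1/6
        assert watterson_theta(2) == pytest.approx(1 / 6)

    def test_decreasing_in_sample_size(self):
        assert watterson_theta(10) > watterson_theta(100)

    @pytest.mark.parametrize("n", [2, 5, 17, 64])
    def test_matches_exact_rational_arithmetic(self, n):
        theta = 1 / sum(Fraction(1, m) for m in range(1, n))
        expect = theta / (2 * (n + theta))
        assert watterson_theta(n) == pytest.approx(float(expect), rel=1e-14)

    def test_rejects_single_haplotype(self):
        with pytest.raises(ValueError):
            watterson_theta(1)


class TestPaintOracle:
    @pytest.mark.parametrize("trial", range(12))
    def test_forward_backward_equals_path_enumeration(self, trial):
        """All instances with <=4 sites and <=6 donors match brute force."""
        rng = np.random.default_rng(100 + trial)
        panel = _random_instance(rng, rng.integers(1, 4), rng.integers(2, 5))
        gmap = GeneticMap.uniform(rng.uniform(0.3, 3.0))
        rho = rng.uniform(10.0, 1e5)
        mu = watterson_theta(panel.n_haps - 2)
        params = PaintingParams(rho=rho, theta=mu)
        res = paint_haplotype(0, panel, gmap, params)

        donors = np.flatnonzero(panel.hap_to_ind != 0)
        g, half = _intervals(panel, gmap)
        match = (panel.alleles[donors] == panel.alleles[0]).T
        bc, bl, bm, brec, bll = enumerate_paintings(
            match, np.exp(-rho * g), mu, half)
        agg = np.zeros((3, panel.n_ind))
        for col, d in enumerate(donors):
            i = panel.hap_to_ind[d]
            agg[0, i] += bc[col]
            agg[1, i] += bl[col]
            agg[2, i] += bm[col]
        np.testing.assert_allclose(res["chunks"], agg[0], atol=1e-10)
        np.testing.assert_allclose(res["lengths"], agg[1], atol=1e-10)
        np.testing.assert_allclose(res["muts"], agg[2], atol=1e-10)
        assert res["loglik"] == pytest.approx(bll, abs=1e-10)
        assert res["expected_switches"] == pytest.approx(brec, abs=1e-10)

    def test_identical_donor_dominates(self, rng):
        """A donor identical to the recipient collects nearly all chunks."""
        L = 10
        recipient = rng.integers(0, 2, size=L)
        alleles = np.vstack([
            recipient, recipient[::-1],  # individual 0 (hap 0 = recipient)
            recipient,                   # the twin donor
            1 - recipient,
            1 - recipient,
            1 - recipient,
        ])
        panel = HaplotypePanel(alleles, np.arange(1, L + 1) * 1000,
                               hap_to_ind=np.array([0, 0, 1, 1, 2, 2]))
        res = paint_haplotype(0, panel, GeneticMap.uniform(1.0),
                              PaintingParams(rho=100.0))
        share = res["chunks"][1] / res["chunks"].sum()
        assert share > 0.99

    def test_site_posteriors_normalized(self, small_panel, uniform_map):
        res = paint_haplotype(3, small_panel, uniform_map,
                              PaintingParams(rho=500.0),
                              return_site_posteriors=True)
        sums = res["site_posteriors"].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_total_chunks_is_one_plus_switches(self, small_panel, uniform_map):
        res = paint_haplotype(0, small_panel, uniform_map,
                              PaintingParams(rho=2000.0))
        assert res["chunks"].sum() == pytest.approx(
            1.0 + res["expected_switches"], abs=1e-9)


class TestSamplePainting:
    def test_segments_tile_all_sites(self, small_panel, uniform_map):
        segs = sample_painting(0, small_panel, uniform_map,
                               PaintingParams(rho=5000.0), seed=7)
        covered = []
        for s, e, d in segs:
            covered.extend(range(s, e))
        assert covered == list(range(small_panel.n_sites))

    def test_same_seed_reproduces(self, small_panel, uniform_map):
        p = PaintingParams(rho=5000.0)
        a = sample_painting(2, small_panel, uniform_map, p, seed=11)
        b = sample_painting(2, small_panel, uniform_map, p, seed=11)
        assert a == b

    def test_empirical_frequencies_match_posterior(self):
        """Sampled donor frequencies agree with forward-backward marginals."""
        rng = np.random.default_rng(5)
        panel = _random_instance(rng, 2, 6)
        gmap = GeneticMap.uniform(1.0)
        params = PaintingParams(rho=3e4)
        res = paint_haplotype(0, panel, gmap, params,
                              return_site_posteriors=True)
        post = res["site_posteriors"]  # (L, N)
        n = 100_000
        counts = np.zeros_like(post)
        for s in range(n):
            for start, end, d in sample_painting(0, panel, gmap, params,
                                                 seed=s):
                counts[start:end, panel.hap_to_ind[d]] += 1
        freq = counts / n
        se = np.sqrt(np.maximum(post * (1 - post), 1e-12) / n)
        assert np.all(np.abs(freq - post) < 3 * se + 3e-3)


def _mosaic_panel(rng, L=5000, H=40, rho_true=300.0, miscopy=0.002):
    """Haplotypes built by the copying process itself: each is a mosaic of
    6 founder sequences with switch rate ``rho_true`` per Morgan."""
    founders = rng.integers(0, 2, size=(6, L))
    alleles = np.empty((H, L), dtype=np.int8)
    g = 1e-5  # Morgans between adjacent sites (uniform 1 cM/Mb, 1 kb)
    switch = 1 - np.exp(-rho_true * g)
    for h in range(H):
        src = rng.integers(6)
        for l in range(L):
            if rng.random() < switch:
                src = rng.integers(6)
            a = founders[src, l]
            alleles[h, l] = a if rng.random() > miscopy else 1 - a
    return HaplotypePanel(alleles, np.arange(1, L + 1) * 1000)


class TestEmRho:
    def test_recovers_generating_rho_with_monotone_loglik(self):
        rng = np.random.default_rng(21)
        panel = _mosaic_panel(rng)
        gmap = GeneticMap.uniform(1.0)
        rho, hist, _ = em_fit_rho(panel, gmap,
                                  PaintingParams(rho=2000.0, n_em_iters=8))
        assert rho == pytest.approx(300.0, rel=0.35)
        logliks = [ll for _, ll in hist]
        assert all(b - a > -1e-8 for a, b in zip(logliks, logliks[1:]))

    def test_fixed_point_self_consistency(self):
        """At the converged estimate, one further EM update barely moves."""
        rng = np.random.default_rng(3)
        panel = _mosaic_panel(rng, L=3000)
        gmap = GeneticMap.uniform(1.0)
        rho_hat, _, _ = em_fit_rho(
            panel, gmap, PaintingParams(rho=2000.0, n_em_iters=10))
        rho_next, _, _ = em_fit_rho(
            panel, gmap, PaintingParams(rho=rho_hat, n_em_iters=1))
        assert rho_next == pytest.approx(rho_hat, rel=0.05)


class TestBuildCoancestry:
    def test_additive_over_chromosomes(self, rng):
        p1 = _random_instance(rng, 4, 30)
        p2 = HaplotypePanel(rng.integers(0, 2, size=(10, 25)),
                            np.arange(1, 26) * 500)
        gmap = GeneticMap.uniform(1.0)
        params = PaintingParams(rho=1000.0, theta=0.01)
        both = build_coancestry([p1, p2], [gmap, gmap], params)
        solo = (build_coancestry(p1, gmap, params).X
                + build_coancestry(p2, gmap, params).X)
        np.testing.assert_allclose(both.X, solo, atol=1e-9)

    def test_permutation_equivariance(self, rng):
        panel = _random_instance(rng, 4, 40)
        gmap = GeneticMap.uniform(1.0)
        params = PaintingParams(rho=1000.0, theta=0.01)
        X = build_coancestry(panel, gmap, params).X
        perm = rng.permutation(panel.n_ind)
        hap_perm = np.concatenate([panel.haps_of(i) for i in perm])
        panel2 = HaplotypePanel(panel.alleles[hap_perm], panel.positions)
        X2 = build_coancestry(panel2, gmap, params).X
        np.testing.assert_allclose(X2, X[np.ix_(perm, perm)], atol=1e-9)

    def test_nonnegative_zero_diagonal_row_sums(self, small_panel,
                                                uniform_map):
        res = build_coancestry(small_panel, uniform_map,
                               PaintingParams(rho=800.0))
        for M in (res.X, res.Y, res.M):
            assert (M >= 0).all()
            np.testing.assert_allclose(np.diag(M), 0.0)
        # Y per recipient covers the whole map for both haplotypes
        g, _ = _intervals(small_panel, uniform_map)
        np.testing.assert_allclose(res.Y.sum(axis=1), 2 * g.sum(), rtol=1e-9)

    def test_infinite_rho_limit_equals_unlinked(self, rng):
        alleles = rng.integers(0, 2, size=(40, 200))
        panel = HaplotypePanel(alleles, np.arange(1, 201) * 1000)
        panel = panel.restrict_sites(panel.singleton_mask())
        res = build_coancestry(panel, GeneticMap.uniform(1.0),
                               PaintingParams(rho=1e12))
        Xu = unlinked_coancestry(panel, symmetrize=False)
        assert np.abs(res.X - Xu).max() < 1e-6


class TestUnlinked:
    def test_single_snp_bayes_weight(self):
        """One informative site: weights follow match/mismatch emissions."""
        alleles = np.array([
            [1], [1],   # recipient individual (both haps allele 1)
            [1], [1],   # donor ind 1: both match
            [0], [0],   # donor ind 2: both mismatch
            [0], [0],   # donor ind 3: both mismatch
        ])
        panel = HaplotypePanel(alleles, [1])
        mu = 0.05
        X = unlinked_coancestry(panel, theta=mu, symmetrize=False)
        Z = 2 * (1 - mu) + 4 * mu
        np.testing.assert_allclose(X[0, 1], 2 * 2 * (1 - mu) / Z)
        np.testing.assert_allclose(X[0, 2], 2 * 2 * mu / Z)

    def test_symmetric_to_machine_precision(self, rng):
        alleles = rng.integers(0, 2, size=(30, 300))
        panel = HaplotypePanel(alleles, np.arange(1, 301))
        X = unlinked_coancestry(panel)
        np.testing.assert_allclose(X, X.T, atol=0.0)

    def test_haplotype_and_genotype_routes_agree(self, rng):
        alleles = rng.integers(0, 2, size=(24, 150))
        panel = HaplotypePanel(alleles, np.arange(1, 151))
        X_h = unlinked_coancestry(panel)
        X_g = unlinked_coancestry(panel.genotypes(),
                                  theta=watterson_theta(panel.n_haps - 2))
        np.testing.assert_allclose(X_h, X_g, atol=1e-12)

    def test_all_singletons_rejected(self):
        alleles = np.zeros((6, 3), dtype=int)
        alleles[0, :] = 1  # every site varies in individual 0 only
        panel = HaplotypePanel(alleles, [1, 2, 3])
        with pytest.raises(ValueError):
            unlinked_coancestry(panel)

    def test_row_sums_equal_ploidy_times_sites(self, rng):
        alleles = rng.integers(0, 2, size=(20, 100))
        panel = HaplotypePanel(alleles, np.arange(1, 101))
        keep = panel.singleton_mask()
        X = unlinked_coancestry(panel, symmetrize=False)
        np.testing.assert_allclose(X.sum(axis=1), 2 * keep.sum(), rtol=1e-12)
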