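import numpy as np
import pytest
from collections import Counter

from scipy.integrate import quad
from scipy.special import betaln, gammaln
from scipy.stats import spearmanr

from coancestry.calibration import estimate_c
from coancestry.cluster import (
    FineStructureModel,
    FsModel,
    Partition,
    _logpost_kernel,
    convergence_compare,
    dp_log_prior,
    log_marginal_posterior,
    map_search,
    pairwise_coincidence,
    propose,
    run_mcmc,
)
from coancestry.painting import unlinked_coancestry

from conftest import all_partitions


def _toy_X(rng, n, scale=15):
    X = rng.integers(1, scale, size=(n, n)).astype(float)
    np.fill_diagonal(X, 0.0)
    return X


def _block_X(n_per=6, within=10.0, between=1.0, jitter=0.0, rng=None):
    """Strong 2-population chunk-count matrix (within:between 10:1)."""
    N = 2 * n_per
    X = np.full((N, N), between)
    X[:n_per, :n_per] = within
    X[n_per:, n_per:] = within
    if jitter and rng is not None:
        X += rng.uniform(0, jitter, size=(N, N))
    np.fill_diagonal(X, 0.0)
    return X


class TestPartition:
    def test_label_free_equality(self):
        assert Partition([1, 1, 0, 2]) == Partition([0, 0, 1, 2])
        assert Partition([0, 1]) != Partition([0, 0])

    def test_from_groups_round_trip(self):
        p = Partition([0, 1, 0, 2, 1])
        assert Partition.from_groups(p.groups()) == p

    def test_co_assignment(self):
        p = Partition([0, 0, 1])
        expect = [[1, 1, 0], [1, 1, 0], [0, 0, 1]]
        np.testing.assert_array_equal(p.co_assignment(), expect)


class TestCrpPrior:
    def test_two_individuals_half(self):
        assert np.exp(dp_log_prior(Partition([0, 0]), 1.0)) == pytest.approx(0.5)
        assert np.exp(dp_log_prior(Partition([0, 1]), 1.0)) == pytest.approx(0.5)

    @pytest.mark.parametrize("alpha", [0.3, 1.0, 2.5])
    def test_normalized_over_partitions_of_four(self, alpha):
        total = sum(np.exp(dp_log_prior(p, alpha)) for p in all_partitions(4))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_small_alpha_concentrates_on_one_group(self):
        one = dp_log_prior(Partition([0] * 5), 1e-6)
        two = dp_log_prior(Partition([0, 0, 0, 0, 1]), 1e-6)
        assert one > two + 10  # overwhelming preference for K=1


class TestMarginalPosterior:
    def test_label_invariance(self, rng):
        X = _toy_X(rng, 6)
        m = FsModel(c=1.3, delta=1.5, kappa=2.0)
        a = log_marginal_posterior(Partition([0, 0, 1, 1, 2, 2]), X, m)
        b = log_marginal_posterior(Partition([2, 2, 0, 0, 1, 1]), X, m)
        assert a == b

    def test_single_group_closed_form(self, rng):
        """K=1 has no free donor proportions: only the donor-spreading term
        and the CRP prior remain."""
        X = _toy_X(rng, 3)
        m = FsModel(c=1.7, delta=1.3, kappa=2.1, alpha=0.8)
        part = Partition([0, 0, 0])
        expect = -np.sum(X / m.c) * np.log(2.0) + dp_log_prior(part, m.alpha)
        assert log_marginal_posterior(part, X, m) == pytest.approx(expect)

    def test_matches_quadrature_on_two_doubletons(self, rng):
        """Analytic Dirichlet-multinomial integration vs adaptive quadrature."""
        X = _toy_X(rng, 4)
        m = FsModel(c=1.7, delta=1.3, kappa=2.1, alpha=0.8)
        part = Partition([0, 0, 1, 1])
        groups = [[0, 1], [2, 3]]
        sizes = np.array([2.0, 2.0])
        total = dp_log_prior(part, m.alpha)
        for a in range(2):
            Y = np.zeros(2)
            for b in range(2):
                for i in groups[a]:
                    for j in groups[b]:
                        if j != i:
                            Y[b] += X[i, j] / m.c
            eye = np.eye(2)
            ntilde = sizes[None, :] - eye
            beta = m.kappa * (1 + m.delta * eye) * ntilde / 3.0
            ba = beta[a]
            lnB = gammaln(ba[0]) + gammaln(ba[1]) - gammaln(ba.sum())

            def logf(p):
                return ((Y[0] + ba[0] - 1) * np.log(p)
                        + (Y[1] + ba[1] - 1) * np.log1p(-p) - lnB)

            mode = (Y[0] + ba[0] - 1) / (Y.sum() + ba.sum() - 2)
            shift = logf(np.clip(mode, 1e-6, 1 - 1e-6))
            val, _ = quad(lambda p: np.exp(logf(p) - shift), 0, 1,
                          epsabs=1e-14, epsrel=1e-12)
            total += shift + np.log(val)
            total -= np.sum(Y * np.log(np.where(ntilde[a] > 0, ntilde[a], 1)))
        mine = log_marginal_posterior(part, X, m)
        assert mine == pytest.approx(total, abs=1e-3)

    def test_monotone_and_continuous_in_c(self, rng):
        X = _toy_X(rng, 5)
        part = Partition([0, 0, 1, 1, 2])
        grid = np.linspace(0.2, 8.0, 60)
        vals = [log_marginal_posterior(part, X, FsModel(c=c)) for c in grid]
        assert np.isfinite(vals).all()
        assert (np.diff(vals) > 0).all()
        # halving the grid step roughly halves the increments: no jumps
        fine = np.linspace(0.2, 8.0, 120)
        fine_vals = [log_marginal_posterior(part, X, FsModel(c=c))
                     for c in fine]
        assert np.max(np.diff(fine_vals)) < 0.75 * np.max(np.diff(vals))

    def test_kernel_agrees_with_reference(self, rng):
        for _ in range(25):
            n = rng.integers(3, 12)
            X = _toy_X(rng, n)
            m = FsModel(c=float(rng.uniform(0.3, 3)),
                        delta=float(rng.uniform(0.2, 3)),
                        kappa=float(rng.uniform(0.2, 3)))
            part = Partition(rng.integers(0, 4, size=n))
            ref = log_marginal_posterior(part, X, m)
            fast = _logpost_kernel(np.asarray(part.assignment, np.int64),
                                   X / m.c, m.delta, m.kappa, m.alpha)
            assert fast == pytest.approx(ref, abs=1e-9)

    def test_empty_group_rejected(self, rng):
        X = _toy_X(rng, 3)
        part = Partition.from_groups([[0, 1, 2]])
        # fabricate an inconsistent call: partition over wrong size
        with pytest.raises(ValueError):
            log_marginal_posterior(part, _toy_X(rng, 5), FsModel())


class TestPropose:
    def test_deterministic_under_seed(self):
        p = Partition([0, 0, 1, 1, 2, 2])
        for move in ("merge", "split", "merge_resplit", "move_individual"):
            a = propose(p, move, np.random.default_rng(3))
            b = propose(p, move, np.random.default_rng(3))
            assert a[0] == b[0] and a[1] == b[1]

    def test_move_individual_rejected_at_k1(self):
        prop, lh = propose(Partition([0, 0, 0]), "move_individual",
                           np.random.default_rng(0))
        assert prop is None and lh == float("-inf")

    def test_pair_moves_respect_pair_grouping(self):
        # in a 2-singleton state no pair shares a group: split impossible
        prop, lh = propose(Partition([0, 1]), "split",
                           np.random.default_rng(1))
        assert prop is None

    def test_fast_and_slow_allocation_agree(self, rng):
        X = _toy_X(rng, 10)
        Xc = X / 0.7
        delta, kappa, alpha = 1.4, 2.2, 1.0

        def scorer(arr):
            return _logpost_kernel(arr, Xc, delta, kappa, alpha)

        for seed in range(60):
            part = Partition(np.random.default_rng(500 + seed)
                             .integers(0, 3, size=10))
            mv = ("merge", "split", "merge_resplit")[seed % 3]
            slow = propose(part, mv, np.random.default_rng(seed),
                           scorer=scorer)
            fast = propose(part, mv, np.random.default_rng(seed),
                           scorer=(Xc, delta, kappa, alpha))
            assert (slow[0] is None) == (fast[0] is None)
            if slow[0] is not None:
                assert slow[0] == fast[0]
                assert slow[1] == pytest.approx(fast[1], abs=1e-9)


class TestPriorRecovery:
    def test_likelihood_off_chain_samples_crp(self):
        """Moves + Hastings ratios leave the CRP invariant (N=5)."""
        N, alpha = 5, 1.0
        parts = list(all_partitions(N))
        truth = {p: np.exp(dp_log_prior(p, alpha)) for p in parts}
        trace = run_mcmc(np.zeros((N, N)), FsModel(alpha=alpha),
                         iters=300_000, burnin=5_000, thin=1, seed=2,
                         likelihood_on=False)
        counts = Counter(Partition(a) for a in trace.assignments)
        tv = 0.5 * sum(abs(counts.get(p, 0) / trace.n_samples - truth[p])
                       for p in parts)
        assert tv < 0.03


class TestRunMcmc:
    def test_strong_two_population_fixture(self, rng):
        X = _block_X(jitter=0.5, rng=rng)
        truth = Partition([0] * 6 + [1] * 6)
        res = FineStructureModel(X, c=1.0).fit(iters=4000, burnin=4000,
                                               thin=10, seed=0)
        coin = res.coincidence()
        true_co = truth.co_assignment()
        # posterior mass concentrated on the true split
        frac = np.mean([Partition(a) == truth
                        for a in res.trace.assignments])
        assert frac > 0.99
        assert np.abs(coin - true_co).max() < 0.05
        assert res.map_partition == truth

    def test_posterior_depends_on_data_only_through_counts(self, rng):
        """Sufficiency: identical X gives identical posterior values."""
        X = _block_X(jitter=1.0, rng=rng)
        m = FsModel(c=0.8, delta=1.2, kappa=0.9)
        p = Partition(rng.integers(0, 3, size=12))
        assert log_marginal_posterior(p, X, m) == \
            log_marginal_posterior(p, X.copy(), m)

    def test_nonfinite_initial_state_rejected(self):
        X = np.full((4, 4), np.nan)
        with pytest.raises(ValueError):
            run_mcmc(X, FsModel(), iters=10, burnin=0, thin=1, seed=0)


class TestCoincidence:
    def test_single_sample_is_binary(self, rng):
        X = _block_X()
        trace = run_mcmc(X, FsModel(c=1.0), iters=1, burnin=0, thin=1, seed=0)
        coin = pairwise_coincidence(trace)
        assert set(np.unique(coin)) <= {0.0, 1.0}

    def test_symmetric_unit_diagonal(self, rng):
        X = _block_X(jitter=0.5, rng=rng)
        trace = run_mcmc(X, FsModel(c=1.0), iters=2000, burnin=1000, thin=5,
                         seed=1)
        coin = pairwise_coincidence(trace)
        np.testing.assert_allclose(coin, coin.T)
        np.testing.assert_allclose(np.diag(coin), 1.0)

    def test_two_seeds_agree_on_strong_fixture(self, rng):
        X = _block_X(jitter=0.5, rng=rng)
        t1 = run_mcmc(X, FsModel(c=1.0), iters=4000, burnin=4000, thin=10,
                      seed=1)
        t2 = run_mcmc(X, FsModel(c=1.0), iters=4000, burnin=4000, thin=10,
                      seed=2)
        report = convergence_compare(t1, t2, threshold=0.05)
        assert report["converged"]

    def test_identical_traces_zero_difference(self, rng):
        X = _block_X(jitter=0.5, rng=rng)
        t1 = run_mcmc(X, FsModel(c=1.0), iters=1000, burnin=500, thin=5,
                      seed=1)
        report = convergence_compare(t1, t1)
        assert report["max_abs_diff"] == 0.0

    def test_unconverged_run_is_flagged(self, rng):
        """A run denied its burnin still sits near the K=1 start and must
        disagree with a converged run."""
        X = _block_X(jitter=0.5, rng=rng)
        good = run_mcmc(X, FsModel(c=1.0), iters=4000, burnin=4000, thin=10,
                        seed=1)
        bad = run_mcmc(X, FsModel(c=1.0), iters=2, burnin=0, thin=1, seed=2)
        report = convergence_compare(good, bad, threshold=0.05)
        assert not report["converged"]

    def test_mismatched_sizes_rejected(self, rng):
        X1 = _block_X(n_per=4)
        X2 = _block_X(n_per=5)
        t1 = run_mcmc(X1, FsModel(c=1.0), iters=10, burnin=0, thin=1, seed=0)
        t2 = run_mcmc(X2, FsModel(c=1.0), iters=10, burnin=0, thin=1, seed=0)
        with pytest.raises(ValueError):
            convergence_compare(t1, t2)


class TestMapSearch:
    def test_never_decreases_and_finds_fixture_truth(self, rng):
        X = _block_X(jitter=0.5, rng=rng)
        truth = Partition([0] * 6 + [1] * 6)
        trace = run_mcmc(X, FsModel(c=1.0), iters=2000, burnin=2000, thin=10,
                         seed=3)
        m = FsModel(c=1.0)
        start = trace.map_sample()
        found = map_search(trace, X, m)
        assert log_marginal_posterior(found, X, m) >= \
            log_marginal_posterior(start, X, m)
        assert found == truth

    def test_global_optimum_is_fixed_point(self, rng):
        """If the trace already contains the optimum, hill climbing keeps it."""
        X = _block_X(jitter=0.5, rng=rng)
        truth = Partition([0] * 6 + [1] * 6)

        class Stub:
            def map_sample(self):
                return truth

        assert map_search(Stub(), X, FsModel(c=1.0)) == truth


class TestStructureEquivalence:
    @pytest.mark.parametrize("seed", [7, 8, 9])
    def test_rank_agreement_with_genotype_likelihood(self, seed):
        """Under moderate structure and an empirically calibrated c, the
        partition ordering agrees with a no-admixture genotype marginal
        likelihood (integrated Beta(1,1) frequencies) over every partition
        of 8 individuals."""
        rng = np.random.default_rng(seed)
        N, L, f = 8, 800, 0.02
        panc = rng.uniform(0.1, 0.9, L)
        p1 = rng.beta(panc * (1 - f) / f, (1 - panc) * (1 - f) / f)
        p2 = rng.beta(panc * (1 - f) / f, (1 - panc) * (1 - f) / f)
        G = np.empty((N, L), dtype=int)
        for i in range(4):
            G[i] = rng.binomial(2, p1)
        for i in range(4, 8):
            G[i] = rng.binomial(2, p2)
        X = unlinked_coancestry(G, ploidy=2)
        blocks = [unlinked_coancestry(G[:, s:s + L // 10], ploidy=2)
                  for s in range(0, L, L // 10)]
        model = FsModel(c=estimate_c(blocks))

        def structure_score(part):
            s = 0.0
            for grp in part.groups():
                x = G[grp].sum(axis=0)
                n2 = 2 * len(grp)
                s += np.sum(betaln(1 + x, 1 + n2 - x) - betaln(1, 1))
            return s + dp_log_prior(part, 1.0)

        parts = list(all_partitions(N))
        mine = np.array([log_marginal_posterior(p, X, model) for p in parts])
        theirs = np.array([structure_score(p) for p in parts])
        rho, _ = spearmanr(mine, theirs)
        assert rho > 0.9
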