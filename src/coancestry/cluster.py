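"""Bayesian clustering of individuals from the coancestry matrix.

Individuals are partitioned into populations; within a population every
member is assumed to draw its chunks from the same latent donor-proportion
vector.  A conjugate Dirichlet prior over each population's donor
proportions lets those proportions be integrated out analytically, leaving
a marginal posterior over partitions (times a Chinese-restaurant-process
prior on the partition itself), which is explored by Metropolis-Hastings
MCMC with merge / split / merge-resplit / single-individual moves.

Model, pinned form (see docs/methods.md):

* counts: ``y_ib`` = chunks individual ``i`` receives from population
  ``b``, divided by the normalizer ``c``; rescaled counts enter Gamma
  functions so need not be integers;
* per recipient population ``a``, donor proportions
  ``P_a ~ Dirichlet(beta_a)`` with
  ``beta_ab = kappa (1 + delta 1[a=b]) (n_b - 1[a=b]) / (N - 1)``:
  ``kappa`` is a shared variance scale, ``delta`` boosts expected
  within-population sharing, and sizes are self-exclusion adjusted because
  individuals cannot donate to themselves;
* within population ``b`` the donated mass is spread uniformly over its
  ``n_b - 1[a=b]`` eligible members.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.special import gammaln

__all__ = [
    "Partition",
    "FsModel",
    "McmcTrace",
    "dp_log_prior",
    "log_marginal_posterior",
    "propose",
    "run_mcmc",
    "pairwise_coincidence",
    "convergence_compare",
    "map_search",
    "FineStructureModel",
    "FineStructureResults",
]


# ---------------------------------------------------------------------------
# partitions


def _canonical(assign) -> np.ndarray:
    """Relabel groups by order of first appearance (label-free form)."""
    assign = np.asarray(assign, dtype=np.int64)
    out = np.empty_like(assign)
    seen: dict[int, int] = {}
    for idx, a in enumerate(assign):
        if a not in seen:
            seen[a] = len(seen)
        out[idx] = seen[a]
    return out


@dataclass(frozen=True)
class Partition:
    """Unlabeled assignment of N individuals into K non-empty groups.

    Stored canonically (groups numbered by first appearance), so two
    partitions identical up to relabeling compare equal and hash equal —
    the unordered co-assignment view of the state.
    """

    assignment: tuple

    def __init__(self, assignment):
        object.__setattr__(self, "assignment",
                           tuple(int(x) for x in _canonical(assignment)))

    @classmethod
    def from_groups(cls, groups, n: int | None = None) -> "Partition":
        n = n if n is not None else sum(len(g) for g in groups)
        assign = np.full(n, -1, dtype=np.int64)
        for lbl, g in enumerate(groups):
            assign[list(g)] = lbl
        if (assign < 0).any():
            raise ValueError("groups do not cover all individuals")
        return cls(assign)

    @property
    def n(self) -> int:
        return len(self.assignment)

    @property
    def k(self) -> int:
        return max(self.assignment) + 1

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(np.asarray(self.assignment))

    def groups(self) -> list[list[int]]:
        out = [[] for _ in range(self.k)]
        for i, a in enumerate(self.assignment):
            out[a].append(i)
        return out

    def co_assignment(self) -> np.ndarray:
        a = np.asarray(self.assignment)
        return (a[:, None] == a[None, :]).astype(float)


@dataclass
class FsModel:
    """Hyperparameters of the partition posterior.

    c
        Chunk normalizer dividing the coancestry counts; fixed during MCMC.
    delta, kappa
        Within-population Dirichlet boost and shared variance scale;
        both updated by random-walk Metropolis under Gamma hyperpriors.
    alpha
        Dirichlet-process concentration (fixed by default).
    """

    c: float = 1.0
    delta: float = 1.0
    kappa: float = 1.0
    alpha: float = 1.0
    delta_hyper: tuple = (1.0, 1.0)  # Gamma(shape, rate)
    kappa_hyper: tuple = (1.0, 1.0)

    def __post_init__(self) -> None:
        for name in ("c", "delta", "kappa", "alpha"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


def dp_log_prior(partition: Partition, alpha: float) -> float:
    """Chinese-restaurant-process log probability of an unlabeled partition.

    ``P(z) = alpha^K prod_a (n_a - 1)! / (alpha (alpha+1) ... (alpha+N-1))``.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    sizes = partition.sizes
    n = partition.n
    return float(
        partition.k * np.log(alpha)
        + gammaln(sizes).sum()
        + gammaln(alpha)
        - gammaln(alpha + n)
    )


def log_marginal_posterior(partition: Partition, X: np.ndarray,
                           model: FsModel) -> float:
    """Log posterior of a partition with donor proportions integrated out.

    Up to an additive constant shared by all partitions of the same data:
    the Dirichlet-multinomial marginal of the rescaled counts, the
    self-exclusion donor-spreading term, and the CRP prior.
    """
    X = np.asarray(X, dtype=float)
    n_ind = X.shape[0]
    assign = np.asarray(partition.assignment)
    if len(assign) != n_ind:
        raise ValueError("partition size does not match the matrix")
    K = partition.k
    sizes = np.bincount(assign, minlength=K).astype(float)
    if (sizes == 0).any():
        raise ValueError("empty group in partition")
    # population-aggregated rescaled counts: Y[a, b] = chunks received by
    # members of a from members of b, over c (diag(X)=0 handles self)
    R = np.zeros((K, n_ind))
    R[assign, np.arange(n_ind)] = 1.0
    Y = R @ (X / model.c) @ R.T
    eye = np.eye(K)
    ntilde = sizes[None, :] - eye
    beta = model.kappa * (1.0 + model.delta * eye) * ntilde / max(n_ind - 1, 1)
    valid = ntilde > 0  # singleton self-component is degenerate at zero
    total = 0.0
    bsum = beta.sum(axis=1)
    ysum = Y.sum(axis=1)
    total += float(np.sum(gammaln(bsum) - gammaln(bsum + ysum)))
    total += float(np.sum(gammaln(beta[valid] + Y[valid]) - gammaln(beta[valid])))
    total -= float(np.sum(Y[valid] * np.log(ntilde[valid])))
    return total + dp_log_prior(partition, model.alpha)


@njit(cache=True)
def _logpost_kernel(assign, Xc, delta, kappa, alpha):
    """Fast path for :func:`log_marginal_posterior` on rescaled counts.

    Mirrors the reference implementation exactly (tested to agree to
    1e-10); used inside the MCMC loop where the numpy version's overhead
    dominates.
    """
    N = assign.shape[0]
    K = 0
    for i in range(N):
        if assign[i] + 1 > K:
            K = assign[i] + 1
    sizes = np.zeros(K)
    for i in range(N):
        sizes[assign[i]] += 1.0
    Y = np.zeros((K, K))
    for i in range(N):
        a = assign[i]
        for j in range(N):
            Y[a, assign[j]] += Xc[i, j]
    total = 0.0
    denom = N - 1.0 if N > 1 else 1.0
    for a in range(K):
        bsum = 0.0
        ysum = 0.0
        for b in range(K):
            same = 1.0 if a == b else 0.0
            ntilde = sizes[b] - same
            beta = kappa * (1.0 + delta * same) * ntilde / denom
            bsum += beta
            ysum += Y[a, b]
            if ntilde > 0.0:
                total += math.lgamma(beta + Y[a, b]) - math.lgamma(beta)
                total -= Y[a, b] * math.log(ntilde)
        total += math.lgamma(bsum) - math.lgamma(bsum + ysum)
    # CRP prior
    total += K * math.log(alpha) + math.lgamma(alpha) - math.lgamma(alpha + N)
    for a in range(K):
        total += math.lgamma(sizes[a])
    return total


# ---------------------------------------------------------------------------
# MCMC moves

MOVES = ("merge", "split", "merge_resplit", "move_individual")


def _score_assign(assign: np.ndarray, scorer) -> float:
    # labels need to be compact and non-empty for the posterior kernel;
    # np.unique relabels by sorted value, which the posterior is invariant to
    _, inv = np.unique(assign, return_inverse=True)
    return scorer(inv.astype(np.int64))


def _seq_allocate(assign, pool, i, j, label_i, label_j, rng, scorer,
                  target=None, order=None):
    """Sequentially allocate ``pool`` members between two seeded parts.

    ``i`` and ``j`` seed parts ``label_i`` / ``label_j``; remaining members
    are visited in a uniformly random order and sent to one part with
    probability proportional to (when ``scorer`` is given) the exponential
    of the partial-configuration score, the not-yet-allocated block keeping
    a temporary label of its own; without a scorer the two parts are
    equiprobable.  Returns ``(assign, log_prob)`` for the sampled outcome,
    or the log-probability of reproducing ``target`` (a boolean array over
    ``pool``: True means ``label_i``) under the same allocation order.
    """
    if isinstance(scorer, tuple):
        return _seq_allocate_fast(assign, pool, i, j, label_i, label_j, rng,
                                  scorer, target=target, order=order)
    assign = assign.copy()
    rest_label = int(assign.max()) + 2
    pool = np.asarray(pool)
    rest = pool[(pool != i) & (pool != j)]
    if order is None:
        order = rng.permutation(rest)
    assign[rest] = rest_label
    assign[i] = label_i
    assign[j] = label_j
    idx_of = {m: t for t, m in enumerate(pool)}
    logq = 0.0
    for m in order:
        if scorer is None:
            lp_i = lp_j = np.log(0.5)
        else:
            assign[m] = label_i
            s_i = _score_assign(assign, scorer)
            assign[m] = label_j
            s_j = _score_assign(assign, scorer)
            tot = np.logaddexp(s_i, s_j)
            lp_i, lp_j = s_i - tot, s_j - tot
        if target is None:
            go_i = np.log(rng.random()) < lp_i
        else:
            go_i = bool(target[idx_of[m]])
        assign[m] = label_i if go_i else label_j
        logq += lp_i if go_i else lp_j
    return assign, logq, order


@njit(cache=True)
def _affected_terms(Y, sizes, p1, p2, delta, kappa, alpha, N):
    """Posterior terms that differ between placing a pending member in one
    of two parts: the full rows of both parts, the two parts' columns in
    every other row, the parts' Dirichlet-normaliser terms, and the CRP
    size factorials.  All other terms are identical for the two candidate
    placements and cancel in the allocation log-odds."""
    G = sizes.shape[0]
    denom = N - 1.0 if N > 1 else 1.0
    total = 0.0
    for a in range(G):
        if sizes[a] <= 0.0:
            continue
        if a == p1 or a == p2:
            bsum = 0.0
            ysum = 0.0
            for b in range(G):
                if sizes[b] <= 0.0:
                    continue
                same = 1.0 if a == b else 0.0
                ntilde = sizes[b] - same
                beta = kappa * (1.0 + delta * same) * ntilde / denom
                bsum += beta
                ysum += Y[a, b]
                if ntilde > 0.0:
                    total += math.lgamma(beta + Y[a, b]) - math.lgamma(beta)
                    total -= Y[a, b] * math.log(ntilde)
            total += math.lgamma(bsum) - math.lgamma(bsum + ysum)
        else:
            for b in (p1, p2):
                if sizes[b] <= 0.0:
                    continue
                ntilde = sizes[b]  # a != b here
                beta = kappa * ntilde / denom
                if ntilde > 0.0:
                    total += math.lgamma(beta + Y[a, b]) - math.lgamma(beta)
                    total -= Y[a, b] * math.log(ntilde)
    total += math.lgamma(sizes[p1]) + math.lgamma(sizes[p2])
    return total


@njit(cache=True)
def _alloc_loop(Xc, work, order, u, target, use_target, p1, p2, rest,
                delta, kappa, alpha):
    """Sequential allocation with incremental group-count bookkeeping.

    ``work`` holds the current compact labels with pending members in group
    ``rest``; members listed in ``order`` are moved to part ``p1`` or
    ``p2`` one at a time, with log-odds from the exact posterior difference
    of the two partial configurations.  Samples when ``use_target`` is
    false (consuming one uniform per member), otherwise accumulates the
    log-probability of reproducing ``target``.  Returns the allocation
    log-probability; ``work`` is updated in place.
    """
    N = work.shape[0]
    G = 0
    for idx in range(N):
        if work[idx] + 1 > G:
            G = work[idx] + 1
    sizes = np.zeros(G)
    for idx in range(N):
        sizes[work[idx]] += 1.0
    Y = np.zeros((G, G))
    for a_i in range(N):
        la = work[a_i]
        for b_i in range(N):
            Y[la, work[b_i]] += Xc[a_i, b_i]
    srow = np.zeros(G)
    scol = np.zeros(G)
    logq = 0.0
    for t in range(order.shape[0]):
        m = order[t]
        # detach m from rest
        for g in range(G):
            srow[g] = 0.0
            scol[g] = 0.0
        for j in range(N):
            if j != m:
                srow[work[j]] += Xc[m, j]
                scol[work[j]] += Xc[j, m]
        for g in range(G):
            Y[rest, g] -= srow[g]
            Y[g, rest] -= scol[g]
        sizes[rest] -= 1.0
        work[m] = -1
        # candidate placements
        s12 = np.empty(2)
        for cand in range(2):
            p = p1 if cand == 0 else p2
            for g in range(G):
                Y[p, g] += srow[g]
                Y[g, p] += scol[g]
            sizes[p] += 1.0
            s12[cand] = _affected_terms(Y, sizes, p1, p2, delta, kappa,
                                        alpha, N)
            for g in range(G):
                Y[p, g] -= srow[g]
                Y[g, p] -= scol[g]
            sizes[p] -= 1.0
        d = s12[0] - s12[1]
        # log softmax from the difference alone
        if d >= 0.0:
            lp1 = -math.log1p(math.exp(-d))
            lp2 = lp1 - d
        else:
            lp2 = -math.log1p(math.exp(d))
            lp1 = lp2 + d
        if use_target:
            go1 = target[t]
        else:
            go1 = math.log(u[t]) < lp1
        p = p1 if go1 else p2
        for g in range(G):
            Y[p, g] += srow[g]
            Y[g, p] += scol[g]
        sizes[p] += 1.0
        work[m] = p
        logq += lp1 if go1 else lp2
    return logq


def _seq_allocate_fast(assign, pool, i, j, label_i, label_j, rng, params,
                       target=None, order=None):
    """Numba-backed equivalent of the scorer path of :func:`_seq_allocate`.

    ``params`` is ``(Xc, delta, kappa, alpha)``.  Consumes the rng in the
    same pattern as the slow path (one permutation, then one uniform per
    sampled member), so the two paths are interchangeable draw-for-draw.
    """
    Xc, delta, kappa, alpha = params
    assign = np.asarray(assign)
    pool = np.asarray(pool)
    rest = pool[(pool != i) & (pool != j)]
    if order is None:
        order = rng.permutation(rest)
    # compact working labels: base groups 0..B-1, then part1, part2, rest
    mask = np.ones(len(assign), dtype=bool)
    mask[pool] = False
    base = np.unique(assign[mask])
    remap = -np.ones(int(assign.max()) + 3, dtype=np.int64)
    remap[base] = np.arange(len(base))
    work = remap[assign]
    B = len(base)
    p1, p2, rl = B, B + 1, B + 2
    work[rest] = rl
    work[i] = p1
    work[j] = p2
    if target is None:
        u = rng.random(len(order))
        tgt = np.zeros(len(order), dtype=np.bool_)
        use_target = False
    else:
        u = np.empty(0)
        idx_of = {m: t for t, m in enumerate(pool)}
        tgt = np.array([bool(target[idx_of[m]]) for m in order])
        use_target = True
    logq = _alloc_loop(Xc, work, order.astype(np.int64), u, tgt, use_target,
                       p1, p2, rl, delta, kappa, alpha)
    # map back to the caller's labelling
    out = np.asarray(assign).copy()
    out[work == p1] = label_i
    out[work == p2] = label_j
    return out, float(logq), order


def _move_dests(sizes, K: int, src: int) -> list:
    """Valid destinations for a single-individual move.

    Other existing groups, plus a fresh singleton group when the source
    keeps at least one member.  A destination that would collapse the
    partition to K=1 is excluded: single-individual moves never cross the
    K=1 boundary (merge/split do), keeping the move self-reversible.
    """
    dests = [g for g in range(K) if g != src]
    if sizes[src] == 1 and K == 2:
        dests = []
    if sizes[src] >= 2:
        dests.append(K)
    return dests


def propose(partition: Partition, move: str, rng: np.random.Generator,
            scorer=None):
    """Propose a modified partition; returns ``(proposal, log_hastings)``.

    ``log_hastings`` is ``log q(z'->z) - log q(z->z')``; an invalid move for
    the current state returns ``(None, -inf)`` and is rejected
    deterministically.

    Merge, split and merge-resplit are keyed by a uniformly drawn ordered
    pair of individuals ``(i, j)`` plus a uniformly drawn allocation order
    (a sequentially-allocated merge-split scheme): if ``i`` and ``j`` share
    a group, that group can be split with ``i``/``j`` seeding the two
    parts; if they differ, their two groups can be merged (or merged and
    resplit).  For a fixed pair and order the merge direction is
    deterministic while the split direction has an exactly computable
    allocation probability, giving a valid Hastings ratio; ``scorer``
    (a callable on assignment arrays, e.g. the posterior kernel) steers
    the allocation toward high-posterior splits and may be ``None`` for
    equiprobable allocation.
    """
    assign = np.asarray(partition.assignment)
    K = partition.k
    N = partition.n
    sizes = partition.sizes
    neginf = float("-inf")

    if move in ("merge", "split", "merge_resplit"):
        i = int(rng.integers(N))
        j = int(rng.integers(N - 1))
        j += j >= i
        same = assign[i] == assign[j]

        if move == "split":
            if not same:
                return None, neginf
            g = assign[i]
            pool = np.flatnonzero(assign == g)
            new, log_fwd, _ = _seq_allocate(assign, pool, i, j, g, K, rng,
                                            scorer)
            # reverse: merging the groups of i and j is deterministic
            return Partition(new), -log_fwd

        if move == "merge":
            if same:
                return None, neginf
            a, b = assign[i], assign[j]
            pool = np.flatnonzero((assign == a) | (assign == b))
            new = assign.copy()
            new[new == b] = a
            # reverse: split of the merged group seeded by (i, j) must
            # reproduce the current bipartition under the same order
            target = assign[pool] == a
            _, log_rev, _ = _seq_allocate(new, pool, i, j, a,
                                          int(new.max()) + 1, rng, scorer,
                                          target=target)
            return Partition(new), log_rev

        # merge_resplit: pool the two groups and re-allocate around (i, j)
        if same:
            return None, neginf
        a, b = assign[i], assign[j]
        pool = np.flatnonzero((assign == a) | (assign == b))
        merged = assign.copy()
        merged[pool] = a
        new, log_fwd, order = _seq_allocate(merged, pool, i, j, a, b, rng,
                                            scorer)
        target = assign[pool] == a
        _, log_rev, _ = _seq_allocate(merged, pool, i, j, a, b, rng, scorer,
                                      target=target, order=order)
        return Partition(new), log_rev - log_fwd

    if move == "move_individual":
        if K < 2:
            return None, neginf
        i = int(rng.integers(N))
        dests = _move_dests(sizes, K, assign[i])
        if not dests:
            return None, neginf
        d = dests[int(rng.integers(len(dests)))]
        new = assign.copy()
        new[i] = d
        prop = Partition(new)
        log_fwd = -np.log(N) - np.log(len(dests))
        rev_dests = _move_dests(prop.sizes, prop.k, prop.assignment[i])
        log_rev = -np.log(N) - np.log(len(rev_dests))
        return prop, log_rev - log_fwd

    raise ValueError(f"unknown move {move!r}")


# ---------------------------------------------------------------------------
# the chain


@dataclass
class McmcTrace:
    """Recorded post-burnin samples at the thinning interval."""

    assignments: np.ndarray  # (S, N) canonical labels
    delta: np.ndarray
    kappa: np.ndarray
    logpost: np.ndarray
    seed: int
    acceptance: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.assignments.shape[0]

    @property
    def n(self) -> int:
        return self.assignments.shape[1]

    def k_values(self) -> np.ndarray:
        return self.assignments.max(axis=1) + 1

    def partitions(self):
        return [Partition(a) for a in self.assignments]

    def map_sample(self) -> Partition:
        return Partition(self.assignments[int(np.argmax(self.logpost))])


def run_mcmc(
    X: np.ndarray,
    model: FsModel,
    iters: int = 100_000,
    burnin: int = 100_000,
    thin: int = 100,
    seed: int = 0,
    likelihood_on: bool = True,
    init: Partition | None = None,
    update_hypers: bool = True,
) -> McmcTrace:
    """Metropolis-Hastings sampler over partitions (and delta, kappa).

    Each iteration proposes one partition move chosen uniformly from
    merge / split / merge-resplit / move-individual, then random-walk
    updates of ``delta`` and ``kappa`` on the log scale under their Gamma
    hyperpriors.  With ``likelihood_on=False`` the chain targets the CRP
    prior alone (used to validate the moves).
    """
    X = np.asarray(X, dtype=float)
    N = X.shape[0]
    rng = np.random.default_rng(seed)
    state = init if init is not None else Partition(np.zeros(N, dtype=int))
    model = FsModel(**{**model.__dict__})
    Xc = X / model.c

    def score(p: Partition, m: FsModel) -> float:
        if likelihood_on:
            return float(_logpost_kernel(np.asarray(p.assignment, np.int64),
                                         Xc, m.delta, m.kappa, m.alpha))
        return dp_log_prior(p, m.alpha)

    cur = score(state, model)
    if not np.isfinite(cur):
        raise ValueError("non-finite posterior at the initial state")


    S = iters // thin
    out_assign = np.empty((S, N), dtype=np.int64)
    out_delta = np.empty(S)
    out_kappa = np.empty(S)
    out_logpost = np.empty(S)
    att = dict.fromkeys(MOVES, 0)
    acc = dict.fromkeys(MOVES, 0)
    s_idx = 0
    for it in range(burnin + iters):
        move = MOVES[int(rng.integers(len(MOVES)))]
        att[move] += 1
        alloc = (Xc, model.delta, model.kappa, model.alpha) \
            if likelihood_on else None
        prop, log_h = propose(state, move, rng, scorer=alloc)
        if prop is not None:
            new = score(prop, model)
            if np.log(rng.random()) < new - cur + log_h:
                state, cur = prop, new
                acc[move] += 1
        if likelihood_on and update_hypers:
            for name, hyper in (("delta", model.delta_hyper),
                                ("kappa", model.kappa_hyper)):
                old = getattr(model, name)
                newv = old * np.exp(0.5 * rng.standard_normal())
                shape, rate = hyper
                # log-scale RW: include the Jacobian old->new
                setattr(model, name, newv)
                cand = score(state, model)
                log_r = (cand - cur
                         + shape * (np.log(newv) - np.log(old))
                         - rate * (newv - old))
                if np.log(rng.random()) < log_r:
                    cur = cand
                else:
                    setattr(model, name, old)
        if it >= burnin and (it - burnin) % thin == thin - 1 and s_idx < S:
            out_assign[s_idx] = state.assignment
            out_delta[s_idx] = model.delta
            out_kappa[s_idx] = model.kappa
            out_logpost[s_idx] = cur
            s_idx += 1
    return McmcTrace(
        assignments=out_assign[:s_idx],
        delta=out_delta[:s_idx],
        kappa=out_kappa[:s_idx],
        logpost=out_logpost[:s_idx],
        seed=seed,
        acceptance={m: (acc[m], att[m]) for m in MOVES},
    )


def pairwise_coincidence(trace: McmcTrace) -> np.ndarray:
    """Posterior co-assignment probability per pair; symmetric, unit diagonal."""
    if trace.n_samples == 0:
        raise ValueError("empty trace")
    A = trace.assignments
    out = np.zeros((trace.n, trace.n))
    for a in A:
        out += a[:, None] == a[None, :]
    return out / trace.n_samples


def convergence_compare(trace_a: McmcTrace, trace_b: McmcTrace,
                        threshold: float = 0.05) -> dict:
    """Compare coincidence matrices of two independent runs.

    Converged runs differ only by Monte-Carlo error; the report gives the
    max and mean absolute per-pair difference and a pass flag at
    ``threshold``.
    """
    if trace_a.n != trace_b.n:
        raise ValueError("traces are over different numbers of individuals")
    d = np.abs(pairwise_coincidence(trace_a) - pairwise_coincidence(trace_b))
    off = ~np.eye(trace_a.n, dtype=bool)
    return {
        "max_abs_diff": float(d[off].max()) if off.any() else 0.0,
        "mean_abs_diff": float(d[off].mean()) if off.any() else 0.0,
        "threshold": threshold,
        "converged": bool(d[off].max() <= threshold) if off.any() else True,
    }


def map_search(trace: McmcTrace, X: np.ndarray, model: FsModel,
               max_rounds: int = 50) -> Partition:
    """Hill-climb from the best trace sample to a local posterior optimum.

    Deterministic first-improvement scans in fixed individual order:
    single-individual reassignments (including opening a new group),
    then all pairwise merges; repeated until no move strictly increases the
    posterior.
    """
    X = np.asarray(X, dtype=float)
    Xc = X / model.c

    def _score(p: Partition) -> float:
        return float(_logpost_kernel(np.asarray(p.assignment, np.int64), Xc,
                                     model.delta, model.kappa, model.alpha))

    state = trace.map_sample()
    cur = _score(state)
    for _ in range(max_rounds):
        improved = False
        # individual reassignments
        for i in range(state.n):
            assign = np.asarray(state.assignment)
            K = state.k
            src = assign[i]
            dests = [g for g in range(K) if g != src]
            if state.sizes[src] >= 2:
                dests.append(K)
            for d in dests:
                new = assign.copy()
                new[i] = d
                cand = Partition(new)
                val = _score(cand)
                if val > cur:
                    state, cur = cand, val
                    improved = True
                    break
        # pairwise merges
        K = state.k
        for a in range(K - 1):
            if a >= state.k - 1:
                break
            for b in range(a + 1, state.k):
                assign = np.asarray(state.assignment)
                new = assign.copy()
                new[new == b] = a
                cand = Partition(new)
                val = _score(cand)
                if val > cur:
                    state, cur = cand, val
                    improved = True
                    break
        if not improved:
            break
    return state


# ---------------------------------------------------------------------------
# model / results front end


class FineStructureModel:
    """Model object: partition inference from a coancestry matrix.

    Parameters
    ----------
    X
        ``(N, N)`` coancestry matrix (zero diagonal).
    c
        Chunk normalizer; required (estimate it with
        :func:`coancestry.calibration.estimate_c` or the unlinked closed
        form).
    alpha, delta, kappa
        Prior settings; ``delta`` and ``kappa`` are starting values for
        their MH updates.
    """

    def __init__(self, X, c: float, alpha: float = 1.0, delta: float = 1.0,
                 kappa: float = 1.0, labels=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] != X.shape[1]:
            raise ValueError("X must be square")
        if (X < 0).any():
            raise ValueError("X must be non-negative")
        self.X = X
        self.model = FsModel(c=c, alpha=alpha, delta=delta, kappa=kappa)
        self.labels = labels

    def fit(self, iters: int = 100_000, burnin: int = 100_000,
            thin: int = 100, seed: int = 0) -> "FineStructureResults":
        trace = run_mcmc(self.X, self.model, iters=iters, burnin=burnin,
                         thin=thin, seed=seed)
        map_part = map_search(trace, self.X, self.model)
        return FineStructureResults(self, trace, map_part)


class FineStructureResults:
    """Posterior summaries of a fitted partition model."""

    def __init__(self, parent: FineStructureModel, trace: McmcTrace,
                 map_partition: Partition):
        self.model = parent
        self.trace = trace
        self.map_partition = map_partition

    def coincidence(self) -> np.ndarray:
        return pairwise_coincidence(self.trace)

    def k_posterior(self) -> dict:
        vals, counts = np.unique(self.trace.k_values(), return_counts=True)
        return {int(v): int(c) for v, c in zip(vals, counts)}

    @property
    def map_logpost(self) -> float:
        return log_marginal_posterior(self.map_partition, self.model.X,
                                      self.model.model)

    def summary(self) -> str:
        kp = self.k_posterior()
        mode_k = max(kp, key=kp.get)
        lines = [
            "fineSTRUCTURE-style partition inference",
            f"  individuals:        {self.trace.n}",
            f"  samples:            {self.trace.n_samples}",
            f"  posterior K mode:   {mode_k}",
            f"  K posterior:        {kp}",
            f"  MAP K:              {self.map_partition.k}",
            f"  MAP log-posterior:  {self.map_logpost:.4f}",
            f"  delta (post. mean): {self.trace.delta.mean():.4f}",
            f"  kappa (post. mean): {self.trace.kappa.mean():.4f}",
        ]
        for move, (a, t) in self.trace.acceptance.items():
            lines.append(f"  accept {move:<16s} {a}/{t}")
        return "\n".join(lines)
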