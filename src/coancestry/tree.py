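"""Greedy population tree over the MAP partition.

Starting from the best partition found by MCMC, populations are merged one
pair at a time, always taking the merge with the highest marginal posterior,
until a single group remains; the merge order defines a bifurcating tree.
Within-population counts mostly reflect private drift and would block every
merge, so before scoring, the population-level count matrix has its diagonal
"flattened" to the row's next-highest value.

The tree is a similarity guide: it is built from the clustering posterior,
not from any model of population differentiation, and the emitted newick
carries a comment saying so.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cluster import FsModel, Partition, dp_log_prior, log_marginal_posterior

__all__ = ["PopTree", "flatten_diagonal", "build_tree", "to_newick", "write_tree"]

NEWICK_CAVEAT = (
    "greedy-merge similarity tree; not based on a model of population"
    " differentiation"
)


@dataclass
class PopTree:
    """Binary merge tree whose leaves are the MAP populations.

    ``merges`` lists ``(left, right, score)`` node indices in merge order:
    leaves are nodes ``0..K-1`` (the MAP populations, in canonical order),
    internal nodes are numbered on from ``K``.  ``score`` is the marginal
    log-posterior of the partition in force after the merge.
    """

    leaves: list  # member lists per MAP population
    merges: list  # (node_a, node_b, score)
    leaf_names: list | None = None

    @property
    def k(self) -> int:
        return len(self.leaves)

    def names(self) -> list[str]:
        return self.leaf_names or [f"pop{i}" for i in range(self.k)]


def flatten_diagonal(X_pop: np.ndarray) -> np.ndarray:
    """Replace each diagonal entry with its row's largest off-diagonal value.

    Off-diagonal entries are untouched; a 1x1 matrix is returned unchanged.
    """
    X_pop = np.asarray(X_pop, dtype=float)
    if X_pop.shape[0] != X_pop.shape[1]:
        raise ValueError("population matrix must be square")
    out = X_pop.copy()
    K = out.shape[0]
    if K == 1:
        return out
    masked = out + np.where(np.eye(K, dtype=bool), -np.inf, 0.0)
    np.fill_diagonal(out, masked.max(axis=1))
    return out


def _pop_aggregate(X: np.ndarray, partition: Partition) -> np.ndarray:
    assign = np.asarray(partition.assignment)
    K = partition.k
    R = np.zeros((K, len(assign)))
    R[assign, np.arange(len(assign))] = 1.0
    return R @ X @ R.T


def _spread_to_individuals(F: np.ndarray, partition: Partition) -> np.ndarray:
    """Even per-pair redistribution of population-level counts.

    Produces an individual-level matrix with zero diagonal whose population
    aggregation equals ``F``; used so merge candidates can be scored with
    the same marginal posterior as the MCMC.
    """
    assign = np.asarray(partition.assignment)
    sizes = partition.sizes
    n = len(assign)
    a = assign[:, None]
    b = assign[None, :]
    pairs = sizes[a].astype(float) * (sizes[b] - (a == b)).astype(float)
    out = F[a, b] / np.where(pairs > 0, pairs, 1.0)
    np.fill_diagonal(out, 0.0)
    return out


def build_tree(
    map_partition: Partition,
    X: np.ndarray,
    model: FsModel,
    flatten: bool = True,
    include_prior: bool = True,
    names: list | None = None,
) -> PopTree:
    """Greedy bifurcating merge tree over the MAP populations.

    At each of the ``K - 1`` steps every pairwise merge of current groups is
    scored by the marginal partition posterior (on the diagonal-flattened,
    evenly redistributed counts) and the argmax taken; ties break on the
    smallest population indices.  ``include_prior=False`` scores merges by
    the integrated likelihood alone, without the CRP term.
    """
    X = np.asarray(X, dtype=float)
    leaves = map_partition.groups()
    K = len(leaves)
    F = flatten_diagonal(_pop_aggregate(X, map_partition)) if flatten else \
        _pop_aggregate(X, map_partition)
    Xf = _spread_to_individuals(F, map_partition)

    def score(p: Partition) -> float:
        val = log_marginal_posterior(p, Xf, model)
        if not include_prior:
            val -= dp_log_prior(p, model.alpha)
        return val

    # active maps current group label -> tree node index
    assign = np.asarray(map_partition.assignment).copy()
    active = {g: g for g in range(K)}
    next_node = K
    merges = []
    while len(active) > 1:
        labels = sorted(active)
        best = None
        for ia, ga in enumerate(labels):
            for gb in labels[ia + 1 :]:
                cand = assign.copy()
                cand[cand == gb] = ga
                val = score(Partition(cand))
                if best is None or val > best[0]:
                    best = (val, ga, gb)
        val, ga, gb = best
        merges.append((active[ga], active[gb], float(val)))
        assign[assign == gb] = ga
        active[ga] = next_node
        del active[gb]
        next_node += 1
    return PopTree(leaves=leaves, merges=merges, leaf_names=names)


def to_newick(tree: PopTree, decimals: int = 4) -> str:
    """Newick string with merge scores as internal-node support values."""
    names = tree.names()
    reps = {i: names[i] for i in range(tree.k)}
    node = tree.k
    for a, b, score in tree.merges:
        reps[node] = f"({reps.pop(a)},{reps.pop(b)}){score:.{decimals}f}"
        node += 1
    (root,) = reps.values()
    return root + ";"


def write_tree(tree: PopTree, path) -> None:
    from pathlib import Path

    Path(path).write_text(f"[{NEWICK_CAVEAT}]\n{to_newick(tree)}\n")
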