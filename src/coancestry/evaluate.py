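"""Scoring utilities: partition agreement and half-genome pairing.

``partition_correlation`` quantifies agreement between an inferred and a
true partition as the Pearson correlation between the off-diagonal entries
of their co-assignment indicator matrices — label-free, bounded in
``[-1, 1]``, and equal to 1 exactly when the partitions coincide up to
relabeling.

``half_genome_pairing`` is the self-validation scheme for inferred fine
structure: the two halves of one individual's genome share their ancestry
exactly, so if painting profiles carry individual-level signal, an
individual's "A" half should be matched (by profile correlation) to its own
"B" half more often than label- or population-sharing alone predicts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cluster import Partition
from .io import HaplotypePanel
from .painting import PaintingParams, build_coancestry

__all__ = [
    "partition_correlation",
    "PairingReport",
    "half_genome_pairing",
    "hudson_fst",
]


def partition_correlation(estimated: Partition, truth: Partition) -> float:
    """Pearson correlation of off-diagonal co-assignment indicators.

    1.0 iff the partitions are identical up to group labels.  When either
    indicator vector is constant (all-in-one or all-singleton partitions)
    the correlation is degenerate; identical partitions score 1, otherwise
    0 by convention.
    """
    if estimated.n != truth.n:
        raise ValueError("partitions are over different numbers of individuals")
    if estimated == truth:
        return 1.0
    n = estimated.n
    off = ~np.eye(n, dtype=bool)
    a = estimated.co_assignment()[off]
    b = truth.co_assignment()[off]
    if a.std() == 0.0 or b.std() == 0.0:
        return 1.0 if estimated == truth else 0.0
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class PairingReport:
    """Outcome of the half-genome matching validation."""

    success_fraction: float
    n_targets: int
    matched: np.ndarray  # per-target correct-match flag
    label_baseline: float | None = None
    population_baseline: float | None = None

    def summary(self) -> str:
        lines = [
            "Half-genome pairing",
            f"  targets:              {self.n_targets}",
            f"  matched to self:      {self.success_fraction:.3f}",
        ]
        if self.label_baseline is not None:
            lines.append(f"  label baseline:       {self.label_baseline:.3f}")
        if self.population_baseline is not None:
            lines.append(
                f"  population baseline:  {self.population_baseline:.3f}")
        return "\n".join(lines)


def _subpanel(panel: HaplotypePanel, individuals) -> HaplotypePanel:
    individuals = list(individuals)
    haps = np.concatenate([panel.haps_of(i) for i in individuals])
    hap_to_ind = np.repeat(np.arange(len(individuals)), panel.ploidy)
    return HaplotypePanel(panel.alleles[haps], panel.positions,
                          chrom=panel.chrom, hap_to_ind=hap_to_ind)


def _profiles(panels, maps, params, targets, donors):
    """Chunk-count profile of each target against a fixed donor set."""
    profiles = np.zeros((len(targets), len(donors)))
    for t_idx, t in enumerate(targets):
        sub_panels = [_subpanel(p, list(donors) + [t]) for p in panels]
        res = build_coancestry(sub_panels, maps, params)
        profiles[t_idx] = res.X[len(donors), :len(donors)]
    return profiles


def half_genome_pairing(
    panels,
    maps=None,
    params: PaintingParams | None = None,
    labels: list | None = None,
    populations: Partition | None = None,
) -> PairingReport:
    """Match genome halves across individuals by painting-profile similarity.

    The sample is split approximately evenly within each label into two
    halves; each half in turn provides the common donor set against which
    every individual of the other half is painted twice — once on the
    even-index regions (half "A") and once on the odd-index regions (half
    "B").  Each A profile is paired with the most Pearson-correlated B
    profile; the report gives the fraction paired to the same individual,
    with chance baselines for label-level and (optionally) inferred
    population-level profile sharing.
    """
    params = params or PaintingParams()
    if isinstance(panels, HaplotypePanel):
        panels = [panels]
    if len(panels) < 2:
        raise ValueError("half-genome pairing needs at least 2 regions")
    if maps is None:
        maps = [None] * len(panels)
    N = panels[0].n_ind
    if labels is None:
        labels = panels[0].labels or ["all"] * N
    labels = list(labels)

    # split each label's individuals alternately into the two sample halves
    half_of = np.zeros(N, dtype=int)
    for lab in dict.fromkeys(labels):
        members = [i for i in range(N) if labels[i] == lab]
        for rank, i in enumerate(members):
            half_of[i] = rank % 2
    even = [p for r, p in enumerate(panels) if r % 2 == 0]
    odd = [p for r, p in enumerate(panels) if r % 2 == 1]
    even_maps = [m for r, m in enumerate(maps) if r % 2 == 0]
    odd_maps = [m for r, m in enumerate(maps) if r % 2 == 1]

    matched = []
    base_label = []
    base_pop = []
    pops = None
    if populations is not None:
        pops = np.asarray(populations.assignment)
    for donors_half in (0, 1):
        donors = [i for i in range(N) if half_of[i] == donors_half]
        targets = [i for i in range(N) if half_of[i] != donors_half]
        if len(donors) < 2 or len(targets) < 1:
            continue
        prof_a = _profiles(even, even_maps, params, targets, donors)
        prof_b = _profiles(odd, odd_maps, params, targets, donors)
        za = prof_a - prof_a.mean(axis=1, keepdims=True)
        zb = prof_b - prof_b.mean(axis=1, keepdims=True)
        za /= np.linalg.norm(za, axis=1, keepdims=True)
        zb /= np.linalg.norm(zb, axis=1, keepdims=True)
        corr = za @ zb.T
        best = corr.argmax(axis=1)
        matched.extend(best == np.arange(len(targets)))
        for i in targets:
            same_lab = sum(1 for j in targets if labels[j] == labels[i])
            base_label.append(1.0 / same_lab)
            if pops is not None:
                same_pop = sum(1 for j in targets if pops[j] == pops[i])
                base_pop.append(1.0 / same_pop)
    matched = np.asarray(matched, dtype=bool)
    return PairingReport(
        success_fraction=float(matched.mean()),
        n_targets=int(matched.size),
        matched=matched,
        label_baseline=float(np.mean(base_label)) if base_label else None,
        population_baseline=float(np.mean(base_pop)) if base_pop else None,
    )


def linked_vs_unlinked_sweep(
    scenario,
    region_counts,
    seed: int = 0,
    mcmc_iters: int = 30_000,
    mcmc_burnin: int = 30_000,
    thin: int = 30,
    em_iters: int = 6,
) -> dict:
    """Partition recovery versus genome size, linked against unlinked.

    Simulates ``scenario`` once at its full region count, paints every
    region under both models (the recombination scaling fitted by EM on the
    first two regions), then for each entry of ``region_counts`` runs the
    clustering on the first ``R`` regions' summed matrices, with the chunk
    normalizer re-estimated from those regions' contributions.  Returns the
    truth correlation per region count for both models and the smallest
    region count achieving perfect recovery (``inf`` if none does).
    """
    from .calibration import estimate_c
    from .cluster import FineStructureModel
    from .painting import build_coancestry, unlinked_coancestry, em_fit_rho
    from .simulate import simulate_linked

    region_counts = sorted(region_counts)
    if scenario.n_regions < max(region_counts):
        raise ValueError("scenario holds fewer regions than requested")
    pairs = simulate_linked(scenario, seed=seed)
    panels = [p for p, _ in pairs]
    maps = [m for _, m in pairs]
    labels = panels[0].labels
    leaf_id = {lab: i for i, lab in enumerate(dict.fromkeys(labels))}
    truth = Partition([leaf_id[lab] for lab in labels])
    rho, _, _ = em_fit_rho(panels[:2], maps[:2],
                           PaintingParams(rho=2000.0, n_em_iters=em_iters))
    params = PaintingParams(rho=rho)
    linked = [build_coancestry(p, m, params).X for p, m in zip(panels, maps)]
    unlinked = [unlinked_coancestry(p) for p in panels]
    out = {"region_counts": list(region_counts), "rho": float(rho),
           "linked_corr": [], "unlinked_corr": [],
           "linked_k": [], "unlinked_k": []}
    for mode, mats in (("linked", linked), ("unlinked", unlinked)):
        for R in region_counts:
            X = np.sum(mats[:R], axis=0)
            c = estimate_c(mats[:R])
            res = FineStructureModel(X, c=c).fit(
                iters=mcmc_iters, burnin=mcmc_burnin, thin=thin, seed=seed)
            out[f"{mode}_corr"].append(
                partition_correlation(res.map_partition, truth))
            out[f"{mode}_k"].append(res.map_partition.k)
    for mode in ("linked", "unlinked"):
        perfect = [R for R, r in zip(region_counts, out[f"{mode}_corr"])
                   if r >= 1.0 - 1e-12]
        out[f"{mode}_min_perfect"] = min(perfect) if perfect else float("inf")
    return out


def hudson_fst(panel: HaplotypePanel | np.ndarray, pop_of) -> np.ndarray:
    """Pairwise Hudson FST between populations (ratio-of-averages form)."""
    if isinstance(panel, HaplotypePanel):
        alleles = panel.alleles
        pop_of = np.repeat(np.asarray(pop_of), panel.ploidy) if \
            len(pop_of) == panel.n_ind else np.asarray(pop_of)
    else:
        alleles = np.asarray(panel)
        pop_of = np.asarray(pop_of)
    pops = np.unique(pop_of)
    K = len(pops)
    p = np.stack([alleles[pop_of == g].mean(axis=0) for g in pops])
    n = np.array([(pop_of == g).sum() for g in pops], dtype=float)
    out = np.zeros((K, K))
    for a in range(K):
        for b in range(a + 1, K):
            pa, pb = p[a], p[b]
            num = ((pa - pb) ** 2
                   - pa * (1 - pa) / (n[a] - 1)
                   - pb * (1 - pb) / (n[b] - 1))
            den = pa * (1 - pb) + pb * (1 - pa)
            fst = num.sum() / den.sum()
            out[a, b] = out[b, a] = fst
    return out
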