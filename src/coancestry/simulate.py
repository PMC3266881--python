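"""Synthetic panels with known population structure.

Two generators over the same :class:`Scenario` (a population tree with
per-branch drift):

* :func:`simulate_unlinked` — independent SNPs: ancestral frequencies are
  drawn once, each branch applies Balding-Nichols (beta) drift, and
  haplotypes are Bernoulli draws from the leaf frequencies.  No LD by
  construction.
* :func:`simulate_linked` — recombining 5 Mb-style regions sampled with
  msprime under the same tree, converting each branch's drift ``F`` to a
  divergence time ``t = -2 Ne ln(1 - F)``; emits phased haplotypes and the
  true (uniform) map per region, so the linked painting model can exploit
  real LD decay.

The ``fig2`` preset encodes the five-population scenario used throughout
the tests: A splits earliest, then B and C, each of which recently split in
two (B1/B2 the most recent), 20 diploids per population by default, with
differentiation at the few-percent FST level typical of within-continent
human structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import msprime
import numpy as np

from .io import GeneticMap, HaplotypePanel

__all__ = [
    "Scenario",
    "fig2_scenario",
    "simulate_tree_freqs",
    "simulate_unlinked",
    "simulate_linked",
]


@dataclass
class Scenario:
    """Population tree with per-branch drift plus sampling plan.

    nodes
        ``(name, parent, drift)`` triples; parent ``None`` for the root.
        ``drift`` in (0, 1) is the Balding-Nichols differentiation accrued
        along the branch from the parent.  Leaves (nodes that are nobody's
        parent) are the sampled populations.
    sample_sizes
        Diploid individuals per leaf population.
    n_regions, region_bp
        Number and physical length of independent recombining regions.
    rec_rate, mut_rate
        Per-bp per-generation rates for the linked generator.  The defaults
        implement a rescaled-coalescent design: with ``ne = 1000`` they hold
        per-bp diversity (``4 Ne mu ~ 1e-3``) and LD decay
        (``4 Ne r ~ 4e-4/bp``) at human sequence-data levels, so one 0.5 Mb
        region carries about 5 cM of map and ~3000 common SNPs — the
        information content of a several-Mb human region at a fraction of
        the compute.
    ne
        Diploid effective size within each population branch.
    maf_floor
        Minimum sample minor-allele frequency; lower-frequency unlinked
        sites are redrawn and lower-frequency linked sites dropped.
    """

    nodes: list = field(default_factory=list)
    sample_sizes: dict = field(default_factory=dict)
    n_regions: int = 10
    region_bp: float = 5e5
    rec_rate: float = 1e-7
    mut_rate: float = 2.5e-7
    ne: float = 1000.0
    maf_floor: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        names = [n for n, _, _ in self.nodes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate node names")
        for _, parent, drift in self.nodes:
            if parent is not None and not 0.0 < drift < 1.0:
                raise ValueError("branch drift must lie in (0, 1)")
        for leaf in self.leaves():
            if self.sample_sizes.get(leaf, 0) < 1:
                raise ValueError(f"leaf {leaf!r} needs a sample size >= 1")

    def leaves(self) -> list:
        parents = {p for _, p, _ in self.nodes if p is not None}
        return [n for n, _, _ in self.nodes if n not in parents]

    def labels(self) -> list:
        out = []
        for leaf in self.leaves():
            out.extend([leaf] * int(self.sample_sizes[leaf]))
        return out

    def n_ind(self) -> int:
        return sum(int(self.sample_sizes[l]) for l in self.leaves())


def fig2_scenario(per_pop: int = 20, n_regions: int = 10,
                  region_bp: float = 5e5, seed: int = 0) -> Scenario:
    """Five populations related by three nested splits.

    A diverges first; the BC ancestor then splits into B and C; B1/B2 and
    C1/C2 are recent splits, B1/B2 the most subtle pair.
    """
    nodes = [
        ("root", None, 0.0),
        ("A", "root", 0.075),
        ("BC", "root", 0.040),
        ("B", "BC", 0.020),
        ("C", "BC", 0.025),
        ("B1", "B", 0.015),
        ("B2", "B", 0.015),
        ("C1", "C", 0.020),
        ("C2", "C", 0.020),
    ]
    sizes = {p: per_pop for p in ("A", "B1", "B2", "C1", "C2")}
    return Scenario(nodes=nodes, sample_sizes=sizes, n_regions=n_regions,
                    region_bp=region_bp, seed=seed)


def simulate_tree_freqs(scenario: Scenario, L: int,
                        rng: np.random.Generator | None = None) -> dict:
    """Per-population allele frequencies after hierarchical drift.

    Ancestral frequencies are Uniform(0.05, 0.95); along each branch with
    drift ``F`` the child frequency is Balding-Nichols:
    ``p' ~ Beta(p (1-F)/F, (1-p)(1-F)/F)`` (mean ``p``, variance
    ``F p (1-p)``), so sister populations stay more correlated than distant
    ones.  Returns ``{node name: (L,) frequency array}`` for all nodes.
    """
    rng = rng if rng is not None else np.random.default_rng(scenario.seed)
    freqs: dict = {}
    pending = list(scenario.nodes)
    while pending:
        nxt = []
        for name, parent, drift in pending:
            if parent is None:
                freqs[name] = rng.uniform(0.05, 0.95, size=L)
            elif parent in freqs:
                p = freqs[parent]
                if drift <= 0:
                    freqs[name] = p.copy()
                else:
                    a = p * (1.0 - drift) / drift
                    b = (1.0 - p) * (1.0 - drift) / drift
                    q = rng.beta(a, b)
                    freqs[name] = np.clip(q, 1e-9, 1.0 - 1e-9)
            else:
                nxt.append((name, parent, drift))
                continue
        if len(nxt) == len(pending):
            raise ValueError("tree has an unreachable node")
        pending = nxt
    return freqs


def simulate_unlinked(scenario: Scenario, L: int,
                      seed: int | None = None) -> HaplotypePanel:
    """Independent-SNP panel: Bernoulli draws from leaf frequencies.

    Sites whose realised sample minor-allele frequency falls below the
    scenario's floor are redrawn (with fresh frequencies), so the emitted
    spectrum respects the floor exactly.
    """
    if not 0.0 <= scenario.maf_floor < 0.5:
        raise ValueError("maf_floor must lie in [0, 0.5)")
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    leaves = scenario.leaves()
    n_hap_per = {l: 2 * int(scenario.sample_sizes[l]) for l in leaves}
    H = sum(n_hap_per.values())
    out = np.empty((H, 0), dtype=np.int8)
    need = L
    while need > 0:
        draw = max(need * 2, 64)
        freqs = simulate_tree_freqs(scenario, draw, rng)
        cols = []
        for leaf in leaves:
            p = freqs[leaf]
            cols.append((rng.random((n_hap_per[leaf], draw)) < p).astype(np.int8))
        block = np.concatenate(cols, axis=0)
        maf = block.mean(axis=0)
        maf = np.minimum(maf, 1.0 - maf)
        block = block[:, maf >= scenario.maf_floor]
        take = min(need, block.shape[1])
        out = np.concatenate([out, block[:, :take]], axis=1)
        need -= take
    return HaplotypePanel(out, np.arange(1, L + 1, dtype=np.int64) * 1000,
                          chrom="un", labels=scenario.labels())


def _demography(scenario: Scenario) -> msprime.Demography:
    dem = msprime.Demography()
    children: dict = {}
    for name, parent, _ in scenario.nodes:
        dem.add_population(name=name, initial_size=scenario.ne)
        if parent is not None:
            children.setdefault(parent, []).append(name)
    # drift F on a branch corresponds to residence time t = -2 Ne ln(1 - F)
    depth: dict = {}

    def leaf_depth(name: str) -> float:
        if name in depth:
            return depth[name]
        kids = children.get(name)
        if not kids:
            d = 0.0
        else:
            d = max(leaf_depth(k) + _branch_time(scenario, k) for k in kids)
        depth[name] = d
        return d

    def _branch_time(sc: Scenario, node: str) -> float:
        drift = next(dr for n, _, dr in sc.nodes if n == node)
        return -2.0 * sc.ne * np.log(1.0 - drift)

    # schedule splits shallowest-first: each internal node absorbs its children
    internal = [n for n, _, _ in scenario.nodes if n in children]
    events = []
    for node in internal:
        t = leaf_depth(node)
        events.append((t, node, children[node]))
    for t, node, kids in sorted(events, key=lambda e: e[0]):
        dem.add_population_split(time=max(t, 1e-9), derived=kids,
                                 ancestral=node)
    return dem


def simulate_linked(scenario: Scenario, seed: int | None = None) -> list:
    """Recombining regions under the population tree.

    Returns ``[(HaplotypePanel, GeneticMap), ...]`` with one pair per
    region: coalescent-with-recombination sampling at human-like per-bp
    rates, biallelic sites only, minor-allele frequency floor applied, and
    the true uniform map attached.  Byte-identical for a fixed seed.
    """
    base_seed = scenario.seed if seed is None else seed
    rng = np.random.default_rng(base_seed)
    leaves = scenario.leaves()
    dem = _demography(scenario)
    samples = {l: int(scenario.sample_sizes[l]) for l in leaves}
    out = []
    labels = scenario.labels()
    for _ in range(scenario.n_regions):
        s1, s2 = rng.integers(1, 2**31 - 1, size=2)
        ts = msprime.sim_ancestry(
            samples=samples,
            demography=dem,
            sequence_length=scenario.region_bp,
            recombination_rate=scenario.rec_rate,
            random_seed=int(s1),
        )
        mts = msprime.sim_mutations(ts, rate=scenario.mut_rate,
                                    random_seed=int(s2))
        G = mts.genotype_matrix()  # (sites, haps)
        biallelic = np.array(
            [len(s.alleles) == 2 for s in mts.sites()], dtype=bool
        )
        pos = np.array([s.position for s in mts.sites()])
        G = G[biallelic]
        pos = pos[biallelic]
        maf = G.mean(axis=1)
        maf = np.minimum(maf, 1.0 - maf)
        keep = maf >= scenario.maf_floor
        G, pos = G[keep], pos[keep]
        # floor() can collide; keep the first site at each integer position
        floors = np.floor(pos).astype(np.int64) + 1
        _, first = np.unique(floors, return_index=True)
        G, ipos = G[first], floors[first]
        panel = HaplotypePanel(G.T.astype(np.int8), ipos, chrom="sim",
                               labels=labels)
        gmap = GeneticMap.uniform(scenario.rec_rate / 1e-8)
        out.append((panel, gmap))
    return out


def with_regions(scenario: Scenario, n_regions: int) -> Scenario:
    return replace(scenario, n_regions=n_regions)
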