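# Methods

This note documents the statistical models implemented in `coancestry`,
the choices made where a design was genuinely open, and what the synthetic
data used by the test suite does and does not establish.

## Chromosome painting

Each haplotype in the sample (the *recipient*) is modelled as a mosaic of
segments copied from the haplotypes of all **other** individuals (the
*donors*), under the Li & Stephens copying model. The hidden state at site
`l` is the donor haplotype being copied; the model is pinned as:

- **Initial state**: uniform over the `k` donor haplotypes.
- **Transitions**: between adjacent sites at genetic distance `g` Morgans,
  a recombination occurs with probability `1 − exp(−ρ g)`; given a
  recombination the new donor is drawn uniformly from all `k` donors
  (possibly the same one). `ρ` is a single global switch rate per Morgan,
  shared by all individuals.
- **Emission**: the recipient allele equals the donor allele with
  probability `1 − μ` and differs with probability `μ` (symmetric miscopy,
  no allele-frequency weighting). By default
  `μ = θ̃ / (2 (k + θ̃))` with Watterson's estimator
  `θ̃ = 1 / Σ_{m=1}^{k−1} 1/m`.

A *chunk* is a maximal copied segment; every recombination event starts a
new chunk, including a recombination that re-selects the same donor. This
convention makes the expected total chunk count per haplotype equal
`1 + E[#recombinations]`, and makes the infinite-recombination limit
(below) exact. Expected chunk counts per donor are accumulated from the
scaled linear-space forward–backward recursions as
`P(donor d at site 1) + Σ_l P(recombination in interval l ∧ donor d at l)`;
expected donated lengths use trapezoidal per-site genetic spans, and
expected mismatch counts use the same site posteriors. Per-site rescaling
of the forward vector prevents underflow and yields the log-likelihood.
Forward–backward output is verified against exhaustive enumeration of all
(donor path × recombination indicator) combinations on small instances, to
1e−10.

Aggregating expected chunk counts from donor haplotypes to donor
individuals, summing over both recipient haplotypes and over chromosomes,
gives the coancestry matrix `X` (recipients × donors, zero diagonal), plus
the analogous lengths `Y` and mismatch counts `M`.

**EM for ρ.** The E-step computes the posterior expected number of
recombinations per inter-site interval from the same forward–backward
pass; the M-step maximises the expected complete-data log-likelihood
`Σ_l [R_l log(1−e^{−ρ g_l}) − (H − R_l) ρ g_l]` in `log ρ` (root of the
score by bisection). The observed-data log-likelihood is non-decreasing
across iterations. θ stays fixed at the Watterson value by default; a flag
re-estimates it from the expected mismatch fraction.

## The unlinked special case

As `ρ → ∞` every site becomes its own chunk and the matrix has a closed
form: at each site a recipient haplotype with allele `a` weights each
donor haplotype by the match emission (`1−μ` if the donor carries `a`,
`μ` otherwise), normalised over the donor set. The computation only needs
genotype dosages, never phase. Sites whose minor allele is carried by a
single individual are uninformative (all matching haplotypes are excluded
as donors) and are dropped first.

Because each recipient's normaliser depends on its own excluded genotypes,
the raw recipient-by-donor matrix is only symmetric to `O(1/N)`; it is,
however, the *exact* `ρ → ∞` limit of the linked painting, which the tests
verify to 1e−6. The matrix handed to downstream inference is the
donor/recipient average `(X + Xᵀ)/2`, which is symmetric to machine
precision; `symmetrize=False` exposes the raw limit.

## PCA

The (linked) coancestry matrix is slightly asymmetric, so it is
symmetrised by averaging with its transpose and then doubly centered.
For unlinked data the centered matrix is an affine rescaling of the
genotype covariance used by Eigenstrat-style PCA, up to one systematic
difference: self-copying is excluded, which (after centering) shifts the
whole non-trivial spectrum downward by a near-uniform constant. The shift
preserves the ordering of the meaningful eigenvectors but parks the exact
zero eigenvalue of the trivial constant direction in the middle of the
spectrum; `pca` therefore drops the constant direction of a centered
matrix before ordering eigenpairs (which also caps the components at
N−1). With that convention the top components of the unlinked matrix and
of the Eigenstrat reference agree to |r| > 0.99 on structured panels, and
the same eigenanalysis applied to the linked matrix additionally exploits
LD.

## Clustering model

Individuals are partitioned into populations. Writing `y_ib` for the
chunks individual `i` receives from population `b` and `n_b` for
population sizes, the model says every member of population `a` draws its
chunks i.i.d. from a population-level donor-proportion vector `P_a`, with
the donated mass spread uniformly over the `n_b − 1[a=b]` eligible members
(individuals cannot donate to themselves). The counts enter divided by a
normalizer `c` (below); rescaled counts are not integers, which is fine
because the likelihood only involves Gamma functions.

The prior on each row is conjugate:
`P_a ~ Dirichlet(β_a)` with

    β_ab = κ (1 + δ 1[a=b]) (n_b − 1[a=b]) / (N − 1)

so `κ` is a shared variance scale, `δ` boosts expected within-population
sharing, and the base measure donates proportionally to (self-exclusion
adjusted) population size. Integrating `P` analytically leaves a
closed-form marginal per recipient population (ratios of multivariate Beta
functions) plus the donor-spreading term `−Σ y_ab log(n_b − 1[a=b])`; a
singleton population's self-component is degenerate at zero and is
dropped. The partition itself gets a Chinese-restaurant-process prior with
concentration `α` (fixed at 1 by default); `δ` and `κ` get broad Gamma(1,1)
hyperpriors and are updated by log-scale random-walk Metropolis. The
analytic marginal is validated against adaptive quadrature of the
Dirichlet integrals on toy counts.

### MCMC moves

Four move types are mixed uniformly: merge, split, merge-then-resplit and
single-individual reassignment. The first three are keyed by a uniformly
drawn ordered pair of individuals plus a uniformly drawn allocation order
(a sequentially-allocated merge-split scheme): when the pair shares a
group, that group may be split with the two individuals seeding the two
parts and the remaining members allocated one at a time with probability
proportional to the exponential of the partial-configuration posterior;
when the pair spans two groups, those groups may be merged (deterministic)
or pooled and resplit around the pair. For a fixed pair and order the
allocation probability of any outcome is an exact product, giving exact
Hastings ratios in both directions; with the likelihood switched off the
chain reproduces the enumerated CRP distribution to the Monte-Carlo floor,
which is the test that pins the bookkeeping. Posterior-guided allocation
is what lets the sampler propose subtle splits that uniform bipartitions
would essentially never find. Single-individual moves may open a new
group; destinations that would collapse the partition to K=1 are excluded
so the move stays self-reversible (merges handle the K=1 boundary).

The MAP state is the best trace sample refined by deterministic
first-improvement hill climbing (individual reassignments in fixed order,
then pairwise merges) — ties therefore resolve deterministically.
Convergence is assessed by comparing pairwise coincidence matrices of
independently seeded runs, never assumed.

## The normalizer c

`c` converts expected chunk counts into an effective number of independent
multinomial draws. It is estimated by variance matching: the painting
accumulates per-region contributions (default regions: 5 cM of genetic
map, since the independence argument is recombinational) inside a single
forward–backward pass, so region matrices sum exactly to `X`; `c` is the
ratio of the mean observed between-region variance to the variance
predicted by the rescaled multinomial model at the fitted proportions.

The match is made on symmetric pair sums `X_ij + X_ji`, not on single
entries. A shared haplotype tract is counted once in each direction, so
the two directed counts are positively correlated — while the multinomial
likelihood treats recipient rows as independent. Matching pair sums
charges that duplication to `c` (inflating it by one plus the pair
correlation: a factor near 2 for unlinked sites, less for linked chunks,
and exactly neutral for genuinely independent multinomial rows). Matching
single entries instead leaves the duplication uncharged and produces
spurious splits on structureless data; the structureless-panel check in
the suite guards this.

For truly unlinked, non-rare markers with no structure the match has a
closed form. One site's donation from individual `i` to `j` is
approximately `Σ_a g_i^a g_j^a / n_a` (allele-dosage products over allele
counts), whose variance under binomial genotype sampling is exactly
`ploidy² / n²` *independent of the allele frequency* while its mean is
`ploidy² / n`; the same quantity flows in both directions (pair
correlation → 1), so equating the pair-sum variance to the two-entry
multinomial prediction gives

    c_unlinked = 2 ploidy (N − 1)² / ((ploidy N)² (N − 2))  ≈  1/N

for diploids. The smoothing of the expectation step makes the unlinked
matrix far less variable than one multinomial draw per site, so the
effective chunk count is much larger than the site count. This is a
leading-order result: finite samples add `O(1/N)` relative error (about
+3% at N=100) and rare variants inflate the variance, so the test suite
checks the empirical estimator against the closed form at N=100 on
non-rare sites, within 10%. On structured data the empirical estimator
exceeds the unstructured closed form — by design, since between-region
genealogical noise is real variance the multinomial must absorb.

A known limit (inherited from the model): with *strong* structure and
truly unlinked data the multinomial form degrades; the package does not
implement a modified-count correction for that regime and documents the
moderate-structure assumption instead. Within that regime the partition
ordering of the integrated likelihood agrees with a no-admixture
genotype marginal likelihood (integrated Beta(1,1) frequencies) at rank
correlation > 0.9 over all partitions of 8 individuals, which is the
package's check that coancestry clustering and classical genotype
clustering use the same information on unlinked data.

## Tree building

Starting from the MAP partition, populations are merged greedily: each
step scores all pairwise merges with the same marginal posterior
(optionally without the CRP term) and takes the argmax, ties breaking on
the smallest population indices; K−1 merges give a bifurcating tree with
the merge-step log posterior as internal support. Before scoring, the
population-level count matrix has each diagonal entry replaced by its
row's largest off-diagonal value ("diagonal flattening") and is spread
evenly back over individual pairs: within-population counts mostly
reflect private drift and would otherwise veto every merge. The tree is a
similarity guide built from the clustering posterior — it is not derived
from any model of population differentiation, and the emitted newick
carries a comment saying so.

## Synthetic data

The `Scenario` object is a population tree with a Balding–Nichols drift
parameter `F ∈ (0,1)` per branch.

- **Unlinked panels**: ancestral frequencies Uniform(0.05, 0.95), each
  branch draws `p' ~ Beta(p(1−F)/F, (1−p)(1−F)/F)` (mean `p`, variance
  `F p (1−p)`), haplotypes are Bernoulli draws from leaf frequencies, and
  sites below the minor-allele-frequency floor (default 0.05) are redrawn.
  No LD by construction.
- **Linked regions**: coalescent-with-recombination sampling (msprime)
  under the same tree, with branch drift converted to divergence time via
  `t = −2 Ne ln(1 − F)`. The default regime is a rescaled design: a small
  effective size (Ne = 1000) with per-bp rates inflated
  (μ = 2.5e−7, r = 1e−7) so that per-bp diversity (`4Neμ ≈ 1e−3`) and LD
  decay (`4Ner ≈ 4e−4`/bp) sit at human sequence-data levels. One 0.5 Mb
  region then carries ~5 cM of genetic map and ~3000 common SNPs — the
  information content of a several-Mb human region at a fraction of the
  compute. The generator emits phased haplotypes plus the true uniform
  map per region.

The `fig2` preset is the five-population scenario used throughout the
tests: population A splits earliest (branch F = 0.075), the BC ancestor
then splits into B and C (0.020/0.025 after a shared 0.040 branch), and
each recently split in two (B1/B2 at F = 0.015 each — the hardest pair —
and C1/C2 at 0.020), with 20 diploids per population. Pairwise FST runs
from ~0.015 (B1–B2) to ~0.12 (A vs the rest): within-continent human
levels, with the subtlest split deliberately near the detection threshold
for the genome sizes the tests use.

What passing tests show — and what they do not: the generator produces
drift-structured, recombining, phased data with realistic diversity and
LD decay, but no admixture, no phasing error, no genotyping error, no
ascertainment bias, and uniform maps. Results on it validate the
inference machinery, not robustness to those real-data complications
(phasing error in particular is known to matter for linked painting).

## Problem sizes used by the checks

The acceptance script and end-to-end tests run deliberately reduced
versions of the full experiments: exhaustive-enumeration checks at ≤4
sites × ≤6 donors; the unlinked limit at 20 individuals × 200 SNPs; PCA
agreement at N=100, 5000 SNPs; CRP recovery at N=6 with 1e6 sweeps;
single-population robustness at N=50 with 2000 SNPs; calibration at
N=100 with 15000 non-rare SNPs; the linked-versus-unlinked sweep over
{2, 4, 8, 16} regions at 3 seeds; tree recovery over 20 replicates; and
half-genome pairing on a 30-individual, 6-region version of the preset.
At these sizes the linked model reaches perfect recovery of all five
populations by 16 regions while the unlinked model does not, mirroring at
reduced scale the full-size finding that LD-aware painting needs
substantially less genome for the same resolution.

## Numerical notes

- Forward–backward runs in scaled linear space (per-site normalisers),
  not log space; agreement with enumeration to 1e−10 is part of the suite.
- `1 − exp(−ρg)` is computed via `expm1` where small intervals matter.
- The posterior kernel used inside the MCMC is an exact reimplementation
  of the reference marginal (agreement to 1e−9 is a test), with
  incremental count updates during sequential allocation.
- Genetic maps integrate cM/Mb rates trapezoidally; coordinates outside a
  map extend the edge rate; absent maps fall back to uniform 1 cM/Mb.
- Degenerate inputs are errors, not silent defaults: fewer than 4
  haplotypes, non-biallelic sites in strict mode, all-singleton panels,
  a single calibration region, zero between-region variance, empty donor
  sets, non-finite posteriors at the MCMC start.
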