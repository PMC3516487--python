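"""Neutral coalescent simulation with infinite-sites mutation.

Implements the standard Hudson coalescent for a single equilibrium
population and for a two-population split-with-migration model.  Time is
measured in units of 2N generations and the mutation parameter is the
locus-wide theta = 4*N*mu_locus, so the expected number of mutations on a
genealogy is (theta/2) * (total branch length).  A fixed-S mode places
exactly S mutations on the genealogy (branch chosen proportionally to its
length), the usual conditioning for null distributions of frequency-spectrum
statistics such as Tajima's D.

No intra-locus recombination is modelled: loci are short (~450 bp) Sanger
amplicons, and loci are treated as independent realizations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ratpopgen.errors import ModelError

SINGLE = "single"
SPLIT = "split"


def as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class DemographicModel:
    """Demography for one locus.

    Parameters
    ----------
    mode:
        ``"single"`` (one equilibrium population) or ``"split"`` (two
        populations of equal size N that merge, looking backwards, at
        ``split_time``).
    n_per_pop:
        Sampled allele counts, one entry per population.
    theta_locus:
        Locus-wide 4*N*mu (absolute, not per site).
    split_time:
        Population split time in units of 2N generations (split mode).
    migration_rate:
        Scaled migration rate 4*N*m between the two daughter populations
        (split mode); each lineage migrates backwards at rate
        ``migration_rate / 2``.
    L:
        Number of sites available for placing infinite-sites mutations.
    """

    mode: str
    n_per_pop: tuple[int, ...]
    theta_locus: float = 0.0
    split_time: float = 0.0
    migration_rate: float = 0.0
    L: int = 1000

    def __post_init__(self) -> None:
        if self.mode not in (SINGLE, SPLIT):
            raise ModelError(f"unknown mode {self.mode!r}")
        if self.mode == SINGLE and len(self.n_per_pop) != 1:
            raise ModelError("single mode takes exactly one sample size")
        if self.mode == SPLIT and len(self.n_per_pop) != 2:
            raise ModelError("split mode takes exactly two sample sizes")
        if sum(self.n_per_pop) < 2:
            raise ModelError("need at least two sampled alleles in total")
        if min(self.n_per_pop) < 0:
            raise ModelError("negative sample size")
        if self.theta_locus < 0 or self.split_time < 0 or self.migration_rate < 0:
            raise ModelError("theta, split_time and migration_rate must be >= 0")
        if self.L < 1:
            raise ModelError("L must be >= 1")

    @property
    def n_total(self) -> int:
        return int(sum(self.n_per_pop))


@dataclass
class Genealogy:
    """Binary coalescent tree over ``n`` leaves (nodes ``0..2n-2``, root
    last); ``time`` is the node age in units of 2N generations."""

    n: int
    parent: np.ndarray  # int, -1 at the root
    time: np.ndarray  # float node ages
    leaf_population: np.ndarray  # int population of each leaf

    @property
    def n_nodes(self) -> int:
        return 2 * self.n - 1

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def tmrca(self) -> float:
        return float(self.time[self.root])

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each non-root node (0 for the root)."""
        out = np.zeros(self.n_nodes)
        nonroot = np.arange(self.n_nodes - 1)
        out[nonroot] = self.time[self.parent[nonroot]] - self.time[nonroot]
        return out

    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def leaf_counts(self) -> np.ndarray:
        """Number of sampled leaves below each node (1 for leaves)."""
        out = np.zeros(self.n_nodes, dtype=np.int64)
        out[: self.n] = 1
        # children have smaller node ids than parents by construction
        for v in range(self.n_nodes - 1):
            out[self.parent[v]] += out[v]
        return out

    def leaves_under(self, node: int) -> np.ndarray:
        """Leaf ids in the subtree of ``node``."""
        member = np.zeros(self.n_nodes, dtype=bool)
        member[node] = True
        for v in range(self.n_nodes - 2, -1, -1):
            if member[self.parent[v]]:
                member[v] = True
        return np.flatnonzero(member[: self.n])

    def pair_tmrca(self, i: int, j: int) -> float:
        """Age of the most recent common ancestor of leaves i and j."""
        anc_i = set()
        v = i
        while v != -1:
            anc_i.add(v)
            v = int(self.parent[v])
        v = j
        while v not in anc_i:
            v = int(self.parent[v])
        return float(self.time[v])


@dataclass
class CoalescentReplicate:
    """One simulated locus: genealogy, infinite-sites mutations and the
    resulting 0/1 haplotypes (columns ordered by site position)."""

    genealogy: Genealogy
    mutations: list[tuple[int, int]]  # (site position, node below the branch)
    positions: np.ndarray  # int sites, ascending
    alleles: np.ndarray  # (n_samples, S) 0/1
    seed: int | None = None
    n_site_collisions: int = 0

    @property
    def S(self) -> int:
        return int(self.alleles.shape[1])

    def derived_counts(self) -> np.ndarray:
        return self.alleles.sum(axis=0)

    def mean_pairwise_differences(self) -> float:
        n = self.alleles.shape[0]
        c = self.derived_counts()
        return float((2.0 * c * (n - c) / (n * (n - 1))).sum())

    def tajima_d(self) -> float | None:
        from ratpopgen.diversity import tajima_d

        if self.S == 0:
            return None
        return tajima_d(self.S, self.mean_pairwise_differences(), self.alleles.shape[0])


def simulate_genealogy(
    model: DemographicModel, seed: int | np.random.Generator | None = None
) -> Genealogy:
    """Sample one genealogy under the model.

    Coalescence within a population of k lineages occurs at rate k*(k-1)/2
    per unit of 2N generations with a uniformly chosen pair merging; in split
    mode each lineage additionally migrates at rate ``migration_rate/2`` and
    the two populations are pooled at ``split_time`` (backwards in time).
    """
    rng = as_rng(seed)
    n = model.n_total
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    time = np.zeros(n_nodes)
    leaf_pop = np.zeros(n, dtype=np.int64)
    if model.mode == SPLIT:
        leaf_pop[model.n_per_pop[0] :] = 1

    # active lineages per population (single mode: everything in pop 0)
    pops: list[list[int]] = [list(range(model.n_per_pop[0]))]
    if model.mode == SPLIT:
        pops.append(list(range(model.n_per_pop[0], n)))
    merged = model.mode == SINGLE
    t = 0.0
    nxt = n
    mig = model.migration_rate / 2.0

    while nxt < n_nodes:
        ks = [len(p) for p in pops]
        coal_rates = [k * (k - 1) / 2.0 for k in ks]
        mig_rate = 0.0 if merged else mig * sum(ks)
        total = sum(coal_rates) + mig_rate
        if total == 0.0:
            # lone lineages stranded in separate populations: jump to the merge
            t = max(t, model.split_time)
            pops = [pops[0] + pops[1]]
            merged = True
            continue
        dt = rng.exponential(1.0 / total)
        if not merged and t + dt >= model.split_time:
            t = model.split_time
            pops = [pops[0] + pops[1]]
            merged = True
            continue
        t += dt
        u = rng.uniform(0.0, total)
        if u < mig_rate:
            # a uniformly chosen lineage switches population
            ks_cum = np.cumsum(ks)
            j = int(rng.integers(sum(ks)))
            src = 0 if j < ks_cum[0] else 1
            lineage = pops[src].pop(j - (0 if src == 0 else ks_cum[0]))
            pops[1 - src].append(lineage)
            continue
        u -= mig_rate
        pop_idx = 0
        for i, r in enumerate(coal_rates):
            if u < r:
                pop_idx = i
                break
            u -= r
        lineages = pops[pop_idx]
        i, j = rng.choice(len(lineages), size=2, replace=False)
        a, b = lineages[int(i)], lineages[int(j)]
        parent[a] = nxt
        parent[b] = nxt
        time[nxt] = t
        lineages[:] = [x for x in lineages if x not in (a, b)] + [nxt]
        nxt += 1

    return Genealogy(n=n, parent=parent, time=time, leaf_population=leaf_pop)


def _place_mutations(
    gen: Genealogy,
    n_mut: int,
    L: int,
    rng: np.random.Generator,
) -> tuple[list[tuple[int, int]], np.ndarray, np.ndarray, int]:
    """Assign ``n_mut`` mutations to branches (proportional to length) and to
    distinct uniform sites in 0..L-1, resampling site collisions."""
    lengths = gen.branch_lengths()[:-1]
    collisions = 0
    if n_mut == 0:
        return [], np.empty(0, dtype=np.int64), np.zeros((gen.n, 0), dtype=np.int8), 0
    probs = lengths / lengths.sum()
    nodes = rng.choice(len(lengths), size=n_mut, p=probs)
    used: set[int] = set()
    sites = []
    for _ in range(n_mut):
        while True:
            s = int(rng.integers(L))
            if s not in used:
                used.add(s)
                sites.append(s)
                break
            collisions += 1
            if len(used) >= L:
                raise ModelError(f"more mutations ({n_mut}) than sites (L={L})")
    order = np.argsort(sites)
    muts = [(sites[i], int(nodes[i])) for i in order]
    positions = np.array([m[0] for m in muts], dtype=np.int64)
    alleles = np.zeros((gen.n, n_mut), dtype=np.int8)
    for col, (_, node) in enumerate(muts):
        alleles[gen.leaves_under(node), col] = 1
    return muts, positions, alleles, collisions


def drop_mutations(
    gen: Genealogy,
    theta_locus: float,
    L: int,
    seed: int | np.random.Generator | None = None,
) -> CoalescentReplicate:
    """Poisson infinite-sites mutations: the count is Poisson with mean
    (theta_locus/2) * total branch length."""
    rng = as_rng(seed)
    if theta_locus < 0:
        raise ModelError("theta_locus must be >= 0")
    n_mut = int(rng.poisson(0.5 * theta_locus * gen.total_branch_length()))
    muts, pos, alleles, coll = _place_mutations(gen, n_mut, L, rng)
    return CoalescentReplicate(
        genealogy=gen, mutations=muts, positions=pos, alleles=alleles,
        n_site_collisions=coll,
    )


def simulate_fixed_s(
    model: DemographicModel, S: int, seed: int | np.random.Generator | None = None
) -> CoalescentReplicate:
    """Simulate a genealogy and place exactly S mutations on it."""
    if S < 1:
        raise ValueError("fixed-S mode needs S >= 1")
    rng = as_rng(seed)
    gen = simulate_genealogy(model, rng)
    muts, pos, alleles, coll = _place_mutations(gen, S, model.L, rng)
    return CoalescentReplicate(
        genealogy=gen, mutations=muts, positions=pos, alleles=alleles,
        n_site_collisions=coll,
    )


def fixed_s_tajima_null(
    n: int, S: int, n_reps: int, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Null distribution of Tajima's D under the standard coalescent
    conditioned on S segregating sites (single equilibrium population).

    A fast path: only branch lengths and leaf counts are needed, so no allele
    matrix is built.
    """
    from ratpopgen.diversity import tajima_constants

    rng = as_rng(seed)
    c = tajima_constants(n)
    denom = np.sqrt(c["e1"] * S + c["e2"] * S * (S - 1))
    model = DemographicModel(mode=SINGLE, n_per_pop=(n,))
    pair_norm = 2.0 / (n * (n - 1))
    out = np.empty(n_reps)
    for r in range(n_reps):
        gen = simulate_genealogy(model, rng)
        lengths = gen.branch_lengths()[:-1]
        counts = gen.leaf_counts()[:-1]
        nodes = rng.choice(len(lengths), size=S, p=lengths / lengths.sum())
        k = counts[nodes]
        k_bar = float((k * (n - k)).sum()) * pair_norm
        out[r] = (k_bar - S / c["a1"]) / denom
    return out


def replicate_to_tsv(rep: CoalescentReplicate, path) -> None:
    """Write the 0/1 haplotype matrix as TSV (rows = samples, columns = site
    positions)."""
    import pandas as pd

    df = pd.DataFrame(
        rep.alleles,
        columns=[f"site_{p}" for p in rep.positions],
        index=[f"sample_{i}" for i in range(rep.alleles.shape[0])],
    )
    df.to_csv(path, sep="\t")
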