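"""Structured-coalescent simulation of benchmark genotype datasets.

Simulates unlinked diallelic loci under demographies used to benchmark
cluster-number estimators: a star-shaped simultaneous split (``split``), a
caterpillar tree of successive splits (``tree``), a split followed by
symmetric island migration (``island_split``), and a star split with partial
self-fertilization within demes (``inbred``).

Conventions follow the classic coalescent simulator ``ms``: time is scaled
in units of 4N generations (so a within-deme lineage pair coalesces at rate
2), the migration parameter M = 4Nm is the scaled rate at which a lineage
migrates to each specific other deme, and every locus carries exactly one
segregating site placed uniformly on the genealogy's total branch length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genotypes import GenotypeTable

MODEL_KINDS = ("split", "tree", "island_split", "inbred")
_SELFING_GEN_CAP = 10  # generations of selfing tracked per individual


@dataclass
class DemographicModel:
    """Scenario descriptor.

    Parameters
    ----------
    kind
        One of ``split``, ``tree``, ``island_split``, ``inbred``.
    n_demes
        The true number of subpopulations K.
    split_time
        Divergence time tau of the (most recent) split, in 4N units.
    split_spacing
        For ``tree``: interval between successive splits (deepest split at
        ``split_spacing * (n_demes - 1)``).
    migration_rate
        For ``island_split``: scaled rate M = 4Nm per ordered deme pair.
    selfing_rates
        For ``inbred``: per-deme selfing probability in [0, 1). ``None``
        means sample one per deme per dataset from Uniform(0, 0.99).
    """

    kind: str
    n_demes: int
    split_time: float = 0.5
    split_spacing: float = 0.5
    migration_rate: float = 0.0
    selfing_rates: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.n_demes < 1:
            raise ValueError("n_demes must be >= 1")
        if self.split_time <= 0:
            raise ValueError("split_time must be > 0")
        if self.migration_rate < 0:
            raise ValueError("migration_rate must be >= 0")
        if self.selfing_rates is not None:
            s = np.asarray(self.selfing_rates, dtype=float)
            if s.shape != (self.n_demes,) or (s < 0).any() or (s >= 1).any():
                raise ValueError("selfing_rates must be n_demes values in [0, 1)")
            self.selfing_rates = s

    def merge_events(self) -> list[tuple[float, int, int]]:
        """Backward-time merge schedule as (time, source deme, target deme)."""
        k = self.n_demes
        if k == 1:
            return []
        if self.kind == "tree":
            # Caterpillar: demes k-1 and k-2 merge first, then successively
            # deeper joins at multiples of split_spacing.
            return [
                (self.split_spacing * j, k - j, k - j - 1) for j in range(1, k)
            ]
        return [(self.split_time, d, 0) for d in range(1, k)]


@dataclass
class SimConfig:
    individuals_per_deme: int = 50
    n_loci: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.individuals_per_deme < 1 or self.n_loci < 1:
            raise ValueError("counts must be > 0")


@dataclass
class SimSummary:
    """Dataset-level differentiation summary."""

    mean_pairwise_fst: float | None
    per_locus_fst: np.ndarray | None
    polymorphic_loci: int
    pairwise_fst: dict[tuple[int, int], float] = field(default_factory=dict)


@dataclass
class Genealogy:
    """Binary ultrametric tree over sampled haplotypes.

    Nodes ``0..n_leaves-1`` are tips at time 0; internal nodes are appended
    in coalescence order. ``parent[root] == -1``.
    """

    parent: np.ndarray
    node_time: np.ndarray
    n_leaves: int
    leaf_demes: np.ndarray

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent == -1)[0])

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each node (0 for the root)."""
        bl = np.zeros(len(self.parent))
        has_parent = self.parent >= 0
        bl[has_parent] = (
            self.node_time[self.parent[has_parent]] - self.node_time[has_parent]
        )
        return bl

    def total_length(self) -> float:
        return float(self.branch_lengths().sum())

    def leaves_below(self, node: int) -> np.ndarray:
        """Tip ids in the subtree rooted at ``node``."""
        children: list[list[int]] = [[] for _ in self.parent]
        for u, p in enumerate(self.parent):
            if p >= 0:
                children[p].append(u)
        out, stack = [], [node]
        while stack:
            u = stack.pop()
            if u < self.n_leaves:
                out.append(u)
            else:
                stack.extend(children[u])
        return np.array(sorted(out), dtype=np.int64)


def simulate_genealogy(
    model: DemographicModel,
    sample_sizes: list[int] | np.ndarray,
    rng: np.random.Generator | int,
) -> Genealogy:
    """Simulate one structured-coalescent genealogy.

    Within each deme a lineage pair coalesces at rate 2 (time in 4N units).
    Under ``island_split`` each lineage additionally migrates to each other
    deme at rate ``migration_rate`` until the demes merge at ``split_time``.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    sample_sizes = list(int(x) for x in sample_sizes)
    if len(sample_sizes) != model.n_demes or any(s < 1 for s in sample_sizes):
        raise ValueError("need one sample size >= 1 per deme")
    n_tips = sum(sample_sizes)
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    node_time = np.zeros(n_nodes)
    leaf_demes = np.repeat(np.arange(model.n_demes), sample_sizes)

    lineages: list[list[int]] = []
    tip = 0
    for d, s in enumerate(sample_sizes):
        lineages.append(list(range(tip, tip + s)))
        tip += s
    pending = sorted(model.merge_events())
    migration_on = model.kind == "island_split" and model.migration_rate > 0

    t = 0.0
    nxt = n_tips
    n_active = n_tips
    exp = rng.exponential
    while n_active > 1:
        coal_rates = [len(l) * (len(l) - 1) for l in lineages]  # pair rate 2
        total_coal = float(sum(coal_rates))
        if migration_on and t < model.split_time and len(lineages) > 1:
            mig_rate = n_active * model.migration_rate * (len(lineages) - 1)
        else:
            mig_rate = 0.0
        total = total_coal + mig_rate
        t_next_merge = pending[0][0] if pending else math.inf
        if total > 0:
            wait = exp(1.0 / total)
        else:
            wait = math.inf
        if t + wait >= t_next_merge:
            t = t_next_merge
            while pending and pending[0][0] <= t:
                _, src, dst = pending.pop(0)
                lineages[dst].extend(lineages[src])
                lineages[src] = []
            # drop emptied demes at the tail only when schedule allows;
            # keep list indices stable by leaving empty lists in place
            continue
        t += wait
        if rng.random() * total < total_coal:
            # coalescence: pick deme proportional to n_d (n_d - 1)
            u = rng.random() * total_coal
            acc = 0.0
            for d, r in enumerate(coal_rates):
                acc += r
                if u < acc:
                    break
            pool = lineages[d]
            i, j = rng.choice(len(pool), size=2, replace=False)
            a, b = pool[i], pool[j]
            parent[a] = parent[b] = nxt
            node_time[nxt] = t
            pool[:] = [x for x in pool if x not in (a, b)] + [nxt]
            nxt += 1
            n_active -= 1
        else:
            # migration: uniform lineage, uniform other deme
            flat = [(d, i) for d, pool in enumerate(lineages) for i in range(len(pool))]
            d, i = flat[rng.integers(len(flat))]
            others = [x for x in range(len(lineages)) if x != d]
            dst = others[rng.integers(len(others))]
            lineages[dst].append(lineages[d].pop(i))
    return Genealogy(parent=parent, node_time=node_time, n_leaves=n_tips, leaf_demes=leaf_demes)


def mutate_one_site(gen: Genealogy, rng: np.random.Generator | int) -> np.ndarray:
    """Place exactly one mutation uniformly on total branch length.

    Returns a 0/1 haplotype vector over tips; tips below the mutated branch
    carry the derived allele. A non-root branch always subtends a proper
    non-empty subset of tips, so the locus is polymorphic by construction.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if gen.n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    bl = gen.branch_lengths()
    probs = bl / bl.sum()
    node = rng.choice(len(bl), p=probs)
    derived = gen.leaves_below(int(node))
    out = np.zeros(gen.n_leaves, dtype=np.int8)
    out[derived] = 1
    return out


def expected_autozygosity(s: float) -> float:
    """Closed-form mean per-locus autozygosity s / (2 - s) under geometric
    selfing-generation counts (ignoring the generation cap)."""
    return s / (2.0 - s)


def diploidize_with_selfing(
    haplotypes: np.ndarray,
    deme_of_haplotype: np.ndarray,
    selfing_rates: np.ndarray,
    rng: np.random.Generator | int,
) -> tuple[np.ndarray, np.ndarray]:
    """Pair haplotypes into diploids within demes, applying partial selfing.

    Each individual draws a number of selfing generations
    ``g ~ Geometric(1 - s)`` (counting generations of selfing before the
    first outcross, capped at 10); each locus then becomes autozygous
    independently with probability ``1 - 2^-g``, copying one of its two
    alleles (chosen fairly) over the other.

    Returns ``(genotypes, deme_of_individual)`` with genotypes shaped
    ``n_ind x L x 2``.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    haplotypes = np.asarray(haplotypes)
    deme_of_haplotype = np.asarray(deme_of_haplotype)
    selfing_rates = np.asarray(selfing_rates, dtype=float)
    if ((selfing_rates < 0) | (selfing_rates >= 1)).any():
        raise ValueError("selfing rates must lie in [0, 1)")
    n_hap, n_loci = haplotypes.shape
    if n_hap % 2:
        raise ValueError("haplotype count must be even")

    order = np.argsort(deme_of_haplotype, kind="stable")
    haps = haplotypes[order]
    demes = deme_of_haplotype[order]
    if (demes[::2] != demes[1::2]).any():
        raise ValueError("odd haplotype count within a deme")
    n_ind = n_hap // 2
    geno = np.stack([haps[::2], haps[1::2]], axis=2).astype(np.int32)
    ind_deme = demes[::2].copy()

    s = selfing_rates[ind_deme]
    # geometric(p) counts trials to first success; failures = selfing rounds
    g = np.minimum(rng.geometric(1.0 - s) - 1, _SELFING_GEN_CAP)
    p_auto = 1.0 - np.power(2.0, -g.astype(float))
    auto = rng.random((n_ind, n_loci)) < p_auto[:, None]
    keep_first = rng.random((n_ind, n_loci)) < 0.5
    kept = np.where(keep_first, geno[:, :, 0], geno[:, :, 1])
    geno[:, :, 0] = np.where(auto, kept, geno[:, :, 0])
    geno[:, :, 1] = np.where(auto, kept, geno[:, :, 1])
    return geno, ind_deme


def hudson_fst(
    table: GenotypeTable, labels: np.ndarray | list
) -> SimSummary:
    """Hudson ratio-of-sums FST over all deme pairs for diallelic loci.

    Per locus and deme pair, with sample allele-1 frequencies p1, p2 from
    n1, n2 non-missing allele copies::

        num = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
        den = p1(1-p2) + p2(1-p1)

    The pairwise dataset value is sum(num)/sum(den) over loci (negative
    per-locus values retained); the dataset summary is the mean over pairs.
    """
    labels = np.asarray(labels)
    demes = np.unique(labels)
    if len(demes) < 2:
        raise ValueError("need >= 2 demes for FST")
    if (table.locus_allele_counts > 2).any():
        raise ValueError("hudson_fst supports diallelic loci only")
    dos = table.dosage_matrix(allele=1)  # N x L copies of allele 1, NaN missing
    cnt1, n_copies = {}, {}
    for d in demes:
        sub = dos[labels == d]
        n_copies[d] = 2.0 * np.sum(~np.isnan(sub), axis=0)
        cnt1[d] = np.nansum(sub, axis=0)
        if (n_copies[d] < 2).all():
            raise ValueError(f"deme {d!r} has < 2 sampled allele copies everywhere")

    l = table.n_loci
    per_locus_acc = np.zeros(l)
    pair_fst: dict[tuple[int, int], float] = {}
    pairs = [(a, b) for i, a in enumerate(demes) for b in demes[i + 1:]]
    for a, b in pairs:
        n1, n2 = n_copies[a], n_copies[b]
        ok = (n1 >= 2) & (n2 >= 2)
        p1 = np.divide(cnt1[a], n1, out=np.zeros(l), where=n1 > 0)
        p2 = np.divide(cnt1[b], n2, out=np.zeros(l), where=n2 > 0)
        num = (p1 - p2) ** 2
        num -= np.divide(p1 * (1 - p1), n1 - 1, out=np.zeros(l), where=ok)
        num -= np.divide(p2 * (1 - p2), n2 - 1, out=np.zeros(l), where=ok)
        den = p1 * (1 - p2) + p2 * (1 - p1)
        pair_fst[(a, b)] = float(num[ok].sum() / den[ok].sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            per_locus_acc += np.where(ok & (den > 0), num / np.where(den > 0, den, 1), 0.0)

    poly = int(np.sum(table.locus_allele_counts >= 2))
    return SimSummary(
        mean_pairwise_fst=float(np.mean(list(pair_fst.values()))),
        per_locus_fst=per_locus_acc / len(pairs),
        polymorphic_loci=poly,
        pairwise_fst=pair_fst,
    )


def simulate_dataset(
    model: DemographicModel, config: SimConfig
) -> tuple[GenotypeTable, SimSummary]:
    """Simulate a complete dataset of unlinked single-site loci.

    Each locus draws an independent genealogy and one mutation; haplotypes
    are paired into diploids within demes (with selfing under ``inbred``).
    True deme labels are attached as ``population_labels``.
    """
    rng = np.random.default_rng(config.seed)
    k = model.n_demes
    n_hap = 2 * config.individuals_per_deme
    sample_sizes = [n_hap] * k

    haps = np.empty((n_hap * k, config.n_loci), dtype=np.int8)
    leaf_demes = None
    for j in range(config.n_loci):
        gen = simulate_genealogy(model, sample_sizes, rng)
        haps[:, j] = mutate_one_site(gen, rng)
        leaf_demes = gen.leaf_demes

    if model.kind == "inbred":
        if model.selfing_rates is not None:
            s = model.selfing_rates
        else:
            s = rng.uniform(0.0, 0.99, size=k)
    else:
        s = np.zeros(k)
    geno, ind_deme = diploidize_with_selfing(haps, leaf_demes, s, rng)

    # raw labels 1/2 for ancestral/derived, STRUCTURE-style
    table = GenotypeTable(
        alleles=geno,
        locus_allele_counts=np.full(config.n_loci, 2, dtype=np.int64),
        individual_labels=[f"ind_{i + 1}" for i in range(len(ind_deme))],
        allele_labels=[np.array([1, 2])] * config.n_loci,
        population_labels=[str(d + 1) for d in ind_deme],
    )
    if k >= 2:
        summary = hudson_fst(table, ind_deme)
    else:
        summary = SimSummary(
            mean_pairwise_fst=None,
            per_locus_fst=None,
            polymorphic_loci=config.n_loci,
        )
    return table, summary


def make_model(
    name: str,
    n_demes: int,
    split_time: float = 0.5,
    selfing_rates: np.ndarray | None = None,
) -> DemographicModel:
    """Build one of the named benchmark scenarios.

    ``name`` is one of ``split``, ``tree``, ``m0.5``, ``m2.0``, ``m10``,
    ``inbred`` (case-insensitive).
    """
    name = name.lower()
    if name == "split":
        return DemographicModel("split", n_demes, split_time=split_time)
    if name == "tree":
        return DemographicModel("tree", n_demes, split_spacing=split_time)
    if name.startswith("m"):
        m = float(name[1:].lstrip("_"))
        return DemographicModel(
            "island_split", n_demes, split_time=split_time, migration_rate=m
        )
    if name == "inbred":
        return DemographicModel(
            "inbred", n_demes, split_time=split_time, selfing_rates=selfing_rates
        )
    raise ValueError(f"unknown scenario name {name!r}")
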