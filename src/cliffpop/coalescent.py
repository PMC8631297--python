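"""Backward-in-time coalescent simulation of island-colonization scenarios.

Four demographic scenarios describe how a mainland population (Palinuro) and
two island populations (Capri, Strombolicchio) came to be:

1. Capri founded from Palinuro at t1, Strombolicchio founded from Capri at
   t2; each founding passes through a bottleneck of Nb founders lasting db
   generations.
2. As 1, but Strombolicchio is founded directly from Palinuro.
3. Capri and Palinuro split from an ancestral population at t1 with no
   bottleneck; Strombolicchio founded from Capri at t2 with a bottleneck.
4. As 3, but Strombolicchio is founded from Palinuro.

Time is counted in generations backward from sampling; the ancestral
population size equals the Palinuro size. Nuclear loci are unlinked
biallelic SNPs simulated with the one-SNP-per-locus convention: a single
mutation is placed on the genealogy with probability proportional to branch
length, so every locus is polymorphic in the pooled sample — the convention
of SNP-mode ABC simulators. The plastid locus is a single non-recombining
haploid sequence (effective size half the diploid deme size, maternal
inheritance) with infinite-sites Poisson mutations.

The simulator is a discrete-event structured coalescent written here from
scratch (no migration after founding, piecewise-constant deme sizes);
msprime serves only as an independent cross-check in the test suite.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import numpy as np

from .genotypes import MISSING, GenotypeMatrix, PopulationMap

__all__ = [
    "PALINURO",
    "CAPRI",
    "STROMBOLICCHIO",
    "DEFAULT_SAMPLE_SIZES",
    "PriorSet",
    "ParameterDraw",
    "DemographicModel",
    "Genealogy",
    "sample_prior",
    "simulate_genealogy",
    "simulate_dataset",
    "simulate_plastid",
    "default_population_map",
]

PALINURO = "Palinuro"
CAPRI = "Capri"
STROMBOLICCHIO = "Strombolicchio"
_DEMES = (PALINURO, CAPRI, STROMBOLICCHIO)

#: Diploid sample sizes of the reduced dataset (10/8/7).
DEFAULT_SAMPLE_SIZES: dict[str, int] = {PALINURO: 10, CAPRI: 8, STROMBOLICCHIO: 7}


@dataclass(frozen=True)
class PriorSet:
    """Uniform prior ranges (inclusive integer bounds) for the demographic parameters.

    Defaults follow the study design for a narrow endemic: small effective
    sizes (mainland 100-500, islands down to 10-50), founder numbers 5-50,
    split times 10-50,000 generations, bottleneck durations 10-100
    generations, with t1 > t2 (Capri is the older colony) and db < t2.
    """

    n_palinuro: tuple[int, int] = (100, 500)
    n_capri: tuple[int, int] = (10, 500)
    n_strombolicchio: tuple[int, int] = (10, 50)
    n1b: tuple[int, int] = (5, 50)
    n2b: tuple[int, int] = (5, 50)
    t1: tuple[int, int] = (10, 50_000)
    t2: tuple[int, int] = (10, 50_000)
    db: tuple[int, int] = (10, 100)
    generation_time_years: float = 10.0

    def __post_init__(self) -> None:
        for name in ("n_palinuro", "n_capri", "n_strombolicchio", "n1b", "n2b", "t1", "t2", "db"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return ("n_palinuro", "n_capri", "n_strombolicchio", "n1b", "n2b", "t1", "t2", "db")


@dataclass(frozen=True)
class ParameterDraw:
    """One concrete draw: diploid effective sizes and times in generations."""

    n_palinuro: int
    n_capri: int
    n_strombolicchio: int
    n1b: int
    n2b: int
    t1: int
    t2: int
    db: int
    generation_time_years: float = 10.0

    def __post_init__(self) -> None:
        if not (self.t1 > self.t2 > 0):
            raise ValueError(f"need t1 > t2 > 0, got t1={self.t1}, t2={self.t2}")
        if not self.db < self.t2:
            raise ValueError(f"need db < t2, got db={self.db}, t2={self.t2}")

    def as_dict(self) -> dict[str, float]:
        return {
            k: getattr(self, k)
            for k in ("n_palinuro", "n_capri", "n_strombolicchio", "n1b", "n2b", "t1", "t2", "db")
        }


@dataclass(frozen=True)
class DemographicModel:
    """Scenario topology; 1-4 as documented in the module docstring.

    ``scenario_id = 0`` (via :meth:`panmictic`) disables both events and
    keeps all samples in a single population — a control for calibration
    tests, not one of the study scenarios.
    """

    scenario_id: int

    def __post_init__(self) -> None:
        if self.scenario_id not in (0, 1, 2, 3, 4):
            raise ValueError("scenario_id must be 1-4 (or 0 for the panmictic control)")

    @classmethod
    def panmictic(cls) -> "DemographicModel":
        return cls(0)

    def schedule(self, d: ParameterDraw):
        """Backward-time size segments and merge events.

        Returns ``(segments, merges)`` where ``segments[deme]`` is a list of
        ``(t_start, diploid_size)`` pieces (constant from t_start until the
        next piece or a merge) and ``merges`` is a time-sorted list of
        ``(time, source, destination)``.
        """
        if self.scenario_id == 0:
            return {PALINURO: [(0.0, d.n_palinuro)]}, []
        segs = {PALINURO: [(0.0, d.n_palinuro)]}
        if self.scenario_id in (1, 2):
            # Capri founded at t1: bottleneck of n1b founders on (t1-db, t1]
            segs[CAPRI] = [(0.0, d.n_capri), (d.t1 - d.db, d.n1b)]
        else:
            # ancestral split at t1, no bottleneck
            segs[CAPRI] = [(0.0, d.n_capri)]
        segs[STROMBOLICCHIO] = [(0.0, d.n_strombolicchio), (d.t2 - d.db, d.n2b)]
        strombolicchio_source = CAPRI if self.scenario_id in (1, 3) else PALINURO
        merges = [(float(d.t2), STROMBOLICCHIO, strombolicchio_source), (float(d.t1), CAPRI, PALINURO)]
        return segs, merges


@dataclass
class Genealogy:
    """A single coalescent tree over haploid lineages.

    Nodes 0..n_leaves-1 are leaves; internal nodes are appended in
    coalescence order, the root last. ``parent[root] == -1``.
    """

    parent: list[int]
    time: list[float]
    left: list[int]
    right: list[int]
    n_leaves: int
    leaf_demes: list[str]

    @property
    def root(self) -> int:
        return len(self.parent) - 1

    @property
    def tmrca(self) -> float:
        return self.time[self.root]

    def branch_lengths(self) -> list[float]:
        """Length of the branch above each non-root node."""
        return [self.time[self.parent[v]] - self.time[v] for v in range(self.root)]

    def leaves_below(self, v: int) -> list[int]:
        out, stack = [], [v]
        while stack:
            u = stack.pop()
            if u < self.n_leaves:
                out.append(u)
            else:
                stack.append(self.left[u])
                stack.append(self.right[u])
        return out


def sample_prior(p: PriorSet, seed: int | None = None, rng: random.Random | None = None,
                 max_attempts: int = 100_000) -> ParameterDraw:
    """Draw parameters uniformly within ranges, rejecting until t1 > t2 and db < t2."""
    rnd = rng if rng is not None else random.Random(seed)
    for _ in range(max_attempts):
        draw = {name: rnd.randint(*getattr(p, name)) for name in p.parameter_names}
        if draw["t1"] > draw["t2"] and draw["db"] < draw["t2"]:
            return ParameterDraw(**draw, generation_time_years=p.generation_time_years)
    raise RuntimeError("could not satisfy t1 > t2 and db < t2 within the prior ranges")


def _size_at(segments: list[tuple[float, float]], t: float) -> float:
    size = segments[0][1]
    for t_start, s in segments:
        if t >= t_start:
            size = s
        else:
            break
    return size


def simulate_genealogy(
    m: DemographicModel,
    d: ParameterDraw,
    sample_sizes: dict[str, int] | None = None,
    rng: random.Random | None = None,
    seed: int | None = None,
    copies_per_diploid: float = 2.0,
) -> Genealogy:
    """Simulate one coalescent genealogy of all sampled lineages.

    ``copies_per_diploid`` scales deme capacity in gene copies per diploid
    census unit: 2.0 for nuclear loci (2N copies in a deme of N diploids),
    0.5 for the maternally inherited plastid (N/2).

    ``sample_sizes`` counts *haploid lineages* contributed per deme when
    ``copies_per_diploid != 2``; for nuclear simulations the caller passes
    diploid counts and each individual contributes two lineages.
    """
    rnd = rng if rng is not None else random.Random(seed)
    sizes = dict(DEFAULT_SAMPLE_SIZES if sample_sizes is None else sample_sizes)
    segs, merges = m.schedule(d)
    if m.scenario_id == 0:
        # panmictic control: pool every sampled lineage into one deme
        total = sum(sizes.values())
        sizes = {PALINURO: total}

    lineages_per_deme = {
        deme: (2 * k if copies_per_diploid == 2.0 else k) for deme, k in sizes.items() if k > 0
    }
    leaf_demes: list[str] = []
    for deme in _DEMES:
        if deme in lineages_per_deme:
            leaf_demes.extend([deme] * lineages_per_deme[deme])
    n = len(leaf_demes)
    if n < 2:
        raise ValueError("need at least two sampled lineages in total")
    n_nodes = 2 * n - 1
    parent = [-1] * n_nodes
    time = [0.0] * n_nodes
    left = [-1] * n_nodes
    right = [-1] * n_nodes

    active: dict[str, list[int]] = {deme: [] for deme in segs}
    for i, deme in enumerate(leaf_demes):
        active[deme].append(i)

    merge_times = [mt for mt, _, _ in merges]
    bounds = sorted(
        {ts for seg in segs.values() for ts, _ in seg if ts > 0.0} | set(merge_times)
    )
    bounds.append(math.inf)

    nxt = n
    t = 0.0
    expovariate = rnd.expovariate
    for b in bounds:
        # sizes are constant on [t, b)
        while nxt < n_nodes:
            demes = [dm for dm, lin in active.items() if len(lin) > 1]
            rates = [
                len(active[dm]) * (len(active[dm]) - 1) / 2.0
                / (copies_per_diploid * _size_at(segs[dm], t))
                for dm in demes
            ]
            total_rate = sum(rates)
            if total_rate == 0.0:
                break  # isolated singletons; wait for a merge
            dt = expovariate(total_rate)
            if t + dt >= b:
                break
            t += dt
            u = rnd.random() * total_rate
            acc = 0.0
            dm = demes[-1]
            for deme_i, r in zip(demes, rates):
                acc += r
                if u < acc:
                    dm = deme_i
                    break
            lin = active[dm]
            k = len(lin)
            i = rnd.randrange(k)
            j = rnd.randrange(k - 1)
            if j >= i:
                j += 1
            a, c = lin[i], lin[j]
            node = nxt
            nxt += 1
            time[node] = t
            left[node], right[node] = a, c
            parent[a] = parent[c] = node
            # replace a with the new node, remove c (order irrelevant)
            lin[i] = node
            lin[j] = lin[-1]
            lin.pop()
        if nxt == n_nodes:
            break
        t = b
        for mt, src, dst in merges:
            if mt == b and src in active:
                active[dst].extend(active.pop(src))
    if nxt != n_nodes:
        raise RuntimeError("genealogy did not fully coalesce (impossible inputs)")
    return Genealogy(parent, time, left, right, n, leaf_demes)


def default_population_map(sample_sizes: dict[str, int] | None = None) -> PopulationMap:
    """Population map matching the individual ids of :func:`simulate_dataset`."""
    sizes = DEFAULT_SAMPLE_SIZES if sample_sizes is None else sample_sizes
    assignment = {}
    for deme in _DEMES:
        for i in range(sizes.get(deme, 0)):
            assignment[f"{deme[:3]}_{i + 1:02d}"] = deme
    return PopulationMap(assignment)


def _mutation_column(rnd: random.Random, tree: Genealogy) -> np.ndarray:
    """Alt-allele counts per diploid after one branch-proportional mutation."""
    lengths = tree.branch_lengths()
    total = math.fsum(lengths)
    u = rnd.random() * total
    acc = 0.0
    branch = tree.root - 1
    for v, ln in enumerate(lengths):
        acc += ln
        if u < acc:
            branch = v
            break
    derived = tree.leaves_below(branch)
    n_ind = tree.n_leaves // 2
    col = np.zeros(n_ind, dtype=np.int8)
    for leaf in derived:
        col[leaf // 2] += 1
    return col


def simulate_dataset(
    m: DemographicModel,
    d: ParameterDraw,
    sample_sizes: dict[str, int] | None = None,
    n_loci: int = 120,
    seed: int = 0,
    missing_prob: float = 0.0,
    maf_floor: float | None = None,
    max_redraws: int = 100,
) -> GenotypeMatrix:
    """Simulate unlinked biallelic SNP genotypes under a scenario.

    One independent genealogy per locus; one mutation placed on a branch
    chosen with probability proportional to its length, so every locus is
    polymorphic across the pooled sample. Diploid genotypes pair consecutive
    lineages within each deme (lineages are exchangeable, so the pairing
    convention is immaterial). ``missing_prob`` overlays ddRAD-style random
    genotype dropout; ``maf_floor`` optionally redraws the mutation until the
    pooled minor-allele frequency reaches the floor (off by default).
    Deterministic for a given seed.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    sizes = dict(DEFAULT_SAMPLE_SIZES if sample_sizes is None else sample_sizes)
    if any(v < 1 for v in sizes.values()):
        raise ValueError("sample sizes must be >= 1 for extant populations")
    rnd = random.Random(seed)
    n_ind = sum(sizes.values())
    n_hap = 2 * n_ind
    cols = np.empty((n_loci, n_ind), dtype=np.int8)
    for locus in range(n_loci):
        tree = simulate_genealogy(m, d, sizes, rng=rnd, copies_per_diploid=2.0)
        col = _mutation_column(rnd, tree)
        if maf_floor is not None:
            attempts = 0
            while True:
                ac = int(col.sum())
                if min(ac, n_hap - ac) / n_hap >= maf_floor or attempts >= max_redraws:
                    break
                col = _mutation_column(rnd, tree)
                attempts += 1
        cols[locus] = col
    genotypes = cols.T.copy()
    if missing_prob > 0.0:
        mask = np.array(
            [rnd.random() < missing_prob for _ in range(genotypes.size)], dtype=bool
        ).reshape(genotypes.shape)
        genotypes[mask] = MISSING

    ind_ids = []
    for deme in _DEMES:
        for i in range(sizes.get(deme, 0)):
            ind_ids.append(f"{deme[:3]}_{i + 1:02d}")
    locus_ids = tuple(f"L{j + 1:04d}" for j in range(n_loci))
    return GenotypeMatrix(genotypes, tuple(ind_ids), locus_ids)


def simulate_plastid(
    m: DemographicModel,
    d: ParameterDraw,
    sample_sizes: dict[str, int] | None = None,
    seq_len: int = 1000,
    mu_per_seq: float = 1e-3,
    seed: int = 0,
):
    """Simulate one non-recombining haploid (plastid) locus.

    One lineage is sampled per individual; the haploid effective size is
    half the diploid deme size. Mutations fall on branches as a Poisson
    process with total per-generation rate ``mu_per_seq`` per lineage,
    under the infinite-sites convention (each mutation hits a fresh site).
    Returns a :class:`~cliffpop.haplonet.HaplotypeSet`.
    """
    from .haplonet import HaplotypeSet

    if seq_len < 1:
        raise ValueError("seq_len must be >= 1")
    sizes = dict(DEFAULT_SAMPLE_SIZES if sample_sizes is None else sample_sizes)
    rnd = random.Random(seed)
    tree = simulate_genealogy(m, d, sizes, rng=rnd, copies_per_diploid=0.5)
    lengths = tree.branch_lengths()
    n_mut_per_branch = [
        _poisson(rnd, ln * mu_per_seq) if ln > 0 else 0 for ln in lengths
    ]
    total_mut = sum(n_mut_per_branch)
    if total_mut > seq_len:
        raise ValueError(
            f"{total_mut} mutations exceed seq_len={seq_len}; "
            "infinite-sites assumption violated (lower mu_per_seq)"
        )
    positions = rnd.sample(range(seq_len), total_mut)
    bases = "ACGT"
    ref = ["A"] * seq_len
    seqs = [ref.copy() for _ in range(tree.n_leaves)]
    pi = 0
    for v, n_mut in enumerate(n_mut_per_branch):
        for _ in range(n_mut):
            pos = positions[pi]
            pi += 1
            derived = rnd.choice([b for b in bases if b != ref[pos]])
            for leaf in tree.leaves_below(v):
                seqs[leaf][pos] = derived

    seq_to_id: dict[str, str] = {}
    freqs: dict[str, int] = {}
    pops: dict[str, dict[str, int]] = {}
    for leaf in range(tree.n_leaves):
        s = "".join(seqs[leaf])
        hid = seq_to_id.setdefault(s, f"H{len(seq_to_id) + 1}")
        freqs[hid] = freqs.get(hid, 0) + 1
        pops.setdefault(hid, {})
        deme = tree.leaf_demes[leaf]
        pops[hid][deme] = pops[hid].get(deme, 0) + 1
    return HaplotypeSet(
        sequences={hid: s for s, hid in seq_to_id.items()},
        frequencies=freqs,
        population_counts=pops,
    )


def _poisson(rnd: random.Random, lam: float) -> int:
    """Knuth sampler for small lambda; normal approximation above 50."""
    if lam <= 0.0:
        return 0
    if lam > 50.0:
        return max(0, round(rnd.gauss(lam, math.sqrt(lam))))
    L = math.exp(-lam)
    k, p = 0, 1.0
    while True:
        p *= rnd.random()
        if p <= L:
            return k
        k += 1
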