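"""Statistical-parsimony (TCS-style) haplotype networks for plastid data.

Haplotypes are connected in increasing order of mutational distance up to a
parsimony connection limit; a connection of d steps inserts d-1 inferred
intermediate nodes carrying reconstructed sequences, so every edge spans
exactly one mutational step. The connection limit is the largest number of
steps whose probability of parsimony (no superimposed changes) still meets
a confidence level, conventionally 0.95.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx

from .popgen import DistanceMatrix

__all__ = [
    "HaplotypeSet",
    "HaplotypeNetwork",
    "read_fasta_haplotypes",
    "read_haplotype_table",
    "hamming_matrix",
    "parsimony_probability",
    "parsimony_limit",
    "build_network",
    "figure_fixture",
]

_MISSING_CHARS = {"-", "N", "n", "?"}


@dataclass(frozen=True)
class HaplotypeSet:
    """Equal-length haplotype sequences with carrier counts.

    ``population_counts`` maps haplotype id -> {population: count}; counts
    must sum to the haplotype's frequency when both are given.
    """

    sequences: dict[str, str]
    frequencies: dict[str, int] | None = None
    population_counts: dict[str, dict[str, int]] | None = None

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("empty haplotype set")
        lens = {len(s) for s in self.sequences.values()}
        if len(lens) != 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lens)}")
        freqs = self.frequencies or {h: 1 for h in self.sequences}
        if set(freqs) != set(self.sequences):
            raise ValueError("frequencies must cover exactly the haplotype ids")
        if any(f < 1 for f in freqs.values()):
            raise ValueError("frequencies must be >= 1")
        object.__setattr__(self, "frequencies", dict(freqs))
        if self.population_counts is not None:
            for h, per_pop in self.population_counts.items():
                if sum(per_pop.values()) != freqs[h]:
                    raise ValueError(f"population counts for {h!r} do not sum to its frequency")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(self.sequences)

    @property
    def seq_len(self) -> int:
        return len(next(iter(self.sequences.values())))


@dataclass(frozen=True)
class HaplotypeNetwork:
    """Graph of sampled haplotypes plus inferred intermediates.

    Nodes carry ``sampled`` (bool), ``sequence``, ``frequency`` and optional
    ``populations`` attributes; every edge spans exactly one mutational step.
    """

    graph: nx.Graph

    @property
    def sampled_nodes(self) -> tuple[str, ...]:
        return tuple(n for n, d in self.graph.nodes(data=True) if d["sampled"])

    @property
    def inferred_nodes(self) -> tuple[str, ...]:
        return tuple(n for n, d in self.graph.nodes(data=True) if not d["sampled"])

    def steps_between(self, a: str, b: str) -> int:
        """Number of mutational steps (edges) on the shortest path a-b."""
        return nx.shortest_path_length(self.graph, a, b)

    def to_graphml(self, path) -> None:
        g = self.graph.copy()
        for _, d in g.nodes(data=True):
            if d.get("populations") is not None:
                d["populations"] = ";".join(f"{p}:{c}" for p, c in sorted(d["populations"].items()))
            else:
                d.pop("populations", None)
        nx.write_graphml(g, path)

    def to_edgelist_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("node_a\tnode_b\n")
            for a, b in sorted(self.graph.edges()):
                fh.write(f"{a}\t{b}\n")

    def to_nodes_tsv(self, path) -> None:
        """Per-node table: sampled flag, carrier count, population composition."""
        with open(path, "w") as fh:
            fh.write("node\tsampled\tfrequency\tpopulations\n")
            for n in sorted(self.graph.nodes):
                d = self.graph.nodes[n]
                pops = d.get("populations")
                pop_str = (
                    ";".join(f"{p}:{c}" for p, c in sorted(pops.items())) if pops else "."
                )
                fh.write(f"{n}\t{int(d['sampled'])}\t{d['frequency']}\t{pop_str}\n")


def read_fasta_haplotypes(path) -> HaplotypeSet:
    """Read haploid sequences from FASTA, collapsing identical sequences.

    Haplotype ids are taken from the first occurrence of each distinct
    sequence; frequency is the number of records carrying it. A record header
    of the form ``>ind|population`` contributes to per-population counts.
    """
    from Bio import SeqIO

    seq_to_id: dict[str, str] = {}
    freqs: dict[str, int] = {}
    pops: dict[str, dict[str, int]] = {}
    any_pop = False
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        s = str(rec.seq).upper()
        hid = seq_to_id.setdefault(s, f"H{len(seq_to_id) + 1}")
        freqs[hid] = freqs.get(hid, 0) + 1
        if "|" in rec.id:
            any_pop = True
            pop = rec.id.split("|", 1)[1]
            pops.setdefault(hid, {})
            pops[hid][pop] = pops[hid].get(pop, 0) + 1
    if not seq_to_id:
        raise ValueError(f"no sequences in {path!r}")
    return HaplotypeSet(
        sequences={hid: s for s, hid in seq_to_id.items()},
        frequencies=freqs,
        population_counts=pops if any_pop else None,
    )


def read_haplotype_table(path) -> HaplotypeSet:
    """Read a 3-column tab-separated haplotype table: id, sequence, count."""
    seqs: dict[str, str] = {}
    freqs: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"malformed haplotype-table line: {line!r}")
            hid, seq, count = parts
            if hid in seqs:
                raise ValueError(f"duplicate haplotype id {hid!r}")
            seqs[hid] = seq.upper()
            freqs[hid] = int(count)
    if not seqs:
        raise ValueError(f"empty haplotype table {path!r}")
    return HaplotypeSet(sequences=seqs, frequencies=freqs)


def _pair_hamming(a: str, b: str) -> int:
    """Differing positions, excluding sites missing (gap/N/?) in either."""
    return sum(
        1
        for x, y in zip(a, b)
        if x != y and x not in _MISSING_CHARS and y not in _MISSING_CHARS
    )


def hamming_matrix(h: HaplotypeSet) -> DistanceMatrix:
    """Pairwise mutational distances between haplotypes."""
    import numpy as np

    ids = h.ids
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = _pair_hamming(h.sequences[ids[i]], h.sequences[ids[j]])
    return DistanceMatrix(ids, out, kind="hamming")


def parsimony_probability(j: int, seq_len: int) -> float:
    """Probability that j observed differences arose without superimposed changes.

    Per-site substitution counts are modelled as Poisson(lambda) with lambda
    estimated from the observed difference fraction, lambda = -ln(1 - j/m);
    parsimony holds when each differing site changed exactly once, giving
    P_j = [lambda e^-lambda / (1 - e^-lambda)]^j. P_0 = 1; j >= m gives 0.
    """
    if j < 0:
        raise ValueError("j must be >= 0")
    if j == 0:
        return 1.0
    m = seq_len
    if j >= m:
        return 0.0
    lam = -math.log(1.0 - j / m)
    p_single = lam * math.exp(-lam) / (1.0 - math.exp(-lam))
    return p_single**j


def parsimony_limit(seq_len: int, alpha: float = 0.95) -> int:
    """Largest step count j with parsimony probability >= alpha (floor 1).

    Single-step connections are always trusted, so the limit is at least 1;
    the limit is non-increasing in alpha.
    """
    if seq_len < 1:
        raise ValueError("seq_len must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    j = 1
    while j + 1 < seq_len and parsimony_probability(j + 1, seq_len) >= alpha:
        j += 1
    return j


def _intermediate_chain(a_seq: str, b_seq: str) -> list[str]:
    """Sequences of the d-1 intermediates on a stepwise path a -> b.

    Differing positions are changed one at a time in ascending position
    order (a deterministic, documented convention; any order is equally
    parsimonious under this distance).
    """
    diff = [i for i, (x, y) in enumerate(zip(a_seq, b_seq)) if x != y]
    chain = []
    cur = list(a_seq)
    for pos in diff[:-1]:
        cur[pos] = b_seq[pos]
        chain.append("".join(cur))
    return chain


def build_network(h: HaplotypeSet, limit: int | None = None, alpha: float = 0.95) -> HaplotypeNetwork:
    """Agglomerative statistical-parsimony network.

    Candidate haplotype pairs are processed in increasing mutational
    distance; a pair already connected is skipped (spanning-tree behaviour,
    which also prevents loops), and pairs beyond the connection limit are
    left in separate components. Among equal-distance alternatives the pair
    with the higher combined carrier frequency attaches first (ties broken
    lexicographically by id). Each accepted connection of d steps inserts
    d-1 inferred intermediate nodes so that every edge is one mutational step.
    """
    if limit is None:
        limit = parsimony_limit(h.seq_len, alpha)
    if limit < 1:
        raise ValueError("limit must be >= 1")
    ids = h.ids
    dm = hamming_matrix(h)
    g = nx.Graph()
    for hid in ids:
        g.add_node(
            hid,
            sampled=True,
            sequence=h.sequences[hid],
            frequency=h.frequencies[hid],
            populations=(h.population_counts or {}).get(hid),
        )
    pairs = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = ids[i], ids[j]
            d = int(dm.values[i, j])
            if 0 < d <= limit:
                freq = h.frequencies[a] + h.frequencies[b]
                pairs.append((d, -freq, tuple(sorted((a, b))), a, b))
    pairs.sort()

    n_inferred = 0
    for d, _negfreq, _key, a, b in pairs:
        if nx.has_path(g, a, b):
            continue  # already connected through earlier, shorter links
        chain = _intermediate_chain(h.sequences[a], h.sequences[b])
        prev = a
        for seq in chain:
            n_inferred += 1
            node = f"mv{n_inferred}"
            g.add_node(node, sampled=False, sequence=seq, frequency=0, populations=None)
            g.add_edge(prev, node)
            prev = node
        g.add_edge(prev, b)
    return HaplotypeNetwork(g)


def figure_fixture() -> HaplotypeSet:
    """The packaged three-haplotype plastid arrangement (synthetic states).

    Three haplotypes over three segregating sites: H1 and H2 one step apart,
    H3 two steps from H2 (and three from H1); H2 occurs at all three sites,
    H1 on the mainland (Palinuro) and Capri, H3 only on Strombolicchio.
    The actual nucleotide states are synthetic — only the step structure and
    the geographic composition are meaningful.
    """
    return HaplotypeSet(
        sequences={"H1": "ATC", "H2": "GTC", "H3": "GCT"},
        frequencies={"H1": 6, "H2": 7, "H3": 3},
        population_counts={
            "H1": {"Palinuro": 4, "Capri": 2},
            "H2": {"Palinuro": 2, "Capri": 3, "Strombolicchio": 2},
            "H3": {"Strombolicchio": 3},
        },
    )
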