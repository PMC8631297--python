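"""Diversity and population-structure statistics for diploid SNP data.

Implements Nei-style gene diversity (Ho, He, Fis), Weir & Cockerham (1984)
pairwise theta (Fst) combined across loci as a ratio of summed variance
components, allele-sharing and SNP-difference (co-ancestry) distances,
classical (Torgerson) multidimensional scaling, and neighbor-joining trees.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, PopulationMap

__all__ = [
    "DistanceMatrix",
    "DiversityTable",
    "diversity_stats",
    "pairwise_fst",
    "allele_sharing_distance",
    "coancestry_matrix",
    "mds_embed",
    "nj_tree",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric labelled pairwise matrix.

    ``kind`` tags the semantics: ``allele_sharing`` (in [0,1]),
    ``coancestry_differences`` (SNP-difference counts), ``fst``
    (Weir–Cockerham theta; small negative estimates are preserved), or
    ``hamming``. Undefined pairs are NaN.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    kind: str = "generic"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    def as_similarity(self) -> "DistanceMatrix":
        """Max-minus-value transform for heatmap display of count matrices."""
        top = float(np.nanmax(self.values))
        vals = top - self.values
        np.fill_diagonal(vals, top)
        return DistanceMatrix(self.labels, vals, kind=f"{self.kind}_similarity")


@dataclass(frozen=True)
class DiversityTable:
    """Per-population Ho, He and Fis plus across-population means.

    Ho is the mean observed heterozygote fraction over loci, He the mean
    unbiased gene diversity (Nei), and Fis = 1 - Ho/He computed from those
    means (ratio of means, stable under monomorphic loci). A population
    monomorphic at every locus has undefined (NaN) Fis.
    """

    table: pd.DataFrame  # index: population (+ "Mean" row); columns Ho, He, Fis

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", float_format="%.6f")

    def __str__(self) -> str:
        buf = io.StringIO()
        self.table.round(4).to_string(buf)
        return buf.getvalue()


def _per_locus_ho_he(gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus observed het fraction and unbiased gene diversity.

    He uses Nei's sample-size correction (2n/(2n-1)) * (1 - sum p^2) over the
    n non-missing diploids at the locus; loci with no data are NaN.
    """
    obs = gt != MISSING
    n = obs.sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ho = np.where(obs, gt == 1, False).sum(axis=0) / n
        p = np.where(obs, gt, 0).sum(axis=0) / (2.0 * n)
        he = (2.0 * n / (2.0 * n - 1.0)) * (1.0 - p**2 - (1.0 - p) ** 2)
    ho[n == 0] = np.nan
    he[n <= 0.5] = np.nan  # n==0; guard 2n-1 at n=0.5 impossible for ints
    return ho, he


def diversity_stats(g: GenotypeMatrix, pm: PopulationMap) -> DiversityTable:
    """Observed/expected heterozygosity and inbreeding coefficient per population."""
    if g.n_loci == 0:
        raise ValueError("empty genotype matrix")
    groups = pm.indices_by_population(g)
    rows = {}
    for pop, idx in groups.items():
        if len(idx) == 0:
            raise ValueError(f"population {pop!r} has no individuals")
        ho_l, he_l = _per_locus_ho_he(g.genotypes[idx, :])
        if np.isnan(ho_l).all():
            rows[pop] = {"Ho": np.nan, "He": np.nan, "Fis": np.nan}
            continue
        ho = float(np.nanmean(ho_l))
        he = float(np.nanmean(he_l))
        fis = 1.0 - ho / he if he > 0 else np.nan
        rows[pop] = {"Ho": ho, "He": he, "Fis": fis}
    table = pd.DataFrame.from_dict(rows, orient="index")
    mean = table[["Ho", "He"]].mean(axis=0)
    table.loc["Mean"] = {"Ho": mean["Ho"], "He": mean["He"], "Fis": np.nan}
    return DiversityTable(table)


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) theta


def _wc_components(gt_by_pop: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus WC84 variance components (a, b, c) for r populations.

    Each element of ``gt_by_pop`` is an (n_i x L) slice of alt-allele counts.
    Loci where any population has <1 observed genotype, or with fewer than
    two populations observed, yield NaN components.
    """
    r = len(gt_by_pop)
    L = gt_by_pop[0].shape[1]
    n = np.zeros((r, L))
    p = np.zeros((r, L))
    h = np.zeros((r, L))
    for i, gt in enumerate(gt_by_pop):
        obs = gt != MISSING
        ni = obs.sum(axis=0).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            p[i] = np.where(obs, gt, 0).sum(axis=0) / (2.0 * ni)
            h[i] = np.where(obs, gt == 1, False).sum(axis=0) / ni
        n[i] = ni

    ok = (n >= 1).all(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        nbar = n.mean(axis=0)
        nc = (r * nbar - (n**2).sum(axis=0) / (r * nbar)) / (r - 1.0)
        pbar = (n * p).sum(axis=0) / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (n * h).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - ((r - 1.0) / r) * s2 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    bad = ~ok | (nbar <= 1) | (nc <= 0)
    for comp in (a, b, c):
        comp[bad] = np.nan
    return a, b, c


def wc_theta(gt_by_pop: list[np.ndarray]) -> float:
    """Multi-locus WC84 theta: sum(a) / sum(a+b+c) over defined loci."""
    a, b, c = _wc_components(gt_by_pop)
    ok = ~np.isnan(a)
    denom = np.nansum(a[ok] + b[ok] + c[ok])
    if not ok.any() or denom == 0:
        return float("nan")
    return float(np.nansum(a[ok]) / denom)


def pairwise_fst(g: GenotypeMatrix, pm: PopulationMap) -> DistanceMatrix:
    """Pairwise Weir–Cockerham theta between populations.

    Variance components are summed across loci before taking the ratio;
    negative estimates (sampling noise around zero differentiation) are
    reported as-is. A pair with no jointly informative locus is NaN.
    """
    groups = pm.indices_by_population(g)
    pops = list(groups)
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    for p, idx in groups.items():
        if len(idx) < 2:
            raise ValueError(f"population {p!r} has fewer than two individuals")
    k = len(pops)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            theta = wc_theta([g.genotypes[groups[pops[i]], :], g.genotypes[groups[pops[j]], :]])
            out[i, j] = out[j, i] = theta
    return DistanceMatrix(tuple(pops), out, kind="fst")


# ---------------------------------------------------------------------------
# Individual-level distances


def allele_sharing_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """1 - (shared alleles) / (2 x jointly observed loci) per individual pair.

    Genotypes are compared as unordered allele multisets, so 0/0 vs 0/1 share
    one allele of two. Pairs with no jointly observed locus are NaN.
    """
    if g.n_individuals < 2:
        raise ValueError("need at least two individuals")
    gt = g.genotypes.astype(float)
    obs = gt >= 0
    gt0 = np.where(obs, gt, 0.0)
    diff = np.abs(gt0[:, None, :] - gt0[None, :, :])  # |alt_i - alt_j|
    both = obs[:, None, :] & obs[None, :, :]
    shared = np.where(both, 2.0 - diff, 0.0).sum(axis=2)
    n_both = both.sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 - shared / (2.0 * n_both)
    d[n_both == 0] = np.nan
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(g.individual_ids, d, kind="allele_sharing")


def coancestry_matrix(g: GenotypeMatrix) -> DistanceMatrix:
    """Count of differing SNP genotypes between individual pairs.

    Only loci non-missing in both members of a pair are compared; a
    similarity heatmap view is the max count minus each entry.
    """
    if g.n_individuals < 2:
        raise ValueError("need at least two individuals")
    gt = g.genotypes
    obs = gt != MISSING
    both = obs[:, None, :] & obs[None, :, :]
    ne = gt[:, None, :] != gt[None, :, :]
    counts = (ne & both).sum(axis=2).astype(float)
    counts[both.sum(axis=2) == 0] = np.nan
    np.fill_diagonal(counts, 0.0)
    return DistanceMatrix(g.individual_ids, counts, kind="coancestry_differences")


# ---------------------------------------------------------------------------
# Embedding and trees


def mds_embed(d: DistanceMatrix, dims: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) metric MDS of a distance matrix.

    Double-centers the squared distances and takes the leading ``dims``
    eigenvectors scaled by sqrt(eigenvalue); exactly reproduces Euclidean
    distances when the matrix is embeddable in ``dims`` dimensions.
    Negative eigenvalues (non-Euclidean input) are truncated to zero.
    """
    if dims < 1:
        raise ValueError("dims must be >= 1")
    D = np.asarray(d.values, dtype=float)
    if np.isnan(D).any():
        raise ValueError("distance matrix contains undefined entries")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, v = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:dims]
    lam = np.clip(w[order], 0.0, None)
    # zero out numerically-null axes so duplicates stay exactly coincident
    lam[lam < np.max(lam, initial=0.0) * 1e-12] = 0.0
    coords = v[:, order] * np.sqrt(lam)
    return pd.DataFrame(
        coords, index=d.labels, columns=[f"dim{i + 1}" for i in range(coords.shape[1])]
    )


def nj_tree(d: DistanceMatrix) -> str:
    """Saitou–Nei neighbor joining; returns a Newick string.

    Exact on additive matrices: tree path lengths reproduce the input.
    """
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj

    if d.n < 3:
        raise ValueError("need at least three labels for a tree")
    if np.isnan(d.values).any():
        raise ValueError("distance matrix contains undefined entries")
    tree = nj(SkbioDM(d.values, ids=list(d.labels)))
    return str(tree).strip()
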