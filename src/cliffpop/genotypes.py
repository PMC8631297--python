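"""Diploid SNP genotype matrices: VCF I/O, population maps, and locus filtering.

Genotypes are stored as the per-individual count of alternate alleles at each
biallelic locus (0, 1 or 2), with ``MISSING`` (-1) for uncalled genotypes —
the ddRAD convention of unlinked biallelic SNPs with substantial dropout.
VCF coordinates are 1-based per the standard; internal indices are 0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "PopulationMap",
    "FilterConfig",
    "read_vcf",
    "write_vcf",
    "read_population_map",
    "write_population_map",
    "filter_loci",
    "select_individuals",
    "missingness_report",
]

logger = logging.getLogger(__name__)

MISSING = -1


@dataclass(frozen=True)
class GenotypeMatrix:
    """Individuals x loci matrix of alternate-allele counts.

    Parameters
    ----------
    genotypes
        Integer array of shape (n_individuals, n_loci); entries in {0, 1, 2}
        or ``MISSING`` (-1).
    individual_ids
        Unique ordered sample labels (rows).
    locus_ids
        Unique ordered locus labels (columns).
    chrom, pos
        Optional per-locus chromosome names and 1-based positions, populated
        when the matrix was read from VCF.
    ref, alt
        Optional per-locus reference/alternate alleles.
    """

    genotypes: np.ndarray
    individual_ids: tuple[str, ...]
    locus_ids: tuple[str, ...]
    chrom: tuple[str, ...] | None = None
    pos: tuple[int, ...] | None = None
    ref: tuple[str, ...] | None = None
    alt: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes, dtype=np.int8)
        object.__setattr__(self, "genotypes", g)
        if g.ndim != 2:
            raise ValueError("genotypes must be a 2-D array")
        if g.shape != (len(self.individual_ids), len(self.locus_ids)):
            raise ValueError(
                f"genotype grid {g.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.locus_ids)} loci"
            )
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("individual_ids are not unique")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValueError("locus_ids are not unique")
        valid = np.isin(g, (MISSING, 0, 1, 2))
        if not valid.all():
            bad = np.unique(g[~valid])
            raise ValueError(f"invalid genotype codes {bad.tolist()}; expected 0/1/2/{MISSING}")
        for name in ("chrom", "pos", "ref", "alt"):
            v = getattr(self, name)
            if v is not None and len(v) != len(self.locus_ids):
                raise ValueError(f"{name} length does not match number of loci")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.genotypes == MISSING

    def take_loci(self, idx: np.ndarray) -> "GenotypeMatrix":
        """Submatrix keeping loci at integer positions ``idx`` (order preserved)."""
        idx = np.asarray(idx, dtype=int)
        sub = lambda t: tuple(np.asarray(t, dtype=object)[idx]) if t is not None else None
        return GenotypeMatrix(
            self.genotypes[:, idx],
            self.individual_ids,
            tuple(np.asarray(self.locus_ids, dtype=object)[idx]),
            chrom=sub(self.chrom),
            pos=tuple(int(p) for p in np.asarray(self.pos)[idx]) if self.pos is not None else None,
            ref=sub(self.ref),
            alt=sub(self.alt),
        )


@dataclass(frozen=True)
class PopulationMap:
    """Mapping from individual id to population label."""

    assignment: dict[str, str]

    @property
    def populations(self) -> tuple[str, ...]:
        # first-appearance order, stable across runs
        seen: dict[str, None] = {}
        for pop in self.assignment.values():
            seen.setdefault(pop)
        return tuple(seen)

    def individuals_in(self, population: str) -> tuple[str, ...]:
        return tuple(i for i, p in self.assignment.items() if p == population)

    def indices_by_population(self, g: GenotypeMatrix) -> dict[str, np.ndarray]:
        """Row indices of ``g`` per population; every row must be assigned."""
        unassigned = [i for i in g.individual_ids if i not in self.assignment]
        if unassigned:
            raise KeyError(f"individuals without population assignment: {unassigned}")
        out: dict[str, list[int]] = {}
        for row, ind in enumerate(g.individual_ids):
            out.setdefault(self.assignment[ind], []).append(row)
        return {p: np.asarray(v, dtype=int) for p, v in out.items()}


@dataclass(frozen=True)
class FilterConfig:
    """Locus-filtering thresholds.

    maf_min
        Minimum minor allele frequency over observed (non-missing) alleles.
    obs_het_max
        Maximum observed heterozygote fraction among non-missing genotypes
        (removes paralog-collapse artefacts).
    locus_presence_min
        Minimum fraction of individuals with a called genotype (0.70 for the
        full-dataset convention, 0.95 for the reduced one).
    max_missing_individuals
        Alternative absolute cap on missing individuals per locus; overrides
        ``locus_presence_min`` when set.
    """

    maf_min: float = 0.05
    obs_het_max: float = 0.70
    locus_presence_min: float = 0.70
    max_missing_individuals: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must lie in [0, 0.5]")
        for name in ("obs_het_max", "locus_presence_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.max_missing_individuals is not None and self.max_missing_individuals < 0:
            raise ValueError("max_missing_individuals must be >= 0")


# ---------------------------------------------------------------------------
# VCF I/O


def read_vcf(path) -> GenotypeMatrix:
    """Read diploid GT calls from a VCF into a :class:`GenotypeMatrix`.

    Only biallelic SNV records are retained; multiallelic records are skipped
    with a logged warning. ``./.`` becomes ``MISSING``.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError subclasses
        raise OSError(f"cannot read VCF {path!r}: {exc}") from exc

    samples = tuple(vcf.samples)
    cols: list[np.ndarray] = []
    locus_ids: list[str] = []
    chrom: list[str] = []
    pos: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            logger.warning(
                "skipping non-biallelic record %s:%d (ALT=%s)", var.CHROM, var.POS, var.ALT
            )
            continue
        col = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            a, b = gt[0], gt[1]
            col[i] = MISSING if (a < 0 or b < 0) else a + b
        cols.append(col)
        lid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        locus_ids.append(lid)
        chrom.append(var.CHROM)
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(var.ALT[0])
    vcf.close()
    if not cols:
        raise ValueError(f"no biallelic sites found in {path!r} ({n_skipped} records skipped)")
    return GenotypeMatrix(
        np.column_stack(cols),
        samples,
        tuple(locus_ids),
        chrom=tuple(chrom),
        pos=tuple(pos),
        ref=tuple(ref),
        alt=tuple(alt),
    )


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write ``g`` as a minimal VCF v4.2 with GT-only genotype fields.

    Round-trips exactly through :func:`read_vcf` (genotypes, ids, missingness).
    """
    chrom = g.chrom or tuple("1" for _ in g.locus_ids)
    pos = g.pos or tuple(range(1, g.n_loci + 1))
    ref = g.ref or tuple("A" for _ in g.locus_ids)
    alt = g.alt or tuple("T" for _ in g.locus_ids)
    contigs: dict[str, None] = {}
    for c in chrom:
        contigs.setdefault(c)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=cliffpop\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.individual_ids)
            + "\n"
        )
        gt = g.genotypes
        for j in range(g.n_loci):
            fields = [
                chrom[j],
                str(pos[j]),
                str(g.locus_ids[j]),
                ref[j],
                alt[j],
                ".",
                "PASS",
                ".",
                "GT",
            ]
            fields.extend(_GT_STR[int(gt[i, j])] for i in range(g.n_individuals))
            fh.write("\t".join(fields) + "\n")


def read_population_map(path) -> PopulationMap:
    """Read a 2-column tab-separated (individual, population) file."""
    assignment: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"malformed population-map line: {line!r}")
            ind, pop = parts
            if ind in assignment:
                raise ValueError(f"duplicate individual {ind!r} in population map")
            assignment[ind] = pop
    if not assignment:
        raise ValueError(f"empty population map {path!r}")
    return PopulationMap(assignment)


def write_population_map(pm: PopulationMap, path) -> None:
    with open(path, "w") as fh:
        for ind, pop in pm.assignment.items():
            fh.write(f"{ind}\t{pop}\n")


# ---------------------------------------------------------------------------
# Filtering


def _locus_predicates(g: GenotypeMatrix, cfg: FilterConfig):
    """Vectorized per-locus keep masks (presence, MAF, het-excess)."""
    gt = g.genotypes
    obs = gt != MISSING
    n_obs = obs.sum(axis=0)

    if cfg.max_missing_individuals is not None:
        presence_ok = (g.n_individuals - n_obs) <= cfg.max_missing_individuals
    else:
        presence_ok = n_obs >= cfg.locus_presence_min * g.n_individuals

    with np.errstate(divide="ignore", invalid="ignore"):
        alt_count = np.where(obs, gt, 0).sum(axis=0)
        p_alt = np.where(n_obs > 0, alt_count / (2.0 * n_obs), np.nan)
        maf = np.minimum(p_alt, 1.0 - p_alt)
        het = np.where(obs, gt == 1, False).sum(axis=0)
        het_frac = np.where(n_obs > 0, het / n_obs, np.nan)

    # loci with zero observed alleles are always removed
    maf_ok = (n_obs > 0) & (maf >= cfg.maf_min - 1e-12)
    het_ok = (n_obs > 0) & (het_frac <= cfg.obs_het_max + 1e-12)
    return presence_ok, maf_ok, het_ok


def filter_loci(g: GenotypeMatrix, cfg: FilterConfig | None = None) -> GenotypeMatrix:
    """Retain loci passing presence, MAF and heterozygote-excess thresholds.

    The three predicates are conjunctive, so the (logged) order
    presence → MAF → het-excess does not affect the result; locus order is
    preserved and the operation is idempotent. Removing every locus returns
    an empty matrix with a warning, not an error.
    """
    if g.n_loci == 0:
        raise ValueError("empty genotype matrix")
    cfg = cfg or FilterConfig()
    presence_ok, maf_ok, het_ok = _locus_predicates(g, cfg)
    logger.info(
        "filter_loci: %d loci in; presence pass %d; +MAF pass %d; +het pass %d",
        g.n_loci,
        int(presence_ok.sum()),
        int((presence_ok & maf_ok).sum()),
        int((presence_ok & maf_ok & het_ok).sum()),
    )
    keep = presence_ok & maf_ok & het_ok
    if not keep.any():
        logger.warning("filter_loci removed every locus")
    return g.take_loci(np.flatnonzero(keep))


def select_individuals(g: GenotypeMatrix, keep: list[str]) -> GenotypeMatrix:
    """Row submatrix in the requested order; loci untouched."""
    index = {ind: i for i, ind in enumerate(g.individual_ids)}
    unknown = [k for k in keep if k not in index]
    if unknown:
        raise KeyError(f"unknown individual ids: {unknown}")
    rows = [index[k] for k in keep]
    return replace(g, genotypes=g.genotypes[rows, :], individual_ids=tuple(keep))


def missingness_report(g: GenotypeMatrix) -> dict[str, float]:
    """Overall missingness under both common conventions.

    Returns the per-genotype missing fraction (missing cells / all cells) and
    the mean per-locus missing fraction; with a rectangular matrix the two
    coincide, but they are both reported because tools differ in convention.
    """
    miss = g.missing_mask
    per_genotype = float(miss.mean()) if miss.size else float("nan")
    per_locus = float(miss.mean(axis=0).mean()) if miss.size else float("nan")
    per_individual = float(miss.mean(axis=1).mean()) if miss.size else float("nan")
    return {
        "per_genotype": per_genotype,
        "per_locus_mean": per_locus,
        "per_individual_mean": per_individual,
    }
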