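"""End-to-end orchestration: fixtures, configuration and the demo pipeline.

The pipeline mirrors the shape of a three-population ddRAD phylogeography
study: SNP filtering, diversity and structure statistics, cluster-number
selection, a plastid haplotype network, and ABC random-forest scenario
choice with parameter estimation — all runnable on packaged synthetic
fixtures with a single master seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .abcrf import build_reference_table, choose_scenario, estimate_parameters, summary_vector
from .clustering import select_k_gap
from .coalescent import (
    DEFAULT_SAMPLE_SIZES,
    DemographicModel,
    ParameterDraw,
    PriorSet,
    default_population_map,
    simulate_dataset,
)
from .genotypes import (
    FilterConfig,
    read_population_map,
    read_vcf,
    write_population_map,
    write_vcf,
    filter_loci,
    missingness_report,
)
from .haplonet import build_network, figure_fixture, parsimony_limit
from .model import ColonizationABC
from .popgen import allele_sharing_distance, diversity_stats, nj_tree, pairwise_fst

__all__ = ["PipelineConfig", "make_fixtures", "run_pipeline", "FIXTURE_DRAW", "SAMPLING_SITES"]

logger = logging.getLogger(__name__)

#: Site manifest of the sampling design: six sites, 51 sampled individuals.
SAMPLING_SITES = (
    ("Capri - Grotta dell'Acqua", "C", "Capri", 120, 18),
    ("Strombolicchio", "K", "Strombolicchio", 60, 12),
    ("Palinuro Porto", "P", "Palinuro", 40, 16),
    ("Palinuro Punta Iacco", "PIK", "Palinuro", 40, 1),
    ("Palinuro Cala Fetente", "CFK", "Palinuro", 50, 2),
    ("Palinuro-Camerota", "CAM", "Palinuro", 15, 2),
)

#: Mid-prior scenario-1 parameters used for the packaged nuclear fixture.
FIXTURE_DRAW = ParameterDraw(
    n_palinuro=300,
    n_capri=255,
    n_strombolicchio=30,
    n1b=28,
    n2b=28,
    t1=37_500,
    t2=12_500,
    db=55,
)


@dataclass
class PipelineConfig:
    """Validated configuration for a pipeline run.

    Unknown keys in a config file are rejected; the effective configuration
    is echoed to the log and embedded in the report.
    """

    vcf: str
    popmap: str
    fasta: str | None = None
    out_dir: str = "cliffpop_run"
    filter: FilterConfig = field(default_factory=FilterConfig)
    priors: PriorSet = field(default_factory=PriorSet)
    n_per_scenario: int = 500
    n_trees: int = 1500
    k_min: int = 1
    k_max: int = 6
    n_gap_ref: int = 100
    plastid_alignment_length: int = 1000
    seed: int = 0

    _SIMPLE_KEYS = (
        "vcf", "popmap", "fasta", "out_dir", "n_per_scenario", "n_trees",
        "k_min", "k_max", "n_gap_ref", "plastid_alignment_length", "seed",
    )

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = set(cls._SIMPLE_KEYS) | {"filter", "priors"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        filt = FilterConfig(**raw.pop("filter", {}))
        priors_raw = raw.pop("priors", {})
        priors = PriorSet(**{k: tuple(v) if isinstance(v, list) else v for k, v in priors_raw.items()})
        return cls(filter=filt, priors=priors, **raw)

    def echo(self) -> dict:
        d = {k: getattr(self, k) for k in self._SIMPLE_KEYS}
        d["filter"] = vars(self.filter).copy()
        d["priors"] = {k: list(getattr(self.priors, k)) for k in self.priors.parameter_names}
        d["priors"]["generation_time_years"] = self.priors.generation_time_years
        return d


def make_fixtures(out_dir, seed: int = 0) -> dict[str, str]:
    """Write the packaged synthetic demo inputs.

    Produces (a) the six-site sampling manifest (51 sampled individuals),
    (b) the three-haplotype plastid FASTA (synthetic nucleotide states with
    the observed step structure and geographic composition), and (c) a
    nuclear VCF of 25 individuals (10/8/7) x 120 SNP loci simulated under
    scenario 1 at mid-prior parameters, with its population map and a
    manifest of scenario, parameters and seed. Byte-identical for a fixed
    seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest_path = out / "sampling_sites.tsv"
    with open(manifest_path, "w") as fh:
        fh.write("site\tabbreviation\tpopulation\tcensus_individuals\tsampled_individuals\n")
        for site, abbr, pop, census, sampled in SAMPLING_SITES:
            fh.write(f"{site}\t{abbr}\t{pop}\t{census}\t{sampled}\n")

    haps = figure_fixture()
    fasta_path = out / "plastid_haplotypes.fasta"
    with open(fasta_path, "w") as fh:
        for hid in haps.ids:
            k = 0
            for pop, count in sorted(haps.population_counts[hid].items()):
                for _ in range(count):
                    k += 1
                    fh.write(f">{hid}_{k:02d}|{pop}\n{haps.sequences[hid]}\n")

    g = simulate_dataset(
        DemographicModel(1), FIXTURE_DRAW, DEFAULT_SAMPLE_SIZES, n_loci=120, seed=seed
    )
    pm = default_population_map(DEFAULT_SAMPLE_SIZES)
    vcf_path = out / "nuclear_snps.vcf"
    popmap_path = out / "popmap.tsv"
    write_vcf(g, vcf_path)
    write_population_map(pm, popmap_path)

    meta_path = out / "fixture_manifest.json"
    with open(meta_path, "w") as fh:
        json.dump(
            {
                "scenario": 1,
                "parameters": FIXTURE_DRAW.as_dict(),
                "seed": seed,
                "sample_sizes": DEFAULT_SAMPLE_SIZES,
                "n_loci": 120,
                "note": "synthetic data; plastid nucleotide states are synthetic",
            },
            fh,
            indent=2,
        )
        fh.write("\n")
    return {
        "sampling_sites": str(manifest_path),
        "plastid_fasta": str(fasta_path),
        "vcf": str(vcf_path),
        "popmap": str(popmap_path),
        "manifest": str(meta_path),
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute filter -> statistics -> clustering -> network -> ABC.

    Every stage derives its seed from the configured master seed; the
    returned report (also written as JSON) pins seeds, configuration and
    versions so the run can be replayed exactly. Inputs are never mutated;
    outputs are written once into the run directory.
    """
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": cfg.echo(), "stages": {}}
    rng = np.random.default_rng(cfg.seed)
    stage_seeds = {
        name: int(s)
        for name, s in zip(
            ("cluster", "abc"), rng.integers(0, 2**31 - 1, size=2)
        )
    }
    report["stage_seeds"] = stage_seeds

    def stage(name):
        logger.info("stage %-10s starting", name)
        report["stages"][name] = {"t_start": round(time.time() - t0, 2)}
        return report["stages"][name]

    try:
        s = stage("load")
        g = read_vcf(cfg.vcf)
        pm = read_population_map(cfg.popmap)
        s.update(individuals=g.n_individuals, loci=g.n_loci,
                 missingness=missingness_report(g))

        s = stage("filter")
        gf = filter_loci(g, cfg.filter)
        s.update(loci_in=g.n_loci, loci_out=gf.n_loci)
        logger.info("filter funnel: %d -> %d loci", g.n_loci, gf.n_loci)

        s = stage("diversity")
        div = diversity_stats(gf, pm)
        div.to_tsv(out / "diversity.tsv")
        s["table"] = json.loads(div.table.to_json())

        s = stage("fst")
        fst = pairwise_fst(gf, pm)
        fst.to_tsv(out / "fst.tsv")
        with open(out / "fst_nj.nwk", "w") as fh:
            fh.write(nj_tree(fst) + "\n")
        s["matrix"] = fst.to_dataframe().to_dict()

        s = stage("cluster")
        asd = allele_sharing_distance(gf)
        asd.to_tsv(out / "allele_sharing.tsv")
        sel = select_k_gap(asd, cfg.k_min, cfg.k_max, n_ref=cfg.n_gap_ref,
                           seed=stage_seeds["cluster"])
        s.update(best_k=sel.best_k, gap=list(sel.gap), se=list(sel.se))

        if cfg.fasta:
            s = stage("network")
            from .haplonet import read_fasta_haplotypes

            haps = read_fasta_haplotypes(cfg.fasta)
            limit = parsimony_limit(cfg.plastid_alignment_length)
            net = build_network(haps, limit=limit)
            net.to_graphml(out / "haplotype_network.graphml")
            net.to_edgelist_tsv(out / "haplotype_network_edges.tsv")
            net.to_nodes_tsv(out / "haplotype_network_nodes.tsv")
            s.update(
                n_haplotypes=len(haps.ids),
                n_inferred=len(net.inferred_nodes),
                n_edges=net.graph.number_of_edges(),
                connection_limit=limit,
            )

        s = stage("abc")
        abc = ColonizationABC(gf, pm, priors=cfg.priors)
        res = abc.fit(
            n_per_scenario=cfg.n_per_scenario,
            n_trees=cfg.n_trees,
            seed=stage_seeds["abc"],
        )
        res.reference_table.to_tsv(out / "reference_table.tsv")
        res.posterior.to_tsv(out / "posterior.tsv")
        s.update(res.to_report())
        with open(out / "summary.txt", "w") as fh:
            fh.write(res.summary())
    except Exception as exc:
        failed = next(reversed(report["stages"]), "?")
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc
    finally:
        for st in report["stages"].values():
            st.setdefault("t_end", round(time.time() - t0, 2))

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
        fh.write("\n")
    return report
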