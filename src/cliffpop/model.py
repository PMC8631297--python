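"""Model/Results interface for the colonization-history ABC analysis.

:class:`ColonizationABC` bundles the observed SNP data, the population map
and the prior specification; ``fit()`` simulates the reference table, runs
random-forest scenario choice, and estimates the parameter posteriors under
the winning scenario, returning a :class:`ColonizationABCResults` with a
``summary()`` table.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import pandas as pd

from .abcrf import (
    ModelChoiceResult,
    ParameterEstimator,
    PosteriorSummary,
    ReferenceTable,
    SummaryStatVector,
    build_reference_table,
    choose_scenario,
    generations_to_years,
    summary_vector,
)
from .coalescent import PriorSet
from .genotypes import GenotypeMatrix, PopulationMap

__all__ = ["ColonizationABC", "ColonizationABCResults"]


class ColonizationABC:
    """ABC random-forest inference of island-colonization history.

    Parameters
    ----------
    genotypes
        Observed diploid SNP matrix.
    popmap
        Individual-to-population assignment; population labels must match
        the scenario demes (Palinuro / Capri / Strombolicchio by default).
    priors
        Uniform prior ranges; defaults to the study priors.
    scenarios
        Candidate scenario ids to compare.
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        popmap: PopulationMap,
        priors: PriorSet | None = None,
        scenarios: tuple[int, ...] = (1, 2, 3, 4),
    ):
        self.genotypes = genotypes
        self.popmap = popmap
        self.priors = priors or PriorSet()
        self.scenarios = tuple(scenarios)
        counts: dict[str, int] = {}
        for ind in genotypes.individual_ids:
            pop = popmap.assignment.get(ind)
            if pop is None:
                raise KeyError(f"individual {ind!r} missing from population map")
            counts[pop] = counts.get(pop, 0) + 1
        self.sample_sizes = counts
        self.observed: SummaryStatVector = summary_vector(genotypes, popmap)

    @classmethod
    def from_vcf(cls, vcf_path, popmap_path, **kwargs) -> "ColonizationABC":
        from .genotypes import read_population_map, read_vcf

        return cls(read_vcf(vcf_path), read_population_map(popmap_path), **kwargs)

    def fit(
        self,
        n_per_scenario: int = 500,
        n_trees: int = 1500,
        seed: int = 0,
        reference_table: ReferenceTable | None = None,
        lda_mode: str = "append",
    ) -> "ColonizationABCResults":
        """Simulate (or reuse) the reference table and run both forest steps."""
        rt = reference_table
        if rt is None:
            rt = build_reference_table(
                scenarios=self.scenarios,
                priors=self.priors,
                n_per_scenario=n_per_scenario,
                sample_sizes=self.sample_sizes,
                n_loci=self.genotypes.n_loci,
                seed=seed,
            )
        choice = choose_scenario(rt, self.observed, n_trees=n_trees, seed=seed, lda_mode=lda_mode)
        estimator = ParameterEstimator(
            rt.restrict_to(choice.best_scenario), n_trees=n_trees, seed=seed + 7
        )
        posterior = estimator.predict(self.observed)
        return ColonizationABCResults(self, rt, choice, posterior)


@dataclass
class ColonizationABCResults:
    """Fitted scenario choice and parameter posteriors."""

    model: ColonizationABC
    reference_table: ReferenceTable
    choice: ModelChoiceResult
    posterior: PosteriorSummary

    @property
    def best_scenario(self) -> int:
        return self.choice.best_scenario

    @property
    def votes(self) -> dict[int, int]:
        return self.choice.votes

    @property
    def posterior_probability(self) -> float:
        return self.choice.posterior_probability

    def split_times_mya(self) -> dict[str, float]:
        """Posterior-mean split times converted to Mya (generation time applied)."""
        gt = self.model.priors.generation_time_years
        out = {}
        for name in ("t1", "t2"):
            if name in self.posterior.table.index:
                _, mya = generations_to_years(self.posterior.table.loc[name, "mean"], gt)
                out[name] = mya
        return out

    def summary(self) -> str:
        buf = io.StringIO()
        buf.write("Colonization-history ABC random forest\n")
        buf.write("=" * 54 + "\n")
        buf.write(
            f"Observed data: {self.model.genotypes.n_individuals} individuals, "
            f"{self.model.genotypes.n_loci} loci\n"
        )
        buf.write(
            f"Reference table: {self.reference_table.n_rows} simulations "
            f"({len(self.model.scenarios)} scenarios), {self.choice.n_trees} trees\n\n"
        )
        buf.write("Scenario votes:\n")
        for s in sorted(self.votes):
            marker = "  <- best" if s == self.best_scenario else ""
            buf.write(f"  scenario {s}: {self.votes[s]:6d}{marker}\n")
        buf.write(
            f"\nPosterior probability of scenario {self.best_scenario}: "
            f"{self.posterior_probability:.3f}\n\n"
        )
        buf.write(f"Parameter posteriors (scenario {self.best_scenario}):\n")
        buf.write(self.posterior.table.round(2).to_string())
        times = self.split_times_mya()
        if times:
            buf.write("\n\nSplit times (posterior mean, Mya at "
                      f"{self.model.priors.generation_time_years:g} y/generation): ")
            buf.write(", ".join(f"{k}={v:.2f}" for k, v in times.items()))
        buf.write("\n")
        return buf.getvalue()

    def to_report(self) -> dict:
        """JSON-serializable payload of every fitted quantity."""
        return {
            "votes": {str(k): v for k, v in self.votes.items()},
            "best_scenario": self.best_scenario,
            "posterior_probability": self.posterior_probability,
            "n_trees": self.choice.n_trees,
            "posterior": {
                p: {c: float(self.posterior.table.loc[p, c]) for c in self.posterior.table.columns}
                for p in self.posterior.table.index
            },
            "split_times_mya": self.split_times_mya(),
            "reference_table_rows": self.reference_table.n_rows,
            "stat_set_version": self.reference_table.stat_set_version,
        }
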