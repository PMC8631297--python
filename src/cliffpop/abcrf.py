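"""ABC random-forest scenario choice and parameter estimation.

The approximate Bayesian computation pipeline: a reference table of
simulations (scenario id, parameter draw, summary statistics), a
classification forest voting among scenarios on LDA-augmented summaries,
a regression forest on out-of-bag correctness for the posterior probability
of the chosen scenario, and quantile regression forests for parameter
posteriors — the random-forest ABC recipe of Pudlo et al. (model choice)
and Raynal et al. (parameter estimation).
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coalescent import (
    DEFAULT_SAMPLE_SIZES,
    DemographicModel,
    ParameterDraw,
    PriorSet,
    sample_prior,
    simulate_dataset,
)
from .genotypes import MISSING, GenotypeMatrix, PopulationMap
from .popgen import _per_locus_ho_he, allele_sharing_distance, wc_theta

__all__ = [
    "SummaryStatVector",
    "ReferenceTable",
    "ModelChoiceResult",
    "PosteriorSummary",
    "summary_vector",
    "build_reference_table",
    "ScenarioClassifier",
    "choose_scenario",
    "ParameterEstimator",
    "estimate_parameters",
    "generations_to_years",
]

#: Version tag of the summary-statistic ordering; bump when the set changes.
#: 1.1 added the within-kind contrasts between population pairs, which carry
#: the colonization-topology signal (e.g. is Strombolicchio closer to Capri
#: or to Palinuro) far more directly than the raw pairwise values.
STAT_SET_VERSION = "1.1"


@dataclass(frozen=True)
class SummaryStatVector:
    """Fixed-order summary statistics for one dataset.

    Per population: mean observed heterozygosity, mean gene diversity and
    the proportion of loci polymorphic within the population. Per
    population pair: Weir-Cockerham Fst, Nei's standard genetic distance
    and the mean between-population allele-sharing distance. Per unordered
    pair of population pairs, within each pairwise kind: the contrast
    (difference) between the two pairs' values, which encodes the relative
    affinity structure among the populations. Undefined entries are NaN and
    are imputed (column median) at table-build time.
    """

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.names),):
            raise ValueError("values do not match names")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)


def _nei_standard_distance(gx: np.ndarray, gy: np.ndarray) -> float:
    """Nei (1972) standard genetic distance from biallelic allele frequencies."""
    def freqs(gt):
        obs = gt != MISSING
        n = obs.sum(axis=0).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(obs, gt, 0).sum(axis=0) / (2.0 * n)
        p[n == 0] = np.nan
        return p

    px, py = freqs(gx), freqs(gy)
    ok = ~np.isnan(px) & ~np.isnan(py)
    if not ok.any():
        return float("nan")
    px, py = px[ok], py[ok]
    jxy = float(np.mean(px * py + (1 - px) * (1 - py)))
    jx = float(np.mean(px**2 + (1 - px) ** 2))
    jy = float(np.mean(py**2 + (1 - py) ** 2))
    if jxy <= 0:
        return float("nan")
    return float(-np.log(jxy / np.sqrt(jx * jy)))


def summary_vector(g: GenotypeMatrix, pm: PopulationMap) -> SummaryStatVector:
    """Compute the versioned summary-statistic vector for one dataset."""
    groups = pm.indices_by_population(g)
    pops = list(groups)
    if any(len(idx) == 0 for idx in groups.values()):
        raise ValueError("every population must contain at least one individual")
    names: list[str] = []
    values: list[float] = []

    for pop in pops:
        gt = g.genotypes[groups[pop], :]
        ho_l, he_l = _per_locus_ho_he(gt)
        obs = gt != MISSING
        n_obs = obs.sum(axis=0)
        alt = np.where(obs, gt, 0).sum(axis=0)
        seen = n_obs > 0
        poly = seen & (alt > 0) & (alt < 2 * n_obs)
        prop_poly = float(poly.sum() / seen.sum()) if seen.any() else float("nan")
        names += [f"Ho_{pop}", f"He_{pop}", f"poly_{pop}"]
        values += [float(np.nanmean(ho_l)), float(np.nanmean(he_l)), prop_poly]

    asd = allele_sharing_distance(g) if g.n_individuals >= 2 else None
    pair_vals: dict[str, dict[tuple[str, str], float]] = {"Fst": {}, "NeiD": {}, "ASD": {}}
    pair_order: list[tuple[str, str]] = []
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            a, b = pops[i], pops[j]
            ga, gb = g.genotypes[groups[a], :], g.genotypes[groups[b], :]
            fst = wc_theta([ga, gb]) if min(len(groups[a]), len(groups[b])) >= 2 else float("nan")
            nei = _nei_standard_distance(ga, gb)
            cross = asd.values[np.ix_(groups[a], groups[b])] if asd is not None else np.array([np.nan])
            names += [f"Fst_{a}_{b}", f"NeiD_{a}_{b}", f"ASD_{a}_{b}"]
            values += [fst, nei, float(np.nanmean(cross))]
            pair_vals["Fst"][(a, b)] = fst
            pair_vals["NeiD"][(a, b)] = nei
            pair_vals["ASD"][(a, b)] = float(np.nanmean(cross))
            pair_order.append((a, b))
    # contrasts between population pairs: the relative-affinity signal
    for kind in ("Fst", "NeiD", "ASD"):
        for x in range(len(pair_order)):
            for z in range(x + 1, len(pair_order)):
                (a, b), (c, d) = pair_order[x], pair_order[z]
                names.append(f"d{kind}_{a}.{b}_vs_{c}.{d}")
                values.append(pair_vals[kind][(a, b)] - pair_vals[kind][(c, d)])
    return SummaryStatVector(tuple(names), np.asarray(values))


@dataclass
class ReferenceTable:
    """Simulated (scenario, parameters, summary statistics) rows.

    ``stats`` holds the raw (possibly NaN) statistics; ``imputed_stats``
    fills NaN with per-column medians (recorded in ``column_medians``);
    ``row_seeds`` allow exact replay of any row.
    """

    scenario_ids: np.ndarray
    params: pd.DataFrame
    stats: pd.DataFrame
    row_seeds: np.ndarray
    priors: PriorSet
    sample_sizes: dict[str, int]
    n_loci: int
    master_seed: int
    stat_set_version: str = STAT_SET_VERSION

    @property
    def n_rows(self) -> int:
        return len(self.scenario_ids)

    @property
    def column_medians(self) -> pd.Series:
        return self.stats.median(axis=0, skipna=True)

    @property
    def imputed_stats(self) -> pd.DataFrame:
        med = self.column_medians
        n_nan = int(self.stats.isna().sum().sum())
        if n_nan:
            import logging

            logging.getLogger(__name__).info(
                "imputing %d undefined summary-statistic cells with column medians", n_nan
            )
        return self.stats.fillna(med)

    def restrict_to(self, scenario_id: int) -> "ReferenceTable":
        mask = self.scenario_ids == scenario_id
        if not mask.any():
            raise ValueError(f"no rows for scenario {scenario_id}")
        return ReferenceTable(
            self.scenario_ids[mask],
            self.params.loc[mask].reset_index(drop=True),
            self.stats.loc[mask].reset_index(drop=True),
            self.row_seeds[mask],
            self.priors,
            self.sample_sizes,
            self.n_loci,
            self.master_seed,
            self.stat_set_version,
        )

    def to_tsv(self, path) -> None:
        """Tab-separated rows with a JSON metadata header line."""
        meta = {
            "stat_set_version": self.stat_set_version,
            "master_seed": int(self.master_seed),
            "n_loci": int(self.n_loci),
            "sample_sizes": self.sample_sizes,
            "priors": {k: list(getattr(self.priors, k)) for k in self.priors.parameter_names},
            "generation_time_years": self.priors.generation_time_years,
            "stat_names": list(self.stats.columns),
            "param_names": list(self.params.columns),
        }
        body = pd.concat(
            [
                pd.Series(self.scenario_ids, name="scenario"),
                pd.Series(self.row_seeds, name="row_seed"),
                self.params,
                self.stats,
            ],
            axis=1,
        )
        with open(path, "w") as fh:
            fh.write("#" + json.dumps(meta) + "\n")
            body.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ReferenceTable":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise ValueError("missing JSON metadata header")
            meta = json.loads(header[1:])
            body = pd.read_csv(fh, sep="\t")
        priors = PriorSet(
            **{k: tuple(v) for k, v in meta["priors"].items()},
            generation_time_years=meta["generation_time_years"],
        )
        return cls(
            body["scenario"].to_numpy(),
            body[meta["param_names"]],
            body[meta["stat_names"]],
            body["row_seed"].to_numpy(),
            priors,
            {k: int(v) for k, v in meta["sample_sizes"].items()},
            meta["n_loci"],
            meta["master_seed"],
            meta["stat_set_version"],
        )


def simulate_reference_row(
    scenario_id: int,
    row_seed: int,
    priors: PriorSet,
    sample_sizes: dict[str, int],
    n_loci: int,
    pm: PopulationMap,
    missing_prob: float = 0.0,
) -> tuple[ParameterDraw, SummaryStatVector]:
    """One reference-table row, fully determined by its seed (replayable)."""
    draw = sample_prior(priors, rng=random.Random(row_seed))
    g = simulate_dataset(
        DemographicModel(scenario_id),
        draw,
        sample_sizes,
        n_loci=n_loci,
        seed=(row_seed + 1) % 2**31,
        missing_prob=missing_prob,
    )
    return draw, summary_vector(g, pm)


def build_reference_table(
    scenarios: tuple[int, ...] = (1, 2, 3, 4),
    priors: PriorSet | None = None,
    n_per_scenario: int = 500,
    sample_sizes: dict[str, int] | None = None,
    n_loci: int = 120,
    seed: int = 0,
    missing_prob: float = 0.0,
) -> ReferenceTable:
    """Simulate the ABC reference table.

    Per-row seeds derive reproducibly from the master seed; identical master
    seeds give identical tables. Simulator failures propagate with the
    offending row's scenario and seed in the message.
    """
    if n_per_scenario < 1:
        raise ValueError("n_per_scenario must be >= 1")
    priors = priors or PriorSet()
    sizes = dict(DEFAULT_SAMPLE_SIZES if sample_sizes is None else sample_sizes)
    from .coalescent import default_population_map

    pm = default_population_map(sizes)
    n_rows = n_per_scenario * len(scenarios)
    row_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_rows)
    scen_col = np.repeat(np.asarray(scenarios, dtype=int), n_per_scenario)

    param_rows, stat_rows = [], []
    stat_names: tuple[str, ...] | None = None
    for k, (scen, rs) in enumerate(zip(scen_col, row_seeds)):
        try:
            draw, vec = simulate_reference_row(
                int(scen), int(rs), priors, sizes, n_loci, pm, missing_prob
            )
        except Exception as exc:
            raise RuntimeError(
                f"reference-table row {k} (scenario {scen}, seed {rs}) failed: {exc}"
            ) from exc
        param_rows.append(draw.as_dict())
        stat_rows.append(vec.values)
        stat_names = vec.names
    return ReferenceTable(
        scenario_ids=scen_col,
        params=pd.DataFrame(param_rows),
        stats=pd.DataFrame(np.vstack(stat_rows), columns=list(stat_names)),
        row_seeds=row_seeds,
        priors=priors,
        sample_sizes=sizes,
        n_loci=n_loci,
        master_seed=seed,
    )


@dataclass(frozen=True)
class ModelChoiceResult:
    """Random-forest scenario choice: votes, winner and its posterior probability."""

    votes: dict[int, int]
    best_scenario: int
    posterior_probability: float
    n_trees: int

    def __post_init__(self) -> None:
        if sum(self.votes.values()) != self.n_trees:
            raise ValueError("votes must sum to n_trees")
        if not 0.0 <= self.posterior_probability <= 1.0:
            raise ValueError("posterior probability must lie in [0, 1]")


def _impute_observed(rt: ReferenceTable, observed: SummaryStatVector) -> np.ndarray:
    if tuple(observed.names) != tuple(rt.stats.columns):
        raise ValueError("observed summary-statistic ordering does not match the reference table")
    vals = observed.values.copy()
    med = rt.column_medians.to_numpy()
    nan = np.isnan(vals)
    vals[nan] = med[nan]
    return vals


class ScenarioClassifier:
    """LDA-augmented random-forest scenario choice; fit once, classify many.

    The classification forest is trained on the reference table's summary
    statistics concatenated with LDA axes (fit on reference rows only); the
    companion regression forest is trained on the out-of-bag correctness
    indicator of the classifier, following the ABC-RF posterior-probability
    recipe. Both forests are seeded and reproducible.
    """

    def __init__(self, rt: ReferenceTable, n_trees: int = 1500, seed: int = 0,
                 lda_mode: str = "append"):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

        scen = np.unique(rt.scenario_ids)
        if len(scen) < 2:
            raise ValueError("reference table must contain at least two scenarios")
        if n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        self.rt = rt
        self.n_trees = n_trees
        self.lda_mode = lda_mode
        X_raw = rt.imputed_stats.to_numpy()
        y = rt.scenario_ids.astype(int)
        self._lda = LinearDiscriminantAnalysis(
            n_components=min(len(scen) - 1, X_raw.shape[1])
        )
        self._lda.fit(X_raw, y)
        X = self._augment(X_raw)
        self._clf = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed, oob_score=True, n_jobs=1
        )
        self._clf.fit(X, y)
        oob = self._clf.oob_decision_function_
        valid = ~np.isnan(oob).any(axis=1)
        oob_pred = self._clf.classes_[np.argmax(oob[valid], axis=1)]
        correct = (oob_pred == y[valid]).astype(float)
        self.oob_error = float(1.0 - correct.mean())
        # the error-regression forest needs far fewer trees than the vote
        # forest, and sqrt mtry (the usual RF-regression compromise) keeps it
        # cheap without hurting a 0/1 target
        self._reg = RandomForestRegressor(
            n_estimators=min(n_trees, 500),
            max_features="sqrt",
            random_state=seed + 1,
            n_jobs=1,
        )
        self._reg.fit(X[valid], correct)

    def _augment(self, X: np.ndarray) -> np.ndarray:
        if self.lda_mode == "append":
            return np.hstack([X, self._lda.transform(X)])
        if self.lda_mode == "replace":
            return self._lda.transform(X)
        raise ValueError("lda mode must be 'append' or 'replace'")

    def classify(self, observed: SummaryStatVector) -> ModelChoiceResult:
        obs = self._augment(_impute_observed(self.rt, observed).reshape(1, -1))
        # individual trees predict encoded class indices; map back through classes_
        tree_preds = self._clf.classes_[
            np.array([int(est.predict(obs)[0]) for est in self._clf.estimators_])
        ]
        votes = {int(s): int((tree_preds == s).sum()) for s in np.unique(self.rt.scenario_ids)}
        best = max(votes, key=lambda s: (votes[s], -s))
        p = float(np.clip(self._reg.predict(obs)[0], 0.0, 1.0))
        return ModelChoiceResult(
            votes=votes, best_scenario=int(best), posterior_probability=p, n_trees=self.n_trees
        )


def choose_scenario(
    rt: ReferenceTable,
    observed: SummaryStatVector,
    n_trees: int = 1500,
    seed: int = 0,
    lda_mode: str = "append",
) -> ModelChoiceResult:
    """Classify the observed dataset among scenarios with a random forest.

    Votes are the per-tree predictions at the observed point; the posterior
    probability of the winning scenario is a regression forest trained on
    the out-of-bag correctness indicator of the classification forest,
    evaluated at the observed point and clipped to [0, 1].
    """
    return ScenarioClassifier(rt, n_trees=n_trees, seed=seed, lda_mode=lda_mode).classify(observed)


@dataclass(frozen=True)
class PosteriorSummary:
    """Per-parameter posterior mean, median, 5%/95% quantiles and variance."""

    table: pd.DataFrame  # index: parameter; columns mean, median, q5, q95, variance
    degenerate: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        t = self.table
        if not ((t["q5"] <= t["median"] + 1e-12) & (t["median"] <= t["q95"] + 1e-12)).all():
            raise ValueError("quantile ordering violated")
        if (t["variance"] < -1e-12).any():
            raise ValueError("negative variance")

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", float_format="%.6g")


def _weighted_quantile(y_sorted: np.ndarray, cum_w: np.ndarray, q: float) -> float:
    idx = int(np.searchsorted(cum_w, q, side="left"))
    return float(y_sorted[min(idx, len(y_sorted) - 1)])


class ParameterEstimator:
    """Quantile regression forests for the demographic parameters.

    One regression forest per parameter, fit on a (scenario-restricted)
    reference table; posterior weights at a query point are the standard
    quantile-regression-forest leaf weights, giving weighted mean, median,
    5%/95% quantiles and variance. Fit once, query many.
    """

    def __init__(self, rt_best: ReferenceTable, n_trees: int = 1500, seed: int = 0,
                 min_samples_leaf: int = 5, params: tuple[str, ...] | None = None,
                 max_features: float | str = 1 / 3):
        from sklearn.ensemble import RandomForestRegressor

        if rt_best.n_rows == 0:
            raise ValueError("empty reference table")
        self.rt = rt_best
        self.X = rt_best.imputed_stats.to_numpy()
        self.param_names = list(params) if params is not None else list(rt_best.params.columns)
        unknown = set(self.param_names) - set(rt_best.params.columns)
        if unknown:
            raise KeyError(f"unknown parameters: {sorted(unknown)}")
        self.forests = {}
        self.train_leaves = {}
        self.y = {}
        for k, name in enumerate(self.param_names):
            y = rt_best.params[name].to_numpy(dtype=float)
            self.y[name] = y
            if np.ptp(y) == 0.0:
                self.forests[name] = None  # degenerate prior: constant column
                continue
            f = RandomForestRegressor(
                n_estimators=n_trees,
                random_state=seed + k,
                min_samples_leaf=min_samples_leaf,
                max_features=max_features,  # the usual regression-forest mtry
                n_jobs=1,
            )
            f.fit(self.X, y)
            self.forests[name] = f
            self.train_leaves[name] = f.apply(self.X)

    def _weights(self, name: str, obs: np.ndarray) -> np.ndarray:
        f = self.forests[name]
        leaves_obs = f.apply(obs.reshape(1, -1))[0]
        train = self.train_leaves[name]
        w = np.zeros(train.shape[0])
        for t in range(train.shape[1]):
            mask = train[:, t] == leaves_obs[t]
            w[mask] += 1.0 / (train.shape[1] * mask.sum())
        return w

    def predict(self, observed: SummaryStatVector) -> PosteriorSummary:
        obs = _impute_observed(self.rt, observed)
        rows = {}
        degenerate = []
        for name in self.param_names:
            y = self.y[name]
            if self.forests[name] is None:
                v = float(y[0])
                rows[name] = {"mean": v, "median": v, "q5": v, "q95": v, "variance": 0.0}
                degenerate.append(name)
                continue
            w = self._weights(name, obs)
            order = np.argsort(y)
            ys, ws = y[order], w[order]
            cw = np.cumsum(ws)
            cw /= cw[-1]
            mean = float(np.dot(w, y))
            rows[name] = {
                "mean": mean,
                "median": _weighted_quantile(ys, cw, 0.5),
                "q5": _weighted_quantile(ys, cw, 0.05),
                "q95": _weighted_quantile(ys, cw, 0.95),
                "variance": float(np.dot(w, (y - mean) ** 2)),
            }
        table = pd.DataFrame.from_dict(rows, orient="index")[
            ["mean", "median", "q5", "q95", "variance"]
        ]
        return PosteriorSummary(table=table, degenerate=tuple(degenerate))


def estimate_parameters(
    rt_best: ReferenceTable,
    observed: SummaryStatVector,
    n_trees: int = 1500,
    seed: int = 0,
) -> PosteriorSummary:
    """Posterior summaries for every parameter at the observed point."""
    return ParameterEstimator(rt_best, n_trees=n_trees, seed=seed).predict(observed)


def generations_to_years(g: float, generation_time: float = 10.0) -> tuple[float, float]:
    """Convert generations to (years, Mya rounded to 2 decimals)."""
    if g < 0:
        raise ValueError("generations must be >= 0")
    years = g * generation_time
    return years, round(years / 1e6, 2)
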