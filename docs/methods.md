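# Methods

`cliffpop` reconstructs the colonization history of a species living in three
small, isolated populations — a mainland stand (Palinuro) and two island
stands (Capri and the Strombolicchio islet) — from two kinds of synthetic or
user-supplied data: unlinked biallelic nuclear SNPs (ddRAD-style, with
missing data) and a single non-recombining plastid haplotype per individual.
This note documents the models, the estimators, the numerical conventions,
and the places where a genuine design choice had to be made.

## Genotype model and SNP filtering

Nuclear data are diploid genotypes coded as the count of alternate alleles
(0/1/2, with −1 for missing). Ploidy is fixed at 2 for nuclear loci and 1
for the plastid. VCF coordinates are 1-based (the standard); internal
indices are 0-based. Only the GT field of a VCF is interpreted; multiallelic
records are skipped with a warning.

Locus filtering applies three conjunctive predicates:

* minor allele frequency ≥ `maf_min` (default 0.05), computed on observed
  (non-missing) alleles only — the only defensible convention under
  missingness; loci with zero observed alleles are always removed;
* observed heterozygote fraction ≤ `obs_het_max` (default 0.70), a guard
  against collapsed paralogs;
* call rate ≥ `locus_presence_min` (0.70 for a "full" dataset, 0.95 for a
  "reduced" one), or alternatively an absolute cap on missing individuals
  per locus.

Because the predicates are conjunctive, evaluation order does not affect the
result; the log reports the funnel in the order presence → MAF →
heterozygote excess. The filter is idempotent. Overall missingness is
reported under both the per-genotype and the per-locus convention, since
tools differ and the two can disagree on ragged data.

Individual selection is by explicit id list. (Selecting individuals by raw
read count, as one would during upstream processing, is not representable
once data are a genotype matrix; per-individual missingness is the
post-VCF analogue and is what the synthetic data vary.)

## Diversity and structure statistics

**Ho, He, Fis.** Per locus and population, Ho is the heterozygote fraction
among non-missing genotypes and He is Nei's unbiased gene diversity
(2n/(2n−1))·(1−Σp²) over the n non-missing diploids. Population values are
means over loci, and Fis = 1 − H̄o/H̄e is computed from those means
(ratio-of-means). The alternative — averaging per-locus ratios — is
undefined at monomorphic loci and numerically unstable at nearly-monomorphic
ones; ratio-of-means is the convention hierfstat-style software effectively
reports. A population monomorphic at every locus gets Fis = NaN, never a
silent zero. The across-population "mean" row averages Ho and He
arithmetically; no mean Fis is reported because no convention reproduces a
defensible quantity from the per-population values (the ratio-of-means and
mean-of-ratios answers differ materially).

**Fst.** Pairwise Weir & Cockerham (1984) θ. Per-locus variance components
a (among populations), b (among individuals within populations) and c
(within individuals) are computed from sample sizes, allele frequencies and
heterozygote fractions of the two populations, then summed across loci
before taking θ = Σa / Σ(a+b+c) — the standard multi-locus combination.
Negative estimates (sampling noise around zero differentiation) are
reported as-is. A pair with no jointly informative locus is NaN, flagged.

**Individual distances.** The allele-sharing distance between two
individuals is 1 − (shared alleles)/(2 · jointly observed loci), comparing
genotypes as unordered allele multisets (0/0 vs 0/1 share one allele). The
co-ancestry matrix is simply the count of jointly observed loci with
different genotypes, with a max−count similarity transform for heatmap
display.

**MDS.** Classical (Torgerson) scaling: double-center the squared
distances, eigendecompose, scale eigenvectors by √λ. Eigenvalues below
1e−12 of the leading one are zeroed so duplicated individuals embed exactly
coincident. Exact for Euclidean-embeddable inputs.

**Neighbor joining.** Saitou–Nei NJ via scikit-bio; exact on additive
matrices. Used for the Fst-matrix trees; no bootstrap, no ML trees.

## Cluster-number selection (gap statistic)

Individuals are clustered by Ward linkage on the allele-sharing distance
matrix; for each K in the scanned interval the pooled within-cluster
dispersion is W_K = Σ_clusters (Σ within-cluster squared distances)/(2n_r).
The reference distribution is `n_ref` (default 100) uniform draws in the
axis-aligned bounding box of the full-rank classical-MDS embedding of the
observed distances, clustered identically. gap(K) is the mean reference
log W_K minus the observed log W_K, with se(K) = sd·√(1+1/n_ref).

Best K is the smallest K whose gap lies within one standard error of the
maximal gap ("firstSEmax"). The sequential one-SE stopping rule (stop at the
first K with gap(K) ≥ gap(K+1)−se(K+1)) was evaluated and rejected: on
well-separated three-cluster data the gap curve dips at K=2 before jumping
at K=3, and the sequential rule stops at K=1. The firstSEmax variant returns
K=3 there, K=1 on structureless input, and keeps the parsimony property of
preferring the smallest defensible K. All randomness is seeded.

## Plastid haplotype network (statistical parsimony)

Haplotypes are connected agglomeratively in increasing Hamming distance
(gaps and Ns excluded pairwise), only up to a parsimony connection limit. A
connection of d steps inserts d−1 inferred intermediate nodes whose
sequences change the differing positions one at a time (ascending position
order — a documented tie-break; any order is equally parsimonious), so every
edge spans exactly one mutational step. Pairs already connected are skipped
(spanning-tree behaviour, which also prevents loops), and among
equal-distance candidates the pair with higher combined carrier frequency
attaches first, ties broken lexicographically. This reduces full
statistical-parsimony ambiguity resolution to a deterministic rule — the
networks this package targets are tiny (three haplotypes, two connections)
and reproducibility matters more than ambiguity enumeration.

The connection limit is the largest j whose probability of parsimony still
meets the confidence level α (default 0.95), floored at one step.
The probability model: per-site substitution counts are Poisson(λ) with λ
estimated from the observed difference fraction, λ̂ = −ln(1−j/m) for j
differences over m sites; parsimony holds when every differing site changed
exactly once, P_j = [λ̂e^{−λ̂}/(1−e^{−λ̂})]^j. This is a transparent
re-derivation in the spirit of the classical statistical-parsimony limit
(monotone in α, limit ≈ √(2m·ln(1/α)) for large m; ~10 steps at m=1000,
α=0.95) rather than a line-by-line reproduction of the original recursion.
Because the packaged plastid fixture has three SNP columns, the limit must
be computed from the *alignment* length (configurable, default 1000), not
from the SNP-matrix width.

The packaged three-haplotype fixture reproduces the observed arrangement —
H1–H2 one step apart, H3 two steps from H2 (one inferred intermediate), H2
present at all three sites, H1 at Palinuro and Capri, H3 private to
Strombolicchio — with synthetic nucleotide states, since only the step
structure and geographic composition are published.

## Coalescent simulator

A bespoke discrete-event structured coalescent, written in pure Python and
cross-validated against msprime in the test suite (msprime is never on the
simulation path). Demes have piecewise-constant sizes; there is no
migration after founding, no recombination within loci, no selection.

Four scenarios (times in generations before sampling, t1 > t2):

1. Capri founded from Palinuro at t1 (bottleneck: N1b founders for db
   generations), Strombolicchio founded from Capri at t2 (N2b for db);
2. as 1, but Strombolicchio founded from Palinuro;
3. Capri/Palinuro ancestral split at t1 with no bottleneck; Strombolicchio
   from Capri at t2 with a bottleneck;
4. as 3, but Strombolicchio from Palinuro.

Backward in time a deme of N diploids holds 2N gene copies (nuclear) or N/2
(plastid, maternal haploid); k lineages coalesce at rate k(k−1)/2 divided by
the copy number. A founding at time t with Nb founders is a size change to
Nb on (t−db, t]; at t the deme's lineages move into the source deme. The
ancestral population size equals the Palinuro size — the scenarios assign no
separate ancestral parameter. A panmictic control (`scenario 0`) disables
both events and pools all samples in a single deme of the Palinuro size.

**One SNP per locus.** Nuclear loci are simulated by drawing one genealogy
per locus and placing a single mutation on a branch chosen with probability
proportional to branch length, so every locus is polymorphic in the pooled
sample. This is the SNP-mode convention of ABC simulators: it conditions on
ascertained SNPs and removes the need for an arbitrary per-locus mutation
rate. An optional minor-allele-frequency floor on simulated loci exists and
is off by default. Diploids pair consecutive lineages; lineages within a
deme are exchangeable, so the pairing convention carries no information. An
optional per-genotype dropout probability emulates ddRAD missingness
(default 0 for inference).

**Plastid locus.** One lineage per individual, haploid size N/2,
infinite-sites Poisson mutations at total rate `mu_per_seq` per lineage per
generation; each mutation hits a fresh position and draws a random derived
base.

**Priors.** Uniform integer priors: N_Palinuro 100–500, N_Capri 10–500,
N_Strombolicchio 10–50, founder sizes N1b/N2b 5–50, split times 10–50,000
generations, bottleneck duration 10–100 generations, with t1 > t2 enforced
by rejection. db < t2 is additionally enforced — without it a bottleneck
window would extend past the younger event, which the scenario definitions
implicitly exclude. One shared db applies to both founding events (the
parameterization carries a single db). Generation time is 10 years;
conversions to calendar time multiply by it (24,615 generations → 0.25 Mya
at two decimals).

**What the generator does and does not emulate.** It reproduces the study
conditions — 3 populations sampled 10/8/7 diploids, ~120 unlinked biallelic
SNPs, founder-event demography, optional ddRAD-style dropout, few-SNP
plastid haplotypes — but not linked-SNP haplotype structure, genotyping
error, allele-calling ascertainment beyond the one-SNP conditioning, or
population substructure within sites (the real mainland population is
spread over several cliffs). Passing tests therefore validate the
estimators and the inference machinery under the stated model, not the
upstream bioinformatics of real ddRAD data.

## ABC random forest

**Summary statistics (set version 1.1).** Per population: mean Ho, mean He,
proportion of loci polymorphic within the population. Per population pair:
WC θ, Nei's (1972) standard genetic distance, and the mean
between-population allele-sharing distance. Per unordered pair of
population pairs and each pairwise kind: the difference between the two
values. These contrasts are where the colonization-topology signal lives —
whether Strombolicchio is closer to Capri or to Palinuro is a *difference*
of pairwise statistics, and axis-aligned forest splits recover it far more
readily when it is an explicit feature. The ordering is fixed and
versioned; undefined entries are NaN and imputed with reference-table
column medians (logged).

**Scenario choice.** A linear discriminant analysis with (scenarios−1) axes
is fit on the reference-table statistics only (never on the observed
vector) and its axes are appended to the features (a `replace` mode exists
as a configuration switch). A classification forest (default 1,500 trees,
seeded) votes; the posterior probability of the winning scenario is a
regression forest trained on the out-of-bag correctness indicator of the
classifier, evaluated at the observed point and clipped to [0,1] — the
standard ABC-RF recipe. Votes always sum to the number of trees.

**Parameter estimation.** One quantile regression forest per parameter, fit
on the winning scenario's rows: leaf-weight posterior weights give the
weighted mean, median, 5%/95% quantiles (which are order-consistent by
construction) and variance. A constant parameter column returns a
degenerate summary, flagged. Posterior means necessarily lie inside the
prior range.

**Desk-scale defaults.** 500 simulations per scenario for the pipeline
default and 2,000 in the validation experiments, 120 loci, samples 10/8/7
— a deliberately scaled-down mirror of a production run (which would use
10⁵–10⁶ simulations); the statistical behaviour, not the precision, is
what the package validates at this scale.

**Identifiability.** The four scenarios are partially nested: scenario 3 is
scenario 1 with the Capri founding bottleneck removed, and a bottleneck of
N1b near 50 lasting only ~10 generations is nearly indistinguishable from
none, so the pairs (1,3) and (2,4) overlap across much of the prior.
Whenever t1 greatly exceeds 2N_Capri, lineage sorting completes long before
t1 and the bottleneck axis carries no signal at all; only the colonization
topology (Strombolicchio from Capri vs from Palinuro) remains identifiable
there. Nesting has the usual asymmetric consequence: data generated by the
submodel (ancestral split) are also plausible under the superset
(bottleneck) scenario and tend to be absorbed by it, whereas a strong
bottleneck signature cannot be imitated by the submodel. The validation
suite therefore demonstrates clean recovery of the bottleneck scenarios at
a well-separated parameter point (t1=500, t2=150, db=90, N1b=5, N2b=50,
island sizes at their upper bounds) plus interval-coverage calibration and
point-estimate recovery for t1; it does not claim 90%+ recovery of the
ancestral-split scenarios from 120 loci, which the absorption above
precludes at desk scale. Scenario choice on real-shaped data should be
read the way vote fractions around 50% deserve: a weight of evidence among
overlapping hypotheses, not a categorical verdict.

## Reproducibility and numerics

Every stochastic operation takes an explicit seed; reference-table rows
record per-row seeds derived from the master seed, so any row can be
replayed bit-identically. The pipeline derives all stage seeds from one
configured master seed and embeds them in its report. Known numerical
conventions: genotype codes validated on construction; Fst cells and other
undefined statistics are NaN (never silently 0) and imputed only where the
forests require complete vectors; Wk values are floored at 1e−12 before
logs; tie-breaks (equal-distance haplotype attachments, equal votes) are
deterministic and documented above.

## Problem sizes used by the validation suite

Coalescent calibration uses 2,000 genealogies (pairwise TMRCA) and 5,000
one-SNP loci (site-frequency spectrum). ABC validation uses 2,000
simulations per scenario, 120 loci, 10/8/7 samples, a 1,500-tree
classification forest, 20 pseudo-observed datasets for self-classification
and 50 held-out datasets for t1 interval coverage. The acceptance script
defaults to 500 simulations per scenario with the same 1,500-tree forest.
These sizes are the package's chosen desk-scale study conditions.
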