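# Methods

`coalabc` implements likelihood-free (ABC) inference on population histories
from multilocus genetic data. This note records the models, the numerical
choices, and the places where the design was genuinely open.

## Demographic model and coalescent simulation

A scenario is an ordered event list over a set of populations, read backward
in time (time 0 = most recent sampling, units = generations). Events are
population sampling (possibly serial), divergence (`merge`: the source
population's lineages move into the sink), admixture (`admix`: each lineage
of the admixed population moves to parent 1 with probability r, else parent
2, independently), and instantaneous size change (`varNe`). Within each
inter-event epoch the standard continuous-time coalescent runs per
population: with k lineages among C gene copies, pairs coalesce at rate
k(k−1)/(2C) per generation, with exponential waiting times. The
continuous-time approximation (rather than generation-by-generation
simulation) is accurate for the population sizes in all bundled designs and
is validated against a discrete Wright–Fisher simulation at small size and
against msprime on a two-population divergence model (KS tests in the
suite). Simultaneous events are applied in file order, which makes runs
deterministic.

Five inheritance categories set the effective number of transmitting copies
for a diploid size N and population female fraction f (default 0.5):
autosomal diploid 2N, autosomal haploid N, X-linked (1+f)N, Y-linked (1−f)N,
mitochondrial fN. The mitochondrial fN choice (maternal copies) is isolated
in `effective_copies` so it can be swapped for an N/2 convention if desired.
Sampled copies per individual: 2 (autosomal diploid), 1 (haploid,
mitochondrial), 2 per female + 1 per male (X), 1 per male (Y).

## Mutation models

**Microsatellites** follow a generalized stepwise model: mutations arrive as
a Poisson process at per-locus rate μ_loc along each branch; each mutation
changes the repeat count by ±k with k geometric on {1, 2, ...},
P(k) = (1−P)P^(k−1) (mean step 1/(1−P); the "mean parameter of the
geometric" is read as P itself, giving mean steps of 1.1–1.4 repeats for
P in [0.1, 0.3], in line with GSM practice). Alleles are confined to a
window of 40 contiguous repeat states centered on the ancestral allele
(nominally 50 repeats, so Genepop three-digit length codes stay in range);
steps that would leave the window are redrawn, which conditions the step
distribution on feasibility and avoids boundary pile-up (reflection would
pile density at the edges). An independent Poisson process of
single-nucleotide indels in the flanking region adds ±1 nucleotide to the
reported allele length (length = motif × repeats + offset), taking alleles
off the motif lattice as observed in real data.

Per-locus rates are drawn per simulated dataset from Gamma(mean = the
dataset-level mean drawn from its prior, shape = 2); this applies to μ_loc,
P_loc and the SNI rate (the SNI hierarchy mirrors the GSM one; its shape is
not pinned down elsewhere). A gamma draw can exceed 1 for P_loc (≈1% of
draws at mean 0.3); P_loc is truncated at 0.99 to stay a valid geometric
parameter.

**Sequences** evolve under JC, K2P, HKY or TN. The rate matrix is
normalized so that one unit of branch distance equals one expected
substitution per site at stationarity; branch distance = μ_loc × branch
length in generations. JC and K2P use their closed forms in
`substitution_probability` (JC: probability of a specific different base
= (1/4)(1 − e^(−4d/3))); HKY and TN use the matrix exponential. HKY/TN base
frequencies are parameters fixed from the observed data per locus (default
equal). A fixed fraction of invariant sites is chosen uniformly once per
locus; the remaining sites carry independent Gamma(shape, mean 1) relative
rates. Insertions/deletions in sequences are out of scope.

Simulation uses **uniformization**: candidate events arrive at rate
λ = max_i |Q_ii| and apply the jump kernel I + Q/λ (self-loops allowed).
This reproduces exp(Qd) exactly while touching only sites that receive
events, so a locus costs O(events), not O(sites × branches). The closed
form and the uniformized simulation are two independent routes, and the
suite checks them against each other (two-sequence divergence,
Chapman–Kolmogorov, stationarity).

For the bundled designs the K2P transition/transversion rate ratio is not
published; it is fixed at κ=10 for the mitochondrial locus and κ=4 for
nuclear sequences, typical animal values. Error rates of the mtDNA-only
experiments depend only weakly on κ because all statistics are
frequency/segregating-site based.

## Summary statistics

Statistics are computed per locus and combined within marker groups
(autosomal microsatellites `MIC`, nuclear sequences `NUC`, mitochondrial
`MT`): simple averages for everything except FST (combined as a ratio of
variance-component sums over loci, the standard multilocus estimator) and
LIK (summed over loci: a multilocus log-likelihood). Definitions worth
recording:

* HET/H2P: unbiased expected heterozygosity (n/(n−1))(1 − Σp²).
* MGW: allele count divided by the number of possible states in the
  observed allele-length span, (max−min)/motif + 1, per locus.
* Microsatellite FST: Weir–Cockerham variance components computed on gene
  copies (no within-individual component). Sequence FST: Hudson-style
  1 − π_within/π_between with π_within pooled over both samples, floored at
  0, and 0 by convention when between-sample diversity is 0.
* DAS: 1 − expected allele sharing of random cross-sample copy pairs
  (= 1 − Σ_a p_A(a) p_B(a) per locus), defined for haploid categories too.
* LIK_A_B: mean over individuals of A of −ln of their multilocus genotype
  likelihood under B's allele frequencies; alleles absent from B enter as
  one pseudo-copy, p = 1/(n_B+1). Diploid genotypes use p², 2p_a p_b.
* ADM: maximum-likelihood admixture proportion under a multinomial mixture
  r·p1 + (1−r)·p2 of the parent frequencies (haplotype frequencies for
  sequences), maximized on a 1001-point grid plus golden-section refinement
  to 1e-6; indistinguishable parents return 0.5 with a degeneracy flag.

The hot paths (all loci of a complete autosomal-microsatellite block, and
each sequence locus) are vectorized from shared count tables; the per-locus
reference implementations remain the public functions, and the suite checks
the two against a naive double-loop reimplementation to 1e-10.

## ABC

Rejection standardizes every statistic by its median absolute deviation
over the whole reference table (robust to the heavy tails of e.g. VAR;
swappable to SD), retains the closest `fraction` (default 1%) in Euclidean
distance with ties broken by row index, and excludes zero-spread statistics
with a warning.

**Scenario choice** fits a multinomial logistic regression of the scenario
indicator on the standardized statistic differences (statsmodels MNLogit,
intercept per non-reference scenario, reference = lowest id) and evaluates
it at the observed point; the 95% CI comes from the delta method through
the intercept covariance. When the retained scenarios are separable the
MLE diverges; the capped-iteration iterate still orders the probabilities
correctly (they saturate toward 0/1, as they should under separation), so
non-convergence is accepted, and only a singular/non-finite fit falls back
to the categorical proportions of the retained set, flagged as such.

**Parameter estimation** maps each parameter to an unbounded scale — logit
x ↦ ln((x−a)/(b−x)) over its prior bounds, log for unbounded (gamma)
priors — then fits a weighted local-linear regression of the transformed
parameters on the statistic differences with Epanechnikov weights
(bandwidth = largest retained distance), adjusts the retained draws to the
observed point via the residuals, clips to (a+ε, b−ε) with ε = 1e-9(b−a),
and back-transforms. A rank-deficient design falls back to ridge
(penalty 1e-8), flagged. Point estimate = weighted posterior median.

**Performance measures**: type I error of a scenario = fraction of its own
pseudo-observed datasets where it does not get the highest posterior
probability; type II = fraction of other scenarios' datasets where it does;
RMAE = median over test datasets of |estimate − truth|/truth, with the
prior-median baseline reported alongside.

Reference tables are reproducible: row i of scenario s uses a generator
seeded by (seed, s, i), so parallel builds give the same multiset of rows
and single-worker builds are byte-identical.

## Model checking

The prior-predictive check simulates up to 10,000 datasets from the prior
and ranks each observed statistic in the simulated distribution; the
posterior-predictive check resimulates with parameter sets resampled (with
replacement, weight-proportional) from the ABC posterior sample. The
cumulative probability q = Prob(t_sim < t_obs) uses the add-one/half-tie
estimator (k + ties/2 + 1)/(n + 2), so q never reaches 0 or 1 exactly
(at n = 10,000 the extremes print as 0.0001/0.9999); the two-sided tail
probability is p = min(q, 1−q). Benjamini–Hochberg step-up controls the
FDR across test quantities; reports annotate BH-significant entries with
*/**/*** at 0.05/0.01/0.001. The checking statistic selection is an
explicit argument, independent of the inference selection — checking with
statistics already used for fitting over-estimates the quality of fit, so
the bundled designs reserve VAR/LIK/H2P/DAS for checking and use
NAL/HET/MGW/FST for inference. PCA diagnostics are fitted on the prior
cloud only (centered, unit-scaled); the posterior cloud and observed point
are projected onto the same axes.

## Bundled study designs

`designs.invasion_config()`: source S plus invasive populations 1 and 2, 20
autosomal microsatellites, 30 diploids per sample. Introduction dates are
treated as known (first-observation dates): population 1 founded 5
generations ago, population 2 ten generations ago, and, in the
unsampled-population scenario, U founded 15 generations ago. Every
introduction is followed by a 5-generation bottleneck at size NFi; all
other sizes are NS. Priors NS ~ U[1000, 20000], NFi ~ logU[2, 100]. The
serial scenario introduces population 2 first (S→2 at 10) and population 1
from it (2→1 at 5), which is the only ordering consistent with the shared
founding dates.

`designs.marker_mix_config()`: four sampled populations (30 diploids each;
samples 3 and 4 collected 2 and 4 generations early), three competing
histories with two/one/zero admixture events, and a configurable marker
panel (10 GSM microsatellites, one mitochondrial K2P 1000-nt locus, five
nuclear K2P loci; 10% invariant sites, gamma shape 2). The published
description of this design fixes the population counts, which samples are
admixed, and all priors (N shared by all populations ~ U[10, 10000]; times
t1 ~ U[1,100] ... t5 ~ U[50000, 500000] with t4 > t3; rates
r1, r2 ~ U[0.1, 0.9]), but not the full event lists; the topologies here
are one concrete reconstruction satisfying every stated constraint
(scenario 1: populations 2 and 3 admixed at t1 and t2 with unsampled
parents merging at t3 and t4; scenario 2: population 2 admixed with one
unsampled parent diverging at t3a; root divergence at t5 in all three).
Quantities that depend on the exact topology — notably the scenario-choice
error rates — should be read with that caveat.

Sequence loci draw their per-locus mean rate directly from the configured
prior each dataset (mtDNA U[1e-8, 1e-7], nuclear U[1e-9, 1e-8]);
microsatellite loci share dataset-level mean μ and mean P with the
per-locus gamma hierarchy described above.

## Problem sizes in the validation runs

The validation script (`scripts/acceptance.py`) uses reference tables of
2×10⁴ rows per scenario and 200 pseudo-observed datasets per experiment
arm, and the test suite uses tables of 3–6×10³ rows with tens of test
datasets; both are deliberate reductions of the original Monte-Carlo
designs (10⁶-row tables, 500–1000 test sets), chosen so a full run
completes on a single CPU in minutes. Monte-Carlo tolerances in the tests
are computed as three binomial standard errors at the sizes actually used.

## What the synthetic data do and do not show

All experiments run on data generated by the package's own simulator, so
they validate the inferential machinery (rejection, regression, error
rates, checking) under the stated models — well-calibrated priors, free
recombination between loci, no recombination within sequences, no
migration after divergence, selective neutrality, and the exact mutation
models above. They cannot detect misspecification that real data would
bring (genotyping error, marker ascertainment, within-locus recombination,
gene flow), and a passing suite should be read accordingly.

## Known limitations

* No migration between coexisting populations; only stepwise size changes.
* Scenario-choice CIs are delta-method approximations and degrade under
  separation (the probabilities themselves remain usable).
* The marker-mix scenario topologies are a reconstruction (above); the
  invasion-design error rates are sensitive to how the bottlenecks overlap
  the shared introduction history.
* X-linked genotype files assume females are listed before males within
  each sample.
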