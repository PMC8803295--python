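# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `hybkit`, in the order the analyses usually run.

## Genotype data model

Diploid, codominant, multiallelic genotypes for n individuals × L loci.
Allele codes are opaque positive integers (fragment sizes); no binning is
performed — binning belongs upstream of this package. Missingness is per
individual × locus (both gene copies absent together; a half-missing
GenePop call is collapsed to fully missing). Every statistic downstream
uses complete cases per locus; no imputation is attempted anywhere.
GenePop 2- versus 3-digit coding is auto-detected per file and mixed
widths within a locus are rejected.

## Genotypic classes and ancestry profiles

A genotypic class is defined by an explicit cross pedigree whose founders
are tagged with parental pool A (savanna) or B (forest). With g(x) the
probability that a gamete from node x carries A ancestry —
g = 1 for A founders, 0 for B founders, and (g(p₁)+g(p₂))/2 for a child —
the focal individual's per-locus ancestry profile is

    φ₂ = g(p₁)·g(p₂),  φ₁ = g(p₁)(1−g(p₂)) + (1−g(p₁))g(p₂),
    φ₀ = (1−g(p₁))(1−g(p₂)),

computed in exact rational arithmetic (`fractions.Fraction`) and converted
to floating point only at the classifier boundary. The factorisation
requires the focal's two parental lineages to share no ancestors, which
the pedigree validator enforces; inbred or looped pedigrees are rejected
as unsupported. A Monte-Carlo gene-dropping routine provides an
independent check of the recursion and is used as its oracle in the test
suite.

The standard sets are six = {P1, P2, F1, F2, B1, B2}, twelve = six ∪
{B3…B8}, fourteen = twelve ∪ {F3, F4}, with B1 = F1×savanna,
B2 = F1×forest, B3 = F2×savanna, B4 = F2×forest, B5 = savanna×(F1×savanna),
B6 = forest×(F1×forest), B7 = savanna×(F2×savanna), B8 = forest×(F2×forest),
F3 = F2×F2, F4 = F3×F3. Under the per-locus-independent model several
classes carry *identical* profiles and are therefore unidentifiable from
unlinked markers:

    {B1, B3}, {B2, B4}, {B5, B7}, {B6, B8}, {F2, F3, F4}.

This is the mechanistic reason backcross resolution collapses when
fourteen simulated classes are scored against the twelve-class model. The
{B2, B4} pair is the mirror image of {B1, B3} and belongs in this list
even though it is easy to overlook.

## Bayesian class posterior

Latent structure per individual i: class z_i with mixing proportions π
(symmetric Dirichlet(½) prior); per-locus ancestry state
w_il ∈ {2, 1, 0 A-copies} with P(w | z) = φ_z; per-gene-copy pool-origin
indicators; and per-pool, per-locus allele frequencies θ_A,l, θ_B,l with
symmetric Dirichlet(½) priors over the alleles observed at the locus.
Genotype likelihood given w is Hardy–Weinberg within the contributing
pool(s); for w = 1 a heterozygote (a, b) has likelihood
θ_A(a)θ_B(b) + θ_A(b)θ_B(a) and a homozygote (a, a) has θ_A(a)θ_B(a).
Equal prior class probabilities are realised through the symmetric prior
on π. The "Jeffreys-like" reading of the ½ concentrations follows common
NewHybrids usage.

One Gibbs sweep updates z (with w summed out), π, w, the pool-origin
indicators and θ, in that order, iterating individuals-then-loci with a
single seeded generator, so runs are bit-reproducible per seed. Defaults
are 10⁶ iterations with 10⁵ burn-in; the scaled studies in this
repository use 5×10⁴ iterations, which on these problem sizes (≤ 140
individuals × 11 loci) mix well — the log-likelihood trace is stored
(thinned) so this can be checked. The reported posterior is the
post-burn-in average of the *conditional* class probabilities
(Rao-Blackwellised), which has strictly lower Monte-Carlo variance than
averaging sampled indicators.

**Label anchoring.** The two pool labels are exchangeable a priori. θ is
initialised from the most frequency-divergent sample partition — the
savanna/forest ecotype labels when present, otherwise the most
differentiated population pair — and a label-swap diagnostic (mean
posterior agreement of the anchored partition) is reported. Individuals
with known classes can be supplied as `reference_individuals`; their z
stays clamped, which is the recommended anchor and is what the
diagnostic-locus tests use. Individuals missing at every locus receive
the mixing-proportion posterior and are flagged.

Thresholded calls (`purity_call`) label an individual with the argmax
class when its posterior reaches the threshold, else "unassigned"; ties
break by class-set order (parentals first). Thresholds at or below 0.5
with more than two classes trigger a warning since uniqueness is no
longer guaranteed.

## Hybrid index and Q12

The hybrid index treats each of the individual's gene copies as an
independent draw from the mixture (1−h)·p_A + h·p_B over the parental
frequencies, h being the forest-pool proportion (orientation is a named
option). ℓ(h) is maximised on a 0.001 grid with bounded golden-section
refinement in the bracketing cell; the 95% CI is the profile-likelihood
set {h : ℓ(h) ≥ ℓ(ĥ) − 1.92} (χ²₁ 0.95 cutoff / 2) read off the grid. A
flat likelihood (p_A = p_B everywhere) returns ĥ = 0.5 with CI [0, 1] and
a flag rather than an arbitrary point. An allele unseen in both parental
pools receives the floor frequency 1/(2·G+1) in *both* pools, G being the
larger parental gene-copy count — finite likelihood, no directional bias.

Q12 is the average over usable loci of the posterior probability of the
one-copy-each ancestry state, under a uniform (⅓, ⅓, ⅓) prior over the
three states and the same per-state likelihoods as the classifier. The
uniform prior (rather than an h-dependent one) is a deliberate,
documented choice: it keeps Q12 a per-locus quantity independent of the
hybrid-index estimate; sensitivity to this choice is easy to probe by
recomputing with binomial(2, ĥ) weights. At fully diagnostic loci Q12 is
exactly 1 for F1s and 0 for pure parentals; at partially shared loci its
expectation for F1s is well below 1 (the triangle plot's apex is only
reached with diagnostic markers). Per-individual triangle excess
max(0, Q12 − (1 − |2ĥ − 1|)) flags points above the feasible region,
which with real microsatellites usually indicates allele homoplasy
between the pools.

## Diversity statistics

Per group: A (mean alleles/locus); allelic richness by hypergeometric
rarefaction to g gene copies, g defaulting to the smallest typed count
over the compared group × locus cells (FSTAT convention, recorded in the
output); H_O; unbiased H_E with the 2n/(2n−1) correction; and F_IS as the
Weir–Cockerham within-population f, multi-locus and multi-allele
ratio-of-sums. Monomorphic loci contribute H = 0 and drop out of F_IS;
an entirely monomorphic group reports F_IS = NA. "Overall" rows for
pooled groups are computed by pooling individuals and are labelled as
such (they absorb any Wahlund component).

The F_IS permutation null shuffles gene copies among individuals within
the group per locus — random union of gametes, allele counts preserved
exactly — giving a one-tailed p for heterozygote deficit, Holm-adjusted
across groups. The null-allele check is a deliberately simplified
Micro-Checker-style screen: n_sim Hardy–Weinberg datasets are simulated
from the observed frequencies at matched sample size and a group × locus
cell is flagged when its observed homozygote count exceeds the simulated
97.5th percentile. There is no size-stutter model and no Brookfield
frequency estimator; the check is a QC gate, not a correction — corrupted
loci stay in the data unless the user removes them.

## AMOVA and pairwise θ

The hierarchical AMOVA partitions one-hot allele-indicator variance over
gene copies within populations, populations within groups, and groups,
by unbalanced nested ANOVA method of moments: per locus, sums of squares
at the three levels, expected-mean-square coefficients from the group and
population gene-copy counts, components solved top-down, then combined
across loci with weights proportional to typed gene copies. Components
can legitimately be negative (they are *estimates*); F_CT, F_SC, F_ST are
formed from the combined components. This is the F_ST-like AMOVA on
allele identity, not an allele-size/R_ST analysis — microsatellite
stepwise-mutation distances are out of scope.

Permutation schemes: whole populations among groups for F_CT (population
sufficient statistics are invariant, so these permutations are cheap);
individuals among populations within groups for F_SC; individuals among
all populations for F_ST. With few populations the F_CT permutation space
is coarse — six populations in a 3+3 design admit only ten distinct
splits, so p ≥ ~0.1 regardless of effect size; this is a property of the
design, not the implementation.

Pairwise differentiation uses the Weir–Cockerham (1984) θ with the full
(a, b, c) decomposition including the observed-heterozygosity terms,
summed over alleles and loci before the ratio; p-values permute
individuals between the pair. Negative estimates are reported as computed
(a truncation toggle exists). Under the F-model (below) θ estimates the
divergence parameter F itself, which is what the calibration tests
verify.

## Distance trees

Nei's standard distance uses arithmetic means across loci of the gene
identities J_X, J_Y, J_XY, with the unbiased within-population identity
(2n·Σp² − 1)/(2n − 1) by default (a toggle recovers the plug-in version
for oracle checks). No shared alleles anywhere gives J_XY = 0 and an
infinite-distance flag; such taxa must be pruned before tree building.

Neighbor joining follows Saitou–Nei with two deterministic conventions:
Q-matrix ties resolve to the first minimal pair in current node order,
and a negative branch length is clamped to zero with the deficit moved to
its sister branch, preserving the pair's patristic distance. The final
three nodes are joined exactly (linear solve). Bootstrap resamples loci
with replacement, rebuilds the tree, and reports for each internal edge
the percentage of replicates containing the same leaf bipartition,
written as integer node labels in Newick.

## Landscape tests

Geographic distance is great-circle (haversine, radius 6371.0088 km) on
decimal-degree coordinates. Environmental distance is Mahalanobis with
the covariance across populations; constant variables are dropped with a
warning and a singular covariance falls back to the Moore–Penrose
pseudo-inverse with the rank logged. Correlated variable panels (e.g. 19
bioclim layers) can first be reduced by PCA on standardised variables,
retaining either a fixed count or the smallest number of components
reaching a variance fraction. Raster download and extraction are out of
scope; the environment table arrives pre-extracted.

The Mantel statistic is the Pearson correlation of off-diagonal upper
triangles; significance is one-tailed (upper) by jointly permuting rows
and columns of one matrix with the (n_greater+1)/(n_perm+1) estimator
(≥ 1/(n_perm+1) by construction), or exhaustively over all n!
relabellings for small n. The partial Mantel r is the first-order partial
correlation from the three pairwise r's; its null permutes the second
matrix while the first and the control stay fixed (r(d1, control) is
unaffected — the convention is documented because several exist). The
degenerate case d2 = control returns r = 0 (the algebraic limit);
|r(d1, control)| = 1 is an error. Genetic distance for these tests is
pairwise θ by default, with F_ST/(1−F_ST) linearisation available but off
by default.

## Synthetic data

Parental pools follow the F-model: per locus an ancestral frequency
vector from a flat Dirichlet over k alleles, then each pool independently
from Dirichlet(ancestral·(1−F)/F). Defaults — 11 loci, 8 alleles per
locus, F = 0.35, 100 individuals per class, 5 datasets — mirror the
two-ecotype study design the package targets: F = 0.35 sits in the
observed between-biome pairwise F_ST range (≈ 0.33–0.40), and 8 alleles
per locus gives per-population mean allele counts in the observed 4–10
band. Individuals are produced by Mendelian gene-dropping through the
class pedigree: founder copies are Hardy–Weinberg draws from their pool;
every transmission picks one of the parent's two copies uniformly,
independently per locus.

Corruption models: call-wise missingness at a fixed rate, and a
segregating null allele at frequency ν per gene copy — null homozygotes
become missing calls, null heterozygotes surface as visible-allele
homozygotes. This is the standard microsatellite artifact model; the
null-allele check above is calibrated against it in the tests.

What the generator does **not** emulate: linkage between loci, allele
homoplasy between pools (every allele is shared or not by frequency
alone), size-dependent mutation/stutter, spatial genetic structure within
populations, and inbreeding. Tests passing on these synthetics therefore
demonstrate correctness of the estimators under the stated model, not
robustness to those real-data features.

## Assignment evaluation

"Correct at threshold t" means the posterior probability of the *true*
class reaches t — not merely argmax (an argmax criterion is available
behind a flag). Correct/misassigned/unassigned sum to one per true class;
the parental average is the mean of the P1 and P2 proportions. The
three-arm design scores six-class data against the six-class model and
fourteen-class data against both the six- and twelve-class models, at
thresholds 0.5/0.75/0.85/0.9, aggregated over replicate datasets both as
unweighted means and pooled (identical at equal class sizes; both are
reported since the convention matters at unequal sizes).
Equivalence-aware scoring merges the confounded groups listed above
before scoring and can only raise correct proportions.

A practical caveat: with F-model pools at F = 0.35 and 11 loci, the
correct-rate separation between F2 and the first-generation backcrosses
at high thresholds is small, so in cohorts of tens of individuals the
F2-versus-backcross ordering sits at counting-noise resolution. The test
suite compares the sampler against an ideal observer given the true pool
frequencies: the two agree for the well-identified classes (P1, P2, F1),
while unsupervised backcross posteriors fall below the oracle at small
sample sizes because backcross alleles blur into the nearer estimated
pool. Larger cohorts (the 100-per-class design) and more diagnostic
panels restore the clean ordering.

## Problem sizes used in the repository

The test suite and `scripts/acceptance.py` run everything at desk scale,
chosen as the smallest sizes at which each statistical claim is testable:
10⁶ gene-dropping replicates for the profile oracle; 50,000 MCMC
iterations for classifier checks; 10 individuals per class × 2 datasets
for the three-arm study; 500 simulated individuals for hybrid-index
recovery; 100 replicates for θ calibration; 500 replicates × 199
permutations for the F_CT type-I calibration; 200 replicates for the
IBE/IBD discrimination design. Production analyses should use the
defaults (10⁶ iterations, 10⁴ permutations, ≥ 1000 bootstrap replicates).

## Known limitations

* Unlinked-locus assumption throughout; no linkage-disequilibrium tests.
* The class posterior and Q12 share the two-pool ancestry model; both are
  blind to more than two source pools.
* No null-allele or genotyping-error terms inside the likelihoods; QC is
  a separate screen.
* NewHybrids-family classes are unidentifiable within the confounded
  groups; the twelve-class analysis can only allocate mass within each
  group, never resolve it.
* F_CT permutation resolution is limited by the number of populations.
* No R_ST/stepwise statistics, no clustering (STRUCTURE/DAPC-style), no
  migration-rate estimation, no dbRDA/sPCA — these remain with the
  established external tools.
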