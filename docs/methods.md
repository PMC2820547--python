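# Methods

`clonescan` asks one question of a multilocus haploid sample: do these
strains recombine, or are they clones?  It implements the classical
desk-scale toolkit for that question — site statistics, distance-based
split networks, three complementary recombination tests, intragenic
screens, Hudson's FST, genealogical-concordance species recognition, and an
incremental procedure for locating the boundary of a recombining
population — together with a coalescent simulator that produces datasets
of known truth at the scale of a small fungal multilocus study (a few
dozen strains, three loci of 355–509 nt).

## Data model and conventions

A locus is an aligned matrix of haploid DNA rows over `{A,C,G,T,-,N}`;
`-` and `N` are both *missing* for every site and distance computation
("gaps treated as missing characters").  IUPAC ambiguity codes other than
N are coerced to N with a warning.  Allele identity, used by clone
correction and the index of association, is deliberately stricter: two
locus sequences are the same allele only if their literal uppercased
strings match, so a `-` vs `N` mismatch separates alleles.  The strict
rule can only *under*-collapse, which is the conservative direction for
clone correction.

External coordinates (partition maps, Rm intervals) are 1-based inclusive;
all internal indexing is 0-based half-open.  Taxon matching is exact and
case-sensitive.  Every permutation p-value uses the add-one estimator
`(1 + b) / (1 + m)` and records its seed and replicate count, so any
stochastic result is reproducible from the report alone.

## Site classification

Per column, among non-missing residues: *constant* means at most one
distinct state; *parsimony-informative* means at least two states each
carried by at least two strains; *singleton* is variable but not
informative; a column with no residue is *all-missing*.  Counts are
invariant under row and column permutation, and classification commutes
with concatenation.

## Distances

The Kimura three-substitution-type distance separates transitions
(A↔G, C↔T; proportion P) from the two transversion classes (A↔T/C↔G: Q;
A↔C/G↔T: R) among the jointly observed sites of each pair:

    d = −¼ [ ln(1−2P−2Q) + ln(1−2P−2R) + ln(1−2Q−2R) ].

Pairwise deletion (not complete deletion) keeps every pair's comparable
sites maximal.  When a log argument is non-positive the pair is saturated;
the default is a hard error, and `cap=True` substitutes a finite ceiling
(d_max = 10) with a warning because network construction needs finite
inputs.  When Q = R = 0 the formula collapses to −½·ln(1−2P), which the
tests assert against the closed form.  A plain p-distance (proportion or
count) backs the FST and bootstrap machinery.

## Split decomposition

A bipartition A|B of the strains is a *d-split* when its isolation index

    α(A|B) = ½ · min_{a,a'∈A; b,b'∈B} [ max{ d(a,b)+d(a',b'),
             d(a,b')+d(a',b), d(a,a')+d(b,b') } − d(a,a') − d(b,b') ]

is positive (repeats allowed; ties in the max need no breaking).  The
system of all d-splits is built by incremental taxon insertion — extend
every retained split by the new taxon on either side, add the new trivial
split, recompute α, discard non-positives — which is order-independent for
d-splits; a tolerance of 1e−10 suppresses floating-point ghosts.  On an
additive metric the result is exactly the generating tree (weights equal
branch lengths, fit 100%); the *fit percentage* is the share of the
pairwise-distance sum reproduced by the split metric.  The *networked*
flag is true when two positive-weight splits are incompatible (all four
side intersections non-empty): conflicting phylogenetic signal that no
single tree can carry, the signature recombination leaves in distances.
Drawing the splits graph is out of scope; systems are exported as
SplitsTree-compatible NEXUS.

Split decomposition is known to lose resolution as samples grow: with ~25
strains only strongly supported splits survive the min over all quadruples,
so thoroughly shuffled data can yield a *sparse but compatible* system
(low fit, networked = false).  This is a property of the method, not of
the implementation; the simulator's study-scale preset therefore models
recombination as free re-assortment among loci (see below), the regime in
which the network signature is expressed at this sample size.

## Recombination tests

**PHI (pairwise homoplasy index).**  The refined incompatibility of two
site columns is `E − V + C` of their partition intersection graph (V =
observed states of both columns, E = distinct joint states, C = connected
components) — the number of independent cycles, zero exactly when the pair
fits one tree.  Φw is the mean refined incompatibility over pairs of
parsimony-informative sites at most w = 100 alignment positions apart (the
reference implementation's window convention; no window is prescribed by the
statistic itself).  Under clonality, incompatibility (which then only repeat
mutation can cause) is position-independent, so the null permutes the
assignment of informative columns to positions; the one-sided p counts
permutations with Φw* ≤ Φw_obs.  On single-tree infinite-sites data the
statistic is identically zero and p = 1 with no Monte-Carlo noise.  An
optional analytic p-value (normal approximation treating window pairs as a
simple random sample of all informative pairs, ignoring shared-site
dependence) is reported alongside when requested; the permutation p is the
default and the one used everywhere else.

**IA (index of association).**  Alleles are distinct locus haplotypes.
With d the number of loci at which two strains differ, IA = V_O/V_E − 1,
where V_O is the variance of d over all strain pairs and V_E the sum over
loci of the variance of the per-locus mismatch indicator (population
variances).  Panmixia gives 0; complete linkage of two-allele loci gives
1.  The null shuffles alleles among strains independently within each
locus (artificial recombination, sampling without replacement); p counts
permutations with IA* ≥ IA_obs.  Clone correction first is the default,
matching standard practice.  Note the direction: *clonal* data give an
inflated IA and a small p; a clonal sample escapes significance only when
clone correction leaves too few haplotypes for power — the typical fate
of a genuinely clonal taxon in a small panel.

**PHT / ILD (partition homogeneity).**  The statistic is the sum over loci
of maximum-parsimony tree lengths (variable columns only; constant columns
add no length).  Replicates re-partition the pooled variable columns into
pseudo-loci of the original sizes without replacement.  Recombination
makes real loci internally congruent but mutually conflicting, so the
observed sum is unusually *short*: p counts replicates with Σ* ≤ Σ_obs.
An exhaustive mode enumerates every re-partition when feasible (the
4-taxon two-locus toy has C(6,3) = 20, two of which — the two pure
assignments — tie the observed sum, hence p = 0.1 exactly); Monte-Carlo
mode uses the add-one estimator.  Replicates default to 1000; a flag raises
them to the traditional 10,000.

**Parsimony engine.**  Fitch small-parsimony counts on an arbitrary
rooting, with a missing residue treated as the universal state set.  Exact
MP length enumerates all (2n−5)!! unrooted topologies and refuses beyond
9 taxa; the heuristic takes random-addition starting trees (10 by default)
improved by steepest-descent NNI sweeps (best improving interchange per
sweep, ties broken first-found in a seeded shuffle) to a local optimum.
NNI with random addition is adequate at desk scale (≤ 40 strains); it is
an upper bound by construction, agrees with the exact search on the test
suite's random instances up to 7 taxa, and the acceptance script reports
its measured agreement rate (residual misses on saturated random data sit
at the percent level).

**Tajima's D** uses the standard a₁…e₂ coefficients with S the count of
segregating sites (a site with more than two states still counts once) and
π the mean pairwise difference count under pairwise deletion; S = 0 yields
an explicit "undefined" flag rather than a number.  **Rm** applies the
Hudson–Kaplan interval reduction: among biallelic sites (multistate sites
skipped with a warning), every pair showing all four gametes delimits an
open interval that must contain a crossover; Rm is the maximum number of
pairwise-disjoint such intervals (greedy by right endpoint).

**Hudson FST** is 1 − Hw/Hb with Hw the unweighted mean of the two
within-group mean pairwise difference counts and Hb the between-group
mean; a group below two strains contributes no within term (with a
warning) and Hb = 0 is an error.  Negative estimates are reported, not
truncated.  The all-pairs convenience scans every pair of geographic
groups in the metadata.

## Gene trees, GCPSR, and the boundary procedure

Gene trees come from an in-package neighbor-joining implementation
(validated against scikit-bio's on additive metrics) with two guards:
negative branch lengths are clamped to zero with a warning, and
zero-length internal edges are collapsed into polytomies.  The collapse
matters: NJ resolves ties among identical sequences arbitrarily but
deterministically, and without the collapse every bootstrap replicate
reproduces the same arbitrary clade, fabricating 100% support for
structure that is not in the data.  Bootstrap supports are the fraction of
column-resampled NJ replicates containing each internal bipartition.

GCPSR recognises a bipartition as an evolutionary lineage when it is
supported at ≥ τ (default 0.95, the conventional significance threshold
for Bayesian posterior probabilities; bootstrap proportions stand in for
them here) in
at least two gene trees and no gene tree holds an incompatible bipartition
at ≥ τ — "contradicted" reuses τ, since the recognition rule names no
separate threshold.  The *species partition* is the finest partition in which every
recognised split is a union of blocks, i.e. strains belong to the same
species unless some recognised split separates them.  This is the
orientation-free reading of "maximal recognised clades": recognised splits
from unrooted gene trees do not single out one side as "the clade", and
any rooting convention (midpoint, size, outgroup-free) was found to merge
or fragment valid species in edge cases, while the split-intersection
partition is well defined because recognised splits are mutually
compatible by construction.  With no recognised split the sample is one
species.

The boundary-expansion procedure requires a seed set that itself shows no
recombination signal (PHI p > α, else an error; a helper searches random
subsamples for one, mirroring the usual first step of locating a
non-recombining subsample).  Candidate groups are then added cumulatively
— whole groups by default, single strains optionally — ordered by
increasing mean K3ST distance to the seed ("gradually added", nearest
relatives outward, reproducibly), with PHI re-run after each addition; the
group whose inclusion first drives p < α is classified as recombining with
the seed, and the full trajectory is returned.  One behaviour discovered
during validation and worth stating: adding *any* strains, even a clonal
outgroup, enlarges the set of parsimony-informative sites (minor alleles
gain second carriers), which can unmask genuine recombination *within* a
seed drawn from a panmictic clade.  The stays-quiet property of a clonal
outgroup therefore holds when the seed is effectively clonal, and that is
how the tests exercise it.

## The synthetic-data generator

Time is in coalescent units; θ is the per-locus population mutation
parameter (default 15 per locus, which at three loci of 509/377/355 nt
puts variable-site counts on the order of a typical three-locus panel's
~140 variable sites in 1241 nt).
Genealogies are Kingman coalescent trees; mutations arrive as a Poisson
process of rate θ/2 per unit of total branch length, hit uniform sites,
and change state under Jukes–Cantor (an infinite-sites flag forbids
repeat hits).  Intralocus recombination is modelled by segment-independent
genealogies at uniform breakpoints — not an SMC, but sufficient to create
the compatibility structure the tests detect.

Three dataset builders carry known truth objects (per-segment genealogies,
species labels, clonality flags, all child seeds derived from one master
seed):

* **clonal** — one genealogy shared by every locus (complete linkage);
* **recombining** — an independent genealogy per locus plus optional
  within-locus breakpoints;
* **two-species preset** — 25 recombining + 6 clonal + 2 minor-clade
  strains, a realistic sympatric sample structure.  Species subtrees are joined at a
  stated gap above the deeper subtree root (2.0 between the main clades,
  1.0 for the minor clade) — no shared ancestral polymorphism, a
  deliberate simplification that guarantees per-locus species monophyly.
  The clonal clade's within-species branch lengths are scaled by 0.05: an
  agamospecies sampled as a recent clonal expansion, matching an agamospecies in
  which many strains share identical three-locus haplotypes (exactly the
  situation clone correction exists for).  Its mating types are all
  MAT1-1 except one MAT1-2 strain, echoing the skew reported for the
  clonal taxon; the recombining clade draws mating types and geographic
  labels at random (panmixia, so FST between regions is ~0).  The preset
  models the recombining clade's shuffling as free re-assortment among
  loci with no intralocus breakpoints: at n = 25 this is the regime where
  split decomposition still expresses the network signature (see above),
  while the PHI power analyses use the recombining builder with 4
  segments per locus.

What the generator does *not* emulate: selection, migration structure,
indels, rate heterogeneity among sites, shared ancestral polymorphism,
and intermediate (partial) rates of recombination.  Passing tests
demonstrate correct behaviour under these idealised regimes, not
performance on borderline real data.

## Pipeline

`run_full_analysis` composes the stages — per-locus and concatenated site
statistics, GCPSR (optionally defining the clades), per-clade clone
correction, PHI, IA, PHT, split decomposition with the networked flag, an
FST scan over geographic groups, and an optional boundary expansion — into
one JSON report.  Stages are isolated: a precondition failure (say, FST
without metadata) is recorded under `errors` and never perturbs another
stage.  Per-stage seeds are derived from the master seed by hashing the
stage name, so adding or removing a stage does not shift its siblings'
randomness, and the report is regenerable byte-identically.  P-values are
reported raw, with no multiple-testing correction, matching the source
analysis.  The `clonescan` CLI is a thin wrapper over these functions;
the pipeline's configuration is taken as command-line flags and small
per-purpose files (strain lists, clade tables) rather than a monolithic
config file.

## Problem sizes and numerical choices

Defaults that matter: PHI window 100 nt, 1000 permutations; IA 1000
permutations with clone correction; PHT 1000 replicates, parsimony exact
to 7 taxa and 4-start NNI beyond; bootstrap 500 replicates (validation
studies in the test suite use 200–500 permutations and 200 bootstrap
replicates; statistical conclusions are unchanged at these sizes).  The
acceptance script simulates 100 datasets per error-rate estimate, 60
random metrics/alignments for the exact-recovery checks, and 30
end-to-end study-scale runs.  Saturation capping, the 1e−10 split-weight
tolerance, the NJ zero-edge collapse, and the add-one p-value convention
are the load-bearing numerical choices; degenerate inputs (no variable
sites, monomorphic loci, single-strain groups, S = 0) produce explicit
errors or flags rather than silent numbers.

## Known limitations

The heuristic parsimony search is NNI-only and approximate above the
exact-search range; PHT significance therefore inherits search noise on
large strain sets.  The analytic PHI p ignores pair dependence.  Split
decomposition's conservatism at n ≳ 25 means "networked = false" is weak
evidence against recombination in large samples (the tests' power
analyses quantify this only for the simulated regimes).  GCPSR with three
loci can, rarely, recognise a chance concordant cherry inside a
recombining clade and oversplit; the end-to-end recovery rate in the
acceptance suite quantifies the combined frequency of all such failure
modes.  Bootstrap proportions are not posterior probabilities, though
both are used at the same 0.95 threshold.
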