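# Methods

This note documents the models implemented in `delimix`, the defaults
they run with, and the choices made where the design was genuinely open.

## Coalescent simulator (`delimix.sim`)

Genealogies are drawn from the structured coalescent in continuous time.
The demographic model is a rooted tree of K demes with split times in
generations, per-deme effective sizes N (diploid individuals), and a
backwards-in-time migration rate matrix (per lineage per generation).
Within a deme each lineage pair coalesces at rate `1 / (2 Ne_locus)` with

    Ne_locus = N * multiplier * ploidy

so a biparental diploid locus drifts like 2N gene copies and a maternal
haploid locus with the default multiplier 0.25 like N/4 — the classic
mtDNA scaling from uniparental haploid inheritance.  On this scale a
single deme gives E[TMRCA] = 4·Ne_locus·(1 − 1/n) and a nucleotide
diversity of θ = 4·Ne_locus·μ per site, both verified by Monte-Carlo
tests.  Sex-biased dispersal is a per-locus scaling: maternal loci see
migration rates multiplied by (1 − sex_bias), biparental loci the full
rate.  `sex_bias = 1` therefore reproduces the female-philopatry
discordance — mitochondrial structure with nuclear panmixia — with no
explicit two-sex model; that minimal mechanism is all the downstream
statistics can detect.  Waiting times are exponential (no per-generation
loop); at each split time the child demes' lineages merge into the
parent.  A configuration in which lineages can never meet (isolated demes
with an effectively infinite root time) is detected by a `time_cap`
guard, 1e8 generations by default, and reported as an error naming the
situation rather than looping forever.

Mutations follow Jukes–Cantor over a finite number of sites: branch
counts are Poisson(μ · length · branch length), each hit rewrites a
uniform site with a uniform different base.  JC is deliberately the
simplest model with a closed-form distance; the pipeline's inference side
only needs *testable structure*, not a realistic substitution process.
Recombination within loci, selection, and explicit geography are out of
scope.  One global seed spawns named per-locus substreams (CRC32 of the
locus name), so adding a locus never perturbs the others.

Default study designs (`recovery_config`, `discordance_config`,
`hierarchical_config`) use demes of N = 200 (150 for the hierarchical
design), one maternal locus of 800 bp at μ = 1e-5 and four biparental
loci of 600 bp at μ = 3e-6, and 10 individuals per locality (6 for the
hierarchical design).  These rates put ~16 fixed differences on a deep
mtDNA split with low within-deme diversity, and give each nuclear locus a
handful of shared haplotypes per deme — enough allele-frequency signal
for clustering without every copy being a private haplotype (which would
carry no frequency information at all).  No field estimates of mouse
lemur effective sizes or divergence times exist to calibrate against;
these values are illustrative study conditions, not parameter estimates.

## Summary statistics (`delimix.popgen`)

Variable sites count columns with ≥ 2 distinct non-missing bases; gaps
and N are missing everywhere (excluded pairwise for distances, never a
fifth allele).  Haplotype collapse partitions gene copies by exact
sequence identity and is lossless by construction.

The recombination lower bound Rm is Hudson–Kaplan's: all site pairs
exhibiting four gametes (biallelic sites only; more than two alleles at a
site skips it) define open intervals, and Rm is the size of a maximal
disjoint subset, found by the earliest-right-endpoint greedy sweep and
cross-checked against exhaustive search in the tests.

Fu & Li's F* uses the corrected variance coefficients in common use with
folded singletons (minor-allele count 1 — the no-outgroup convention).
Significance comes from a simulated null rather than interpolated tables:
neutral Kingman genealogies at the observed n with exactly S mutations
dropped proportionally to branch length, two-sided band at the 2.5/97.5
percentiles (10,000 draws by default; bands are cached per (n, S)).
Conditioning on S makes the test exact regardless of θ, and calibration
(type-I error within [3%, 7%] at nominal 5% over 500 replicates) is
itself a test.

## Tree collections (`delimix.genetrees`)

Downstream statistics consume only a weighted collection of rooted trees;
where the collection comes from is orthogonal.  The built-in source is a
site-resampled bootstrap over neighbor joining on Jukes–Cantor distances
(pairwise-deletion of missing data; saturation p ≥ 0.75 is an error
naming the pair).  Externally produced newick posterior samples import
interchangeably.  Full Bayesian tree MCMC is intentionally not
implemented.

NJ is the canonical Q-criterion algorithm with two reproducibility rules:
ties in Q break toward the lowest row-major index, and negative branch
lengths are clamped to zero with the deficit shifted to the sibling
branch.  Correctness is cross-checked against an exhaustive nonnegative
least-squares topology search on random additive matrices.  Rooting is by
outgroup when outgroup tips are given (falling back to midpoint, flagged,
when the outgroup is not separable); otherwise midpoint.  A bootstrap
resample with no variable sites yields star-like trees and flags the
collection instead of failing.

Monophyly support for a group is the weighted fraction of trees in which
its copies form a clade.  The majority-rule consensus retains rooted
clades with weighted frequency > 0.5, annotated with their frequencies;
no greedy completion of compatible minority clades is performed, so
consensus trees are generally multifurcating (which the sorting index
supports natively).

## Genealogical sorting index (`delimix.gsi`)

For a group of k tips on a rooted tree, let U be every internal node on a
path from a group tip to the group's MRCA (inclusive).  The sorting score
is gs = (k − 1) / Σ_{u∈U} (deg(u) − 2), where degrees count an implicit
ancestral edge at the root (root degree = children + 1).  With that
convention gs = 1 exactly for clades and only for clades — each foreign
subtree hanging off the uniting paths adds at least one unit to the
denominator — and the maximal-dispersion denominator is T − 1 for T tips
regardless of multifurcation.  The index rescales between the extremes:

    gsi = (gs − gs_min) / (1 − gs_min),   gs_min = (k − 1)/(T − 1).

The implementation is one O(nodes) postorder pass per evaluation and is
verified against a brute-force path-walking oracle over every rooted
topology with up to 6 tips (and samples at 7–8) for all groups of size
2–4.

Significance: group labels are permuted across tips (sizes preserved) and
the statistic recomputed; p = (b + 1)/(m + 1).  Because the index takes
few distinct values on small trees, ties between observed and permuted
values are broken uniformly at random (a shared jitter rank), making the
p-value exactly uniform on its grid under the null rather than
conservative — the property the calibration test checks.  For a tree
collection the ensemble gsi_T is the weighted mean of per-tree values,
and each permutation replicate applies *one* label permutation to every
tree: the trees are dependent samples of one history, and permuting
independently per tree would overstate significance.  The multilocus
ensemble treats the per-locus consensus trees as an equal-weight
collection over the shared individual namespace (diploid allele copies
inherit their individual's label; a locus missing an individual
contributes its available copies).

## Admixture model (`delimix.admixture`)

Sequence loci enter as one multi-allelic marker each: distinct haplotypes
map to stable integer alleles; missing copies are −9 and excluded from
every update.  The sampler is the standard admixture-model Gibbs scheme —
allele-copy origins z | (Q, P); cluster frequencies P | z by
Dirichlet-conjugate counts (under the correlated-frequencies F-model the
prior is Dirichlet(p_A (1 − F_k)/F_k), with ancestral frequencies p_A and
per-cluster drift F_k updated by random-walk Metropolis, F_k prior
uniform(0,1)); memberships Q | z as Dirichlet(α + counts); a single α
shared across clusters by random-walk Metropolis **on the log scale**
(uniform(0, 10) prior, Jacobian-corrected) — cleanly separated data favor
α ≈ 0.05, which a linear walk reaches too slowly at desk-scale chain
lengths.  Default schedule: 200 burn-in + 400 retained sweeps (the
pipeline uses 150 + 250), several replicate chains with seeds = base +
replicate index.  These lengths are the package's desk-scale defaults and
are fully configurable.

ln Pr(X|K) is estimated as mean − var/2 of the retained log-likelihood
trace (sample variance); the posterior probability of K under a uniform
prior is a max-stabilized softmax of those estimates; Evanno's
ΔK(K) = mean_r |L_r(K+1) − 2L_r(K) + L_r(K−1)| / sd_r(L(K)) flags the top
level of hierarchical structure.  The pipeline's working K is the
posterior-probability argmax, and the reported Q is the highest-ln Pr
replicate at that K: averaging replicates smears memberships whenever K
exceeds the true cluster number, because column matching is ill-defined
for near-empty clusters.  Label switching across replicates is repaired
by greedy maximum-correlation column matching (checked against exhaustive
assignment in the tests).  Membership post-processing zeroes coefficients
below 0.05 and renormalizes each row; a row entirely below the floor is
left unchanged with a warning.

## Rule engine (`delimix.delimit`)

Thresholds (all configurable): characteristic_min = 0.9,
foreign_max = 0.05, monophyly_min = 0.5.  The monophyly threshold is set
at 0.5 because the evidence tables this engine reproduces treat clade
support of 0.77 as qualifying; 0.95 would contradict them.

A lineage is diagnosed iff:

* **(a)** mtDNA monophyly probability ≥ monophyly_min, or the lineage
  carries the `composite-mtDNA-clades` flag (it is a union of separately
  monophyletic clades);
* **(b)** a characteristic cluster set exists: clusters added in
  decreasing membership order until the combined coefficient reaches
  characteristic_min, at most four (the smallest such union — maximizing
  membership outright would always take four);
* **(c)** every other lineage with a disjoint locality set has ≤
  foreign_max average membership in each characteristic cluster.
  Aggregate rows (strict supersets of another row's localities) are
  excluded as foreign evidence: they re-describe individuals already
  represented, with diluted profiles.  One exception, *absorption*: a
  foreign lineage wholly assigned to the characteristic set (≥
  characteristic_min) is excused when the focal lineage has significant
  ensemble gsi_T, the foreign one does not, and at least one third
  lineage is cleanly excluded from the set (so the cluster separates
  something).  This is what lets a genealogically supported lineage
  subsume an over-split mtDNA lineage with an identical nuclear profile,
  and withholds diagnosis from the over-split one.
* The explicit `geographic-override` flag waives (a) and (c): it encodes
  a judgment from information outside the genetic table (geographically
  separated lineages sharing clusters through historical gene flow) and
  is never inferred from the data.

After per-row verdicts, any diagnosed row whose locality set strictly
contains another diagnosed row's locality set is demoted
(`superseded-by-finer-partition`): it is an aggregate of finer diagnosed
lineages, not a lineage of its own.  Rows without nuclear data get
`insufficient-data`.  Every verdict carries a full rule trace.

Diagnosis is monotone (raising foreign_max never removes a lineage;
raising characteristic_min never adds one) and invariant to row order and
cluster relabeling.

## Pipeline and candidate lineages (`delimix.pipeline`)

Hypothesized lineages are read off the mtDNA consensus tree: every clade
whose tip set is exactly the union of some sampling localities proposes
that locality set, plus every single locality.  The end-to-end run wires
stats → bootstrap trees and consensus (mtDNA regions concatenated
first) → K sweep with replicates → postprocessed memberships → multilocus
gsi per candidate → rule engine, and, on simulated data, scores the
diagnosed locality sets against the true deme partition (precision /
recall; a true positive is an exact match of one deme's individual set).
Desk-scale problem sizes used by the test suite: 2–4 demes, 6–10
individuals per locality, 25–60 bootstrap trees, K swept 1–6 with 3
replicates, 120–300 permutations; a full 4-deme replicate runs in ~20 s
and the statistical acceptance checks use 10 seeded replicates each.

## What the simulations do and do not show

The generator produces clean island/split histories with JC mutation,
free recombination between loci and none within, equal sampling per
locality, and no missing data, genotyping error, allele dropout, or
selection.  Passing the recovery and discordance tests therefore shows
the *inferential machinery* is sound — it does not certify performance on
real data with unbalanced sampling, marker ascertainment, or violations
of the island-split model.  The bundled mouse-lemur evidence table
provides the complementary check on a real published evidence
configuration, at the level of the rule engine rather than the raw data.
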