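# Methods

This note documents the models, estimators and numerical conventions
implemented in `hexapop`, the design choices made where several readings
were defensible, and what the synthetic-data tests do and do not show about
real data.

## Allele scoring from ranked peaks

Fragment sizes are converted to integer repeat units by anchoring at the
marker's minimum fragment size over *all* peaks of the dataset:
`allele = round((size − min_size)/motif_length)`. The anchor is offset-free —
every downstream statistic (Bruvo, Goldstein, frequencies) depends only on
repeat-count *differences* — so the unknowable true repeat number of the
shortest allele is irrelevant. Using the pre-filter minimum also makes
filtering monotone: raising a marker's rank threshold can only remove
alleles from a phenotype, never shift them. Sizes more than 0.35 repeat
units off the integer grid are rounded with a logged warning, as are
distinct sizes that collapse into one bin; electrophoretic size drift makes
both situations routine.

A *ranking combination* maps each nuclear marker to a rank threshold in
[7, 10]; peaks at or above their marker's threshold are scored. Cells with
more than 6 surviving alleles (impossible in a hexaploid) are capped by
keeping the 6 highest-ranked peaks, ties broken toward larger fragments —
longer fragments are less likely to be stutter, which sits one repeat
*below* a true allele. Candidate combinations come in three modes: the four
uniform levels; a per-marker sweep around a base level (4 + 3·n_markers
candidates after deduplication, the default); or an explicit list.

Combinations are scored on a clone/ramet validation panel: exact clone
recovery first (every ramet of a clone in one inferred group with no
foreign member — deliberately stricter than co-membership), then the mean
bootstrap support of the smallest clades containing each clone's ramets;
ties go to the most inclusive (lowest) thresholds. A caveat found during
validation: under the Bruvo metric an admitted stutter allele moves a
pairwise distance by only ~0.05 per affected locus, so overly *inclusive*
thresholds are nearly harmless, whereas overly *stringent* thresholds drop
genuine low-rank peaks differently in different ramets and split clones.
Threshold choice matters, but the dangerous direction is stringency; the
test suite exercises exactly that contrast.

## Bruvo distance

Allele kernel `1 − 2^(−|Δ repeats|)` (stepwise-mutation geometry). For
equal-size phenotypes the genotype distance is the minimum over allele
bijections of the mean kernel value, solved as a linear assignment problem.
For unequal apparent ploidy the smaller set is padded with virtual alleles
under two models and the final value is the mean of both:

* *genome addition* — virtual alleles are copies of the smaller set's own
  alleles. Because each virtual copy is chosen freely, this reduces to an
  assignment with wildcard columns whose cost to each large allele is its
  nearest small allele.
* *genome loss* — virtual alleles are copies of the larger set's alleles;
  each unmatched large allele can pair with its own copy at zero cost, so
  this is the rectangular assignment of the smaller set into the larger.

Both reductions are verified exhaustively against brute-force enumeration
of all fills and bijections for every phenotype pair with ≤ 4 alleles.
Multilocus distance is the mean over loci non-missing in both samples;
pairs with no shared scored locus either raise or (in scoring contexts,
where stringent thresholds can empty a profile) receive the maximal
distance 1. Phenotype-pair distances are memoized and per-locus distance
matrices cached, so a locus bootstrap only averages precomputed matrices.

## Trees and clones

Neighbour joining follows the Saitou–Nei Q-criterion with deterministic
tie-breaking (first minimal (i, j) pair in the current agglomeration order)
and clamps negative branch lengths to zero, transferring the deficit to the
sister edge so the joined pair's path length is preserved. Supports come
from a locus (column) bootstrap — the resampling unit for multilocus
distance trees — and are mapped onto the full-data tree as the percentage
of replicates containing each bipartition; a majority-rule consensus writer
is provided for parity but the mapped-support tree is the primary output,
being deterministic in topology. Clone groups are the single-linkage
connected components at Bruvo distance ≤ 0.2; single linkage is what the
threshold semantics of "mismatch ≤ t means same clone" implies, and it
makes the partition invariant to sample order. PCoA is classical Torgerson
scaling; explained proportions are taken over positive eigenvalues only,
since negative eigenvalues of non-Euclidean genetic distances carry no
variance interpretation.

## Diversity and differentiation

Dosage being unobservable, allele frequencies are estimated under an
equal-dosage assumption: each individual contributes uniformly over its
observed alleles, and the population frequency is the mean over non-missing
individuals. This is the natural maximum-ignorance estimator for phenotype
data; it biases toward rare-allele overweighting when true dosage is
skewed, a caveat shared by all phenotype-based polyploid estimators.

The Shannon index is computed over distinct *multilocus genotypes*
(`H = −Σ f ln f`, natural log), i.e. clonal diversity: it equals `ln N`
exactly when all N genotypes are unique. This reading is pinned by the
emulated study's own diversity table, where every all-unique population
prints exactly `ln N` (2.08 for N = 8, 1.61 for N = 5, 2.56 for N = 13),
including one population printing 1.39 = ln 4 at N = 6.

Jost's D per locus is `(H_T − H_S)/(1 − H_S) · n/(n−1)` with n = 2
populations; G_ST is `(H_T − H_S)/H_T` (the quantity often labelled F_ST by
polyploid software; it is named `g_st` here to avoid overclaiming). Global
values are across-locus means, skipping monomorphic loci. No sample-size
bias correction is applied to H_S beyond the n/(n−1) factor, so D runs high
for very polymorphic markers at small N — visible in the worked example.
Significance comes from bootstrapping individuals within populations and
reporting the fraction of replicates at or below zero.

AMOVA operates on the presence/absence expansion (one column per observed
locus–allele) with mismatch-count distances. Sums of squares follow the
standard pairwise form (`SS = Σ_{i<j} d_ij / n` within each stratum),
variance components by method of moments with
`n0 = (N − Σ n_p²/N)/(P−1)`; σ²_A may be negative and is reported as such,
with Φ_PT truncated at zero only for the display percentages. The
permutation p-value is `(1 + #{Φ_perm ≥ Φ_obs})/(n_perm + 1)` over random
relabelings, verified against exhaustive enumeration on 4-sample instances.

## Haplotype network and percolation

Distinct cpSSR haplotypes are labelled AA, AB, … in lexicographic order of
their repeat vectors, making tables independent of input order. The network
is the complete graph under the Goldstein distance — mean over loci of
squared repeat differences by default; a sum-over-loci flag exists because
the printed value of a percolation threshold cannot disambiguate the two
conventions without raw data. The percolation threshold scans the sorted
unique edge weights and returns the smallest weight maximizing the
susceptibility `χ = Σ s²·n_s / N` over components *excluding the largest*.
A structural property of this estimator, worth knowing when reading its
output: in a two-cluster geometry it often selects the notch just below
full within-cluster connection, detaching one or two outlying haplotypes,
because a counted singleton raises χ above the clean two-component value.
The two largest components at the threshold are still pure cluster cores;
the tests assert exactly that.

## Assignment

Queries are haploid multilocus cpSSR profiles. The reference likelihood per
locus is the Rannala–Mountain posterior predictive
`(n_a + 1/k_l)/(n_l + 1)`, where `k_l` counts distinct alleles at the locus
over the full dataset (references plus queries); the 1/k prior keeps
alleles unseen in a reference from zeroing the likelihood. Scores are
likelihoods normalized across references (summing to 100%), ties broken by
label order. Exclusion simulates 10 000 genotypes from the reference's
allele frequencies (loci independent) and ranks the observed log-likelihood
in that null with the add-one estimator. QI is defined as the mean
leave-one-out score granted to each reference individual's true population;
the cited procedure is described only loosely in the literature this
follows, so the exact formula is a package decision. Note that the 1/k
prior keeps QI strictly below 100 even for fully diagnostic references.
Evanno's ΔK is the absolute second difference of mean log-probability over
K divided by the across-run standard deviation, undefined at the endpoints
and wherever the sd is zero.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *design* of a two-cluster range-wide survey:
2 clusters × 4 populations × 40 trees by default (~320 samples), 12 nuclear
loci with 20 possible alleles each (range-wide SSR surveys of outcrossing
conifers typically segregate ~20 alleles per locus), hexaploid genotypes
drawn i.i.d. from population frequencies, ~10% of samples in clones of 2–3
ramets with somatic ±1 mutations at rate 0.01/locus/ramet, and 6
chloroplast loci mutated stepwise from cluster founders. Population
frequencies follow the F-model: Dirichlet draws centred on a cluster
baseline with concentration `(1−F)/F`, so `divergence_F` (default 0.1,
"weak") controls differentiation. Peak ranks are discrete triangular
distributions — rising over [threshold, 10] for true alleles, falling over
[3, threshold−1] for stutter — contaminated with uniform overlap at rate
`1 − rank_reliability` (default 0.98), so the 7–10 band is the
discriminative region and threshold choice has consequences. A single
master seed spawns deterministic per-stage generators; every artifact is
bit-identical under a fixed seed.

Not emulated: linkage and identity disequilibrium, null alleles, selfing
or spatial genetic structure, realistic electropherogram shapes, allele-size
homoplasy, and coalescent ancestry (frequencies are drawn, not evolved).
Passing parameter-recovery tests therefore demonstrates internal
consistency of the estimators under the stated model, not robustness to
those real-data complications.

Problem sizes in the test suite are chosen for breadth within a desk-scale
run: clone recovery runs at the full default design over 10 seeds;
differentiation monotonicity uses 2 populations × 15 samples per cluster
over a six-point F grid; calibration of the exclusion test uses 1 000
queries at 10 000 simulations each.

## Numerical conventions

* Identical membership vectors short-circuit to similarity exactly 1.0 in
  normalized mode (immune to square-root round-off); the normalized index
  is clamped at 1 against floating-point overshoot.
* The raw (unnormalized) similarity index is retained because it is the
  literal printed formula; it fails the "identical ⇒ 1" property, which is
  why normalized mode is the default. The discrepancy is deliberate and
  surfaced rather than silently resolved.
* Q-matrix rows are renormalized on read when within [0.99, 1.01] of 1,
  rejected otherwise; generated rows are renormalized to machine precision.
* Distance matrices are symmetrized (`(D + Dᵀ)/2`) and validated (finite,
  non-negative, zero diagonal) at construction.
* All permutation/bootstrap p-values use add-one estimators where the
  observed configuration is a valid permutation, keeping p in (0, 1].
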