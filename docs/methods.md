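# Methods

This note documents the statistical models behind `ratpopgen`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical corner cases.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Data model

A locus is a pre-aligned set of allele sequences over {A, C, G, T, N, −}
with per-sequence labels (individual, allele 1|2, population), a reading
frame offset (0–2) and optionally a single aligned outgroup sequence.
Coordinates are 0-based half-open internally; report layers print 1-based
positions.  Only the standard nuclear genetic code is wired in, but the
code table is data (a plain codon → amino-acid map), so alternates can be
added without touching logic.

## Site classification (Nei–Gojobori)

Effective synonymous/replacement site totals are fractional: each position
of a codon contributes syn = (number of its three possible single-base
changes that preserve the amino acid)/3, remainder to replacement, so
syn + repl = 3 exactly per included codon.  Changes creating a stop codon
count as non-preserving.  Fractions are computed on the majority-consensus
codon, ties broken by the first-listed allele — the counting reference had
to be fixed somehow, and the consensus is deterministic and standard.

Missing-data policy: codons containing N or a gap in **any** analysed
sequence are excluded from the totals for all sequences (complete-case per
codon), applied within whatever population subset is being analysed.  This
makes per-population site totals differ slightly, which is the behaviour
real surveys show when each population has its own missing individuals.
Variable positions are classified by translating the observed codon
variants: one amino acid → synonymous, more than one → replacement.  Codons
segregating at two or more positions have an ambiguous mutational pathway
and are excluded from per-class variable-site counts (with a logged
reason); they still contribute to the site totals.

## Diversity statistics

* θ<sub>π</sub>: per variable site with k non-missing alleles and allele
  frequencies p, the unbiased heterozygosity (1 − Σp²)·k/(k−1) is summed
  and divided by the class site total L.  This equals the average
  proportion of differing sites over all allele pairs.
* θ<sub>W</sub> = S/(a<sub>n</sub>L), a<sub>n</sub> = Σ<sub>i=1</sub><sup>n−1</sup> 1/i.
* Tajima's D uses the standard constants (a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂);
  it is undefined (None, never 0) when S = 0 and also at n = 2, where the
  normalizing variance vanishes identically.
* Per-locus n: alleles with ≥ 20% missing sites at a locus are dropped
  before any counting.  The 20% cut is a pragmatic default — strict
  complete-case would discard whole loci for one bad read, while keeping
  near-empty alleles would distort S.
* Pooling across loci sums S, L and the pairwise-difference sums; pooled
  θ<sub>W</sub> is Σ(S<sub>i</sub>/a<sub>n_i</sub>)/ΣL, which reduces to Watterson on the summed
  counts when all loci share n.  The pooled Tajima's D uses the modal
  allele count (per-locus n values are retained in the result).

The "all sites" class for D spans every variable position inside included
codons regardless of class, since genome-wide D statements conventionally
refer to all sites; per-class D is available through the same call.

## Coalescent simulator

Standard Hudson coalescent; time in units of 2N generations, θ = 4Nμ per
locus.  Single-population mode: exponential waiting times at rate k(k−1)/2,
uniform pair merging.  Split mode: two equal-size daughter populations
coalescing independently, per-lineage migration at rate 4Nm/2 backwards in
time, and a forced pooling of lineages at the split time.  Mutations are
infinite-sites: Poisson with mean (θ/2)·(total branch length), branch
chosen proportionally to length, site uniform with collision resampling
(collisions are counted and surface as a warning counter).  The fixed-S
mode places exactly S mutations — the usual conditioning for null
distributions of frequency-spectrum statistics, and the default null for
Tajima's D significance (a fixed-θ mode is retained for sensitivity
analysis).  No intra-locus recombination is modelled: the target loci are
~450 bp amplicons, and loci are treated as independent.

The test suite pins the simulator to closed forms (E[TMRCA], E[total
length], E[S] = θ·a<sub>n</sub>) and cross-checks the TMRCA and total-length
distributions against msprime, which is a test-only dependency.

## Population structure

F<sub>st</sub> is Hudson's sequence-based estimator 1 − H<sub>w</sub>/H<sub>b</sub>:
per variable site H<sub>w</sub> is the mean over the two populations of the
unbiased within-population heterozygosity and H<sub>b</sub> = 1 − Σ<sub>a</sub>
p<sub>1,a</sub>p<sub>2,a</sub>; multilocus values combine sites by ratio of sums,
which is the bootstrap-friendly form.  This choice — rather than
Weir–Cockerham — is the conventional estimator for sequence data where the
analysis is organized around sites rather than variance components;
negative per-site estimates are reported as computed.  The CI is a
percentile bootstrap over loci, default 1,000 replicates; replicates with
no usable polymorphic site are excluded and counted.  Site-level (not
haplotype-level) heterozygosity is used throughout.

Sharing classification: a pooled-variable site is *shared* if polymorphic
in both populations, *private* if polymorphic in exactly one, and a *fixed
difference* if each population is monomorphic for different alleles; the
tallies sum exactly to the number of analysed variable sites.

Clustering export writes the de-facto STRUCTURE text format (two rows per
individual, integer alleles, −9 missing).  Singletons — pooled
minor-allele count 1 — are uninformative for clustering and removed first;
in one-SNP-per-locus mode a remaining SNP is drawn uniformly per locus
under the supplied seed, and in haplotypes-as-alleles mode the distinct
remaining haplotypes are enumerated in order of first appearance.  The
Evanno ΔK statistic |L(K+1) − 2L(K) + L(K−1)|/sd(L(K)) is computed on
replicate means; a zero standard deviation yields an undefined (NaN) ΔK
rather than infinity, and ties for the maximum are all flagged.

## Neutrality tests

* Tajima's D p-value: two-tailed empirical p from the fixed-S null,
  p = 2·min(tail proportions) with the (b+1)/(n_reps+1) correction per
  tail, capped at 1.  Doubling the smaller tail is the simplest two-sided
  construction when the null is asymmetric; 1,000 replicates is the
  default.
* Hardy–Weinberg: the exact conditional test — given the allele counts,
  the probability of each attainable heterozygote count (same parity) is
  computed in closed form via log-gamma, and the p-value sums those with
  probability ≤ the observed configuration.  Monomorphic sites return
  p = 1 and are flagged uninformative.  The test oracle in the suite is an
  independent exact-rational enumeration.
* McDonald–Kreitman: polymorphic sites take their class from the
  within-species classification; fixed differences are positions where all
  ingroup alleles share one state and the outgroup another, classified by
  the single change from the ingroup consensus codon.  Codons where a
  fixed difference co-occurs with another difference are excluded
  (ambiguous pathway, logged).  NI = (P<sub>n</sub>/P<sub>s</sub>)/(D<sub>n</sub>/D<sub>s</sub>) is
  undefined — reported, not raised — when a denominator margin is zero;
  the two-sided p is the exact conditional 2×2 test.
* Multiple testing: raw p-values are reported, matching common practice
  for per-locus scans; a Benjamini–Hochberg column is available as a
  clearly-labelled extension.

## Demography

The multilocus likelihood for per-site θ treats S at each locus as Poisson
with mean θ·a<sub>n</sub>·L.  This free-recombination approximation is adopted
because its maximizer is the transparent closed form ΣS/Σ(a<sub>n</sub>L) —
identical to pooled Watterson — and because the exact no-recombination
distribution of S (a signed geometric mixture, provided as
`method="exact"`) differs negligibly at θ per locus ≪ 1 while being
numerically delicate at large n.  The 95% CI inverts
2·[lnL(θ̂) − lnL(θ)] ≤ χ²₁(0.95) = 3.841 by bisection on each side
(relative tolerance 10⁻¹⁰); with ΣS = 0 the estimate is 0 with a one-sided
interval.

μ = d·r/(1+r)/(T·g), where d is total interspecific synonymous divergence,
T the split time in years, g generations per year, and r the
focal/sister-lineage rate ratio (default r = 1.15, the midpoint of the
10–20% rate excess reported for the rat lineage relative to mouse;
overridable).  N<sub>e</sub> = θ/(4μ), with CI bounds mapped monotonically from
the θ bounds.  All rounding happens in the report layer only.

## Synthetic-data generator

The generator emulates the study conditions end to end: 30 loci × 450 bp
coding sequence, 22 and 7 diploids (44/14 alleles) in two populations,
within-population synonymous θ = 0.002/site, replacement θ thinned to
0.2× synonymous, sporadic whole-individual dropout at 5% per locus, and a
clean two-population split calibrated to a target F<sub>st</sub> of 0.25 via
T = F<sub>st</sub>/(1 − F<sub>st</sub>) in 2N-generation units (within-pair
coalescence time 1, between-pair T + 1, so 1 − H<sub>w</sub>/H<sub>b</sub> →
F<sub>st</sub>; with nonzero migration the calibration is only approximate and
says so).  Within each daughter population the genealogy is exactly the
neutral single-population coalescent, so within-population estimators are
unbiased for the θ targets, while sample-pooled estimators are inflated by
the between-population divergence — the parameter-recovery tests therefore
score within-population θ<sub>W</sub> against truth.

Mutations are mapped onto codon positions so that class identity is exact:
a synonymous mutation is drawn uniformly from the amino-acid-preserving
single-base changes available on the ancestral sequence (which weights
positions by their synonymous fraction, consistent with Nei–Gojobori
counting), a replacement mutation from the amino-acid-changing ones, and
changes creating stops are never drawn.  At most one mutation lands per
codon (collisions resampled), so every variable site in the FASTA has an
unambiguous class recorded in the truth ledger.  Ancestral sequences are
uniform over the 61 sense codons, giving a replacement:synonymous site
ratio of 3.10 analytically — close to the ≈3.4:1 of real mammalian coding
surveys.  An optional outgroup is produced by placing divergence mutations
on codons untouched by the polymorphism layer.

What the generator does **not** emulate: sequencing error, chromatogram
ambiguity, alignment error, codon-usage bias, recombination within loci,
explicit fitness effects (replacement thinning is a statistical, not
mechanistic, stand-in for purifying selection), and non-equilibrium
demography beyond the clean split.  Passing the recovery tests therefore
demonstrates correctness of the estimators under the stated model, not
robustness to these real-data complications.  Because ancestral sequences
contain no stops, the stop-codon exclusion path of the site counter is
exercised by dedicated corrupt-input fixtures in the unit tests instead.

## Problem sizes and reproducibility

The Monte-Carlo checks use sizes chosen to give stable assertions at
3-standard-error tolerances: 5,000 replicates for the simulator closed
forms, 200 synthetic corpora for parameter recovery and CI coverage, and
1,000 outer × 200 inner replicates for the type-I calibration of the D
test.  Every stochastic function accepts either an integer seed or a numpy
Generator; the synthetic generator derives per-locus streams from a root
SeedSequence, so corpora are byte-identical for a fixed seed, and the CLI
records seeds, package version and a config hash in `provenance.json`.

## Known limitations

* The χ²/Poisson CI for θ ignores the extra (non-Poisson) variance of S
  under linkage within loci; at the θ ≈ 0.3/locus scale of these data the
  effect on coverage is small (the coverage test bounds it) but the
  interval is slightly anticonservative in principle.
* The exact-S likelihood's alternating sum loses precision for large n
  combined with large θ per locus; it is intended for the small-θ regime.
* The HWE and MK tests are exact but conditional; their discreteness makes
  them conservative at small counts (the super-uniformity test documents
  this).
* Fst calibration of the generator targets the ratio-of-expectations; the
  ratio-of-sums estimator over 30 loci carries a small finite-sample bias
  that the recovery test's Monte-Carlo band absorbs.
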