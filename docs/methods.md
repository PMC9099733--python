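# Methods

This note documents the statistical models, conventions and design
choices behind `dartpop`, in the spirit of the methods documentation
of mature scientific packages.  It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Data model

Genotypes are integer calls per accession × locus: 0 (reference
homozygote), 1 (heterozygous), 2 (alternative homozygote), −1
(missing).  The data come from pooled DNA samples — each cultivar is
represented by a bulk of several seedlings — of a self-pollinating
crop.  Individual plants are therefore (almost) fully homozygous, and
a heterozygous *call* records that the pooled seedlings carry both
alleles: it measures **intra-cultivar heterogeneity**, not individual
heterozygosity.  All downstream statistics treat the pooled sample as
one diploid individual, because that is how the genotype table is
coded; the interpretation of `Ho` as heterogeneity follows from the
sampling design, not from a change of formula.

The two-row DArTseq dialect encodes each locus as a reference-allele
presence row and an alternative-allele presence row of 0/1 scores.
Presence scores (not counts) are assumed.  Chromosome labels are
1H–7H or `Un` (unassigned); `Un` loci carry no position, are excluded
from window scans, and are included in genome-wide statistics.

## Quality filtering

Loci are removed when reproducibility (RepAvg), call rate, or minor
allele frequency falls **strictly below** its threshold (defaults
0.95, 0.95, 0.01); boundary values are kept.  Filtering is a single
pass with each removal attributed to the first criterion failed, in
the order RepAvg → call rate → MAF.  MAF is computed from non-missing
calls over all accessions, two allele copies per homozygote and one
of each per heterozygote.  The report's counts always sum to the
input locus count, and filtering is idempotent.

## Diversity statistics

* **PIC** uses the diversity form `1 − p² − q²` (biallelic maximum
  0.5).  Botstein's PIC (maximum 0.375 for biallelic markers) is *not*
  used: panels of this type report PIC values up to ~0.5, which only
  the diversity form can produce.
* **uHe** is Nei's unbiased gene diversity
  `2n/(2n−1) · (1 − p² − q²)`, with `n` the number of accessions with
  a non-missing call at the locus.
* **F** = `(uHe − Ho)/uHe`, 0 at monomorphic loci by convention.
  Group-level `F` is computed from the group's mean `Ho` and mean
  `uHe` (this is the construction under which the reference panel's
  printed mean triple is self-consistent); per-locus `F` values are
  also available for averaging the other way.
* **Allelic richness** is Hurlbert rarefaction,
  `AR = Σ_a [1 − C(N−N_a, g)/C(N, g)]`, evaluated with log-gamma
  arithmetic; the default rarefaction size is `g = 2 ×` the smallest
  group's accession count.  The closed form is tested against full
  subsample enumeration for `N ≤ 8`.
* The SNP-type table counts the 12 ordered substitution classes;
  transitions are A>G, G>A, C>T, T>C.

## Sliding windows

The scan uses windows of fixed width (default 500 kb) at a fixed
number of evenly spaced centers (default 250) from `width/2` to
`length − width/2`.  With chromosomes of 560–770 Mbp, 250 windows of
500 kb cannot tile the chromosome: windows **sample** positions along
it, leaving gaps.  Windows are half-open, `[center − w/2,
center + w/2)`.  An empty window reports a missing value and count 0.

## FST and the power transform

Between-group differentiation is the two-population Wright/Nei form
`FST = (HT − H̄S)/HT`, `HT = 2p̄(1−p̄)` with `p̄` the unweighted mean
of the group frequencies, clipped to [0, 1], with `FST = 0` where
`HT = 0`.  This simple estimator was chosen over Weir–Cockerham
because only "Wright's FST" is specified for this analysis type; it
carries a finite-sample upward bias of order `1/(2n)`, which the
near-zero-divergence test accounts for by using 50 accessions per
group.  `FST^10` is a plotting transform only: monotone, it compresses
the low-FST background so swept regions stand out.

## Unique alleles

An allele (ref or alt) is unique to a group when its frequency is
`≥ threshold` there (0.25 for common variants, 0.05 for rare) and
**exactly 0** among the other group's non-missing calls — no epsilon.
Lost/gained counts compare consecutive breeding periods pairwise;
group-vs-all-others uniqueness is available through
`unique_allele_mask` for the per-group window tracks.

## Distances and ordination

Each locus expands to two presence bits (ref present: call ∈ {0, 1};
alt present: call ∈ {1, 2}), mirroring the two-row source encoding.
Jaccard distance is computed over loci non-missing in both accessions
of a pair; a heterozygote shares one bit with either homozygote, so a
0-vs-1 pair contributes 0.5, not 1.  PCoA is classical scaling of the
double-centered `−D²/2`; negative eigenvalues (non-Euclidean residue)
are dropped without Cailliez/Lingoes correction — the simplest
defensible choice — and percent variance is relative to the positive
spectrum only.

## AMOVA

Distance-based (Excoffier) sums of squares on the squared Jaccard
matrix: `SS_total = Σ_pairs d²/N`, within-group analogously per group;
`σ²_w = SS_w/(N−k)`, `σ²_a = (SS_a/(k−1) − σ²_w)/n₀` with the
standard unequal-size coefficient `n₀ = (N − Σn_g²/N)/(k−1)`.
Negative `σ²_a` is truncated to 0 before percentages.  The p-value is
`(b+1)/(m+1)` over seeded label permutations of Φ_ST.

## Admixture model

The model is the standard admixture likelihood: accession `i` draws
each of its two allele copies at locus `l` from pool `k` with
probability `q_ik`, and the copy is the alternative allele with
probability `p_kl`.  The log-likelihood
`Σ_{i,l} [g log(Qp) + (2−g) log(Q(1−p))]` (missing calls skipped) is
maximised by EM with simultaneous multiplicative updates of Q and P;
the trace is monotone non-decreasing and the fit stops when the
improvement drops below `tol` (default 1e−6) or at `max_iter`
(default 2000).  P is clipped to `[1e−6, 1−1e−6]` to keep the
likelihood finite.

This is a deliberate maximum-likelihood substitution for the Bayesian
MCMC approach traditionally used for this analysis: the point
estimates of Q and P are the same model quantities, and replicate
log-likelihoods stand in for the model log-probability in the Evanno
statistic, which changes no formula in ΔK.  Full posterior sampling,
burn-in diagnostics and the correlated-frequencies prior are out of
scope.

Replicate label alignment minimises `Σ|Q_ref − Q_rep·Π|` over column
permutations — exhaustively for K ≤ 8, by Hungarian assignment above
(the objective is column-separable, so both are exact).  ΔK is
`mean_r |L_r(K+1) − 2L_r(K) + L_r(K−1)| / sd(L(K))`, defined at
interior K; zero replicate spread flags an infinite ΔK.  Membership
assignment at threshold 0.8 is **inclusive** (`q ≥ 0.8` is pure).
The study-scale grid is K = 1–16 with six replicates; the pipeline's
default is K = 1–6 with three replicates, a desk-scale choice that the
three-pool recovery tests show is sufficient for the panel sizes the
package targets (both are configurable).

## Identity by descent

The PLINK-style method of moments: per pair, observed counts of loci
identical-by-state at 0/1/2 alleles are set against their
expectations under panel allele frequencies and Hardy–Weinberg
proportions, solved sequentially for P(IBD=0/1/2); negative estimates
are truncated and the triple renormalised.  `P̂ = P(2) + P(1)/2`.
Monomorphic loci are excluded (they carry no information); pairs with
fewer than 50 jointly non-missing loci are flagged low-confidence.
No LD pruning is applied.

Because pooled-sample calls of a selfing crop violate Hardy–Weinberg
(strong heterozygote deficit), absolute P̂ values between unrelated
accessions are inflated above zero (≈0.25–0.3 on structured panels).
This does not affect duplicate detection: planted duplicates sit
above 0.99 − 0.01·(perturbed loci) and the 0.95 cutoff separates them
from the background by a wide margin, as the ten-seed recall test
shows.  The near-zero null behaviour of the estimator is verified on
panels whose calls are Hardy–Weinberg draws (two seedlings, full
mixing).  Duplicate clusters are connected components of the
P̂ > 0.95 graph (transitive, matching single-link presentation), and
the verdict table requires low distance (< 0.05), identical dominant
pool, and IBD jointly; passport flags are informative only.

## Core collection

Allele classes are the observed (locus, allele) pairs, heterozygotes
carrying both.  The minimum covering subset is found by best-first
search with the admissible bound `h = ⌈uncovered / best single
accession gain⌉`, seeded and pruned by a greedy solution; equal-size
solutions tie-break to the lexicographically smallest id set.  The
frontier is capped (default 10,000 states, 50,000 expansions); when
the cap trips, the incumbent is completed greedily and the result is
marked `beam` instead of `exact`.  Exact mode is proven against
exhaustive search on panels of ≤ 12 accessions; on 83-accession
panels the search typically degrades to beam mode, which still
guarantees coverage 1.0 and a core no larger than greedy.
Phenotype-trait class binning is out of scope — only marker classes
are covered.

## Synthetic panels

The generator emulates the study design, not sequence evolution:

* ancestral allele frequency `p₀ ~ U(0.05, 0.95)` per locus; pool
  frequencies from a Balding–Nichols beta with drift parameter
  `pool_divergence` (default 0.15, a moderate value typical of
  structured crop germplasm);
* 11 gene pools and five breeding-period groups of 13/14/18/26/12
  accessions; each accession draws a Dirichlet membership `Q*`
  concentrated on its period's focal pools (round-robin assignment,
  base weight 0.2, focal +3.0);
* seedlings are fully inbred; at a per-group fraction of loci
  (defaults 0.16/0.12/0.09/0.06/0.03, declining with period to mirror
  the increasing uniformity of modern cultivars) the 8-seedling pool
  is drawn independently from the accession's mixture frequency, so
  disagreement yields a heterozygous call; elsewhere the pool is
  clonal.  Residual seedling heterozygosity is not modelled — the
  heterogeneity fraction is the exposed parameter;
* chromosome lengths follow the published barley assembly values
  (558.54–768.08 Mbp) so window geometry matches real panels;
  positions are denser toward chromosome ends (mixture of two edge
  betas); substitution types are drawn with the reference panel's
  relative frequencies;
* duplicates copy an accession (including its true membership) and
  re-draw 0.5% of calls; sweeps fix the alternative allele over a
  positional window in the affected groups (defaults: 5H 100–140 Mbp
  in the two most recent periods, 3H in the newest);
* quality metadata plant a configurable fraction of filter failures
  (2% low RepAvg, 2% low call rate); missingness is 0.5%.

What the defaults do **not** emulate: linkage disequilibrium beyond
sweep blocks, recombination maps, allele-frequency spectra shaped by
ascertainment, genotyping error beyond the duplicate perturbation,
and the real panel's locus density (the default 1,450 loci keep the
test suite fast; density-sensitive properties such as sweep
localisation are tested at 1,000 loci per chromosome, and functions
scale to real panel sizes).  Passing tests therefore demonstrate
estimator correctness and pipeline behaviour under the declared
model, not robustness to every artefact of real DArTseq data.

## Determinism and problem sizes

Every stochastic component takes an integer seed; the pipeline fans a
single global seed out to stages by fixed offsets, and repeated runs
are byte-identical (CSV floats are written to 12 significant digits).
The bundled acceptance script runs the default 83 × 1,450 panel, ten
replicate panels for duplicate detection, a 60-accession three-pool
panel for ΔK, and a 7,000-locus panel for sweep localisation —
sizes chosen so the whole script completes in well under a minute on
one CPU while keeping every recovery margin wide.
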