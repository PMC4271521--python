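# Methods

## Background

Four-taxon ("ABBA-BABA") statistics detect an excess of derived alleles
shared between non-sister taxa.  Given populations P1, P2, P3 and an
outgroup O related as (((P1,P2),P3),O), incomplete lineage sorting
makes the two discordant site patterns ABBA (derived allele in P2 and
P3) and BABA (derived allele in P1 and P3) equally frequent; gene flow
between P2 and P3 — or structure in their common ancestral population —
creates an ABBA excess.  This package computes the window-scale versions
of these statistics, the admixture-proportion estimators built on them,
and the simulation framework used to characterize their behavior when
applied to small genomic windows rather than whole genomes.

## Statistics

For each biallelic site *i*, with `p_ij` the derived-allele frequency
in group *j*:

    C_ABBA(i) = (1 - p_i1) p_i2 p_i3 (1 - p_i4)
    C_BABA(i) = p_i1 (1 - p_i2) p_i3 (1 - p_i4)

    S(P1,P2,P3,O) = sum_i [ C_ABBA(i) - C_BABA(i) ]
    D = S / sum_i [ C_ABBA(i) + C_BABA(i) ]

The three estimators of the admixture proportion *f* divide the
observed S by the S expected under complete introgression from P3 into
P2:

* `f_G = S(P1,P2,P3,O) / S(P1,P3a,P3b,O)` — the P3 sample split into
  two halves.  The split is deterministic and interleaved (even sample
  indices vs odd; the even half takes the extra haplotype when the
  count is odd), because a contiguous half/half split degenerates
  whenever derived alleles cluster by sample order; a seeded random
  split is available as an option.  `f_G` can exceed 1 when the halves
  happen to disagree.
* `f_hom = S(P1,P2,P3,O) / S(P1,P3,P3,O)` — complete introgression
  assumed to homogenize P2/P3 allele frequencies; conservative.
* `f_d = S(P1,P2,P3,O) / S(P1,PD,PD,O)` with `pD = max(p2, p3)` per
  site (P3 on ties; either choice yields the same term).  On windows
  with an ABBA excess (D >= 0) this bounds the estimate to [0, 1].

All four carry an explicit missing state when the denominator is zero
(D) or non-positive (the f ratios).  f values are computed for every
window but are only meaningful estimates of introgression on windows
with D >= 0; downstream outlier selection enforces this.

Polarization: a site enters the pattern statistics iff it is biallelic
across all called haplotypes and each of the four groups has at least
one call there (frequencies are undefined otherwise).  The ancestral
allele is the allele fixed among called outgroup haplotypes; if the
outgroup is polymorphic, the overall majority allele is ancestral (ties
broken toward the alphabetically first nucleotide).  The outgroup
derived frequency p4 is retained as observed — the (1 - p4) factor in
the weights is then active for polymorphic outgroups — with a switch
(`outgroup_derived_freq=False`) to force p4 = 0 after polarization.

## Windows, pi and d_XY

Windows tile each scaffold independently from coordinate 0 (0-based
half-open internally, 1-based inclusive in written tables),
nonoverlapping by default at 5 kb; trailing sub-length windows are
emitted but flagged partial.  A window is retained when at least
`min_genotyped_sites` (default 3,000) of its sites have complete
genotype calls in at least half of the individuals (rounding the
threshold up for odd counts); retention at exactly the threshold is
inclusive.

pi (within a population) and d_XY (between populations) are per-site
means over pairs of haplotypes: each pair contributes
(differences / jointly called sites), pairs with no jointly called
site are excluded, and every pair weighs equally.  By default pi
excludes pairs of haplotypes drawn from the same individual
(configurable), since "pairs of individuals" is ambiguous for diploid
data; d_XY uses all between-population haplotype pairs.  Diploid VCF
genotypes are expanded to two haplotypes per sample — phasing is
irrelevant because every statistic is frequency- or pairwise-difference
based.  Only single-nucleotide records are used; invariant records of
an all-sites VCF count toward call denominators, while positions absent
from the input are unknown and excluded.

## Simulator

Genealogies are sampled with msprime under ms-style scaling: haploid
samples (8 per population by default), population size 1/2, so one
engine generation equals one unit of 4N generations and a pair of
lineages coalesces at rate 2.  All split times are in 4N units with the
root fixed at 3.0.  Recombination is the per-bp population rate 4Nr
(default 0.01; total window rate = 4Nr x window length, e.g. 50 for a
5-kb window).  Mutations are finite-site HKY at 0.01 substitutions per
site per branch-length unit, matching a branch scaling of 0.01 in a
sequence simulator; recurrent hits can produce multiallelic sites
(excluded by polarization) and back mutations.  The HKY rate ratio
defaults to kappa = 1.0 with equal base frequencies, which equals a
transition/transversion ratio of 0.5 — the default of the classic
sequence simulators; both are configurable.

Instantaneous unidirectional admixture on the species topology is the
ms `-es/-ej` idiom: tracing time backwards, each recipient lineage
moves to the donor population with probability f at time t_GF < t12.
With f = 0 the event is a no-op (verified distributionally); with f = 1
from P3 into P2 at recent t_GF, f_hom approaches 1.

Combined Background/Alternate datasets mix windows from the species
topology (((P1,P2),P3),O) with windows from ((P1,(P2,P3)),O), making
sharing complete (f = 1) in the Alternate fraction (10% by default,
9,000 + 1,000 windows).  The alternate topology is parameterized by its
two join times:

* gene flow P3->P2: P2 joins P3 at t_GF (< t12) and the pair joins P1
  at the background t23;
* gene flow P2->P3: P2 and P3 join at t_GF and the merged lineage
  follows the background P1-P2 split (t12) — the merged ancestor
  behaves as a P2 lineage;
* ancestral structure: P2 and P3 join at the background t23 and the P1
  join is delayed to t_STR > t23.  This keeps the marginal P2-P3
  coalescence process identical between Background and Alternate
  windows (both pairs enter a common population at t23), which is what
  makes structure produce an ABBA excess *without* reduced d_XY.

The model survey enumerates split times over 0.2, 0.4, ..., 2.0 (4N
units): the 45 ordered pairs t12 < t23 for null models and the 120
ordered triples for each of the three non-null scenarios (t_GF < t12 <
t23 for gene flow, t12 < t23 < t_STR for structure), 405 models
overall.  The survey's exact original parameterizations are not
reproduced row-by-row (only the grid range and counts are fixed by the
design); this enumeration reproduces the counts and covers the same
range.  A deterministic evenly spaced subsample supports desk-scale
runs.

## Outlier evaluation

`select_outliers` ranks windows by a statistic and takes the top
`round(0.1 x n)` among eligible candidates (D > 0 for D; D >= 0 for f
estimators), ties broken by window order.  `compare_dxy` compares
P2-P3 d_XY between candidates (true Alternate labels or outliers) and
all remaining windows: means, the outlier-to-nonoutlier percentage, a
one-sided Wilcoxon rank-sum p (candidates lower; two-sided available),
Bonferroni correction over the models of the scenario actually run,
and significance at adjusted p < 0.01 *and* a lower candidate mean.
The Wilcoxon is unconditional (no normality screening); small samples
(total <= 20) use exact enumeration of all group assignments with
midranks, larger samples the tie-corrected normal approximation.

## Problem sizes and what the tests show

The full survey (405 models x 10,000 windows x 2
recombination rates) is large; the package's own verification runs
evenly subsampled grids, chosen as follows:

* Gene-flow scenarios at 4Nr = 0.01, true labels: 10-12 models x 1,000
  windows.  The Alternate-window d_XY reduction here is enormous
  (coalescence before t12), so the significance count is insensitive
  to the window count.
* Structure at 4Nr = 0.01 (true labels; expected: never significant)
  and structure D outliers at 4Nr = 0.001: 10-12 models x 1,000-2,000
  windows.
* Null-model f_d outliers at 4Nr = 0.001: 10 models at the full 10,000
  windows per model.  This count is power-limited: the outlier bias is
  a modest d_XY reduction (a few percent), and the rank-sum z statistic
  grows like sqrt(n), so an all-models-significant count is
  a property of the 10,000-window datasets and is not reproduced at
  much smaller n.
* Estimator accuracy: the design's full per-setting size (100 windows) on
  the 11-point f grid at t_GF = 0.1, 5 kb, 4Nr = 0.01.

Because windows are simulated independently, these datasets emulate
free recombination between windows and uniform mutation and
recombination rates within them.  Real genomes violate both
(heterogeneous diversity, linked selection, rate variation), so passing
tests demonstrate the statistics' sampling behavior under the idealized
model, not robustness to genomic heterogeneity — indeed the motivating
analyses show D's variance inflation in low-diversity regions of real
data.

## Numerical choices

* Oracle comparisons and algebraic identities at relative 1e-9;
  pi/d_XY hand examples at 1e-12.
* Statistics carry `None` (written as NA) rather than NaN for missing.
* Outlier ranking uses a stable sort; equal values keep window order.
* Degenerate chromosome summaries (single window, constant columns)
  yield missing variances/correlations rather than errors.
* Seeds: every stochastic entry point takes one integer seed; internal
  streams are derived via `numpy.random.SeedSequence` and msprime
  seeds stay below 2^31.  Batch simulation is reproducible at batch
  granularity (replicate genealogies share one seeded engine run; each
  window gets its own recorded mutation seed).

## Known limitations

* No block-jackknife or genome-wide significance machinery — the
  window statistics are descriptive; formal genome-wide tests are out
  of scope.
* Continuous migration, selection and varying population size are not
  modeled.
* The FASTA export fills invariant sites from equilibrium base
  frequencies (seeded per window); alignments are statistically, not
  byte-wise, equivalent to a full sequence simulation.
* f_G's split-half denominator needs at least 2 P3 haplotypes; with
  one haplotype the second half falls back to the full-P3 frequency
  (equivalent to f_hom).
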