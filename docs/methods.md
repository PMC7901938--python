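# Methods

`driftscan` detects selection in a population sampled over a few dozen years
with two complementary scans: a Wright–Fisher hidden Markov model
likelihood-ratio test on generation-binned allele-frequency series, and the
nSL haplotype-homozygosity statistic on phased present-day haplotypes.  This
note documents the models, the tunable parameters, the synthetic-data
generator used to validate everything, and the numerical choices made where
the design was open.

## Wright–Fisher HMM for temporal allele frequencies

The population allele frequency at a biallelic SNP is modelled as a hidden
Markov chain.  One generation of drift and genic selection moves the allele
count k (of 2Ne) to

    k' ~ Binomial(2Ne, p'),   p' = p(1+s) / (1+ps),   p = k/2Ne.

Counts 0 and 2Ne are absorbing.  The selection model is *genic*: one
parameter s multiplies the fitness of each allele copy; no dominance
parameter exists, matching the one-parameter likelihood-ratio test.

**State space.** Exact allele-count states (2Ne+1 of them) whenever
2Ne ≤ 400; beyond that, a fixed grid of G = 201 equispaced frequencies, with
each row's binomial mass aggregated to the nearest grid point through the
binomial CDF evaluated at count-space midpoints (rows stay stochastic by
construction).  The forward recursion against the reduced grid converges to
the exact value as G grows; the unit tests assert this monotone trend and
the exact agreement at G = 2Ne+1.

**Observations.** At a sampled generation with 2n observed allele copies and
c alt copies, the emission is Binomial(2n, f) at c given hidden frequency f;
generations with no data emit probability 1 (equivalently, the transition
matrix is raised to the gap).  The forward pass runs scaled (not in log
space) and is validated against exhaustive hidden-path enumeration on
five-state models to 1e-10.  The initial distribution is uniform over states
(configurable); with ~8 sampled generations the likelihood ratio is driven by
the trajectory, not the prior.

**Test.** Per SNP, the null log-likelihood at s = 0 and the alternative
maximized first on the grid {−0.9, −0.5, −0.3, −0.2, −0.1, −0.05, 0, 0.05,
0.1, 0.2, 0.3, 0.5, 0.9}, then refined by bounded scalar minimization in the
bracketing interval (tolerance 1e-3 on s).  LRT = 2(ℓ₁−ℓ₀) is referred to
the χ²(1) upper tail.  The χ² reference is known to be anti-conservative for
rare alleles, which is exactly why the pipeline removes SNPs with pooled MAF
below 5% before testing; on neutral simulations that pass this filter the
p-value distribution is close to uniform with a small deficit of very small
p-values (the absorbing boundaries truncate extreme trajectories), asserted
as a KS distance below 0.08 and a sub-0.05 tail within [0.03, 0.07].

**Effective population size.** Ne is estimated before per-SNP testing by
summing the neutral (s = 0) forward log-likelihood over all loci on a grid
of candidate Ne values (default 50–800 by 50), refining the maximum with a
parabolic fit through its neighbours, and reporting the 95%
profile-likelihood interval {Ne : ℓ(Ne) ≥ ℓmax − 1.92} with linearly
interpolated crossings.  Grid-edge maxima are flagged.  Ne is in diploid
individuals throughout.  The per-SNP test then fixes Ne at the point
estimate; integrating over the CI is not implemented.

## Local score

Per-SNP p-values become scores X = −log10(p) − ξ with offset ξ = 1, chosen
so the score has negative drift under uniform p-values (mean 1/ln10 − 1 ≈
−0.566) and excursions of the Lindley process H_i = max(0, H_{i−1} + X_i)
stay finite.  A region is significant when its excursion peak reaches a
chromosome-wide threshold calibrated so a fully neutral chromosome of L SNPs
exceeds it with probability α.

**Thresholds.** The default calibration is Monte-Carlo: 2,000 simulated
chromosomes of L i.i.d. uniform p-values, threshold = the (1−α) quantile of
the max of H.  A closed-form cross-check uses the Cramér-type tail
P(max H ≥ a) ≈ 1 − exp(−L·K·e^{−λa}), where λ ≈ 1.987 is the positive root
of e^{−λξ} ln10/(ln10 − λ) = 1.  For the prefactor this package derives
K = (1 − λ/ln10) · λ/(ln10 − λ) · 10^{−ξ} ≈ 0.086 from the stationary
upcrossing rate of the Lindley chain: the stationary law of H is the
all-time-maximum law of the underlying random walk — an atom at zero plus an
Exp(λ) tail with mass q = 1 − λ/ln10, exact here because the score's upper
tail is exponential — and the rate of upcrossings of level a is
e^{−ln10(a+ξ)}·E[e^{ln10·H}; H < a].  A unit prefactor would inflate
thresholds by ~ln(1/K)/λ ≈ 1.2 score units (≈30% at L = 1000); with K the
analytic and Monte-Carlo thresholds agree within a few percent for
L ∈ [10³, 3·10⁴], asserted at 15% tolerance in tests.

**Region extent.** The spec of an excursion's boundaries is open; this
package reports the widest window achieving the peak segmental sum, using
the identity H_i = S_i − min_{k≤i} S_k (S = prefix sums): the region runs
from the SNP after the earliest prefix-sum minimum attaining the peak to the
last SNP before H returns to zero, and overlapping regions merge.  With 28
chromosomes scanned at per-chromosome α = 0.10, the expected number of
false-positive regions genome-wide is 28 × 0.10 = 2.8, and neutral
simulations reproduce it.

## nSL

For focal SNP s, SL_alt is the mean over all pairs of alt-carrying
haplotypes of the number of SNPs in the maximal interval containing s over
which the pair is identical (truncated at chromosome ends, 0 on
disagreement at s); SL_ref likewise for ref carriers; raw nSL =
ln(SL_ref/SL_alt).  Measuring length in SNPs rather than map distance makes
the statistic robust to local recombination-rate variation.  The score is
undefined when either class has fewer than two haplotypes.  Pairwise
identity intervals are computed per pair in maximal identical blocks (every
SNP in a block shares the block length), validated against a direct
per-SNP scan to 1e-12; no maximum-extension cap is applied by default (a cap
is exposed as an option).

Scores are oriented positive — if raw nSL < 0 the allele roles swap and the
oriented frequency becomes 1 − alt frequency — so candidates are read from
the upper tail only, without outgroup polarization.  Oriented scores are
standardized within 20 equal-width bins of the post-orientation allele
frequency (pre-orientation binning available by flag; the choice is
ambiguous in principle and immaterial in our simulations); bins with fewer
than two defined scores merge into the nearest occupied bin, and a
zero-variance bin standardizes to 0 with a warning.  Candidates are SNPs
with standardized score above 5 (6 for the "strong" tier), grouped into
regions when consecutive candidates lie within 1 Mb (the grouping gap is a
package choice — the analyses this mirrors report grouped regions without
stating a rule — and is configurable and logged).  A region audit compares
each region's mean per-SNP imputed-genotype count with the genome-wide
distribution by a two-sided permutation test over random same-size SNP sets.

## Synthetic data

The generator emulates a livestock breed genotyped across ~8 generations by
three technologies:

* **Temporal genotypes** — independent biallelic SNPs evolve forward in time
  under the binomial Wright–Fisher law with genic selection (defaults: Ne a
  few hundred, 8 generations, 5–30 diploids sampled per generation, initial
  frequencies uniform).  Sampled genotypes are Binomial(2, freq); birth years
  are drawn inside each generation's 4-year window so calendar binning
  recovers the truth.  Per-source missingness (configurable rate; ~25–40%
  emulates genotype-quality masking of modest-coverage sequencing, <5%
  emulates chips) comes with phred-like GQ values: calls uniform on 20–60
  with a configurable fraction uniform on 0–9 to exercise the GQ < 10 mask.
  Ref/alt inversions between sources (the real failure mode of
  multi-technology merges, especially at strand-ambiguous A/T and G/C SNPs)
  are injected by the involutory recode g → 2−g.
* **Phased haplotypes** — a population of Ne diploids evolves by random
  union of gametes with per-adjacent-interval crossover probability r;
  founders carry standing variation at linkage equilibrium.  An injected
  sweep places all initial copies of the focal allele on one shared founder
  background (the haplotype structure of a hard sweep, whose brief early
  stochastic phase is not simulated) and conditions the run, by restart, on
  the allele reaching a target frequency — optionally within a bounded
  number of generations, making the accepted sweep a *recent* one.

What the generator does **not** model: mutation during the simulated window,
linkage between the temporal-scan SNPs, demographic change, genotyping batch
effects beyond missingness/inversions, or realistic site-frequency spectra
(founder frequencies are uniform).  Passing tests therefore demonstrate the
statistical machinery under the stated model, not performance on real data
with background LD, ascertainment bias or population structure.

## Validation experiments and problem sizes

The calibration/recovery experiments (in `driftscan.experiments`, run by the
tests and by `scripts/acceptance.py`) use these sizes, chosen to finish on a
single CPU in minutes while leaving Monte-Carlo error well inside the
asserted bands:

* type-I calibration: 500 neutral SNPs, Ne = 100, 8 generations, 20 diploids
  per generation, MAF ≥ 5%;
* null region calls: 200 genomes × 28 chromosomes × 1,000 uniform p-values,
  α = 0.10, Monte-Carlo thresholds from 2,000 replicates;
* Ne recovery: truth 200, 50 replicates × 500 SNPs × 8 generations × 30
  diploids, grid 100–350 by 25;
* s recovery: 200 replicates at s = 0.5, Ne = 100, p₀ = 0.2, 50 diploids per
  generation;
* sweep power: 50 replicates of 40 haplotypes × 2,000 SNPs, hard sweep
  s = 0.1 from p₀ = 0.04 (all copies on one shared background) to target 0.8
  within 60 generations, Ne = 2,000, r = 2·10⁻³ per interval (chip-like
  marker spacing at ~0.2 cM between adjacent SNPs); success = focal SNP's
  standardized nSL in the chromosome's top 1%; the sampled panel is
  conditioned to a focal frequency within ±0.05 of the target.

The sweep experiment's free parameters deserve a note: with s fixed at 0.1 a
sweep to 80% takes ~50 generations, so the population must be large enough
(Ne = 2,000) that background haplotype diversity is not consumed by drift on
the same timescale, and marker spacing such that the swept identity tract
(mean ≈ 1/(2·T·r) SNPs per side for a tract of age T) stands clear of the
background identity length yet does not blanket the chromosome.  At much
smaller Ne, drift alone produces extreme nSL scores and power collapses — a
genuine property of the statistic in small inbred populations, not an
implementation artifact.  Even under these conditions the focal SNP itself
occasionally ranks behind its own hitchhikers or, when all sampled sweep
haplotypes coalesce near the sweep's origin, carries a tract no longer than
the background, so single-SNP power saturates near 70% even though the swept
region as a whole is detected far more often — which is why the scan reports
regions, not single SNPs.

## Numerical choices and degenerate inputs

* Missingness thresholds are strict ("more than X%" removed): boundary
  fractions survive.  MAF filters are inclusive at the boundary.
* Transition matrices are cached per (Ne, s, G) and shared across SNPs and
  replicates; matrix powers per gap are cached per model.  This is the
  decisive performance lever of the scan.
* All randomness flows from one root seed through named substreams; equal
  seeds give bit-identical outputs everywhere, including VCF/TSV writers.
* Degenerate cases: a SNP with no observed copies at any generation is
  flagged untestable rather than scored; a chromosome whose Lindley track
  never reaches the threshold returns no regions; a monomorphic-only GRM
  input raises; relatedness filtering breaks ties (equal inbreeding) by
  sample id so retained sets are reproducible.
* Merging on (chrom, pos) reconciles swapped ref/alt by recoding and logs
  it, but never at strand-ambiguous SNPs, which instead pass through
  unrecoded for the discordance flag (frequency ≥ 1−ε in one source and
  ≤ ε in another, ε = 0.05) to catch — mirroring how such inversions are
  actually discovered, post hoc, as impossibly discordant frequencies.

## Known limitations

* The HMM treats loci independently; linked-site joint likelihoods are out
  of scope, and the local score reintroduces spatial information only
  through the p-value sequence.
* χ²(1) calibration degrades for short series (< 4 sampled generations) and
  near-fixed SNPs even above the MAF filter.
* The nSL implementation is O(n² m) in haplotypes × SNPs; it is meant for
  panels of tens of haplotypes and thousands of SNPs per chromosome, not
  biobank scale.
* Ne estimation assumes neutrality of the bulk of loci; strong pervasive
  selection would bias it downward (apparent extra drift).
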