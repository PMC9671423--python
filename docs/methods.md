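# Methods

## The statistical problem

Genome-wide association studies (GWASs) identify regions of the genome
associated with a complex trait. A natural question is whether those
regions carry unusual signatures of selection — elevated sequence
conservation (PhyloP, PhastCons, LINSIGHT), population differentiation
(F_ST), recent positive selection (XP-EHH), balancing selection (Beta
Score), or unusual allele age. Comparing trait-associated regions to the
genome-wide average of such a measure is misleading, because the genomic
attributes that drive ascertainment and power in a GWAS — allele frequency
and linkage disequilibrium (LD) above all — also shape the expected value
of most evolutionary measures. The framework implemented here builds, for
each trait, an empirical null distribution from background regions matched
on exactly those attributes, and expresses enrichment on a scale comparable
across measures.

## Pipeline

1. **Clumping** (`evoenrich.clumping`). Variants with association
   p < 5×10⁻⁸ are reduced to independent trait-associated regions by greedy
   p-value-ordered LD clumping: the unassigned variant with the smallest
   p-value becomes a region lead, and every unassigned significant variant
   on the same chromosome within 500 kb and with r² ≥ 0.9 to the lead joins
   its region. Both boundaries are inclusive. Ties on the lead p-value
   break by chromosome label, position, then variant id. Significant
   variants absent from the LD reference are dropped with a logged count
   rather than promoted to singleton regions of unknown LD.

2. **Matched backgrounds** (`evoenrich.matching`). For each region,
   `n_sets` (default 5,000) control lead variants are sampled from the
   genome-wide SNP universe, matched to the region's lead on four
   properties:

   | property | band | strictest → most liberal |
   |---|---|---|
   | minor allele frequency | absolute, ± percentage points | 1, 2, 3, 4, 5 |
   | LD buddies (r² > 0.9 partners) | relative ± | 2%, 4%, 6%, 8%, 10% |
   | gene density (genes in a 2 Mb window) | relative ± | 10%…50% |
   | distance to nearest gene (bp) | relative ± | 10%…50% |

   Matching is attempted five times, strictest band first; the first level
   with a nonempty candidate pool is used. Controls are drawn without
   replacement when the pool holds at least `n_sets` candidates, otherwise
   with replacement (flagged). Each control is extended with
   `(region size − 1)` LD partners drawn uniformly from its r² > 0.9
   buddies, so every matched region mirrors its trait region's variant
   count; candidates are pre-filtered to those with enough buddies whenever
   that leaves at least `n_sets/10` of them, and residual shortfalls are
   flagged per replicate. A region with an empty pool at the most liberal
   level is discarded from all further analysis. Every region draws from
   its own seeded random stream keyed on (master seed, lead id), so results
   do not depend on region order.

3. **Scores and enrichment** (`evoenrich.enrichment`). A region's score for
   a measure is its *region-average*: the member annotation value of
   greatest absolute magnitude, sign retained (a tie between −x and +x
   resolves to +x; configurable via the documented tie rule, deterministic
   under both orderings). The trait-level statistic is the mean of region
   scores; regions with no annotated member are excluded from both the
   observed and the background mean (paired exclusion, keeping the two
   exchangeable). Each matched replicate yields the same statistic over its
   control regions, giving an empirical background distribution of `n_sets`
   means. The two-sided empirical p-value counts replicates at least as far
   from the background mean as the observed value, with a +1 pseudo-count:
   p = (c+1)/(n+1), so the floor at 5,000 replicates is 1/5001.
   Standardized enrichment is
   (observed mean − background mean) / genome-wide SD of the measure,
   where the SD is the sample SD over all annotated SNPs in the store
   (SNP level — the only genome-wide quantity available); positive values
   mean enrichment, negative depletion. Benjamini–Hochberg FDR adjustment
   is applied per trait across measures (single-GWAS mode), per measure
   across traits (atlas mode), or globally.

4. **Stratification and convergence** (`evoenrich.stratify`). Regions can
   be partitioned into quantile bins of the lead's signed effect size
   (most negative to most positive) or p-value — equal counts, remainder to
   the earliest bins — and the enrichment recomputed per bin against the
   aligned matched entries. The undersampling analysis subsamples regions
   without replacement (a flag switches to with-replacement) and tracks how
   the observed mean and background percentiles stabilize with region
   count.

## Synthetic data generator

`evoenrich.fixtures` produces complete, internally consistent input bundles
with known ground truth; every test and the acceptance script run on them
without any download. The generator emulates the structure the framework
relies on, not human population history:

* **LD blocks.** Disjoint blocks (default 2,000 blocks of 25 SNPs) with
  pairwise within-block r² = 0.7 + 0.3·Beta(6, 1) and zero between-block
  LD. Disjoint blocks keep the brute-force clumping oracle exact and the
  matching pools unambiguous.
* **Allele frequencies.** A block-level MAF drawn from
  0.01 + 0.49·Beta(1.2, 3), jittered per SNP (SD 0.015): variants in strong
  LD share similar allele frequencies. This block correlation is what makes
  trait-associated regions systematically common-variant regions, and hence
  what a naive genome-wide background gets wrong.
* **Gene map.** Exponential intergenic gaps (mean 20 kb) and uniform gene
  lengths (5–50 kb); gene density counts genes overlapping a 2 Mb window,
  distance is 0 inside a gene. Matching properties are recomputed from the
  emitted LD and gene files, so the property table is exactly
  self-consistent.
* **Association signal.** Trait blocks are ascertained with probability
  proportional to mean block heterozygosity, and the lead within a block
  proportional to SNP heterozygosity — the power profile of a GWAS. Leads
  get p = 10^−U(8.5, 20); their r² ≥ 0.9 buddies get p = 10^−U(7.5, lead),
  i.e. genome-wide significant members, shared effect direction; all other
  SNPs are null.
* **Annotations.** Per measure, a Gaussian base (signed measures) or
  half-Gaussian base (non-negative, conservation-like), with ~5% missing
  values. `confounder_strength` adds a standardized linear term in
  logit-MAF and LD-buddy count — confounding without any trait link.
  `planted_delta` shifts every SNP in trait blocks by delta × genome-SD;
  because the shift is uniform within a region and the planted measure
  non-negative, the region-average moves by exactly the shift, so the
  standardized enrichment estimates delta directly.

What the generator does **not** emulate: realistic haplotype structure and
recombination (blocks are disjoint and r² values are not constrained to a
valid correlation matrix), population structure and stratification,
realistic marginal distributions of the eleven published measures, or
between-measure correlation. Passing tests therefore demonstrate the
statistical machinery — clumping semantics, matching fidelity, calibration
under MAF/LD confounding, recovery of planted signal — not robustness to
every pathology of real GWAS summary statistics.

## Study conditions and problem sizes

* **Matching audit**: the standard genome (2,000 × 25 = 50,000 SNPs,
  50 trait blocks) with the full 5,000 replicates per region.
* **Null calibration**: 200 independently resampled null traits
  (confounder strength 1, planted shift 0, 20 regions per trait) on a
  15,000-block × 8-SNP genome (120,000 SNPs), 500 replicates per region,
  against both matched and naive backgrounds, scored on the signed measure.
* **Recovery**: planted shifts of 0.5, 1 and 2 genome-SD at 50 trait
  regions, 50 replicate traits per shift, 500 replicates per region, on an
  8,000-block × 8-SNP genome, scored on the non-negative measure.

The calibration genome is deliberately the largest of the three: the
method accepts the first tolerance level with *any* candidate, and on a
small SNP universe the strictest bands can leave only a handful of
candidates, collapsing the background onto a few atoms and understating its
sampling variance. With ~10⁵ SNPs the strictest-level pools are typically
tens to thousands of candidates and the empirical p-values are uniform
under the null. This mirrors the intended regime of the method, whose
real-data universe is ~9.5 million SNPs; undersized universes are a known
limitation, visible in the match report's pool sizes.

## Numerical and design choices

* p-values of exactly 0 are rejected at read time (opt-in clamping to
  1e-300) — silent clamping hides corrupt inputs.
* Missing annotations are absent values (NaN), never numeric sentinels;
  coverage and genome SD are computed over annotated SNPs only.
* GWAS/LD/property tables use 1-based positions; BED is 0-based half-open
  and converted at read time (a SNP whose 1-based position equals a BED
  `end` sits on the interval's last covered base).
* Band comparisons are inclusive with a 1e-9 relative slack so boundary
  candidates are not lost to float rounding; the slack is far below any
  band width of interest.
* The empirical p-value uses "as or more extreme" (≥) and a +1
  pseudo-count; a zero-variance background with a matching observed value
  gives p = 1. A constant measure yields enrichment 0 (zero difference)
  rather than a 0/0 error.
* All randomness flows from one master seed through named
  `SeedSequence` streams (per region, per trait, per study), so outputs are
  bit-reproducible and order-independent; file outputs are canonically
  sorted and serialized at full precision (results tables at 6 significant
  digits).

## Known limitations

* Only the mean is implemented as the trait-level summary (the interface
  is pluggable but untested for alternatives).
* The matched background corrects for the four matching properties only;
  residual confounders (e.g. recombination rate, background selection) are
  out of scope.
* With 200 simulated traits the rejection-rate estimate itself has a
  binomial SD of ~0.015 at a true rate of 0.05, so repeated runs of the
  calibration study scatter accordingly.
* The region-average is a maximum-based statistic; its value grows with
  region size, which is why matched regions always mirror the trait
  region's variant count and why shortfalls are tracked explicitly.
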