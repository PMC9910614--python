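# Methods

## The scan

The pipeline targets the classical signature of a recent hard sweep: an
allele that rose quickly leaves unusually long, unusually homogeneous
haplotypes around it, and unusually large allele-frequency divergence from
populations that did not experience the sweep.

**EHH and iHH.** For a core SNP and a set of carrier haplotypes, EHH at a
position x is the probability that two randomly drawn carriers are identical
at every SNP between the core and x. We track it incrementally: carriers
start in one group and are split as sites are added outward; EHH is
`Σ c_g(c_g−1) / k(k−1)` over group sizes. iHH is the trapezoidal integral of
EHH over genetic distance (cM), per side, down to the point where EHH
crosses a floor (0.05 by default), with the final segment linearly
interpolated to the crossing. A side that hits the chromosome end or a
physical gap larger than `max_gap` (200 kb) before reaching the floor
invalidates the core for iHS/XP-EHH — the integral would be censored.
These floor and gap defaults are the established community defaults for
haplotype scans; both are configurable.

**iHS** = `ln(iHH_ancestral / iHH_derived)` at cores with focal minor allele
frequency above `maf_haplo` (default 0.05). Negative values mean long
derived haplotypes. Raw scores are z-standardized within 50 equal-width
derived-allele-frequency bins (bins with <20 sites are merged toward the
interior) because the expected iHH ratio depends on allele frequency.

**XP-EHH** = `ln(iHH_focal / iHH_reference)` with allele-agnostic cores: all
haplotypes of a population start in a single group (EHH(0) = 1; the core's
own alleles do not split it). Computed against the more diverged reference
by default, at sites with MAF > `maf_haplo` in both populations, and
standardized genome-wide (per-frequency-bin standardization is available by
flag).

**F_ST and PBS.** Per-SNP Weir & Cockerham (1984) variance-components
estimator on haploid (haplotype) counts; a per-SNP estimator is required
because PBS is a per-SNP transform, so no ratio-of-averages smoothing is
applied. Negative estimates are floored at 0 and values are capped at
1 − 1e−8 before `T = −ln(1 − F_ST)`;
`PBS = (T_f,r1 + T_f,r2 − T_r1,r2)/2` at sites with MAF > `maf_pbs`
(default 0.01) in all three populations. PBS is not floored at zero: a
negative focal branch is informative and the downstream ranking is
upper-tail anyway.

**FCS.** Each statistic is ranked over its valid sites, extreme first —
|iHS| (two-sided: sweeps produce both signs), XP-EHH upper tail, PBS upper
tail — with average ranks for ties; `p = rank/(N+1)` keeps log-p finite;
`FCS = −2 Σ ln p`. By default a site needs all three statistics valid
(`min_stats = 3`) so FCS is on a common scale; sites valid for fewer are
dropped rather than rescaled.

**Windows and regions.** The genome is tiled into half-open 50-kb windows
(tail windows kept, flagged partial). Windows with fewer than
`min_window_snps` (10) FCS sites are ineligible. Approach A calls windows
whose count of top-`q_site` (1%) FCS SNPs strictly exceeds the top-`q_winA`
(1%) count quantile; approach B calls windows whose median FCS strictly
exceeds the top-`q_winB` (0.5%) quantile. Strict exceedance makes the
degenerate constant-FCS field call nothing. The union (with per-window
provenance) is collapsed into nonoverlapping candidate regions, merging
book-ended windows by default. Candidate genes are those overlapping a
region; a wider list records genes whose transcript start or end lies
within 250 kb (boundary inclusive). Trait enrichment of candidate genes
uses the upper-tail hypergeometric test with BH correction across traits,
restricted to traits with more than six associated genes.

## Polygenic selection tests

A trait's window set is either the 50-kb windows containing a GWAS hit with
p strictly below 5e−8, or the windows intersecting the coding span ±10 kb
of any gene in a curated (e.g. virus-interacting) list. The observed
statistic is the median over trait windows of the window median FCS.

*Scheme 1 (matched windows):* each trait window is replaced by a uniformly
drawn non-trait window from the same joint quartile stratum of
(n_snps, n_conserved_snps, mean_recomb_rate); quartile edges are computed
over all eligible windows (trait windows included) so strata are identical
across traits. Sampling is without replacement within a draw and with
replacement across draws. A stratum whose non-trait pool is smaller than
5× its trait-window count is relaxed to a 2-of-3 covariate match (logged);
if still unfillable the test aborts loudly rather than silently degrade.
*Scheme 2 (matched genes):* resample the same number of genes from the
non-focal universe, expand to windows, take the median — this preserves the
adjacency structure of gene-derived window sets.

The empirical p is the proportion of null draws whose median is strictly
higher than observed, so the minimal attainable p is 0; a `(k+1)/(n+1)`
correction is available by flag but off by default to match the strict
definition. BH FDR at 10% across traits; traits whose testable-window count
is ≥10-fold below the across-trait median are flagged (not dropped).

## The synthetic-data generator

A forward-time diploid Wright–Fisher simulator with a ladder demography of
one to three populations (the last population branches first), per-population
bottlenecks, optional symmetric migration, infinite-sites mutation on a
discrete bp grid (occupied positions redrawn), and crossover from a uniform
rate or a piecewise genetic map. A hard sweep assigns fitness
1 / 1+hs / 1+2s to the derived allele in the target population, introduced
as a new mutation (or standing variant) at a configured time; replicates are
replayed from the injection generation until the final frequency lands in a
configured band.

Runtimes are kept at desk scale by N_e rescaling: population sizes are
~0.01× human-like values and per-generation mutation and recombination rates
are scaled up to preserve θ = 4Nμ and ρ = 4Nr per bp (defaults:
θ ≈ 4.5e−4/bp, ρ ≈ 5e−4/bp). Genetic maps are therefore in *rescaled* cM;
since iHS/XP-EHH are log-ratios and standardized, the unit cancels. The
burn-in is seeded with a draw from the neutral equilibrium site-frequency
spectrum (E[ξ_i] ∝ 1/i) at linkage equilibrium, then run for
`burn_in_factor × N` generations (4N in the default configuration) to build
linkage structure — equilibrium diversity from the first generation,
equilibrium LD after a few N generations, at a fraction of the cost of a
cold 10N burn-in (the factor remains configurable, and 10N is the
conservative choice for non-warm starts).

The default three-population configuration mimics the intended use case: an
ancestral population (N = 80 rescaled) splits 50 (rescaled) generations ago
into a diverged reference and an intermediate ancestor, which splits 30
generations ago into the focal population (founding bottleneck to N = 50
for 10 generations, then N = 100) and a close reference. Realized
differentiation is moderate: mean per-SNP F_ST ≈ 0.06 focal–close
reference, ≈ 0.09–0.11 against the diverged reference.

What the generator emulates: phased biallelic SNPs with known ancestral
states, shared and private variation with realistic SFS shape, LD decay on
the scale set by ρ, drift-driven F_ST noise, hitchhiking and partial/complete
sweeps, plus annotation layers (Poisson conserved elements, non-overlapping
genes, log-normal piecewise recombination maps, GWAS hits, virus gene
lists). What it does not emulate: genotyping-array ascertainment (the site
frequency spectrum is sequencing-like, so joint-common site density is lower
than array data), mutation-rate and recombination hotspot fine structure,
gene conversion, background selection, soft sweeps from multiple origins,
admixture and phasing error. Passing tests therefore demonstrate correctness
and calibration of the *method* under a faithful neutral/sweep model, not
performance on any particular real dataset.

## Calibration and power (what the checks mean)

- Standardized iHS on neutral data has |iHS| > 2 at close to the normal
  tail rate (measured ≈ 0.044 vs 0.0455). The comparison interval is a
  binomial CI at the scale of one replicate's site count: sites within a
  replicate share genealogy, so pooling sites would overstate precision.
- Under an exchangeable null (statistics permuted across sites), the three
  rank p-values at a site are independent and FCS is χ²₆; its tail
  probabilities pass KS uniformity. On *unpermuted* neutral data the three
  statistics are correlated through the shared genealogy, so FCS is
  deliberately interpreted by rank, never by a χ² p-value.
- Outlier-window false-positive rates follow the configured quantiles up to
  the discreteness of a ~95-eligible-window genome: approach B's strict
  top-0.5% rule calls exactly the top order statistic (rate 1/n), approach
  A's tied counts call at most the nominal fraction.
- Sweep-recovery power is measured on a 2-Mb mini-genome with the sweep at
  a window midpoint, conditioned on an ongoing sweep (final frequency
  0.70–0.95). Near-fixed sweeps strip the core window of MAF-passing sites —
  the known blind spot of frequency-filtered haplotype statistics — and the
  calling quantiles are opened to 12% / min 5 SNPs because 40 windows cannot
  emulate the tail resolution of a genome-wide tiling. Measured power at
  s = 0.5 (rescaled; Ns = 50) is ≳0.9, and detection is monotone in s.
- Neutral-null percentiles: a window *median* is a much tighter statistic
  than a single site's FCS, so queries are ranked in a pooled null of
  like-for-like window medians; held-out neutral windows rank uniformly,
  and the peak window of a strong sweep's footprint exceeds the 99th
  percentile in the large majority of replicates.

## Numerical and degenerate-input conventions

- Coordinates are 0-based half-open everywhere in memory; VCF (1-based) and
  ancestral tables are converted at the boundary.
- Half-called phased genotypes (`.|1`) are treated as missing for both
  haplotypes of the individual; haplotypes missing at an allele-specific
  core are excluded from the carrier set; a missing call at a visited site
  breaks haplotype identity (matches nobody). Sites with >10% missing
  haplotypes in any population are dropped up front (configurable).
- Undefined statistics are NaN plus an explicit validity flag, never a
  silent zero; log-ratios guard against zero and infinite iHH.
- All randomness flows from a single `numpy.random.Generator`; population
  iteration orders are explicitly sorted so identical seeds give
  bit-identical output across processes.
- The EHH kernels are numba-compiled; a pure-NumPy reference path
  (`ehh_decay`/`integrate_ihh`) computes the same quantities and the test
  suite asserts exact agreement between the two.

## Known limitations

- Per-SNP W&C F_ST at n = 100 haplotypes is noisy; PBS inherits that noise,
  which is why the scan leans on the FCS combination rather than any single
  statistic.
- Rescaling caps the attainable Ns: real strong sweeps (Ns ~ 10²–10³ at
  human N_e) are represented by s up to ~0.5 at N = 100, i.e. Ns ≤ 50.
- The matched permutation's 2-of-3 fallback can let pools from neighboring
  strata overlap within a draw; exact within-draw exclusivity holds only for
  full three-covariate strata.
- Multi-chromosome inputs are handled by running the scan per chromosome
  and concatenating tables before ranking; the simulator emits one
  chromosome per call.
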