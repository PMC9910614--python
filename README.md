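# sweepscan

Haplotype-based scans for recent positive selection in one focal population
against one or two reference populations, and permutation tests for polygenic
selection — with a built-in forward-time simulator so the entire pipeline can
be exercised, calibrated and tested on fully synthetic data.

The package is aimed at population geneticists studying recent adaptation in
small, historically bottlenecked populations (for example indigenous South
American groups scanned against 1000 Genomes reference panels), where
individual-level data are typically access-restricted and methods must be
validated on simulations.

## What it computes

For every biallelic SNP in phased, ancestral-polarized data:

- **iHS** — the integrated haplotype score, `ln(iHH_A / iHH_D)`, where
  `iHH_A` and `iHH_D` integrate the extended haplotype homozygosity (EHH)
  decay around the ancestral- and derived-allele carriers over genetic
  distance, truncated at EHH = 0.05. Standardized within derived-allele
  frequency bins.
- **XP-EHH** — `ln(iHH_focal / iHH_ref)` with allele-agnostic cores,
  standardized genome-wide; detects sweeps complete or nearly complete in
  the focal population.
- **PBS** — the population branch statistic
  `(T_f,r1 + T_f,r2 − T_r1,r2)/2` with `T = −ln(1 − F_ST)`, from per-SNP
  Weir & Cockerham F_ST on haplotype counts; the length of the focal branch
  on the three-population tree.

The three statistics are summarized per SNP as a **Fisher's combined score**
(FCS): each statistic is ranked genome-wide (extreme first), converted to an
empirical p-value `rank/(N+1)`, and combined as `−2 Σ ln p`. The genome is
tiled into 50-kb windows and outlier windows are called by two approaches —
(A) windows enriched for top-1% FCS SNPs, (B) windows with top-0.5% median
FCS — whose union is collapsed into nonoverlapping candidate regions and
annotated with overlapping genes and genes within 250 kb.

Downstream, the package tests a priori trait-associated window sets
(GWAS-hit windows, or windows touching virus-interacting genes ±10 kb) for
elevated median FCS against nulls matched on SNP count, conserved-SNP count
and recombination-rate quartiles (10,000 resamples, BH FDR), and compares
candidate-region scores against a simulated neutral FCS distribution.

## Worked example

Everything runs from a synthetic fixture — no external data needed:

```bash
sweepscan simulate --seed 7 --sequence-length 2000000 --out fixture/
sweepscan scan --vcf fixture/panel.vcf --samples fixture/samples.yaml \
    --genetic-map fixture/genetic_map.txt --ancestral fixture/ancestral.tsv \
    --out scan/
sweepscan regions --scan-table scan/fcs.tsv --chrom-length 2000000 \
    --genes fixture/genes.tsv --out regions/
```

which prints

```
wrote fixture bundle to fixture
scan: 11679 sites, 948 FCS sites -> scan
2 outlier windows -> 2 regions
```

The scan found 11,679 biallelic SNPs shared by the three simulated
populations; 948 passed every per-statistic filter (iHS valid at 2,145
sites, XP-EHH at 1,140, PBS at 1,224 — FCS requires all three) and received
a combined score. Two 50-kb windows exceeded the outlier thresholds and
collapsed to two candidate regions; `regions/regions_annex.tsv` lists each
region with its median FCS (here 9.17 and 8.92 against a genome median of
~5) and its overlapping and nearby genes:

```
chrom  start    end      n_windows  median_fcs  overlapping_genes        ...
chr1   750000   800000   1          9.167       G0026,G0027,G0028,G0029  ...
chr1   1050000  1100000  1          8.924       G0037,G0038              ...
```

The `polygenic` subcommand runs the matched-window permutation test on GWAS
hit tables and virus gene lists from the same fixture bundle, and `nullcmp`
ranks candidate regions against a freshly simulated neutral FCS null.

In the library, the same pipeline is three calls:

```python
from sweepscan import (default_demography, simulate_panels, compute_scan,
                       ranks_to_fcs)
demog = default_demography(2_000_000)
panels, truth = simulate_panels(demog, seed=7)
scan = compute_scan(panels["focal"], [panels["ref1"], panels["ref2"]],
                    demog.genetic_map())
fcs = ranks_to_fcs(scan)
```

## Layout

- `sweepscan.io` — phased VCF (via cyvcf2), ancestral-allele tables and
  polarization, genetic maps, BED masks, gene tables; all coordinates
  0-based half-open internally.
- `sweepscan.ehh` / `sweepscan.stats` — EHH/iHH kernels (numba), iHS,
  XP-EHH, F_ST, PBS, standardization, the per-chromosome scan driver.
- `sweepscan.windows` — FCS, window tiling/annotation, outlier calling,
  region collapsing, gene annotation, hypergeometric trait enrichment.
- `sweepscan.polygenic` — trait/virus window sets, quartile matching, both
  permutation schemes, BH FDR.
- `sweepscan.simulate` — rescaled forward Wright–Fisher simulator with hard
  sweeps, annotation generators, neutral FCS null, power curves.
- `sweepscan.cli` — `sweepscan simulate|scan|regions|polygenic|nullcmp`.

See `docs/methods.md` for the model, parameter choices and limitations.
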