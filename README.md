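# pmdkit

Partially-methylated-domain (PMD) detection and paired-tumor methylome
heterogeneity analysis for whole-genome bisulfite sequencing (WGBS) data.

## The problem

Cancer genomes lose methylation in broad (100 kb-scale) blocks — partially
methylated domains. This global hypomethylation is most visible at
**solo-WCGW CpGs**: CpGs flanked by A/T on both sides (the W-C-G-W context)
with no neighbouring CpG within ±35 bp. In tumor cohorts, PMD
hypomethylation dominates the variance between methylomes and can swamp the
focal, gene-regulatory methylation differences an analyst is usually after.
`pmdkit` implements the full workflow for dealing with this in a cohort of
paired tumors (e.g. primary and recurrent disease from the same patients):

1. **Per-sample PMD calling.** The genome is tiled into non-overlapping
   100 kb bins; each bin's mean solo-WCGW methylation β is transformed to an
   M-value, `M = log2(β / (1 − β))`, and the per-sample M-value distribution
   is fit with a 3-component Gaussian mixture (EM, unequal variances,
   restarts). Components are labelled *low / intermediate / high* by
   ascending mean; a bin is a PMD bin when its posterior probability of the
   *high* (fully methylated) component is < 0.01, and consecutive PMD bins
   merge into domains.
2. **Cohort-common PMDs and masking.** Bins called PMD in ≥ 10 samples form
   the cohort-common PMD set, optionally united with an external common-PMD
   catalog; CpGs inside the combined set are masked out of downstream
   analyses, and each sample receives a *solo-WCGW score* (mean solo-WCGW β
   inside the combined set) summarising its PMD hypomethylation depth.
3. **Heterogeneity.** PCA on the top 10,000 most variable CpGs (coverage
   ≥ 10 in every sample), Pearson correlation of PC1 with the solo-WCGW
   scores, pairwise Euclidean distances with intra- vs inter-patient
   comparison (one-sided Mann–Whitney U), mQTL intersection and
   hypergeometric tests for gene sets inside PMDs.
4. **DMR post-processing.** Differentially methylated regions from an
   external caller (metilene-style tables) are filtered to regions shared by
   ≥ 2 patients, merged within 250 bp (bedtools `-d 250` semantics),
   classified as concordant or discordant by the signs of per-patient
   methylation deltas (recurrent − primary), and tested for annotation
   enrichment against random backgrounds matched on region size — or on
   size *and* CpG count — with calls at > 15 % change from background.
5. **DMR-to-gene linking.** Transcripts are filtered (> 300 bp, TPM > 0.05,
   isoform share > 1 %, expressed in > 5 samples, blacklist removed); DMRs
   within 2 kb of a TSS link to the closest gene ("promoter"), distal DMRs
   to the 10 nearest genes on each side; per link, Spearman correlation of
   per-patient methylation and expression changes, retained at p < 0.05.

A fully seeded synthetic cohort generator (`pmdkit.simulate`) produces
paired methylomes with planted PMDs, planted DMRs of known concordance, and
transcript expression with planted methylation–expression links, so every
stage is testable end-to-end with known truth.

## Worked example

```python
import pmdkit as pk

cfg = pk.CohortConfig(seed=1, n_patients=4,
                      chrom_sizes={"chr1": 2_000_000, "chr2": 2_000_000},
                      n_genes=40)
cohort = pk.simulate_cohort(cfg)

sample = pk.filter_by_coverage(cohort.samples["pt01_P"], min_cov=5)
profile = pk.bin_solo_wcgw_means(sample, cohort.sites, cohort.truth.grid)
m_values = pk.beta_to_m(profile.informative["mean_beta"].to_numpy())
fit = pk.fit_gmm3(m_values, seed=1)
calls = pk.call_pmds(profile, fit, p_high_cutoff=0.01)

frac = pk.pmd_genome_fraction(calls, cohort.genome.chrom_sizes)
truth = cohort.truth_pmds["pt01_P"]
jac = (calls.intervals.intersect(truth).total_length()
       / calls.intervals.union(truth).total_length())
print(f"component means (M): {fit.means_.round(2)}")
print(f"component weights:   {fit.weights_.round(2)}")
print(f"PMD genome fraction: {frac:.3f}")
print(f"Jaccard vs truth:    {jac:.3f}")
```

prints

```
component means (M): [-0.18  0.92  2.89]
component weights:   [0.17 0.05 0.77]
PMD genome fraction: 0.225
Jaccard vs truth:    1.000
```

The three mixture components sit at M ≈ −0.2 and 0.9 (deep and shallow PMD
bins, β ≈ 0.47 / 0.65) and M ≈ 2.9 (the methylated background, β ≈ 0.88).
22.5 % of this sample's genome is called PMD, and the calls exactly tile the
planted domains (Jaccard 1.0).

The same workflow is available from the shell:

```bash
pmdkit --seed 1 simulate --set n_patients=4 --out sim/
pmdkit --seed 1 run-all --out run/        # simulate → PMDs → masking → PCA → DMRs → links
```

`run-all` writes a `manifest.json` with parameters, seeds and per-stage
output checksums; rerunning with the same seed reproduces the checksums
byte-for-byte.

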