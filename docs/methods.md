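# Methods

This note documents the models, conventions and numerical choices behind
`pmdkit`, and what the synthetic-data generator does and does not emulate.

## Coordinates and sequence conventions

All genomic intervals are 0-based half-open (BED semantics); a CpG site is
identified by the 0-based plus-strand position of its C. The solo-WCGW
definition used throughout: the base before the C and the base after the G
are both A or T, and no other CpG's C lies within ±35 bp, measured C-to-C
and inclusive at the boundary. The neighbourhood arithmetic (C-to-C vs
interval overlap, inclusive vs exclusive) is not uniquely fixed by the
literature; C-to-C inclusive is the simplest testable reading, the window is
a parameter, and the chosen rule is verified against brute-force scanners in
the test suite. The WCGW context is palindromic, so the solo-WCGW set is
invariant under reverse complement (tested). N bases never form CpGs and
disqualify the WCGW context. CpGs at chromosome edges with a missing flank
are never solo-WCGW.

Strand collapsing: records at positions p and p+1 of a CpG are pooled with
coverage-weighted β, which equals recomputing β from pooled read counts.
Whether to collapse before binning is an analysis choice; both paths are
supported and collapsing is the default.

Missing CpGs (uncovered, low-coverage or masked) are absent records, never
zeros: all downstream code distinguishes "unmethylated" from "unobserved".

## PMD calling

Per sample: mean β of covered solo-WCGW CpGs in non-overlapping 100 kb bins
(bins with < 10 informative CpGs are missing — the floor guards the mixture
against 1-CpG bins); M = log2(β/(1−β)) with β clipped to [1e-3, 1−1e-3]
(bin means of exactly 0 or 1 occur in small genomes and the transform is
undefined there); then a 3-component univariate Gaussian mixture fit by EM.

EM details: unequal component variances (the most general univariate
choice), k-means++-style initialisation on the data points, 10 restarts
keeping the best final log-likelihood, convergence at relative
log-likelihood change ≤ 1e-8, max 1000 iterations, variance floor 1e-6
(engaged rather than fatal when a component tightens onto near-duplicate
values; a restart is triggered only when a component's responsibility mass
vanishes or the likelihood becomes non-finite). The per-iteration
log-likelihood trace is stored and is non-decreasing by construction; the
suite asserts this and compares fitted means against an independently coded
naive EM. Fits require ≥ 30 informative bins and are strictly per sample,
never pooled.

Components are labelled low/intermediate/high by ascending mean *after*
fitting, so calls are invariant to component permutation. A bin is PMD iff
its posterior P(high) < 0.01 (strict); missing bins are never PMD and break
runs (a configurable `max_gap_bins`, default 0, can bridge missing bins —
whether the original procedure tolerated gaps is unknowable from published
descriptions, so strict adjacency is the default). Consecutive PMD bins
merge into one domain. Terminal partial bins participate when they meet the
CpG floor, and their true (shorter) extent is used in genome-fraction math.

## Cohort-level PMDs

PMD frequency is counted on the bin grid (calls are unions of bins, so
bin-level counting is lossless). Common PMDs are bins with count ≥ 10
("more than 9 samples"); the threshold is a config knob because the
inflection-point heuristic sometimes used to pick it is not an algorithm —
the frequency histogram is emitted as data and the choice is left explicit.
The combined mask is the union of cohort-common PMDs and an external
common-PMD catalog, with per-base provenance (cohort-only / external-only /
both) and span fractions recomputed for whatever inputs are supplied.
External interval sets are validated only for chromosome names; assembly
liftover is out of scope.

The solo-WCGW score of a sample is the unweighted mean β over covered
solo-WCGW CpGs inside the combined set — a single number summarising PMD
hypomethylation depth.

## Heterogeneity

The CpG matrix is complete-case: sites with coverage ≥ 10 in *every*
sample, ranked by cross-sample variance with a deterministic
(variance, chrom, pos) tie-break, top 10,000 kept. PCA and distances run on
β values (β is the unit in which the data are reported; M-values are a
per-sample modelling device here), column-centred and unscaled; PC signs are
fixed by making each PC's largest-magnitude loading positive. Explained
variance fractions are non-increasing and rank-deficient input truncates to
the available components.

Intra- vs inter-patient distances are compared with a one-sided
Mann–Whitney U (intra < inter): the published analyses report p-values
without naming a test, a rank test needs no distributional assumption on
Euclidean distances, and its exact small-sample null is enumerable in tests.
scipy's exact method is used for small tie-free samples, the tie-corrected
normal approximation otherwise; results are labelled with the test used.

Gene-in-PMD membership uses any-bp overlap (simplest, testable; fractional
overlap is a config option). The hypergeometric p is the exact tail
(enrichment: P(X ≥ k); depletion: P(X ≤ k)) and is verified against
exhaustive enumeration on small universes. mQTL intersection filters at
p < 5.0e-8 strictly and intersects positions exactly.

## DMR post-processing

Input is metilene-style per-patient tables; the caller itself is not
reimplemented. Sharing: records are clustered into connected overlap
components (≥ 1 bp, half-open, so abutting regions do not overlap);
components with ≥ 2 distinct patients are retained. Merging follows
bedtools `-d` semantics (gap ≤ 250 bp merges transitively), verified
against a reference implementation including the 250/251 boundary.

Delta convention: **recurrent − primary** mean β, so positive = gains
methylation at recurrence; output headers state this. Discordance: a shared
region is discordant when at least one patient delta is positive and one
negative (a magnitude floor `min_abs_delta` is available, default 0 — no
published magnitude filter exists); all-zero deltas are "null-change". The
four statuses partition the shared set.

Matched backgrounds: per query, `n_per_query` random intervals of exactly
the query's length, placed uniformly on size-weighted chromosomes, avoiding
the query set (sampled intervals may overlap each other — shuffle-style
nulls behave the same and the statistic is a mean). In size-plus-CpG mode,
draws are rejection-sampled until the CpG count is within ±10 % (relative)
of the query's; queries unmatched within the try budget are excluded and
reported. The enrichment metric is the fraction of regions with ≥ 1 bp
annotation overlap (base-pair fraction is a config option); percent change
is 100·(obs − bg)/bg with calls at strictly > +15 % (enriched) or
< −15 % (depleted). The strict threshold is guarded by a 1e-9 epsilon so a
computed value landing exactly on the boundary is never called. A zero
background mean leaves the change undefined rather than infinite.

## Expression linking

Transcript filter: length > 300 bp, and (TPM > 0.05 AND isoform share
> 1 %) in ≥ 6 samples — the conjunction is the strictest consistent reading
of the published thresholds and each piece is a parameter — plus blacklist
removal. Gene expression is log2(sum of retained transcript TPMs + 1): a
transparent variance-stabilising summary chosen over package-specific
normalisations; it is monotone in expression, so rank-based link statistics
are unaffected by the exact transform.

Candidate geometry: distance is TSS-to-DMR-edge (0 when the TSS falls
inside the DMR), matching the promoter rule's geometry; promoter DMRs
(distance < 2 kb, strict, ties resolve distal) link only to the closest
gene, distal DMRs to ≤ 10 genes per side with (distance, gene_id)
tie-break. Links are Spearman correlations over per-patient
(Δ methylation, Δ expression) pairs restricted to the patients in which the
DMR was identified, retained at two-sided p < 0.05 on the raw p-value (the
published rule); Benjamini–Hochberg q-values are reported alongside so a
caller can choose the stricter column. Constant vectors leave ρ undefined
and the link is discarded with a reason.

## The synthetic cohort generator

What it emulates: a random genome with CpG-dense islands at TSSs and
isolated WCGW-context CpGs between them (mean spacing 500 bp; 5 % of
incidental background CpGs retained); a genome-level "PMD-capable" subset
of bins (40 % of full bins) from which each patient draws PMDs — capping
the capable fraction reproduces the strong cross-tumor sharing of real PMD
landscapes and leaves PMD-free space for planting DMRs; per-sample PMD span
~ Normal(0.30, 0.05) truncated to [0.05, 0.6]; in-PMD solo-WCGW β with a
per-sample depth (Normal(0.55, 0.10)) and a per-bin deep/shallow offset of
±0.12 — PMD hypomethylation in real tumors is itself heterogeneous across
domains, and this bimodality is exactly the low/intermediate structure the
3-component mixture separates from the β ≈ 0.88 background; island CpGs
near β = 0.08, other CpGs near 0.85 (Beta distributions with concentrations
20–40). Reads: coverage ~ Binomial(40, 0.75) (mean 30×) and methylated
reads ~ Binomial(coverage, β), so observed β is unbiased for true β — the
binomial model is the default precisely because that unbiasedness is
analytically checkable; a negative-binomial alternative would add
overdispersion but no new structure at these depths. Recurrent tumors are
the patient's primary plus Gaussian β-noise (sd 0.02) — strong
intra-patient preservation — or an independent redraw
(`independent_recurrent`) giving the exchangeable null under which
intra/inter p-values are uniform. Planted DMRs live in PMD-free space with
per-patient deltas (±0.30 in 2–5 patients, mixed signs for discordant
truth; a "graded" mode gives every patient a continuous delta for link
analyses); truth records carry the *realised* mean delta after [0.02, 0.98]
clipping so truth matches what is observable. Planted expression links set
the per-patient expression change to a Gaussian-copula draw at rank
correlation 0.7 against the observed DMR methylation change, one DMR per
target gene.

What it does not emulate: read-level artefacts (bisulfite conversion
failure, mapping bias), copy-number structure, fine-scale methylation
autocorrelation within bins, biological covariates (purity, subtype), or
realistic gene structure (transcripts are single-exon stand-ins with
Dirichlet isoform shares). Passing tests therefore demonstrate that the
*procedures* recover planted statistical structure under a faithful noise
model — not that the pipeline is robust to every artefact of real WGBS.

## Problem sizes

Defaults are 2 chromosomes × 10 Mb and 14 patients (28 methylomes): large
enough for ≥ 30 informative 100 kb bins per sample and non-degenerate
mixtures, small enough for minutes-scale runs. The acceptance studies use
2 × 10 Mb cohorts for PMD recovery and the cohort pipeline, and 2 × 1 Mb
or 2 × 0.5 Mb cohorts (where the mixture model is not involved) for
replicate-heavy calibrations — distance-test power and null uniformity, and
link retention with 27 patient pairs. At those scales the top-variable-CpG
step returns all eligible sites (fewer than 10,000 exist), which it reports
with a warning.

## Known limitations

- The common-PMD threshold is a constant, not an automatic inflection-point
  detector; choosing it remains the analyst's call.
- The mixture has exactly three components by design; no model selection
  over component counts is attempted, and genomes without a trimodal
  M-value structure (e.g. PMD-free normals) will produce degenerate-but-
  flagged fits rather than a different model.
- Enrichment backgrounds match marginal properties (size, CpG count), not
  the joint spatial distribution of queries (e.g. distance to genes).
- `filter_transcripts` treats isoform percentages as supplied; it does not
  recompute them after filtering.
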