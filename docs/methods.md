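# Methods

## Model and assumptions

`smrtriage` tests, per molecular probe (gene expression, CpG methylation,
protein abundance or chromatin peak), whether the probe's cis-genetic signal
and a disease GWAS signal are consistent with a shared causal variant, using
only summary statistics and an external LD reference.

**Single-SNP SMR.** Let `b_x, se_x` be the exposure (QTL) effect of the top
cis instrument and `b_g, se_g` the outcome (GWAS) effect at the same SNP,
both aligned to the same effect allele.  With `z_g = b_g/se_g` and
`z_x = b_x/se_x`, the two-stage test statistic is

```
T_SMR = z_g^2 z_x^2 / (z_g^2 + z_x^2)   ~  chi^2_1  under H0
```

and the Wald ratio `b_SMR = b_g/b_x` estimates the exposure-on-outcome
effect, with delta-method standard error
`se_SMR = sqrt((se_g/b_x)^2 + (b_g se_x / b_x^2)^2)` (a form that remains
finite as `b_g → 0`, where `b_SMR = 0` and `p = 1` by continuity).  The test
assumes the instrument is a valid cis instrument (strong, and acting on the
outcome only through — or jointly with — the exposure), two possibly
non-overlapping cohorts, and approximately normal marginal effect estimates.
`T_SMR` is bounded by `min(z_g^2, z_x^2)`, so with instruments of finite
strength the test is slightly conservative; at the default instrument
threshold (p < 5e-8) the deficit at alpha = 0.05 is about 0.002–0.005 and the
calibration suite's binomial envelope absorbs it.

**HEIDI.** Under pleiotropy (one shared causal variant) every cis SNP in LD
with it estimates the *same* ratio `b_xy`; under linkage (distinct causal
variants) the ratios disagree.  For non-top SNPs `i` the statistic uses
`d_i = b_g_i/b_x_i − b_g_top/b_x_top`, whose joint covariance follows from
the delta method with `cov(b_g_i, b_g_j) = r_ij se_g_i se_g_j` (and likewise
for the QTL block; GWAS and QTL blocks independent), `r_ij` estimated from
the reference panel after aligning dosages to each source's effect allele.
With `z_d = d / sd(d)`, `T_HEIDI = Σ z_d^2` is referred to the tail of
`Σ λ_k χ²_1`, `λ_k` the eigenvalues of the correlation matrix of `z_d`.
Small `p_HEIDI` ⇒ heterogeneity ⇒ linkage; candidate associations require
`p_HEIDI > 0.01`.  If the correlation matrix is numerically singular the SNP
most collinear with the rest is dropped and the test retried; with fewer than
`heidi_min_snps` non-top SNPs the p-value is reported missing (and a missing
HEIDI p does not pass the filter, tallied separately).

**Multi-SNP SMR.** Instruments are greedily pruned to pairwise `r² < 0.9`
(best QTL p kept per clash); `T_multi = Σ T_SMR,i` over the retained set is
referred to `Σ λ_k χ²_1` with `λ_k` the eigenvalues of the retained SNPs' LD
correlation matrix — the null distribution of a sum of squared standard
normals with correlation `R`, exact in the strong-instrument limit.  With one
retained SNP the single-SNP p is returned unchanged.  (Some descriptions
label the multi-exposure extension Bayesian; the implemented test is the
frequentist multi-SNP chi-square combination, which is what reference
implementations compute.)

**Weighted chi-square tails.** Single-weight and equal-weight cases use exact
chi-square expressions.  The general case evaluates Imhof's inversion
integral on a finite interval with composite 8-point Gauss–Legendre panels:
the panel count scales with the integrand's maximum angular rate
`(x + Σλ)/2`, and the truncation point is chosen so the neglected oscillatory
tail (integration-by-parts bound) is below 1e-8.  Agreement with 4×10⁶-draw
Monte-Carlo tails is within sampling error across p ∈ [0.001, 0.5].  A seeded
Monte-Carlo estimate (2×10⁵ draws) backs up pathological weight
configurations.

## Default parameters

All exposed in `SMRConfig` / `SignificanceConfig`; defaults mirror the
reference SMR tooling and the study design the package reproduces.

| Parameter | Default | Meaning |
| --- | --- | --- |
| `cis_window_kb` | 2000 | instrument discovery window around the probe (kb) |
| `p_instrument` | 5e-8 | QTL significance required of the top instrument |
| `heidi_window_kb` / `heidi_max_snps` | 500 / 20 | HEIDI uses the top 20 eligible SNPs within 500 kb |
| `heidi_p_qtl` | 1.57e-3 | HEIDI SNP eligibility threshold (laxer than the instrument's) |
| `heidi_r2_min` / `heidi_r2_max` | 0.05 / 0.9 | bounds on r² with the top SNP for HEIDI SNPs |
| `heidi_min_snps` | 3 | minimum non-top SNPs for a reported HEIDI p |
| `prune_r2_max` | 0.9 | multi-SNP SMR pruning threshold |
| `freq_tol` | 0.2 | max allele-frequency discrepancy across sources |
| `alpha` / `n_genes_tested` | 0.05 / 16,875 | Bonferroni family: alpha over protein-coding genes tested |
| `p_heidi_min` | 0.01 | HEIDI floor for candidate inclusion |
| `relaxed_p` | 0.05 | relaxed lookup threshold for cross-disease pleiotropy probing |
| MHC interval | chr6:28,477,797–33,448,354 | extended MHC, hg19; genes overlapping it are excluded |

Bonferroni thresholds are always exact quotients (0.05/16,875 ≈ 2.963e-6);
rounded figures seen in print (2.95e-6, 1.58e-8) are kept as metadata
constants only and never used for filtering.

The exclusion rules run in the fixed order annotation → protein-coding → MHC
→ `p_SMR_multi` → `p_HEIDI`, a row counting against the first rule it fails,
so exclusion reports are reproducible and partition the input.

**Z-score completion.** QTL panels that distribute only Z scores are
completed with `se = 1/sqrt(2 f (1−f)(n + z²))`, `beta = z·se`, using the
panel allele frequency `f` and study sample size `n`; `beta/se` equals `z`
exactly and `se` decreases monotonically in `n` and in `2f(1−f)`.

**Harmonization.** GWAS records are aligned to the QTL's effect allele:
swapped-allele SNPs get `b → −b`, `f → 1−f`; SNPs with incompatible allele
sets, frequency discrepancies above `freq_tol`, or (when a panel is given)
absence from the LD panel are dropped with per-rule logs.  Strand-ambiguous
(A/T, C/G) SNPs are retained but flagged: the pipeline's LD panel carries
explicit allele labels, which disambiguates them here; applying the package
to externally stranded data may warrant stricter handling.

## Expression percentile ranks

Counts are length-normalized per cell (`counts/exon_length`, rescaled to sum
to 10⁶ = TPM); a gene's EPR in a cell is `100 × ECDF(cell's TPM values)` at
the gene's TPM, ties sharing the maximal rank of the tie group — hence EPR is
invariant to any per-cell monotone rescaling.  Ranks are computed within each
cell and then averaged over the cells of each cell type (the alternative —
pooling cells of a type before ranking — is *not* used; per-cell ranking then
averaging matches the "mean EPR per gene across cells" definition).  The mean
EPR is binned `off` (< 10), `high` (> 90), `low` otherwise; boundary values
10 and 90 fall in `low`, a choice made because the published bin notation
leaves both endpoints open.  Exon lengths are an input column; a helper
derives them from a GTF by unioning exon intervals per gene (strand ignored).

## Synthetic data: what it emulates and what it does not

`simulate_ld_panel` draws haplotypes from a latent AR(1) Gaussian threshold
model (latent correlation `ld_rho`, MAF uniform in [0.05, 0.5], 25 kb SNP
spacing); genotypes are sums of two haplotypes.  Thresholding attenuates
correlation: latent 0.7 yields adjacent genotype r ≈ 0.4, decaying
geometrically — a reasonable stand-in for a cis region, though without hot
and cold recombination spots, allele-frequency–dependent LD, or population
structure.

`simulate_scenario` simulates *individual-level* phenotypes with unit total
variance and reduces them to per-SNP marginal regressions, so the LD-induced
correlation of summary statistics — exactly what HEIDI and multi-SNP SMR
consume — arises mechanically rather than by assumption.  Scenarios:
*pleiotropy* (one causal SNP: exposure effect `b_zx = 0.3`, outcome effect
`b_zx·b_xy` with `b_xy = 0.2`), *linkage* (exposure SNP A, outcome SNP B
chosen as the panel SNP whose realized |r| with A is closest to `r_link`),
*null* (exposure effects only).  Default cohort sizes `n_gwas = 5×10⁴`,
`n_qtl = 5×10³` and `m_snps = 30`, `ld_rho = 0.7` define the calibration
grid used across the test suites.

For the replicate suites, `simulate_replicates` draws cohort genotypes once
per scenario and redraws phenotypes per replicate (vectorized in chunks).
Type-I error and recovery are then assessed over phenotype randomness
conditional on one genotype draw — under which the marginal tests are exact —
at a fraction of the cost of redrawing cohorts.  Replicate counts (2,000 for
calibration, 500 for recovery, 200 per arm for HEIDI discrimination) were
sized to give binomial/Monte-Carlo error comfortably inside the asserted
envelopes.

`simulate_counts` draws negative-binomial counts (dispersion size 2.0) with
gene × cell-type means supplied by the caller; it emulates overdispersed
single-nucleus counts but not dropout/ambient contamination, batch effects,
or cell-type–specific library sizes.  Consequently, passing tests demonstrate
correctness of the EPR pipeline's arithmetic and ranking behaviour, not
robustness to real single-nucleus artifacts.

## Packaged fixtures

`smrtriage.fixtures` carries the published 15-gene multi-disease candidate
table and the published 41/3/115 novel/known/difficult tier lists verbatim.
The druggability set, drug-indication table and interaction edges are
*synthetic snapshots*: constructed to be consistent with those tier lists and
with specific published companion relations (TRIM27 → MAPK14 with an
NDD-approved proxy drug; OXT as CD38's companion for the liver-toxicity
example), not exports of DGIdb, the druggable-genome annotation, Open Targets
or SIGNOR.  The drug→gene assignment within the known tier is one consistent
choice among several the published text permits.

## Numerical and design choices

- **Gene identity** is by symbol after an optional alias map; unresolved
  symbols are flagged `unannotated` and classified difficult, never dropped.
- **"Approved for an NDD"** requires an `approved` status on one of the six
  study diseases; trial-stage evidence never promotes a gene to `known`.
- **Determinism**: results tables are sorted (disease, omic-tissue, chrom,
  position); companion reports by (direction, symbol); all generators are
  seeded.  Identical inputs give byte-identical outputs.
- **Missing values** in text stores use the reserved sentinel `NA`; readers
  restore them as missing, never as zero.  Floats are parsed with exact
  round-trip parsing so write→read→write is byte-stable.
- **Degenerate inputs**: all-zero cells, monomorphic variants, empty variant
  intersections, zero exposure effects and empty candidate sets raise typed
  errors naming the offender rather than propagating NaNs.

## Known limitations

- No sample-overlap correction between GWAS and QTL cohorts, no trans-QTL or
  conditional (COJO-style) analysis.
- The multi-SNP and HEIDI tails treat per-SNP statistics as (correlated)
  unit-weight chi-squares, exact only in the strong-instrument limit; with
  weak instruments both tests become conservative.
- LD is estimated from a finite panel; very small panels propagate noise into
  HEIDI eigenvalues (the singularity guard drops offending SNPs rather than
  regularizing).
- The liver-eQTL toxicity flag is a proxy, not a pharmacokinetic model; the
  EPR bins describe baseline expression support, not druggability per se.
- Colocalization posterior probabilities, genome-build conversion and live
  database queries are out of scope; snapshots stand in for the latter.
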