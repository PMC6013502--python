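# Methods

This note documents the models, parameter choices and numerical decisions
behind `regmod`, and what the synthetic-data validation does and does not
demonstrate.

## The θ statistic

θ compares two association patterns — vectors of per-variant −log₁₀(p)
with effect signs — for evidence that they are driven by the same
underlying regulatory variant(s). Variants enter the comparison when they
lie within 1 Mb of either pattern's anchor (the probe midpoint for an
eQTL; for a disease pattern the risk-locus interval replaces the distance
rule) and carry −log₁₀(p) > 1.3 (p < 0.05) for at least one of the two
traits; weaker variants are uninformative for both and would only dilute
the correlation. Weights `w_i = max(x_i/x_max, y_i/y_max)^p` (default
p = 1) emphasise the pattern peaks. The weighted correlation r_w and its
sign-aware version r_ws (y negated on sign-discordant variants, weights
from the unflipped magnitudes) are combined through a logistic link
`θ = r_ws / (1 + e^{−k(r_w − T)})`, k = 30, T = 0.3, which shrinks the
signed correlation toward zero when the unsigned similarity is low.

Numerical decisions:

- −log is base 10 throughout (the 1.3 threshold corresponds to p = 0.05).
- A comparison needs ≥ 2 informative variants (hard floor for a defined
  correlation); below 10 a warning is logged.
- The sign-flip step is not exactly symmetric under exchanging the two
  patterns when only part of the variants are discordant, because the
  weighted mean and SD of the flipped vector change. `compare_patterns`
  therefore fixes a canonical orientation (lexicographic trait id), making
  the public comparison exactly symmetric; the low-level
  `signed_weighted_correlation(x, y, …)` applies the flip to `y` as
  defined.
- Zero weighted variance (e.g. a constant pattern) raises an explicit
  undefined-comparison signal rather than returning NaN silently.
- Allele harmonisation matches variants on chrom+pos+allele pair, flips
  the second pattern's sign when ref/alt are swapped, drops incompatible
  allele pairs, and optionally drops strand-ambiguous A/T and C/G
  variants.

## cis-eQTL scan

Expression is residualised on known covariates, then on the leading
principal components of the residual matrix; the PC count can be chosen
automatically as the value maximising the number of probes with a
window-minimum nominal p ≤ 10⁻⁶ (grid 0, 5, …, 60 by default — the
effective range depends on sample size). Each probe is tested against all
variants within ±1 Mb of the probe midpoint (closed interval) under the
additive model: a per-variant least-squares fit of expression on dosage,
two-sided t test on the slope, computed through the log survival function
so that extreme signals do not underflow (capped at −log₁₀ p = 320).
Window-wide multiplicity is corrected by permuting the expression sample
labels and recording each permutation's window-minimum p, with the add-one
convention (r+1)/(n+1), so the smallest achievable corrected p is
1/(n_perm+1). With complete genotype data the permutation loop reduces to
a max-|correlation| matrix product; with missing dosages (complete-case
per variant) a slower exact path is taken. Per-tissue q values are
Benjamini–Hochberg; a Storey-style π₀ rescaling (2 × fraction of p > 0.5,
capped at 1) is available by flag.

## Regulatory modules

Patterns whose anchors lie within 2 Mb are compared pairwise (the pairing
radius is the dominant unstated parameter of the clustering and is exposed
in the config). Edges with |θ| > 0.6 define a graph whose connected
components are the modules — single-link clustering, so a chain A–B–C is
one module even when θ(A, C) is small. Curated edge removals are supplied
as a config list (a reproducible audit trail replacing manual curation).
Modules are classified by their member gene and tissue sets; signed θ is
kept on edges but sign consistency within a module is reported, not
enforced. Excess sharing of modules between cell types is tested by
reassigning the reference type's pairwise sharing events to the other
types with probabilities proportional to their module counts (multinomial,
5000 draws by default, add-one p).

## Case–control algebra and simulated disease patterns

For pooled allele frequency p, case shift d and control shift
δ = −d·n₁/n₂ (pooled frequency conserved exactly), the between/within
variance ratio is

    F = d²(1 + n₁/n₂) / [(1 + n₂/n₁)(p − p²) − d²(1 + n₁/n₂)],

inverted in closed form by d = ±√(−γ/α) with α = (1+n₁/n₂)(1+F),
γ = −(p−p²)(1+n₂/n₁)F (the sign is configurable; + by default). A disease
pattern of calibrated strength is simulated by drawing case and control
genotype classes at the causal variant from Hardy–Weinberg proportions at
p+d and p+δ, resampling whole individuals (with replacement) from the
cohort by genotype class — which preserves local LD — and scanning the
locus with a 1-df allelic chi-square (a logistic fit is intentionally out
of scope; the allelic test matches the allele-frequency framing of the F
algebra). The empirical p value for an observed θ draws (by default)
MAF-matched candidate variants in the locus (window ±0.05, doubling until
enough candidates), simulates a variance-matched eQTL for each — genotype
class means fixed at −1/0/+1, residuals N(0, σ²_RES) with
σ²_RES = σ²_eQTL(1/h² − 1) — and compares |θ| against the fixed pattern.
The class variance uses the /n_T denominator while the total expression
variance uses /(n_T − 1); the slight mismatch is kept as printed, with a
`consistent_denominators` switch for the purist.

## Burden tests

Genotypes are called from the alternate-allele read fraction
([0, 0.15] → hom-ref, [0.25, 0.75] → het, [0.85, 1] → hom-alt, otherwise
or depth < 20 → missing), then filtered on call rate ≥ 95% and an exact
Hardy–Weinberg test (enumeration over heterozygote counts conditional on
allele counts, α = 10⁻⁶); samples need ≥ 95% target coverage and at most
one minor allele across the ancestry discrimination panel. Qualifying
variants are LoF + damaging with MAF ≤ 0.005 over the full cohort.

CAST collapses a gene to its carrier indicator and tests the
carrier-frequency difference one-sided, the side chosen by the gene's θ
with the disease (θ < 0 → enrichment in cases, θ > 0 → in controls; in
multi-gene modules each gene's own θ sign governs its side). The
SKAT-style statistic is Q = Σⱼ wⱼ²(Σᵢ G_ij(yᵢ − ȳ))², flat weights on the
qualifying set by default (no weight scheme is canonical here; Beta(1,25)
MAF weights by flag), singletons included by default with an exclusion
flag. All p values come from phenotype permutation with the add-one
convention. SKAT p values are deflated by the median-based genomic-control
λ, estimated on the synonymous control category when one is provided (else
on the test set itself).

The global-shift test asks whether the per-gene best p values (min of CAST
and GC-corrected SKAT) are collectively smaller than permutation expects:
the Fisher statistic −2Σ ln p over genes is compared to its distribution
under shared phenotype permutations, and per-rank medians and 95% bands of
−log₁₀(best p) are reported for QQ-style display. Computing a permutation
p value *for each permuted dataset* would naively require nested
permutations; instead each phenotype permutation (shared across genes)
serves once as the pseudo-observed dataset and its p value is its rank
within the same pool — an exact identity for permutation p values, not an
approximation. The module-level test Fisher-combines member-gene best p
values on the same pool. Orthogonal tests compare the summed age-of-onset
(one-sided by θ, two-sided variant for the SKAT pairing) and the familial
fraction of carrier cases against random draws of equally many cases.

## Synthetic data: what it emulates

The generator reproduces the statistical structure the pipeline assumes,
at desk scale: ~300-sample multi-tissue expression with planted cis-eQTL
of specified h², genotypes with block LD and MAF > 0.05, case–control
cohorts with planted common-variant effects of specified F, and rare
damaging/synonymous variants (MAF ≤ 0.005) with specified case enrichment.

- **LD model** — haplotype copying: within a block every haplotype copies
  a shared block indicator and each variant is independently refreshed
  with probability ε, giving valid {0,1,2} genotypes, exact HWE, and
  within-block genotype r² = (1−ε)⁴, i.e. ε = 1 − r²_target^¼. Variants
  within a block share one allele frequency (drawn per block from
  U(0.1, 0.5)), which makes the r² target exact; blocks are independent.
  Variants whose realised MAF falls to ≤ 0.05 are dropped, mirroring the
  common-variant QC the downstream stages assume.
- **Expression** — planted probes use the variance-matched construction
  above; tissues sharing a module share the causal variant with
  independent residuals per tissue (the joint cross-tissue residual
  distribution is not modelled — an explicit assumption).
- **Phenotypes** — age-of-onset is Normal(28, 10) truncated at 5 years;
  familiality is Bernoulli(0.2); both are synthetic stand-ins (no
  generative model is implied by the science), with optional carrier
  shifts to exercise the orthogonal tests.
- **Rare variants** — control per-allele frequency uniform in the
  configured range; case frequency multiplied by the category's relative
  risk (1 for synonymous), so the case:control carrier ratio converges to
  the relative risk for rare variants.

What passing tests therefore show: the statistics are computed exactly as
specified (oracle equivalence to 10⁻¹²), every permutation p value is
calibrated under its null, planted parameters (h², F, relative risk) are
recovered without bias, and the end-to-end chain finds a planted
shared-causal-variant module with |θ| > 0.6 in nearly every seeded run.
What they do not show: behaviour under real-data complications — array
probe effects, population structure, imputation error, cryptic
relatedness, cross-tissue residual correlation — none of which the
generator models.

## Problem sizes and runtime

Simulation-based checks use cohorts of 200–600 for eQTL-scale analyses,
1000–3000 per arm for case–control and burden analyses, 150–2000
permutations, and 15–200 seeded replicates per property; the acceptance
script completes in about two minutes on one CPU and the full test suite
in under two minutes. The null-calibration checks use more seeds for null
rates (where the binomial noise of a 5% event dominates) than for strongly
powered detection rates.

## Known limitations

- The allelic chi-square in the disease scan assumes HWE within cohorts
  (true by construction for the simulator); a logistic Wald flag exists
  for dosage-level scans but covariate-adjusted disease scans are out of
  scope.
- BH FDR treats probes as exchangeable; hierarchical (probe→gene)
  correction is not implemented.
- The frequentist colocalisation criterion conditions on one variant at a
  time; multi-signal loci can defeat it (the θ route is the primary one).
- Module ids are deterministic for a fixed input ordering but not stable
  across catalogue revisions.
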