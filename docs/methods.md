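# Methods notes

This note records the statistical model the package implements, the
defaults and why they were chosen, what the synthetic-data engine does and
does not emulate, and the numerical choices that matter for
reproducibility.

## Per-variant summaries

**Trios.** For each biallelic variant, transmissions from heterozygous
parents to the affected child are deduced per trio: a homozygous parent
transmits its allele deterministically, so the number of minor alleles the
child received from heterozygous parents is `t = g_child − #(hom-minor
parents)`; `t` outside `[0, n_het]` is a Mendelian inconsistency and the
trio is skipped *at that variant only* (and tallied). The
double-heterozygote mating with a heterozygous child contributes one minor
and one major transmission — which parent sent which is unidentifiable but
the totals are not. Summaries are β̂ = log(b/c), V̂ = (b+c)/(bc), and the
TDT χ² (b−c)²/(b+c). When b or c is zero the Haldane–Anscombe correction
adds 0.5 to both cells (flag `corrected`); an alternative `zero_cell="drop"`
discards the variant. The correction keeps rare variants — the method's
focus — in the analysis with finite summaries.

**Unrelated subjects.** β̂, V̂ come from per-variant ML regression
(logistic or OLS) with complete-case handling of missing genotypes.
Complete or quasi-complete separation — routine for rare variants — falls
back to a Firth (Jeffreys-prior) penalized fit, which is deterministic and
keeps Wald summaries finite. For the no-covariate binary case the fits are
solved on the 2×3 genotype-by-outcome table (sufficient statistics), which
makes per-region fitting cost independent of sample size; the solver is
cross-checked against statsmodels IRLS to 1e-6 in the tests. Covariates
are supported only for unrelated designs: the TDT is covariate-free by
construction.

## Bayes factor and prior

The Wakefield form `BF = sqrt(V̂/(V̂+W)) · exp(β̂²W / (2V̂(V̂+W)))` is the
exact marginal-likelihood ratio under the normal approximation to the
likelihood and a N(0, W) effect prior; the tests verify it against direct
quadrature to 1e-8. All computation is in log space so genome-scale
signals cannot overflow. Defaults: prior sd 0.2 (W = 0.04, the WTCCC GWAS
prior for log odds ratios) labelled ADABF; sd 0.1 (W = 0.01) labelled
ADABF1 as a sensitivity setting. For quantitative traits this prior is
meant for a standardized outcome; `regression_effect` warns when the
outcome sd deviates from 1 by more than 10% rather than silently
rescaling, since standardization changes the meaning of β̂. A per-variant
(e.g. MAF-dependent) W can be passed by constructing `PriorSpec` values
per call, but no MAF-dependent rule ships because none is established.

One analytic point worth recording: at a *fixed* Wald statistic, BF → 0 as
V̂ → 0 but BF → 1 (not 0) as V̂ → ∞ — an imprecise estimate carries no
evidence either way. The evidence peak sits at intermediate variance.

## Region test

Per-variant scores are log BF (ADABF/ADABF1) or −log P (ADA). The top-k
summary S_k is the sum of the k largest scores, k = 1…L, ties broken by
ascending variant index. S_k need not be monotone in k because log BF < 0
(evidence for the null) is possible; the adaptive minimum over k handles
this naturally.

Null calibration draws B vectors β̂₀ ~ N(0, V), V_ij = R_ij √(V̂_i V̂_j),
where R is the Pearson correlation of genotype scores (founders only in
trio designs), computed pairwise-complete over missing data and
eigenvalue-clipped back to positive semidefiniteness (floor 1e-10, then
renormalized to unit diagonal) because pairwise-complete estimates need
not be PSD. Monomorphic or uninformative variants must be filtered before
correlation/resampling; the region drivers do this and report the count.

Per-k P-values count resamples with S_k^(b) ≥ S_k. Each resample's own
MinP^(b) is computed by ranking it against the full ensemble *with itself
included* (so per-k P ≥ 1/B for resamples), the standard ARTP convention
that avoids a second resampling layer. The adjusted P is the fraction of
MinP^(b) ≤ MinP, floored at 1/B with a `floor` flag when no resample is as
extreme — a conservative bound rather than an exact zero. Because only
≥/≤ comparisons enter, the adjusted P is invariant to order-preserving
affine rescaling of all scores and to variant permutation (tested).

The sequential schedule starts at B = 100 and draws a *fresh* independent
ensemble 10× larger while adjusted P ≤ 10/B, stopping at B = 10⁷ by
default. Stage seeds derive from the master seed and the stage index
(`numpy.random.SeedSequence`), so results are bit-reproducible. Fresh
rather than extended ensembles keep every stage unbiased at the cost of
discarding earlier draws; the discarded work is at most 11% of the final
stage. Memory is B×L doubles for the score matrix, so B = 10⁷ with L = 150
is only reachable on large-memory machines; the simulation harnesses cap
B at 10⁵ (calibration) or 10⁴ (power) because their decisions are taken at
α ≥ 0.01 and the stop rule makes larger B unreachable there anyway.

With L = 1 the procedure reduces to a Monte-Carlo single-variant test:
ADA and ADABF give identical adjusted P-values (both scores are monotone
in |β̂| at fixed V̂) converging to the analytic Wald P.

## Burden baseline

The TLC baseline is the plain unweighted linear combination: for trios,
Z = Σ(b_l − c_l)/√Σ(b_l + c_l) against N(0,1); for unrelated subjects, a
regression of the outcome on the per-subject genotype sum with covariates.
No MAF weighting is applied, matching the fair-comparison configuration
used in the benchmarks. This is a deliberate simplification of
kernel/haplotype-based burden implementations, adequate for its role as a
benchmarking baseline: it is exactly the test that cancels under mixed
deleterious/protective effects.

## Synthetic data

`make_pool` emulates resequencing-scale variation in a ~20 kb region:
150 sites, 10,000 haplotypes, per-site target MAFs from a density ∝ 1/f on
[1/H, 0.5] (inverse-CDF sampling), giving the L-shaped spectrum typical of
sequence data. Haplotypes threshold a latent Gaussian AR(1) process along
the region; the `ld` parameter (default 0.7) is the *latent* adjacent-site
correlation, and realized allele-level r is attenuated toward 0 for rare
sites, as in real data. Residual monomorphic sites are seeded with their
expected carrier count; sites realized above 0.5 are flipped to
minor-allele orientation.

What this does **not** emulate: coalescent genealogy, recombination
hotspots, long-range LD blocks, population structure, genotyping error.
Consequently, passing calibration/power/ranking tests show the *method's*
behaviour under a realistic frequency spectrum and local LD, not
quantitative agreement with any particular empirical LD landscape —
printed benchmark means that depend on a specific coalescent simulator's
LD are treated as qualitative properties, not reproduction targets.

Disease status follows logit P(Y=1) = α + Σβ_k G_k with
α = log(0.05/0.95) ≈ −2.944 (prevalence exactly 5%). Trios are
rejection-sampled on an affected child (four parental haplotypes drawn
with replacement, one transmitted per parent at random — random mating, so
founder genotypes are in Hardy–Weinberg proportions by construction);
case-control samples fill fixed quotas (defaults 1,000 + 1,000). An
expected ascertainment probability below 1e-4 aborts with a diagnostic.
Causal variants are drawn uniformly among polymorphic sites, re-drawn per
replicate, optionally restricted by MAF; in the mixed scenario half the
effects (rounded up) are deleterious and half protective, |β| = log 1.5 or
log 1.25.

Experiment defaults follow the benchmark designs: 2,000 trios or
1,000+1,000 unrelated subjects; effect sizes ±log 1.5 / ±log 1.25 with
d ∈ {2, 4} causal variants; the ranking experiment plants one causal
variant with β = log 1.5 in a 1,000+1,000 case-control sample. Replicate
counts are desk-scale (2,000 for calibration, 5,000 for ranking, 150 for
power in the shipped harness runs) rather than the 10⁵–10⁶ used for the
published tables; binomial CIs are reported alongside every rate.

## Calibration behaviour

The MinP/sequential machinery is exactly calibrated when observed effects
truly follow the resampling model: feeding it MVN draws reproduces nominal
levels (measured rejection 0.054 / 0.011 at α = 0.05 / 0.01; KS p = 0.45
for uniformity of the adjusted P). On simulated genotype data the test is
mildly conservative (≈ 0.038–0.044 at α = 0.05 with the default
generator), because finite-count TDT and Firth estimates are discrete and
lighter-tailed than their normal approximation — most visibly for rare
variants with few informative transmissions. The effect shrinks with
sample size; at the default sample sizes both designs sit inside the 99%
binomial band around the nominal level. Severely reduced sample sizes
(e.g. 300 trios) push the test conservative — a known limitation to keep
in mind when applying the method to small studies.

## IO conventions

VCF 4.x (GT only, biallelic records; multi-allelic sites skipped with a
warning) via cyvcf2, PLINK-style .ped/.map text, .fam-style pedigrees, BED
regions (0-based half-open, converted to 1-based inclusive internally;
variant-to-region assignment uses the closed interval
[start − flank, end + flank], default flank 30 kb), TSV phenotypes.
Genotype scores count the minor allele, determined on founders (trios) or
all subjects (unrelated); an exact 0.5 frequency tie breaks by
lexicographic allele name so orientation is deterministic. QC inside the
tool is minimal (monomorphic/uninformative variants are dropped per
region); call-rate, HWE and Mendelian-error sample screening are expected
upstream. Gene-based significance conventions (2.5×10⁻⁶ genome-wide,
5×10⁻⁵ suggestive) are documentation guidance, not enforced thresholds.

## Known limitations

- Trio analysis assumes autosomal biallelic variants and complete
  father-mother-child trios; sibships, X-linked TDT and haplotype phase
  are out of scope.
- The genotype-correlation approximation for the null covariance is
  asymptotic; with very few founders the estimated R is noisy (the PSD
  repair handles rank issues but not estimation variance).
- Adjusted P-values are Monte-Carlo estimates with resolution 1/B; the
  floor flag marks results that are upper bounds.
- The burden baseline is intentionally minimal and should not be read as
  a faithful reimplementation of any specific published burden package.
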