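# Methods

This note documents the models implemented in `qtlmodules`, the defaults
and why they were chosen, the numerical decisions, and what the synthetic
validation studies do and do not demonstrate.

## Synthetic study generator

**Genotypes.** Variants live on one synthetic chromosome at a fixed
10 kb grid (1-based positions) and are organised in LD blocks. Every
block draws one population allele frequency p uniformly from
`maf_range`; each sample carries two haplotypes with Bernoulli(p)
alleles under Hardy–Weinberg equilibrium. Within a block, the haplotype
allele of variant j+1 copies variant j with probability √r²_target and
is redrawn fresh at p otherwise. Copying correlates haplotypes by
√r²_target, so the expected adjacent-pair *dosage* r² equals r²_target
and decays geometrically with block distance; blocks are independent.
This founder-copy-with-flip model was chosen over coalescent machinery
because its r² is analytically controllable, which the LD-expansion
recovery tests rely on. No recombination maps, population structure or
sex chromosomes are modelled.

**Expression.** For each tissue, gene expression is

    y_g = f_{m(g)} + Σ_effects β · dosage + ε,   ε ~ N(0, noise_sd²)

where f_m ~ N(0, module_factor_sd²) is one latent factor per planted
module per tissue (genes outside modules have none, module loadings are
1). β is the shift per copy of the effect allele, in pre-transform
expression SD units — the additive-model, effect-allele convention used
for normalized effect sizes. Columns are then rank-based
inverse-normal transformed (Blom offset 3/8), the standard normalization
for expression panels of this kind; `inverse_normal: false` disables it
for exact-recovery experiments, since the transform compresses the
slope's scale.

The intra-module Pearson correlation implied by the factor model is
s²/(s²+1) for factor SD s and unit noise: s = 3 gives ρ ≈ 0.90, s = 4
gives ρ ≈ 0.94. Spearman runs ~1 % below Pearson for bivariate normal
data, which matters when recruiting partners at a sharp |ρ| ≥ 0.90
cutoff — the demo config therefore recruits at 0.8.

**Summary statistics.** Colocalization scenarios simulate trait values
as causal-dosage × β + standard normal noise over the leading n1 (n2)
samples and regress every region variant on each trait. Scenario labels
H0–H4 follow from which causal variants are set and whether they
coincide.

**Pathways.** GMT sets are exact module copies, partial overlaps
(`round(size·overlap)` members from the module, remainder from outside)
or uniform draws from the universe; Jaccard overlaps against every
planted module are recorded in the truth table.

**Seeding.** One master seed; child streams are derived with fixed
spawn keys per purpose (genotypes; expression per tissue; summary
statistics per scenario; pathways), so adding tissues or scenarios never
perturbs existing draws. Every generator is a pure function of
(spec, seed).

## QTL mapping

Ordinary least squares of expression on dosage with an intercept;
two-sided t-test on the slope; missing dosages handled by
pairwise-complete deletion; monomorphic variants are errors (single
fits) or dropped (bulk scans). p-values are floored at the smallest
positive double so exact fits do not produce p = 0. No covariate or
latent-factor correction is applied — effect sizes are therefore not
comparable to published panels that adjust for such covariates.

cis tests pair a variant with every gene whose TSS lies within 1 Mb on
the same chromosome (the conventional cis window). trans tests are
restricted to genes whose TSS falls inside chromatin-interaction target
ranges (BEDPE, 0-based half-open) anchored at the variant's locus, on
the same chromosome, excluding genes already covered by the cis window.

**Empirical significance.** For each gene, expression is permuted B
times across samples; each permutation records the minimal nominal p
over the gene's cis variants (computed via max |dosage–expression
correlation|, which is equivalent at common df and numerically stable).
The empirical p is the +1-corrected rank, so it is never zero and is
invariant to monotone relabelings of the nominal scale. The direct
empirical p is used rather than a beta-distribution approximation to the
permutation null: at desk scale B is configurable and the exact rank is
simpler and honest. B = 1000 in the demo config; B = 200 in the
calibration studies (the discreteness of k/(B+1) is accounted for in
the calibration test's goodness-of-fit support).

**eGene rule.** Benjamini–Hochberg on the gene empirical p-values at
FDR 0.05; the boundary gene is the rejected gene with the largest
empirical p ("closest to the FDR threshold"). Its empirical p, p\*, is
the probability level at which each eGene's own permutation min-p
distribution is cut (linear-interpolation quantile) to give that gene's
nominal threshold; a variant–gene pair is a significant eQTL iff its
gene is an eGene and its nominal p is at or below that threshold. If
nothing is rejected, no eQTLs are called. Genes with no polymorphic cis
variant are skipped with a warning and can never be eGenes — planted
trans effects therefore appear in the QTL table but are not flagged
significant, a deliberate consequence of the cis-anchored rule.

Protein/metabolite summary QTLs use the fixed genome-wide rule
p < 5·10⁻⁸ (strict inequality).

## LD

r² is the squared Pearson correlation of dosage vectors — phase-free,
so no haplotype inference is needed, and invariant under allele flips
(2 − dosage). Lead expansion searches a 1 Mb window around the lead on
the same chromosome at r² ≥ 0.80, returns proxies sorted by descending
r² (ties by position) and always includes the lead at r² = 1.

## Colocalization

Wakefield approximate Bayes factor per variant,
log ABF = ½[ln(1−r) + z²r], r = W/(V+W), z = β/se, with prior effect SD
√W = 0.15 for quantitative traits (configurable). Hypothesis sums S0–S4
use per-variant priors p1 = p2 = 1e-4, p12 = 1e-5 (the conventional
defaults for this framework) and are accumulated in log space, so
|z| up to ~50 cannot overflow. The H3 (two distinct causal variants)
term is the off-diagonal pair sum; for regions up to 2048 variants it is
computed by explicit log-sum-exp over the i ≠ j matrix, because the
algebraically equivalent difference form
log Σᵢ + log Σⱼ − correction cancels catastrophically when a single
variant dominates both traits. All five posteriors are always reported;
PP.H4 > 0.9 is additionally exposed as a decision flag. If both traits
carry allele columns, trait-2 betas are sign-flipped where effect/other
alleles are swapped and strand-ambiguous (A/T, C/G) variants are dropped
with a warning; without allele columns, alignment is assumed.

A configuration-enumeration oracle (every causal assignment with its
prior and likelihood ratio, regions ≤ 12 variants) validates the region
computation to 1e-10 relative in the tests.

## Module detection

Partner recruitment uses Spearman correlation (Pearson on mid-ranks,
average ranks for ties). The printed form of the recruitment rule is
read as |ρ| ≥ threshold; a `signed` flag offers the literal one-sided
reading. Partners are sought transcriptome-wide within the tissue.

Clustering is agglomerative with average linkage on D = 1 − ρ, a
standard pairing for correlation distance; the tree is cut with
`cut_tree` to exactly K clusters, and labels are renumbered by first
appearance so the partition is stable under gene input order.

The number of modules is selected with the gap statistic:
W_k = Σ_clusters (Σ pairwise squared distances)/(2·cluster size) —
identically the within-cluster sum of squares — on the gene expression
profiles with Euclidean geometry; B reference datasets are drawn
uniformly over the observed per-feature ranges and clustered with the
same average-linkage routine; s_k = sd_b(log W\*_kb)·√(1+1/B).
globalSEmax returns the smallest k with Gap(k) ≥ Gap(k_gm) − s_{k_gm},
k_gm the global maximiser (the rule yields one k; "maximizing" it is
read as applying it). k = n is excluded as degenerate (zero dispersion
for both data and reference). Because inverse-normal-transformed genes
are standardized, squared Euclidean distance is an affine function of
1 − ρ_Pearson, so gap selection on Euclidean profiles and the final cut
on correlation distance are mutually consistent; the split is a design
choice where the literature admits several reference schemes. Defaults:
Kmax = min(10, n_genes − 1), B = 100 (50 in the demo for speed).

## Enrichment and retention

One Fisher's exact test per (module, pathway) pair with at least one
shared gene, over the universe of all genes in the tissue's expression
matrix — the least-biased background available, and configurable. The
odds ratio is the sample OR a·d/(b·c) with +inf / 0 / NaN conventions
for zero products; the p-value is two-sided (one-sided available).
BH adjustment is applied within tissue for the retention filter, with a
raw-p option since published analyses of this design often report
unadjusted Fisher p-values. Retention: a module is kept iff it contains
≥ 1 eGene and has ≥ 1 pathway at the configured (adjusted) alpha;
dropped modules are logged with the reason.

## Reporting

Sharing summaries count distinct tissues per eGene, per
(variant, gene) pair and per retained enriched pathway, flag beta
sign-consistency across tissues, and total distinct variants, eGenes
and (variant, gene, tissue) triples. "Detected in a tissue" means the
per-tissue significance flag, not a nominal-p cut. Modality overlap
labels each variant with the subset of {eQTL, pQTL, mQTL} it belongs to
after each modality's own significance rule. Outputs are TSVs; plotting
is intentionally out of scope.

## Pipeline

Stages run in order simulate → map-qtl → ld → coloc → modules → enrich
→ report, writing every intermediate as TSV (tab-separated, header,
UTF-8, '.' decimal, `NA` missing; 1-based coordinates except BEDPE).
The JSON manifest records the config SHA-256, seed, per-stage row
counts and wall clock; identical config + seed reproduces identical
tables byte-for-byte (wall clock excluded from the determinism
contract). Configuration is YAML with all thresholds surfaced
(r² ≥ 0.80, |ρ| ≥ 0.90, FDR 0.05, p < 5·10⁻⁸, PP.H4 > 0.9 defaults).

## Validation studies and their limits

The test suite validates by construction: exact oracles (normal
equations; full hypergeometric enumeration; causal-configuration
enumeration; brute-force agglomeration and dispersion), null
calibration (uniform nominal p on 5000 null tests; eGene proportion at
FDR 0.05 within sampling error over 50 null tissues of 500 genes,
B = 200), parameter recovery (planted β = 0.8 at n = 300; r² = 0.9
proxies recovered and r² = 0.5 excluded at n = 2000), colocalization
decisions (shared-causal PP.H4 > 0.9; distinct-causal H3 top, 50
regions of 200 variants at n = 2000), module recovery (4 planted
modules of 25 genes at factor SD 3× noise, n = 500: globalSEmax k = 4,
ARI ≥ 0.9, planted pathway top-enriched) and bit-identical demo reruns.
Study sizes were chosen so the whole suite completes in a few minutes
on one CPU while keeping Monte-Carlo error small relative to the
asserted margins.

Two calibration caveats are inherent rather than implementation
artifacts. First, Fisher's exact test has discrete, conservative
p-values with a point mass at 1, so its null distribution is validated
by level (type-I error ≤ α at several α), not by a continuous
uniformity test. Second, the ±0.15 recovery band for β = 0.8 at
n = 300 with unit noise corresponds to ±1.84 sampling SDs of the OLS
slope even at the most informative allele frequency (maf 0.5,
Var(dosage) = 0.5), i.e. an expected 93.4 % success rate; the recovery
test asserts the nominal 95 % bar and is expected to sit marginally
below it.

What passing does **not** show: the generator has no covariate
structure (ancestry, batch, cell-type composition), no realistic LD
beyond block-geometric decay, Gaussian expression noise only, and
single-causal-variant colocalization scenarios. Behaviour on real
panels — where covariate correction, allele-frequency spectra and
multi-causal regions matter — is out of scope, as are WGCNA-style
soft-threshold modules, GSEA-style rank enrichment, fine-mapping and
conditional analyses.
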