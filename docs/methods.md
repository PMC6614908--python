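# Methods

`cpgfinemap` is a simulation framework for a specific question: how much
does genotype imputation error degrade statistical fine-mapping when the
causal variant is known?  DNA methylation at a CpG-SNP is the model trait:
a SNP that destroys the C or G of a CpG dinucleotide abolishes methylation
at that site, so the trait has a known causal variant of large effect.
Everything below is synthetic; the package never touches cohort data.

## Trait model

Phenotypes follow the standard additive model

    y = Σ_c X_c β_c + ε,   β_c ~ N(0, 1),   ε ~ N(0, σ_e²),

with σ_e² set so that the genetic fraction of the phenotypic variance
equals the target narrow-sense heritability h².  The genetic variance is
computed from the realized covariance of the causal dosage columns (not
the independent-site approximation), so causal sites in LD are handled
exactly.  h² is enforced at the population level: each replicate's
realized variance explained fluctuates around h², and only the mean over
replicates is pinned.  With a single causal variant, h² *is* the variance
explained by that variant, which is what makes coverage a clean metric.
Defaults mirror the regime of interest: h² ∈ {0.05, 0.1, 0.2} with 0.2 as
the headline value, n = 1366 samples, causal MAF > 0.05.  Methylation
β-value bounding to [0, 1] and covariate structure (chip, cell counts,
sex) are deliberately not emulated: the simulated trait stands for the
*residualized* methylation level that association analyses actually use.

## Genotype simulation

Cohort haplotypes are replaced by a founder-mosaic generator: each
haplotype copies from a pool of founder haplotypes (allele frequencies
drawn from a U-shaped Beta(0.8, 0.8)), switching founders between
adjacent sites with probability 1 − exp(−recomb_rate × distance) and
flipping alleles at a small per-site mutation rate.  Defaults (12
founders, 2×10⁻⁶ per bp switch rate, 0.002 mutation rate, 200 kb region,
~100–150 sites) produce block-structured LD that decays with distance —
the only property of real haplotypes the downstream analysis exploits.
No claim of coalescent realism is made; parameters were chosen once for
qualitative LD realism.  Monomorphic sites are dropped at construction
(logged), mirroring MAF QC.  Exact small loci (e.g. the masking
configuration) are instead built from explicit haplotype-frequency
tables, with multinomial sampling or largest-remainder "exact" rounding.

## Imputation emulation

The array→imputation path is emulated, not wrapped: sites are masked to
an "array" subset, and the hidden sites are filled in per haplotype by a
Li–Stephens copying HMM against a reference panel (forward–backward;
emission error `mismatch_rate` = 0.005 at observed sites; transition
switch probability 1 − exp(−switch_rate × distance), `switch_rate` =
10⁻⁶/bp; posterior-mean allele at unobserved sites; diploid dosage = sum
over the two haplotypes).  Two deliberate simplifications:

* **Phasing is bypassed.**  The HMM runs on each *true* target haplotype
  (known in simulation), isolating imputation error from phasing error.
* **No genetic map.**  Scalar mismatch/switch rates; the experimental
  knobs are the reference panel's **size** and its **divergence** from
  the study population (extra per-site allele flips at a drift rate),
  because the claim under study is about reference-panel quality, not any
  particular HMM parameterization.

The per-site info score is the MaCH/IMPUTE-style ratio of observed dosage
variance to the 2p(1−p) expected under Hardy–Weinberg, clipped to [0, 1].
QC applies MAF ≥ 0.01, Hardy–Weinberg exact-test P ≥ 10⁻⁶ (Wigginton-style
exact computation on rounded genotypes), missingness ≤ 5%, and info ≥ 0.8
(stringent default) or ≥ 0.3 (permissive alternative); all filters are
evaluated on the input and the union removed, so ordering is immaterial.
Dataset arms are restricted to their common post-QC sites before
fine-mapping, so every method sees the same candidates in every arm.

## Fine-mapping methods

All three construct a nominal 95% set under a hard-wired single-causal
assumption, and all treat complete-LD groups (r² = 1 on the analyzed
dosages, tolerance 1 − 10⁻⁹) as single units — tested once, counted
together, admitted together.

**J-test.**  Rank SNPs by association (ascending p, ties by |t| then
position).  The top SNP enters the set; for N = 2, 3, … regress y on the
N-th SNP plus the fitted values of the top-SNP regression and test the
fitted-values coefficient λ_N at the Bonferroni-corrected level
α/(N−1).  Significance means the top SNP explains significantly more
variance than rival N: stop and exclude N and everything below;
otherwise rival N joins the set.  Note the direction: *larger* α stops
earlier and can only shrink the set (level = 1 − α).

**PPA.**  Per-SNP Bayes factor of the single-SNP model against the
intercept-only null, normalized locus-wide: PPA_i = BF_i / Σ_j BF_j
(log-space, max-subtracted), then SNPs accumulate in descending PPA until
0.95.  The default BF is Wakefield's approximation
√(V/(V+W))·exp(z²W/(2(V+W))) from the OLS estimate (V = se²), with prior
effect variance W = 0.5 — deliberately wide because CpG-SNP mQTL effects
are very large; ranking is insensitive to W in the regimes tested.  An
exact conjugate BF (β ~ N(0, Wσ²), flat intercept, Jeffreys σ²) is
available as `model="conjugate_exact"`.

**MCMC counting.**  A spike-and-slab Gibbs sampler over a sparse linear
model on standardized dosages: per-site inclusion indicators with
π ~ Beta(1, M), slab variance σ_b² ~ InvGamma(2, 1), Jeffreys residual
variance; conjugate block updates of (γ_j, β_j) with an incrementally
maintained residual correlation vector.  Defaults: 11,000 iterations,
1,000 burn-in, thinning 10.  At every counted iteration the included site
with the largest |β| (on standardized genotypes) is recorded; the 95% set
accumulates sites by descending count share, ties broken by position.
This sampler is the sparse (BVSR) limit of the mixed-model samplers used
for this task in practice; the counting procedure — which is the part
under study — is agnostic to the exact sparse prior.

## Conditional analyses

Two multi-signal procedures on individual-level data with a genome-wide
threshold of 5×10⁻⁸ and a collinearity cap of r² = 0.9: forward selection
(condition on the accumulated top SNPs until nothing remains significant;
conditional tests use Frisch–Waugh residualization, equivalent to the
joint OLS t-test) and stepwise joint selection (alternating forward and
backward steps with the collinearity screen — the individual-level
analogue of summary-statistic conditional-and-joint analysis; summary
algebra is unnecessary here because individual genotypes always exist).

## The masking configuration

`build_masking_scenario` constructs the adversarial locus: the two-locus
haplotype class {top-major, cpg-minor} is absent, so D′ = 1 while r² < 1,
and the top SNP's minor allele (frequency 0.30) carries every CpG-SNP
minor allele (frequency 0.15) plus additional trait-lowering chromosomes.
Defaults effect_cpg = −0.5, effect_top = −1.0, h² = 0.2, n = 1366 were
fixed by a power calculation: both marginal effects are genome-wide
significant (χ² ≈ 50 and 75), the top SNP explains more variance, and the
conditional CpG-SNP test sits at χ² ≈ 15 (p ≈ 10⁻⁴) — well clear of
5×10⁻⁸ — so conditional analysis reports a single signal at the wrong
SNP while the credible sets exclude the causal variant.  Ten unlinked
neutral sites pad the locus so set construction is non-trivial.

## Pre-registered experiments and problem sizes

`cpgfinemap.experiments` freezes the study conditions; the acceptance
script and the heavy tests only call these functions.

* **Nominal coverage** — 300 single-causal loci, true genotypes,
  n = 1366, ~150 sites, h² = 0.2, causal MAF > 0.05.  Expected: each
  method's coverage ≥ 0.95 within two binomial SE.
* **Heritability recovery** — 500 replicate phenotypes on one fixed
  n = 1366 dataset; mean causal-SNP regression r² ≈ 0.2.
* **Degradation ordering** — 300 matched loci, three arms: truth,
  imputation against a large reference (400 haplotypes, 2% divergence)
  and against a small one (50 haplotypes, 5% divergence); array = every
  4th site, causal never genotyped; QC at info ≥ 0.3.  Two aspects of
  this design are load-bearing.  First, both panels are external to the
  study population, as real panels are: a same-population panel is
  oracle-grade — any high-LD array rival that could displace the causal
  SNP simultaneously pins the causal's imputation to near-perfection, so
  a matched panel shows no degradation at all.  Second, the permissive
  info threshold: at info ≥ 0.8 the emulator mostly *removes* poorly
  imputed causal sites, and since arms are intersected, removal dilutes
  every arm equally instead of expressing the between-arm contrast.  A
  causal variant absent from the intersection counts as a miss in every
  arm.
* **Masking reproduction** — 50 replicates of the masking scenario.
* **Stratified coverage** — 150 loci against the small panel, causal
  genotyped on the array in half of them; coverage by provenance stratum.

## Numerical choices and degenerate inputs

Zero-variance (monomorphic) sites: excluded from association ranking
(NaN statistics), BF fixed at 1 with a warning, zero counts in the
sampler, dropped by MAF QC.  Unphased LD falls back to two-locus EM
(linkage-equilibrium start, 100 iterations or Δ < 10⁻¹²).  The 95%
quantile of set sizes uses the nearest-rank convention.  Coverage is
stored at full precision and formatted only at presentation.  Credible
sets store evidence in construction order; PPA normalization is exact to
10⁻¹² in log space.  Per-locus child seeds are spawned as
SeedSequence([master, locus]), so any locus reproduces in isolation and
aggregation is order-independent.  The two Monte-Carlo-heavy kernels
(Li–Stephens forward–backward, Gibbs sampler) are numba-compiled.

## What passing tests do and do not show

The generator reproduces block LD, Hardy–Weinberg diploids, missing
haplotype classes, panel-size/divergence-dependent imputation error, and
info-score behaviour — enough to exercise every decision the fine-mapping
methods make.  It does not reproduce human allele-frequency spectra,
fine-scale recombination maps, genotyping-array site-selection bias,
phasing error, or multi-ancestry reference mixtures; absolute coverage
numbers from these simulations therefore do not transfer to any real
cohort.  What does transfer is the mechanism: the ordering of arms by
reference-panel quality, the genotyped-vs-imputed stratum gap, and the
D′ = 1 masking failure mode are structural results that the synthetic
data are sufficient to demonstrate.

## Known limitations

Single causal variant is assumed by every set constructor (by design —
the object of study, not a modelling oversight).  The J-test Bonferroni
index reading α/(N−1) is one of two defensible conventions; it is the
implemented default and switching would only loosen/tighten stopping
slightly.  The spike-and-slab sampler is a surrogate for heavier
mixed-model samplers; its counts agree on dominant-signal loci but are
not a drop-in reimplementation.  EM-based LD from unphased data can be
biased near fixation.  The imputation emulator's info scores track true
accuracy more faithfully than real pipelines' estimates do, which makes
QC *more* effective in simulation than in practice.
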