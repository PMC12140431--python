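# Methods

## Model

`colocpriors` implements single-causal-variant Bayesian colocalisation of
two traits from regional summary statistics. For each variant i the
Wakefield approximate Bayes factor against the null is computed from
z = β/se, V = se² and a normal effect prior N(0, W):

    lABF_i = ½ [ln(1 − r_i) + r_i z_i²],   r_i = W / (V_i + W).

W defaults to 0.15² for quantitative traits (scaled by sdY when supplied,
default 1) and 0.2² for case-control traits, matching the conventional
choices for standardized and log-odds effects. All Bayes-factor
arithmetic is in natural-log space with log-sum-exp reductions, since z²
in strongly associated loci overflows linear space.

A causal configuration assigns trait 1's causal variant to
{none, 1, …, Q} and likewise for trait 2. Configuration priors are built
from per-variant probabilities p₁ᵢ, p₂ᵢ, p₁₂ᵢ: configuration (i, none)
has prior p₁ᵢ; (none, j) has p₂ⱼ; (i, j) with i ≠ j has p₁ᵢ·p₂ⱼ; (i, i)
has p₁₂ᵢ; and the double null carries the remaining mass
1 − Σ(all of the above). Posterior hypothesis probabilities are the
likelihood-weighted sums of configuration masses binned into H0–H4. The
H3 double sum is collapsed to the algebraically identical
product-minus-diagonal form, Σ_{i≠j} aᵢbⱼ = (Σa)(Σb) − Σᵢaᵢbᵢ, keeping
the computation linear in Q; `brute_force_posterior` performs the literal
(Q+1)² enumeration (Q ≤ 12) and the test suite asserts agreement to 1e-10
on a thousand random instances.

Note one deliberate convention: the double-null configuration carries its
*exact* prior mass 1 − Σ(…) rather than the common shortcut of giving H0
unit weight. The two differ by a relative O(Q·(p1+p2)) ≈ 10⁻³ at typical
region sizes; exact enumeration is self-consistent with the brute-force
oracle and with the property that unit Bayes factors return exactly the
normalised prior hypothesis masses.

## Variant-specific priors

User-supplied non-negative weights w₁ᵢ, w₂ᵢ are converted by

    p_{k,i} = Q · p_k · w_{k,i} / Σ_j w_{k,j}
    p_{12,i} = (p12 / (p1·p2)) · p_{1,i} · p_{2,i}

so the priors are proportional to the weights while Σᵢ p_{k,i} = Q·p_k
always, and Σᵢ p_{12,i} = Q·p12 whenever at most one trait's weights are
non-uniform. When both traits carry non-uniform weights the product form
is applied literally and the realised H4 prior mass can drift from
Q·p12 (upward for positively correlated weight vectors, by
Cauchy–Schwarz); the library warns with the realised mass rather than
silently renormalising, and the recommended usage is to weight one trait
at a time. Individual zero weights are legal (the variant simply gets
zero prior); an all-zero vector is rejected because the normalisation is
undefined. If floating-point cancellation drives the H3 numerator
non-positive while its prior mass is structurally positive, PP.H3 is
clamped to zero with a warning when the relative magnitude is below
1e-12, and treated as an input error otherwise.

Base priors default to (p1, p2, p12) = (1e-4, 1e-4, 5e-6), values known
to give robust inference across scenarios; Q·p_k is validated against the
total prior mass exceeding 1.

## Prior sources

**eQTL–TSS distance density.** Significant eQTL records (p < 5×10⁻⁸) are
reduced to the single most significant record per gene (ties broken by
TSS distance, then variant id). Signed distances d = p − t for + strand
genes and t − p for − strand genes are accumulated within a ±500 kb
window and smoothed by a Gaussian KDE. The bandwidth is the
Sheather–Jones solve-the-equation plug-in — implemented here with binned
pair counts (1,000 bins) because no installed library provides it; a
frozen test pins it to within 1% of the exact solve-the-equation solution
computed independently in R — multiplied by 8 to absorb uncertainty in
the true TSS location. The estimate is evaluated at 512 equally spaced
points spanning exactly the observed data range (a zero-cut grid), so the
trapezoid integral can fall slightly below 1 when kernel tails cross the
range boundary; the container accepts [0.9, 1.1]. Weights for a region
are linear interpolations of the grid at each variant's signed distance,
with boundary clamping outside the grid and a 1e-12 floor so a weight
vector can never be identically zero. Interpolation rule and boundary
clamping are this package's choices; the 512-point representation,
bandwidth rule, zero cut and ×8 adjustment follow the estimator's stated
settings. If the plug-in solver fails on pathological data the code falls
back to Silverman's rule with a warning.

**ABC enhancer–gene scores.** Records are filtered to the gene of
interest; per enhancer interval the score is the median across
biosamples; a variant inside an interval (0-based half-open test against
pos − 1) takes that score, the maximum when intervals overlap (our
choice: keep the strongest regulatory evidence); a variant in no interval
takes the constant 0.0075 — half of 0.015, the minimum score retained in
the public dataset — rather than half the *observed* minimum, for
bit-compatibility with the described processing.

**Gnocchi constraint.** A variant takes the signed constraint score of
the 1 kb region containing it, else of the nearest scored region
(interval-edge distance, ties to the lower start coordinate). Scores map
to weights by a max-subtracted softmax computed over the analysed
region's variants only — Eq-style normalisation renormalises within the
region anyway, so a genome-wide softmax would change nothing.

**PolyFun per-SNP heritability.** Weights are tabulated per-SNP variance
estimates matched by id, falling back to (chrom, pos); unmatched SNPs
receive the minimum variance present in the table. An all-zero result
(conceivable if every matched variance is zero) falls back to a flat
vector.

## Simulator

Synthetic binary haplotypes stand in for a phased reference panel.
Latent Gaussians with one of two block structures — `ar` (AR(1) decay
within blocks) or `exchangeable` (constant latent correlation within
blocks, an LD plateau) — are thresholded at each variant's target allele
frequency; LD and MAF are then the *empirical* values computed from the
haplotypes, and monomorphic columns are resampled with a warning.

Marginal association z-scores follow the standard single-causal-variant
construction: with causal variant c, log-odds effect γ, case fraction φ
and N = cases + controls,

    se_i = [2 f_i (1 − f_i) φ (1 − φ) N]^{-1/2},
    μ_i  = r_{i,c} · γ / se_c,
    z ~ MVN(μ, R),

where R is the LD matrix (repaired by eigenvalue clipping at 1e-10 when
it is not numerically PSD). Study-design defaults: 2,000 cases and 2,000
controls; γ drawn as the maximum of 100 N(0, 0.0025) variables (variance
notation, i.e. sd 0.05 — an sd of 0.0025 would make the acceptance rule
essentially unreachable at this sample size); a simulated region is
accepted only when its minimum two-sided p-value is below 5×10⁻⁶,
retrying up to 2,000 draws and raising a typed `SimulationError`
otherwise. The retry filter is applied to each trait independently.
Under H4 both traits share the causal variant drawn from the supplied
distance density; under H3 trait 2's causal variant is uniform over the
remaining variants.

## The simulation study in the test suite

The directional acceptance test uses 200 simulated pairs per hypothesis,
split over two contrasting 500-variant high-LD regions:

* `SimConfig.high_ld` — one AR(0.99) block spanning the region, so
  correlation decays gradually and the region ends are distinguishable;
* `SimConfig.ld_plateau` — two exchangeable blocks with latent
  correlation 0.97, emulating loci where a single haplotype block spans
  hundreds of kb and distinct causal variants are nearly confusable.

Both restrict to common variants (MAF 0.1–0.5), since thresholding
attenuates binary LD most for rare variants and the loci this emulates
are common-variant dense. The ground-truth causal density is a
Laplace(10 kb) at the TSS — the sharp concentration seen for top
whole-blood eQTLs, where half the mass lies within ~7 kb of the TSS — and
the same density supplies the trait-1 weights. The two region types play
complementary roles: with gradually decaying LD an informative prior
sharpens a true shared signal (raising Pr(H4) under H4), while on an LD
plateau distinct causal variants masquerade as shared and the prior's
penalty on the distal variant is what lowers Pr(H4) under H3. At the
suite's fixed seed the study yields mean ΔPr(H4) ≈ +0.07 under H4 and
≈ −0.03 under H3 (one-sided t-tests p < 10⁻³), and the H4 gain is larger
for causal variants in the top decile of prior density than in the
bottom decile.

The prior is applied to trait 1 only — the trait whose causal variant is
density-drawn under both hypotheses — consistent with the recommendation
to weight one trait at a time; weighting both traits with the literal
product form inflates the H4 prior mass and reverses the H3 direction,
which is precisely why the library warns in that case.

What the generator does *not* emulate: real LD (only two stylised block
structures), allele-frequency/LD coupling, imputation noise, multiple
causal variants, or quantitative traits. Passing these tests shows the
weighted posterior arithmetic and the direction of prior effects under
the model's own assumptions, not performance on any real cohort.

## Benchmark metrics

Calls are aggregated to (query gene, target gene) pairs by the maximum
Pr(H4) across datasets. Significance is strict: Pr(H4) > threshold
(0.8 by convention). True/false positives are significant same-/
different-gene pairs; false/true negatives their non-significant
counterparts; recall = TP/(TP+FN) (identical to TPR), precision =
TP/(TP+FP), FPR = FP/(FP+TN), swept over thresholds 0.50–0.95 in steps
of 0.05 with undefined ratios reported as missing (NaN). GWAS peaks are
merged over 5 rounds; in each round peaks are visited in order of
increasing p-value and absorb every remaining peak within 1 Mb, the
merged peak keeping the most significant lead's position (the
lead-variant convention; the pre-merge peak definition is left to the
caller). Significance-change reports restrict to loci with some evidence
of colocalisation (max of the two runs > 0.5) and count threshold
crossings in both directions.

## Numerical and interface choices

* Positions are 1-based; interval tables (ABC, constraint) are 0-based
  half-open, the convention of each format family.
* No allele harmonisation is attempted: `harmonise()` matches on variant
  id only and documents the assumption that inputs are pre-harmonised;
  duplicate variant ids within a dataset are rejected rather than merged.
* Missing p-values are recomputed from z = β/se via the two-sided normal
  tail.
* Multiple TSSs per gene should be reduced to their median position
  upstream (even counts: mean of the central pair).
* TSV readers parse floats in round-trip mode so write→read is
  value-identical.
* The CLI resolves options as flags > config file > built-in defaults and
  exits 2 on usage errors, 1 on data/validation errors.
* All randomness flows from `numpy.random.default_rng` generators passed
  explicitly or seeded from configuration; identical seed and
  configuration reproduce outputs byte-identically (fixture bundles
  contain no timestamps).

## Problem sizes

The test suite runs the full simulation study (400 pairs at Q = 500), a
thousand-instance oracle comparison at Q ≤ 8, thousand-vector prior
conservation checks up to Q = 2,000, density estimation at n = 10,000,
and an 11-replicate timing comparison at Q = 2,000 (weighted vs
unweighted median runtime within 2×); the whole suite completes in well
under a minute on one CPU.

## Known limitations

* Single causal variant per trait; multi-signal analyses must supply
  externally fine-mapped per-signal log-BF vectors to `coloc_from_lbf`.
* Beta/se input is required; p/MAF-only summary statistics are rejected
  rather than converted.
* The two-sided weighted case (both traits non-uniform) is supported but
  only with the literal product prior and a warning; no renormalisation
  scheme is offered.
* The Sheather–Jones implementation targets the solve-the-equation
  variant only (no direct-plug-in mode).
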