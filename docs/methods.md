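# Methods

This note records the statistical models, numerical choices, and known
limitations of the `irisqtl` pipeline. Problem sizes quoted here (group
sizes, bootstrap counts, variant counts) are the package's defaults and
can be changed through the relevant configuration objects and options.

## 1. Colorimetry

**Color space.** Photographs are converted from 8-bit sRGB to CIE
L\*a\*b\* (D65 illuminant, 2° observer) with the IEC 61966-2-1 piecewise
companding, the standard sRGB→XYZ matrix, and the CIE piecewise
cube-root Lab functions. The reference white is the image of RGB
(1, 1, 1) under the sRGB matrix rather than the nominal
(0.95047, 1, 1.08883): the two agree to ~1e-7, but the matrix-consistent
white maps the gray axis *exactly* onto a\* = b\* = 0, which keeps
achromatic pixels achromatic to machine precision. Tests verify
agreement with `skimage.color.rgb2lab` (max deviation < 0.01) and with
an independently coded evaluation of the formulas (< 1e-13).

**White balance.** Gray-world: each channel is rescaled so channel
means over the reference pixels are equal to their common mean. The
default reference is the whole image; `reference="background"`
restricts the means to non-iris pixels. Scaling is always applied to
the whole image, and output is re-quantized to 8 bits.

**Pixel exclusion.** Specular highlights are pixels with all three
channels > 250, shadows all three < 10 (thresholds inclusive-retained:
exactly 250/10 survive). Requiring *all* channels keeps saturated
chromatic pixels — a deep blue (0, 0, 255) pixel is signal, not
artifact; `channel_rule="any"` gives the stricter per-channel variant.
An image in which no pixel survives is an analysis-level exclusion and
raises (the CLI logs it and exits 1).

**Phenotype.** Per image: median a\* and median b\* over retained
pixels (even counts use the mean of the middle two). Medians resist the
residual artifact tail better than means. L\* is deliberately not
summarized: it measures lighting, not pigmentation.

## 2. Two clusters versus one

**Model and statistic.** For a univariate phenotype sample, the
maximized log-likelihood of a two-component Gaussian mixture (unequal
variances) is compared with that of a single Gaussian:
λ = 2(ℓ₂ − ℓ₁), clipped at 0. The models are nested, so λ ≥ 0 by
construction — one EM restart starts at the single-Gaussian solution.

**Calibration.** Mixture boundary geometry invalidates chi-square
asymptotics, so λ is calibrated by a parametric bootstrap: B datasets
are simulated from the fitted single Gaussian, λ is recomputed on each
with the *same* fitting configuration, and
p = (n_exceed + 1)/(B + 1) — the add-one estimator, which is never 0
and is exact-conservative. Default B = 100,000 (minimum representable
p = 1e-5); tests calibrate at B = 999. Measured type-I rate at
α = 0.05: 0.036–0.058 over 500 replicates at n = 8, inside the exact
binomial 99% interval.

**Numerics.** All EM fits (observed statistic, bootstrap replicates,
subsamples) are stacked into a single (datasets × restarts, n) array
and iterated together with an active-set convergence mask; a
100,000-replicate null costs seconds, not hours. Component variances
are floored at 1e-6 × sample variance (an absolute fallback of
1e-12·max(1, μ²) covers zero-variance input, with a warning). The
unequal-variance mixture likelihood is unbounded; maximizers in which a
floored-variance component carries essentially a single observation
(weight < 1.5/n) are the classical *spurious* solutions and are
excluded from the restart max whenever a non-spurious solution exists.
Genuine tight clusters (e.g. two point masses of four observations
each) are not spurious under this rule and are kept.

**Initialization schedule.** Deterministic restarts first — symmetric
split of the single-Gaussian fit, below/above-median split, quartile
split, and two boundary starts placing a floor-variance component on
the extreme low/high observation — then random two-point starts. For
small samples an `exhaustive` mode adds every contiguous sorted window
of size 1–3 and every prefix threshold split as starting points, and a
`polish` mode refines the top-ranked EM solutions by direct Nelder–Mead
maximization (EM converges linearly and can stall on likelihood ridges;
near-tied restarts can sit in different basins, so the top eight are
polished, not just the best). In this most thorough mode the estimator
matches an independent dense grid search to ~1e-15 on datasets with
n ≤ 10, on a bounded parameter space (variance floor 0.05 × sample
variance — with a near-zero floor the global "optimum" is always a
degenerate singleton spike whose height is set by the floor itself, so
an unbounded-space comparison would only test floor bookkeeping).

**Related-sample handling.** `min_related_subset` greedily removes the
individual with the most remaining kinship violations (ties broken by
identifier order) until all pairs satisfy φ ≤ 0.125 (avuncular or more
distant). The result is maximal (nothing removed can be added back) but
not guaranteed maximum — greedy vertex deletion is a heuristic.
`subsample_comparison` places a small group's observed λ within the
distribution of λ over m random size-k subsamples of a larger group
(default m = 1000, k = 8).

## 3. Pedigree kinship

Kinship coefficients follow the tabular recursion in topological
(parents-first) order:

    φ(i,i) = ½(1 + φ(f_i, m_i))
    φ(i,j) = ½(φ(f_i, j) + φ(m_i, j))    (j not a descendant of i)

with founders non-inbred and pairwise unrelated; unknown parents are
treated as unique unrelated founders. All quantities are binary
fractions, so results are *exact* in floating point — the hand-pedigree
test asserts equality, not closeness. The relatedness matrix K = 2φ is
verified positive semi-definite (eigenvalue tolerance −1e-8). Pedigree
validation rejects duplicate ids, cycles, and individuals appearing as
both sire and dam; parents referenced without their own record become
implicit founders. Gene dropping provides an independent stochastic
check: across many simulated loci, corr(gᵢ, gⱼ) ≈ K_ij.

## 4. Mixed-model association

**Model.** y = Wα + xβ + u + ε, u ~ N(0, σg²K), ε ~ N(0, σe²I). The
variance ratio λ = σg²/σe² is REML-estimated by one-dimensional bounded
minimization over log λ ∈ [−10, 10] (with explicit endpoint
comparison, since interior search can miss boundary optima). Rotating y
and the design into the eigenbasis of K makes the covariance diagonal
(λs + 1), so each objective evaluation is O(np²); the eigendecomposition
is computed once per kinship matrix and shared across a variant scan.
Given λ̂, β is estimated by GLS and tested with the Wald statistic
β̂²/se² against chi-square(1).

**Preprocessing.** Quantitative phenotypes are rank-based
inverse-normal transformed (average ranks for ties; rank r of n maps to
Φ⁻¹((r − 0.5)/n)). Ages enter as adjusted age = 2·age/max_age ∈ [0, 2].
A two-species categorical phenotype is coded 2/1 and used raw —
normalizing a two-point distribution would only relabel it. Candidate
covariates are screened one at a time as the focal fixed effect in the
same mixed model and retained at p < α (default 0.05).

**Missing genotypes.** Mean imputation per variant (default) or
dropping individuals; dropping re-eigendecomposes the kinship submatrix
since the cached rotation no longer applies. Monomorphic or all-missing
variants return NA rows (`tested=False`) rather than errors.

**Verification.** At λ = 0 with identity K the model reduces to OLS;
β̂ and se match statsmodels to 1e-8 and p to 1e-6. Under the generative
model with β = 0 the causal-site p-value is uniform (KS p ≈ 0.8 over
500 replicates, n ≈ 100); with β = 1 the mean β̂ over 200 replicates is
within Monte-Carlo error of 1.

## 5. Variant tables

Segregating sites are alignment columns where ingroup haplotypes carry
exactly two distinct bases (N and gaps ignored). The ancestral state is
the outgroup base when it matches an ingroup allele; otherwise the site
is flagged unpolarized and the major allele is reported ancestral.
Columns with more than two alleles are excluded with a warning.
Positions are signed offsets from the anchor column counted in ungapped
coordinates of the reference sequence (default: the outgroup); columns
where the reference is gapped have no coordinate and are excluded.
Derived-allele frequencies are tabulated per group over *founder*
haplotypes only, to avoid double-counting transmitted alleles; per-
individual dosages sum derived alleles over each individual's called
haplotypes. The report table merges mixed-model p-values by offset when
a scan table is supplied.

## 6. Synthetic data

Generators produce every pipeline input with ground truth: iris images
(elliptical mask, base Lab color rendered to sRGB plus Gaussian channel
noise clipped into the retained range [10, 250], then *exactly*
n_highlight and n_shadow planted achromatic artifact pixels — so the
expected kept-pixel count is known exactly); random-mating multi-
generation pedigrees; Mendelian gene dropping of biallelic variants;
phenotypes from the generative mixed model with a pedigree-structured
random effect drawn through the eigendecomposition of K; one- or
two-component mixture samples; and aligned haplotypes with planted
substitutions at known anchored offsets, an outgroup, and optional
reference-gap columns. Default group sizes (8 lemurs, 33 captive + 19
wild macaques, 119 humans, 6 spider monkeys) mirror a realistic
multi-species study design.

## 7. Pipeline CLI

Subcommands `simulate`, `quantify`, `cluster-test`, `kinship`, `assoc`,
`report` each run one stage on the previous stage's files. Every stage
writes `manifest_<stage>.json` with the configuration, seed, and
SHA-256 digests of inputs and outputs; identical seeds reproduce
identical files. Exit codes: 0 success, 1 partial success with logged
exclusions (e.g. unusable photographs), 2 fatal (no usable input, id
mismatch between tables).

## Limitations

- **Cluster-test power at small n.** At n = 8 with a 4-within-sd
  separation, the bootstrap LRT has ~4–12% power at α = 0.01 (depending
  on restart schedule), far below 80%. This is intrinsic to the
  unequal-variance mixture LRT: the null distribution of λ is
  heavy-tailed (99th percentile ≈ 13, driven by tight two- and
  three-point clusters under the nearly unbounded likelihood), while
  the observed λ at that separation has median ≈ 6. Because λ is
  affine-invariant, the parametric-bootstrap null equals the pooled
  null exactly, so no restart policy changes this. Raising the variance
  floor or constraining equal variances would buy power but would also
  change what the test detects (it would no longer flag genuine tight
  clusters such as two point masses). Separations of ~10 sds are
  detected reliably at this n. One acceptance test documents this gap
  and is expected to fail.
- **Greedy relatedness reduction** returns a maximal, not maximum,
  unrelated subset.
- **REML λ is bounded** to e^±10; data genuinely outside that range pin
  at the boundary.
- **Wald p-values use chi-square(1)**, slightly anti-conservative
  versus the t reference at very small n; calibration is verified at
  n ≈ 100.
- **The synthetic image model** is i.i.d. Gaussian channel noise with a
  flat base color — no gradients, pupils, or eyelash occlusion. It
  validates the pixel bookkeeping and color math, not segmentation.
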