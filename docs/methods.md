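# Methods

## Intensity estimation

The estimator is a locally weighted polynomial regression of the
per-individual homozygosity indicator on physical position, with two
multiplicative weights per site: a tricube kernel K(u) = (1 − |u|³)³ on
|u| < 1 localising the fit around the anchor, and a locus weight
L = min(MAF/0.05, 1) discounting rare variants, whose common homozygotes
carry little information about runs of homozygosity. The intercept of the
fit at an anchor position is the homozygosity intensity λ̂ there.

Assumptions worth keeping in mind: the indicator process is treated as a
smooth-intensity Bernoulli sequence along the chromosome, so the estimate is
a local probability of homozygosity, not an identity-by-descent posterior;
sites contribute independently given the local intensity; and missing
indicators are simply given zero weight (no imputation), which is unbiased
when missingness is unrelated to homozygosity.

### Windows

Windows are nearest-neighbour: for a chromosome with m_c sites and window
fraction b% (default 5), each anchor's window holds the k = ceil(b/100 · m_c)
sites closest in physical distance, ties broken toward the lower position
(deterministic). Because positions are sorted, the members are always a
contiguous slice around the anchor. The bandwidth is set to
h = (1 + 1e−9) · d_(k), just beyond the k-th neighbour distance, so the
outermost member receives a strictly positive kernel weight instead of being
annihilated at |u| = 1. When all member positions coincide with the anchor
(d_(k) = 0) the bandwidth defaults to 1 bp, giving all members full weight.

By default the intensity is evaluated at every SNV (anchor stride 1); a
stride parameter thins the anchors for large scans. The simulation
experiments below use stride 20.

### Numerical choices

* The polynomial is fit in scaled offsets u = (x_i − x)/h ∈ (−1, 1). The
  intercept — the only quantity reported — is invariant to this scaling, and
  the moment matrices stay well conditioned even for cubic fits over
  megabase windows.
* Degree p defaults to 1 (local linear), the standard bias/variance
  compromise for local polynomial regression; degrees 0–3 are supported.
* Degenerate windows (fewer than p + 1 positively weighted, non-missing
  sites, or a singular design) fall back to the degree-0 weighted mean; if
  even that is impossible (no usable sites) the anchor's intensity is
  missing and a warning is emitted. The fallback preserves profile
  alignment across individuals.
* The intercept is clamped to [0, 1]. For degree 0 the estimate is a convex
  combination of 0/1 indicators and clamping never binds; for degree ≥ 1
  extrapolation at chromosome edges can leave the interval, and clamping is
  the minimal mechanism keeping the profile interpretable as a probability.
* The vectorised scan solves the per-window normal equations from weighted
  moment sums (closed form for degrees ≤ 1, batched solves above); a test
  pins it against an explicit per-window weighted least squares at 1e−10.

## Region calling

A region of HD is a maximal run of consecutive anchors with intensity at or
above 0.9 whose anchor-to-anchor span is at least 5 Mb; both rules are
inclusive. Missing-intensity anchors break runs. Span is measured from the
first to the last qualifying anchor — window half-widths do not extend it —
which is the conservative, reproducible reading. Summary quantiles
(five-number summaries of region lengths and of per-individual totals) use
linear interpolation (type 7). Regions belong to individuals and are never
merged across relatives; familial aggregation is reported by a separate
within-pedigree overlap report.

## Association testing

Blood-pressure preprocessing: hypertension is defined on raw values (ever
medicated, or DBP > 90 mm Hg, or SBP > 140 mm Hg, strict inequalities);
afterwards medicated individuals' DBP/SBP are raised by 5/10 mm Hg; the
quantitative responses are then log-transformed and winsorised at the
0.01/0.99 quantiles (type-7 quantiles, applied after the log). The
adjustment is guarded against double application.

Each window is tested by a marginal regression

    g(E[response]) = β0 + β1·λ̂(window) + β2·age + β3·sex

fit by GEE with pedigree clusters, exchangeable working correlation, and
robust sandwich covariance; the Wald p-value for β1 is reported. Identity
link for quantitative responses, logit for binary. Exchangeable correlation
is the standard choice for pedigree clusters when no kinship matrix is
modelled; the sandwich estimator makes the test valid even when that working
structure is wrong, provided the number of clusters is moderate (tens).
P-values are BH-FDR adjusted across all windows genome-wide per response;
untestable windows (no intensity variance, or a non-converged fit) carry
missing p-values and are excluded from the adjustment's test count. A
"significant region" is a maximal run of consecutive windows with adjusted
p ≤ 0.05, reported by its first and last anchor.

The GEE solver is implemented in-package: with an exchangeable structure,
R⁻¹ has the Sherman–Morrison form (1−α)⁻¹(I − γ11ᵀ), so every per-cluster
quantity reduces to column sums and the scan avoids per-cluster matrix
inversions entirely. Its moment estimators for the dispersion and for α
follow statsmodels' conventions, and the test suite verifies agreement with
`statsmodels.GEE` to ~1e−8 on both links; with all-singleton clusters the
fit provably reduces to the independence GLM with HC0 robust covariance,
also pinned by test.

For expression analysis, a region's intensity is summarised per individual
as the mean intensity over the anchors inside the region (the natural
summary given the region is defined by its anchors), and each transcript is
tested with the identity link, FDR-adjusted across transcripts. The volcano
fold change is log2 of mean expression in individuals with region intensity
≥ 0.9 over those below — a descriptive convention for plotting; no test
depends on it.

## Synthetic data

The generator emulates a family-based sequencing study:

* **Pedigrees** — independent three-generation families: a founding couple,
  n₂ children each married to a founder spouse, n₃ grandchildren per union
  (defaults 6 and 5: 44 members). The default cohort is 20 pedigrees (880
  individuals); a 25 × 20 variant (n₂ = 3, n₃ = 4) provides a 500-individual
  design for power runs.
* **Genotypes** — founder haplotypes are Bernoulli draws at each site's alt
  frequency (Hardy–Weinberg founders); children receive one randomly chosen
  allele per site from each parent (gene dropping), so relatives share
  alleles identical by descent at the pedigree's kinship rates — the
  within-pedigree correlation the GEE must absorb.
* **Sites** — 2,000 sites at ~50 kb mean spacing (uniform jitter), i.e. a
  ~100 Mb chromosome; 30% rare sites with MAF uniform on (0.005, 0.05),
  common sites uniform on (0.05, 0.5). With b = 5% a window holds 100 sites
  (~5 Mb), matching the region-calling scale.
* **Trait** — Q1 ~ Normal(10, 2) i.i.d., drawn from a stream independent of
  the genotype stream. The mean/sd are chosen so the logistic implantation
  grid b0 ∈ [−25, −10], b1 ∈ [0.3, 1.0] spans replacement probabilities
  from ~0 to ~1 (at b0 = −10, b1 = 1 the average probability is ½).
* **Implantation** — with probability logistic(b0 + b1·Q1), an individual's
  heterozygous calls inside the target region all become the homozygote of
  the site's major allele (homozygous and missing calls are untouched);
  sites outside the region never change. Target regions can be placed at a
  chosen percentile of local rare-variant fraction (10th/50th/90th
  mirrored in the power design).
* **Streams** — genotypes, covariates (age uniform 20–80, sex Bernoulli ½),
  trait, and implantation each use a separate generator spawned from one
  seed, so every experiment is bit-reproducible and changing one ingredient
  leaves the others untouched.

What the generator does **not** emulate: linkage disequilibrium and
recombination (sites are independent given the pedigree, so no natural ROH
arise — background intensity hovers around the expected homozygosity
~0.6–0.7 and HD tracts exist only where implanted), realistic allele
frequency spectra, genotyping error, and missingness. Passing tests
therefore demonstrate the estimator's and test's statistical behaviour under
clean pedigree-clustered data, not robustness to LD-induced autocorrelation
or data artefacts in real sequencing studies.

## Operating-characteristic experiments

* **Type-1** — one cohort (20 pedigrees × 44, 2,000 sites) is generated
  once; each of 200 replicates redraws Q1 independently of the genotypes
  and runs the full pipeline (intensity with b = 5%, degree 1, anchors every
  20th SNV → 100 windows; GEE scan; BH-FDR at 0.05). The per-replicate
  type-1 error is the fraction of testable windows declared significant;
  the experiment reports the mean and its Monte-Carlo SE. Keeping the
  genotypes fixed across replicates matches a design in which one genotype
  data set is analysed against many simulated trait sets.
* **Power** — 200 replicates on a 500-individual cohort: each replicate
  redraws Q1, re-implants the target region (one region spanning 10% of the
  chromosome by default), recomputes MAF and the intensity profile from the
  implanted genotypes, and scans; detection means at least one
  FDR-significant window whose member span overlaps the region. Power is
  the detected fraction. A grid helper sweeps (b0, b1).

The anchor stride of 20 for these experiments is the package's choice of
problem size: it keeps windows densely overlapping (adjacent windows share
80% of their members) while making 200-replicate experiments run in about a
minute on one CPU.

## Known limitations

* No kinship-matrix modelling: exchangeable GEE treats all within-pedigree
  pairs alike; with very few clusters (≲10) the sandwich variance is
  anti-conservative, as in any cluster-robust analysis.
* Region span is anchor-based; with sparse anchors the reported bounds are
  granular to the anchor spacing.
* Multiallelic VCF records are split into biallelic sites sharing a
  position; genotypes carrying an unrepresented allele become missing.
* MAF is computed from the full analysed sample, not founders only; in deep
  pedigrees this slightly biases frequencies toward the founders of large
  families.
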