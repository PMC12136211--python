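# Methods

## Ancestry PCs from SNP-overlapping methylation probes

A CpG probe whose target cytosine coincides with a common SNP measures, in
effect, a noisy transform of the local genotype: the beta value
β = M/(M + U + offset) clusters near distinct levels for the three
genotypes. PCA across many such probes therefore recovers axes of genetic
ancestry. The difficulty is that methylation intensities also carry
technical variation (plates, slides, scanner drift — summarized well by the
array's control probes) and biological variation (leukocyte composition,
sex, age), which can out-weigh the ancestry signal and capture the leading
PCs.

The package computes three variants of ancestry PCs over the selected
probes:

* **raw** — PCA of row-centered betas; the classic baseline.
* **residualized** — each probe's betas are first replaced by OLS residuals
  on a nuisance design X = [1, sex, age, cell-proportion PCs, 10
  control-probe PCs]; the hat-matrix projection is shared across probes.
  Residual rows are exactly orthogonal to every design column (validated to
  1e-8 in normalized terms).
* **combined** — the residual rows are stacked with genotype dosages called
  from the array's dedicated rs probes, then every row is centered. Genotype
  calls are essentially noise-free ancestry features, which stabilizes the
  leading PCs when technical effects are strong.

PCA is center-only (no variance scaling — rows are already centered and all
features live on the beta/dosage scale), computed by SVD with samples as
observations. Signs are fixed by making each component's largest-magnitude
loading positive. Score columns are then min–max scaled to [0, 1] so
variants are directly comparable; the unscaled scores and
explained-variance fractions (computed before scaling) are also returned.

## Probe selection

SNP0bp probes are CpG-kind probes with SNP overlap distance exactly 0 and
MAF ≥ 0.05 (inclusive); probes with absent MAF or distance are excluded.
rs probes are taken wholesale. Annotation tables are plain TSV/CSV with a
per-platform column mapping; for EPICv1, two published overlap annotations
may be supplied and are unioned (first occurrence wins on duplicate ids).
Selections are sorted lexicographically by probe id so outputs are
order-independent. Cross-reactive/multi-mapping flags are deliberately not
used as exclusion criteria — only SNP overlap and MAF.

## Preprocessing

* **Background correction** subtracts, per sample and channel, the 5th
  percentile of that sample/channel's negative-control intensities; results
  are floored at 1 AU. Type-II probes route M to the green and U to the red
  channel.
* **Detection p-values** model the total intensity M + U under
  Normal(μ_bg, σ_bg²) from the matching channel's negative controls
  (type II pools both channels); p is the upper tail, σ floored at 1e-6.
  The formula is this package's choice; the quantity itself is standard.
  Entries with p > 1e-16 become missing (strict inequality; the threshold is
  configurable).
* **Probe QC** removes a probe when strictly more than 5% of samples have a
  bead count below 3, or strictly more than 10% are missing. Boundary
  fractions are retained.
* **Quantile normalization** is across-sample, missing-aware: the reference
  is the mean of per-sample empirical quantile functions; ties map to the
  average of their target quantiles. M and U are normalized as separate
  matrices, over the retained SNP0bp probes.
* **rs probes are *not* quantile normalized** (a flag restores joint
  normalization). The panel here is small and each sample's rs beta
  distribution depends on its genotype composition, which differs across
  ancestry groups; forcing a common distribution measurably blurs the
  trimodal clusters (per-genotype SD roughly tripled in simulation). rs
  betas are therefore computed from background-corrected, masked
  intensities directly.
* **Imputation** is k-nearest-neighbour over probe rows (k = 5): distances
  are RMS differences over jointly observed samples; a missing entry is the
  1/distance-weighted mean of the k nearest probes observed at that sample
  (exact-duplicate rows dominate exactly); with fewer than k usable
  neighbours the probe's row mean is used. Output values are clipped to
  [0, 1].

## Covariates

Control-probe PCs are computed from log2 intensities (both channels
concatenated as features), column-centered, no scaling; ten PCs by default,
fewer (with a warning) if the matrix is rank deficient. Cell-proportion PCs
use all d − 1 components of the compositional simplex rather than a
variance cutoff. Sex is coded F = 0 / M = 1; age enters in years,
untransformed. Samples with missing sex or age are rejected rather than
imputed, and the assembled design must be full column rank — a single-sex
cohort, for example, fails fast with the collinear column named.

## Genotype calling

rs betas below 0.25 → dosage 0, above 0.75 → dosage 1, in between (both
boundaries included) → 0.5. Fixed thresholds are used instead of per-probe
mixture clustering because rs probes are engineered to be cleanly trimodal
and determinism simplifies validation. Genotype rows containing missing
calls are dropped (logged) before stacking; when no rs probe survives, the
combined variant degenerates to the residualized one with a warning.

## Evaluation battery

All clustering metrics operate on the first three scaled PCs ("3D"
framing; configurable). Silhouette s(i) = (b − a)/max(a, b) with Euclidean
distances; singleton clusters score 0, as does the degenerate a = b = 0
case. Centroids are coordinate-wise means, cluster density the mean member
distance to its centroid, and separation the pairwise centroid distance
matrix. PC-vs-group association uses one-way ANOVA when Shapiro–Wilk on the
one-way residuals and median-centered Levene both exceed α = 0.05,
otherwise Kruskal–Wallis; groups with fewer than three members are excluded
from testing. Correlation with genotyping PCs is the 3 × 3 grid of absolute
Pearson coefficients plus its mean, with undefined (constant-column) cells
excluded. Covariate screening with repeated samples uses a random-intercept
mixed model fit by ML (not REML, so the fixed-effect likelihood-ratio test
is valid) with χ²(#groups − 1) reference; optimizers are retried and the
best likelihood kept, because a stalled fit can otherwise produce a
negative LRT.

For summarizing how well PC1 tracks ancestry we report the **multiple
correlation** of the PC with the group factor (square root of the one-way
R²). With two groups it equals |Pearson r| against the 0/1 code; with more
groups a literal 0/1/2 coding would make the number depend on an arbitrary
ordering of group labels, whereas the multiple correlation is invariant.

## Synthetic cohorts

The simulator produces everything the pipeline reads plus full ground truth.
Defaults define the standard study conditions and are fixed:

| parameter | default | meaning |
|---|---|---|
| groups | 3 × 50 individuals | ancestry groups |
| repeats | 20% of individuals ×2 | repeat samples (fresh batch/cell/noise) |
| fst | 0.1 | Balding–Nichols divergence |
| n_snp0bp / n_rs / n_control | 500 / 50 / 200 | probe panel |
| genotype_means | 0.1 / 0.5 / 0.9 | trimodal beta levels |
| noise_sd | 0.05 | beta-scale residual SD (rs: half) |
| batch_sd | 0.15 | per-probe loading SD per batch factor |
| n_batches × factors | 6 × 3 | latent technical structure |
| cell_sd | 0.5 | loading per unit cell-proportion deviation |
| sex / age effects | 0.05 / 0.002 per yr | covariate effects |
| detect_fail / low_bead | 0.002 each | sporadic QC failures |

Population structure follows Balding–Nichols: group frequencies are
Beta(p(1−F)/F, (1−p)(1−F)/F) draws around a base frequency p ~ U(0.1, 0.9);
genotypes are Binomial(2, group frequency) per individual and shared across
an individual's repeat samples. Batch effects act through three latent
factors per batch — a plate/slide/position-style structure; with a single
scalar factor and only six batches, the realized technical variance
fluctuates so much between replicates that the baseline's PC1 is sometimes
an ancestry axis, which is not the regime the comparison is about. The same
factors load on the control probes (log2 scale), which is exactly the
mechanism that lets control-probe PCs remove the batch term. rs probes
receive a 5×-shrunk total batch loading (split across factors), reflecting
their engineered robustness; together with noise_sd/2 this keeps their
per-genotype cluster SD near 0.04, consistent with ≥ 99% call recovery by
fixed thresholds. Cell proportions are Dirichlet(10, 8, 5, 3, 2, 2) —
blood-like composition. Intensities invert the beta formula around a
log-normal total intensity (median 10⁴ AU, log-SD 0.3) with Gaussian
channel background (mean 200, SD 30 for the negative controls) added;
detection failures are forced to background level. A `confounded` flag ties
batch, sex, age and cell composition to the groups, reproducing designs
where residualization removes ancestry signal itself.

What the simulator does **not** emulate: linkage disequilibrium between
sites, genomic coordinates, probe-chemistry differences between type I and
II beyond channel routing, dye bias, and admixed individuals. Passing tests
therefore demonstrate correctness of the algorithms and the direction of
the method comparison under the modeled confounding structure, not
performance on any particular real cohort.

## Problem sizes and numerical choices

The standard cohort (≈180 samples × 600 probes) runs end to end in well
under a second, so the replicate comparison uses 50 seeded cohorts and the
mixed-model calibration 200 simulations. The no-nuisance agreement check
uses a 2-group × 600-individual cohort: residualizing against k ≈ 17
covariate columns removes an expected k/n fraction of any score vector even
when the covariates carry no signal, so PC1 agreement at |r| > 0.99 between
the raw and residualized variants is only observable when n ≫ k/0.02;
n = 1200 gives an expected |r| ≈ 0.993. Two groups (rather than three) are
used there so the leading ancestry axis is unique and PC1 cannot swap with
a near-degenerate second axis.

Other numerical conventions: PCA rank is the count of singular values above
s₁·max(n,p)·ε; requested k is clipped to the rank with a warning;
explained-variance fractions use all singular values. Min–max scaling maps
constant columns to zero with a warning. The detection-threshold literal
"10E−16" is read as 1 × 10⁻¹⁶ (a flag allows 10⁻¹⁵). TSV output uses
`%.17g` floats and `NA` for missing, guaranteeing bit-exact round-trips.

## Known limitations

* Genotype calling by fixed thresholds assumes well-calibrated trimodal rs
  betas; arrays with strong dye bias may need the per-probe clustering mode
  (not enabled by default).
* The mixed-model LRT uses a χ² reference for the fixed effect only; random
  -effect boundary issues are not involved, but small-sample calibration is
  approximate (validated to the 1–9% band at 40 individuals × 2 repeats).
* The unweighted stacking of residual and genotype blocks implicitly weights
  them by their variances on the beta/dosage scale; no block reweighting is
  exposed.
* IDAT parsing, dye-bias/Noob/functional normalization, probe-type beta
  -mixture correction, and reference-based cell deconvolution are out of
  scope: cell proportions are consumed as an input table.
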