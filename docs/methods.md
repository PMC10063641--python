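# Methods

This note documents the models, estimators, numerical conventions, and
design choices behind `deltarad`, and what the synthetic-data tests do and
do not establish about real data.

## Kinetic maps

Inside the tumor mask, with acquisition times `(t0, t1, t2)` (default
`(0, 2.5, 7.5)` minutes) and signal intensities `I0, I1, I2`:

- `PE = max over {t1, t2} of (I_t - I0)/I0`, with `tPE` the *earliest*
  maximizing time (t1 wins ties). The maximization is restricted to the
  post-contrast times because the relative enhancement at `t0` is
  identically zero; for all-negative enhancement the larger post-contrast
  value is still taken so `tPE` stays well defined.
- `SER = (I1 - I0)/(I2 - I0)`. When `|I2 - I0| < 1e-9 |I0|` the ratio is
  set to 0, marking "no net late enhancement" rather than letting an
  infinity propagate into texture statistics.
- `WIS = PE/(tPE - t0)` (per minute), zero if `tPE = t0` (cannot occur
  under the post-contrast restriction, but the guard is kept);
  `WOS = (I2 - I1)/(t2 - tPE)` (intensity units per minute), zero exactly
  where `tPE = t2`.
- Voxels with `I0 <= 0` are flagged invalid, excluded from all feature
  masks, and counted in the map set's QC metadata.

In-plane resampling (for multi-resolution cohorts) interpolates intensity
slices bilinearly and masks by nearest neighbor (preserving binarity);
output coordinate `i` maps to input coordinate `i * in/out`
(origin-aligned), so 2x upsampling samples the midpoints between original
voxels. The synthetic pipeline runs on a uniform grid and skips
resampling by default; `StudyParams.resample_to=(256, 256)` enables it.

The functional tumor volume covariate is the simple enhancement-threshold
surrogate `FTV = #(mask voxels with PE >= threshold) x voxel volume`
(default threshold 0.7, reported in cm^3); it deliberately omits the
clinical protocol's bounding boxes, SER criteria, and manual refinement.

## Radiomic feature bank

22 features per kinetic map (88 per subject/time-point):

- **Intensity** (10): mean, sd, skewness, kurtosis, 10th/50th/90th
  percentiles, IQR, range, histogram entropy (32 min-max bins). Values
  whose within-mask range is at float precision are treated as constant
  (zero entropy/skewness/kurtosis).
- **Texture** (5): 3-D gray-level co-occurrence features — contrast,
  correlation, energy, homogeneity, entropy — with 32 min-max gray levels
  inside the mask, symmetric counting, distance 1, averaged over the 13
  unique 3-D direction offsets. Per-offset averaging makes the features
  exactly invariant to axis-aligned 90-degree rotations at isotropic
  spacing. A constant region yields energy 1, contrast 0, entropy 0, and
  correlation 1 (zero-variance convention).
- **Morphology** (7, computed once per mask and replicated under each map
  prefix): volume, surface area, sphericity
  `(36 pi V^2)^(1/3) / A`, major/minor ellipsoid diameters `4 sqrt(l1)`,
  `4 sqrt(l2)` from the eigenvalues of the spacing-scaled voxel-coordinate
  covariance, elongation `sqrt(l1/l2) >= 1` (higher = more elongated) and
  flatness `sqrt(l3/l1) <= 1` (higher = rounder). The elongation
  convention is chosen so the default sign table is internally consistent
  (both +1 elongation and -1 flatness point toward "more irregular =
  higher"). Surface area comes from marching cubes on the mask after
  half-voxel Gaussian smoothing; the raw staircase surface overestimates
  smooth shapes by ~9%, while the smoothed mesh puts digitized spheres
  within ~4% of the analytic area.

The bank intentionally targets the same feature families as the large
radiomics toolkits without reproducing any specific toolkit's 104-feature
list; the pipeline is feature-bank-agnostic and every downstream stage
works from column names of the form `{map}.{family}.{name}`.

## Delta features, normalization, and QC

Features are first multiplied by a per-feature sign in {+1, -1} mapping
them onto a common "higher = more heterogeneous" axis (spread, entropy and
contrast positive; energy, homogeneity, correlation, sphericity and
flatness negative; pure level/size features kept at +1 as
direction-neutral). The delta feature is `Δf = (f_T2 - f_T1)/f_T1`;
entries whose baseline magnitude falls below `1e-8` times the column's
median absolute baseline are flagged missing rather than zeroed.

Order of operations in the pipeline: columns with more than 20% missing
entries are dropped, the remainder are z-scored (sample sd, ddof 1;
zero-sd columns dropped), and the skewness/IQR screen (|skewness| > 5 or
IQR < 1 dropped) is applied to the **standardized** values. Applied after
standardization, the IQR threshold acts as a spikiness/shape filter (a
Gaussian column has z-scored IQR ~1.35); applied to raw relative deltas —
whose natural scale is well below 1 — it would empty the table. Skewness
is scale-invariant, so only the IQR verdicts depend on this ordering.
`qc_filter` itself is a pure function of whatever table it is given, and
the skewness threshold is taken on the absolute value (a tail-shape
guard, not a direction preference). Validation cohorts reuse the
discovery cohort's frozen means and standard deviations verbatim.

## Consensus clustering and the choice of k

Monti-style consensus: 500 resamples at 80% subsampling (defaults),
hierarchical clustering per subsample (Ward/Euclidean for tumors,
average linkage on `1 - Pearson r` for features), consensus(i,j) =
co-clustered / co-sampled. For each candidate k in 2..6 the empirical CDF
of the off-diagonal consensus values gives an area A(k).

The stable k is selected in two stages:

1. **Stability shortcut.** If some k yields an essentially unambiguous
   consensus matrix — proportion of off-diagonal entries strictly inside
   (0.1, 0.9) at most 0.05 — the smallest such k wins. A perfectly stable
   partition cannot be improved, and the CDF area necessarily keeps
   growing beyond it merely because subdividing a stable cluster is
   arbitrary across subsamples (the subdivided cluster alternates,
   halving within-cluster consensus). On cleanly separated data the
   relative-area rule alone therefore always overshoots the true k; the
   shortcut restores planted-k recovery.
2. **Area rule.** Otherwise the smallest k whose next relative increment
   `Δ(k+1) = (A(k+1) - A(k))/A(k)` falls below 10% is chosen (the largest
   candidate if none qualifies).

Both diagnostics (areas, relative increases, ambiguity proportions per k)
are recorded in the `ConsensusResult`.

## SigClust-style significance

For a two-way split, the cluster index is
`CI = (sum of within-cluster squared deviations from cluster means) /
(total squared deviation from the overall mean)`. The null hypothesis is
a single multivariate Gaussian with diagonal covariance. Its spectrum is
estimated from the Ledoit-Wolf shrinkage covariance — raw sample
eigenvalues overstate anisotropy at moderate n/d (Marchenko-Pastur
spread), which makes the simulated null too easy to cluster and the test
conservative (measured type-I ~0.01 with the raw spectrum vs ~0.03-0.05
with shrinkage at n=50, d=6). A background noise floor
`sigma^2 = (MAD/0.6745)^2` from the pooled centered entries is applied by
variance-preserving soft thresholding (common downward shift tau, floored
at sigma^2).

The null CI for each simulated dataset is the cluster index of a
deterministic 2-means: initialization by sign of the projection on the
first principal axis (median split), refined by Lloyd iterations; the
same routine supplies observed assignments in calibration settings. In
the pipeline, splits are tested from the dendrogram root downward and
discovery stops at the first non-significant division (p >= 0.05); the
Ward-cut observed assignment makes the pipeline test slightly
conservative relative to the 2-means optimum, which is the safe
direction. p is reported with a ~95% Monte-Carlo half-width.

## Phenotype labeling and validation projection

Within each feature group, PCA loadings are oriented so the sum of
loadings is non-negative; since input features are sign-adjusted toward
"higher = more heterogeneous", higher component values then read as
increasing heterogeneity. The cluster with the lower grand mean over the
retained oriented components becomes Phenotype 1 (decreasing
heterogeneity); ties break by size (larger cluster = 1). Validation
cohorts are z-scored with frozen statistics, projected onto the frozen
group loadings, truncated to the retained components, and assigned to the
nearest phenotype centroid (Euclidean; ties to the lower-numbered
phenotype). The serialized model carries a schema version and every seed
used during discovery.

## Signature scoring

Signature definitions are data files (JSON), not code constants. The
bundled models are **synthetic stand-ins** (marked `*_synthetic` in both
filename and model name): randomly generated centroids over placeholder
gene identifiers with the published conventions layered on top — a 0.4
cosine cut for the MammaPrint-style low-risk call; ROR-S weights
(-0.34 LumA, +0.23 LumB, +0.12 Her2, +0.05 Basal) over Spearman
correlations, with tier cuts frozen at the midpoints of the zero-noise
class scores at fixture-generation time; Spearman nearest-centroid
wildtype/mutant for p53. Boundary convention everywhere: a score exactly
at a threshold classifies to the lower-risk side. Real signature
definitions with the same schema can be dropped in without code changes.

## Survival analysis

- **Cox models**: Newton-Raphson on the Breslow partial likelihood with
  centered/scaled covariates, step halving, collinearity and separation
  guards. Breslow ties make the partial likelihood invariant under
  subject duplication and are verified against an independent
  implementation in the tests. The explicit log partial likelihood feeds
  the nested likelihood-ratio chi-square test.
- **Concordance**: Harrell's c over event-anchored usable pairs
  (`t_i < t_j` and subject i had the event), predictor ties counted 0.5;
  verified to equal brute-force pair enumeration exactly.
- **Cross-validation**: stratified (on the event indicator) 5-fold splits,
  100 replicates by default; one c per replicate computed on the pooled
  out-of-fold linear predictors (stabler than averaging per-fold c at
  ~30-events scale); the mean and the 2.5/97.5 percentile interval are
  reported. Covariates constant within a training fold are dropped for
  that fold (coefficient zero). The model roster is declarative data —
  three univariable signature models, the clinical baseline, and the
  incremental volume/signature/phenotype additions (eight models).
- **Associations**: chi-square without continuity correction for
  categorical covariates (with an expected-count<5 note), Kruskal-Wallis
  for continuous; Bonferroni threshold `alpha/m` with m the tests
  actually performed.
- **Risk stratification**: linear-predictor median split, boundary subject
  assigned low risk. Confusion matrices map phenotype 2 / "high risk" /
  mutant to "predicted event" and report PPV and NPV.

## The synthetic cohort generator

The generator defines the study conditions; its defaults emulate the
cohort structure of a ~100-subject neoadjuvant trial population:
phenotype-2 fraction 0.42, HR+ rate 0.45, HER2+ rate 0.34, overall pCR
rate ~0.27 (phenotype-dependent: 0.35 vs 0.16, reflecting the reported
direction that decreasing-heterogeneity tumors respond more often),
MammaPrint low/high 7%/93%, p53 wildtype/mutant 46%/54%, ROR-S 31/31/38.
Age, HR, and HER2 are drawn independently of phenotype (the simplest
faithful null for covariate-association testing).

**Images.** Tumors are ellipsoids (base radii 12x10x8 mm, lognormal size
factor sd 0.15) with a smoothly perturbed boundary, on a 32^3 grid at
1.5 mm isotropic spacing — a deliberately scaled-down grid that keeps a
full cohort cheap while leaving ~600-1200 mask voxels for texture
estimation. The enhancement field is
`E = E0 (1 + a g)` with `E0 = 0.8`, where `g` mixes coarse
(sigma 2.5 vox) and fine (sigma 0.8 vox) unit-variance Gaussian random
fields. The planted signal is the texture factor
`kappa = 1 ± heterogeneity_delta` applied at T2 (up for phenotype 2, down
for phenotype 1) to (a) the fluctuation amplitude `a = 0.15 kappa`,
(b) the fine-scale mixing weight `w = 0.3 + 0.5 (kappa - 1)`, and (c) the
boundary perturbation. Driving the fine-scale *fraction* — not just the
amplitude — is essential: min-max gray-level quantization removes overall
amplitude, so a pure amplitude change would be invisible to GLCM
features. The late/early ratio field `r ~ 0.75 (1 + 0.12 kappa g')`
carries the signal into the SER and WOS maps. T1 statistics are identical
across phenotypes; only the T1-to-T2 change differs. The default
`heterogeneity_delta = 0.5` represents clearly separated adaptive/
responding subpopulations. Tumor shrinkage under therapy is lognormal
around 0.85 per-axis (sd 0.10) and identical in distribution across
phenotypes; no claim is made that this matches any particular trial's
size-change distribution.

**Survival.** `T ~ Exponential(lambda)` with
`lambda = 0.03 * exp(1.5 * 1{phenotype 2} + 0.05 * (V_T2 - V_ref))` per
year, where `V_T2` is the subject's analytic ellipsoid volume (cm^3) at
T2 — the latent counterpart of the measured FTV covariate. Censoring is
`C = min(7, U(0, 14))` years: uniform dropout with probability one half,
administrative censoring at 7 years otherwise. These defaults imply an
analytic event fraction of ~0.29 (closed form in
`synthetic.event_probability`, verified against numeric integration and
against the empirical fraction at n = 10,000).

**Expression.** Class centroid plus i.i.d. N(0, sd^2) noise
(default sd 0.2) per signature, concatenated over the three gene sets;
classes are drawn independently of phenotype, matching the reported null
association between signatures and imaging phenotypes.

**Reproducibility.** A master seed spawns per-subject substreams by
counter (`SeedSequence([seed, subject, stream])`): covariates drawn
before the cohort-wide phenotype allocation are invariant to cohort size,
and the clinical table is bit-identical whether or not images are
rendered.

**What the generator does not emulate:** scanner and contrast-agent
physics (no pharmacokinetic modeling), bias fields, registration error or
patient motion, non-ellipsoidal/multi-focal lesions, correlated gene
expression beyond the class centroids, and covariate-phenotype
confounding. Passing the planted-recovery tests therefore demonstrates
that the pipeline's machinery is correct and well calibrated under its
assumed statistical structure — not that the biological effect would be
detectable at any particular real-world effect size.

## Problem sizes used in the checks

The shipped acceptance checks run the full pipeline on 100-subject
cohorts (20 seeds for recovery statistics), calibrate the SigClust null
with 200 repeats of 1000 simulations at n=50/d=6, and evaluate the Cox
machinery with 100-200 simulations at n=150-500; these sizes give stable
Monte-Carlo estimates at a few minutes of single-CPU compute and are the
package's standard verification conditions.

## Known limitations

- The feature bank is fixed at extraction time; wavelet/filtered-image
  features and 2-D slice features are out of scope by design.
- The consensus stability shortcut's ambiguity band ((0.1, 0.9), ceiling
  0.05) is a documented operationalization of a directional rule; other
  choices are defensible.
- SigClust inherits mild conservatism from testing the Ward split rather
  than the 2-means optimum in the pipeline path.
- The CLI's `run` pipeline supports discovery studies; fitting a
  discovery model and applying it to a separately ingested validation
  cohort is available through the library/CLI `assign` path.
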