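# deltarad

Delta-radiomic phenotyping of longitudinal breast DCE-MRI under
neoadjuvant chemotherapy: voxel-wise kinetic maps, change ("delta")
radiomic features, unsupervised discovery of heterogeneity-change
phenotypes with cluster-significance testing, gene-signature risk scoring,
and survival evaluation — plus a seeded synthetic cohort generator so the
entire analysis is runnable and testable end to end without any patient
data.

The package is aimed at quantitative-imaging and imaging-genomics
researchers who want to study *how* a tumor's internal heterogeneity
changes between a pre-treatment scan (T1) and an early-treatment scan
(T2), and whether that change carries prognostic information beyond
established covariates such as functional tumor volume (FTV) and
gene-expression risk scores.

## The method

**Kinetic maps.** From a three-point dynamic series (pre-contrast `I0`,
post-contrast `I1` at ~2.5 min and `I2` at ~7.5 min), four voxel-wise maps
are computed inside the tumor mask:

    PE  = max_t (I_t - I0) / I0            (peak enhancement; tPE = earliest peak time)
    SER = (I1 - I0) / (I2 - I0)            (signal enhancement ratio)
    WIS = PE / (tPE - t0)   if tPE != t0, else 0
    WOS = (I2 - I1) / (t2 - tPE)  if t2 != tPE, else 0

**Delta radiomics.** A 22-feature 3-D bank (intensity statistics, 3-D GLCM
texture, mask morphology) is extracted per map and time point. Features
are sign-adjusted so that *higher = more heterogeneous*, then the delta
feature is the relative change

    Δf = (f_T2 - f_T1) / f_T1 .

Delta features are z-scored and screened by a skewness/IQR quality filter.

**Phenotype discovery.** Features are grouped by consensus-clustered
agglomerative clustering (distance `1 - Pearson r`); each group is
summarized by PCA components retained to >85% cumulative explained
variance, oriented so higher component values read as increasing
heterogeneity. Tumors are clustered in this component space (Ward linkage,
Euclidean distance); the cluster number comes from consensus clustering
over subject subsamples, and the two-way split is tested against a
single-Gaussian null with a SigClust-style cluster-index Monte-Carlo test.
The cluster with the lower mean component value is labeled *Phenotype 1
(decreasing heterogeneity)*, the other *Phenotype 2 (increasing
heterogeneity)*. A frozen `PhenotypeModel` (z-score statistics, feature
groups, loadings, centroids) assigns validation cohorts by nearest
phenotype centroid.

**Signatures and survival.** Expression profiles are scored with three
nearest-centroid style classifiers (cosine similarity to a good-prognosis
centroid; an ROR-S weighted sum of correlations with intrinsic-subtype
centroids; Spearman nearest wildtype/mutant centroid). Recurrence-free
survival is analyzed with Kaplan-Meier/log-rank, a declarative roster of
Cox proportional-hazards models (Breslow ties) evaluated by 5-fold
cross-validated Harrell concordance averaged over replicates, nested
likelihood-ratio tests, median risk-score stratification, and
event/censor confusion matrices (PPV/NPV).

## Worked example

```sh
python examples/04_phenotype_discovery.py
```

runs discovery on a 60-subject synthetic cohort and prints:

```
retained delta features after QC: 76 of 88
feature groups (consensus): 4
retained principal components: 12 (['C1-PC1', 'C1-PC2', ...])
tumor clusters (consensus): 2
SigClust root split: cluster index = 0.640, p = 0.0000
  Phenotype 1 (decreasing heterogeneity): n = 35
  Phenotype 2 (increasing heterogeneity): n = 25
agreement with planted labels: ARI = 1.00 (1.0 = perfect)
frozen-model self-assignment agreement: 100%
```

Reading: the QC filter keeps 76 of 88 delta features; consensus
clustering finds four stable groups of correlated features, summarized by
12 principal components; tumor clustering is stable at two clusters whose
split is far from what a single Gaussian produces (cluster index 0.640,
Monte-Carlo p < 0.001); the discovered labels coincide exactly with the
generator's planted phenotypes, and re-assigning the cohort through its
own frozen model reproduces every label.

`examples/06_survival_models.py` continues the story on the survival
side — adding the phenotype to a clinical + tumor-volume Cox model lifts
the cross-validated c-statistic from 0.526 to 0.702 (likelihood-ratio
p ≈ 1e-10 for the phenotype term). The other examples cover kinetic maps,
cohort simulation, delta features, and signature scoring; a `deltarad`
CLI (`simulate`, `kinetics`, `features`, `delta`, `discover`, `assign`,
`signatures`, `survival`, `run`, `report`) wraps the same library for
file-based pipelines with a reproducibility manifest.

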