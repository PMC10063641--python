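"""End-to-end study orchestration (in-memory layer).

``run_study`` drives the full analysis on a cohort object: kinetic maps ->
radiomic features -> sign-adjusted delta features -> z-scoring and QC ->
feature grouping -> group PCA -> tumor clustering with significance ->
phenotype labels -> signature scoring -> survival modeling.  The file-based
pipeline and CLI wrap this layer (see :mod:`deltarad.io` and
:mod:`deltarad.cli`).

Normalization/QC order: delta features are z-scored first and the
skewness/IQR screen is applied to the standardized values, so the IQR
threshold acts as a shape (spikiness) filter rather than an absolute-scale
cut; relative delta features have natural scales well below 1 and an
absolute IQR cut would empty the table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import radiomics, signatures
from .kinetics import compute_kinetic_maps, compute_ftv, resample_inplane
from .phenotyping import (PhenotypeModel, build_phenotype_model,
                          cluster_features, cluster_tumors, label_phenotypes,
                          sigclust_test, summarize_groups_pca)
from .survival import (DEFAULT_MODEL_ROSTER, confusion_metrics,
                       covariate_association, cv_cstatistic, fit_cox,
                       km_estimate, logrank_test, lr_test)


@dataclass
class StudyParams:
    """Analysis knobs (thresholds and seeds, all recorded in results)."""

    pe_threshold: float = 0.7
    resample_to: tuple = None        # e.g. (256, 256); None = keep grid
    skew_max: float = 5.0
    iqr_min: float = 1.0
    variance_threshold: float = 0.85
    k_range: tuple = (2, 3, 4, 5, 6)
    consensus_resamples: int = 500
    subsample_fraction: float = 0.8
    sigclust_sims: int = 1000
    cv_folds: int = 5
    cv_replicates: int = 100
    seed: int = 0
    model_roster: dict = field(
        default_factory=lambda: dict(DEFAULT_MODEL_ROSTER))


@dataclass
class StudyResult:
    features: pd.DataFrame
    deltas: pd.DataFrame
    z_deltas: pd.DataFrame
    qc_report: dict
    groups: dict
    pc_table: pd.DataFrame
    feature_consensus: object
    tumor_consensus: object
    phenotypes: pd.Series
    phenotype_labels: dict
    sigclust: dict
    model: PhenotypeModel
    clinical: pd.DataFrame
    signature_scores: pd.DataFrame
    survival: dict
    qc_counts: dict


def extract_cohort_features(cohort, params: StudyParams):
    """Kinetic maps and radiomic features for every subject/time-point.

    Returns ``(feature_table, ftv2 Series, dropped subjects)``; the table
    is indexed by (subject_id, timepoint).
    """
    rows = {}
    ftv2 = {}
    dropped = {}
    for (sid, tp), series in sorted(cohort.series.items()):
        kmaps = compute_kinetic_maps(series)
        if params.resample_to is not None:
            maps = {}
            mask = None
            for name, vol in kmaps.map_dict().items():
                v, m = resample_inplane(vol, kmaps.mask & kmaps.valid,
                                        params.resample_to)
                maps[name] = v
                mask = m
            kmaps.pe, kmaps.ser = maps["PE"], maps["SER"]
            kmaps.wis, kmaps.wos = maps["WIS"], maps["WOS"]
            kmaps.mask = mask.astype(bool)
            kmaps.valid = kmaps.mask
            nx, ny, _ = series.volumes.shape[1:]
            sx, sy, sz = kmaps.spacing
            kmaps.spacing = (sx * nx / params.resample_to[0],
                             sy * ny / params.resample_to[1], sz)
        try:
            rows[(sid, tp)] = radiomics.extract_features(kmaps)
        except ValueError as exc:
            dropped[(sid, tp)] = str(exc)
            continue
        if tp == "T2":
            ftv2[sid] = compute_ftv(kmaps, params.pe_threshold, unit="cm3")
    table = pd.DataFrame(rows).T
    table.index.names = ["subject_id", "timepoint"]
    return table, pd.Series(ftv2, name="ftv2"), dropped


def delta_feature_table(features: pd.DataFrame, params: StudyParams):
    """Sign-adjust, take deltas, z-score, and QC-screen the features."""
    signs = radiomics.default_sign_table(features.columns)
    adjusted = radiomics.sign_adjust(features, signs)
    f_t1 = adjusted.xs("T1", level="timepoint")
    f_t2 = adjusted.xs("T2", level="timepoint")
    common = f_t1.index.intersection(f_t2.index)
    deltas = radiomics.compute_delta(f_t1.loc[common], f_t2.loc[common])
    # drop high-missingness columns before z-scoring
    frac_missing = deltas.isna().mean()
    deltas = deltas.loc[:, frac_missing <= 0.2]
    z, stats = radiomics.zscore_fit_apply(deltas)
    z_kept, qc_report = radiomics.qc_filter(z, skew_max=params.skew_max,
                                            iqr_min=params.iqr_min)
    for col in features.columns:
        if col not in qc_report:
            qc_report[col] = ("dropped:missing>0.2"
                              if col in frac_missing.index
                              and frac_missing[col] > 0.2
                              else "dropped:zero-sd")
    stats = stats.loc[z_kept.columns]
    return deltas, z_kept, stats, qc_report


def discover_phenotypes(z_deltas: pd.DataFrame, stats: pd.DataFrame,
                        params: StudyParams):
    """Feature grouping, group PCA, tumor clustering, and labeling."""
    groups, feat_cons = cluster_features(
        z_deltas, k_range=params.k_range,
        resamples=params.consensus_resamples,
        subsample_fraction=params.subsample_fraction, seed=params.seed)
    pc_table, gpca = summarize_groups_pca(
        z_deltas, groups, variance_threshold=params.variance_threshold)
    linkage, assignment, tum_cons = cluster_tumors(
        pc_table, k_range=params.k_range,
        resamples=params.consensus_resamples,
        subsample_fraction=params.subsample_fraction, seed=params.seed + 1)
    # root split significance (top-down testing; discovery stops at the
    # first non-significant division)
    from scipy.cluster import hierarchy as _h
    root2 = _h.fcluster(linkage, t=2, criterion="maxclust")
    ci, p, half = sigclust_test(pc_table, root2,
                                n_sim=params.sigclust_sims,
                                seed=params.seed + 2)
    phen, labels = label_phenotypes(pc_table, assignment)
    model = build_phenotype_model(
        z_deltas, stats, groups, gpca, pc_table, phen, labels,
        seeds={"consensus_features": params.seed,
               "consensus_tumors": params.seed + 1,
               "sigclust": params.seed + 2},
        thresholds={"variance_threshold": params.variance_threshold,
                    "skew_max": params.skew_max,
                    "iqr_min": params.iqr_min})
    return {
        "groups": groups, "feature_consensus": feat_cons,
        "pc_table": pc_table, "tumor_consensus": tum_cons,
        "assignment": assignment, "phenotypes": phen,
        "phenotype_labels": labels,
        "sigclust": {"cluster_index": ci, "p": p, "mc_halfwidth": half},
        "model": model,
    }


def assemble_clinical(cohort, ftv2: pd.Series, phenotypes: pd.Series,
                      scores: pd.DataFrame) -> pd.DataFrame:
    """Merge covariates into the survival analysis table.

    Signature covariates enter as classes: MammaPrint high risk = 1,
    ROR-S ordinal 0/1/2 (low/intermediate/high), p53 mutant = 1; the
    phenotype covariate is 1 for Phenotype 2 (increasing heterogeneity).
    """
    clin = cohort.clinical.copy()
    clin["ftv2"] = ftv2
    clin["phenotype"] = (phenotypes == 2).astype(float)
    ror_map = {"low risk": 0.0, "intermediate risk": 1.0, "high risk": 2.0}
    clin["mammaprint"] = (scores["mammaprint_class"] == "high risk") \
        .astype(float)
    clin["ror_s"] = scores["ror_s_class"].map(ror_map)
    clin["p53"] = (scores["p53_class"] == "mutant").astype(float)
    return clin


def survival_analysis(clinical: pd.DataFrame, params: StudyParams,
                      roster=None, lrt_pairs=None):
    """KM/log-rank by phenotype, the model roster with CV c, LRTs, and
    confusion metrics for each binary predictor."""
    roster = params.model_roster if roster is None else roster
    out = {}
    t = clinical["rfs_years"].to_numpy()
    e = clinical["event"].to_numpy()
    phen2 = clinical["phenotype"].to_numpy() > 0
    out["km_by_phenotype"] = km_estimate(t, e, np.where(phen2, 2, 1))
    out["logrank_phenotype"] = logrank_test(t, e, np.where(phen2, 2, 1))

    fits, cvs = {}, {}
    for mid, covs in roster.items():
        # covariates constant in this cohort cannot enter the model
        covs = [c for c in covs if clinical[c].nunique() > 1]
        if not covs:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fits[mid] = fit_cox(clinical, covs)
            cvs[mid] = cv_cstatistic(clinical, covs, folds=params.cv_folds,
                                     replicates=params.cv_replicates,
                                     seed=params.seed + 10, model_id=mid)
    out["fits"] = fits
    out["cv"] = cvs

    lrt_pairs = lrt_pairs if lrt_pairs is not None else [
        ("model1_baseline", "model2_ftv"),
        ("model2_ftv", "model3_signatures"),
        ("model2_ftv", "model4_phenotype"),
        ("model3_signatures", "model5_combined"),
    ]
    out["lrt"] = {}
    for nested, full in lrt_pairs:
        if nested in fits and full in fits:
            out["lrt"][f"{full}_vs_{nested}"] = lr_test(fits[nested],
                                                        fits[full])

    # median risk-score stratification from the clinical + volume model
    if "model2_ftv" in fits:
        from .survival import risk_stratify
        try:
            risk, group = risk_stratify(fits["model2_ftv"], clinical)
            out["risk_split"] = {
                "risk": risk, "group": group,
                "logrank": logrank_test(t, e, group.to_numpy()),
            }
        except ValueError:
            out["risk_split"] = None

    out["confusion"] = {}
    preds = {"phenotype": phen2}
    if "mammaprint" in clinical:
        preds["mammaprint"] = clinical["mammaprint"].to_numpy() > 0
        preds["ror_s"] = clinical["ror_s"].to_numpy() == 2
        preds["p53"] = clinical["p53"].to_numpy() > 0
    for name, pred in preds.items():
        out["confusion"][name] = confusion_metrics(pred, e)
    return out


def run_study(cohort, params: StudyParams = None) -> StudyResult:
    """Full discovery analysis of a cohort (see module docstring)."""
    params = params or StudyParams()
    features, ftv2, dropped = extract_cohort_features(cohort, params)
    deltas, z_deltas, stats, qc_report = delta_feature_table(features, params)
    disc = discover_phenotypes(z_deltas, stats, params)
    models = signatures.load_bundled_models()
    scores = signatures.score_cohort(cohort.expression, models)
    clinical = assemble_clinical(cohort, ftv2, disc["phenotypes"], scores)
    surv = survival_analysis(clinical, params)
    assoc_types = {"age": "continuous", "hr_status": "categorical",
                   "her2_status": "categorical", "pcr": "categorical",
                   "ftv2": "continuous", "mammaprint": "categorical",
                   "p53": "categorical", "ror_s": "categorical"}
    surv["associations"] = covariate_association(
        clinical, disc["phenotypes"].reindex(clinical.index), assoc_types)
    n_kept = z_deltas.shape[1]
    qc_counts = {
        "subjects": int(cohort.clinical.shape[0]),
        "subject_timepoints_dropped": len(dropped),
        "features_extracted": int(features.shape[1]),
        "features_retained": int(n_kept),
        "pcs_retained": int(disc["pc_table"].shape[1]),
    }
    return StudyResult(
        features=features, deltas=deltas, z_deltas=z_deltas,
        qc_report=qc_report, groups=disc["groups"],
        pc_table=disc["pc_table"],
        feature_consensus=disc["feature_consensus"],
        tumor_consensus=disc["tumor_consensus"],
        phenotypes=disc["phenotypes"],
        phenotype_labels=disc["phenotype_labels"],
        sigclust=disc["sigclust"], model=disc["model"],
        clinical=clinical, signature_scores=scores, survival=surv,
        qc_counts=qc_counts)
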