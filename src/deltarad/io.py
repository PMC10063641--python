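"""Standard-format adapters, the file-based pipeline, and run manifests.

Conventions: voxel indexing is 0-based and half-open throughout; world
coordinates come from the NIfTI affine (the synthetic writer emits a
diagonal affine from the voxel spacing).  Floating-point tabular output is
written with 10 significant digits so byte-identical re-runs can be
audited.  JSON artifacts carry a schema/version field and loaders refuse
unknown versions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .kinetics import DceSeries
from .synthetic import SimulationConfig, SyntheticCohort

log = logging.getLogger("deltarad")

FLOAT_FMT = "%.10g"
CLINICAL_COLUMNS = ["age", "hr_status", "her2_status", "pcr",
                    "rfs_years", "event"]
MANIFEST_VERSION = 1


# ---------------------------------------------------------------------------
# NIfTI

def save_nifti(path, array, spacing):
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(array), affine)
    nib.save(img, str(path))


def load_nifti(path):
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), spacing, img.affine


# ---------------------------------------------------------------------------
# cohort directory layout

def write_cohort(cohort: SyntheticCohort, outdir):
    """Write a cohort as NIfTI volumes + clinical CSV + expression TSV."""
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for (sid, tp), series in sorted(cohort.series.items()):
        for d in range(3):
            save_nifti(outdir / f"{sid}_{tp}_dyn{d}.nii.gz",
                       series.volumes[d], series.spacing)
        save_nifti(outdir / f"{sid}_{tp}_mask.nii.gz",
                   series.mask.astype(np.uint8), series.spacing)
    write_table(cohort.clinical.reset_index(), outdir / "clinical.csv")
    write_table(cohort.expression.reset_index(), outdir / "expression.tsv")
    meta = {"schema_version": 1,
            "acquisition_times": list(cohort.config.acquisition_times),
            "config": dataclasses.asdict(cohort.config)}
    with open(outdir / "cohort_meta.json", "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True, default=_jsonify)
        fh.write("\n")


def read_cohort(indir) -> SyntheticCohort:
    """Load a cohort directory written by :func:`write_cohort`.

    Every subject must have both time points and all three dynamics; a
    missing file halts with the subject and file named.
    """
    indir = pathlib.Path(indir)
    with open(indir / "cohort_meta.json") as fh:
        meta = json.load(fh)
    if meta.get("schema_version") != 1:
        raise ValueError("unsupported cohort_meta schema version")
    times = tuple(meta["acquisition_times"])
    config = SimulationConfig(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in meta["config"].items()})
    clinical = read_clinical_csv(indir / "clinical.csv")
    expression = pd.read_csv(indir / "expression.tsv", sep="\t",
                             index_col="gene")
    series = {}
    for sid in clinical.index:
        for tp in ("T1", "T2"):
            vols = []
            spacing = None
            for d in range(3):
                path = indir / f"{sid}_{tp}_dyn{d}.nii.gz"
                if not path.exists():
                    raise FileNotFoundError(
                        f"subject {sid}: missing {path.name}")
                arr, spacing, _ = load_nifti(path)
                vols.append(np.asarray(arr, dtype=float))
            mpath = indir / f"{sid}_{tp}_mask.nii.gz"
            if not mpath.exists():
                raise FileNotFoundError(f"subject {sid}: missing {mpath.name}")
            mask, mspacing, _ = load_nifti(mpath)
            if mask.shape != vols[0].shape or not np.allclose(
                    mspacing, spacing):
                raise ValueError(
                    f"subject {sid} {tp}: mask grid/spacing mismatch")
            series[(sid, tp)] = DceSeries(
                volumes=np.stack(vols), times=times, spacing=spacing,
                mask=mask.astype(bool), subject_id=sid, timepoint=tp)
    return SyntheticCohort(config=config, clinical=clinical,
                           expression=expression, series=series)


# ---------------------------------------------------------------------------
# tables

def write_table(df: pd.DataFrame, path):
    path = pathlib.Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df.to_csv(path, sep=sep, index=False, float_format=FLOAT_FMT)


def read_clinical_csv(path) -> pd.DataFrame:
    """Clinical table with schema validation (column presence and ranges)."""
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise ValueError("clinical CSV: missing column 'subject_id'")
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical CSV: missing column(s) {missing}")
    df = df.set_index("subject_id")
    if (df["rfs_years"] <= 0).any():
        raise ValueError("clinical CSV: rfs_years must be > 0")
    if not df["event"].isin((0, 1)).all():
        raise ValueError("clinical CSV: event must be 0/1")
    return df


def read_feature_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    index_cols = [c for c in ("subject_id", "timepoint") if c in df.columns]
    if not index_cols:
        raise ValueError("feature TSV: missing 'subject_id' column")
    return df.set_index(index_cols)


def write_feature_tsv(df: pd.DataFrame, path):
    write_table(df.reset_index(), path)


# ---------------------------------------------------------------------------
# pipeline config and manifest

@dataclasses.dataclass
class PipelineConfig:
    """File-based run description (YAML-serializable)."""

    out_dir: str
    cohort_dir: str = None          # existing cohort; else simulate
    simulate: dict = None           # SimulationConfig overrides
    params: dict = None             # StudyParams overrides
    write_kinetic_maps: bool = False

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            obj = yaml.safe_load(fh)
        cfg = cls(**obj)
        if cfg.cohort_dir is not None and \
                not pathlib.Path(cfg.cohort_dir).exists():
            raise FileNotFoundError(f"cohort_dir not found: {cfg.cohort_dir}")
        return cfg

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def sha256_file(path):
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def summarize_survival(surv: dict) -> dict:
    """JSON-friendly snapshot of the survival analysis outputs."""
    out = {
        "logrank_phenotype": {"statistic": surv["logrank_phenotype"][0],
                              "p": surv["logrank_phenotype"][1]},
        "models": {}, "lrt": {}, "confusion": surv["confusion"],
    }
    for mid, cv in surv["cv"].items():
        fit = surv["fits"][mid]
        out["models"][mid] = {
            "covariates": cv.covariates,
            "cv_mean_c": cv.mean_c,
            "cv_percentile_interval": list(cv.percentile_interval),
            "fit_c": fit.c_statistic,
            "coef": {k: float(v) for k, v in zip(fit.covariates, fit.coef)},
            "log_likelihood": fit.log_likelihood,
        }
    for key, (stat, df, p) in surv["lrt"].items():
        out["lrt"][key] = {"statistic": stat, "df": df, "p": p}
    if surv.get("risk_split"):
        stat, p = surv["risk_split"]["logrank"]
        out["risk_split_logrank"] = {"statistic": stat, "p": p}
    if "associations" in surv:
        assoc = surv["associations"]
        out["associations"] = {
            "alpha_bonferroni": assoc.attrs["alpha_bonferroni"],
            "tests": {i: {"test": r["test"], "p": r["p"]}
                      for i, r in assoc.iterrows()},
        }
    return out


def run_pipeline(config: PipelineConfig):
    """Execute the full study from a file-based configuration.

    Simulates or ingests the cohort, runs the in-memory study, writes all
    tabular/JSON artifacts into ``out_dir`` and returns the manifest dict
    (also written as ``manifest.json``) listing every output with its
    SHA-256 digest, the seeds used, and QC counts.
    """
    from .pipeline import StudyParams, run_study
    from .synthetic import simulate_cohort

    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.cohort_dir:
        log.info("ingesting cohort from %s", config.cohort_dir)
        cohort = read_cohort(config.cohort_dir)
    else:
        sim_cfg = SimulationConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in (config.simulate or {}).items()})
        log.info("simulating cohort (n=%d, seed=%d)",
                 sim_cfg.n_subjects, sim_cfg.seed)
        cohort = simulate_cohort(sim_cfg)

    params = StudyParams(**(config.params or {}))
    result = run_study(cohort, params)

    write_feature_tsv(result.features, out / "features.tsv")
    write_feature_tsv(result.deltas, out / "deltas.tsv")
    write_feature_tsv(result.z_deltas, out / "zdeltas.tsv")
    result.model.save(out / "phenotype_model.json")
    write_table(result.phenotypes.rename("phenotype").reset_index()
                .rename(columns={"index": "subject_id"}),
                out / "phenotypes.csv")
    write_table(result.signature_scores.reset_index(),
                out / "signature_scores.csv")
    write_table(result.clinical.reset_index(), out / "clinical_full.csv")
    with open(out / "qc_report.json", "w") as fh:
        json.dump(result.qc_report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(out / "survival_summary.json", "w") as fh:
        json.dump(summarize_survival(result.survival), fh, indent=1,
                  sort_keys=True, default=_jsonify)
        fh.write("\n")

    from . import __version__
    artifacts = sorted(p.name for p in out.iterdir()
                       if p.name != "manifest.json")
    manifest = {
        "manifest_version": MANIFEST_VERSION,
        "software_version": __version__,
        "config": dataclasses.asdict(config),
        "seeds": {"simulation": cohort.config.seed if config.cohort_dir is
                  None else None, "analysis": params.seed},
        "qc_counts": result.qc_counts,
        "outputs": {name: sha256_file(out / name) for name in artifacts},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=_jsonify)
        fh.write("\n")
    log.info("pipeline complete: %d artifacts in %s", len(artifacts), out)
    return manifest
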