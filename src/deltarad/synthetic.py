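"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a neoadjuvant-chemotherapy DCE-MRI study: every
subject has a pre-treatment (T1) and an early-treatment (T2) dynamic series
(pre-contrast + two post-contrast volumes) with an ellipsoidal tumor mask,
a clinical/survival record, and an expression vector over the bundled
signature gene lists.

Two planted tumor subpopulations differ only in how their intratumor
heterogeneity *changes* from T1 to T2: the enhancement field is a two-scale
Gaussian random field whose fluctuation amplitude and fine-scale fraction
are scaled up at T2 for phenotype 2 and down for phenotype 1 (controlled by
``heterogeneity_delta``); T1 is statistically identical across phenotypes.
Recurrence-free survival is exponential with hazard
``baseline_hazard * exp(b_ph * 1{phenotype 2} + b_ftv * (V_T2 - V_ref))``
and administrative-plus-uniform-dropout censoring at ``censor_time_max``.
Expression vectors are class centroids plus i.i.d. Gaussian noise; risk
classes are drawn independently of phenotype with the cohort proportions
of the emulated trial population (MammaPrint 7/93 low/high, p53 46/54
wildtype/mutant, ROR-S 31/31/38, HR+ 45%, HER2+ 34%, pCR 27%).

A single master seed spawns per-subject substreams by counter, so subject
``i`` is reproducible independently of the cohort size, and the clinical
table is bit-identical whether or not image volumes are rendered.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd
from scipy import ndimage

from .kinetics import DceSeries
from .signatures import SignatureModel, load_bundled_models


@dataclass
class SimulationConfig:
    """Study conditions for a synthetic cohort.

    The defaults are the emulated study's conditions: three dynamic
    acquisitions at (0, 2.5, 7.5) minutes, a 42% phenotype-2 fraction, a
    log hazard ratio of 1.5 for phenotype 2 and a weak volume effect, and
    an event fraction of ~0.30 implied by the exponential/censoring
    parameters.
    """

    n_subjects: int = 100
    phenotype2_fraction: float = 0.42
    grid_shape: tuple = (32, 32, 32)
    voxel_spacing: tuple = (1.5, 1.5, 1.5)     # mm
    acquisition_times: tuple = (0.0, 2.5, 7.5)  # minutes
    heterogeneity_delta: float = 0.5
    hazard_log_hr_phenotype: float = 1.5
    hazard_log_hr_ftv: float = 0.05            # per cm^3 of T2 tumor volume
    baseline_hazard: float = 0.03              # events per year
    censor_time_max: float = 7.0               # years
    expression_noise_sd: float = 0.2
    seed: int = 0
    # secondary knobs (documented defaults, rarely moved)
    base_radii_mm: tuple = (12.0, 10.0, 8.0)
    size_factor_sd: float = 0.15               # lognormal sd of tumor size
    shrinkage_mean: float = 0.85               # T2/T1 radius ratio
    shrinkage_sd: float = 0.10                 # lognormal sd of the ratio
    enhancement_mean: float = 0.8              # mean relative enhancement
    fluct_amplitude: float = 0.15              # texture field amplitude
    field_sigma_coarse: float = 2.5            # voxels
    field_sigma_fine: float = 0.8              # voxels
    boundary_noise: float = 0.08
    hr_rate: float = 0.45
    her2_rate: float = 0.34
    pcr_rates: tuple = (0.35, 0.16)            # by phenotype (1, 2)
    mammaprint_high_rate: float = 0.93
    p53_mutant_rate: float = 0.54
    ror_s_rates: tuple = (0.31, 0.31, 0.38)    # low / intermediate / high

    def __post_init__(self):
        for f in dc_fields(self):
            v = getattr(self, f.name)
            vals = v if isinstance(v, (tuple, list)) else (v,)
            for x in vals:
                if not np.isfinite(x):
                    raise ValueError(f"non-finite value in config field "
                                     f"{f.name!r}: {x!r}")
        if not 0 < self.phenotype2_fraction < 1:
            raise ValueError("phenotype2_fraction must be in (0, 1)")
        t0, t1, t2 = self.acquisition_times
        if not (t0 == 0 and t0 < t1 < t2):
            raise ValueError("acquisition_times must be strictly increasing "
                             "with t0 = 0")
        for name in ("baseline_hazard", "censor_time_max",
                     "expression_noise_sd", "fluct_amplitude"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")


@dataclass
class SyntheticCohort:
    """Generated study: per-subject image series, clinical table, expression."""

    config: SimulationConfig
    clinical: pd.DataFrame                  # indexed by subject_id
    expression: pd.DataFrame                # genes x subjects
    series: dict = field(default_factory=dict)  # (subject_id, "T1"/"T2") -> DceSeries

    @property
    def subjects(self):
        return list(self.clinical.index)


def _subject_rng(seed: int, subject_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int(subject_index), int(stream)]))


def _texture_factor(phenotype: int, timepoint: str, delta: float) -> float:
    if timepoint == "T1":
        return 1.0
    return 1.0 + delta if phenotype == 2 else 1.0 - delta


def _smooth_unit_field(rng, shape, sigma):
    g = ndimage.gaussian_filter(rng.normal(size=shape), sigma)
    sd = g.std()
    return g / sd if sd > 0 else g


def _ellipsoid_mask(rng, config, radii_vox, kappa):
    """Ellipsoid with a smoothly perturbed boundary; checks grid fit."""
    shape = tuple(int(s) for s in config.grid_shape)
    for n, r in zip(shape, radii_vox):
        if r < 1.0:
            raise ValueError("tumor radii too small for a 3-D mask")
        if 2 * (r + 2) >= n:
            raise ValueError(
                f"grid too small to contain the ellipsoid: shape {shape}, "
                f"radii (vox) {tuple(round(x, 2) for x in radii_vox)}")
    center = np.array(shape) / 2.0 - 0.5 + rng.uniform(-0.5, 0.5, size=3)
    grids = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    d2 = sum(((g - c) / r) ** 2
             for g, c, r in zip(grids, center, radii_vox))
    bnd = _smooth_unit_field(rng, shape, config.field_sigma_coarse)
    level = 1.0 + config.boundary_noise * kappa * bnd
    mask = d2 <= level
    if mask.sum() < 27:
        # guaranteed-minimum fallback: drop the perturbation
        mask = d2 <= 1.0
    return mask


def simulate_dce_tumor(phenotype: int, timepoint: str,
                       config: SimulationConfig, seed: int,
                       size_factor: float = 1.0, shrink: float = None,
                       subject_id: str = "") -> DceSeries:
    """One subject/time-point dynamic series with a planted texture level.

    The enhancement field is ``E = E0 * (1 + a * g)`` where ``g`` mixes a
    coarse and a fine unit-variance Gaussian random field; both the
    amplitude ``a`` and the fine-scale mixing weight scale with the
    phenotype/time-point texture factor, so at T2 phenotype-2 tumors gain
    and phenotype-1 tumors lose spatial heterogeneity.  The late volume is
    ``I2 = I0 * (1 + E * r)`` with a wash-out ratio field ``r < 1`` whose
    variability also carries the texture factor (this drives SER and WOS
    texture).  All intensities are non-negative.
    """
    if phenotype not in (1, 2):
        raise ValueError("phenotype must be 1 or 2")
    if timepoint not in ("T1", "T2"):
        raise ValueError("timepoint must be 'T1' or 'T2'")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    kappa = _texture_factor(phenotype, timepoint, config.heterogeneity_delta)

    if shrink is None:
        shrink = 1.0 if timepoint == "T1" else config.shrinkage_mean
    radii_mm = np.asarray(config.base_radii_mm) * size_factor * (
        1.0 if timepoint == "T1" else shrink)
    radii_vox = radii_mm / np.asarray(config.voxel_spacing)

    mask = _ellipsoid_mask(rng, config, radii_vox, kappa)
    shape = mask.shape

    g_coarse = _smooth_unit_field(rng, shape, config.field_sigma_coarse)
    g_fine = _smooth_unit_field(rng, shape, config.field_sigma_fine)
    w = float(np.clip(0.3 + 0.5 * (kappa - 1.0), 0.05, 0.95))
    g = (1 - w) * g_coarse + w * g_fine
    g /= max(g.std(), 1e-12)

    amp = config.fluct_amplitude * kappa
    E = config.enhancement_mean * np.clip(1.0 + amp * g, 0.05, None)

    g2 = _smooth_unit_field(rng, shape, config.field_sigma_coarse)
    g2f = _smooth_unit_field(rng, shape, config.field_sigma_fine)
    gr = (1 - w) * g2 + w * g2f
    gr /= max(gr.std(), 1e-12)
    r = np.clip(0.75 * (1.0 + 0.12 * kappa * gr), 0.2, 1.3)

    base = _smooth_unit_field(rng, shape, config.field_sigma_coarse)
    I0 = 100.0 * np.clip(1.0 + 0.05 * base, 0.1, None)
    enh = np.where(mask, E, 0.0)
    I1 = I0 * (1.0 + enh)
    I2 = I0 * (1.0 + enh * r)

    return DceSeries(volumes=np.stack([I0, I1, I2]),
                     times=tuple(config.acquisition_times),
                     spacing=tuple(config.voxel_spacing), mask=mask,
                     subject_id=subject_id, timepoint=timepoint)


def _ellipsoid_volume_cm3(radii_mm) -> float:
    return float(4.0 / 3.0 * math.pi * np.prod(radii_mm) / 1000.0)


def event_probability(lam: float, censor_time_max: float) -> float:
    """Analytic P(event) for one subject under the generator's censoring.

    The censoring time is ``C = min(c_max, U)`` with ``U ~ Uniform(0, 2
    c_max)``: uniform dropout on (0, c_max) with probability 1/2 and
    administrative censoring at c_max otherwise.
    """
    c = censor_time_max
    if lam <= 0:
        return 0.0
    tail = 1.0 - math.exp(-lam * c)
    return (c - tail / lam) / (2 * c) + 0.5 * tail


def simulate_clinical(config: SimulationConfig, models: dict = None):
    """Clinical/survival table plus the latent per-subject parameters.

    Returns ``(clinical, latent)`` where ``latent`` holds the geometry and
    class draws needed to render images or expression for each subject.
    """
    if models is None:
        models = load_bundled_models()
    n = config.n_subjects
    n2 = int(round(n * config.phenotype2_fraction))
    order = np.random.default_rng(
        np.random.SeedSequence([config.seed, 2 ** 20])).permutation(n)
    phenotypes = np.ones(n, dtype=int)
    phenotypes[order[:n2]] = 2

    vol_ref = _ellipsoid_volume_cm3(
        np.asarray(config.base_radii_mm) * config.shrinkage_mean)

    rows, latent = [], []
    for i in range(n):
        sid = f"subj{i:03d}"
        ph = int(phenotypes[i])
        rng = _subject_rng(config.seed, i, 0)
        size_factor = float(np.exp(rng.normal(0.0, config.size_factor_sd)))
        shrink = float(np.exp(rng.normal(math.log(config.shrinkage_mean),
                                         config.shrinkage_sd)))
        age = float(rng.uniform(29.0, 66.0))
        hr = int(rng.random() < config.hr_rate)
        her2 = int(rng.random() < config.her2_rate)
        pcr = int(rng.random() < config.pcr_rates[ph - 1])
        mp_class = ("high risk" if rng.random() < config.mammaprint_high_rate
                    else "low risk")
        p53_class = ("mutant" if rng.random() < config.p53_mutant_rate
                     else "wildtype")
        ror_class = ("low risk", "intermediate risk", "high risk")[
            rng.choice(3, p=np.asarray(config.ror_s_rates)
                       / sum(config.ror_s_rates))]

        radii_t2 = np.asarray(config.base_radii_mm) * size_factor * shrink
        vol_t2 = _ellipsoid_volume_cm3(radii_t2)
        lam = config.baseline_hazard * math.exp(
            config.hazard_log_hr_phenotype * (ph == 2)
            + config.hazard_log_hr_ftv * (vol_t2 - vol_ref))
        t_event = rng.exponential(1.0 / lam)
        c = min(config.censor_time_max,
                rng.uniform(0.0, 2.0 * config.censor_time_max))
        rfs = max(min(t_event, c), 1.0 / 365.0)
        event = int(t_event <= c)
        rows.append({
            "subject_id": sid, "age": age, "hr_status": hr,
            "her2_status": her2, "pcr": pcr,
            "rfs_years": rfs, "event": event, "true_phenotype": ph,
        })
        latent.append({
            "subject_id": sid, "phenotype": ph, "size_factor": size_factor,
            "shrink": shrink, "vol_t2_cm3": vol_t2, "hazard": lam,
            "mammaprint_class": mp_class, "p53_class": p53_class,
            "ror_s_class": ror_class,
        })
    clinical = pd.DataFrame(rows).set_index("subject_id")
    latent = pd.DataFrame(latent).set_index("subject_id")
    return clinical, latent


def simulate_expression(risk_class: str, signature_model: SignatureModel,
                        noise_sd: float, seed) -> pd.Series:
    """Class centroid plus i.i.d. Gaussian noise over the model's genes."""
    if risk_class not in signature_model.class_centroid_map:
        raise KeyError(
            f"unknown risk class {risk_class!r} for {signature_model.name}; "
            f"known: {sorted(signature_model.class_centroid_map)}")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    centroid = signature_model.centroids[
        signature_model.class_centroid_map[risk_class]]
    vec = centroid + rng.normal(0.0, noise_sd, size=centroid.size) \
        if noise_sd > 0 else centroid.copy()
    return pd.Series(vec, index=signature_model.genes)


def simulate_cohort(config: SimulationConfig, images: bool = True,
                    models: dict = None) -> SyntheticCohort:
    """Full synthetic cohort; same config and seed give identical output.

    Exactly ``round(n_subjects * phenotype2_fraction)`` subjects carry the
    planted phenotype 2.  With ``images=False`` the (identical) clinical
    and expression tables are produced without rendering volumes.
    """
    if models is None:
        models = load_bundled_models()
    clinical, latent = simulate_clinical(config, models)

    expr_cols = {}
    for i, sid in enumerate(clinical.index):
        rng = _subject_rng(config.seed, i, 1)
        parts = [
            simulate_expression(latent.loc[sid, "mammaprint_class"],
                                models["mammaprint"],
                                config.expression_noise_sd, rng),
            simulate_expression(latent.loc[sid, "ror_s_class"],
                                models["ror_s"],
                                config.expression_noise_sd, rng),
            simulate_expression(latent.loc[sid, "p53_class"], models["p53"],
                                config.expression_noise_sd, rng),
        ]
        expr_cols[sid] = pd.concat(parts)
    expression = pd.DataFrame(expr_cols)
    expression.index.name = "gene"

    series = {}
    if images:
        for i, sid in enumerate(clinical.index):
            ph = int(clinical.loc[sid, "true_phenotype"])
            sf = float(latent.loc[sid, "size_factor"])
            sh = float(latent.loc[sid, "shrink"])
            for stream, tp in ((2, "T1"), (3, "T2")):
                rng = _subject_rng(config.seed, i, stream)
                series[(sid, tp)] = simulate_dce_tumor(
                    ph, tp, config, rng, size_factor=sf, shrink=sh,
                    subject_id=sid)
    cohort = SyntheticCohort(config=config, clinical=clinical,
                             expression=expression, series=series)
    cohort.latent = latent
    return cohort
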