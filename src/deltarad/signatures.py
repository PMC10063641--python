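"""Gene-expression signature scoring.

Three nearest-centroid style classifiers used as prognostic covariates:

* **MammaPrint-style 70-gene score** — cosine similarity of a sample's
  signature-gene vector to a "good prognosis" centroid; samples at or above
  the threshold (default 0.4) are called low risk.
* **ROR-S (PAM50 risk of recurrence)** — weighted sum of the sample's
  correlations with the five intrinsic-subtype centroids, tiered into
  low / intermediate / high risk by ordered cuts.  Spearman correlation by
  default (Pearson available).
* **p53 mutation signature** — the sample is assigned to whichever of the
  wildtype/mutant centroids has the larger Spearman correlation.

Centroids, weights, and thresholds are data (JSON model files), not code
constants.  The bundled ``*_synthetic.json`` models are synthetic stand-ins
with the published weight pattern and threshold conventions; real
signature definitions can be dropped in with the same schema.

Boundary convention: a score exactly at a threshold classifies to the
lower-risk side (``>=`` inclusive for MammaPrint low risk, ``<=`` inclusive
for the ROR-S low/intermediate cuts).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sstats

SCHEMA_VERSION = 1


@dataclass
class SignatureModel:
    """A signature definition: gene list, centroids, weights, thresholds."""

    name: str
    genes: list
    centroids: dict          # label -> vector over `genes`
    weights: dict = field(default_factory=dict)   # label -> float (ROR-S)
    thresholds: dict = field(default_factory=dict)
    correlation: str = "spearman"   # "cosine" | "pearson" | "spearman"
    class_centroid_map: dict = field(default_factory=dict)  # risk class -> centroid

    def __post_init__(self):
        n = len(self.genes)
        self.centroids = {k: np.asarray(v, dtype=float)
                          for k, v in self.centroids.items()}
        for k, v in self.centroids.items():
            if v.shape != (n,):
                raise ValueError(f"centroid {k!r} does not match gene list")
            if not np.isfinite(v).all():
                raise ValueError(f"centroid {k!r} has non-finite entries")
        if any(not np.isfinite(w) for w in self.weights.values()):
            raise ValueError("weights must be finite")

    def to_json(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "name": self.name,
            "genes": list(self.genes),
            "centroids": {k: [round(float(x), 6) for x in v]
                          for k, v in self.centroids.items()},
            "weights": self.weights,
            "thresholds": self.thresholds,
            "correlation": self.correlation,
            "class_centroid_map": self.class_centroid_map,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "SignatureModel":
        version = obj.get("schema_version")
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported signature model schema version: {version!r}")
        return cls(name=obj["name"], genes=obj["genes"],
                   centroids=obj["centroids"],
                   weights=obj.get("weights", {}),
                   thresholds=obj.get("thresholds", {}),
                   correlation=obj.get("correlation", "spearman"),
                   class_centroid_map=obj.get("class_centroid_map", {}))

    @classmethod
    def load(cls, path) -> "SignatureModel":
        with open(path) as fh:
            return cls.from_json(json.load(fh))


def load_bundled_models() -> dict:
    """Load the packaged synthetic MammaPrint / PAM50 / p53 models."""
    out = {}
    for key, fname in (("mammaprint", "mammaprint_synthetic.json"),
                       ("ror_s", "pam50_synthetic.json"),
                       ("p53", "p53_synthetic.json")):
        text = resources.files("deltarad").joinpath("data", fname).read_text()
        out[key] = SignatureModel.from_json(json.loads(text))
    return out


def _signature_vector(expr, model: SignatureModel) -> np.ndarray:
    if isinstance(expr, pd.Series):
        missing = [g for g in model.genes if g not in expr.index]
        if missing:
            raise KeyError(
                f"{model.name}: expression missing {len(missing)} signature "
                f"genes (first: {missing[:5]})")
        return expr.loc[model.genes].to_numpy(dtype=float)
    v = np.asarray(expr, dtype=float)
    if v.shape != (len(model.genes),):
        raise ValueError("expression vector does not match gene list")
    return v


def _corr(x, y, kind):
    if kind == "cosine":
        nx, ny = np.linalg.norm(x), np.linalg.norm(y)
        if nx == 0 or ny == 0:
            raise ValueError("zero-norm vector in cosine similarity")
        return float(x @ y / (nx * ny))
    if kind == "pearson":
        return float(sstats.pearsonr(x, y).statistic)
    if kind == "spearman":
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError("constant vector: Spearman correlation undefined")
        return float(sstats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown correlation kind {kind!r}")


def score_mammaprint(expr, model: SignatureModel):
    """Cosine similarity to the good-prognosis centroid; low risk iff
    score >= threshold."""
    v = _signature_vector(expr, model)
    centroid = model.centroids["good_prognosis"]
    score = _corr(v, centroid, "cosine")
    cut = float(model.thresholds.get("low_risk_min", 0.4))
    label = "low risk" if score >= cut else "high risk"
    return score, label


def score_ror_s(expr, model: SignatureModel):
    """Weighted sum of subtype correlations, tiered into risk classes."""
    v = _signature_vector(expr, model)
    if not model.weights:
        raise ValueError("ROR-S model requires subtype weights")
    score = 0.0
    for subtype, w in model.weights.items():
        if subtype not in model.centroids:
            raise KeyError(f"missing subtype centroid {subtype!r}")
        score += w * _corr(v, model.centroids[subtype], model.correlation)
    c_low = float(model.thresholds["low_max"])
    c_int = float(model.thresholds["intermediate_max"])
    if not c_low <= c_int:
        raise ValueError("ROR-S thresholds must be ordered")
    if score <= c_low:
        label = "low risk"
    elif score <= c_int:
        label = "intermediate risk"
    else:
        label = "high risk"
    return score, label


def classify_p53(expr, model: SignatureModel, tie_default: str = "wildtype"):
    """Nearest centroid (wildtype vs mutant) by Spearman correlation."""
    v = _signature_vector(expr, model)
    corrs = {k: _corr(v, c, "spearman") for k, c in model.centroids.items()}
    if corrs["wildtype"] == corrs["mutant"]:
        return tie_default, corrs
    label = max(corrs, key=corrs.get)
    return label, corrs


def score_cohort(expr: pd.DataFrame, models: dict) -> pd.DataFrame:
    """Score every subject (columns of a genes x subjects table).

    Returns a table with columns ``mammaprint_score, mammaprint_class,
    ror_s, ror_s_class, p53_class`` indexed by subject id.
    """
    rows = {}
    for subject in expr.columns:
        e = expr[subject]
        mp_score, mp_class = score_mammaprint(e, models["mammaprint"])
        ror, ror_class = score_ror_s(e, models["ror_s"])
        p53_class, _ = classify_p53(e, models["p53"])
        rows[subject] = {
            "mammaprint_score": mp_score, "mammaprint_class": mp_class,
            "ror_s": ror, "ror_s_class": ror_class, "p53_class": p53_class,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "subject_id"
    return out
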