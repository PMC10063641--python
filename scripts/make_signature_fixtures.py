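"""Regenerate the bundled synthetic signature model fixtures.

The original MammaPrint / PAM50 / p53 centroid data are not redistributable
here, so the package ships synthetic stand-ins with the same schema,
published weight pattern, and threshold conventions.  This script is the
frozen provenance of those fixtures: rerunning it reproduces
``src/deltarad/data/*.json`` bit-for-bit.

ROR-S tier cuts are set at the midpoints of the zero-noise scores of the
three generating classes (LumA -> low, Her2 -> intermediate, LumB -> high),
computed with the model's own scorer at fixture-generation time.
"""

import json
import pathlib

import numpy as np

import sys
sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from deltarad.signatures import SignatureModel, score_ror_s  # noqa: E402

OUT = pathlib.Path(__file__).resolve().parents[1] / "src" / "deltarad" / "data"

rng = np.random.default_rng(20230330)


def rvec(n):
    return np.round(rng.normal(size=n), 4)


def write(model, fname):
    OUT.mkdir(parents=True, exist_ok=True)
    path = OUT / fname
    with open(path, "w") as fh:
        json.dump(model.to_json(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    print("wrote", path)


# --- MammaPrint-style 70-gene model -----------------------------------
mp_genes = [f"MPSYN{i:04d}" for i in range(1, 71)]
good = rvec(70)
mammaprint = SignatureModel(
    name="mammaprint_synthetic", genes=mp_genes,
    centroids={"good_prognosis": good, "poor_prognosis": -good},
    thresholds={"low_risk_min": 0.4},
    correlation="cosine",
    class_centroid_map={"low risk": "good_prognosis",
                        "high risk": "poor_prognosis"},
)
write(mammaprint, "mammaprint_synthetic.json")

# --- PAM50-style ROR-S model ------------------------------------------
pam_genes = [f"PAMSYN{i:03d}" for i in range(1, 51)]
centroids = {name: rvec(50)
             for name in ("LumA", "LumB", "Her2", "Basal", "Normal")}
weights = {"Basal": 0.05, "Her2": 0.12, "LumA": -0.34, "LumB": 0.23}
tmp = SignatureModel(name="tmp", genes=pam_genes, centroids=centroids,
                     weights=weights,
                     thresholds={"low_max": 0.0, "intermediate_max": 0.0},
                     correlation="spearman")
class_map = {"low risk": "LumA", "intermediate risk": "Her2",
             "high risk": "LumB"}
scores = {}
for cls, cname in class_map.items():
    scores[cls], _ = score_ror_s(centroids[cname], tmp)
print("zero-noise class scores:", scores)
low_max = round((scores["low risk"] + scores["intermediate risk"]) / 2, 4)
int_max = round((scores["intermediate risk"] + scores["high risk"]) / 2, 4)
ror = SignatureModel(
    name="pam50_ror_s_synthetic", genes=pam_genes, centroids=centroids,
    weights=weights,
    thresholds={"low_max": low_max, "intermediate_max": int_max},
    correlation="spearman", class_centroid_map=class_map,
)
write(ror, "pam50_synthetic.json")

# --- p53 mutation signature -------------------------------------------
p53_genes = [f"P53SYN{i:03d}" for i in range(1, 33)]
p53 = SignatureModel(
    name="p53_synthetic", genes=p53_genes,
    centroids={"wildtype": rvec(32), "mutant": rvec(32)},
    correlation="spearman",
    class_centroid_map={"wildtype": "wildtype", "mutant": "mutant"},
)
write(p53, "p53_synthetic.json")
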