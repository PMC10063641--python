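"""3-D radiomic features on kinetic maps, delta features, and QC.

The feature bank is a defined 22-feature-per-map set covering the same
families as the large commercial/toolkit banks (intensity statistics, 3-D
gray-level co-occurrence texture, and mask morphology).  Per kinetic map
(PE, SER, WIS, WOS):

* intensity (within-mask): mean, sd, skewness, kurtosis, 10th/50th/90th
  percentiles, IQR, range, histogram entropy (32 min-max bins);
* texture: 3-D GLCM contrast, correlation, energy, homogeneity, entropy,
  averaged over the 13 unique distance-1 direction offsets, 32 min-max
  gray levels within the mask, symmetric accumulation;
* morphology (mask-only, identical across the four maps): volume, surface
  area (marching cubes), sphericity, major/minor ellipsoid diameters from
  the eigen-decomposition of the voxel-coordinate covariance, elongation
  ``sqrt(l1/l2) >= 1`` (higher = more elongated) and flatness
  ``sqrt(l3/l1) <= 1`` (higher = rounder).

Every feature carries an entry in the default sign table mapping it onto a
common "higher = more heterogeneous" orientation; the *delta* feature of a
sign-adjusted feature f is the relative change (f_T2 - f_T1) / f_T1.
Columns are then z-scored and screened by the skewness/IQR quality filter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy import ndimage
from skimage import measure

from .kinetics import KineticMapSet

GLCM_LEVELS = 32

# 13 unique 3-D direction offsets at distance 1 (half of the 26-neighborhood)
OFFSETS_3D = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1),
    (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

MAP_NAMES = ("PE", "SER", "WIS", "WOS")

INTENSITY_FEATURES = ("mean", "sd", "skewness", "kurtosis", "p10", "p50",
                      "p90", "iqr", "range", "entropy")
TEXTURE_FEATURES = ("contrast", "correlation", "energy", "homogeneity",
                    "entropy")
MORPHOLOGY_FEATURES = ("volume", "surface_area", "sphericity",
                       "major_axis", "minor_axis", "elongation", "flatness")


def quantize(values: np.ndarray, levels: int = GLCM_LEVELS) -> np.ndarray:
    """Min-max quantize a value array to integer levels 0..levels-1."""
    lo, hi = values.min(), values.max()
    if hi <= lo:
        return np.zeros(values.shape, dtype=np.int32)
    q = np.floor((values - lo) / (hi - lo) * levels).astype(np.int32)
    return np.clip(q, 0, levels - 1)


def glcm_3d(volume: np.ndarray, mask: np.ndarray, levels: int = GLCM_LEVELS,
            offsets=OFFSETS_3D) -> np.ndarray:
    """Per-offset symmetric co-occurrence matrices inside a mask.

    Returns an array of shape ``(len(offsets), levels, levels)`` of raw
    symmetric counts; only voxel pairs with both members inside the mask
    contribute.
    """
    mask = mask.astype(bool)
    q = np.zeros(volume.shape, dtype=np.int32)
    q[mask] = quantize(np.asarray(volume, dtype=float)[mask], levels)
    out = np.zeros((len(offsets), levels, levels), dtype=np.int64)
    for k, (dx, dy, dz) in enumerate(offsets):
        src = _shift_slices(volume.shape, (dx, dy, dz), source=True)
        dst = _shift_slices(volume.shape, (dx, dy, dz), source=False)
        m = mask[src] & mask[dst]
        a = q[src][m]
        b = q[dst][m]
        np.add.at(out[k], (a, b), 1)
        np.add.at(out[k], (b, a), 1)
    return out


def _shift_slices(shape, offset, source):
    sl = []
    for n, d in zip(shape, offset):
        if d >= 0:
            sl.append(slice(0, n - d) if source else slice(d, n))
        else:
            sl.append(slice(-d, n) if source else slice(0, n + d))
    return tuple(sl)


def glcm_features(counts: np.ndarray) -> dict:
    """Direction-averaged Haralick-style features from per-offset counts.

    Offsets with no co-occurring pairs are skipped; a constant image yields
    energy 1, contrast 0, homogeneity 1, entropy 0 and correlation 1 (the
    zero-variance correlation is defined as 1 by convention).
    """
    levels = counts.shape[1]
    i = np.arange(levels)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    feats = {name: [] for name in TEXTURE_FEATURES}
    for k in range(counts.shape[0]):
        total = counts[k].sum()
        if total == 0:
            continue
        p = counts[k] / total
        contrast = float((p * (ii - jj) ** 2).sum())
        energy = float((p ** 2).sum())
        homogeneity = float((p / (1.0 + (ii - jj) ** 2)).sum())
        nz = p[p > 0]
        entropy = float(-(nz * np.log2(nz)).sum())
        pi = p.sum(axis=1)
        mu = float((i * pi).sum())
        var = float(((i - mu) ** 2 * pi).sum())
        if var <= 0:
            correlation = 1.0
        else:
            correlation = float(((ii - mu) * (jj - mu) * p).sum() / var)
        for name, v in zip(TEXTURE_FEATURES,
                           (contrast, correlation, energy, homogeneity,
                            entropy)):
            feats[name].append(v)
    if not feats["contrast"]:
        raise ValueError("no co-occurring voxel pairs inside the mask")
    return {name: float(np.mean(v)) for name, v in feats.items()}


def intensity_features(values: np.ndarray) -> dict:
    """First-order statistics of the within-mask voxel values."""
    v = np.asarray(values, dtype=float)
    near_constant = np.ptp(v) < 1e-12 * max(1.0, float(np.abs(v).max()))
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    if sd > 0 and not near_constant:
        skew = float(sstats.skew(v, bias=True))
        kurt = float(sstats.kurtosis(v, bias=True))
    else:
        skew, kurt = 0.0, 0.0
    p10, p50, p90 = (float(x) for x in np.percentile(v, (10, 50, 90)))
    q1, q3 = np.percentile(v, (25, 75))
    # near-constant values (range at float precision) carry zero entropy
    if near_constant:
        entropy = 0.0
    else:
        hist, _ = np.histogram(v, bins=GLCM_LEVELS)
        p = hist[hist > 0] / v.size
        entropy = float(-(p * np.log2(p)).sum())
    return {
        "mean": float(v.mean()), "sd": sd, "skewness": skew,
        "kurtosis": kurt, "p10": p10, "p50": p50, "p90": p90,
        "iqr": float(q3 - q1), "range": float(v.max() - v.min()),
        "entropy": entropy,
    }


def morphology_features(mask: np.ndarray, spacing) -> dict:
    """Mask-only shape descriptors (mm-based where dimensional)."""
    mask = mask.astype(bool)
    n = int(mask.sum())
    coords = np.argwhere(mask) * np.asarray(spacing, dtype=float)
    if n < 4 or np.linalg.matrix_rank(coords - coords.mean(0)) < 3:
        raise ValueError("mask needs >= 4 non-coplanar voxels for morphology")
    voxel = float(np.prod(spacing))
    volume = n * voxel
    # light smoothing before meshing: marching cubes on a raw binary mask
    # overestimates the area of smooth shapes by ~9% (staircase surface);
    # half-voxel smoothing brings digitized spheres within ~4% of analytic
    padded = ndimage.gaussian_filter(np.pad(mask.astype(float), 2), 0.5)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5,
                                                spacing=tuple(spacing))
    area = float(measure.mesh_surface_area(verts, faces))
    sphericity = float((36.0 * np.pi * volume ** 2) ** (1.0 / 3.0) / area)
    cov = np.cov(coords.T)
    lam = np.sort(np.linalg.eigvalsh(cov))[::-1]
    lam = np.clip(lam, 1e-12, None)
    major = float(4.0 * np.sqrt(lam[0]))
    minor = float(4.0 * np.sqrt(lam[1]))
    elongation = float(np.sqrt(lam[0] / lam[1]))
    flatness = float(np.sqrt(lam[2] / lam[0]))
    return {
        "volume": volume, "surface_area": area, "sphericity": sphericity,
        "major_axis": major, "minor_axis": minor,
        "elongation": elongation, "flatness": flatness,
    }


def extract_features(kmaps: KineticMapSet, spacing=None) -> pd.Series:
    """One feature vector for a subject/time-point.

    Columns are named ``{map}.{family}.{name}``; morphology is computed
    once from the (valid) mask and replicated under each map prefix, so it
    is identical across the four maps by construction.
    """
    spacing = kmaps.spacing if spacing is None else spacing
    roi = kmaps.mask & kmaps.valid
    if roi.sum() < 2:
        raise ValueError("degenerate mask: fewer than 2 valid voxels")
    morph = morphology_features(roi, spacing)
    out = {}
    for name, vol in kmaps.map_dict().items():
        vals = vol[roi]
        for feat, v in intensity_features(vals).items():
            out[f"{name}.intensity.{feat}"] = v
        counts = glcm_3d(vol, roi)
        for feat, v in glcm_features(counts).items():
            out[f"{name}.texture.{feat}"] = v
        for feat, v in morph.items():
            out[f"{name}.morphology.{feat}"] = v
    return pd.Series(out)


# default orientation of each feature onto "higher = more heterogeneous";
# rationale strings document the reading of each feature definition
_SIGN_RULES = {
    "intensity.mean": (+1, "level shift; orientation neutral, kept as-is"),
    "intensity.sd": (+1, "more spread = more heterogeneous"),
    "intensity.skewness": (+1, "stronger asymmetry = more heterogeneous"),
    "intensity.kurtosis": (+1, "heavier tails = more heterogeneous"),
    "intensity.p10": (+1, "level shift; orientation neutral"),
    "intensity.p50": (+1, "level shift; orientation neutral"),
    "intensity.p90": (+1, "level shift; orientation neutral"),
    "intensity.iqr": (+1, "more spread = more heterogeneous"),
    "intensity.range": (+1, "more spread = more heterogeneous"),
    "intensity.entropy": (+1, "flatter histogram = more heterogeneous"),
    "texture.contrast": (+1, "larger local gray-level steps"),
    "texture.correlation": (-1, "high spatial correlation = orderly"),
    "texture.energy": (-1, "high energy = uniform co-occurrence"),
    "texture.homogeneity": (-1, "high homogeneity = smooth texture"),
    "texture.entropy": (+1, "disordered co-occurrence"),
    "morphology.volume": (+1, "size; orientation neutral"),
    "morphology.surface_area": (+1, "more surface = more irregular"),
    "morphology.sphericity": (-1, "spherical = regular shape"),
    "morphology.major_axis": (+1, "larger extent/irregularity"),
    "morphology.minor_axis": (+1, "larger extent/irregularity"),
    "morphology.elongation": (+1, "sqrt(l1/l2) >= 1; higher = more elongated"),
    "morphology.flatness": (-1, "sqrt(l3/l1); higher = rounder/regular"),
}


def default_sign_table(columns) -> pd.DataFrame:
    """Sign table (+1/-1 with rationale) covering the given feature columns."""
    rows = {}
    for col in columns:
        try:
            _, family, name = col.split(".")
        except ValueError as exc:
            raise ValueError(f"malformed feature id: {col!r}") from exc
        key = f"{family}.{name}"
        if key not in _SIGN_RULES:
            raise KeyError(f"no default sign for feature {col!r}")
        sign, why = _SIGN_RULES[key]
        rows[col] = {"sign": sign, "rationale": why}
    return pd.DataFrame.from_dict(rows, orient="index")


def sign_adjust(table: pd.DataFrame, signs: pd.DataFrame) -> pd.DataFrame:
    """Multiply each feature column by its +-1 sign (involution)."""
    missing = [c for c in table.columns if c not in signs.index]
    if missing:
        raise KeyError(f"features missing from sign table: {missing}")
    s = signs.loc[table.columns, "sign"].astype(float)
    if not set(np.unique(s)) <= {-1.0, 1.0}:
        raise ValueError("signs must be +1 or -1")
    return table * s


def compute_delta(f_t1: pd.DataFrame, f_t2: pd.DataFrame,
                  eps_rel: float = 1e-8) -> pd.DataFrame:
    """Relative change (f_T2 - f_T1) / f_T1 of sign-adjusted features.

    Entries whose baseline magnitude is below ``eps_rel`` times the column
    median absolute baseline are set to NaN (flagged, not zeroed).
    """
    if list(f_t1.columns) != list(f_t2.columns):
        raise ValueError("T1/T2 feature tables must share columns")
    if not f_t1.index.equals(f_t2.index):
        raise ValueError("T1/T2 feature tables must share subjects")
    base = f_t1.to_numpy(dtype=float)
    late = f_t2.to_numpy(dtype=float)
    med = np.nanmedian(np.abs(base), axis=0)
    eps = eps_rel * np.where(med > 0, med, 1.0)
    bad = np.abs(base) < eps
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = (late - base) / np.where(bad, 1.0, base)
    delta[bad] = np.nan
    return pd.DataFrame(delta, index=f_t1.index, columns=f_t1.columns)


def qc_filter(deltas: pd.DataFrame, skew_max: float = 5.0,
              iqr_min: float = 1.0, max_missing: float = 0.2):
    """Drop columns with extreme skewness, low IQR, or too many missing.

    Skewness is taken in absolute value (the threshold is a tail-shape
    guard, not a direction preference).  Returns ``(kept_table, report)``
    where ``report`` maps every input column to ``"kept"`` or a
    machine-readable drop reason.
    """
    if deltas.shape[0] < 8:
        raise ValueError("QC filtering needs at least 8 subjects")
    report = {}
    keep = []
    for col in deltas.columns:
        v = deltas[col]
        frac_missing = float(v.isna().mean())
        if frac_missing > max_missing:
            report[col] = f"dropped:missing>{max_missing:g}"
            continue
        vv = v.dropna().to_numpy(dtype=float)
        skew = abs(float(sstats.skew(vv, bias=True))) if vv.std() > 0 else 0.0
        q1, q3 = np.percentile(vv, (25, 75))
        iqr = float(q3 - q1)
        if skew > skew_max:
            report[col] = f"dropped:|skewness|>{skew_max:g}"
        elif iqr < iqr_min:
            report[col] = f"dropped:IQR<{iqr_min:g}"
        else:
            report[col] = "kept"
            keep.append(col)
    if not keep:
        reasons = pd.Series(report).value_counts().to_dict()
        raise ValueError(f"all columns dropped by QC: {reasons}")
    return deltas[keep], report


def zscore_fit_apply(deltas: pd.DataFrame, stats: pd.DataFrame = None):
    """Z-score columns; fit mode computes mean/sd (ddof=1), apply reuses.

    In fit mode, columns with zero sample sd are dropped (reason recorded
    in the returned stats attrs).  Returns ``(z_table, stats)`` where
    ``stats`` has columns ``mean`` and ``sd`` indexed by feature.
    """
    if stats is None:
        mean = deltas.mean()
        sd = deltas.std(ddof=1)
        dropped = list(deltas.columns[(sd == 0) | sd.isna()])
        kept = [c for c in deltas.columns if c not in dropped]
        stats = pd.DataFrame({"mean": mean[kept], "sd": sd[kept]})
        stats.attrs["dropped_zero_sd"] = dropped
        z = (deltas[kept] - stats["mean"]) / stats["sd"]
        return z, stats
    missing = [c for c in deltas.columns if c not in stats.index]
    if missing:
        raise KeyError(f"stats missing for columns: {missing}")
    sub = stats.loc[deltas.columns]
    return (deltas - sub["mean"]) / sub["sd"], stats
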