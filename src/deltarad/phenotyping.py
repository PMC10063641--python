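"""Unsupervised discovery and validation of heterogeneity-change phenotypes.

Pipeline: (1) delta features are grouped by consensus-clustered
agglomerative clustering with correlation distance ``1 - r``; (2) each
group is summarized by PCA components retained up to >85% cumulative
explained variance, with loadings oriented so their sum is non-negative
(higher component value = increasing heterogeneity); (3) tumors are
clustered in the retained-component space with Ward linkage / Euclidean
distance, the cluster number chosen by the consensus CDF rule and the
two-way split tested for significance against a single-Gaussian null
(SigClust); (4) the frozen discovery model (z-score statistics, groups,
loadings, centroids) assigns new cohorts by nearest phenotype centroid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.optimize import brentq
from scipy.spatial.distance import squareform

MODEL_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# consensus clustering (Monti-style subsampling)

@dataclass
class ConsensusResult:
    """Consensus matrices and CDF-area diagnostics per candidate k."""

    consensus: dict            # k -> (n, n) matrix in [0, 1]
    areas: dict                # k -> area under the consensus CDF
    rel_increase: dict         # k -> (A(k) - A(k-1)) / A(k-1)
    pac: dict                  # k -> proportion of ambiguous pairs
    chosen_k: int
    params: dict

    def cdf(self, k, grid=None):
        vals = _offdiag(self.consensus[k])
        grid = np.linspace(0, 1, 101) if grid is None else grid
        return grid, np.searchsorted(np.sort(vals), grid, side="right") / vals.size


def _offdiag(m):
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def _linkage_labels(dist_condensed, method, k_values, n):
    z = hierarchy.linkage(dist_condensed, method=method)
    return {k: hierarchy.fcluster(z, t=k, criterion="maxclust")
            for k in k_values}, z


def consensus_cluster(items, k_range=(2, 3, 4, 5, 6), resamples=500,
                      subsample_fraction=0.8, linkage_method="ward",
                      distance="euclidean", seed=0,
                      min_cosample=1, pac_max=0.05) -> ConsensusResult:
    """Subsampling-based cluster-stability analysis.

    Parameters
    ----------
    items : ndarray (n, d) of item coordinates, or (n, n) distance matrix
        when ``distance="precomputed"``.
    k_range : iterable of candidate cluster numbers (within [2, n-1]).
    linkage_method, distance : hierarchical clustering configuration
        (Ward/Euclidean for tumors; average/correlation for features).
    min_cosample : pairs co-sampled fewer times than this raise an error.
    pac_max : ambiguity ceiling for the stability shortcut (below).

    The consensus entry for a pair is (# subsamples co-clustered) /
    (# subsamples co-sampled).  The CDF over off-diagonal consensus values
    gives an area A(k).  The stable k is selected in two stages: if any
    candidate yields an (almost) unambiguous consensus matrix — proportion
    of off-diagonal entries strictly inside (0.1, 0.9) at most ``pac_max``
    — the smallest such k is chosen, since a perfectly stable partition
    cannot be improved and the CDF area keeps growing merely by
    subdividing stable clusters.  Otherwise the area rule applies: the
    smallest k whose next relative increment
    Delta(k+1) = (A(k+1) - A(k)) / A(k) falls below 10%, the largest
    candidate if none does.
    """
    items = np.asarray(items, dtype=float)
    n = items.shape[0]
    k_values = sorted(int(k) for k in k_range)
    if k_values[0] < 2 or k_values[-1] > n - 1:
        raise ValueError("k_range must lie within [2, n-1]")
    if not 0 < subsample_fraction < 1:
        raise ValueError("subsample_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    m = max(2, int(round(subsample_fraction * n)))

    if distance == "precomputed":
        if items.shape != (n, n):
            raise ValueError("precomputed distance must be square")
        full_dist = items
    else:
        full_dist = None

    co_cluster = {k: np.zeros((n, n)) for k in k_values}
    co_sample = np.zeros((n, n))
    for _ in range(resamples):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        if full_dist is not None:
            sub = squareform(full_dist[np.ix_(idx, idx)], checks=False)
        else:
            from scipy.spatial.distance import pdist
            sub = pdist(items[idx], metric=distance)
        labels_by_k, _ = _linkage_labels(sub, linkage_method, k_values, m)
        sel = np.ix_(idx, idx)
        co_sample[sel] += 1
        for k, labels in labels_by_k.items():
            same = labels[:, None] == labels[None, :]
            co_cluster[k][sel] += same
    if (_offdiag(co_sample) < min_cosample).any():
        raise ValueError("some item pairs were never co-sampled; "
                         "increase resamples or subsample_fraction")

    consensus = {}
    for k in k_values:
        with np.errstate(invalid="ignore"):
            c = np.where(co_sample > 0, co_cluster[k] /
                         np.where(co_sample > 0, co_sample, 1), 0.0)
        np.fill_diagonal(c, 1.0)
        consensus[k] = (c + c.T) / 2.0

    areas = {}
    for k in k_values:
        vals = np.sort(_offdiag(consensus[k]))
        cdf = np.arange(1, vals.size + 1) / vals.size
        # area under the empirical CDF over [0, 1]
        xs = np.concatenate([[0.0], vals, [1.0]])
        ys = np.concatenate([[0.0], cdf, [1.0]])
        areas[k] = float(np.trapezoid(ys, xs))

    rel = {}
    for prev, k in zip(k_values[:-1], k_values[1:]):
        rel[k] = (areas[k] - areas[prev]) / areas[prev] if areas[prev] > 0 \
            else np.inf
    pac = {k: float(np.mean((v > 0.1) & (v < 0.9)))
           for k, v in ((k, _offdiag(consensus[k])) for k in k_values)}
    stable = [k for k in k_values if pac[k] <= pac_max]
    if stable:
        chosen = stable[0]
    else:
        chosen = next((k for k in k_values[:-1]
                       if rel.get(k + 1, np.inf) < 0.10), k_values[-1])
    return ConsensusResult(consensus=consensus, areas=areas, rel_increase=rel,
                           pac=pac, chosen_k=chosen,
                           params={"resamples": resamples,
                                   "subsample_fraction": subsample_fraction,
                                   "k_range": k_values,
                                   "linkage_method": linkage_method,
                                   "distance": distance, "seed": seed})


# ---------------------------------------------------------------------------
# feature grouping

def feature_distance_matrix(deltas: pd.DataFrame) -> np.ndarray:
    """1 - Pearson r between feature columns (signed correlation)."""
    x = deltas.to_numpy(dtype=float)
    sd = x.std(axis=0)
    if (sd == 0).any():
        bad = list(deltas.columns[sd == 0])
        raise ValueError(f"constant feature columns (drop in QC): {bad}")
    r = np.corrcoef(x, rowvar=False)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


def cluster_features(deltas: pd.DataFrame, k_range=(2, 3, 4, 5, 6),
                     resamples=500, subsample_fraction=0.8, seed=0):
    """Group correlated delta features; returns (feature->group, ConsensusResult).

    Features are the items: distance 1 - r, average linkage, group count
    chosen by consensus clustering over feature subsamples.
    """
    if deltas.shape[1] < 4:
        raise ValueError("need at least 4 retained features to group")
    dist = feature_distance_matrix(deltas)
    k_range = [k for k in k_range if k <= deltas.shape[1] - 1]
    res = consensus_cluster(dist, k_range=k_range, resamples=resamples,
                            subsample_fraction=subsample_fraction,
                            linkage_method="average", distance="precomputed",
                            seed=seed)
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(z, t=res.chosen_k, criterion="maxclust")
    groups = {feat: int(lab) for feat, lab in zip(deltas.columns, labels)}
    return groups, res


# ---------------------------------------------------------------------------
# per-group PCA summarization

@dataclass
class GroupPca:
    features: list
    mean: np.ndarray
    loadings: np.ndarray       # (n_retained, n_features), oriented, unit norm
    explained_variance_ratio: list
    n_retained: int


def summarize_groups_pca(deltas: pd.DataFrame, groups: dict,
                         variance_threshold: float = 0.85):
    """PCA per feature group; retain the smallest prefix of components with
    cumulative explained variance above the threshold.

    Loading vectors are oriented so the sum of loadings is >= 0, making
    higher component values read as increasing heterogeneity (the input
    features are already sign-adjusted that way).  A single-feature group
    passes through as its own component with unit loading.  Returns
    ``(pc_table, {group_id: GroupPca})`` with columns ``C{group}-PC{index}``.
    """
    missing = [f for f in groups if f not in deltas.columns]
    if missing:
        raise KeyError(f"grouped features absent from table: {missing}")
    pcs = {}
    models = {}
    for gid in sorted(set(groups.values())):
        feats = [f for f, g in groups.items() if g == gid]
        x = deltas[feats].to_numpy(dtype=float)
        mean = x.mean(axis=0)
        xc = x - mean
        if len(feats) == 1:
            load = np.ones((1, 1))
            evr = [1.0]
            n_keep = 1
            scores = xc
        else:
            u, s, vt = np.linalg.svd(xc, full_matrices=False)
            var = s ** 2
            evr = list(var / var.sum()) if var.sum() > 0 else \
                [1.0 / len(s)] * len(s)
            cum = np.cumsum(evr)
            n_keep = int(np.searchsorted(cum, variance_threshold) + 1)
            n_keep = min(n_keep, len(feats))
            load = vt[:n_keep]
            flip = np.where(load.sum(axis=1) < 0, -1.0, 1.0)
            load = load * flip[:, None]
            scores = xc @ load.T
        models[gid] = GroupPca(features=feats, mean=mean, loadings=load,
                               explained_variance_ratio=[float(e) for e in
                                                         evr][:n_keep],
                               n_retained=n_keep)
        for j in range(n_keep):
            pcs[f"C{gid}-PC{j + 1}"] = scores[:, j]
    return pd.DataFrame(pcs, index=deltas.index), models


# ---------------------------------------------------------------------------
# tumor clustering

def cluster_tumors(pc_table: pd.DataFrame, k_range=(2, 3, 4, 5, 6),
                   resamples=500, subsample_fraction=0.8, seed=0):
    """Ward/Euclidean clustering of subjects in retained-component space.

    The cluster number comes from consensus clustering over subject
    subsamples; the assignment is the full-data dendrogram cut at that k.
    Returns ``(linkage_matrix, assignment Series, ConsensusResult)``.
    """
    n = pc_table.shape[0]
    if n < 8:
        raise ValueError("need at least 8 subjects to cluster")
    x = pc_table.to_numpy(dtype=float)
    k_range = [k for k in k_range if k <= n - 1]
    res = consensus_cluster(x, k_range=k_range, resamples=resamples,
                            subsample_fraction=subsample_fraction,
                            linkage_method="ward", distance="euclidean",
                            seed=seed)
    z = hierarchy.linkage(x, method="ward")
    if len(np.unique(x, axis=0)) < res.chosen_k:
        raise ValueError("fewer distinct subject rows than clusters")
    labels = hierarchy.fcluster(z, t=res.chosen_k, criterion="maxclust")
    assignment = pd.Series(labels, index=pc_table.index, name="cluster")
    return z, assignment, res


# ---------------------------------------------------------------------------
# SigClust

def cluster_index(x: np.ndarray, labels: np.ndarray) -> float:
    """Normalized two-cluster within-scatter: sum of within-cluster squared
    deviations from the cluster means over total squared deviation from the
    overall mean (the standard cluster-index form)."""
    x = np.asarray(x, dtype=float)
    total = ((x - x.mean(axis=0)) ** 2).sum()
    if total <= 0:
        return 0.0
    within = 0.0
    for lab in np.unique(labels):
        sub = x[labels == lab]
        within += ((sub - sub.mean(axis=0)) ** 2).sum()
    return float(within / total)


def _two_means_batch(x: np.ndarray, n_iter: int = 25) -> np.ndarray:
    """Cluster index of principal-direction-initialized 2-means, batched.

    ``x`` has shape (S, n, d); returns CI per dataset.  Initialization
    splits each dataset by the sign of its projection onto the first
    principal axis; Lloyd iterations then refine the split.  Deterministic
    given the data.
    """
    x = np.asarray(x, dtype=float)
    s_, n, d = x.shape
    xc = x - x.mean(axis=1, keepdims=True)
    cov = np.einsum("sni,snj->sij", xc, xc) / (n - 1)
    _, vecs = np.linalg.eigh(cov)
    pc1 = vecs[:, :, -1]
    proj = np.einsum("snd,sd->sn", xc, pc1)
    assign = proj > np.median(proj, axis=1, keepdims=True)
    for _ in range(n_iter):
        w = assign[..., None]
        cnt1 = assign.sum(axis=1, keepdims=True)[..., None]
        cnt0 = (~assign).sum(axis=1, keepdims=True)[..., None]
        c1 = (x * w).sum(axis=1, keepdims=True) / np.maximum(cnt1, 1)
        c0 = (x * ~w).sum(axis=1, keepdims=True) / np.maximum(cnt0, 1)
        d1 = ((x - c1) ** 2).sum(axis=2)
        d0 = ((x - c0) ** 2).sum(axis=2)
        new = d1 < d0
        # keep both clusters non-empty: fall back to the PC split if collapsed
        collapsed = (new.all(axis=1) | (~new).all(axis=1))
        if collapsed.any():
            new[collapsed] = assign[collapsed]
        if (new == assign).all():
            assign = new
            break
        assign = new
    tss = (xc ** 2).sum(axis=(1, 2))
    w = assign[..., None]
    cnt1 = np.maximum(assign.sum(axis=1, keepdims=True)[..., None], 1)
    cnt0 = np.maximum((~assign).sum(axis=1, keepdims=True)[..., None], 1)
    c1 = (x * w).sum(axis=1, keepdims=True) / cnt1
    c0 = (x * ~w).sum(axis=1, keepdims=True) / cnt0
    wss = (((x - c1) ** 2).sum(axis=2) * assign).sum(axis=1) + \
          (((x - c0) ** 2).sum(axis=2) * ~assign).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ci = np.where(tss > 0, wss / np.where(tss > 0, tss, 1.0), 0.0)
    return ci


def two_means_labels(x: np.ndarray) -> np.ndarray:
    """Deterministic 2-means labels for one dataset (see _two_means_batch)."""
    x = np.asarray(x, dtype=float)[None]
    xc = x[0] - x[0].mean(axis=0)
    cov = np.cov(xc.T) if x.shape[2] > 1 else np.atleast_2d(np.var(xc, ddof=1))
    _, vecs = np.linalg.eigh(cov)
    proj = xc @ vecs[:, -1]
    assign = proj > np.median(proj)
    for _ in range(25):
        if assign.all() or (~assign).all():
            break
        c1 = x[0][assign].mean(axis=0)
        c0 = x[0][~assign].mean(axis=0)
        new = ((x[0] - c1) ** 2).sum(1) < ((x[0] - c0) ** 2).sum(1)
        if new.all() or (~new).all():
            break
        if (new == assign).all():
            break
        assign = new
    return assign.astype(int)


def null_eigenvalues(x: np.ndarray) -> np.ndarray:
    """Covariance eigenvalues for the single-Gaussian SigClust null.

    Raw sample eigenvalues overstate the population anisotropy (the
    Marchenko-Pastur spread makes the largest too large and the smallest
    too small at these n/d ratios), which would make the simulated null
    too easy to cluster and the test conservative; the spectrum is
    therefore taken from the Ledoit-Wolf shrinkage covariance.  A
    background noise floor ``sigma^2 = (MAD / 0.6745)^2`` is estimated
    from the pooled, column-centered data entries, and the eigenvalues are
    soft-thresholded: shifted down by a common tau >= 0 and floored at
    sigma^2, with tau chosen so the total variance is preserved when
    possible.
    """
    from sklearn.covariance import LedoitWolf
    x = np.asarray(x, dtype=float)
    xc = x - x.mean(axis=0)
    mad = np.median(np.abs(xc - np.median(xc)))
    sig2 = (mad / 0.6745) ** 2
    if x.shape[1] == 1:
        lam = np.atleast_1d(np.var(xc[:, 0], ddof=1))
    else:
        lam = np.sort(np.linalg.eigvalsh(
            LedoitWolf().fit(x).covariance_))[::-1]
    total = lam.sum()
    floor_total = sig2 * lam.size

    def shifted_sum(tau):
        return np.maximum(lam - tau, sig2).sum()

    if total <= floor_total or shifted_sum(0.0) <= total:
        tau = 0.0
    else:
        hi = lam.max()
        tau = brentq(lambda t: shifted_sum(t) - total, 0.0, hi)
    return np.maximum(lam - tau, sig2)


def sigclust_test(pc_table, assignment, n_sim: int = 1000, seed: int = 0,
                  batch: int = 20000):
    """Significance of a two-way split against a single-Gaussian null.

    The observed statistic is the cluster index of the given assignment.
    The null simulates ``n_sim`` datasets from a zero-mean Gaussian with
    diagonal covariance ``diag(null_eigenvalues(x))`` and takes each
    dataset's optimal (principal-direction-initialized) 2-means cluster
    index.  Returns ``(ci, p, mc_halfwidth)`` where the half-width is the
    ~95% Monte-Carlo uncertainty of p.
    """
    x = pc_table.to_numpy(dtype=float) if hasattr(pc_table, "to_numpy") \
        else np.asarray(pc_table, dtype=float)
    labels = np.asarray(assignment)
    uniq = np.unique(labels)
    if uniq.size != 2 or any((labels == u).sum() == 0 for u in uniq):
        raise ValueError("assignment must split subjects into two "
                         "non-empty groups")
    import warnings
    if n_sim < 100:
        warnings.warn("n_sim < 100: p-value will be very coarse")
    ci_obs = cluster_index(x, labels)
    lam = null_eigenvalues(x)
    n, d = x.shape
    rng = np.random.default_rng(seed)
    count = 0
    done = 0
    scale = np.sqrt(lam)
    while done < n_sim:
        s_ = min(batch, n_sim - done)
        sims = rng.normal(size=(s_, n, d)) * scale
        ci_null = _two_means_batch(sims)
        count += int((ci_null <= ci_obs).sum())
        done += s_
    p = count / n_sim
    half = 1.96 * np.sqrt(max(p * (1 - p), 1.0 / n_sim) / n_sim)
    return ci_obs, p, half


# ---------------------------------------------------------------------------
# labeling and the frozen model

def label_phenotypes(pc_table: pd.DataFrame, assignment: pd.Series):
    """Map cluster ids onto phenotype labels by heterogeneity direction.

    The cluster with the lower mean oriented component value becomes
    "Phenotype 1 (decreasing heterogeneity)", the higher "Phenotype 2
    (increasing heterogeneity)"; ties break by size (larger cluster = 1).
    Returns ``(phenotype Series with values 1/2, {phenotype: description})``.
    """
    clusters = np.unique(assignment)
    if clusters.size < 2:
        raise ValueError("need at least 2 clusters to label")
    means = {c: float(pc_table.loc[assignment == c].to_numpy().mean())
             for c in clusters}
    sizes = {c: int((assignment == c).sum()) for c in clusters}
    order = sorted(clusters, key=lambda c: (means[c], -sizes[c]))
    mapping = {order[0]: 1}
    for c in order[1:]:
        mapping[c] = 2
    phen = assignment.map(mapping).rename("phenotype")
    descriptions = {1: "Phenotype 1 (decreasing heterogeneity)",
                    2: "Phenotype 2 (increasing heterogeneity)"}
    return phen, descriptions


@dataclass
class PhenotypeModel:
    """Frozen discovery artifacts for validation-cohort assignment."""

    zscore_stats: pd.DataFrame          # mean/sd per feature
    feature_groups: dict                # feature -> group id
    group_pca: dict                     # group id -> GroupPca
    pc_columns: list
    centroids: dict                     # phenotype (int) -> vector
    labels: dict                        # phenotype -> description
    seeds: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)

    def project(self, deltas: pd.DataFrame) -> pd.DataFrame:
        """Z-score with frozen stats and project into retained-PC space."""
        needed = list(self.feature_groups)
        missing = [f for f in needed if f not in deltas.columns]
        if missing:
            raise KeyError(f"validation table missing model features: "
                           f"{missing}")
        z, _ = _apply_stats(deltas[needed], self.zscore_stats)
        pcs = {}
        for gid, gp in self.group_pca.items():
            xc = z[gp.features].to_numpy(dtype=float) - gp.mean
            scores = xc @ gp.loadings.T
            for j in range(gp.n_retained):
                pcs[f"C{gid}-PC{j + 1}"] = scores[:, j]
        return pd.DataFrame(pcs, index=deltas.index)[self.pc_columns]

    def assign(self, deltas: pd.DataFrame) -> pd.Series:
        """Nearest phenotype centroid in the frozen component space.

        Ties go to the lower-numbered phenotype.
        """
        pcs = self.project(deltas)
        phens = sorted(self.centroids)
        cents = np.stack([np.asarray(self.centroids[p]) for p in phens])
        d2 = ((pcs.to_numpy()[:, None, :] - cents[None]) ** 2).sum(axis=2)
        best = np.argmin(d2, axis=1)   # argmin takes the first (lowest) tie
        return pd.Series([phens[i] for i in best], index=deltas.index,
                         name="phenotype")

    # --- serialization ---------------------------------------------------
    def to_json(self) -> dict:
        return {
            "schema_version": MODEL_SCHEMA_VERSION,
            "zscore_stats": {f: {"mean": float(r["mean"]),
                                 "sd": float(r["sd"])}
                             for f, r in self.zscore_stats.iterrows()},
            "feature_groups": self.feature_groups,
            "group_pca": {
                str(g): {"features": gp.features,
                         "mean": list(map(float, gp.mean)),
                         "loadings": [list(map(float, row))
                                      for row in gp.loadings],
                         "explained_variance_ratio":
                             gp.explained_variance_ratio,
                         "n_retained": gp.n_retained}
                for g, gp in self.group_pca.items()},
            "pc_columns": self.pc_columns,
            "centroids": {str(p): list(map(float, v))
                          for p, v in self.centroids.items()},
            "labels": {str(k): v for k, v in self.labels.items()},
            "seeds": self.seeds,
            "thresholds": self.thresholds,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "PhenotypeModel":
        version = obj.get("schema_version")
        if version != MODEL_SCHEMA_VERSION:
            raise ValueError(
                f"unsupported phenotype model schema version: {version!r}")
        stats = pd.DataFrame.from_dict(obj["zscore_stats"], orient="index")
        gpca = {int(g): GroupPca(
            features=d["features"], mean=np.asarray(d["mean"]),
            loadings=np.asarray(d["loadings"]),
            explained_variance_ratio=d["explained_variance_ratio"],
            n_retained=d["n_retained"])
            for g, d in obj["group_pca"].items()}
        return cls(zscore_stats=stats,
                   feature_groups=obj["feature_groups"],
                   group_pca=gpca, pc_columns=obj["pc_columns"],
                   centroids={int(p): np.asarray(v)
                              for p, v in obj["centroids"].items()},
                   labels={int(k): v for k, v in obj["labels"].items()},
                   seeds=obj.get("seeds", {}),
                   thresholds=obj.get("thresholds", {}))

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "PhenotypeModel":
        with open(path) as fh:
            return cls.from_json(json.load(fh))


def _apply_stats(deltas, stats):
    missing = [c for c in deltas.columns if c not in stats.index]
    if missing:
        raise KeyError(f"stats missing for columns: {missing}")
    sub = stats.loc[deltas.columns]
    return (deltas - sub["mean"]) / sub["sd"], stats


def build_phenotype_model(z_deltas: pd.DataFrame, zscore_stats: pd.DataFrame,
                          groups: dict, group_pca: dict,
                          pc_table: pd.DataFrame, phenotypes: pd.Series,
                          labels: dict, seeds=None,
                          thresholds=None) -> PhenotypeModel:
    """Freeze discovery artifacts; centroids are per-phenotype PC means."""
    centroids = {int(p): pc_table.loc[phenotypes == p].mean(axis=0)
                 .to_numpy() for p in sorted(phenotypes.unique())}
    return PhenotypeModel(zscore_stats=zscore_stats, feature_groups=groups,
                          group_pca=group_pca,
                          pc_columns=list(pc_table.columns),
                          centroids=centroids, labels=labels,
                          seeds=seeds or {}, thresholds=thresholds or {})


def assign_validation(deltas_validation: pd.DataFrame,
                      model: PhenotypeModel) -> pd.Series:
    """Assign a new cohort through the frozen discovery model."""
    return model.assign(deltas_validation)
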