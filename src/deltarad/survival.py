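"""Survival and association analyses for phenotype prognosis.

Kaplan-Meier curves and log-rank tests (via lifelines), Cox
proportional-hazards models with Breslow tie handling (Newton-Raphson on
the partial likelihood; the explicit log-likelihood feeds the nested
likelihood-ratio test), Harrell's concordance, repeated stratified 5-fold
cross-validated c-statistics, median risk-score stratification,
confusion-matrix PPV/NPV, and covariate-by-phenotype association tests
with Bonferroni correction.

Model rosters are declarative: a model is just a named covariate list, so
the study's eight-model comparison is data, not code (see
:data:`DEFAULT_MODEL_ROSTER`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sstats
from sklearn.model_selection import StratifiedKFold

# the eight-model roster: three univariable signature models, the clinical
# baseline, then the incremental additions up to the combined model
DEFAULT_MODEL_ROSTER = {
    "mammaprint": ["mammaprint"],
    "ror_s": ["ror_s"],
    "p53": ["p53"],
    "model1_baseline": ["age", "hr_status", "her2_status"],
    "model2_ftv": ["age", "hr_status", "her2_status", "ftv2"],
    "model3_signatures": ["age", "hr_status", "her2_status", "ftv2",
                          "mammaprint", "ror_s", "p53"],
    "model4_phenotype": ["age", "hr_status", "her2_status", "ftv2",
                         "phenotype"],
    "model5_combined": ["age", "hr_status", "her2_status", "ftv2",
                        "mammaprint", "ror_s", "p53", "phenotype"],
}


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank

def km_estimate(times, events, groups=None):
    """Product-limit survival curves per group.

    Returns ``{group: DataFrame(time, survival)}``; curves start at 1 and
    are non-increasing.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if (times < 0).any():
        raise ValueError("negative survival times")
    groups = np.zeros(times.size, dtype=int) if groups is None \
        else np.asarray(groups)
    out = {}
    for g in np.unique(groups):
        sel = groups == g
        if sel.sum() == 0:
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel])
        sf = kmf.survival_function_
        out[g] = pd.DataFrame({"time": sf.index.to_numpy(),
                               "survival": sf.iloc[:, 0].to_numpy()})
    return out


def logrank_test(times, events, groups):
    """Multi-group log-rank chi-square test (df = groups - 1)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    uniq, counts = np.unique(groups, return_counts=True)
    if uniq.size < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    if (counts == 0).any():
        raise ValueError("log-rank test: empty group")
    if events.sum() == 0:
        raise ValueError("log-rank test needs at least one event")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow ties)

@dataclass
class CoxFit:
    covariates: list
    coef: np.ndarray
    log_likelihood: float
    log_likelihood_null: float
    c_statistic: float
    linear_predictor: pd.Series
    n: int
    n_events: int
    converged: bool = True
    separation: bool = False
    meta: dict = field(default_factory=dict)


def _breslow_loglik(beta, x, times, events):
    """Breslow log partial likelihood with gradient and Hessian.

    Rows must be sorted by descending time so risk sets are cumulative
    prefixes.
    """
    eta = x @ beta
    w = np.exp(eta)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w[:, None] * x, axis=0)
    s2 = np.cumsum(w[:, None, None] * (x[:, :, None] * x[:, None, :]), axis=0)
    # group tied event times (Breslow: one denominator per distinct time)
    ll, grad = 0.0, np.zeros(beta.size)
    hess = np.zeros((beta.size, beta.size))
    i = 0
    n = times.size
    while i < n:
        j = i
        while j < n and times[j] == times[i]:
            j += 1
        # risk set for time times[i] is rows 0..j-1 (times sorted desc)
        d_idx = [k for k in range(i, j) if events[k]]
        d = len(d_idx)
        if d > 0:
            r0 = s0[j - 1]
            r1 = s1[j - 1]
            r2 = s2[j - 1]
            ll += eta[d_idx].sum() - d * np.log(r0)
            grad += x[d_idx].sum(axis=0) - d * r1 / r0
            hess -= d * (r2 / r0 - np.outer(r1, r1) / r0 ** 2)
        i = j
    return ll, grad, hess


def _check_collinear(x, names):
    xc = x - x.mean(axis=0)
    sd = xc.std(axis=0)
    if (sd == 0).any():
        bad = [n for n, s in zip(names, sd) if s == 0]
        raise ValueError(f"constant covariate(s): {bad}")
    r = np.corrcoef(xc, rowvar=False)
    if x.shape[1] > 1:
        iu = np.triu_indices(x.shape[1], k=1)
        close = np.abs(r[iu]) > 1 - 1e-10
        if close.any():
            a, b = iu[0][close][0], iu[1][close][0]
            raise ValueError(
                f"collinear covariates: {names[a]!r} and {names[b]!r}")
    if np.linalg.matrix_rank(xc) < x.shape[1]:
        raise ValueError(f"rank-deficient design among {names}")


def fit_cox(table: pd.DataFrame, covariates, time_col="rfs_years",
            event_col="event", max_iter=60, tol=1e-9) -> CoxFit:
    """Newton-Raphson Cox regression with Breslow tie handling.

    Rows with missing values in the model's columns are excluded (count in
    ``meta["n_dropped"]``).  Monotone-likelihood separation is detected by
    coefficient blow-up and flagged rather than silently reported.
    """
    cols = list(covariates) + [time_col, event_col]
    sub = table[cols].dropna()
    n_dropped = len(table) - len(sub)
    x = sub[list(covariates)].to_numpy(dtype=float)
    times = sub[time_col].to_numpy(dtype=float)
    events = sub[event_col].to_numpy(dtype=int)
    names = list(covariates)
    _check_collinear(x, names)
    if events.sum() < len(names) + 1:
        warnings.warn(f"only {events.sum()} events for {len(names)} "
                      "covariates; estimates may be unstable")
    # center and scale for stable Newton steps; coefficients mapped back
    mu, sd = x.mean(axis=0), x.std(axis=0)
    xs = (x - mu) / sd
    order = np.argsort(-times, kind="stable")
    xs_o, t_o, e_o = xs[order], times[order], events[order]

    beta = np.zeros(len(names))
    ll0, _, _ = _breslow_loglik(beta, xs_o, t_o, e_o)
    ll_prev = ll0
    converged = False
    for _ in range(max_iter):
        ll, grad, hess = _breslow_loglik(beta, xs_o, t_o, e_o)
        try:
            step = np.linalg.solve(hess - 1e-12 * np.eye(len(names)), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        new = beta - step
        ll_new, _, _ = _breslow_loglik(new, xs_o, t_o, e_o)
        halv = 0
        while not np.isfinite(ll_new) or ll_new < ll - 1e-12:
            step *= 0.5
            new = beta - step
            ll_new, _, _ = _breslow_loglik(new, xs_o, t_o, e_o)
            halv += 1
            if halv > 30:
                break
        beta = new
        if abs(ll_new - ll_prev) < tol * (abs(ll_prev) + 1):
            converged = True
            ll_prev = ll_new
            break
        ll_prev = ll_new
    separation = bool(np.abs(beta / 1.0).max() > 15)
    if separation:
        warnings.warn("possible monotone likelihood (separation): "
                      "coefficient magnitude exceeds 15 on scaled covariates")
    coef = beta / sd
    lp = pd.Series(x @ coef, index=sub.index, name="linear_predictor")
    c = harrell_c(lp.to_numpy(), times, events)
    return CoxFit(covariates=names, coef=coef, log_likelihood=float(ll_prev),
                  log_likelihood_null=float(ll0), c_statistic=c,
                  linear_predictor=lp, n=len(sub),
                  n_events=int(events.sum()), converged=converged,
                  separation=separation,
                  meta={"n_dropped": n_dropped, "center": list(mu),
                        "scale": list(sd), "ties": "breslow"})


# ---------------------------------------------------------------------------
# concordance

def harrell_c(lp, times, events):
    """Harrell's c over event-anchored usable pairs; predictor ties 0.5.

    A pair (i, j) is usable when ``t_i < t_j`` and subject i had the event;
    it is concordant when the earlier-event subject has the higher
    predicted risk.  Undefined (no usable pairs) returns NaN.
    """
    lp = np.asarray(lp, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if not lp.size == times.size == events.size:
        raise ValueError("length mismatch")
    ti = times[:, None]
    tj = times[None, :]
    usable = (ti < tj) & (events[:, None] == 1)
    if not usable.any():
        return float("nan")
    li = lp[:, None]
    lj = lp[None, :]
    conc = (li > lj) & usable
    tie = (li == lj) & usable
    return float((conc.sum() + 0.5 * tie.sum()) / usable.sum())


def harrell_c_bruteforce(lp, times, events):
    """Pair-by-pair reference implementation (oracle route)."""
    n = len(lp)
    num = den = 0.0
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i] == 1:
                den += 1
                if lp[i] > lp[j]:
                    num += 1
                elif lp[i] == lp[j]:
                    num += 0.5
    return float("nan") if den == 0 else num / den


# ---------------------------------------------------------------------------
# cross-validated c-statistic

@dataclass
class CvResult:
    model_id: str
    covariates: list
    c_per_replicate: np.ndarray
    mean_c: float
    percentile_interval: tuple
    folds: int
    replicates: int
    seed: int
    meta: dict = field(default_factory=dict)


def cv_cstatistic(table: pd.DataFrame, covariates, folds=5, replicates=100,
                  seed=0, model_id="", time_col="rfs_years",
                  event_col="event") -> CvResult:
    """Repeated stratified k-fold out-of-sample concordance.

    Per replicate: folds stratified on the event indicator; the model is
    fitted on each training split and linear predictors computed for the
    held-out fold; the pooled out-of-fold predictors give one Harrell c
    per replicate.  Reported: mean and the 2.5/97.5 percentile interval
    across replicates.
    """
    cols = list(covariates) + [time_col, event_col]
    sub = table[cols].dropna().reset_index(drop=True)
    times = sub[time_col].to_numpy(dtype=float)
    events = sub[event_col].to_numpy(dtype=int)
    cs = np.empty(replicates)
    rng = np.random.default_rng(seed)
    for rep in range(replicates):
        lp = np.empty(len(sub))
        for attempt in range(10):
            skf = StratifiedKFold(n_splits=folds, shuffle=True,
                                  random_state=int(rng.integers(2 ** 31)))
            splits = list(skf.split(np.zeros(len(sub)), events))
            if all(events[tr].sum() > 0 for tr, _ in splits):
                break
        else:
            raise RuntimeError("could not build folds with events in "
                               "every training split")
        for train, test in splits:
            # covariates constant within a training fold carry no
            # information there; they are dropped for that fold (coef 0)
            tr = sub.iloc[train]
            usable = [c for c in covariates if tr[c].nunique() > 1]
            if not usable:
                lp[test] = 0.0
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_cox(tr, usable,
                              time_col=time_col, event_col=event_col)
            lp[test] = sub.iloc[test][usable].to_numpy(
                dtype=float) @ fit.coef
        cs[rep] = harrell_c(lp, times, events)
    lo, hi = np.percentile(cs, (2.5, 97.5))
    return CvResult(model_id=model_id, covariates=list(covariates),
                    c_per_replicate=cs, mean_c=float(cs.mean()),
                    percentile_interval=(float(lo), float(hi)),
                    folds=folds, replicates=replicates, seed=seed,
                    meta={"pooling": "out-of-fold linear predictors",
                          "n": len(sub), "n_events": int(events.sum())})


def lr_test(fit_nested: CoxFit, fit_full: CoxFit):
    """Likelihood-ratio test of nested Cox models.

    Returns ``(statistic, df, p)`` with statistic ``2 (ll_full -
    ll_nested)`` on the covariate-count difference degrees of freedom.
    """
    if not set(fit_nested.covariates) <= set(fit_full.covariates):
        raise ValueError("models are not nested")
    if fit_nested.n != fit_full.n:
        raise ValueError("nested comparison requires identical rows")
    df = len(fit_full.covariates) - len(fit_nested.covariates)
    if df == 0:
        raise ValueError("models have the same covariates")
    stat = 2.0 * (fit_full.log_likelihood - fit_nested.log_likelihood)
    p = float(sstats.chi2.sf(max(stat, 0.0), df))
    return float(stat), df, p


# ---------------------------------------------------------------------------
# risk stratification / confusion / associations

def risk_stratify(fit: CoxFit, table: pd.DataFrame):
    """Cox linear-predictor risk score with a median split.

    The subject at the median goes to the low-risk group (documented
    convention).  Returns ``(risk Series, label Series with 'high'/'low')``.
    """
    x = table[fit.covariates].to_numpy(dtype=float)
    risk = pd.Series(x @ fit.coef, index=table.index, name="risk_score")
    if risk.nunique() == 1:
        raise ValueError("all risk scores equal; stratification refused")
    med = float(risk.median())
    label = pd.Series(np.where(risk > med, "high", "low"),
                      index=table.index, name="risk_group")
    return risk, label


def confusion_metrics(predicted_positive, event):
    """2x2 event/censor confusion counts with PPV/NPV and sens/spec.

    ``predicted_positive`` is the binary prediction that the subject will
    have an event (e.g. phenotype 2, "high risk", mutant).
    """
    pred = np.asarray(predicted_positive, dtype=bool)
    ev = np.asarray(event, dtype=int)
    tp = int((pred & (ev == 1)).sum())
    fp = int((pred & (ev == 0)).sum())
    fn = int((~pred & (ev == 1)).sum())
    tn = int((~pred & (ev == 0)).sum())
    out = {"tp": tp, "fp": fp, "fn": fn, "tn": tn}
    out["ppv"] = tp / (tp + fp) if tp + fp > 0 else float("nan")
    out["npv"] = tn / (tn + fn) if tn + fn > 0 else float("nan")
    out["sensitivity"] = tp / (tp + fn) if tp + fn > 0 else float("nan")
    out["specificity"] = tn / (tn + fp) if tn + fp > 0 else float("nan")
    return out


def covariate_association(table: pd.DataFrame, phenotype, covariate_types,
                          alpha=0.05):
    """Per-covariate tests across phenotypes with Bonferroni correction.

    ``covariate_types`` maps column -> "categorical" (chi-square on the
    contingency table, no continuity correction) or "continuous"
    (Kruskal-Wallis).  The corrected per-test threshold is ``alpha / m``
    with m the number of tests actually performed.
    """
    phen = np.asarray(phenotype)
    if np.unique(phen).size < 2:
        raise ValueError("need at least 2 phenotypes")
    rows = []
    for col, kind in covariate_types.items():
        v = table[col]
        if kind == "categorical":
            if v.nunique() < 2:
                rows.append({"covariate": col, "test": "chi2", "stat": np.nan,
                             "p": np.nan, "note": "skipped:single-level"})
                continue
            ct = pd.crosstab(v, phen)
            stat, p, _, expected = sstats.chi2_contingency(ct,
                                                           correction=False)
            note = "expected-count<5" if (expected < 5).any() else ""
            rows.append({"covariate": col, "test": "chi2",
                         "stat": float(stat), "p": float(p), "note": note})
        elif kind == "continuous":
            samples = [v[phen == g].dropna() for g in np.unique(phen)]
            stat, p = sstats.kruskal(*samples)
            rows.append({"covariate": col, "test": "kruskal",
                         "stat": float(stat), "p": float(p), "note": ""})
        else:
            raise ValueError(f"unknown covariate type {kind!r} for {col!r}")
    res = pd.DataFrame(rows).set_index("covariate")
    m = int(res["p"].notna().sum())
    res.attrs["n_tests"] = m
    res.attrs["alpha"] = alpha
    res.attrs["alpha_bonferroni"] = alpha / m if m else float("nan")
    res["significant_raw"] = res["p"] < alpha
    res["significant_bonferroni"] = res["p"] < (alpha / m if m else np.nan)
    return res
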