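"""Outcome statistics for hypoxia-dynamics and delta-radiomics predictors.

Survival endpoints (overall and progression-free survival) are analysed with
Kaplan–Meier curves, the two-group log-rank test and multivariate Cox
regression; binary endpoints (local recurrence, distant metastasis) with the
Mann–Whitney U test and single-feature logistic models whose prediction
performance (AUC, specificity) is estimated by imbalance-adjusted —
class-stratified, equal per-class weight — bootstrap resampling.  Candidate
features are de-duplicated with a Spearman redundancy filter (|r| > 0.8),
p-values are corrected per endpoint and time-point with the
Benjamini–Hochberg step-up procedure, and a feature is only called predictive
when its corrected significance holds at both in-treatment time-points
(W2 and W5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .volumes import OutcomeRecord  # re-export: the outcome table's row type

__all__ = [
    "OutcomeRecord", "PredictionResult",
    "kaplan_meier", "logrank", "cox_hr", "mann_whitney",
    "bootstrap_logistic_auc", "spearman_redundancy_filter",
    "bh_adjust", "two_timepoint_confirmation", "analyze_delta_features",
]

SURVIVAL_ENDPOINTS = ("os", "pfs")
BINARY_ENDPOINTS = ("lr", "dm")


@dataclass(frozen=True)
class PredictionResult:
    """One feature × endpoint × time-point prediction record."""

    feature_name: str
    endpoint: str
    p_raw: float
    p_adjusted: float
    auc: float | None = None
    specificity: float | None = None
    hr: float | None = None
    hr_ci: tuple[float, float] | None = None
    confirmed_w5: bool = False


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def kaplan_meier(times: Sequence[float], events: Sequence[int]) -> pd.DataFrame:
    """Product-limit survival estimate as step-function coordinates."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("need at least one observation")
    if (times < 0).any():
        raise ValueError("survival times must be >= 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.values, "survival": sf.iloc[:, 0].values})


def logrank(
    times_a, events_a, times_b, events_b
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    ea, eb = np.asarray(events_a, int), np.asarray(events_b, int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be nonempty")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("need at least one event overall")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def cox_hr(times, events, covariates: pd.DataFrame) -> pd.DataFrame:
    """Multivariate Cox regression: hazard ratios with Wald 95% CI.

    Returns a DataFrame indexed by covariate with columns
    ``hr, ci_low, ci_high, p``.  Non-convergence (e.g. separation) raises a
    RuntimeError so callers can flag the covariate set.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if events.sum() < covariates.shape[1]:
        raise ValueError("fewer events than covariates; Cox fit is unidentified")
    df = covariates.reset_index(drop=True).copy()
    df["_t"] = times
    df["_e"] = events
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="_t", event_col="_e")
    except ConvergenceError as err:
        raise RuntimeError(f"Cox model did not converge (possible separation): {err}")
    summary = cph.summary
    return pd.DataFrame({
        "hr": np.exp(summary["coef"]),
        "ci_low": np.exp(summary["coef lower 95%"]),
        "ci_high": np.exp(summary["coef upper 95%"]),
        "p": summary["p"],
    })


def mann_whitney(values_a, values_b) -> tuple[float, float]:
    """Mann–Whitney U test; exact p for small samples without ties.

    Returns (U statistic of the first sample, two-sided p-value).
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (combined.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Bootstrap logistic AUC
# ---------------------------------------------------------------------------

def _fit_logistic_1d(x: np.ndarray, y: np.ndarray, max_iter: int = 50) -> tuple[float, float, bool]:
    """Newton–Raphson fit of P(y=1) = sigmoid(b0 + b1 x).

    Returns (b0, b1, separated).  Coefficients are capped when the likelihood
    is unbounded (complete separation).
    """
    xs = (x - x.mean()) / (x.std() + 1e-12)
    b0, b1 = 0.0, 0.0
    separated = False
    for _ in range(max_iter):
        eta = np.clip(b0 + b1 * xs, -35, 35)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        g0 = float((y - p).sum())
        g1 = float(((y - p) * xs).sum())
        h00 = float(w.sum())
        h01 = float((w * xs).sum())
        h11 = float((w * xs * xs).sum())
        det = h00 * h11 - h01 * h01
        if det < 1e-12:
            separated = True
            break
        d0 = (h11 * g0 - h01 * g1) / det
        d1 = (h00 * g1 - h01 * g0) / det
        b0 += d0
        b1 += d1
        if abs(b1) > 30:
            separated = True
            break
        if abs(d0) < 1e-10 and abs(d1) < 1e-10:
            break
    # undo standardisation
    sd = x.std() + 1e-12
    beta1 = b1 / sd
    beta0 = b0 - b1 * x.mean() / sd
    return beta0, beta1, separated


def _rank_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Mann–Whitney AUC with tie correction (0.5 credit for ties)."""
    n1 = int(y.sum())
    n0 = y.size - n1
    if n0 == 0 or n1 == 0:
        return math.nan
    ranks = stats.rankdata(scores)
    u1 = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u1 / (n0 * n1))


def _balanced_specificity(scores: np.ndarray, y: np.ndarray) -> float:
    """Specificity at the threshold where sensitivity and specificity are
    closest (ties broken toward the larger Youden index)."""
    s0 = scores[y == 0]
    s1 = scores[y == 1]
    if s0.size == 0 or s1.size == 0:
        return math.nan
    cand = np.unique(scores)
    thresholds = np.concatenate([cand, [cand[-1] + 1.0]])
    sens = (s1[None, :] >= thresholds[:, None]).mean(axis=1)
    spec = (s0[None, :] < thresholds[:, None]).mean(axis=1)
    gap = np.abs(sens - spec)
    best = np.flatnonzero(gap == gap.min())
    youden = sens[best] + spec[best]
    pick = best[np.argmax(youden)]
    return float(spec[pick])


def bootstrap_logistic_auc(
    feature,
    labels,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    stratified: bool = True,
) -> dict:
    """Single-feature logistic prediction with bootstrap performance estimates.

    The imbalance-adjusted scheme resamples each outcome class separately to
    equal effective weight (⌈n/2⌉ draws per class), fits the logistic model on
    the bootstrap sample, and evaluates AUC and balanced-threshold specificity
    on the out-of-bag patients.  ``stratified=False`` falls back to the plain
    bootstrap.  Model coefficients are reported as bootstrap means.
    """
    x = np.asarray(feature, float)
    y = np.asarray(labels, int)
    if x.size != y.size:
        raise ValueError("feature and labels differ in length")
    if x.size < 8:
        raise ValueError("need at least 8 patients")
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    idx0 = np.flatnonzero(y == 0)
    idx1 = np.flatnonzero(y == 1)
    n = x.size
    m_half = (n + 1) // 2

    b0_full, b1_full, separated = _fit_logistic_1d(x, y)
    scores_full = b0_full + b1_full * x
    auc_apparent = _rank_auc(scores_full, y)

    aucs, specs, b0s, b1s = [], [], [], []
    for _ in range(n_boot):
        if stratified:
            take = np.concatenate([rng.choice(idx0, m_half, replace=True),
                                   rng.choice(idx1, m_half, replace=True)])
        else:
            take = rng.integers(0, n, n)
        b0, b1, _ = _fit_logistic_1d(x[take], y[take])
        b0s.append(b0)
        b1s.append(b1)
        oob = np.setdiff1d(np.arange(n), take, assume_unique=False)
        if oob.size and len(np.unique(y[oob])) == 2:
            xe, ye = x[oob], y[oob]
        else:
            xe, ye = x, y
        scores = b0 + b1 * xe
        if b1 == 0:                     # uninformative: orientation-free ties
            scores = np.zeros_like(xe)
        aucs.append(_rank_auc(scores, ye))
        specs.append(_balanced_specificity(scores, ye))

    return {
        "auc": float(np.nanmean(aucs)),
        "specificity": float(np.nanmean(specs)),
        "auc_apparent": float(auc_apparent),
        "coef": float(np.mean(b1s)),
        "intercept": float(np.mean(b0s)),
        "separated": bool(separated),
        "n_boot": n_boot,
    }


# ---------------------------------------------------------------------------
# Feature selection and multiplicity
# ---------------------------------------------------------------------------

def spearman_redundancy_filter(
    delta_table: pd.DataFrame,
    p_values: pd.Series,
    r_threshold: float = 0.8,
) -> list[str]:
    """Drop mutually redundant features, keeping the most significant.

    Features are visited by ascending p-value; each kept feature removes every
    not-yet-visited feature whose Spearman |r| with it exceeds the threshold.
    """
    features = [f for f in p_values.sort_values().index if f in delta_table.columns]
    if len(features) < 2:
        return features
    corr = delta_table[features].corr(method="spearman")
    kept: list[str] = []
    removed: set[str] = set()
    for f in features:
        if f in removed:
            continue
        kept.append(f)
        for g in features:
            if g not in removed and g != f and abs(corr.loc[f, g]) > r_threshold:
                removed.add(g)
    return kept


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment (monotone, capped at 1).

    NaN entries stay NaN and do not count toward the family size.
    """
    p = np.asarray(p_values, float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def two_timepoint_confirmation(
    results_w2: pd.DataFrame,
    results_w5: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Confirm predictors across both in-treatment scans.

    Both inputs carry one row per (feature_name, endpoint) with a
    ``p_adjusted`` column; a predictor is confirmed when its BH-adjusted
    p-value is <= alpha at W2 AND at W5 for the same endpoint.
    """
    key = ["feature_name", "endpoint"]
    w2 = results_w2.set_index(key)["p_adjusted"]
    w5 = results_w5.set_index(key)["p_adjusted"]
    if set(w2.index.get_level_values(0)) != set(w5.index.get_level_values(0)):
        raise ValueError("feature lists differ between time-points")
    merged = pd.DataFrame({"p_adjusted_w2": w2, "p_adjusted_w5": w5})
    merged["confirmed"] = (merged["p_adjusted_w2"] <= alpha) & (
        merged["p_adjusted_w5"] <= alpha)
    return merged.reset_index()


# ---------------------------------------------------------------------------
# Cohort-level inference
# ---------------------------------------------------------------------------

def _survival_p(feature: pd.Series, times, events) -> float:
    """Log-rank p after a median dichotomisation of a continuous feature."""
    vals = feature.values
    cut = np.nanmedian(vals)
    hi = vals >= cut
    lo = ~hi
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if hi.sum() == 0 or lo.sum() == 0:
        return math.nan
    try:
        return logrank(times[hi], events[hi], times[lo], events[lo])[1]
    except ValueError:
        return math.nan


def analyze_delta_features(
    delta_table: pd.DataFrame,
    outcomes: pd.DataFrame,
    endpoints: Sequence[str] = SURVIVAL_ENDPOINTS + BINARY_ENDPOINTS,
    alpha: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
    auc_for: str = "significant",
) -> pd.DataFrame:
    """Per-feature outcome prediction for one time-point pair.

    delta_table : patients × features (relative deviations; NaN = missing)
    outcomes : per-patient columns ``pfs_months, pfs_event, os_months,
        os_event, local_recurrence, distant_metastasis`` aligned on index

    Binary endpoints use the Mann–Whitney U test; survival endpoints use the
    log-rank test on a median split.  p-values are BH-adjusted per endpoint
    across the feature family.  Bootstrap AUC/specificity are computed for
    binary-endpoint features (``auc_for='significant'`` restricts the costly
    bootstrap to BH-significant ones; ``'all'`` / ``'none'`` as named).
    """
    outcomes = outcomes.loc[delta_table.index]
    rows = []
    rng = np.random.default_rng(seed)
    for endpoint in endpoints:
        for feat in delta_table.columns:
            col = delta_table[feat]
            ok = col.notna()
            if ok.sum() < 4:
                rows.append((feat, endpoint, math.nan))
                continue
            sub = col[ok]
            out = outcomes.loc[ok.values]
            if endpoint in BINARY_ENDPOINTS:
                y = out["local_recurrence" if endpoint == "lr" else "distant_metastasis"]
                y = y.values.astype(int)
                if y.min() == y.max():
                    p = math.nan
                else:
                    p = mann_whitney(sub.values[y == 1], sub.values[y == 0])[1]
            elif endpoint in SURVIVAL_ENDPOINTS:
                t = out[f"{endpoint}_months"].values
                e = out[f"{endpoint}_event"].values
                p = _survival_p(sub, t, e)
            else:
                raise ValueError(f"unknown endpoint {endpoint!r}")
            rows.append((feat, endpoint, p))

    res = pd.DataFrame(rows, columns=["feature_name", "endpoint", "p_raw"])
    res["p_adjusted"] = np.nan
    for endpoint in endpoints:
        m = res["endpoint"] == endpoint
        res.loc[m, "p_adjusted"] = bh_adjust(res.loc[m, "p_raw"])
    res["significant"] = res["p_adjusted"] <= alpha

    res["auc"] = np.nan
    res["specificity"] = np.nan
    if auc_for != "none":
        for i, row in res.iterrows():
            if row["endpoint"] not in BINARY_ENDPOINTS:
                continue
            if auc_for == "significant" and not row["significant"]:
                continue
            col = delta_table[row["feature_name"]]
            ok = col.notna()
            ycol = "local_recurrence" if row["endpoint"] == "lr" else "distant_metastasis"
            y = outcomes.loc[ok.values, ycol].values.astype(int)
            if ok.sum() < 8 or y.min() == y.max():
                continue
            boot = bootstrap_logistic_auc(col[ok].values, y, n_boot=n_boot, seed=rng)
            res.loc[i, "auc"] = boot["auc"]
            res.loc[i, "specificity"] = boot["specificity"]
    return res
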