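"""Clinical models: an L1-penalized logistic diagnostic score and
cutpoint-based survival analysis of CpG methylation.

The diagnostic model is a LASSO logistic regression of tumor/normal status on
promoter activities, with the penalty chosen at minimum mean cross-validated
deviance over a geometric lambda path (10-fold CV, fixed fold seed).  The
sample score is the printed linear form sum(activity x coefficient), without
the intercept.  Prognosis dichotomizes a CpG's beta at the maximally selected
log-rank cutpoint (minimum group proportion 10%) and compares overall
survival with Kaplan-Meier curves and the log-rank test over a 10-year
horizon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "DiagnosticModel",
    "SurvivalAnalysisResult",
    "fit_diagnostic",
    "score_samples",
    "roc_auc",
    "logrank",
    "optimal_cutpoint",
    "km_logrank",
    "flag_prognostic_mraps",
    "HORIZON_YEARS",
]

HORIZON_YEARS = 10.0
MINPROP = 0.1


@dataclass
class DiagnosticModel:
    """Fitted LASSO diagnostic model on the original activity scale.

    ``coefficients`` holds every input promoter; non-selected promoters have
    coefficient exactly 0.  ``lambda_`` is on the glmnet scale
    (penalty = lambda * n * sum|beta| on standardized features).
    """

    selected_promoters: list[str]
    coefficients: pd.Series
    intercept: float
    lambda_: float
    cv_folds: int
    seed: int
    cv_path: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "selected_promoters": list(self.selected_promoters),
            "coefficients": {k: float(v)
                             for k, v in self.coefficients.items()
                             if v != 0.0},
            "intercept": float(self.intercept),
            "lambda": float(self.lambda_),
            "cv_folds": int(self.cv_folds),
            "seed": int(self.seed),
        }


@dataclass
class SurvivalAnalysisResult:
    probe_id: str
    cutpoint: float
    n_high: int
    n_low: int
    logrank_p: float
    direction: str  # high_meth_better / low_meth_better
    is_prognostic: bool
    observed_minus_expected_high: float = float("nan")
    curves: pd.DataFrame | None = field(repr=False, default=None)


def _lambda_path(X_std: np.ndarray, y: np.ndarray, n_lambdas: int) -> np.ndarray:
    """Geometric lambda path from the smallest all-zero lambda downward.

    The path floor follows the glmnet convention: lambda_max/100 when there
    are fewer samples than features, lambda_max/10^4 otherwise.
    """
    n, p = X_std.shape
    lam_max = np.abs(X_std.T @ (y - y.mean())).max() / n
    if lam_max <= 0:
        return np.array([])
    ratio = 1e-2 if n < p else 1e-4
    return np.geomspace(lam_max, lam_max * ratio, n_lambdas)


def fit_diagnostic(activity: pd.DataFrame, labels: pd.Series,
                   folds: int = 10, seed: int = 0,
                   n_lambdas: int = 100,
                   lambda_rule: str = "min") -> DiagnosticModel:
    """LASSO logistic regression of tumor status on promoter activities.

    ``activity`` is samples x promoters; ``labels`` maps sample to
    {tumor, normal} (or {1, 0}).  Features are standardized internally; the
    returned coefficients are on the original scale.  Lambda is chosen at the
    minimum mean cross-validated binomial deviance (``lambda_rule="min"``,
    the default) or by the sparser one-standard-error rule
    (``lambda_rule="1se"``), with the fold assignment fixed by ``seed``;
    ties prefer the sparser (larger) lambda.
    """
    if lambda_rule not in ("min", "1se"):
        raise ValueError("lambda_rule must be 'min' or '1se'")
    X = activity.to_numpy(dtype=float)
    y = pd.Series(labels).reindex(activity.index)
    if y.dtype == object:
        y = y.map({"tumor": 1, "normal": 0})
    y = y.to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("diagnostic fit needs both classes present")
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("diagnostic fit needs >= 2 samples per class")

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    Xs = (X - mu) / sd_safe
    n = len(y)

    lambdas = _lambda_path(Xs, y, n_lambdas)
    if len(lambdas) == 0:  # all features constant: intercept-only model
        p1 = y.mean()
        intercept = math.log(p1 / (1 - p1)) if 0 < p1 < 1 else 0.0
        coef = pd.Series(0.0, index=activity.columns)
        return DiagnosticModel([], coef, intercept, math.inf, folds, seed)

    folds_eff = min(folds, int((y == 1).sum()), int((y == 0).sum()))
    skf = StratifiedKFold(n_splits=folds_eff, shuffle=True, random_state=seed)
    splits = list(skf.split(Xs, y))

    deviance = np.zeros((len(lambdas), len(splits)))
    for j, (tr, te) in enumerate(splits):
        for i, lam in enumerate(lambdas):
            clf = LogisticRegression(l1_ratio=1.0, C=1.0 / (n * lam),
                                     solver="liblinear", max_iter=2000,
                                     random_state=0)
            clf.fit(Xs[tr], y[tr])
            prob = clf.predict_proba(Xs[te])[:, 1]
            deviance[i, j] = 2.0 * log_loss(y[te], prob, labels=[0.0, 1.0])
    mean_dev = deviance.mean(axis=1)
    best = int(np.argmin(mean_dev))  # argmin takes the first = largest lambda
    if lambda_rule == "1se":
        se = deviance.std(axis=1, ddof=1)[best] / math.sqrt(deviance.shape[1])
        best = int(np.flatnonzero(mean_dev <= mean_dev[best] + se)[0])
    lam = float(lambdas[best])

    clf = LogisticRegression(l1_ratio=1.0, C=1.0 / (n * lam),
                             solver="liblinear", max_iter=5000,
                             random_state=0)
    clf.fit(Xs, y)
    coef_std = clf.coef_.ravel()
    coef = pd.Series(coef_std / sd_safe, index=activity.columns)
    intercept = float(clf.intercept_[0] - np.sum(coef_std * mu / sd_safe))
    selected = [c for c in activity.columns if coef[c] != 0.0]
    cv_path = pd.DataFrame({"lambda": lambdas, "mean_deviance": mean_dev})
    return DiagnosticModel(selected, coef, intercept, lam, folds_eff, seed,
                           cv_path)


def score_samples(model: DiagnosticModel, activity: pd.DataFrame) -> pd.Series:
    """Model score per sample: sum(promoter activity x coefficient), no intercept."""
    missing = [p for p in model.selected_promoters
               if p not in activity.columns]
    if missing:
        raise ValueError("selected promoter(s) missing from activity matrix: "
                         + ", ".join(missing))
    coef = model.coefficients.reindex(activity.columns).fillna(0.0)
    score = activity.to_numpy(dtype=float) @ coef.to_numpy()
    return pd.Series(score, index=activity.index, name="score")


def roc_auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC; ties count 0.5."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if y.dtype == object or y.dtype.kind in "US":
        y = (y == "tumor").astype(int)
    y = y.astype(int)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(scores)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def logrank(times, events, high) -> dict[str, float]:
    """Two-group log-rank test via the standard hypergeometric moments.

    Returns observed-minus-expected events in the high group, its variance,
    the chi-square statistic and p-value.  Identical groups give statistic 0
    and p = 1.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    high = np.asarray(high, dtype=bool)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = int(at_risk.sum())
        nh = int((at_risk & high).sum())
        dead = (times == t) & (events == 1)
        d = int(dead.sum())
        dh = int((dead & high).sum())
        o_minus_e += dh - d * nh / n
        if n > 1:
            var += d * (nh / n) * (1 - nh / n) * (n - d) / (n - 1)
    chi2 = (o_minus_e ** 2 / var) if var > 0 else 0.0
    p = float(stats.chi2.sf(chi2, df=1)) if var > 0 else 1.0
    return {"o_minus_e_high": float(o_minus_e), "var": float(var),
            "chi2": float(chi2), "p": p}


def optimal_cutpoint(betas, times, events, minprop: float = MINPROP
                     ) -> tuple[float, float]:
    """Maximally selected log-rank cutpoint on a CpG's beta values.

    Candidate thresholds are the midpoints between sorted distinct betas;
    a threshold is eligible when both groups (beta <= t vs beta > t) hold at
    least ``minprop`` of the samples.  Returns (cutpoint, |standardized
    statistic|); ties keep the lower threshold.  Raises when no threshold is
    eligible (e.g. constant betas).
    """
    betas = np.asarray(betas, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = len(betas)
    distinct = np.unique(betas)
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    best = None
    for thr in candidates:
        high = betas > thr
        n_high = int(high.sum())
        if min(n_high, n - n_high) < minprop * n:
            continue
        res = logrank(times, events, high)
        z = (abs(res["o_minus_e_high"]) / math.sqrt(res["var"])
             if res["var"] > 0 else 0.0)
        if best is None or z > best[1]:
            best = (float(thr), z)
    if best is None:
        raise ValueError("no cutpoint satisfies the minimum group proportion")
    return best


def km_logrank(high, times, events, horizon: float = HORIZON_YEARS,
               probe_id: str = "", cutpoint: float = float("nan"),
               p_threshold: float = 0.05) -> SurvivalAnalysisResult:
    """Kaplan-Meier + log-rank comparison of two groups within a horizon.

    Follow-up is administratively censored at ``horizon``: times are capped
    and events beyond it become censored.  Direction reflects which group's
    survival dominates (fewer observed than expected events = better).
    """
    from lifelines import KaplanMeierFitter

    high = np.asarray(high, dtype=bool)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if not high.any() or high.all():
        raise ValueError("both groups must be non-empty")
    events = np.where(times > horizon, 0, events)
    times = np.minimum(times, horizon)

    res = logrank(times, events, high)
    curves = []
    for name, mask in (("high", high), ("low", ~high)):
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask], label=name)
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        sf["group"] = name
        curves.append(sf)
    direction = ("high_meth_better" if res["o_minus_e_high"] <= 0
                 else "low_meth_better")
    return SurvivalAnalysisResult(
        probe_id=probe_id,
        cutpoint=float(cutpoint),
        n_high=int(high.sum()),
        n_low=int((~high).sum()),
        logrank_p=res["p"],
        direction=direction,
        is_prognostic=bool(res["p"] < p_threshold),
        observed_minus_expected_high=res["o_minus_e_high"],
        curves=pd.concat(curves, ignore_index=True),
    )


def flag_prognostic_mraps(links: pd.DataFrame, cohort_beta: pd.DataFrame,
                          clinical: pd.DataFrame,
                          minprop: float = MINPROP,
                          horizon: float = HORIZON_YEARS) -> pd.DataFrame:
    """Cutpoint + log-rank survival analysis per representative CpG.

    ``links`` maps promoter_id (index) to probe_id; ``cohort_beta`` is
    probes x cohort samples; ``clinical`` has sample_id, time (years), event.
    CpGs absent from the cohort, or with no eligible cutpoint, are marked
    untestable and excluded from the prognostic denominator.
    """
    clin = clinical.set_index("sample_id") if "sample_id" in clinical.columns \
        else clinical
    rows = []
    for pid, link in links.iterrows():
        probe = link["probe_id"]
        rec = {"promoter_id": pid, "probe_id": probe, "status": "untestable",
               "cutpoint": np.nan, "logrank_p": np.nan, "direction": "",
               "is_prognostic": False}
        if probe in cohort_beta.index:
            samples = [s for s in clin.index if s in cohort_beta.columns]
            b = cohort_beta.loc[probe, samples].to_numpy(dtype=float)
            ok = np.isfinite(b)
            t = clin.loc[samples, "time"].to_numpy(dtype=float)[ok]
            e = clin.loc[samples, "event"].to_numpy(dtype=int)[ok]
            try:
                cut, _ = optimal_cutpoint(b[ok], t, e, minprop=minprop)
                res = km_logrank(b[ok] > cut, t, e, horizon=horizon,
                                 probe_id=probe, cutpoint=cut)
                rec.update(status="tested", cutpoint=cut,
                           logrank_p=res.logrank_p, direction=res.direction,
                           is_prognostic=res.is_prognostic)
            except ValueError:
                pass
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("promoter_id")
    return out
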