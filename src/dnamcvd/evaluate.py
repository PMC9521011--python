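"""Validation analytics for risk scores.

Two designs are supported, mirroring how composite methylation scores are
validated in practice: nested case-control sets are evaluated with
horizon-censored ROC sweeps (relabel events past a follow-up horizon as
non-events, fit a logistic model adjusted for the matching covariates, report
AUC with a DeLong confidence interval and the operating point closest to the
top-left ROC corner); cohort sets are evaluated with Cox models (hazard ratio
per SD of the score and Harrell's concordance index with a jackknife
confidence interval).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from statsmodels.duration.hazard_regression import PHReg

logger = logging.getLogger("dnamcvd.evaluate")

HORIZON_COLUMNS = ["horizon", "n_events", "auc", "auc_ci_low", "auc_ci_high",
                   "sensitivity", "specificity", "threshold", "deviance"]


def censor_at_horizon(time, event, horizon: float) -> np.ndarray:
    """Binary labels after right-censoring at a horizon: 1 iff the event
    occurred within ``horizon`` years; later events are relabelled 0 and kept."""
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    return ((event == 1) & (time <= horizon)).astype(int)


# ---------------------------------------------------------------------------
# ROC / AUC with DeLong variance


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_auc_variance(pred, labels) -> tuple[float, float]:
    """Midrank AUC of ``pred`` for ``labels`` and its DeLong variance."""
    pred = np.asarray(pred, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos, neg = pred[labels == 1], pred[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    tz = _midrank(np.concatenate([pos, neg]))
    tx, ty = _midrank(pos), _midrank(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n
    v10 = 1.0 - (tz[m:] - ty) / m
    var = 0.0
    if m > 1:
        var += np.var(v01, ddof=1) / m
    if n > 1:
        var += np.var(v10, ddof=1) / n
    return float(auc), float(var)


def _dummy_covars(covars: pd.DataFrame) -> np.ndarray:
    num = covars.copy()
    for col in num.columns:
        if not np.issubdtype(num[col].dtype, np.number):
            if set(num[col].dropna().unique()) <= {"female", "male"}:
                from .io import sex_to_numeric
                num[col] = sex_to_numeric(num[col])
            else:
                num = pd.concat(
                    [num.drop(columns=[col]),
                     pd.get_dummies(num[col], prefix=col, drop_first=True, dtype=float)],
                    axis=1)
    return num.to_numpy(dtype=float)


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    sensitivity: float
    specificity: float
    threshold: float
    n_pos: int
    n_neg: int
    deviance: float


def _logistic_lp_and_deviance(X: np.ndarray, labels: np.ndarray):
    clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000)
    clf.fit(X, labels)
    lp = clf.decision_function(X)
    prob = np.clip(1.0 / (1.0 + np.exp(-lp)), 1e-12, 1 - 1e-12)
    dev = -2.0 * float(np.sum(labels * np.log(prob) + (1 - labels) * np.log(1 - prob)))
    return lp, dev


def _roc_from_predictor(lp: np.ndarray, labels: np.ndarray) -> RocResult:
    auc, var = delong_auc_variance(lp, labels)
    half = 1.959963984540054 * np.sqrt(max(var, 0.0))
    thr = np.unique(lp)
    pos, neg = lp[labels == 1], lp[labels == 0]
    sens = np.array([(pos >= t).mean() for t in thr])
    spec = np.array([(neg < t).mean() for t in thr])
    dist = np.sqrt((1 - sens) ** 2 + (1 - spec) ** 2)
    k = int(np.argmin(dist))
    return RocResult(auc=auc, ci_low=max(0.0, auc - half), ci_high=min(1.0, auc + half),
                     sensitivity=float(sens[k]), specificity=float(spec[k]),
                     threshold=float(thr[k]), n_pos=len(pos), n_neg=len(neg),
                     deviance=np.nan)


def adjusted_logistic_roc(score, labels, covars: pd.DataFrame | None = None) -> RocResult:
    """ROC analysis of a score, optionally adjusted for matching covariates.

    With covariates the ROC is built on the fitted logistic linear predictor
    (model-level AUC); without covariates the raw score is the predictor, so
    the AUC equals the Mann-Whitney rank statistic exactly.  The operating
    point minimises the distance to the top-left ROC corner.
    """
    score = np.asarray(score, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class")
    if covars is None:
        X = score[:, None]
        lp = score
    else:
        X = np.column_stack([score, _dummy_covars(covars)])
        lp, _ = _logistic_lp_and_deviance(X, labels)
    _, dev = _logistic_lp_and_deviance(X, labels)
    res = _roc_from_predictor(lp, labels)
    res.deviance = dev
    return res


def horizon_sweep(score, pheno: pd.DataFrame, covars: pd.DataFrame | None = None,
                  horizon_max: float = 18, horizon_min: float = 2, step: float = 1,
                  time_col: str = "follow_up_time", event_col: str = "event"
                  ) -> pd.DataFrame:
    """ROC analysis per follow-up horizon, descending from max to min.

    A horizon whose relabelled outcome is single-class yields a row with
    missing AUC and a warning rather than an error.
    """
    if horizon_min > horizon_max or step <= 0:
        raise ValueError("need horizon_min <= horizon_max and step > 0")
    score = np.asarray(score, dtype=float)
    time = pheno[time_col].to_numpy(dtype=float)
    event = pheno[event_col].to_numpy()
    rows = []
    h = float(horizon_max)
    while h >= horizon_min - 1e-9:
        labels = censor_at_horizon(time, event, h)
        row = {"horizon": h, "n_events": int(labels.sum())}
        if len(np.unique(labels)) < 2:
            warnings.warn(f"horizon {h}: single-class labels; AUC not computed")
            row.update({c: np.nan for c in HORIZON_COLUMNS[2:]})
        else:
            r = adjusted_logistic_roc(score, labels, covars)
            row.update(auc=r.auc, auc_ci_low=r.ci_low, auc_ci_high=r.ci_high,
                       sensitivity=r.sensitivity, specificity=r.specificity,
                       threshold=r.threshold, deviance=r.deviance)
        rows.append(row)
        h -= step
    return pd.DataFrame(rows, columns=HORIZON_COLUMNS)


# ---------------------------------------------------------------------------
# Cox evaluation


def harrell_c(pred, time, event) -> tuple[float, float]:
    """Harrell's concordance of a risk prediction and its jackknife SE.

    A pair is comparable iff the shorter follow-up time ends in an event
    (ties in time are not comparable); higher prediction with shorter
    survival is concordant; prediction ties count 1/2.
    """
    pred = np.asarray(pred, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    n = len(pred)
    shorter = time[:, None] < time[None, :]
    comp = shorter & (event[:, None] == 1)
    conc = pred[:, None] > pred[None, :]
    tie = pred[:, None] == pred[None, :]
    u = comp * (conc + 0.5 * tie)
    W = comp.sum()
    if W == 0:
        raise ValueError("no comparable pairs")
    U = u.sum()
    c = U / W
    u_i = u.sum(axis=1) + u.sum(axis=0)
    w_i = comp.sum(axis=1) + comp.sum(axis=0)
    psi = (u_i - c * w_i) / W
    se = float(np.sqrt((n - 1) / n * np.sum(psi ** 2)))
    return float(c), se


@dataclass
class CoxEvalResult:
    hr_per_sd: float
    hr_ci_low: float
    hr_ci_high: float
    c_index: float
    c_ci_low: float
    c_ci_high: float
    n: int
    n_events: int
    deviance: float


def cox_eval(score, time, event, covars: pd.DataFrame | None = None) -> CoxEvalResult:
    """Cox model of time-to-event on the standardised score (+ covariates).

    Breslow tie handling; hazard ratio per one SD of the score with a Wald
    95% CI; Harrell's C on the model linear predictor with a jackknife CI.
    """
    score = np.asarray(score, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    if event.sum() < 2:
        raise ValueError("need at least 2 events")
    zscore = (score - score.mean()) / score.std(ddof=1)
    X = zscore[:, None] if covars is None else np.column_stack(
        [zscore, _dummy_covars(covars)])
    model = PHReg(time, X, status=event, ties="breslow")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        fit = model.fit(disp=False)
    beta, se = fit.params[0], fit.bse[0]
    if np.all(np.isfinite(fit.params)):
        lp = X @ fit.params
    else:
        # monotone (separating) score: the partial likelihood has no interior
        # maximum; rank the subjects by the score itself
        warnings.warn("Cox fit did not converge to finite coefficients; "
                      "concordance computed on the raw standardised score")
        lp = zscore
    c, cse = harrell_c(lp, time, event)
    zcrit = 1.959963984540054
    return CoxEvalResult(
        hr_per_sd=float(np.exp(beta)),
        hr_ci_low=float(np.exp(beta - zcrit * se)),
        hr_ci_high=float(np.exp(beta + zcrit * se)),
        c_index=c,
        c_ci_low=max(0.0, c - zcrit * cse),
        c_ci_high=min(1.0, c + zcrit * cse),
        n=len(time), n_events=int(event.sum()),
        deviance=-2.0 * float(fit.llf),
    )


# ---------------------------------------------------------------------------
# Multi-model comparison


def plot_horizon_auc(tables: dict[str, pd.DataFrame], ax=None):
    """AUC as a function of the follow-up horizon for one or more models.

    ``tables`` maps a model name to a :func:`horizon_sweep` result.  Returns
    the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    for name, tab in tables.items():
        ax.plot(tab["horizon"], tab["auc"], marker="o", ms=3, label=name)
    ax.set_xlabel("follow-up horizon (years)")
    ax.set_ylabel("AUC")
    ax.invert_xaxis()
    ax.axhline(0.5, color="grey", lw=0.6, ls="--")
    ax.legend(frameon=False)
    return ax


def compare_models(data: pd.DataFrame, bundles: dict[str, list[str]],
                   design: str = "cohort", adjust: tuple[str, ...] = (),
                   time_col: str = "follow_up_time", event_col: str = "event",
                   horizon_max: float = 18, horizon_min: float = 2,
                   step: float = 1) -> pd.DataFrame:
    """Evaluate named covariate/score bundles side by side.

    ``bundles`` maps a model name to the data columns it uses, so composite
    scores, refit traditional-risk-factor sets and enriched combinations are
    all expressible.  Cohort design: one Cox row per bundle.  Nested
    case-control design: one horizon-sweep row per bundle and horizon, the
    ROC built on the logistic linear predictor of bundle + adjustment
    columns.
    """
    for name, cols in bundles.items():
        missing = [c for c in list(cols) + list(adjust) if c not in data.columns]
        if missing:
            raise ValueError(f"bundle {name!r} references unknown columns: {missing}")
    time = data[time_col].to_numpy(dtype=float)
    event = data[event_col].to_numpy()
    rows = []
    if design == "cohort":
        for name, cols in bundles.items():
            X = _dummy_covars(data[list(cols) + list(adjust)])
            fit = PHReg(time, X, status=np.asarray(event).astype(int),
                        ties="breslow").fit(disp=False)
            lp = X @ fit.params
            c, cse = harrell_c(lp, time, np.asarray(event).astype(int))
            zcrit = 1.959963984540054
            rows.append({"bundle": name, "n": len(data),
                         "n_events": int(np.asarray(event).sum()),
                         "c_index": c, "c_ci_low": max(0.0, c - zcrit * cse),
                         "c_ci_high": min(1.0, c + zcrit * cse),
                         "deviance": -2.0 * float(fit.llf)})
        return pd.DataFrame(rows)
    if design == "nested_cc":
        for name, cols in bundles.items():
            h = float(horizon_max)
            while h >= horizon_min - 1e-9:
                labels = censor_at_horizon(time, event, h)
                row = {"bundle": name, "horizon": h, "n_events": int(labels.sum())}
                if len(np.unique(labels)) < 2:
                    warnings.warn(f"horizon {h}: single-class labels")
                    row.update({c: np.nan for c in HORIZON_COLUMNS[2:]})
                else:
                    X = _dummy_covars(data[list(cols) + list(adjust)])
                    lp, dev = _logistic_lp_and_deviance(X, labels)
                    r = _roc_from_predictor(lp, labels)
                    row.update(auc=r.auc, auc_ci_low=r.ci_low, auc_ci_high=r.ci_high,
                               sensitivity=r.sensitivity, specificity=r.specificity,
                               threshold=r.threshold, deviance=dev)
                rows.append(row)
                h -= step
        return pd.DataFrame(rows)
    raise ValueError(f"unknown design: {design}")
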