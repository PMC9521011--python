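"""Stability-selected elastic-net Cox model defining the composite
methylation cardiovascular risk score.

The score is a linear combination of standardised surrogate features.  It is
fitted by repeated elastic-net Cox regressions on random 80% subsamples
(without replacement): a feature enters the score when its coefficient is
nonzero in at least a threshold fraction of subsamples, and its weight is
the average of its nonzero coefficients across subsamples.  A packaged
ten-feature coefficient table (the published composite weights) ships with
the code for scoring cohorts without refitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.metrics import concordance_index_censored
from sksurv.util import Surv

from .scoring import SurrogateMatrix

logger = logging.getLogger("dnamcvd.composite")


@dataclass
class PenaltyConfig:
    """Elastic-net Cox penalty configuration.

    ``alpha`` is the L1/L2 mixing (1 = lasso, 0 = ridge); the penalty weight
    lambda is chosen on a log grid by k-fold cross-validation on Harrell's
    concordance of the held-out linear predictor (maximised by default;
    ``maximise_concordance=False`` preserves the literal minimising reading).
    ``lambda_rule='1se'`` (default) takes the largest lambda whose mean CV
    concordance is within one standard error of the optimum — the glmnet
    parsimony convention; ``'best'`` takes the optimum itself.
    """

    alpha: float = 0.5
    n_lambda: int = 30
    lambda_min_ratio: float = 0.01
    cv_folds: int = 10
    maximise_concordance: bool = True
    lambda_rule: str = "1se"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.lambda_rule not in ("1se", "best"):
            raise ValueError("lambda_rule must be '1se' or 'best'")


@dataclass
class StabilityResult:
    table: pd.DataFrame  # index feature; columns selection_frequency, mean_nonzero_coef
    n_perm: int
    subsample_fraction: float
    subsample_size: int
    freq_threshold: float
    seed: int


@dataclass
class CVDScoreModel:
    """Selected features and their composite-score coefficients."""

    feature_names: list[str]
    coefficients: pd.Series
    provenance: str = "fitted"

    def __post_init__(self):
        self.coefficients = pd.Series(self.coefficients, dtype=float)
        if len(self.coefficients) < 1:
            raise ValueError("a score model needs at least one feature")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")


def _as_frame(Z) -> pd.DataFrame:
    return Z.values if isinstance(Z, SurrogateMatrix) else pd.DataFrame(Z)


def enet_cox_lambda_max(Z, time, event, alpha: float) -> float:
    """Smallest penalty that zeroes all coefficients, from the null-model
    Breslow score vector: ``max_j |(1/n) sum_events (x_j - riskset mean)| / alpha``."""
    X = _as_frame(Z).to_numpy(dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    n = len(time)
    order = np.argsort(-time, kind="mergesort")  # descending: cumulative = risk set
    Xo, to, eo = X[order], time[order], event[order]
    csum = np.cumsum(Xo, axis=0)
    counts = np.arange(1, n + 1)
    score = np.zeros(X.shape[1])
    for i in range(n):
        if eo[i] != 1:
            continue
        # risk set: subjects with time >= t_i -> prefix of the descending order
        k = np.searchsorted(-to, -to[i], side="right")
        score += Xo[i] - csum[k - 1] / counts[k - 1]
    lam = np.max(np.abs(score)) / n / max(alpha, 1e-12)
    return float(lam)


def _lambda_grid(Z, time, event, pc: PenaltyConfig) -> np.ndarray:
    lam_max = enet_cox_lambda_max(Z, time, event, pc.alpha) * 1.001
    return np.logspace(np.log10(lam_max),
                       np.log10(lam_max * pc.lambda_min_ratio), pc.n_lambda)


def fit_enet_cox(Z, time, event, pc: PenaltyConfig | None = None,
                 lambda_grid=None) -> tuple[pd.Series, float]:
    """Elastic-net Cox fit with CV-chosen penalty.

    Maximises the Breslow partial log-likelihood minus
    ``lambda * (alpha ||b||_1 + (1 - alpha)/2 ||b||^2)`` (glmnet scaling,
    log-likelihood divided by n).  Returns the coefficient vector on the
    input feature scale and the selected lambda.
    """
    pc = pc or PenaltyConfig()
    Zf = _as_frame(Z)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    if event.sum() < 2:
        raise ValueError("need at least 2 events")
    if (Zf.std(axis=0, ddof=0) <= 0).all():
        raise ValueError("all feature columns are constant")
    X = Zf.to_numpy(dtype=float)
    grid = np.sort(np.asarray(lambda_grid, float))[::-1] if lambda_grid is not None \
        else _lambda_grid(Zf, time, event, pc)
    y = Surv.from_arrays(event=event.astype(bool), time=time)

    if len(grid) > 1:
        skf = StratifiedKFold(n_splits=pc.cv_folds, shuffle=True, random_state=pc.seed)
        cindex = np.zeros((pc.cv_folds, len(grid)))
        for f, (tr, te) in enumerate(skf.split(X, event)):
            est = CoxnetSurvivalAnalysis(l1_ratio=max(pc.alpha, 1e-6), alphas=grid,
                                         fit_baseline_model=False, tol=1e-7)
            est.fit(X[tr], y[tr])
            fitted = np.asarray(est.alphas_)
            for k, lam in enumerate(grid):
                kk = int(np.argmin(np.abs(fitted - lam)))
                lp = X[te] @ est.coef_[:, kk]
                if event[te].sum() == 0 or np.allclose(lp, lp[0]):
                    cindex[f, k] = 0.5
                else:
                    cindex[f, k] = concordance_index_censored(
                        event[te].astype(bool), time[te], lp)[0]
        mean_c = cindex.mean(axis=0)
        se_c = cindex.std(axis=0, ddof=1) / np.sqrt(cindex.shape[0])
        best = int(np.argmax(mean_c)) if pc.maximise_concordance else int(np.argmin(mean_c))
        if pc.lambda_rule == "1se":
            # grid is descending, so the first index within 1 SE of the
            # optimum is the largest (most parsimonious) such lambda
            if pc.maximise_concordance:
                ok = mean_c >= mean_c[best] - se_c[best]
            else:
                ok = mean_c <= mean_c[best] + se_c[best]
            best = int(np.flatnonzero(ok)[0])
        lam_sel = float(grid[best])
    else:
        lam_sel = float(grid[0])

    est = CoxnetSurvivalAnalysis(l1_ratio=max(pc.alpha, 1e-6), alphas=grid,
                                 fit_baseline_model=False, tol=1e-9)
    est.fit(X, y)
    kk = int(np.argmin(np.abs(np.asarray(est.alphas_) - lam_sel)))
    coefs = pd.Series(est.coef_[:, kk], index=Zf.columns)
    return coefs, lam_sel


def subsample_size(n: int, fraction: float) -> int:
    return int(np.ceil(fraction * n))


def stability_select(Z, time, event, pc: PenaltyConfig | None = None,
                     n_perm: int = 1000, fraction: float = 0.8,
                     freq_threshold: float = 0.5, seed: int = 0,
                     exclude_features: list[str] | None = None
                     ) -> tuple[StabilityResult, CVDScoreModel]:
    """Stability selection around the elastic-net Cox fit.

    Repeats the CV-tuned fit on ``n_perm`` random subsamples of size
    ``ceil(fraction * N)`` drawn without replacement.  A feature is selected
    when its selection frequency reaches ``freq_threshold``; its score
    coefficient is the mean of its nonzero coefficients across subsamples
    (zeros excluded).  Deterministic given the seed, and frequencies permute
    with the feature columns.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pc = pc or PenaltyConfig()
    Zf = _as_frame(Z)
    if exclude_features:
        Zf = Zf.drop(columns=list(exclude_features))
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    n = len(Zf)
    size = subsample_size(n, fraction)

    rng = np.random.default_rng(seed)
    coefs = np.zeros((n_perm, Zf.shape[1]))
    for b in range(n_perm):
        for _ in range(100):
            idx = rng.choice(n, size=size, replace=False)
            if event[idx].sum() >= 2:
                break
        else:
            raise ValueError("could not draw a subsample with >= 2 events")
        sub_pc = PenaltyConfig(alpha=pc.alpha, n_lambda=pc.n_lambda,
                               lambda_min_ratio=pc.lambda_min_ratio,
                               cv_folds=pc.cv_folds,
                               maximise_concordance=pc.maximise_concordance,
                               seed=int(rng.integers(2 ** 31)))
        c, _ = fit_enet_cox(Zf.iloc[idx], time[idx], event[idx], sub_pc)
        coefs[b] = c.to_numpy()

    nonzero = coefs != 0
    freq = nonzero.mean(axis=0)
    with np.errstate(invalid="ignore"):
        mean_nonzero = np.where(nonzero.any(axis=0),
                                coefs.sum(axis=0) / np.maximum(nonzero.sum(axis=0), 1),
                                np.nan)
    table = pd.DataFrame({"selection_frequency": freq,
                          "mean_nonzero_coef": mean_nonzero}, index=Zf.columns)
    result = StabilityResult(table=table, n_perm=n_perm, subsample_fraction=fraction,
                             subsample_size=size, freq_threshold=freq_threshold,
                             seed=seed)
    selected = table.index[freq >= freq_threshold].tolist()
    if not selected:
        raise ValueError(
            "no feature reached the selection-frequency threshold "
            f"{freq_threshold}; max frequency {freq.max():.2f} - review the threshold")
    # features selected by a zero threshold but never nonzero contribute 0
    coef_sel = table.loc[selected, "mean_nonzero_coef"].fillna(0.0)
    model = CVDScoreModel(feature_names=selected, coefficients=coef_sel,
                          provenance="fitted")
    return result, model


def compute_cvd_score(Z, model: CVDScoreModel) -> pd.Series:
    """Linear combination of standardised surrogate features; no intercept."""
    if isinstance(Z, SurrogateMatrix) and not Z.standardized:
        raise ValueError("surrogate matrix must be standardised before scoring")
    Zf = _as_frame(Z)
    missing = [f for f in model.feature_names if f not in Zf.columns]
    if missing:
        raise ValueError(f"missing score features: {missing}")
    vals = Zf[model.feature_names].to_numpy(dtype=float) @ model.coefficients.to_numpy()
    return pd.Series(vals, index=Zf.index, name="DNAmCVDscore")


def load_packaged_cvdscore() -> CVDScoreModel:
    """The packaged ten-feature composite-score coefficient table."""
    path = resources.files("dnamcvd.data") / "dnamcvdscore_coefficients.csv"
    with resources.as_file(path) as p:
        df = pd.read_csv(p)
    return CVDScoreModel(feature_names=df["feature"].tolist(),
                         coefficients=pd.Series(df["coefficient"].to_numpy(),
                                                index=df["feature"]),
                         provenance="packaged")


# ---------------------------------------------------------------------------
# Model/Results presentation


class CVDScoreCox:
    """Stability-selected elastic-net Cox model of time-to-event on a
    standardised surrogate matrix."""

    def __init__(self, Z, time, event, penalty: PenaltyConfig | None = None,
                 n_perm: int = 1000, fraction: float = 0.8,
                 freq_threshold: float = 0.5, seed: int = 0,
                 exclude_features: list[str] | None = None):
        self.Z, self.time, self.event = Z, time, event
        self.penalty = penalty or PenaltyConfig()
        self.n_perm, self.fraction = n_perm, fraction
        self.freq_threshold, self.seed = freq_threshold, seed
        self.exclude_features = exclude_features

    def fit(self) -> "CVDScoreResults":
        stab, model = stability_select(
            self.Z, self.time, self.event, self.penalty, n_perm=self.n_perm,
            fraction=self.fraction, freq_threshold=self.freq_threshold,
            seed=self.seed, exclude_features=self.exclude_features)
        return CVDScoreResults(self, stab, model)


class CVDScoreResults:
    def __init__(self, spec: CVDScoreCox, stability: StabilityResult,
                 model: CVDScoreModel):
        self.model_spec = spec
        self.stability = stability
        self.model = model

    @property
    def selection_frequencies(self) -> pd.Series:
        return self.stability.table["selection_frequency"]

    def predict(self, Z) -> pd.Series:
        return compute_cvd_score(Z, self.model)

    def summary(self) -> str:
        t = self.stability.table.sort_values("selection_frequency", ascending=False)
        lines = [
            "Composite score: stability-selected elastic-net Cox",
            "=" * 55,
            f"subsamples            {self.stability.n_perm}"
            f" x {self.stability.subsample_size} samples"
            f" ({self.stability.subsample_fraction:.0%} without replacement)",
            f"selection threshold   {self.stability.freq_threshold}",
            f"selected features     {len(self.model.feature_names)}",
            "",
            t.to_string(float_format=lambda v: f"{v: .4f}"),
        ]
        return "\n".join(lines)
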