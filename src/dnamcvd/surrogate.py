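"""Training of DNA-methylation surrogate biomarkers.

A surrogate for a measured risk factor is built in three steps:

1. one-way ANOVA of the (log) marker across recruitment centres decides the
   modelling route: markers with significant between-centre differences get a
   random centre intercept, the rest a plain fixed-effects model;
2. an epigenome-wide scan (one linear model per CpG, adjusted for age and sex
   and, on the mixed route, whitened for the centre random intercept) ranks
   probes by p-value and keeps the top fraction;
3. the log marker is regressed on the retained probes with an L1 penalty
   (LASSO, or its random-intercept analogue on the mixed route), age and sex
   unpenalised, the penalty chosen by k-fold cross-validation.

The fitted prediction rule is ``intercept + sum_j w_j beta_j + age/sex
terms``; the centre random intercept is never part of the prediction rule, so
surrogates remain computable in cohorts with unknown centres.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold

from .io import BetaMatrix, WeightTable, sex_to_numeric

logger = logging.getLogger("dnamcvd.surrogate")

__all__ = [
    "EwasResult", "SurrogateModel", "SurrogateRegression", "SurrogateResults",
    "TrainConfig", "centre_anova", "ewas_rank", "fit_lasso_surrogate",
    "fit_mixed_lasso_surrogate", "train_surrogate", "validate_surrogate",
    "meta_analyse_correlations", "lasso_kkt_violation",
]


# ---------------------------------------------------------------------------
# Step 1: centre ANOVA


def centre_anova(y, centre) -> tuple[float, float]:
    """One-way ANOVA F statistic and p-value for marker differences across centres."""
    y = np.asarray(y, dtype=float)
    centre = np.asarray(centre)
    levels = pd.unique(centre)
    if len(levels) < 2:
        raise ValueError("centre ANOVA needs at least 2 centres")
    groups = [y[centre == c] for c in levels]
    if min(len(g) for g in groups) < 2:
        raise ValueError("each centre needs at least 2 observations")
    means = np.array([g.mean() for g in groups])
    if np.ptp(means) == 0.0:
        return 0.0, 1.0
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


# ---------------------------------------------------------------------------
# Random-intercept variance components (EM) and whitening


def _ml_random_intercept(r, codes, n_groups):
    """ML variance components (sigma2_between, sigma2_within) of
    ``r = b_group + e`` by profiling the marginal Gaussian likelihood over
    the variance ratio ``theta = s2b / s2e``.

    The within-group variance has a closed form given theta, so the profile
    objective is a scalar function minimised on [0, theta_max]; an estimate
    on the boundary comes back as exactly 0 (no between-group variance).
    """
    from scipy.optimize import minimize_scalar

    r = np.asarray(r, dtype=float)
    n = len(r)
    m = np.bincount(codes, minlength=n_groups).astype(float)
    gsum = np.bincount(codes, weights=r, minlength=n_groups)
    ss_total = float(r @ r)

    def profile(theta):
        a = 1.0 + m * theta
        q = ss_total - float(np.sum(theta / a * gsum ** 2))
        q = max(q, 1e-300)
        return n * np.log(q / n) + float(np.sum(np.log(a)))

    res = minimize_scalar(profile, bounds=(0.0, 1e4), method="bounded",
                          options={"xatol": 1e-12})
    theta = float(res.x)
    if profile(0.0) <= res.fun or theta < 1e-12:
        theta = 0.0
    a = 1.0 + m * theta
    s2e = max((ss_total - float(np.sum(theta / a * gsum ** 2))) / n, 1e-300)
    return theta * s2e, s2e


def _whiten_rows(M, codes, n_groups, s2b, s2e):
    """Scaled GLS whitening for a random-intercept covariance.

    Subtracts ``c_g`` times the group mean from each row, with
    ``c_g = 1 - sqrt(s2e / (s2e + m_g * s2b))``; the transform is the identity
    when ``s2b = 0`` and maps the marginal covariance to ``s2e * I``.
    """
    M = np.asarray(M, dtype=float)
    squeeze = M.ndim == 1
    if squeeze:
        M = M[:, None]
    if s2b <= 0:
        return M[:, 0] if squeeze else M.copy()
    m = np.bincount(codes, minlength=n_groups).astype(float)
    c = 1.0 - np.sqrt(s2e / (s2e + m * s2b))
    out = M.copy()
    for g in range(n_groups):
        rows = codes == g
        if m[g] > 0:
            out[rows] -= c[g] * out[rows].mean(axis=0)
    return out[:, 0] if squeeze else out


def _centre_codes(centre):
    codes, levels = pd.factorize(pd.Series(centre).astype(str), sort=True)
    return codes, list(levels)


# ---------------------------------------------------------------------------
# Step 2: EWAS ranking


@dataclass
class EwasResult:
    """Per-probe association statistics and the p-value ranking."""

    table: pd.DataFrame            # index: probe id; columns: coef, se, p
    ranked_probes: list[str]       # ascending p, ties broken by probe id
    top_probes: list[str]
    top_fraction: float
    mixed: bool
    sigma2_between: float | None = None
    sigma2_within: float | None = None


def _covariate_design(pheno: pd.DataFrame) -> np.ndarray:
    return np.column_stack([
        np.ones(len(pheno)),
        pheno["age"].to_numpy(dtype=float),
        sex_to_numeric(pheno["sex"]),
    ])


def ewas_rank(bm: BetaMatrix, y, covars: pd.DataFrame, centre=None,
              top_fraction: float = 0.01) -> EwasResult:
    """Epigenome-wide scan: one model per probe, ``y ~ beta_j + age + sex``.

    With ``centre`` given, the centre random intercept is handled by
    estimating variance components once from the covariate-only model and
    whitening; probe p-values then use the large-sample normal approximation.
    On the fixed route p-values are two-sided t tests.
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must be in (0, 1]")
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite")
    B = bm.data.to_numpy()
    if np.isnan(B).any():
        raise ValueError("beta matrix must be fully imputed before EWAS")
    n, P = B.shape
    C = _covariate_design(covars)

    mixed = centre is not None
    s2b = s2e = None
    if mixed:
        codes, _ = _centre_codes(centre)
        coef0, *_ = np.linalg.lstsq(C, y, rcond=None)
        s2b, s2e = _ml_random_intercept(y - C @ coef0, codes, codes.max() + 1)
        y = _whiten_rows(y, codes, codes.max() + 1, s2b, s2e)
        C = _whiten_rows(C, codes, codes.max() + 1, s2b, s2e)
        B = _whiten_rows(B, codes, codes.max() + 1, s2b, s2e)

    # Frisch-Waugh: residualise y and every probe on the covariate design
    pinv = np.linalg.pinv(C)
    ytil = y - C @ (pinv @ y)
    Btil = B - C @ (pinv @ B)
    xtx = np.einsum("ij,ij->j", Btil, Btil)
    ok = xtx > 1e-12
    coef = np.zeros(P)
    coef[ok] = (Btil.T @ ytil)[ok] / xtx[ok]
    rss = float(ytil @ ytil) - coef ** 2 * xtx
    dof = n - C.shape[1] - 1
    if dof < 1:
        raise ValueError("not enough samples for the EWAS design")
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.maximum(rss, 0.0) / dof / xtx)
        tstat = coef / se
    pvals = np.ones(P)
    if mixed:
        pvals[ok] = 2.0 * stats.norm.sf(np.abs(tstat[ok]))
    else:
        pvals[ok] = 2.0 * stats.t.sf(np.abs(tstat[ok]), dof)
    se[~ok] = np.inf

    table = pd.DataFrame({"coef": coef, "se": se, "p": pvals}, index=bm.probe_ids)
    ranked = table.sort_index(kind="mergesort") \
                  .sort_values("p", kind="mergesort").index.tolist()
    n_top = max(1, int(np.ceil(top_fraction * P)))
    return EwasResult(table=table, ranked_probes=ranked, top_probes=ranked[:n_top],
                      top_fraction=top_fraction, mixed=mixed,
                      sigma2_between=s2b, sigma2_within=s2e)


# ---------------------------------------------------------------------------
# Step 3: L1-penalised fits


@dataclass
class SurrogateModel:
    """Fitted sparse surrogate: CpG weights plus unpenalised age/sex terms."""

    marker_name: str
    model_type: str                      # fixed_lasso | mixed_lasso
    intercept: float
    probe_weights: pd.Series             # original beta scale, zeros retained
    covariate_weights: dict[str, float]
    lambda_selected: float
    transform: str = "log"
    sigma2_between: float | None = None
    sigma2_within: float | None = None
    anova_f: float | None = None
    anova_p: float | None = None
    n_train: int = 0
    seed: int = 0
    objective_path: list[float] = field(default_factory=list)

    @property
    def n_probes_nonzero(self) -> int:
        return int((self.probe_weights != 0).sum())

    @property
    def surrogate_name(self) -> str:
        """Feature name of the surrogate (DNAm<marker> convention)."""
        return f"DNAm{self.marker_name}"

    def to_weight_table(self, nonzero_only: bool = True) -> WeightTable:
        w = self.probe_weights[self.probe_weights != 0] if nonzero_only else self.probe_weights
        if len(w) == 0:
            w = self.probe_weights.iloc[:1]  # degenerate all-zero fit
        return WeightTable(marker_name=self.surrogate_name, intercept=self.intercept,
                           probe_weights=w, covariate_weights=self.covariate_weights,
                           transform=self.transform,
                           provenance=f"dnamcvd:{self.model_type}:{self.marker_name}")


def _partial_out(y, X, C):
    """Residualise y and X on the unpenalised design C (Frisch-Waugh)."""
    pinv = np.linalg.pinv(C)
    return y - C @ (pinv @ y), X - C @ (pinv @ X)


def _standardise_columns(X):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    ok = sd > 1e-12
    Xs = np.zeros_like(X)
    Xs[:, ok] = (X[:, ok] - mean[ok]) / sd[ok]
    return Xs, sd, ok


def _lasso_solve(Xs, y, lam, tol=1e-12):
    if lam <= 0:
        w, *_ = np.linalg.lstsq(Xs, y, rcond=None)
        return w
    model = Lasso(alpha=lam, fit_intercept=False, tol=tol, max_iter=500_000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(Xs, y)
    return model.coef_


def _default_lambda_grid(lam_max, n_points=100, decades=4.0):
    lam_max = max(lam_max, 1e-12)
    return np.logspace(np.log10(lam_max), np.log10(lam_max) - decades, n_points)


def _cv_lambda(Xs, y, grid, cv_folds, seed):
    """k-fold CV mean squared prediction error along a descending lambda grid."""
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    sse = np.zeros(len(grid))
    for tr, te in kf.split(Xs):
        model = Lasso(alpha=grid[0], fit_intercept=False, warm_start=True,
                      tol=1e-8, max_iter=100_000)
        for k, lam in enumerate(grid):
            if lam <= 0:
                w = _lasso_solve(Xs[tr], y[tr], 0.0)
            else:
                model.alpha = lam
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    model.fit(Xs[tr], y[tr])
                w = model.coef_
            sse[k] += np.sum((y[te] - Xs[te] @ w) ** 2)
    return int(np.argmin(sse)), sse / len(y)


def _finish_fit(y, X_arr, C, w_orig):
    """Unpenalised intercept/age/sex terms given the probe weights."""
    coef, *_ = np.linalg.lstsq(C, y - X_arr @ w_orig, rcond=None)
    return float(coef[0]), {"age": float(coef[1]), "sex": float(coef[2])}


def fit_lasso_surrogate(y, X: pd.DataFrame, covars: pd.DataFrame,
                        lambda_grid=None, cv_folds: int = 10, seed: int = 0,
                        marker_name: str = "marker") -> SurrogateModel:
    """LASSO of y on probe betas with unpenalised intercept/age/sex.

    Minimises ``(1/2n) ||y - Xw - Zc - b0||^2 + lambda * ||w_std||_1`` with the
    penalty applied on internally standardised probe columns (glmnet
    convention); weights are returned on the original beta scale.  Lambda is
    chosen on a log grid spanning four decades below the data-driven maximum
    by k-fold cross-validated mean squared prediction error.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < cv_folds:
        raise ValueError("need at least cv_folds samples")
    if np.std(y) == 0:
        raise ValueError("constant y")
    X_arr = X.to_numpy(dtype=float)
    C = _covariate_design(covars)
    ytil, Xtil = _partial_out(y, X_arr, C)
    Xs, sd, ok = _standardise_columns(Xtil)

    if lambda_grid is None:
        lam_max = np.max(np.abs(Xs.T @ ytil)) / n
        grid = _default_lambda_grid(lam_max)
    else:
        grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]

    if len(grid) == 1:
        best, lam = 0, float(grid[0])
    else:
        best, _ = _cv_lambda(Xs, ytil, grid, cv_folds, seed)
        lam = float(grid[best])
    w_std = _lasso_solve(Xs, ytil, lam)
    w_orig = np.zeros(X_arr.shape[1])
    w_orig[ok] = w_std[ok] / sd[ok]
    intercept, covw = _finish_fit(y, X_arr, C, w_orig)
    return SurrogateModel(marker_name=marker_name, model_type="fixed_lasso",
                          intercept=intercept,
                          probe_weights=pd.Series(w_orig, index=X.columns),
                          covariate_weights=covw, lambda_selected=lam,
                          n_train=n, seed=seed)


def lasso_kkt_violation(model: SurrogateModel, y, X: pd.DataFrame,
                        covars: pd.DataFrame) -> float:
    """Maximum violation of the LASSO stationarity conditions at the solution.

    Zero within solver tolerance certifies optimality of the penalised
    objective: ``|x_j' r| / n <= lambda`` for inactive probes and
    ``x_j' r / n = lambda * sign(w_j)`` for active ones, in the standardised
    partialled-out parametrisation the solver works in.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    X_arr = X.to_numpy(dtype=float)
    C = _covariate_design(covars)
    ytil, Xtil = _partial_out(y, X_arr, C)
    Xs, sd, ok = _standardise_columns(Xtil)
    w_std = np.zeros(X_arr.shape[1])
    w_std[ok] = model.probe_weights.to_numpy()[ok] * sd[ok]
    g = Xs.T @ (ytil - Xs @ w_std) / n
    lam = model.lambda_selected
    active = w_std != 0
    viol = 0.0
    if np.any(~active & ok):
        viol = max(viol, float(np.max(np.abs(g[~active & ok]) - lam)))
    if active.any():
        viol = max(viol, float(np.max(np.abs(g[active] - lam * np.sign(w_std[active])))))
    return max(viol, 0.0)


def fit_mixed_lasso_surrogate(y, X: pd.DataFrame, covars: pd.DataFrame, centre,
                              lambda_grid=None, cv_folds: int = 10, seed: int = 0,
                              max_iter: int = 100, tol: float = 1e-6,
                              marker_name: str = "marker") -> SurrogateModel:
    """Random-intercept LASSO: L1-penalised fixed effects with a centre
    random intercept, fit by alternating variance-component (profiled ML) updates and
    coordinate-descent L1 steps on whitened data.

    Convergence is declared when the relative change of the penalised
    whitened objective falls below ``tol``; the random intercepts are not
    part of the prediction rule.  Raises on non-convergence.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    codes, levels = _centre_codes(centre)
    if len(levels) < 2:
        raise ValueError("mixed-effect LASSO needs at least 2 centres")
    if n < cv_folds:
        raise ValueError("need at least cv_folds samples")
    X_arr = X.to_numpy(dtype=float)
    C = _covariate_design(covars)
    G = len(levels)

    coef0, *_ = np.linalg.lstsq(C, y, rcond=None)
    s2b, s2e = _ml_random_intercept(y - C @ coef0, codes, G)

    lam = None
    grid = None if lambda_grid is None else np.sort(np.asarray(lambda_grid, float))[::-1]
    w_orig = np.zeros(X_arr.shape[1])
    objective = []
    for _ in range(max_iter):
        yw = _whiten_rows(y, codes, G, s2b, s2e)
        Cw = _whiten_rows(C, codes, G, s2b, s2e)
        Xw = _whiten_rows(X_arr, codes, G, s2b, s2e)
        ytil, Xtil = _partial_out(yw, Xw, Cw)
        Xs, sd, ok = _standardise_columns(Xtil)
        if lam is None:
            if grid is None:
                grid = _default_lambda_grid(np.max(np.abs(Xs.T @ ytil)) / n)
            if len(grid) == 1:
                lam = float(grid[0])
            else:
                best, _ = _cv_lambda(Xs, ytil, grid, cv_folds, seed)
                lam = float(grid[best])
        w_std = _lasso_solve(Xs, ytil, lam)
        w_orig = np.zeros(X_arr.shape[1])
        w_orig[ok] = w_std[ok] / sd[ok]
        # GLS covariate terms on whitened data
        cw, *_ = np.linalg.lstsq(Cw, yw - Xw @ w_orig, rcond=None)
        r_w = ytil - Xs @ w_std
        obj = float(r_w @ r_w) / (2 * n) + lam * float(np.sum(np.abs(w_std)))
        objective.append(obj)
        if len(objective) > 1 and abs(objective[-2] - obj) <= tol * max(abs(objective[-2]), 1e-12):
            break
        # variance components from original-scale residuals
        r = y - X_arr @ w_orig - C @ cw
        s2b, s2e = _ml_random_intercept(r, codes, G)
    else:
        raise RuntimeError(
            "mixed-effect LASSO did not converge after "
            f"{max_iter} iterations; objective tail {objective[-3:]}, "
            f"sigma2_between={s2b:.3e}, sigma2_within={s2e:.3e}")

    # GLS covariate estimates (consistent under centre correlation)
    intercept, covw = float(cw[0]), {"age": float(cw[1]), "sex": float(cw[2])}
    return SurrogateModel(marker_name=marker_name, model_type="mixed_lasso",
                          intercept=intercept,
                          probe_weights=pd.Series(w_orig, index=X.columns),
                          covariate_weights=covw, lambda_selected=lam,
                          sigma2_between=s2b, sigma2_within=s2e,
                          n_train=n, seed=seed, objective_path=objective)


# ---------------------------------------------------------------------------
# Full three-step training and validation


@dataclass
class TrainConfig:
    top_fraction: float = 0.01
    anova_p_threshold: float = 0.05
    cv_folds: int = 10
    lambda_grid: object = None
    seed: int = 0


def train_surrogate(marker_name: str, bm: BetaMatrix, pheno: pd.DataFrame,
                    config: TrainConfig | None = None) -> SurrogateModel:
    """Run the three-step surrogate construction for one marker.

    The marker column must be strictly positive (it is log-transformed); the
    mixed route is taken when the centre ANOVA p-value is below the configured
    threshold and a centre column is available.
    """
    config = config or TrainConfig()
    marker = pheno[marker_name].to_numpy(dtype=float)
    if np.any(marker <= 0) or np.any(~np.isfinite(marker)):
        raise ValueError(f"marker {marker_name!r} must be strictly positive and finite")
    y = np.log(marker)

    anova_f = anova_p = None
    centre = None
    if "centre" in pheno.columns and pheno["centre"].nunique() > 1:
        anova_f, anova_p = centre_anova(y, pheno["centre"])
        if anova_p < config.anova_p_threshold:
            centre = pheno["centre"]
    ewas = ewas_rank(bm, y, pheno, centre=centre, top_fraction=config.top_fraction)
    X = bm.data[ewas.top_probes]
    if centre is not None:
        model = fit_mixed_lasso_surrogate(y, X, pheno, centre,
                                          lambda_grid=config.lambda_grid,
                                          cv_folds=config.cv_folds, seed=config.seed,
                                          marker_name=marker_name)
    else:
        model = fit_lasso_surrogate(y, X, pheno, lambda_grid=config.lambda_grid,
                                    cv_folds=config.cv_folds, seed=config.seed,
                                    marker_name=marker_name)
    model.anova_f, model.anova_p = anova_f, anova_p
    logger.info("trained surrogate %s: route=%s, nonzero probes=%d",
                marker_name, model.model_type, model.n_probes_nonzero)
    return model


def validate_surrogate(model: SurrogateModel, bm_test: BetaMatrix,
                       pheno_test: pd.DataFrame) -> tuple[float, float, int]:
    """Pearson correlation of predicted surrogate vs observed log marker."""
    from .scoring import compute_surrogate

    pred = compute_surrogate(bm_test, pheno_test, model.to_weight_table())
    obs = np.log(pheno_test[model.marker_name].to_numpy(dtype=float))
    n = len(obs)
    if n < 3:
        raise ValueError("need at least 3 test samples")
    r, p = stats.pearsonr(pred.to_numpy(), obs)
    return float(r), float(p), n


def meta_analyse_correlations(studies, method: str = "fixed") -> tuple[float, float]:
    """Pool per-study Pearson correlations via Fisher's z transform.

    ``studies`` is a list of (r, n).  Fixed-effect pooling uses inverse
    variance weights (n - 3); ``method='random'`` applies the
    DerSimonian-Laird between-study variance.
    """
    rs = np.array([s[0] for s in studies], dtype=float)
    ns = np.array([s[1] for s in studies], dtype=float)
    if np.any(ns < 4):
        raise ValueError("each study needs n >= 4")
    if np.any(np.abs(rs) >= 1.0):
        raise ValueError("|r| = 1 has infinite Fisher z")
    z = np.arctanh(rs)
    w = ns - 3.0
    if method == "random" and len(rs) > 1:
        zbar_f = np.sum(w * z) / np.sum(w)
        q = float(np.sum(w * (z - zbar_f) ** 2))
        c = float(np.sum(w) - np.sum(w ** 2) / np.sum(w))
        tau2 = max(0.0, (q - (len(rs) - 1)) / c) if c > 0 else 0.0
        w = 1.0 / (1.0 / w + tau2)
    elif method not in ("fixed", "random"):
        raise ValueError(f"unknown meta-analysis method: {method}")
    zbar = float(np.sum(w * z) / np.sum(w))
    se = 1.0 / np.sqrt(np.sum(w))
    p = 2.0 * stats.norm.sf(abs(zbar) / se)
    return float(np.tanh(zbar)), float(p)


# ---------------------------------------------------------------------------
# Model/Results presentation


class SurrogateRegression:
    """Three-step surrogate model builder for one risk factor.

    Parameters mirror :func:`train_surrogate`; ``fit`` returns a
    :class:`SurrogateResults` carrying the weights and diagnostics.
    """

    def __init__(self, marker_name: str, beta: BetaMatrix, pheno: pd.DataFrame,
                 top_fraction: float = 0.01, anova_p_threshold: float = 0.05,
                 cv_folds: int = 10, seed: int = 0):
        self.marker_name = marker_name
        self.beta = beta
        self.pheno = pheno
        self.config = TrainConfig(top_fraction=top_fraction,
                                  anova_p_threshold=anova_p_threshold,
                                  cv_folds=cv_folds, seed=seed)

    def fit(self) -> "SurrogateResults":
        model = train_surrogate(self.marker_name, self.beta, self.pheno, self.config)
        return SurrogateResults(self, model)


class SurrogateResults:
    def __init__(self, model_spec: SurrogateRegression, model: SurrogateModel):
        self.model_spec = model_spec
        self.model = model

    def predict(self, bm: BetaMatrix, pheno: pd.DataFrame) -> pd.Series:
        from .scoring import compute_surrogate
        return compute_surrogate(bm, pheno, self.model.to_weight_table())

    def validate(self, bm: BetaMatrix, pheno: pd.DataFrame):
        return validate_surrogate(self.model, bm, pheno)

    def summary(self) -> str:
        m = self.model
        lines = [
            f"Surrogate regression results: {m.marker_name}",
            "=" * 46,
            f"model type          {m.model_type}",
            f"n (training)        {m.n_train}",
            f"lambda selected     {m.lambda_selected:.6g}",
            f"nonzero CpG weights {m.n_probes_nonzero}",
            f"intercept           {m.intercept:.4f}",
            f"age weight          {m.covariate_weights.get('age', 0.0):.6f}",
            f"sex weight          {m.covariate_weights.get('sex', 0.0):.6f}",
        ]
        if m.anova_p is not None:
            lines.append(f"centre ANOVA        F={m.anova_f:.3f}, p={m.anova_p:.3g}")
        if m.sigma2_between is not None:
            lines.append(f"sigma2 between      {m.sigma2_between:.6g}")
            lines.append(f"sigma2 within       {m.sigma2_within:.6g}")
        return "\n".join(lines)
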