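"""Apply surrogate weight tables to a cohort and build the candidate feature
matrix for the composite score.

A panel mixes newly trained surrogates, literature weight tables (published
CpG panels for proteins, clocks, cell proportions, ...) and precomputed
feature columns (e.g. an externally computed clock output).  Standardisation
is within the population being scored by default; training-set statistics can
be frozen and re-applied for deployment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import BetaMatrix, WeightTable, sex_to_numeric

logger = logging.getLogger("dnamcvd.scoring")


@dataclass
class SurrogatePanel:
    """Ordered collection of weight tables and precomputed feature columns."""

    weight_tables: list[WeightTable] = field(default_factory=list)
    precomputed: dict[str, pd.Series] = field(default_factory=dict)
    order: list[str] | None = None  # feature order; defaults to tables then precomputed

    def feature_names(self) -> list[str]:
        names = [wt.marker_name for wt in self.weight_tables] + list(self.precomputed)
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in panel")
        if self.order is not None:
            if set(self.order) != set(names):
                raise ValueError("panel order must list exactly the panel features")
            return list(self.order)
        return names

    @property
    def size(self) -> int:
        return len(self.feature_names())


@dataclass
class SurrogateMatrix:
    """Samples x surrogate-feature values with standardisation state."""

    values: pd.DataFrame
    standardized: bool = False
    feature_means: pd.Series | None = None
    feature_sds: pd.Series | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)


def compute_surrogate(bm: BetaMatrix, pheno: pd.DataFrame, wt: WeightTable,
                      missing_probe_policy: str = "lenient",
                      max_missing_fraction: float = 0.2) -> pd.Series:
    """Evaluate one weight table on a cohort.

    ``value_i = intercept + sum_j w_j beta_ij + age/sex terms``.  Probes in
    the table but absent from the matrix contribute 0 under the lenient
    policy (warned, and an error if more than ``max_missing_fraction`` of the
    weighted probes are absent); the strict policy errors on any absence.
    """
    if missing_probe_policy not in ("lenient", "strict"):
        raise ValueError(f"unknown missing-probe policy: {missing_probe_policy}")
    if bm.n_missing:
        raise ValueError("beta matrix must be imputed before scoring")
    present = wt.probe_weights.index.intersection(bm.data.columns)
    n_absent = len(wt.probe_weights) - len(present)
    if n_absent:
        if missing_probe_policy == "strict":
            raise ValueError(
                f"{n_absent} weighted probes absent from the beta matrix (strict policy)")
        frac = n_absent / len(wt.probe_weights)
        if frac > max_missing_fraction:
            raise ValueError(
                f"{frac:.1%} of weighted probes absent exceeds the "
                f"{max_missing_fraction:.0%} lenient-policy limit")
        warnings.warn(f"{n_absent} weighted probes absent; contributing 0")
    vals = np.full(len(bm.sample_ids), wt.intercept, dtype=float)
    if len(present):
        vals = vals + bm.data[present].to_numpy() @ wt.probe_weights[present].to_numpy()
    if "age" in wt.covariate_weights:
        vals = vals + wt.covariate_weights["age"] * pheno["age"].to_numpy(dtype=float)
    if "sex" in wt.covariate_weights:
        vals = vals + wt.covariate_weights["sex"] * sex_to_numeric(pheno["sex"])
    return pd.Series(vals, index=bm.sample_ids, name=wt.marker_name)


def assemble_panel(bm: BetaMatrix, pheno: pd.DataFrame,
                   panel: SurrogatePanel, **score_kwargs) -> SurrogateMatrix:
    """Score every panel entry; column order follows the panel order."""
    names = panel.feature_names()
    cols: dict[str, pd.Series] = {}
    for wt in panel.weight_tables:
        cols[wt.marker_name] = compute_surrogate(bm, pheno, wt, **score_kwargs)
    for name, series in panel.precomputed.items():
        s = pd.Series(series).reindex(bm.sample_ids)
        if s.isna().any():
            raise ValueError(f"precomputed column {name!r} missing samples")
        cols[name] = s
    df = pd.DataFrame({n: cols[n] for n in names}, index=bm.sample_ids)
    return SurrogateMatrix(values=df, standardized=False)


def standardise(sm: SurrogateMatrix, stats: tuple[pd.Series, pd.Series] | None = None
                ) -> SurrogateMatrix:
    """Centre/scale each feature to mean 0, sd 1 (denominator n - 1).

    By default statistics come from the population being scored; pass
    ``stats=(means, sds)`` to re-apply frozen training-set statistics.
    """
    if stats is None:
        means = sm.values.mean(axis=0)
        sds = sm.values.std(axis=0, ddof=1)
        const = sds[sds <= 0]
        if len(const):
            raise ValueError(f"constant feature cannot be standardised: {const.index[0]!r}")
    else:
        means, sds = (pd.Series(s) for s in stats)
        if (sds <= 0).any():
            raise ValueError("frozen sds must be positive")
    z = (sm.values - means) / sds
    return SurrogateMatrix(values=z, standardized=True,
                           feature_means=means, feature_sds=sds)
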