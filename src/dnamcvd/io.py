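"""Tabular I/O and probe-level quality control for blood methylation data.

Methylation is handled as beta values: per-CpG fractions of methylated over
total signal intensity, bounded in [0, 1].  On disk a beta matrix follows the
series-matrix convention (probes as rows, samples as columns); in memory the
canonical orientation is samples x probes.  Missing calls (e.g. masked by a
detection p-value filter) are NaN.

Phenotype tables are plain pandas DataFrames with a ``sample_id`` column and
the covariates used throughout the pipeline (age in years, sex coded
female/male, recruitment centre, biomarkers on their original measurement
scale, follow-up time in years and a 0/1 event indicator).  Sex is coded
numerically as 0 = female, 1 = male wherever a model needs a number; this
coding is part of the weight-table contract and must not change, otherwise
published weight tables stop being portable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("dnamcvd.io")

SEX_LEVELS = ("female", "male")
TRANSFORMS = ("identity", "log")
COVARIATE_TERMS = ("age", "sex")


def sex_to_numeric(sex) -> np.ndarray:
    """Map female/male labels to the fixed 0/1 coding (0 = female, 1 = male)."""
    s = pd.Series(sex)
    if s.dtype.kind in "ifb":
        vals = s.to_numpy(dtype=float)
        bad = ~np.isin(vals[~np.isnan(vals)], (0.0, 1.0))
        if bad.any():
            raise ValueError("numeric sex values must be 0 (female) or 1 (male)")
        return vals
    unknown = set(s.dropna().unique()) - set(SEX_LEVELS)
    if unknown:
        raise ValueError(f"unknown sex labels: {sorted(unknown)}")
    return s.map({"female": 0.0, "male": 1.0}).to_numpy(dtype=float)


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


@dataclass
class BetaMatrix:
    """Samples x probes methylation beta values with NaN as the missing marker."""

    data: pd.DataFrame

    def __post_init__(self):
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups[:5]}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probe identifiers: {dups[:5]}")
        try:
            self.data = self.data.astype(float)
        except (TypeError, ValueError):
            cell = self._first_non_numeric()
            raise ValueError(f"non-numeric beta value at sample {cell[0]!r}, probe {cell[1]!r}")
        vals = self.data.to_numpy()
        with np.errstate(invalid="ignore"):
            bad = (vals < 0.0) | (vals > 1.0)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ValueError(
                "beta value out of [0, 1] at sample "
                f"{self.data.index[i]!r}, probe {self.data.columns[j]!r}: {vals[i, j]}"
            )

    def _first_non_numeric(self):
        for j, col in enumerate(self.data.columns):
            coerced = pd.to_numeric(self.data.iloc[:, j], errors="coerce")
            bad = coerced.isna() & self.data.iloc[:, j].notna()
            if bad.any():
                return self.data.index[bad.to_numpy().argmax()], col
        return self.data.index[0], self.data.columns[0]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())


def read_beta_matrix(path, orientation: str = "probes_by_samples",
                     clamp: bool = False, sep: str | None = None) -> BetaMatrix:
    """Read a delimited beta matrix into the canonical samples x probes layout.

    ``orientation`` describes the file on disk.  With ``clamp=True`` values are
    clipped into [0, 1] (useful for normalisation overshoot); otherwise any
    out-of-range value raises, naming the offending cell.
    """
    if orientation not in ("probes_by_samples", "samples_by_probes"):
        raise ValueError(f"unknown orientation: {orientation}")
    df = pd.read_csv(path, sep=sep or _sep_for(path), index_col=0)
    if df.empty:
        raise ValueError(f"empty beta matrix file: {path}")
    if orientation == "probes_by_samples":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if clamp:
        df = df.apply(pd.to_numeric).clip(0.0, 1.0)
    return BetaMatrix(df)


def write_beta_matrix(bm: BetaMatrix, path, orientation: str = "probes_by_samples",
                      sep: str | None = None) -> None:
    if orientation not in ("probes_by_samples", "samples_by_probes"):
        raise ValueError(f"unknown orientation: {orientation}")
    out = bm.data.T if orientation == "probes_by_samples" else bm.data
    out.to_csv(path, sep=sep or _sep_for(path))


def read_matrix(path, orientation: str = "probes_by_samples", sep: str | None = None) -> pd.DataFrame:
    """Read an auxiliary numeric matrix (e.g. detection p-values) as samples x probes."""
    df = pd.read_csv(path, sep=sep or _sep_for(path), index_col=0)
    if orientation == "probes_by_samples":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df.astype(float)


def apply_probe_exclusions(bm: BetaMatrix, exclusion_ids: Iterable[str]) -> BetaMatrix:
    """Drop probes on an exclusion list (cross-reactive / polymorphic CpGs).

    Ids absent from the matrix are ignored with a warning; the order of
    surviving probes is preserved.
    """
    excl = set(exclusion_ids)
    absent = excl - set(bm.probe_ids)
    if absent:
        logger.warning("%d exclusion ids not present in the beta matrix", len(absent))
    keep = [p for p in bm.probe_ids if p not in excl]
    return BetaMatrix(bm.data[keep].copy())


def mask_by_detection_p(bm: BetaMatrix, detp, threshold: float = 0.01) -> BetaMatrix:
    """Set beta values with detection p-value above ``threshold`` to missing."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    if isinstance(detp, pd.DataFrame):
        if detp.shape != bm.shape:
            raise ValueError(f"detection-p shape {detp.shape} != beta shape {bm.shape}")
        detp = detp.reindex(index=bm.data.index, columns=bm.data.columns)
        if detp.isna().all(axis=None) and bm.shape != (0, 0):
            raise ValueError("detection-p labels do not match the beta matrix")
        dvals = detp.to_numpy(dtype=float)
    else:
        dvals = np.asarray(detp, dtype=float)
        if dvals.shape != bm.shape:
            raise ValueError(f"detection-p shape {dvals.shape} != beta shape {bm.shape}")
    masked = bm.data.mask(dvals > threshold)
    return BetaMatrix(masked)


def impute_missing(bm: BetaMatrix, method: str = "probe_mean") -> BetaMatrix:
    """Replace missing beta values by the per-probe mean of observed values."""
    if method != "probe_mean":
        raise ValueError(f"unknown imputation method: {method}")
    if bm.n_missing == 0:
        return BetaMatrix(bm.data.copy())
    fully_missing = bm.data.columns[bm.data.isna().all(axis=0)]
    if len(fully_missing):
        raise ValueError(f"probe with no observed values: {fully_missing[0]!r}")
    return BetaMatrix(bm.data.fillna(bm.data.mean(axis=0)))


# ---------------------------------------------------------------------------
# Phenotype tables


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    if "sample_id" not in df.columns:
        raise ValueError("phenotype table requires a 'sample_id' column")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in phenotype table")
    if "event" in df.columns:
        ev = df["event"].dropna()
        if not ev.isin((0, 1)).all():
            raise ValueError("event must be 0/1")
    if "follow_up_time" in df.columns:
        ft = df["follow_up_time"].dropna()
        if (ft <= 0).any():
            raise ValueError("follow_up_time must be positive")
    if "sex" in df.columns:
        sex_to_numeric(df["sex"])
    return df


def read_phenotypes(path, sep: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep or _sep_for(path))
    df["sample_id"] = df["sample_id"].astype(str)
    return validate_phenotypes(df)


def write_phenotypes(df: pd.DataFrame, path, sep: str | None = None) -> None:
    validate_phenotypes(df).to_csv(path, sep=sep or _sep_for(path), index=False)


# ---------------------------------------------------------------------------
# Weight tables


@dataclass
class WeightTable:
    """Sparse linear predictor of one risk factor from CpG betas plus age/sex.

    The predicted value for a sample is
    ``intercept + sum_j w_j * beta_j + age_w * age + sex_w * sex`` on the
    ``transform`` scale of the marker (log for strictly positive biomarkers).
    """

    marker_name: str
    intercept: float
    probe_weights: pd.Series
    covariate_weights: Mapping[str, float] = field(default_factory=dict)
    transform: str = "log"
    provenance: str = ""

    def __post_init__(self):
        self.probe_weights = pd.Series(self.probe_weights, dtype=float)
        if len(self.probe_weights) == 0:
            raise ValueError("probe_weights must be non-empty")
        if self.probe_weights.index.duplicated().any():
            dup = self.probe_weights.index[self.probe_weights.index.duplicated()][0]
            raise ValueError(f"duplicate probe id in weight table: {dup!r}")
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform: {self.transform}")
        bad = set(self.covariate_weights) - set(COVARIATE_TERMS)
        if bad:
            raise ValueError(f"unknown covariate terms: {sorted(bad)}")
        self.covariate_weights = dict(self.covariate_weights)
        self.intercept = float(self.intercept)


def write_weight_table(wt: WeightTable, path, sep: str | None = None) -> None:
    rows = [{"term": "(Intercept)", "term_type": "intercept", "weight": wt.intercept}]
    rows += [{"term": k, "term_type": "covariate", "weight": float(v)}
             for k, v in wt.covariate_weights.items()]
    rows += [{"term": p, "term_type": "probe", "weight": float(w)}
             for p, w in wt.probe_weights.items()]
    df = pd.DataFrame(rows)
    df.insert(0, "marker_name", wt.marker_name)
    df["transform"] = wt.transform
    df["provenance"] = wt.provenance
    df.to_csv(path, sep=sep or _sep_for(path), index=False)


def read_weight_table(path, sep: str | None = None) -> WeightTable:
    df = pd.read_csv(path, sep=sep or _sep_for(path), keep_default_na=False,
                     na_values=[""], dtype={"provenance": str})
    required = {"marker_name", "term", "term_type", "weight"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"weight table missing columns: {sorted(missing)}")
    probes = df[df["term_type"] == "probe"]
    if probes["term"].duplicated().any():
        dup = probes["term"][probes["term"].duplicated()].iloc[0]
        raise ValueError(f"duplicate probe row in weight table: {dup!r}")
    inter = df[df["term_type"] == "intercept"]["weight"]
    covs = df[df["term_type"] == "covariate"]
    prov = df["provenance"].iloc[0] if "provenance" in df.columns else ""
    return WeightTable(
        marker_name=str(df["marker_name"].iloc[0]),
        intercept=float(inter.iloc[0]) if len(inter) else 0.0,
        probe_weights=pd.Series(probes["weight"].to_numpy(dtype=float),
                                index=probes["term"].astype(str)),
        covariate_weights={str(t): float(w) for t, w in zip(covs["term"], covs["weight"])},
        transform=str(df["transform"].iloc[0]) if "transform" in df.columns else "log",
        provenance="" if pd.isna(prov) else str(prov),
    )
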