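"""Covariate adjustment of phenotypes and reference-based SD scores.

Raw densitometry values are regressed on age, sex and BMI before entering
the pair likelihood; T-scores (already standardized to a young-adult
reference) are adjusted for age and BMI only, and Z-scores (age- and
sex-matched reference) for BMI only.  Adjustment is ordinary least
squares on all individuals pooled; the residuals are the adjusted
phenotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_io import CohortTable
from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

#: Default covariate sets per phenotype kind.
DEFAULT_COVARIATES: dict[str, tuple[str, ...]] = {
    "raw_bmd": ("age", "sex", "bmi"),
    "t_score": ("age", "bmi"),
    "z_score": ("bmi",),
}

# Sex enters the design as an indicator: F -> 0, M -> 1.
_SEX_CODE = {"F": 0.0, "M": 1.0}


@dataclass(frozen=True)
class AdjustmentSpec:
    """Which covariates to regress out of a phenotype."""

    phenotype_kind: str
    covariates: tuple[str, ...]


@dataclass(frozen=True)
class ReferenceCurve:
    """Stratified reference means/SDs for computing T- or Z-style scores.

    ``strata`` maps (sex, age_low, age_high) to (mean, sd); an age band
    covers ``age_low <= age < age_high``.
    """

    strata: tuple[tuple[str, float, float, float, float], ...]

    def lookup(self, sex: str, age: float) -> tuple[float, float]:
        for s, lo, hi, mean, sd in self.strata:
            if s == sex and lo <= age < hi:
                if sd <= 0:
                    raise DataError(f"reference stratum ({s}, {lo}-{hi}) has sd <= 0")
                return mean, sd
        raise DataError(f"no reference stratum for sex={sex!r}, age={age}")

    @classmethod
    def from_csv(cls, path) -> "ReferenceCurve":
        df = pd.read_csv(path)
        need = {"sex", "age_low", "age_high", "mean", "sd"}
        if not need.issubset(df.columns):
            raise DataError(f"reference curve CSV must have columns {sorted(need)}")
        strata = tuple(
            (str(r.sex), float(r.age_low), float(r.age_high), float(r.mean), float(r.sd))
            for r in df.itertuples()
        )
        return cls(strata)


def default_adjustment(phenotype_kind: str) -> AdjustmentSpec:
    """The standard covariate set for a phenotype kind.

    ``raw_bmd`` -> age, sex, BMI; ``t_score`` -> age, BMI;
    ``z_score`` -> BMI.
    """
    if phenotype_kind not in DEFAULT_COVARIATES:
        raise ConfigError(
            f"unknown phenotype kind {phenotype_kind!r}; "
            f"expected one of {sorted(DEFAULT_COVARIATES)} or use a custom spec"
        )
    return AdjustmentSpec(phenotype_kind, DEFAULT_COVARIATES[phenotype_kind])


def infer_phenotype_kind(name: str) -> str:
    """Guess the phenotype kind from a column name suffix.

    ``*_t`` / ``*_t_score`` -> t_score, ``*_z`` / ``*_z_score`` -> z_score,
    anything else -> raw_bmd.
    """
    low = name.lower()
    if low.endswith(("_t", "_t_score", "_tscore")):
        return "t_score"
    if low.endswith(("_z", "_z_score", "_zscore")):
        return "z_score"
    return "raw_bmd"


def _design_matrix(
    df: pd.DataFrame, covariates: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    """Intercept + covariate columns, dropping degenerate (constant) ones."""
    cols: list[np.ndarray] = [np.ones(len(df))]
    kept: list[str] = []
    for cov in covariates:
        if cov == "sex":
            x = df["sex"].map(_SEX_CODE).to_numpy(dtype=float)
        else:
            if cov not in df.columns:
                raise DataError(f"covariate {cov!r} not present in cohort")
            x = df[cov].to_numpy(dtype=float)
        if not np.all(np.isfinite(x)):
            raise DataError(f"covariate {cov!r} has missing or non-finite values")
        if np.ptp(x) == 0:
            logger.warning("covariate %r is constant in this subset; dropped", cov)
            continue
        cols.append(x)
        kept.append(cov)
    return np.column_stack(cols), kept


def residualize(
    cohort: CohortTable,
    phenotype: str,
    spec: AdjustmentSpec,
) -> pd.Series:
    """OLS residuals of a phenotype on the spec's covariates, pooled.

    Returns a series aligned with ``cohort.data``; its mean is zero to
    numerical tolerance.  Constant covariates (e.g. sex in a female-only
    subset) are dropped with a logged warning rather than producing a
    rank-deficient design.
    """
    if phenotype not in cohort.data.columns:
        raise DataError(f"phenotype {phenotype!r} not present in cohort")
    y = cohort.data[phenotype].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise DataError(f"phenotype {phenotype!r} has missing or non-finite values")
    X, kept = _design_matrix(cohort.data, spec.covariates)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    logger.debug(
        "residualize %s on %s: kept covariates %s, residual sd %.4g",
        phenotype, spec.covariates, kept, resid.std(),
    )
    return pd.Series(resid, index=cohort.data.index, name=phenotype)


def score_from_reference(
    value: float, curve: ReferenceCurve, sex: str, age: float
) -> float:
    """SD score of a measurement against a stratified reference: (x - mean)/sd."""
    mean, sd = curve.lookup(sex, age)
    return (value - mean) / sd
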