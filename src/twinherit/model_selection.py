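"""Nested-model comparison and parsimony selection.

Submodels (AE, CE, E; ADE on request) are compared to the full model by a
likelihood-ratio chi-square test, and the most parsimonious model is the
one with the smallest AIC.  Plain chi-square p-values are the default; a
boundary-corrected 50:50 chi-square mixture (appropriate when a variance
component sits on the zero boundary under the null) is available as an
option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .errors import DataError, FitError
from .variance_components import MODEL_COMPONENTS, ModelFit

logger = logging.getLogger(__name__)

_SLACK = 1e-6

#: Tie-break order: fewer parameters first is handled separately; among
#: equal-k models the genetic model is preferred over the environmental one.
_PREFERENCE = ("AE", "CE", "ADE", "ACE", "E")


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio test of a nested model against a fuller one."""

    statistic: float
    df: int
    p_value: float


def lrt(full: ModelFit, nested: ModelFit, *, boundary_mixture: bool = False) -> LRTResult:
    """Chi-square likelihood-ratio test: nested deviance minus full deviance.

    ``boundary_mixture=True`` uses the 0.5*chi2(df-1) + 0.5*chi2(df) mixture
    for a variance component tested on its boundary.
    """
    if nested.k >= full.k:
        raise DataError(f"nested model must have fewer parameters ({nested.k} >= {full.k})")
    stat = nested.minus2LL - full.minus2LL
    if stat < -_SLACK:
        raise FitError(
            f"nested {nested.model} fit beat full {full.model} fit by {-stat:.3g}; "
            "optimizer inconsistency"
        )
    stat = max(stat, 0.0)
    df = full.k - nested.k
    if boundary_mixture:
        p_hi = stats.chi2.sf(stat, df)
        p_lo = stats.chi2.sf(stat, df - 1) if df > 1 else float(stat <= 0)
        p = 0.5 * (p_lo + p_hi)
    else:
        p = float(stats.chi2.sf(stat, df))
    return LRTResult(float(stat), int(df), float(p))


def aic(fit: ModelFit) -> float:
    """Akaike information criterion: deviance + 2 * parameter count."""
    if not fit.converged:
        raise FitError(f"AIC of a non-converged {fit.model} fit is not meaningful")
    return fit.minus2LL + 2.0 * fit.k


def select_parsimonious(
    fits: Mapping[str, ModelFit] | Iterable[ModelFit],
    *,
    full_model: str | None = None,
    boundary_mixture: bool = False,
) -> tuple[ModelFit, pd.DataFrame]:
    """Pick the most parsimonious adequate model by AIC.

    Returns the chosen fit and a comparison table with each model's
    deviance, k, AIC and its LRT against the fullest model.  Ties in AIC
    go to the model with fewer parameters, then to the genetic model (AE
    over CE).  Non-converged fits are excluded with a warning.
    """
    if not isinstance(fits, Mapping):
        fits = {f.model: f for f in fits}
    usable: dict[str, ModelFit] = {}
    for name, f in fits.items():
        if f.converged:
            usable[name] = f
        else:
            logger.warning("excluding non-converged %s fit from selection", name)
    if not usable:
        raise FitError("no converged fits to select from")

    if full_model is None:
        full_model = max(usable, key=lambda m: usable[m].k)
    full = usable[full_model]

    rows = []
    for name, f in usable.items():
        if f is full:
            test = LRTResult(0.0, 0, 1.0)
        elif f.k < full.k:
            test = lrt(full, f, boundary_mixture=boundary_mixture)
        else:  # same dimension (e.g. ADE vs ACE): not nested, no LRT
            test = LRTResult(float("nan"), 0, float("nan"))
        rows.append(
            {
                "model": name,
                "minus2LL": f.minus2LL,
                "k": f.k,
                "AIC": aic(f),
                "lrt_stat": test.statistic,
                "lrt_df": test.df,
                "p_vs_full": test.p_value,
            }
        )
    table = pd.DataFrame(rows).set_index("model")

    def rank(name: str) -> tuple:
        f = usable[name]
        pref = _PREFERENCE.index(name) if name in _PREFERENCE else len(_PREFERENCE)
        return (round(aic(f), 9), f.k, pref)

    chosen_name = min(usable, key=rank)
    return usable[chosen_name], table
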