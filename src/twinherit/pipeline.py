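"""End-to-end study orchestration and report rendering.

For each phenotype: pick the covariate set from the phenotype kind,
residualize, form per-zygosity pairs, compute intrapair correlations, fit
the biometric models, select the most parsimonious one by AIC, and attach
profile-likelihood confidence intervals.  An optional subset filter (e.g.
females only) is applied before adjustment; covariates that become
constant in the subset are dropped automatically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .adjust import AdjustmentSpec, default_adjustment, infer_phenotype_kind, residualize
from .cohort_io import CohortTable
from .errors import ConfigError, DataError
from .model_selection import select_parsimonious
from .twin_correlations import intrapair_correlation
from .variance_components import (
    MODEL_COMPONENTS,
    SummaryStats,
    fit_model,
    profile_ci,
)

logger = logging.getLogger(__name__)

DEFAULT_MODELS = ("ACE", "AE", "CE", "E")


@dataclass(frozen=True)
class StudyConfig:
    """Settings for one full study run."""

    phenotypes: tuple[str, ...] | None = None
    kinds: Mapping[str, str] = field(default_factory=dict)
    models: tuple[str, ...] = DEFAULT_MODELS
    include_ade: bool = False
    subset: Mapping[str, str] | None = None
    ci_level: float = 0.95
    min_pairs: int = 4
    n_restarts: int = 5
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["kinds"] = dict(self.kinds)
        d["subset"] = dict(self.subset) if self.subset else None
        d["phenotypes"] = list(self.phenotypes) if self.phenotypes else None
        d["models"] = list(self.models)
        return d


@dataclass
class StudyReport:
    """Per-phenotype results plus run metadata; JSON-serializable."""

    rows: list[dict]
    metadata: dict

    def to_dict(self) -> dict:
        return {"rows": self.rows, "metadata": self.metadata}

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "StudyReport":
        return cls(rows=d["rows"], metadata=d["metadata"])

    @classmethod
    def from_json(cls, text: str) -> "StudyReport":
        return cls.from_dict(json.loads(text))


def _py(obj):
    """Recursively convert numpy scalars/arrays so json round-trips exactly."""
    if isinstance(obj, dict):
        return {k: _py(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_py(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def run_study(cohort: CohortTable, config: StudyConfig | None = None) -> StudyReport:
    """Run the full twin analysis on every configured phenotype."""
    config = config or StudyConfig()
    if cohort.n_individuals == 0:
        raise DataError("empty cohort")
    for m in config.models:
        if m not in MODEL_COMPONENTS:
            raise ConfigError(f"unknown model {m!r} in config")

    if config.subset:
        mask = pd.Series(True, index=cohort.data.index)
        for col, val in config.subset.items():
            if col not in cohort.data.columns:
                raise ConfigError(f"subset column {col!r} not in cohort")
            mask &= cohort.data[col].astype(str) == str(val)
        cohort = cohort.subset(mask)
        if cohort.n_individuals == 0:
            raise DataError(f"subset {dict(config.subset)} matched no complete pairs")

    phenotypes = list(config.phenotypes or cohort.phenotype_names)
    models = list(config.models)
    if config.include_ade and "ADE" not in models:
        models.append("ADE")

    rows: list[dict] = []
    for phen in phenotypes:
        try:
            rows.append(_analyze_phenotype(cohort, phen, models, config))
        except DataError as exc:
            logger.warning("phenotype %s failed: %s", phen, exc)
            rows.append({"phenotype": phen, "status": "insufficient-data", "reason": str(exc)})

    cfg = config.to_dict()
    meta = {
        "software": "twinherit",
        "version": _version(),
        "seed": config.seed,
        "subset": cfg["subset"],
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest()[:16],
        "n_individuals": int(cohort.n_individuals),
        "n_pairs": int(cohort.n_pairs),
    }
    return StudyReport(rows=_py(rows), metadata=_py(meta))


def _version() -> str:
    from . import __version__

    return __version__


def _analyze_phenotype(
    cohort: CohortTable, phen: str, models: Sequence[str], config: StudyConfig
) -> dict:
    kind = config.kinds.get(phen) or infer_phenotype_kind(phen)
    spec = default_adjustment(kind)
    adjusted = residualize(cohort, phen, spec)
    pairs = cohort.pairs(adjusted)
    arrays = {
        z: np.array([(p.value_1, p.value_2) for p in pairs[z]], dtype=float).reshape(-1, 2)
        for z in ("MZ", "DZ")
    }
    for z in ("MZ", "DZ"):
        if arrays[z].shape[0] < config.min_pairs:
            raise DataError(
                f"{phen}: only {arrays[z].shape[0]} {z} pairs (< {config.min_pairs})"
            )

    corr = {
        z: intrapair_correlation(arrays[z], z, level=config.ci_level)
        for z in ("MZ", "DZ")
    }
    stats_ = SummaryStats.from_pairs(arrays)

    fits = {
        m: fit_model(stats_, m, n_restarts=config.n_restarts, seed=config.seed)
        for m in models
    }
    full_model = "ACE" if "ACE" in fits else max(fits, key=lambda m: fits[m].k)
    chosen, table = select_parsimonious(fits, full_model=full_model)
    for comp in MODEL_COMPONENTS[chosen.model]:
        profile_ci(chosen, comp, level=config.ci_level)

    std = chosen.std_components
    return {
        "phenotype": phen,
        "status": "ok",
        "kind": kind,
        "covariates": list(spec.covariates),
        "n_mz_pairs": corr["MZ"].n_pairs,
        "n_dz_pairs": corr["DZ"].n_pairs,
        "r_mz": {"r": corr["MZ"].r, "ci": [corr["MZ"].ci_low, corr["MZ"].ci_high]},
        "r_dz": {"r": corr["DZ"].r, "ci": [corr["DZ"].ci_low, corr["DZ"].ci_high]},
        "selected_model": chosen.model,
        "components": std.as_dict(),
        "ci": {k: list(v) for k, v in chosen.ci.items()},
        "model_fit_p": float(table.loc[chosen.model, "p_vs_full"]),
        "comparison": table.reset_index().to_dict(orient="records"),
    }


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _fmt(x: float) -> str:
    """Three decimals with trailing zeros trimmed, matching report style."""
    s = f"{x:.3f}".rstrip("0").rstrip(".")
    return s if s not in ("", "-0") else "0"


def _cell(value: float, ci: Sequence[float] | None) -> str:
    if ci is None:
        return _fmt(value)
    return f"{_fmt(value)}({_fmt(ci[0])}, {_fmt(ci[1])})"


def render_report(report: StudyReport, fmt: str = "tsv", path=None) -> str:
    """Render a study report as TSV (one row per phenotype) or JSON.

    The TSV layout follows the conventional twin-study summary: measure,
    rMZ, rDZ, standardized A/C/D/E with 95% CIs in parentheses, and the
    model-fit p-value of the selected model against the full model.
    Components fixed at zero by the selected model render as ``0``.
    """
    if fmt == "json":
        text = report.to_json(indent=2)
    elif fmt == "tsv":
        lines = ["measure\tmodel\trMZ\trDZ\tA\tC\tD\tE\tmodel_fit_p"]
        for row in report.rows:
            if row.get("status") != "ok":
                lines.append(
                    f"{row['phenotype']}\t{row.get('status')}\t\t\t\t\t\t\t"
                )
                continue
            comps = row["components"]
            ci = row["ci"]
            cells = [
                row["phenotype"],
                row["selected_model"],
                _cell(row["r_mz"]["r"], row["r_mz"]["ci"]),
                _cell(row["r_dz"]["r"], row["r_dz"]["ci"]),
            ]
            for comp in ("a2", "c2", "d2", "e2"):
                if comps.get(comp, 0.0) == 0.0 and comp not in ci:
                    cells.append("0")
                else:
                    cells.append(_cell(comps[comp], ci.get(comp)))
            cells.append(_fmt(row["model_fit_p"]))
            lines.append("\t".join(cells))
        text = "\n".join(lines) + "\n"
    else:
        raise ConfigError(f"unknown report format {fmt!r}; use 'tsv' or 'json'")
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text
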