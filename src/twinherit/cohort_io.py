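"""Twin cohort tables: reading, validation, derived covariates, descriptives.

A cohort is one row per individual.  Twins are linked by ``pair_id`` and
distinguished by ``twin_index`` (1 or 2).  Zygosity and sex must agree
within a pair (the design uses same-sex pairs only).  Phenotypes are any
extra numeric columns, e.g. site-specific bone mineral density or the
derived T/Z scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

#: Columns every cohort table must provide (after schema mapping).
REQUIRED_COLUMNS = ("pair_id", "twin_index", "zygosity", "sex", "age")

#: Optional standard columns; anything else numeric is treated as a phenotype.
OPTIONAL_COLUMNS = ("height", "weight", "bmi", "smoking", "pack_years")

VALID_ZYGOSITY = frozenset({"MZ", "DZ"})
VALID_SEX = frozenset({"F", "M"})
VALID_SMOKING = frozenset({"never", "former", "active"})


@dataclass(frozen=True)
class TwinRecord:
    """One individual of a twin pair."""

    pair_id: str
    twin_index: int
    zygosity: str
    sex: str
    age: float
    height: float | None = None
    weight: float | None = None
    bmi: float | None = None
    smoking: str | None = None
    pack_years: float | None = None
    phenotypes: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class TwinPair:
    """A zygosity-labelled pair of (adjusted) phenotype values.

    This is the observational unit of the pair likelihood; both values
    must be finite.
    """

    pair_id: str
    zygosity: str
    value_1: float
    value_2: float


@dataclass
class CohortTable:
    """A validated cohort, stored as one pandas row per individual.

    ``data`` carries the standard columns plus one column per phenotype;
    ``phenotype_names`` lists which columns are phenotypes.
    """

    data: pd.DataFrame
    phenotype_names: list[str]

    @property
    def n_individuals(self) -> int:
        return len(self.data)

    @property
    def n_pairs(self) -> int:
        return self.data["pair_id"].nunique()

    def records(self) -> Iterator[TwinRecord]:
        for _, row in self.data.iterrows():
            phen = {p: float(row[p]) for p in self.phenotype_names}
            yield TwinRecord(
                pair_id=str(row["pair_id"]),
                twin_index=int(row["twin_index"]),
                zygosity=str(row["zygosity"]),
                sex=str(row["sex"]),
                age=float(row["age"]),
                height=_opt(row, "height"),
                weight=_opt(row, "weight"),
                bmi=_opt(row, "bmi"),
                smoking=row.get("smoking") if isinstance(row.get("smoking"), str) else None,
                pack_years=_opt(row, "pack_years"),
                phenotypes=phen,
            )

    def subset(self, mask: pd.Series, *, on_incomplete: str = "drop") -> "CohortTable":
        """Row-subset of the cohort; pairs broken by the filter are dropped.

        Filtering individuals (e.g. females only) can leave half-pairs,
        which a pairwise likelihood cannot use; they are removed with a
        logged count.
        """
        sub = self.data.loc[mask].copy()
        counts = sub.groupby("pair_id")["twin_index"].size()
        complete = counts[counts == 2].index
        dropped = int((counts != 2).sum())
        if dropped:
            logger.info("subset: dropped %d incomplete pair(s)", dropped)
            if on_incomplete == "error":
                raise DataError(f"subset produced {dropped} incomplete pair(s)")
        sub = sub[sub["pair_id"].isin(complete)].reset_index(drop=True)
        return CohortTable(sub, list(self.phenotype_names))

    def pairs(self, values: pd.Series) -> dict[str, list[TwinPair]]:
        """Arrange a per-individual value series into per-zygosity pairs.

        ``values`` must be indexed like ``self.data``.  Returns a dict
        mapping zygosity to a list of :class:`TwinPair`, ordered by
        twin_index within each pair.
        """
        out: dict[str, list[TwinPair]] = {"MZ": [], "DZ": []}
        df = self.data.assign(_value=values)
        for pair_id, grp in df.groupby("pair_id", sort=True):
            grp = grp.sort_values("twin_index")
            v = grp["_value"].to_numpy(dtype=float)
            if len(v) != 2:
                raise DataError(f"pair {pair_id!r} does not have exactly 2 rows")
            if not np.all(np.isfinite(v)):
                raise DataError(f"pair {pair_id!r} has non-finite phenotype values")
            zyg = str(grp["zygosity"].iloc[0])
            out[zyg].append(TwinPair(str(pair_id), zyg, float(v[0]), float(v[1])))
        return out


def _opt(row: pd.Series, col: str) -> float | None:
    val = row.get(col)
    if val is None or (isinstance(val, float) and np.isnan(val)):
        return None
    try:
        return float(val)
    except (TypeError, ValueError):
        return None


def compute_bmi(weight: float, height: float) -> float:
    """Body mass index, weight (kg) / height (m) squared."""
    if weight <= 0 or height <= 0:
        raise DataError(f"BMI requires positive weight and height, got ({weight}, {height})")
    return weight / height**2


def compute_pack_years(cigarettes_per_day: float, years_smoked: float) -> float:
    """Smoking exposure in pack-years: cigarettes/day times years, over 20."""
    if cigarettes_per_day < 0 or years_smoked < 0:
        raise DataError("pack-years inputs must be non-negative")
    return cigarettes_per_day * years_smoked / 20.0


def read_cohort(
    path,
    schema: Mapping[str, str] | None = None,
    *,
    phenotype_names: Sequence[str] | None = None,
    on_incomplete: str = "error",
) -> CohortTable:
    """Read a delimited cohort table and validate it.

    Parameters
    ----------
    path
        CSV file (comma separated, header row).
    schema
        Optional map from canonical column names (``pair_id`` etc.) to the
        file's column names, for registry exports with different headers.
    phenotype_names
        Explicit phenotype columns; by default every numeric non-standard
        column is a phenotype.
    on_incomplete
        ``"error"`` (strict, default) rejects pairs without exactly two
        rows; ``"drop"`` removes them with a logged count.
    """
    if on_incomplete not in ("error", "drop"):
        raise ConfigError(f"on_incomplete must be 'error' or 'drop', got {on_incomplete!r}")
    df = pd.read_csv(path)
    if schema:
        rename = {v: k for k, v in schema.items()}
        missing_src = [v for v in schema.values() if v not in df.columns]
        if missing_src:
            raise DataError(f"schema maps to missing column(s): {missing_src}")
        df = df.rename(columns=rename)
    return cohort_from_frame(df, phenotype_names=phenotype_names, on_incomplete=on_incomplete)


def cohort_from_frame(
    df: pd.DataFrame,
    *,
    phenotype_names: Sequence[str] | None = None,
    on_incomplete: str = "error",
) -> CohortTable:
    """Build and validate a :class:`CohortTable` from an in-memory frame."""
    df = df.copy()
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"missing required column(s): {missing}")

    df["pair_id"] = df["pair_id"].astype(str)
    df["zygosity"] = df["zygosity"].astype(str).str.upper()
    df["sex"] = df["sex"].astype(str).str.upper()
    try:
        df["twin_index"] = df["twin_index"].astype(int)
        df["age"] = df["age"].astype(float)
    except (TypeError, ValueError) as exc:
        raise DataError(f"could not parse twin_index/age as numeric: {exc}") from exc

    bad_zyg = set(df["zygosity"]) - VALID_ZYGOSITY
    if bad_zyg:
        raise DataError(f"invalid zygosity value(s): {sorted(bad_zyg)}")
    bad_sex = set(df["sex"]) - VALID_SEX
    if bad_sex:
        raise DataError(f"invalid sex value(s): {sorted(bad_sex)}")
    if not (df["twin_index"].isin((1, 2))).all():
        raise DataError("twin_index must be 1 or 2")
    if (df["age"] <= 0).any():
        raise DataError("age must be positive")

    # BMI: derive from height/weight when both are present and bmi is absent.
    if "bmi" not in df.columns:
        df["bmi"] = np.nan
    if "height" in df.columns and "weight" in df.columns:
        need = df["bmi"].isna() & df["height"].notna() & df["weight"].notna()
        if need.any():
            hw = df.loc[need]
            if (hw["height"] <= 0).any() or (hw["weight"] <= 0).any():
                raise DataError("height and weight must be positive to derive BMI")
            df.loc[need, "bmi"] = hw["weight"] / hw["height"] ** 2
    if (df["bmi"].dropna() <= 0).any():
        raise DataError("bmi must be positive when present")

    # Pair completeness and within-pair consistency.
    counts = df.groupby("pair_id")["twin_index"].agg(["size", "nunique"])
    bad = counts[(counts["size"] != 2) | (counts["nunique"] != 2)]
    if len(bad):
        if on_incomplete == "error":
            raise DataError(
                f"{len(bad)} pair(s) without exactly two distinct twins: "
                f"{sorted(bad.index)[:5]}"
            )
        logger.warning("dropping %d incomplete pair(s)", len(bad))
        df = df[~df["pair_id"].isin(bad.index)]
    for col in ("zygosity", "sex"):
        nuniq = df.groupby("pair_id")[col].nunique()
        inconsistent = nuniq[nuniq > 1]
        if len(inconsistent):
            raise DataError(
                f"{col} differs within pair(s): {sorted(inconsistent.index)[:5]}"
            )
    df = df.reset_index(drop=True)

    standard = set(REQUIRED_COLUMNS) | set(OPTIONAL_COLUMNS)
    if phenotype_names is None:
        phenotype_names = [
            c for c in df.columns
            if c not in standard and pd.api.types.is_numeric_dtype(df[c])
        ]
    else:
        missing_ph = [p for p in phenotype_names if p not in df.columns]
        if missing_ph:
            raise DataError(f"phenotype column(s) not found: {missing_ph}")
    for p in phenotype_names:
        try:
            df[p] = df[p].astype(float)
        except (TypeError, ValueError) as exc:
            bad_rows = df.index[pd.to_numeric(df[p], errors="coerce").isna()].tolist()
            raise DataError(
                f"non-numeric phenotype {p!r} at row(s) {bad_rows[:5]}"
            ) from exc
    return CohortTable(df, list(phenotype_names))


def write_cohort(cohort: CohortTable, path) -> None:
    """Write the cohort as CSV (UTF-8, comma separated, header row)."""
    cohort.data.to_csv(path, index=False)


def descriptive_stats(
    cohort: CohortTable, variables: Sequence[str] | None = None
) -> pd.DataFrame:
    """Mean and SD per group (total / MZ / DZ) with MZ-vs-DZ Welch t-tests.

    One row per variable with columns ``total_mean``, ``total_sd``,
    ``mz_mean``, ``mz_sd``, ``dz_mean``, ``dz_sd``, ``t``, ``p`` and a
    ``significant`` flag at p < 0.05.  Zero-variance variables get NaN
    test statistics rather than raising.
    """
    df = cohort.data
    if variables is None:
        variables = ["age", "bmi"] + list(cohort.phenotype_names)
        variables = [v for v in variables if v in df.columns]
    mz = df[df["zygosity"] == "MZ"]
    dz = df[df["zygosity"] == "DZ"]
    if len(mz) < 2 or len(dz) < 2:
        raise DataError("descriptive_stats needs at least 2 individuals per zygosity group")

    rows = []
    for var in variables:
        x_all = df[var].dropna().to_numpy(dtype=float)
        x_mz = mz[var].dropna().to_numpy(dtype=float)
        x_dz = dz[var].dropna().to_numpy(dtype=float)
        if np.allclose(x_mz, x_mz.mean() if len(x_mz) else 0.0) and np.allclose(
            x_dz, x_dz.mean() if len(x_dz) else 0.0
        ):
            if len(x_mz) and len(x_dz) and np.isclose(x_mz.mean(), x_dz.mean()):
                t_stat, p_val = 0.0, 1.0
            else:
                t_stat, p_val = np.nan, np.nan
        else:
            t_stat, p_val = stats.ttest_ind(x_mz, x_dz, equal_var=False)
        rows.append(
            {
                "variable": var,
                "total_mean": x_all.mean(),
                "total_sd": x_all.std(ddof=1),
                "mz_mean": x_mz.mean(),
                "mz_sd": x_mz.std(ddof=1),
                "dz_mean": x_dz.mean(),
                "dz_sd": x_dz.std(ddof=1),
                "t": float(t_stat),
                "p": float(p_val),
                "significant": bool(p_val < 0.05) if np.isfinite(p_val) else False,
            }
        )
    return pd.DataFrame(rows).set_index("variable")
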