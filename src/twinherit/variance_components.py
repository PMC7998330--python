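"""Biometric variance decomposition for twin pairs.

The classical twin design contrasts monozygotic (MZ) pairs, who share all
segregating genes, with dizygotic (DZ) pairs, who share half on average
(a quarter for dominance deviations).  Phenotypic variance splits into
additive genetic (A), shared environment (C) or dominance (D), and unique
environment (E, which absorbs measurement error).  The expected 2x2 pair
covariance is

    diag:      a2 + c2 + d2 + e2
    MZ off:    a2 + c2 + d2
    DZ off:    a2/2 + c2 + d2/4

and the model is fitted by maximizing the two-group Gaussian likelihood,
either on per-group summary covariance matrices or on raw pair data.
C and D are never estimated together (not identified with twins reared
together), and E is never dropped.

Confidence intervals are likelihood-based: the bound is where the profile
deviance (re-optimized over all other free parameters) rises by the
chi-square(1) quantile above its minimum, on the standardized scale.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .cohort_io import TwinPair
from .errors import DataError, FitError

logger = logging.getLogger(__name__)

#: Free variance components per model (E is always present).
MODEL_COMPONENTS: dict[str, tuple[str, ...]] = {
    "ACE": ("a2", "c2", "e2"),
    "ADE": ("a2", "d2", "e2"),
    "AE": ("a2", "e2"),
    "CE": ("c2", "e2"),
    "E": ("e2",),
}

#: Genetic/environmental sharing coefficients of the off-diagonal covariance.
_KINSHIP: dict[str, dict[str, float]] = {
    "MZ": {"a2": 1.0, "c2": 1.0, "d2": 1.0, "e2": 0.0},
    "DZ": {"a2": 0.5, "c2": 1.0, "d2": 0.25, "e2": 0.0},
}

_LOG_2PI = math.log(2.0 * math.pi)

#: e2 is floored at this fraction of the total variance during fitting.
E2_FLOOR_REL = 1e-6

#: Big-but-finite deviance returned for non-positive-definite candidates.
_PENALTY = 1e12


@dataclass(frozen=True)
class VarianceComponents:
    """Raw or standardized a2 / c2 / d2 / e2 variance components."""

    a2: float = 0.0
    c2: float = 0.0
    d2: float = 0.0
    e2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("a2", "c2", "d2", "e2"):
            if getattr(self, name) < 0:
                raise DataError(f"variance component {name} must be >= 0")
        if self.c2 > 0 and self.d2 > 0:
            raise DataError("C and D cannot both be nonzero (not identified)")

    @property
    def total(self) -> float:
        return self.a2 + self.c2 + self.d2 + self.e2

    @property
    def is_standardized(self) -> bool:
        return abs(self.total - 1.0) <= 1e-10

    def standardized(self) -> "VarianceComponents":
        t = self.total
        if t <= 0:
            raise DataError("cannot standardize zero total variance")
        return VarianceComponents(self.a2 / t, self.c2 / t, self.d2 / t, self.e2 / t)

    def as_dict(self) -> dict[str, float]:
        return {"a2": self.a2, "c2": self.c2, "d2": self.d2, "e2": self.e2}


@dataclass
class SummaryStats:
    """Sufficient statistics of the two-group Gaussian pair likelihood.

    One 2x2 sample covariance (or correlation) matrix per zygosity and the
    pair counts.  Groups are weighted by n_pairs in the deviance (ML
    convention).
    """

    cov_mz: np.ndarray
    cov_dz: np.ndarray
    n_mz: int
    n_dz: int

    def __post_init__(self) -> None:
        self.cov_mz = np.asarray(self.cov_mz, dtype=float)
        self.cov_dz = np.asarray(self.cov_dz, dtype=float)
        for name, m, n in (("MZ", self.cov_mz, self.n_mz), ("DZ", self.cov_dz, self.n_dz)):
            if m.shape != (2, 2):
                raise DataError(f"{name} covariance must be 2x2")
            if not np.allclose(m, m.T, atol=1e-10):
                raise DataError(f"{name} covariance must be symmetric")
            if np.linalg.eigvalsh(m).min() < -1e-10:
                raise DataError(f"{name} covariance must be positive semi-definite")
            if n < 3:
                raise DataError(f"need at least 3 {name} pairs, got {n}")

    @classmethod
    def from_correlations(
        cls, r_mz: float, r_dz: float, n_mz: int, n_dz: int, variance: float = 1.0
    ) -> "SummaryStats":
        """Build unit-diagonal (times ``variance``) matrices from intrapair correlations."""
        mz = variance * np.array([[1.0, r_mz], [r_mz, 1.0]])
        dz = variance * np.array([[1.0, r_dz], [r_dz, 1.0]])
        return cls(mz, dz, n_mz, n_dz)

    @classmethod
    def from_pairs(cls, pairs_by_zygosity: Mapping[str, object]) -> "SummaryStats":
        """Symmetrized per-group moments about each group's double-entry mean.

        The diagonal is the pooled per-twin variance and the off-diagonal the
        within-pair covariance, both about the group mean over all 2n values,
        so the result is invariant to twin order (divisor n_pairs).
        """
        mats = {}
        ns = {}
        for zyg in ("MZ", "DZ"):
            arr = _as_pair_array(pairs_by_zygosity[zyg])
            m = arr.mean()
            dev = arr - m
            s11 = float(np.mean(dev**2))
            s12 = float(np.mean(dev[:, 0] * dev[:, 1]))
            mats[zyg] = np.array([[s11, s12], [s12, s11]])
            ns[zyg] = arr.shape[0]
        return cls(mats["MZ"], mats["DZ"], ns["MZ"], ns["DZ"])

    def intrapair_r(self, zygosity: str) -> float:
        m = self.cov_mz if zygosity == "MZ" else self.cov_dz
        return float(m[0, 1] / math.sqrt(m[0, 0] * m[1, 1]))


@dataclass
class ModelFit:
    """One fitted biometric model."""

    model: str
    components: VarianceComponents
    std_components: VarianceComponents
    mean: float | None
    total_variance: float
    minus2LL: float
    k: int
    converged: bool
    n_restarts_used: int
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    _data: object = field(default=None, repr=False, compare=False)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "components": self.components.as_dict(),
            "std_components": self.std_components.as_dict(),
            "mean": self.mean,
            "total_variance": self.total_variance,
            "minus2LL": self.minus2LL,
            "k": self.k,
            "converged": self.converged,
            "n_restarts_used": self.n_restarts_used,
            "ci": {k: list(v) for k, v in self.ci.items()},
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def _as_pair_array(pairs) -> np.ndarray:
    if isinstance(pairs, np.ndarray):
        arr = np.asarray(pairs, dtype=float)
    else:
        arr = np.array([(p.value_1, p.value_2) for p in pairs], dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise DataError("pair data must have shape (n_pairs, 2)")
    if not np.all(np.isfinite(arr)):
        raise DataError("pair data must be finite")
    return arr


def _check_model_components(vc: VarianceComponents, model: str | None) -> None:
    if model is None:
        return
    if model not in MODEL_COMPONENTS:
        raise DataError(f"unknown model {model!r}")
    comps = MODEL_COMPONENTS[model]
    for name in ("a2", "c2", "d2"):
        if name not in comps and getattr(vc, name) != 0:
            raise DataError(f"component {name} must be 0 under the {model} model")


def expected_pair_covariance(
    vc: VarianceComponents, zygosity: str, model: str | None = None
) -> np.ndarray:
    """Model-implied 2x2 covariance of a twin pair's phenotype values."""
    if zygosity not in _KINSHIP:
        raise DataError(f"zygosity must be 'MZ' or 'DZ', got {zygosity!r}")
    _check_model_components(vc, model)
    coef = _KINSHIP[zygosity]
    total = vc.total
    off = sum(coef[name] * getattr(vc, name) for name in ("a2", "c2", "d2"))
    return np.array([[total, off], [off, total]])


def _group_deviance_summary(sigma: np.ndarray, s: np.ndarray, n: int) -> float:
    """n * (ln det Sigma + tr(S Sigma^-1)) for one group, 2x2 closed form."""
    det = sigma[0, 0] * sigma[1, 1] - sigma[0, 1] ** 2
    if det <= 0 or sigma[0, 0] <= 0:
        return _PENALTY - det
    tr = (
        sigma[1, 1] * s[0, 0] - 2.0 * sigma[0, 1] * s[0, 1] + sigma[0, 0] * s[1, 1]
    ) / det
    return n * (math.log(det) + tr)


def neg2_loglik_summary(
    vc: VarianceComponents, stats_: SummaryStats, model: str | None = None
) -> float:
    """Two-group summary deviance, constants in 2*pi omitted.

    Sum over zygosity groups of n_pairs * (ln det Sigma_g + tr(S_g Sigma_g^-1)).
    The omitted constant cancels in every model comparison.  Singular
    candidate covariances yield a large penalty value rather than raising.
    """
    sig_mz = expected_pair_covariance(vc, "MZ", model)
    sig_dz = expected_pair_covariance(vc, "DZ", model)
    return _group_deviance_summary(sig_mz, stats_.cov_mz, stats_.n_mz) + _group_deviance_summary(
        sig_dz, stats_.cov_dz, stats_.n_dz
    )


def neg2_loglik_raw(
    mean: float,
    vc: VarianceComponents,
    pairs_by_zygosity: Mapping[str, object],
    model: str | None = None,
) -> float:
    """Raw-data deviance: -2 log bivariate-normal likelihood, 2*pi included.

    All pairs share a common mean; each zygosity group uses its expected
    covariance.
    """
    total = 0.0
    for zyg in ("MZ", "DZ"):
        if zyg not in pairs_by_zygosity:
            continue
        arr = _as_pair_array(pairs_by_zygosity[zyg])
        if arr.shape[0] == 0:
            continue
        sigma = expected_pair_covariance(vc, zyg, model)
        det = sigma[0, 0] * sigma[1, 1] - sigma[0, 1] ** 2
        if det <= 0 or sigma[0, 0] <= 0:
            return _PENALTY - det
        dev = arr - mean
        # quadratic form with the explicit 2x2 inverse
        q = (
            sigma[1, 1] * dev[:, 0] ** 2
            - 2.0 * sigma[0, 1] * dev[:, 0] * dev[:, 1]
            + sigma[0, 0] * dev[:, 1] ** 2
        ) / det
        n = arr.shape[0]
        total += n * (2.0 * _LOG_2PI + math.log(det)) + float(q.sum())
    return total


# ---------------------------------------------------------------------------
# Fitting
#
# Summary fits use a standardized parameterization: the correlation
# structure R_g depends only on the component *proportions*, and the common
# variance V that minimizes sum_g n_g (ln det V R_g + tr(S_g R_g^-1)/V) has
# the closed form V = sum_g n_g tr(S_g R_g^-1) / (2 sum_g n_g).  This
# reduces AE/CE to a 1-D and ACE/ADE to a 2-D bounded optimization, solved
# to high precision.  Raw-data fits optimize (mean, paths) by Nelder-Mead
# with multiple starts; squaring the paths enforces non-negativity.
# ---------------------------------------------------------------------------


def _vc_from_props(model: str, props: Sequence[float], scale: float = 1.0) -> VarianceComponents:
    comps = MODEL_COMPONENTS[model]
    kw = {name: scale * p for name, p in zip(comps, props)}
    return VarianceComponents(**kw)


def _profiled_deviance_summary(
    model: str, props: Sequence[float], stats_: SummaryStats
) -> tuple[float, float]:
    """(deviance, V_hat) at given proportions with V profiled in closed form."""
    vc = _vc_from_props(model, props)
    r_mz = expected_pair_covariance(vc, "MZ", None)
    r_dz = expected_pair_covariance(vc, "DZ", None)
    n_tot = stats_.n_mz + stats_.n_dz
    tr_sum = 0.0
    logdet_sum = 0.0
    for r_mat, s, n in ((r_mz, stats_.cov_mz, stats_.n_mz), (r_dz, stats_.cov_dz, stats_.n_dz)):
        det = r_mat[0, 0] * r_mat[1, 1] - r_mat[0, 1] ** 2
        if det <= 0:
            return _PENALTY - det, 1.0
        tr = (r_mat[1, 1] * s[0, 0] - 2 * r_mat[0, 1] * s[0, 1] + r_mat[0, 0] * s[1, 1]) / det
        tr_sum += n * tr
        logdet_sum += n * math.log(det)
    v_hat = tr_sum / (2.0 * n_tot)
    if v_hat <= 0:
        return _PENALTY, 1.0
    dev = logdet_sum + 2.0 * n_tot * math.log(v_hat) + tr_sum / v_hat
    return dev, v_hat


def _props_from_free(free: Sequence[float], n_comps: int) -> np.ndarray:
    """Stick-breaking map from [0,1]^(k-1) to the k-simplex (E gets the rest)."""
    free = np.clip(np.asarray(free, dtype=float), 0.0, 1.0)
    props = np.empty(n_comps)
    remaining = 1.0
    for i in range(n_comps - 1):
        props[i] = remaining * free[i]
        remaining -= props[i]
    props[-1] = remaining
    return props


def _fit_summary(model: str, stats_: SummaryStats, n_restarts: int, seed: int):
    comps = MODEL_COMPONENTS[model]
    k = len(comps)
    e2_cap = 1.0 - E2_FLOOR_REL

    if k == 1:  # E model: independence, V in closed form
        dev, v_hat = _profiled_deviance_summary(model, [1.0], stats_)
        return np.array([1.0]), v_hat, dev, True, 0

    if k == 2:
        def obj(t: float) -> float:
            return _profiled_deviance_summary(model, [t, 1.0 - t], stats_)[0]

        res = optimize.minimize_scalar(
            obj, bounds=(0.0, e2_cap), method="bounded",
            options={"xatol": 1e-12},
        )
        t = float(res.x)
        props = np.array([t, 1.0 - t])
        dev, v_hat = _profiled_deviance_summary(model, props, stats_)
        return props, v_hat, dev, bool(res.success), 1

    # k == 3 (ACE / ADE): 2-D Nelder-Mead over stick-breaking coordinates,
    # multi-start, then a 1-D polish of the first coordinate.
    rng = np.random.default_rng(seed)
    r_mz = stats_.intrapair_r("MZ")
    r_dz = stats_.intrapair_r("DZ")
    if model == "ACE":
        g0 = float(np.clip(2.0 * (r_mz - r_dz), 0.0, e2_cap))
        s0 = float(np.clip(2.0 * r_dz - r_mz, 0.0, e2_cap - g0))
    else:  # ADE: dominance shows as rMZ > 2 rDZ
        g0 = float(np.clip(4.0 * r_dz - r_mz, 0.0, e2_cap))
        s0 = float(np.clip(2.0 * r_mz - 4.0 * r_dz, 0.0, e2_cap - g0))
    starts = [np.array([g0, s0 / (1.0 - g0) if g0 < 1 else 0.5])]
    while len(starts) < max(1, n_restarts):
        starts.append(rng.uniform(0.05, 0.95, size=2))

    def obj2(free: np.ndarray) -> float:
        props = _props_from_free(free, 3)
        if props[-1] < E2_FLOOR_REL:
            props = props.copy()
            excess = E2_FLOOR_REL - props[-1]
            props[-1] = E2_FLOOR_REL
            props[:2] *= max(0.0, 1.0 - E2_FLOOR_REL) / max(props[:2].sum(), 1e-300)
        return _profiled_deviance_summary(model, props, stats_)[0]

    best_props = None
    best_dev = np.inf
    best_ok = False
    used = 0
    for x0 in starts:
        used += 1
        res = optimize.minimize(
            obj2, x0, method="Nelder-Mead",
            options={"xatol": 1e-11, "fatol": 1e-13, "maxiter": 4000, "maxfev": 8000},
        )
        if res.fun < best_dev:
            best_dev = res.fun
            best_props = _props_from_free(res.x, 3)
            best_ok = bool(res.success)

    # The MLE frequently sits on a boundary (one component at zero); solve
    # those 1-D profiles exactly so boundary solutions are never missed.
    for zero_idx in (0, 1):
        def obj1(t: float, zi=zero_idx) -> float:
            props = [0.0, 0.0, 1.0 - t]
            props[1 - zi] = t
            return _profiled_deviance_summary(model, props, stats_)[0]

        res1 = optimize.minimize_scalar(
            obj1, bounds=(0.0, e2_cap), method="bounded", options={"xatol": 1e-12}
        )
        if res1.fun < best_dev + 1e-10:
            t = float(res1.x)
            props = [0.0, 0.0, 1.0 - t]
            props[1 - zero_idx] = t
            if res1.fun < best_dev:
                best_dev = float(res1.fun)
                best_props = np.asarray(props)
                best_ok = bool(res1.success)
            elif not best_ok:
                best_ok = bool(res1.success)

    dev, v_hat = _profiled_deviance_summary(model, best_props, stats_)
    return np.asarray(best_props), v_hat, dev, best_ok, used


def _fit_raw(model: str, pairs_by_zygosity, n_restarts: int, seed: int):
    comps = MODEL_COMPONENTS[model]
    k = len(comps)
    stats_ = SummaryStats.from_pairs(pairs_by_zygosity)
    all_vals = np.concatenate(
        [_as_pair_array(pairs_by_zygosity[z]).ravel() for z in ("MZ", "DZ")]
    )
    m0 = float(all_vals.mean())
    v0 = float(all_vals.var())

    # warm-start from the summary fit
    props0, vhat0, *_ = _fit_summary(model, stats_, n_restarts=1, seed=seed)

    def obj(x: np.ndarray) -> float:
        mean = x[0]
        paths = x[1:]
        vc = _vc_from_props(model, paths**2)
        if vc.total <= 0 or vc.e2 < E2_FLOOR_REL * vc.total:
            return _PENALTY
        return neg2_loglik_raw(mean, vc, pairs_by_zygosity)

    rng = np.random.default_rng(seed)
    starts = [np.concatenate([[m0], np.sqrt(np.maximum(props0 * vhat0, 1e-12))])]
    while len(starts) < max(1, n_restarts):
        props = rng.dirichlet(np.ones(k))
        starts.append(np.concatenate([[m0], np.sqrt(np.maximum(props * v0, 1e-12))]))

    best = None
    used = 0
    for x0 in starts:
        used += 1
        res = optimize.minimize(
            obj, x0, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 6000, "maxfev": 12000},
        )
        if best is None or res.fun < best.fun:
            best = res
    mean = float(best.x[0])
    raw = best.x[1:] ** 2
    total = float(raw.sum())
    props = raw / total if total > 0 else np.full(k, 1.0 / k)
    return props, total, float(best.fun), bool(best.success), used, mean


def fit_model(
    data,
    model: str = "ACE",
    *,
    n_restarts: int = 5,
    seed: int = 0,
) -> ModelFit:
    """Maximum-likelihood fit of one biometric model.

    ``data`` is either a :class:`SummaryStats` (summary likelihood, 2*pi
    constants omitted) or a mapping ``{"MZ": pairs, "DZ": pairs}`` of raw
    pair data (full Gaussian deviance, common mean estimated).  Estimates
    use a non-negative parameterization; the standardized components sum
    to one.  Non-convergence is reported honestly via ``converged``.
    """
    if model not in MODEL_COMPONENTS:
        raise DataError(f"unknown model {model!r}; expected one of {sorted(MODEL_COMPONENTS)}")
    comps = MODEL_COMPONENTS[model]
    if isinstance(data, SummaryStats):
        props, v_hat, dev, ok, used = _fit_summary(model, data, n_restarts, seed)
        mean = None
        k = len(comps)
    elif isinstance(data, Mapping):
        props, v_hat, dev, ok, used, mean = _fit_raw(model, data, n_restarts, seed)
        k = len(comps) + 1  # common mean is a free parameter
    else:
        raise DataError(
            "data must be SummaryStats or a mapping {'MZ': pairs, 'DZ': pairs}"
        )
    if not ok:
        logger.warning("fit of %s did not converge after %d start(s)", model, used)
    raw_vc = _vc_from_props(model, props, scale=v_hat)
    std_vc = _vc_from_props(model, np.asarray(props) / np.sum(props))
    return ModelFit(
        model=model,
        components=raw_vc,
        std_components=std_vc,
        mean=mean,
        total_variance=float(v_hat),
        minus2LL=float(dev),
        k=k,
        converged=ok,
        n_restarts_used=used,
        _data=data,
    )


def standardize(fit_or_vc) -> VarianceComponents:
    """Components as proportions of total variance (sum to one)."""
    vc = fit_or_vc.components if isinstance(fit_or_vc, ModelFit) else fit_or_vc
    return vc.standardized()


# ---------------------------------------------------------------------------
# Profile-likelihood confidence intervals
# ---------------------------------------------------------------------------


def _profile_deviance(fit: ModelFit, comp: str, t: float) -> float:
    """Deviance with the standardized ``comp`` proportion fixed at ``t``,
    minimized over every other free parameter."""
    model = fit.model
    comps = MODEL_COMPONENTS[model]
    others = [c for c in comps if c != comp]
    data = fit._data

    def props_at(w: float) -> list[float]:
        rest = 1.0 - t
        vals = {comp: t}
        if len(others) == 1:
            vals[others[0]] = rest
        else:  # two remaining components split by w
            vals[others[0]] = rest * w
            vals[others[1]] = rest * (1.0 - w)
        return [vals[c] for c in comps]

    if isinstance(data, SummaryStats):
        if len(others) <= 1:
            return _profiled_deviance_summary(model, props_at(0.0), data)[0]

        def obj(w: float) -> float:
            return _profiled_deviance_summary(model, props_at(w), data)[0]

        res = optimize.minimize_scalar(
            obj, bounds=(0.0, 1.0), method="bounded", options={"xatol": 1e-10}
        )
        return float(res.fun)

    # raw data: minimize over (mean, log V[, w])
    mean0 = fit.mean if fit.mean is not None else 0.0
    logv0 = math.log(max(fit.total_variance, 1e-12))

    def obj_raw(x: np.ndarray) -> float:
        mean, logv = x[0], x[1]
        w = float(np.clip(x[2], 0.0, 1.0)) if len(x) > 2 else 0.0
        v = math.exp(logv)
        props = np.clip(props_at(w), 0.0, None)
        vc = _vc_from_props(model, props, scale=v)
        if vc.e2 < E2_FLOOR_REL * max(vc.total, 1e-300):
            return _PENALTY
        return neg2_loglik_raw(mean, vc, data)

    x0 = [mean0, logv0] + ([0.5] if len(others) == 2 else [])
    res = optimize.minimize(
        obj_raw, np.asarray(x0), method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 4000},
    )
    return float(res.fun)


def profile_ci(
    fit: ModelFit, component: str, level: float = 0.95
) -> tuple[float, float]:
    """Likelihood-based CI for a standardized component.

    The bound is where the profile deviance rises by the chi-square(1)
    quantile (3.841 at 95%) above its minimum; clipped to [0, 1] and
    guaranteed to contain the point estimate.  A boundary estimate yields
    a one-sided interval with the boundary as one endpoint.
    """
    if not fit.converged:
        raise FitError("profile_ci requires a converged fit")
    comps = MODEL_COMPONENTS[fit.model]
    if component not in comps:
        raise DataError(f"component {component!r} is not free in model {fit.model}")
    if fit._data is None:
        raise FitError("fit carries no data reference; refit with fit_model")

    q = stats.chi2.ppf(level, df=1)
    t_hat = getattr(fit.std_components, component)
    d_hat = _profile_deviance(fit, component, t_hat)
    d_min = min(d_hat, fit.minus2LL)

    def f(t: float) -> float:
        return _profile_deviance(fit, component, t) - d_min - q

    t_lo_edge = 0.0 if component != "e2" else E2_FLOOR_REL
    t_hi_edge = 1.0 - (E2_FLOOR_REL if component != "e2" else 0.0)

    if t_hat <= t_lo_edge + 1e-12 or f(t_lo_edge) <= 0:
        low = 0.0
        if t_hat <= t_lo_edge + 1e-12:
            logger.info("%s estimate on the boundary; one-sided interval", component)
    else:
        low = float(optimize.brentq(f, t_lo_edge, t_hat, xtol=1e-6))

    if t_hat >= t_hi_edge - 1e-12 or f(t_hi_edge) <= 0:
        high = 1.0
    else:
        high = float(optimize.brentq(f, t_hat, t_hi_edge, xtol=1e-6))

    low, high = max(0.0, low), min(1.0, high)
    fit.ci[component] = (low, high)
    return low, high
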