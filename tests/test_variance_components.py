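import math

import numpy as np
import pytest

from twinherit import (
    SummaryStats,
    VarianceComponents,
    expected_pair_covariance,
    fit_model,
    neg2_loglik_raw,
    neg2_loglik_summary,
    profile_ci,
    standardize,
)
from twinherit.errors import DataError


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def dense_deviance(vc, stats):
    """Summary deviance via generic numpy linalg (independent of the 2x2 closed form)."""
    total = 0.0
    for zyg, s, n in (("MZ", stats.cov_mz, stats.n_mz), ("DZ", stats.cov_dz, stats.n_dz)):
        coef = 1.0 if zyg == "MZ" else 0.5
        dcoef = 1.0 if zyg == "MZ" else 0.25
        off = coef * vc.a2 + vc.c2 + dcoef * vc.d2
        sigma = np.array([[vc.total, off], [off, vc.total]])
        sign, logdet = np.linalg.slogdet(sigma)
        total += n * (logdet + np.trace(s @ np.linalg.inv(sigma)))
    return total


def grid_ae_fit(r_mz, r_dz, n_mz, n_dz, step=1e-4):
    """Brute-force AE fit: scan standardized a2; profile the variance in closed form."""
    h2 = np.arange(0.0, 1.0, step)
    n_tot = n_mz + n_dz
    tr_mz = 2.0 * (1.0 - h2 * r_mz) / (1.0 - h2**2)
    tr_dz = 2.0 * (1.0 - 0.5 * h2 * r_dz) / (1.0 - (0.5 * h2) ** 2)
    tr_sum = n_mz * tr_mz + n_dz * tr_dz
    v = tr_sum / (2.0 * n_tot)
    dev = (
        n_mz * np.log(1.0 - h2**2)
        + n_dz * np.log(1.0 - (0.5 * h2) ** 2)
        + 2.0 * n_tot * np.log(v)
        + tr_sum / v
    )
    i = int(np.argmin(dev))
    return float(h2[i]), float(dev[i])


# ---------------------------------------------------------------------------
# expected covariance structure
# ---------------------------------------------------------------------------


class TestExpectedPairCovariance:
    def test_ace_mz(self):
        vc = VarianceComponents(a2=0.6, c2=0.2, e2=0.2)
        np.testing.assert_allclose(
            expected_pair_covariance(vc, "MZ"), [[1.0, 0.8], [0.8, 1.0]]
        )

    def test_ace_dz_halves_additive(self):
        vc = VarianceComponents(a2=0.6, c2=0.2, e2=0.2)
        np.testing.assert_allclose(
            expected_pair_covariance(vc, "DZ"), [[1.0, 0.5], [0.5, 1.0]]
        )

    def test_dominance_quarter_in_dz(self):
        vc = VarianceComponents(a2=0.4, d2=0.4, e2=0.2)
        cov = expected_pair_covariance(vc, "DZ")
        assert cov[0, 1] == pytest.approx(0.5 * 0.4 + 0.25 * 0.4)

    def test_c_and_d_mutually_exclusive(self):
        with pytest.raises(DataError):
            VarianceComponents(a2=0.2, c2=0.2, d2=0.2, e2=0.4)

    def test_negative_component_rejected(self):
        with pytest.raises(DataError):
            VarianceComponents(a2=-0.1, e2=1.1)


# ---------------------------------------------------------------------------
# likelihoods
# ---------------------------------------------------------------------------


class TestSummaryLikelihood:
    def test_identity_case(self):
        stats = SummaryStats(np.eye(2), np.eye(2), 62, 46)
        vc = VarianceComponents(e2=1.0)
        assert neg2_loglik_summary(vc, stats) == pytest.approx(2 * 62 + 2 * 46)

    def test_saturated_lower_bound(self):
        """At the truth Sigma = S the deviance equals sum n (ln det S + 2),
        the saturated-model minimum; any other candidate is larger."""
        stats = SummaryStats.from_correlations(0.8, 0.4, 62, 46)
        sat = sum(
            n * (math.log(np.linalg.det(s)) + 2.0)
            for s, n in ((stats.cov_mz, 62), (stats.cov_dz, 46))
        )
        vc_true = VarianceComponents(a2=0.8, e2=0.2)
        assert neg2_loglik_summary(vc_true, stats) == pytest.approx(sat, abs=1e-10)
        for a2 in (0.3, 0.6, 0.95):
            vc = VarianceComponents(a2=a2, e2=1 - a2)
            assert neg2_loglik_summary(vc, stats) >= sat - 1e-10

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        r_mz, r_dz = rng.uniform(0.1, 0.9), rng.uniform(0.0, 0.5)
        stats = SummaryStats.from_correlations(r_mz, r_dz, 50, 40, variance=1.7)
        p = rng.dirichlet([1, 1, 1])
        vc = VarianceComponents(a2=2 * p[0], c2=2 * p[1], e2=2 * p[2])
        assert neg2_loglik_summary(vc, stats) == pytest.approx(
            dense_deviance(vc, stats), abs=1e-10
        )

    def test_singular_candidate_penalized_not_crash(self):
        stats = SummaryStats.from_correlations(0.9, 0.45, 10, 10)
        vc = VarianceComponents(a2=1.0, e2=0.0)  # correlation 1, singular MZ
        assert neg2_loglik_summary(vc, stats) > 1e9


class TestRawLikelihood:
    def test_single_pair_at_mode(self):
        pairs = {"MZ": np.array([[0.0, 0.0]]), "DZ": np.zeros((0, 2))}
        vc = VarianceComponents(e2=1.0)
        assert neg2_loglik_raw(0.0, vc, pairs) == pytest.approx(2 * math.log(2 * math.pi))

    def test_duplication_doubles_deviance(self):
        rng = np.random.default_rng(4)
        mz = rng.standard_normal((6, 2))
        dz = rng.standard_normal((5, 2))
        vc = VarianceComponents(a2=0.5, e2=0.5)
        d1 = neg2_loglik_raw(0.1, vc, {"MZ": mz, "DZ": dz})
        d2 = neg2_loglik_raw(
            0.1, vc, {"MZ": np.vstack([mz, mz]), "DZ": np.vstack([dz, dz])}
        )
        assert d2 == pytest.approx(2 * d1)


def exact_moment_pairs(s11, s12):
    """Four pairs whose double-entry moments are exactly (mean 0, var s11, cov s12)."""
    u = math.sqrt(2 * (s11 + s12))
    v = math.sqrt(2 * (s11 - s12))
    x, y = (u + v) / 2, (u - v) / 2
    return np.array([[x, y], [-x, -y], [y, x], [-y, -x]])


class TestFitModel:
    def test_closed_form_when_rmz_is_twice_rdz(self):
        stats = SummaryStats.from_correlations(0.8, 0.4, 62, 46)
        fit = fit_model(stats, "AE")
        assert fit.converged
        assert fit.std_components.a2 == pytest.approx(0.8, abs=1e-6)
        assert fit.std_components.e2 == pytest.approx(0.2, abs=1e-6)

    def test_matches_grid_search_oracle(self):
        stats = SummaryStats.from_correlations(0.6, 0.2, 50, 50)
        fit = fit_model(stats, "AE")
        a2_grid, dev_grid = grid_ae_fit(0.6, 0.2, 50, 50)
        assert fit.std_components.a2 == pytest.approx(a2_grid, abs=1e-3)
        assert fit.minus2LL <= dev_grid + 1e-6

    def test_ae_stationary_point_bracketed(self):
        """The AE estimate lies between min and max of (rMZ, 2 rDZ).

        With the total variance profiled rather than fixed, the stationary
        point can overshoot the bracket by a few thousandths (verified
        against a brute-force scan), hence the small slack.
        """
        for r_mz in (0.3, 0.5, 0.7, 0.85):
            for r_dz in (0.1, 0.25, 0.4):
                stats = SummaryStats.from_correlations(r_mz, r_dz, 60, 45)
                a2 = fit_model(stats, "AE").std_components.a2
                lo = min(r_mz, 2 * r_dz)
                hi = min(max(r_mz, 2 * r_dz), 1.0)
                assert lo - 5e-3 <= a2 <= hi + 5e-3

    def test_monotone_nesting(self):
        for r_mz, r_dz in ((0.8, 0.3), (0.5, 0.4), (0.6, 0.1)):
            stats = SummaryStats.from_correlations(r_mz, r_dz, 62, 46)
            fits = {m: fit_model(stats, m) for m in ("ACE", "AE", "CE", "E")}
            assert fits["E"].minus2LL >= fits["AE"].minus2LL - 1e-6
            assert fits["AE"].minus2LL >= fits["ACE"].minus2LL - 1e-6
            assert fits["CE"].minus2LL >= fits["ACE"].minus2LL - 1e-6

    def test_raw_and_summary_fits_agree_on_matched_moments(self):
        pairs = {
            "MZ": exact_moment_pairs(1.0, 0.8),
            "DZ": exact_moment_pairs(1.0, 0.4),
        }
        stats = SummaryStats.from_pairs(pairs)
        np.testing.assert_allclose(stats.cov_mz, [[1.0, 0.8], [0.8, 1.0]], atol=1e-12)
        fit_s = fit_model(stats, "AE")
        fit_r = fit_model(pairs, "AE")
        assert fit_r.mean == pytest.approx(0.0, abs=1e-5)
        for comp in ("a2", "e2"):
            assert getattr(fit_r.std_components, comp) == pytest.approx(
                getattr(fit_s.std_components, comp), abs=1e-4
            )

    def test_ade_fit_recovers_dominance_signal(self):
        # rMZ > 2 rDZ implies dominance under the ADE family
        stats = SummaryStats.from_correlations(0.8, 0.2, 500, 500)
        fit = fit_model(stats, "ADE")
        assert fit.std_components.d2 > 0.1
        assert fit.std_components.c2 == 0.0

    def test_unknown_model_rejected(self):
        stats = SummaryStats.from_correlations(0.8, 0.4, 10, 10)
        with pytest.raises(DataError):
            fit_model(stats, "ACDE")


class TestStandardize:
    def test_normalization(self):
        vc = VarianceComponents(a2=2.0, e2=2.0)
        std = standardize(vc)
        assert std.a2 == pytest.approx(0.5)
        assert std.e2 == pytest.approx(0.5)

    def test_idempotent(self):
        vc = VarianceComponents(a2=0.6, c2=0.2, e2=0.2)
        assert standardize(standardize(vc)) == standardize(vc)

    def test_scale_invariant(self):
        base = VarianceComponents(a2=0.6, c2=0.2, e2=0.2)
        scaled = VarianceComponents(a2=0.6 * 7.3, c2=0.2 * 7.3, e2=0.2 * 7.3)
        std = standardize(scaled)
        assert std.a2 == pytest.approx(0.6)
        assert std.c2 == pytest.approx(0.2)
        assert std.e2 == pytest.approx(0.2)

    def test_zero_total_errors(self):
        with pytest.raises(DataError):
            standardize(VarianceComponents())


class TestProfileCI:
    def test_contains_point_estimate(self):
        stats = SummaryStats.from_correlations(0.834, 0.304, 62, 46)
        fit = fit_model(stats, "AE")
        lo, hi = profile_ci(fit, "a2")
        assert lo <= fit.std_components.a2 <= hi
        assert 0.0 <= lo and hi <= 1.0

    def test_bisection_matches_dense_scan(self):
        """CI bounds from bisection agree with a dense scan of the profile deviance."""
        stats = SummaryStats.from_correlations(0.7, 0.3, 62, 46)
        fit = fit_model(stats, "AE")
        lo, hi = profile_ci(fit, "a2")
        # dense scan oracle
        grid = np.arange(1e-4, 1.0, 1e-3)
        dev = np.array([_ae_profile_dev(t, stats) for t in grid])
        q = 3.841458820694124  # chi2(1) 95% quantile
        inside = grid[dev <= dev.min() + q]
        assert lo == pytest.approx(inside.min(), abs=2e-3)
        assert hi == pytest.approx(inside.max(), abs=2e-3)

    def test_boundary_component_one_sided(self):
        # rMZ slightly above 2 rDZ: ACE MLE puts c2 on the zero boundary
        stats = SummaryStats.from_correlations(0.8, 0.3, 62, 46)
        fit = fit_model(stats, "ACE")
        assert fit.std_components.c2 == pytest.approx(0.0, abs=1e-6)
        lo, hi = profile_ci(fit, "c2")
        assert lo == 0.0
        assert hi > 0.0

    def test_raw_data_ci_close_to_summary_ci(self):
        pairs = {
            "MZ": exact_moment_pairs(1.0, 0.8),
            "DZ": exact_moment_pairs(1.0, 0.4),
        }
        # replicate pairs so the interval is not trivially [0, 1]
        pairs = {z: np.tile(arr, (12, 1)) for z, arr in pairs.items()}
        stats = SummaryStats.from_pairs(pairs)
        fit_s = fit_model(stats, "AE")
        fit_r = fit_model(pairs, "AE")
        ci_s = profile_ci(fit_s, "a2")
        ci_r = profile_ci(fit_r, "a2")
        assert ci_r[0] == pytest.approx(ci_s[0], abs=5e-3)
        assert ci_r[1] == pytest.approx(ci_s[1], abs=5e-3)


def _ae_profile_dev(t, stats):
    """Independent closed-form AE profile deviance at standardized a2 = t."""
    n_mz, n_dz = stats.n_mz, stats.n_dz
    n_tot = n_mz + n_dz
    r_mz = stats.cov_mz[0, 1] / stats.cov_mz[0, 0]
    r_dz = stats.cov_dz[0, 1] / stats.cov_dz[0, 0]
    s_mz, s_dz = stats.cov_mz[0, 0], stats.cov_dz[0, 0]
    tr_mz = 2 * s_mz * (1 - t * r_mz) / (1 - t**2)
    tr_dz = 2 * s_dz * (1 - 0.5 * t * r_dz) / (1 - (0.5 * t) ** 2)
    tr_sum = n_mz * tr_mz + n_dz * tr_dz
    v = tr_sum / (2 * n_tot)
    return (
        n_mz * math.log(1 - t**2)
        + n_dz * math.log(1 - (0.5 * t) ** 2)
        + 2 * n_tot * math.log(v)
        + tr_sum / v
    )
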