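"""Profile likelihoods, sensitivities and approximate confidence bands."""

from types import SimpleNamespace

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from ifnkin.estimation import IfnKineticsModel
from ifnkin.network import RateConstants, build_network
from ifnkin.simulate import StimulusCondition
from ifnkin.uncertainty import (ConfidenceBand, ProfileResult, chi2_threshold,
                                confidence_bands,
                                finite_difference_sensitivity,
                                inactivation_contrast, profile_parameter,
                                sensitivity_matrix)


class TestChi2Threshold:
    def test_standard_quantiles(self):
        assert chi2_threshold(0.95, 1) == pytest.approx(3.841, abs=1e-3)
        assert chi2_threshold(0.95, 2) == pytest.approx(5.991, abs=1e-3)

    def test_vanishes_as_alpha_to_zero(self):
        assert chi2_threshold(1e-12, 1) < 1e-6

    def test_invalid_alpha_rejected(self):
        for alpha in (0.0, 1.0, -0.5):
            with pytest.raises(ValueError):
                chi2_threshold(alpha)


class LinearFixture:
    """Weighted straight-line regression y = a x + b with positive a, b.

    The least-squares surface is exactly quadratic, so profile-likelihood
    bounds must coincide with the closed-form Wald interval.
    """

    param_names = ["slope", "intercept"]
    bounds_decades = 4.0
    rtol = atol = None

    _minimise = IfnKineticsModel._minimise

    def __init__(self, seed=11, n=12, sigma=0.5, a=2.0, b=3.0):
        rng = np.random.default_rng(seed)
        self.x = np.linspace(0.5, 6.0, n)
        self.y = a * self.x + b + rng.normal(0, sigma, n)
        self.sigma = sigma
        self.theta0 = np.log10([a, b])

    def residuals(self, theta):
        a, b = 10.0 ** np.asarray(theta)
        return (a * self.x + b - self.y) / self.sigma

    def ols_results(self):
        X = np.column_stack([self.x, np.ones_like(self.x)])
        W = np.eye(len(self.x)) / self.sigma ** 2
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ self.y)
        cov = np.linalg.inv(X.T @ W @ X)
        resid = (X @ beta - self.y) / self.sigma
        return beta, cov, float(resid @ resid)


@pytest.fixture(scope="module")
def linear_profile():
    fx = LinearFixture()
    beta, cov, wssr_opt = fx.ols_results()
    results = SimpleNamespace(model=fx, theta=np.log10(beta), wssr=wssr_opt)
    return fx, beta, cov, results


class TestProfileLikelihood:
    def test_linear_model_bounds_match_wald(self, linear_profile):
        fx, beta, cov, results = linear_profile
        prof = profile_parameter(results, "slope", crossing_xtol=1e-12)
        half = np.sqrt(chi2_threshold(0.95, 1) * cov[0, 0])
        assert prof.identifiability == "identifiable"
        assert prof.lower == pytest.approx(beta[0] - half, rel=1e-6)
        assert prof.upper == pytest.approx(beta[0] + half, rel=1e-6)

    def test_profile_wssr_never_below_optimum(self, linear_profile):
        _, _, _, results = linear_profile
        prof = profile_parameter(results, "intercept")
        assert np.all(prof.dchi2 >= -1e-9)
        assert prof.dchi2.min() == pytest.approx(0.0, abs=1e-9)

    def test_unknown_parameter_rejected(self, linear_profile):
        _, _, _, results = linear_profile
        with pytest.raises(KeyError):
            profile_parameter(results, "k_act_I")

    def test_parameter_without_effect_is_structurally_nonidentifiable(self):
        """A parameter absent from the predictions yields a flat profile."""

        class Flat(LinearFixture):
            param_names = ["slope", "dummy"]

            def residuals(self, theta):
                a = 10.0 ** theta[0]
                return (a * self.x - self.y) / self.sigma

        fx = Flat()
        fx.y = 2.0 * fx.x
        results = SimpleNamespace(model=fx, theta=np.log10([2.0, 1.0]),
                                  wssr=0.0)
        prof = profile_parameter(results, "dummy", max_steps=12)
        assert prof.identifiability == "structurally non-identifiable"


class TestInactivationContrast:
    def _prof(self, lo, up):
        grid = np.array([lo or 0.1, up or 10.0])
        return ProfileResult("k", grid, np.array([5.0, 5.0]), 0.0, 3.84,
                             0.95, lower=lo, upper=up)

    def test_disjoint_intervals_detected(self):
        out = inactivation_contrast(self._prof(0.01, 0.05),
                                    self._prof(0.2, 0.8))
        assert out["significant"] is True

    def test_overlapping_intervals_not_significant(self):
        out = inactivation_contrast(self._prof(0.01, 0.3),
                                    self._prof(0.2, 0.8))
        assert out["significant"] is False

    def test_open_profile_is_indeterminate(self):
        out = inactivation_contrast(self._prof(0.01, None),
                                    self._prof(0.2, 0.8))
        assert out["significant"] is None and out["indeterminate"]

    def test_planted_tenfold_contrast_recovered_at_low_noise(self):
        """Synthetic truth with IFNLR-complex inactivation ten-fold slower
        than IFNAR: at low replicate noise the two 95% profile intervals
        are disjoint with the type III rate smaller."""
        import ifnkin as ik
        from ifnkin.network import RATE_FREE_GROUPS

        cfg = ik.GeneratorConfig(seed=1, cv=0.05)
        ds = ik.generate_viperin_dataset(cfg)
        model = IfnKineticsModel(ds, variant="M3",
                                 free_groups=RATE_FREE_GROUPS)
        res = model.fit(n_starts=2, seed=1)
        out = inactivation_contrast(
            profile_parameter(res, "k_inact_III"),
            profile_parameter(res, "k_inact_I"))
        assert out["significant"] is True


class TestSensitivities:
    def test_linear_model_sensitivity_is_design_column(self):
        x = np.linspace(0, 5, 7)
        S = finite_difference_sensitivity(lambda th: th[0] * x, np.array([2.0]))
        assert S[:, 0] == pytest.approx(x, abs=1e-9)

    def test_inactive_parameter_gives_zero_column(self):
        x = np.linspace(0, 5, 7)
        S = finite_difference_sensitivity(lambda th: th[0] * x,
                                          np.array([2.0, 3.0]))
        assert np.allclose(S[:, 1], 0.0)

    def test_ode_sensitivity_step_convergence(self, network, params):
        """Richardson check: halving the step barely changes the entries."""
        times = [3.0, 6.0, 12.0, 24.0]
        cond = StimulusCondition("I", 0.33)
        kw = dict(param_names=["k_inact_I", "isg_gain_I"], condition=cond,
                  rtol=1e-10, atol=1e-12)
        S1 = sensitivity_matrix(network, params, "ISG_FC", times,
                                rel_step=1e-4, **kw)
        S2 = sensitivity_matrix(network, params, "ISG_FC", times,
                                rel_step=5e-5, **kw)
        scale = np.max(np.abs(S1), axis=0)
        assert np.max(np.abs(S1 - S2) / scale) < 1e-4


class TestProfileCoverage:
    def test_profile_interval_covers_truth_across_replicates(self):
        """Scaled coverage experiment: over 8 seeded replicates of a small
        design, the 95% profile interval of the IFNAR activation rate
        contains the generating value in at least 6 (binomial slack for
        n = 8 at nominal 95%)."""
        import ifnkin as ik
        from ifnkin.network import RATE_FREE_GROUPS

        hits = 0
        for rep in range(8):
            cfg = ik.GeneratorConfig(seed=300 + rep, cv=0.15,
                                     doses_I=(0.033, 0.33),
                                     doses_III=(0.137, 13.7))
            ds = ik.generate_viperin_dataset(cfg)
            model = IfnKineticsModel(ds, variant="M3",
                                     free_groups=RATE_FREE_GROUPS)
            res = model.fit(n_starts=2, seed=rep)
            prof = profile_parameter(res, "k_act_I")
            lo, up = prof.interval
            if lo is not None and up is not None and \
                    lo <= cfg.truth.k_act_I <= up:
                hits += 1
        assert hits >= 6


@pytest.fixture(scope="module")
def regression():
    rng = np.random.default_rng(4)
    x = np.linspace(0, 10, 15)
    y = 1.5 + 0.8 * x + rng.normal(0, 0.7, x.size)
    X = sm.add_constant(x)
    ols = sm.OLS(y, X).fit()
    return x, y, X, ols


class TestConfidenceBands:
    def test_mean_band_matches_textbook_t_band(self, regression):
        x, y, X, ols = regression
        pred = ols.get_prediction(X).summary_frame(alpha=0.05)
        band = confidence_bands(ols.fittedvalues, X, ols.mse_resid,
                                len(y), 2, alpha=0.95, kind="mean")
        half = (pred["mean_ci_upper"] - pred["mean_ci_lower"]).to_numpy() / 2
        assert band.half_width == pytest.approx(half, rel=1e-6)

    def test_prediction_band_matches_textbook_interval(self, regression):
        x, y, X, ols = regression
        pred = ols.get_prediction(X).summary_frame(alpha=0.05)
        band = confidence_bands(ols.fittedvalues, X, ols.mse_resid,
                                len(y), 2, alpha=0.95, kind="prediction")
        half = (pred["obs_ci_upper"] - pred["obs_ci_lower"]).to_numpy() / 2
        assert band.half_width == pytest.approx(half, rel=1e-6)

    def test_zero_mse_gives_zero_width(self, regression):
        x, y, X, _ = regression
        band = confidence_bands(y, X, 0.0, len(y), 2)
        assert np.allclose(band.half_width, 0.0)

    def test_wider_alpha_wider_band(self, regression):
        x, y, X, ols = regression
        b95 = confidence_bands(ols.fittedvalues, X, ols.mse_resid, len(y), 2,
                               alpha=0.95)
        b99 = confidence_bands(ols.fittedvalues, X, ols.mse_resid, len(y), 2,
                               alpha=0.99)
        assert np.all(b99.half_width >= b95.half_width)

    def test_band_contains_central_value(self, regression):
        x, y, X, ols = regression
        band = confidence_bands(ols.fittedvalues, X, ols.mse_resid, len(y), 2)
        assert np.all(band.lower <= band.central)
        assert np.all(band.upper >= band.central)

    def test_zero_sensitivity_column_is_ignored(self, regression):
        x, y, X, ols = regression
        padded = np.column_stack([X, np.zeros(len(y))])
        a = confidence_bands(ols.fittedvalues, X, ols.mse_resid, len(y), 3)
        b = confidence_bands(ols.fittedvalues, padded, ols.mse_resid,
                             len(y), 3)
        assert b.half_width == pytest.approx(a.half_width, rel=1e-12)

    def test_collinear_sensitivities_raise_with_hint(self, regression):
        x, y, X, ols = regression
        bad = np.column_stack([X, X[:, 1]])
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            confidence_bands(ols.fittedvalues, bad, ols.mse_resid,
                             len(y), 3)
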