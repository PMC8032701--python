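import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from actihsmm import (ModelConfig, effect_size_percent, effect_table,
                      population_regress, sandwich_ols,
                      stack_subject_estimates, wald_test)
from actihsmm.estimators import SubjectFit
from actihsmm.parameters import n_free_parameters
from actihsmm.population import _family_columns

from conftest import random_valid_params


class TestSandwichOls:
    def test_intercept_only_closed_form(self):
        y = np.array([1.0, 2.0, 4.0])
        beta, cov = sandwich_ols(y, np.ones((3, 1)))
        assert beta[0] == pytest.approx(7 / 3)
        e = y - y.mean()
        assert cov[0, 0] == pytest.approx((e ** 2).sum() / 9)

    def test_three_subject_toy_hand_calculation(self):
        # estimates (1, 2, 4) on centered w = (-1, 0, 1):
        # slope 3/2, intercept 7/3, sandwich diag (1/54, 1/72)
        y = np.array([1.0, 2.0, 4.0])
        X = np.column_stack([np.ones(3), [-1.0, 0.0, 1.0]])
        beta, cov = sandwich_ols(y, X)
        np.testing.assert_allclose(beta, [7 / 3, 1.5], atol=1e-12)
        np.testing.assert_allclose(cov, [[1 / 54, 0.0], [0.0, 1 / 72]],
                                   atol=1e-12)

    def test_zero_residuals_zero_covariance(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        y = 2.0 + 3.0 * np.arange(5.0)
        _, cov = sandwich_ols(y, X)
        np.testing.assert_allclose(cov, 0.0, atol=1e-20)

    def test_agrees_with_statsmodels_hc0(self, rng):
        """Dual route: our Kronecker-structured sandwich vs statsmodels HC0."""
        for _ in range(10):
            n = int(rng.integers(5, 11))
            d = int(rng.integers(1, 3))
            X = np.column_stack([np.ones(n), rng.normal(size=(n, d))])
            y = rng.normal(size=n)
            beta, cov = sandwich_ols(y, X)
            ref = sm.OLS(y, X).fit(cov_type="HC0")
            np.testing.assert_allclose(beta, ref.params, atol=1e-10)
            np.testing.assert_allclose(cov, ref.cov_params(), atol=1e-10)


class TestPopulationRegress:
    def test_centering_changes_only_the_intercept(self, rng):
        n, d = 20, 2
        est = pd.DataFrame(rng.normal(size=(n, 3)))
        W = pd.DataFrame(rng.normal(2.0, 1.0, size=(n, d)), columns=["a", "b"])
        c = population_regress(est, W, center=True)
        u = population_regress(est, W, center=False)
        np.testing.assert_allclose(c.coef[["a", "b"]], u.coef[["a", "b"]],
                                   atol=1e-10)
        np.testing.assert_allclose(c.se[["a", "b"]], u.se[["a", "b"]],
                                   atol=1e-10)
        assert not np.allclose(c.coef["intercept"], u.coef["intercept"])

    def test_too_few_subjects(self, rng):
        est = pd.DataFrame(rng.normal(size=(3, 2)))
        W = pd.DataFrame(rng.normal(size=(3, 2)))
        with pytest.raises(ValueError, match="at least"):
            population_regress(est, W)

    def test_collinear_columns_named(self, rng):
        n = 12
        w = rng.normal(size=n)
        W = pd.DataFrame({"w1": w, "w2": 2.0 * w})
        est = pd.DataFrame(rng.normal(size=(n, 1)))
        with pytest.raises(ValueError, match="w2"):
            population_regress(est, W)

    def test_covariance_matrices_psd(self, rng):
        est = pd.DataFrame(rng.normal(size=(15, 4)))
        W = pd.DataFrame(rng.normal(size=(15, 2)))
        pop = population_regress(est, W)
        for k in range(4):
            eigs = np.linalg.eigvalsh(pop.cov[k])
            assert np.all(eigs >= -1e-12)


class TestWaldAndEffectSize:
    @pytest.mark.parametrize("est,se,p_expected", [
        (-0.0299, 0.0433, 0.4899),
        (0.0819, 0.0235, 0.0005),
    ])
    def test_reported_pairs(self, est, se, p_expected):
        _, p = wald_test(est, se)
        assert p == pytest.approx(p_expected, abs=0.0015)

    def test_null_estimate(self):
        z, p = wald_test(0.0, 0.7)
        assert (z, p) == (0.0, 1.0)

    def test_se_must_be_positive(self):
        with pytest.raises(ValueError):
            wald_test(1.0, 0.0)

    @pytest.mark.parametrize("coef,expected", [
        (0.0914, 9.14), (0.0728, 7.28), (0.0, 0.0),
    ])
    def test_percent_convention(self, coef, expected):
        assert effect_size_percent(coef) == pytest.approx(expected, abs=1e-12)

    def test_exponential_alternative_is_explicit(self):
        assert effect_size_percent(0.1, exponential=True) == \
            pytest.approx(100 * (np.exp(0.1) - 1))


def _make_fit(sid, config, rng, converged=True, scale=0.3):
    params = random_valid_params(config, rng, scale=scale)
    return SubjectFit(subject_id=sid, params_hat=params, config=config,
                      loglik=-10.0, n_params=n_free_parameters(config),
                      T=1000, bic=0.0, converged=converged,
                      n_restarts_used=1, gradient_norm=0.0)


class TestStacking:
    CFG = ModelConfig(M=2, D_max=10, q=1, p_dim=1)

    def test_reshaping_contract(self, rng):
        fits = {s: _make_fit(s, self.CFG, rng) for s in ("a", "b")}
        frame, excluded = stack_subject_estimates(fits, "emission_treatment")
        assert frame.shape == (2, 3)  # zero-inflation + 2 intensity states
        assert excluded == []
        np.testing.assert_allclose(
            frame.loc["a", ("intensity", 2, 0)],
            fits["a"].params_hat.emission.b1[1, 0])

    def test_unconverged_excluded_with_report(self, rng):
        fits = {s: _make_fit(s, self.CFG, rng) for s in ("a", "b", "c")}
        fits["b"].converged = False
        frame, excluded = stack_subject_estimates(fits, "emission_treatment")
        assert frame.shape[0] == 2
        assert excluded == ["b"]

    def test_empty_input_error(self):
        with pytest.raises(ValueError, match="no subject fits"):
            stack_subject_estimates({}, "emission_treatment")

    def test_inconsistent_m_error(self, rng):
        other = ModelConfig(M=3, D_max=10, q=1, p_dim=1)
        fits = {"a": _make_fit("a", self.CFG, rng),
                "b": _make_fit("b", other, rng)}
        with pytest.raises(ValueError, match="disagree"):
            stack_subject_estimates(fits, "emission_treatment")

    def test_other_families(self, rng):
        fits = {s: _make_fit(s, self.CFG, rng) for s in ("a", "b")}
        dur, _ = stack_subject_estimates(fits, "duration_treatment")
        assert dur.shape == (2, 2)
        tr, _ = stack_subject_estimates(fits, "transition_treatment")
        assert tr.shape == (2, 0)  # M=2: every destination is the reference


class TestEffectTable:
    CFG = ModelConfig(M=6, D_max=10, q=1, p_dim=2)

    def _population(self, rng, zero_estimates=False):
        cols = _family_columns("emission_treatment", self.CFG)
        n = 10
        data = np.zeros((n, len(cols))) if zero_estimates \
            else rng.normal(0.05, 0.02, size=(n, len(cols)))
        est = pd.DataFrame(data)
        est.columns = pd.MultiIndex.from_tuples(cols)
        return population_regress(est, None)

    def test_row_structure_matches_six_state_report(self, rng):
        table = effect_table(self._population(rng), self.CFG)
        assert len(table.frame) == 7
        assert table.frame.index[0] == "State 1: odds of zero"
        assert table.frame.index[-1] == "State 6: mean activity count"

    def test_internal_z_consistency(self, rng):
        table = effect_table(self._population(rng), self.CFG)
        np.testing.assert_allclose(
            table.frame["z"], table.frame["estimate"] / table.frame["se"],
            atol=1e-12)

    def test_all_zero_estimates_give_p_one(self, rng):
        table = effect_table(self._population(rng, zero_estimates=True),
                             self.CFG)
        np.testing.assert_allclose(table.frame["p_value"], 1.0)

    def test_renders(self, rng):
        table = effect_table(self._population(rng), self.CFG)
        text = table.to_text()
        md = table.to_markdown()
        assert "State 4: mean activity count" in text
        assert md.count("|") > 20
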