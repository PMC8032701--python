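import numpy as np
import pytest

from actihsmm import (ZeroInflatedPoissonHSMM, fit_subject,
                      forward_log_likelihood, select_num_states,
                      validate_parameters)
from actihsmm.experiments import (alternating_schedule, two_state_config,
                                  two_state_parameters)
from actihsmm.parameters import to_unconstrained
from actihsmm.simulate import simulate_subject
import actihsmm.estimators as est_mod


@pytest.fixture(scope="module")
def small_sim():
    config = two_state_config()
    params = two_state_parameters()
    # T below the advisory 50-per-parameter floor on purpose: every fit in
    # this module should raise the data-size warning
    x, z = alternating_schedule(500, block=250)
    series, _ = simulate_subject(params, x, z, config, seed=5)
    return config, params, series


class TestFitSubject:
    def test_deterministic_given_data_and_seed(self, small_sim):
        config, _, series = small_sim
        with pytest.warns(UserWarning):
            f1 = fit_subject(series, 2, config, seed=3, n_restarts=2)
            f2 = fit_subject(series, 2, config, seed=3, n_restarts=2)
        np.testing.assert_array_equal(to_unconstrained(f1.params_hat),
                                      to_unconstrained(f2.params_hat))
        assert f1.loglik == f2.loglik
        assert f1.bic == f2.bic

    def test_fit_at_least_as_good_as_truth(self, small_sim):
        config, params, series = small_sim
        with pytest.warns(UserWarning):
            fit = fit_subject(series, 2, config, seed=0, n_restarts=1)
        ll_truth = forward_log_likelihood(series, params, config)
        assert fit.loglik >= ll_truth - 1e-6
        assert validate_parameters(fit.params_hat, config) == []

    def test_bic_formula(self, small_sim):
        config, _, series = small_sim
        with pytest.warns(UserWarning):
            fit = fit_subject(series, 2, config, seed=0, n_restarts=1)
        assert fit.bic == pytest.approx(
            -2 * fit.loglik + fit.n_params * np.log(series.T), abs=1e-10)

    def test_short_series_warns(self, small_sim):
        config, _, series = small_sim
        with pytest.warns(UserWarning, match="advisory minimum"):
            fit_subject(series, 2, config, seed=0, n_restarts=1, max_iter=5)

    def test_delta_reestimation_from_decoded_path(self, small_sim):
        config, _, series = small_sim
        with pytest.warns(UserWarning):
            fit = fit_subject(series, 2, config, seed=0, n_restarts=1,
                              reestimate_delta=True)
        assert fit.params_hat.delta.sum() == pytest.approx(1.0)
        assert np.all(fit.params_hat.delta > 0)
        assert np.isfinite(fit.loglik)
        # the re-estimated delta reflects decoded state frequencies,
        # which are not uniform on this data
        assert not np.allclose(fit.params_hat.delta, 0.5)

    def test_degenerate_data_flagged_not_raised(self):
        from actihsmm import ActivitySeries
        config = two_state_config()
        series = ActivitySeries("flat", np.zeros(700, dtype=int),
                                np.zeros((700, 1)), np.zeros((700, 0)))
        with pytest.warns(UserWarning, match="degenerate data"):
            fit = fit_subject(series, 2, config, seed=0, n_restarts=1,
                              max_iter=50)
        assert np.isfinite(fit.loglik)
        assert validate_parameters(fit.params_hat, config) == []


class TestEstimatorInterface:
    def test_sklearn_params_round_trip(self):
        est = ZeroInflatedPoissonHSMM(M=3, D_max=30, q=1, p_dim=0)
        params = est.get_params()
        assert params["M"] == 3
        est2 = ZeroInflatedPoissonHSMM(**params)
        assert est2.get_params() == params
        est2.set_params(M=2)
        assert est2.M == 2

    def test_fitted_attributes_and_methods(self, small_sim):
        config, _, series = small_sim
        est = ZeroInflatedPoissonHSMM(M=2, D_max=config.D_max, q=1, p_dim=0,
                                      n_restarts=1, random_state=0)
        with pytest.warns(UserWarning):
            est.fit(series)
        assert est.converged_ in (True, False)
        assert est.bic_ == pytest.approx(
            -2 * est.log_likelihood_ + est.n_parameters_ * np.log(series.T))
        assert est.score(series) == pytest.approx(est.log_likelihood_, abs=1e-8)
        states = est.predict(series)
        assert states.shape == (series.T,)
        assert set(np.unique(states)) <= {1, 2}
        sim, path = est.sample(series.x, series.z, random_state=0)
        assert sim.T == series.T


class TestSelectNumStates:
    def test_single_candidate(self, small_sim):
        config, _, series = small_sim
        with pytest.warns(UserWarning):
            M_star, table, _ = select_num_states(series, {2}, config, seed=0,
                                                 n_restarts=1)
        assert M_star == 2
        assert list(table.index) == [2]

    def test_bic_audit_and_tie_break(self, small_sim):
        config, _, series = small_sim
        with pytest.warns(UserWarning):
            M_star, table, fits = select_num_states(series, [1, 2], config,
                                                    seed=0, n_restarts=1)
        for M, row in table.iterrows():
            assert row["bic"] == pytest.approx(
                -2 * row["loglik"] + row["n_params"] * np.log(series.T),
                abs=1e-9)
        assert M_star == int(table["bic"].idxmin())

    def test_failures_propagate_into_table(self, small_sim, monkeypatch):
        config, _, series = small_sim

        real_fit = est_mod.fit_subject

        def flaky(series, M, config, **kw):
            if M == 3:
                raise RuntimeError("synthetic failure")
            return real_fit(series, M, config, **kw)

        monkeypatch.setattr(est_mod, "fit_subject", flaky)
        with pytest.warns(UserWarning):
            M_star, table, _ = est_mod.select_num_states(
                series, [2, 3], config, seed=0, n_restarts=1)
        assert M_star == 2
        assert "synthetic failure" in table.loc[3, "error"]
        assert np.isnan(table.loc[3, "bic"])

    def test_empty_candidates_error(self, small_sim):
        config, _, series = small_sim
        with pytest.raises(ValueError, match="nonempty"):
            select_num_states(series, [], config)
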