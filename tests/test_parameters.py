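import json

import numpy as np
import pytest

from actihsmm import ModelConfig, validate_parameters
from actihsmm.parameters import (default_parameters, from_unconstrained,
                                 n_free_parameters, n_unconstrained,
                                 params_from_dict, params_to_dict,
                                 to_unconstrained)

from conftest import random_valid_params

CFG = ModelConfig(M=3, D_max=20, q=1, p_dim=2)


class TestReparameterization:
    def test_round_trip_many_random_draws(self, rng):
        """from_unconstrained(to_unconstrained(theta)) == theta componentwise.

        (The unconstrained vector itself is not unique: squared slope
        increments lose the sign of their coordinate, by construction.)"""
        for _ in range(100):
            u = rng.normal(0, 1.0, n_unconstrained(CFG))
            params = from_unconstrained(u, CFG)
            params2 = from_unconstrained(to_unconstrained(params), CFG)
            np.testing.assert_allclose(params2.delta, params.delta, atol=1e-10)
            em, em2 = params.emission, params2.emission
            for a, b in ((em2.b00, em.b00), (em2.b10, em.b10),
                         (em2.gamma0, em.gamma0), (em2.b0, em.b0),
                         (em2.b1, em.b1), (em2.gamma, em.gamma),
                         (params2.duration.shape, params.duration.shape),
                         (params2.duration.scale, params.duration.scale),
                         (params2.duration.c, params.duration.c),
                         (params2.duration.eta, params.duration.eta),
                         (params2.transition.d_coef, params.transition.d_coef),
                         (params2.transition.rho, params.transition.rho)):
                np.testing.assert_allclose(b, a, atol=1e-10)

    def test_zero_vector_is_valid(self):
        params = from_unconstrained(np.zeros(n_unconstrained(CFG)), CFG)
        assert validate_parameters(params, CFG) == []

    def test_any_vector_is_valid(self, rng):
        for scale in (0.5, 3.0, 20.0):
            params = from_unconstrained(
                rng.normal(0, scale, n_unconstrained(CFG)), CFG)
            assert validate_parameters(params, CFG) == []

    def test_tiny_increments_keep_strict_ordering(self):
        """Intercept increments of exp(-50) still give b0 strictly increasing."""
        u = np.zeros(n_unconstrained(CFG))
        params0 = from_unconstrained(u, CFG)
        # locate the b0 block: first intercept then M-1 log-increments
        base = (CFG.M - 1) + 1 + CFG.q + CFG.p_dim
        u[base] = 0.0            # b0_1 = 0
        u[base + 1:base + CFG.M] = -50.0
        params = from_unconstrained(u, CFG)
        assert np.all(np.diff(params.emission.b0) > 0)
        assert validate_parameters(params, CFG) == []
        # even at increments far below float resolution
        u[base + 1:base + CFG.M] = -800.0
        params = from_unconstrained(u, CFG)
        assert np.all(np.diff(params.emission.b0) > 0)

    def test_wrong_length_errors(self):
        with pytest.raises(ValueError, match="length"):
            from_unconstrained(np.zeros(3), CFG)

    def test_free_parameter_count_excludes_delta(self):
        assert n_free_parameters(CFG) == n_unconstrained(CFG) - (CFG.M - 1)


class TestValidation:
    def test_intercept_ordering_violation(self):
        cfg = ModelConfig(M=2, D_max=5, q=1, p_dim=1)
        params = default_parameters(cfg)
        params.emission.b0 = np.array([1.0, 0.5])
        codes = [c for c, _ in validate_parameters(params, cfg)]
        assert codes == ["b0_ordering"]

    def test_simplex_violation(self):
        cfg = ModelConfig(M=2, D_max=5, q=1, p_dim=1)
        params = default_parameters(cfg)
        params.delta = np.array([0.6, 0.6])
        codes = [c for c, _ in validate_parameters(params, cfg)]
        assert codes == ["delta_simplex"]

    def test_valid_default_passes(self):
        assert validate_parameters(default_parameters(CFG), CFG) == []

    def test_dimension_mismatch_reported_first(self):
        cfg = ModelConfig(M=2, D_max=5, q=1, p_dim=1)
        params = default_parameters(cfg)
        params.delta = np.array([1.0])
        codes = [c for c, _ in validate_parameters(params, cfg)]
        assert "dim_delta" in codes

    def test_validation_never_raises(self):
        cfg = ModelConfig(M=2, D_max=5, q=1, p_dim=1)
        params = default_parameters(cfg)
        params.duration.shape = np.array([-1.0, 0.0])
        assert any(c == "duration_positivity"
                   for c, _ in validate_parameters(params, cfg))


class TestJsonSchema:
    def test_round_trip_exact(self, rng):
        params = random_valid_params(CFG, rng)
        blob = json.dumps(params_to_dict(params, CFG))
        params2, cfg2 = params_from_dict(json.loads(blob))
        assert cfg2 == CFG
        np.testing.assert_array_equal(params2.emission.b0, params.emission.b0)
        np.testing.assert_array_equal(params2.duration.scale, params.duration.scale)
        np.testing.assert_array_equal(params2.transition.d_coef,
                                      params.transition.d_coef)

    def test_version_mismatch(self, rng):
        data = params_to_dict(random_valid_params(CFG, rng), CFG)
        data["schema_version"] = "0.9"
        with pytest.raises(ValueError, match="schema version"):
            params_from_dict(data)

    def test_unknown_field_warns_but_loads(self, rng):
        data = params_to_dict(random_valid_params(CFG, rng), CFG)
        data["future_extension"] = 42
        with pytest.warns(UserWarning, match="unknown fields"):
            params_from_dict(data)

    def test_invalid_parameters_rejected_on_load(self, rng):
        data = params_to_dict(random_valid_params(CFG, rng), CFG)
        data["emission"]["b0"] = [1.0, 0.5, 2.0]
        with pytest.raises(ValueError, match="violate"):
            params_from_dict(data)
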