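import numpy as np
import pytest
from scipy import stats

from actihsmm import ModelConfig, StudyDesign, duration_pmf, transition_row
from actihsmm.experiments import (alternating_schedule, two_state_config,
                                  two_state_parameters)
from actihsmm.parameters import to_unconstrained
from actihsmm.simulate import (default_paper_like_truth, homogeneous_truth,
                               realize_subject_parameters, simulate_study,
                               simulate_subject)

from conftest import random_valid_params


class TestSimulateSubject:
    def test_poisson_mean_single_state(self):
        """M=1 with no zero inflation: empirical mean matches lambda = 3."""
        config = ModelConfig(M=1, D_max=10, q=1, p_dim=0)
        params = random_valid_params(config, np.random.default_rng(0))
        params.emission.b00 = -30.0          # p_zero ~ 0
        params.emission.b0 = np.array([np.log(3.0)])
        params.emission.b10[:] = 0.0
        T = 100_000
        series, states = simulate_subject(params, np.zeros((T, 1)),
                                          np.zeros((T, 0)), config, seed=1)
        se = series.y.std() / np.sqrt(T)
        assert abs(series.y.mean() - 3.0) < 4 * se
        assert np.all(states == 1)

    def test_dwell_lengths_follow_duration_pmf(self):
        """Chi-square goodness of fit of generated state-1 dwell lengths."""
        config = two_state_config(D_max=12)
        params = two_state_parameters(dwell_scale=3.0)
        T = 200_000
        series, states = simulate_subject(params, np.zeros((T, 1)),
                                          np.zeros((T, 0)), config, seed=7)
        # dwell lengths of state 1, excluding the (censored) final dwell
        changes = np.flatnonzero(np.diff(states)) + 1
        bounds = np.concatenate([[0], changes, [T]])
        lengths = np.diff(bounds)[:-1]
        which = states[bounds[:-1]][:-1]
        d1 = lengths[which == 1]
        pmf, _ = duration_pmf(1, [0.0], np.zeros(0), params.duration, config)
        observed = np.bincount(d1, minlength=config.D_max + 1)[1:]
        expected = pmf * d1.size
        keep = expected >= 5
        obs = observed[keep].astype(float)
        exp = expected[keep]
        if (~keep).any():
            obs = np.append(obs, observed[~keep].sum())
            exp = np.append(exp, expected[~keep].sum())
        chi = stats.chisquare(obs, exp * obs.sum() / exp.sum())
        assert chi.pvalue > 0.001

    def test_transition_frequencies_match_kernel(self):
        """Total-variation distance of empirical jump frequencies from the
        transition row < 0.05 on a long single-subject path."""
        config = ModelConfig(M=3, D_max=8, q=1, p_dim=0)
        params = random_valid_params(config, np.random.default_rng(5),
                                     scale=0.4)
        params.duration.scale[:] = 2.5
        params.duration.shape[:] = 1.2
        T = 500_000
        x = np.ones((T, 1))
        series, states = simulate_subject(params, x, np.zeros((T, 0)),
                                          config, seed=3)
        changes = np.flatnonzero(np.diff(states))
        for m in (1, 2, 3):
            mask = states[changes] == m
            dests = states[changes + 1][mask]
            emp = np.bincount(dests, minlength=4)[1:] / dests.size
            row = transition_row(m, [1.0], np.zeros(0), params.transition)
            assert 0.5 * np.abs(emp - row).sum() < 0.05

    def test_seed_reproducibility(self):
        config = two_state_config()
        params = two_state_parameters()
        x, z = alternating_schedule(5000)
        s1, p1 = simulate_subject(params, x, z, config, seed=42)
        s2, p2 = simulate_subject(params, x, z, config, seed=42)
        np.testing.assert_array_equal(s1.y, s2.y)
        np.testing.assert_array_equal(p1, p2)

    def test_zero_fraction_monotone_in_b00(self):
        config = ModelConfig(M=1, D_max=10, q=1, p_dim=0)
        fractions = []
        for b00 in (-2.0, -0.5, 1.0, 2.5):
            params = random_valid_params(config, np.random.default_rng(2))
            params.emission.b00 = b00
            params.emission.b0 = np.array([np.log(2.0)])
            series, _ = simulate_subject(params, np.zeros((20_000, 1)),
                                         np.zeros((20_000, 0)), config, seed=0)
            fractions.append(np.mean(series.y == 0))
        assert np.all(np.diff(fractions) > 0)


class TestSimulateStudy:
    def test_zero_noise_zero_slopes_identical_subjects(self):
        config = two_state_config(d=2)
        truth = homogeneous_truth(config, two_state_parameters())
        design = StudyDesign(n_subjects=3)
        _, _, truth = simulate_study(truth, design, seed=0,
                                     total_minutes=200)
        vecs = [to_unconstrained(p) for p in truth.subject_params.values()]
        for v in vecs[1:]:
            np.testing.assert_array_equal(v, vecs[0])

    def test_master_seed_reproducibility(self):
        truth1 = default_paper_like_truth()
        truth2 = default_paper_like_truth()
        design = StudyDesign(n_subjects=2)
        s1, b1, _ = simulate_study(truth1, design, seed=9, total_minutes=2000)
        s2, b2, _ = simulate_study(truth2, design, seed=9, total_minutes=2000)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.y, b.y)
        np.testing.assert_array_equal(b1.to_numpy(), b2.to_numpy())

    def test_sequences_alternate_and_schedules_differ(self):
        truth = default_paper_like_truth()
        design = StudyDesign(n_subjects=2)
        series, baseline, truth = simulate_study(truth, design, seed=1,
                                                 total_minutes=None)
        assert truth.subject_sequences[series[0].subject_id] == "A"
        assert truth.subject_sequences[series[1].subject_id] == "B"
        assert not np.array_equal(series[0].x, series[1].x)
        # the sequence indicator is the last baseline column
        assert baseline.iloc[0, -1] == 0.0
        assert baseline.iloc[1, -1] == 1.0

    def test_incompatible_truth_raises_projection_error(self):
        config = two_state_config(d=0)
        base = two_state_parameters()
        truth = homogeneous_truth(config, base,
                                  noise_sd={"emission": 0.05})
        # population treatment effects strongly DECREASING across states
        # cannot live in the nondecreasing cone: projection must displace
        # far beyond the noise scale and the generator must refuse
        truth.emission_intercept[1, 0] = 0.5
        truth.emission_intercept[2, 0] = -0.5
        design = StudyDesign(n_subjects=3)
        with pytest.raises(ValueError, match="noise"):
            simulate_study(truth, design, seed=0, total_minutes=100)

    def test_realized_parameters_follow_hierarchy(self):
        config = two_state_config(d=1)
        truth = homogeneous_truth(config, two_state_parameters(),
                                  noise_sd={"emission": 0.01})
        truth.emission_slope[2, 0, 0] = 0.2
        rng = np.random.default_rng(0)
        draws = []
        for w in (-1.0, 0.0, 1.0):
            params, disp = realize_subject_parameters(truth, [w], rng)
            assert disp == 0.0
            draws.append(params.emission.b1[1, 0])
        # slope 0.2 on W shifts the state-2 coefficient accordingly
        assert draws[2] - draws[0] == pytest.approx(0.4, abs=0.06)


class TestPaperLikeTruth:
    def test_requires_six_states(self):
        with pytest.raises(ValueError, match="M=6"):
            default_paper_like_truth(ModelConfig(M=2, D_max=10, q=1, p_dim=2))

    def test_smoke_calibration(self):
        """Small-sample sanity of the shipped truth (the full calibration
        check runs in the acceptance suite)."""
        truth = default_paper_like_truth()
        design = StudyDesign(n_subjects=2)
        series, _, truth = simulate_study(truth, design, seed=4,
                                          total_minutes=7 * 1440)
        y = np.concatenate([s.y for s in series])
        assert np.mean(y == 0) > 0.6
        assert y.max() > 50  # heavy right tail
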