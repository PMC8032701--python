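"""Reusable simulation experiments exercising the full pipeline.

Each experiment simulates from a documented truth, runs the estimation
machinery exactly as a user would, and returns summary statistics.  Problem
sizes default to reduced-scale regimes (hundreds of subject-fits rather than
the 11-week, 58-subject scale of a real crossover study) so a full study runs
on a laptop in minutes; the regimes keep the n/T << 1 relationship under
which the two-stage asymptotics apply.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import ModelConfig
from .decoding import state_occupancy, viterbi_decode
from .design import StudyDesign
from .durations import DurationModel
from .emissions import EmissionCoefficients
from .estimators import fit_subject, select_num_states
from .parameters import SubjectParameters
from .population import population_regress, stack_subject_estimates
from .simulate import (default_paper_like_truth, homogeneous_truth,
                       realize_subject_parameters, simulate_study,
                       simulate_subject)
from .transitions import TransitionCoefficients


def two_state_parameters(b0=(np.log(0.3), np.log(5.0)), b00: float = 0.5,
                         b1=(-0.3, 0.3), b10: float = -0.03,
                         dwell_scale: float = 3.0, dwell_shape: float = 1.2,
                         c=(0.1, -0.1)) -> SubjectParameters:
    """Compact two-state subject with short dwells (q=1, no environment)."""
    em = EmissionCoefficients(
        b00=b00, b10=np.array([b10]), gamma0=np.zeros(0),
        b0=np.asarray(b0, dtype=float),
        b1=np.asarray(b1, dtype=float)[:, None], gamma=np.zeros((2, 0)))
    dur = DurationModel(shape=np.full(2, dwell_shape),
                        scale=np.full(2, dwell_scale),
                        c=np.asarray(c, dtype=float)[:, None],
                        eta=np.zeros((2, 0)))
    tr = TransitionCoefficients(d_coef=np.zeros((2, 2, 1)),
                                rho=np.zeros((2, 2, 0)))
    return SubjectParameters(delta=np.array([0.5, 0.5]), emission=em,
                             duration=dur, transition=tr)


def two_state_config(D_max: int = 6, d: int = 0) -> ModelConfig:
    return ModelConfig(M=2, D_max=D_max, q=1, p_dim=0, d=d)


def alternating_schedule(T: int, block: int = 1250):
    """Treatment indicator alternating in blocks (crossover-like exposure)."""
    x = ((np.arange(T) // block) % 2).astype(float)[:, None]
    return x, np.zeros((T, 0))


# ---------------------------------------------------------------------------
# two-stage coverage
# ---------------------------------------------------------------------------

def coverage_experiment(n_subjects: int = 40, T: int = 5000,
                        n_replicates: int = 100, seed: int = 1,
                        level: float = 0.95, noise_sd: float = 0.1,
                        omega0: float = 0.3, omega1: float = 0.1,
                        tol: float = 1e-8) -> dict:
    """Empirical coverage of the two-stage Wald interval.

    Subjects draw their state-2 intensity treatment coefficient from the
    hierarchy ``b1_2 = omega0 + omega1 * W + noise`` (W standard normal,
    d = 1); each replicate fits every subject, regresses the stacked
    estimates on W with the sandwich covariance, and checks whether the
    nominal interval for the intercept (the average treatment effect on the
    state-2 log intensity) covers ``omega0``.
    """
    config = two_state_config(d=1)
    base = two_state_parameters()
    truth = homogeneous_truth(config, base, noise_sd={"emission": noise_sd})
    truth.emission_intercept[2, 0] = omega0
    truth.emission_slope[2, 0, 0] = omega1
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    x, z = alternating_schedule(T)
    covered, estimates, ses = [], [], []
    for rep in range(n_replicates):
        rng = np.random.default_rng([seed, rep])
        W = rng.normal(0.0, 1.0, n_subjects)
        fits = {}
        for i in range(n_subjects):
            params, _ = realize_subject_parameters(truth, W[i], rng)
            series, _ = simulate_subject(params, x, z, config, seed=rng,
                                         subject_id=f"S{i:03d}")
            fits[series.subject_id] = fit_subject(series, 2, config, seed=0,
                                                  n_restarts=1, tol=tol)
        est_frame, _ = stack_subject_estimates(fits, "emission_treatment")
        baseline = pd.DataFrame({"w": W},
                                index=[f"S{i:03d}" for i in range(n_subjects)])
        baseline = baseline.loc[est_frame.index]
        # uncentered design: the intercept then estimates omega0 itself (the
        # centered intercept instead targets omega0 + omega1 * mean(W), which
        # is the average effect, not the coefficient under test)
        pop = population_regress(est_frame, baseline, center=False)
        key = ("intensity", 2, 0)
        est = float(pop.coef.loc[[key], "intercept"].iloc[0])
        se = float(pop.se.loc[[key], "intercept"].iloc[0])
        covered.append(abs(est - omega0) <= zcrit * se)
        estimates.append(est)
        ses.append(se)
    return {
        "coverage": float(np.mean(covered)),
        "n_replicates": n_replicates,
        "mean_estimate": float(np.mean(estimates)),
        "truth": omega0,
        "mean_se": float(np.mean(ses)),
        "sd_estimates": float(np.std(estimates)),
    }


# ---------------------------------------------------------------------------
# single-subject intensity recovery
# ---------------------------------------------------------------------------

def recovery_experiment(T_values=(5000, 20000, 80000), n_replicates: int = 5,
                        seed: int = 2, b0_truth=(0.0, np.log(5.0))) -> dict:
    """Recovery of the intensity intercepts as the series grows.

    Returns per-T estimates of (b0_1, b0_2) across replicates and the pooled
    RMSE per T.
    """
    config = two_state_config()
    params = two_state_parameters(b0=b0_truth, b00=-1.0, b1=(0.0, 0.1))
    truth = np.asarray(b0_truth, dtype=float)
    out = {"T": list(T_values), "rmse": [], "estimates": {}}
    for T in T_values:
        x, z = alternating_schedule(int(T))
        ests = []
        for rep in range(n_replicates):
            rng = np.random.default_rng([seed, int(T), rep])
            series, _ = simulate_subject(params, x, z, config, seed=rng)
            fit = fit_subject(series, 2, config, seed=0, n_restarts=1)
            ests.append(fit.params_hat.emission.b0.copy())
        ests = np.asarray(ests)
        out["estimates"][int(T)] = ests
        out["rmse"].append(float(np.sqrt(np.mean((ests - truth) ** 2))))
    return out


# ---------------------------------------------------------------------------
# BIC state-number selection
# ---------------------------------------------------------------------------

def bic_selection_experiment(n_replicates: int = 20, T: int = 20000,
                             candidates=(1, 2, 3), seed: int = 3,
                             intensity_ratio: float = 10.0) -> dict:
    """How often BIC recovers M = 2 from well-separated 2-state data."""
    config = two_state_config()
    params = two_state_parameters(
        b0=(np.log(0.5), np.log(0.5 * intensity_ratio)), b00=0.0)
    x, z = alternating_schedule(T)
    selected = []
    for rep in range(n_replicates):
        rng = np.random.default_rng([seed, rep])
        series, _ = simulate_subject(params, x, z, config, seed=rng)
        M_star, _, _ = select_num_states(series, candidates, config, seed=0,
                                         n_restarts=1)
        selected.append(M_star)
    selected = np.asarray(selected)
    return {
        "selected": selected.tolist(),
        "proportion_correct": float(np.mean(selected == 2)),
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------------------
# generator calibration (6-state demonstration truth)
# ---------------------------------------------------------------------------

def calibration_summary(seed: int = 4, n_subjects: int = 10,
                        weeks: int = 2) -> dict:
    """Descriptive statistics of the shipped 6-state truth at reduced length.

    Simulates ``n_subjects`` over ``weeks`` weeks of minutes, then decodes
    each subject with its own generating parameters to summarize time in
    state (a generator-calibration check, independent of any fitting).
    """
    truth = default_paper_like_truth()
    design = StudyDesign(n_subjects=n_subjects)
    total_minutes = weeks * 7 * 1440
    series_list, baseline, truth = simulate_study(
        truth, design, seed=seed, total_minutes=total_minutes,
        store_paths=True)
    y_all = np.concatenate([s.y for s in series_list])
    paths, labels = {}, {}
    for s in series_list:
        path = viterbi_decode(s, truth.subject_params[s.subject_id],
                              truth.config)
        paths[s.subject_id] = path
        labels[s.subject_id] = np.repeat("all", s.T)
    occ = state_occupancy(paths, labels, M=truth.config.M)
    decoded_acc = float(np.mean([
        np.mean(paths[s.subject_id].states == truth.subject_paths[s.subject_id])
        for s in series_list]))
    return {
        "zero_fraction": float(np.mean(y_all == 0)),
        "q75": float(np.percentile(y_all, 75)),
        "q99": float(np.percentile(y_all, 99)),
        "max_count": int(y_all.max()),
        "state1_occupancy_percent": float(occ.loc[1, "all"]),
        "occupancy": occ,
        "decoded_path_accuracy": decoded_acc,
        "n_minutes": int(y_all.size),
    }


# ---------------------------------------------------------------------------
# population effect recovery (for reporting)
# ---------------------------------------------------------------------------

def effect_recovery_experiment(n_subjects: int = 40, T: int = 5000,
                               seed: int = 5, omega_low: float = 0.02,
                               omega_high: float = 0.08,
                               noise_sd: float = 0.05) -> dict:
    """One full two-stage run: simulate, fit all subjects, report effects.

    The truth places a small treatment effect on the low state's intensity
    and a larger one on the high state's; returns the recovered average
    effects (as percent effect sizes), their sandwich standard errors and
    Wald p-values.
    """
    from .population import effect_size_percent, wald_test

    config = two_state_config(d=1)
    base = two_state_parameters(b1=(omega_low, omega_high))
    truth = homogeneous_truth(config, base, noise_sd={"emission": noise_sd})
    x, z = alternating_schedule(T)
    rng = np.random.default_rng([seed, 0])
    W = rng.normal(0.0, 1.0, n_subjects)
    fits = {}
    for i in range(n_subjects):
        params, _ = realize_subject_parameters(truth, W[i], rng)
        series, _ = simulate_subject(params, x, z, config, seed=rng,
                                     subject_id=f"S{i:03d}")
        fits[series.subject_id] = fit_subject(series, 2, config, seed=0,
                                              n_restarts=1)
    est_frame, excluded = stack_subject_estimates(fits, "emission_treatment")
    baseline = pd.DataFrame({"w": W},
                            index=[f"S{i:03d}" for i in range(n_subjects)])
    pop = population_regress(est_frame, baseline.loc[est_frame.index])
    out = {"excluded": excluded, "truth_low": omega_low,
           "truth_high": omega_high}
    for state, tag in ((1, "low"), (2, "high")):
        key = ("intensity", state, 0)
        est = float(pop.coef.loc[[key], "intercept"].iloc[0])
        se = float(pop.se.loc[[key], "intercept"].iloc[0])
        z_stat, p = wald_test(est, se)
        out[f"effect_{tag}"] = est
        out[f"effect_{tag}_percent"] = effect_size_percent(est)
        out[f"se_{tag}"] = se
        out[f"p_{tag}"] = p
    return out
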